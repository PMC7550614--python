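"""Configuration-driven orchestration of the full synthetic workflow.

Stages, in dependency order: simulate -> DE per condition -> replicate ->
intersect -> sensitivity -> modules (+ enrichment) -> closeness -> GO
enrichment -> semantic similarity -> cross-tissue.  Each stage writes its
outputs plus a manifest entry (parameters, derived seed, checksums of
written files), so a completed run is reproducible from config + master
seed, and single stages can be re-run in isolation.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_tissue, io, network, ontology, rankprod, signatures, simulate

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "de", "replicate", "intersect", "sensitivity",
    "module", "closeness", "enrich", "semsim", "crosstissue",
)


@dataclass
class PipelineConfig:
    """Thresholds, iteration counts, cohort sizes and the master seed.

    Threshold defaults follow the analysis's stated cut-offs: pfp < 0.05 for
    discovery calls, two-sided p < 0.05 at replication, interactome combined
    confidence > 0.4, BH q < 0.05 for enrichment, and z < -1.65 for module
    closeness.
    """

    outdir: str = "pesignet_run"
    seed: int = 0
    # synthetic cohort structure
    n_genes: int = 1000
    discovery_n: int = 157
    replication_pe_n: int = 30
    replication_other_n: int = 24
    core_size: int = 15
    signature_sizes: dict | None = None  # None -> generator defaults
    effect_size: float = 1.0
    noise_sd: float = 0.5
    placenta_n: int = 60
    placenta_concordance: float = 0.41
    # interactome generation
    interactome_model: str = "powerlaw_cluster"
    module_boost: float = 0.3
    cross_module_boost: float = 0.03
    # ontology generation
    n_terms: int = 150
    annotations_per_gene: int = 3
    # thresholds
    pfp_threshold: float = 0.05
    replication_alpha: float = 0.05
    min_confidence: float = 0.4
    bh_q_threshold: float = 0.05
    closeness_z_threshold: float = -1.65
    # iteration counts / problem-size controls
    n_permutations: int = 100
    enrichment_iters: int = 999
    closeness_iters: int = 300
    n_pairs_cap: int = 800

    def validate(self) -> None:
        for name in ("pfp_threshold", "replication_alpha", "bh_q_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.min_confidence < 1:
            raise ValueError(f"min_confidence must be in [0, 1), got {self.min_confidence}")
        if self.closeness_z_threshold >= 0:
            raise ValueError("closeness_z_threshold must be negative")
        if not 0 <= self.placenta_concordance <= 1:
            raise ValueError("placenta_concordance must be in [0, 1]")
        if self.n_permutations < 1 or self.enrichment_iters < 100 or self.closeness_iters < 100:
            raise ValueError("iteration counts too small")


def validate_config(source) -> PipelineConfig:
    """Load a YAML config file (or dict); fill defaults and range-check.

    An empty file yields all defaults.  Unknown keys raise.
    """
    if isinstance(source, PipelineConfig):
        cfg = source
    else:
        if isinstance(source, dict):
            data = source
        else:
            data = yaml.safe_load(Path(source).read_text()) or {}
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(STAGES, children)
    }


def run_pipeline(config) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "config": asdict(cfg),
        "stage_seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "files": {},
    }

    def record(stage: str, summary: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = summary
        for f in files:
            manifest["files"][str(f.relative_to(outdir))] = io.sha256_of(f)
        log.info("stage %s done: %s", stage, summary)

    current = "simulate"
    try:
        # -- simulate -------------------------------------------------------
        sim_seed = seeds["simulate"]
        spec_kw = {}
        if cfg.signature_sizes is not None:
            spec_kw["signature_sizes"] = dict(cfg.signature_sizes)
        spec = simulate.CohortSpec(
            n_genes=cfg.n_genes, n_samples=cfg.discovery_n,
            core_size=cfg.core_size, effect_size=cfg.effect_size,
            noise_sd=cfg.noise_sd, seed=sim_seed, **spec_kw,
        )
        discovery, truth = simulate.simulate_cohort(spec)
        rep_studies = {}
        for i, cond in enumerate(simulate.CONDITIONS):
            n = cfg.replication_pe_n if cond == "PE" else cfg.replication_other_n
            # replication cohorts are case-enriched for their target condition
            rspec = simulate.replication_spec(spec, n, sim_seed + 1 + i)
            rspec.condition_prevalences = {
                **spec.condition_prevalences, cond: 0.5,
            }
            rep_studies[cond], _ = simulate.simulate_cohort(rspec, truth=truth)
        planted = [
            sorted(truth.index[truth[c]]) for c in simulate.CONDITIONS
        ]
        net = simulate.simulate_interactome(
            cfg.n_genes, model=cfg.interactome_model, planted_modules=planted,
            boost=cfg.module_boost, cross_boost=cfg.cross_module_boost,
            seed=sim_seed + 10, genes=list(truth.index),
        )
        dag, annotations = simulate.simulate_ontology(
            cfg.n_terms, genes=list(truth.index),
            annotations_per_gene=cfg.annotations_per_gene, seed=sim_seed + 11,
        )
        placenta, placenta_truth = simulate.simulate_placenta(
            truth, concordance=cfg.placenta_concordance,
            n_samples=cfg.placenta_n, seed=sim_seed + 12,
            noise_sd=cfg.noise_sd,
        )
        files = [
            *io.write_study(discovery, outdir, "discovery"),
            io.write_truth(truth, outdir / "truth.tsv"),
            io.write_interactome_tsv(net, outdir / "interactome.tsv"),
            io.write_obo(dag, outdir / "ontology.obo"),
            io.write_annotations(annotations, outdir / "annotations.tsv"),
            *io.write_study(placenta, outdir, "placenta"),
            io.write_truth(placenta_truth, outdir / "placenta_truth.tsv"),
        ]
        for cond, st in rep_studies.items():
            files.extend(io.write_study(st, outdir, f"replication_{cond}"))
        record("simulate", {
            "n_genes": cfg.n_genes, "discovery_n": cfg.discovery_n,
            "core_size": cfg.core_size,
            "interactome_edges": net.graph.number_of_edges(),
        }, files)

        # -- discovery DE ---------------------------------------------------
        current = "de"
        scheme = rankprod.PairingScheme(n_pairs_cap=cfg.n_pairs_cap)
        disc_results, disc_sigs = {}, {}
        files = []
        for i, cond in enumerate(simulate.CONDITIONS):
            # adjust each contrast for the other three measured conditions
            others = [c for c in simulate.CONDITIONS if c != cond]
            res = rankprod.permutation_pfp(
                rankprod.residualize(discovery, others), cond,
                scheme=scheme, B=cfg.n_permutations, seed=seeds["de"] + i,
            )
            disc_results[cond] = res
            disc_sigs[cond] = rankprod.call_de(res, cfg.pfp_threshold)
            files.append(io.write_de_result(res, outdir / f"de_{cond}.tsv"))
            files.append(io.write_signature(disc_sigs[cond], outdir / f"sig_{cond}.tsv"))
        record("de", {c: len(s) for c, s in disc_sigs.items()}, files)

        # -- replication ----------------------------------------------------
        current = "replicate"
        rep_sigs = {}
        files = []
        for i, cond in enumerate(simulate.CONDITIONS):
            others = [c for c in simulate.CONDITIONS if c != cond]
            res = rankprod.permutation_pfp(
                rankprod.residualize(rep_studies[cond], others), cond,
                scheme=scheme, B=cfg.n_permutations,
                seed=seeds["replicate"] + i,
            )
            rep_sigs[cond] = signatures.replicate_signature(
                disc_sigs[cond], res, alpha=cfg.replication_alpha
            )
            files.append(io.write_de_result(res, outdir / f"de_replication_{cond}.tsv"))
            files.append(
                io.write_signature(rep_sigs[cond], outdir / f"sig_replicated_{cond}.tsv")
            )
        record("replicate", {c: len(s) for c, s in rep_sigs.items()}, files)

        # -- intersection ---------------------------------------------------
        current = "intersect"
        report = signatures.intersect_signatures(
            [rep_sigs[c] for c in simulate.CONDITIONS]
        )
        overlap = report.overlap
        core = set(simulate.core_genes(truth))
        recovered = len(overlap.genes & core)
        core_recovery_pct = round(100.0 * recovered / len(core), 1) if core else 0.0
        files = [
            io.write_json(report.to_json_dict(), outdir / "intersection.json"),
            io.write_signature(overlap, outdir / "sig_overlap.tsv"),
        ]
        record("intersect", {
            "overlap_size": len(overlap),
            "core_recovery_pct": core_recovery_pct,
        }, files)

        # -- sensitivity ----------------------------------------------------
        current = "sensitivity"
        flags = discovery.phenotypes[list(simulate.CONDITIONS)].astype(bool)
        has_all = flags.all(axis=1)
        has_none = ~flags.any(axis=1)
        keep = has_all | has_none
        sub = simulate.ExpressionStudy(
            discovery.values.loc[:, keep[keep].index],
            discovery.phenotypes.loc[keep].assign(all_four=has_all[keep].astype(int)),
        )
        sens_summary: dict = {"n_all": int(has_all.sum()), "n_none": int(has_none.sum())}
        files = []
        if has_all.sum() >= 2 and has_none.sum() >= 2 and len(overlap) > 0:
            res = rankprod.permutation_pfp(
                sub, "all_four", scheme=scheme, B=cfg.n_permutations,
                seed=seeds["sensitivity"],
            )
            tab = res.table
            p_two = np.minimum(1.0, 2.0 * np.minimum(tab["p_up"], tab["p_down"]))
            entries = {
                g: ("up" if tab.loc[g, "p_up"] <= tab.loc[g, "p_down"] else "down")
                for g in tab.index[p_two < cfg.replication_alpha]
            }
            sens_sig = signatures.GeneSignature("all_vs_none", entries)
            pct, shared = signatures.sensitivity_overlap(sens_sig, overlap)
            sens_summary.update({"n_de": len(sens_sig), "shared": shared, "percent": pct})
            files.append(io.write_signature(sens_sig, outdir / "sig_all_vs_none.tsv"))
        else:
            sens_summary["skipped"] = "too few all/none samples or empty overlap"
        files.append(io.write_json(sens_summary, outdir / "sensitivity.json"))
        record("sensitivity", sens_summary, files)

        # -- modules + edge enrichment -------------------------------------
        current = "module"
        modules = {}
        mod_summary = {}
        files = []
        for cond, sig in {**rep_sigs, "overlap": overlap}.items():
            if len(sig) == 0:
                continue
            m = network.build_module(sig, net)
            if m.is_empty:
                continue
            modules[cond] = m
            stats = network.module_stats(m)
            enr = network.edge_enrichment_test(
                m, net, n_iter=cfg.enrichment_iters, seed=seeds["module"]
            )
            mod_summary[cond] = {
                **stats.to_json_dict(),
                "mapped_pct": m.mapped_fraction,
                "enrichment_p": enr.p_empirical,
                "enrichment_z": enr.z,
            }
            files.append(io.write_graphml(m.subgraph, outdir / f"module_{cond}.graphml"))
            attr = pd.DataFrame({
                "degree": stats.degree,
                "betweenness": stats.betweenness,
            })
            attr.index.name = "gene"
            path = outdir / f"module_{cond}_nodes.tsv"
            attr.to_csv(path, sep="\t")
            files.append(path)
        files.append(io.write_json(mod_summary, outdir / "modules.json"))
        record("module", {c: s["n_nodes"] for c, s in mod_summary.items()}, files)

        # -- closeness ------------------------------------------------------
        current = "closeness"
        closeness = []
        for a, b in itertools.combinations(simulate.CONDITIONS, 2):
            if a in modules and b in modules:
                res = network.module_closeness(
                    modules[a], modules[b], net,
                    n_iter=cfg.closeness_iters, seed=seeds["closeness"],
                )
                closeness.append(res.to_json_dict())
        files = [io.write_json(closeness, outdir / "closeness.json")]
        record("closeness", {
            "n_pairs": len(closeness),
            "all_significant": all(c["z_score"] < cfg.closeness_z_threshold
                                   for c in closeness) if closeness else False,
        }, files)

        # -- GO enrichment --------------------------------------------------
        current = "enrich"
        universe = list(truth.index)
        enr_summary: dict = {}
        files = []
        if len(overlap) > 0:
            table = ontology.ora(overlap, universe, annotations)
            path = outdir / "enrichment.tsv"
            table.to_csv(path, sep="\t", index=False)
            files.append(path)
            enr_summary = {
                "n_tested": int(len(table)),
                "n_significant": int((table["q"] < cfg.bh_q_threshold).sum()),
            }
        record("enrich", enr_summary, files)

        # -- semantic similarity -------------------------------------------
        current = "semsim"
        sem = {}
        ref = rep_sigs["PE"]
        for cond in simulate.CONDITIONS[1:]:
            if len(ref) and len(rep_sigs[cond]):
                sem[f"PE_vs_{cond}"] = round(ontology.set_sim(
                    ref.genes, rep_sigs[cond].genes, annotations, dag
                ), 4)
        files = [io.write_json(sem, outdir / "semsim.json")]
        record("semsim", sem, files)

        # -- cross-tissue ---------------------------------------------------
        current = "crosstissue"
        ct_summary: dict = {}
        files = []
        if len(overlap) > 0:
            rep = cross_tissue.tissue_replication(
                overlap, placenta, group_flag="PE",
                alpha=cfg.replication_alpha, B=cfg.n_permutations,
                seed=seeds["crosstissue"], net=net, scheme=scheme,
            )
            ct_summary = rep.to_json_dict()
            files.append(io.write_json(ct_summary, outdir / "crosstissue.json"))
        record("crosstissue", ct_summary, files)
    except Exception:
        manifest["failed_stage"] = current
        io.write_json(manifest, outdir / "manifest.json")
        log.exception("pipeline failed at stage %s", current)
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
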