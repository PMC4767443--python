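"""End-to-end orchestration of the synthetic-cohort analysis.

``run_all`` drives simulate -> call -> copy number -> driver genes -> pathways
-> signatures -> multi-region heterogeneity and writes every intermediate in
its standard format plus summary figures.  One global seed is fanned out to the
stages through a stage-name-keyed derivation so each stage is independently
reproducible; stage toggles let any prefix of the pipeline run alone, and a
stage whose inputs were not produced refuses to run with a clear message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calling, copynumber, drivers, heterogeneity, io, plots, signatures, simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "call", "cna", "smg", "pathway", "signatures", "het")

_STAGE_INPUTS = {  # stage -> stages whose outputs it consumes
    "call": ("simulate",),
    "cna": ("simulate",),
    "smg": ("simulate", "call"),
    "pathway": ("simulate", "call", "smg"),
    "signatures": ("simulate", "call", "cna"),
    "het": ("simulate",),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed keyed by the stage name."""
    return int(np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Round-trippable configuration of the full pipeline."""

    seed: int = 0
    out_dir: str = "somascape_out"
    log_level: str = "INFO"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulation
    n_samples: int = 12
    mean_depth: float = 100.0
    purity: float = 0.7
    n_genes: int = 40
    # the simulated footprint is ~1/250 of a real exome; scaling the per-base
    # background keeps per-sample mutation totals at realistic magnitudes
    background_scale: float = 30.0
    driver_genes: dict = field(default_factory=lambda: {"G0003": 30.0, "G0017": 30.0})
    cna_gain_frequency: float = 0.6
    # caller
    p_max: float = 0.01
    min_alt: int = 4
    min_vaf: float = 0.05
    # CBS / recurrence
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 200
    cbs_min_width: int = 3
    cbs_merge_tol: float = 0.1
    cbs_max_bins: int = 500  # per chromosome; finer grids are aggregated first
    marker_width: int = 100_000
    recurrence_n_perm: int = 200
    # drivers / pathways
    q_max: float = 0.05
    gmt_path: str | None = None
    # signatures
    s_min: int = 1
    s_max: int = 3
    em_restarts: int = 5
    # heterogeneity
    n_regions: int = 3
    trunk: int = 13
    shared: int = 2
    private: tuple = (7, 12, 8)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["private"] = list(self.private)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        if "private" in payload:
            payload["private"] = tuple(payload["private"])
        cfg = cls(**payload)
        if "stages" in payload:
            bad = sorted(set(payload["stages"]) - set(STAGES))
            if bad:
                raise ValueError(f"unknown stages: {bad}")
        return cfg

    def sim_config(self) -> simulate.SimConfig:
        genes = simulate.default_genes(self.n_genes)
        cna = [
            # a recurrent 12q-like amplicon plus a hemizygous and a homozygous loss
            simulate.CnaSpec("chr12", 800_000, 1_400_000, 6, self.cna_gain_frequency),
            simulate.CnaSpec("chr1", 200_000, 500_000, 1, 0.3),
            simulate.CnaSpec("chr1", 1_500_000, 1_600_000, 0, 0.15),
        ]
        rates = {
            k: v * self.background_scale for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()
        }
        return simulate.SimConfig(
            n_samples=self.n_samples,
            genes=genes,
            background_rates=rates,
            purity=self.purity,
            mean_depth=self.mean_depth,
            driver_spec=dict(self.driver_genes),
            cna_spec=cna,
            seed=stage_seed(self.seed, "simulate"),
        )


def _require(outputs: dict, stage: str) -> None:
    for dep in _STAGE_INPUTS.get(stage, ()):
        if dep not in outputs:
            raise RuntimeError(
                f"stage '{stage}' requires output of stage '{dep}', which is toggled off"
            )


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages and return the summary report (also written to
    ``out_dir/report.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    report: dict = {"somascape": __version__, "seed": config.seed, "stages": {}}
    try:
        if config.stages.get("simulate", False):
            _run_simulate(config, out, outputs, report)
        if config.stages.get("call", False):
            _require(outputs, "call")
            _run_call(config, out, outputs, report)
        if config.stages.get("cna", False):
            _require(outputs, "cna")
            _run_cna(config, out, outputs, report)
        if config.stages.get("smg", False):
            _require(outputs, "smg")
            _run_smg(config, out, outputs, report)
        if config.stages.get("pathway", False):
            _require(outputs, "pathway")
            _run_pathway(config, out, outputs, report)
        if config.stages.get("signatures", False):
            _require(outputs, "signatures")
            _run_signatures(config, out, outputs, report)
        if config.stages.get("het", False):
            _require(outputs, "het")
            _run_het(config, out, outputs, report)
    except Exception as exc:
        report["failed_stage"] = getattr(exc, "_stage", "unknown")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, default=io._json_default)
        raise
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=io._json_default)
    return report


def _stage(name):
    def deco(fn):
        def wrapped(config, out, outputs, report):
            try:
                fn(config, out, outputs, report)
            except Exception as exc:
                exc._stage = name
                log.error("stage %s failed: %s", name, exc)
                raise
            log.info("stage %s done", name)

        return wrapped

    return deco


@_stage("simulate")
def _run_simulate(config, out, outputs, report):
    cohort = simulate.simulate_cohort(config.sim_config())
    outputs["simulate"] = cohort
    seed = stage_seed(config.seed, "simulate")
    for sample, df in cohort.site_tables.items():
        io.write_site_counts(df, out / "sites" / f"{sample}.tsv", seed=seed)
    for sample, df in cohort.depth_tables.items():
        io.write_depth_bins(df, out / "depths" / f"{sample}.tsv", seed=seed)
    io.write_truth(cohort.truth, out / "truth.json", seed=seed)
    io.write_tsv(cohort.footprint, out / "footprint.tsv", seed=seed)
    report["stages"]["simulate"] = {
        "n_samples": len(cohort.site_tables),
        "n_somatic": int(len(cohort.truth.somatic)),
    }


@_stage("call")
def _run_call(config, out, outputs, report):
    cohort = outputs["simulate"]
    params = calling.CallerParams(p_max=config.p_max, min_alt=config.min_alt, min_vaf=config.min_vaf)
    all_calls = []
    for sample, sites in cohort.site_tables.items():
        calls = calling.call_somatic(sites, mode="paired", params=params)
        calls.insert(0, "sample", sample)
        io.write_vcf(calls, out / "calls" / f"{sample}.vcf", seed=config.seed)
        all_calls.append(calls)
    calls = pd.concat(all_calls, ignore_index=True)
    io.write_maf(calls, out / "calls.maf.tsv", seed=config.seed)
    outputs["call"] = calls
    acc = calls[calls["status"] == "accepted"]
    report["stages"]["call"] = {"n_candidates": int(len(calls)), "n_accepted": int(len(acc))}
    plots.mutation_landscape(acc, out / "figures" / "landscape.png")


@_stage("cna")
def _run_cna(config, out, outputs, report):
    cohort = outputs["simulate"]
    seed = stage_seed(config.seed, "cna")
    seg_frames = []
    seg_by_sample = {}
    for i, (sample, depths) in enumerate(sorted(cohort.depth_tables.items())):
        max_per_chrom = int(depths.groupby("chrom").size().max())
        factor = max(1, -(-max_per_chrom // config.cbs_max_bins))
        bins = copynumber.depth_ratio(copynumber.aggregate_bins(depths, factor))
        segs = copynumber.cbs_segment(
            bins,
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            min_width=config.cbs_min_width,
            merge_tol=config.cbs_merge_tol,
            seed=seed + i,
            bin_size=cohort.config.bin_size * factor,
        )
        segs = copynumber.call_states(segs)
        seg_by_sample[sample] = segs
        labeled = segs.copy()
        labeled.insert(0, "sample", sample)
        seg_frames.append(labeled)
    all_segs = pd.concat(seg_frames, ignore_index=True)
    io.write_seg(all_segs, out / "segments.seg", seed=seed)
    io.write_bed(all_segs[all_segs["state"] != "neutral"], out / "non_neutral.bed")
    rec = copynumber.recurrence_score(
        seg_by_sample,
        marker_width=config.marker_width,
        n_perm=config.recurrence_n_perm,
        seed=stage_seed(config.seed, "recurrence"),
        genome=cohort.config.genome,
    )
    io.write_tsv(rec.markers, out / "recurrence.tsv", seed=seed)
    plots.recurrence_profile(rec.markers, out / "figures" / "recurrence.png")
    outputs["cna"] = {"segments": seg_by_sample, "recurrence": rec}
    report["stages"]["cna"] = {
        "n_segments": int(len(all_segs)),
        "max_amp_gscore": float(rec.markers["amp_gscore"].max()),
    }


@_stage("smg")
def _run_smg(config, out, outputs, report):
    cohort = outputs["simulate"]
    calls = outputs["call"]
    acc = calls[(calls["status"] == "accepted") & (calls["gene"] != "")].copy()
    acc["category"] = drivers.classify_mutations(acc)
    bmr = drivers.estimate_bmr(acc, cohort.footprint, n_samples=config.n_samples)
    results = drivers.smg_test(acc, cohort.footprint, bmr, q_max=config.q_max)
    io.write_tsv(results, out / "smg.tsv", seed=config.seed)
    outputs["smg"] = results
    report["stages"]["smg"] = {
        "significant": results[results["significant"]]["gene"].tolist(),
        "bmr": {k: float(v) for k, v in bmr.rates.items()},
    }


@_stage("pathway")
def _run_pathway(config, out, outputs, report):
    results = outputs["smg"]
    if config.gmt_path:
        sets = io.read_gmt(config.gmt_path)
    else:
        genes = sorted(results["gene"])
        driver = sorted(config.driver_genes)
        decoys = [g for g in genes if g not in driver]
        sets = {"planted_driver_pathway": driver}
        rng = np.random.default_rng(stage_seed(config.seed, "pathway"))
        for i in range(10):
            sets[f"decoy_{i:02d}"] = sorted(rng.choice(decoys, size=min(5, len(decoys)), replace=False))
        io.write_gmt(sets, out / "pathways.gmt")
    table = drivers.pathway_burden(sets, results, q_max=config.q_max)
    io.write_tsv(table, out / "pathways.tsv", seed=config.seed)
    outputs["pathway"] = table
    report["stages"]["pathway"] = {"top": table.iloc[0]["pathway"] if len(table) else None}


@_stage("signatures")
def _run_signatures(config, out, outputs, report):
    calls = outputs["call"]
    acc = calls[calls["status"] == "accepted"]
    mat, n_indels = signatures.classify_channels(acc)
    seg_by_sample = outputs["cna"]["segments"]
    opp = np.vstack(
        [
            copynumber.opportunity_from_segments(
                seg_by_sample[s], copynumber.uniform_context_counts(seg_by_sample[s])
            )
            for s in mat.index
        ]
    ) if len(mat) else None
    s_range = range(config.s_min, config.s_max + 1)
    best_s, table = signatures.select_n_signatures(
        mat, opp, s_range,
        random_state=stage_seed(config.seed, "signatures"),
        n_restarts=config.em_restarts,
    )
    est = signatures.PoissonSignatureEM(
        n_signatures=best_s, n_restarts=config.em_restarts,
        random_state=stage_seed(config.seed, "signatures"),
    ).fit(mat, opp)
    io.write_tsv(table, out / "signatures" / "model_selection.tsv", seed=config.seed)
    io.write_tsv(
        pd.DataFrame(est.signatures_.T, index=list(mat.columns),
                     columns=[f"sig{k+1}" for k in range(best_s)]),
        out / "signatures" / "signatures.tsv", seed=config.seed, channel_order=True, index=True,
    )
    io.write_tsv(
        pd.DataFrame(est.exposures_, index=list(mat.index),
                     columns=[f"sig{k+1}" for k in range(best_s)]),
        out / "signatures" / "exposures.tsv", seed=config.seed, index=True,
    )
    plots.signature_bars(est.signatures_, out / "figures" / "signatures.png")
    outputs["signatures"] = est
    report["stages"]["signatures"] = {
        "best_s": best_s,
        "loglik": est.loglik_,
        "n_indels_excluded": n_indels,
    }


@_stage("het")
def _run_het(config, out, outputs, report):
    cohort_cfg = outputs["simulate"].config
    het_cfg = dataclasses.replace(cohort_cfg, seed=stage_seed(config.seed, "het"))
    region_sites, truth = simulate.simulate_multiregion(
        het_cfg, config.n_regions, config.trunk, config.shared, tuple(config.private)
    )
    params = calling.CallerParams(p_max=config.p_max, min_alt=config.min_alt, min_vaf=config.min_vaf)
    region_calls = {
        r: calling.accepted(calling.call_somatic(df, mode="paired", params=params))
        for r, df in region_sites.items()
    }
    matrix = heterogeneity.build_presence(region_calls)
    labels, counts = heterogeneity.classify(matrix)
    venn = heterogeneity.venn_counts(matrix)
    tree = heterogeneity.clonal_ordering_tree(matrix)
    io.write_tsv(matrix.reset_index(), out / "het" / "presence.tsv", seed=config.seed)
    io.write_tsv(
        pd.DataFrame(
            [{"regions": "|".join(sorted(k)), "count": v} for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))]
        ),
        out / "het" / "venn.tsv", seed=config.seed,
    )
    (out / "het").mkdir(parents=True, exist_ok=True)
    with open(out / "het" / "tree.nwk", "w", encoding="utf-8") as fh:
        fh.write(tree.newick() + "\n")
    outputs["het"] = {"matrix": matrix, "counts": counts, "tree": tree}
    report["stages"]["het"] = {
        "counts": counts,
        "newick": tree.newick(),
        "n_conflicts": len(tree.conflicts),
    }
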