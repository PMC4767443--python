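"""Somatic SNV/indel calling from tumor/normal allele counts.

The caller consumes per-site read-count evidence (no BAMs) and applies, in order:
per-site read-evidence filters, a one-sided Fisher exact test of alt enrichment in
the tumor against the matched normal, support thresholds, known-SNP/synonymous
exclusion, and — for samples without a matched normal — removal of copy-neutral
variants with allele frequency in the 45–55% germline band unless they are on a
somatic whitelist (COSMIC-like).  Filter flags are accumulated, never
short-circuited, so the flag content is independent of cascade order; a call is
accepted iff its flag set is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FILTER_FLAGS = (
    "low_mapq_evidence",
    "high_mismatch_evidence",
    "known_snp",
    "synonymous",
    "germline_band",
    "low_support",
)

VariantKey = tuple[str, int, str, str]


@dataclass
class CallerParams:
    """Acceptance thresholds of the calling cascade (all configurable)."""

    p_max: float = 0.01
    min_alt: int = 4
    min_vaf: float = 0.05
    max_normal_vaf: float = 0.02
    min_mapq_pass: float = 0.5       # minimum surviving-read fraction (mapping quality)
    min_mismatch_pass: float = 0.5   # minimum surviving-read fraction (mismatch count)
    vaf_band: tuple[float, float] = (0.45, 0.55)  # closed interval


def fisher_somatic_test(t_ref, t_alt, n_ref, n_alt):
    """One-sided Fisher exact p for alt enrichment in tumor.

    The 2x2 table is [[t_alt, t_ref], [n_alt, n_ref]]; with margins fixed the
    tumor alt count is hypergeometric and the p-value is its upper tail
    P(X >= t_alt).  Accepts scalars or arrays; the p-value lies in (0, 1].
    """
    t_ref = np.asarray(t_ref)
    t_alt = np.asarray(t_alt)
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    if (t_ref < 0).any() or (t_alt < 0).any() or (n_ref < 0).any() or (n_alt < 0).any():
        raise ValueError("negative read counts")
    total = t_ref + t_alt + n_ref + n_alt
    if (total == 0).any():
        raise ValueError("all-zero contingency table: no read evidence at site")
    p = stats.hypergeom.sf(t_alt - 1, total, t_alt + n_alt, t_alt + t_ref)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def read_evidence_filter(
    mapq_pass_fraction: float,
    mismatch_pass_fraction: float,
    min_mapq_pass: float = 0.5,
    min_mismatch_pass: float = 0.5,
) -> set[str]:
    """Flags for a site whose read-level filter survival is summarized as fractions.

    Raw reads are not available at this stage of the pipeline, so the per-read
    mapping-quality and mismatch-count filters are represented by the fraction of
    reads that survived them; a site fails when fewer than the threshold fraction
    survived.  Returns the (possibly empty) set of flags.
    """
    for f in (mapq_pass_fraction, mismatch_pass_fraction, min_mapq_pass, min_mismatch_pass):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    flags = set()
    if mapq_pass_fraction < min_mapq_pass:
        flags.add("low_mapq_evidence")
    if mismatch_pass_fraction < min_mismatch_pass:
        flags.add("high_mismatch_evidence")
    return flags


def exclude_known(
    calls: pd.DataFrame,
    dbsnp_set: set[VariantKey] | None = None,
    panel_of_normals_set: set[VariantKey] | None = None,
) -> pd.DataFrame:
    """Flag calls present in dbSNP-like or panel-of-normals blacklists, and
    synonymous calls; flagged calls become rejected."""
    calls = calls.copy().reset_index(drop=True)
    dbsnp_set = dbsnp_set or set()
    panel_of_normals_set = panel_of_normals_set or set()
    keys = list(zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"]))
    in_dbsnp = np.array([k in dbsnp_set for k in keys], dtype=bool)
    in_pon = np.array([k in panel_of_normals_set for k in keys], dtype=bool)
    calls["dbsnp"] = in_dbsnp
    for i, known in enumerate(in_dbsnp | in_pon):
        if known:
            _add_flag(calls, i, "known_snp")
    for i, eff in enumerate(calls["effect"]):
        if eff == "synonymous":
            _add_flag(calls, i, "synonymous")
    _refresh_status(calls)
    return calls


def unmatched_filter(
    calls: pd.DataFrame,
    segments: pd.DataFrame | None,
    cosmic_set: set[VariantKey] | None = None,
    vaf_band: tuple[float, float] = (0.45, 0.55),
) -> pd.DataFrame:
    """Germline-band filter for samples without a matched normal.

    A call is rejected with ``germline_band`` iff its VAF lies in the closed
    band, the overlapping copy-number segment is neutral (absent coverage
    defaults to neutral), and the variant is not on the somatic whitelist.
    """
    calls = calls.copy().reset_index(drop=True)
    cosmic_set = cosmic_set or set()
    lo, hi = vaf_band
    for i, row in calls.iterrows():
        key = (row["chrom"], row["pos"], row["ref"], row["alt"])
        in_cosmic = key in cosmic_set
        calls.at[i, "cosmic"] = in_cosmic
        state = _segment_state_at(segments, row["chrom"], row["pos"])
        if lo <= row["vaf"] <= hi and state == "neutral" and not in_cosmic:
            _add_flag(calls, i, "germline_band")
    _refresh_status(calls)
    return calls


def _segment_state_at(segments: pd.DataFrame | None, chrom: str, pos: int) -> str:
    if segments is None or not len(segments):
        return "neutral"
    hit = segments[
        (segments["chrom"] == chrom)
        & (segments["start"] < pos)
        & (segments["end"] >= pos)
    ]
    if not len(hit):
        return "neutral"
    return str(hit.iloc[0].get("state", "neutral"))


def _add_flag(calls: pd.DataFrame, idx, flag: str) -> None:
    cur = calls.at[idx, "filter_flags"]
    parts = set(cur.split(";")) - {""} if isinstance(cur, str) else set()
    parts.add(flag)
    calls.at[idx, "filter_flags"] = ";".join(sorted(parts))


def _refresh_status(calls: pd.DataFrame) -> None:
    calls["status"] = np.where(calls["filter_flags"] == "", "accepted", "rejected")


def call_somatic(
    sites: pd.DataFrame,
    mode: str = "paired",
    params: CallerParams | None = None,
    dbsnp_set: set[VariantKey] | None = None,
    panel_of_normals_set: set[VariantKey] | None = None,
    cosmic_set: set[VariantKey] | None = None,
    segments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full calling cascade over a site-count table.

    Returns every candidate with its p-value, VAF, accumulated filter flags and
    accepted/rejected status; accepted calls sort by (chrom, pos).  ``paired``
    mode requires normal read-count columns; ``tumor_only`` mode requires
    copy-number segments (or defaults everything to neutral) plus a COSMIC-like
    whitelist for the germline-band rescue.
    """
    if mode not in ("paired", "tumor_only"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or CallerParams()
    calls = sites.copy().reset_index(drop=True)
    if not len(calls):
        for col, val in (
            ("p_value", np.nan), ("vaf", np.nan), ("filter_flags", ""),
            ("status", ""), ("dbsnp", False), ("cosmic", False),
        ):
            calls[col] = pd.Series([], dtype=object)
        return calls
    if mode == "paired" and (calls["n_ref"].isna().any() or calls["n_alt"].isna().any()):
        raise ValueError("paired mode requires normal read counts at every site")

    t_depth = calls["t_ref"] + calls["t_alt"]
    calls["vaf"] = np.where(t_depth > 0, calls["t_alt"] / t_depth.replace(0, 1), 0.0)
    calls["filter_flags"] = ""
    calls["dbsnp"] = False
    calls["cosmic"] = False

    # read-evidence filter
    low_mapq = calls["mapq_pass_fraction"] < params.min_mapq_pass
    high_mm = calls["mismatch_pass_fraction"] < params.min_mismatch_pass
    # Fisher test (paired) and support thresholds; all support-type failures
    # share the low_support flag
    if mode == "paired":
        calls["p_value"] = fisher_somatic_test(
            calls["t_ref"].to_numpy(), calls["t_alt"].to_numpy(),
            calls["n_ref"].to_numpy(), calls["n_alt"].to_numpy(),
        )
        n_depth = calls["n_ref"] + calls["n_alt"]
        n_vaf = np.where(n_depth > 0, calls["n_alt"] / n_depth.replace(0, 1), 0.0)
        weak = (
            (calls["p_value"] >= params.p_max)
            | (calls["t_alt"] < params.min_alt)
            | (calls["vaf"] < params.min_vaf)
            | (n_vaf > params.max_normal_vaf)
        )
    else:
        calls["p_value"] = np.nan
        weak = (calls["t_alt"] < params.min_alt) | (calls["vaf"] < params.min_vaf)
    lm = low_mapq.to_numpy()
    hm = high_mm.to_numpy()
    wk = np.asarray(weak)
    calls["filter_flags"] = [
        ";".join(sorted(
            (["low_mapq_evidence"] if a else [])
            + (["high_mismatch_evidence"] if b else [])
            + (["low_support"] if c else [])
        ))
        for a, b, c in zip(lm, hm, wk)
    ]
    _refresh_status(calls)
    calls = exclude_known(calls, dbsnp_set, panel_of_normals_set)
    if mode == "tumor_only":
        calls = unmatched_filter(calls, segments, cosmic_set, params.vaf_band)
    calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return calls


def accepted(calls: pd.DataFrame) -> pd.DataFrame:
    """The accepted subset, sorted by (chrom, pos)."""
    out = calls[calls["status"] == "accepted"]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
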