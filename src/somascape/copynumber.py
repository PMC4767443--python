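"""Depth-ratio copy-number analysis: CBS segmentation, state calls, cohort
recurrence scoring and per-sample 96-channel mutation opportunity.

Tumor/normal read depths on a 100-bp grid are library-size normalized into log2
ratios, segmented by circular binary segmentation (CBS: the maximal two-sample
t-statistic over all arcs of the circularized bin sequence, accepted by a
permutation test and applied recursively), and thresholded into discrete states.
Cohort recurrence uses a marker-level G-score (sum over samples of positive or
negative amplitude) against a within-sample circular-permutation null — a
deliberately simplified relative of GISTIC's scoring that makes no peak-level
claims.  Opportunity converts segments plus per-segment trinucleotide counts
into the per-channel mutable-base counts that scale signature activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import channels as ch

log = logging.getLogger(__name__)

STATES = ("homdel", "loss", "neutral", "gain", "amp")


@dataclass
class StateThresholds:
    """log2-ratio cutoffs for discrete state calls."""

    amp: float = 0.9
    gain: float = 0.2
    loss: float = -0.2
    homdel: float = -1.0

    def classify(self, mean_log2: float) -> str:
        if not np.isfinite(mean_log2):
            raise ValueError("mean_log2 must be finite")
        if mean_log2 <= self.homdel:
            return "homdel"
        if mean_log2 >= self.amp:
            return "amp"
        if mean_log2 >= self.gain:
            return "gain"
        if mean_log2 <= self.loss:
            return "loss"
        return "neutral"


def depth_ratio(depth_bins: pd.DataFrame) -> pd.DataFrame:
    """Library-size-normalized log2 depth ratios per bin.

    Input columns: chrom, bin_start, t_depth, n_depth on a shared grid.  Bins
    with zero depth in either sample are dropped (count logged and reported in
    ``DataFrame.attrs['n_dropped']``).
    """
    req = {"chrom", "bin_start", "t_depth", "n_depth"}
    if not req.issubset(depth_bins.columns):
        raise ValueError(f"depth table must have columns {sorted(req)}")
    if depth_bins["bin_start"].lt(0).any():
        raise ValueError("negative bin start")
    df = depth_bins.copy()
    t_total = df["t_depth"].sum()
    n_total = df["n_depth"].sum()
    if t_total <= 0 or n_total <= 0:
        raise ValueError("zero total depth")
    keep = (df["t_depth"] > 0) & (df["n_depth"] > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d zero-depth bins", n_dropped)
    df = df[keep].reset_index(drop=True)
    df["log2_ratio"] = np.log2((df["t_depth"] / t_total) / (df["n_depth"] / n_total))
    df.attrs["n_dropped"] = n_dropped
    return df


def aggregate_bins(depth_bins: pd.DataFrame, factor: int) -> pd.DataFrame:
    """Sum tumor/normal depths over windows of ``factor`` consecutive bins.

    CBS cost grows quadratically in the bin count, so fine pileup grids are
    aggregated to a working resolution before segmentation; the returned table
    keeps the depth-bin schema with the coarser grid.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return depth_bins.copy()
    df = depth_bins.copy()
    widths = df.groupby("chrom")["bin_start"].apply(
        lambda s: int(np.median(np.diff(np.sort(s)))) if len(s) > 1 else 1
    )
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        w = widths[chrom]
        grp = grp.sort_values("bin_start")
        window = (grp["bin_start"] // (w * factor)) * (w * factor)
        agg = grp.groupby(window).agg(t_depth=("t_depth", "sum"), n_depth=("n_depth", "sum"))
        agg.index.name = "bin_start"
        agg = agg.reset_index()
        agg.insert(0, "chrom", chrom)
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def _max_t(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t| over all circular arcs, as (t, i, j) with arc x[i:j].

    Every circular arc or its complement is a contiguous window, so scanning
    contiguous windows of length min_width..n-min_width covers all splits.  The
    variance is the fixed whole-segment variance, which is permutation-invariant.
    """
    n = len(x)
    var = float(np.var(x))
    if n < 2 * min_width or var == 0.0:
        return 0.0, 0, n
    cum = np.concatenate(([0.0], np.cumsum(x)))
    tot = cum[-1]
    best_t, best_i, best_j = 0.0, 0, n
    for k in range(min_width, n - min_width + 1):
        wsum = cum[k:] - cum[:-k]
        m1 = wsum / k
        m2 = (tot - wsum) / (n - k)
        t = np.abs(m1 - m2) / math.sqrt(var * (1.0 / k + 1.0 / (n - k)))
        i = int(np.argmax(t))
        if t[i] > best_t:
            best_t, best_i, best_j = float(t[i]), i, i + k
    return best_t, best_i, best_j


def _perm_decision(
    x: np.ndarray,
    observed_t: float,
    min_width: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Permutation test of the max-t split; returns (accept_split, p).

    Processes permutations in blocks and stops early once enough exceedances
    have accrued to guarantee p >= alpha (the split can only be refused).
    """
    n = len(x)
    var = float(np.var(x))
    refuse_at = math.ceil(alpha * (n_perm + 1))
    exceed, done = 0, 0
    block = 128
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = rng.permuted(np.tile(x, (b, 1)), axis=1)
        cums = np.concatenate([np.zeros((b, 1)), np.cumsum(perm, axis=1)], axis=1)
        tot = cums[:, -1:]
        tmax = np.zeros(b)
        for k in range(min_width, n - min_width + 1):
            wsum = cums[:, k:] - cums[:, :-k]
            m1 = wsum / k
            m2 = (tot - wsum) / (n - k)
            t = np.abs(m1 - m2) / math.sqrt(var * (1.0 / k + 1.0 / (n - k)))
            np.maximum(tmax, t.max(axis=1), out=tmax)
        exceed += int((tmax >= observed_t - 1e-12).sum())
        done += b
        if exceed >= refuse_at:
            return False, (1 + exceed) / (1 + done)
    p = (1 + exceed) / (1 + n_perm)
    return p < alpha, p


def _segment_indices(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    offset: int = 0,
) -> list[tuple[int, int]]:
    n = len(x)
    if n < 2 * min_width or np.ptp(x) == 0.0:
        return [(offset, offset + n)]
    tmax, i, j = _max_t(x, min_width)
    if tmax <= 0.0:
        return [(offset, offset + n)]
    split, _ = _perm_decision(x, tmax, min_width, alpha, n_perm, rng)
    if not split:
        return [(offset, offset + n)]
    pieces = [(0, i), (i, j), (j, n)]
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        if b > a:
            out.extend(_segment_indices(x[a:b], alpha, n_perm, min_width, rng, offset + a))
    return out


def _merge_adjacent(x: np.ndarray, bounds: list[tuple[int, int]], merge_tol: float) -> list[tuple[int, int]]:
    bounds = list(bounds)
    while len(bounds) > 1:
        means = [x[a:b].mean() for a, b in bounds]
        diffs = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        i = int(np.argmin(diffs))
        if diffs[i] >= merge_tol:
            break
        bounds[i] = (bounds[i][0], bounds[i + 1][1])
        del bounds[i + 1]
    return bounds


def cbs_segment(
    bins: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    merge_tol: float = 0.1,
    seed: int | np.random.Generator = 0,
    bin_size: int | None = None,
) -> pd.DataFrame:
    """Circular binary segmentation of per-bin log2 ratios.

    Input columns: chrom, bin_start, log2_ratio.  Each chromosome is segmented
    independently; a split is accepted when its permutation p-value is < alpha,
    recursion continues on every resulting piece, and adjacent segments whose
    means differ by less than ``merge_tol`` are merged back.  Returns segments
    (chrom, start, end, n_bins, mean_log2) with half-open bp coordinates.
    """
    if not {"chrom", "bin_start", "log2_ratio"}.issubset(bins.columns):
        raise ValueError("bins must have columns chrom, bin_start, log2_ratio")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for chrom, grp in bins.groupby("chrom", sort=True):
        grp = grp.sort_values("bin_start")
        x = grp["log2_ratio"].to_numpy(dtype=float)
        starts = grp["bin_start"].to_numpy()
        if len(x) < 2:
            raise ValueError(f"chromosome {chrom}: need >= 2 bins")
        width = bin_size if bin_size is not None else int(np.median(np.diff(starts))) if len(starts) > 1 else 1
        bounds = _segment_indices(x, alpha, n_perm, min_width, rng)
        bounds = _merge_adjacent(x, sorted(bounds), merge_tol)
        for a, b in bounds:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(starts[b - 1]) + width,
                    "n_bins": b - a,
                    "mean_log2": float(x[a:b].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean_log2"])


def call_states(segments: pd.DataFrame, thresholds: StateThresholds | None = None) -> pd.DataFrame:
    """Attach a discrete state column to CBS segments."""
    thresholds = thresholds or StateThresholds()
    segments = segments.copy()
    segments["state"] = [thresholds.classify(v) for v in segments["mean_log2"]]
    return segments


@dataclass
class RecurrenceProfile:
    """Marker-level cohort recurrence scores."""

    markers: pd.DataFrame  # chrom, start, end, amp_gscore, del_gscore, freq_amp, freq_del, q_amp, q_del
    n_samples: int
    n_perm: int


def _paint_profile(
    segments: pd.DataFrame, marker_starts: dict[str, np.ndarray], marker_width: int
) -> dict[str, np.ndarray]:
    out = {c: np.zeros(len(s)) for c, s in marker_starts.items()}
    for _, seg in segments.iterrows():
        c = seg["chrom"]
        if c not in out:
            continue
        starts = marker_starts[c]
        mask = (starts + marker_width > seg["start"]) & (starts < seg["end"])
        out[c][mask] = seg["mean_log2"]
    return out


def recurrence_score(
    cohort_segments: dict[str, pd.DataFrame],
    marker_width: int = 100_000,
    n_perm: int = 1000,
    seed: int = 0,
    thresholds: StateThresholds | None = None,
    genome: tuple[tuple[str, int], ...] | None = None,
) -> RecurrenceProfile:
    """Marker-level recurrence G-scores with a circular-permutation null.

    The amplification G-score at a marker is the cohort sum of positive
    amplitudes (negative for deletions).  The null rolls each sample's
    whole-genome marker profile by a random circular offset; permuted scores
    pooled over markers give one-sided p-values, BH-corrected into q-values.
    Per-marker non-neutral frequencies use the state thresholds.
    """
    if not cohort_segments:
        raise ValueError("empty cohort")
    thresholds = thresholds or StateThresholds()
    rng = np.random.default_rng(seed)
    # shared marker grid spanning the union of segment extents (or the genome)
    extents: dict[str, int] = {}
    if genome is not None:
        extents = {c: l for c, l in genome}
    else:
        for segs in cohort_segments.values():
            for _, s in segs.iterrows():
                extents[s["chrom"]] = max(extents.get(s["chrom"], 0), int(s["end"]))
    marker_starts = {
        c: np.arange(0, l, marker_width) for c, l in sorted(extents.items())
    }
    chroms = sorted(marker_starts)
    sizes = [len(marker_starts[c]) for c in chroms]
    total = sum(sizes)
    profiles = np.zeros((len(cohort_segments), total))
    freq_amp = np.zeros(total)
    freq_del = np.zeros(total)
    for si, (sample, segs) in enumerate(sorted(cohort_segments.items())):
        painted = _paint_profile(segs, marker_starts, marker_width)
        flat = np.concatenate([painted[c] for c in chroms]) if total else np.zeros(0)
        profiles[si] = flat
        states = np.array([thresholds.classify(v) for v in flat])
        freq_amp += np.isin(states, ("gain", "amp"))
        freq_del += np.isin(states, ("loss", "homdel"))
    n_samples = len(cohort_segments)
    amp_g = np.clip(profiles, 0, None).sum(axis=0)
    del_g = np.clip(-profiles, 0, None).sum(axis=0)

    null_amp = []
    null_del = []
    for _ in range(n_perm):
        rolled = np.vstack([np.roll(profiles[s], rng.integers(total)) for s in range(n_samples)])
        null_amp.append(np.clip(rolled, 0, None).sum(axis=0))
        null_del.append(np.clip(-rolled, 0, None).sum(axis=0))
    if n_perm:
        null_amp = np.concatenate(null_amp)
        null_del = np.concatenate(null_del)
        p_amp = (1 + (null_amp[None, :] >= amp_g[:, None] - 1e-12).sum(axis=1)) / (1 + len(null_amp))
        p_del = (1 + (null_del[None, :] >= del_g[:, None] - 1e-12).sum(axis=1)) / (1 + len(null_del))
    else:
        p_amp = np.ones(total)
        p_del = np.ones(total)
    q_amp = multipletests(p_amp, method="fdr_bh")[1] if total else np.array([])
    q_del = multipletests(p_del, method="fdr_bh")[1] if total else np.array([])
    rows = []
    k = 0
    for c in chroms:
        for s in marker_starts[c]:
            rows.append(
                {
                    "chrom": c,
                    "start": int(s),
                    "end": int(s) + marker_width,
                    "amp_gscore": amp_g[k],
                    "del_gscore": del_g[k],
                    "freq_amp": freq_amp[k] / n_samples,
                    "freq_del": freq_del[k] / n_samples,
                    "q_amp": q_amp[k],
                    "q_del": q_del[k],
                }
            )
            k += 1
    return RecurrenceProfile(pd.DataFrame(rows), n_samples, n_perm)


def opportunity_from_segments(
    segments: pd.DataFrame,
    context_counts: pd.DataFrame,
) -> np.ndarray:
    """96-channel mutation opportunity from copy-number segments.

    ``context_counts`` has one row per segment (aligned by position with
    ``segments``) and one column per pyrimidine-centred trinucleotide context
    (any subset of the 32).  Each segment contributes copies x context count,
    with copies = round(2 * 2**mean_log2) floored at 0; the three alternate
    bases of a context share its opportunity.
    """
    if len(segments) != len(context_counts):
        raise ValueError("segments and context_counts must align row-wise")
    opp = np.zeros(96)
    copies = np.maximum(np.round(2.0 * np.power(2.0, segments["mean_log2"].to_numpy())), 0.0)
    for ctx in context_counts.columns:
        idx = ch.channels_of_context(ctx)
        contrib = float((copies * context_counts[ctx].to_numpy()).sum())
        for i in idx:
            opp[i] += contrib
    return opp


def uniform_context_counts(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-segment context counts assuming a uniform trinucleotide composition."""
    per = segments["end"].to_numpy() - segments["start"].to_numpy()
    data = {ctx: per / 32.0 for ctx in ch.CONTEXTS_32}
    return pd.DataFrame(data, index=segments.index)
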