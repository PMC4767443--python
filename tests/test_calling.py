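"""Fisher-exact somatic test and the filter cascade."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact, poisson, binom

from somascape import calling, simulate

ZERO_RATES = {k: 0.0 for k in simulate.DEFAULT_BACKGROUND_RATES}


def fisher_oracle(t_ref, t_alt, n_ref, n_alt):
    """Exhaustive hypergeometric enumeration with exact integer arithmetic."""
    N = t_ref + t_alt + n_ref + n_alt
    K = t_alt + n_alt  # alt reads in the urn
    n = t_alt + t_ref  # tumor draws
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(t_alt, min(K, n) + 1)
    )
    return num / denom


class TestFisher:
    def test_no_alt_reads_is_p_one(self):
        assert calling.fisher_somatic_test(10, 0, 10, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        p = calling.fisher_somatic_test(10, 10, 20, 0)
        assert p == pytest.approx(fisher_oracle(10, 10, 20, 0), abs=1e-12)

    def test_matches_scipy_greater(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            ours = calling.fisher_somatic_test(b, a, d, c)
            ref = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    @given(
        t_ref=st.integers(0, 20), n_ref=st.integers(0, 20),
        n_alt=st.integers(0, 10), t_alt=st.integers(0, 19),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_more_tumor_alt_never_raises_p(self, t_ref, n_ref, n_alt, t_alt):
        if t_ref + t_alt + n_ref + n_alt == 0:
            return  # empty table is a separate error case
        p1 = calling.fisher_somatic_test(t_ref, t_alt, n_ref, n_alt)
        p2 = calling.fisher_somatic_test(t_ref, t_alt + 1, n_ref, n_alt)
        assert p2 <= p1 + 1e-12

    def test_all_zero_table_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            calling.fisher_somatic_test(0, 0, 0, 0)
        with pytest.raises(ValueError):
            calling.fisher_somatic_test(-1, 2, 3, 4)


class TestReadEvidenceFilter:
    def test_clean_site_passes(self):
        assert calling.read_evidence_filter(1.0, 1.0) == set()

    def test_low_mapq_fails(self):
        assert calling.read_evidence_filter(0.2, 1.0) == {"low_mapq_evidence"}

    def test_all_reads_dirty_fails(self):
        assert calling.read_evidence_filter(1.0, 0.0) == {"high_mismatch_evidence"}

    def test_both_fail_accumulates(self):
        assert calling.read_evidence_filter(0.1, 0.1) == {
            "low_mapq_evidence", "high_mismatch_evidence",
        }


def _site(**kw):
    base = dict(
        chrom="chr1", pos=100, ref="C", alt="T", t_ref=60, t_alt=40,
        n_ref=100, n_alt=0, context="ACG", gene="G1", effect="missense",
        mapq_pass_fraction=1.0, mismatch_pass_fraction=1.0,
    )
    base.update(kw)
    return base


def _calls(*sites):
    df = pd.DataFrame([_site(**s) for s in sites])
    return calling.call_somatic(df, mode="paired")


class TestCascade:
    def test_clean_somatic_site_accepted(self):
        calls = _calls({})
        assert calls.loc[0, "status"] == "accepted"
        assert calls.loc[0, "filter_flags"] == ""

    def test_blacklisted_site_rejected(self):
        df = pd.DataFrame([_site()])
        calls = calling.call_somatic(df, dbsnp_set={("chr1", 100, "C", "T")})
        assert calls.loc[0, "status"] == "rejected"
        assert "known_snp" in calls.loc[0, "filter_flags"]

    def test_synonymous_rejected_missense_kept(self):
        calls = _calls({"effect": "synonymous"}, {"pos": 200})
        syn = calls[calls["pos"] == 100].iloc[0]
        mis = calls[calls["pos"] == 200].iloc[0]
        assert syn["status"] == "rejected" and "synonymous" in syn["filter_flags"]
        assert mis["status"] == "accepted"

    def test_flags_accumulate_not_short_circuit(self):
        df = pd.DataFrame([_site(effect="synonymous", t_alt=1, t_ref=99, mapq_pass_fraction=0.1)])
        calls = calling.call_somatic(df, dbsnp_set={("chr1", 100, "C", "T")})
        flags = set(calls.loc[0, "filter_flags"].split(";"))
        assert {"synonymous", "known_snp", "low_mapq_evidence", "low_support"} <= flags

    def test_empty_input(self):
        calls = calling.call_somatic(pd.DataFrame(columns=list(calling.FILTER_FLAGS)))
        assert len(calls) == 0

    def test_missing_normal_in_paired_mode(self):
        df = pd.DataFrame([_site(n_ref=np.nan)])
        with pytest.raises(ValueError, match="normal"):
            calling.call_somatic(df, mode="paired")


class TestUnmatchedFilter:
    segments = pd.DataFrame(
        [{"chrom": "chr1", "start": 0, "end": 10_000, "mean_log2": 0.0, "state": "neutral"}]
    )

    def _one(self, vaf_reads, cosmic=None, segments=None):
        t_alt, t_ref = vaf_reads
        df = pd.DataFrame([_site(t_alt=t_alt, t_ref=t_ref, n_ref=0, n_alt=0)])
        return calling.call_somatic(
            df, mode="tumor_only", cosmic_set=cosmic,
            segments=self.segments if segments is None else segments,
        ).iloc[0]

    def test_band_neutral_not_cosmic_rejected(self):
        row = self._one((50, 50))
        assert row["status"] == "rejected"
        assert "germline_band" in row["filter_flags"]

    def test_band_but_cosmic_rescued(self):
        row = self._one((50, 50), cosmic={("chr1", 100, "C", "T")})
        assert row["status"] == "accepted"

    def test_outside_band_accepted(self):
        row = self._one((30, 70))
        assert row["status"] == "accepted"

    def test_band_inclusive_endpoints(self):
        assert "germline_band" in self._one((45, 55))["filter_flags"]
        assert "germline_band" in self._one((55, 45))["filter_flags"]

    def test_non_neutral_segment_escapes_band(self):
        segs = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 10_000, "mean_log2": 1.0, "state": "amp"}]
        )
        assert self._one((50, 50), segments=segs)["status"] == "accepted"


class TestOnSimulations:
    def test_recall_on_planted_sites(self):
        """Nonsynonymous planted sites at depth 100, purity 0.7 are recovered."""
        rates = {k: v * 200 for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()}
        cfg = simulate.SimConfig(n_samples=1, seed=21, background_rates=rates)
        cohort = simulate.simulate_cohort(cfg)
        truth = cohort.truth.somatic.query("effect != 'synonymous'")
        assert len(truth) >= 50
        acc = calling.accepted(calling.call_somatic(cohort.site_tables["S000"]))
        tk = set(zip(truth["chrom"], truth["pos"]))
        ak = set(zip(acc["chrom"], acc["pos"]))
        assert len(tk & ak) / len(tk) >= 0.95
        # nothing accepted off the planted somatic set
        all_truth = cohort.truth.somatic
        assert ak <= set(zip(all_truth["chrom"], all_truth["pos"]))

    def test_germline_band_rejection_matches_binomial_mass(self):
        """Tumor-only: diploid het germline rejected at the exact binomial rate."""
        cfg = simulate.SimConfig(
            n_samples=1, seed=22, background_rates=dict(ZERO_RATES),
            germline_het_rate=5e-4, mean_depth=100.0,
        )
        cohort = simulate.simulate_cohort(cfg)
        calls = calling.call_somatic(cohort.site_tables["S000"], mode="tumor_only")
        frac = calls["filter_flags"].str.contains("germline_band").mean()
        # expected mass of VAF in [0.45, 0.55] under Binom(D, 0.5), D ~ Poisson(100)
        ds = np.arange(50, 160)
        wd = poisson.pmf(ds, 100.0)
        mass = sum(
            w * (binom.cdf(np.floor(0.55 * d), d, 0.5) - binom.cdf(np.ceil(0.45 * d) - 1, d, 0.5))
            for d, w in zip(ds, wd)
        )
        assert frac == pytest.approx(mass, abs=0.05)

    def test_germline_band_rejection_dominates_at_depth_400(self):
        cfg = simulate.SimConfig(
            n_samples=1, seed=23, background_rates=dict(ZERO_RATES),
            germline_het_rate=5e-4, mean_depth=400.0,
        )
        cohort = simulate.simulate_cohort(cfg)
        calls = calling.call_somatic(cohort.site_tables["S000"], mode="tumor_only")
        assert calls["filter_flags"].str.contains("germline_band").mean() >= 0.9
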