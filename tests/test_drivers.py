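"""Background mutation rate, SMG Poisson test, and pathway burden."""

import math

import numpy as np
import pandas as pd
import pytest

from somascape import channels as ch
from somascape import drivers, simulate


def _footprint(**bases):
    """One-gene footprint with explicit per-category available bases."""
    row = {"gene": bases.pop("gene", "G1")}
    for c in ch.CATEGORIES:
        row[c] = bases.get(c, 0.0)
    return pd.DataFrame([row])


def _mutations(rows):
    return pd.DataFrame(
        rows, columns=["sample", "gene", "chrom", "pos", "ref", "alt", "context", "effect", "category"]
    )


class TestBmr:
    def test_no_mutations_zero_rates(self):
        fp = _footprint(CpG_transition=1e6)
        bmr = drivers.estimate_bmr(_mutations([]), fp, n_samples=5)
        assert all(r == 0.0 for r in bmr.rates.values())

    def test_direct_division(self):
        """50 CpG transitions over 1e7 cohort CpG bases give rate 5e-6."""
        fp = _footprint(CpG_transition=1e6)
        muts = _mutations(
            [("S0", "G1", "chr1", i + 1, "C", "T", "ACG", "missense", "CpG_transition")
             for i in range(50)]
        )
        bmr = drivers.estimate_bmr(muts, fp, n_samples=10)
        assert bmr.rates["CpG_transition"] == pytest.approx(5e-6)

    def test_count_with_zero_bases_is_error(self):
        fp = _footprint()  # all-zero footprint
        muts = _mutations([("S0", "G1", "chr1", 1, "C", "T", "ACG", "missense", "CpG_transition")])
        with pytest.raises(ValueError, match="zero available bases"):
            drivers.estimate_bmr(muts, fp, n_samples=1)

    def test_category_conservation(self):
        rates = {k: v * 80 for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()}
        cfg = simulate.SimConfig(n_samples=5, seed=31, background_rates=rates)
        cohort = simulate.simulate_cohort(cfg)
        truth = cohort.truth.somatic
        bmr = drivers.estimate_bmr(truth, cohort.footprint, n_samples=5)
        assert sum(bmr.counts.values()) == len(truth)

    def test_rate_recovery_on_planted_simulation(self):
        """Planted per-category rates recovered within 10% at high counts."""
        # equalize expected counts (~2000) per category across the class bases
        genes = simulate.default_genes(100)
        fp = simulate.footprint_table(genes)
        n_samples, target = 30, 2000.0
        rates = {c: target / (fp[c].sum() * n_samples) for c in ch.CATEGORIES}
        cfg = simulate.SimConfig(
            n_samples=n_samples, seed=32, genes=genes,
            background_rates=rates, germline_het_rate=0.0,
        )
        cohort = simulate.simulate_cohort(cfg)
        bmr = drivers.estimate_bmr(cohort.truth.somatic, cohort.footprint, n_samples=n_samples)
        for c in ch.CATEGORIES:
            assert bmr.counts[c] >= 200
            assert bmr.rates[c] == pytest.approx(rates[c], rel=0.10)


class TestSmg:
    def _bmr_with_lambda(self, lam, bases=1e6, n_samples=1):
        rates = {c: 0.0 for c in ch.CATEGORIES}
        rates["CG_transition"] = lam / bases
        return drivers.BmrEstimate(
            counts={c: 0 for c in ch.CATEGORIES},
            bases={c: bases for c in ch.CATEGORIES},
            rates=rates,
            n_samples=n_samples,
        )

    def test_zero_observed_is_p_one(self):
        fp = _footprint(CG_transition=1e6)
        res = drivers.smg_test(_mutations([]), fp, self._bmr_with_lambda(1.0))
        assert res.loc[0, "p_value"] == 1.0

    def test_poisson_tail_closed_form(self):
        """lambda = 1, k = 3: p = 1 - e^-1 (1 + 1 + 1/2) ~ 0.0803."""
        fp = _footprint(CG_transition=1e6)
        muts = _mutations(
            [("S0", "G1", "chr1", i + 1, "C", "T", "ACT", "missense", "CG_transition")
             for i in range(3)]
        )
        res = drivers.smg_test(muts, fp, self._bmr_with_lambda(1.0))
        expected = 1.0 - math.exp(-1) * (1 + 1 + 0.5)
        assert res.loc[0, "lam"] == pytest.approx(1.0)
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_exact_convolution_close_to_poisson_at_small_rate(self):
        fp = _footprint(CG_transition=1e6)
        muts = _mutations(
            [("S0", "G1", "chr1", i + 1, "C", "T", "ACT", "missense", "CG_transition")
             for i in range(3)]
        )
        bmr = self._bmr_with_lambda(1.0)
        p_pois = drivers.smg_test(muts, fp, bmr).loc[0, "p_value"]
        p_exact = drivers.smg_test(muts, fp, bmr, exact=True).loc[0, "p_value"]
        assert p_exact == pytest.approx(p_pois, rel=1e-3)

    def test_driver_gene_detected_on_simulation(self):
        rates = {k: v * 60 for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()}
        cfg = simulate.SimConfig(
            n_samples=20, seed=33, background_rates=rates,
            driver_spec={"G0007": 40.0}, germline_het_rate=0.0,
        )
        cohort = simulate.simulate_cohort(cfg)
        bmr = drivers.estimate_bmr(cohort.truth.somatic, cohort.footprint, n_samples=20)
        res = drivers.smg_test(cohort.truth.somatic, cohort.footprint, bmr)
        assert res.iloc[0]["gene"] == "G0007"
        assert res.iloc[0]["significant"]

    def test_null_q_values_rarely_significant(self):
        """With no drivers the BH-selected fraction stays below its target."""
        fracs = []
        for seed in range(5):
            rates = {k: v * 60 for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()}
            cfg = simulate.SimConfig(
                n_samples=10, seed=100 + seed, background_rates=rates,
                genes=simulate.default_genes(200), germline_het_rate=0.0,
            )
            cohort = simulate.simulate_cohort(cfg)
            bmr = drivers.estimate_bmr(cohort.truth.somatic, cohort.footprint, n_samples=10)
            res = drivers.smg_test(cohort.truth.somatic, cohort.footprint, bmr)
            fracs.append(res["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_bh_q_monotone_in_rank(self):
        rates = {k: v * 60 for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()}
        cfg = simulate.SimConfig(n_samples=10, seed=35, background_rates=rates,
                                 germline_het_rate=0.0)
        cohort = simulate.simulate_cohort(cfg)
        bmr = drivers.estimate_bmr(cohort.truth.somatic, cohort.footprint, n_samples=10)
        res = drivers.smg_test(cohort.truth.somatic, cohort.footprint, bmr)
        by_p = res.sort_values("p_value")
        assert by_p["q_value"].is_monotonic_increasing


class TestPathway:
    def _results(self):
        return pd.DataFrame(
            [
                {"gene": "A", "k": 0, "lam": 0.5},
                {"gene": "B", "k": 3, "lam": 0.5},
                {"gene": "C", "k": 0, "lam": 2.0},
            ]
        )

    def test_zero_mutation_pathway_p_one(self):
        out = drivers.pathway_burden({"pw": ["A", "C"]}, self._results())
        assert out.loc[0, "p_value"] == 1.0

    def test_poisson_additivity(self):
        """Two genes with lambda 0.5 each and k = 3 total: Poisson(1) tail."""
        out = drivers.pathway_burden({"pw": ["A", "B"]}, self._results())
        expected = 1.0 - math.exp(-1) * (1 + 1 + 0.5)
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_unknown_genes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="unknown genes"):
            out = drivers.pathway_burden({"pw": ["A", "ZZZ"]}, self._results())
        assert out.loc[0, "n_genes"] == 1

    def test_empty_pathway_is_error(self):
        with pytest.raises(ValueError, match="empty"), pytest.warns(UserWarning):
            drivers.pathway_burden({"pw": ["ZZZ"]}, self._results())

    def test_planted_pathway_ranks_first(self):
        rates = {k: v * 60 for k, v in simulate.DEFAULT_BACKGROUND_RATES.items()}
        hits = 0
        for seed in range(5):
            cfg = simulate.SimConfig(
                n_samples=15, seed=200 + seed, background_rates=rates,
                driver_spec={"G0003": 25.0, "G0011": 25.0}, germline_het_rate=0.0,
            )
            cohort = simulate.simulate_cohort(cfg)
            bmr = drivers.estimate_bmr(cohort.truth.somatic, cohort.footprint, n_samples=15)
            res = drivers.smg_test(cohort.truth.somatic, cohort.footprint, bmr)
            rng = np.random.default_rng(seed)
            decoys = [g for g in res["gene"] if g not in ("G0003", "G0011")]
            sets = {"planted": ["G0003", "G0011"]}
            for i in range(20):
                sets[f"decoy{i}"] = list(rng.choice(decoys, size=2, replace=False))
            out = drivers.pathway_burden(sets, res)
            hits += out.iloc[0]["pathway"] == "planted"
        assert hits >= 4


def test_gene_sample_frequency_rounds_to_whole_percent():
    muts = _mutations(
        [(f"S{i:03d}", "NF1", "chr17", 1000 + i, "C", "T", "ACG", "missense", "CpG_transition")
         for i in range(17)]
    )
    assert drivers.gene_sample_frequency(muts, "NF1", 86) == 20
    assert drivers.gene_sample_frequency(muts, "ABSENT", 86) == 0
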