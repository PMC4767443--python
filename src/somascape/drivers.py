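"""Significantly mutated genes against a seven-category background mutation rate,
plus a pathway-level mutation-burden test.

Every mutation is classified into one of seven categories (A/T transitions and
transversions, CpG transitions and transversions, other C/G transitions and
transversions, indels).  The background mutation rate (BMR) of a category is the
cohort mutation count divided by the cohort's available bases for that category.
A gene's expected nonsynonymous burden is lambda_g = sum_c rate_c * bases_{g,c}
* n_samples, and its significance is the Poisson upper tail P(X >= k_g); a
convolution-of-binomials exact variant is available for small-lambda validation.
Gene q-values use Benjamini-Hochberg.  The pathway test aggregates member-gene
counts and expectations into one cohort-level Poisson burden test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import channels as ch

categorize = ch.categorize  # re-export: the per-mutation classifier

NONSYNONYMOUS = ("missense", "nonsense", "frameshift", "splice")


@dataclass
class BmrEstimate:
    """Per-category cohort mutation counts, available bases and rates."""

    counts: dict[str, int]
    bases: dict[str, float]
    rates: dict[str, float]
    n_samples: int


def _category_bases_columns(footprint: pd.DataFrame) -> None:
    missing = [c for c in ch.CATEGORIES if c not in footprint.columns]
    if missing:
        raise ValueError(f"footprint table lacks category columns: {missing}")


def classify_mutations(mutations: pd.DataFrame) -> pd.Series:
    """Category per mutation row (columns: ref, alt, context)."""
    return pd.Series(
        [
            ch.categorize(r, a, None if ch.is_indel(r, a) else c)
            for r, a, c in zip(mutations["ref"], mutations["alt"], mutations["context"])
        ],
        index=mutations.index,
        name="category",
    )


def estimate_bmr(
    mutations: pd.DataFrame,
    footprint: pd.DataFrame,
    n_samples: int,
    exclude_genes: set[str] | None = None,
) -> BmrEstimate:
    """Cohort background mutation rate per category.

    ``mutations`` needs ref/alt/context (a precomputed ``category`` column is
    honoured); ``footprint`` gives per-gene available bases per category.  All
    genes contribute by default; candidate drivers can be excluded via
    ``exclude_genes``.
    """
    _category_bases_columns(footprint)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    fp = footprint
    muts = mutations
    if exclude_genes:
        fp = fp[~fp["gene"].isin(exclude_genes)]
        muts = muts[~muts["gene"].isin(exclude_genes)]
    if "category" in muts.columns:
        cats = muts["category"]
    else:
        cats = classify_mutations(muts)
    counts = {c: int((cats == c).sum()) for c in ch.CATEGORIES}
    bases = {c: float(fp[c].sum()) * n_samples for c in ch.CATEGORIES}
    rates = {}
    for c in ch.CATEGORIES:
        if bases[c] <= 0:
            if counts[c] > 0:
                raise ValueError(f"category {c}: mutations observed but zero available bases")
            rates[c] = 0.0
        else:
            rates[c] = counts[c] / bases[c]
    return BmrEstimate(counts, bases, rates, n_samples)


def _poisson_binomial_tail(k: int, ns: np.ndarray, ps: np.ndarray, support: int = 512) -> float:
    """P(X >= k) for a sum of independent binomials, by truncated pmf convolution."""
    pmf = np.zeros(support + 1)
    pmf[0] = 1.0
    for n, p in zip(ns, ps):
        if n <= 0 or p <= 0:
            continue
        comp = stats.binom.pmf(np.arange(0, support + 1), int(n), p)
        pmf = np.convolve(pmf, comp)[: support + 1]
    return float(max(1.0 - pmf[:k].sum(), 0.0))


def smg_test(
    mutations: pd.DataFrame,
    footprint: pd.DataFrame,
    bmr: BmrEstimate,
    q_max: float = 0.05,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-gene significance of the observed nonsynonymous burden over the BMR.

    Observed counts include nonsynonymous SNVs and indels (synonymous calls are
    ignored).  p = P(X >= k_g) with X ~ Poisson(lambda_g); ``exact=True``
    replaces the Poisson by the convolution of per-category binomials, useful
    at small lambda.  Returns gene, k, lam, p_value, q_value, significant.
    """
    _category_bases_columns(footprint)
    muts = mutations[mutations["effect"].isin(NONSYNONYMOUS)].copy()
    if "category" not in muts.columns:
        muts["category"] = classify_mutations(muts)
    k_by_gene = muts.groupby("gene").size()
    rows = []
    for _, g in footprint.iterrows():
        gene = g["gene"]
        lam = sum(bmr.rates[c] * float(g[c]) * bmr.n_samples for c in ch.CATEGORIES)
        k = int(k_by_gene.get(gene, 0))
        if k == 0:
            p = 1.0
        elif exact:
            ns = np.array([round(float(g[c]) * bmr.n_samples) for c in ch.CATEGORIES])
            ps = np.array([bmr.rates[c] for c in ch.CATEGORIES])
            p = _poisson_binomial_tail(k, ns, ps)
        elif lam == 0.0:
            p = 0.0
        else:
            p = float(stats.poisson.sf(k - 1, lam))
        rows.append({"gene": gene, "k": k, "lam": lam, "p_value": min(max(p, 0.0), 1.0)})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < q_max
    return out.sort_values(["q_value", "p_value", "gene"], kind="mergesort").reset_index(drop=True)


def pathway_burden(
    gene_sets: dict[str, list[str]],
    gene_results: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Cohort-level Poisson burden test per pathway.

    For each gene set, k = sum of member-gene observed counts and lambda = sum
    of member-gene expectations; p = P(Poisson(lambda) >= k).  Genes absent
    from the tested table are dropped with a warning; a pathway left empty
    after filtering is an error.
    """
    known = set(gene_results["gene"])
    by_gene = gene_results.set_index("gene")
    rows = []
    for name, genes in gene_sets.items():
        members = [g for g in genes if g in known]
        unknown = sorted(set(genes) - known)
        if unknown:
            warnings.warn(f"pathway {name}: dropping unknown genes {unknown}", stacklevel=2)
        if not members:
            raise ValueError(f"pathway {name} is empty after filtering unknown genes")
        k = int(by_gene.loc[members, "k"].sum())
        lam = float(by_gene.loc[members, "lam"].sum())
        if k == 0:
            p = 1.0
        elif lam == 0.0:
            p = 0.0
        else:
            p = float(stats.poisson.sf(k - 1, lam))
        rows.append({"pathway": name, "n_genes": len(members), "k": k, "lam": lam, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < q_max
    return out.sort_values(["q_value", "p_value", "pathway"], kind="mergesort").reset_index(drop=True)


def gene_sample_frequency(mutations: pd.DataFrame, gene: str, n_samples: int) -> float:
    """Percent of cohort samples carrying >= 1 nonsynonymous mutation in a gene,
    rounded to the nearest whole percent (the convention used for reporting
    per-gene mutation frequencies)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    muts = mutations[(mutations["gene"] == gene) & mutations["effect"].isin(NONSYNONYMOUS)]
    n_mutated = muts["sample"].nunique()
    return round(100.0 * n_mutated / n_samples)
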