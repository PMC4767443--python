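"""Mutational-signature extraction by opportunity-aware Poisson EM.

Counts M[s, c] of mutations per sample s and 96-channel c are modelled as

    M[s, c] ~ Poisson( O[s, c] * sum_k e[s, k] * sig[k, c] )

where O is the per-sample, per-channel mutation opportunity (mutable bases
weighted by local copy number), e >= 0 are per-sample exposures, and each
signature sig[k, :] is a probability vector over the 96 channels.  The EM
alternates Poisson-mixture responsibilities with closed-form exposure updates
and a simplex-constrained signature update (a one-dimensional Lagrange root per
signature, needed because the opportunity varies across channels).  Model
selection over the number of signatures uses BIC.

The extractor follows the scikit-learn estimator protocol: configure in the
constructor, ``fit`` the count matrix, read fitted attributes with trailing
underscores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from . import channels as ch


def classify_channels(calls: pd.DataFrame, sample_col: str = "sample") -> tuple[pd.DataFrame, int]:
    """Samples x 96 channel count matrix from a call table.

    Purine-reference substitutions are reverse-complemented onto the pyrimidine
    strand.  Indels are excluded; their count is returned alongside the matrix.
    Total SNV counts are conserved.
    """
    samples = sorted(calls[sample_col].unique()) if len(calls) else []
    mat = pd.DataFrame(0, index=samples, columns=list(ch.CHANNELS_96), dtype=int)
    n_indels = 0
    for _, row in calls.iterrows():
        if ch.is_indel(row["ref"], row["alt"]):
            n_indels += 1
            continue
        lab = ch.channel_label(row["ref"], row["alt"], row["context"])
        mat.loc[row[sample_col], lab] += 1
    return mat, n_indels


def _poisson_ll(M: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-300)
    return float((M * np.log(mu) - mu - gammaln(M + 1.0)).sum())


def _solve_simplex_lagrange(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Maximize sum_c A_c log s_c - B_c s_c subject to s on the simplex.

    Solution s_c = A_c / (B_c + lam) with lam chosen so the s sum to one; lam is
    the unique root of the monotone function f(lam) = sum A/(B+lam) - 1 on
    (-min B over supported channels, inf).
    """
    s = np.zeros_like(A)
    support = A > 0
    if not support.any():
        return s
    As, Bs = A[support], B[support]

    def f(lam: float) -> float:
        return float((As / (Bs + lam)).sum() - 1.0)

    bmin = float(Bs.min())
    lo = -bmin + max(1e-12, 1e-9 * abs(bmin))  # keep B + lam strictly positive
    if f(lo) < 0:  # root is at the boundary within numerical noise
        s[support] = As / As.sum()
        return s
    hi = float(As.sum()) - bmin + 1.0
    while f(hi) > 0:
        hi *= 2.0
    lam = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    s[support] = As / (Bs + lam)
    s /= s.sum()
    return s


class PoissonSignatureEM:
    """Opportunity-aware Poisson EM signature extractor.

    Parameters
    ----------
    n_signatures : number of signatures S (>= 1).
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap per restart.
    n_restarts : random restarts; the best final log-likelihood wins.
    random_state : seed for the Dirichlet initialization.

    Attributes (after ``fit``)
    --------------------------
    signatures_ : (S, 96) array, rows summing to 1.
    exposures_ : (n_samples, S) array of nonnegative exposures.
    loglik_ : final log-likelihood of the best restart.
    bic_ : -2 LL + n_params ln(n_obs), n_params = S*(96-1) + n_samples*S.
    ll_trace_ : per-iteration log-likelihood of the best restart (non-decreasing).
    n_iter_ : iterations used by the best restart.
    """

    def __init__(
        self,
        n_signatures: int = 1,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        n_restarts: int = 10,
        random_state: int | None = 0,
    ) -> None:
        self.n_signatures = n_signatures
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_signatures": self.n_signatures,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "PoissonSignatureEM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def _one_fit(
        self, M: np.ndarray, O: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, list[float]]:
        n, C = M.shape
        S = self.n_signatures
        sig = rng.dirichlet(np.ones(C), size=S)
        e = np.full((n, S), M.sum(axis=1, keepdims=True) / S / max(O.mean(), 1e-12))
        trace: list[float] = []
        ll_prev = -np.inf
        for _ in range(self.max_iter):
            g = e @ sig  # (n, C) mixture intensity before opportunity
            mu = O * g
            ll = _poisson_ll(M, mu)
            trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * (abs(ll_prev) + 1e-12):
                break
            ll_prev = ll
            W = np.where(g > 0, M / np.maximum(g, 1e-300), 0.0)  # M / g
            # exposure update (EM surrogate maximizer with signatures fixed)
            denom_e = O @ sig.T  # (n, S)
            e = e * (W @ sig.T) / np.maximum(denom_e, 1e-300)
            # fresh E-step at (e_new, sig_old), then the simplex-constrained
            # signature update: together a conditional-maximization EM sweep,
            # so the log-likelihood is non-decreasing
            g = e @ sig
            W = np.where(g > 0, M / np.maximum(g, 1e-300), 0.0)
            A = sig * (e.T @ W)
            B = e.T @ O  # (S, C)
            for k in range(S):
                if A[k].sum() > 0:
                    sig[k] = _solve_simplex_lagrange(A[k], B[k])
        return e, sig, trace

    def fit(self, M, O=None) -> "PoissonSignatureEM":
        """Fit the model to a samples x 96 count matrix.

        ``M`` may be a DataFrame (channel columns) or array; ``O`` is the
        matching opportunity matrix, a per-sample 96-vector, or None for flat
        opportunity.  O must be strictly positive wherever M > 0.
        """
        Mdf = M if isinstance(M, pd.DataFrame) else None
        M = np.asarray(M, dtype=float)
        if M.ndim != 2 or M.shape[1] != 96:
            raise ValueError("M must be samples x 96")
        if (M < 0).any():
            raise ValueError("negative counts")
        n, C = M.shape
        if self.n_signatures < 1:
            raise ValueError("need at least one signature")
        if self.n_signatures > n * C:
            raise ValueError("more signatures than observations")
        if O is None:
            O = np.ones_like(M)
        else:
            O = np.asarray(O, dtype=float)
            if O.ndim == 1:
                O = np.tile(O, (n, 1))
            if O.shape != M.shape:
                raise ValueError("opportunity must match the count matrix shape")
        if ((O <= 0) & (M > 0)).any():
            raise ValueError("zero opportunity at a channel with observed mutations")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(self.n_restarts, 1)):
            e, sig, trace = self._one_fit(M, O, rng)
            if best is None or trace[-1] > best[2][-1]:
                best = (e, sig, trace)
        e, sig, trace = best
        order = np.argsort(-e.sum(axis=0))  # stable order: by total exposure
        self.exposures_ = e[:, order]
        self.signatures_ = sig[order]
        self.ll_trace_ = np.array(trace)
        self.loglik_ = float(trace[-1])
        self.n_iter_ = len(trace)
        n_params = self.n_signatures * (C - 1) + n * self.n_signatures
        self.bic_ = float(-2.0 * self.loglik_ + n_params * np.log(n * C))
        self.channel_names_ = list(Mdf.columns) if Mdf is not None else list(ch.CHANNELS_96)
        self.n_samples_ = n
        return self

    def fitted_means(self, O=None) -> np.ndarray:
        """Fitted Poisson means mu = O * (e @ sig) of the training fit."""
        g = self.exposures_ @ self.signatures_
        if O is None:
            return g
        O = np.asarray(O, dtype=float)
        return O * g


def select_n_signatures(
    M,
    O=None,
    s_range: range | list[int] = range(1, 6),
    random_state: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[int, pd.DataFrame]:
    """Fit each candidate S and pick the BIC minimizer.

    Returns (best S, table of S / log-likelihood / BIC).
    """
    s_range = list(s_range)
    if not s_range:
        raise ValueError("empty S range")
    rows = []
    fits = {}
    for S in s_range:
        est = PoissonSignatureEM(
            n_signatures=S, tol=tol, max_iter=max_iter,
            n_restarts=n_restarts, random_state=random_state,
        ).fit(M, O)
        fits[S] = est
        rows.append({"S": S, "loglik": est.loglik_, "bic": est.bic_})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["bic"].idxmin(), "S"])
    return best, table


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_signatures(recovered: np.ndarray, planted: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy max-cosine matching of recovered to planted signatures."""
    pairs = []
    used_r, used_p = set(), set()
    sims = [
        (cosine_similarity(recovered[i], planted[j]), i, j)
        for i in range(len(recovered))
        for j in range(len(planted))
    ]
    for sim, i, j in sorted(sims, reverse=True):
        if i in used_r or j in used_p:
            continue
        used_r.add(i)
        used_p.add(j)
        pairs.append((i, j, sim))
    return pairs
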