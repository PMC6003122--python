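"""All-pairs Spearman correlation with small-sample-valid p-values.

Correlations are computed on midranks (average ranks for ties) with
pairwise-complete deletion: each pair of variables uses exactly the subjects
jointly non-missing for that pair, and the pairwise n is recorded so the
resulting networks stay auditable.  Two-tailed p-values come from three
regimes:

``exact``
    n <= ``exact_max_n`` and no ties: full enumeration of the n! rank
    permutations (null distribution cached per n).
``mc_permutation``
    n <= ``exact_max_n`` with ties: seeded Monte-Carlo permutation p with
    ``n_permutations`` draws (add-one estimator), flagged as such.
``t_approx``
    larger n: the usual t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.

Pairs whose usable n falls below ``min_n``, or where either vector is
constant after deletion, are *invalid* — carried with a reason, never as a
zero correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import CohortTable

__all__ = [
    "PairResult",
    "SpearmanCorrelation",
    "spearman_pair",
    "correlation_matrix",
]

_EPS = 1e-12


@lru_cache(maxsize=16)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! permutations of tie-free ranks (cached)."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    d = perms - np.arange(n, dtype=np.int64)
    rho = 1.0 - 6.0 * (d * d).sum(axis=1) / (n * (n * n - 1))
    return np.sort(np.abs(rho))


def _exact_p(rho: float, n: int) -> float:
    null = _exact_null_abs_rho(n)
    # count permutations at least as extreme, with a float-safety margin
    idx = np.searchsorted(null, abs(rho) - _EPS, side="left")
    return float(null.size - idx) / null.size


def _t_approx_p(rho, n):
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - rho * rho
        t = rho * np.sqrt(np.maximum(n - 2, 0) / np.maximum(denom, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    return np.where(denom <= _EPS, 0.0, p)


def _midranks(a: np.ndarray) -> np.ndarray:
    """Average ranks (midranks) for ties; lean equivalent of rankdata."""
    order = np.argsort(a, kind="stable")
    sa = a[order]
    new_group = np.empty(a.size, dtype=bool)
    new_group[0] = True
    np.not_equal(sa[1:], sa[:-1], out=new_group[1:])
    gid = np.cumsum(new_group) - 1
    counts = np.bincount(gid)
    ends = np.cumsum(counts)
    mid = (ends - counts + ends + 1) / 2.0  # mean of ranks start+1..end
    out = np.empty(a.size, dtype=float)
    out[order] = mid[gid]
    return out


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx * cx).sum() * (cy * cy).sum())
    rho = float((cx * cy).sum() / denom)
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) > 1.0 - 1e-12:
        rho = float(np.sign(rho))
    return rho


def _mc_permutation_p(rx: np.ndarray, ry: np.ndarray, n_permutations: int,
                      seed: int) -> float:
    """Seeded Monte-Carlo permutation p for tied small samples (add-one)."""
    rng = np.random.default_rng(seed)
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    sx = np.sqrt((cx * cx).sum())
    sy = np.sqrt((cy * cy).sum())
    obs = float((cx * cy).sum() / (sx * sy))
    draws = rng.permuted(
        np.broadcast_to(cy, (n_permutations, n)).copy(), axis=1
    )
    perm_rho = draws @ cx / (sx * sy)
    hits = int(np.sum(np.abs(perm_rho) >= abs(obs) - _EPS))
    return (1 + hits) / (n_permutations + 1)


@dataclass(frozen=True)
class PairResult:
    """Spearman correlation between one pair of variables."""

    var_a: str
    var_b: str
    rho: float
    p_value: float
    n_pairs: int
    valid: bool
    method: str
    reason: str = ""


def spearman_pair(
    x,
    y,
    min_n: int = 5,
    exact_max_n: int = 9,
    n_permutations: int = 20000,
    permutation_seed: int = 0,
    var_a: str = "x",
    var_b: str = "y",
) -> PairResult:
    """Spearman rho and two-tailed p for one pair, pairwise-complete.

    Missing entries (NaN) are removed pairwise before ranking.  See the
    module docstring for the p-value regimes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"spearman_pair needs two equal-length 1-d vectors, got "
            f"{x.shape} and {y.shape}"
        )
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        return PairResult(var_a, var_b, np.nan, np.nan, n, False, "none",
                          f"insufficient n ({n} < min_n={min_n})")
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return PairResult(var_a, var_b, np.nan, np.nan, n, False, "none",
                          "constant vector after pairwise deletion")
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) > 1.0 - 1e-12:  # snap float dust on perfect monotone pairs
        rho = float(np.sign(rho))
    has_ties = (np.unique(xs).size < n) or (np.unique(ys).size < n)
    if n <= exact_max_n:
        if has_ties:
            p = _mc_permutation_p(rx, ry, n_permutations, permutation_seed)
            method = "mc_permutation"
        else:
            p = _exact_p(rho, n)
            method = "exact"
    else:
        p = float(_t_approx_p(np.array(rho), np.array(n)))
        method = "t_approx"
    return PairResult(var_a, var_b, rho, min(1.0, p), n, True, method)


class SpearmanCorrelation(BaseEstimator):
    """All-pairs Spearman correlation matrix estimator.

    Parameters
    ----------
    min_n : int, default 5
        Minimum pairwise-complete n for a pair to be valid.
    exact_max_n : int, default 9
        Largest n for which the exact (or tied Monte-Carlo) permutation
        p-value is used instead of the t approximation.
    n_permutations : int, default 20000
        Monte-Carlo permutation draws for tied small samples.
    permutation_seed : int, default 0
        Seed for the Monte-Carlo permutation fallback.

    Attributes (after :meth:`fit`)
    ------------------------------
    variables_ : list of str
    rho_, p_value_ : (K, K) ndarrays, symmetric; diagonal 1 and 0.
    n_pairs_ : (K, K) int ndarray of pairwise-complete counts.
    valid_ : (K, K) bool ndarray; invalid entries hold NaN in rho_/p_value_.
    reasons_ : dict mapping invalid (var_a, var_b) pairs to a reason string.
    """

    def __init__(self, min_n: int = 5, exact_max_n: int = 9,
                 n_permutations: int = 20000, permutation_seed: int = 0):
        self.min_n = min_n
        self.exact_max_n = exact_max_n
        self.n_permutations = n_permutations
        self.permutation_seed = permutation_seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None) -> "SpearmanCorrelation":
        frame = self._as_frame(X)
        if frame.shape[1] < 2:
            raise ValueError("need at least 2 variables")
        if self.min_n < 3:
            raise ValueError("min_n must be at least 3")
        values = frame.to_numpy(dtype=float)
        n, k = values.shape
        self.variables_ = [str(c) for c in frame.columns]
        self.n_features_in_ = k

        if (not np.isnan(values).any() and n > self.exact_max_n
                and n >= self.min_n):
            self._fit_complete(values)
        else:
            self._fit_pairwise(values)
        return self

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, CohortTable):
            return X.data
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-d subjects-by-variables array")
        return pd.DataFrame(arr, columns=[f"V{i}" for i in range(arr.shape[1])])

    def _fit_complete(self, values: np.ndarray) -> None:
        """Vectorized path for complete data above the exact-p regime."""
        n, k = values.shape
        ranks = stats.rankdata(values, axis=0)
        sd = ranks.std(axis=0)
        constant = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks.T)
        rho = np.clip(rho, -1.0, 1.0)
        rho = np.where(np.abs(rho) > 1.0 - 1e-12, np.sign(rho), rho)
        p = _t_approx_p(rho, n)
        valid = ~(constant[:, None] | constant[None, :])
        rho = np.where(valid, rho, np.nan)
        p = np.where(valid, p, np.nan)
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(p, 0.0)
        np.fill_diagonal(valid, True)
        self.rho_, self.p_value_ = rho, p
        self.n_pairs_ = np.full((k, k), n, dtype=int)
        self.valid_ = valid
        self.reasons_ = {
            (self.variables_[i], self.variables_[j]):
                "constant vector after pairwise deletion"
            for i in range(k) for j in range(i + 1, k)
            if not valid[i, j]
        }
        self.methods_ = {"default": "t_approx"}

    def _fit_pairwise(self, values: np.ndarray) -> None:
        n, k = values.shape
        rho = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        npairs = np.zeros((k, k), dtype=int)
        valid = np.zeros((k, k), dtype=bool)
        reasons: dict[tuple[str, str], str] = {}
        methods: dict[tuple[str, str], str] = {}
        cols = [values[:, j] for j in range(k)]
        finite = [np.isfinite(c) for c in cols]
        deferred_i, deferred_j = [], []  # t-regime pairs, p computed in batch
        for i in range(k):
            for j in range(i + 1, k):
                mask = finite[i] & finite[j]
                m = int(mask.sum())
                npairs[i, j] = npairs[j, i] = m
                pair_key = (self.variables_[i], self.variables_[j])
                if m < self.min_n:
                    reasons[pair_key] = (
                        f"insufficient n ({m} < min_n={self.min_n})"
                    )
                    methods[pair_key] = "none"
                    continue
                xs, ys = cols[i][mask], cols[j][mask]
                if xs.min() == xs.max() or ys.min() == ys.max():
                    reasons[pair_key] = "constant vector after pairwise deletion"
                    methods[pair_key] = "none"
                    continue
                rx, ry = _midranks(xs), _midranks(ys)
                r = _rank_corr(rx, ry)
                rho[i, j] = rho[j, i] = r
                valid[i, j] = valid[j, i] = True
                if m <= self.exact_max_n:
                    ties = (np.unique(xs).size < m) or (np.unique(ys).size < m)
                    if ties:
                        pv = _mc_permutation_p(rx, ry, self.n_permutations,
                                               self.permutation_seed)
                        methods[pair_key] = "mc_permutation"
                    else:
                        pv = _exact_p(r, m)
                        methods[pair_key] = "exact"
                    p[i, j] = p[j, i] = min(1.0, pv)
                else:
                    deferred_i.append(i)
                    deferred_j.append(j)
                    methods[pair_key] = "t_approx"
        if deferred_i:
            ii = np.array(deferred_i)
            jj = np.array(deferred_j)
            pv = _t_approx_p(rho[ii, jj], npairs[ii, jj])
            p[ii, jj] = pv
            p[jj, ii] = pv
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(p, 0.0)
        np.fill_diagonal(valid, True)
        counts = np.isfinite(values).sum(axis=0)
        np.fill_diagonal(npairs, 0)
        for j in range(k):
            npairs[j, j] = counts[j]
        self.rho_, self.p_value_ = rho, p
        self.n_pairs_, self.valid_ = npairs, valid
        self.reasons_, self.methods_ = reasons, methods

    # -------------------------------------------------------------- queries
    def pair(self, var_a: str, var_b: str) -> PairResult:
        i = self.variables_.index(var_a)
        j = self.variables_.index(var_b)
        reason = self.reasons_.get((var_a, var_b)) or self.reasons_.get(
            (var_b, var_a), ""
        )
        return PairResult(
            var_a, var_b, float(self.rho_[i, j]), float(self.p_value_[i, j]),
            int(self.n_pairs_[i, j]), bool(self.valid_[i, j]),
            method="", reason=reason,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per unordered variable pair."""
        rows = []
        k = len(self.variables_)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "var_a": self.variables_[i],
                        "var_b": self.variables_[j],
                        "rho": self.rho_[i, j],
                        "p": self.p_value_[i, j],
                        "n": int(self.n_pairs_[i, j]),
                        "valid": bool(self.valid_[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p", "n",
                                           "valid"])

    @classmethod
    def from_matrices(cls, variables, rho, p, n_pairs, valid=None,
                      min_n: int = 5) -> "SpearmanCorrelation":
        """Assemble a fitted estimator from precomputed matrices (interop)."""
        est = cls(min_n=min_n)
        est.variables_ = [str(v) for v in variables]
        k = len(est.variables_)
        est.rho_ = np.asarray(rho, dtype=float)
        est.p_value_ = np.asarray(p, dtype=float)
        est.n_pairs_ = np.asarray(n_pairs, dtype=int)
        est.valid_ = (np.ones((k, k), dtype=bool) if valid is None
                      else np.asarray(valid, dtype=bool))
        est.reasons_ = {}
        est.n_features_in_ = k
        for name, m in (("rho", est.rho_), ("p", est.p_value_)):
            if m.shape != (k, k) or not np.allclose(
                np.where(np.isnan(m), 0, m), np.where(np.isnan(m.T), 0, m.T)
            ):
                raise ValueError(f"{name} matrix must be square and symmetric")
        return est


def correlation_matrix(cohort, min_n: int = 5, **kwargs) -> SpearmanCorrelation:
    """All-pairs Spearman correlation of a cohort (fitted estimator)."""
    return SpearmanCorrelation(min_n=min_n, **kwargs).fit(cohort)
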