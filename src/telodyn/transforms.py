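"""Rank-based transforms, covariate residualization, telomere-attrition
construction, and the exact-permutation Wilcoxon-Mann-Whitney test.

These are the model-free preprocessing steps of the analysis: telomere
T/S ratios are mapped to inverse-normal quantile scores before any
likelihood-based modelling, adjusted for sex and age by ordinary least
squares where the analysis calls for residuals, and differenced across
time points to measure attrition.  Raw-scale group comparisons use a
permutation Mann-Whitney test whose null distribution is enumerated
exactly when feasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitVector",
    "MedianTestResult",
    "inverse_normal_transform",
    "residualize",
    "delta_ltl",
    "exact_mwu_test",
]

_SCALES = ("raw", "inormal", "residual")


@dataclass(frozen=True)
class TraitVector:
    """Per-individual values of one trait, with a scale tag.

    The scale tag tracks where a vector sits in the raw -> inverse-normal
    -> residual chain so that downstream operations can insist on the
    representation they were designed for.
    """

    ids: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    scale: str = "raw"
    name: str = ""

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        values = np.asarray(self.values, dtype=float)
        if ids.shape != values.shape or ids.ndim != 1:
            raise ValueError("ids and values must be 1-d and equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("trait ids must be unique")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_series(cls, s: pd.Series, scale: str = "raw", name: str | None = None) -> "TraitVector":
        return cls(s.index.to_numpy(), s.to_numpy(dtype=float), scale,
                   name if name is not None else (s.name or ""))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name=self.name or None)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class MedianTestResult:
    """Outcome of the permutation Mann-Whitney comparison."""

    statistic: float
    p_value: float
    method: str  # "exact" | "monte_carlo"
    n_permutations: int | None = None
    n_a: int = 0
    n_b: int = 0


def inverse_normal_transform(v: TraitVector, offset: float = 0.5) -> TraitVector:
    """Rank-based inverse Gaussian (inverse-normal) quantile scores.

    value_i = Phi^-1((rank_i - offset) / (n - 2*offset + 1)), with midranks
    for ties.  ``offset=0.5`` gives the (r - 1/2)/n convention; ``offset=3/8``
    gives Blom scores (r - 3/8)/(n + 1/4).  Missing values stay missing and
    do not consume ranks.
    """
    if v.scale != "raw":
        raise ValueError("inverse_normal_transform expects a raw-scale vector")
    x = v.values
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    obs = x[finite]
    if np.all(obs == obs[0]):
        raise ValueError("all values identical: transform is degenerate")
    ranks = stats.rankdata(obs, method="average")
    scores = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    out = np.full_like(x, np.nan)
    out[finite] = scores
    return TraitVector(v.ids, out, "inormal", v.name)


def residualize(v: TraitVector, covariates: pd.DataFrame,
                drop_constant: bool = True) -> TraitVector:
    """OLS residuals of a trait on an intercept plus covariate columns.

    Rows are aligned by id; rows missing the trait or any covariate are
    excluded (their residuals stay NaN).  Zero-variance covariates are
    dropped when ``drop_constant`` is true; a rank-deficient design after
    that raises.
    """
    s = v.to_series()
    cov = covariates.reindex(s.index)
    keep = s.notna() & cov.notna().all(axis=1)
    y = s[keep].to_numpy(dtype=float)
    C = cov.loc[keep]
    if drop_constant:
        C = C.loc[:, C.nunique() > 1]
    X = np.column_stack([np.ones(len(y))] + [C[c].to_numpy(dtype=float) for c in C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear (rank-deficient) covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = pd.Series(np.nan, index=s.index)
    out[keep] = resid
    return TraitVector(v.ids, out.to_numpy(), "residual", v.name)


def delta_ltl(t0: TraitVector, t2: TraitVector,
              mode: str = "adjusted_residual") -> TraitVector:
    """Telomere attrition: per-individual baseline minus follow-up value.

    Positive values mean shortening.  ``mode`` declares the scale the two
    inputs must be on: ``raw_inormal`` expects inverse-normal scores,
    ``adjusted_residual`` expects sex/age-adjusted residuals.  Individuals
    missing either time point are dropped.
    """
    expected = {"raw_inormal": "inormal", "adjusted_residual": "residual"}
    if mode not in expected:
        raise ValueError(f"mode must be one of {sorted(expected)}")
    want = expected[mode]
    for tv in (t0, t2):
        if tv.scale != want:
            raise ValueError(
                f"mode {mode!r} requires scale {want!r}, got {tv.scale!r}"
            )
    a, b = t0.to_series(), t2.to_series()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no individuals present at both time points")
    d = (a[common] - b[common]).dropna()
    return TraitVector(d.index.to_numpy(), d.to_numpy(), "raw",
                       name=f"delta_{t0.name or 'ltl'}")


def _rank_sum_tail_counts(ranks: np.ndarray, n_a: int, observed: float,
                          chunk: int = 200_000):
    """Exact tail counts of the group-a rank sum over all label assignments.

    Enumerates C(n, n_a) index subsets in chunks.  Returns counts of
    assignments with rank sum <= and >= the observed value, plus the total.
    Half-integer midranks are doubled to integers first so comparisons
    are exact.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    obs2 = int(np.rint(2.0 * observed))
    n = len(ranks)
    total = math.comb(n, n_a)
    le = ge = 0
    it = itertools.combinations(range(n), n_a)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        sums = r2[np.asarray(block, dtype=np.intp)].sum(axis=1)
        le += int((sums <= obs2).sum())
        ge += int((sums >= obs2).sum())
    return le, ge, total


def exact_mwu_test(a, b, alternative: str = "two_sided",
                   max_exact: int = 2_000_000, seed: int | None = None,
                   n_monte_carlo: int = 100_000) -> MedianTestResult:
    """Permutation Wilcoxon-Mann-Whitney test on two samples.

    The statistic is the midrank sum of group ``a`` in the pooled sample
    (equivalent in ordering to the Mann-Whitney U).  If the number of
    label assignments C(n_a+n_b, n_a) is at most ``max_exact`` the null
    distribution is enumerated exactly; otherwise it is sampled with
    ``n_monte_carlo`` random assignments and the add-one estimate
    (k+1)/(B+1).  Two-sided p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError("alternative must be two_sided, less or greater")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled, method="average")
    n_a, n = len(a), len(pooled)
    observed = float(ranks[:n_a].sum())

    if math.comb(n, n_a) <= max_exact:
        le, ge, total = _rank_sum_tail_counts(ranks, n_a, observed)
        p_less, p_greater = le / total, ge / total
        method, n_perm = "exact", None
    else:
        rng = np.random.default_rng(seed)
        B = int(n_monte_carlo)
        le = ge = 0
        block_size = max(1, min(B, 20_000_000 // n))
        done = 0
        while done < B:
            m = min(block_size, B - done)
            keys = rng.random((m, n))
            idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
            sums = ranks[idx].sum(axis=1)
            le += int((sums <= observed).sum())
            ge += int((sums >= observed).sum())
            done += m
        p_less = (le + 1) / (B + 1)
        p_greater = (ge + 1) / (B + 1)
        method, n_perm = "monte_carlo", B

    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return MedianTestResult(observed, float(p), method, n_perm, n_a, len(b))
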