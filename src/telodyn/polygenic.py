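"""Maximum-likelihood polygenic variance decomposition on pedigrees.

The phenotype vector y of n related individuals is modelled as

    y ~ N(X beta,  sigma2_g * 2*Phi + sigma2_e * I)

where 2*Phi is the additive (numerator) relationship matrix derived from
the pedigree, sigma2_g the additive-genetic variance and sigma2_e the
residual environmental variance.  Heritability is
h2 = sigma2_g / (sigma2_g + sigma2_e).

Fitting strategy: eigendecompose A = 2*Phi once (A = U D U'), rotate
y and X by U'.  In the rotated basis the covariance is diagonal,
sigma2 * W(h2) with W = h2*D + (1-h2)*I and sigma2 = sigma2_g + sigma2_e,
so for each candidate h2 the GLS beta and the total variance sigma2 have
closed forms and the objective profiles down to a 1-d function of h2
maximized by bounded scalar search on [0, 1].

Two estimation criteria are available.  ``method="reml"`` (the default)
maximizes the restricted likelihood, which removes the downward
small-sample bias that plain ML variance components incur from the
fixed-effect degrees of freedom — at cohort sizes of a couple of
hundred related animals that bias is material (~0.05 on h2).
``method="ml"`` maximizes the ordinary multivariate-normal likelihood.

Hypothesis tests always compare ordinary ML log-likelihoods, whatever
the point-estimation method: covariate significance is a likelihood-
ratio test against the model with that coefficient constrained to zero
(chi-square, 1 df; REML likelihoods are not comparable across different
fixed-effect designs), and the test of h2 = 0 sits on the boundary of
the parameter space, so its null is the mixture 0.5*chi2(0) +
0.5*chi2(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import KinshipMatrix

__all__ = [
    "PolygenicModelSpec",
    "PolygenicFit",
    "AssociationRow",
    "fit_polygenic",
    "lrt_covariate",
    "lrt_heritability",
    "covariate_association",
    "naive_association",
]

_H2_TOL = 1e-8
_PSD_TOL = -1e-8
_FLAT_TOL = 1e-7


class CovarianceError(ValueError):
    """Kinship-derived covariance is not positive semi-definite."""


class CollinearityError(ValueError):
    """Rotated fixed-effect design is singular."""


@dataclass(frozen=True)
class PolygenicModelSpec:
    """Declaration of one polygenic model: trait, covariates, kinship."""

    trait: str
    covariates: tuple[str, ...]
    kinship: KinshipMatrix = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class PolygenicFit:
    """MLEs, standard errors and log-likelihood of one polygenic fit."""

    beta: dict[str, tuple[float, float]]  # name -> (estimate, se)
    sigma2_g: float
    sigma2_e: float
    h2: float
    h2_se: float
    loglik: float
    n: int
    p_values: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def boundary(self) -> bool:
        return "boundary" in self.flags


@dataclass(frozen=True)
class AssociationRow:
    """One row of an association table: predictor, R2, r and P."""

    predictor: str
    r2: float
    r: float
    p: float
    n: int
    beta: float


class _RotatedModel:
    """Eigen-rotated data for one (trait, covariates, row-set) problem.

    Produced once per fit; shared between full and nested null fits so
    likelihood-ratio tests compare identical rows.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, names: list[str],
                 A: np.ndarray):
        eigval, eigvec = np.linalg.eigh(A)
        if eigval.min() < _PSD_TOL:
            raise CovarianceError(
                f"2*Phi has negative eigenvalue {eigval.min():.3g}"
            )
        self.d = np.clip(eigval, 0.0, None)
        self.y = eigvec.T @ y
        self.X = eigvec.T @ X
        self.names = names
        self.n = len(y)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise CollinearityError("rotated design matrix is singular")

    def drop(self, name: str) -> "_RotatedModel":
        j = self.names.index(name)
        out = object.__new__(_RotatedModel)
        out.d = self.d
        out.y = self.y
        out.X = np.delete(self.X, j, axis=1)
        out.names = [nm for nm in self.names if nm != name]
        out.n = self.n
        if np.linalg.matrix_rank(out.X) < out.X.shape[1]:
            raise CollinearityError("rotated design matrix is singular")
        return out

    def profile(self, h2: float, method: str = "ml"):
        """Profiled objective at h2, with GLS beta and sigma2 hat.

        For ``method="ml"`` the objective is the ordinary log-likelihood
        with sigma2 = RSS_w / n; for ``method="reml"`` it is the
        restricted log-likelihood with sigma2 = RSS_w / (n - p).
        """
        w = h2 * self.d + (1.0 - h2)
        if w.min() <= 0:
            return -np.inf, None, np.nan, None
        wi = 1.0 / w
        Xw = self.X * wi[:, None]
        XtWX = self.X.T @ Xw
        XtWy = Xw.T @ self.y
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(str(exc)) from exc
        resid = self.y - self.X @ beta
        rss = float(resid @ (wi * resid))
        p = self.X.shape[1]
        if rss <= 0:
            return -np.inf, beta, 0.0, XtWX
        if method == "ml":
            sigma2 = rss / self.n
            ll = -0.5 * (
                self.n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
                + float(np.log(w).sum())
            )
        elif method == "reml":
            df = self.n - p
            sigma2 = rss / df
            sign, logdet_xwx = np.linalg.slogdet(XtWX)
            if sign <= 0:
                raise CollinearityError("X' W^-1 X not positive definite")
            ll = -0.5 * (
                df * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
                + float(np.log(w).sum())
                + logdet_xwx
            )
        else:
            raise ValueError("method must be 'ml' or 'reml'")
        return ll, beta, sigma2, XtWX

    def loglik(self, h2: float, method: str = "ml") -> float:
        return self.profile(h2, method)[0]


def _maximize_h2(model: _RotatedModel, method: str) -> tuple[float, float, list[str]]:
    """Grid scan plus bounded refinement of the profiled objective."""
    grid = np.linspace(0.0, 1.0 - 1e-9, 21)
    lls = np.array([model.loglik(h, method) for h in grid])
    flags: list[str] = []
    if lls.max() - lls.min() < _FLAT_TOL:
        # flat ridge (e.g. unrelated individuals): resolve to h2 = 0
        return 0.0, float(model.loglik(0.0, method)), ["unidentifiable", "boundary"]
    k = int(np.argmax(lls))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda h: -model.loglik(h, method), bounds=(lo, hi), method="bounded",
        options={"xatol": _H2_TOL},
    )
    h2, ll = float(res.x), float(-res.fun)
    for bound, val in ((0.0, model.loglik(0.0, method)),
                       (1.0 - 1e-12, model.loglik(1.0 - 1e-12, method))):
        if val > ll:
            h2, ll = bound, val
    if h2 < 1e-6:
        h2 = 0.0
        ll = float(model.loglik(0.0, method))
        flags.append("boundary")
    elif h2 > 1.0 - 1e-6:
        flags.append("boundary")
    return h2, ll, flags


def _h2_standard_error(model: _RotatedModel, h2: float, method: str) -> float:
    """SE from the numerical curvature of the profiled objective."""
    step = 1e-4
    lo, hi = max(0.0, h2 - step), min(1.0 - 1e-12, h2 + step)
    if hi - lo < step:  # too close to a bound for a central difference
        return float("nan")
    f0 = model.loglik(h2, method)
    fm = model.loglik(h2 - (h2 - lo), method)
    fp = model.loglik(h2 + (hi - h2), method)
    d2 = (fp - 2.0 * f0 + fm) / ((hi - h2) * (h2 - lo))
    if d2 >= 0:
        return float("nan")
    return float(1.0 / math.sqrt(-d2))


def _prepare(spec: PolygenicModelSpec, data: pd.DataFrame,
             extra: tuple[str, ...] = (), min_rows: int = 10):
    """Listwise-delete rows, align with the kinship matrix, build X."""
    cols = [spec.trait, *spec.covariates, *extra]
    if "id" in data.columns:
        data = data.set_index(data["id"].astype(str))
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"phenotype table lacks columns: {missing}")
    known = [i for i in data.index if i in set(spec.kinship.ids)]
    sub = data.loc[known, cols].apply(pd.to_numeric, errors="coerce").dropna()
    y = sub[spec.trait].to_numpy(dtype=float)
    if len(sub) and np.ptp(y) == 0:
        raise ValueError("trait is constant")
    if len(sub) < min_rows:
        raise ValueError(f"only {len(sub)} usable phenotyped individuals")
    names = ["intercept", *spec.covariates, *extra]
    X = np.column_stack(
        [np.ones(len(sub))]
        + [sub[c].to_numpy(dtype=float) for c in (*spec.covariates, *extra)]
    )
    A = spec.kinship.submatrix(list(sub.index)).additive_relationship()
    return _RotatedModel(y, X, names, A)


def _fit(model: _RotatedModel, method: str = "reml") -> PolygenicFit:
    h2, ll, flags = _maximize_h2(model, method)
    _, beta, sigma2, XtWX = model.profile(h2, method)
    beta_cov = sigma2 * np.linalg.inv(XtWX)
    beta_se = np.sqrt(np.diag(beta_cov))
    h2_se = (float("nan") if "boundary" in flags
             else _h2_standard_error(model, h2, method))
    return PolygenicFit(
        beta={nm: (float(b), float(se))
              for nm, b, se in zip(model.names, beta, beta_se)},
        sigma2_g=float(h2 * sigma2),
        sigma2_e=float((1.0 - h2) * sigma2),
        h2=h2,
        h2_se=h2_se,
        loglik=ll,
        n=model.n,
        flags=tuple(flags),
    )


def fit_polygenic(spec: PolygenicModelSpec, data: pd.DataFrame,
                  method: str = "reml") -> PolygenicFit:
    """Maximize the polygenic model for one trait.

    ``data`` is a phenotype table indexed by (or containing) individual
    ids; rows with any missing model column are dropped before fitting.
    ``method`` selects the variance-component criterion: restricted
    likelihood (``"reml"``, default — unbiased to first order in the
    fixed-effect count) or ordinary likelihood (``"ml"``).  The reported
    ``loglik`` is that of the chosen criterion.
    """
    return _fit(_prepare(spec, data), method)


def lrt_covariate(spec: PolygenicModelSpec, data: pd.DataFrame,
                  covariate: str) -> float:
    """P-value of the likelihood-ratio test that a covariate's mean
    effect is zero (chi-square with 1 df, interior parameter).

    Both fits are ordinary-ML on identical rows: restricted likelihoods
    are not comparable between models with different fixed effects.
    """
    if covariate not in spec.covariates:
        raise ValueError(f"{covariate!r} not among model covariates")
    try:
        model = _prepare(spec, data)
    except CollinearityError:
        # if the design is singular only because of the tested covariate
        # (e.g. an identically-zero column), constraining it changes
        # nothing: the statistic is 0 by construction
        reduced = PolygenicModelSpec(
            spec.trait,
            tuple(c for c in spec.covariates if c != covariate),
            spec.kinship,
        )
        _prepare(reduced, data)  # re-raises if still singular
        return 1.0
    full = _fit(model, "ml")
    null = _fit(model.drop(covariate), "ml")
    lam = max(0.0, 2.0 * (full.loglik - null.loglik))
    return float(stats.chi2.sf(lam, df=1))


def lrt_heritability(spec: PolygenicModelSpec, data: pd.DataFrame,
                     method: str = "reml") -> float:
    """P-value of the test that h2 = 0.

    Full and null models share the same fixed effects, so the likelihood
    ratio may be formed on either criterion; the default follows the
    estimation default (restricted likelihood), which is both valid here
    and markedly more powerful than the ordinary-ML ratio at these
    sample sizes.  The genetic variance sits on the boundary of its
    parameter space under the null, so the statistic is referred to the
    mixture 0.5*chi2(0) + 0.5*chi2(1); a zero statistic gives p = 0.5.
    """
    model = _prepare(spec, data)
    full = _fit(model, method)
    ll0 = model.loglik(0.0, method)
    lam = max(0.0, 2.0 * (full.loglik - ll0))
    if lam == 0.0:
        return 0.5
    return float(0.5 * stats.chi2.sf(lam, df=1))


def covariate_association(spec: PolygenicModelSpec, data: pd.DataFrame,
                          predictor: str,
                          method: str = "reml") -> AssociationRow:
    """Association of a predictor with the trait inside the kinship model.

    The predictor is added as one more covariate; its effect size is
    reported as R2 = beta^2 * Var(predictor) / Var(trait), the signed
    correlation r = sign(beta) * sqrt(R2), and the P-value of the
    likelihood-ratio test (ordinary ML) that beta = 0.
    """
    model = _prepare(spec, data, extra=(predictor,))
    full = _fit(model, method)
    full_ml = full if method == "ml" else _fit(model, "ml")
    null_ml = _fit(model.drop(predictor), "ml")
    lam = max(0.0, 2.0 * (full_ml.loglik - null_ml.loglik))
    p = float(stats.chi2.sf(lam, df=1))
    b = full.beta[predictor][0]
    jx = model.names.index(predictor)
    # variances on the analysis rows, in the original (unrotated) basis:
    # the rotation is orthogonal, so sample variances are preserved up to
    # the mean term, which we remove explicitly.
    x = model.X[:, jx]
    y = model.y
    ones_rot = model.X[:, model.names.index("intercept")]
    var_x = _rotated_variance(x, ones_rot, model.n)
    var_y = _rotated_variance(y, ones_rot, model.n)
    r2 = float(b * b * var_x / var_y)
    r = float(math.copysign(math.sqrt(r2), b))
    return AssociationRow(predictor, r2, r, p, model.n, float(b))


def _rotated_variance(v: np.ndarray, ones_rot: np.ndarray, n: int) -> float:
    """Sample variance of a vector given only its orthogonal rotation.

    For rotated data U'v the mean of the original vector is
    (U'1 . U'v)/n and the sum of squares is preserved, so
    var = (||v||^2 - n*mean^2)/(n-1).
    """
    mean = float(ones_rot @ v) / n
    ss = float(v @ v) - n * mean * mean
    return ss / (n - 1)


def naive_association(data: pd.DataFrame, trait: str, predictor: str) -> AssociationRow:
    """Plain Pearson correlation ignoring kinship, for comparison with
    the model-based association."""
    sub = data[[trait, predictor]].apply(pd.to_numeric, errors="coerce").dropna()
    r, p = stats.pearsonr(sub[predictor], sub[trait])
    return AssociationRow(predictor, float(r * r), float(r), float(p),
                          len(sub), float(r))
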