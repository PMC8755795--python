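"""Parametric distribution fitting with goodness-of-fit model selection.

Replaces the spreadsheet-suite "batch fit" step of probabilistic exposure
assessment: each candidate family is fit by maximum likelihood (method of
moments for the discrete geometric family), scored by the Anderson–Darling
statistic on the fitted CDF, a chi-square statistic on equiprobable cells,
and the Kolmogorov–Smirnov distance, and the family with the smallest
Anderson–Darling statistic wins (ties: smaller chi-square, then fewer
parameters).

Family notes
------------
* ``lognormal`` is the 3-parameter form with a free location shift.
* ``beta``, ``uniform`` and ``triangular`` are rescaled to the observed
  range padded by 1% on each side, avoiding boundary likelihood
  singularities.
* ``gumbel_max`` is the maximum extreme-value distribution.
* ``logistic`` ("Logic" in spreadsheet nomenclature) and the
  location-scale ``student_t`` carry mean/midpoint and scaling parameters.
* ``geometric`` is fit by method of moments on rounded day counts and is
  sampled as a discrete variate clipped to the physical support [1, 365].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDataError,
    FitError,
    InsufficientDataError,
    NoFitError,
)

__all__ = [
    "FittedDistribution",
    "GOFStats",
    "fit_family",
    "gof",
    "select_best",
    "DEFAULT_FAMILIES",
    "MIN_FIT_SIZE",
]

#: Union of the families named anywhere in the study's fitting workflow.
DEFAULT_FAMILIES = (
    "normal",
    "lognormal",
    "beta",
    "gamma",
    "weibull",
    "gumbel_max",
    "logistic",
    "student_t",
    "geometric",
    "uniform",
    "triangular",
)

MIN_FIT_SIZE = 15
_BOUND_PAD = 0.01  # fraction of the data range added to each bounded-family edge
_GEOM_SUPPORT = (1.0, 365.0)


@dataclass(frozen=True)
class GOFStats:
    anderson_darling: float
    chi_square: float
    ks: float


@dataclass
class FittedDistribution:
    """A fitted family: named parameters, frozen sampler, support and GOF."""

    family: str
    params: dict[str, float]
    dist: object  # frozen scipy.stats distribution
    support: tuple[float, float]
    n: int
    gof: GOFStats | None = None
    discrete: bool = False

    @property
    def n_params(self) -> int:
        return len(self.params)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = np.asarray(
            self.dist.rvs(size=size, random_state=rng), dtype=float
        )
        lo, hi = self.support
        if np.isfinite(lo) or np.isfinite(hi):
            draws = np.clip(draws, lo, hi)
        return draws

    def cdf(self, x):
        return self.dist.cdf(x)

    def ppf(self, q):
        return self.dist.ppf(q)

    def mean(self) -> float:
        return float(self.dist.mean())


# ---------------------------------------------------------------------------
# Family-specific fitters
# ---------------------------------------------------------------------------


def _padded_range(data: np.ndarray) -> tuple[float, float]:
    lo, hi = float(data.min()), float(data.max())
    pad = _BOUND_PAD * (hi - lo)
    return lo - pad, hi + pad


def _fit_normal(data):
    loc, scale = stats.norm.fit(data)
    return {"mean": loc, "sd": scale}, stats.norm(loc, scale), (-np.inf, np.inf), False


def _fit_lognormal(data):
    s, loc, scale = stats.lognorm.fit(data)
    params = {"meanlog": float(np.log(scale)), "sdlog": s, "location": loc}
    return params, stats.lognorm(s, loc, scale), (loc, np.inf), False


def _fit_beta(data):
    lo, hi = _padded_range(data)
    a, b, loc, scale = stats.beta.fit(data, floc=lo, fscale=hi - lo)
    params = {"alpha": a, "beta": b, "lo": lo, "hi": hi}
    return params, stats.beta(a, b, loc, scale), (lo, hi), False


def _fit_gamma(data):
    a, loc, scale = stats.gamma.fit(data)
    return (
        {"shape": a, "location": loc, "scale": scale},
        stats.gamma(a, loc, scale),
        (loc, np.inf),
        False,
    )


def _fit_weibull(data):
    c, loc, scale = stats.weibull_min.fit(data)
    return (
        {"shape": c, "location": loc, "scale": scale},
        stats.weibull_min(c, loc, scale),
        (loc, np.inf),
        False,
    )


def _fit_gumbel_max(data):
    loc, scale = stats.gumbel_r.fit(data)
    return (
        {"mode": loc, "scale": scale},
        stats.gumbel_r(loc, scale),
        (-np.inf, np.inf),
        False,
    )


def _fit_logistic(data):
    loc, scale = stats.logistic.fit(data)
    return (
        {"mean": loc, "scaling": scale},
        stats.logistic(loc, scale),
        (-np.inf, np.inf),
        False,
    )


def _fit_student_t(data):
    df, loc, scale = stats.t.fit(data)
    return (
        {"midpoint": loc, "scaling": scale, "freedom": df},
        stats.t(df, loc, scale),
        (-np.inf, np.inf),
        False,
    )


def _fit_uniform(data):
    lo, hi = _padded_range(data)
    return {"lo": lo, "hi": hi}, stats.uniform(lo, hi - lo), (lo, hi), False


def _fit_triangular(data):
    lo, hi = _padded_range(data)
    c, loc, scale = stats.triang.fit(data, floc=lo, fscale=hi - lo)
    params = {"lo": lo, "mode": lo + c * (hi - lo), "hi": hi}
    return params, stats.triang(c, loc, scale), (lo, hi), False


def _fit_geometric(data):
    counts = np.round(data)
    if np.any(counts < 1):
        raise FitError("geometric family requires day counts ≥ 1")
    p = 1.0 / float(counts.mean())  # method of moments on day counts
    return {"p": p}, stats.geom(p), _GEOM_SUPPORT, True


_FITTERS: dict[str, Callable] = {
    "normal": _fit_normal,
    "lognormal": _fit_lognormal,
    "beta": _fit_beta,
    "gamma": _fit_gamma,
    "weibull": _fit_weibull,
    "gumbel_max": _fit_gumbel_max,
    "logistic": _fit_logistic,
    "student_t": _fit_student_t,
    "geometric": _fit_geometric,
    "uniform": _fit_uniform,
    "triangular": _fit_triangular,
}


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def _anderson_darling(data: np.ndarray, cdf: Callable) -> float:
    x = np.sort(data)
    n = len(x)
    u = np.clip(cdf(x), 1e-12, 1.0 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))


def _chi_square(data: np.ndarray, cdf: Callable) -> float:
    """Chi-square on equiprobable cells of the fitted CDF transform."""
    n = len(data)
    k = max(5, n // 5)
    u = np.clip(cdf(data), 0.0, np.nextafter(1.0, 0.0))
    observed = np.bincount((u * k).astype(int), minlength=k)
    expected = n / k
    return float(np.sum((observed - expected) ** 2) / expected)


def gof(data: np.ndarray, fitted: FittedDistribution) -> GOFStats:
    """Anderson–Darling, chi-square and KS statistics of a fit."""
    data = np.asarray(data, dtype=float)
    ad = _anderson_darling(data, fitted.cdf)
    chi2 = _chi_square(data, fitted.cdf)
    ks = float(stats.kstest(data, fitted.cdf).statistic)
    return GOFStats(anderson_darling=ad, chi_square=chi2, ks=ks)


# ---------------------------------------------------------------------------
# Fitting and selection
# ---------------------------------------------------------------------------


def _validate_sample(data) -> np.ndarray:
    data = np.asarray(data, dtype=float).ravel()
    if data.size < MIN_FIT_SIZE:
        raise InsufficientDataError(
            f"need at least {MIN_FIT_SIZE} observations to fit, got {data.size}"
        )
    if not np.all(np.isfinite(data)):
        raise FitError("data contain non-finite values")
    if np.ptp(data) == 0:
        raise DegenerateDataError("zero-variance data cannot be fit")
    return data


def fit_family(data, family: str) -> FittedDistribution:
    """Fit one named family and attach its goodness-of-fit statistics."""
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; choose from {DEFAULT_FAMILIES}")
    data = _validate_sample(data)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            params, dist, support, discrete = _FITTERS[family](data)
        except FitError:
            raise
        except Exception as exc:  # scipy fit failures become FitError
            raise FitError(f"{family}: fit failed ({exc})") from exc
    if not all(np.isfinite(v) for v in params.values()):
        raise FitError(f"{family}: non-finite fitted parameters {params}")
    fitted = FittedDistribution(
        family=family,
        params=params,
        dist=dist,
        support=support,
        n=int(data.size),
        discrete=discrete,
    )
    stats_ = gof(data, fitted)
    if not np.isfinite(stats_.anderson_darling):
        raise FitError(f"{family}: degenerate likelihood (non-finite GOF)")
    fitted.gof = stats_
    return fitted


def select_best(
    data, candidates: Sequence[str] | None = None
) -> FittedDistribution:
    """Fit every candidate family and return the Anderson–Darling winner.

    Ties are broken by the chi-square statistic, then by fewer parameters.
    Selection is invariant to candidate order up to those tie-breaks.
    """
    candidates = tuple(candidates) if candidates else DEFAULT_FAMILIES
    data = _validate_sample(data)
    fits: list[FittedDistribution] = []
    diagnostics: dict[str, str] = {}
    for family in candidates:
        try:
            fits.append(fit_family(data, family))
        except (FitError, InsufficientDataError, DegenerateDataError) as exc:
            diagnostics[family] = str(exc)
    if not fits:
        raise NoFitError(
            f"no candidate family could be fit (tried {list(candidates)})",
            diagnostics=diagnostics,
        )
    fits.sort(
        key=lambda f: (f.gof.anderson_darling, f.gof.chi_square, f.n_params, f.family)
    )
    return fits[0]
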