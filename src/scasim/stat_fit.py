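"""Fitting and sampling the three target statistics of a reference matrix.

The simulator matches three summary statistics of real data:

* library size — total counts per cell (log-transformed before fitting),
* cell non-zero proportion — fraction of peaks detected per cell
  (log-transformed before fitting),
* peak summation — total counts per peak.

In pseudo-cell-type mode each cell type gets its own models: two-component
Gaussian mixtures for the two log-scale cell statistics and a long-tailed
discrete distribution (the zero-shifted log-series "log-variant" by default)
for peak summation. In discrete/continuous mode a single Gaussian KDE per
statistic is fit on the whole matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats
from sklearn.mixture import GaussianMixture

from .exceptions import FitError, ParameterError, ValidationError
from .io_formats import CountMatrix

__all__ = [
    "StatTriple",
    "GMM2Model",
    "DiscreteFit",
    "KDESampler",
    "StatModels",
    "compute_statistics",
    "fit_gmm2",
    "fit_discrete",
    "select_best_discrete",
    "fit_kde",
    "build_stat_models",
    "DISCRETE_FAMILIES",
]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class StatTriple:
    lib_size: np.ndarray  # per cell
    nonzero_prop: np.ndarray  # per cell, in [0, 1]
    peak_sum: np.ndarray  # per peak

    def __post_init__(self) -> None:
        if self.lib_size.sum() != self.peak_sum.sum():
            raise ValidationError("lib_size and peak_sum totals disagree")


def compute_statistics(cm: CountMatrix) -> StatTriple:
    """Library size, non-zero proportion per cell and summation per peak."""
    if cm.npeak == 0 or cm.ncell == 0:
        raise ValidationError("empty count matrix")
    counts = cm.counts
    lib = np.asarray(counts.sum(axis=0)).ravel()
    nnz = np.asarray((counts > 0).sum(axis=0)).ravel()
    peak = np.asarray(counts.sum(axis=1)).ravel()
    return StatTriple(
        lib_size=lib.astype(np.int64),
        nonzero_prop=nnz / cm.npeak,
        peak_sum=peak.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture
# ---------------------------------------------------------------------------

@dataclass
class GMM2Model:
    """Two-component univariate Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(2, size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        parts = (
            np.log(self.weights)
            + scipy.stats.norm.logpdf(x, self.means, self.sds)
        )
        return scipy.special.logsumexp(parts, axis=-1)


def fit_gmm2(values: np.ndarray, random_state: int = 0) -> GMM2Model:
    """EM fit of a 2-component mixture (10 restarts, tol 1e-6, <=500 iters)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"need >= 10 finite values, got {x.size}")
    if np.unique(x).size < 2:
        raise FitError("degenerate data: fewer than 2 distinct values")
    gm = GaussianMixture(
        n_components=2,
        n_init=10,
        tol=1e-6,
        max_iter=500,
        random_state=random_state,
    ).fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    return GMM2Model(
        weights=gm.weights_[order].copy(),
        means=gm.means_.ravel()[order].copy(),
        sds=np.sqrt(gm.covariances_.ravel()[order]).copy(),
    )


# ---------------------------------------------------------------------------
# Discrete families for peak summation
# ---------------------------------------------------------------------------

@dataclass
class DiscreteFit:
    """A fitted discrete distribution on (a shift of) the non-negative integers.

    Internally the variate is ``scipy_variate + shift`` so families whose
    natural support starts at 1 (log-series, zipf, geometric) can model data
    that include zero.
    """

    family: str
    params: Dict[str, float]
    loglik: float
    ks: float
    shift: int = 0
    _dist: object = field(default=None, repr=False, compare=False)

    def pmf(self, k) -> np.ndarray:
        return self._dist.pmf(np.asarray(k) - self.shift)

    def cdf(self, k) -> np.ndarray:
        return self._dist.cdf(np.asarray(k) - self.shift)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self._dist.rvs(size=n, random_state=rng)) + self.shift


def _discrete_ks(data: np.ndarray, cdf: Callable) -> float:
    """One-sample KS statistic of integer data against a model CDF."""
    support = np.arange(0, int(data.max()) + 1)
    ecdf = np.cumsum(np.bincount(data, minlength=support.size)) / data.size
    return float(np.abs(ecdf - np.asarray(cdf(support))).max())


def _logser_mean(p: float) -> float:
    return -p / ((1.0 - p) * np.log1p(-p))


def _fit_logser_by_mean(target_mean: float) -> float:
    """Solve the log-series MLE mean equation for p (mean is increasing in p)."""
    if target_mean <= 1.0 + 1e-12:
        raise FitError("log-series fit is degenerate: mean <= 1")
    return float(
        scipy.optimize.brentq(
            lambda p: _logser_mean(p) - target_mean, 1e-12, 1.0 - 1e-12, xtol=1e-14
        )
    )


def _finish(family, params, shift, dist, data) -> DiscreteFit:
    loglik = float(np.sum(dist.logpmf(data - shift)))
    fit = DiscreteFit(
        family=family, params=params, loglik=loglik, ks=0.0, shift=shift, _dist=dist
    )
    fit.ks = _discrete_ks(data, fit.cdf)
    return fit


def _fit_logvariant(data: np.ndarray) -> DiscreteFit:
    # zero-shifted log-series: PMF(k; p) = -p^(k+1) / ((k+1) ln(1-p)), k >= 0
    p = _fit_logser_by_mean(data.mean() + 1.0)
    return _finish("logvariant", {"p": p}, -1, scipy.stats.logser(p), data)


def _fit_poisson(data: np.ndarray) -> DiscreteFit:
    lam = float(data.mean())  # closed-form MLE
    return _finish("poisson", {"lam": lam}, 0, scipy.stats.poisson(lam), data)


def _fit_negative_binomial(data: np.ndarray) -> DiscreteFit:
    m = data.mean()
    if m <= 0:
        raise FitError("negative-binomial fit needs a positive mean")

    def nll(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + m)  # profile MLE of p given r
        return -float(np.sum(scipy.stats.nbinom.logpmf(data, r, p)))

    res = scipy.optimize.minimize_scalar(
        nll, bounds=(-6.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise FitError(f"negative-binomial optimizer did not converge: {res.message}")
    r = float(np.exp(res.x))
    p = float(r / (r + m))
    return _finish(
        "negative_binomial", {"r": r, "p": p}, 0, scipy.stats.nbinom(r, p), data
    )


def _fit_geometric(data: np.ndarray) -> DiscreteFit:
    p = float(1.0 / (1.0 + data.mean()))  # closed-form MLE on support {0,1,...}
    return _finish("geometric", {"p": p}, -1, scipy.stats.geom(p), data)


def _fit_zipf(data: np.ndarray) -> DiscreteFit:
    # zero-shifted zipf: data + 1 ~ Zipf(a)
    shifted = data + 1

    def nll(a: float) -> float:
        return -float(np.sum(scipy.stats.zipf.logpmf(shifted, a)))

    res = scipy.optimize.minimize_scalar(
        nll, bounds=(1.0 + 1e-6, 20.0), method="bounded", options={"xatol": 1e-10}
    )
    if not res.success:
        raise FitError(f"zipf optimizer did not converge: {res.message}")
    a = float(res.x)
    return _finish("zipf", {"a": a}, -1, scipy.stats.zipf(a), data)


def _fit_logarithmic(data: np.ndarray) -> DiscreteFit:
    # natural support {1, 2, ...}; the log-variant is its zero-shifted form
    if data.min() < 1:
        raise FitError("logarithmic family has support k >= 1 but data contain 0")
    p = _fit_logser_by_mean(float(data.mean()))
    return _finish("logarithmic", {"p": p}, 0, scipy.stats.logser(p), data)


DISCRETE_FAMILIES: Dict[str, Callable] = {
    "logvariant": _fit_logvariant,
    "poisson": _fit_poisson,
    "negative_binomial": _fit_negative_binomial,
    "geometric": _fit_geometric,
    "zipf": _fit_zipf,
    "logarithmic": _fit_logarithmic,
}


def fit_discrete(values: np.ndarray, family: str) -> DiscreteFit:
    """Maximum-likelihood fit of one discrete family to integer data."""
    if family not in DISCRETE_FAMILIES:
        raise ParameterError(
            f"unknown family {family!r}; choose from {sorted(DISCRETE_FAMILIES)}"
        )
    data = np.asarray(values)
    if data.size < 50:
        raise FitError(f"need >= 50 observations, got {data.size}")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValidationError("discrete fits require integer data")
        data = np.round(data).astype(np.int64)
    if (data < 0).any():
        raise ValidationError("discrete fits require non-negative data")
    return DISCRETE_FAMILIES[family](data.astype(np.int64))


def select_best_discrete(
    values: np.ndarray, families: Sequence[str]
) -> DiscreteFit:
    """Fit several families; return the one with the smallest KS statistic.

    Ties are broken by higher log-likelihood; families that fail to fit are
    skipped (an aggregate error is raised if all fail).
    """
    if len(families) < 2 and len(families) != 1:
        raise ParameterError("provide at least one family")
    fits, errors = [], []
    for fam in families:
        try:
            fits.append(fit_discrete(values, fam))
        except (FitError, ValidationError) as exc:
            errors.append(f"{fam}: {exc}")
    if not fits:
        raise FitError("all discrete fits failed: " + "; ".join(errors))
    return min(fits, key=lambda f: (f.ks, -f.loglik))


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

@dataclass
class KDESampler:
    """Gaussian-KDE sampler (Scott's rule): resample data + bandwidth noise.

    Samples outside ``domain`` are redrawn (up to ``max_attempts`` rounds)
    then projected onto the boundary.
    """

    data: np.ndarray
    bandwidth: float
    domain: tuple = (-np.inf, np.inf)
    max_attempts: int = 100

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.domain
        idx = rng.integers(0, self.data.size, size=n)
        out = self.data[idx] + rng.normal(0.0, self.bandwidth, size=n)
        for _ in range(self.max_attempts):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                return out
            k = int(bad.sum())
            idx = rng.integers(0, self.data.size, size=k)
            out[bad] = self.data[idx] + rng.normal(0.0, self.bandwidth, size=k)
        return np.clip(out, lo, hi)


def fit_kde(values: np.ndarray, domain: tuple = (-np.inf, np.inf)) -> KDESampler:
    """Fit a Gaussian KDE; degenerate (zero-variance) data give a point mass."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"need >= 10 finite values, got {x.size}")
    if np.std(x) == 0:
        warnings.warn("zero-variance data: KDE degenerates to a point mass")
        return KDESampler(data=x, bandwidth=0.0, domain=domain)
    kde = scipy.stats.gaussian_kde(x)  # Scott's rule bandwidth
    return KDESampler(
        data=x, bandwidth=float(np.sqrt(kde.covariance[0, 0])), domain=domain
    )


# ---------------------------------------------------------------------------
# StatModels: the per-mode bundle
# ---------------------------------------------------------------------------

_PROP_FLOOR = 1e-12


@dataclass
class TripleSampler:
    """Samplers for one group's library size, non-zero proportion, peak sum.

    ``model_l`` and ``model_c`` operate on the natural-log scale; the
    convenience methods return values on the original scale with domain
    clamps applied (library size > 0, proportion in (0, 1], peak sum >= 0).
    """

    model_l: object
    model_c: object
    model_p: object
    backend: str  # "gmm2+discrete" or "kde"
    peak_log1p: bool = False  # KDE backend fits peak sums on the log1p scale

    def sample_lib(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.model_l.sample(n, rng))

    def sample_prop(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.clip(np.exp(self.model_c.sample(n, rng)), _PROP_FLOOR, 1.0)

    def sample_peak(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raw = np.asarray(self.model_p.sample(n, rng), dtype=float)
        if self.peak_log1p:
            raw = np.expm1(raw)
        return np.maximum(raw, 0.0)


@dataclass
class StatModels:
    """Fitted statistic models, keyed by cell type or the global key."""

    GLOBAL = "__all__"

    models: Dict[str, TripleSampler]
    mode: str

    def get(self, cell_type: Optional[str] = None) -> TripleSampler:
        key = self.GLOBAL if cell_type is None else cell_type
        return self.models[key]

    @property
    def cell_types(self):
        return [k for k in self.models if k != self.GLOBAL]


def _log_positive(values: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    pos = v > 0
    if not pos.all():
        warnings.warn(
            f"{int((~pos).sum())} cells with zero {what} excluded from the fit"
        )
    return np.log(v[pos])


def build_stat_models(
    cm: CountMatrix,
    mode: str,
    labels: Optional[np.ndarray] = None,
    peak_family: str = "logvariant",
    random_state: int = 0,
) -> StatModels:
    """Fit the statistic models the given simulation mode requires.

    pseudo_cell_type: per cell type, GMM(2) on log library size and log
    non-zero proportion plus a discrete fit on that type's peak summation.
    discrete/continuous: a single global KDE per statistic (labels ignored).
    """
    if mode == "pseudo_cell_type":
        if labels is None:
            if "cell_type" not in cm.cells.columns:
                raise ParameterError("pseudo_cell_type mode requires cell labels")
            labels = cm.cells["cell_type"].to_numpy()
        labels = np.asarray(labels)
        models: Dict[str, TripleSampler] = {}
        for t in pd_unique_stable(labels):
            idx = np.flatnonzero(labels == t)
            if idx.size < 10:
                raise FitError(
                    f"cell type {t!r} has only {idx.size} cells (< 10); "
                    "filter the reference first"
                )
            sub = cm.subset(cell_idx=idx)
            st = compute_statistics(sub)
            models[str(t)] = TripleSampler(
                model_l=fit_gmm2(
                    _log_positive(st.lib_size, "library size"), random_state
                ),
                model_c=fit_gmm2(
                    _log_positive(st.nonzero_prop, "non-zero proportion"),
                    random_state,
                ),
                model_p=fit_discrete(st.peak_sum, peak_family),
                backend="gmm2+discrete",
            )
        return StatModels(models=models, mode=mode)

    if mode in ("discrete", "continuous"):
        st = compute_statistics(cm)
        models = {
            StatModels.GLOBAL: TripleSampler(
                model_l=fit_kde(_log_positive(st.lib_size, "library size")),
                model_c=fit_kde(
                    _log_positive(st.nonzero_prop, "non-zero proportion"),
                    domain=(-np.inf, 0.0),
                ),
                # log1p scale: peak sums are heavy-tailed and bounded at 0, so
                # a raw-scale Gaussian KDE would inflate the total count mass
                model_p=fit_kde(
                    np.log1p(np.asarray(st.peak_sum, dtype=float)),
                    domain=(0.0, np.inf),
                ),
                backend="kde",
                peak_log1p=True,
            )
        }
        return StatModels(models=models, mode=mode)

    raise ParameterError(f"unknown mode {mode!r}")


def pd_unique_stable(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]
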