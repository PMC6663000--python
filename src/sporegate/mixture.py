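"""Gaussian mixture models fitted by expectation-maximisation.

Two uses in the pipeline: a univariate g=2 mixture on a stained channel to
score how well cells and spores separate, and a g=3 mixture on the
(SSC, FL1) plane to cluster vegetative cells, endospore-containing mother
cells and free spores.

Covariance structure is the most flexible choice: unequal variances in one
dimension, full per-component covariance matrices in d > 1. Initialisation
is deterministic: quantile midpoints in one dimension, seeded k-means on
lexicographically sorted rows otherwise, so fits are reproducible and
invariant to row order. The log-likelihood trace of every fit is recorded;
EM guarantees it is non-decreasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DegeneracyError, SampleSizeError, ValidationError

__all__ = ["GaussianComponent", "MixtureModel", "fit_gmm", "mixture_density"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: weight, mean vector, covariance matrix."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        object.__setattr__(
            self, "covariance", np.atleast_2d(np.asarray(self.covariance, float))
        )
        if not (0.0 < self.weight <= 1.0):
            raise ValidationError(f"component weight must be in (0, 1], got {self.weight}")

    @property
    def d(self) -> int:
        return self.mean.shape[0]

    @property
    def sigma(self) -> float:
        """Standard deviation (univariate components only)."""
        if self.d != 1:
            raise ValidationError("sigma is defined for univariate components only")
        return float(np.sqrt(self.covariance[0, 0]))

    def log_density(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValidationError(f"expected {self.d}-dim points, got {X.shape[1]}")
        L = np.linalg.cholesky(self.covariance)
        z = np.linalg.solve(L, (X - self.mean).T)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return -0.5 * (self.d * _LOG2PI + logdet + np.sum(z * z, axis=0))


@dataclass(frozen=True)
class MixtureModel:
    """A fitted g-component Gaussian mixture.

    Components are sorted by ascending first-dimension mean, so in the
    stain-separation fit component 0 is the low-fluorescence (LP) and
    component 1 the high-fluorescence (HP) population.
    """

    g: int
    components: tuple[GaussianComponent, ...]
    log_likelihood: float
    n_iter: int
    converged: bool
    dims: tuple[str, ...] = ()
    ll_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self):
        if len(self.components) != self.g:
            raise ValidationError(
                f"g={self.g} but {len(self.components)} components given"
            )
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"component weights sum to {total}, not 1")

    @property
    def d(self) -> int:
        return self.components[0].d

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.vstack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.covariance for c in self.components])

    # -- inference ---------------------------------------------------------
    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        """(n, g) matrix of log(weight_k * N(x; mu_k, Sigma_k))."""
        X = self._as_matrix(X)
        return np.column_stack(
            [np.log(c.weight) + c.log_density(X) for c in self.components]
        )

    def density(self, x) -> np.ndarray | float:
        """Mixture density sum_k weight_k N(x; mu_k, Sigma_k)."""
        scalar = np.ndim(x) == 0 or (self.d > 1 and np.ndim(x) == 1)
        out = np.exp(logsumexp(self.component_log_densities(x), axis=1))
        return float(out[0]) if scalar else out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """(n, g) responsibilities."""
        log_wd = self.component_log_densities(X)
        return np.exp(log_wd - logsumexp(log_wd, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard maximum-posterior component index per event."""
        return np.argmax(self.component_log_densities(X), axis=1)

    def _as_matrix(self, x) -> np.ndarray:
        arr = np.asarray(x, dtype=float)
        if self.d == 1:
            arr = arr.reshape(-1, 1)
        elif arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.ndim != 2 or arr.shape[1] != self.d:
            raise ValidationError(f"expected points of dimension {self.d}, got {arr.shape}")
        return arr

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "g": self.g,
            "dims": list(self.dims),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureModel":
        comps = tuple(
            GaussianComponent(weight=w, mean=m, covariance=c)
            for w, m, c in zip(
                payload["weights"], payload["means"], payload["covariances"]
            )
        )
        return cls(
            g=payload["g"],
            components=comps,
            log_likelihood=payload["log_likelihood"],
            n_iter=payload["n_iter"],
            converged=payload["converged"],
            dims=tuple(payload.get("dims", ())),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        return cls.from_dict(json.loads(text))


def _init_parameters(X: np.ndarray, g: int, seed: int):
    """Deterministic starting point: quantile midpoints (d=1) or k-means."""
    n, d = X.shape
    if d == 1:
        qs = (np.arange(g) + 0.5) / g
        means = np.quantile(X[:, 0], qs).reshape(-1, 1)
        var = max(np.var(X[:, 0]), np.finfo(float).tiny)
        covs = np.tile(np.array([[var]]), (g, 1, 1))
        weights = np.full(g, 1.0 / g)
        return weights, means, covs
    from sklearn.cluster import KMeans

    order = np.lexsort(X.T[::-1])  # row-order invariance for the init
    km = KMeans(n_clusters=g, random_state=seed, n_init=10).fit(X[order])
    means = km.cluster_centers_
    labels = km.labels_
    weights = np.bincount(labels, minlength=g).astype(float)
    weights = np.maximum(weights, 1.0)
    weights /= weights.sum()
    overall = np.atleast_2d(np.cov(X, rowvar=False, ddof=0))
    covs = np.tile(overall, (g, 1, 1))
    return weights, means, covs


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    z = np.linalg.solve(L, (X - mean).T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG2PI + logdet + np.sum(z * z, axis=0))


def fit_gmm(
    values: np.ndarray,
    g: int,
    init: str = "auto",
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    dims: tuple[str, ...] = (),
    var_floor_frac: float = 1e-6,
) -> MixtureModel:
    """Fit a g-component Gaussian mixture by EM.

    Parameters
    ----------
    values
        (n,) vector or (n, d) matrix of (transformed) signal values.
    g
        Number of components.
    init
        ``"auto"`` (quantile midpoints in 1-D, seeded k-means otherwise);
        kept as a parameter for forward compatibility.
    tol
        Convergence threshold on the relative log-likelihood change.
    max_iter
        Iteration cap; the fit is flagged unconverged if reached.
    seed
        Seed for the k-means initialisation (no other randomness is used).

    Raises
    ------
    SampleSizeError
        If ``n <= g * (d + 1)``.
    DegeneracyError
        If a component collapses onto the variance floor
        (``var_floor_frac`` times the average per-dimension data variance).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValidationError(f"values must be 1-D or 2-D, got shape {X.shape}")
    n, d = X.shape
    if g < 1:
        raise ValidationError(f"g must be >= 1, got {g}")
    if n <= g * (d + 1):
        raise SampleSizeError(f"need more than {g * (d + 1)} events to fit g={g}, got {n}")
    if not tol > 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    if init not in ("auto", "quantile", "kmeans"):
        raise ValidationError(f"unknown init strategy {init!r}")

    floor = var_floor_frac * float(np.mean(np.var(X, axis=0)))
    floor = max(floor, np.finfo(float).tiny)

    if g == 1:  # closed form: no EM needed
        mean = X.mean(axis=0)
        cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=0))
        ll = float(np.sum(_log_gaussian(X, mean, cov)))
        comp = GaussianComponent(weight=1.0, mean=mean, covariance=cov)
        return MixtureModel(
            g=1, components=(comp,), log_likelihood=ll, n_iter=0,
            converged=True, dims=tuple(dims), ll_trace=(ll,),
        )

    weights, means, covs = _init_parameters(X, g, seed)

    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_wd = np.column_stack(
            [np.log(weights[k]) + _log_gaussian(X, means[k], covs[k]) for k in range(g)]
        )
        log_norm = logsumexp(log_wd, axis=1)
        ll = float(np.sum(log_norm))
        trace.append(ll)
        resp = np.exp(log_wd - log_norm[:, None])

        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < d + 1):
            raise DegeneracyError(
                f"component collapsed: effective size {nk.min():.2f} < {d + 1}"
            )
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        new_covs = np.empty_like(covs)
        for k in range(g):
            diff = X - means[k]
            cov_k = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            eigvals = np.linalg.eigvalsh(cov_k)
            if eigvals.min() < floor:
                raise DegeneracyError(
                    f"component {k} variance hit the floor "
                    f"(min eigenvalue {eigvals.min():.3e} < {floor:.3e}); "
                    "data may contain repeated values or g may be too large"
                )
            new_covs[k] = cov_k
        covs = new_covs

        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(ll):
            converged = True
            break
        prev_ll = ll

    order = np.argsort(means[:, 0], kind="stable")
    comps = tuple(
        GaussianComponent(weight=float(weights[k]), mean=means[k], covariance=covs[k])
        for k in order
    )
    return MixtureModel(
        g=g,
        components=comps,
        log_likelihood=trace[-1],
        n_iter=n_iter,
        converged=converged,
        dims=tuple(dims),
        ll_trace=tuple(trace),
    )


def mixture_density(model: MixtureModel, x) -> np.ndarray | float:
    """Evaluate the fitted mixture density at ``x`` (scalar, vector or matrix)."""
    return model.density(x)
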