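"""Agglomerate (doublet) exclusion via robust bivariate-normal gating.

Doublets ride through the flow cell as one event with roughly additive pulse
area/height but an inflated pulse width, so they separate from singlets on
the height/width plane. For each configured channel pair (FSC-H/FSC-W and
SSC-H/SSC-W by default) a bivariate normal is fitted robustly with the
minimum covariance determinant (MCD) estimator and events beyond a
Mahalanobis-distance cutoff are flagged.

The MCD estimator minimises det(cov) over subsets of h points (half the data
by default), which is immune to the doublets it is meant to find. The raw
best-subset covariance systematically underestimates the scatter of the
clean data; following the standard covMcd recipe, the returned estimate is
the raw one multiplied by the asymptotic consistency factor, then refined by
a one-step reweighting. ``scale_factor`` multiplies the final covariance and
defaults to 1 (no extra scaling of the gating ellipse).

By default the pair channels are asinh-transformed before fitting: pulse
signals are near log-normally distributed and the MCD model assumes
elliptical symmetry, so fitting on the transformed scale keeps the
false-exclusion rate of genuine singlets at its nominal level. Set
``asinh_pairs=False`` to gate on raw channel values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegeneracyError, SampleSizeError, ValidationError
from .events import EventTable

__all__ = [
    "RobustEstimate",
    "SingletMask",
    "fit_mcd",
    "exclude_agglomerates",
    "mahalanobis_distance",
    "consistency_factor",
    "DEFAULT_PAIRS",
    "DEFAULT_CUTOFF",
]

#: Channel pairs gated by default.
DEFAULT_PAIRS = (("FSC-H", "FSC-W"), ("SSC-H", "SSC-W"))
#: Default cutoff: sqrt of the chi-squared 0.975 quantile with 2 df.
DEFAULT_CUTOFF = "chi2_0.975"

_EXHAUSTIVE_LIMIT = 30_000  # max number of h-subsets to enumerate exactly
_SEARCH_MAX_N = 5_000  # subset-search sample size for very large n


@dataclass(frozen=True)
class RobustEstimate:
    """Robust location/scatter of one channel pair.

    ``covariance`` is the consistency-corrected, reweighted estimate
    (multiplied by ``scale_factor``); ``raw_covariance`` is the plain sample
    covariance of the determinant-minimising h-subset, kept for objective
    checks.
    """

    center: np.ndarray
    covariance: np.ndarray
    support_size: int
    scale_factor: float
    raw_center: np.ndarray
    raw_covariance: np.ndarray
    raw_determinant: float
    n: int

    def distances(self, points: np.ndarray) -> np.ndarray:
        """Mahalanobis distances of ``points`` to (center, covariance)."""
        return mahalanobis_distance(points, self.center, self.covariance)


@dataclass(frozen=True)
class SingletMask:
    """Boolean keep-mask plus the per-pair robust fits that produced it."""

    keep: np.ndarray
    pair_estimates: Mapping[str, RobustEstimate]
    cutoff: float

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.keep))


def mahalanobis_distance(
    points: np.ndarray, center: np.ndarray, covariance: np.ndarray
) -> np.ndarray:
    diff = np.atleast_2d(points) - center
    try:
        L = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError("covariance is not positive definite") from exc
    z = np.linalg.solve(L, diff.T)
    return np.sqrt(np.sum(z * z, axis=0))


def consistency_factor(alpha: float, d: int) -> float:
    """Asymptotic factor making a (1-alpha)-trimmed normal covariance unbiased.

    For an h-subset MCD fit use ``alpha = h/n``; for a reweighting step that
    keeps points inside the chi2(q) ellipse use ``alpha = q``.
    """
    q = stats.chi2.ppf(alpha, d)
    return alpha / stats.chi2.cdf(q, d + 2)


def _subset_stats(X: np.ndarray, idx: np.ndarray):
    sub = X[idx]
    center = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sign, logdet = np.linalg.slogdet(cov)
    det = sign * np.exp(logdet) if sign > 0 else 0.0
    return center, cov, det


def _c_step(X: np.ndarray, center: np.ndarray, cov: np.ndarray, h: int):
    d2 = mahalanobis_distance(X, center, cov)
    idx = np.argpartition(d2, h - 1)[:h]
    return _subset_stats(X, idx), np.sort(idx)


def _c_steps_to_convergence(X, center, cov, det, h, max_steps=200):
    support = None
    for _ in range(max_steps):
        if det <= 0 or not np.isfinite(det):
            break
        (center2, cov2, det2), support2 = _c_step(X, center, cov, h)
        if det2 <= 0 or not np.isfinite(det2):
            center, cov, det, support = center2, cov2, det2, support2
            break
        if support is not None and np.array_equal(support2, support):
            break
        converged = det2 >= det * (1 - 1e-12)
        center, cov, det, support = center2, cov2, det2, support2
        if converged:
            break
    return center, cov, det, support


def fit_mcd(
    points: np.ndarray,
    h: int | None = None,
    scale_factor: float = 1.0,
    seed: int = 0,
    n_trials: int = 500,
    n_best: int = 10,
    method: str = "auto",
) -> RobustEstimate:
    """Minimum covariance determinant fit of location and scatter.

    Parameters
    ----------
    points
        (n, d) data matrix.
    h
        Subset size; default ``floor((n + d + 1) / 2)`` ("half of all data
        points"). Must satisfy ``floor((n+d+1)/2) <= h <= n``.
    scale_factor
        Multiplier applied to the final covariance (default 1).
    seed
        Seed for the random subset search; the fit is deterministic given it.
    method
        ``"auto"`` (exhaustive when at most ~30000 h-subsets exist, FAST-MCD
        otherwise), ``"exhaustive"`` or ``"fast"``.

    Notes
    -----
    The exhaustive path enumerates all h-subsets and returns the global
    determinant minimum exactly. The FAST-MCD search uses random
    (d+1)-point starts, two concentration (C-) steps each, then full
    refinement of the best candidates. For n > 5000 the search runs on a
    random sub-sample and the winner is refined by C-steps on the full data.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"points must be 2-D, got shape {X.shape}")
    n, d = X.shape
    if n < 2 * (d + 1):
        raise SampleSizeError(f"need at least {2 * (d + 1)} points for MCD, got {n}")
    h_min = (n + d + 1) // 2
    if h is None:
        h = h_min
    h = int(h)
    if not (h_min <= h <= n):
        raise ValidationError(f"h must be in [{h_min}, {n}], got {h}")
    if not scale_factor > 0:
        raise ValidationError(f"scale_factor must be > 0, got {scale_factor}")
    if method not in ("auto", "exhaustive", "fast"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "exhaustive" and comb(n, h) > _EXHAUSTIVE_LIMIT:
        raise ValidationError(
            f"exhaustive enumeration of C({n},{h}) subsets is not feasible"
        )
    exhaustive = method == "exhaustive" or (
        method == "auto" and comb(n, h) <= _EXHAUSTIVE_LIMIT
    )

    rng = np.random.default_rng(seed)

    if h == n:
        center, cov, det = _subset_stats(X, np.arange(n))
        support = np.arange(n)
    elif exhaustive:
        best = None
        for idx in combinations(range(n), h):
            c, S, det = _subset_stats(X, np.asarray(idx))
            if det > 0 and (best is None or det < best[2]):
                best = (c, S, det, np.asarray(idx))
        if best is None:
            raise DegeneracyError(
                "every h-subset has a singular covariance (collinear or "
                "zero-variance data)"
            )
        center, cov, det, support = best
    else:
        if n > _SEARCH_MAX_N:
            search_idx = rng.choice(n, size=_SEARCH_MAX_N, replace=False)
            Xs = X[search_idx]
            hs = max((len(Xs) + d + 1) // 2, int(round(h / n * len(Xs))))
        else:
            Xs, hs = X, h
        ns = len(Xs)
        candidates = []
        for _ in range(n_trials):
            idx = rng.choice(ns, size=d + 1, replace=False)
            c, S, det = _subset_stats(Xs, idx)
            # grow degenerate starting subsets until the covariance is regular
            while (det <= 0 or not np.isfinite(det)) and len(idx) < hs:
                extra = rng.choice(ns, size=d + 1, replace=False)
                idx = np.unique(np.concatenate([idx, extra]))
                c, S, det = _subset_stats(Xs, idx)
            if det <= 0 or not np.isfinite(det):
                continue
            for _ in range(2):  # two cheap concentration steps per start
                (c, S, det), _sup = _c_step(Xs, c, S, hs)
                if det <= 0 or not np.isfinite(det):
                    break
            if det > 0 and np.isfinite(det):
                candidates.append((det, c, S))
        if not candidates:
            raise DegeneracyError(
                "MCD subset search failed: data may be collinear or constant"
            )
        candidates.sort(key=lambda t: t[0])
        refined = []
        for det, c, S in candidates[:n_best]:
            c, S, det, _sup = _c_steps_to_convergence(Xs, c, S, det, hs)
            if det > 0 and np.isfinite(det):
                refined.append((det, c, S))
        if not refined:
            raise DegeneracyError("MCD refinement collapsed to a singular fit")
        refined.sort(key=lambda t: t[0])
        det, center, cov = refined[0]
        # final concentration on the full data at the requested h
        center, cov, det, support = _c_steps_to_convergence(X, center, cov, det, h)
        if support is None or det <= 0 or not np.isfinite(det):
            raise DegeneracyError("MCD fit is singular on the full data")

    raw_center, raw_cov, raw_det = center, cov, det
    if raw_det <= 0 or not np.isfinite(raw_det):
        raise DegeneracyError("best MCD subset has a singular covariance")

    # consistency correction, then one-step reweighting (covMcd defaults)
    c1 = consistency_factor(h / n, d)
    cov_c = raw_cov * c1
    d_all = mahalanobis_distance(X, raw_center, cov_c)
    w = d_all <= np.sqrt(stats.chi2.ppf(0.975, d))
    if int(np.sum(w)) > d + 1:
        center_rw = X[w].mean(axis=0)
        cov_rw = np.atleast_2d(np.cov(X[w], rowvar=False, ddof=1))
        cov_rw = cov_rw * consistency_factor(0.975, d)
    else:  # degenerate reweighting; keep the corrected raw estimate
        center_rw, cov_rw = raw_center, cov_c
    final_cov = cov_rw * scale_factor
    sign, _ = np.linalg.slogdet(final_cov)
    if sign <= 0:
        raise DegeneracyError("reweighted covariance is not positive definite")

    return RobustEstimate(
        center=np.asarray(center_rw, dtype=float),
        covariance=final_cov,
        support_size=h,
        scale_factor=float(scale_factor),
        raw_center=np.asarray(raw_center, dtype=float),
        raw_covariance=np.asarray(raw_cov, dtype=float),
        raw_determinant=float(raw_det),
        n=n,
    )


def resolve_cutoff(cutoff, d: int = 2) -> float:
    """Turn a cutoff spec (float or ``"chi2_<q>"``) into a distance value."""
    if cutoff is None:
        cutoff = DEFAULT_CUTOFF
    if isinstance(cutoff, str):
        if not cutoff.startswith("chi2_"):
            raise ValidationError(f"unrecognised cutoff spec {cutoff!r}")
        q = float(cutoff.split("_", 1)[1])
        return float(np.sqrt(stats.chi2.ppf(q, d)))
    value = float(cutoff)
    if not value > 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    return value


def exclude_agglomerates(
    table: EventTable,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    cutoff: float | str | None = None,
    seed: int = 0,
    scale_factor: float = 1.0,
    asinh_pairs: bool = True,
    cofactor: float = 1.0,
) -> SingletMask:
    """Flag agglomerates on every configured height/width channel pair.

    An event is kept iff its Mahalanobis distance to the robust bivariate
    normal fit is at or below ``cutoff`` on *every* pair. Distances are
    computed on asinh-transformed channel values by default (see module
    docstring); the mask refers to rows of ``table`` either way.
    """
    if len(pairs) == 0:
        raise ValidationError("at least one channel pair is required")
    cut = resolve_cutoff(cutoff, d=2)
    keep = np.ones(table.n_events, dtype=bool)
    estimates: dict[str, RobustEstimate] = {}
    for pair in pairs:
        if len(pair) != 2:
            raise ValidationError(f"channel pair must have 2 names, got {pair!r}")
        P = table.channels(pair)
        if asinh_pairs:
            P = np.arcsinh(P / cofactor)
        est = fit_mcd(P, scale_factor=scale_factor, seed=seed)
        name = f"{pair[0]}/{pair[1]}"
        estimates[name] = est
        keep &= est.distances(P) <= cut
    return SingletMask(keep=keep, pair_estimates=estimates, cutoff=cut)
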