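"""Stain-separation statistics and the cell/spore visualisation threshold.

Given a two-component univariate mixture fitted on a stained channel, stain
quality is scored by the distance between the component means,

    mu_HP-LP = mu_HP - mu_LP,

where HP/LP are the higher-/lower-signal populations, on the spread scale of
the pooled standard deviation

    sigma_HP-LP = sqrt((sigma_HP^2 + sigma_LP^2) / 2).

A threshold between the two populations is computed as the root of the
difference of the fitted component densities between the two means: the
point where the (by default weight-scaled) component densities cross. The
threshold is for visualisation and QC only; three-population classification
never uses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import bisect

from .errors import DegeneracyError, NoRootError, ValidationError
from .mixture import GaussianComponent, MixtureModel

__all__ = ["SeparationReport", "separation_metrics", "find_threshold"]


@dataclass(frozen=True)
class SeparationReport:
    """Two-population separation statistics for one stained sample."""

    mu_LP: float
    mu_HP: float
    sigma_LP: float
    sigma_HP: float
    lambda_LP: float
    lambda_HP: float
    mu_diff: float
    sigma_pooled: float
    threshold: float | None = None
    channel: str | None = None
    dye: str | None = None
    sample_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "dye": self.dye,
            "channel": self.channel,
            "mu_LP": self.mu_LP,
            "mu_HP": self.mu_HP,
            "sigma_LP": self.sigma_LP,
            "sigma_HP": self.sigma_HP,
            "lambda_LP": self.lambda_LP,
            "lambda_HP": self.lambda_HP,
            "mu_diff": self.mu_diff,
            "sigma_pooled": self.sigma_pooled,
            "threshold": self.threshold,
        }

    def with_threshold(self, threshold: float) -> "SeparationReport":
        return replace(self, threshold=float(threshold))


def _two_univariate_components(model: MixtureModel):
    if model.g != 2 or model.d != 1:
        raise ValidationError(
            f"separation analysis needs a univariate 2-component model, "
            f"got g={model.g}, d={model.d}"
        )
    lp, hp = model.components  # sorted ascending by mean
    return lp, hp


def separation_metrics(
    model: MixtureModel,
    channel: str | None = None,
    dye: str | None = None,
    sample_id: str | None = None,
) -> SeparationReport:
    """Mean distance and pooled SD of a univariate two-component fit.

    The higher-mean component is HP, so ``mu_diff >= 0`` by convention. The
    returned report has no threshold; see :func:`find_threshold`.
    """
    lp, hp = _two_univariate_components(model)
    mu_lp, mu_hp = float(lp.mean[0]), float(hp.mean[0])
    s_lp, s_hp = lp.sigma, hp.sigma
    if channel is None and model.dims:
        channel = model.dims[0]
    return SeparationReport(
        mu_LP=mu_lp,
        mu_HP=mu_hp,
        sigma_LP=s_lp,
        sigma_HP=s_hp,
        lambda_LP=float(lp.weight),
        lambda_HP=float(hp.weight),
        mu_diff=mu_hp - mu_lp,
        sigma_pooled=float(np.sqrt((s_hp**2 + s_lp**2) / 2.0)),
        channel=channel,
        dye=dye,
        sample_id=sample_id,
    )


def _component_density(comp: GaussianComponent, x: np.ndarray, weighted: bool):
    z = (np.asarray(x, dtype=float) - comp.mean[0]) / comp.sigma
    dens = np.exp(-0.5 * z * z) / (comp.sigma * np.sqrt(2.0 * np.pi))
    return comp.weight * dens if weighted else dens


def find_threshold(
    model: MixtureModel,
    tol: float = 1e-8,
    weighted: bool = True,
    grid: int = 2048,
) -> float:
    """Crossover point of the two fitted component densities.

    Solves ``f(x) = 0`` for
    ``f(x) = lambda_HP N(x; mu_HP, sigma_HP) - lambda_LP N(x; mu_LP, sigma_LP)``
    by bisection, bracketed by the two component means. With
    ``weighted=False`` the unit-weight densities are subtracted instead.

    With unequal sigmas the difference can have two roots in the bracket; the
    one closest to the midpoint of the means is returned and a multiplicity
    warning is emitted.

    Raises
    ------
    DegeneracyError
        If the component means coincide.
    NoRootError
        If the difference does not change sign between the means (one
        component engulfs the other).
    """
    if not tol > 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    lp, hp = _two_univariate_components(model)
    mu_lp, mu_hp = float(lp.mean[0]), float(hp.mean[0])
    if mu_lp == mu_hp:
        raise DegeneracyError("component means coincide; no threshold exists")

    def f(x):
        return _component_density(hp, x, weighted) - _component_density(lp, x, weighted)

    xs = np.linspace(mu_lp, mu_hp, grid + 1)
    fs = f(xs)
    sign_change = np.nonzero(np.diff(np.signbit(fs)))[0]
    exact = np.nonzero(fs == 0.0)[0]
    roots = [float(xs[i]) for i in exact]
    for i in sign_change:
        if fs[i] == 0.0 or fs[i + 1] == 0.0:
            continue  # endpoint already collected as an exact root
        roots.append(float(bisect(f, xs[i], xs[i + 1], xtol=tol)))
    if not roots:
        raise NoRootError(
            "component-density difference has no root between the means "
            f"({mu_lp:.4g}, {mu_hp:.4g}); one component may engulf the other "
            f"(lambda_LP={lp.weight:.3f}, sigma_LP={lp.sigma:.3g}, "
            f"lambda_HP={hp.weight:.3f}, sigma_HP={hp.sigma:.3g})"
        )
    if len(roots) > 1:
        warnings.warn(
            f"{len(roots)} density crossovers between the component means; "
            "returning the one closest to the midpoint",
            stacklevel=2,
        )
    midpoint = 0.5 * (mu_lp + mu_hp)
    return min(roots, key=lambda r: abs(r - midpoint))
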