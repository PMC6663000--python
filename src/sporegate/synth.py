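"""Synthetic flow-cytometry cultures with ground-truth labels.

Events are drawn per subpopulation from correlated log-normal distributions
(cytometric scatter and fluorescence signals are near log-normal, which is
why the pipeline asinh-transforms before modelling). The default preset
encodes the qualitative structure of a stained sporulating culture:

* vegetative cells - dye-permeable, high FL1, low SSC;
* endospore-containing mother cells - still high FL1, elevated SSC (the
  developing coat raises granularity) and slightly higher FSC;
* free spores - low FL1 (the finished coat blocks the dye), elevated SSC.

Fluorescence separates the populations strongly, side scatter somewhat and
forward scatter barely; pulse heights are noisier than areas and pulse
widths are tight. Absolute signal levels are free parameters in arbitrary
detector units.

Agglomerates (doublets) are simulated by summing the area/height signals of
two random singlets and inflating the width channels, which is exactly the
signature the height/width singlet gate looks for.

Ground-truth labels and doublet flags are returned alongside the event
table (and written as a sidecar CSV by the CLI), never embedded in the FCS
payload.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .events import EventTable

__all__ = [
    "PopulationSpec",
    "SynthConfig",
    "simulate_culture",
    "simulate_timecourse",
    "default_populations",
    "write_truth",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H", "SSC-W", "FL1-A")

# log-scale signal model shared by the default preset (a.u.):
# pulse height tracks area at an offset and with extra noise; width is tight.
_H_OFFSET = -0.15
_SD_SCATTER_A = 0.18
_SD_FL1_A = 0.22
_SD_H = 0.35
_SD_W = 0.05
_W_MEAN = 4.6
# within-event correlations on the log scale
_CORR = {
    ("FSC-A", "FSC-H"): 0.9,
    ("SSC-A", "SSC-H"): 0.9,
    ("FSC-A", "SSC-A"): 0.5,
    ("FSC-H", "SSC-H"): 0.5,
    ("FSC-A", "SSC-H"): 0.45,
    ("FSC-H", "SSC-A"): 0.45,
    ("FSC-A", "FL1-A"): 0.2,
    ("FSC-H", "FL1-A"): 0.2,
    ("SSC-A", "FL1-A"): 0.2,
    ("SSC-H", "FL1-A"): 0.2,
}
# population centers (log a.u.): FL1 orders spore << endospore ~ vegetative,
# SSC orders vegetative < spore < endospore, FSC differences are minor
_PRESET_LOG_MEANS = {
    "vegetative": {"FSC-A": 7.0, "SSC-A": 6.6, "FL1-A": 8.7},
    "endospore": {"FSC-A": 7.2, "SSC-A": 7.25, "FL1-A": 7.8},
    "spore": {"FSC-A": 7.1, "SSC-A": 7.0, "FL1-A": 5.0},
}


@dataclass(frozen=True)
class PopulationSpec:
    """Log-normal signal model of one subpopulation.

    ``log_means``/``log_sds`` give the natural-log-scale location and spread
    of each channel's raw signal; ``channel_correlations`` optionally sets
    log-scale correlations for channel pairs (default: uncorrelated).
    """

    label: str
    proportion: float
    log_means: Mapping[str, float]
    log_sds: Mapping[str, float]
    channel_correlations: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.proportion <= 1.0):
            raise ValidationError(
                f"proportion must be in [0, 1], got {self.proportion} for {self.label!r}"
            )
        for ch, sd in self.log_sds.items():
            if not sd > 0:
                raise ValidationError(f"log_sd for {ch!r} must be > 0, got {sd}")

    def covariance(self, channels: Sequence[str]) -> np.ndarray:
        """Log-scale covariance matrix over ``channels``."""
        sds = np.array([self.log_sds[c] for c in channels], dtype=float)
        corr = np.eye(len(channels))
        index = {c: i for i, c in enumerate(channels)}
        for (a, b), rho in self.channel_correlations.items():
            if a in index and b in index and a != b:
                corr[index[a], index[b]] = corr[index[b], index[a]] = float(rho)
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValidationError(
                f"correlation matrix for {self.label!r} is not positive semi-definite"
            )
        return corr * np.outer(sds, sds)

    def mean_vector(self, channels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.log_means[c] for c in channels], dtype=float)
        except KeyError as exc:
            raise ValidationError(
                f"population {self.label!r} has no log_mean for channel {exc}"
            ) from None


def default_populations(
    proportions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[PopulationSpec, ...]:
    """The default three-subpopulation preset with the given proportions."""
    if len(proportions) != 3:
        raise ValidationError(f"need 3 proportions, got {len(proportions)}")
    specs = []
    for label, prop in zip(("vegetative", "endospore", "spore"), proportions):
        base = _PRESET_LOG_MEANS[label]
        log_means = {
            "FSC-A": base["FSC-A"],
            "FSC-H": base["FSC-A"] + _H_OFFSET,
            "FSC-W": _W_MEAN,
            "SSC-A": base["SSC-A"],
            "SSC-H": base["SSC-A"] + _H_OFFSET,
            "SSC-W": _W_MEAN,
            "FL1-A": base["FL1-A"],
        }
        log_sds = {
            "FSC-A": _SD_SCATTER_A,
            "FSC-H": _SD_H,
            "FSC-W": _SD_W,
            "SSC-A": _SD_SCATTER_A,
            "SSC-H": _SD_H,
            "SSC-W": _SD_W,
            "FL1-A": _SD_FL1_A,
        }
        specs.append(
            PopulationSpec(
                label=label,
                proportion=float(prop),
                log_means=log_means,
                log_sds=log_sds,
                channel_correlations=dict(_CORR),
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one simulated culture."""

    populations: tuple[PopulationSpec, ...] = field(default_factory=default_populations)
    n_events: int = 100_000
    doublet_rate: float = 0.05
    width_inflation: float = 2.0
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.n_events < 0:
            raise ValidationError(f"n_events must be >= 0, got {self.n_events}")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValidationError(
                f"doublet_rate must be in [0, 1), got {self.doublet_rate}"
            )
        if not self.width_inflation > 1.0:
            raise ValidationError(
                f"width_inflation must be > 1, got {self.width_inflation}"
            )
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"population proportions sum to {total}, not 1")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SynthConfig":
        payload = dict(payload)
        pops = payload.pop("populations", None)
        if pops is None:
            proportions = payload.pop("proportions", (1 / 3, 1 / 3, 1 / 3))
            populations = default_populations(proportions)
        else:
            populations = tuple(
                PopulationSpec(
                    label=p["label"],
                    proportion=p["proportion"],
                    log_means=p["log_means"],
                    log_sds=p["log_sds"],
                    channel_correlations={
                        tuple(k.split(":")): v
                        for k, v in p.get("channel_correlations", {}).items()
                    },
                )
                for p in pops
            )
        return cls(populations=populations, **payload)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SynthConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "channels" in payload:
            payload["channels"] = tuple(payload["channels"])
        return cls.from_dict(payload)


def _draw_population(
    spec: PopulationSpec, channels: Sequence[str], n: int, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.empty((0, len(channels)))
    mu = spec.mean_vector(channels)
    cov = spec.covariance(channels)
    log_signals = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    return np.exp(log_signals)


def _draw_mixture(
    populations: Sequence[PopulationSpec],
    channels: Sequence[str],
    n: int,
    rng: np.random.Generator,
):
    props = np.array([p.proportion for p in populations])
    counts = rng.multinomial(n, props)
    blocks = [_draw_population(p, channels, c, rng) for p, c in zip(populations, counts)]
    labels = np.repeat([p.label for p in populations], counts)
    return np.vstack(blocks) if blocks else np.empty((0, len(channels))), labels


def simulate_culture(
    config: SynthConfig, metadata: Mapping | None = None
) -> tuple[EventTable, np.ndarray, np.ndarray]:
    """Simulate one culture.

    Returns ``(table, labels, doublet_flags)`` where ``labels[i]`` is the
    true subpopulation of event i (for a doublet: of its first constituent)
    and ``doublet_flags[i]`` marks simulated agglomerates. A fraction
    ``doublet_rate`` of the ``n_events`` rows are doublets built by summing
    the area/height signals of two random singlets and multiplying the
    width channels by ``width_inflation``. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    channels = config.channels
    n = config.n_events
    n_doublets = int(round(config.doublet_rate * n))
    n_singlets = n - n_doublets

    singlets, singlet_labels = _draw_mixture(config.populations, channels, n_singlets, rng)
    first, first_labels = _draw_mixture(config.populations, channels, n_doublets, rng)
    second, _ = _draw_mixture(config.populations, channels, n_doublets, rng)

    is_width = np.array([c.endswith("-W") for c in channels])
    doublets = first + second  # additive pulse area and height
    if n_doublets:
        doublets[:, is_width] = (
            config.width_inflation * 0.5 * (first[:, is_width] + second[:, is_width])
        )

    events = np.vstack([singlets, doublets])
    labels = np.concatenate([singlet_labels, first_labels])
    flags = np.concatenate(
        [np.zeros(n_singlets, dtype=bool), np.ones(n_doublets, dtype=bool)]
    )
    order = rng.permutation(n)
    meta = {"sample_id": "synthetic", "synth_seed": config.seed}
    meta.update(metadata or {})
    table = EventTable(
        events=events[order], channel_names=channels, metadata=meta
    )
    return table, labels[order], flags[order]


def _derive_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_timecourse(
    base: SynthConfig,
    schedule: Sequence[tuple[float, Sequence[float]]],
) -> list[tuple[EventTable, np.ndarray, np.ndarray]]:
    """One simulated sample per ``(time_h, proportions)`` schedule entry.

    Seeds are derived deterministically from the base seed and the entry
    index, so repeated entries (replicates) give distinct but reproducible
    samples. Population signal models are those of ``base``; only the
    proportions change along the schedule.
    """
    if len(base.populations) == 0:
        raise ValidationError("base config has no populations")
    out = []
    for idx, entry in enumerate(schedule):
        try:
            time_h, props = entry
            props = tuple(float(p) for p in props)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"schedule entry {idx} must be (time_h, proportions), got {entry!r}"
            ) from exc
        if len(props) != len(base.populations):
            raise ValidationError(
                f"schedule entry {idx}: {len(props)} proportions for "
                f"{len(base.populations)} populations"
            )
        pops = tuple(
            replace(p, proportion=pr) for p, pr in zip(base.populations, props)
        )
        config = replace(base, populations=pops, seed=_derive_seed(base.seed, idx))
        table, labels, flags = simulate_culture(
            config,
            metadata={"sample_id": f"sim_t{idx:02d}", "time_h": float(time_h)},
        )
        out.append((table, labels, flags))
    return out


def write_truth(
    path: str | os.PathLike, labels: np.ndarray, doublet_flags: np.ndarray
) -> None:
    """Write ground-truth labels/flags as a sidecar CSV keyed by event index."""
    pd.DataFrame(
        {
            "event_index": np.arange(len(labels)),
            "label": labels,
            "is_doublet": doublet_flags.astype(int),
        }
    ).to_csv(path, index=False)
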