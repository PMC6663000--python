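"""Three-population classification by reference-model label transfer.

A g=3 Gaussian mixture is fitted once on a reference sample known to contain
all three subpopulations. Clusters are mapped to biological labels from the
staining mechanism: dye permeability drops once the spore coat is complete,
so the cluster with the lowest FL1 mean is the free spores; of the two
high-fluorescence clusters, the developing coat raises granularity, so the
one with the higher SSC mean is the endospore-containing mother cells and
the remainder the vegetative cells.

Every other sample in the experiment set is then classified with this one
reference model (label transfer) - by Euclidean distance to the component
centers (default) or by maximum posterior - and per-sample population
fractions are tabulated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChannelLookupError,
    MappingError,
    SampleSizeError,
    ValidationError,
)
from .events import EventTable
from .mixture import MixtureModel, fit_gmm

__all__ = [
    "LABELS",
    "ReferenceClassifier",
    "PopulationFractions",
    "fit_reference",
    "assign_labels",
    "population_fractions",
    "timecourse_report",
    "DEFAULT_DIMS",
]

#: Canonical biological labels, in reporting order.
LABELS = ("vegetative", "endospore", "spore")

#: Default feature space: the two discriminating (transformed) area channels.
DEFAULT_DIMS = ("SSC-A", "FL1-A")

#: Minimum events to fit a reference model.
MIN_REFERENCE_EVENTS = 300

#: QC threshold: warn when a fitted component carries less weight than this.
MIN_COMPONENT_WEIGHT = 0.02


@dataclass(frozen=True)
class ReferenceClassifier:
    """A fitted 3-component model plus its cluster-to-label mapping."""

    model: MixtureModel
    label_map: Mapping[int, str]
    dims: tuple[str, ...]
    assignment_rule: str = "euclidean"

    def __post_init__(self):
        if sorted(self.label_map.values()) != sorted(LABELS):
            raise ValidationError(
                f"label_map must be a bijection onto {LABELS}, got {dict(self.label_map)}"
            )
        if tuple(self.model.dims) != tuple(self.dims):
            raise ValidationError("classifier dims do not match the model dims")
        if self.assignment_rule not in ("euclidean", "posterior"):
            raise ValidationError(
                f"assignment_rule must be 'euclidean' or 'posterior', "
                f"got {self.assignment_rule!r}"
            )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "label_map": {str(k): v for k, v in self.label_map.items()},
            "dims": list(self.dims),
            "assignment_rule": self.assignment_rule,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ReferenceClassifier":
        return cls(
            model=MixtureModel.from_dict(payload["model"]),
            label_map={int(k): v for k, v in payload["label_map"].items()},
            dims=tuple(payload["dims"]),
            assignment_rule=payload["assignment_rule"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceClassifier":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PopulationFractions:
    """Counts and fractions of the three subpopulations in one sample."""

    sample_id: str
    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    n_total: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.n_total:
            raise ValidationError("counts do not sum to n_total")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("fractions do not sum to 1")

    def to_dict(self) -> dict:
        row = {"sample_id": self.sample_id, "n_total": self.n_total}
        for label in LABELS:
            row[f"count_{label}"] = self.counts[label]
            row[f"frac_{label}"] = self.fractions[label]
        return row


def _find_dim(dims: Sequence[str], token: str) -> int:
    hits = [i for i, name in enumerate(dims) if token.upper() in name.upper()]
    if len(hits) != 1:
        raise MappingError(
            f"cannot identify the {token} dimension among {tuple(dims)}; "
            "pass fl1_channel/ssc_channel explicitly"
        )
    return hits[0]


def _map_labels(model: MixtureModel, fl1_dim: int, ssc_dim: int) -> dict[int, str]:
    """Spore = lowest FL1 mean; endospore = higher SSC of the remaining two."""
    means = model.means
    fl1 = means[:, fl1_dim]
    order = np.argsort(fl1)
    if fl1[order[0]] == fl1[order[1]]:
        raise MappingError(
            f"two clusters tie on the FL1 mean ({fl1[order[0]]:.6g}); "
            "cannot identify the spore cluster"
        )
    spore = int(order[0])
    rest = [k for k in range(model.g) if k != spore]
    ssc = means[:, ssc_dim]
    if ssc[rest[0]] == ssc[rest[1]]:
        raise MappingError(
            f"the two high-FL1 clusters tie on the SSC mean ({ssc[rest[0]]:.6g}); "
            "cannot separate endospores from vegetative cells"
        )
    endo = rest[0] if ssc[rest[0]] > ssc[rest[1]] else rest[1]
    veg = rest[0] if endo == rest[1] else rest[1]
    return {veg: "vegetative", endo: "endospore", spore: "spore"}


def fit_reference(
    table: EventTable,
    dims: Sequence[str] = DEFAULT_DIMS,
    seed: int = 0,
    assignment_rule: str = "euclidean",
    fl1_channel: str | None = None,
    ssc_channel: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ReferenceClassifier:
    """Fit the 3-cluster reference model and name its clusters.

    ``table`` must already be transformed and singlet-gated and should come
    from a biological sample containing all three subpopulations. A QC
    warning fires if any fitted component weight is below 2%, which usually
    means a subpopulation is (nearly) absent from the chosen reference.
    """
    dims = tuple(dims)
    if table.n_events < MIN_REFERENCE_EVENTS:
        raise SampleSizeError(
            f"reference fit needs >= {MIN_REFERENCE_EVENTS} events, "
            f"got {table.n_events}"
        )
    X = table.channels(dims)
    if X.shape[1] < 2:
        raise ValidationError("reference model needs at least 2 feature dimensions")
    model = fit_gmm(X, g=3, seed=seed, dims=dims, tol=tol, max_iter=max_iter)
    fl1_dim = dims.index(fl1_channel) if fl1_channel else _find_dim(dims, "FL")
    ssc_dim = dims.index(ssc_channel) if ssc_channel else _find_dim(dims, "SSC")
    label_map = _map_labels(model, fl1_dim=fl1_dim, ssc_dim=ssc_dim)
    small = model.weights < MIN_COMPONENT_WEIGHT
    if np.any(small):
        which = [label_map[int(k)] for k in np.nonzero(small)[0]]
        warnings.warn(
            f"reference component(s) {which} carry < {MIN_COMPONENT_WEIGHT:.0%} "
            "of events; the reference sample may not contain all three "
            "subpopulations",
            stacklevel=2,
        )
    return ReferenceClassifier(
        model=model, label_map=label_map, dims=dims, assignment_rule=assignment_rule
    )


def assign_labels(
    classifier: ReferenceClassifier,
    table: EventTable,
    rule: str | None = None,
) -> np.ndarray:
    """Label every event of ``table`` with the reference model.

    ``euclidean``: nearest component mean in the classifier's feature space
    (l2 norm); ``posterior``: maximum-posterior component. Ties go to the
    lowest cluster index in both rules.
    """
    rule = rule or classifier.assignment_rule
    if rule not in ("euclidean", "posterior"):
        raise ValidationError(f"unknown assignment rule {rule!r}")
    missing = [d for d in classifier.dims if d not in table.channel_names]
    if missing:
        raise ChannelLookupError(
            f"table lacks classifier dims {missing}; available: {table.channel_names}"
        )
    X = table.channels(classifier.dims)
    if rule == "euclidean":
        d2 = np.sum((X[:, None, :] - classifier.model.means[None, :, :]) ** 2, axis=2)
        idx = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    else:
        idx = classifier.model.predict(X)
    labels = np.array([classifier.label_map[k] for k in range(classifier.model.g)])
    return labels[idx]


def population_fractions(
    labels: Sequence[str] | np.ndarray, sample_id: str = ""
) -> PopulationFractions:
    """Exact counts and fractions per biological label.

    Labels absent from the vector get count 0; an empty vector is an error.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("cannot compute fractions of an empty label vector")
    unknown = set(np.unique(labels)) - set(LABELS)
    if unknown:
        raise ValidationError(f"unknown labels {sorted(unknown)}; expected {LABELS}")
    n = int(labels.size)
    counts = {label: int(np.sum(labels == label)) for label in LABELS}
    fractions = {label: counts[label] / n for label in LABELS}
    return PopulationFractions(
        sample_id=sample_id, counts=counts, fractions=fractions, n_total=n
    )


def timecourse_report(
    samples: Iterable[EventTable | tuple[EventTable, Mapping]],
    classifier: ReferenceClassifier,
    rule: str | None = None,
) -> pd.DataFrame:
    """Population fractions for every sample, via one shared classifier.

    The same reference classifier is applied to every sample (label
    transfer); nothing is refitted per sample. ``samples`` may be event
    tables (metadata taken from each table) or ``(table, metadata)`` pairs.
    Returns one row per sample with sample_id, strain, time_h, replicate,
    n_total and the per-label counts and fractions.
    """
    rows = []
    for item in samples:
        if isinstance(item, tuple):
            table, meta = item
            meta = {**table.metadata, **dict(meta)}
        else:
            table, meta = item, dict(item.metadata)
        labels = assign_labels(classifier, table, rule=rule)
        fracs = population_fractions(labels, sample_id=str(meta.get("sample_id", "")))
        row = fracs.to_dict()
        row["strain"] = meta.get("strain")
        row["time_h"] = meta.get("time_h")
        row["replicate"] = meta.get("replicate")
        rows.append(row)
    if not rows:
        raise ValidationError("no samples given")
    cols = (
        ["sample_id", "strain", "time_h", "replicate", "n_total"]
        + [f"count_{label}" for label in LABELS]
        + [f"frac_{label}" for label in LABELS]
    )
    return pd.DataFrame(rows)[cols]
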