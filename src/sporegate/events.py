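"""The event table: the in-memory currency of the pipeline.

An :class:`EventTable` is an (n_events x n_channels) float matrix with named
channels plus free-form sample metadata (sample_id, strain, time_h,
replicate, ...). All pipeline stages consume and return event tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelLookupError, ValidationError

__all__ = ["EventTable"]


@dataclass(frozen=True)
class EventTable:
    """Events-by-channels matrix with named channels and sample metadata.

    Parameters
    ----------
    events
        Real-valued array of shape (n_events, n_channels), detector a.u.
    channel_names
        Unique channel names, one per column (e.g. ``"FSC-A"``, ``"FL1-A"``).
    metadata
        Sample annotations; conventional keys are ``sample_id``, ``strain``,
        ``time_h`` and ``replicate``.
    """

    events: np.ndarray
    channel_names: tuple[str, ...]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 2:
            raise ValidationError(f"events must be 2-D, got shape {ev.shape}")
        names = tuple(str(c) for c in self.channel_names)
        if ev.shape[1] != len(names):
            raise ValidationError(
                f"{ev.shape[1]} columns but {len(names)} channel names"
            )
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate channel names: {names}")
        if not np.all(np.isfinite(ev)):
            raise ValidationError("events contain NaN or infinite values")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "channel_names", names)

    # -- shape ------------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    # -- channel access ---------------------------------------------------
    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelLookupError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Values of one channel (read-only view)."""
        return self.events[:, self.channel_index(name)]

    def channels(self, names: Sequence[str]) -> np.ndarray:
        """Matrix of the named channels, in the order given."""
        idx = [self.channel_index(n) for n in names]
        return self.events[:, idx]

    # -- derived tables ---------------------------------------------------
    def with_events(self, events: np.ndarray) -> "EventTable":
        """Same channels/metadata, new event matrix."""
        return replace(self, events=events, metadata=dict(self.metadata))

    def take(self, index: np.ndarray) -> "EventTable":
        """Row subset (boolean mask or integer index array)."""
        return self.with_events(self.events[index])

    def with_metadata(self, **updates: Any) -> "EventTable":
        md = dict(self.metadata)
        md.update(updates)
        return replace(self, metadata=md)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=list(self.channel_names))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metadata: Mapping[str, Any] | None = None
    ) -> "EventTable":
        return cls(
            events=df.to_numpy(dtype=float),
            channel_names=tuple(df.columns),
            metadata=dict(metadata or {}),
        )
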