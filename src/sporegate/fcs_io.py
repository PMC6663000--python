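"""FCS 3.0/3.1 list-mode I/O and event subsampling.

Scope is the modern float dialect: files are written as FCS 3.1, ``$MODE L``,
``$DATATYPE F`` (IEEE float32, little-endian) and read back as FCS 3.0 or 3.1
with ``$DATATYPE F`` or ``D``. Integer+gain and FCS 2.0 dialects are out of
scope. Experimental-design metadata that has no FCS keyword (strain, time_h)
travels in a sidecar sample sheet (CSV: sample_id, path, strain, time_h,
replicate).
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError, UnsupportedModeError, ValidationError
from .events import EventTable

__all__ = [
    "read_fcs",
    "write_fcs",
    "subsample_events",
    "read_sample_sheet",
    "DEFAULT_N_MAX",
    "DEFAULT_SEED",
]

#: Number of events evaluated per analysis; larger acquisitions are
#: randomly subsampled down to this size.
DEFAULT_N_MAX = 100_000
#: Documented default seed for the subsampling RNG.
DEFAULT_SEED = 0

_HEADER_LEN = 58  # 10-byte version field + six 8-byte ASCII offsets
_DELIM = "/"
# metadata keys mirrored into (and recovered from) the TEXT segment
_META_KEYWORDS = {
    "sample_id": "SAMPLE_ID",
    "strain": "STRAIN",
    "time_h": "TIME_H",
    "replicate": "REPLICATE",
}


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def _build_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        value = str(value)
        if value == "":
            value = " "  # FCS forbids empty keyword values
        parts.append(f"{_escape(key)}{_DELIM}{_escape(value)}{_DELIM}")
    return "".join(parts).encode("utf-8")


def write_fcs(table: EventTable, path: str | os.PathLike) -> None:
    """Write an event table as an FCS 3.1 float list-mode file.

    Channel names go to ``$PnN``; sample metadata (sample_id, strain,
    time_h, replicate) is mirrored into non-standard TEXT keywords so a
    write/read roundtrip preserves it.
    """
    if table.n_channels < 1:
        raise ValidationError("cannot write an FCS file with zero channels")
    data = np.ascontiguousarray(table.events, dtype="<f4")
    n_tot, n_par = data.shape
    payload = data.tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width placeholders so TEXT length is offset-independent
        "$BEGINDATA": "0" * 10,
        "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(table.channel_names, start=1):
        rng_max = float(np.max(table.events[:, i - 1])) if n_tot else 1.0
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(rng_max, 1.0)) + 1)
    for meta_key, kw in _META_KEYWORDS.items():
        if table.metadata.get(meta_key) is not None:
            keywords[kw] = str(table.metadata[meta_key])

    text = _build_text(keywords)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    if payload:
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1
    else:
        data_start = data_end = 0
    # patch the fixed-width data offsets into the TEXT bytes
    text = text.replace(
        f"{_DELIM}$BEGINDATA{_DELIM}{'0' * 10}{_DELIM}".encode(),
        f"{_DELIM}$BEGINDATA{_DELIM}{data_start:010d}{_DELIM}".encode(),
    ).replace(
        f"{_DELIM}$ENDDATA{_DELIM}{'0' * 10}{_DELIM}".encode(),
        f"{_DELIM}$ENDDATA{_DELIM}{data_end:010d}{_DELIM}".encode(),
    )

    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise FormatError("TEXT segment too short")
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("utf-8", errors="replace")
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters show up as empty tokens
    tokens = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        # re-join escaped delimiters: "a", "", "b" -> "a/b"
        while i + 2 <= len(tokens) - 1 and tokens[i + 1] == "":
            tok = tok + delim + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if len(merged) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of tokens")
    return {
        merged[j].strip().upper(): merged[j + 1]
        for j in range(0, len(merged), 2)
    }


def _header_offset(buf: bytes, lo: int) -> int:
    field = buf[lo : lo + 8].decode("latin-1").strip()
    if field == "":
        return 0
    try:
        return int(field)
    except ValueError as exc:
        raise FormatError(f"bad header offset field {field!r}") from exc


def read_fcs(path: str | os.PathLike) -> EventTable:
    """Read an FCS 3.0/3.1 float list-mode file into an :class:`EventTable`.

    Raises
    ------
    FormatError
        Unreadable, truncated or non-FCS input.
    UnsupportedModeError
        Non-list-mode files or integer/ASCII data types.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < _HEADER_LEN:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = buf[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported or missing FCS version {version!r}")
    text_start = _header_offset(buf, 10)
    text_end = _header_offset(buf, 18)
    data_start = _header_offset(buf, 26)
    data_end = _header_offset(buf, 34)
    if not (0 < text_start <= text_end < len(buf)):
        raise FormatError(f"{path}: TEXT segment offsets out of range")
    kw = _parse_text_segment(buf[text_start : text_end + 1])

    mode = kw.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise UnsupportedModeError(f"{path}: only list mode is supported, got $MODE={mode}")
    datatype = kw.get("$DATATYPE", "").strip().upper()
    if datatype not in ("F", "D"):
        raise UnsupportedModeError(
            f"{path}: only float list mode ($DATATYPE F/D) is supported, got {datatype!r}"
        )
    byteord = kw.get("$BYTEORD", "").replace(" ", "")
    if byteord == "1,2,3,4":
        order = "<"
    elif byteord == "4,3,2,1":
        order = ">"
    else:
        raise UnsupportedModeError(f"{path}: unsupported $BYTEORD {byteord!r}")
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing/invalid $PAR or $TOT") from exc

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        names.append(name.strip())
        width = kw.get(f"$P{i}B", "32").strip()
        expected = "32" if datatype == "F" else "64"
        if width != expected:
            raise UnsupportedModeError(
                f"{path}: $P{i}B={width} inconsistent with $DATATYPE {datatype}"
            )

    itemsize = 4 if datatype == "F" else 8
    n_bytes = n_tot * n_par * itemsize
    if n_bytes == 0:
        events = np.zeros((n_tot, n_par), dtype=float)
    else:
        if data_start == 0 and data_end == 0:  # offsets delegated to TEXT
            data_start = int(kw.get("$BEGINDATA", "0"))
            data_end = int(kw.get("$ENDDATA", "0"))
        if data_start <= 0 or data_end + 1 > len(buf):
            raise FormatError(f"{path}: DATA segment offsets out of range")
        raw = buf[data_start : data_start + n_bytes]
        if len(raw) != n_bytes:
            raise FormatError(
                f"{path}: truncated DATA segment "
                f"({len(raw)} bytes, expected {n_bytes})"
            )
        dtype = np.dtype(f"{order}f{itemsize}")
        events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)

    metadata: dict[str, Any] = {}
    for meta_key, keyword in _META_KEYWORDS.items():
        if keyword in kw:
            metadata[meta_key] = kw[keyword].strip()
    if "time_h" in metadata:
        try:
            metadata["time_h"] = float(metadata["time_h"])
        except ValueError:
            pass
    if "replicate" in metadata:
        try:
            metadata["replicate"] = int(metadata["replicate"])
        except ValueError:
            pass
    metadata["fcs_keywords"] = kw
    return EventTable(events=events, channel_names=tuple(names), metadata=metadata)


def subsample_events(
    table: EventTable, n_max: int = DEFAULT_N_MAX, seed: int = DEFAULT_SEED
) -> EventTable:
    """Uniform random subsample without replacement down to ``n_max`` events.

    Tables with at most ``n_max`` events are returned unchanged. Sampling is
    deterministic given ``seed``; the acquisition order of the retained
    events is preserved.
    """
    if int(n_max) < 1:
        raise ValidationError(f"n_max must be >= 1, got {n_max}")
    if table.n_events <= n_max:
        return table
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_events, size=int(n_max), replace=False))
    return table.take(idx).with_metadata(subsampled_from=table.n_events)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sidecar sample sheet (CSV).

    Required columns: ``sample_id``, ``path``. Optional: ``strain``,
    ``time_h``, ``replicate``. Relative FCS paths are resolved against the
    sheet's own directory.
    """
    df = pd.read_csv(path)
    missing = {"sample_id", "path"} - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet is missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id values in sample sheet: {dupes}")
    base = os.path.dirname(os.fspath(path))
    df["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]
    ]
    return df
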