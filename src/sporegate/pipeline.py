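"""End-to-end pipeline stages: stain QC and experiment-level classification.

Both entry points run the same front end - read FCS, subsample to the
evaluation budget, asinh-transform the area channels, exclude agglomerates
on the H/W pairs - and log the event count after every gate. All randomness
derives from one top-level seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    DEFAULT_DIMS,
    ReferenceClassifier,
    fit_reference,
    timecourse_report,
)
from .errors import ConfigurationError, PipelineError, ValidationError
from .events import EventTable
from .fcs_io import DEFAULT_N_MAX, read_fcs, read_sample_sheet, subsample_events
from .mixture import fit_gmm
from .robust_gating import DEFAULT_CUTOFF, DEFAULT_PAIRS, exclude_agglomerates
from .separation import SeparationReport, find_threshold, separation_metrics
from .transforms import DEFAULT_AREA_CHANNELS, TransformSpec, asinh_transform

__all__ = ["PipelineConfig", "run_stain_qc", "run_experiment"]

# fixed per-stage seed stream indices (derived from the top-level seed)
_STAGE_STREAMS = {"subsample": 0, "gating": 1, "mixture": 2}


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    transform_channels: tuple[str, ...] = DEFAULT_AREA_CHANNELS
    cofactor: float = 1.0
    gating_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    gating_cutoff: float | str = DEFAULT_CUTOFF
    gating_scale_factor: float = 1.0
    gating_asinh: bool = True
    mixture_tol: float = 1e-8
    mixture_max_iter: int = 1000
    classify_dims: tuple[str, ...] = DEFAULT_DIMS
    classify_rule: str = "euclidean"
    n_max: int = DEFAULT_N_MAX
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "transform_channels", tuple(self.transform_channels))
        object.__setattr__(
            self, "gating_pairs", tuple(tuple(p) for p in self.gating_pairs)
        )
        object.__setattr__(self, "classify_dims", tuple(self.classify_dims))

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), _STAGE_STREAMS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["transform_channels"] = list(self.transform_channels)
        payload["gating_pairs"] = [list(p) for p in self.gating_pairs]
        payload["classify_dims"] = list(self.classify_dims)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def _prepare(
    table: EventTable, config: PipelineConfig, log: dict[str, Any]
) -> EventTable:
    """Shared front end: subsample, transform areas, singlet-gate."""
    log["n_read"] = table.n_events
    if table.n_events == 0:
        with _stage("read"):
            raise ValidationError("empty input: the file contains no events")
    with _stage("subsample"):
        table = subsample_events(table, config.n_max, seed=config.stage_seed("subsample"))
    log["n_subsampled"] = table.n_events
    with _stage("transform"):
        spec = TransformSpec(channels=config.transform_channels, cofactor=config.cofactor)
        table = asinh_transform(table, spec)
    with _stage("singlet_gate"):
        mask = exclude_agglomerates(
            table,
            pairs=config.gating_pairs,
            cutoff=config.gating_cutoff,
            seed=config.stage_seed("gating"),
            scale_factor=config.gating_scale_factor,
            asinh_pairs=config.gating_asinh,
            cofactor=config.cofactor,
        )
        table = table.take(mask.keep)
    log["n_singlets"] = table.n_events
    return table


def run_stain_qc(
    sample: str | os.PathLike | EventTable,
    config: PipelineConfig | None = None,
    channel: str = "FL1-A",
    dye: str | None = None,
) -> tuple[SeparationReport, dict[str, Any]]:
    """Stain-separation QC on one two-population sample.

    Read -> subsample -> transform -> singlet-gate -> fit a univariate
    two-component mixture on ``channel`` -> separation statistics plus the
    density-crossover threshold. Returns the report and a stage log with the
    event counts after every gate.
    """
    config = config or PipelineConfig()
    log: dict[str, Any] = {"channel": channel, "seed": config.seed}
    if isinstance(sample, EventTable):
        table = sample
    else:
        with _stage("read"):
            table = read_fcs(sample)
        log["path"] = os.fspath(sample)
    table = _prepare(table, config, log)
    with _stage("mixture_fit"):
        model = fit_gmm(
            table.channel(channel),
            g=2,
            tol=config.mixture_tol,
            max_iter=config.mixture_max_iter,
            seed=config.stage_seed("mixture"),
            dims=(channel,),
        )
    with _stage("separation"):
        report = separation_metrics(
            model,
            channel=channel,
            dye=dye,
            sample_id=str(table.metadata.get("sample_id", "")),
        )
        report = report.with_threshold(find_threshold(model, tol=config.mixture_tol))
    return report, log


def run_experiment(
    samplesheet: str | os.PathLike,
    reference: str,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> tuple[pd.DataFrame, ReferenceClassifier, dict[str, Any]]:
    """Classify every sample of an experiment set against one reference.

    The sample sheet (CSV: sample_id, path, strain, time_h, replicate) lists
    the FCS files; ``reference`` names the sample_id of the biological sample
    containing all three subpopulations. The classifier is fitted once on the
    reference and label-transferred to every sample.

    When ``out_dir`` is given, writes ``fractions.csv``, ``classifier.json``,
    ``config.yaml`` (verbatim echo) and ``run_log.json`` (package version,
    seeds, per-stage event counts) - enough to reproduce the run.
    """
    config = config or PipelineConfig()
    sheet = read_sample_sheet(samplesheet)
    if reference not in set(sheet["sample_id"].astype(str)):
        raise ConfigurationError(
            f"reference sample {reference!r} is not in the sample sheet "
            f"({sorted(sheet['sample_id'].astype(str))})"
        )

    run_log: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_STREAMS},
        "reference": reference,
        "samples": {},
    }
    prepared: dict[str, EventTable] = {}
    for row in sheet.itertuples(index=False):
        sid = str(row.sample_id)
        log: dict[str, Any] = {"path": row.path}
        with _stage("read"):
            table = read_fcs(row.path)
        meta = {"sample_id": sid}
        for key in ("strain", "time_h", "replicate"):
            if hasattr(row, key) and pd.notna(getattr(row, key)):
                meta[key] = getattr(row, key)
        table = _prepare(table.with_metadata(**meta), config, log)
        prepared[sid] = table
        run_log["samples"][sid] = log

    with _stage("reference_fit"):
        classifier = fit_reference(
            prepared[reference],
            dims=config.classify_dims,
            seed=config.stage_seed("mixture"),
            assignment_rule=config.classify_rule,
        )
    with _stage("label_transfer"):
        fractions = timecourse_report(
            [prepared[str(sid)] for sid in sheet["sample_id"].astype(str)], classifier
        )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        fractions.to_csv(os.path.join(out_dir, "fractions.csv"), index=False)
        with open(os.path.join(out_dir, "classifier.json"), "w") as fh:
            fh.write(classifier.to_json())
        config.to_yaml(os.path.join(out_dir, "config.yaml"))
        with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
            json.dump(run_log, fh, indent=2, default=str)
    return fractions, classifier, run_log
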