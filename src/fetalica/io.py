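"""Recording/annotation I/O, configuration files, run reports, benchmarking.

The interchange format is CSV: one row per sample, a header row of
channel labels, an optional leading ``time_s`` column (the sampling rate
is inferred from it; otherwise it must be supplied by the caller), '.'
decimal separator.  Values are written with 17 significant digits so a
write → read round trip is bit-identical.  Channels whose label starts
with ``direct`` are treated as a direct fetal-scalp reference (the
ADFECGDB layout) and excluded from the abdominal matrix by default.

WFDB and EDF container formats are recognised but require the ``wfdb``
and ``pyedflib`` readers; without them those paths raise
:class:`FormatError`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    build_segment_matrix,
    detection_stats,
    match_beats,
    snr_eig,
    snr_rms,
)
from .exceptions import FormatError, StageError, ValidationError
from .ica import IcaConfig, MultichannelRecording
from .pipeline import PipelineConfig, extract_fecg
from .qrs import BeatAnnotations
from .synthetic import SynthConfig, SyntheticRecord, synth_abdominal

__all__ = [
    "load_recording",
    "save_recording",
    "load_beats",
    "save_beats",
    "load_config",
    "RunReport",
    "run_benchmark",
]

#: Label prefix marking the direct fetal-scalp reference channel.
REFERENCE_PREFIX = "direct"


def save_recording(
    recording: MultichannelRecording, path, include_time: bool = True
) -> None:
    """Write a recording as CSV (samples as rows, channels as columns)."""
    path = Path(path)
    cols = {}
    if include_time:
        cols["time_s"] = np.arange(recording.n_samples) / recording.fs
    for i, label in enumerate(recording.labels):
        cols[label] = recording.data[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def load_recording(
    path,
    format_hint: str | None = None,
    fs: float | None = None,
    keep_reference: bool = False,
) -> MultichannelRecording:
    """Load a recording from CSV (WFDB/EDF are recognised but need readers).

    Parameters
    ----------
    path
        Input file.  Format is taken from ``format_hint`` if given, else
        from the extension.
    fs
        Sampling rate in Hz; required when the CSV has no ``time_s``
        column.
    keep_reference
        Keep channels labelled ``direct*`` (the fetal-scalp reference)
        in the returned matrix instead of dropping them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt in ("dat", "hea", "wfdb"):
        raise FormatError(
            "WFDB records require the 'wfdb' reader, which is not installed; "
            "convert the record to CSV (channels as columns)"
        )
    if fmt == "edf":
        raise FormatError(
            "EDF records require the 'pyedflib' reader, which is not installed; "
            "convert the record to CSV (channels as columns)"
        )
    if fmt != "csv":
        raise FormatError(f"unknown recording format {fmt!r}")

    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.isna().any().any():
        raise ValidationError("CSV has missing values (unequal channel lengths?)")
    labels = list(frame.columns)
    if labels and labels[0] == "time_s":
        t = frame.pop("time_s").to_numpy()
        labels = labels[1:]
        if t.size < 2:
            raise ValidationError("time_s column too short to infer fs")
        fs = round(float((t.size - 1) / (t[-1] - t[0])), 9)
    if fs is None:
        raise ValidationError(
            "CSV has no time_s column; pass the sampling rate explicitly"
        )
    if not keep_reference:
        labels = [c for c in labels if not c.lower().startswith(REFERENCE_PREFIX)]
        if not labels:
            raise ValidationError("no abdominal channels left after dropping "
                                  "reference channels")
    data = frame[labels].to_numpy().T
    return MultichannelRecording(data=data, fs=fs, labels=labels)


def save_beats(beats: BeatAnnotations, path) -> None:
    """Write annotations as two-column CSV (sample_index, time_s)."""
    pd.DataFrame(
        {"sample_index": beats.samples, "time_s": beats.times_s}
    ).to_csv(path, index=False, float_format="%.17g")


def load_beats(path, fs: float | None = None) -> BeatAnnotations:
    """Read annotations written by :func:`save_beats`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if "sample_index" not in frame.columns:
        raise FormatError("beat CSV must have a sample_index column")
    if fs is None:
        if "time_s" not in frame.columns:
            raise ValidationError("no time_s column; pass fs explicitly")
        idx = frame["sample_index"].to_numpy()
        t = frame["time_s"].to_numpy()
        nz = t > 0
        if not nz.any():
            raise ValidationError("cannot infer fs from beat times")
        fs = round(float(np.median(idx[nz] / t[nz])), 9)
    return BeatAnnotations(frame["sample_index"].to_numpy(dtype=np.int64), fs)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _build(cls, mapping, nested=()):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = dict(mapping)
    for key, sub_cls in nested:
        if key in kw and isinstance(kw[key], dict):
            kw[key] = _build(sub_cls, kw[key])
    for key in ("beat_window_ms", "maternal_hr_band", "fetal_hr_band",
                "fetal_window_ms"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    return cls(**kw)


def load_config(path) -> dict:
    """Read a YAML config file with optional ``synth``/``pipeline`` sections.

    Returns ``{'synth': SynthConfig, 'pipeline': PipelineConfig}`` built
    from the sections present (defaults otherwise).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config YAML must be a mapping")
    return {
        "synth": _build(SynthConfig, raw.get("synth", {})),
        "pipeline": _build(
            PipelineConfig, raw.get("pipeline", {}), nested=[("ica", IcaConfig)]
        ),
    }


@dataclass
class RunReport:
    """JSON-serialisable record of one pipeline run (enough to re-run it)."""

    command: str
    seed: int
    config: dict
    iterations: list[int] = field(default_factory=list)
    alpha_used: list[float] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def config_snapshot(cfg) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg), default=_jsonable))


# ---------------------------------------------------------------------------
# Benchmarking
# ---------------------------------------------------------------------------


def run_benchmark(
    record: SyntheticRecord | MultichannelRecording | SynthConfig,
    n_repeats: int = 10,
    methods: tuple[str, ...] = ("improved", "conventional"),
    seed: int = 0,
    config: PipelineConfig | None = None,
    tol_ms: float = 50.0,
) -> pd.DataFrame:
    """Repeatedly run the pipeline with fresh random initial vectors.

    For each method and repeat the full pipeline runs with a fresh seed
    drawn from one seeded stream, recording the total ICA iteration
    count and the beat-consistency SNRs of the extracted fetal signal;
    with a :class:`SyntheticRecord` the detection statistics against the
    ground-truth fetal beats are added.  Per-repeat rows are followed by
    one ``mean`` row per method.  Stage failures are recorded in the
    ``error`` column rather than aborting the sweep.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    if isinstance(record, SynthConfig):
        record = synth_abdominal(record)
    cfg = config or PipelineConfig()
    truth = record.fetal_beats if isinstance(record, SyntheticRecord) else None
    recording = record.recording if isinstance(record, SyntheticRecord) else record
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=(len(methods), n_repeats))
    rows = []
    for mi, method in enumerate(methods):
        for rep in range(n_repeats):
            ica_cfg = cfg.ica.replace(method=method, seed=int(child_seeds[mi, rep]))
            run_cfg = dataclasses.replace(cfg, ica=ica_cfg)
            row = {"method": method, "repeat": rep}
            try:
                result = extract_fecg(recording, run_cfg)
            except StageError as err:
                row["error"] = str(err)
                rows.append(row)
                continue
            row["total_iterations"] = result.separation.total_iterations
            try:
                seg = build_segment_matrix(
                    result.fetal_signal, result.fetal_beats, *cfg.fetal_window_ms
                )
                row["snr_eig"] = snr_eig(seg)
                row["snr_rms"] = snr_rms(seg)
            except ValidationError as err:
                row["error"] = f"snr: {err}"
            if truth is not None:
                counts = match_beats(result.fetal_beats, truth, tol_ms)
                sens, ppa, f1 = detection_stats(counts)
                row.update(tp=counts.tp, fp=counts.fp, fn=counts.fn,
                           sens_pct=sens, ppa_pct=ppa, f1_pct=f1)
            rows.append(row)
    table = pd.DataFrame(rows)
    means = []
    numeric = [c for c in table.columns
               if c not in ("method", "repeat", "error")]
    for method in methods:
        sub = table[table["method"] == method]
        mean_row = {"method": method, "repeat": "mean"}
        for col in numeric:
            if col in sub:
                mean_row[col] = sub[col].mean()
        means.append(mean_row)
    return pd.concat([table, pd.DataFrame(means)], ignore_index=True)
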