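"""File formats: TSV channel matrices, JSON manifests, SNIRF (read-only),
and delimited feature tables.

The native on-disk format is one TSV per subject (rows = samples, columns =
``ch01_HbO … chNN_HbO, ch01_HbR … chNN_HbR``) with a JSON sidecar/manifest
carrying sampling rate and paradigm timing.  SNIRF v1 (HDF5) files holding
processed HbO/HbR blocks are read via h5py.  Time is sample-indexed
internally; all window boundaries are half-open ``[start, end)`` in samples.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import TaskParadigm

__all__ = [
    "HemoRecording",
    "OpticalRecording",
    "FeatureTable",
    "LoadError",
    "read_recording",
    "write_recording",
    "read_snirf",
    "write_feature_table",
    "read_feature_table",
]

SPECIES = ("HbO", "HbR")


class LoadError(ValueError):
    """Raised when an on-disk recording fails validation."""


@dataclass
class HemoRecording:
    """Hemoglobin concentration-change time series.

    ``data`` has shape (n_samples, n_channels, 2) with the species axis
    ordered (HbO, HbR).  Units are concentration change (arbitrary unless
    stated in ``units``); features downstream are scale-covariant, so the
    unit convention does not affect classification.
    """

    data: np.ndarray
    sampling_hz: float
    paradigm: TaskParadigm | None = None
    channel_ids: list[str] = field(default_factory=list)
    units: str = "uM"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ValueError("data must be (n_samples, n_channels, 2)")
        if self.data.shape[1] < 1:
            raise ValueError("need at least one channel")
        if not self.channel_ids:
            self.channel_ids = [
                f"ch{c + 1:02d}" for c in range(self.data.shape[1])
            ]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def task_segment(self) -> np.ndarray:
        """Data restricted to the task window (requires a paradigm)."""
        if self.paradigm is None:
            raise ValueError("recording has no paradigm")
        a, b = self.paradigm.task_window()
        return self.data[a:b]

    def copy_with(self, data: np.ndarray) -> "HemoRecording":
        return HemoRecording(
            data=data,
            sampling_hz=self.sampling_hz,
            paradigm=self.paradigm,
            channel_ids=list(self.channel_ids),
            units=self.units,
        )


@dataclass
class OpticalRecording:
    """Optical-density change per channel at two wavelengths.

    ``od`` has shape (n_samples, n_channels, 2) with the wavelength axis in
    the order of ``wavelengths_nm`` (short, long).
    """

    od: np.ndarray
    sampling_hz: float
    wavelengths_nm: tuple[float, float] = (659.0, 830.0)
    paradigm: TaskParadigm | None = None
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[2] != 2:
            raise ValueError("od must be (n_samples, n_channels, 2)")
        if not self.channel_ids:
            self.channel_ids = [
                f"ch{c + 1:02d}" for c in range(self.od.shape[1])
            ]


def _recording_columns(channel_ids: list[str]) -> list[str]:
    return [f"{ch}_{sp}" for sp in SPECIES for ch in channel_ids]


def write_recording(rec: HemoRecording, path: str | Path,
                    sidecar: bool = True) -> Path:
    """Write a recording as TSV (plus a JSON sidecar with metadata)."""
    path = Path(path)
    nc = rec.n_channels
    flat = np.concatenate([rec.data[:, :, 0], rec.data[:, :, 1]], axis=1)
    df = pd.DataFrame(flat, columns=_recording_columns(rec.channel_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "sampling_hz": rec.sampling_hz,
            "units": rec.units,
            "channel_ids": rec.channel_ids,
            "n_channels": nc,
        }
        if rec.paradigm is not None:
            meta["paradigm"] = rec.paradigm.to_dict()
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    return path


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    manifest = path.parent / "manifest.json"
    if manifest.exists():
        with open(manifest) as fh:
            return json.load(fh)
    return {}


def read_recording(path: str | Path, format: str = "tsv",
                   sampling_hz: float | None = None,
                   paradigm: TaskParadigm | None = None) -> HemoRecording:
    """Read a recording from TSV (+ sidecar/manifest) or SNIRF.

    Validation: every ``chXX_HbO`` column must have a matching ``chXX_HbR``;
    cells must be numeric; NaN runs longer than 1 s are fatal, shorter gaps
    are linearly interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    if format == "snirf":
        return read_snirf(path, paradigm=paradigm)
    if format != "tsv":
        raise ValueError(f"unknown format: {format!r}")

    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise LoadError(
                f"non-numeric value at row {row}, column {col!r} in {path}"
            )
    hbo_cols = [c for c in df.columns if c.endswith("_HbO")]
    hbr_cols = [c.replace("_HbO", "_HbR") for c in hbo_cols]
    missing = [c for c in hbr_cols if c not in df.columns]
    if not hbo_cols or missing:
        raise LoadError(
            f"channel columns incomplete in {path}: missing {missing or 'HbO'}"
        )
    channel_ids = [re.sub(r"_HbO$", "", c) for c in hbo_cols]

    meta = _load_sidecar(path)
    fs = sampling_hz or meta.get("sampling_hz")
    if fs is None:
        raise LoadError(f"sampling rate not given and no sidecar for {path}")
    if sampling_hz is not None and "sampling_hz" in meta and \
            abs(meta["sampling_hz"] - sampling_hz) > 1e-9:
        raise LoadError(
            f"sampling-rate mismatch: caller {sampling_hz} Hz vs "
            f"sidecar {meta['sampling_hz']} Hz"
        )
    if paradigm is None and "paradigm" in meta:
        paradigm = TaskParadigm.from_dict(meta["paradigm"])

    data = np.stack(
        [df[hbo_cols].to_numpy(float), df[hbr_cols].to_numpy(float)], axis=2
    )
    data = _repair_nans(data, float(fs), path)
    return HemoRecording(
        data=data,
        sampling_hz=float(fs),
        paradigm=paradigm,
        channel_ids=channel_ids,
        units=meta.get("units", "uM"),
    )


def _repair_nans(data: np.ndarray, fs: float, path: Path) -> np.ndarray:
    """Interpolate NaN gaps up to 1 s; longer runs are a load error."""
    max_run = int(round(fs))
    if not np.isnan(data).any():
        return data
    out = data.copy()
    n = data.shape[0]
    for c in range(data.shape[1]):
        for s in range(2):
            x = out[:, c, s]
            isnan = np.isnan(x)
            if not isnan.any():
                continue
            # longest run of NaNs
            runs = np.diff(np.flatnonzero(np.diff(
                np.concatenate([[0], isnan.view(np.int8), [0]])
            )))[::2]
            if runs.max() > max_run or isnan.all():
                raise LoadError(
                    f"NaN run longer than 1 s in channel {c}, species {s} "
                    f"of {path}"
                )
            idx = np.arange(n)
            x[isnan] = np.interp(idx[isnan], idx[~isnan], x[~isnan])
    return out


def read_snirf(path: str | Path,
               paradigm: TaskParadigm | None = None) -> HemoRecording:
    """Read processed HbO/HbR blocks from a SNIRF v1 (HDF5) file.

    Channels are keyed by (sourceIndex, detectorIndex); each must appear with
    both an ``HbO`` and an ``HbR`` dataTypeLabel.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data_grp = nirs["data1"]
        ts = np.asarray(data_grp["dataTimeSeries"], dtype=float)
        time = np.asarray(data_grp["time"], dtype=float).ravel()
        if time.size >= 2:
            fs = 1.0 / float(np.median(np.diff(time)))
        else:
            raise LoadError(f"SNIRF time vector too short in {path}")

        ml_names = sorted(
            (k for k in data_grp.keys() if k.startswith("measurementList")),
            key=lambda k: int(k.replace("measurementList", "") or 0),
        )
        columns: dict[tuple[int, int], dict[str, int]] = {}
        for j, name in enumerate(ml_names):
            ml = data_grp[name]
            src = int(np.asarray(ml["sourceIndex"]).item())
            det = int(np.asarray(ml["detectorIndex"]).item())
            label = ""
            if "dataTypeLabel" in ml:
                raw = np.asarray(ml["dataTypeLabel"]).item()
                label = raw.decode() if isinstance(raw, bytes) else str(raw)
            columns.setdefault((src, det), {})[label] = j
        pairs = sorted(columns)
        for pair in pairs:
            have = set(columns[pair])
            if not {"HbO", "HbR"} <= have:
                raise LoadError(
                    f"SNIRF channel S{pair[0]}-D{pair[1]} lacks HbO/HbR "
                    f"blocks (has {sorted(have)}) in {path}"
                )
        data = np.empty((ts.shape[0], len(pairs), 2))
        for c, pair in enumerate(pairs):
            data[:, c, 0] = ts[:, columns[pair]["HbO"]]
            data[:, c, 1] = ts[:, columns[pair]["HbR"]]
        channel_ids = [f"S{s}-D{d}" for s, d in pairs]
    data = _repair_nans(data, fs, path)
    return HemoRecording(
        data=data, sampling_hz=fs, paradigm=paradigm, channel_ids=channel_ids
    )


@dataclass
class FeatureTable:
    """Named feature matrix (subjects × features) with per-subject labels.

    Thin wrapper over a pandas DataFrame whose column names encode
    provenance: ``TF.<kind>.<channel>.<species>`` for temporal features and
    ``CF.pearson.<chA>-<chB>.<species>`` for correlation features.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate feature names: {list(dup)[:5]}")
        self.labels = self.labels.reindex(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def family_columns(self, family: str) -> list[str]:
        return [c for c in self.values.columns if c.startswith(family + ".")]

    def subset_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.values[names].copy(), self.labels.copy())

    def subset_subjects(self, ids: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[ids].copy(), self.labels.loc[ids].copy()
        )

    def sorted_by_id(self) -> "FeatureTable":
        order = sorted(self.values.index)
        return self.subset_subjects(order)

    def X(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def y(self) -> np.ndarray:
        return self.labels.to_numpy()


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as TSV: subject id first, label last."""
    path = Path(path)
    df = table.values.copy()
    df.insert(0, "subject", df.index)
    df["label"] = table.labels.values
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "subject" not in df.columns or "label" not in df.columns:
        raise LoadError(f"feature table {path} lacks subject/label columns")
    df = df.set_index("subject")
    labels = df.pop("label")
    return FeatureTable(df, labels)
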