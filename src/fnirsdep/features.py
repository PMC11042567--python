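"""Temporal and correlation feature extraction from task-window signals.

Per channel and hemoglobin species, nine temporal features (TF) are
computed on the 60-s task segment: maximum, minimum, mean, rectified mean,
skewness, peak (crest) factor, mean squared frequency, power spectral
entropy and singular spectral entropy.  For 18 channels × 2 species this
gives 18×2×9 = 324 TF.  Correlation features (CF) are the Pearson
correlations of every unordered channel pair, separately for ΔHbO and
ΔHbR: C(18,2)×2 = 306 CF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import FeatureTable, HemoRecording

__all__ = [
    "TF_KINDS",
    "TemporalFeatureSet",
    "temporal_features",
    "power_spectral_entropy",
    "singular_spectral_entropy",
    "mean_square_frequency",
    "correlation_features",
    "correlation_feature_names",
    "build_feature_table",
]

log = logging.getLogger(__name__)

TF_KINDS = (
    "max",
    "min",
    "mean",
    "rect_mean",
    "skewness",
    "peak_factor",
    "mean_square_freq",
    "spectral_entropy",
    "singular_entropy",
)

DEFAULT_EMBED_LEN = 50  # singular-spectrum window: 5 s at 10 Hz


@dataclass(frozen=True)
class TemporalFeatureSet:
    """The nine temporal features of one signal."""

    max: float
    min: float
    mean: float
    rect_mean: float
    skewness: float
    peak_factor: float
    mean_square_freq: float
    spectral_entropy: float
    singular_entropy: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, k) for k in TF_KINDS)


def _periodogram(x: np.ndarray, sampling_hz: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided unwindowed FFT periodogram (freqs, power)."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sampling_hz)
    return freqs, spec


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats of a non-negative weight vector."""
    total = p.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    q = p / total
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)))


def power_spectral_entropy(x: np.ndarray, sampling_hz: float = 10.0) -> float:
    """Shannon entropy (nats) of the normalized one-sided periodogram."""
    _, spec = _periodogram(x, sampling_hz)
    if spec.sum() == 0:
        raise ValueError("signal has zero energy")
    return _entropy(spec)


def mean_square_frequency(x: np.ndarray, sampling_hz: float = 10.0) -> float:
    """Power-weighted mean of squared frequency: Σf²P(f) / ΣP(f)."""
    freqs, spec = _periodogram(x, sampling_hz)
    total = spec.sum()
    if total == 0:
        raise ValueError("signal has zero energy")
    return float(np.sum(freqs**2 * spec) / total)


def singular_spectral_entropy(x: np.ndarray,
                              embed_len: int = DEFAULT_EMBED_LEN) -> float:
    """Shannon entropy (nats) of the normalized singular values of the
    Hankel trajectory matrix with window ``embed_len``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 1 < embed_len < n:
        raise ValueError("embed_len must lie strictly between 1 and n")
    ncols = n - embed_len + 1
    idx = np.arange(embed_len)[:, None] + np.arange(ncols)[None, :]
    traj = x[idx]
    sv = np.linalg.svd(traj, compute_uv=False)
    if sv.sum() == 0:
        raise ValueError("signal has zero energy")
    return _entropy(sv)


def temporal_features(x: np.ndarray, sampling_hz: float = 10.0,
                      embed_len: int = DEFAULT_EMBED_LEN
                      ) -> TemporalFeatureSet:
    """Compute the nine temporal features of one task-window signal.

    Degenerate constant signals get defined sentinels: skewness 0 and peak
    factor 1 (logged); the entropies of an all-zero signal are 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    rms = float(np.sqrt(np.mean(x * x)))
    if np.ptp(x) == 0:
        log.warning("constant signal: skewness/peak-factor sentinels used")
        skew = 0.0
        pf = 1.0
    else:
        skew = float(sstats.skew(x))
        pf = float(np.max(np.abs(x)) / rms)
    if rms == 0:
        hf = 0.0
        msf = 0.0
        ht = 0.0
    else:
        hf = power_spectral_entropy(x, sampling_hz)
        msf = mean_square_frequency(x, sampling_hz)
        ht = singular_spectral_entropy(x, min(embed_len, x.size - 1))
    return TemporalFeatureSet(
        max=float(np.max(x)),
        min=float(np.min(x)),
        mean=float(np.mean(x)),
        rect_mean=float(np.mean(np.abs(x))),
        skewness=skew,
        peak_factor=pf,
        mean_square_freq=msf,
        spectral_entropy=hf,
        singular_entropy=ht,
    )


def correlation_features(rec: HemoRecording) -> np.ndarray:
    """Pearson r of every unordered channel pair on the task window,
    HbO pairs first then HbR: C(n,2)×2 values in [-1, 1].

    Zero-variance channels yield r = 0 for their pairs (logged).
    """
    if rec.n_channels < 2:
        raise ValueError("need at least two channels")
    seg = rec.task_segment()
    nc = rec.n_channels
    iu = np.triu_indices(nc, k=1)
    out = []
    for s in range(2):
        block = seg[:, :, s]
        sd = block.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            log.warning("zero-variance channels %s: correlations set to 0",
                        list(np.flatnonzero(degenerate)))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(block, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        out.append(r[iu])
    return np.concatenate(out)


def correlation_feature_names(channel_ids: list[str]) -> list[str]:
    iu = np.triu_indices(len(channel_ids), k=1)
    names = []
    for sp in ("HbO", "HbR"):
        names.extend(
            f"CF.pearson.{channel_ids[i]}-{channel_ids[j]}.{sp}"
            for i, j in zip(*iu)
        )
    return names


def temporal_feature_names(channel_ids: list[str]) -> list[str]:
    return [
        f"TF.{kind}.{ch}.{sp}"
        for kind in TF_KINDS
        for ch in channel_ids
        for sp in ("HbO", "HbR")
    ]


def build_feature_table(recordings: list[HemoRecording],
                        labels: list[str],
                        subject_ids: list[str] | None = None,
                        families: tuple[str, ...] = ("TF", "CF"),
                        embed_len: int = DEFAULT_EMBED_LEN) -> FeatureTable:
    """Assemble the subjects × features matrix for a cohort.

    Column order is deterministic: TF block (kind, channel, species) then
    CF block (species, pair).  For n channels the counts are n×2×9 TF and
    n(n−1) CF.
    """
    if not recordings:
        raise ValueError("empty cohort")
    nc = recordings[0].n_channels
    ids0 = recordings[0].channel_ids
    for rec in recordings:
        if rec.n_channels != nc:
            raise ValueError("heterogeneous channel counts in cohort")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(recordings))]

    columns: list[str] = []
    if "TF" in families:
        columns += temporal_feature_names(ids0)
    if "CF" in families:
        columns += correlation_feature_names(ids0)

    rows = np.empty((len(recordings), len(columns)))
    for i, rec in enumerate(recordings):
        vals: list[float] = []
        if "TF" in families:
            seg = rec.task_segment()
            feats = np.empty((len(TF_KINDS), nc, 2))
            for c in range(nc):
                for s in range(2):
                    feats[:, c, s] = temporal_features(
                        seg[:, c, s], rec.sampling_hz, embed_len
                    ).as_tuple()
            vals.extend(feats.ravel())
        if "CF" in families:
            vals.extend(correlation_features(rec))
        rows[i] = vals

    df = pd.DataFrame(rows, index=subject_ids, columns=columns)
    return FeatureTable(df, pd.Series(labels, index=subject_ids))
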