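"""Synthetic fNIRS cohort generation.

Emulates a block-design verbal fluency task (VFT) recording: a task-locked
hemodynamic response (boxcar convolved with a canonical double-gamma HRF),
physiological nuisance components (cardiac 0.5-2.0 Hz, respiration
0.2-0.4 Hz, slow drift), broadband sensor noise, and spike/shift motion
artifacts.  Two diagnostic groups ("mild" and "severe" depression) differ in
the mean task-evoked prefrontal activation amplitude, with mild > severe.

Every random draw flows from a single explicit seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TaskParadigm",
    "NoiseProfile",
    "CohortSpec",
    "SyntheticSubject",
    "double_gamma_hrf",
    "task_regressor",
    "simulate_recording",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class TaskParadigm:
    """Block paradigm timing: rest / task / rest, in seconds."""

    pre_rest_s: float = 30.0
    task_s: float = 60.0
    post_rest_s: float = 30.0
    sampling_hz: float = 10.0

    def __post_init__(self) -> None:
        for name in ("pre_rest_s", "task_s", "post_rest_s", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TaskParadigm.{name} must be positive")

    @property
    def n_samples(self) -> int:
        total = self.pre_rest_s + self.task_s + self.post_rest_s
        return int(round(total * self.sampling_hz))

    def task_window(self) -> tuple[int, int]:
        """Half-open [start, end) sample window covering the task block."""
        start = int(round(self.pre_rest_s * self.sampling_hz))
        end = start + int(round(self.task_s * self.sampling_hz))
        return start, end

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskParadigm":
        return cls(**d)


@dataclass(frozen=True)
class NoiseProfile:
    """Amplitudes and band centres of the nuisance components.

    Frequencies are jittered per subject but stay inside the physiological
    bands (cardiac 0.5-2.0 Hz, respiration 0.2-0.4 Hz).  Amplitudes are in
    the same arbitrary concentration units as the evoked response (which has
    unit peak amplitude for the reference "severe" group).
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.25
    resp_hz: float = 0.3
    resp_amp: float = 0.3
    drift_amp: float = 0.4
    white_sigma: float = 0.15
    artifact_rate: float = 2.0  # expected motion artifacts per recording

    def is_silent(self) -> bool:
        return (
            self.cardiac_amp == 0
            and self.resp_amp == 0
            and self.drift_amp == 0
            and self.white_sigma == 0
            and self.artifact_rate == 0
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CohortSpec:
    """Composition and effect structure of a synthetic cohort."""

    n_severe: int = 82
    n_mild: int = 58
    n_channels: int = 18
    effect_size: float = 1.0
    noise_profile: NoiseProfile = field(default_factory=NoiseProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_severe < 0 or self.n_mild < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")


@dataclass
class SyntheticSubject:
    """One simulated participant: noisy recording plus its clean ground truth.

    ``recording`` and ``ground_truth`` are (n_samples, n_channels, 2) arrays,
    species axis ordered (HbO, HbR).  The clean traces enable true-SNR
    validation of denoising methods.
    """

    subject_id: str
    label: str  # "mild" | "severe"
    recording: "HemoRecording"
    ground_truth: np.ndarray
    amplitude: float  # realized subject-level evoked amplitude

    def __post_init__(self) -> None:
        if self.recording.data.shape != self.ground_truth.shape:
            raise ValueError("recording and ground truth must share shape")


# severe group mean evoked amplitude (arbitrary conc. units) and the
# marginal per-channel amplitude SD used to standardize the group
# difference; amplitude variance splits evenly between a subject-level
# latent and independent per-channel deviations, so the group effect is
# spatially distributed rather than a single shared latent
_BASE_AMP = 1.0
_BETWEEN_SD = 0.3
_SUBJECT_SD = _BETWEEN_SD / np.sqrt(2.0)
_CHANNEL_SD = _BETWEEN_SD / np.sqrt(2.0)
_HBR_RATIO = -1.0 / 3.0
_HBR_LAG_S = 1.0


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Positive gamma peaking near ``peak_s`` minus a scaled undershoot gamma;
    normalized to unit peak.
    """
    h = _gamma_dist.pdf(t, a=peak_s, scale=1.0)
    h = h - undershoot_ratio * _gamma_dist.pdf(t, a=undershoot_s, scale=1.0)
    m = h.max()
    if m > 0:
        h = h / m
    return h


def task_regressor(paradigm: TaskParadigm) -> np.ndarray:
    """Boxcar over the task block convolved with the canonical HRF.

    Normalized to unit peak, so a subject's evoked amplitude is directly the
    peak concentration change.
    """
    n = paradigm.n_samples
    fs = paradigm.sampling_hz
    box = np.zeros(n)
    a, b = paradigm.task_window()
    box[a:b] = 1.0
    t_hrf = np.arange(0, 32.0, 1.0 / fs)
    hrf = double_gamma_hrf(t_hrf)
    reg = np.convolve(box, hrf)[:n]
    m = np.abs(reg).max()
    if m > 0:
        reg = reg / m
    return reg


def _smooth_spike(n: int, center: int, width_samples: int,
                  amp: float) -> np.ndarray:
    """Impulse smoothed with a Gaussian bump of the given width (samples)."""
    t = np.arange(n)
    sigma = max(width_samples / 4.0, 1.0)
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _artifact_series(n: int, fs: float, rate: float,
                     scale: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-placed spike and step-shift motion artifacts."""
    art = np.zeros(n)
    if rate <= 0:
        return art
    k = rng.poisson(rate)
    for _ in range(k):
        pos = int(rng.integers(0, n))
        amp = scale * rng.uniform(2.0, 5.0) * rng.choice([-1.0, 1.0])
        if rng.uniform() < 0.5:  # spike smoothed over 0.5 s
            art += _smooth_spike(n, pos, int(round(0.5 * fs)), amp)
        else:  # baseline shift
            art[pos:] += amp
    return art


def group_mean_amplitude(label: str, effect_size: float) -> float:
    """Mean evoked amplitude for a group; mild exceeds severe by
    ``effect_size`` between-subject standard deviations."""
    if label == "severe":
        return _BASE_AMP
    if label == "mild":
        return _BASE_AMP + effect_size * _BETWEEN_SD
    raise ValueError(f"unknown group label: {label!r}")


def simulate_recording(spec: CohortSpec, label: str, paradigm: TaskParadigm,
                       rng: np.random.Generator,
                       subject_id: str = "sub-000") -> SyntheticSubject:
    """Simulate one subject's multichannel ΔHbO/ΔHbR recording.

    ΔHbO per channel = subject amplitude × channel gain × HRF regressor,
    plus cardiac + respiratory sinusoids, linear drift, white noise and
    motion artifacts.  ΔHbR is a −1/3-scaled, 1-s-lagged counterpart with
    proportionally scaled noise.  The clean (noise-free) traces are kept
    alongside.
    """
    from .io import HemoRecording  # local import to avoid cycle

    n = paradigm.n_samples
    fs = paradigm.sampling_hz
    nc = spec.n_channels
    prof = spec.noise_profile

    mu = group_mean_amplitude(label, spec.effect_size)
    amp = mu + rng.normal(0.0, _SUBJECT_SD)  # subject-level latent

    reg = task_regressor(paradigm)
    t = np.arange(n) / fs

    # subject-level nuisance frequencies, clipped to physiological bands
    f_card = float(np.clip(rng.normal(prof.cardiac_hz, 0.15), 0.55, 1.95))
    f_resp = float(np.clip(rng.normal(prof.resp_hz, 0.03), 0.21, 0.39))

    lag = int(round(_HBR_LAG_S * fs))
    clean = np.empty((n, nc, 2))
    noisy = np.empty((n, nc, 2))
    for c in range(nc):
        amp_c = max(amp + rng.normal(0.0, _CHANNEL_SD), 0.05)
        hbo_clean = amp_c * reg
        hbr_clean = _HBR_RATIO * np.concatenate(
            [np.repeat(hbo_clean[0], lag), hbo_clean[: n - lag]]
        )
        clean[:, c, 0] = hbo_clean
        clean[:, c, 1] = hbr_clean
        for s, base in ((0, hbo_clean), (1, hbr_clean)):
            sc = 1.0 if s == 0 else abs(_HBR_RATIO)
            noise = (
                sc * prof.cardiac_amp
                * np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi))
                + sc * prof.resp_amp
                * np.sin(2 * np.pi * f_resp * t + rng.uniform(0, 2 * np.pi))
                + sc * prof.drift_amp * rng.uniform(-1, 1) * (t / t[-1])
            )
            if prof.white_sigma > 0:
                noise = noise + rng.normal(0, sc * prof.white_sigma, n)
            noise = noise + _artifact_series(
                n, fs, prof.artifact_rate, sc * 0.5, rng
            )
            noisy[:, c, s] = base + noise

    rec = HemoRecording(
        data=noisy,
        sampling_hz=fs,
        paradigm=paradigm,
        channel_ids=[f"ch{c + 1:02d}" for c in range(nc)],
    )
    return SyntheticSubject(
        subject_id=subject_id,
        label=label,
        recording=rec,
        ground_truth=clean,
        amplitude=amp,
    )


def simulate_cohort(spec: CohortSpec,
                    paradigm: TaskParadigm | None = None
                    ) -> list[SyntheticSubject]:
    """Simulate ``n_severe + n_mild`` subjects, reproducibly from the seed."""
    paradigm = paradigm or TaskParadigm()
    labels = ["severe"] * spec.n_severe + ["mild"] * spec.n_mild
    seeds = np.random.SeedSequence(spec.seed).spawn(len(labels))
    cohort = []
    for i, (label, ss) in enumerate(zip(labels, seeds)):
        rng = np.random.default_rng(ss)
        cohort.append(
            simulate_recording(spec, label, paradigm, rng,
                               subject_id=f"sub-{i + 1:03d}")
        )
    return cohort


def write_cohort(cohort: list[SyntheticSubject], out_dir: str | Path,
                 spec: CohortSpec | None = None) -> Path:
    """Write one TSV matrix per subject plus a JSON cohort manifest."""
    from .io import write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    if spec is not None:
        manifest["seed"] = spec.seed
        manifest["n_severe"] = spec.n_severe
        manifest["n_mild"] = spec.n_mild
        manifest["effect_size"] = spec.effect_size
        manifest["noise_profile"] = spec.noise_profile.to_dict()
    for subj in cohort:
        fname = f"{subj.subject_id}.tsv"
        write_recording(subj.recording, out_dir / fname)
        manifest["subjects"].append(
            {"id": subj.subject_id, "label": subj.label, "file": fname}
        )
    if cohort:
        manifest["paradigm"] = cohort[0].recording.paradigm.to_dict()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir
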