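"""Synthetic paired pre/post fNIRS cohorts with known ground-truth connectivity.

The generator emulates 5-minute, 22-channel resting-state recordings at
7.4074 Hz.  The hemodynamic component is a band-limited (0.02-0.1 Hz)
Gaussian process whose cross-channel correlation equals a planted
correlation matrix exactly in population: white noise is filtered with the
same Butterworth band design used in preprocessing, standardized, and mixed
through the symmetric square root of the target correlation matrix.  On top
of that, each channel independently receives nuisance oscillators (cardiac
~1.2 Hz, respiratory ~0.3 Hz, Mayer waves ~0.1 Hz, random phase per
channel), a linear slow drift, broadband white noise, and sparse motion
spikes (boxcar-plus-exponential transients).

Noise amplitudes are expressed as multiples of the hemodynamic signal's
standard deviation; concentrations are in delta-mM with a 1 uM hemodynamic
scale.  All generators are pure functions of their arguments including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import montage as mtg
from .errors import InvalidParameterError
from .preprocess import (
    DEFAULT_FS,
    HEMO_BAND,
    HbTimeSeries,
    MbllParams,
    RawIntensityRecording,
    bandpass,
    mbll_forward,
)

#: standard deviation of the hemodynamic component, delta-mM (= 1 uM)
HEMO_SD_MM = 1e-3

DEFAULT_DURATION_S = 300.0
PAPER_GROUP_SIZES = {"morning": 17, "afternoon": 18, "night": 19}


@dataclass(frozen=True)
class NoiseSpec:
    """Nuisance model for one recording.

    Oscillator and spike amplitudes are in units of the hemodynamic signal
    SD; ``drift_slope_sd`` is the SD of the half-excursion of a linear drift
    over the recording; ``spike_rate_per_min`` is the expected number of
    motion transients per channel per minute.
    """

    cardiac_hz: float = 1.2
    resp_hz: float = 0.3
    mayer_hz: float = 0.1
    osc_amplitudes: tuple[float, float, float] = (0.5, 0.4, 0.3)
    drift_slope_sd: float = 1.0
    white_sd: float = 0.4
    spike_rate_per_min: float = 0.5
    spike_amplitude_sd: float = 3.0

    def __post_init__(self) -> None:
        amps = (*self.osc_amplitudes, self.drift_slope_sd, self.white_sd,
                self.spike_rate_per_min, self.spike_amplitude_sd)
        if any(a < 0 for a in amps):
            raise InvalidParameterError("noise amplitudes and rates must be non-negative")
        if len(self.osc_amplitudes) != 3:
            raise InvalidParameterError("osc_amplitudes must give (cardiac, resp, mayer)")

    @classmethod
    def quiet(cls) -> "NoiseSpec":
        """All nuisance components switched off (pure hemodynamic signal)."""
        return cls(osc_amplitudes=(0.0, 0.0, 0.0), drift_slope_sd=0.0,
                   white_sd=0.0, spike_rate_per_min=0.0, spike_amplitude_sd=0.0)

    def validate_for_fs(self, fs: float) -> None:
        for f in (self.cardiac_hz, self.resp_hz, self.mayer_hz):
            if f >= fs / 2:
                raise InvalidParameterError(f"oscillator at {f} Hz is above Nyquist ({fs / 2} Hz)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted population channel-pair correlation structure."""

    correlation: np.ndarray
    hemo_band: tuple[float, float] = HEMO_BAND

    def __post_init__(self) -> None:
        c = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidParameterError("correlation target must be square")
        if not np.allclose(c, c.T, atol=1e-12):
            raise InvalidParameterError("correlation target must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise InvalidParameterError("correlation target must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise InvalidParameterError("correlation target is not positive semidefinite")

    @property
    def n_channels(self) -> int:
        return self.correlation.shape[0]

    def mixing_matrix(self) -> np.ndarray:
        """Symmetric square root of the correlation target."""
        w, v = np.linalg.eigh(self.correlation)
        w = np.clip(w, 0.0, None)
        return (v * np.sqrt(w)) @ v.T


@dataclass
class SyntheticCohort:
    """Paired pre/post recordings for one shift group, with planted truth."""

    group_label: str
    subjects: list[tuple[HbTimeSeries, HbTimeSeries]]
    truth_pre: GroundTruth
    truth_post: GroundTruth
    seed: int
    fs_hz: float = DEFAULT_FS
    duration_s: float = DEFAULT_DURATION_S
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def pre(self) -> list[HbTimeSeries]:
        return [s[0] for s in self.subjects]

    @property
    def post(self) -> list[HbTimeSeries]:
        return [s[1] for s in self.subjects]


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at 0 followed by diagonal renormalization."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, 0.0, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(c), 1e-12, None))
    c = c / np.outer(d, d)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


def make_block_correlation(
    within_r: float,
    between_r: float,
    partition: dict[str, tuple[int, ...]] | None = None,
    n_channels: int = mtg.N_CHANNELS,
) -> GroundTruth:
    """ROI-block correlation target: ``within_r`` inside each ROI block,
    ``between_r`` elsewhere off-diagonal, repaired to the nearest valid
    correlation matrix if needed.

    ``partition`` maps block labels to 1-based channel indices and defaults
    to the montage's dlPFC/FPC/OFC partition.
    """
    if not (-1.0 < between_r <= within_r < 1.0):
        raise InvalidParameterError("require -1 < between_r <= within_r < 1")
    if partition is None:
        partition = mtg.ROI_CHANNELS
    c = np.full((n_channels, n_channels), between_r, dtype=float)
    for members in partition.values():
        idx = np.asarray(members, dtype=int) - 1
        c[np.ix_(idx, idx)] = within_r
    np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() < 0:
        c = _nearest_correlation(c)
    return GroundTruth(correlation=c)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def simulate_hb(
    truth: GroundTruth,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    subject_id: str = "",
    session: str = "pre",
) -> HbTimeSeries:
    """Simulate one oxy-Hb recording with the planted correlation structure.

    Deterministic given ``seed``.  See the module docstring for the model.
    """
    if noise is None:
        noise = NoiseSpec()
    n = int(round(duration_s * fs))
    if n < 64:
        raise InvalidParameterError("duration_s * fs must give at least 64 samples")
    noise.validate_for_fs(fs)
    nch = truth.n_channels
    rng = np.random.default_rng(seed)

    # band-limited hemodynamic process with planted cross-channel correlation
    white = rng.standard_normal((nch, n))
    base = bandpass(white, fs, truth.hemo_band[0], truth.hemo_band[1])
    sd = base.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    base = (base - base.mean(axis=1, keepdims=True)) / sd
    values = HEMO_SD_MM * (truth.mixing_matrix() @ base)

    t = np.arange(n) / fs
    freqs = (noise.cardiac_hz, noise.resp_hz, noise.mayer_hz)
    for f, amp in zip(freqs, noise.osc_amplitudes):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=nch)
        if amp > 0:
            values += amp * HEMO_SD_MM * np.sin(2.0 * np.pi * f * t[None, :] + phases[:, None])

    slopes = rng.normal(0.0, noise.drift_slope_sd, size=nch)
    if noise.drift_slope_sd > 0:
        ramp = (t / t[-1]) * 2.0 - 1.0  # -1..1 over the recording
        values += HEMO_SD_MM * slopes[:, None] * ramp[None, :]

    if noise.white_sd > 0:
        values += rng.normal(0.0, noise.white_sd * HEMO_SD_MM, size=(nch, n))
    else:
        rng.normal(0.0, 1.0, size=(nch, n))  # keep the draw sequence fixed

    values += _motion_spikes(rng, noise, nch, n, fs)

    return HbTimeSeries(values, fs_hz=fs, chromophore="oxy",
                        subject_id=subject_id, session=session)


def _motion_spikes(rng: np.random.Generator, noise: NoiseSpec,
                   nch: int, n: int, fs: float) -> np.ndarray:
    """Sparse boxcar-plus-exponential transients, Poisson-many per channel."""
    out = np.zeros((nch, n))
    expected = noise.spike_rate_per_min * (n / fs) / 60.0
    counts = rng.poisson(expected, size=nch)
    if noise.spike_rate_per_min == 0 or noise.spike_amplitude_sd == 0:
        return out
    box = int(round(0.4 * fs))  # ~0.4 s plateau
    tau = 1.5 * fs              # ~1.5 s recovery
    tail = np.exp(-np.arange(int(6 * tau)) / tau)
    kernel = np.concatenate([np.ones(max(box, 1)), tail])
    for ch in range(nch):
        for _ in range(counts[ch]):
            onset = rng.integers(0, n)
            amp = rng.normal(0.0, noise.spike_amplitude_sd * HEMO_SD_MM)
            seg = kernel[: n - onset]
            out[ch, onset:onset + seg.size] += amp * seg
    return out


def hb_to_intensity(
    hb: HbTimeSeries,
    baseline_intensity: float | np.ndarray = 1.0,
    mbll_params: MbllParams | None = None,
    deoxy: HbTimeSeries | None = None,
) -> RawIntensityRecording:
    """Exact forward MBLL: concentrations -> dual-wavelength intensities.

    If no deoxy series is supplied it is assumed zero (flagged on the
    recording).  The recording stores its baseline so that
    ``intensity_to_od(rec, baseline="stored")`` followed by ``mbll`` is an
    algebraic identity.
    """
    if mbll_params is None:
        mbll_params = MbllParams()
    deoxy_vals = np.zeros_like(hb.values) if deoxy is None else deoxy.values
    od = mbll_forward(hb.values, deoxy_vals, mbll_params)
    base = np.asarray(baseline_intensity, dtype=float)
    if base.ndim == 0:
        base = np.full((hb.n_channels, 2), float(base))
    if np.any(base <= 0):
        raise InvalidParameterError("baseline intensity must be positive")
    intensities = base[:, :, None] * 10.0 ** (-od)
    return RawIntensityRecording(
        intensities,
        fs_hz=hb.fs_hz,
        subject_id=hb.subject_id,
        session=hb.session,
        baseline_intensity=base,
        deoxy_assumed_zero=deoxy is None,
    )


def generate_paired_cohort(
    n_subjects: int,
    truth_pre: GroundTruth,
    truth_post: GroundTruth,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    group_label: str = "morning",
) -> SyntheticCohort:
    """Paired pre/post cohort; per-subject seeds derived from the master seed."""
    if n_subjects < 2:
        raise InvalidParameterError("a paired cohort needs at least 2 subjects")
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))
    subjects = []
    for i in range(n_subjects):
        sid = f"{group_label}-{i + 1:02d}"
        pre = simulate_hb(truth_pre, duration_s, fs, noise, int(sub_seeds[i, 0]),
                          subject_id=sid, session="pre")
        post = simulate_hb(truth_post, duration_s, fs, noise, int(sub_seeds[i, 1]),
                           subject_id=sid, session="post")
        subjects.append((pre, post))
    return SyntheticCohort(
        group_label=group_label, subjects=subjects, truth_pre=truth_pre,
        truth_post=truth_post, seed=seed, fs_hz=fs, duration_s=duration_s,
        noise=noise,
    )
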