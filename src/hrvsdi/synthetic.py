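"""Synthetic anaesthesia cases with known ground truth.

Every downstream stage of the pipeline (R-peak detection, Berger
resampling, the SDI, the regression onto expert consciousness scores)
is validated against data produced here: a four-stage depth-of-anaesthesia
(DoA) trajectory, an R-R interval process whose variability tracks that
trajectory, a rendered single-lead ECG with exact ground-truth R-peak
times, and a panel of noisy simulated assessor curves.

The generator's core premise is the clinical observation the SDI
exploits: beat-to-beat heart-rate variability is high while a patient is
awake and strongly suppressed under anaesthetic maintenance.  R-R mean
and standard deviation therefore interpolate between an "awake" and an
"anaesthesia" regime as a function of the instantaneous DoA score, with
a respiratory sinus-arrhythmia modulation whose amplitude also scales
with DoA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError

STAGES = ("awake", "induction", "maintenance", "emergence")

# Fractions of total case duration spent in each anaesthetic stage.
_STAGE_FRACTIONS = {"awake": 0.12, "induction": 0.10, "maintenance": 0.63, "emergence": 0.15}

# DoA score levels (0 = deep coma, 100 = fully awake).
_AWAKE_LEVEL = 94.0
_MAINTENANCE_LEVEL = 52.0
_EMERGENCE_LEVEL = 88.0
_PROFILE_DT = 1.0  # s, grid step of the ground-truth trajectory


@dataclass(frozen=True)
class StateProfile:
    """Ground-truth DoA trajectory on a uniform grid.

    times
        Seconds, strictly increasing, uniform.
    doa
        Dimensionless consciousness score in [0, 100].
    stage_labels
        One of ``awake``/``induction``/``maintenance``/``emergence`` per
        time point; stages occur in that order.
    """

    times: np.ndarray
    doa: np.ndarray
    stage_labels: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("profile times must be strictly increasing")
        if np.any(self.doa < 0) or np.any(self.doa > 100):
            raise InvalidArgumentError("doa scores must lie in [0, 100]")

    def doa_at(self, t: np.ndarray | float) -> np.ndarray:
        """Linearly interpolated DoA score at arbitrary times."""
        return np.interp(t, self.times, self.doa)

    def stage_mask(self, stage: str) -> np.ndarray:
        return self.stage_labels == stage


@dataclass
class SimulationParams:
    """Knobs of the synthetic-case generator.

    All times in seconds, amplitudes in mV, scores on the 0-100 DoA
    scale.  ``rr_sd_awake > rr_sd_anaesthesia`` is the generator's core
    premise (variability falls under anaesthesia) and is enforced.
    """

    duration: float = 1800.0
    ecg_fs: float = 500.0
    rr_mean_awake: float = 0.8
    rr_mean_anaesthesia: float = 1.0
    rr_sd_awake: float = 0.05
    rr_sd_anaesthesia: float = 0.01
    rr_rsa_amplitude: float = 0.02
    respiratory_freq: float = 0.25
    powerline_amplitude: float = 0.05
    noise_sd: float = 0.02
    n_assessors: int = 5
    assessor_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for name in ("duration", "ecg_fs", "rr_mean_awake", "rr_mean_anaesthesia",
                     "rr_sd_awake", "rr_sd_anaesthesia", "respiratory_freq"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        for name in ("rr_rsa_amplitude", "powerline_amplitude", "noise_sd", "assessor_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")
        if self.n_assessors < 1:
            raise InvalidArgumentError("n_assessors must be >= 1")
        if self.rr_sd_awake <= self.rr_sd_anaesthesia:
            raise InvalidArgumentError(
                "rr_sd_awake must exceed rr_sd_anaesthesia (variability falls under anaesthesia)")

    def to_dict(self) -> dict:
        return asdict(self)


def _smooth_noise(rng: np.random.Generator, n: int, sigma_samples: float, sd: float) -> np.ndarray:
    """Zero-mean low-pass noise with the requested pointwise SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    raw = ndimage.gaussian_filter1d(rng.normal(size=n + 200), sigma_samples, mode="reflect")
    raw = raw[100:100 + n]
    raw -= raw.mean()
    s = raw.std()
    return raw * (sd / s) if s > 0 else np.zeros(n)


def generate_state_profile(duration: float, seed: int) -> StateProfile:
    """Generate a four-stage DoA trajectory: awake plateau, monotone
    induction descent, maintenance plateau fluctuating inside [40, 65],
    and monotone emergence ascent.

    Parameters
    ----------
    duration
        Total case length in seconds; must be >= 300 so every stage has
        room to exist.
    seed
        Seeds the plateau fluctuations; the call is fully deterministic.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if duration < 300:
        raise InvalidArgumentError("duration must be >= 300 s for all four stages to fit")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, _PROFILE_DT)
    n = times.size

    bounds = np.cumsum([_STAGE_FRACTIONS[s] for s in STAGES]) * n
    i_awake, i_ind, i_maint, _ = (int(round(b)) for b in bounds)

    labels = np.empty(n, dtype=object)
    labels[:i_awake] = "awake"
    labels[i_awake:i_ind] = "induction"
    labels[i_ind:i_maint] = "maintenance"
    labels[i_maint:] = "emergence"

    doa = np.empty(n)
    # Awake plateau: near-full consciousness with slow jitter.
    awake = _AWAKE_LEVEL + _smooth_noise(rng, i_awake, 30.0, 1.5)
    doa[:i_awake] = np.clip(awake, 88.0, 100.0)
    # Maintenance plateau: surgical range, slow fluctuation kept inside [42, 64].
    maint = _MAINTENANCE_LEVEL + _smooth_noise(rng, i_maint - i_ind, 60.0, 4.0)
    doa[i_ind:i_maint] = np.clip(maint, 42.0, 64.0)
    # Induction: monotone cosine descent joining the two plateaus.
    m = i_ind - i_awake
    ramp = 0.5 * (1 + np.cos(np.pi * np.arange(1, m + 1) / (m + 1)))
    doa[i_awake:i_ind] = doa[i_ind] + (doa[i_awake - 1] - doa[i_ind]) * ramp
    # Emergence: monotone ascent back toward wakefulness.
    m = n - i_maint
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, m + 1) / m))
    doa[i_maint:] = doa[i_maint - 1] + (_EMERGENCE_LEVEL - doa[i_maint - 1]) * ramp

    return StateProfile(times=times, doa=np.clip(doa, 0.0, 100.0),
                        stage_labels=np.asarray(labels, dtype=object))


def generate_rr_from_state(profile: StateProfile, params: SimulationParams):
    """Simulate R-peak times whose local R-R mean/SD interpolate between
    the awake and anaesthesia regimes as a function of DoA.

    Beat k at time t draws its interval from
    ``N(mu(doa), sd(doa)^2)`` plus a respiratory sinus-arrhythmia term
    ``a * (doa/100) * sin(2*pi*f_resp*t)``; intervals are floored at
    0.25 s.  Returns an :class:`~hrvsdi.hrv.RRSeries`.
    """
    from .hrv import RRSeries  # local import to avoid a cycle

    rng = np.random.default_rng(params.seed)
    duration = float(profile.times[-1])
    peak_times = []
    t = 0.0
    while t <= duration:
        peak_times.append(t)
        frac = float(profile.doa_at(t)) / 100.0
        mu = params.rr_mean_anaesthesia + frac * (params.rr_mean_awake - params.rr_mean_anaesthesia)
        sd = params.rr_sd_anaesthesia + frac * (params.rr_sd_awake - params.rr_sd_anaesthesia)
        rsa = params.rr_rsa_amplitude * frac * np.sin(2 * np.pi * params.respiratory_freq * t)
        rr = mu + sd * rng.standard_normal() + rsa
        t += max(rr, 0.25)
    peaks = np.asarray(peak_times)
    return RRSeries(peak_times=peaks, intervals=np.diff(peaks))


# --- ECG rendering -----------------------------------------------------

# QRS-complex template: localized Gaussian bumps (amplitude mV, centre s, width s).
_TEMPLATE_BUMPS = (
    (0.12, -0.20, 0.025),   # P wave
    (-0.10, -0.025, 0.008),  # Q
    (1.00, 0.0, 0.009),      # R (the detected peak)
    (-0.15, 0.025, 0.009),   # S
    (0.25, 0.22, 0.045),     # T wave
)
_TEMPLATE_HALF_WIDTH = 0.35  # s

R_AMPLITUDE = 1.0  # mV, template R-peak height


def ecg_template(t: np.ndarray) -> np.ndarray:
    """Beat template evaluated at offsets ``t`` (s) from the R peak."""
    out = np.zeros_like(np.asarray(t, dtype=float))
    for amp, centre, width in _TEMPLATE_BUMPS:
        out += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return out


def render_ecg(rr, params: SimulationParams):
    """Render a waveform by placing the beat template at each R time.

    Returns ``(ECGRecord, true_peak_times)`` where the peak times are the
    exact template centres (the generator's ground truth).  Optional
    additive 60 Hz powerline interference and white broadband noise are
    controlled by ``params.powerline_amplitude`` and ``params.noise_sd``.
    """
    from .preprocessing import ECGRecord

    if len(rr.peak_times) == 0:
        raise InvalidArgumentError("rr series is empty")
    if params.ecg_fs < 100:
        raise InvalidArgumentError("ecg_fs must be >= 100 Hz to resolve the QRS template")

    fs = params.ecg_fs
    peaks = np.asarray(rr.peak_times, dtype=float)
    n = int(np.ceil((peaks[-1] + _TEMPLATE_HALF_WIDTH) * fs)) + 1
    samples = np.zeros(n)
    half = int(np.ceil(_TEMPLATE_HALF_WIDTH * fs))
    for p in peaks:
        centre = int(round(p * fs))
        lo, hi = max(0, centre - half), min(n, centre + half + 1)
        tt = np.arange(lo, hi) / fs - p
        samples[lo:hi] += ecg_template(tt)

    rng = np.random.default_rng(params.seed + 1)
    t_axis = np.arange(n) / fs
    if params.powerline_amplitude > 0:
        samples = samples + params.powerline_amplitude * np.sin(2 * np.pi * 60.0 * t_axis)
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, size=n)

    record = ECGRecord(fs=fs, samples=samples, artifact_mask=np.zeros(n, dtype=bool),
                       meta={"synthetic": True, "n_beats": int(peaks.size)})
    return record, peaks.copy()


def simulate_assessors(profile: StateProfile, params: SimulationParams) -> list:
    """Simulate the panel of expert assessor curves.

    Each assessor sees the true trajectory through a small time lag and a
    smooth (low-pass) zero-mean score offset, clipped to [0, 100] — the
    hand-drawn, visually smooth curves clinicians produce.  Both the lag
    scale and the offset SD are proportional to ``assessor_noise_sd`` so
    a zero-noise panel reproduces the ground truth exactly.

    Returns a list of ``(times, scores)`` pairs on the profile grid.
    """
    rng = np.random.default_rng(params.seed + 2)
    curves = []
    n = profile.times.size
    for _ in range(params.n_assessors):
        lag = rng.normal(0.0, 0.4 * params.assessor_noise_sd)  # s
        offset = _smooth_noise(rng, n, 45.0 / _PROFILE_DT, params.assessor_noise_sd)
        scores = np.interp(profile.times - lag, profile.times, profile.doa) + offset
        curves.append((profile.times.copy(), np.clip(scores, 0.0, 100.0)))
    return curves


def simulate_case(params: SimulationParams):
    """Convenience: full synthetic case (profile, rr, ecg, true peaks, assessors)."""
    profile = generate_state_profile(params.duration, params.seed)
    rr = generate_rr_from_state(profile, params)
    record, true_peaks = render_ecg(rr, params)
    assessors = simulate_assessors(profile, params)
    return profile, rr, record, true_peaks, assessors
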