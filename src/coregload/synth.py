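"""Ground-truth simulator for co-registered EEG + eye-tracking sessions.

The generator produces a multichannel EEG stream (1/f background plus
band-limited theta and alpha noise carriers with per-channel topographies
and per-condition power multipliers, plus blink/saccade EOG transients with
a frontal-max projection), a slower eye-tracking stream (piecewise-constant
fixations, raised-cosine saccade ramps, a pupil channel with load-dependent
offsets and blink dropouts), and trigger tables in both streams that agree
up to a configurable jitter and an imposed stream offset.

Everything the downstream pipeline is supposed to recover — event times,
expected band powers, condition intervals, the stream offset — is returned
as an explicit :class:`GroundTruth` so each stage can be tested against a
known answer.  Oscillation carriers are narrow-band-filtered Gaussian
noise rather than sinusoids, so the injected effect lives in band *power*
and does not collapse into single FFT bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import PUPIL_SENTINEL, EventTable, Recording

__all__ = [
    "SCALP_CHANNELS",
    "SimConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_nback_block",
    "expected_condition_band_power",
    "expected_erd_percent",
    "write_ground_truth",
]

#: 30-channel scalp montage (10/20 layout) used by default, EOG appended.
SCALP_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "CP3", "CP4", "POz", "O1", "O2",
]

# crude anterior->posterior coordinate per channel, used to build the
# default frontal-max / parietal-max topographies
_AP_POSITION = {
    "Fp1": 0.0, "Fp2": 0.0,
    "F7": 0.15, "F3": 0.15, "Fz": 0.15, "F4": 0.15, "F8": 0.15,
    "FC5": 0.3, "FC1": 0.3, "FC2": 0.3, "FC6": 0.3,
    "T7": 0.5, "C3": 0.5, "Cz": 0.5, "C4": 0.5, "T8": 0.5,
    "CP5": 0.65, "CP1": 0.65, "CP2": 0.65, "CP6": 0.65,
    "CP3": 0.65, "CP4": 0.65,
    "P7": 0.8, "P3": 0.8, "Pz": 0.8, "P4": 0.8, "P8": 0.8,
    "POz": 0.9, "O1": 1.0, "O2": 1.0,
}

# lateral eccentricity (0 = midline), used to peak topographies at Fz / Pz
_ECC = {
    "Fp1": 0.3, "Fp2": 0.3, "F7": 1.0, "F3": 0.5, "Fz": 0.0, "F4": 0.5,
    "F8": 1.0, "FC5": 0.8, "FC1": 0.3, "FC2": 0.3, "FC6": 0.8,
    "T7": 1.0, "C3": 0.5, "Cz": 0.0, "C4": 0.5, "T8": 1.0,
    "CP5": 0.8, "CP1": 0.3, "CP2": 0.3, "CP6": 0.8, "CP3": 0.5, "CP4": 0.5,
    "P7": 1.0, "P3": 0.5, "Pz": 0.0, "P4": 0.5, "P8": 1.0,
    "POz": 0.0, "O1": 0.3, "O2": 0.3,
}


def _default_topography(channels: list[str], kind: str) -> np.ndarray:
    """Frontal-max (theta, peak Fz) or parietal-max (alpha, peak Pz) weights."""
    w = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        if ch not in _AP_POSITION:  # EOG reference etc. carries no oscillation
            continue
        ap = _AP_POSITION[ch]
        ecc = _ECC[ch]
        center = 0.15 if kind == "frontal" else 0.8
        w[i] = np.exp(-((ap - center) ** 2) / (2 * 0.25**2)) * np.exp(-(ecc**2) / 2)
    return w


def _default_eog_topography(channels: list[str]) -> np.ndarray:
    w = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        if ch == "EOG":
            w[i] = 1.0
        elif ch in _AP_POSITION:
            w[i] = np.exp(-_AP_POSITION[ch] / 0.2) * np.exp(-(_ECC[ch] ** 2) / 4)
    return w


@dataclass
class SimConfig:
    """All knobs of the session generator; defaults mirror the montage,
    rates, bands, AOI geometry and trial timing of the emulated setup."""

    seed: int = 0
    n_subjects: int = 1
    conditions: tuple[str, ...] = ("CC", "IC", "DC", "NC")
    task: str = "reading"  # "reading" | "nback"
    eeg_rate: float = 1000.0
    et_rate: float = 250.0
    channels: list[str] = field(default_factory=lambda: SCALP_CHANNELS + ["EOG"])
    alpha_band: tuple[float, float] = (8.0, 13.0)
    theta_band: tuple[float, float] = (4.0, 6.0)
    alpha_topography: np.ndarray | None = None  # parietal-max by default
    theta_topography: np.ndarray | None = None  # frontal-max by default
    background_exponent: float = 1.0
    background_std_uv: float = 6.0
    alpha_amp_uv: float = 5.0  # carrier std at a weight-1.0 channel
    theta_amp_uv: float = 4.0
    condition_power_multipliers: dict[str, dict[str, float]] = field(
        default_factory=dict
    )  # condition -> {"alpha": m, "theta": m}; absent -> 1.0
    blink_rate_per_min: float = 8.0
    blink_duration_ms: tuple[float, float] = (120.0, 260.0)
    blink_amplitude_uv: float = 150.0
    saccade_eog_uv_per_deg: float = 1.5
    fixation_duration_gamma: tuple[float, float] = (4.0, 60.0)  # shape, scale (ms)
    saccade_amplitude_deg: tuple[float, float] = (1.0, 8.0)  # uniform range
    px_per_deg: float = 30.0
    screen_px: tuple[int, int] = (1920, 1200)
    aoi_text: tuple[float, float, float, float] = (360.0, 300.0, 1160.0, 900.0)
    aoi_picture: tuple[float, float, float, float] = (1260.0, 450.0, 1660.0, 750.0)
    p_fixation_aoi: tuple[float, float, float] = (0.55, 0.3, 0.15)  # text/pic/other
    gaze_noise_px: float = 1.0
    pupil_baseline: float = 4.0
    pupil_load_gain: dict[str, float] = field(default_factory=dict)
    pupil_drift_amp: float = 0.05
    pupil_noise: float = 0.01
    trigger_jitter_max: int = 3  # EEG samples
    stream_offset_ms: float = 400.0
    n_paragraphs: int = 5
    paragraph_duration_s: float = 20.0
    n_trials: int = 60
    trial_duration_s: float = 2.0
    p_correct: float = 0.9

    def __post_init__(self) -> None:
        if self.eeg_rate <= 0 or self.et_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.et_rate > self.eeg_rate:
            raise ValueError("et_rate must not exceed eeg_rate")
        if self.trigger_jitter_max < 0:
            raise ValueError("trigger_jitter_max must be >= 0")
        for name, band in (("alpha", self.alpha_band), ("theta", self.theta_band)):
            if not (0 < band[0] < band[1]):
                raise ValueError(f"bad {name} band {band}")
            if band[1] >= self.eeg_rate / 2 or band[1] >= self.et_rate / 2:
                raise ValueError(f"{name} band {band} exceeds Nyquist")
        for cond, bands in self.condition_power_multipliers.items():
            for b, m in bands.items():
                if m <= 0:
                    raise ValueError(f"multiplier {cond}/{b} must be > 0, got {m}")
        if self.alpha_topography is None:
            self.alpha_topography = _default_topography(self.channels, "parietal")
        if self.theta_topography is None:
            self.theta_topography = _default_topography(self.channels, "frontal")
        self.alpha_topography = np.asarray(self.alpha_topography, dtype=float)
        self.theta_topography = np.asarray(self.theta_topography, dtype=float)
        if (self.alpha_topography < 0).any() or (self.theta_topography < 0).any():
            raise ValueError("topography weights must be nonnegative")

    def multiplier(self, condition: str, band: str) -> float:
        return float(
            self.condition_power_multipliers.get(condition, {}).get(band, 1.0)
        )

    def condition_duration_s(self) -> float:
        if self.task == "reading":
            return self.n_paragraphs * self.paragraph_duration_s
        return self.n_trials * self.trial_duration_s


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, in simulator coordinates."""

    true_fixations: list[tuple[int, int, float, float]]  # on, off (ET), x, y
    true_saccades: list[tuple[int, int, float]]  # on, off (ET), amplitude px
    true_blinks: list[tuple[int, int]]  # on, off (ET samples)
    true_band_power: dict[str, dict[str, np.ndarray]]  # cond -> band -> per-channel
    condition_intervals: list[tuple[int, int, str]]  # EEG samples, half-open
    stream_offset_ms: float
    background_band_power: dict[str, float]  # band -> per-channel bg contribution
    carrier_band_power: dict[str, np.ndarray]  # band -> per-channel carrier power


# ---------------------------------------------------------------------------
# spectral building blocks
# ---------------------------------------------------------------------------

def _pink_shaping(n: int, rate: float, exponent: float) -> np.ndarray:
    """Per-rfft-bin amplitude gains for 1/f^exponent noise, unit variance."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    g = np.zeros(freqs.size)
    g[1:] = freqs[1:] ** (-exponent / 2.0)
    # variance of irfft(rfft(white) * g); the Nyquist bin (even n) counts once
    doubled = g[1:-1] if n % 2 == 0 else g[1:]
    nyquist = g[-1] ** 2 if n % 2 == 0 else 0.0
    var = (g[0] ** 2 + 2 * np.sum(doubled**2) + nyquist) / n
    return g / np.sqrt(var)


def _shaped_noise(rng: np.random.Generator, n: int, gains: np.ndarray) -> np.ndarray:
    white = rng.standard_normal(n)
    return np.fft.irfft(np.fft.rfft(white) * gains, n=n)


def _band_carrier(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise strictly band-limited to ``band``."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no FFT bins at n={n}")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    # E[var] = 2 * n_band_bins / n for interior bins
    return x / np.sqrt(2.0 * mask.sum() / n)


def _band_variance_fraction(
    n: int, rate: float, gains: np.ndarray, band: tuple[float, float]
) -> float:
    """Expected variance of shaped noise falling inside ``band`` (inclusive)."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(2.0 * np.sum(gains[mask] ** 2) / n)


# ---------------------------------------------------------------------------
# expected power / ERD oracles
# ---------------------------------------------------------------------------

def expected_condition_band_power(
    config: SimConfig,
    band_name: str,
    *,
    rereferenced: bool = False,
    scalp_only: bool = True,
) -> dict[str, np.ndarray]:
    """Analytic per-condition, per-channel expected band power (µV²).

    With ``rereferenced=True`` the expectation accounts for average
    re-referencing of the scalp channels: the carrier amplitude at channel i
    becomes ``topo_i - mean(topo)`` and independent background noise loses a
    1/n share of its variance.
    """
    n_ref = 16384  # long reference FFT for the variance-fraction integrals
    band = config.alpha_band if band_name == "alpha" else config.theta_band
    amp = config.alpha_amp_uv if band_name == "alpha" else config.theta_amp_uv
    topo = (
        config.alpha_topography if band_name == "alpha" else config.theta_topography
    )
    gains = _pink_shaping(n_ref, config.eeg_rate, config.background_exponent)
    bg_frac = _band_variance_fraction(n_ref, config.eeg_rate, gains, band)
    bg_power = config.background_std_uv**2 * bg_frac

    if scalp_only:
        scalp_idx = [i for i, ch in enumerate(config.channels) if ch != "EOG"]
    else:
        scalp_idx = list(range(len(config.channels)))
    topo = topo[scalp_idx]
    n_sc = len(scalp_idx)
    if rereferenced:
        eff_topo = topo - topo.mean()
        bg_chan = np.full(n_sc, bg_power * (1.0 - 1.0 / n_sc))
    else:
        eff_topo = topo
        bg_chan = np.full(n_sc, bg_power)
    out = {}
    for cond in config.conditions:
        m = config.multiplier(cond, band_name)
        out[cond] = bg_chan + m * (amp * eff_topo) ** 2
    return out


def expected_erd_percent(
    config: SimConfig,
    band_name: str,
    channel: str,
    *,
    rereferenced: bool = True,
) -> dict[str, float]:
    """Analytic ERD/ERS% per condition at ``channel`` under the generator."""
    powers = expected_condition_band_power(
        config, band_name, rereferenced=rereferenced
    )
    scalp = [ch for ch in config.channels if ch != "EOG"]
    idx = scalp.index(channel)
    per_cond = np.array([powers[c][idx] for c in config.conditions])
    baseline = per_cond.mean()
    return {
        c: float((p - baseline) / baseline * 100.0)
        for c, p in zip(config.conditions, per_cond)
    }


# ---------------------------------------------------------------------------
# gaze / event scaffolding
# ---------------------------------------------------------------------------

def _raised_cosine_position(n: int) -> np.ndarray:
    """Normalized 0->1 displacement with raised-cosine velocity over n steps."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return t - np.sin(2 * np.pi * t) / (2 * np.pi)


def _sample_point_in_rect(rng, rect, margin=20.0):
    x0, y0, x1, y1 = rect
    return (
        rng.uniform(x0 + margin, x1 - margin),
        rng.uniform(y0 + margin, y1 - margin),
    )


def _build_gaze(
    config: SimConfig, rng: np.random.Generator, n_et: int
) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Piecewise fixation/saccade gaze trace plus ground-truth event lists."""
    rate = config.et_rate
    shape, scale = config.fixation_duration_gamma
    gx = np.empty(n_et)
    gy = np.empty(n_et)
    fixations: list[tuple[int, int, float, float]] = []
    saccades: list[tuple[int, int, float]] = []
    other_rect = (80.0, 60.0, config.screen_px[0] - 80.0, 260.0)
    rects = [config.aoi_text, config.aoi_picture, other_rect]
    p = np.asarray(config.p_fixation_aoi, dtype=float)
    p = p / p.sum()

    pos = _sample_point_in_rect(rng, config.aoi_text)
    cursor = 0
    while cursor < n_et:
        # fixation
        dur_ms = rng.gamma(shape, scale)
        n_fix = max(int(round(dur_ms / 1000.0 * rate)), int(0.06 * rate))
        end = min(cursor + n_fix, n_et)
        gx[cursor:end] = pos[0]
        gy[cursor:end] = pos[1]
        fixations.append((cursor, end, pos[0], pos[1]))
        cursor = end
        if cursor >= n_et:
            break
        # saccade to the next target
        rect = rects[rng.choice(3, p=p)]
        target = _sample_point_in_rect(rng, rect)
        dist_px = float(np.hypot(target[0] - pos[0], target[1] - pos[1]))
        amp_deg = dist_px / config.px_per_deg
        dur_sac_ms = float(np.clip(20.0 + 2.7 * amp_deg, 20.0, 80.0))
        n_sac = max(int(round(dur_sac_ms / 1000.0 * rate)), 3)
        end = min(cursor + n_sac, n_et)
        ramp = _raised_cosine_position(n_sac)[: end - cursor]
        gx[cursor:end] = pos[0] + (target[0] - pos[0]) * ramp
        gy[cursor:end] = pos[1] + (target[1] - pos[1]) * ramp
        saccades.append((cursor, end, dist_px))
        cursor = end
        pos = target

    # smooth fixation jitter (AR(1)) so noise velocities stay below saccadic ones
    if config.gaze_noise_px > 0:
        from scipy.signal import lfilter

        noise = lfilter([1.0], [1.0, -0.7], rng.standard_normal((2, n_et)), axis=1)
        noise *= config.gaze_noise_px / np.sqrt(1 / (1 - 0.7**2))
        sac_mask = np.zeros(n_et, dtype=bool)
        for on, off, _ in saccades:
            sac_mask[on:off] = True
        gx[~sac_mask] += noise[0, ~sac_mask]
        gy[~sac_mask] += noise[1, ~sac_mask]
    return gx, gy, fixations, saccades


def _place_blinks(
    config: SimConfig,
    rng: np.random.Generator,
    fixations: list[tuple[int, int, float, float]],
    n_et: int,
) -> list[tuple[int, int]]:
    """Sample blink spans strictly inside fixations (never during saccades)."""
    rate = config.et_rate
    duration_s = n_et / rate
    n_blinks = rng.poisson(config.blink_rate_per_min * duration_s / 60.0)
    lo_ms, hi_ms = config.blink_duration_ms
    blinks: list[tuple[int, int]] = []
    margin = max(int(0.02 * rate), 2)
    candidates = [f for f in fixations if f[1] - f[0] > 2 * margin + int(lo_ms / 1000 * rate)]
    if not candidates:
        return []
    for _ in range(n_blinks):
        on_f, off_f, _, _ = candidates[rng.integers(len(candidates))]
        dur = int(round(rng.uniform(lo_ms, hi_ms) / 1000.0 * rate))
        latest = off_f - margin - dur
        if latest <= on_f + margin:
            continue
        start = int(rng.integers(on_f + margin, latest))
        span = (start, start + dur)
        if any(not (span[1] <= b0 or span[0] >= b1) for b0, b1 in blinks):
            continue
        blinks.append(span)
    blinks.sort()
    return blinks


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_session(
    config: SimConfig,
) -> tuple[Recording, Recording, EventTable, EventTable, GroundTruth]:
    """Generate one co-registered session and its ground truth.

    Identical ``(config, seed)`` reproduce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    eeg_rate, et_rate = config.eeg_rate, config.et_rate
    cond_dur = config.condition_duration_s()
    n_cond = len(config.conditions)
    total_s = cond_dur * n_cond
    n_eeg = int(round(total_s * eeg_rate))
    # the ET stream starts stream_offset_ms BEFORE the EEG stream, so every
    # EEG sample has an ET counterpart: ET sample s <-> EEG time
    # s/et_rate - stream_offset_ms/1000
    offset_samples = config.stream_offset_ms / 1000.0 * eeg_rate
    n_et = int(np.ceil((total_s + config.stream_offset_ms / 1000.0) * et_rate)) + 1
    if n_et <= 0:
        raise ValueError("stream offset leaves no ET samples")

    condition_intervals = [
        (int(round(i * cond_dur * eeg_rate)), int(round((i + 1) * cond_dur * eeg_rate)), c)
        for i, c in enumerate(config.conditions)
    ]

    # ----- gaze + blinks on the ET timeline -----
    gx, gy, fixations, saccades = _build_gaze(config, rng, n_et)
    blinks = _place_blinks(config, rng, fixations, n_et)

    # ----- pupil -----
    t_et = np.arange(n_et) / et_rate
    eeg_time_of_et = t_et - config.stream_offset_ms / 1000.0
    pupil = np.full(n_et, config.pupil_baseline)
    for start, end, cond in condition_intervals:
        m = (eeg_time_of_et >= start / eeg_rate) & (eeg_time_of_et < end / eeg_rate)
        pupil[m] += config.pupil_load_gain.get(cond, 0.0)
    pupil += config.pupil_drift_amp * np.sin(2 * np.pi * t_et / 60.0)
    pupil += config.pupil_noise * rng.standard_normal(n_et)
    for on, off in blinks:
        pupil[on:off] = PUPIL_SENTINEL

    et = Recording(
        np.vstack([gx, gy, pupil]),
        et_rate,
        ["gaze_x", "gaze_y", "pupil"],
        ["px", "px", "au"],
    )

    # ----- EEG -----
    channels = config.channels
    n_ch = len(channels)
    gains = _pink_shaping(n_eeg, eeg_rate, config.background_exponent)
    data = np.empty((n_ch, n_eeg))
    for ch in range(n_ch):
        data[ch] = config.background_std_uv * _shaped_noise(rng, n_eeg, gains)

    amp_env = {
        "alpha": np.empty(n_eeg),
        "theta": np.empty(n_eeg),
    }
    for start, end, cond in condition_intervals:
        for band in ("alpha", "theta"):
            amp_env[band][start:end] = np.sqrt(config.multiplier(cond, band))
    for band, band_def, amp, topo in (
        ("theta", config.theta_band, config.theta_amp_uv, config.theta_topography),
        ("alpha", config.alpha_band, config.alpha_amp_uv, config.alpha_topography),
    ):
        carrier = _band_carrier(rng, n_eeg, eeg_rate, band_def) * amp_env[band]
        data += (amp * topo)[:, None] * carrier[None, :]

    # ----- ocular transients projected onto the scalp -----
    eog_topo = _default_eog_topography(channels)
    eog = np.zeros(n_eeg)
    scale = eeg_rate / et_rate
    for on, off in blinks:
        s0 = int(round(scale * on - offset_samples))
        s1 = int(round(scale * off - offset_samples))
        s0, s1 = max(s0, 0), min(s1, n_eeg)
        if s1 <= s0:
            continue
        bump = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(s1 - s0) / (s1 - s0))
        eog[s0:s1] += config.blink_amplitude_uv * bump
    for on, off, amp_px in saccades:
        s0 = int(round(scale * on - offset_samples))
        s1 = int(round(scale * off - offset_samples))
        s0, s1 = max(s0, 0), min(s1, n_eeg)
        if s1 <= s0:
            continue
        spike = np.sin(np.pi * np.arange(s1 - s0) / max(s1 - s0, 1))
        eog[s0:s1] += (
            config.saccade_eog_uv_per_deg * (amp_px / config.px_per_deg) * spike
        )
    data += eog_topo[:, None] * eog[None, :]

    eeg = Recording(data, eeg_rate, list(channels), ["uV"] * n_ch)

    # ----- triggers -----
    eeg_samples: list[int] = []
    labels: list[str] = []
    attrs: list[dict] = []
    if config.task == "reading":
        for start, _, cond in condition_intervals:
            for j in range(config.n_paragraphs):
                s = start + int(round(j * config.paragraph_duration_s * eeg_rate))
                eeg_samples.append(s)
                labels.append(f"par_{cond}_{j}")
                attrs.append({"condition": cond, "paragraph": j})
    else:
        for start, _, cond in condition_intervals:
            block = simulate_nback_block(config, rng=rng)
            for s, _lab, at in block:
                eeg_samples.append(start + s)
                labels.append(f"trial_{cond}_{at['trial']}")
                attrs.append(dict(at, condition=cond))
    eeg_events = EventTable(np.asarray(eeg_samples), list(labels), [dict(a) for a in attrs])

    jmax = config.trigger_jitter_max
    et_samples = []
    for s in eeg_samples:
        jitter = int(rng.integers(-jmax, jmax + 1)) if jmax > 0 else 0
        et_s = int(round((s + jitter + offset_samples) / scale))
        et_samples.append(int(np.clip(et_s, 0, n_et - 1)))
    order = np.argsort(et_samples, kind="stable")
    et_events = EventTable(
        np.asarray(et_samples)[order],
        [labels[i] for i in order],
        [dict(attrs[i]) for i in order],
    )

    # ----- ground truth -----
    true_band_power: dict[str, dict[str, np.ndarray]] = {}
    bg: dict[str, float] = {}
    carrier_power: dict[str, np.ndarray] = {}
    for band in ("alpha", "theta"):
        per_cond = expected_condition_band_power(config, band, scalp_only=False)
        for cond in config.conditions:
            true_band_power.setdefault(cond, {})[band] = per_cond[cond]
        band_def = config.alpha_band if band == "alpha" else config.theta_band
        amp = config.alpha_amp_uv if band == "alpha" else config.theta_amp_uv
        topo = config.alpha_topography if band == "alpha" else config.theta_topography
        bg[band] = float(
            config.background_std_uv**2
            * _band_variance_fraction(16384, eeg_rate, _pink_shaping(16384, eeg_rate, config.background_exponent), band_def)
        )
        carrier_power[band] = (amp * topo) ** 2

    truth = GroundTruth(
        true_fixations=fixations,
        true_saccades=saccades,
        true_blinks=blinks,
        true_band_power=true_band_power,
        condition_intervals=condition_intervals,
        stream_offset_ms=config.stream_offset_ms,
        background_band_power=bg,
        carrier_band_power=carrier_power,
    )
    return eeg, et, eeg_events, et_events, truth


def simulate_nback_block(
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
) -> EventTable:
    """One n-back block: ``n_trials`` onsets spaced one trial apart.

    Stimulus (500 ms word + 1500 ms fixation cross) gives a constant 2 s
    trial; exactly one third of the trials carry the target flag, in
    seed-reproducible pseudo-random order.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    spacing = int(round(config.trial_duration_s * config.eeg_rate))
    n_targets = n // 3
    is_target = np.zeros(n, dtype=bool)
    is_target[:n_targets] = True
    rng.shuffle(is_target)
    samples = np.arange(n, dtype=np.int64) * spacing
    labels = ["target" if t else "nontarget" for t in is_target]
    attrs = [
        {
            "trial": i,
            "target": bool(t),
            "correct": bool(rng.random() < config.p_correct),
        }
        for i, t in enumerate(is_target)
    ]
    return EventTable(samples, labels, attrs)


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Persist ground truth as TSV event files plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "true_events.tsv").open("w") as fh:
        fh.write("onset_sample\toffset_sample\ttype\tx\ty\n")
        for on, off, x, y in truth.true_fixations:
            fh.write(f"{on}\t{off}\tfixation\t{x!r}\t{y!r}\n")
        for on, off, amp in truth.true_saccades:
            fh.write(f"{on}\t{off}\tsaccade\t{amp!r}\t\n")
        for on, off in truth.true_blinks:
            fh.write(f"{on}\t{off}\tblink\t\t\n")
    sidecar = {
        "stream_offset_ms": truth.stream_offset_ms,
        "condition_intervals": truth.condition_intervals,
        "true_band_power": {
            cond: {band: list(map(float, v)) for band, v in bands.items()}
            for cond, bands in truth.true_band_power.items()
        },
        "background_band_power": truth.background_band_power,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
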