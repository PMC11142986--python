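"""Band power per epoch and the ERD/ERS% transform; pupil summaries.

Power is estimated with a Hanning-tapered sliding FFT (500 ms windows,
250 ms steps), each window zero-padded so the discrete frequency spacing is
0.125 Hz, window powers averaged over the epoch, and the grid restricted to
2-30 Hz.  ERD/ERS% expresses each condition's mean band power relative to
the unweighted mean over all conditions of the task (the global condition
baseline): ``(P_c - B) / B * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EpochSet

__all__ = [
    "PowerSpectrum",
    "epoch_power",
    "band_power",
    "erd_ers",
    "epoch_band_power",
    "ConditionEmptyError",
    "pupil_summary_stimulus",
    "pupil_summary_fixation",
]

_GRID_LO, _GRID_HI = 2.0, 30.0
_EDGE_TOL = 1e-9


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, uniform spacing
    power: np.ndarray  # channels x freqs, µV²
    n_windows: int

    def __post_init__(self) -> None:
        if (self.power < 0).any():
            raise ValueError("power must be nonnegative")
        if self.freqs.size > 1:
            d = np.diff(self.freqs)
            if not np.allclose(d, d[0]):
                raise ValueError("frequency grid must be uniform")


class ConditionEmptyError(ValueError):
    """A condition has no kept epochs; the subject must be excluded."""


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    if win > n_samples:
        raise ValueError(f"window of {win} samples exceeds epoch of {n_samples}")
    return np.arange(0, n_samples - win + 1, step)


def epoch_power(
    epoch: np.ndarray,
    rate: float,
    win_ms: float = 500.0,
    step_ms: float = 250.0,
    pad_to_spacing_hz: float = 0.125,
) -> PowerSpectrum:
    """Average sliding-window power spectrum of one (channels x samples) epoch.

    Each window is Hanning-tapered and zero-padded to ``rate /
    pad_to_spacing_hz`` points.  One-sided power is scaled by
    ``2 / sum(w)^2`` (amplitude-squared convention); the absolute scale
    cancels in ERD/ERS%, which is scale-free.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_ch, n_samples = epoch.shape
    win = int(round(win_ms / 1000.0 * rate))
    step = int(round(step_ms / 1000.0 * rate))
    nfft = int(round(rate / pad_to_spacing_hz))
    if nfft < win:
        raise ValueError("pad_to_spacing_hz too coarse for the window length")
    starts = _window_starts(n_samples, win, step)
    taper = np.hanning(win)
    scale = 2.0 / taper.sum() ** 2
    # stack all windows: (n_win, n_ch, win)
    segs = np.stack([epoch[:, s: s + win] for s in starts], axis=0) * taper
    spec = np.fft.rfft(segs, n=nfft, axis=-1)
    power = scale * np.mean(np.abs(spec) ** 2, axis=0)  # n_ch x freqs
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    keep = (freqs >= _GRID_LO - _EDGE_TOL) & (freqs <= _GRID_HI + _EDGE_TOL)
    return PowerSpectrum(freqs[keep], power[:, keep], n_windows=len(starts))


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Per-channel mean power over bins with ``lo <= f <= hi`` (inclusive)."""
    lo, hi = band
    if lo < _GRID_LO - _EDGE_TOL or hi > _GRID_HI + _EDGE_TOL:
        raise ValueError(f"band {band} outside the {_GRID_LO}-{_GRID_HI} Hz grid")
    mask = (spectrum.freqs >= lo - _EDGE_TOL) & (spectrum.freqs <= hi + _EDGE_TOL)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid bins")
    return spectrum.power[:, mask].mean(axis=1)


def epoch_band_power(
    epochs: EpochSet,
    band: tuple[float, float],
    win_ms: float = 500.0,
    step_ms: float = 250.0,
    pad_to_spacing_hz: float = 0.125,
    *,
    kept_only: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Band power for every (kept) epoch: (n_epochs x channels, conditions)."""
    es = epochs.kept() if kept_only else epochs
    out = np.empty((es.n_epochs, len(es.channel_labels)))
    for j in range(es.n_epochs):
        spec = epoch_power(es.epochs[j], es.rate, win_ms, step_ms, pad_to_spacing_hz)
        out[j] = band_power(spec, band)
    return out, list(es.condition)


def erd_ers(
    per_epoch_band_power: np.ndarray,
    condition_labels: list[str],
    conditions: tuple[str, ...] | list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ERD/ERS% per condition against the global condition baseline.

    Parameters
    ----------
    per_epoch_band_power
        ``(n_epochs, n_channels)`` band power of kept epochs.
    condition_labels
        Condition of each epoch row.
    conditions
        Condition order of the output.

    Returns
    -------
    values
        ``(n_conditions, n_channels)`` percent change.
    baseline
        ``(n_channels,)`` unweighted mean over the per-condition means.
    cond_power
        ``(n_conditions, n_channels)`` per-condition mean power.

    Raises
    ------
    ConditionEmptyError
        If a requested condition has no epochs (the paper's rule: that
        subject is excluded from this analysis).
    """
    bp = np.atleast_2d(np.asarray(per_epoch_band_power, dtype=float))
    labels = np.asarray(condition_labels)
    if bp.shape[0] != labels.size:
        raise ValueError("condition labels must match epoch rows")
    cond_power = []
    for cond in conditions:
        m = labels == cond
        if not m.any():
            raise ConditionEmptyError(f"condition {cond!r} has no kept epochs")
        cond_power.append(bp[m].mean(axis=0))
    cond_power = np.asarray(cond_power)
    baseline = cond_power.mean(axis=0)
    values = (cond_power - baseline) / baseline * 100.0
    return values, baseline, cond_power


def pupil_summary_stimulus(
    pupil: np.ndarray,
    epochs: EpochSet,
    conditions: tuple[str, ...] | list[str],
) -> dict[str, float]:
    """Mean pupil size over all kept epochs, per condition.

    ``pupil`` must be blink-interpolated and on the same timeline / rate as
    the epochs' anchor samples.
    """
    es = epochs.kept()
    n_len = int(round(es.length_s * es.rate))
    sums: dict[str, float] = {c: 0.0 for c in conditions}
    counts: dict[str, int] = {c: 0 for c in conditions}
    for j in range(es.n_epochs):
        a = int(es.anchor_sample[j])
        seg = pupil[a: a + n_len]
        seg = seg[np.isfinite(seg)]
        if seg.size == 0:
            continue
        c = es.condition[j]
        if c in sums:
            sums[c] += float(seg.sum())
            counts[c] += seg.size
    out = {}
    for c in conditions:
        if counts[c] == 0:
            raise ValueError(f"no valid pupil samples in condition {c!r}")
        out[c] = sums[c] / counts[c]
    return out


def pupil_summary_fixation(
    pupil: np.ndarray,
    intervals: list[tuple[int, int, str]],
    conditions: tuple[str, ...] | list[str],
) -> dict[str, float]:
    """Mean pupil during labeled fixation intervals, per condition."""
    sums = {c: 0.0 for c in conditions}
    counts = {c: 0 for c in conditions}
    for on, off, cond in intervals:
        if cond not in sums:
            continue
        seg = pupil[on:off]
        seg = seg[np.isfinite(seg)]
        sums[cond] += float(seg.sum())
        counts[cond] += seg.size
    out = {}
    for c in conditions:
        if counts[c] == 0:
            raise ValueError(f"no valid pupil samples in condition {c!r}")
        out[c] = sums[c] / counts[c]
    return out
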