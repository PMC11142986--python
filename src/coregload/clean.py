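"""EEG cleaning: FIR filtering, ICA-based ocular artifact removal, average
re-referencing, epoching, and amplitude-based epoch rejection.

The pipeline order is fixed: filter -> EOG removal -> re-reference ->
epoch -> reject.  Component selection for the ocular step is automated by
time-course correlation against one or more EOG reference channels, and the
returned report makes the selection auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import EpochSet, EventTable, Recording

__all__ = [
    "fir_filter",
    "remove_eog",
    "EogReport",
    "rereference_average",
    "extract_epochs",
    "reject_artifacts",
]


def fir_filter(
    rec: Recording,
    hp_hz: float = 0.25,
    lp_hz: float = 48.0,
    *,
    transition_hz: float | None = None,
) -> Recording:
    """Zero-phase linear-phase FIR band-pass.

    A Hamming-window band-pass (odd tap count, symmetric) is applied by
    overlap-add convolution with ``mode='same'``, which exactly compensates
    the group delay, so event latencies are preserved.  The transition width
    defaults to ``hp_hz`` so the stopband (>= 50 dB down with the Hamming
    window) is reached one octave below the high-pass edge; the low-pass
    stopband is reached far less than one octave above ``lp_hz``.
    """
    nyq = rec.rate / 2.0
    if not (0 < hp_hz < lp_hz < nyq):
        raise ValueError(f"invalid band edges hp={hp_hz}, lp={lp_hz} at rate {rec.rate}")
    width = transition_hz if transition_hz is not None else hp_hz
    numtaps = int(np.ceil(3.3 * rec.rate / width))
    numtaps += 1 - numtaps % 2  # force odd for exact delay compensation
    taps = signal.firwin(
        numtaps, [hp_hz, lp_hz], pass_zero=False, window="hamming", fs=rec.rate
    )
    out = np.empty_like(rec.data)
    for ch in range(rec.n_channels):
        out[ch] = signal.oaconvolve(rec.data[ch], taps, mode="same")
    return Recording(out, rec.rate, list(rec.channel_labels), list(rec.units))


@dataclass
class EogReport:
    """Audit trail of the ocular-ICA step."""

    converged: bool
    n_components: int
    removed: list[int] = field(default_factory=list)
    correlations: np.ndarray | None = None  # components x references
    passthrough: bool = False  # True when data returned unchanged


def remove_eog(
    rec: Recording,
    eog_reference: list[str],
    corr_threshold: float = 0.7,
    *,
    seed: int = 0,
    n_components: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-3,
    drop_reference: bool = False,
) -> tuple[Recording, EogReport]:
    """Remove ICA components correlated with the EOG reference channels.

    ICA (FastICA, deterministic given ``seed``) is fitted on all channels
    except the references, after PCA reduction to ``n_components`` (default
    ``min(20, n_data_channels)``, which also stabilizes convergence).
    Components whose absolute time-course correlation with any reference
    exceeds ``corr_threshold`` have their contribution subtracted from the
    data; everything outside the removed subspace — including the discarded
    PCA tail — is left bit-identical.  If the decomposition fails to
    converge the input is passed through unchanged and the report carries
    ``passthrough=True``.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    missing = [ch for ch in eog_reference if ch not in rec.channel_labels]
    if missing:
        raise KeyError(f"EOG reference channels not found: {missing}")
    data_idx = [
        i for i, ch in enumerate(rec.channel_labels) if ch not in eog_reference
    ]
    if len(data_idx) < 8:
        raise ValueError(f"need >= 8 data channels for ICA, have {len(data_idx)}")
    if n_components is None:
        n_components = min(20, len(data_idx))
    refs = np.vstack([rec.channel(ch) for ch in eog_reference])
    X = rec.data[data_idx].T  # samples x channels

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(X)
        except ConvergenceWarning:
            report = EogReport(converged=False, n_components=0, passthrough=True)
            return rec.copy(), report

    n_comp = sources.shape[1]
    refs_c = refs - refs.mean(axis=1, keepdims=True)
    src_c = sources - sources.mean(axis=0, keepdims=True)
    num = src_c.T @ refs_c.T  # comps x refs
    denom = np.outer(
        np.sqrt((src_c**2).sum(axis=0)), np.sqrt((refs_c**2).sum(axis=1))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    removed = [int(i) for i in np.flatnonzero(np.abs(corr).max(axis=1) > corr_threshold)]

    out = rec.data.copy()
    if removed:
        # mixing_ columns map sources to channels: X ≈ S @ mixing_.T + mean_
        artifact = sources[:, removed] @ ica.mixing_[:, removed].T
        out[data_idx] = (X - artifact).T
    cleaned = Recording(out, rec.rate, list(rec.channel_labels), list(rec.units))
    if drop_reference:
        keep = data_idx
        cleaned = Recording(
            cleaned.data[keep],
            rec.rate,
            [rec.channel_labels[i] for i in keep],
            [rec.units[i] for i in keep],
        )
    return cleaned, EogReport(
        converged=True,
        n_components=n_comp,
        removed=removed,
        correlations=corr,
    )


def rereference_average(rec: Recording, exclude_labels: list[str]) -> Recording:
    """Average re-reference over the included channels; excluded ones dropped.

    The per-sample mean of the included channels is subtracted from each
    included channel, so the output channel sum is zero at every sample.
    """
    unknown = [ch for ch in exclude_labels if ch not in rec.channel_labels]
    if unknown:
        raise KeyError(f"exclude labels not in recording: {unknown}")
    keep = [i for i, ch in enumerate(rec.channel_labels) if ch not in exclude_labels]
    if not keep:
        raise ValueError("exclusion empties the channel set")
    data = rec.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(
        data,
        rec.rate,
        [rec.channel_labels[i] for i in keep],
        [rec.units[i] for i in keep],
    )


def extract_epochs(
    rec: Recording,
    anchors: EventTable,
    lock: str,
    condition_intervals: list[tuple[int, int, str]],
    length_s: float = 2.0,
    *,
    tile: bool = False,
    min_anchor_gap_s: float | None = None,
) -> EpochSet:
    """Cut fixed-length epochs ``[anchor, anchor + length_s)``.

    Each epoch inherits the condition of the interval containing its anchor
    and is dropped if it would cross that interval's end (i.e. run into the
    next condition) or the end of the recording.  With ``tile=True``
    (stimulus-locked reading) each anchor additionally seeds a contiguous
    train of epochs running until the next anchor or the condition boundary.
    ``min_anchor_gap_s`` optionally enforces non-overlapping anchors by
    skipping anchors closer than the gap to the previously accepted one.
    """
    if lock not in ("stimulus", "fixation"):
        raise ValueError(f"unknown lock {lock!r}")
    n_len = int(round(length_s * rec.rate))
    intervals = sorted(condition_intervals)

    def condition_at(sample: int) -> tuple[str, int]:
        for start, end, cond in intervals:
            if start <= sample < end:
                return cond, end
        raise ValueError(f"anchor {sample} outside every condition interval")

    anchor_list = sorted(int(s) for s in anchors.sample)
    if any(s < 0 or s >= rec.n_samples for s in anchor_list):
        raise ValueError("anchor outside recording")

    starts: list[int] = []
    conds: list[str] = []
    last_accepted = -np.inf
    for i, s in enumerate(anchor_list):
        cond, cond_end = condition_at(s)
        if min_anchor_gap_s is not None and s - last_accepted < min_anchor_gap_s * rec.rate:
            continue
        last_accepted = s
        if tile:
            stop = min(
                cond_end,
                anchor_list[i + 1] if i + 1 < len(anchor_list) else rec.n_samples,
            )
            k = s
            while k + n_len <= min(stop, rec.n_samples):
                starts.append(k)
                conds.append(cond)
                k += n_len
        else:
            if s + n_len <= min(cond_end, rec.n_samples):
                starts.append(s)
                conds.append(cond)

    epochs = np.empty((len(starts), rec.n_channels, n_len))
    for j, s in enumerate(starts):
        epochs[j] = rec.data[:, s: s + n_len]
    return EpochSet(
        epochs,
        rec.rate,
        list(rec.channel_labels),
        lock,
        conds,
        np.asarray(starts, dtype=np.int64),
        length_s,
    )


def reject_artifacts(
    epochs: EpochSet,
    limit_uv: float = 100.0,
    *,
    channel_labels: list[str] | None = None,
) -> EpochSet:
    """Flag epochs whose amplitude strictly exceeds ``±limit_uv``.

    The comparison is strict: an epoch whose largest magnitude equals the
    limit exactly is kept.  ``channel_labels`` restricts the screen to a
    channel subset (e.g. scalp channels when gaze channels are appended).
    """
    if channel_labels is None:
        idx = slice(None)
    else:
        idx = [epochs.channel_labels.index(ch) for ch in channel_labels]
    keep = epochs.keep.copy()
    for j in range(epochs.n_epochs):
        if np.max(np.abs(epochs.epochs[j][idx])) > limit_uv:
            keep[j] = False
    return EpochSet(
        epochs.epochs,
        epochs.rate,
        list(epochs.channel_labels),
        epochs.lock,
        list(epochs.condition),
        epochs.anchor_sample,
        epochs.length_s,
        keep,
    )
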