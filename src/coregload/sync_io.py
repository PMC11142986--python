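"""Stream I/O and EEG / eye-tracking synchronization.

Interchange format
------------------
One TSV per stream: three ``#``-prefixed header lines (``#rate``, ``#labels``,
``#units``), then one row of tab-separated floats per sample.  Event tables
are TSVs with columns ``sample``, ``label``, ``attributes`` (JSON object).
Everything is plain text and diffable.

Synchronization fits an affine sample map ET -> EEG through the shared
trigger markers by least squares, reports the per-marker residual jitter,
and refuses to proceed if any residual exceeds the allowed jitter.  The
eye-tracking channels are then linearly upsampled onto the EEG grid and
appended to the EEG recording as extra channels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import (
    AffineMap,
    CoRegisteredSession,
    EventTable,
    FormatError,
    Recording,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "estimate_offset",
    "upsample_et",
    "merge",
]


# ---------------------------------------------------------------------------
# interchange I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    """Write a recording to the TSV interchange format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#rate\t{rec.rate!r}\n")
        fh.write("#labels\t" + "\t".join(rec.channel_labels) + "\n")
        fh.write("#units\t" + "\t".join(rec.units) + "\n")
        for col in rec.data.T:
            fh.write("\t".join(repr(float(v)) for v in col) + "\n")


def read_recording(path) -> Recording:
    """Read a recording from the TSV interchange format.

    Raises
    ------
    FormatError
        On a malformed header, a ragged data row, or an invalid rate; the
        message names the offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: expected 3 header lines, got {len(lines)}")
    header: dict[str, list[str]] = {}
    for i, key in enumerate(("#rate", "#labels", "#units")):
        parts = lines[i].split("\t")
        if parts[0] != key:
            raise FormatError(f"{path}, line {i + 1}: expected {key!r} header")
        header[key] = parts[1:]
    try:
        rate = float(header["#rate"][0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}, line 1: unreadable rate") from None
    if rate <= 0:
        raise FormatError(f"{path}, line 1: rate must be > 0, got {rate}")
    labels = header["#labels"]
    units = header["#units"]
    if len(units) != len(labels):
        raise FormatError(f"{path}, line 3: {len(units)} units for {len(labels)} labels")
    rows = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(labels):
            raise FormatError(
                f"{path}, line {lineno}: {len(parts)} values for {len(labels)} channels"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: non-numeric value") from None
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(labels)).T
    return Recording(data, rate, labels, units)


def write_events(events: EventTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\tlabel\tattributes\n")
        for sample, label, attrs in events:
            fh.write(f"{sample}\t{label}\t{json.dumps(attrs, sort_keys=True)}\n")


def read_events(path) -> EventTable:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["sample", "label", "attributes"]:
        raise FormatError(f"{path}, line 1: bad event header")
    samples, labels, attrs = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}, line {lineno}: expected 3 columns")
        try:
            samples.append(int(parts[0]))
            attrs.append(json.loads(parts[2]))
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: unreadable row") from None
        labels.append(parts[1])
    return EventTable(np.asarray(samples, dtype=np.int64), labels, attrs)


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def estimate_offset(
    eeg_events: EventTable,
    et_events: EventTable,
    max_jitter: float = 3.0,
    *,
    drift: bool = True,
    eeg_rate: float | None = None,
    et_rate: float | None = None,
) -> AffineMap:
    """Fit the affine map ET sample -> EEG sample through shared markers.

    Markers are paired by label in order of occurrence.  With ``drift=True``
    both offset and scale are free (least squares); otherwise the scale is
    fixed to ``eeg_rate / et_rate`` and only the offset is fitted.

    Raises
    ------
    ValueError
        If fewer than two common markers exist, the shared labels occur in a
        different order in the two tables, or any post-fit residual exceeds
        ``max_jitter`` (EEG samples).
    """
    common = sorted(set(eeg_events.label) & set(et_events.label))
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 shared marker labels, found {len(common)}: {common}"
        )
    eeg_sel = eeg_events.select(common)
    et_sel = et_events.select(common)
    if eeg_sel.label != et_sel.label:
        raise ValueError("shared markers occur in different orders")
    x = et_sel.sample.astype(float)
    y = eeg_sel.sample.astype(float)
    if drift:
        A = np.column_stack([np.ones_like(x), x])
        (offset, scale), *_ = np.linalg.lstsq(A, y, rcond=None)
    else:
        if eeg_rate is None or et_rate is None:
            raise ValueError("offset-only fit needs eeg_rate and et_rate")
        scale = eeg_rate / et_rate
        offset = float(np.mean(y - scale * x))
    residuals = y - (offset + scale * x)
    worst = float(np.max(np.abs(residuals))) if residuals.size else 0.0
    if worst > max_jitter + 1e-9:
        raise ValueError(
            f"marker residual {worst:.3f} samples exceeds max_jitter={max_jitter}"
        )
    return AffineMap(float(offset), float(scale), residuals=residuals)


def upsample_et(
    et: Recording,
    target_rate: float,
    *,
    sentinel: float = 0.0,
) -> Recording:
    """Linearly interpolate the eye-tracking channels onto a finer grid.

    Sample ``i`` of the output sits at time ``i / target_rate``; original
    sample times are ``j / et.rate``.  Dropout sentinels are propagated, not
    interpolated across: any output sample bracketed by a sentinel input
    sample on either side is itself set to the sentinel, so sentinel-run
    boundaries keep their positions in time.
    """
    if target_rate < et.rate:
        raise ValueError(f"target_rate {target_rate} < source rate {et.rate}")
    n_src = et.n_samples
    n_dst = int(np.floor((n_src - 1) * target_rate / et.rate)) + 1
    t_dst = np.arange(n_dst) / target_rate
    t_src = np.arange(n_src) / et.rate
    left = np.clip(np.searchsorted(t_src, t_dst, side="right") - 1, 0, n_src - 1)
    right = np.clip(left + 1, 0, n_src - 1)
    out = np.empty((et.n_channels, n_dst), dtype=float)
    for ch in range(et.n_channels):
        src = et.data[ch]
        out[ch] = np.interp(t_dst, t_src, src)
        bad = ~np.isfinite(src) | (src == sentinel)
        if bad.any():
            out[ch][bad[left] | bad[right]] = sentinel
    return Recording(out, target_rate, list(et.channel_labels), list(et.units))


def merge(
    eeg: Recording,
    et: Recording,
    mapping: AffineMap,
    *,
    eeg_events: EventTable | None = None,
    et_events: EventTable | None = None,
    pad_value: float = np.nan,
    edge_slack_samples: int = 8,
) -> CoRegisteredSession:
    """Append eye-tracking channels to the EEG on the EEG timeline.

    The eye-tracking recording is upsampled to the EEG rate first, then each
    ET sample lands at EEG sample ``round(offset + scale_et * original_sample)``.
    Stretches of the EEG timeline not covered by the ET stream are padded
    with ``pad_value``.  ET events, if given, are mapped through ``mapping``
    and concatenated with the EEG events.
    """
    et_up = upsample_et(et, eeg.rate) if et.rate != eeg.rate else et
    # mapping is expressed in original ET samples; rescale to upsampled ones
    up_factor = eeg.rate / et.rate
    n = eeg.n_samples
    appended = np.full((et_up.n_channels, n), pad_value, dtype=float)
    # destination sample of upsampled ET sample j: offset + (scale/up_factor)*j
    per_sample_scale = mapping.scale / up_factor
    dst = np.rint(mapping.offset + per_sample_scale * np.arange(et_up.n_samples))
    dst = dst.astype(np.int64)
    ok = (dst >= 0) & (dst < n)
    appended[:, dst[ok]] = et_up.data[:, ok]
    data = np.vstack([eeg.data, appended])
    labels = list(eeg.channel_labels) + list(et_up.channel_labels)
    units = list(eeg.units) + list(et_up.units)
    combined = Recording(data, eeg.rate, labels, units)

    ev_samples: list[int] = []
    ev_labels: list[str] = []
    ev_attrs: list[dict] = []
    if eeg_events is not None:
        for s, lab, at in eeg_events:
            ev_samples.append(s)
            ev_labels.append(lab)
            ev_attrs.append(dict(at, stream="eeg"))
    if et_events is not None:
        mapped = mapping.apply(et_events.sample)
        # trigger jitter can push edge markers a few samples past the span;
        # clip those, but refuse events that are genuinely outside
        if mapped.size and (
            mapped.min() < -edge_slack_samples
            or mapped.max() >= n + edge_slack_samples
        ):
            raise ValueError("mapping sends an ET event outside the EEG span")
        mapped = np.clip(mapped, 0, n - 1)
        for s, (_, lab, at) in zip(mapped, et_events):
            ev_samples.append(int(s))
            ev_labels.append(lab)
            ev_attrs.append(dict(at, stream="et"))
    order = np.argsort(np.asarray(ev_samples, dtype=np.int64), kind="stable")
    events = EventTable(
        np.asarray(ev_samples, dtype=np.int64)[order],
        [ev_labels[i] for i in order],
        [ev_attrs[i] for i in order],
    )
    events.validate_against(combined)
    return CoRegisteredSession(
        combined, events, mapping, et_channel_labels=list(et_up.channel_labels)
    )
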