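"""Minimal European Data Format (EDF) writer.

Writes continuous multi-channel data as plain EDF (int16 samples, ASCII
header, one-second data records).  Only the subset of the format needed to
store synthetic EEG is implemented; files are readable by standard EDF
readers (round-trip against ``mne.io.read_raw_edf`` is covered by tests).

Each channel is scaled independently to the int16 digital range from its
physical extrema, so the quantization error is below 1e-4 of the signal
range.  The recording is truncated to a whole number of one-second
records; callers should pass durations that are integer seconds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_float(v: float, widen: int) -> str:
    """Format a float into <= 8 ASCII chars, rounding outward.

    ``widen`` is -1 for a minimum (round down) and +1 for a maximum (round
    up) so the stored range always covers the data.
    """
    for prec in range(6, -1, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            break
    else:
        s = f"{v:.0e}"
    parsed = float(s)
    if (widen < 0 and parsed > v) or (widen > 0 and parsed < v):
        # nudge outward by one unit in the last place of the format
        margin = max(abs(v) * 1e-3, 1e-3)
        return _ascii_float(v + widen * margin, widen=0) if widen else s
    return s


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sfreq: float,
    channel_labels: list[str] | tuple[str, ...],
    physical_dim: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate X X X X",
) -> None:
    """Write ``data`` (channels x samples, physical units) to an EDF file.

    ``sfreq`` must be a whole number of samples per second.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (channels, samples)")
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")
    spr = int(round(sfreq))
    if abs(spr - sfreq) > 1e-9:
        raise ValueError("sfreq must be an integer number of Hz")
    n_records = n_samp // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s data record")

    # per-channel physical scaling to the int16 range; the header stores
    # extrema as 8-char ASCII, so quantize against the values as written
    pmin_raw = data.min(axis=1)
    pmax_raw = data.max(axis=1)
    pmax_raw = np.where(pmax_raw - pmin_raw <= 0, pmin_raw + 1.0, pmax_raw)
    pmin_str = [_ascii_float(v, widen=-1) for v in pmin_raw]
    pmax_str = [_ascii_float(v, widen=+1) for v in pmax_raw]
    pmin = np.array([float(s) for s in pmin_str])
    pmax = np.array([float(s) for s in pmax_str])
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * gain[:, None]) + _DIG_MIN,
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    parts = [
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),  # record duration, seconds
        _field(str(n_ch), 4),
    ]
    parts += [_field(lbl, 16) for lbl in channel_labels]
    parts += [_field("", 80)] * n_ch  # transducer
    parts += [_field(physical_dim, 8)] * n_ch
    parts += [_field(s, 8) for s in pmin_str]
    parts += [_field(s, 8) for s in pmax_str]
    parts += [_field(str(_DIG_MIN), 8)] * n_ch
    parts += [_field(str(_DIG_MAX), 8)] * n_ch
    parts += [_field("", 80)] * n_ch  # prefiltering
    parts += [_field(str(spr), 8)] * n_ch
    parts += [_field("", 32)] * n_ch

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
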