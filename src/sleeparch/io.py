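"""File formats: hypnogram CSV, EDF signals, tidy result tables, config.

The hypnogram CSV dialect is comma-separated UTF-8 with a mandatory header
``epoch_index,zt_seconds,state`` and one-letter state tokens (W/N/R).
Writers are deterministic (stable row order, fixed float formatting) so
outputs are diffable; missing values are serialized as empty fields, never
as 0.

EDF reading goes through :mod:`mne` when available.  A minimal EDF writer
(16-bit samples, standard 256-byte headers) is included so synthetic
recordings can be round-tripped through the field's container format.
"""

from __future__ import annotations

import csv
import io as _io
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, StateLabel

__all__ = ["read_hypnogram_csv", "write_hypnogram_csv", "read_eeg_csv",
           "write_eeg_csv", "read_edf", "write_edf"]


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    """Write ``epoch_index,zt_seconds,state`` rows; exact read-back guaranteed."""
    zt = h.zt_seconds()
    with open(path, "w", newline="", encoding="utf-8") as f:
        w = csv.writer(f)
        w.writerow(["epoch_index", "zt_seconds", "state"])
        for i, code in enumerate(h.labels):
            w.writerow([i, f"{zt[i]:.3f}", StateLabel(code).token])


def read_hypnogram_csv(path, epoch_s: float | None = None,
                       lights_on_h: float = 0.0,
                       lights_off_h: float = 12.0) -> Hypnogram:
    """Read a hypnogram CSV; malformed rows raise with their line number.

    The epoch length is inferred from consecutive ``zt_seconds`` values
    unless given explicitly; ``zt_seconds`` of the first row anchors the ZT
    clock.
    """
    codes: list[int] = []
    zts: list[float] = []
    with open(path, newline="", encoding="utf-8") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:3]] != \
                ["epoch_index", "zt_seconds", "state"]:
            raise ValueError(f"{path}: missing or wrong header; expected "
                             "'epoch_index,zt_seconds,state'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                idx = int(row[0])
                zt = float(row[1])
                state = StateLabel.from_token(row[2])
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from None
            if idx != len(codes):
                raise ValueError(f"{path}: line {lineno}: epoch_index {idx} "
                                 f"out of order (expected {len(codes)})")
            codes.append(int(state))
            zts.append(zt)
    if not codes:
        raise ValueError(f"{path}: no epochs")
    if epoch_s is None:
        epoch_s = 10.0 if len(zts) < 2 else \
            float(np.round((zts[1] - zts[0]) % 86400.0, 6))
    return Hypnogram(np.array(codes, dtype=np.int8), epoch_s, zts[0] % 86400.0,
                     lights_on_h, lights_off_h)


def write_eeg_csv(samples: np.ndarray, fs: float, path) -> None:
    """One sample per row plus a JSON sidecar (`<path>.json`) holding fs."""
    import json
    np.savetxt(path, np.asarray(samples, dtype=float), fmt="%.6f")
    Path(str(path) + ".json").write_text(json.dumps({"fs": fs}))


def read_eeg_csv(path) -> tuple[np.ndarray, float]:
    import json
    samples = np.loadtxt(path, dtype=float)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return samples, float(meta["fs"])


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(path, signals: dict[str, np.ndarray], fs: float,
              record_s: float = 1.0, physical_range: tuple[float, float] | None = None,
              start="2024-01-01 00:00:00") -> None:
    """Write channels to a minimal EDF file (16-bit, one data-record block size).

    All channels must share ``fs`` and length, and the length must be a
    whole number of ``record_s`` records.  Quantization to the 16-bit grid
    limits round-trip accuracy to the physical range over 65535 steps.
    """
    names = list(signals)
    arrs = [np.asarray(signals[n], dtype=float) for n in names]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all channels must have equal length")
    spr = int(round(fs * record_s))
    if n % spr != 0:
        raise ValueError("signal length must be a whole number of data records")
    n_rec = n // spr
    if physical_range is None:
        lim = max(1e-9, max(float(np.abs(a).max()) for a in arrs))
        physical_range = (-lim, lim)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    ns = len(names)

    def pad(s, width):
        b = str(s).encode("ascii")[:width]
        return b + b" " * (width - len(b))

    date, time = start.split(" ")
    y, mo, d = date.split("-")
    hh, mm, ss = time.split(":")
    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad(f"{d}.{mo}.{y[2:]}", 8), pad(f"{hh}.{mm}.{ss}", 8),
        pad(256 * (ns + 1), 8), pad("", 44), pad(n_rec, 8),
        pad(f"{record_s:g}", 8), pad(ns, 4),
    ])
    sig_hdr = b"".join([
        b"".join(pad(nm, 16) for nm in names),
        b"".join(pad("", 80) for _ in names),
        b"".join(pad("", 8) for _ in names),  # blank unit: no reader rescaling
        b"".join(pad(f"{pmin:.6g}", 8) for _ in names),
        b"".join(pad(f"{pmax:.6g}", 8) for _ in names),
        b"".join(pad(dmin, 8) for _ in names),
        b"".join(pad(dmax, 8) for _ in names),
        b"".join(pad("", 80) for _ in names),
        b"".join(pad(spr, 8) for _ in names),
        b"".join(pad("", 32) for _ in names),
    ])
    gain = (pmax - pmin) / (dmax - dmin)
    digs = [np.clip(np.round((a - pmin) / gain + dmin), dmin, dmax).astype("<i2")
            for a in arrs]
    with open(path, "wb") as f:
        f.write(hdr + sig_hdr)
        for r in range(n_rec):
            for dig in digs:
                f.write(dig[r * spr:(r + 1) * spr].tobytes())


def read_edf(path, channels: list[str] | None = None,
             expected_fs: float | None = None):
    """Read EDF channels via mne; returns (data dict, fs, annotations).

    ``data`` maps channel name to a float array in physical units.  A
    requested channel absent from the file raises.  When ``expected_fs`` is
    given and differs from the file's sampling rate, a warning is logged and
    the file's rate wins (the container is authoritative for its own data).
    """
    import logging
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF reading requires mne (install extra 'edf')") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-9:
        logging.getLogger(__name__).warning(
            "EDF sampling rate %.6g Hz differs from configured %.6g Hz; "
            "using the file's rate", fs, expected_fs)
    names = channels if channels is not None else raw.ch_names
    missing = [c for c in names if c not in raw.ch_names]
    if missing:
        raise ValueError(f"{path}: channels not present: {missing} "
                         f"(file has {raw.ch_names})")
    data = {c: raw.get_data(picks=[c])[0] for c in names}
    annots = [(float(a["onset"]), float(a["duration"]), a["description"])
              for a in raw.annotations] if len(raw.annotations) else []
    return data, fs, annots


def annotations_to_hypnogram(annotations, label_map: dict[str, str],
                             epoch_s: float = 10.0, zt_start_s: float = 0.0,
                             **kw) -> Hypnogram:
    """Convert EDF annotations to a hypnogram using an explicit label map.

    ``label_map`` maps annotation descriptions to W/N/R tokens; unmapped
    descriptions raise.  Each annotation must span a whole number of epochs.
    """
    codes: list[int] = []
    for onset, duration, desc in sorted(annotations):
        if desc not in label_map:
            raise ValueError(f"annotation description {desc!r} has no entry "
                             "in the label map")
        n = duration / epoch_s
        if abs(n - round(n)) > 1e-6:
            raise ValueError(f"annotation at {onset}s spans {duration}s, not a "
                             f"whole number of {epoch_s}s epochs")
        codes.extend([int(StateLabel.from_token(label_map[desc]))] * int(round(n)))
    return Hypnogram(np.array(codes, dtype=np.int8), epoch_s, zt_start_s, **kw)
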