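"""File I/O: minimal EDF writing, EDF reading, and an array+JSON container.

EDF (European Data Format) is the lingua franca for clinical EEG. Writing
uses a self-contained 16-bit encoder (continuous signals, one-second data
records, per-channel physical scaling); reading goes through MNE's EDF
reader, which also serves as the independent check on the encoder.

Analysis products (epochs, spectra, state spaces) are stored as one ``.npz``
array file plus a JSON header holding the sampling rate, axes and
parameters, so every array on disk is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf", "save_container", "load_container"]


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    signal: np.ndarray,
    fs: float,
    ch_names: list[str] | None = None,
) -> None:
    """Write channels x samples to a 16-bit EDF file.

    Signals are scaled per channel to the full digital range; the trailing
    partial data record is zero-padded (store the true sample count in a
    side-car if exact length matters).
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_ch, n_samp = signal.shape
    if ch_names is None:
        ch_names = [f"CH{i + 1}" for i in range(n_ch)]
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))

    phys_min = signal.min(axis=1)
    phys_max = signal.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    hdr = b""
    hdr += _ascii("0", 8)
    hdr += _ascii("X X X X", 80)
    hdr += _ascii("Startdate X X X X", 80)
    hdr += _ascii("01.01.00", 8)
    hdr += _ascii("00.00.00", 8)
    hdr += _ascii(256 * (n_ch + 1), 8)
    hdr += _ascii("", 44)
    hdr += _ascii(n_rec, 8)
    hdr += _ascii(1, 8)
    hdr += _ascii(n_ch, 4)
    for field, width in (
        (ch_names, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV"] * n_ch, 8),
        ([f"{v:.6g}"[:8] for v in phys_min], 8),
        ([f"{v:.6g}"[:8] for v in phys_max], 8),
        ([dig_min] * n_ch, 8),
        ([dig_max] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([spr] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ):
        for v in field:
            hdr += _ascii(v, width)

    # re-parse the truncated ascii physical range so scaling matches readers
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (dig_max - dig_min) / (pmax - pmin)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = signal
    padded[:, n_samp:] = pmin[:, None]  # pad at the physical minimum
    digital = np.rint((padded - pmin[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE; returns (channels x samples, fs, names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE converts uV to V; undo
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def save_container(stem: str | Path, arrays: dict, header: dict) -> None:
    """Save named arrays to ``<stem>.npz`` and a JSON header to ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(stem.with_suffix(".npz"), **arrays)
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1, default=str))


def load_container(stem: str | Path) -> tuple[dict, dict]:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    header = json.loads(stem.with_suffix(".json").read_text())
    return arrays, header
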