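"""Minimal WFDB header/signal I/O (format 16 only).

Reads and writes the ``.hea``/``.dat`` pairs used by public ECG archives
such as PTB-XL: a text header describing the signals and a little-endian
16-bit integer file with samples interleaved across channels.  Physical
units are recovered as ``(adc - baseline) / gain``.  Only what the
package needs is supported; other storage formats raise.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np


class WFDBFormatError(ValueError):
    pass


def read_header(hea_path: Path) -> dict:
    lines = [
        ln.strip()
        for ln in Path(hea_path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise WFDBFormatError(f"empty WFDB header: {hea_path}")
    top = lines[0].split()
    name = top[0].split("/")[0]
    n_sig = int(top[1])
    fs = float(top[2].split("/")[0]) if len(top) > 2 else 250.0
    n_samp = int(top[3]) if len(top) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, None, "mV"
        if len(parts) > 2:
            spec = parts[2]
            m = re.match(r"([-\d.eE+]+)(\((-?\d+)\))?(/(\S+))?", spec)
            if m:
                gain = float(m.group(1)) or 200.0
                if m.group(3) is not None:
                    baseline = int(m.group(3))
                if m.group(5) is not None:
                    units = m.group(5)
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = parts[8] if len(parts) > 8 else f"ch{len(signals)}"
        signals.append(
            {
                "file": fname,
                "format": int(fmt),
                "gain": gain,
                "baseline": baseline,
                "units": units,
                "description": desc,
            }
        )
    if len(signals) != n_sig:
        raise WFDBFormatError(f"header lists {n_sig} signals, found {len(signals)}")
    return {"name": name, "n_sig": n_sig, "fs": fs, "n_samp": n_samp, "signals": signals}


def read_record(path) -> tuple[np.ndarray, float, list[str]]:
    """Read a WFDB record (path without extension).

    Returns ``(signal, fs, channel_names)`` with ``signal`` shaped
    (n_channels, n_samples) in physical units.
    """
    path = Path(path)
    header = read_header(path.with_suffix(".hea"))
    fmts = {s["format"] for s in header["signals"]}
    if fmts != {16}:
        raise WFDBFormatError(f"unsupported WFDB storage format(s) {fmts}; only 16")
    dat_files = {s["file"] for s in header["signals"]}
    if len(dat_files) != 1:
        raise WFDBFormatError("multi-file WFDB records are not supported")
    raw = np.fromfile(path.parent / dat_files.pop(), dtype="<i2")
    n_sig = header["n_sig"]
    if header["n_samp"] and raw.size != n_sig * header["n_samp"]:
        raise WFDBFormatError(
            f"signal file has {raw.size} samples, header promises "
            f"{n_sig * header['n_samp']}"
        )
    adc = raw.reshape(-1, n_sig).T.astype(np.float64)
    gains = np.array([s["gain"] for s in header["signals"]])[:, None]
    base = np.array([s["baseline"] for s in header["signals"]])[:, None]
    physical = (adc - base) / gains
    names = [s["description"] for s in header["signals"]]
    return physical, header["fs"], names


def write_record(path, signal: np.ndarray, fs: float, channel_names, gain=1000.0):
    """Write a format-16 WFDB record; inverse of :func:`read_record`."""
    path = Path(path)
    signal = np.asarray(signal, dtype=np.float64)
    n_sig, n_samp = signal.shape
    if len(channel_names) != n_sig:
        raise ValueError("channel_names length must match signal rows")
    adc = np.round(signal * gain)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValueError("signal overflows int16 at this gain")
    adc = adc.astype("<i2")
    dat_name = path.stem + ".dat"
    lines = [f"{path.stem} {n_sig} {fs:g} {n_samp}"]
    for ch in channel_names:
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {ch}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.T.reshape(-1).tofile(path.parent / dat_name)
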