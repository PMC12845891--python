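"""Minimal reader/writer for the WFDB record format family.

Covers the subset this package needs: plain-text ``.hea`` headers,
format-16 (little-endian int16) ``.dat`` signal files, and MIT-format
``.atr`` beat annotation files (2-byte words, type in the high 6 bits,
interval in the low 10 bits, with SKIP escapes for long intervals).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .records import ECGRecord

# annotation-code <-> mnemonic table (beat codes of the standard family)
CODE_TO_MNEMONIC = {
    1: "NORMAL", 2: "LBBB", 3: "RBBB", 4: "ABERR", 5: "PVC", 6: "FUSION",
    7: "NPC", 8: "APC", 9: "SVPB", 10: "VESC", 11: "NESC", 12: "PACE",
    13: "UNKNOWN", 25: "BBB", 34: "AESC", 35: "SVESC", 41: "RONT",
}
MNEMONIC_TO_CODE = {v: k for k, v in CODE_TO_MNEMONIC.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_EOF = 0

DEFAULT_GAIN = 200.0  # ADC units per mV


def write_signal(base: str | Path, record: ECGRecord, gain: float = DEFAULT_GAIN) -> None:
    """Write ``<base>.hea`` and ``<base>.dat`` (format 16)."""
    base = Path(base)
    name = base.name
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    n_sig, n_samp = adc.shape
    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for i in range(n_sig):
        first = int(adc[i, 0]) if n_samp else 0
        checksum = int(np.sum(adc[i], dtype=np.int64) & 0xFFFF)
        lines.append(
            f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 {record.lead_ids[i]}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    # format 16: samples interleaved across signals
    base.with_suffix(".dat").write_bytes(adc.T.reshape(-1).tobytes())


def read_signal(base: str | Path) -> ECGRecord:
    """Read ``<base>.hea`` + ``<base>.dat`` into an :class:`ECGRecord`."""
    base = Path(base)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing header file {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig, fs = int(head[1]), float(head[2])
    n_samp = int(head[3]) if len(head) > 3 else None
    gains, leads = [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fmt = parts[1].split("x")[0]
        if fmt != "16":
            raise IOError(f"unsupported WFDB signal format {parts[1]!r} (only 16)")
        gain_spec = parts[2]
        gain = float(gain_spec.split("(")[0].split("/")[0] or DEFAULT_GAIN)
        gains.append(gain if gain > 0 else DEFAULT_GAIN)
        leads.append(parts[-1] if len(parts) >= 9 else f"lead{len(leads)}")
    raw = np.frombuffer(base.with_suffix(".dat").read_bytes(), dtype="<i2")
    sig = raw.reshape(-1, n_sig).T.astype(np.float64)
    if n_samp is not None:
        sig = sig[:, :n_samp]
    sig /= np.asarray(gains)[:, None]
    return ECGRecord(samples=sig, fs=fs, lead_ids=leads, source_id=base.name)


def write_annotations(
    path: str | Path, indices: list[int], mnemonics: list[str]
) -> None:
    """Write an MIT-format annotation file (``.atr``/``.ann``)."""
    order = np.argsort(np.asarray(indices, dtype=np.int64), kind="stable")
    out = bytearray()
    prev = 0
    for k in order:
        idx, mn = int(indices[k]), mnemonics[k]
        code = MNEMONIC_TO_CODE.get(mn)
        if code is None:
            raise ValueError(f"unknown annotation mnemonic {mn!r}")
        interval = idx - prev
        if interval < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if interval > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (interval >> 16) & 0xFFFF)
            out += struct.pack("<H", interval & 0xFFFF)
            interval = 0
            out += struct.pack("<H", (code << 10) | interval)
        else:
            out += struct.pack("<H", (code << 10) | interval)
        prev = idx
    out += struct.pack("<H", _EOF)
    Path(path).write_bytes(bytes(out))


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into (index, mnemonic) pairs."""
    data = Path(path).read_bytes()
    words = np.frombuffer(data, dtype="<u2")
    pairs: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        if code == _EOF and interval == 0:
            break
        if code == _SKIP:
            pending_skip = (int(words[i + 1]) << 16) | int(words[i + 2])
            if pending_skip & 0x80000000:  # sign-extend
                pending_skip -= 1 << 32
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            i += 1 + (interval + 1) // 2
            continue
        t += interval + pending_skip
        pending_skip = 0
        mnemonic = CODE_TO_MNEMONIC.get(code, f"CODE{code}")
        pairs.append((t, mnemonic))
        i += 1
    return pairs
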