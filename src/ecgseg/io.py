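"""Record/annotation I/O (WFDB and CSV), class mapping, and preprocessing.

The CSV dialect is deliberately simple and fixture-friendly: first line
``fs=<Hz>``, second line comma-separated lead names, then one row per
sample. Beat lists are CSV with columns ``sample_index,label[,confidence]``
where label is ``N``/``V``/``S`` (or the long class names).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.signal

from . import _wfdb_lite
from .records import (
    CLASS_TO_SYMBOL,
    NORMAL,
    PAC,
    PVC,
    SYMBOL_TO_CLASS,
    BeatAnnotation,
    ECGRecord,
    validate_annotations,
)

__all__ = [
    "PreprocessConfig",
    "EXCLUDED",
    "map_codes",
    "read_record",
    "write_record",
    "preprocess",
    "segment_record",
    "read_beat_csv",
    "write_beat_csv",
]

#: sentinel class for annotation codes outside the three target classes
EXCLUDED = -1

# annotation-code mapping onto the three classes (case-sensitive mnemonics)
_CODE_MAP = {
    **{m: NORMAL for m in ("NORMAL", "LBBB", "RBBB", "BBB")},
    **{m: PAC for m in ("NPC", "APC", "SVPB", "ABERR", "NESC", "AESC", "SVESC")},
    **{m: PVC for m in ("RONT", "PVC", "VESC")},
}


def map_codes(raw_codes: list[str]) -> list[int]:
    """Map annotation mnemonics to {NORMAL, PVC, PAC, EXCLUDED}.

    Exactly the listed mnemonics map to the three beat classes; every other
    code maps to :data:`EXCLUDED`. Total and case-sensitive.
    """
    return [_CODE_MAP.get(code, EXCLUDED) for code in raw_codes]


@dataclass(frozen=True)
class PreprocessConfig:
    """Signal-conditioning parameters.

    High-pass cutoff 0.5 Hz (baseline removal), Butterworth order 2 applied
    forward-backward (effective order 4), powerline notch (Q=30) at 50 or
    60 Hz, then linear-interpolation resampling to ``target_fs``.
    Amplitude is deliberately not normalized.
    """

    highpass_hz: float = 0.5
    butter_order: int = 2
    powerline_hz: float = 50.0
    notch_q: float = 30.0
    target_fs: float = 125.0

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.target_fs / 2:
            raise ValueError("highpass_hz must be in (0, target_fs/2)")
        if self.powerline_hz >= self.target_fs * 4:  # sanity only; checked vs fs later
            raise ValueError("powerline_hz implausibly high")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")


def preprocess(
    record: ECGRecord,
    config: PreprocessConfig = PreprocessConfig(),
    annotations: list[BeatAnnotation] | None = None,
):
    """Zero-phase high-pass, powerline notch, then resample to ``target_fs``.

    The high-pass Butterworth filter is applied forward-backward (zero
    phase), the notch likewise; resampling uses linear interpolation.
    Annotation indices, when given, are rescaled by ``target_fs/fs`` and
    rounded half up; returns ``record`` or ``(record, annotations)``.
    """
    fs = record.fs
    if fs <= 2 * config.powerline_hz:
        raise ValueError(
            f"sampling rate {fs} Hz cannot represent the {config.powerline_hz} Hz "
            "powerline component; configuration invalid"
        )
    sos = scipy.signal.butter(
        config.butter_order, config.highpass_hz, btype="highpass", fs=fs, output="sos"
    )
    y = scipy.signal.sosfiltfilt(sos, record.samples, axis=1)
    b, a = scipy.signal.iirnotch(config.powerline_hz, config.notch_q, fs=fs)
    y = scipy.signal.filtfilt(b, a, y, axis=1)

    if config.target_fs != fs:
        n_new = int(round(record.n_samples * config.target_fs / fs))
        t_old = np.arange(record.n_samples) / fs
        t_new = np.arange(n_new) / config.target_fs
        y = np.stack([np.interp(t_new, t_old, lead) for lead in y])
    out = ECGRecord(
        samples=y,
        fs=config.target_fs,
        lead_ids=list(record.lead_ids),
        source_id=record.source_id,
    )
    if annotations is None:
        return out
    ratio = config.target_fs / fs
    new_anns = []
    for ann in annotations:
        idx = int(np.floor(ann.index * ratio + 0.5))  # round half up
        idx = min(idx, out.n_samples - 1)
        new_anns.append(BeatAnnotation(index=idx, label=ann.label, raw_code=ann.raw_code))
    return out, new_anns


def segment_record(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    window_s: float = 20.0,
) -> list[tuple[ECGRecord, list[BeatAnnotation]]]:
    """Split into non-overlapping windows; the final short window is
    zero-padded to full length. Annotations are re-indexed per window and
    conserved (none dropped, none duplicated)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * record.fs))
    n_seg = max(1, int(np.ceil(record.n_samples / win)))
    segments = []
    for s in range(n_seg):
        lo, hi = s * win, min((s + 1) * win, record.n_samples)
        chunk = record.samples[:, lo:hi]
        if chunk.shape[1] < win:
            chunk = np.pad(chunk, ((0, 0), (0, win - chunk.shape[1])))
        seg_rec = ECGRecord(
            samples=chunk,
            fs=record.fs,
            lead_ids=list(record.lead_ids),
            source_id=f"{record.source_id}_s{s}",
        )
        seg_anns = [
            BeatAnnotation(index=a.index - lo, label=a.label, raw_code=a.raw_code)
            for a in annotations
            if lo <= a.index < lo + win
        ]
        segments.append((seg_rec, seg_anns))
    return segments


# ---------------------------------------------------------------------------
# record + annotation file round-trips


def write_record(
    base: str | Path,
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    format: str = "csv",
) -> None:
    """Write a record + annotations pair in the named dialect.

    ``csv``: ``<base>.csv`` (signal) and ``<base>.ann.csv`` (beat list).
    ``wfdb``: ``<base>.hea``/``.dat``/``.atr``.
    """
    base = Path(base)
    if format == "csv":
        lines = [f"fs={record.fs:g}", ",".join(record.lead_ids)]
        for row in record.samples.T:
            lines.append(",".join(f"{v:.6f}" for v in row))
        base.with_suffix(".csv").write_text("\n".join(lines) + "\n")
        write_beat_csv(base.with_suffix(".ann.csv"), annotations)
    elif format == "wfdb":
        _wfdb_lite.write_signal(base, record)
        mnemonics = {NORMAL: "NORMAL", PVC: "PVC", PAC: "SVPB"}
        _wfdb_lite.write_annotations(
            base.with_suffix(".atr"),
            [a.index for a in annotations],
            [a.raw_code if a.raw_code in _CODE_MAP else mnemonics[a.label] for a in annotations],
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_record(
    path: str | Path, format: str = "csv"
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Read a record + annotations pair.

    Annotations are returned sorted by index; codes outside the three
    target classes are excluded (the raw code list is available through
    :func:`ecgseg._wfdb_lite.read_annotations` when needed).
    """
    path = Path(path)
    if format == "csv":
        record = _read_csv_signal(path.with_suffix(".csv"))
        ann_path = path.with_suffix(".ann.csv")
        annotations = read_beat_csv(ann_path) if ann_path.exists() else []
    elif format == "wfdb":
        record = _wfdb_lite.read_signal(path)
        atr = path.with_suffix(".atr")
        annotations = []
        if atr.exists():
            for idx, mnemonic in _wfdb_lite.read_annotations(atr):
                label = _CODE_MAP.get(mnemonic, EXCLUDED)
                if label != EXCLUDED:
                    annotations.append(
                        BeatAnnotation(index=idx, label=label, raw_code=mnemonic)
                    )
    else:
        raise ValueError(f"unknown format {format!r}")
    annotations.sort(key=lambda a: a.index)
    validate_annotations(annotations, record.n_samples)
    return record, annotations


def _read_csv_signal(path: Path) -> ECGRecord:
    if not path.exists():
        raise IOError(f"missing signal file {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise IOError(f"{path}: first line must be 'fs=<Hz>', got {header!r}")
        fs = float(header[3:])
        leads = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return ECGRecord(samples=data.T, fs=fs, lead_ids=leads, source_id=path.stem)


def write_beat_csv(path: str | Path, beats, confidences=None) -> None:
    """Write a beat list as ``sample_index,label,confidence`` CSV."""
    lines = ["sample_index,label,confidence"]
    for i, b in enumerate(beats):
        conf = getattr(b, "confidence", None)
        if conf is None and confidences is not None:
            conf = confidences[i]
        conf_s = f"{conf:.4f}" if conf is not None else ""
        lines.append(f"{b.index},{CLASS_TO_SYMBOL[b.label]},{conf_s}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_beat_csv(path: str | Path) -> list[BeatAnnotation]:
    """Read a beat-list CSV; accepts N/V/S symbols or long class names."""
    long_names = {"NORMAL": NORMAL, "PVC": PVC, "PAC": PAC}
    out = []
    lines = Path(path).read_text().splitlines()
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.lower().startswith("sample_index"):
            continue
        parts = ln.split(",")
        sym = parts[1].strip()
        label = SYMBOL_TO_CLASS.get(sym, long_names.get(sym))
        if label is None:
            continue
        out.append(BeatAnnotation(index=int(parts[0]), label=label, raw_code=sym))
    return out
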