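"""Core containers: multi-lead ECG records and beat annotations.

Beat classes are fixed throughout the package as
``(background, Normal, PVC, PAC) = (0, 1, 2, 3)``; sample indices are
0-based and intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: integer codes of the segmentation classes
BACKGROUND, NORMAL, PVC, PAC = 0, 1, 2, 3

#: human-readable class names, indexed by class code
CLASS_NAMES = ("background", "NORMAL", "PVC", "PAC")

#: beat classes that correspond to an actual beat (exclude background)
BEAT_CLASSES = (NORMAL, PVC, PAC)

#: single-letter mnemonics used for on-disk beat lists (WFDB convention)
CLASS_TO_SYMBOL = {NORMAL: "N", PVC: "V", PAC: "S"}
SYMBOL_TO_CLASS = {v: k for k, v in CLASS_TO_SYMBOL.items()}


@dataclass
class BeatAnnotation:
    """A single annotated (or detected) beat.

    Parameters
    ----------
    index : int
        0-based sample position of the R-peak.
    label : int
        One of ``NORMAL``, ``PVC``, ``PAC``.
    raw_code : str
        Original annotation mnemonic (e.g. ``"LBBB"``); empty when the
        annotation was produced by this package.
    """

    index: int
    label: int
    raw_code: str = ""

    def __post_init__(self) -> None:
        if self.label not in BEAT_CLASSES:
            raise ValueError(f"label must be one of {BEAT_CLASSES}, got {self.label}")
        if self.index < 0:
            raise ValueError(f"annotation index must be >= 0, got {self.index}")


@dataclass
class ECGRecord:
    """Multi-lead sampled voltage trace.

    Attributes
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Voltage in mV.
    fs : float
        Sampling rate in Hz.
    lead_ids : list of str
        One name per lead.
    source_id : str
        Free-text record identifier.
    """

    samples: np.ndarray
    fs: float
    lead_ids: list[str] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")
        if not self.lead_ids:
            self.lead_ids = [f"lead{i}" for i in range(self.samples.shape[0])]
        if len(self.lead_ids) != self.samples.shape[0]:
            raise ValueError("lead_ids length does not match number of leads")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, i: int = 0) -> np.ndarray:
        """Return one lead as a 1-D array."""
        return self.samples[i]


def validate_annotations(annotations: list[BeatAnnotation], length: int) -> None:
    """Raise if any annotation index falls outside ``[0, length)``."""
    for ann in annotations:
        if not (0 <= ann.index < length):
            raise ValueError(
                f"annotation index {ann.index} outside record of length {length}"
            )
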