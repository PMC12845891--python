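"""Seedable generator of annotated synthetic single-lead ECG strips.

Beats are rendered as sums of Gaussian waves (P, Q, R, S, T) placed
relative to the R-peak — the standard analytic construction for synthetic
ECG. Rhythm structure covers isolated ectopy, bigeminy-like alternation,
couplets and runs of three or more ectopic beats:

* **Normal** beats: full P-QRS-T morphology at the sinus RR interval.
* **PVC**: widened QRS (x2), larger amplitude (x1.3), no P-wave, inverted
  T, premature coupling and a compensatory pause (the RR pair around the
  ectopic beat spans two sinus intervals).
* **PAC**: normal narrow-QRS morphology, premature coupling, jittered
  P-wave amplitude, non-compensatory reset of the sinus clock.

Additive corruption at generation time is white Gaussian noise at a target
SNR plus an optional baseline sinusoid; heavier corruption (pink/brown
noise, spikes, wander mixtures) belongs to the augmentation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import NORMAL, PAC, PVC, BeatAnnotation, ECGRecord

__all__ = [
    "BeatTemplate",
    "RhythmSpec",
    "normal_template",
    "pvc_template",
    "pac_template",
    "generate_record",
    "generate_dataset",
    "default_training_mix",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-sum description of one beat morphology.

    ``wave_params`` holds one ``(amplitude_mv, center_offset_ms, sigma_ms)``
    triple per wave, offsets relative to the R-peak.
    """

    wave_params: tuple[tuple[float, float, float], ...]
    qrs_width_ms: float
    has_p_wave: bool

    def __post_init__(self) -> None:
        if self.qrs_width_ms <= 0:
            raise ValueError("qrs_width_ms must be positive")
        for amp, _center, sigma in self.wave_params:
            if sigma <= 0:
                raise ValueError(f"wave sigma must be positive, got {sigma}")

    def render(self, t_s: np.ndarray, r_time_s: float, p_scale: float = 1.0) -> np.ndarray:
        """Evaluate the beat waveform on the time grid ``t_s`` (seconds)."""
        y = np.zeros_like(t_s)
        waves = list(self.wave_params)
        for i, (amp, center_ms, sigma_ms) in enumerate(waves):
            if self.has_p_wave and i == 0:
                amp = amp * p_scale
            mu = r_time_s + center_ms / 1000.0
            sig = sigma_ms / 1000.0
            # restrict to +-5 sigma for speed
            lo = np.searchsorted(t_s, mu - 5 * sig)
            hi = np.searchsorted(t_s, mu + 5 * sig)
            y[lo:hi] += amp * np.exp(-0.5 * ((t_s[lo:hi] - mu) / sig) ** 2)
        return y


def normal_template() -> BeatTemplate:
    """Sinus beat: P, Q, R, S, T Gaussians (amplitudes in mV)."""
    return BeatTemplate(
        wave_params=(
            (0.15, -200.0, 25.0),   # P
            (-0.10, -25.0, 8.0),    # Q
            (1.20, 0.0, 10.0),      # R
            (-0.15, 25.0, 8.0),     # S
            (0.35, 220.0, 55.0),    # T
        ),
        qrs_width_ms=80.0,
        has_p_wave=True,
    )


def pvc_template() -> BeatTemplate:
    """Ventricular ectopic: QRS widened x2 and scaled x1.3, no P, inverted T."""
    base = normal_template()
    p, q, r, s, t = base.wave_params
    widen = tuple(
        (amp * 1.3, center * 2.0, sigma * 2.0) for amp, center, sigma in (q, r, s)
    )
    t_wave = (-0.40, t[1] * 1.1, t[2] * 1.2)
    return BeatTemplate(
        wave_params=widen + (t_wave,),
        qrs_width_ms=base.qrs_width_ms * 2.0,
        has_p_wave=False,
    )


def pac_template() -> BeatTemplate:
    """Atrial ectopic: normal narrow-QRS morphology (timing carries the cue)."""
    return normal_template()


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm-level generation parameters.

    Parameters
    ----------
    mean_rr_s : float
        Mean sinus RR interval in seconds (0.8 s = 75 bpm).
    rr_jitter_frac : float
        Fractional Gaussian jitter on sinus RR intervals.
    pvc_rate, pac_rate : float
        Per-beat probability that a beat is a PVC / PAC.
    run_prob : float
        Probability that an ectopic beat extends into a run of >= 3.
    coupling_frac : float
        Prematurity of ectopic beats as a fraction of the sinus RR.
    noise_snr_db : float
        Target SNR of the additive white noise (dB); ``inf`` disables it.
    baseline_amp_mv, baseline_freq_hz : float
        Optional baseline sinusoid.
    """

    mean_rr_s: float = 0.8
    rr_jitter_frac: float = 0.05
    pvc_rate: float = 0.0
    pac_rate: float = 0.0
    run_prob: float = 0.0
    coupling_frac: float = 0.6
    noise_snr_db: float = 20.0
    baseline_amp_mv: float = 0.0
    baseline_freq_hz: float = 0.25
    templates: dict = field(
        default_factory=lambda: {
            NORMAL: normal_template(),
            PVC: pvc_template(),
            PAC: pac_template(),
        }
    )

    def __post_init__(self) -> None:
        for name in ("pvc_rate", "pac_rate", "run_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pvc_rate + self.pac_rate > 1.0:
            raise ValueError("pvc_rate + pac_rate must not exceed 1")
        if not 0.3 <= self.mean_rr_s <= 2.0:
            raise ValueError(f"mean_rr_s must be in [0.3, 2.0], got {self.mean_rr_s}")
        if not 0.0 < self.coupling_frac < 1.0:
            raise ValueError(f"coupling_frac must be in (0, 1), got {self.coupling_frac}")
        if self.rr_jitter_frac < 0:
            raise ValueError("rr_jitter_frac must be >= 0")


def _draw_beat_times(
    rhythm: RhythmSpec, duration_s: float, rng: np.random.Generator
) -> list[tuple[float, int]]:
    """Draw (r_time_s, label) pairs covering the record duration."""
    beats: list[tuple[float, int]] = []
    mean_rr = rhythm.mean_rr_s
    t = 0.45 * mean_rr + 0.1  # leave room for the first P-wave
    label = NORMAL
    run_remaining = 0
    prev_rr = mean_rr
    while t < duration_s - 0.05:
        beats.append((t, label))
        # choose the next label
        if run_remaining > 0:
            run_remaining -= 1
            next_label = label
        else:
            u = rng.uniform()
            if u < rhythm.pvc_rate:
                next_label = PVC
            elif u < rhythm.pvc_rate + rhythm.pac_rate:
                next_label = PAC
            else:
                next_label = NORMAL
            if next_label != NORMAL and rhythm.run_prob > 0 and rng.uniform() < rhythm.run_prob:
                # total run length >= 3: this beat plus at least two more
                run_remaining = 2 + rng.geometric(0.5) - 1
        # choose the RR interval leading to the next beat
        if next_label != NORMAL:
            rr = rhythm.coupling_frac * mean_rr * (1 + 0.02 * rng.standard_normal())
        elif label == PVC:
            # compensatory pause after the last PVC of a group: the RR pair
            # around an isolated PVC spans two sinus intervals
            rr = max(2.0 * mean_rr - prev_rr, 0.3 * mean_rr)
        else:
            rr = mean_rr * (1 + rhythm.rr_jitter_frac * rng.standard_normal())
        rr = max(rr, 0.25 * mean_rr)
        t = t + rr
        prev_rr = rr
        label = next_label
    return beats


def generate_record(
    rhythm: RhythmSpec,
    duration_s: float,
    fs: float,
    seed: int,
    source_id: str = "",
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Generate one annotated synthetic single-lead strip.

    Returns a record of exactly ``round(duration_s * fs)`` samples and the
    beat annotations sorted by index. Identical ``seed`` gives bitwise
    identical output.
    """
    if duration_s < 3.2:
        raise ValueError(f"duration_s must be >= 3.2 s, got {duration_s}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t_s = np.arange(n) / fs

    beats = _draw_beat_times(rhythm, duration_s, rng)
    y = np.zeros(n)
    annotations: list[BeatAnnotation] = []
    for r_time, label in beats:
        idx = int(round(r_time * fs))
        if not 0 <= idx < n:
            continue
        p_scale = rng.uniform(0.5, 1.3) if label == PAC else 1.0
        y += rhythm.templates[label].render(t_s, r_time, p_scale=p_scale)
        annotations.append(BeatAnnotation(index=idx, label=label))

    if np.isfinite(rhythm.noise_snr_db):
        p_signal = float(np.mean(y**2))
        noise_std = np.sqrt(p_signal / 10 ** (rhythm.noise_snr_db / 10.0))
        y = y + noise_std * rng.standard_normal(n)
    if rhythm.baseline_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        y = y + rhythm.baseline_amp_mv * np.sin(
            2 * np.pi * rhythm.baseline_freq_hz * t_s + phase
        )

    record = ECGRecord(
        samples=y[None, :], fs=fs, lead_ids=["I"], source_id=source_id or f"syn{seed}"
    )
    return record, annotations


def generate_dataset(
    n_records: int,
    rhythm_mix: list[RhythmSpec],
    duration_s: float = 20.0,
    fs: float = 125.0,
    seed: int = 0,
) -> tuple[list[tuple[ECGRecord, list[BeatAnnotation]]], dict]:
    """Generate ``n_records`` strips, cycling through ``rhythm_mix``.

    Per-record seeds are derived deterministically from the master seed.
    Returns the records plus a manifest dict with per-record and total
    beat counts.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if not rhythm_mix:
        raise ValueError("rhythm_mix must not be empty")
    rng = np.random.default_rng(seed)
    record_seeds = rng.integers(0, 2**31 - 1, size=n_records)
    dataset = []
    manifest_records = []
    totals = {"NORMAL": 0, "PVC": 0, "PAC": 0}
    for i in range(n_records):
        spec = rhythm_mix[i % len(rhythm_mix)]
        rec, anns = generate_record(
            spec, duration_s, fs, int(record_seeds[i]), source_id=f"syn{seed}_{i:04d}"
        )
        dataset.append((rec, anns))
        counts = {
            "NORMAL": sum(a.label == NORMAL for a in anns),
            "PVC": sum(a.label == PVC for a in anns),
            "PAC": sum(a.label == PAC for a in anns),
        }
        for k in totals:
            totals[k] += counts[k]
        manifest_records.append(
            {"source_id": rec.source_id, "seed": int(record_seeds[i]), **counts}
        )
    manifest = {
        "n_records": n_records,
        "duration_s": duration_s,
        "fs": fs,
        "master_seed": seed,
        "totals": totals,
        "records": manifest_records,
    }
    return dataset, manifest


def default_training_mix() -> list[RhythmSpec]:
    """Rhythm mix used for the end-to-end synthetic experiments.

    Roughly 10% PVC and 10% PAC beats overall, with run enrichment and two
    heart-rate regimes, at 20 dB SNR with mild baseline wander.
    """
    base = dict(pvc_rate=0.1, pac_rate=0.1, run_prob=0.15, coupling_frac=0.6)
    return [
        RhythmSpec(mean_rr_s=0.8, noise_snr_db=20.0, baseline_amp_mv=0.05, **base),
        RhythmSpec(mean_rr_s=0.65, noise_snr_db=18.0, baseline_amp_mv=0.08, **base),
        RhythmSpec(mean_rr_s=0.95, noise_snr_db=22.0, baseline_amp_mv=0.05, **base),
    ]
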