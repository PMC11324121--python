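"""Synthetic 12-lead ECG cohorts with an EF-linked morphology signal.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) — a simplified
take on the classic Gaussian-wave ECG simulators.  Beats are strung
together with jittered RR intervals, projected to 12 leads by a fixed
polarity vector, and corrupted with sinusoidal baseline wander plus
white noise.

Patients with left-ventricular systolic dysfunction (ejection fraction
below 40%) receive a morphology shift whose size scales with
``effect_size``: reduced R amplitude (more so at lower EF), widened QRS
waves and a faster heart rate.  With ``effect_size = 0`` the two groups
are statistically identical, which gives the null condition used by the
integrity tests.

Cohort-level defaults follow the demographics of large hospital
ECG–echocardiography registries: non-LVSD ejection fractions around
61.6 +/- 14.2 percent and an LVSD prevalence of 8.3%.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .ecg_io import DEFAULT_SAMPLING_RATE, ECGRecord, EchoExam, LEAD_NAMES

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Default single-beat morphology: (amplitude mV, center within beat s, width s).
DEFAULT_WAVES = {
    "P": (0.15, 0.20, 0.025),
    "Q": (-0.10, 0.36, 0.010),
    "R": (1.00, 0.40, 0.012),
    "S": (-0.25, 0.44, 0.010),
    "T": (0.35, 0.70, 0.060),
}

#: Per-lead projection of the base waveform, roughly mimicking the polarity
#: pattern of limb and precordial leads (aVR inverted, V-leads ramping up).
DEFAULT_PROJECTION = np.array(
    [0.6, 1.0, 0.4, -0.8, 0.2, 0.7, -0.3, 0.2, 0.5, 0.8, 1.0, 0.9]
)


@dataclass
class BeatParams:
    """Gaussian-bump beat morphology plus rhythm settings."""

    waves: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    heart_rate: float = 60.0       # bpm
    rr_jitter_sd: float = 0.02     # s

    def __post_init__(self):
        if not (30 <= self.heart_rate <= 200):
            raise ValueError(f"heart rate {self.heart_rate} outside [30, 200] bpm")
        for name, (_, _, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name} has non-positive width")


@dataclass
class PatientState:
    """Everything needed to synthesise one patient's ECGs."""

    patient_id: str
    beat: BeatParams
    projection: np.ndarray
    noise_sd: float
    wander_amp: float
    wander_freq: float
    ejection_fraction: float
    lvsd: int


@dataclass
class SynthConfig:
    n_patients: int = 400
    #: probability table: number of ECGs per patient -> probability
    ecgs_per_patient: dict = field(default_factory=lambda: {1: 0.75, 2: 0.20, 3: 0.05})
    lvsd_prevalence: float = 0.083
    effect_size: float = 1.0
    noise_sd: float = 0.05         # mV
    wander_amp: float = 0.10       # mV
    wander_freq: float = 0.30      # Hz
    ef_normal_mean: float = 61.6   # percent
    ef_normal_sd: float = 14.2
    ef_lvsd_range: tuple = (15.0, 39.5)
    missing_ef_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.lvsd_prevalence <= 1):
            raise ValueError("lvsd_prevalence must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        total = sum(self.ecgs_per_patient.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ecgs_per_patient probabilities must sum to 1")


def synth_beat(params: BeatParams, sampling_rate: int = DEFAULT_SAMPLING_RATE,
               rr: float | None = None) -> np.ndarray:
    """One beat: sum of five Gaussian bumps over a single RR interval."""
    if rr is None:
        rr = 60.0 / params.heart_rate
    n = max(1, int(round(rr * sampling_rate)))
    t = np.arange(n) / sampling_rate
    out = np.zeros(n)
    for amp, center, width in params.waves.values():
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def synth_record(state: PatientState, seed: int,
                 record_id: str = "synth", acquisition_date=None) -> ECGRecord:
    """Synthesise one 12-lead, 10 s, 500 Hz record; deterministic per seed."""
    rng = np.random.default_rng(seed)
    fs = DEFAULT_SAMPLING_RATE
    total = fs * 10
    pieces = []
    length = 0
    while length < total:
        rr = 60.0 / state.beat.heart_rate
        if state.beat.rr_jitter_sd > 0:
            rr = max(0.3, rr + rng.normal(0.0, state.beat.rr_jitter_sd))
        beat = synth_beat(state.beat, fs, rr=rr)
        pieces.append(beat)
        length += beat.size
    base = np.concatenate(pieces)[:total]
    signal = state.projection[:, None] * base[None, :]
    t = np.arange(total) / fs
    if state.wander_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=12)
        signal = signal + state.wander_amp * np.sin(
            2 * np.pi * state.wander_freq * t[None, :] + phases[:, None]
        )
    if state.noise_sd > 0:
        signal = signal + rng.normal(0.0, state.noise_sd, size=signal.shape)
    return ECGRecord(
        record_id=record_id,
        patient_id=state.patient_id,
        acquisition_date=acquisition_date,
        signal=signal,
    )


def lvsd_shift(beat: BeatParams, effect_size: float, ef: float) -> BeatParams:
    """Apply the LVSD morphology shift for a given effect size and EF.

    R amplitude is multiplied by ``1 - 0.4 * e * (1 - EF/60)``, the QRS
    wave widths by ``1 + 0.5 * e``, and the heart rate increases by
    ``10 * e`` bpm.  With ``e = 0`` the beat is returned unchanged.
    """
    waves = dict(beat.waves)
    r_amp, r_c, r_w = waves["R"]
    waves["R"] = (r_amp * (1.0 - 0.4 * effect_size * (1.0 - ef / 60.0)), r_c, r_w)
    widen = 1.0 + 0.5 * effect_size
    for w in ("Q", "R", "S"):
        amp, c, width = waves[w]
        waves[w] = (amp, c, width * widen)
    return BeatParams(
        waves=waves,
        heart_rate=min(200.0, beat.heart_rate + 10.0 * effect_size),
        rr_jitter_sd=beat.rr_jitter_sd,
    )


def _draw_patient(rng: np.random.Generator, cfg: SynthConfig, pid: str
                  ) -> PatientState:
    lvsd = int(rng.random() < cfg.lvsd_prevalence)
    if lvsd:
        ef = rng.uniform(*cfg.ef_lvsd_range)
    else:
        ef = rng.normal(cfg.ef_normal_mean, cfg.ef_normal_sd)
        while ef < 40 or ef >= 95:
            ef = rng.normal(cfg.ef_normal_mean, cfg.ef_normal_sd)
    waves = {}
    for name, (amp, center, width) in DEFAULT_WAVES.items():
        waves[name] = (amp * rng.normal(1.0, 0.05), center, width)
    beat = BeatParams(
        waves=waves,
        heart_rate=float(np.clip(rng.normal(68.0, 8.0), 45.0, 110.0)),
        rr_jitter_sd=0.02,
    )
    if lvsd:
        beat = lvsd_shift(beat, cfg.effect_size, ef)
    projection = DEFAULT_PROJECTION * rng.normal(1.0, 0.05, size=12)
    return PatientState(
        patient_id=pid,
        beat=beat,
        projection=projection,
        noise_sd=cfg.noise_sd,
        wander_amp=cfg.wander_amp,
        wander_freq=cfg.wander_freq,
        ejection_fraction=float(ef),
        lvsd=lvsd,
    )


def synth_cohort(cfg: SynthConfig, generate_signals: bool = True
                 ) -> tuple[list, list[EchoExam]]:
    """Generate a multi-ECG-per-patient cohort with one echo per patient.

    Every patient receives at least one ECG dated within 28 days of their
    echo exam.  Deterministic for a fixed ``cfg.seed``.

    With ``generate_signals=False`` the voltage synthesis is skipped and
    lightweight metadata stubs are returned instead of
    :class:`~ecgmae.ecg_io.ECGRecord` objects; the random stream is
    consumed identically, so labels, dates and EFs match the full run.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = sorted(cfg.ecgs_per_patient.items())
    count_vals = np.array([c for c, _ in counts])
    count_probs = np.array([p for _, p in counts])
    base_date = _dt.date(2020, 1, 1)
    records: list[ECGRecord] = []
    echoes: list[EchoExam] = []
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        state = _draw_patient(rng, cfg, pid)
        echo_date = base_date + _dt.timedelta(days=int(rng.integers(0, 365)))
        ef = state.ejection_fraction
        if cfg.missing_ef_rate > 0 and rng.random() < cfg.missing_ef_rate:
            ef = None
        echoes.append(EchoExam(f"E{i:05d}", pid, echo_date, ef))
        n_ecg = int(rng.choice(count_vals, p=count_probs))
        offsets = rng.integers(-14, 15, size=n_ecg)
        for j, off in enumerate(offsets):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            date = echo_date + _dt.timedelta(days=int(off))
            rid = f"R{i:05d}_{j}"
            if generate_signals:
                records.append(synth_record(state, seed=rec_seed,
                                            record_id=rid,
                                            acquisition_date=date))
            else:
                records.append(RecordStub(rid, pid, date))
    return records, echoes


@dataclass
class RecordStub:
    """Metadata-only stand-in for an ECG record (no voltages)."""

    record_id: str
    patient_id: str
    acquisition_date: _dt.date
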