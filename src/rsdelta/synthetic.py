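"""Synthetic resting-state EEG cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a 1/f
broadband background, a posterior-dominant alpha rhythm centered at a
per-subject individual alpha frequency (IAF), small delta/theta bumps, a
group-dependent elevation of temporal delta power, injected epileptiform
transients (spikes / sharp waves with slow after-waves), benign rhythmic
delta runs (TIRDA/FIRDA) and ocular / muscle / movement artifacts.

Three groups are generated: normal elderly controls ("Nold"), amnesic MCI
patients without epileptiform activity ("noADMCI-noEEA") and with it
("noADMCI-EEA"), with default sizes 30/19/13.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import CHANNELS_1020, Recording

GROUPS = ("Nold", "noADMCI-noEEA", "noADMCI-EEA")

#: alpha-gradient weight per channel (posterior-dominant topography)
_ALPHA_GRADIENT = {
    "O1": 1.0, "O2": 1.0, "P3": 0.75, "Pz": 0.75, "P4": 0.75,
    "T5": 0.6, "T6": 0.6, "T3": 0.35, "T4": 0.35,
    "C3": 0.2, "Cz": 0.2, "C4": 0.2,
    "F7": 0.0, "F3": 0.0, "Fz": 0.0, "F4": 0.0, "F8": 0.0,
    "Fp1": 0.0, "Fp2": 0.0,
}

TEMPORAL_CHANNELS = ("T3", "T4", "T5", "T6")
FRONTAL_INJ_CHANNELS = ("F7", "F3", "Fz", "F4", "F8", "Fp1", "Fp2")

#: spatial neighbours used to spread focal transients
_NEIGHBORS = {
    "Fp1": ["F7", "F3", "Fp2"], "Fp2": ["F8", "F4", "Fp1"],
    "F7": ["Fp1", "F3", "T3"], "F8": ["Fp2", "F4", "T4"],
    "F3": ["Fp1", "Fz", "C3"], "F4": ["Fp2", "Fz", "C4"],
    "Fz": ["F3", "F4", "Cz"],
    "T3": ["F7", "C3", "T5"], "T4": ["F8", "C4", "T6"],
    "C3": ["F3", "Cz", "P3", "T3"], "C4": ["F4", "Cz", "P4", "T4"],
    "Cz": ["Fz", "C3", "C4", "Pz"],
    "T5": ["T3", "P3", "O1"], "T6": ["T4", "P4", "O2"],
    "P3": ["C3", "Pz", "O1", "T5"], "P4": ["C4", "Pz", "O2", "T6"],
    "Pz": ["P3", "P4", "Cz", "O1", "O2"],
    "O1": ["T5", "P3", "O2"], "O2": ["T6", "P4", "O1"],
}

_MIRROR = {
    "Fp1": "Fp2", "Fp2": "Fp1", "F7": "F8", "F8": "F7", "F3": "F4",
    "F4": "F3", "T3": "T4", "T4": "T3", "C3": "C4", "C4": "C3",
    "T5": "T6", "T6": "T5", "P3": "P4", "P4": "P3", "O1": "O2",
    "O2": "O1", "Fz": "Fz", "Cz": "Cz", "Pz": "Pz",
}

#: between-subject SD of the log10 delta-bump power across subjects
LOG10_DELTA_POWER_SD = 0.15

#: log10 power gain applied to the temporal-channel delta component per
#: unit of delta_effect_size. Calibrated once so that d = 1 yields a
#: roughly one-to-1.5-SD elevation of the measured temporal-ROI log10
#: source activity under default desk-scale conditions: the gain acts on
#: the delta bump only, which rides on the 1/f background, and part of it
#: is absorbed by band individualization and relative-power
#: normalization, so the injected gain must exceed the target shift.
EFFECT_LOG10_POWER_PER_D = 0.38


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    ``delta_effect_size`` is the standardized (Cohen's d) elevation of
    log10 temporal delta power in the EEA group, implemented as a gain on
    the temporal-channel delta component so that recovery through the
    source-mapping inverse is meaningful. Rates are per minute.
    """

    n_per_group: tuple[int, int, int] = (30, 19, 13)
    fs: float = 128.0
    duration_s: float = 180.0
    patient_duration_s: float | None = None   # None -> same as duration_s
    iaf_mean: float = 9.5
    iaf_sd: float = 0.8
    alpha_power: float = 20.0                 # µV²/Hz alpha peak scale
    posterior_gain: float = 2.0               # alpha anterior-posterior gradient
    delta_effect_size: float = 1.0
    eea_event_rate: float = 3.0
    artifact_rate: float = 2.0
    tirda_rate: float = 0.2
    emulate_gender_skew: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ConfigurationError("each group needs at least 2 subjects")
        if not 128 <= self.fs <= 512:
            raise ConfigurationError("fs must be in [128, 512] Hz")
        if not 6 <= self.iaf_mean <= 14:
            raise ConfigurationError("iaf_mean must be in [6, 14] Hz")
        for name in ("eea_event_rate", "artifact_rate", "tirda_rate",
                     "iaf_sd", "alpha_power", "posterior_gain"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything that was injected, for recovery checks."""

    groups: dict[str, str] = field(default_factory=dict)
    iaf: dict[str, float] = field(default_factory=dict)
    delta_multiplier: dict[str, float] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    tirda_runs: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)

    def events_for(self, subject_id: str) -> list[dict]:
        return [e for e in self.events if e["subject_id"] == subject_id]


# ---------------------------------------------------------------------------
# background synthesis
# ---------------------------------------------------------------------------

def synthesize_background(fs: float, duration_s: float, iaf: float = 9.5,
                          posterior_gain: float = 2.0, seed: int = 0,
                          subject_id: str = "S000",
                          alpha_power: float = 20.0,
                          background_power: float = 20.0,
                          delta_power: float = 8.0,
                          theta_power: float = 2.0,
                          delta_gain_temporal: float = 1.0,
                          rng: np.random.Generator | None = None) -> Recording:
    """1/f background plus narrowband alpha with a posterior gradient.

    Power parameters are one-sided PSD scales in µV²/Hz: ``background_power``
    is the 1/f level at 1 Hz, the others are Gaussian-bump peak heights
    (alpha at ``iaf``, delta at 2.2 Hz, theta at 4.8 Hz).
    ``delta_gain_temporal`` multiplies the delta *amplitude* on temporal
    channels only (the group effect enters here).
    """
    if fs < 128:
        raise ConfigurationError("fs must be >= 128 Hz")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    labels = list(CHANNELS_1020) + ["EOG"]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    f_safe = np.maximum(freqs, 0.5)

    def bump(center, width):
        return np.exp(-((freqs - center) ** 2) / (2 * width ** 2))

    alpha_shape = bump(iaf, 1.2)
    delta_shape = bump(2.2, 0.7)
    theta_shape = bump(4.8, 0.8)
    pink = background_power / f_safe

    data = np.empty((len(labels), n))
    for i, ch in enumerate(labels):
        if ch == "EOG":
            psd = 25.0 / f_safe ** 1.5
        else:
            w_alpha = 0.4 + posterior_gain * _ALPHA_GRADIENT[ch]
            d_gain = delta_gain_temporal if ch in TEMPORAL_CHANNELS else 1.0
            psd = (pink
                   + alpha_power * w_alpha * alpha_shape
                   + delta_power * d_gain ** 2 * delta_shape
                   + theta_power * theta_shape)
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white) * np.sqrt(psd * fs / 2)
        spec[freqs < 0.3] = 0.0  # acquisition high-pass emulation
        data[i] = np.fft.irfft(spec, n)
    return Recording(labels=labels, data=data, fs=fs, subject_id=subject_id)


# ---------------------------------------------------------------------------
# transient injection
# ---------------------------------------------------------------------------

def _spike_waveform(fs: float, duration_ms: float, amplitude: float,
                    rise_fraction: float = 0.3,
                    afterwave: bool = True,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Asymmetric epileptiform transient: fast linear rise, slower decay,
    small opposite-polarity undershoot, optional slow after-wave."""
    d = duration_ms / 1000.0
    tr = rise_fraction * d
    td = d - tr
    n_r = max(int(round(tr * fs)), 2)
    n_d = max(int(round(td * fs)), 3)
    rise = np.linspace(0.0, 1.0, n_r, endpoint=False)
    decay = np.linspace(1.0, 0.0, n_d)
    w = np.concatenate([rise, decay])
    # biphasic undershoot (makes the wave di-phasic)
    n_u = max(int(round(0.8 * td * fs)), 3)
    under = -0.3 * np.sin(np.linspace(0, np.pi, n_u))
    w = np.concatenate([w, under])
    if afterwave:
        # slow after-wave (~1.3 Hz half period), same polarity as the
        # peak and of comparable magnitude, as in spike-wave complexes
        n_a = int(round(0.38 * fs))
        after = 0.8 * np.sin(np.linspace(0, np.pi, n_a))
        w = np.concatenate([w, after])
    return amplitude * w


def classify_injected_kind(duration_ms: float) -> str:
    if 30 <= duration_ms < 80:
        return "spike"
    if 80 <= duration_ms <= 200:
        return "sharp_wave"
    return "other"


def inject_epileptiform(recording: Recording, rate: float,
                        duration_range_ms: tuple[float, float] = (40.0, 160.0),
                        afterwave: bool = True,
                        channels: tuple[str, ...] | None = None,
                        amplitude_uv: float = 130.0,
                        seed: int = 0,
                        rng: np.random.Generator | None = None
                        ) -> tuple[Recording, list[dict]]:
    """Add focal spikes / sharp waves; returns the modified recording and
    the ground-truth event list (onset, duration, channels, kind)."""
    lo, hi = duration_range_ms
    if lo < 20 or hi > 250 or lo >= hi:
        raise ConfigurationError("duration range must lie within [20, 250] ms")
    if channels is None:
        # anterior temporal / frontal predominance, the typical scalp
        # topography of temporal-lobe interictal discharges
        channels = ("T3", "T4", "F7", "F8", "Fp1", "Fp2")
    for ch in channels:
        if ch not in CHANNELS_1020:
            raise ConfigurationError(f"unknown injection channel {ch!r}")
    if rate == 0:
        return recording, []
    if rng is None:
        rng = np.random.default_rng(seed)

    rec = recording.copy()
    fs, n = rec.fs, rec.n_samples
    n_events = int(round(rate * rec.duration_s / 60.0))
    events: list[dict] = []
    min_gap = int(2.0 * fs)
    onsets = np.sort(rng.uniform(1.0, rec.duration_s - 2.0, size=n_events))
    last = -10 * fs
    for onset_s in onsets:
        start = int(onset_s * fs)
        if start - last < min_gap:
            continue
        last = start
        duration_ms = float(rng.uniform(lo, hi))
        primary = str(rng.choice(channels))
        amp = float(amplitude_uv * rng.uniform(0.9, 1.3))
        sign = -1.0 if rng.uniform() < 0.7 else 1.0  # spikes mostly negative
        w = _spike_waveform(fs, duration_ms, sign * amp,
                            afterwave=afterwave, rng=rng)
        stop = min(start + len(w), n)
        # steep spatial falloff: the focal field drops quickly toward the
        # neighbours and the contralateral homologue
        gains = {primary: 1.0}
        for nb in _NEIGHBORS[primary]:
            gains[nb] = float(rng.uniform(0.2, 0.4))
        gains.setdefault(_MIRROR[primary], 0.15)
        for ch, g in gains.items():
            rec.data[rec.index(ch), start:stop] += g * w[: stop - start]
        apex_s = onset_s + 0.3 * duration_ms / 1000.0
        events.append({
            "subject_id": rec.subject_id, "onset_s": float(onset_s),
            "apex_s": float(apex_s), "duration_ms": duration_ms,
            "amplitude_uv": amp, "channels": sorted(gains),
            "primary": primary, "kind": classify_injected_kind(duration_ms),
        })
    return rec, events


def inject_rhythmic_delta(recording: Recording, rate: float,
                          region: str = "temporal", seed: int = 0,
                          rng: np.random.Generator | None = None
                          ) -> tuple[Recording, list[dict]]:
    """Add benign rhythmic delta runs (TIRDA when temporal, FIRDA when
    frontal): uniform-morphology sine waves, 50-100 µV, no sharp component."""
    if region not in ("temporal", "frontal"):
        raise ConfigurationError("region must be 'temporal' or 'frontal'")
    if rate == 0:
        return recording, []
    if rng is None:
        rng = np.random.default_rng(seed)
    rec = recording.copy()
    fs = rec.fs
    n_runs = int(round(rate * rec.duration_s / 60.0))
    runs: list[dict] = []
    for _ in range(n_runs):
        f = float(rng.uniform(1.2, 2.8))
        n_waves = int(rng.integers(3, 7))
        dur = n_waves / f
        onset_s = float(rng.uniform(1.0, max(1.5, rec.duration_s - dur - 1.0)))
        amp = float(rng.uniform(55.0, 95.0))
        if region == "temporal":
            side = ["T3", "T5"] if rng.uniform() < 0.5 else ["T4", "T6"]
        else:
            side = list(rng.choice(FRONTAL_INJ_CHANNELS, size=3,
                                   replace=False))
        # integer number of full cycles: starts and ends on a zero
        # crossing, every wave at full amplitude (uniform morphology)
        t = np.arange(int(dur * fs)) / fs
        wave = amp * np.sin(2 * np.pi * f * t)
        start = int(onset_s * fs)
        stop = min(start + len(wave), rec.n_samples)
        for ch in side:
            rec.data[rec.index(ch), start:stop] += wave[: stop - start]
        runs.append({"subject_id": rec.subject_id, "onset_s": onset_s,
                     "duration_s": dur, "freq_hz": f, "amplitude_uv": amp,
                     "channels": side, "region": region})
    return rec, runs


def inject_artifacts(recording: Recording,
                     kinds: tuple[str, ...] = ("ocular", "muscle", "movement"),
                     rate: float = 2.0, seed: int = 0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[Recording, list[dict]]:
    """Add ocular blinks (frontal + EOG mirror), broadband muscle bursts and
    large synchronous movement deflections."""
    if not kinds:
        raise ConfigurationError("kinds must be non-empty")
    for k in kinds:
        if k not in ("ocular", "muscle", "movement"):
            raise ConfigurationError(f"unknown artifact kind {k!r}")
    if rate == 0:
        return recording, []
    if rng is None:
        rng = np.random.default_rng(seed)
    rec = recording.copy()
    fs, n = rec.fs, rec.n_samples
    n_art = int(round(rate * rec.duration_s / 60.0))
    arts: list[dict] = []
    for _ in range(n_art):
        kind = str(rng.choice(kinds))
        if kind == "ocular":
            dur = float(rng.uniform(0.3, 0.6))
            onset = float(rng.uniform(0.5, rec.duration_s - dur - 0.5))
            t = np.arange(int(dur * fs)) / fs
            blink = 180.0 * np.exp(-((t - dur / 2) / (dur / 5)) ** 2)
            start = int(onset * fs)
            stop = min(start + len(blink), n)
            seg = blink[: stop - start]
            for ch, g in (("Fp1", 1.0), ("Fp2", 1.0), ("F3", 0.5),
                          ("F4", 0.5), ("Fz", 0.45), ("F7", 0.4),
                          ("F8", 0.4)):
                rec.data[rec.index(ch), start:stop] += g * seg
            rec.data[rec.index("EOG"), start:stop] += 1.6 * seg
            chs = ["Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8"]
        elif kind == "muscle":
            dur = float(rng.uniform(1.0, 2.5))
            onset = float(rng.uniform(0.5, rec.duration_s - dur - 0.5))
            start = int(onset * fs)
            stop = min(start + int(dur * fs), n)
            m = stop - start
            freqs = np.fft.rfftfreq(m, 1 / fs)
            # EMG-like: power rising gently above 25 Hz
            shape = np.where(freqs >= 22.0, (freqs / 40.0) ** 0.4, 0.0)
            chs = list(rng.choice(
                ["F7", "F8", "T3", "T4", "Fp1", "Fp2", "T5", "T6"],
                size=6, replace=False))
            for ch in chs:
                spec = np.fft.rfft(rng.standard_normal(m)) * shape
                burst = np.fft.irfft(spec, m)
                burst *= 28.0 / (burst.std() + 1e-12)
                rec.data[rec.index(ch), start:stop] += burst
        else:  # movement
            dur = float(rng.uniform(1.0, 2.0))
            onset = float(rng.uniform(0.5, rec.duration_s - dur - 0.5))
            t = np.arange(int(dur * fs)) / fs
            wave = 260.0 * np.sin(np.pi * t / dur)
            start = int(onset * fs)
            stop = min(start + len(wave), n)
            gains = rng.uniform(0.8, 1.2, size=19)
            for i, ch in enumerate(CHANNELS_1020):
                rec.data[rec.index(ch), start:stop] += \
                    gains[i] * wave[: stop - start]
            chs = list(CHANNELS_1020)
        arts.append({"subject_id": rec.subject_id, "kind": kind,
                     "onset_s": onset, "duration_s": dur, "channels": chs})
    return rec, arts


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig
                    ) -> tuple[list[Recording], pd.DataFrame, GroundTruth]:
    """Generate one recording per subject plus metadata and ground truth.

    EEA-group subjects receive the temporal delta elevation and injected
    epileptiform events; patient groups additionally receive benign
    rhythmic delta runs at ``tirda_rate``. Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    recordings: list[Recording] = []
    meta_rows = []
    mmse_mean = {"Nold": 28.7, "noADMCI-noEEA": 26.2, "noADMCI-EEA": 26.3}
    mmse_sd = {"Nold": 1.1, "noADMCI-noEEA": 2.2, "noADMCI-EEA": 2.9}
    male_frac = {"Nold": 6 / 30, "noADMCI-noEEA": 6 / 19, "noADMCI-EEA": 0.0}

    idx = 0
    for group, n_grp in zip(GROUPS, config.n_per_group):
        for _ in range(n_grp):
            sid = f"S{idx:03d}"
            idx += 1
            sub_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
            iaf = float(np.clip(sub_rng.normal(config.iaf_mean, config.iaf_sd),
                                7.0, 13.0))
            # subject-level delta variability (log10 amplitude SD = half the
            # log10 power SD), plus the group effect on temporal channels
            amp_mult = 10 ** sub_rng.normal(0.0, LOG10_DELTA_POWER_SD / 2)
            gain_t = 1.0
            if group == "noADMCI-EEA":
                gain_t = 10 ** (config.delta_effect_size
                                * EFFECT_LOG10_POWER_PER_D / 2)
            duration = config.duration_s
            if group != "Nold" and config.patient_duration_s is not None:
                duration = config.patient_duration_s
            rec = synthesize_background(
                config.fs, duration, iaf=iaf,
                posterior_gain=config.posterior_gain,
                alpha_power=config.alpha_power,
                delta_power=8.0 * amp_mult ** 2,
                delta_gain_temporal=gain_t,
                subject_id=sid, rng=sub_rng)
            if config.artifact_rate > 0:
                rec, arts = inject_artifacts(
                    rec, rate=config.artifact_rate, rng=sub_rng)
                truth.artifacts.extend(arts)
            if group != "Nold" and config.tirda_rate > 0:
                rec, runs = inject_rhythmic_delta(
                    rec, rate=config.tirda_rate, region="temporal",
                    rng=sub_rng)
                truth.tirda_runs.extend(runs)
            if group == "noADMCI-EEA" and config.eea_event_rate > 0:
                rec, events = inject_epileptiform(
                    rec, rate=config.eea_event_rate, rng=sub_rng)
                truth.events.extend(events)
            recordings.append(rec)
            truth.groups[sid] = group
            truth.iaf[sid] = iaf
            truth.delta_multiplier[sid] = gain_t ** 2
            if config.emulate_gender_skew:
                p_male = male_frac[group]
            else:
                p_male = 12 / 62
            meta_rows.append({
                "subject_id": sid, "group": group,
                "age": float(np.clip(sub_rng.normal(69.0, 6.5), 55, 90)),
                "gender": "M" if sub_rng.uniform() < p_male else "F",
                "education": float(np.clip(sub_rng.normal(9.6, 4.0), 5, 20)),
                "mmse": float(np.clip(sub_rng.normal(mmse_mean[group],
                                                     mmse_sd[group]), 24, 30)),
            })
    metadata = pd.DataFrame(meta_rows)
    return recordings, metadata, truth
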