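"""Reading, writing and preprocessing of 19-channel resting-state EEG.

The recording model mirrors a clinical acquisition: 19 scalp electrodes of
the 10-20 system plus one EOG channel, sampled at 128-512 Hz, amplitudes in
microvolts. Preprocessing follows the conventional quantitative-EEG recipe:
the first minutes of the recording are cut into consecutive 2-s epochs, and
epochs contaminated by ocular, muscle or movement artifacts (or by signs of
drowsiness) are excluded by rule before any spectral analysis.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Canonical 19-channel 10-20 montage (scalp EEG).
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Frontal electrodes used for the ocular-contamination rule.
FRONTAL_CHANNELS = ("F7", "F3", "Fz", "F4", "F8", "Fp1", "Fp2")

#: Standard longitudinal bipolar pairs used for transient review.
LONGITUDINAL_PAIRS = (
    ("Fp2", "T4"), ("T4", "O2"), ("Fp2", "C4"), ("C4", "O2"),
    ("Fp1", "T3"), ("T3", "O1"), ("Fp1", "C3"), ("C3", "O1"),
)

EPOCH_LABELS = ("clean", "ocular", "muscle", "movement", "sleep", "eea")


class MissingChannelError(ValueError):
    """A canonical 10-20 channel is absent from a recording or file."""


@dataclass
class Recording:
    """Multichannel EEG time series in microvolts.

    ``data`` is channels x samples; ``labels`` must contain every canonical
    10-20 channel exactly once (an EOG channel is optional but needed for
    the ocular artifact rule).
    """

    labels: list[str]
    data: np.ndarray
    fs: float
    reference: str = "linked-earlobe"
    subject_id: str = "S000"
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data must be (n_channels={len(self.labels)}) x n_samples, "
                f"got {self.data.shape}"
            )
        if not 128 <= self.fs <= 512:
            raise ValueError(f"sampling rate {self.fs} Hz outside [128, 512]")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("samples must be finite")
        lower = [lab.lower() for lab in self.labels]
        missing = [ch for ch in CHANNELS_1020 if ch.lower() not in lower]
        if missing:
            raise MissingChannelError(
                "missing canonical channels: " + ", ".join(missing)
            )
        for ch in CHANNELS_1020:
            if lower.count(ch.lower()) > 1:
                raise ValueError(f"duplicate channel {ch}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def index(self, label: str) -> int:
        lower = [lab.lower() for lab in self.labels]
        try:
            return lower.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.index(label)]

    def eeg_data(self) -> np.ndarray:
        """The 19 canonical channels, in canonical order."""
        return self.data[[self.index(ch) for ch in CHANNELS_1020]]

    def copy(self) -> "Recording":
        return replace(self, labels=list(self.labels), data=self.data.copy(),
                       annotations=list(self.annotations))


@dataclass(frozen=True)
class Epoch:
    """A contiguous, non-overlapping analysis window (2 s by default)."""

    subject_id: str
    start: int              # first sample, 0-based
    n_samples: int          # exactly window_s * fs
    label: str = "clean"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")

    @property
    def stop(self) -> int:
        return self.start + self.n_samples

    def sl(self) -> slice:
        return slice(self.start, self.stop)

    def relabel(self, label: str, provenance: str = "") -> "Epoch":
        return Epoch(self.subject_id, self.start, self.n_samples, label,
                     provenance)


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def write_edf(recording: Recording, path) -> None:
    """Write a recording as a plain EDF file (16-bit, 1-s data records).

    The physical range is set per channel from the data with headroom, so
    the quantization step is small relative to EEG amplitudes.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(recording.labels)
    n_records = recording.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s data record")
    data = recording.data[:, : n_records * fs]

    phys_min = np.floor(data.min(axis=1) - 1.0)
    phys_max = np.ceil(data.max(axis=1) + 1.0)
    dig_min, dig_max = -32768, 32767

    header = b""
    header += b"0".ljust(8)
    header += recording.subject_id.encode("ascii", "replace").ljust(80)[:80]
    header += f"Startdate rsdelta ref={recording.reference}".encode().ljust(80)[:80]
    header += b"01.01.00".ljust(8)
    header += b"00.00.00".ljust(8)
    header += str(256 * (n_ch + 1)).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_records).encode().ljust(8)
    header += b"1".ljust(8)                       # record duration, s
    header += str(n_ch).encode().ljust(4)

    def col(values, width):
        return b"".join(str(v).encode("ascii").ljust(width)[:width]
                        for v in values)

    header += col(recording.labels, 16)
    header += col(["AgAgCl electrode"] * n_ch, 80)
    header += col(["uV"] * n_ch, 8)
    header += col([f"{v:g}" for v in phys_min], 8)
    header += col([f"{v:g}" for v in phys_max], 8)
    header += col([dig_min] * n_ch, 8)
    header += col([dig_max] * n_ch, 8)
    header += col([""] * n_ch, 80)
    header += col([fs] * n_ch, 8)
    header += col([""] * n_ch, 32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs: (rec + 1) * fs]
            fh.write(chunk.tobytes())


def read_edf(path, subject_id: str | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (amplitudes in µV).

    Channel names are matched case-insensitively against the canonical
    10-20 set; a missing canonical channel raises
    :class:`MissingChannelError` naming the absentees.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # volts -> µV
    fs = float(raw.info["sfreq"])
    lower = [lab.lower() for lab in labels]
    missing = [ch for ch in CHANNELS_1020 if ch.lower() not in lower]
    if missing:
        raise MissingChannelError(
            "EDF file missing canonical channels: " + ", ".join(missing)
        )
    if not 128 <= fs <= 512:
        raise ValueError(f"unsupported sampling rate {fs} Hz")
    sid = subject_id
    if sid is None:
        sid = str(raw.info["subject_info"] or "S000")
        sid = raw._raw_extras[0].get("subject_info", None) or "S000"
        if not isinstance(sid, str):
            sid = "S000"
    return Recording(labels=labels, data=data, fs=fs, subject_id=sid)


# ---------------------------------------------------------------------------
# Montage derivation
# ---------------------------------------------------------------------------

def to_bipolar(recording: Recording,
               pairs=LONGITUDINAL_PAIRS) -> tuple[np.ndarray, list[str]]:
    """Derive bipolar channels (anode minus cathode, samplewise).

    Returns ``(series, names)`` with ``series`` of shape
    ``(len(pairs), n_samples)`` and names like ``"Fp2-T4"``.
    """
    rows = []
    names = []
    for anode, cathode in pairs:
        rows.append(recording.channel(anode) - recording.channel(cathode))
        names.append(f"{anode}-{cathode}")
    return np.array(rows), names


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def segment_epochs(recording: Recording, window_s: float = 2.0,
                   span_s: float = 180.0) -> list[Epoch]:
    """Cut consecutive non-overlapping epochs from the start of a recording.

    Only the first ``span_s`` seconds are used (3 min by default), any
    remainder shorter than one window is discarded.
    """
    n_win = int(round(window_s * recording.fs))
    if recording.n_samples < n_win:
        raise ValueError("recording shorter than one epoch window")
    usable = min(recording.n_samples, int(round(span_s * recording.fs)))
    n_epochs = usable // n_win
    return [Epoch(recording.subject_id, i * n_win, n_win)
            for i in range(n_epochs)]


# ---------------------------------------------------------------------------
# Artifact labeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactConfig:
    """Thresholds of the rule-based surrogate for visual artifact review.

    These operationalize what a human scorer judges qualitatively; they are
    calibrated on the synthetic cohorts, not clinically validated.
    """

    eog_corr_threshold: float = 0.7
    ocular_amplitude_uv: float = 80.0      # low-passed peak-to-peak on frontal
    movement_amplitude_uv: float = 100.0   # <2 Hz peak-to-peak
    movement_channel_fraction: float = 0.9
    muscle_slope_threshold: float = 0.0    # log10-power slope 25 Hz -> top
    muscle_power_min: float = 0.5          # µV²/Hz mean in the high band
    sleep_score_threshold: float = 0.8
    sleep_amplitude_uv: float = 75.0


def _lowpass(x: np.ndarray, fs: float, fc: float) -> np.ndarray:
    sos = sps.butter(4, fc / (fs / 2), btype="low", output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _kcomplex_template(fs: float) -> np.ndarray:
    """Surrogate K-complex: sharp negative wave followed by a slow positive."""
    t = np.arange(int(0.9 * fs)) / fs
    return (-np.exp(-((t - 0.15) / 0.07) ** 2)
            + 0.8 * np.exp(-((t - 0.45) / 0.16) ** 2))


def detect_artifacts(epochs: list[Epoch], recording: Recording,
                     eog: str | None = "EOG",
                     config: ArtifactConfig = ArtifactConfig()) -> list[Epoch]:
    """Label epochs as clean / ocular / muscle / movement / sleep by rule.

    * ocular -- EOG correlates strongly with a frontal channel and that
      channel carries a large low-frequency deflection;
    * movement -- a slow (<2 Hz) deflection above threshold appears on at
      least 90% of channels simultaneously;
    * muscle -- the high band (30 Hz to min(100, Nyquist)) is elevated and
      the log-power trend from 25 Hz upward does not decline;
    * sleep -- a K-complex-like matched-filter response above threshold.

    Precedence when several rules fire: movement > muscle > ocular > sleep.
    """
    fs = recording.fs
    eeg = recording.eeg_data()
    frontal_idx = [CHANNELS_1020.index(ch) for ch in FRONTAL_CHANNELS]
    eog_sig = None
    if eog is not None:
        try:
            eog_sig = recording.channel(eog)
        except KeyError:
            logger.warning("EOG channel %r absent: ocular rule skipped", eog)

    nyq = fs / 2
    hi_top = min(100.0, nyq - 1e-9)
    slow_all = _lowpass(eeg, fs, 2.0)
    slow5_frontal = _lowpass(eeg[frontal_idx], fs, 7.0)
    template = _kcomplex_template(fs)
    template = (template - template.mean()) / np.linalg.norm(template)

    out = []
    for ep in epochs:
        seg = eeg[:, ep.sl()]
        label, prov = "clean", ""

        # movement: synchronous large slow deflection
        slow = slow_all[:, ep.sl()]
        p2p = slow.max(axis=1) - slow.min(axis=1)
        frac = np.mean(p2p > config.movement_amplitude_uv)
        if frac >= config.movement_channel_fraction:
            label, prov = "movement", f"slow p2p on {frac:.0%} of channels"

        # muscle: non-declining high-band spectrum
        if label == "clean":
            f, pxx = sps.welch(seg, fs=fs, nperseg=min(seg.shape[1], int(fs)))
            hi = (f >= 30) & (f <= hi_top)
            tail = (f >= 25) & (f <= hi_top)
            mean_hi = float(np.mean(pxx[:, hi]))
            logp = np.log10(np.mean(pxx[:, tail], axis=0) + 1e-12)
            slope = np.polyfit(f[tail], logp, 1)[0]
            if (mean_hi > config.muscle_power_min
                    and slope >= config.muscle_slope_threshold):
                label, prov = "muscle", f"high-band slope {slope:.3g}"

        # ocular: EOG-correlated frontal deflection
        if label == "clean" and eog_sig is not None:
            e = eog_sig[ep.sl()]
            if np.ptp(e) > 1e-9:
                fr = seg[frontal_idx]
                es = (e - e.mean()) / (e.std() + 1e-12)
                frs = (fr - fr.mean(axis=1, keepdims=True)) \
                    / (fr.std(axis=1, keepdims=True) + 1e-12)
                corr = np.abs(frs @ es) / len(es)
                lowfr = slow5_frontal[:, ep.sl()]
                p2p_f = lowfr.max(axis=1) - lowfr.min(axis=1)
                hit = (corr > config.eog_corr_threshold) \
                    & (p2p_f > config.ocular_amplitude_uv)
                if hit.any():
                    ch = FRONTAL_CHANNELS[int(np.argmax(corr * hit))]
                    label, prov = "ocular", f"EOG corr on {ch}"

        # sleep: K-complex surrogate matched filter
        if label == "clean":
            mean_sig = seg.mean(axis=0)
            sc = sps.correlate(mean_sig, template, mode="valid")
            norm = np.sqrt(np.convolve(mean_sig ** 2,
                                       np.ones(len(template)), "valid")) + 1e-12
            score = np.max(np.abs(sc) / norm)
            if (score > config.sleep_score_threshold
                    and np.ptp(mean_sig) > config.sleep_amplitude_uv):
                label, prov = "sleep", f"K-complex score {score:.2f}"

        out.append(ep.relabel(label, prov) if label != "clean" else ep)
    return out


def select_clean_epochs(epochs: list[Epoch],
                        warn_retention: float = 0.8) -> tuple[list[Epoch], float]:
    """Keep epochs labeled clean; report the retention fraction.

    Epochs flagged as containing epileptiform events (label ``"eea"``) are
    excluded along with artifacts. Logs a warning when retention drops
    below ``warn_retention`` and raises if nothing survives.
    """
    if not epochs:
        raise ValueError("no epochs to select from")
    clean = [ep for ep in epochs if ep.label == "clean"]
    retention = len(clean) / len(epochs)
    if not clean:
        raise ValueError("zero clean epochs: downstream spectra undefined")
    if retention < warn_retention:
        logger.warning("artifact-free retention %.0f%% below %.0f%%",
                       100 * retention, 100 * warn_retention)
    return clean, retention
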