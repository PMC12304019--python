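"""Reading, preprocessing and labelling of EEG recordings.

Covers the ingestion side of the pipeline: EDF reading with a channel
preference list (frontal Fp2-F4 / F2-F4, central fallback), per-epoch
stage annotations in a simple one-token-per-epoch text dialect,
R&K -> AASM stage merging (S3 + S4 -> NREMS3), 30 Hz zero-phase lowpass
filtering, polyphase resampling, and alignment of windowed entropy
series with stage labels into feature tables.

A minimal 16-bit EDF writer is included for generating synthetic
fixtures; real-world EDF reading goes through mne.
"""

from __future__ import annotations

import math
import struct
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .entropy import EntropySeries

__all__ = [
    "Signal",
    "LabeledWindows",
    "SLEEP_STAGES",
    "ANESTHESIA_LEVELS",
    "read_edf",
    "write_edf",
    "read_stage_annotations",
    "write_stage_annotations",
    "merge_rk_to_aasm",
    "lowpass_filter",
    "resample",
    "align_windows_to_labels",
]

#: AASM sleep-stage vocabulary after R&K merging.
SLEEP_STAGES = ("WAKE", "REMS", "NREMS1", "NREMS2", "NREMS3")
#: Anesthesia-level vocabulary (wakefulness, light, deep, burst suppression).
ANESTHESIA_LEVELS = ("wake", "inter1", "inter2", "burst_suppression")

#: R&K scoring tokens -> AASM stages.
_RK_TO_AASM = {
    "W": "WAKE",
    "S1": "NREMS1",
    "S2": "NREMS2",
    "S3": "NREMS3",
    "S4": "NREMS3",
    "R": "REMS",
    "REM": "REMS",
}

#: Channels counted as "centrally located" for the fallback rule.
CENTRAL_CHANNELS = ("C4-A1", "C4-P4", "C3-A2", "C3-P3", "Cz-A1", "C4", "C3", "Cz")
DEFAULT_CHANNEL_PREFERENCE = ("Fp2-F4", "F2-F4")


class ChannelNotFoundError(KeyError):
    """No preferred or fallback channel present in the recording."""


class AlignmentError(ValueError):
    """Window grid and label epoch grid do not match."""


@dataclass
class Signal:
    """A single-channel sample sequence with its sampling rate.

    Amplitudes are in microvolts for EEG, arbitrary units otherwise.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in signal")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_seconds(self) -> float:
        return self.n / self.sampling_rate


@dataclass
class LabeledWindows:
    """Per-epoch vigilance-state labels of one recording.

    ``labels`` holds one token per epoch; ``None`` marks an unlabeled
    (rejected) epoch that is excluded downstream.  Unknown tokens met
    during parsing are reported in ``rejects``.
    """

    labels: list
    epoch_seconds: float
    recording_id: str = ""
    rejects: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# EDF


def read_edf(
    path,
    channel_preference=DEFAULT_CHANNEL_PREFERENCE,
    fallback=CENTRAL_CHANNELS,
) -> Signal:
    """Read one EEG channel from an EDF/EDF+ file.

    The first channel found in ``channel_preference`` is returned; when
    none is present the ``fallback`` list (by default centrally located
    electrodes) is searched.  Amplitudes are returned in microvolts.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    except Exception as exc:  # surface a structured error naming the file
        raise IOError(f"cannot parse EDF file {path}: {exc}") from exc
    available = {name.strip(): name for name in raw.ch_names}
    chosen = None
    for name in tuple(channel_preference) + tuple(fallback):
        if name in available:
            chosen = available[name]
            break
    if chosen is None:
        raise ChannelNotFoundError(
            f"none of {list(channel_preference)} (or fallbacks {list(fallback)}) "
            f"in {path}; channels present: {raw.ch_names}"
        )
    raw.load_data(verbose="error")
    data = raw.get_data(picks=[chosen], units="uV")[0]
    return Signal(data, float(raw.info["sfreq"]), channel_name=chosen.strip())


def _pad(text: str, width: int) -> bytes:
    out = text.encode("ascii", "replace")[:width]
    return out + b" " * (width - len(out))


def write_edf(signal: Signal, path, recording_id: str = "synthetic") -> None:
    """Write a single-channel 16-bit EDF file (fixture writer).

    Uses 1 s data records, so the sampling rate must be a positive
    integer and the signal a whole number of seconds.  Amplitudes are
    stored as microvolts with full-range 16-bit quantization.
    """
    fs = signal.sampling_rate
    if fs != int(fs) or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(fs)
    if signal.n % spr != 0:
        raise ValueError(
            f"signal length {signal.n} is not a whole number of 1 s records at {spr} Hz"
        )
    n_records = signal.n // spr
    x = signal.samples
    pmin, pmax = float(x.min()), float(x.max())
    if pmax <= pmin:  # constant signal: give the range nonzero width
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(recording_id, 80),
            _pad(f"Startdate 01-JAN-2000 {recording_id}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 + 256), 8),  # header bytes: fixed + 1 signal
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),  # record duration, seconds
            _pad("1", 4),  # number of signals
            # per-signal fields
            _pad(signal.channel_name or "EEG", 16),
            _pad("", 80),  # transducer
            _pad("uV", 8),
            _pad(f"{pmin:.6g}", 8),
            _pad(f"{pmax:.6g}", 8),
            _pad(str(dmin), 8),
            _pad(str(dmax), 8),
            _pad("", 80),  # prefiltering
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# stage annotations

_ANNOTATION_HEADER = "epoch_seconds"


def read_stage_annotations(path, epoch_seconds: float | None = None) -> LabeledWindows:
    """Read per-epoch stage labels: one token per line, optional
    ``epoch_seconds=<s>`` header line, ``#`` comments ignored.

    Tokens are preserved verbatim (R&K codes stay R&K until
    :func:`merge_rk_to_aasm`).  Tokens outside both the R&K and the
    study vocabularies (e.g. ``MT`` movement epochs) are recorded in
    ``rejects`` and their epochs marked unlabeled.
    """
    path = Path(path)
    tokens: list[str] = []
    header_epoch = None
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(_ANNOTATION_HEADER):
            header_epoch = float(line.split("=", 1)[1])
            continue
        tokens.append(line.split(",")[0].strip() if "," in line else line)
    if epoch_seconds is None:
        epoch_seconds = header_epoch if header_epoch is not None else 30.0
    known = set(_RK_TO_AASM) | set(_RK_TO_AASM.values()) | set(ANESTHESIA_LEVELS)
    labels: list[str | None] = []
    rejects: list[tuple[int, str]] = []
    for i, tok in enumerate(tokens):
        if tok in known:
            labels.append(tok)
        else:
            labels.append(None)
            rejects.append((i, tok))
    if not labels:
        warnings.warn(f"no epochs found in {path}", stacklevel=2)
    return LabeledWindows(labels, epoch_seconds, recording_id=path.stem, rejects=rejects)


def write_stage_annotations(lw: LabeledWindows, path) -> None:
    """Write annotations in the dialect read by read_stage_annotations."""
    lines = [f"{_ANNOTATION_HEADER}={lw.epoch_seconds:g}"]
    lines += [lab if lab is not None else "UNKNOWN" for lab in lw.labels]
    Path(path).write_text("\n".join(lines) + "\n")


def merge_rk_to_aasm(lw: LabeledWindows) -> LabeledWindows:
    """Merge R&K stages into AASM: S3 and S4 both become NREMS3.

    Idempotent; epoch counts are conserved, already-AASM or
    non-sleep labels pass through unchanged.
    """
    merged = [_RK_TO_AASM.get(lab, lab) if lab is not None else None for lab in lw.labels]
    return LabeledWindows(merged, lw.epoch_seconds, lw.recording_id, list(lw.rejects))


# ---------------------------------------------------------------------------
# preprocessing


def lowpass_filter(s: Signal, cutoff_hz: float, order: int = 4) -> Signal:
    """Zero-phase Butterworth lowpass (forward-backward, no group
    delay, length preserved).  Standard EEG preprocessing applies
    30 Hz."""
    nyquist = s.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz at "
            f"{s.sampling_rate} Hz sampling"
        )
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=s.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, s.samples)
    return Signal(filtered, s.sampling_rate, s.channel_name)


def resample(s: Signal, target_hz: float) -> Signal:
    """Polyphase resampling to ``target_hz`` with built-in
    anti-aliasing; duration preserved within one sample period."""
    if not target_hz > 0:
        raise ValueError(f"target rate must be positive, got {target_hz}")
    if target_hz == s.sampling_rate:
        return Signal(s.samples.copy(), s.sampling_rate, s.channel_name)
    ratio = Fraction(target_hz / s.sampling_rate).limit_denominator(1000)
    resampled = sps.resample_poly(s.samples, ratio.numerator, ratio.denominator)
    return Signal(resampled, target_hz, s.channel_name)


# ---------------------------------------------------------------------------
# label alignment


def align_windows_to_labels(series: EntropySeries, lw: LabeledWindows) -> pd.DataFrame:
    """Pair each valid entropy window with its epoch label.

    Requires the entropy windows and label epochs to lie on the same
    grid (equal length, aligned starts).  Invalid (tie-discarded) and
    unlabeled windows are dropped; the result has one row per valid
    labeled window.
    """
    if not math.isclose(series.window_seconds, lw.epoch_seconds):
        raise AlignmentError(
            f"window length {series.window_seconds} s != epoch length "
            f"{lw.epoch_seconds} s"
        )
    if series.n_windows > lw.n_epochs:
        raise AlignmentError(
            f"{series.n_windows} windows but only {lw.n_epochs} label epochs"
        )
    expected_starts = np.arange(series.n_windows) * lw.epoch_seconds
    offsets = series.window_start_times - expected_starts
    if np.max(np.abs(offsets), initial=0.0) > 1e-9:
        raise AlignmentError(f"window grid offset from epoch grid by {offsets!r}")
    frame = series.to_frame()
    frame["label"] = [lw.labels[i] for i in frame["window_index"]]
    frame["recording_id"] = lw.recording_id or frame["recording_id"]
    keep = frame["valid"] & frame["label"].notna()
    return frame.loc[keep].reset_index(drop=True)
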