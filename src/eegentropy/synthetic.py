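"""Seeded synthetic inputs: white noise and two-state vigilance EEG.

The white-noise generator reproduces the benchmark harness design used
for runtime/complexity analysis: uniform(0, 1) samples from a Mersenne
Twister, default length 14.4e6, seeds 1..20 (only distributional
properties are asserted anywhere; the exact stream is RNG-specific).

The vigilance generator emulates the one robust feature of real sleep /
anesthesia EEG that entropy measures exploit: the shift of spectral
mass from broadband activity during wakefulness to slow oscillations in
deep states.  Each state is 1/f^alpha Gaussian noise lowpassed at a
state-specific corner frequency; wake-like epochs are broadband
(corner near 30 Hz), deep-like epochs delta-dominated (corner ~4 Hz),
so their pattern entropy is lower in expectation.  Epoch-to-epoch
corner jitter provides within-state variability and a small white
measurement-noise floor keeps the signal from being pathologically
smooth.  It makes no attempt at real EEG morphology (spindles,
K-complexes, burst-suppression bursts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_io import LabeledWindows, Signal, write_edf, write_stage_annotations

__all__ = [
    "StateProfile",
    "SyntheticStudySpec",
    "white_noise",
    "synthetic_vigilance_recording",
    "write_fixture_study",
    "quantize",
    "BENCHMARK_LENGTH",
    "BENCHMARK_SEEDS",
]

#: Benchmark white-noise vector length (20 min at 12 kHz equivalent).
BENCHMARK_LENGTH = 14_400_000
#: Benchmark seeds.
BENCHMARK_SEEDS = tuple(range(1, 21))


def _rng(seed: int) -> np.random.Generator:
    # Mersenne Twister bit generator (the field's customary default)
    return np.random.Generator(np.random.MT19937(seed))


def white_noise(n: int, seed: int, sampling_rate: float = 200.0) -> Signal:
    """i.i.d. uniform(0, 1) samples, deterministic per seed.

    At double precision the probability of tied samples is zero, so
    white noise exercises the tie-free paths; use :func:`quantize` to
    inject ties deliberately.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    samples = _rng(seed).random(n)
    return Signal(samples, sampling_rate, channel_name=f"noise[seed={seed}]")


@dataclass(frozen=True)
class StateProfile:
    """Spectral recipe of one vigilance state.

    ``corner_hz`` is the lowpass corner of the state's dominant
    activity; ``one_over_f_exponent`` the 1/f^alpha slope above 1 Hz;
    ``amplitude_uv`` the rms amplitude.  Slow-wave states carry much
    larger amplitudes than wake EEG, which keeps their smooth
    trajectories above the measurement-noise floor — the property that
    makes slow states low-entropy in real recordings.
    """

    label: str
    corner_hz: float
    one_over_f_exponent: float = 1.0
    amplitude_uv: float = 15.0


#: Default two-state study: broadband low-amplitude wake-like activity vs
#: high-amplitude delta-dominated deep-like activity (labels drawn from the
#: sleep-stage vocabulary so fixtures re-ingest cleanly).
DEFAULT_STATES = (
    StateProfile("WAKE", corner_hz=30.0, one_over_f_exponent=1.0,
                 amplitude_uv=15.0),
    StateProfile("NREMS3", corner_hz=4.0, one_over_f_exponent=2.0,
                 amplitude_uv=75.0),
)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of a synthetic labeled recording.

    Defaults mirror the sleep-analysis conditions: 30 s epochs at
    200 Hz (6000-point windows), 100 epochs per state.  ``corner_jitter``
    scales each epoch's corner by 2**U(-j, j), providing the
    within-state spectral variability of real recordings;
    ``noise_floor_uv`` is the white amplifier-noise amplitude relative
    to the 10 uV signal scale.
    """

    states: tuple = DEFAULT_STATES
    epoch_seconds: float = 30.0
    epochs_per_state: int = 100
    sampling_rate_hz: float = 200.0
    seed: int = 0
    corner_jitter: float = 0.5
    noise_floor_uv: float = 0.5

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("need at least 2 states")
        nyquist = self.sampling_rate_hz / 2.0
        for state in self.states:
            if not 0 < state.corner_hz < nyquist:
                raise ValueError(
                    f"state {state.label!r} corner {state.corner_hz} Hz outside "
                    f"(0, {nyquist}) Hz"
                )


def _shaped_epoch(
    rng: np.random.Generator,
    n: int,
    fs: float,
    corner_hz: float,
    alpha: float,
    amplitude_uv: float,
    noise_floor: float,
) -> np.ndarray:
    """One epoch of 1/f^alpha noise lowpassed at corner_hz."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = 1.0 / np.sqrt(1.0 + (freqs / corner_hz) ** 8)  # 4th-order-like rolloff
    with np.errstate(divide="ignore"):
        pink = np.where(freqs >= 1.0, freqs**-alpha, 1.0)
    spectrum *= gain * pink
    shaped = np.fft.irfft(spectrum, n=n)
    shaped *= amplitude_uv / max(shaped.std(), 1e-12)
    if noise_floor > 0:
        shaped = shaped + noise_floor * rng.standard_normal(n)
    return shaped


def synthetic_vigilance_recording(
    spec: SyntheticStudySpec,
) -> tuple[Signal, LabeledWindows]:
    """Concatenated labeled epochs in seeded-shuffled order.

    Bit-identical for identical spec + seed.  By construction the
    entropy of deep-like epochs is lower than of wake-like epochs in
    expectation (slower dominant rhythms -> fewer distinct local
    patterns), emulating the WAKE > REMS > NREMS2 > NREMS3 ordering of
    real sleep EEG.
    """
    rng = _rng(spec.seed)
    n_epoch = int(round(spec.epoch_seconds * spec.sampling_rate_hz))
    order = np.repeat(np.arange(len(spec.states)), spec.epochs_per_state)
    rng.shuffle(order)
    pieces = []
    labels = []
    for state_idx in order:
        state = spec.states[state_idx]
        corner = state.corner_hz * 2.0 ** rng.uniform(-spec.corner_jitter, spec.corner_jitter)
        corner = min(corner, 0.49 * spec.sampling_rate_hz)
        pieces.append(
            _shaped_epoch(
                rng,
                n_epoch,
                spec.sampling_rate_hz,
                corner,
                state.one_over_f_exponent,
                state.amplitude_uv,
                spec.noise_floor_uv,
            )
        )
        labels.append(state.label)
    signal = Signal(
        np.concatenate(pieces), spec.sampling_rate_hz, channel_name="synthetic"
    )
    lw = LabeledWindows(labels, spec.epoch_seconds, recording_id=f"synthetic-{spec.seed}")
    return signal, lw


def write_fixture_study(
    spec: SyntheticStudySpec, out_dir, n_subjects: int = 3
) -> list[tuple[Path, Path]]:
    """Write one EDF + one stage-annotation file per synthetic subject.

    Subject i uses seed ``spec.seed + i``; files are re-ingestable by
    signal_io with zero rejects.  Returns (edf_path, annotation_path)
    pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n_subjects):
        subject_spec = SyntheticStudySpec(
            states=spec.states,
            epoch_seconds=spec.epoch_seconds,
            epochs_per_state=spec.epochs_per_state,
            sampling_rate_hz=spec.sampling_rate_hz,
            seed=spec.seed + i,
            corner_jitter=spec.corner_jitter,
            noise_floor_uv=spec.noise_floor_uv,
        )
        signal, lw = synthetic_vigilance_recording(subject_spec)
        rec_id = f"subj{i:02d}"
        signal.channel_name = "Fp2-F4"
        edf_path = out_dir / f"{rec_id}.edf"
        ann_path = out_dir / f"{rec_id}.stages.txt"
        try:
            write_edf(signal, edf_path, recording_id=rec_id)
            lw_named = LabeledWindows(lw.labels, lw.epoch_seconds, rec_id, lw.rejects)
            write_stage_annotations(lw_named, ann_path)
        except OSError as exc:
            raise OSError(f"cannot write fixture for {rec_id} under {out_dir}: {exc}")
        paths.append((edf_path, ann_path))
    return paths


def quantize(signal: Signal, levels: int = 256) -> Signal:
    """Quantize amplitudes to a small number of levels, deliberately
    injecting ties (to exercise tie policies)."""
    x = signal.samples
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return Signal(x.copy(), signal.sampling_rate, signal.channel_name)
    q = np.round((x - lo) / (hi - lo) * (levels - 1))
    return Signal(q, signal.sampling_rate, signal.channel_name)
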