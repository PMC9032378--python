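"""Cochlear-microphonic extraction from alternating-polarity raw buffers.

Consecutive response buffers are recorded to condensation and rarefaction
stimuli.  The cochlear microphonic (CM) follows the stimulus waveform and so
inverts with polarity, while neural and summating contributions do not;
subtracting the two buffers of a pair therefore isolates the CM.  Pairs are
averaged until the spectral signal-to-noise ratio reaches a stopping criterion
(default 12 dB) or a maximum number of averages (default 40) is spent, the CM
epoch is Fourier transformed, and the response is read off the FFT bin that
contains the stimulus frequency.  The noise floor is the mean magnitude of a
few bins surrounding that bin.

Conventions
-----------
* ``difference_average`` divides the polarity difference by 2 so amplitudes
  stay in physical microvolts.
* The analysis window is the central ``window_samples`` (default 464) samples
  of each buffer; at 9,280 Hz that is exactly 50 ms, giving 20 Hz bin spacing
  so a 500 Hz stimulus sits exactly on bin 25.  Rectangular window, no zero
  padding: an on-bin sinusoid leaks nothing, so no taper is needed.
* Spectral magnitude is single-sided and normalised so a unit-amplitude
  on-bin sinusoid yields magnitude 1.
* Phase is the argument of the stimulus bin, in degrees in (-180, 180],
  relative to the analysis-window start; a cosine starting at the window start
  has phase 0, and delaying it by a quarter period gives -90 degrees.
* SNR is amplitude-ratio dB: ``20*log10(amplitude / noise_floor)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .stimulus import CONDENSATION, SAMPLE_RATE_HZ, StimulusSpec

#: Clamp applied to the noise-floor estimate so SNR is always finite.
FLOOR_CLAMP_UV = 1e-12


@dataclass(frozen=True)
class RawBuffer:
    """One digitised response epoch.

    ``samples`` are electrode-referred microvolts (the amplifier gain has
    already been divided out; ``gain_applied`` is metadata only).
    """

    samples: np.ndarray
    polarity: str
    t_acquired: float
    gain_applied: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("buffer samples must be finite")


@dataclass(frozen=True)
class ExtractionConfig:
    """Averaging / detection parameters.

    snr_stop_db
        Averaging stops once the running SNR reaches this value (default 12).
    max_averages
        Hard ceiling on pairs averaged into one point (default 40).
    noise_bins_each_side, guard_bins
        The floor is the mean magnitude of ``noise_bins_each_side`` bins on
        each side of the stimulus bin, skipping ``guard_bins`` bins adjacent
        to it.
    window_samples
        Length of the central analysis window (see module notes).
    """

    snr_stop_db: float = 12.0
    max_averages: int = 40
    noise_bins_each_side: int = 3
    guard_bins: int = 1
    window_samples: int = 464
    sample_rate_hz: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.snr_stop_db <= 0:
            raise ValueError("snr_stop_db must be positive")
        if self.max_averages < 1:
            raise ValueError("max_averages must be >= 1")
        if self.noise_bins_each_side < 1:
            raise ValueError("need at least one noise bin per side")
        if self.guard_bins < 0:
            raise ValueError("guard_bins must be >= 0")


@dataclass(frozen=True)
class EcochgPoint:
    """One monitored time point of the insertion."""

    t: float
    amplitude_uv: float
    phase_deg: float
    noise_floor_uv: float
    n_averages: int
    snr_db: float

    @property
    def above_floor(self) -> bool:
        """Response amplitude exceeds the measured noise floor (SNR > 0 dB)."""
        return self.snr_db > 0.0


@dataclass
class InsertionTrace:
    """Ordered monitoring points for one electrode insertion."""

    subject_id: str
    points: list[EcochgPoint]
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("trace must contain at least one point")
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValueError("point times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points])

    @property
    def amplitudes_uv(self) -> np.ndarray:
        return np.array([p.amplitude_uv for p in self.points])

    @property
    def phases_deg(self) -> np.ndarray:
        return np.array([p.phase_deg for p in self.points])

    @property
    def snrs_db(self) -> np.ndarray:
        return np.array([p.snr_db for p in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "t": self.times,
                "amplitude_uv": self.amplitudes_uv,
                "phase_deg": self.phases_deg,
                "noise_floor_uv": [p.noise_floor_uv for p in self.points],
                "n_averages": [p.n_averages for p in self.points],
                "snr_db": self.snrs_db,
                "above_floor": [p.above_floor for p in self.points],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, stimulus: StimulusSpec | None = None) -> "InsertionTrace":
        ids = df["subject_id"].unique()
        if len(ids) != 1:
            raise ValueError("expected a single subject per trace frame")
        pts = [
            EcochgPoint(
                t=float(r.t),
                amplitude_uv=float(r.amplitude_uv),
                phase_deg=float(r.phase_deg),
                noise_floor_uv=float(r.noise_floor_uv),
                n_averages=int(r.n_averages),
                snr_db=float(r.snr_db),
            )
            for r in df.sort_values("t").itertuples()
        ]
        return cls(subject_id=str(ids[0]), points=pts, stimulus=stimulus or StimulusSpec())


@dataclass(frozen=True)
class Spectrum:
    """Single-sided, amplitude-normalised spectrum of one CM epoch."""

    values: np.ndarray  # complex, length n_window//2 + 1
    bin_hz: float

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.values)

    def bin_index(self, frequency_hz: float) -> int:
        """Index of the bin nearest ``frequency_hz``."""
        k = int(round(frequency_hz / self.bin_hz))
        return min(k, len(self.values) - 1)


def difference_average(pair: tuple[RawBuffer, RawBuffer]) -> np.ndarray:
    """CM epoch from one alternating-polarity pair: (condensation - rarefaction)/2.

    Polarity-invariant components cancel exactly; the polarity-following CM is
    preserved in microvolts.
    """
    a, b = pair
    if a.polarity == b.polarity:
        raise ValueError("pair must have opposite polarities")
    if len(a.samples) != len(b.samples):
        raise ValueError("pair buffers must have equal length")
    cond, rar = (a, b) if a.polarity == CONDENSATION else (b, a)
    return (cond.samples - rar.samples) / 2.0


def analysis_window(epoch: np.ndarray, window_samples: int) -> np.ndarray:
    """Central ``window_samples`` slice of an epoch."""
    n = len(epoch)
    if n < window_samples:
        raise ValueError(f"epoch of {n} samples shorter than window {window_samples}")
    start = (n - window_samples) // 2
    return epoch[start : start + window_samples]


def spectrum(
    epoch: np.ndarray,
    window_samples: int | None = None,
    sample_rate_hz: float = SAMPLE_RATE_HZ,
) -> Spectrum:
    """Amplitude-normalised single-sided spectrum of the central window.

    A unit-amplitude sinusoid exactly on a bin yields magnitude 1 at that bin
    (DC and Nyquist bins are not doubled).
    """
    epoch = np.asarray(epoch, dtype=float)
    n = len(epoch) if window_samples is None else window_samples
    x = analysis_window(epoch, n)
    raw = np.fft.rfft(x)
    scale = np.full(len(raw), 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    return Spectrum(values=raw * scale, bin_hz=sample_rate_hz / n)


def response_magnitude_phase(spec: Spectrum, stimulus_frequency_hz: float) -> tuple[float, float]:
    """Amplitude (uV) and phase (deg, in (-180, 180]) at the stimulus bin."""
    k = spec.bin_index(stimulus_frequency_hz)
    value = spec.values[k]
    amplitude = float(np.abs(value))
    phase = float(np.degrees(np.angle(value)))
    if phase <= -180.0:
        phase += 360.0
    return amplitude, phase


def noise_floor(
    spec: Spectrum,
    stimulus_frequency_hz: float,
    noise_bins_each_side: int = 3,
    guard_bins: int = 1,
) -> float:
    """Mean magnitude of the bins surrounding the stimulus bin, in microvolts.

    ``guard_bins`` bins adjacent to the stimulus bin are excluded on each side
    before ``noise_bins_each_side`` bins are averaged.  The result is clamped
    to a tiny positive value so SNR stays finite on noiseless input.
    """
    k = spec.bin_index(stimulus_frequency_hz)
    lo = np.arange(k - guard_bins - noise_bins_each_side, k - guard_bins)
    hi = np.arange(k + guard_bins + 1, k + guard_bins + 1 + noise_bins_each_side)
    idx = np.concatenate([lo, hi])
    if idx[0] < 0 or idx[-1] >= len(spec.values):
        raise ValueError("not enough bins on both sides of the stimulus bin")
    return max(float(np.mean(spec.magnitudes[idx])), FLOOR_CLAMP_UV)


def _pairs(stream: Iterator[RawBuffer]) -> Iterator[tuple[RawBuffer, RawBuffer] | None]:
    """Yield alternating-polarity pairs; None signals a clean end of stream."""
    while True:
        try:
            first = next(stream)
        except StopIteration:
            yield None
            return
        try:
            second = next(stream)
        except StopIteration:
            raise ValueError("buffer stream exhausted mid-pair") from None
        yield (first, second)


def extract_point(
    buffer_stream: Iterable[RawBuffer] | Iterator[RawBuffer],
    config: ExtractionConfig = ExtractionConfig(),
    stimulus_frequency_hz: float = 500.0,
) -> EcochgPoint:
    """Average pairs until the SNR stopping rule fires; return one point.

    Pairs are accumulated into a strict arithmetic running mean.  After each
    pair the windowed spectrum is evaluated; averaging stops as soon as
    ``snr_db >= config.snr_stop_db`` or ``config.max_averages`` pairs have
    been consumed, whichever comes first.  ``t`` is the acquisition time of
    the first buffer consumed.
    """
    stream = iter(buffer_stream)
    point, _ = _extract_point_from(_pairs(stream), config, stimulus_frequency_hz)
    if point is None:
        raise ValueError("buffer stream is empty")
    return point


def _extract_point_from(
    pair_iter: Iterator[tuple[RawBuffer, RawBuffer] | None],
    config: ExtractionConfig,
    stimulus_frequency_hz: float,
) -> tuple[EcochgPoint | None, bool]:
    """Inner stopping-rule loop.  Returns (point or None, stream_ended)."""
    accum: np.ndarray | None = None
    t0 = 0.0
    n = 0
    ended = False
    last: tuple[float, float, float] | None = None
    while n < config.max_averages:
        pair = next(pair_iter)
        if pair is None:
            ended = True
            break
        if n == 0:
            t0 = pair[0].t_acquired
        epoch = difference_average(pair)
        accum = epoch if accum is None else accum + epoch
        n += 1
        spec = spectrum(accum / n, config.window_samples, config.sample_rate_hz)
        amp, ph = response_magnitude_phase(spec, stimulus_frequency_hz)
        floor = noise_floor(
            spec, stimulus_frequency_hz, config.noise_bins_each_side, config.guard_bins
        )
        snr = 20.0 * np.log10(max(amp, FLOOR_CLAMP_UV) / floor)
        last = (amp, ph, floor)
        if snr >= config.snr_stop_db:
            break
    if n == 0:
        return None, ended
    amp, ph, floor = last  # type: ignore[misc]
    snr = 20.0 * np.log10(max(amp, FLOOR_CLAMP_UV) / floor)
    return (
        EcochgPoint(
            t=t0,
            amplitude_uv=amp,
            phase_deg=ph,
            noise_floor_uv=floor,
            n_averages=n,
            snr_db=float(snr),
        ),
        ended,
    )


def extract_trace(
    buffer_stream: Iterable[RawBuffer] | Iterator[RawBuffer],
    config: ExtractionConfig = ExtractionConfig(),
    stimulus: StimulusSpec | None = None,
    subject_id: str = "subject",
) -> InsertionTrace:
    """Consume a whole insertion's buffer stream into an ordered trace.

    Points are emitted back to back until the stream ends.  A stream that ends
    between pairs before the stopping rule fires emits a final point from the
    pairs accumulated so far; ending mid-pair is an error.
    """
    stimulus = stimulus or StimulusSpec()
    stream = iter(buffer_stream)
    pair_iter = _pairs(stream)
    points: list[EcochgPoint] = []
    while True:
        point, ended = _extract_point_from(pair_iter, config, stimulus.frequency_hz)
        if point is not None:
            points.append(point)
        if ended:
            break
    if not points:
        raise ValueError("buffer stream is empty")
    return InsertionTrace(subject_id=subject_id, points=points, stimulus=stimulus)


def read_buffers_csv(path) -> list[RawBuffer]:
    """Read one subject's raw-buffer CSV (columns t_acquired, polarity, s0...)."""
    df = pd.read_csv(path)
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    mat = df[sample_cols].to_numpy(dtype=float)
    return [
        RawBuffer(samples=mat[i], polarity=str(pol), t_acquired=float(t))
        for i, (t, pol) in enumerate(zip(df["t_acquired"], df["polarity"]))
    ]


def write_buffers_csv(buffers: Sequence[RawBuffer], path) -> None:
    """Write raw buffers as a wide CSV, one row per buffer."""
    n = len(buffers[0].samples)
    data = {
        "t_acquired": [b.t_acquired for b in buffers],
        "polarity": [b.polarity for b in buffers],
    }
    mat = np.stack([b.samples for b in buffers])
    frame = pd.DataFrame(data)
    samples = pd.DataFrame(mat, columns=[f"s{i}" for i in range(n)])
    pd.concat([frame, samples], axis=1).to_csv(path, index=False, float_format="%.5f")
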