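"""Acoustic stimulus description and waveform synthesis.

The monitoring stimulus is a low-frequency sinusoidal tone burst delivered at a
high level through an insert earphone while the electrode array advances.  Only
the stimulus *shape* matters downstream (the cochlear-microphonic response is
synthesised directly in electrode-referred microvolts), so the waveform here is
a pressure-proportional sequence on an arbitrary linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default acquisition rate of the implant's back-telemetry amplifier, in Hz.
SAMPLE_RATE_HZ = 9280.0

#: Stimulus level that maps to unit waveform amplitude.  The transfer function
#: from dB SPL at the eardrum to recorded microvolts is hardware- and
#: subject-specific and never needed in absolute terms; only relative levels
#: matter, so 110 dB SPL (the default presentation level) is the reference.
REF_LEVEL_DBSPL = 110.0

CONDENSATION = "condensation"
RAREFACTION = "rarefaction"
_POLARITIES = (CONDENSATION, RAREFACTION)


@dataclass(frozen=True)
class StimulusSpec:
    """Tone-burst stimulus parameters.

    Parameters
    ----------
    frequency_hz : float
        Carrier frequency of the burst.  Default 500 Hz, chosen clinically to
        probe the low-frequency (apical) region where residual hearing lives.
    duration_ms : float
        Burst duration.  Default 53 ms.
    level_dbspl : float
        Presentation level in dB SPL.  Default 110.
    polarity : str
        ``"condensation"`` or ``"rarefaction"``.  The two polarities are exact
        negations of each other; alternating them lets polarity-following
        (hair-cell) and polarity-invariant (neural/summating) components be
        separated by subtraction.
    """

    frequency_hz: float = 500.0
    duration_ms: float = 53.0
    level_dbspl: float = 110.0
    polarity: str = CONDENSATION

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("stimulus frequency must be positive")
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")

    @property
    def amplitude(self) -> float:
        """Linear waveform amplitude relative to the 110 dB SPL reference."""
        return float(10.0 ** ((self.level_dbspl - REF_LEVEL_DBSPL) / 20.0))

    def flipped(self) -> "StimulusSpec":
        """The same burst with the opposite polarity."""
        other = RAREFACTION if self.polarity == CONDENSATION else CONDENSATION
        return StimulusSpec(self.frequency_hz, self.duration_ms, self.level_dbspl, other)


def make_stimulus(spec: StimulusSpec, sample_rate_hz: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Synthesise the tone-burst waveform.

    Returns a pressure-proportional float array of ``floor(duration * fs)``
    samples.  Rarefaction is the exact elementwise negation of condensation.

    Raises
    ------
    ValueError
        If the carrier is at or above the Nyquist frequency.
    """
    if spec.frequency_hz >= sample_rate_hz / 2.0:
        raise ValueError(
            f"stimulus frequency {spec.frequency_hz} Hz is not below the Nyquist "
            f"frequency {sample_rate_hz / 2.0} Hz"
        )
    n = int(np.floor(spec.duration_ms / 1000.0 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    wave = spec.amplitude * np.sin(2.0 * np.pi * spec.frequency_hz * t)
    if spec.polarity == RAREFACTION:
        wave = -wave
    return wave
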