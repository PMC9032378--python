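"""Cochlear tonotopic place map: insertion angle -> characteristic frequency.

The recording contact's characteristic frequency (CF) is estimated in two
steps:

1. angular insertion depth -> fractional organ-of-Corti length from the
   base, by piecewise-linear interpolation through a control-point table
   shipped as editable CSV (``data/oc_angle_length.csv``).  Angles are
   measured from a 0 deg reference line through the middle of the round
   window and the centre of the modiolus.
2. fractional length -> CF via the Greenwood frequency-position function for
   the human organ of Corti, ``CF = A (10^(alpha (1 - x)) - k)`` with
   ``x`` the fraction from the base and defaults A = 165.4 Hz, alpha = 2.1,
   k = 0.88 (base ~20.7 kHz, apex ~20 Hz).

A drop in CM amplitude late in the insertion can be explained without trauma
when the contact reaches or passes the place tuned to the stimulus frequency:
``cf_passed`` flags ``cf_hz < stimulus frequency``.  In substantially
hearing-impaired cochleae the effective CF map can be shifted basal-ward;
``cf_scale`` exposes that as an optional multiplicative offset (default 1,
i.e. off).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

GREENWOOD_A_HZ = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88

_DEFAULT_TABLE: tuple[np.ndarray, np.ndarray] | None = None


@dataclass(frozen=True)
class InsertionGeometry:
    """Angular insertion depth of the recording contact.

    ``cochlea_scale`` is a relative size factor (1 = average cochlea); the
    effective angle is divided by it, so a small cochlea (< 1) reaches a
    given fractional length at a smaller measured angle.
    """

    angle_deg: float
    cochlea_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.angle_deg < 0:
            raise ValueError("insertion angle must be >= 0")
        if self.cochlea_scale <= 0:
            raise ValueError("cochlea_scale must be positive")


@dataclass(frozen=True)
class CfEstimate:
    """Estimated characteristic frequency at the recording contact."""

    cf_hz: float
    fractional_length_from_base: float
    cf_passed: bool


def _load_table(path=None) -> tuple[np.ndarray, np.ndarray]:
    global _DEFAULT_TABLE
    if path is None:
        if _DEFAULT_TABLE is None:
            with resources.files("ecochg.data").joinpath("oc_angle_length.csv").open() as fh:
                df = pd.read_csv(fh, comment="#")
            _DEFAULT_TABLE = (
                df["angle_deg"].to_numpy(float),
                df["percent_length"].to_numpy(float) / 100.0,
            )
        return _DEFAULT_TABLE
    df = pd.read_csv(Path(path), comment="#")
    return df["angle_deg"].to_numpy(float), df["percent_length"].to_numpy(float) / 100.0


def angle_to_fraction(angle_deg: float, table_path=None) -> float:
    """Fractional organ-of-Corti length from the base at a given angle.

    Strictly increasing over the table's angle range; 0 deg maps to 0.
    Angles beyond the table end (990 deg) are clamped with a warning;
    negative angles are rejected.
    """
    if angle_deg < 0:
        raise ValueError("insertion angle must be >= 0")
    angles, fractions = _load_table(table_path)
    if angle_deg > angles[-1]:
        warnings.warn(
            f"angle {angle_deg:.0f} deg beyond the control table; clamping to {angles[-1]:.0f}",
            stacklevel=2,
        )
        angle_deg = angles[-1]
    return float(np.interp(angle_deg, angles, fractions))


def fraction_to_cf(fraction: float) -> float:
    """Greenwood CF (Hz) at a fractional organ-of-Corti length from the base."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return float(
        GREENWOOD_A_HZ * (10.0 ** (GREENWOOD_ALPHA * (1.0 - fraction)) - GREENWOOD_K)
    )


def cf_to_fraction(cf_hz: float) -> float:
    """Inverse of :func:`fraction_to_cf`."""
    arg = cf_hz / GREENWOOD_A_HZ + GREENWOOD_K
    if arg <= 0:
        raise ValueError("CF out of the map's range")
    fraction = 1.0 - np.log10(arg) / GREENWOOD_ALPHA
    if not -1e-9 <= fraction <= 1.0 + 1e-9:
        raise ValueError("CF out of the map's range")
    return float(np.clip(fraction, 0.0, 1.0))


def estimate_cf(
    geometry: InsertionGeometry,
    stimulus_frequency_hz: float = 500.0,
    cf_scale: float = 1.0,
    table_path=None,
) -> CfEstimate:
    """Compose the two maps and flag whether the stimulus place was passed.

    ``cf_scale`` multiplies the Greenwood CF (a basal-ward shift for
    hearing-impaired cochleae would use a value > 1); default 1 leaves the
    normal-hearing map untouched.
    """
    fraction = angle_to_fraction(geometry.angle_deg / geometry.cochlea_scale, table_path)
    cf = fraction_to_cf(fraction) * cf_scale
    return CfEstimate(
        cf_hz=cf,
        fractional_length_from_base=fraction,
        cf_passed=bool(cf < stimulus_frequency_hz),
    )
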