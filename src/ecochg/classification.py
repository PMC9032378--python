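"""Classification of insertion traces by amplitude pattern and by drop/phase type.

Two complementary groupings of the cochlear-microphonic time course are
computed from an extracted :class:`~ecochg.extraction.InsertionTrace`:

Amplitude pattern
    *growth* — no amplitude drop beyond the threshold (default 5 dB) after
    the maximum; *fluctuating* — at least one larger drop but a measurable
    response at the end; *total_loss* — a response was measurable during
    insertion but not at the end; *no_response* — never measurable.

Response type (amplitude + phase)
    *Type I* — no drop > 5 dB; *Type II* — every drop > 5 dB comes with a
    concurrent phase shift (the recording electrode likely passed the
    response generator, so trauma is unlikely); *Type III* — at least one
    drop > 5 dB without a concurrent phase shift (trauma-suspicious).

A point counts as *detectable* when its SNR reaches ``detect_snr_db``
(default 12 dB, the same value as the averaging stopping rule).  For a
noise-only FFT bin the magnitude is a Rayleigh draw that exceeds the
mean-of-surrounding-bins floor estimate almost half the time, so the raw
SNR > 0 flag is a coin flip in silence; and because the stopping rule checks
the running SNR after every pair, even the 12 dB margin is crossed by pure
noise at a ~2% per-point rate (the reported SNR is maximised over up to 40
looks).  Trace-level decisions therefore require *runs*: a trace "has a
response" only when ``detect_run_points`` (default 3) consecutive points are
detectable (noise fakes that with probability ~1e-4 per trace), and it "ends
with a response" only when its last ``detect_run_points`` points all are.
Real responses clear both by orders of magnitude.

Phase is treated as missing below the detection margin and never
interpolated; isolated detectable points (not adjacent to another detectable
point) are also excluded from phase evaluation, since in silence they carry
uniform random phase.  A drop whose phase cannot be evaluated counts as
*without* a concurrent shift (the damage-suspicious reading dominates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import InsertionTrace

GROWTH = "growth"
FLUCTUATING = "fluctuating"
TOTAL_LOSS = "total_loss"
NO_RESPONSE = "no_response"

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"
UNCLASSIFIABLE = "unclassifiable"

#: Amplitude at a sub-detection point enters dB ratios clamped here.
_EPS_UV = 1e-12


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of both grouping schemes.

    drop_threshold_db
        A fall of more than this below the running maximum is a drop; also the
        growth/fluctuating boundary (5 dB, shared with the type scheme).
    phase_shift_threshold_deg
        Minimum absolute unwrapped phase change over a drop for it to count
        as concurrent.  The near-zero shifts of trauma-suspicious drops and
        the large (up to ~180 deg) shifts of generator-passing drops are far
        apart; 90 deg sits between them.
    detect_snr_db
        Detection margin for "response above the noise floor" (see module
        notes).
    detect_run_points
        Consecutive detectable points required for a trace-level response
        decision (see module notes).
    smoothing_points
        Width of the median filter applied to the dB amplitude series before
        drop detection (odd; 1 disables smoothing).
    recovery_db
        A drop ends once the smoothed amplitude has risen this much above its
        trough, allowing separate events to be emitted for separate dips.
    """

    drop_threshold_db: float = 5.0
    phase_shift_threshold_deg: float = 90.0
    detect_snr_db: float = 12.0
    detect_run_points: int = 3
    smoothing_points: int = 3
    recovery_db: float = 5.0

    def __post_init__(self) -> None:
        if self.drop_threshold_db <= 0:
            raise ValueError("drop_threshold_db must be positive")
        if self.phase_shift_threshold_deg < 0:
            raise ValueError("phase_shift_threshold_deg must be >= 0")
        if self.smoothing_points < 1 or self.smoothing_points % 2 == 0:
            raise ValueError("smoothing_points must be a positive odd integer")


@dataclass(frozen=True)
class AmplitudeFeatures:
    """The three clinical amplitude landmarks of one insertion trace.

    ``a_max_uv`` is the maximal CM amplitude during insertion, ``a_min_uv``
    the minimal amplitude *after* the maximum, and ``a_end_uv`` the final
    amplitude once insertion and coiling are finished.  Ratios are expressed
    in amplitude dB (20 log10).
    """

    a_max_uv: float
    t_max: float
    a_min_uv: float
    a_end_uv: float

    @property
    def min_over_max_db(self) -> float:
        return 20.0 * np.log10(max(self.a_min_uv, _EPS_UV) / self.a_max_uv)

    @property
    def end_over_max_db(self) -> float:
        return 20.0 * np.log10(max(self.a_end_uv, _EPS_UV) / self.a_max_uv)


@dataclass(frozen=True)
class DropEvent:
    """One amplitude drop: from the running maximum at ``t_start`` to the
    trough at ``t_trough``, ``depth_db`` deep (positive)."""

    t_start: float
    t_trough: float
    depth_db: float
    phase_change_deg: float | None = None  # None when phase was unmeasurable

    def __post_init__(self) -> None:
        if self.depth_db < 0:
            raise ValueError("depth_db must be >= 0")
        if self.phase_change_deg is not None and self.phase_change_deg < 0:
            raise ValueError("phase_change_deg must be >= 0")


def _detectable_mask(trace: InsertionTrace, detect_snr_db: float) -> np.ndarray:
    return trace.snrs_db >= detect_snr_db


def _run_mask(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True entries belonging to runs of at least ``min_run``."""
    if min_run <= 1 or len(mask) == 0:
        return mask
    out = np.zeros_like(mask)
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def has_response(trace: InsertionTrace, config: ClassificationConfig = ClassificationConfig()) -> bool:
    """True when the trace contains a sustained measurable response."""
    mask = _detectable_mask(trace, config.detect_snr_db)
    run = min(config.detect_run_points, len(mask))
    return bool(np.any(_run_mask(mask, run)))


def ends_with_response(
    trace: InsertionTrace, config: ClassificationConfig = ClassificationConfig()
) -> bool:
    """True when the final points of the trace are all detectable."""
    mask = _detectable_mask(trace, config.detect_snr_db)
    run = min(config.detect_run_points, len(mask))
    return bool(np.all(mask[-run:]))


def amplitude_features(
    trace: InsertionTrace, config: ClassificationConfig = ClassificationConfig()
) -> AmplitudeFeatures | None:
    """Compute (A_max, A_min-after-max, A_end); None for a no-response trace.

    Amplitudes of all points enter the landmarks (a sub-floor end point
    contributes its measured residual magnitude), but a trace with no
    sustained detectable response has no meaningful landmarks and yields
    ``None``.
    """
    if not has_response(trace, config):
        return None
    amps = trace.amplitudes_uv
    times = trace.times
    i_max = int(np.argmax(amps))
    after = amps[i_max:]
    return AmplitudeFeatures(
        a_max_uv=float(amps[i_max]),
        t_max=float(times[i_max]),
        a_min_uv=float(np.min(after)),
        a_end_uv=float(amps[-1]),
    )


def _median_smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(x) < width:
        return x
    half = width // 2
    padded = np.pad(x, half, mode="edge")
    return np.array([np.median(padded[i : i + width]) for i in range(len(x))])


def _smoothed_db(trace: InsertionTrace, config: ClassificationConfig) -> np.ndarray:
    amps = np.maximum(trace.amplitudes_uv, _EPS_UV)
    return _median_smooth(20.0 * np.log10(amps), config.smoothing_points)


def detect_drops(
    trace: InsertionTrace, config: ClassificationConfig = ClassificationConfig()
) -> list[DropEvent]:
    """Find amplitude drops on the smoothed dB series.

    A drop starts when the series falls more than ``drop_threshold_db`` below
    the running maximum since the last event; its trough is the minimum
    before the series recovers ``recovery_db`` above the trough (or the trace
    ends).  Detection runs on the smoothed series; the trough time and depth
    are then refined on the raw series inside the event (median smoothing
    flattens dip bottoms).  After an event the running maximum restarts from
    the recovery point, so events are non-overlapping and time-ordered.  The
    phase change over each event is attached (see :func:`phase_change_over`).
    """
    raw_db = 20.0 * np.log10(np.maximum(trace.amplitudes_uv, _EPS_UV))
    db = _smoothed_db(trace, config)
    times = trace.times
    events: list[DropEvent] = []
    run_max = db[0]
    run_max_t = times[0]
    i = 1
    n = len(db)
    while i < n:
        if db[i] > run_max:
            run_max = db[i]
            run_max_t = times[i]
            i += 1
            continue
        if run_max - db[i] > config.drop_threshold_db:
            # in a drop: scan for the trough, then for recovery
            trough_i = i
            j = i + 1
            while j < n:
                if db[j] < db[trough_i]:
                    trough_i = j
                if db[j] - db[trough_i] >= config.recovery_db:
                    break
                j += 1
            seg = slice(i, min(j + 1, n))
            trough_i = int(seg.start + np.argmin(raw_db[seg]))
            event = DropEvent(
                t_start=float(run_max_t),
                t_trough=float(times[trough_i]),
                depth_db=float(run_max - raw_db[trough_i]),
            )
            change = phase_change_over(trace, event, config)
            events.append(
                DropEvent(event.t_start, event.t_trough, event.depth_db, change)
            )
            i = min(j, n - 1)
            run_max = db[i]
            run_max_t = times[i]
            if j >= n:
                break
            i += 1
        else:
            i += 1
    return events


def phase_change_over(
    trace: InsertionTrace,
    event: DropEvent,
    config: ClassificationConfig = ClassificationConfig(),
) -> float | None:
    """Absolute net unwrapped phase change across a drop, in degrees.

    Phase is evaluated only at points above the detection margin inside
    ``[t_start, t_trough]`` (isolated detectable points are excluded — see
    module notes); the series is unwrapped (so +170 -> -170 is a 20 deg step,
    not 340) and the absolute start-to-end difference returned.  ``None``
    flags fewer than two usable points.
    """
    times = trace.times
    if event.t_start < times[0] or event.t_trough > times[-1]:
        raise ValueError("drop event lies outside the trace")
    usable = _run_mask(_detectable_mask(trace, config.detect_snr_db), 2)
    mask = (times >= event.t_start) & (times <= event.t_trough) & usable
    phases = trace.phases_deg[mask]
    if len(phases) < 2:
        return None
    unwrapped = np.unwrap(phases, period=360.0)
    return float(abs(unwrapped[-1] - unwrapped[0]))


def classify_pattern(
    features: AmplitudeFeatures | None,
    trace: InsertionTrace,
    config: ClassificationConfig = ClassificationConfig(),
) -> str:
    """Amplitude-pattern group of one trace.

    ``no_response`` if the trace never shows a sustained detectable
    response; ``total_loss`` if it does but its end is not detectable;
    ``growth`` if the worst post-maximum excursion stays within the drop
    threshold; ``fluctuating`` otherwise.
    """
    if not has_response(trace, config):
        return NO_RESPONSE
    if features is None:
        raise ValueError("features missing for a trace with a detectable response")
    if not ends_with_response(trace, config):
        return TOTAL_LOSS
    if features.min_over_max_db > -config.drop_threshold_db:
        return GROWTH
    return FLUCTUATING


def classify_type(
    trace: InsertionTrace, config: ClassificationConfig = ClassificationConfig()
) -> str:
    """Amplitude+phase response type of one trace.

    Type I when no drop exceeds the threshold; Type II when *every* detected
    drop comes with a concurrent phase shift; Type III when *any* drop lacks
    one (including drops whose phase could not be measured) — the
    damage-suspicious reading dominates.  ``unclassifiable`` for traces with
    no detectable response.
    """
    if not has_response(trace, config):
        return UNCLASSIFIABLE
    drops = detect_drops(trace, config)
    if not drops:
        return TYPE_I
    for event in drops:
        if event.phase_change_deg is None:
            return TYPE_III
        if event.phase_change_deg < config.phase_shift_threshold_deg:
            return TYPE_III
    return TYPE_II


def classify_trace(
    trace: InsertionTrace, config: ClassificationConfig = ClassificationConfig()
) -> dict:
    """All per-trace classification outputs as one flat record."""
    features = amplitude_features(trace, config)
    pattern = classify_pattern(features, trace, config)
    rtype = classify_type(trace, config)
    drops = detect_drops(trace, config) if pattern != NO_RESPONSE else []
    phase_changes = [d.phase_change_deg for d in drops if d.phase_change_deg is not None]
    return {
        "pattern_group": pattern,
        "response_type": rtype,
        "a_max_uv": features.a_max_uv if features else np.nan,
        "a_min_uv": features.a_min_uv if features else np.nan,
        "a_end_uv": features.a_end_uv if features else np.nan,
        "min_over_max_db": features.min_over_max_db if features else np.nan,
        "end_over_max_db": features.end_over_max_db if features else np.nan,
        "n_drops": len(drops),
        "max_drop_db": max((d.depth_db for d in drops), default=0.0),
        "max_phase_change_deg": max(phase_changes, default=np.nan),
    }
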