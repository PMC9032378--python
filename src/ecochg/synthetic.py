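"""Synthetic cohort generator for the monitoring pipeline.

No patient recordings are distributable, so every downstream stage is
exercised against seeded synthetic data with the statistical structure the
analysis assumes:

* latent cochlear-microphonic (CM) trajectories of the shapes seen clinically
  — *growth* (steadily rising amplitude), *fluctuating* (one or more drops
  with recovery, with or without concurrent phase shifts), *total loss*
  (response vanishes into the noise before the insertion ends) and
  *no response* (never measurable);
* raw alternating-polarity buffers built from those trajectories, with a
  polarity-invariant nuisance transient and calibrated white noise;
* pre/post pure-tone audiograms whose low-frequency hearing loss depends on
  the ground-truth response type;
* angular insertion depths drawn from the observed clinical distribution
  (mean 375 deg, SD 45 deg, truncated to [290, 500] deg).

Peak CM amplitudes default to the clinically observed ~5-200 uV range and
insertions last 90-120 s (arrays are advanced slowly over 1-2 minutes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import RawBuffer
from .outcomes import AUDIOGRAM_FREQS_HZ, LF_FREQS_HZ, Audiogram
from .stimulus import CONDENSATION, RAREFACTION, SAMPLE_RATE_HZ, StimulusSpec

GROWTH = "growth"
FLUCTUATING = "fluctuating"
TOTAL_LOSS = "total_loss"
NO_RESPONSE = "no_response"
ARCHETYPES = (GROWTH, FLUCTUATING, TOTAL_LOSS, NO_RESPONSE)

#: Buffer geometry: 512 samples (55.2 ms) contain the 53 ms burst; the
#: central 464 samples (exactly 50 ms -> 20 Hz bins) are analysed downstream.
BUFFER_SAMPLES = 512
WINDOW_OFFSET = 24  # start of the analysis window within a buffer
#: One buffer every 62.5 ms -> one alternating pair per 125 ms, i.e. at most
#: 8 monitoring points per second when a single pair suffices.
BUFFER_PERIOD_S = 0.0625
PAIR_PERIOD_S = 2 * BUFFER_PERIOD_S

#: Mean pre-operative thresholds (dB HL) at 125...4000 Hz: a gently sloping
#: severe low-frequency-preserved loss typical of electric-acoustic candidates.
PREOP_MEAN_DB = (40.0, 45.0, 50.0, 60.0, 65.0, 70.0, 75.0)
PREOP_SD_DB = 12.0
AUDIOMETER_FLOOR_DB = -10.0
AUDIOMETER_CEILING_DB = 130.0
#: Inclusion rule: measurable residual hearing, i.e. at least one threshold
#: at or below 80 dB HL.
INCLUSION_MAX_DB = 80.0


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth description of one insertion's latent CM trajectory.

    drop_events are ``(time_s, depth_db, phase_shift_deg)`` triples: at
    ``time_s`` the amplitude dips ``depth_db`` below its drop-free course and
    the phase, for a non-zero shift, ramps to the shifted value across the
    falling flank of the dip and holds thereafter.
    """

    archetype: str = GROWTH
    drop_events: tuple[tuple[float, float, float], ...] = ()
    peak_amplitude_uv: float = 50.0
    end_behavior: str = "above_floor"  # or "at_floor"
    insertion_duration_s: float = 100.0
    rise_db: float = 12.0  # amplitude growth from insertion start to peak
    t_peak_frac: float = 0.25  # non-growth courses peak here, then decline gently
    post_peak_decline_db: float = 2.0
    drop_width_s: float = 3.0  # Gaussian sigma*2 of a dip's dB profile
    jitter_db: float = 0.15

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"archetype must be one of {ARCHETYPES}")
        if not 0 < self.peak_amplitude_uv:
            raise ValueError("peak amplitude must be positive")
        if self.insertion_duration_s <= 0:
            raise ValueError("insertion duration must be positive")
        for t0, depth, _shift in self.drop_events:
            if depth < 0:
                raise ValueError("drop depths must be >= 0")
            if not 0.0 <= t0 <= self.insertion_duration_s:
                raise ValueError("drop time outside insertion duration")


@dataclass(frozen=True)
class LatentTrajectory:
    """Ground-truth amplitude/phase course, for parameter-recovery tests."""

    times: np.ndarray
    amplitude_uv: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.amplitude_uv) == len(self.phase_deg)):
            raise ValueError("times, amplitude and phase must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.amplitude_uv < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    ``type_hl_means`` are the mean post-operative low-frequency threshold
    shifts (dB) by ground-truth response type; ``hl_sd`` is the per-frequency
    SD of those shifts.
    """

    n_subjects: int = 45
    archetype_mix: dict = field(
        default_factory=lambda: {GROWTH: 11 / 40, FLUCTUATING: 25 / 40, TOTAL_LOSS: 4 / 40}
    )
    type_hl_means: dict = field(default_factory=lambda: {"I": 10.0, "II": 10.0, "III": 25.0})
    hl_sd: float = 8.0
    noise_floor_uv: float = 1.0
    seed: int = 0
    # plumbing defaults beyond the headline study conditions
    peak_amplitude_range_uv: tuple[float, float] = (30.0, 150.0)
    fluctuating_type2_prob: float = 0.5
    n_drops_range: tuple[int, int] = (1, 3)
    drop_depth_range_db: tuple[float, float] = (8.0, 20.0)
    type2_shift_range_deg: tuple[float, float] = (135.0, 215.0)
    type3_shift_range_deg: tuple[float, float] = (0.0, 15.0)
    insertion_duration_range_s: tuple[float, float] = (90.0, 120.0)
    angle_mean_deg: float = 375.0
    angle_sd_deg: float = 45.0
    angle_range_deg: tuple[float, float] = (290.0, 500.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("archetype_mix proportions must sum to 1")
        for key in self.archetype_mix:
            if key not in ARCHETYPES:
                raise ValueError(f"unknown archetype {key!r}")
        if self.hl_sd <= 0:
            raise ValueError("hl_sd must be positive")
        if self.noise_floor_uv < 0:
            raise ValueError("noise floor must be non-negative")


@dataclass
class SubjectRecord:
    """One synthetic subject: trajectory spec, audiograms, angle and truth.

    Raw buffers are not stored — they are regenerated deterministically from
    ``buffer_seed`` on demand, which keeps large cohorts cheap to hold.
    """

    subject_id: str
    archetype: str
    true_type: str  # ground-truth response type: I, II, III or unclassifiable
    trajectory_spec: TrajectorySpec
    trajectory_seed: int
    buffer_seed: int
    insertion_angle_deg: float
    audiogram_pre: Audiogram
    audiogram_post: Audiogram
    noise_floor_uv: float
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def latent_trajectory(self) -> LatentTrajectory:
        return make_latent_trajectory(
            self.trajectory_spec, self.trajectory_seed, noise_floor_uv=self.noise_floor_uv
        )

    def buffers(self) -> list[RawBuffer]:
        return synthesize_buffers(
            self.latent_trajectory(), self.stimulus, self.noise_floor_uv, self.buffer_seed
        )


def make_latent_trajectory(
    spec: TrajectorySpec, seed: int, noise_floor_uv: float = 1.0, dt_s: float = PAIR_PERIOD_S
) -> LatentTrajectory:
    """Build the ground-truth amplitude/phase course for one insertion.

    The amplitude course is constructed in dB: a linear rise of ``rise_db``
    toward the peak, Gaussian-profile dips of the requested depths at the
    requested times (amplitude at the dip centre is exactly
    ``drop-free level * 10**(-depth/20)``), and, for ``total_loss``, a
    terminal decay to 26 dB below the noise floor.  Growth trajectories are
    forced monotone non-decreasing by a running maximum after sub-dB jitter.
    Phase is constant except across drop events with a non-zero requested
    shift, where it ramps linearly over the falling flank of the dip (from
    one ``drop_width_s`` before the dip centre to the centre) and holds the
    shifted value afterwards.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, spec.insertion_duration_s + dt_s / 2, dt_s)
    peak_db = 20.0 * np.log10(spec.peak_amplitude_uv)
    floor_db = 20.0 * np.log10(max(noise_floor_uv, 1e-12))

    if spec.archetype == NO_RESPONSE:
        amp_db = np.full_like(times, floor_db - 26.0)
        phase = np.zeros_like(times)
        return LatentTrajectory(times, 10.0 ** (amp_db / 20.0), phase)

    jitter = rng.normal(0.0, spec.jitter_db, len(times)).clip(-0.45, 0.45)
    if spec.archetype == GROWTH:
        # steady approach to the generator: monotone rise to the end
        ramp = np.linspace(peak_db - spec.rise_db, peak_db, len(times))
        amp_db = np.maximum.accumulate(ramp + jitter)
    else:
        # closest approach at t_peak_frac, then a gentle decline as the
        # contact moves past the generator; drops are superimposed on this
        t_peak = spec.t_peak_frac * spec.insertion_duration_s
        ramp = np.interp(
            times,
            [0.0, t_peak, spec.insertion_duration_s],
            [peak_db - spec.rise_db, peak_db, peak_db - spec.post_peak_decline_db],
        )
        amp_db = ramp + jitter

    phase = np.zeros_like(times)
    sigma = spec.drop_width_s / 2.0
    for t0, depth, shift in spec.drop_events:
        amp_db = amp_db - depth * np.exp(-0.5 * ((times - t0) / sigma) ** 2)
        if shift != 0.0:
            # the shift develops on the falling flank and is complete before
            # the trough, where deep dips may fall below the detection margin
            ramp_start = t0 - spec.drop_width_s
            ramp_end = t0 - spec.drop_width_s / 3.0
            frac = np.clip((times - ramp_start) / (ramp_end - ramp_start), 0.0, 1.0)
            phase = phase + shift * frac

    if spec.archetype == TOTAL_LOSS or spec.end_behavior == "at_floor":
        t_fall = 0.72 * spec.insertion_duration_s
        t_dead = 0.90 * spec.insertion_duration_s
        target_db = floor_db - 26.0
        decay = np.clip((times - t_fall) / (t_dead - t_fall), 0.0, 1.0)
        amp_db = np.minimum(amp_db, amp_db * (1 - decay) + target_db * decay)

    return LatentTrajectory(times, 10.0 ** (amp_db / 20.0), phase)


def noise_sigma_for_floor(noise_floor_uv: float, window_samples: int = 464) -> float:
    """Per-sample white-noise SD giving a single-pair spectral floor of ``noise_floor_uv``.

    After subtracting two independent buffers and halving, the per-sample
    noise SD is ``sigma/sqrt(2)``; the amplitude-normalised FFT magnitude of
    white noise at one bin is Rayleigh with mean ``sigma_d*sqrt(pi/N)``, so
    the mean of the surrounding-bin floor estimate equals ``noise_floor_uv``
    when ``sigma = noise_floor_uv * sqrt(2N/pi)``.
    """
    return noise_floor_uv * np.sqrt(2.0 * window_samples / np.pi)


def synthesize_buffers(
    traj: LatentTrajectory,
    spec: StimulusSpec,
    noise_floor_uv: float,
    seed: int,
    nuisance_scale: float = 0.2,
    sample_rate_hz: float = SAMPLE_RATE_HZ,
) -> list[RawBuffer]:
    """Render a latent trajectory into alternating-polarity raw buffers.

    Each buffer is the sum of

    * the CM component — a sinusoid at the stimulus frequency whose amplitude
      and phase are interpolated from the trajectory at the pair's emission
      time, and whose sign flips with polarity.  Its phase convention matches
      extraction: a zero-phase trajectory gives a cosine starting at the
      analysis-window start (sample 24);
    * a polarity-invariant nuisance component — a damped 1 kHz onset burst at
      ``nuisance_scale`` of the local CM amplitude, emulating neural and
      summating contributions (identical for both buffers of a pair, so
      polarity subtraction cancels it exactly);
    * white Gaussian noise calibrated so the single-pair extracted noise
      floor averages ``noise_floor_uv``.

    Condensation leads each pair; pairs are emitted every 125 ms until the
    trajectory ends.
    """
    rng = np.random.default_rng(seed)
    n = BUFFER_SAMPLES
    t_in_buf = np.arange(n) / sample_rate_hz
    omega = 2.0 * np.pi * spec.frequency_hz
    cm_carrier_phase = omega * (np.arange(n) - WINDOW_OFFSET) / sample_rate_hz
    nuisance_shape = np.exp(-t_in_buf / 0.005) * np.sin(2.0 * np.pi * 1000.0 * t_in_buf)
    sigma = noise_sigma_for_floor(noise_floor_uv) if noise_floor_uv > 0 else 0.0

    t_end = traj.times[-1]
    buffers: list[RawBuffer] = []
    t_pair = 0.0
    while t_pair <= t_end:
        amp = float(np.interp(t_pair, traj.times, traj.amplitude_uv))
        phase = float(np.interp(t_pair, traj.times, traj.phase_deg))
        cm = amp * np.cos(cm_carrier_phase + np.radians(phase))
        nuisance = nuisance_scale * amp * nuisance_shape
        for k, polarity in enumerate((CONDENSATION, RAREFACTION)):
            signal = cm if polarity == CONDENSATION else -cm
            noise = rng.normal(0.0, sigma, n) if sigma > 0 else 0.0
            buffers.append(
                RawBuffer(
                    samples=signal + nuisance + noise,
                    polarity=polarity,
                    t_acquired=t_pair + k * BUFFER_PERIOD_S,
                )
            )
        t_pair += PAIR_PERIOD_S
    return buffers


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_audiogram_pair(
    response_type: str, config: CohortConfig, seed: int
) -> tuple[Audiogram, Audiogram]:
    """Draw a (pre-operative, 4-week post-operative) audiogram pair.

    Pre-operative thresholds are drawn per frequency from
    ``N(PREOP_MEAN_DB, PREOP_SD_DB)`` clipped to the audiometer range and
    redrawn until the inclusion rule (at least one threshold <= 80 dB HL)
    holds.  Post-operative thresholds add ``N(type_hl_means[type], hl_sd)``
    independently at each low frequency (125-1500 Hz) and ``N(0, hl_sd)`` at
    2 and 4 kHz, clipped to the audiometer ceiling.  ``unclassifiable``
    (no-response) subjects, which the clinical analysis excludes, use the
    mean of the three type means.
    """
    valid = set(config.type_hl_means) | {"unclassifiable"}
    if response_type not in valid:
        raise ValueError(f"response_type must be one of {sorted(valid)}")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        pre = rng.normal(PREOP_MEAN_DB, PREOP_SD_DB).clip(
            AUDIOMETER_FLOOR_DB, AUDIOMETER_CEILING_DB
        )
        if np.min(pre) <= INCLUSION_MAX_DB:
            break
    else:  # pragma: no cover - practically unreachable under the defaults
        raise RuntimeError("could not draw an audiogram satisfying the inclusion rule")
    if response_type == "unclassifiable":
        mean_shift = float(np.mean(list(config.type_hl_means.values())))
    else:
        mean_shift = float(config.type_hl_means[response_type])
    shifts = np.where(
        np.isin(AUDIOGRAM_FREQS_HZ, LF_FREQS_HZ),
        rng.normal(mean_shift, config.hl_sd, len(AUDIOGRAM_FREQS_HZ)),
        rng.normal(0.0, config.hl_sd, len(AUDIOGRAM_FREQS_HZ)),
    )
    post = (pre + shifts).clip(AUDIOMETER_FLOOR_DB, AUDIOMETER_CEILING_DB)
    return (
        Audiogram(thresholds_db=tuple(pre), timepoint="pre"),
        Audiogram(thresholds_db=tuple(post), timepoint="post4w"),
    )


def _largest_remainder_counts(n: int, mix: dict) -> dict:
    """Apportion ``n`` subjects to archetypes by the largest-remainder rule."""
    keys = list(mix)
    quotas = np.array([n * mix[k] for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _make_trajectory_spec(archetype: str, config: CohortConfig, rng: np.random.Generator):
    """Draw one subject's trajectory spec; returns (spec, ground-truth type)."""
    duration = float(rng.uniform(*config.insertion_duration_range_s))
    peak = float(
        np.exp(rng.uniform(*np.log(config.peak_amplitude_range_uv)))
    )  # log-uniform over the observed amplitude range
    drops: tuple[tuple[float, float, float], ...] = ()
    true_type = {GROWTH: "I", TOTAL_LOSS: "III", NO_RESPONSE: "unclassifiable"}.get(archetype, "")
    if archetype == FLUCTUATING:
        shifted = rng.random() < config.fluctuating_type2_prob
        true_type = "II" if shifted else "III"
        n_drops = int(rng.integers(config.n_drops_range[0], config.n_drops_range[1] + 1))
        # dips must start clear of the course's peak (at 25% of the insertion)
        # so the peak itself is not swallowed by a dip's flank
        width = TrajectorySpec().drop_width_s
        lo = max(0.35 * duration, 0.25 * duration + 2.0 * width + 1.0)
        hi = max(0.80 * duration, lo + 1.0)
        t_drops = np.sort(rng.uniform(lo, hi, n_drops))
        # keep dips separated so each is an individually recoverable event
        for _ in range(200):
            if n_drops == 1 or np.all(np.diff(t_drops) > 10.0):
                break
            t_drops = np.sort(rng.uniform(lo, hi, n_drops))
        shift_range = config.type2_shift_range_deg if shifted else config.type3_shift_range_deg
        drops = tuple(
            (
                float(t0),
                float(rng.uniform(*config.drop_depth_range_db)),
                float(rng.uniform(*shift_range)) * (1 if shifted else rng.choice([-1, 1])),
            )
            for t0 in t_drops
        )
    spec = TrajectorySpec(
        archetype=archetype,
        drop_events=drops,
        peak_amplitude_uv=peak,
        end_behavior="at_floor" if archetype in (TOTAL_LOSS, NO_RESPONSE) else "above_floor",
        insertion_duration_s=duration,
    )
    return spec, true_type


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a full synthetic cohort, a pure function of the config.

    Archetype counts follow ``archetype_mix`` by largest remainder; insertion
    angles are truncated-normal over the observed clinical range; audiograms
    are tied to the ground-truth response type.
    """
    rng = np.random.default_rng(config.seed)
    counts = _largest_remainder_counts(config.n_subjects, config.archetype_mix)
    archetypes = [a for a, c in counts.items() for _ in range(c)]
    rng.shuffle(archetypes)
    angles = np.atleast_1d(
        _truncated_normal(
            rng,
            config.angle_mean_deg,
            config.angle_sd_deg,
            config.angle_range_deg[0],
            config.angle_range_deg[1],
            size=config.n_subjects,
        )
    )
    records = []
    for i, archetype in enumerate(archetypes):
        spec, true_type = _make_trajectory_spec(archetype, config, rng)
        traj_seed = int(rng.integers(0, 2**31 - 1))
        buf_seed = int(rng.integers(0, 2**31 - 1))
        audio_seed = int(rng.integers(0, 2**31 - 1))
        pre, post = make_audiogram_pair(true_type, config, audio_seed)
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                archetype=archetype,
                true_type=true_type,
                trajectory_spec=spec,
                trajectory_seed=traj_seed,
                buffer_seed=buf_seed,
                insertion_angle_deg=float(angles[i]),
                audiogram_pre=pre,
                audiogram_post=post,
                noise_floor_uv=config.noise_floor_uv,
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort persistence


def write_cohort(records: Sequence[SubjectRecord], out_dir) -> None:
    """Persist a cohort: per-subject buffer CSVs, audiogram CSV, truth JSON."""
    from .extraction import write_buffers_csv

    out = Path(out_dir)
    (out / "buffers").mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for rec in records:
        write_buffers_csv(rec.buffers(), out / "buffers" / f"{rec.subject_id}.csv")
        for audio in (rec.audiogram_pre, rec.audiogram_post):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "timepoint": audio.timepoint,
                    **{f"f{int(f)}": thr for f, thr in zip(AUDIOGRAM_FREQS_HZ, audio.thresholds_db)},
                }
            )
        truth[rec.subject_id] = {
            "archetype": rec.archetype,
            "true_type": rec.true_type,
            "insertion_angle_deg": rec.insertion_angle_deg,
            "peak_amplitude_uv": rec.trajectory_spec.peak_amplitude_uv,
            "noise_floor_uv": rec.noise_floor_uv,
        }
    pd.DataFrame(rows).to_csv(out / "audiograms.csv", index=False, float_format="%.3f")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_audiograms_csv(path) -> dict[str, dict[str, Audiogram]]:
    """Load the cohort audiogram CSV as {subject_id: {timepoint: Audiogram}}."""
    df = pd.read_csv(path)
    cols = [f"f{int(f)}" for f in AUDIOGRAM_FREQS_HZ]
    result: dict[str, dict[str, Audiogram]] = {}
    for _, row in df.iterrows():
        audio = Audiogram(
            thresholds_db=tuple(float(row[c]) for c in cols), timepoint=str(row["timepoint"])
        )
        result.setdefault(str(row["subject_id"]), {})[audio.timepoint] = audio
    return result
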