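# ecochg

Intraoperative electrocochleography (ECochG) monitoring for cochlear-implant
surgery: extraction of cochlear-microphonic amplitude and phase from raw
alternating-polarity recordings, classification of insertion traces,
angle-to-characteristic-frequency mapping, and hearing-preservation
statistics — together with a seeded synthetic cohort generator so the whole
pipeline is testable without patient data.

## The problem

During cochlear-implant electrode insertion, residual low-frequency acoustic
hearing is at risk.  ECochG recorded through the implant itself provides
real-time feedback: a low-frequency tone burst (500 Hz, ~110 dB SPL) evokes
the cochlear microphonic (CM), an AC hair-cell potential that follows the
stimulus waveform.  A falling CM can signal impending trauma — but it can
also simply mean the recording contact has passed the place tuned to the
stimulus, in which case the response *phase* shifts strongly while no damage
occurs.  Considering amplitude and phase together separates the two.

## Method

**Extraction.**  Buffers are recorded at 9,280 Hz to alternating
condensation/rarefaction stimuli.  The CM inverts with polarity while neural
and summating components do not, so one pair gives a CM epoch
`(condensation − rarefaction) / 2`.  Pairs are averaged until the spectral
SNR reaches 12 dB or 40 pairs are spent; with strong responses this yields
up to 8 monitoring points per second.  The central 464 samples (exactly
50 ms → 20 Hz bins; 500 Hz sits on bin 25) are Fourier transformed; response
amplitude and phase are read off the stimulus bin and the noise floor is the
mean magnitude of 3 bins on each side (1 guard bin).

**Classification.**  From each trace, the landmarks
`A_max` (maximal CM amplitude), `A_min` (minimum after the maximum) and
`A_end` (final amplitude) define the amplitude pattern —
*growth* / *fluctuating* / *total loss* / *no response* — and a drop
detector (falls > 5 dB below the running maximum on a median-smoothed dB
series) plus unwrapped phase changes across each drop define the response
type:

* **Type I** — no drop > 5 dB;
* **Type II** — every drop comes with a concurrent phase shift (≥ 90° by
  default): the contact likely passed the generator, trauma unlikely;
* **Type III** — at least one drop without a phase shift: trauma-suspicious.

**Tonotopy.**  Angular insertion depth (degrees past the round window) is
mapped through an editable control-point table to fractional organ-of-Corti
length and then through the Greenwood function
`CF = 165.4 (10^{2.1 (1 − x)} − 0.88)` Hz to the contact's characteristic
frequency, flagging whether the 500 Hz place was reached.

**Outcomes.**  The endpoint is low-frequency pure-tone-average hearing loss
(LF PTA HL): the mean threshold increase over 125 Hz–1.5 kHz from before
surgery to ~4 weeks after.  Groups are compared with Kruskal–Wallis plus
Dunn/Holm post-hoc tests, baselines with Welch t-tests, and amplitude
features with Pearson correlations — exposed statsmodels-style via
`CohortOutcomeModel.from_dataframe(...).fit()` → `OutcomeResults.summary()`.

## Worked example

```python
from ecochg import RunConfig, run_pipeline, CohortConfig

config = RunConfig(
    cohort=CohortConfig(n_subjects=20, insertion_duration_range_s=(30.0, 45.0), seed=42),
    seed=42,
)
run_pipeline(config, "demo/")
print(open("demo/report.txt").read())
```

This simulates 20 insertions (raw buffers, audiograms, angles), extracts and
classifies every trace, and prints:

```
Cohort hearing-preservation analysis
======================================
subjects: 20 total, 20 with measurable CM

LF PTA HL by pattern group (fluctuating: n=12, total_loss: n=2, growth: n=6)
  Kruskal-Wallis + Dunn (holm): H = 3.600, omnibus p = 0.1653
    fluctuating vs total_loss: p = 0.1798
    fluctuating vs growth: p = 0.8658
    total_loss vs growth: p = 0.1954

LF PTA HL by response type (II: n=10, III: n=4, I: n=6)
  Kruskal-Wallis + Dunn (holm): H = 9.760, omnibus p = 0.007597
    II vs III: p = 0.005532 *
    II vs I: p = 0.4321
    III vs I: p = 0.05205
...
LF PTA HL per group (dB):
    I: mean 11.5, median 10.9, n = 6
    II: mean 9.6, median 9.7, n = 10
    III: mean 28.4, median 27.3, n = 4
```

The amplitude-only grouping does not separate outcomes (omnibus p = 0.17),
while the amplitude+phase typing does: the trauma-suspicious Type III group
carries the large losses (~28 dB vs ~10 dB) and its pairwise comparisons
reach significance — the pattern the monitoring approach is built on.  The
generator seeded those group differences; the pipeline recovered them from
raw buffers.

The same stages are available from the shell:

```bash
ecochg run --config run.yaml --out results/
ecochg simulate --out cohort/ --seed 1     # or extract / classify / analyze
ecochg cf --angle 375
# angle 375 deg -> CF 779 Hz (64.4% of organ-of-Corti length); cf_passed=False
```

## Layout

```
src/ecochg/
  stimulus.py        tone-burst spec and waveform
  synthetic.py       seeded cohort generator (trajectories, buffers, audiograms)
  extraction.py      polarity subtraction, FFT, noise floor, SNR stopping rule
  classification.py  amplitude patterns and Type I/II/III
  placemap.py        angle -> organ-of-Corti fraction -> Greenwood CF
  outcomes.py        LF PTA HL, Kruskal-Wallis/Dunn, Welch t, Pearson; CohortOutcomeModel
  pipeline.py, cli.py  orchestration and the `ecochg` command
docs/methods.md      model assumptions, parameter choices, limitations
```
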