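"""Hearing-preservation outcomes and cohort statistics.

Audiometric outcome is the change in pure-tone thresholds from before surgery
to the first fitting about four weeks after.  The primary endpoint is the
low-frequency pure-tone-average hearing loss (LF PTA HL): the mean threshold
increase over 125 Hz - 1.5 kHz, the region where residual acoustic hearing is
clinically useful.

Group-level analysis follows standard non-parametric practice for small
clinical cohorts: a Kruskal-Wallis rank-sum omnibus across trace groups,
Dunn's pairwise post-hoc z-tests with Holm adjustment, unpaired (Welch)
t-tests for two-group baseline checks, and Pearson correlations between
intra-operative amplitude features and outcome.

The cohort-level fit is exposed statsmodels-style: build a
:class:`CohortOutcomeModel` from a per-subject dataframe, call ``fit()`` and
inspect the returned :class:`OutcomeResults` (or its ``summary()`` table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: The seven audiometric frequencies measured under headphones.
AUDIOGRAM_FREQS_HZ = (125.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0, 4000.0)
#: Frequencies entering the low-frequency pure-tone average (<= 1.5 kHz).
LF_FREQS_HZ = (125.0, 250.0, 500.0, 1000.0, 1500.0)

TIMEPOINTS = ("pre", "post4w")


@dataclass(frozen=True)
class Audiogram:
    """Pure-tone thresholds (dB HL) at the seven measured frequencies.

    Missing thresholds are carried as NaN and never imputed; operations that
    skip them warn.
    """

    thresholds_db: tuple
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        if len(self.thresholds_db) != len(AUDIOGRAM_FREQS_HZ):
            raise ValueError(f"expected {len(AUDIOGRAM_FREQS_HZ)} thresholds")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        arr = np.asarray(self.thresholds_db, dtype=float)
        finite = arr[np.isfinite(arr)]
        if np.any((finite < -10.0) | (finite > 130.0)):
            raise ValueError("thresholds must lie within [-10, 130] dB HL")

    @classmethod
    def from_mapping(cls, thresholds: dict, timepoint: str = "pre") -> "Audiogram":
        """Build from a {frequency_hz: dB HL} mapping in any key order."""
        missing = set(AUDIOGRAM_FREQS_HZ) - {float(f) for f in thresholds}
        if missing:
            raise ValueError(f"missing frequencies: {sorted(missing)}")
        ordered = tuple(float(thresholds[f]) for f in AUDIOGRAM_FREQS_HZ)
        return cls(thresholds_db=ordered, timepoint=timepoint)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.thresholds_db, dtype=float)

    def lf_pta(self) -> float:
        """Mean threshold over the low frequencies (dB HL), skipping NaN."""
        arr = self.as_array()[: len(LF_FREQS_HZ)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(arr))


@dataclass(frozen=True)
class HearingLossResult:
    """Threshold change post - pre (positive = loss), per frequency and LF PTA."""

    per_frequency_hl: tuple
    lf_pta_hl: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.per_frequency_hl, index=[int(f) for f in AUDIOGRAM_FREQS_HZ])


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + pairwise group test results."""

    group_labels: tuple
    group_ns: tuple
    statistic: float
    omnibus_p: float
    pairwise_p: pd.DataFrame
    method_name: str


@dataclass(frozen=True)
class CorrelationResult:
    var1_name: str
    var2_name: str
    r: float
    p: float
    n: int


def hearing_loss(pre: Audiogram, post: Audiogram) -> HearingLossResult:
    """Per-frequency and LF-PTA threshold change from pre-op to 4 weeks post.

    Positive values are losses; a post-operative improvement at a frequency
    yields a negative value and is kept as is.  Frequencies flagged missing
    (NaN) in either audiogram are skipped from the LF average with a warning.
    """
    if pre.timepoint != "pre" or post.timepoint != "post4w":
        raise ValueError("expected a (pre, post4w) audiogram pair")
    diff = post.as_array() - pre.as_array()
    lf = diff[: len(LF_FREQS_HZ)]
    missing = ~np.isfinite(lf)
    if missing.all():
        raise ValueError("no low-frequency thresholds available")
    if missing.any():
        skipped = [int(f) for f, m in zip(LF_FREQS_HZ, missing) if m]
        warnings.warn(f"skipping missing low frequencies {skipped} in LF PTA", stacklevel=2)
    return HearingLossResult(
        per_frequency_hl=tuple(diff), lf_pta_hl=float(np.mean(lf[~missing]))
    )


def _group_arrays(values: Sequence[float], labels: Sequence) -> dict:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    groups: dict = {}
    for lab in pd.unique(labels[keep]):
        groups[lab] = values[keep & (labels == lab)]
    return groups


def dunn_posthoc(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after a Kruskal-Wallis omnibus.

    For groups i, j with mean ranks ``Ri, Rj`` over the pooled sample of size
    N, ``z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj))`` with the tie
    term ``T = sum(t^3 - t) / (12 (N - 1))``.  Two-sided p values are
    adjusted with the chosen method (Holm by default) and returned as a
    symmetric matrix with 1.0 on the diagonal.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    raw = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = abs(mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw.append(2.0 * stats.norm.sf(z))
    if raw:
        adjusted = multipletests(raw, method=adjust)[1]
    else:
        adjusted = []
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (a, b), p in zip(pairs, adjusted):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def compare_groups(
    values: Sequence[float],
    labels: Sequence,
    posthoc_adjust: str = "holm",
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn/Holm pairwise comparisons.

    Groups with fewer than 2 members are reported in the counts but excluded
    from the omnibus and post-hoc tests with a warning.  If all pooled values
    are identical the omnibus is the degenerate H = 0, p = 1.
    """
    groups = _group_arrays(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        warnings.warn(f"groups {small} have n < 2 and are excluded from testing", stacklevel=2)
    tested = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(tested) < 2:
        raise ValueError("need at least two groups with n >= 2")
    pooled = np.concatenate(list(tested.values()))
    if np.ptp(pooled) == 0:
        statistic, omnibus_p = 0.0, 1.0
        pairwise = pd.DataFrame(
            np.ones((len(tested), len(tested))), index=list(tested), columns=list(tested)
        )
    else:
        statistic, omnibus_p = stats.kruskal(*tested.values())
        pairwise = dunn_posthoc(tested, adjust=posthoc_adjust)
    return GroupComparison(
        group_labels=tuple(groups),
        group_ns=tuple(len(groups[g]) for g in groups),
        statistic=float(statistic),
        omnibus_p=float(omnibus_p),
        pairwise_p=pairwise,
        method_name=f"Kruskal-Wallis + Dunn ({posthoc_adjust})",
    )


def compare_two(
    values: Sequence[float], labels: Sequence, equal_var: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test between exactly two groups (Welch by default).

    With ``equal_var=True`` the pooled-variance Student form is used.  If both
    groups have zero variance the test is degenerate: returns ``(0.0, 1.0)``
    for equal means and ``(inf, 0.0)`` otherwise.
    """
    groups = _group_arrays(values, labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    a, b = groups.values()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def correlate(
    x: Sequence[float], y: Sequence[float], var1_name: str = "x", var2_name: str = "y"
) -> CorrelationResult:
    """Pearson correlation with two-sided p; NaN pairs dropped listwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(len(x) - keep.sum())
    if dropped:
        warnings.warn(f"dropped {dropped} pairs with missing values", stacklevel=2)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(var1_name, var2_name, float(r), float(p), int(len(x)))


# ---------------------------------------------------------------------------
# cohort-level model


@dataclass
class OutcomeResults:
    """Fitted cohort outcome analysis.

    Attributes mirror the clinical report: group comparisons of LF PTA HL by
    amplitude-pattern group and by amplitude+phase response type, baseline
    pre-operative comparisons across types, and the standard correlations
    between intra-operative amplitude features and outcome.
    """

    n_subjects: int
    n_analyzed: int
    by_pattern: GroupComparison | None
    by_type: GroupComparison | None
    baseline_type_t: dict
    correlations: list[CorrelationResult]
    group_hl: pd.DataFrame
    alpha: float = 0.05

    def to_dict(self) -> dict:
        def comp(c: GroupComparison | None):
            if c is None:
                return None
            return {
                "groups": {g: int(n) for g, n in zip(c.group_labels, c.group_ns)},
                "statistic": c.statistic,
                "omnibus_p": c.omnibus_p,
                "pairwise_p": {
                    f"{a} vs {b}": float(c.pairwise_p.loc[a, b])
                    for i, a in enumerate(c.pairwise_p.index)
                    for b in c.pairwise_p.columns[i + 1 :]
                },
                "method": c.method_name,
            }

        return {
            "n_subjects": self.n_subjects,
            "n_analyzed": self.n_analyzed,
            "lf_hl_by_pattern": comp(self.by_pattern),
            "lf_hl_by_type": comp(self.by_type),
            "baseline_preop_t_tests": self.baseline_type_t,
            "correlations": [
                {"var1": c.var1_name, "var2": c.var2_name, "r": c.r, "p": c.p, "n": c.n}
                for c in self.correlations
            ],
            "group_hl_summary": self.group_hl.reset_index().to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = ["Cohort hearing-preservation analysis", "=" * 38]
        lines.append(f"subjects: {self.n_subjects} total, {self.n_analyzed} with measurable CM")
        for name, comp in (("pattern group", self.by_pattern), ("response type", self.by_type)):
            if comp is None:
                continue
            sizes = ", ".join(f"{g}: n={n}" for g, n in zip(comp.group_labels, comp.group_ns))
            lines.append("")
            lines.append(f"LF PTA HL by {name} ({sizes})")
            lines.append(
                f"  {comp.method_name}: H = {comp.statistic:.3f}, omnibus p = {comp.omnibus_p:.4g}"
            )
            for i, a in enumerate(comp.pairwise_p.index):
                for b in comp.pairwise_p.columns[i + 1 :]:
                    p = comp.pairwise_p.loc[a, b]
                    mark = " *" if p < self.alpha else ""
                    lines.append(f"    {a} vs {b}: p = {p:.4g}{mark}")
        if self.baseline_type_t:
            lines.append("")
            lines.append("Baseline (pre-op LF PTA) across types, Welch t:")
            for pair, res in self.baseline_type_t.items():
                lines.append(f"    {pair}: t = {res['t']:.3f}, p = {res['p']:.4g}")
        if self.correlations:
            lines.append("")
            lines.append("Correlations (Pearson):")
            for c in self.correlations:
                lines.append(
                    f"    {c.var1_name} vs {c.var2_name}: r = {c.r:.3f}, p = {c.p:.4g} (n = {c.n})"
                )
        if len(self.group_hl):
            lines.append("")
            lines.append("LF PTA HL per group (dB):")
            for idx, row in self.group_hl.iterrows():
                lines.append(
                    f"    {idx}: mean {row['mean']:.1f}, median {row['median']:.1f}, n = {int(row['n'])}"
                )
        return "\n".join(lines)


class CohortOutcomeModel:
    """Outcome model over a per-subject cohort table.

    The table needs a ``lf_hl`` column (LF PTA hearing loss, dB) plus any of
    the grouping/feature columns ``pattern_group``, ``response_type``,
    ``a_max_uv``, ``a_min_uv``, ``a_end_uv``, ``preop_500_db``,
    ``preop_lf_pta_db`` and optionally ``speech_score``.  Subjects whose
    response type is ``unclassifiable`` (no measurable CM) are excluded from
    the fit, mirroring clinical practice.
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05, ratio_in_db: bool = False):
        if "lf_hl" not in data.columns:
            raise ValueError("cohort table must contain an 'lf_hl' column")
        self.data = data.copy()
        self.alpha = alpha
        self.ratio_in_db = ratio_in_db

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CohortOutcomeModel":
        return cls(data, **kwargs)

    def _ratio(self, num: pd.Series, den: pd.Series) -> pd.Series:
        ratio = num / den
        if self.ratio_in_db:
            return 20.0 * np.log10(ratio)
        return ratio

    def fit(self) -> OutcomeResults:
        df = self.data
        analyzed = df
        if "response_type" in df.columns:
            analyzed = df[df["response_type"] != "unclassifiable"]
        if "pattern_group" in df.columns:
            analyzed = analyzed[analyzed["pattern_group"] != "no_response"]

        def comparison(col: str) -> GroupComparison | None:
            if col not in analyzed.columns:
                return None
            sub = analyzed.dropna(subset=[col, "lf_hl"])
            if sub[col].nunique() < 2:
                return None
            try:
                return compare_groups(sub["lf_hl"].to_numpy(), sub[col].to_numpy())
            except ValueError:
                # too few testable groups in a small cohort
                return None

        by_pattern = comparison("pattern_group")
        by_type = comparison("response_type")

        baseline: dict = {}
        if {"response_type", "preop_lf_pta_db"} <= set(analyzed.columns):
            types = sorted(analyzed["response_type"].dropna().unique())
            for i, a in enumerate(types):
                for b in types[i + 1 :]:
                    sub = analyzed[analyzed["response_type"].isin([a, b])]
                    counts = sub["response_type"].value_counts()
                    if (counts < 2).any() or len(counts) < 2:
                        continue
                    t, p = compare_two(
                        sub["preop_lf_pta_db"].to_numpy(), sub["response_type"].to_numpy()
                    )
                    baseline[f"{a} vs {b}"] = {"t": t, "p": p}

        correlations: list[CorrelationResult] = []

        def corr(x, y, n1, n2):
            try:
                correlations.append(correlate(x, y, n1, n2))
            except ValueError:
                pass

        if {"preop_500_db", "a_max_uv"} <= set(analyzed.columns):
            corr(analyzed["preop_500_db"], analyzed["a_max_uv"], "pre-op 500 Hz threshold", "A_max")
        if "speech_score" in analyzed.columns and "a_max_uv" in analyzed.columns:
            corr(analyzed["a_max_uv"], analyzed["speech_score"], "A_max", "speech score")
        if {"a_min_uv", "a_max_uv"} <= set(analyzed.columns):
            corr(
                self._ratio(analyzed["a_min_uv"], analyzed["a_max_uv"]),
                analyzed["lf_hl"],
                "A_min/A_max",
                "LF HL",
            )
        if {"a_end_uv", "a_max_uv"} <= set(analyzed.columns):
            corr(
                self._ratio(analyzed["a_end_uv"], analyzed["a_max_uv"]),
                analyzed["lf_hl"],
                "A_end/A_max",
                "LF HL",
            )

        group_col = "response_type" if "response_type" in analyzed.columns else None
        if group_col is None and "pattern_group" in analyzed.columns:
            group_col = "pattern_group"
        if group_col is not None:
            group_hl = (
                analyzed.groupby(group_col)["lf_hl"]
                .agg(mean="mean", median="median", n="count")
                .sort_index()
            )
        else:
            group_hl = pd.DataFrame(columns=["mean", "median", "n"])

        return OutcomeResults(
            n_subjects=len(df),
            n_analyzed=len(analyzed),
            by_pattern=by_pattern,
            by_type=by_type,
            baseline_type_t=baseline,
            correlations=correlations,
            group_hl=group_hl,
            alpha=self.alpha,
        )


def analysis_report(data: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-call cohort report: fit the outcome model and return a dict."""
    return CohortOutcomeModel.from_dataframe(data, alpha=alpha).fit().to_dict()
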