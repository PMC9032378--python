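"""Plot helpers for monitoring traces and cohort outcomes (needs matplotlib)."""

from __future__ import annotations

import numpy as np

from .extraction import InsertionTrace


def plot_trace(trace: InsertionTrace, ax=None, detect_snr_db: float = 12.0):
    """Amplitude (log scale) and phase of one insertion trace over time.

    Phase markers are drawn only where the response clears the detection
    margin; the measured noise floor is shaded.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    t = trace.times
    ax.semilogy(t, trace.amplitudes_uv, color="tab:blue", label="CM amplitude")
    floors = np.array([p.noise_floor_uv for p in trace.points])
    ax.fill_between(t, 1e-3, floors, color="0.85", label="noise floor")
    ax.set_xlabel("insertion time (s)")
    ax.set_ylabel("amplitude (uV)", color="tab:blue")
    ax2 = ax.twinx()
    det = trace.snrs_db >= detect_snr_db
    ax2.plot(t[det], trace.phases_deg[det], ".", color="tab:red", ms=3, label="phase")
    ax2.set_ylabel("phase (deg)", color="tab:red")
    ax2.set_ylim(-200, 380)
    ax.set_title(trace.subject_id)
    return ax


def plot_hl_by_group(cohort_table, group_col: str = "response_type", ax=None):
    """Box plot of low-frequency hearing loss per classification group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    sub = cohort_table.dropna(subset=[group_col, "lf_hl"])
    groups = sorted(sub[group_col].unique())
    data = [sub.loc[sub[group_col] == g, "lf_hl"] for g in groups]
    ax.boxplot(data, tick_labels=[f"{g}\n(n={len(d)})" for g, d in zip(groups, data)])
    ax.set_ylabel("LF PTA hearing loss (dB)")
    ax.axhline(0, color="0.7", lw=0.8)
    return ax
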