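import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecochg.extraction import EcochgPoint, InsertionTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trace(
    amplitudes,
    phases=None,
    times=None,
    noise_floor_uv=1.0,
    subject_id="t",
    snr_override=None,
):
    """Build an InsertionTrace directly from amplitude/phase arrays.

    SNR defaults to the actual amplitude/floor ratio, so points below the
    floor come out undetectable and strong points detectable, matching what
    extraction would report.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = len(amplitudes)
    phases = np.zeros(n) if phases is None else np.asarray(phases, dtype=float)
    times = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    points = []
    for i in range(n):
        snr = (
            20.0 * np.log10(max(amplitudes[i], 1e-12) / noise_floor_uv)
            if snr_override is None
            else snr_override[i]
        )
        points.append(
            EcochgPoint(
                t=float(times[i]),
                amplitude_uv=float(amplitudes[i]),
                phase_deg=float(phases[i]),
                noise_floor_uv=noise_floor_uv,
                n_averages=1,
                snr_db=float(snr),
            )
        )
    return InsertionTrace(subject_id=subject_id, points=points)


@pytest.fixture
def trace_factory():
    return make_trace
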