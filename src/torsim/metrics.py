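"""Action-potential trace analysis: biomarkers, repolarization-abnormality
detection (EADs and repolarization failure), and the delayed-peak guard.

An early afterdepolarization (EAD) is called when the membrane voltage
develops a sustained positive derivative later than ``EAD_EXCLUSION_MS``
after the AP peak. Repolarization failure (RF) is called when the final
voltage of the analyzed cycle remains above ``RF_VOLTAGE_MV``. Either
constitutes a repolarization abnormality (RA), the per-cell proarrhythmia
marker aggregated into the TdP risk score.

The numerical constants below are declared, configurable decisions: a
strict > 0 derivative test on adaptive-solver output is numerically
fragile, so "positive derivative" means dV/dt above a small noise
threshold sustained for at least two consecutive grid samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ord_model import APTrace

__all__ = [
    "Biomarkers",
    "RACall",
    "compute_biomarkers",
    "detect_ead",
    "detect_rf",
    "delayed_peak_guard",
    "call_ra",
]

#: EAD search starts this long after the AP peak (ms).
EAD_EXCLUSION_MS = 150.0
#: finite-difference dV/dt above this counts as a positive derivative (mV/ms)
DVDT_THRESHOLD = 0.01
#: the positive derivative must persist over at least this many grid steps
DVDT_PERSIST_SAMPLES = 2
#: RF: final voltage of the analyzed cycle above this (mV), strict
RF_VOLTAGE_MV = -40.0
#: peaks later than this after stimulus onset are flagged for review (ms)
DELAYED_PEAK_MS = 150.0


@dataclass(frozen=True)
class Biomarkers:
    """AP biomarkers of one analyzed beat (times in ms from stimulus onset).

    APDx values are ``None`` when the voltage never recrosses the x%
    repolarization level (e.g. repolarization failure).
    """

    apd90: float | None
    apd50: float | None
    apd40: float | None
    peak_voltage: float
    peak_time: float
    resting_voltage: float
    end_voltage: float


@dataclass(frozen=True)
class RACall:
    """Composed repolarization-abnormality call for one trace."""

    has_ead: bool
    has_rf: bool
    ead_time: float | None
    review_flag: bool

    def __post_init__(self) -> None:
        if self.has_ead != (self.ead_time is not None):
            raise ValueError("ead_time must be present iff has_ead")

    @property
    def ra(self) -> bool:
        return self.has_ead or self.has_rf


def _stimulus_duration(trace: APTrace) -> float:
    return float(trace.metadata.get("stimulus_duration", 0.5))


def compute_biomarkers(trace: APTrace) -> Biomarkers:
    """Biomarkers of a beat spanning one full cycle from stimulus onset.

    Resting voltage is the sample at stimulus onset (t=0); the peak is the
    voltage maximum searched after the stimulus offset (so the stimulus
    artifact is excluded); APDx is the time from stimulus onset until the
    voltage first falls below peak - x%*(peak - rest), searched after the
    peak.
    """
    t, v = trace.time, trace.voltage
    stim_end = _stimulus_duration(trace)
    if t[-1] <= stim_end:
        raise ValueError("trace shorter than the stimulus window")
    rest = float(v[0])
    search = np.searchsorted(t, stim_end)
    i_peak = search + int(np.argmax(v[search:]))
    peak = float(v[i_peak])
    t_peak = float(t[i_peak])

    def apd(frac: float) -> float | None:
        thr = peak - frac * (peak - rest)
        below = np.nonzero(v[i_peak:] < thr)[0]
        if below.size == 0:
            return None
        return float(t[i_peak + below[0]])

    return Biomarkers(
        apd90=apd(0.90),
        apd50=apd(0.50),
        apd40=apd(0.40),
        peak_voltage=peak,
        peak_time=t_peak,
        resting_voltage=rest,
        end_voltage=float(v[-1]),
    )


def detect_ead(trace: APTrace, biomarkers: Biomarkers | None = None,
               ) -> tuple[bool, float | None]:
    """Detect an EAD: sustained positive dV/dt later than ``EAD_EXCLUSION_MS``
    after the AP peak and before cycle end.

    Returns ``(found, first_time)`` where the time marks the start of the
    first qualifying rising segment.
    """
    t, v = trace.time, trace.voltage
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("detect_ead requires a uniform time grid")
    if biomarkers is None:
        biomarkers = compute_biomarkers(trace)
    dvdt = np.diff(v) / dt
    # segment i spans [t[i], t[i+1]); only segments fully after the window
    eligible = t[:-1] >= biomarkers.peak_time + EAD_EXCLUSION_MS
    rising = (dvdt > DVDT_THRESHOLD) & eligible
    run = 0
    for i, flag in enumerate(rising):
        run = run + 1 if flag else 0
        if run >= DVDT_PERSIST_SAMPLES:
            return True, float(t[i + 1 - run])
    return False, None


def detect_rf(trace: APTrace) -> bool:
    """Repolarization failure: final voltage strictly above -40 mV."""
    return bool(trace.voltage[-1] > RF_VOLTAGE_MV)


def delayed_peak_guard(trace: APTrace,
                       biomarkers: Biomarkers | None = None) -> bool:
    """Flag traces whose AP peak is suspiciously late for manual review.

    Very weak upstrokes at high drug concentrations can push the voltage
    maximum deep into the cycle, which shifts the EAD search window and can
    misclassify an ordinary (if sluggish) AP as abnormal. The automated EAD
    call on a flagged trace is preserved but reported separately so
    review-corrected metrics can be recomputed.
    """
    if biomarkers is None:
        biomarkers = compute_biomarkers(trace)
    return bool(biomarkers.peak_time > DELAYED_PEAK_MS)


def call_ra(trace: APTrace, biomarkers: Biomarkers | None = None) -> RACall:
    """Compose the EAD detector, RF detector and delayed-peak guard."""
    if biomarkers is None:
        biomarkers = compute_biomarkers(trace)
    has_ead, ead_time = detect_ead(trace, biomarkers)
    return RACall(
        has_ead=has_ead,
        has_rf=detect_rf(trace),
        ead_time=ead_time,
        review_flag=delayed_peak_guard(trace, biomarkers),
    )
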