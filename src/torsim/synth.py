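"""Synthetic inputs for the whole pipeline: drug panels with known
archetypes and safety margins, calibrated fixture populations, and
analytic voltage traces for exercising the RA detectors.

Everything here is generated programmatically and deterministically from a
seed, in the same CSV dialects the package uses for real potency and
population tables, so swapping in experimental data is a path change only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ord_model import APTrace, ConductanceScaling, PacingProtocol
from .pharm import DrugProfile
from .population import (BiomarkerRanges, Population, PopulationSpec,
                         calibrate, sample_candidates)

__all__ = [
    "ARCHETYPES",
    "HERG_SAFETY_MARGINS",
    "SyntheticTraceSpec",
    "generate_drug_panel",
    "generate_fixture_population",
    "make_trace",
]

ARCHETYPES = ("inactive", "pure_herg", "pure_calcium",
              "balanced_multichannel", "late_sodium_offset")

#: IC50(IKr) / EFTPCmax margins swept by the pure-hERG archetype; a margin
#: of 0.03 means near-total hERG block already at the therapeutic dose.
HERG_SAFETY_MARGINS = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)

# therapeutic free plasma concentrations span ~4 orders of magnitude
_EFTPC_LOG_RANGE = (0.001, 10.0)  # uM
_HILL_RANGE = (0.5, 2.0)


def _draw_eftpc(rng) -> float:
    lo, hi = _EFTPC_LOG_RANGE
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def _draw_hill(rng) -> float:
    return float(rng.uniform(*_HILL_RANGE))


def generate_drug_panel(n_per_archetype: int = 1, seed: int = 0,
                        archetypes=ARCHETYPES,
                        ) -> tuple[list[DrugProfile], dict[str, str]]:
    """Deterministic panel of synthetic compounds with ground-truth labels.

    Pure-hERG profiles sweep the safety margins in ``HERG_SAFETY_MARGINS``
    (cycled when ``n_per_archetype`` differs from the sweep length) with a
    Hill coefficient of 1 on the swept channel so the margin is directly
    interpretable; balanced profiles pair the same IKr potency with a
    matched ICaL (and INa) block; inactive profiles keep every IC50 at
    least 1000x EFTPCmax. Returns ``(profiles, labels)`` with labels mapping
    compound name to archetype.
    """
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    rng = np.random.default_rng(seed)
    profiles: list[DrugProfile] = []
    labels: dict[str, str] = {}

    def add(name: str, archetype: str, channels: dict, eftpc: float) -> None:
        prof = DrugProfile(compound_name=name, channels=channels,
                           eftpc_max=eftpc, dataset_tag=f"synthetic:{archetype}")
        profiles.append(prof)
        labels[name] = archetype

    for archetype in archetypes:
        if archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {archetype!r}")
        count = (len(HERG_SAFETY_MARGINS)
                 if archetype in ("pure_herg", "balanced_multichannel")
                 and n_per_archetype == 1 else n_per_archetype)
        for k in range(count):
            eftpc = _draw_eftpc(rng)
            name = f"{archetype}_{k + 1:02d}"
            if archetype == "inactive":
                margin = float(rng.uniform(1e3, 1e5))
                channels = {ch: (margin * eftpc, _draw_hill(rng))
                            for ch in ("INa", "IKr", "ICaL")}
                add(name, archetype, channels, eftpc)
            elif archetype == "pure_herg":
                margin = HERG_SAFETY_MARGINS[k % len(HERG_SAFETY_MARGINS)]
                add(f"{archetype}_m{margin:g}", archetype,
                    {"IKr": (margin * eftpc, 1.0)}, eftpc)
            elif archetype == "pure_calcium":
                margin = HERG_SAFETY_MARGINS[k % len(HERG_SAFETY_MARGINS)]
                add(name, archetype, {"ICaL": (margin * eftpc, 1.0)}, eftpc)
            elif archetype == "balanced_multichannel":
                margin = HERG_SAFETY_MARGINS[k % len(HERG_SAFETY_MARGINS)]
                channels = {
                    "IKr": (margin * eftpc, 1.0),
                    "ICaL": (margin * eftpc, _draw_hill(rng)),
                    "INa": (3.0 * margin * eftpc, _draw_hill(rng)),
                }
                add(f"{archetype}_m{margin:g}", archetype, channels, eftpc)
            else:  # late_sodium_offset
                margin = HERG_SAFETY_MARGINS[k % len(HERG_SAFETY_MARGINS)]
                channels = {
                    "IKr": (margin * eftpc, 1.0),
                    "INaL": (margin * eftpc, _draw_hill(rng)),
                }
                add(name, archetype, channels, eftpc)
    return profiles, labels


def generate_fixture_population(size: int = 20, seed: int = 0,
                                spec: PopulationSpec | None = None,
                                ranges: BiomarkerRanges | None = None,
                                protocol: PacingProtocol | None = None,
                                solver: str = "rl",
                                max_candidates: int | None = None) -> Population:
    """Sample and calibrate candidates until ``size`` members are accepted.

    A desk-scale stand-in for a full RA-prone population; deterministic for
    a fixed seed. Raises when the candidate budget (default 40x size) is
    exhausted before enough members pass calibration.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    base = spec or PopulationSpec()
    budget = max_candidates if max_candidates is not None else 40 * size
    accepted: list[tuple[str, ConductanceScaling]] = []
    drawn = 0
    batch_no = 0
    while len(accepted) < size:
        if drawn >= budget:
            raise RuntimeError(
                f"candidate budget exhausted: {len(accepted)}/{size} accepted "
                f"after {drawn} candidates")
        batch = min(max(2 * (size - len(accepted)), 8), budget - drawn)
        spec_b = PopulationSpec(ranges=base.ranges, scheme=base.scheme,
                                candidate_count=batch,
                                rng_seed=base.rng_seed + seed + 9973 * batch_no)
        candidates = sample_candidates(spec_b)
        drawn += batch
        batch_no += 1
        try:
            pop = calibrate(candidates, ranges, protocol, solver=solver)
        except ValueError:
            continue  # whole batch rejected; draw again
        for _, scaling in pop:
            if len(accepted) < size:
                accepted.append((f"fix_{len(accepted) + 1:03d}", scaling))
    return Population(members=accepted, provenance=f"fixture(seed={seed})",
                      calibrated=True)


# ---------------------------------------------------------------------------
# Analytic voltage traces (positive/negative detector controls; no ODE)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Geometric recipe for an analytic AP-like voltage trace."""

    kind: str = "normal"  # normal | ead_bump | rf_plateau | delayed_peak
    rest_mv: float = -85.0
    peak_mv: float = 35.0
    apd_ms: float = 300.0
    bump_center_ms: float = 400.0   # after the AP peak (ead_bump)
    bump_amplitude_mv: float = 15.0
    bump_width_ms: float = 20.0
    plateau_end_mv: float = -20.0   # rf_plateau final voltage
    peak_time_ms: float = 1.0       # delayed_peak: time of the maximum
    cycle_length_ms: float = 1000.0
    grid_ms: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "ead_bump", "rf_plateau", "delayed_peak"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if not (0 < self.grid_ms <= 1.0):
            raise ValueError("grid spacing must be in (0, 1] ms")
        if self.peak_mv <= self.rest_mv:
            raise ValueError("peak must exceed rest")


def make_trace(spec: SyntheticTraceSpec) -> APTrace:
    """Piecewise-analytic voltage series with exactly the requested
    morphology (see ``SyntheticTraceSpec.kind``)."""
    cl = spec.cycle_length_ms
    t = np.arange(0.0, cl + spec.grid_ms / 2, spec.grid_ms)
    rest, peak = spec.rest_mv, spec.peak_mv
    amp = peak - rest
    upstroke_ms = 1.0
    up = np.clip(t / upstroke_ms, 0.0, 1.0)

    if spec.kind == "normal":
        rep = 1.0 / (1.0 + np.exp((t - spec.apd_ms) / 10.0))
        v = rest + amp * up * rep
    elif spec.kind == "ead_bump":
        center = upstroke_ms + spec.bump_center_ms
        if not (0.0 < center < cl):
            raise ValueError("EAD bump placed outside the cycle")
        rep = 1.0 / (1.0 + np.exp((t - spec.apd_ms) / 10.0))
        bump = spec.bump_amplitude_mv * np.exp(
            -0.5 * ((t - center) / spec.bump_width_ms) ** 2)
        v = rest + amp * up * rep + bump
    elif spec.kind == "rf_plateau":
        tail = spec.plateau_end_mv + (peak - spec.plateau_end_mv) * np.exp(
            -(t - upstroke_ms) / 150.0)
        v = np.where(t < upstroke_ms, rest + amp * up, tail)
    else:  # delayed_peak: slow dome with its maximum late in the cycle
        tp = spec.peak_time_ms
        width = max(tp / 2.5, 1.0)
        v = rest + amp * np.exp(-0.5 * ((t - tp) / width) ** 2)

    meta = {"synthetic": True, "kind": spec.kind, "cycle_length": cl,
            "stimulus_duration": 0.5}
    return APTrace(time=t, voltage=v, metadata=meta)
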