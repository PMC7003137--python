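"""Construction, calibration and persistence of the repolarization-
abnormality-prone population of ventricular models.

Candidate members are drawn by scaling nine maximal conductances of the
baseline ORd endocardial cell. The sampling ranges are deliberately skewed
to lower the repolarization reserve — weaker IKr, IKs and INaK, stronger
INaL, ICaL and INaCa — emulating the ionic remodelling seen in long-QT
syndrome, hypertrophic cardiomyopathy and heart failure. Candidates are
then calibrated: each is paced drug-free to its analyzed beat and kept only
if its biomarkers fall inside human ventricular acceptance ranges and it
shows no repolarization abnormality at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .ord_model import CHANNELS, ConductanceScaling, PacingProtocol, simulate
from . import metrics

__all__ = [
    "DEFAULT_RANGES",
    "DEFAULT_BIOMARKER_RANGES",
    "PopulationSpec",
    "BiomarkerRanges",
    "Population",
    "sample_candidates",
    "calibrate",
    "load_population",
    "save_population",
]

#: Default per-channel sampling ranges. Repolarization-weakening channels
#: (IKr, IKs, INaK) only scale down; depolarization-strengthening channels
#: (INaL, ICaL, INaCa) only scale up; the rest vary symmetrically.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "INa": (0.5, 1.5),
    "INaL": (1.0, 2.0),
    "Ito": (0.5, 1.5),
    "IKr": (0.1, 1.0),
    "IKs": (0.1, 1.0),
    "IK1": (0.5, 1.5),
    "ICaL": (1.0, 2.0),
    "INaK": (0.1, 1.0),
    "INaCa": (1.0, 2.0),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for population candidates."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    scheme: str = "lhs"  # "lhs" (Latin hypercube) or "uniform"
    candidate_count: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.ranges) != set(CHANNELS):
            raise ValueError(f"ranges must cover exactly the nine channels {CHANNELS}")
        for ch, (lo, hi) in self.ranges.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"range for {ch} must satisfy 0 <= low <= high")
        if self.scheme not in ("lhs", "uniform"):
            raise ValueError("scheme must be 'lhs' or 'uniform'")
        if self.candidate_count < 1:
            raise ValueError("candidate_count must be >= 1")


@dataclass(frozen=True)
class BiomarkerRanges:
    """Acceptance intervals for drug-free calibration, standard human
    ventricular bands from the population-of-models literature."""

    apd90: tuple[float, float] = (180.0, 440.0)     # ms
    apd50: tuple[float, float] = (110.0, 350.0)     # ms
    rmp: tuple[float, float] = (-95.0, -80.0)       # mV
    peak: tuple[float, float] = (10.0, 55.0)        # mV
    triangulation: tuple[float, float] = (50.0, 150.0)  # APD90 - APD40, ms

    def __post_init__(self) -> None:
        for name in ("apd90", "apd50", "rmp", "peak", "triangulation"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} interval is empty")

    def accepts(self, bm: metrics.Biomarkers) -> bool:
        if bm.apd90 is None or bm.apd50 is None or bm.apd40 is None:
            return False
        checks = (
            (self.apd90, bm.apd90),
            (self.apd50, bm.apd50),
            (self.rmp, bm.resting_voltage),
            (self.peak, bm.peak_voltage),
            (self.triangulation, bm.apd90 - bm.apd40),
        )
        return all(lo <= x <= hi for (lo, hi), x in checks)


DEFAULT_BIOMARKER_RANGES = BiomarkerRanges()


@dataclass
class Population:
    """Ordered collection of (model_id, ConductanceScaling) members."""

    members: list[tuple[str, ConductanceScaling]]
    provenance: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids must be unique")

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def scalings(self) -> list[ConductanceScaling]:
        return [s for _, s in self.members]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid, s in self.members:
            row = {"model_id": mid}
            row.update({f"scale_{c}": getattr(s, f"scale_{c}") for c in CHANNELS})
            rows.append(row)
        return pd.DataFrame(rows)


def sample_candidates(spec: PopulationSpec) -> list[ConductanceScaling]:
    """Draw ``candidate_count`` scalings within the per-channel ranges.

    Deterministic for a fixed ``rng_seed``. A degenerate range
    (low == high) yields that constant factor.
    """
    lo = np.array([spec.ranges[c][0] for c in CHANNELS])
    hi = np.array([spec.ranges[c][1] for c in CHANNELS])
    n = spec.candidate_count
    if spec.scheme == "lhs":
        sampler = qmc.LatinHypercube(d=len(CHANNELS), seed=spec.rng_seed)
        u = sampler.random(n)
    else:
        rng = np.random.default_rng(spec.rng_seed)
        u = rng.uniform(size=(n, len(CHANNELS)))
    factors = lo + u * (hi - lo)
    return [ConductanceScaling.from_array(row) for row in factors]


def calibrate(candidates, ranges: BiomarkerRanges | None = None,
              protocol: PacingProtocol | None = None,
              solver: str = "rl") -> Population:
    """Simulate each drug-free candidate and keep those whose biomarkers
    fall inside the acceptance ranges and that show no baseline RA.

    Accepts a list of scalings, (id, scaling) pairs, or a Population;
    existing ids are preserved (so calibration is idempotent on an already
    calibrated population), candidate order is kept.
    """
    ranges = ranges or DEFAULT_BIOMARKER_RANGES
    protocol = protocol or PacingProtocol()
    items = list(candidates)
    if not items:
        raise ValueError("no candidates to calibrate")
    if isinstance(items[0], ConductanceScaling):
        width = max(4, len(str(len(items))))
        items = [(f"model_{i + 1:0{width}d}", s) for i, s in enumerate(items)]

    kept = []
    for model_id, scaling in items:
        trace = simulate(scaling, None, protocol, solver=solver,
                         metadata={"model_id": model_id, "drug": "control"})
        bm = metrics.compute_biomarkers(trace)
        call = metrics.call_ra(trace, bm)
        if ranges.accepts(bm) and not call.ra:
            kept.append((model_id, scaling))
    if not kept:
        raise ValueError(
            "calibration rejected every candidate; consider widening the "
            "sampling or biomarker acceptance ranges")
    return Population(members=kept, provenance="calibrated", calibrated=True)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_SCALE_COLS = tuple(f"scale_{c}" for c in CHANNELS)
_FMT = "%.6f"


def save_population(population: Population, path) -> None:
    """Write the population CSV (`model_id` + nine named scale columns),
    with fixed 6-decimal formatting so save/load round-trips exactly."""
    population.to_frame().to_csv(path, index=False, float_format=_FMT)


def load_population(path) -> Population:
    df = pd.read_csv(path)
    cols = set(df.columns)
    expected = {"model_id", *_SCALE_COLS}
    if cols != expected:
        extra, missing = sorted(cols - expected), sorted(expected - cols)
        raise ValueError(
            f"population CSV columns mismatch: missing {missing}, extra {extra}")
    members = []
    seen = set()
    for idx, row in df.iterrows():
        mid = str(row["model_id"])
        if mid in seen:
            raise ValueError(f"duplicate model_id {mid!r} at row {idx}")
        seen.add(mid)
        try:
            factors = [float(row[c]) for c in _SCALE_COLS]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric scale factor at row {idx} ({mid})") from exc
        if not np.all(np.isfinite(factors)):
            raise ValueError(f"non-finite scale factor at row {idx} ({mid})")
        members.append((mid, ConductanceScaling.from_array(factors)))
    return Population(members=members, provenance=str(path), calibrated=False)
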