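"""Pore-block pharmacology and the multi-concentration population drug trial.

Drug action on a channel is the concentration-dependent conductance scaling

    remaining = 1 / (1 + (C / IC50)^h)

composed multiplicatively with the population member's own conductance
scaling. Each compound is tested at multiples of its maximal effective free
therapeutic plasma concentration (EFTPCmax), by default 1, 3, 10, 30 and
100 fold; channels without a measured potency are left unblocked.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ord_model import (BLOCKABLE_CHANNELS, ConductanceScaling, PacingProtocol,
                        SimulationError, simulate)
from . import metrics

__all__ = [
    "DrugProfile",
    "ConcentrationPlan",
    "ChannelSubset",
    "TrialResult",
    "remaining_fraction",
    "ic50_from_single_point",
    "apply_drug",
    "run_trial",
    "control_biomarkers",
    "read_drug_table",
    "write_drug_table",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugProfile:
    """Per-channel potency (IC50 in uM, Hill coefficient) for one compound.

    ``channels`` maps a channel name (subset of the seven blockable ORd
    currents) to an ``(ic50, hill)`` pair; absent channels mean "no measured
    block". ``eftpc_max`` is the maximal effective free therapeutic plasma
    concentration in uM.
    """

    compound_name: str
    channels: dict[str, tuple[float, float]]
    eftpc_max: float
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eftpc_max) and self.eftpc_max > 0):
            raise ValueError(f"{self.compound_name}: EFTPCmax must be finite and > 0")
        for ch, (ic50, hill) in self.channels.items():
            if ch not in BLOCKABLE_CHANNELS:
                raise ValueError(
                    f"{self.compound_name}: unknown channel {ch!r}; "
                    f"expected one of {BLOCKABLE_CHANNELS}")
            if not (ic50 > 0):
                raise ValueError(f"{self.compound_name}/{ch}: IC50 must be > 0")
            if not (hill > 0):
                raise ValueError(f"{self.compound_name}/{ch}: Hill must be > 0")


@dataclass(frozen=True)
class ConcentrationPlan:
    """Tested concentration multiples of EFTPCmax and their score weights.

    The weight of concentration c = m * EFTPCmax is Wc = EFTPCmax / c = 1/m,
    inversely related to the tested concentration.
    """

    multiples: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0)

    def __post_init__(self) -> None:
        m = self.multiples
        object.__setattr__(self, "multiples", tuple(float(x) for x in m))
        if len(self.multiples) == 0:
            raise ValueError("at least one concentration multiple required")
        if any(x <= 0 for x in self.multiples):
            raise ValueError("concentration multiples must be positive")
        if any(b <= a for a, b in zip(self.multiples, self.multiples[1:])):
            raise ValueError("concentration multiples must be strictly increasing")

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(1.0 / m for m in self.multiples)

    def capped(self, cap: float) -> "ConcentrationPlan":
        kept = tuple(m for m in self.multiples if m <= cap)
        if not kept:
            raise ValueError(f"cap {cap} is below the smallest multiple")
        return ConcentrationPlan(kept)


class ChannelSubset(frozenset):
    """Named selector over the seven blockable channels."""

    PRESETS = {
        "ALL7": BLOCKABLE_CHANNELS,
        "FOUR": ("INa", "INaL", "IKr", "ICaL"),
        "THREE": ("INa", "IKr", "ICaL"),
        "HERG_ONLY": ("IKr",),
    }

    def __new__(cls, channels):
        if isinstance(channels, str):
            try:
                channels = cls.PRESETS[channels]
            except KeyError:
                raise ValueError(
                    f"unknown subset preset {channels!r}; "
                    f"expected one of {sorted(cls.PRESETS)}") from None
        channels = frozenset(channels)
        if not channels:
            raise ValueError("channel subset must be non-empty")
        bad = channels - set(BLOCKABLE_CHANNELS)
        if bad:
            raise ValueError(f"unknown channels in subset: {sorted(bad)}")
        return super().__new__(cls, channels)

    @property
    def name(self) -> str:
        for name, chans in self.PRESETS.items():
            if frozenset(chans) == self:
                return name
        return "+".join(sorted(self))


ALL7 = ChannelSubset("ALL7")
FOUR = ChannelSubset("FOUR")
THREE = ChannelSubset("THREE")
HERG_ONLY = ChannelSubset("HERG_ONLY")


# ---------------------------------------------------------------------------
# Pore-block model
# ---------------------------------------------------------------------------


def remaining_fraction(concentration: float, ic50: float, hill: float) -> float:
    """Fraction of channel conductance remaining under pore block,
    ``1 / (1 + (C/IC50)^h)``; multiplies the channel's conductance."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be > 0")
    if concentration == 0.0:
        return 1.0
    return 1.0 / (1.0 + (concentration / ic50) ** hill)


def ic50_from_single_point(blocked_fraction: float, concentration: float) -> float:
    """IC50 estimated from a single-point block measurement with h = 1.

    Inverts the pore-block model: IC50 = C * (1 - b) / b for blocked
    fraction b at concentration C. A block of exactly 0 or 1 is
    unidentifiable.
    """
    if not (0.0 < blocked_fraction < 1.0):
        raise ValueError("blocked_fraction must be strictly between 0 and 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return concentration * (1.0 - blocked_fraction) / blocked_fraction


def apply_drug(drug: DrugProfile, multiple: float,
               subset: ChannelSubset = ALL7) -> dict[str, float]:
    """Per-channel conductance multipliers for a compound at a concentration
    multiple of its EFTPCmax, restricted to a channel subset.

    Channels outside the subset, or without a measured potency, get 1.0.
    """
    if multiple < 0:
        raise ValueError("concentration multiple must be >= 0")
    conc = multiple * drug.eftpc_max
    out = {}
    for ch in BLOCKABLE_CHANNELS:
        if ch in subset and ch in drug.channels:
            ic50, hill = drug.channels[ch]
            out[ch] = remaining_fraction(conc, ic50, hill)
        else:
            out[ch] = 1.0
    return out


# ---------------------------------------------------------------------------
# Population trial
# ---------------------------------------------------------------------------


@dataclass
class TrialResult:
    """Outcome of one compound's population trial.

    ``n_ra`` counts population members with an RA per concentration as
    called by the automated detectors; ``n_ra_corrected`` additionally
    treats EAD-only calls on review-flagged (delayed-peak) traces as clean.
    Members whose simulation failed at any concentration are excluded from
    both the numerator and the denominator ``n_models``.
    """

    compound: str
    dataset_tag: str
    multiples: tuple[float, ...]
    n_ra: tuple[int, ...]
    n_ra_corrected: tuple[int, ...]
    n_models: int
    tdp_score: float
    tdp_score_corrected: float
    risky: bool
    detail: pd.DataFrame
    failed_models: tuple[str, ...] = ()

    @property
    def incomplete(self) -> bool:
        return len(self.failed_models) > 0


def _cell_ra_flags(call: metrics.RACall) -> tuple[bool, bool]:
    """(raw RA, review-corrected RA) for one cell."""
    raw = call.ra
    corrected = call.has_rf or (call.has_ead and not call.review_flag)
    return raw, corrected


def control_biomarkers(population, protocol: PacingProtocol | None = None,
                       solver: str = "rl") -> pd.DataFrame:
    """Drug-free biomarkers for every population member (shared across a
    drug panel; used as the DAPD reference)."""
    protocol = protocol or PacingProtocol()
    rows = []
    for model_id, scaling in population:
        trace = simulate(scaling, None, protocol, solver=solver,
                         metadata={"model_id": model_id, "drug": "control"})
        bm = metrics.compute_biomarkers(trace)
        call = metrics.call_ra(trace, bm)
        rows.append({"model_id": model_id, "apd90_ms": bm.apd90,
                     "has_ead": call.has_ead, "has_rf": call.has_rf})
    return pd.DataFrame(rows)


def run_trial(drug: DrugProfile, population,
              plan: ConcentrationPlan | None = None,
              subset: ChannelSubset = ALL7,
              protocol: PacingProtocol | None = None,
              solver: str = "rl") -> TrialResult:
    """Run the full multi-concentration trial of one compound on a
    population of models.

    Simulates every (member, concentration) pair from the published resting
    state (independent pre-pacing per run), detects RAs on the analyzed
    beat, tallies ``nRA`` per concentration and computes the TdP risk
    score. Individual simulation failures are recorded and the run
    continues; failed members are dropped from the tallies with a warning.
    """
    from .scoring import tdp_score as _tdp_score  # local: avoids module cycle

    members = list(population)
    if not members:
        raise ValueError("population must be non-empty")
    plan = plan or ConcentrationPlan()
    protocol = protocol or PacingProtocol()

    rows = []
    failed: set[str] = set()
    for model_id, scaling in members:
        for multiple in plan.multiples:
            blocks = apply_drug(drug, multiple, subset)
            row = {"model_id": model_id, "compound": drug.compound_name,
                   "multiple": multiple}
            try:
                trace = simulate(
                    scaling, blocks, protocol, solver=solver,
                    metadata={"model_id": model_id, "drug": drug.compound_name,
                              "concentration": multiple * drug.eftpc_max})
                bm = metrics.compute_biomarkers(trace)
                call = metrics.call_ra(trace, bm)
                raw, corr = _cell_ra_flags(call)
                nan = float("nan")
                row.update(ok=True,
                           apd90_ms=nan if bm.apd90 is None else bm.apd90,
                           has_ead=call.has_ead,
                           ead_time_ms=nan if call.ead_time is None
                           else call.ead_time,
                           has_rf=call.has_rf,
                           review_flag=call.review_flag, ra=raw,
                           ra_corrected=corr, error="")
            except SimulationError as exc:
                failed.add(model_id)
                log.warning("simulation failed: %s", exc)
                row.update(ok=False, apd90_ms=float("nan"), has_ead=False,
                           ead_time_ms=float("nan"), has_rf=False,
                           review_flag=False, ra=False, ra_corrected=False,
                           error=str(exc))
            rows.append(row)

    detail = pd.DataFrame(rows)
    complete = detail[~detail.model_id.isin(failed)]
    n_models = len(members) - len(failed)
    n_ra, n_corr = [], []
    for multiple in plan.multiples:
        at_c = complete[complete.multiple == multiple]
        n_ra.append(int(at_c.ra.sum()))
        n_corr.append(int(at_c.ra_corrected.sum()))
    if n_models > 0:
        score = _tdp_score(n_ra, n_models, plan)
        score_corr = _tdp_score(n_corr, n_models, plan)
    else:
        score = score_corr = float("nan")
    return TrialResult(
        compound=drug.compound_name,
        dataset_tag=drug.dataset_tag,
        multiples=plan.multiples,
        n_ra=tuple(n_ra),
        n_ra_corrected=tuple(n_corr),
        n_models=n_models,
        tdp_score=score,
        tdp_score_corrected=score_corr,
        risky=score > 0,
        detail=detail,
        failed_models=tuple(sorted(failed)),
    )


# ---------------------------------------------------------------------------
# Drug table I/O
# ---------------------------------------------------------------------------

_DRUG_BASE_COLS = ("compound", "dataset", "EFTPCmax_uM")


def _drug_columns() -> list[str]:
    cols = list(_DRUG_BASE_COLS)
    for ch in BLOCKABLE_CHANNELS:
        cols += [f"{ch}_IC50_uM", f"{ch}_hill"]
    return cols


def read_drug_table(path) -> list[DrugProfile]:
    """Read a drug potency CSV (blank cells mean "unmeasured").

    Columns: ``compound,dataset,EFTPCmax_uM`` plus ``{channel}_IC50_uM`` /
    ``{channel}_hill`` for the seven blockable channels. Scientific
    notation is fine; thousands separators are not.
    """
    df = pd.read_csv(path)
    missing = set(_DRUG_BASE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    drugs = []
    for _, row in df.iterrows():
        channels = {}
        for ch in BLOCKABLE_CHANNELS:
            c_ic50, c_hill = f"{ch}_IC50_uM", f"{ch}_hill"
            ic50 = row.get(c_ic50)
            if ic50 is None or pd.isna(ic50):
                continue
            hill = row.get(c_hill)
            hill = 1.0 if hill is None or pd.isna(hill) else float(hill)
            channels[ch] = (float(ic50), hill)
        drugs.append(DrugProfile(
            compound_name=str(row["compound"]),
            channels=channels,
            eftpc_max=float(row["EFTPCmax_uM"]),
            dataset_tag="" if pd.isna(row.get("dataset")) else str(row["dataset"]),
        ))
    return drugs


def write_drug_table(drugs: list[DrugProfile], path) -> None:
    rows = []
    for d in drugs:
        row = {"compound": d.compound_name, "dataset": d.dataset_tag,
               "EFTPCmax_uM": d.eftpc_max}
        for ch, (ic50, hill) in d.channels.items():
            row[f"{ch}_IC50_uM"] = ic50
            row[f"{ch}_hill"] = hill
        rows.append(row)
    pd.DataFrame(rows, columns=_drug_columns()).to_csv(path, index=False)
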