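"""TdP risk score, binary classification, confusion metrics and the
comparison experiments (concentration cap, channel subsets, score-DAPD
correlation).

The concentration-weighted TdP risk score aggregates repolarization
abnormalities across the population and the tested concentrations:

    score = sum_c(Wc * nRA_c) / (N * sum_c Wc),    Wc = EFTPCmax / c

where nRA_c is the number of models showing an RA at concentration c and N
is the population size. Low concentrations dominate the weighting, so RA at
the therapeutic dose carries far more risk than RA only at 100-fold
overdose. The score lies in [0, 1]; a compound is classified risky exactly
when any RA occurred (score > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pharm import ChannelSubset, ConcentrationPlan, DrugProfile, TrialResult, run_trial

__all__ = [
    "ConfusionMetrics",
    "tdp_score",
    "classify",
    "confusion",
    "capped_score",
    "concentration_cap_experiment",
    "channel_subset_experiment",
    "score_apd_correlation",
    "score_floor_for_plot",
    "summary_frame",
]

#: visualization floor for zero scores on log axes; never used in classification
PLOT_FLOOR = 1e-16


def tdp_score(n_ra_by_concentration, n_models: int,
              plan: ConcentrationPlan | None = None) -> float:
    """Concentration-weighted TdP risk score in [0, 1]."""
    plan = plan or ConcentrationPlan()
    counts = [int(c) for c in n_ra_by_concentration]
    if len(counts) != len(plan.multiples):
        raise ValueError("one RA count per planned concentration required")
    if n_models < 1:
        raise ValueError("population size must be >= 1")
    if any(c < 0 or c > n_models for c in counts):
        raise ValueError("RA counts must lie in [0, N]")
    # exact rational evaluation so boundary scores (0, 1) come out exact
    from fractions import Fraction
    w = [1 / Fraction(m) for m in plan.multiples]
    num = sum(wc * c for wc, c in zip(w, counts))
    return float(num / (n_models * sum(w)))


def classify(result: TrialResult | float) -> str:
    """``"risky"`` iff any RA occurred at any tested concentration
    (equivalently, TdP score > 0); ``"safe"`` otherwise."""
    score = result.tdp_score if isinstance(result, TrialResult) else float(result)
    if score < 0 or math.isnan(score):
        raise ValueError("score must be a number >= 0")
    return "risky" if score > 0 else "safe"


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMetrics:
    """TP/TN/FP/FN counts and the derived fractions.

    ``*_pct`` accessors report percentages rounded to the nearest integer
    (table convention); raw fractions are retained.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn,
                           self.tp + self.tn + self.fp + self.fn)

    def _pct(self, x: float) -> int | None:
        return None if math.isnan(x) else int(round(100.0 * x))

    @property
    def sensitivity_pct(self) -> int:
        return self._pct(self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return self._pct(self.specificity)

    @property
    def ppv_pct(self) -> int:
        return self._pct(self.ppv)

    @property
    def npv_pct(self) -> int:
        return self._pct(self.npv)

    @property
    def accuracy_pct(self) -> int:
        return self._pct(self.accuracy)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "ppv_pct": self.ppv_pct,
            "npv_pct": self.npv_pct,
            "accuracy_pct": self.accuracy_pct,
        }


def confusion(predictions: dict[str, bool], labels: dict[str, bool]) -> ConfusionMetrics:
    """Confusion counts of in-silico risky/safe calls against clinical labels.

    ``predictions`` and ``labels`` map compound name to True (risky).
    Every predicted compound must have a label.
    """
    missing = sorted(set(predictions) - set(labels))
    if missing:
        raise ValueError(f"clinical label missing for: {missing}")
    tp = tn = fp = fn = 0
    for name, pred in predictions.items():
        truth = labels[name]
        if pred and truth:
            tp += 1
        elif not pred and not truth:
            tn += 1
        elif pred and not truth:
            fp += 1
        else:
            fn += 1
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def _predictions(results: list[TrialResult], corrected: bool = False) -> dict[str, bool]:
    if corrected:
        return {r.compound: r.tdp_score_corrected > 0 for r in results}
    return {r.compound: r.tdp_score > 0 for r in results}


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def capped_score(result: TrialResult, cap: float, corrected: bool = False) -> float:
    """Recompute a compound's score using only concentrations <= cap,
    re-normalizing the weight sum over the retained concentrations."""
    plan = ConcentrationPlan(result.multiples).capped(cap)
    counts = result.n_ra_corrected if corrected else result.n_ra
    kept = [c for m, c in zip(result.multiples, counts) if m <= cap]
    return tdp_score(kept, result.n_models, plan)


def concentration_cap_experiment(results: list[TrialResult], cap: float,
                                 labels: dict[str, bool] | None = None,
                                 corrected: bool = False):
    """Scores and classifications under a reduced maximum test concentration.

    Returns ``(scores, metrics)`` where ``scores`` maps compound to its
    re-normalized capped score and ``metrics`` is the ConfusionMetrics
    against ``labels`` (None when labels are not supplied).
    """
    scores = {r.compound: capped_score(r, cap, corrected) for r in results}
    cm = None
    if labels is not None:
        cm = confusion({k: v > 0 for k, v in scores.items()}, labels)
    return scores, cm


def channel_subset_experiment(drugs: list[DrugProfile], population,
                              subsets, plan: ConcentrationPlan | None = None,
                              protocol=None, solver: str = "rl",
                              labels: dict[str, bool] | None = None):
    """One full trial of every drug per channel subset.

    Returns ``{subset_name: (results, metrics)}`` plus a paired score table
    under the key ``"scores"`` (compound x subset).
    """
    out = {}
    table = {}
    for subset in subsets:
        subset = ChannelSubset(subset)
        results = [run_trial(d, population, plan, subset, protocol, solver)
                   for d in drugs]
        cm = confusion(_predictions(results), labels) if labels is not None else None
        out[subset.name] = (results, cm)
        table[subset.name] = {r.compound: r.tdp_score for r in results}
    out["scores"] = pd.DataFrame(table)
    return out


def score_apd_correlation(results: list[TrialResult],
                          control: pd.DataFrame,
                          multiple: float = 1.0,
                          aggregate: str = "median"):
    """Correlation between TdP score and APD90 prolongation at a low dose.

    DAPD per compound aggregates (APD90_drug - APD90_control) over the
    models with a defined APD90 in both conditions and no RA at the chosen
    multiple. Returns ``(r_squared, table)``; ``r_squared`` is None when
    either variable has zero variance.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 compounds for a correlation")
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    ctrl = control.set_index("model_id")["apd90_ms"]
    rows = []
    for r in results:
        det = r.detail
        at_m = det[(det.multiple == multiple) & det.ok & ~det.ra]
        deltas = []
        for _, cell in at_m.iterrows():
            base = ctrl.get(cell.model_id)
            if cell.apd90_ms is not None and not pd.isna(cell.apd90_ms) \
                    and base is not None and not pd.isna(base):
                deltas.append(cell.apd90_ms - base)
        agg = (np.median(deltas) if aggregate == "median" else np.mean(deltas)) \
            if deltas else np.nan
        rows.append({"compound": r.compound, "tdp_score": r.tdp_score,
                     "delta_apd90_ms": agg})
    table = pd.DataFrame(rows)
    ok = table.dropna()
    if len(ok) < 3:
        raise ValueError("fewer than 3 compounds with a defined DAPD")
    x, y = ok.tdp_score.to_numpy(), ok.delta_apd90_ms.to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, table
    from scipy.stats import pearsonr
    r, _ = pearsonr(x, y)
    return float(r * r), table


def score_floor_for_plot(score: float) -> float:
    """Clamp a score to the 1e-16 visualization floor for log-scale plots.

    Rendering only — classification never uses the floored value.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    return max(score, PLOT_FLOOR)


def read_labels(path) -> dict[str, bool]:
    """Read a clinical-label CSV (`compound,clinical_risky[,...]`); the
    label column accepts 1/0, true/false, risky/safe."""
    df = pd.read_csv(path)
    for col in ("compound", "clinical_risky"):
        if col not in df.columns:
            raise ValueError(f"labels CSV missing column {col!r}")
    truthy = {"1", "true", "yes", "risky"}
    falsy = {"0", "false", "no", "safe"}
    out = {}
    for _, row in df.iterrows():
        raw = str(row["clinical_risky"]).strip().lower()
        if raw in truthy:
            val = True
        elif raw in falsy:
            val = False
        else:
            raise ValueError(f"unrecognized label {row['clinical_risky']!r} "
                             f"for {row['compound']}")
        out[str(row["compound"])] = val
    return out


def summary_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Per-compound summary table, ranked by decreasing score."""
    rows = []
    for r in results:
        rows.append({
            "compound": r.compound,
            "dataset": r.dataset_tag,
            "tdp_score": r.tdp_score,
            "tdp_score_corrected": r.tdp_score_corrected,
            "risky": r.tdp_score > 0,
            "n_models": r.n_models,
            **{f"nRA_{m:g}x": n for m, n in zip(r.multiples, r.n_ra)},
            "failed_models": ";".join(r.failed_models),
        })
    return (pd.DataFrame(rows)
            .sort_values("tdp_score", ascending=False)
            .reset_index(drop=True))
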