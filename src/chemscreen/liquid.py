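"""Growth-curve validation in liquid medium: AUC fitness and interaction calls.

Stage 2.  Candidate hits from the solid screen are regrown in microplates
(OD600 every 15 min for 24 h) in paired media with and without the compound,
in biological triplicate across two independent experiments.  Fitness is the
area under the growth curve normalized so the wild type in plain medium has
fitness 1.  Interactions are scored against the multiplicative model

    epsilon = W_ij - W_i * W_j

with W_i the wild-type fitness under drug, W_j the mutant fitness in plain
medium and W_ij the mutant fitness under drug.  A strain is called negative
when its mean epsilon is below -0.1 with Welch p <= 0.05 in *both*
experiments (positive symmetrically above +0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .stats import one_sample_t_test, trapezoid_auc, welch_t_test

__all__ = [
    "GrowthCurve",
    "read_plate_reader",
    "curve_fitness",
    "interaction_score",
    "score_strain_experiment",
    "call_interactions",
    "analyze_validation",
    "select_dose",
]

WELL_MAP_COLUMNS = ("well", "strain", "drug", "concentration", "replicate", "experiment")


@dataclass
class GrowthCurve:
    """One well's OD600 time series with its condition metadata."""

    strain_id: str
    drug: str | None
    concentration: float
    replicate: int
    experiment: int
    times: np.ndarray
    od600: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.size != self.od600.size:
            raise InvalidInputError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")

    @property
    def auc(self) -> float:
        """Empirical trapezoidal AUC of the (possibly baseline-corrected) curve."""
        return trapezoid_auc(self.times, self.od600)


def subtract_baseline(curves: Sequence["GrowthCurve"]) -> list["GrowthCurve"]:
    """Subtract each curve's first OD reading (per-well blank), flooring at 0."""
    return [
        GrowthCurve(
            c.strain_id,
            c.drug,
            c.concentration,
            c.replicate,
            c.experiment,
            c.times,
            np.maximum(c.od600 - c.od600[0], 0.0),
            dict(c.meta),
        )
        for c in curves
    ]


def _normalize_drug(value) -> str | None:
    if pd.isna(value) or str(value).strip().lower() in ("", "none", "na"):
        return None
    return str(value)


def read_plate_reader(
    curves_csv: str | Path,
    well_map: str | Path | pd.DataFrame,
    time_column: str = "time",
    subtract_t0: bool = True,
) -> list[GrowthCurve]:
    """Read a wide plate-reader CSV (time column + one column per well).

    ``well_map`` maps each well to (strain, drug, concentration, replicate,
    experiment); extra columns (e.g. ``vector`` for overexpression plasmids)
    are carried along in ``GrowthCurve.meta``.  Ragged rows and unmapped
    wells are errors.  By default each curve's first OD reading is subtracted
    (floored at 0) as a per-well blank.
    """
    data = pd.read_csv(curves_csv)
    if time_column not in data.columns:
        raise InvalidInputError(f"curves file lacks time column {time_column!r}")
    if data.isna().any().any():
        raise InvalidInputError("curves file has missing values (ragged rows?)")
    times = data[time_column].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("time column must be strictly increasing")
    steps = np.diff(times)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError("time grid must be uniform")

    if not isinstance(well_map, pd.DataFrame):
        well_map = pd.read_csv(well_map, sep="\t")
    missing = set(WELL_MAP_COLUMNS) - set(well_map.columns)
    if missing:
        raise InvalidInputError(f"well map missing columns {sorted(missing)}")
    wm = well_map.set_index("well")
    extra_cols = [c for c in well_map.columns if c not in WELL_MAP_COLUMNS]

    wells = [c for c in data.columns if c != time_column]
    unmapped = sorted(set(wells) - set(wm.index.astype(str)))
    if unmapped:
        raise InvalidInputError(f"wells without map entry: {unmapped}")

    curves = []
    for well in wells:
        od = data[well].to_numpy(dtype=float)
        if subtract_t0:
            od = np.maximum(od - od[0], 0.0)
        row = wm.loc[well]
        curves.append(
            GrowthCurve(
                strain_id=str(row["strain"]),
                drug=_normalize_drug(row["drug"]),
                concentration=float(row["concentration"]),
                replicate=int(row["replicate"]),
                experiment=int(row["experiment"]),
                times=times,
                od600=od,
                meta={"well": well, **{c: row[c] for c in extra_cols}},
            )
        )
    return curves


def curve_fitness(aucs: Sequence[float], reference_auc: float) -> np.ndarray:
    """Fitness = AUC / reference AUC (wild type in plain medium)."""
    if not reference_auc > 0:
        raise InvalidInputError("reference AUC must be positive")
    a = np.asarray(aucs, dtype=float)
    if np.any(a < 0):
        raise InvalidInputError("AUC values must be >= 0")
    return a / reference_auc


def interaction_score(w_i: float, w_j: float, w_ij: float) -> float:
    """Multiplicative-model interaction score epsilon = W_ij - W_i * W_j."""
    if w_i < 0 or w_j < 0 or w_ij < 0:
        raise InvalidInputError("fitness values must be >= 0")
    return float(w_ij - w_i * w_j)


def score_strain_experiment(
    wt_drug_fitness: Sequence[float],
    mut_plain_fitness: Sequence[float],
    mut_drug_fitness: Sequence[float],
    method: Literal["two_sample", "one_sample"] = "two_sample",
) -> tuple[np.ndarray, float, float]:
    """Per-replicate epsilon and Welch p-value for one strain in one experiment.

    Replicate k of the observed mutant-in-drug fitness is paired with the
    expected product W_i^(k) * W_j^(k).  The default test compares the
    replicate observed values with the replicate expected products
    (two-sample Welch); ``method='one_sample'`` instead tests the replicate
    epsilons against zero.
    """
    w_i = np.asarray(wt_drug_fitness, dtype=float)
    w_j = np.asarray(mut_plain_fitness, dtype=float)
    w_ij = np.asarray(mut_drug_fitness, dtype=float)
    if not (w_i.size == w_j.size == w_ij.size):
        raise InvalidInputError("replicate sets must have equal size")
    if w_i.size < 2:
        raise InvalidInputError("need >= 2 replicates per experiment")
    expected = w_i * w_j
    eps = w_ij - expected
    if method == "one_sample":
        p = one_sample_t_test(eps, 0.0).p_value
    else:
        p = welch_t_test(w_ij, expected).p_value
    return eps, float(eps.mean()), p


def call_interactions(
    per_experiment: pd.DataFrame,
    neg_thresh: float = -0.1,
    pos_thresh: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine per-experiment scores into one call per strain.

    ``per_experiment`` needs columns strain, experiment, eps_mean, p_value.
    A strain is negative iff *every* experiment has mean epsilon strictly
    below ``neg_thresh`` with p <= alpha (positive symmetrically); otherwise
    none.  The intersection rule never calls a strain that a single
    experiment alone would not.
    """
    required = {"strain", "experiment", "eps_mean", "p_value"}
    if not required <= set(per_experiment.columns):
        raise InvalidInputError(f"per-experiment table needs columns {sorted(required)}")
    rows = []
    for strain, sub in per_experiment.groupby("strain"):
        neg = bool(((sub["eps_mean"] < neg_thresh) & (sub["p_value"] <= alpha)).all())
        pos = bool(((sub["eps_mean"] > pos_thresh) & (sub["p_value"] <= alpha)).all())
        call = "negative" if neg else ("positive" if pos else "none")
        rows.append((strain, len(sub), call))
    return pd.DataFrame(rows, columns=["strain", "n_experiments", "combined_call"])


def analyze_validation(
    curves: Sequence[GrowthCurve],
    wt_strain: str,
    drug: str,
    neg_thresh: float = -0.1,
    pos_thresh: float = 0.1,
    alpha: float = 0.05,
    method: Literal["two_sample", "one_sample"] = "two_sample",
) -> pd.DataFrame:
    """Full liquid-validation analysis from growth curves to combined calls.

    Within each experiment, the reference AUC is the mean wild-type AUC in
    plain medium, so the wild type's mean plain-medium fitness is 1 by
    construction.  Returns one row per (strain, experiment) plus the combined
    call per strain, with columns strain, drug, experiment, w_j_mean,
    w_ij_mean, eps_mean, p_value, experiment_call, combined_call.
    """
    frame = pd.DataFrame(
        {
            "strain": [c.strain_id for c in curves],
            "drug": [c.drug for c in curves],
            "experiment": [c.experiment for c in curves],
            "replicate": [c.replicate for c in curves],
            "auc": [c.auc for c in curves],
        }
    )
    relevant = frame[frame["drug"].isna() | (frame["drug"] == drug)]
    per_exp_rows = []
    for exp, sub in relevant.groupby("experiment"):
        wt_plain = sub[(sub["strain"] == wt_strain) & (sub["drug"].isna())]
        if wt_plain.empty:
            raise InvalidInputError(f"experiment {exp}: no wild-type plain-medium curves")
        ref = wt_plain["auc"].mean()
        sub = sub.copy()
        sub["fitness"] = curve_fitness(sub["auc"].to_numpy(), ref)

        def reps(strain: str, with_drug: bool) -> pd.Series:
            sel = sub[(sub["strain"] == strain) & (sub["drug"].notna() == with_drug)]
            return sel.sort_values("replicate").set_index("replicate")["fitness"]

        w_i = reps(wt_strain, True)
        if w_i.size < 2:
            raise InvalidInputError(f"experiment {exp}: need >= 2 wild-type drug replicates")
        for strain in sorted(sub["strain"].unique()):
            w_j = reps(strain, False)
            w_ij = reps(strain, True)
            shared = w_i.index.intersection(w_j.index).intersection(w_ij.index)
            if len(shared) < 2:
                per_exp_rows.append((strain, drug, exp, np.nan, np.nan, np.nan, np.nan, "uncallable"))
                continue
            eps, eps_mean, p = score_strain_experiment(
                w_i.loc[shared], w_j.loc[shared], w_ij.loc[shared], method=method
            )
            exp_call = "none"
            if eps_mean < neg_thresh and p <= alpha:
                exp_call = "negative"
            elif eps_mean > pos_thresh and p <= alpha:
                exp_call = "positive"
            per_exp_rows.append(
                (strain, drug, exp, float(w_j.loc[shared].mean()), float(w_ij.loc[shared].mean()), eps_mean, p, exp_call)
            )
    per_exp = pd.DataFrame(
        per_exp_rows,
        columns=["strain", "drug", "experiment", "w_j_mean", "w_ij_mean", "eps_mean", "p_value", "experiment_call"],
    )
    callable_ = per_exp[per_exp["experiment_call"] != "uncallable"]
    combined = call_interactions(callable_, neg_thresh, pos_thresh, alpha)
    out = per_exp.merge(combined[["strain", "combined_call"]], on="strain", how="left")
    out["combined_call"] = out["combined_call"].fillna("uncallable")
    return out


def select_dose(dose_response: Mapping[float, float], target_drop: float = 0.4) -> float:
    """Dose whose wild-type fitness is nearest 1 - target_drop (ties: lower dose)."""
    if not dose_response:
        raise InvalidInputError("empty dose-response map")
    target = 1.0 - target_drop
    return min(dose_response, key=lambda d: (abs(dose_response[d] - target), d))
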