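"""Overexpression suppression analysis: AUC ratios versus an empty-vector control.

Stage 3.  Genes whose loss sensitizes cells to the compound are overexpressed
from an inducible plasmid and grown in triplicate with and without drug.  The
per-replicate ratio AUC(drug)/AUC(no drug) is compared with the same ratio
for the empty-vector control strain; a gene is a suppressor when its mean
ratio is at least twofold the control's and the Benjamini–Hochberg-corrected
Welch p-value is <= 0.05.  Overexpression that slows growth even without
drug is flagged separately as a growth cost.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .liquid import GrowthCurve
from .stats import bh_adjust, welch_t_test

__all__ = [
    "auc_ratio",
    "call_suppressors",
    "flag_growth_cost",
    "analyze_suppression",
]


def auc_ratio(auc_drug: Sequence[float], auc_plain: Sequence[float]) -> np.ndarray:
    """Per-replicate AUC(drug)/AUC(no drug), paired by replicate index."""
    d = np.asarray(auc_drug, dtype=float)
    p = np.asarray(auc_plain, dtype=float)
    if d.size != p.size:
        raise InvalidInputError("drug and plain replicate sets must have equal size")
    if d.size == 0:
        raise InvalidInputError("empty replicate sets")
    if np.any(p <= 0):
        raise InvalidInputError("plain-medium AUC must be positive")
    if np.any(d < 0):
        raise InvalidInputError("AUC values must be >= 0")
    return d / p


def flag_growth_cost(
    strain_plain_auc: Sequence[float] | float,
    control_plain_auc: Sequence[float] | float,
    frac: float = 0.8,
) -> bool:
    """True when the strain grows below ``frac`` of the control without drug."""
    s = float(np.mean(strain_plain_auc))
    c = float(np.mean(control_plain_auc))
    if c <= 0:
        raise InvalidInputError("control plain-medium AUC must be positive")
    return s < frac * c


def call_suppressors(
    gene_ratios: Mapping[str, Sequence[float]],
    control_ratios: Sequence[float],
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    plain_aucs: Mapping[str, Sequence[float]] | None = None,
    control_plain_auc: Sequence[float] | None = None,
    growth_cost_frac: float = 0.8,
) -> pd.DataFrame:
    """Suppressor calls for a batch of overexpression strains.

    For each gene: fold = mean ratio / mean control ratio; p from a Welch
    test of the per-replicate ratios against the control's; BH adjustment
    across all genes in the batch.  Suppressor iff fold >= ``fold_threshold``
    and adjusted p <= ``alpha``.  When plain-medium AUCs are supplied the
    growth-cost flag is evaluated too.
    """
    ctrl = np.asarray(control_ratios, dtype=float)
    if ctrl.size < 2:
        raise InvalidInputError("need >= 2 control replicate ratios")
    ctrl_mean = ctrl.mean()
    if ctrl_mean <= 0:
        raise InvalidInputError("control mean ratio must be positive")
    genes = sorted(gene_ratios)
    if not genes:
        raise InvalidInputError("no genes to call")
    rows = []
    for g in genes:
        r = np.asarray(gene_ratios[g], dtype=float)
        if r.size < 2:
            raise InvalidInputError(f"gene {g}: need >= 2 replicate ratios")
        mean_ratio = r.mean()
        fold = mean_ratio / ctrl_mean
        p = welch_t_test(r, ctrl).p_value
        rows.append((g, mean_ratio, fold, p))
    out = pd.DataFrame(rows, columns=["gene", "mean_ratio", "fold_vs_control", "p_value"])
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out["suppressor"] = (out["fold_vs_control"] >= fold_threshold) & (out["p_adj"] <= alpha)
    if plain_aucs is not None:
        if control_plain_auc is None:
            raise InvalidInputError("control plain-medium AUCs required for growth-cost flag")
        out["growth_cost"] = [
            flag_growth_cost(plain_aucs[g], control_plain_auc, frac=growth_cost_frac)
            if g in plain_aucs
            else False
            for g in out["gene"]
        ]
    else:
        out["growth_cost"] = False
    return out


def analyze_suppression(
    curves: Sequence[GrowthCurve],
    drug: str,
    control_vector: str = "empty",
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    growth_cost_frac: float = 0.8,
) -> pd.DataFrame:
    """Suppression analysis straight from growth curves.

    Curves must carry a ``vector`` entry in ``meta`` distinguishing gene
    plasmids from the empty-vector control; the strain id is the
    overexpressed gene.  Ratios are paired by replicate within each strain.
    """
    frame = pd.DataFrame(
        {
            "gene": [c.strain_id for c in curves],
            "vector": [c.meta.get("vector") for c in curves],
            "drug": [c.drug for c in curves],
            "replicate": [c.replicate for c in curves],
            "auc": [c.auc for c in curves],
        }
    )
    if frame["vector"].isna().any():
        raise InvalidInputError("every curve needs a 'vector' entry in meta")
    is_drug = frame["drug"] == drug

    def ratios_of(sub: pd.DataFrame) -> np.ndarray:
        d = sub[is_drug.reindex(sub.index)].sort_values("replicate")
        p = sub[~is_drug.reindex(sub.index)].sort_values("replicate")
        shared = np.intersect1d(d["replicate"], p["replicate"])
        if shared.size < 2:
            raise InvalidInputError("need >= 2 paired replicates per strain")
        d = d.set_index("replicate").loc[shared, "auc"].to_numpy()
        p = p.set_index("replicate").loc[shared, "auc"].to_numpy()
        return auc_ratio(d, p)

    control = frame[frame["vector"] == control_vector]
    if control.empty:
        raise InvalidInputError(f"no control curves with vector {control_vector!r}")
    control_ratios = ratios_of(control)
    control_plain = control[~is_drug.reindex(control.index)]["auc"].to_numpy()

    gene_ratios: dict[str, np.ndarray] = {}
    plain_aucs: dict[str, np.ndarray] = {}
    for gene, sub in frame[frame["vector"] != control_vector].groupby("gene"):
        gene_ratios[gene] = ratios_of(sub)
        plain_aucs[gene] = sub[~is_drug.reindex(sub.index)]["auc"].to_numpy()
    return call_suppressors(
        gene_ratios,
        control_ratios,
        fold_threshold=fold_threshold,
        alpha=alpha,
        plain_aucs=plain_aucs,
        control_plain_auc=control_plain,
        growth_cost_frac=growth_cost_frac,
    )
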