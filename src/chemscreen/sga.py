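"""Simplified synthetic-genetic-array (SGA) scoring of double mutants.

Stage 4.  Validated drug-sensitive alleles are arrayed in quadruplicate,
surrounded by a neutral his3-delta control strain, and crossed to a query
carrying either a wild-type tRNA or a mistranslating tRNA variant.  Each
plate is normalized by the mean colony size of the embedded control strain
(mitigating plate and nutrient effects), and the interaction score for an
array allele follows the multiplicative expectation

    score = mean(double-mutant fitness) - Q * mean(control-query fitness)

where Q is the query single-mutant fitness (the mistranslating tRNA alone
costs ~20% growth, so Q defaults to 0.8).  An allele is called synthetic
(negative) when score <= -0.1 with BH-corrected Welch p <= 0.05 across the
array.  Unlike full SGA software, no row/column/spatial corrections are
applied beyond the control-strain plate normalization.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colony import PlateColonyGrid, collapse_quadruplicates
from .errors import InvalidInputError
from .stats import bh_adjust, welch_t_test

__all__ = ["normalize_sga_plate", "score_sga", "score_array", "analyze_sga"]


def normalize_sga_plate(grid: PlateColonyGrid, control_strain: str) -> pd.Series:
    """Per-strain fitness: quadruplicate colony mean / plate-wide control mean."""
    collapsed = collapse_quadruplicates(grid)
    control = grid.wells[grid.wells["strain"] == control_strain]["size"].dropna()
    if control.empty:
        raise InvalidInputError(
            f"plate {grid.plate_id}: no colonies of control strain {control_strain!r}"
        )
    ref = control.mean()
    if ref <= 0:
        raise InvalidInputError(f"plate {grid.plate_id}: control colonies have zero size")
    return collapsed["size"] / ref


def score_sga(
    double_fitness: Sequence[float],
    reference_fitness: Sequence[float],
    q: float = 0.8,
) -> tuple[float, float]:
    """Score one allele: (score, Welch p) from replicate fitness sets.

    ``double_fitness`` is the allele's normalized fitness under the
    mistranslating query across arrays; ``reference_fitness`` under the
    wild-type-tRNA control query.  The Welch test compares the observed
    double-mutant replicates with the replicate multiplicative expectations
    Q * reference.
    """
    d = np.asarray(double_fitness, dtype=float)
    r = np.asarray(reference_fitness, dtype=float)
    if d.size < 2 or r.size < 2:
        raise InvalidInputError("need >= 2 replicates in each query")
    score = float(d.mean() - q * r.mean())
    p = welch_t_test(d, q * r).p_value
    return score, p


def score_array(
    double: Mapping[str, Sequence[float]],
    reference: Mapping[str, Sequence[float]],
    q: float = 0.8,
    neg_thresh: float = -0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every array allele and call synthetic interactions.

    p-values are BH-adjusted across the array.  Alleles missing from the
    control query are reported uncallable.  Call = negative iff
    score <= ``neg_thresh`` and adjusted p <= ``alpha``.
    """
    alleles = sorted(double)
    rows = []
    for a in alleles:
        if a not in reference or len(reference[a]) < 2 or len(double[a]) < 2:
            rows.append((a, np.nan, np.nan, np.nan, False))
            continue
        d = np.asarray(double[a], dtype=float)
        score, p = score_sga(d, reference[a], q=q)
        rows.append((a, float(d.mean()), score, p, True))
    out = pd.DataFrame(
        rows, columns=["allele", "double_fitness_mean", "sga_score", "p_value", "callable"]
    )
    out["p_adj"] = np.nan
    mask = out["callable"]
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
    out["call"] = "none"
    out.loc[
        mask & (out["sga_score"] <= neg_thresh) & (out["p_adj"] <= alpha), "call"
    ] = "negative"
    out.loc[~mask, "call"] = "uncallable"
    return out


def analyze_sga(
    query_grids: Sequence[PlateColonyGrid],
    control_grids: Sequence[PlateColonyGrid],
    control_strain: str = "his3D",
    q: float = 0.8,
    neg_thresh: float = -0.1,
    alpha: float = 0.05,
    exclude_control: bool = True,
) -> pd.DataFrame:
    """Score an SGA experiment from its plates.

    ``query_grids`` are the arrays mated to the mistranslating query (one
    grid per array replicate); ``control_grids`` the same arrays under the
    wild-type-tRNA query.  Each plate is normalized by its embedded control
    strain, replicate fitness values are collected per allele across arrays
    and scored against the multiplicative expectation.
    """
    if not query_grids or not control_grids:
        raise InvalidInputError("need at least one query and one control plate")

    def collect(grids: Sequence[PlateColonyGrid]) -> dict[str, list[float]]:
        per_allele: dict[str, list[float]] = {}
        for g in grids:
            fitness = normalize_sga_plate(g, control_strain)
            for allele, f in fitness.items():
                if exclude_control and allele == control_strain:
                    continue
                per_allele.setdefault(str(allele), []).append(float(f))
        return per_allele

    return score_array(
        collect(query_grids), collect(control_grids), q=q, neg_thresh=neg_thresh, alpha=alpha
    )
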