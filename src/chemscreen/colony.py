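"""Arrayed colony screen: per-plate fitness, filtering, Z-normalization, hit calls.

Stage 1 of the pipeline.  Mutant collections are pinned in quadruplicate
(2x2 blocks, 1536-colony format = 32 rows x 48 columns) onto paired plates
with and without the compound.  Per strain, fitness is the ratio

    W = colony size with drug / colony size without drug

computed from the quadruplicate means.  Strains whose drug-free colony size
is below 5% of the plate average are removed (dead/slow class), fitness is
Z-normalized per plate, alleles of the same gene are grouped to a single
Z-score, and genes are called positive (Z >= +3, toxicity suppressed) or
negative (Z <= -1.5, drug-sensitized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePlateError, InvalidInputError
from .stats import zscore

__all__ = [
    "StrainAllele",
    "PlateColonyGrid",
    "read_plate_tables",
    "read_plate_table",
    "read_annotations",
    "collapse_quadruplicates",
    "filter_small_colonies",
    "compute_fitness",
    "normalize_plate",
    "group_alleles",
    "run_colony_screen",
]

PLATE_COLUMNS = ("plate", "row", "col", "strain", "size")
ANNOTATION_COLUMNS = ("strain", "gene", "allele", "collection", "essential", "category")


@dataclass(frozen=True)
class StrainAllele:
    """Annotation of one arrayed strain."""

    strain_id: str
    gene: str
    allele: str
    collection: Literal["deletion", "temperature_sensitive"]
    essential: bool = False
    category: str | None = None


@dataclass
class PlateColonyGrid:
    """One arrayed plate of colony sizes.

    ``wells`` has columns row, col (1-based), strain, size and is_border
    (outermost ring of positions, classically affected by edge effects).
    """

    plate_id: str
    n_rows: int
    n_cols: int
    wells: pd.DataFrame
    drug: str | None = None
    concentration: float = 0.0

    def __post_init__(self) -> None:
        w = self.wells
        missing = {"row", "col", "strain", "size"} - set(w.columns)
        if missing:
            raise InvalidInputError(f"wells table missing columns: {sorted(missing)}")
        if w.duplicated(["row", "col"]).any():
            dup = w[w.duplicated(["row", "col"], keep=False)][["row", "col"]]
            raise InvalidInputError(
                f"duplicate well positions on plate {self.plate_id}: "
                f"{dup.drop_duplicates().to_records(index=False).tolist()}"
            )
        bad = (w["row"] < 1) | (w["row"] > self.n_rows) | (w["col"] < 1) | (w["col"] > self.n_cols)
        if bad.any():
            raise InvalidInputError(f"well positions outside {self.n_rows}x{self.n_cols} grid")
        if (w["size"] < 0).any():
            raise InvalidInputError("colony sizes must be >= 0")
        if "is_border" not in w.columns:
            w = w.copy()
            w["is_border"] = (
                (w["row"] == 1)
                | (w["row"] == self.n_rows)
                | (w["col"] == 1)
                | (w["col"] == self.n_cols)
            )
            self.wells = w


def _read_tsv(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    missing = set(required) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{label} {path}: missing columns {sorted(missing)}")
    return df


def read_plate_tables(
    path: str | Path,
    n_rows: int | None = None,
    n_cols: int | None = None,
    drug: str | None = None,
    concentration: float = 0.0,
) -> list[PlateColonyGrid]:
    """Read a colony-size TSV (plate, row, col, strain, size) into grids.

    Grid dimensions default to the maximum observed row/column per plate.
    Malformed rows are reported with their 1-based file line numbers.
    """
    df = _read_tsv(path, PLATE_COLUMNS, "plate table")
    bad_lines: list[int] = []
    for col in ("row", "col", "size"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((df.index[numeric.isna()] + 2).tolist())
        df[col] = numeric
    bad_lines.extend((df.index[df["strain"].isna()] + 2).tolist())
    if bad_lines:
        raise InvalidInputError(f"malformed rows at lines {sorted(set(bad_lines))}")
    if ((df["row"] % 1) != 0).any() or ((df["col"] % 1) != 0).any():
        raise InvalidInputError("row/col must be integers")
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)

    grids = []
    for plate_id, sub in df.groupby("plate", sort=True):
        nr = n_rows or int(sub["row"].max())
        nc = n_cols or int(sub["col"].max())
        wells = sub[["row", "col", "strain", "size"]].reset_index(drop=True)
        grids.append(
            PlateColonyGrid(str(plate_id), nr, nc, wells, drug=drug, concentration=concentration)
        )
    return grids


def read_plate_table(path: str | Path, **kwargs) -> PlateColonyGrid:
    """Read a single-plate colony TSV; error if the file holds several plates."""
    grids = read_plate_tables(path, **kwargs)
    if len(grids) != 1:
        raise InvalidInputError(f"{path} contains {len(grids)} plates, expected 1")
    return grids[0]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the strain annotation TSV (strain, gene, allele, collection, essential, category)."""
    df = _read_tsv(path, ANNOTATION_COLUMNS[:5], "annotation table")
    if "category" not in df.columns:
        df["category"] = None
    if df["strain"].duplicated().any():
        raise InvalidInputError("duplicate strain ids in annotation table")
    df["essential"] = df["essential"].astype(bool)
    return df


def collapse_quadruplicates(
    grid: PlateColonyGrid, stat: Literal["mean", "median"] = "mean"
) -> pd.DataFrame:
    """Collapse replicate colonies to one size per strain.

    Returns a DataFrame indexed by strain with columns ``size`` (mean of the
    non-missing replicate colonies by default; median by config),
    ``n_colonies`` and ``is_border`` (True when any replicate sits on the
    outermost ring).  Strains with no measurable colony yield no row.
    """
    if stat not in ("mean", "median"):
        raise InvalidInputError(f"unknown replicate statistic {stat!r}")
    w = grid.wells.dropna(subset=["size"])
    if w.empty:
        raise InvalidInputError(f"plate {grid.plate_id} has no colonies")
    agg = w.groupby("strain").agg(
        size=("size", stat),
        n_colonies=("size", "size"),
        is_border=("is_border", "any"),
    )
    return agg


def filter_small_colonies(control_sizes: pd.Series, frac: float = 0.05) -> set[str]:
    """Strains growing below ``frac`` of the average drug-free colony size.

    The threshold is strict: a strain exactly at 5% of the plate mean is
    retained.  The plate average is taken over all non-missing strains.
    """
    s = control_sizes.dropna()
    if s.empty:
        raise InvalidInputError("empty plate: no control colony sizes")
    threshold = frac * s.mean()
    return set(s.index[s < threshold])


def compute_fitness(
    control: pd.DataFrame,
    drug: pd.DataFrame,
    excluded: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-strain fitness ratios W = drug size / control size.

    ``control`` and ``drug`` are collapsed per-strain tables
    (:func:`collapse_quadruplicates`).  Strains present in only one condition
    are kept as records excluded with reason ``missing``; strains in
    ``excluded`` (small-colony filter) carry reason ``small_colony``.
    """
    excluded = set(excluded)
    strains = sorted(set(control.index) | set(drug.index))
    rows = []
    for s in strains:
        c = control["size"].get(s, np.nan)
        d = drug["size"].get(s, np.nan)
        border = bool(control["is_border"].get(s, False) or drug["is_border"].get(s, False))
        if s in excluded:
            reason = "small_colony"
        elif np.isnan(c) or np.isnan(d):
            reason = "missing"
        else:
            reason = "none"
        w = d / c if reason == "none" and c > 0 else np.nan
        if reason == "none" and not (c > 0):
            # cannot happen after the small-colony filter, but guard anyway
            reason = "small_colony"
        rows.append((s, c, d, w, reason != "none", reason, border))
    return pd.DataFrame(
        rows,
        columns=[
            "strain",
            "control_size",
            "drug_size",
            "fitness_W",
            "excluded",
            "exclusion_reason",
            "is_border",
        ],
    )


def normalize_plate(
    records: pd.DataFrame,
    include_border: bool = False,
    ddof: int = 1,
    min_retained: int = 10,
) -> pd.DataFrame:
    """Z-normalize fitness per plate: retained strains get mean 0, sd 1.

    Border strains are excluded from the plate mean/SD estimate by default
    (edge effects) but still receive a Z-score on the same scale.  A plate
    with zero spread marks every record excluded with reason
    ``degenerate_plate``.
    """
    rec = records.copy()
    retained = ~rec["excluded"]
    basis = retained & (include_border | ~rec["is_border"])
    if int(basis.sum()) < min_retained:
        raise InvalidInputError(
            f"only {int(basis.sum())} retained strains; need >= {min_retained} to normalize"
        )
    w_basis = rec.loc[basis, "fitness_W"].to_numpy()
    rec["z_score"] = np.nan
    try:
        zscore(w_basis, ddof=ddof)
    except DegeneratePlateError:
        rec.loc[retained, "excluded"] = True
        rec.loc[retained, "exclusion_reason"] = "degenerate_plate"
        return rec
    mean, sd = w_basis.mean(), w_basis.std(ddof=ddof)
    rec.loc[retained, "z_score"] = (rec.loc[retained, "fitness_W"] - mean) / sd
    return rec


def group_alleles(
    records: pd.DataFrame,
    annotations: pd.DataFrame | Iterable[StrainAllele],
    rule: Literal["mean", "min"] = "mean",
    z_pos: float = 3.0,
    z_neg: float = -1.5,
) -> pd.DataFrame:
    """Group alleles of the same gene to one Z-score and call hits.

    Multi-allele genes (ts alleles of essential genes) are summarized by the
    mean allele Z-score by default (``rule='min'`` takes the most negative).
    Calls: positive iff grouped Z >= ``z_pos``; negative iff grouped Z <=
    ``z_neg``.  Unannotated strains fall back to their own id as gene with a
    warning.
    """
    if rule not in ("mean", "min"):
        raise InvalidInputError(f"unknown grouping rule {rule!r}")
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.DataFrame([a.__dict__ for a in annotations]).rename(
            columns={"strain_id": "strain"}
        )
    gene_of = dict(zip(annotations["strain"], annotations["gene"]))
    scored = records.dropna(subset=["z_score"]).copy()
    unknown = sorted(set(scored["strain"]) - set(gene_of))
    if unknown:
        warnings.warn(
            f"{len(unknown)} strains lack annotation; using strain id as gene", stacklevel=2
        )
    scored["gene"] = scored["strain"].map(lambda s: gene_of.get(s, s))
    agg = scored.groupby("gene").agg(
        grouped_z=("z_score", rule),
        member_alleles=("strain", lambda s: sorted(s)),
        n_alleles=("strain", "size"),
    )
    agg = agg.reset_index()
    agg["call"] = "none"
    agg.loc[agg["grouped_z"] >= z_pos, "call"] = "positive"
    agg.loc[agg["grouped_z"] <= z_neg, "call"] = "negative"
    return agg


def run_colony_screen(
    control_grids: Sequence[PlateColonyGrid],
    drug_grids: Sequence[PlateColonyGrid],
    annotations: pd.DataFrame,
    small_colony_frac: float = 0.05,
    replicate_stat: Literal["mean", "median"] = "mean",
    grouping_rule: Literal["mean", "min"] = "mean",
    z_pos: float = 3.0,
    z_neg: float = -1.5,
    include_border: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end solid-medium screen: fitness records and gene-level hits.

    Control and drug grids are paired by ``plate_id``.  Returns
    ``(fitness, hits)``: the per-strain fitness/Z table across all plates and
    the per-gene grouped calls.
    """
    by_id_c = {g.plate_id: g for g in control_grids}
    by_id_d = {g.plate_id: g for g in drug_grids}
    common = sorted(set(by_id_c) & set(by_id_d))
    if not common:
        raise InvalidInputError("no plate ids shared between control and drug grids")
    all_records = []
    for pid in common:
        control = collapse_quadruplicates(by_id_c[pid], stat=replicate_stat)
        drug = collapse_quadruplicates(by_id_d[pid], stat=replicate_stat)
        small = filter_small_colonies(control["size"], frac=small_colony_frac)
        rec = compute_fitness(control, drug, excluded=small)
        rec = normalize_plate(rec, include_border=include_border)
        rec.insert(0, "plate", pid)
        all_records.append(rec)
    fitness = pd.concat(all_records, ignore_index=True)
    hits = group_alleles(fitness, annotations, rule=grouping_rule, z_pos=z_pos, z_neg=z_neg)
    return fitness, hits
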