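"""Cross-condition overlaps, category tallies, and supplementary-table replays.

Stage 5.  Collects hit lists from the other stages into Venn-style overlap
counts (e.g. genes negative with all three amino-acid analogs), per-category
overlap percentages (rounded half-up to whole percent), and — when the
published supplementary tables are available on disk — recomputes the
screen's printed counts from them and flags any discrepancy instead of
silently passing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError
from .stats import bh_adjust, welch_t_test

__all__ = [
    "OverlapSummary",
    "overlap",
    "category_overlap",
    "reproduce_from_supplements",
    "zscore_histogram",
    "PRINTED_COUNTS",
]

#: Published counts the supplement replay compares against.
PRINTED_COUNTS: dict[str, float] = {
    "screen_positive_genes": 19,
    "screen_negative_genes": 255,
    "hap5_z_score": -3.5,
    "validated_negative": 72,
    "validated_positive": 12,
    "thialysine_negative": 29,
    "canavanine_negative": 19,
    "triple_overlap": 15,
    "sga_negative": 20,
    "sga_tested": 72,
    "suppressors": 20,
    "suppression_tested": 53,
    "control_auc_ratio_pct": 18.3,
}


@dataclass(frozen=True)
class OverlapSummary:
    """Intersection counts for named gene sets (inclusion–exclusion consistent)."""

    set_names: tuple[str, ...]
    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    intersection_all: int
    union_size: int


def overlap(sets: Mapping[str, set]) -> OverlapSummary:
    """Exact single, pairwise and full intersection counts for named sets."""
    if not sets:
        raise InvalidInputError("no sets given")
    names = tuple(sets)
    materialized = {k: set(v) for k, v in sets.items()}
    sizes = {k: len(v) for k, v in materialized.items()}
    pairwise = {
        (a, b): len(materialized[a] & materialized[b]) for a, b in combinations(names, 2)
    }
    inter_all = len(set.intersection(*materialized.values()))
    union = len(set.union(*materialized.values()))
    return OverlapSummary(names, sizes, pairwise, inter_all, union)


def _round_half_up_pct(x: float) -> int:
    return int(math.floor(100.0 * x + 0.5))


def category_overlap(
    hit_categories: Mapping[str, str | None], reference_set: set
) -> dict[str, int]:
    """Per functional category, the percent of hits also in ``reference_set``.

    Percentages are rounded half-up to whole percent (2 of 3 shared -> 67%).
    Hits without a category are omitted with a warning.
    """
    by_cat: dict[str, list[str]] = {}
    dropped = 0
    for gene, cat in hit_categories.items():
        if cat is None or (isinstance(cat, float) and math.isnan(cat)) or str(cat) == "":
            dropped += 1
            continue
        by_cat.setdefault(str(cat), []).append(gene)
    if dropped:
        warnings.warn(f"{dropped} hits lack a category annotation; omitted", stacklevel=2)
    return {
        cat: _round_half_up_pct(sum(g in reference_set for g in genes) / len(genes))
        for cat, genes in sorted(by_cat.items())
    }


def _load(directory: Path, spec: Mapping[str, str], key: str) -> pd.DataFrame:
    if key not in spec:
        raise InvalidInputError(f"manifest section missing entry {key!r}")
    path = directory / spec["file"]
    if not path.exists():
        raise InvalidInputError(f"supplement file not found: {path}")
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    wanted = [v for k, v in spec.items() if k != "file"]
    missing = sorted(set(wanted) - set(df.columns))
    if missing:
        raise InvalidInputError(
            f"{path.name}: expected columns {missing} (manifest maps {dict(spec)})"
        )
    return df


def reproduce_from_supplements(
    directory: str | Path,
    manifest: Mapping[str, Mapping[str, str]],
    printed: Mapping[str, float] = PRINTED_COUNTS,
    neg_thresh: float = -0.1,
    pos_thresh: float = 0.1,
    alpha: float = 0.05,
    z_pos: float = 3.0,
    z_neg: float = -1.5,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Recompute the printed screen counts from supplementary-style tables.

    ``manifest`` maps each section (``screen``, ``validation``, ``analogs``,
    ``sga``, ``suppression``) to a file name and its column names, so column
    drift in downloaded tables breaks loudly.  Returns one row per target
    with the recomputed value, the printed value and a match flag; mismatches
    are reported, never silently passed.

    Expected shapes: screen = one row per gene with a Z-score; validation and
    analogs = one row per (strain, [drug,] experiment) with mean epsilon and
    p; sga = one row per allele with score and adjusted p; suppression = one
    row per (gene, replicate) ratio plus control rows flagged by an
    ``is_control`` column.
    """
    directory = Path(directory)
    results: dict[str, float] = {}

    if "screen" in manifest:
        spec = manifest["screen"]
        df = _load(directory, spec, "z")
        z = pd.to_numeric(df[spec["z"]], errors="coerce")
        results["screen_positive_genes"] = int((z >= z_pos).sum())
        results["screen_negative_genes"] = int((z <= z_neg).sum())
        genes = df[spec["gene"]].astype(str).str.lower()
        hap5 = z[genes.isin(["hap5", "hap5d", "hap5Δ".lower()])]
        if not hap5.empty:
            results["hap5_z_score"] = float(hap5.iloc[0])

    azc_negative: set[str] | None = None
    if "validation" in manifest:
        spec = manifest["validation"]
        df = _load(directory, spec, "eps")
        calls = _intersection_calls(
            df, spec["strain"], spec["experiment"], spec["eps"], spec["p"],
            neg_thresh, pos_thresh, alpha,
        )
        azc_negative = {s for s, c in calls.items() if c == "negative"}
        results["validated_negative"] = len(azc_negative)
        results["validated_positive"] = sum(c == "positive" for c in calls.values())

    if "analogs" in manifest:
        spec = manifest["analogs"]
        df = _load(directory, spec, "eps")
        per_drug: dict[str, set[str]] = {}
        for drug, sub in df.groupby(spec["drug"]):
            calls = _intersection_calls(
                sub, spec["strain"], spec["experiment"], spec["eps"], spec["p"],
                neg_thresh, pos_thresh, alpha,
            )
            per_drug[str(drug).lower()] = {s for s, c in calls.items() if c == "negative"}
        if "thialysine" in per_drug:
            results["thialysine_negative"] = len(per_drug["thialysine"])
        if "canavanine" in per_drug:
            results["canavanine_negative"] = len(per_drug["canavanine"])
        if azc_negative is not None and {"thialysine", "canavanine"} <= set(per_drug):
            results["triple_overlap"] = len(
                azc_negative & per_drug["thialysine"] & per_drug["canavanine"]
            )

    if "sga" in manifest:
        spec = manifest["sga"]
        df = _load(directory, spec, "score")
        score = pd.to_numeric(df[spec["score"]], errors="coerce")
        p_adj = pd.to_numeric(df[spec["p_adj"]], errors="coerce")
        results["sga_negative"] = int(((score <= neg_thresh) & (p_adj <= alpha)).sum())
        results["sga_tested"] = int(len(df))

    if "suppression" in manifest:
        spec = manifest["suppression"]
        df = _load(directory, spec, "ratio")
        is_ctrl = df[spec["is_control"]].astype(bool)
        ctrl = pd.to_numeric(df.loc[is_ctrl, spec["ratio"]], errors="coerce").dropna()
        if ctrl.empty:
            raise InvalidInputError("suppression table has no control rows")
        results["control_auc_ratio_pct"] = round(100.0 * float(ctrl.mean()), 1)
        strains = df[~is_ctrl]
        rows = []
        for gene, sub in strains.groupby(spec["gene"]):
            r = pd.to_numeric(sub[spec["ratio"]], errors="coerce").dropna()
            fold = r.mean() / ctrl.mean()
            p = welch_t_test(r, ctrl).p_value
            rows.append((gene, fold, p))
        folds = pd.DataFrame(rows, columns=["gene", "fold", "p"])
        folds["p_adj"] = bh_adjust(folds["p"].to_numpy())
        results["suppressors"] = int(
            ((folds["fold"] >= fold_threshold) & (folds["p_adj"] <= alpha)).sum()
        )
        results["suppression_tested"] = int(len(folds))

    if not results:
        raise InvalidInputError("manifest selected no sections")

    report_rows = []
    for target, value in results.items():
        expected = printed.get(target)
        matches = expected is not None and math.isclose(value, expected, abs_tol=0.05)
        report_rows.append((target, value, expected, matches))
        if expected is not None and not matches:
            warnings.warn(
                f"{target}: recomputed {value} differs from printed {expected}", stacklevel=2
            )
    return pd.DataFrame(
        report_rows, columns=["target", "recomputed", "printed", "matches"]
    )


def _intersection_calls(
    df: pd.DataFrame,
    strain_col: str,
    exp_col: str,
    eps_col: str,
    p_col: str,
    neg_thresh: float,
    pos_thresh: float,
    alpha: float,
) -> dict[str, str]:
    calls: dict[str, str] = {}
    for strain, sub in df.groupby(strain_col):
        eps = pd.to_numeric(sub[eps_col], errors="coerce")
        p = pd.to_numeric(sub[p_col], errors="coerce")
        neg = bool(((eps < neg_thresh) & (p <= alpha)).all())
        pos = bool(((eps > pos_thresh) & (p <= alpha)).all())
        calls[str(strain)] = "negative" if neg else ("positive" if pos else "none")
    return calls


def zscore_histogram(z_scores: Sequence[float], path: str | Path, bins: int = 60) -> Path:
    """Save an SVG histogram of screen Z-scores (distribution-shape summary)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(list(z_scores), bins=bins, color="#4477aa")
    ax.set_xlabel("fitness Z-score")
    ax.set_ylabel("strains")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
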