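"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes:

* colony screen — paired 32x48 plates, quadruplicate 2x2 blocks, a
  multiplicative per-plate effect, lognormal per-colony noise, strain-level
  drug-response heterogeneity, a small dead/slow class, and planted
  sensitive/resistant strains whose drug multiplier is shifted by a chosen
  number of null fitness-ratio standard deviations;
* growth curves — logistic wells from OD 0.1 sampled every 15 min for 24 h,
  with planted multiplicative-model interaction scores realized exactly on
  noiseless data and additive Gaussian OD noise on top;
* SGA arrays — three arrays with allele positions randomized per array,
  surrounded by a control strain that serves as the normalization standard,
  with the query fitness cost and planted deviations applied multiplicatively;
* suppression ratios — per-replicate AUC(drug)/AUC(plain) draws around a
  control level with planted fold-suppression.

Every generator ships a truth table and is bit-identical when re-run with
the same (config, seed): a single integer seed fans out to named substreams
through ``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .colony import PlateColonyGrid
from .errors import InvalidInputError
from .liquid import GrowthCurve
from .stats import logistic_auc, logistic_od

__all__ = [
    "ColonyScreenConfig",
    "GrowthCurveConfig",
    "SGAConfig",
    "SuppressionConfig",
    "simulate_colony_screen",
    "simulate_growth_curves",
    "simulate_sga_array",
    "simulate_suppression_ratios",
    "write_colony_screen",
    "write_growth_curves",
    "write_sga_plates",
]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a single integer seed out to ``n`` independent substreams.

    Substream i is ``SeedSequence(seed).spawn(n)[i]``; callers document which
    index feeds which plate/curve so regeneration is bit-identical.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# colony screen
# ---------------------------------------------------------------------------

@dataclass
class ColonyScreenConfig:
    """Study conditions of the solid-medium screen.

    The null fitness-ratio spread combines quadruplicate colony noise
    (lognormal, CV ``colony_noise_cv`` per colony) with strain-level
    drug-response heterogeneity (relative sd ``response_sd``); planted
    effects shift the drug multiplier by ``*_effect_sd`` times that null sd.
    """

    n_strains: int = 4000
    n_rows: int = 32
    n_cols: int = 48
    base_size: float = 400.0
    plate_effect_sd: float = 0.10
    colony_noise_cv: float = 0.10
    response_sd: float = 0.10
    base_fitness_sd: float = 0.10
    drug: str = "AZC"
    concentration: float = 30.0
    drug_effect: float = 0.60
    frac_sensitive: float = 0.02
    sensitive_effect_sd: float = -3.0
    frac_resistant: float = 0.005
    resistant_effect_sd: float = 4.0
    frac_dead: float = 0.0025
    dead_fitness: float = 0.02
    filler_strain: str = "border_control"

    def __post_init__(self) -> None:
        if self.n_rows % 2 or self.n_cols % 2:
            raise InvalidInputError("plate dimensions must be even (2x2 quadruplicate blocks)")
        fracs = self.frac_sensitive + self.frac_resistant + self.frac_dead
        if not 0 <= fracs <= 1:
            raise InvalidInputError("planted fractions must sum into [0, 1]")
        if not 0 < self.drug_effect:
            raise InvalidInputError("drug_effect must be positive")

    @property
    def null_ratio_sd(self) -> float:
        """Relative sd of the null fitness ratio (measurement + heterogeneity)."""
        meas = self.colony_noise_cv * np.sqrt(2.0) / 2.0  # ratio of two quadruplicate means
        return float(np.sqrt(meas**2 + self.response_sd**2))

    @property
    def interior_blocks(self) -> int:
        return (self.n_rows // 2 - 2) * (self.n_cols // 2 - 2)


def _block_positions(n_rows: int, n_cols: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(interior, border) 2x2 block top-left coordinates, 1-based."""
    interior, border = [], []
    for br in range(n_rows // 2):
        for bc in range(n_cols // 2):
            pos = (2 * br + 1, 2 * bc + 1)
            if br == 0 or bc == 0 or br == n_rows // 2 - 1 or bc == n_cols // 2 - 1:
                border.append(pos)
            else:
                interior.append(pos)
    return interior, border


def simulate_colony_screen(
    config: ColonyScreenConfig | None = None, seed: int = 0
) -> tuple[list[tuple[PlateColonyGrid, PlateColonyGrid]], pd.DataFrame]:
    """Paired (control, drug) plates plus the planted truth table.

    Colony size = plate effect x base size x strain base fitness x
    (drug multiplier on drug plates) x lognormal colony noise.  Strains are
    laid out in interior 2x2 blocks; the border ring of blocks holds a
    filler strain.  Substreams: 0 = strain-level truth, then per plate pair
    1+2i (control) and 2+2i (drug).
    """
    cfg = config or ColonyScreenConfig()
    interior, border = _block_positions(cfg.n_rows, cfg.n_cols)
    per_plate = len(interior)
    n_plates = int(np.ceil(cfg.n_strains / per_plate))
    rngs = _streams(seed, 1 + 2 * n_plates)
    truth_rng = rngs[0]

    n = cfg.n_strains
    strain_ids = np.array([f"S{i:05d}" for i in range(n)])
    n_sens = int(round(cfg.frac_sensitive * n))
    n_res = int(round(cfg.frac_resistant * n))
    n_dead = int(round(cfg.frac_dead * n))
    classes = np.array(["null"] * n, dtype=object)
    perm = truth_rng.permutation(n)
    classes[perm[:n_sens]] = "sensitive"
    classes[perm[n_sens : n_sens + n_res]] = "resistant"
    classes[perm[n_sens + n_res : n_sens + n_res + n_dead]] = "dead"

    base_fitness = np.clip(
        truth_rng.lognormal(0.0, cfg.base_fitness_sd, size=n), 0.3, 1.2
    )
    base_fitness[classes == "dead"] = cfg.dead_fitness

    s_null = cfg.null_ratio_sd
    response = truth_rng.normal(0.0, cfg.response_sd, size=n)  # null heterogeneity
    multiplier = cfg.drug_effect * (1.0 + response)
    multiplier[classes == "sensitive"] = cfg.drug_effect * (
        1.0 + cfg.sensitive_effect_sd * s_null
    )
    multiplier[classes == "resistant"] = cfg.drug_effect * (
        1.0 + cfg.resistant_effect_sd * s_null
    )
    multiplier = np.clip(multiplier, 0.0, None)

    truth = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "base_fitness": base_fitness,
            "drug_multiplier": multiplier,
            "true_class": classes,
            "is_dead": classes == "dead",
            "plate": [f"P{(i // per_plate) + 1:02d}" for i in range(n)],
            "seed": seed,
        }
    )

    pairs = []
    for p in range(n_plates):
        pid = f"P{p + 1:02d}"
        on_plate = strain_ids[p * per_plate : (p + 1) * per_plate]
        idx = np.arange(p * per_plate, min((p + 1) * per_plate, n))
        rng_c, rng_d = rngs[1 + 2 * p], rngs[2 + 2 * p]

        def build(rng: np.random.Generator, with_drug: bool) -> PlateColonyGrid:
            plate_eff = rng.lognormal(0.0, cfg.plate_effect_sd)
            rows_, cols_, strains_, sizes_ = [], [], [], []

            def add_block(top: tuple[int, int], strain: str, mean_size: float) -> None:
                noise = rng.lognormal(0.0, cfg.colony_noise_cv, size=4)
                k = 0
                for dr in (0, 1):
                    for dc in (0, 1):
                        rows_.append(top[0] + dr)
                        cols_.append(top[1] + dc)
                        strains_.append(strain)
                        sizes_.append(plate_eff * mean_size * noise[k])
                        k += 1

            for j, top in enumerate(interior):
                if j < idx.size:
                    i = idx[j]
                    mean = cfg.base_size * base_fitness[i]
                    if with_drug:
                        mean *= multiplier[i]
                    add_block(top, strain_ids[i], mean)
                else:
                    mean = cfg.base_size * (cfg.drug_effect if with_drug else 1.0)
                    add_block(top, cfg.filler_strain, mean)
            for top in border:
                mean = cfg.base_size * (cfg.drug_effect if with_drug else 1.0)
                add_block(top, cfg.filler_strain, mean)

            wells = pd.DataFrame(
                {"row": rows_, "col": cols_, "strain": strains_, "size": sizes_}
            )
            return PlateColonyGrid(
                pid,
                cfg.n_rows,
                cfg.n_cols,
                wells,
                drug=cfg.drug if with_drug else None,
                concentration=cfg.concentration if with_drug else 0.0,
            )

        pairs.append((build(rng_c, False), build(rng_d, True)))
    return pairs, truth


def write_colony_screen(
    pairs: Sequence[tuple[PlateColonyGrid, PlateColonyGrid]],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write control/drug plate TSVs, a matching annotation TSV and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def dump(grids: Sequence[PlateColonyGrid], name: str) -> Path:
        frames = []
        for g in grids:
            f = g.wells[["row", "col", "strain", "size"]].copy()
            f.insert(0, "plate", g.plate_id)
            frames.append(f)
        path = outdir / name
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        return path

    control = dump([c for c, _ in pairs], "control_plates.tsv")
    drug = dump([d for _, d in pairs], "drug_plates.tsv")
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    well_strains = set()
    for c, d in pairs:
        well_strains |= set(c.wells["strain"]) | set(d.wells["strain"])
    fillers = sorted(well_strains - set(truth["strain_id"]))
    strains = list(truth["strain_id"]) + fillers
    annotations = pd.DataFrame(
        {
            "strain": strains,
            "gene": strains,
            "allele": strains,
            "collection": "deletion",
            "essential": False,
            "category": "",
        }
    )
    ann_path = outdir / "annotations.tsv"
    annotations.to_csv(ann_path, sep="\t", index=False)
    return {"control": control, "drug": drug, "truth": truth_path, "annotations": ann_path}


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurveConfig:
    """Study conditions of the liquid validation experiment.

    Cultures start at OD 0.1 and are read every 15 min for 24 h, in
    biological triplicate across two independent experiments.  Fitness is
    realized through the carrying capacity: for each well the logistic K is
    solved so the baseline-subtracted AUC hits the target fitness times the
    wild-type reference, which makes planted epsilons exact on noiseless
    data.  ``fitness_noise_sd`` is additive on the fitness scale;
    ``od_noise_sd`` is additive Gaussian OD noise per reading.
    """

    n_strains: int = 200
    replicates: int = 3
    experiments: int = 2
    duration_h: float = 24.0
    interval_h: float = 0.25
    n0: float = 0.1
    k_wt: float = 1.2
    r_plain: float = 0.5
    r_drug: float = 0.35
    drug: str = "AZC"
    concentration: float = 10.0
    wt_drug_fitness: float = 0.6
    mutant_fitness_mean: float = 0.9
    mutant_fitness_sd: float = 0.05
    fitness_noise_sd: float = 0.05
    od_noise_sd: float = 0.005
    frac_negative: float = 0.0
    frac_positive: float = 0.0
    eps_negative: float = -0.3
    eps_positive: float = 0.3
    wt_strain: str = "WT"


def _solve_k_for_auc(target_auc: float, r: float, n0: float, t_end: float) -> float:
    """Carrying capacity whose baseline-subtracted logistic AUC equals target."""
    if target_auc <= 0:
        raise InvalidInputError("target AUC must be positive")

    def g(k: float) -> float:
        return logistic_auc(k, r, n0, t_end) - n0 * t_end - target_auc

    lo, hi = n0 * (1.0 + 1e-9), max(10.0 * n0, 1.0)
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise InvalidInputError("cannot bracket carrying capacity")
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-14))


def simulate_growth_curves(
    config: GrowthCurveConfig | None = None, seed: int = 0
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Logistic growth curves with planted interaction scores and the truth table.

    Substreams: 0 = strain-level truth, 1 = well noise.  Condition targets:
    wild type plain = 1 (by construction), wild type drug = ``wt_drug_fitness``
    (W_i), mutant plain = per-strain W_j, mutant drug = W_i * W_j + eps.
    """
    cfg = config or GrowthCurveConfig()
    rng_truth, rng_noise = _streams(seed, 2)
    times = np.arange(0.0, cfg.duration_h + cfg.interval_h / 2, cfg.interval_h)

    n = cfg.n_strains
    strain_ids = [f"M{i:04d}" for i in range(n)]
    w_j = np.clip(
        rng_truth.normal(cfg.mutant_fitness_mean, cfg.mutant_fitness_sd, size=n), 0.3, 1.2
    )
    eps = np.zeros(n)
    classes = np.array(["null"] * n, dtype=object)
    n_neg = int(round(cfg.frac_negative * n))
    n_pos = int(round(cfg.frac_positive * n))
    perm = rng_truth.permutation(n)
    eps[perm[:n_neg]] = cfg.eps_negative
    classes[perm[:n_neg]] = "negative"
    eps[perm[n_neg : n_neg + n_pos]] = cfg.eps_positive
    classes[perm[n_neg : n_neg + n_pos]] = "positive"

    truth = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "base_fitness": w_j,
            "interaction_eps": eps,
            "true_class": classes,
            "seed": seed,
        }
    )

    ref_auc = logistic_auc(cfg.k_wt, cfg.r_plain, cfg.n0, cfg.duration_h) - cfg.n0 * cfg.duration_h

    curves: list[GrowthCurve] = []
    well_counter = 0

    def add_curve(strain: str, with_drug: bool, target: float, exp: int, rep: int) -> None:
        nonlocal well_counter
        well_counter += 1
        f = target + rng_noise.normal(0.0, cfg.fitness_noise_sd) if cfg.fitness_noise_sd else target
        f = max(f, 0.05)
        r = cfg.r_drug if with_drug else cfg.r_plain
        k = _solve_k_for_auc(f * ref_auc, r, cfg.n0, cfg.duration_h)
        od = logistic_od(times, k, r, cfg.n0)
        if cfg.od_noise_sd:
            od = np.maximum(od + rng_noise.normal(0.0, cfg.od_noise_sd, size=od.size), 0.0)
        curves.append(
            GrowthCurve(
                strain_id=strain,
                drug=cfg.drug if with_drug else None,
                concentration=cfg.concentration if with_drug else 0.0,
                replicate=rep,
                experiment=exp,
                times=times,
                od600=od,
                meta={"well": f"W{well_counter:05d}"},
            )
        )

    for exp in range(1, cfg.experiments + 1):
        for rep in range(1, cfg.replicates + 1):
            add_curve(cfg.wt_strain, False, 1.0, exp, rep)
            add_curve(cfg.wt_strain, True, cfg.wt_drug_fitness, exp, rep)
            for i, sid in enumerate(strain_ids):
                add_curve(sid, False, w_j[i], exp, rep)
                add_curve(sid, True, cfg.wt_drug_fitness * w_j[i] + eps[i], exp, rep)
    return curves, truth


def write_growth_curves(
    curves: Sequence[GrowthCurve], outdir: str | Path, stem: str = "curves"
) -> dict[str, Path]:
    """Write the wide plate-reader CSV and well-map TSV that the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    times = curves[0].times
    data = {"time": times}
    map_rows = []
    for c in curves:
        well = c.meta.get("well", f"W{len(map_rows) + 1:05d}")
        data[well] = c.od600
        row = {
            "well": well,
            "strain": c.strain_id,
            "drug": c.drug if c.drug is not None else "none",
            "concentration": c.concentration,
            "replicate": c.replicate,
            "experiment": c.experiment,
        }
        for k, v in c.meta.items():
            if k != "well":
                row[k] = v
        map_rows.append(row)
    csv_path = outdir / f"{stem}.csv"
    map_path = outdir / f"{stem}_map.tsv"
    pd.DataFrame(data).to_csv(csv_path, index=False)
    pd.DataFrame(map_rows).to_csv(map_path, sep="\t", index=False)
    return {"curves": csv_path, "map": map_path}


# ---------------------------------------------------------------------------
# SGA arrays
# ---------------------------------------------------------------------------

@dataclass
class SGAConfig:
    """Study conditions of the SGA stage: 3 randomized arrays, quadruplicate
    colonies, a control strain filling every non-allele block, and a query
    single-mutant fitness cost ``q`` applied to array double mutants on the
    mistranslating-query plates.  The control strain is modeled as the
    normalization standard (unit fitness on both queries), so the query cost
    survives plate normalization and null alleles score exactly zero under
    the multiplicative expectation.
    """

    n_alleles: int = 72
    n_arrays: int = 3
    n_rows: int = 32
    n_cols: int = 48
    base_size: float = 400.0
    plate_effect_sd: float = 0.10
    colony_noise_cv: float = 0.05
    q: float = 0.8
    control_strain: str = "his3D"
    allele_fitness_low: float = 0.7
    allele_fitness_high: float = 1.0
    frac_interactions: float = 0.0
    interaction_dev: float = -0.2


def simulate_sga_array(
    config: SGAConfig | None = None, seed: int = 0
) -> tuple[list[tuple[PlateColonyGrid, PlateColonyGrid]], pd.DataFrame]:
    """(control-query plate, mistranslating-query plate) per array, plus truth.

    Substreams: 0 = allele truth, then per array 1+2a (control query) and
    2+2a (mistranslating query); allele positions are randomized per array.
    """
    cfg = config or SGAConfig()
    interior, border = _block_positions(cfg.n_rows, cfg.n_cols)
    if cfg.n_alleles > len(interior):
        raise InvalidInputError(f"at most {len(interior)} alleles fit one array")
    rngs = _streams(seed, 1 + 2 * cfg.n_arrays)
    truth_rng = rngs[0]

    alleles = [f"A{i:03d}" for i in range(cfg.n_alleles)]
    fitness = truth_rng.uniform(cfg.allele_fitness_low, cfg.allele_fitness_high, cfg.n_alleles)
    dev = np.zeros(cfg.n_alleles)
    n_int = int(round(cfg.frac_interactions * cfg.n_alleles))
    dev[truth_rng.permutation(cfg.n_alleles)[:n_int]] = cfg.interaction_dev
    truth = pd.DataFrame(
        {
            "allele": alleles,
            "array_fitness": fitness,
            "planted_deviation": dev,
            "true_class": np.where(dev != 0, "negative", "null"),
            "seed": seed,
        }
    )

    pairs = []
    for a in range(cfg.n_arrays):
        rng_c, rng_q = rngs[1 + 2 * a], rngs[2 + 2 * a]
        layout = rng_c.permutation(len(interior))[: cfg.n_alleles]
        pos_of = {alleles[i]: interior[layout[i]] for i in range(cfg.n_alleles)}
        control_blocks = [interior[j] for j in range(len(interior)) if j not in set(layout)]

        def build(rng: np.random.Generator, mistranslating: bool, array_id: int) -> PlateColonyGrid:
            plate_eff = rng.lognormal(0.0, cfg.plate_effect_sd)
            rows_, cols_, strains_, sizes_ = [], [], [], []

            def add_block(top: tuple[int, int], strain: str, mean_size: float) -> None:
                noise = rng.lognormal(0.0, cfg.colony_noise_cv, size=4)
                k = 0
                for dr in (0, 1):
                    for dc in (0, 1):
                        rows_.append(top[0] + dr)
                        cols_.append(top[1] + dc)
                        strains_.append(strain)
                        sizes_.append(plate_eff * mean_size * noise[k])
                        k += 1

            for i, al in enumerate(alleles):
                mean = cfg.base_size * fitness[i]
                if mistranslating:
                    mean *= cfg.q * (1.0 + dev[i])
                add_block(pos_of[al], al, mean)
            for top in control_blocks + border:
                add_block(top, cfg.control_strain, cfg.base_size)

            wells = pd.DataFrame(
                {"row": rows_, "col": cols_, "strain": strains_, "size": sizes_}
            )
            return PlateColonyGrid(
                f"array{array_id}_{'mist' if mistranslating else 'ctrl'}",
                cfg.n_rows,
                cfg.n_cols,
                wells,
                drug=None,
            )

        pairs.append((build(rng_c, False, a + 1), build(rng_q, True, a + 1)))
    return pairs, truth


def write_sga_plates(
    pairs: Sequence[tuple[PlateColonyGrid, PlateColonyGrid]],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """One TSV per plate plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ctrl, mist in pairs:
        for g in (ctrl, mist):
            f = g.wells[["row", "col", "strain", "size"]].copy()
            f.insert(0, "plate", g.plate_id)
            path = outdir / f"{g.plate_id}.tsv"
            f.to_csv(path, sep="\t", index=False)
            paths[g.plate_id] = path
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# suppression ratios
# ---------------------------------------------------------------------------

@dataclass
class SuppressionConfig:
    """AUC-ratio-level model of the overexpression suppression experiment.

    The control strain's drug/plain AUC ratio sits at ``control_ratio``
    (the drug reduces its AUC to ~18% of plain medium); replicate ratios
    scatter with coefficient of variation ``ratio_cv``.  Planted suppressors
    multiply the ratio by ``suppression_fold``; planted growth-cost genes
    grow at ``growth_cost_factor`` of the control in plain medium.
    """

    n_genes: int = 53
    replicates: int = 3
    control_ratio: float = 0.183
    ratio_cv: float = 0.10
    plain_auc: float = 12.0
    plain_auc_cv: float = 0.05
    frac_suppressors: float = 0.0
    suppression_fold: float = 3.0
    frac_growth_cost: float = 0.0
    growth_cost_factor: float = 0.6


def simulate_suppression_ratios(
    config: SuppressionConfig | None = None, seed: int = 0
) -> tuple[dict[str, np.ndarray], np.ndarray, dict[str, np.ndarray], np.ndarray, pd.DataFrame]:
    """(gene ratios, control ratios, gene plain AUCs, control plain AUCs, truth).

    Substreams: 0 = truth/class assignment, 1 = replicate noise.
    """
    cfg = config or SuppressionConfig()
    rng_truth, rng_noise = _streams(seed, 2)
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    n_sup = int(round(cfg.frac_suppressors * cfg.n_genes))
    n_cost = int(round(cfg.frac_growth_cost * cfg.n_genes))
    perm = rng_truth.permutation(cfg.n_genes)
    is_sup = np.zeros(cfg.n_genes, dtype=bool)
    is_sup[perm[:n_sup]] = True
    has_cost = np.zeros(cfg.n_genes, dtype=bool)
    has_cost[perm[cfg.n_genes - n_cost :]] = True

    def draw_ratios(level: float) -> np.ndarray:
        return np.maximum(
            level * (1.0 + rng_noise.normal(0.0, cfg.ratio_cv, size=cfg.replicates)), 1e-6
        )

    def draw_plain(level: float) -> np.ndarray:
        return np.maximum(
            level * (1.0 + rng_noise.normal(0.0, cfg.plain_auc_cv, size=cfg.replicates)), 1e-6
        )

    control_ratios = draw_ratios(cfg.control_ratio)
    control_plain = draw_plain(cfg.plain_auc)
    gene_ratios, gene_plain = {}, {}
    for i, g in enumerate(genes):
        level = cfg.control_ratio * (cfg.suppression_fold if is_sup[i] else 1.0)
        gene_ratios[g] = draw_ratios(level)
        plain_level = cfg.plain_auc * (cfg.growth_cost_factor if has_cost[i] else 1.0)
        gene_plain[g] = draw_plain(plain_level)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_suppressor": is_sup,
            "has_growth_cost": has_cost,
            "seed": seed,
        }
    )
    return gene_ratios, control_ratios, gene_plain, control_plain, truth
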