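"""Colony-screen stage: IO, filtering, fitness, normalization and hit calls."""

import numpy as np
import pandas as pd
import pytest

from chemscreen import InvalidInputError, colony
from chemscreen.simulate import simulate_colony_screen, ColonyScreenConfig

from conftest import annotations_for


def write_plate(tmp_path, rows, name="plate.tsv"):
    path = tmp_path / name
    lines = ["plate\trow\tcol\tstrain\tsize"]
    lines += ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPlateTable:
    def test_toy_round_trip(self, tmp_path):
        path = write_plate(
            tmp_path,
            [("P1", 1, 1, "a", 100), ("P1", 1, 2, "a", 110), ("P1", 2, 1, "b", 90), ("P1", 2, 2, "b", 95)],
        )
        grid = colony.read_plate_table(path)
        assert len(grid.wells) == 4
        assert grid.n_rows == 2 and grid.n_cols == 2

    def test_duplicate_position_rejected(self, tmp_path):
        path = write_plate(tmp_path, [("P1", 1, 1, "a", 100), ("P1", 1, 1, "b", 90)])
        with pytest.raises(InvalidInputError, match="duplicate"):
            colony.read_plate_table(path)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        path = write_plate(tmp_path, [("P1", 1, 1, "a", 100), ("P1", "x", 2, "b", 90)])
        with pytest.raises(InvalidInputError, match=r"lines \[3\]"):
            colony.read_plate_table(path)

    def test_full_synthetic_file_round_trips(self, tmp_path, small_screen):
        from chemscreen.simulate import write_colony_screen

        _, pairs, truth = small_screen
        paths = write_colony_screen(pairs, truth, tmp_path)
        grids = colony.read_plate_tables(paths["control"], n_rows=32, n_cols=48)
        assert len(grids) == len(pairs)
        assert len(grids[0].wells) == 32 * 48
        # quadruplicates: every strain occupies a multiple of 4 wells
        counts = grids[0].wells.groupby("strain").size()
        assert (counts.drop("border_control") == 4).all()


class TestCollapse:
    def test_full_quadruplicate_mean(self, small_screen):
        _, pairs, _ = small_screen
        grid = pairs[0][0]
        collapsed = colony.collapse_quadruplicates(grid)
        oracle = grid.wells.groupby("strain")["size"].mean()
        assert collapsed["size"].sort_index().to_numpy() == pytest.approx(
            oracle.sort_index().to_numpy()
        )

    def test_partial_replicates_use_available_colonies(self):
        wells = pd.DataFrame(
            {"row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
             "strain": ["a", "a", "a", "a"], "size": [80.0, 120.0, np.nan, np.nan]}
        )
        grid = colony.PlateColonyGrid("P1", 2, 2, wells)
        collapsed = colony.collapse_quadruplicates(grid)
        assert collapsed.loc["a", "size"] == pytest.approx(100.0)
        assert collapsed.loc["a", "n_colonies"] == 2


class TestSmallColonyFilter:
    def test_strict_five_percent_rule(self):
        # plate mean exactly 100 -> threshold 5.0; the rule is strictly "less than"
        sizes = pd.Series({"a": 196.0, "b": 195.0, "dead": 4.0, "edge": 5.0})
        assert sizes.mean() == pytest.approx(100.0)
        excluded = colony.filter_small_colonies(sizes, frac=0.05)
        assert excluded == {"dead"}  # 5.0 sits exactly at 5% and is retained

    def test_empty_plate_rejected(self):
        with pytest.raises(InvalidInputError):
            colony.filter_small_colonies(pd.Series(dtype=float))

    def test_planted_dead_strains_exactly_recovered(self, small_screen):
        _, pairs, truth = small_screen
        control = colony.collapse_quadruplicates(pairs[0][0])
        excluded = colony.filter_small_colonies(control["size"])
        assert excluded == set(truth[truth["is_dead"]]["strain_id"])


class TestFitness:
    def test_ratio_and_zero_drug_growth(self):
        def table(sizes):
            return pd.DataFrame(
                {"size": sizes, "n_colonies": 4, "is_border": False},
                index=list(sizes),
            )

        control = table({"a": 100.0, "b": 100.0})
        drug = table({"a": 60.0, "b": 0.0})
        rec = colony.compute_fitness(control, drug).set_index("strain")
        assert rec.loc["a", "fitness_W"] == pytest.approx(0.6)
        assert rec.loc["b", "fitness_W"] == pytest.approx(0.0)

    def test_one_sided_strain_marked_missing(self):
        control = pd.DataFrame({"size": [100.0], "n_colonies": 4, "is_border": False}, index=["a"])
        drug = pd.DataFrame({"size": [50.0, 60.0], "n_colonies": 4, "is_border": False}, index=["a", "b"])
        rec = colony.compute_fitness(control, drug).set_index("strain")
        assert rec.loc["b", "exclusion_reason"] == "missing"
        assert bool(rec.loc["b", "excluded"])

    def test_synthetic_pair_matches_elementwise_oracle(self, small_screen):
        _, pairs, _ = small_screen
        control = colony.collapse_quadruplicates(pairs[0][0])
        drug = colony.collapse_quadruplicates(pairs[0][1])
        rec = colony.compute_fitness(control, drug).set_index("strain")
        shared = control.index.intersection(drug.index)
        oracle = drug.loc[shared, "size"] / control.loc[shared, "size"]
        kept = rec.loc[shared]
        assert kept["fitness_W"].to_numpy() == pytest.approx(oracle.to_numpy())


def make_records(w, border=None, excluded=None):
    n = len(w)
    return pd.DataFrame(
        {
            "strain": [f"s{i}" for i in range(n)],
            "control_size": 100.0,
            "drug_size": np.asarray(w) * 100.0,
            "fitness_W": w,
            "excluded": excluded if excluded is not None else [False] * n,
            "exclusion_reason": "none",
            "is_border": border if border is not None else [False] * n,
        }
    )


class TestNormalizePlate:
    def test_mean_zero_sd_one(self, rng):
        rec = colony.normalize_plate(make_records(rng.uniform(0.3, 1.0, 50)))
        z = rec["z_score"]
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_triple_scaled(self):
        w = [0.5, 1.0, 1.5] * 4  # 12 strains to satisfy the minimum plate size
        rec = colony.normalize_plate(make_records(w))
        by_w = rec.groupby("fitness_W")["z_score"].first()
        # symmetric around 1.0 and equally spaced
        assert by_w[1.0] == pytest.approx(0.0, abs=1e-12)
        assert by_w[0.5] == pytest.approx(-by_w[1.5])

    def test_degenerate_plate_flagged_not_zeroed(self):
        rec = colony.normalize_plate(make_records([0.7] * 12))
        assert (rec["exclusion_reason"] == "degenerate_plate").all()
        assert rec["z_score"].isna().all()

    def test_excluded_and_border_strains_not_in_basis(self, rng):
        w = np.concatenate([rng.uniform(0.5, 0.7, 20), [5.0, 9.0]])
        excluded = [False] * 20 + [True, False]
        border = [False] * 21 + [True]
        rec = colony.normalize_plate(make_records(w, border=border, excluded=excluded))
        inner = rec[~rec["excluded"] & ~rec["is_border"]]
        assert abs(inner["z_score"].mean()) < 1e-12
        # the border outlier still receives a z on the same scale
        assert rec.iloc[-1]["z_score"] > 3


class TestGroupAlleles:
    def ann(self, mapping):
        return pd.DataFrame(
            {
                "strain": list(mapping),
                "gene": [mapping[s] for s in mapping],
                "allele": list(mapping),
                "collection": "temperature_sensitive",
                "essential": True,
                "category": "",
            }
        )

    def records(self, z):
        return pd.DataFrame({"strain": list(z), "z_score": list(z.values())})

    def test_mean_rule_and_negative_call(self):
        hits = colony.group_alleles(
            self.records({"g-1": -2.0, "g-2": -1.0}), self.ann({"g-1": "G", "g-2": "G"})
        )
        assert hits.loc[0, "grouped_z"] == pytest.approx(-1.5)
        assert hits.loc[0, "call"] == "negative"

    @pytest.mark.parametrize("z, call", [(3.0, "positive"), (-1.49, "none"), (-1.5, "negative")])
    def test_thresholds_are_inclusive(self, z, call):
        hits = colony.group_alleles(self.records({"a": z}), self.ann({"a": "A"}))
        assert hits.loc[0, "call"] == call

    def test_min_rule_config(self):
        hits = colony.group_alleles(
            self.records({"g-1": -2.0, "g-2": -1.0}),
            self.ann({"g-1": "G", "g-2": "G"}),
            rule="min",
        )
        assert hits.loc[0, "grouped_z"] == pytest.approx(-2.0)

    def test_unannotated_strain_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="lack annotation"):
            hits = colony.group_alleles(self.records({"mystery": -2.0}), self.ann({}))
        assert hits.loc[0, "gene"] == "mystery"


class TestEndToEnd:
    def test_calling_monotone_in_drug_size(self, small_screen):
        """Shrinking one strain's drug colonies can only push its call negative."""
        _, pairs, truth = small_screen
        ann = annotations_for(truth)
        control, drug = pairs[0]
        fitness, hits = colony.run_colony_screen([control], [drug], ann)
        target = fitness[~fitness["excluded"] & ~fitness["is_border"]].iloc[0]["strain"]
        shrunk = drug.wells.copy()
        shrunk.loc[shrunk["strain"] == target, "size"] *= 0.2
        drug2 = colony.PlateColonyGrid(drug.plate_id, drug.n_rows, drug.n_cols, shrunk,
                                       drug=drug.drug, concentration=drug.concentration)
        fitness2, hits2 = colony.run_colony_screen([control], [drug2], ann)
        z1 = fitness.set_index("strain").loc[target, "z_score"]
        z2 = fitness2.set_index("strain").loc[target, "z_score"]
        assert z2 < z1
        order = {"positive": 1, "none": 0, "negative": -1}
        c1 = order[hits.set_index("gene").loc[target, "call"]]
        c2 = order[hits2.set_index("gene").loc[target, "call"]]
        assert c2 <= c1

    def test_rerun_is_bit_identical(self, small_screen):
        _, pairs, truth = small_screen
        ann = annotations_for(truth)
        f1, h1 = colony.run_colony_screen([pairs[0][0]], [pairs[0][1]], ann)
        f2, h2 = colony.run_colony_screen([pairs[0][0]], [pairs[0][1]], ann)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_planted_sensitive_recovered_across_seeded_plates(self):
        """A strain planted 3 null-sd below the drug response scores Z <= -1.5
        in at least 95% of independently seeded plates."""
        cfg = ColonyScreenConfig(
            n_strains=308, frac_sensitive=1 / 308, frac_resistant=0.0, frac_dead=0.0
        )
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            pairs, truth = simulate_colony_screen(cfg, seed=seed)
            control = colony.collapse_quadruplicates(pairs[0][0])
            drug = colony.collapse_quadruplicates(pairs[0][1])
            small = colony.filter_small_colonies(control["size"])
            rec = colony.normalize_plate(colony.compute_fitness(control, drug, small))
            sensitive = truth[truth["true_class"] == "sensitive"]["strain_id"].iloc[0]
            z = rec.set_index("strain").loc[sensitive, "z_score"]
            hits += bool(z <= -1.5)
        assert hits / n_runs >= 0.95
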