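"""Reporting stage: overlaps, category percentages, supplement replay."""

import warnings

import numpy as np
import pandas as pd
import pytest

from chemscreen import InvalidInputError, category_overlap, overlap, report


class TestOverlap:
    def test_triple_intersection(self):
        summary = overlap({"A": {"g1", "g2"}, "B": {"g2"}, "C": {"g2"}})
        assert summary.intersection_all == 1
        assert summary.pairwise[("A", "B")] == 1
        assert summary.union_size == 2

    def test_disjoint_sets(self):
        summary = overlap({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert summary.intersection_all == 0
        assert all(v == 0 for v in summary.pairwise.values())

    def test_matches_brute_force_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(50)]
        for _ in range(20):
            sets = {
                name: set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
                for name in ("A", "B", "C")
            }
            s = overlap(sets)
            brute_all = sum(
                1 for g in universe if all(g in sets[n] for n in ("A", "B", "C"))
            )
            assert s.intersection_all == brute_all
            for (a, b), v in s.pairwise.items():
                assert v == sum(1 for g in universe if g in sets[a] and g in sets[b])
            # inclusion-exclusion for the 3-set union
            incl_excl = (
                sum(s.sizes.values())
                - sum(s.pairwise.values())
                + s.intersection_all
            )
            assert s.union_size == incl_excl


class TestCategoryOverlap:
    def test_two_of_three_rounds_to_67(self):
        cats = {"g1": "sorting", "g2": "sorting", "g3": "sorting"}
        assert category_overlap(cats, {"g1", "g2"}) == {"sorting": 67}

    def test_zero_shared(self):
        assert category_overlap({"g1": "rna"}, set()) == {"rna": 0}

    def test_half_up_rounding_and_missing_categories(self):
        cats = {"a": "x", "b": "x", "c": None, "d": "y", "e": "y"}
        with pytest.warns(UserWarning, match="lack a category"):
            out = category_overlap(cats, {"a", "d"})
        assert out == {"x": 50, "y": 50}


def stand_in_supplements(tmp_path):
    """Small synthetic stand-ins shaped like the published supplementary tables."""
    z = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(20)] + ["hap5"],
            "z_score": list(np.linspace(-1.4, 2.9, 18)) + [3.2, -1.6, -3.5],
        }
    )
    z.to_csv(tmp_path / "synthetic_screen.tsv", sep="\t", index=False)

    rows = []
    for strain, eps, p in [("s1", -0.3, 0.01), ("s2", -0.05, 0.5), ("s3", 0.25, 0.01)]:
        for exp in (1, 2):
            rows.append((strain, exp, eps, p))
    pd.DataFrame(rows, columns=["strain", "experiment", "eps", "p"]).to_csv(
        tmp_path / "synthetic_validation.tsv", sep="\t", index=False
    )

    rows = []
    for drug in ("thialysine", "canavanine"):
        for strain, eps, p in [("s1", -0.3, 0.01), ("s2", -0.2 if drug == "thialysine" else 0.0, 0.01)]:
            for exp in (1, 2):
                rows.append((strain, drug, exp, eps, p))
    pd.DataFrame(rows, columns=["strain", "drug", "experiment", "eps", "p"]).to_csv(
        tmp_path / "synthetic_analogs.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        {"allele": ["a1", "a2", "a3"], "score": [-0.2, -0.05, -0.3], "p_adj": [0.01, 0.01, 0.2]}
    ).to_csv(tmp_path / "synthetic_sga.tsv", sep="\t", index=False)

    rows = [("control", True, r) for r in (0.18, 0.19, 0.18)]
    rows += [("MCD4", False, r) for r in (0.60, 0.62, 0.61)]
    rows += [("XRN1", False, r) for r in (0.20, 0.19, 0.21)]
    pd.DataFrame(rows, columns=["gene", "is_control", "ratio"]).to_csv(
        tmp_path / "synthetic_suppression.tsv", sep="\t", index=False
    )

    return {
        "screen": {"file": "synthetic_screen.tsv", "gene": "gene", "z": "z_score"},
        "validation": {
            "file": "synthetic_validation.tsv", "strain": "strain",
            "experiment": "experiment", "eps": "eps", "p": "p",
        },
        "analogs": {
            "file": "synthetic_analogs.tsv", "strain": "strain", "drug": "drug",
            "experiment": "experiment", "eps": "eps", "p": "p",
        },
        "sga": {"file": "synthetic_sga.tsv", "allele": "allele", "score": "score", "p_adj": "p_adj"},
        "suppression": {
            "file": "synthetic_suppression.tsv", "gene": "gene",
            "ratio": "ratio", "is_control": "is_control",
        },
    }


class TestSupplementReplay:
    def test_recomputes_counts_from_stand_in_tables(self, tmp_path):
        manifest = stand_in_supplements(tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # stand-in counts differ from printed ones
            out = report.reproduce_from_supplements(tmp_path, manifest).set_index("target")
        assert out.loc["screen_positive_genes", "recomputed"] == 1
        assert out.loc["screen_negative_genes", "recomputed"] == 2  # -1.6 and -3.5
        assert out.loc["hap5_z_score", "recomputed"] == pytest.approx(-3.5)
        assert out.loc["hap5_z_score", "matches"]
        assert out.loc["validated_negative", "recomputed"] == 1
        assert out.loc["validated_positive", "recomputed"] == 1
        assert out.loc["thialysine_negative", "recomputed"] == 2
        assert out.loc["canavanine_negative", "recomputed"] == 1
        assert out.loc["triple_overlap", "recomputed"] == 1
        assert out.loc["sga_negative", "recomputed"] == 1
        assert out.loc["control_auc_ratio_pct", "recomputed"] == pytest.approx(18.3)
        assert out.loc["control_auc_ratio_pct", "matches"]
        assert out.loc["suppressors", "recomputed"] == 1
        # discrepancies are flagged, not silently passed
        assert not out.loc["validated_negative", "matches"]

    def test_mismatching_counts_warn(self, tmp_path):
        manifest = {"screen": stand_in_supplements(tmp_path)["screen"]}
        with pytest.warns(UserWarning, match="differs from printed"):
            report.reproduce_from_supplements(tmp_path, manifest)

    def test_zscore_histogram_writes_svg(self, tmp_path, rng):
        path = report.zscore_histogram(rng.normal(0, 1, 500), tmp_path / "z.svg")
        assert path.exists() and path.stat().st_size > 0

    def test_renamed_column_breaks_loudly(self, tmp_path):
        manifest = stand_in_supplements(tmp_path)
        manifest["screen"]["z"] = "zscore_renamed"
        with pytest.raises(InvalidInputError, match="zscore_renamed"):
            report.reproduce_from_supplements(tmp_path, {"screen": manifest["screen"]})
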