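import numpy as np
import pandas as pd
import pytest

import lowph
from lowph.expression import ContrastTable
from lowph.response import call_direction, summarize_counts

from oracles import classify_by_direct_scan, random_contrast_pair, venn_regions_by_membership_scan


def contrast_from_dicts(fc_stress: dict, fc_control: dict, mutant: str = "B3") -> ContrastTable:
    table = pd.DataFrame({"fc_stress": pd.Series(fc_stress), "fc_control": pd.Series(fc_control)})
    table.index.name = "gene"
    return ContrastTable(mutant=mutant, reference="KF-7", table=table)


def classify(contrast: ContrastTable) -> lowph.ResponseSet:
    return lowph.classify_response(
        lowph.call_degs(contrast, "stress"),
        lowph.call_degs(contrast, "control"),
        contrast,
    )


class TestDegCalling:
    @pytest.mark.parametrize(
        "fc,expected",
        [
            (0.13, "down"),  # POX1, B3 vs KF-7 at pH 2.5
            (0.52, "none"),  # POX1 at pH 4.5: above the 0.5 cut
            (2.0, "up"),  # boundary inclusive
            (0.5, "down"),  # boundary inclusive
            (1.99, "none"),
            (3.46, "up"),
        ],
    )
    def test_threshold_rule(self, fc, expected):
        assert call_direction(fc) == expected

    def test_undefined_fold_changes_skipped(self):
        c = contrast_from_dicts({"a": 4.0, "b": np.nan}, {"a": 1.0, "b": 1.0})
        calls = lowph.call_degs(c, "stress")
        assert list(calls.index) == ["a"]

    def test_threshold_monotonicity(self):
        """Raising the up threshold can never grow the up-DEG set."""
        rng = np.random.default_rng(11)
        fs, fc = random_contrast_pair(rng, 200)
        c = contrast_from_dicts(fs, fc)
        prev = None
        for theta in (1.5, 2.0, 3.0, 5.0):
            ups = set(
                lowph.call_degs(c, "stress", theta_up=theta)
                .query("direction == 'up'").index
            )
            if prev is not None:
                assert ups <= prev
            prev = ups


class TestResponseFilter:
    def test_printed_worked_examples(self):
        """Fold-change pairs from the published tables classify as reported."""
        c = contrast_from_dicts(
            {"POX1": 0.13, "POT1": 0.06, "HSP30": 3.46},
            {"POX1": 0.52, "POT1": 0.17, "HSP30": 3.51},
            mutant="B3",
        )
        rs = classify(c)
        assert rs.table.at["POX1", "response_class"] == "unique_stress"
        assert rs.table.at["POT1", "response_class"] == "shared_amplified"  # 0.06/0.17 < 0.67
        assert rs.table.at["HSP30", "response_class"] == "shared_flat"  # 3.46/3.51 < 1.5
        assert rs.selected() == {"POX1", "POT1"}
        assert rs.table.at["HSP30", "selected"] == False  # noqa: E712

    def test_direction_flip_lands_in_unique_and_is_logged(self):
        c = contrast_from_dicts({"flip": 4.0}, {"flip": 0.25})
        rs = classify(c)
        assert rs.table.at["flip", "response_class"] == "unique_stress"
        assert rs.direction_flips == ["flip"]

    def test_ratio_threshold_strict(self):
        # ratio exactly 1.5 is NOT amplified (rule is strictly greater)
        c = contrast_from_dicts({"a": 3.0}, {"a": 2.0})
        rs = classify(c)
        assert rs.table.at["a", "response_class"] == "shared_flat"

    def test_gene_missing_from_contrast_is_consistency_error(self):
        c = contrast_from_dicts({"a": 4.0}, {"a": 1.0})
        stray = lowph.call_degs(
            contrast_from_dicts({"a": 4.0, "b": 4.0}, {"a": 1.0, "b": 1.0}), "stress"
        )
        with pytest.raises(ValueError):
            lowph.classify_response(stray, lowph.call_degs(c, "control"), c)

    def test_matches_direct_scan_on_random_contrasts(self):
        """Implementation agrees with a literal re-application of the rules."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            fs, fc = random_contrast_pair(rng, 50)
            c = contrast_from_dicts(fs, fc)
            rs = classify(c)
            expected = classify_by_direct_scan(fs, fc)
            got = rs.table["response_class"].to_dict()
            assert got == expected

    def test_partition_identity_and_tighter_rho_shrinks_amplified(self, noisy_sim):
        _, matrix, _ = noisy_sim
        c = lowph.build_contrasts(matrix)["B3"]
        calls_s = lowph.call_degs(c, "stress")
        calls_c = lowph.call_degs(c, "control")
        prev = None
        for rho_up in (1.2, 1.5, 2.0, 3.0):
            rs = lowph.classify_response(calls_s, calls_c, c, rho_up=rho_up)
            n = rs.table.groupby("direction").size()
            parts = rs.table.groupby(["direction", "response_class"]).size()
            for d in ("up", "down"):
                assert n.get(d, 0) == sum(
                    parts.get((d, k), 0)
                    for k in ("unique_stress", "shared_amplified", "shared_flat")
                )
            amp = rs.genes("shared_amplified", "up")
            if prev is not None:
                assert amp <= prev
            prev = amp


class TestVenn:
    def test_small_example(self):
        vs = lowph.venn_analysis({"B3": {"a", "b", "c"}, "C3": {"b", "c", "d"}, "BC3": {"c"}})
        assert vs.intersection("B3", "C3") == {"b", "c"}
        assert vs.intersection("B3", "C3", "BC3") == {"c"}
        assert vs.regions[frozenset({"B3", "C3"})] == {"b"}

    def test_disjoint_sets(self):
        vs = lowph.venn_analysis({"B3": {"a"}, "C3": {"b"}, "BC3": {"c"}})
        assert vs.intersection("B3", "C3") == set()
        assert vs.region_counts()["B3"] == 1

    def test_triple_subset_of_pairwise(self):
        rng = np.random.default_rng(5)
        pool = [f"g{i}" for i in range(40)]
        sets = {s: set(rng.choice(pool, 15, replace=False)) for s in ("B3", "C3", "BC3")}
        vs = lowph.venn_analysis(sets)
        triple = vs.intersection("B3", "C3", "BC3")
        for pair in (("B3", "C3"), ("B3", "BC3"), ("C3", "BC3")):
            assert triple <= vs.intersection(*pair)

    def test_matches_membership_scan_on_random_sets(self):
        rng = np.random.default_rng(17)
        pool = [f"g{i}" for i in range(60)]
        for _ in range(100):
            sets = {
                s: set(rng.choice(pool, rng.integers(0, 30), replace=False))
                for s in ("B3", "C3", "BC3")
            }
            vs = lowph.venn_analysis(sets)
            expected = venn_regions_by_membership_scan(sets)
            got = {
                "&".join(sorted(k)): v for k, v in vs.regions.items() if v
            }
            assert got == expected


class TestCountReport:
    def test_zero_noise_counts_equal_planted(self, zero_noise_sim):
        cfg, matrix, truth = zero_noise_sim
        contrasts = lowph.build_contrasts(matrix)
        sets = {s: classify(c) for s, c in contrasts.items()}
        counts = summarize_counts(sets)
        for strain in lowph.MUTANT_STRAINS:
            for d in ("up", "down"):
                planted = truth[(truth["direction"] == d)]
                for cls in ("unique_stress", "shared_amplified", "shared_flat"):
                    expected = int((planted["response_class"] == cls).sum())
                    row = counts[(counts["strain"] == strain) & (counts["direction"] == d)]
                    assert int(row[cls].iloc[0]) == expected

    def test_empty_input_all_zeros(self):
        c = contrast_from_dicts({"a": 1.0}, {"a": 1.0})
        counts = summarize_counts({"B3": classify(c)})
        assert (counts[["stress_degs", "unique_stress", "shared_amplified",
                        "shared_flat", "selected"]].to_numpy() == 0).all()
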