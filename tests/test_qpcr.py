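import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lowph
from lowph.qpcr import CtTable


def ct_table_from_means(ct_means: dict, n_technical: int = 1, reference: str = "ACT1") -> CtTable:
    """Build a CtTable from {(gene, sample): mean Ct} with identical technical reps."""
    rows = [
        (gene, sample, tech, ct)
        for (gene, sample), ct in ct_means.items()
        for tech in range(1, n_technical + 1)
    ]
    return CtTable(
        pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"]),
        reference_gene=reference,
    )


class TestDdct:
    def test_hand_arithmetic(self):
        # dCt: 20-18 = 2 (treat), 22-18 = 4 (control); ddCt = -2 -> 2^2 = 4
        ct = ct_table_from_means(
            {
                ("TAR", "t1"): 20.0, ("ACT1", "t1"): 18.0,
                ("TAR", "c1"): 22.0, ("ACT1", "c1"): 18.0,
            }
        )
        assert lowph.ddct_fold_change(ct, "TAR", ["t1"], ["c1"]) == pytest.approx(4.0)

    def test_ddct_zero_gives_one(self):
        ct = ct_table_from_means(
            {
                ("TAR", "t1"): 21.0, ("ACT1", "t1"): 18.0,
                ("TAR", "c1"): 24.0, ("ACT1", "c1"): 21.0,
            }
        )
        assert lowph.ddct_fold_change(ct, "TAR", ["t1"], ["c1"]) == pytest.approx(1.0)

    def test_reference_gene_against_itself_is_one(self):
        ct = ct_table_from_means(
            {("ACT1", "t1"): 18.0, ("ACT1", "c1"): 23.5}
        )
        assert lowph.ddct_fold_change(ct, "ACT1", ["t1"], ["c1"]) == pytest.approx(1.0)

    def test_plate_offset_cancels(self):
        """Adding a constant to every Ct of one sample leaves 2^-ddCt unchanged."""
        base = {
            ("TAR", "t1"): 20.0, ("ACT1", "t1"): 18.0,
            ("TAR", "t2"): 20.4, ("ACT1", "t2"): 18.1,
            ("TAR", "c1"): 22.0, ("ACT1", "c1"): 18.0,
        }
        fc0 = lowph.ddct_fold_change(ct_table_from_means(base), "TAR", ["t1", "t2"], ["c1"])
        shifted = {
            (g, s): ct + (3.7 if s == "t1" else 0.0) for (g, s), ct in base.items()
        }
        fc1 = lowph.ddct_fold_change(ct_table_from_means(shifted), "TAR", ["t1", "t2"], ["c1"])
        assert fc1 == pytest.approx(fc0, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        cts=st.lists(st.floats(10, 35), min_size=4, max_size=4),
        offset=st.floats(-8, 8),
    )
    def test_plate_offset_cancels_property(self, cts, offset):
        base = {
            ("TAR", "t1"): cts[0], ("ACT1", "t1"): cts[1],
            ("TAR", "c1"): cts[2], ("ACT1", "c1"): cts[3],
        }
        shifted = {(g, s): ct + (offset if s == "t1" else 0.0) for (g, s), ct in base.items()}
        fc0 = lowph.ddct_fold_change(ct_table_from_means(base), "TAR", ["t1"], ["c1"])
        fc1 = lowph.ddct_fold_change(ct_table_from_means(shifted), "TAR", ["t1"], ["c1"])
        assert fc1 == pytest.approx(fc0, rel=1e-9)

    def test_technical_replicates_averaged_on_ct_scale(self):
        rows = [
            ("TAR", "t1", 1, 19.0), ("TAR", "t1", 2, 21.0),  # mean 20
            ("ACT1", "t1", 1, 18.0),
            ("TAR", "c1", 1, 22.0), ("ACT1", "c1", 1, 18.0),
        ]
        ct = CtTable(pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"]))
        assert lowph.ddct_fold_change(ct, "TAR", ["t1"], ["c1"]) == pytest.approx(4.0)

    def test_missing_reference_in_a_sample_is_error(self):
        with pytest.raises(ValueError, match="reference gene"):
            ct_table_from_means({("TAR", "t1"): 20.0, ("ACT1", "c1"): 18.0})

    def test_noisy_estimate_within_monte_carlo_band(self):
        """With 0.1-cycle noise and 3 technical reps, the estimate stays inside a
        band derived from a 1000-draw simulation of the same measurement model."""
        rng = np.random.default_rng(0)
        planted_fc = 4.0
        draws = []
        for _ in range(1000):
            # two bio reps per group, 3 technical reps, sd 0.1 cycles
            def mean_ct(true_ct):
                return true_ct + rng.normal(0, 0.1, 3).mean()

            dct_t = [mean_ct(20.0 - math.log2(planted_fc)) - mean_ct(18.0) for _ in range(2)]
            dct_c = [mean_ct(20.0) - mean_ct(18.0) for _ in range(2)]
            fcs = [2.0 ** -(d - np.mean(dct_c)) for d in dct_t]
            draws.append(np.mean(fcs))
        lo, hi = np.quantile(draws, [0.0005, 0.9995])

        _, truth = lowph.simulate_expression(lowph.SimulationConfig(seed=12))
        gene = truth.index[truth["fc_stress"] == 4.0][0]
        ref = truth.index[truth["response_class"] == "null"][-1]
        ct = lowph.simulate_qpcr(truth, [gene], ref, seed=12, noise_sd=0.1, n_technical=3)
        fc = lowph.ddct_fold_change(
            ct, gene,
            ["B3_pH2.5_r1", "B3_pH2.5_r2"],
            ["KF-7_pH2.5_r1", "KF-7_pH2.5_r2"],
        )
        assert lo <= fc <= hi


class TestConcordance:
    def test_identical_vectors_perfect(self):
        fc = {"a": 2.0, "b": 0.3, "c": 5.0}
        rep = lowph.concordance(fc, dict(fc))
        assert rep.sign_agreement == 1.0
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_opposite_vectors_zero_agreement(self):
        q = {"a": 2.0, "b": 0.25, "c": 8.0}
        a = {g: 1.0 / v for g, v in q.items()}
        rep = lowph.concordance(q, a)
        assert rep.sign_agreement == 0.0
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_empty_overlap_is_error(self):
        with pytest.raises(ValueError):
            lowph.concordance({"a": 2.0}, {"b": 2.0})

    def test_noiseless_synthetic_qpcr_agrees_with_planted_fold_changes(self):
        cfg = lowph.SimulationConfig(noise_cv=0.0, seed=4)
        matrix, truth = lowph.simulate_expression(cfg)
        # one gene per planted class x direction so the panel spans distinct fcs
        panel = list(
            truth[truth["direction"] != "none"]
            .groupby(["response_class", "direction"], observed=True)
            .head(1)
            .index
        )
        ref = truth.index[truth["response_class"] == "null"][-1]
        ct = lowph.simulate_qpcr(truth, panel, ref, seed=4, noise_sd=0.0)
        contrast = lowph.build_contrasts(matrix)["B3"]
        qpcr_fc = {
            g: lowph.ddct_fold_change(
                ct, g,
                ["B3_pH2.5_r1", "B3_pH2.5_r2"],
                ["KF-7_pH2.5_r1", "KF-7_pH2.5_r2"],
            )
            for g in panel
        }
        array_fc = {g: float(contrast.table.at[g, "fc_stress"]) for g in panel}
        rep = lowph.concordance(qpcr_fc, array_fc)
        assert rep.sign_agreement == 1.0
        assert rep.spearman_rho == pytest.approx(1.0)
        np.testing.assert_allclose(
            rep.per_gene["qpcr_fc"], rep.per_gene["array_fc"], rtol=1e-9
        )
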