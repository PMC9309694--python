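"""FPKM, TMM normalization, the NB exact conditional test and the filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet import diffexpr, simdata
from cernet.diffexpr import (
    apply_de_filter,
    exact_test,
    fpkm,
    normalization_factors,
    select_candidate_lncrnas,
)
from cernet.seqio import ExpressionMatrix, ValidationError
from conftest import make_matrix


class TestFPKM:
    def test_plug_in_value(self):
        m = make_matrix({"f1": [10, 10], "f2": [999_990, 999_990]})
        m.lengths = pd.Series([1000, 1000], index=["f1", "f2"])
        out = fpkm(m)
        # counts=10, length=1000 bp, library=1e6 reads -> FPKM 10
        assert out.loc["f1"].tolist() == pytest.approx([10.0, 10.0])

    def test_scale_invariance(self):
        m1 = make_matrix({"f1": [10, 20], "f2": [90, 80]})
        m2 = make_matrix({"f1": [20, 40], "f2": [180, 160]})
        m1.lengths = m2.lengths = pd.Series([500, 2000], index=["f1", "f2"])
        assert np.allclose(fpkm(m1).to_numpy(), fpkm(m2).to_numpy())

    def test_matches_naive_recomputation(self, reference_dataset):
        mrna = reference_dataset[2].subset([f"MRN{i:06d}" for i in range(1, 51)])
        mrna.lengths = reference_dataset[2].lengths.loc[mrna.features]
        lib = reference_dataset[2].counts.sum(axis=0)  # library = all mapped reads
        got = fpkm(reference_dataset[2]).loc[mrna.features]
        for f in mrna.features[:10]:
            for s in mrna.samples:
                naive = (
                    reference_dataset[2].counts.loc[f, s]
                    * 1e9
                    / (mrna.lengths[f] * lib[s])
                )
                assert got.loc[f, s] == pytest.approx(naive, rel=1e-9)

    def test_missing_lengths_error(self):
        with pytest.raises(ValidationError, match="length"):
            fpkm(make_matrix({"f1": [1, 2], "f2": [3, 4]}))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        m = make_matrix({f"f{i}": [i + 1, i + 1] for i in range(50)})
        f = normalization_factors(m)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        rows = {f"f{i}": [i + 1, 2 * (i + 1)] for i in range(50)}
        f = normalization_factors(make_matrix(rows))
        assert np.allclose(f.factors, 1.0)
        assert f.effective_lib_sizes.iloc[1] == pytest.approx(
            2 * f.effective_lib_sizes.iloc[0]
        )

    def test_geometric_mean_one(self, reference_dataset):
        f = normalization_factors(reference_dataset[2])
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0)

    def test_recovers_planted_library_sizes(self):
        """Effective library sizes track the generator's multipliers (no DE)."""
        cfg = simdata.SimulationConfig(seed=3, n_lnc=3, n_mir=3, n_mrna=2000,
                                       n_planted_triplets=0)
        _, _, mrna, _ = simdata.simulate_counts(cfg)
        truth = simdata.planted_library_sizes(cfg, "mRNA")
        est = normalization_factors(mrna).effective_lib_sizes
        rho = stats.spearmanr(est.to_numpy(), truth.to_numpy()).statistic
        assert rho > 0.9

    def test_all_zero_sample_rejected(self):
        m = make_matrix({"f1": [1, 0], "f2": [2, 0]})
        with pytest.raises(ValidationError, match="zero"):
            normalization_factors(m)


class TestExactTest:
    def test_symmetric_null_gives_p_one(self):
        m = make_matrix({"f1": [5, 7, 9, 5, 7, 9], "f2": [3, 3, 3, 3, 3, 3]})
        res = exact_test(m)
        assert np.allclose(res["p"], 1.0)

    def test_all_zero_feature(self):
        m = make_matrix({"f0": [0, 0, 0, 0, 0, 0], "f1": [4, 5, 6, 5, 4, 6]})
        res = exact_test(m).set_index("feature_id")
        assert res.loc["f0", "p"] == 1.0
        assert res.loc["f0", "log2fc"] == 0.0

    def test_single_sample_group_flagged_p_one(self):
        m = make_matrix({"f1": [1, 5, 6, 7], "f2": [9, 5, 4, 3]}, n_case=1)
        res = exact_test(m)
        assert (res["p"] == 1.0).all()

    def test_group_swap_symmetry(self, reference_dataset):
        lnc = reference_dataset[0]
        res = exact_test(lnc)
        flipped_groups = lnc.groups.map({"A-ED": "NC", "NC": "A-ED"})
        flipped = ExpressionMatrix(counts=lnc.counts, groups=flipped_groups,
                                   rna_class="lncRNA")
        res2 = exact_test(flipped)
        assert np.allclose(res["p"], res2["p"], atol=1e-9)
        assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-9)

    def test_conditional_p_is_unimodal_in_group_sum(self):
        """Moving the group-A sum away from the centre never increases p."""
        total, n_a, n_b, phi = 40, 3, 3, 0.2
        ps = [diffexpr._exact_p(y, total, n_a, n_b, phi) for y in range(total + 1)]
        peak = int(np.argmax(ps))
        assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(peak))
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(peak, total))

    def test_strong_shift_detected(self):
        m = make_matrix({"f1": [100, 120, 110, 10, 12, 11],
                         "f2": [50, 55, 60, 50, 60, 55],
                         "f3": [30, 28, 35, 30, 33, 29]})
        res = exact_test(m, dispersion=0.1).set_index("feature_id")
        assert res.loc["f1", "p"] < 0.01
        assert res.loc["f1", "log2fc"] > 2
        assert res.loc["f1", "direction"] == "up"

    def test_fdr_monotone_in_p(self, reference_dataset):
        res = exact_test(reference_dataset[2].subset(
            [f"MRN{i:06d}" for i in range(1, 201)]))
        ordered = res.sort_values("p")
        assert (np.diff(ordered["fdr"]) >= -1e-12).all()
        assert (ordered["fdr"] >= ordered["p"] - 1e-12).all()


class TestFilters:
    @staticmethod
    def _frame(**kw):
        base = dict(feature_id="f", rna_class="lncRNA", mean_nc=10.0, mean_aed=10.0,
                    mean_count=10.0, log2fc=3.0, p=0.001, fdr=0.01, direction="up",
                    passes_de=False, passes_candidate_window=False)
        base.update(kw)
        return pd.DataFrame([base])

    def test_de_filter_strict_inequalities(self):
        assert not apply_de_filter(self._frame(p=0.05))["passes_de"].iloc[0]
        assert not apply_de_filter(self._frame(log2fc=2.0))["passes_de"].iloc[0]
        assert apply_de_filter(self._frame(p=0.049, log2fc=2.01))["passes_de"].iloc[0]
        assert apply_de_filter(self._frame(log2fc=-2.5))["passes_de"].iloc[0]

    def test_candidate_window_boundaries(self):
        col = "passes_candidate_window"
        assert not select_candidate_lncrnas(self._frame(mean_count=120.0))[col].iloc[0]
        assert not select_candidate_lncrnas(self._frame(mean_count=1.0))[col].iloc[0]
        assert not select_candidate_lncrnas(self._frame(log2fc=1.0))[col].iloc[0]
        assert select_candidate_lncrnas(self._frame(mean_count=119.9, log2fc=1.1))[
            col
        ].iloc[0]

    def test_recovery_of_planted_features(self, reference_dataset):
        lnc, mir, mrna, truth, _ = reference_dataset
        res = apply_de_filter(exact_test(mrna))
        de = set(res.loc[res["passes_de"], "feature_id"])
        assert len(truth.planted_mrnas & de) / len(truth.planted_mrnas) >= 0.9
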