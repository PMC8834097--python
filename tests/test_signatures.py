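import warnings

import numpy as np
import pytest

import cytosig as cs
from cytosig.panel import PanelError
from cytosig.stability import StabilityProfile


def make_profile(names, means, cvs):
    means = np.asarray(means, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    return StabilityProfile(
        analyte_names=list(names), mean_loading=means,
        sd_loading=cvs * np.abs(means), cv=cvs,
        K=3, n_iterations=100, reference_loadings=means.copy(),
    )


class TestSelectCoincident:
    def test_thresholds_honored_exactly(self):
        names = ["at_mean", "below_mean", "at_cv", "good"]
        a = make_profile(names, [0.2, 0.199, 0.5, 0.3], [0.5, 0.5, 1.0, 0.5])
        b = make_profile(names, [0.2, 0.199, 0.5, 0.3], [0.5, 0.5, 1.0, 0.5])
        sig = cs.select_coincident(a, b)
        # mean ≥ 0.2 inclusive, cv < 1 strict
        assert sig.analytes == ["at_mean", "good"]

    def test_direction_mismatch_excluded(self):
        a = make_profile(["x"], [0.5], [0.2])
        b = make_profile(["x"], [-0.5], [0.2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert cs.select_coincident(a, b).analytes == []
        crit = cs.SignatureCriteria(require_direction_match=False)
        assert cs.select_coincident(a, b, crit).analytes == ["x"]

    def test_case_down_analyte_kept_with_direction(self):
        a = make_profile(["x"], [-0.3], [0.5])
        b = make_profile(["x"], [-0.4], [0.5])
        sig = cs.select_coincident(a, b)
        assert sig.analytes == ["x"]
        assert sig.directions["x"] == "case-down"

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        names = [f"a{i}" for i in range(20)]
        a = make_profile(names, rng.uniform(-0.6, 0.6, 20), rng.uniform(0.1, 2.0, 20))
        b = make_profile(names, rng.uniform(-0.6, 0.6, 20), rng.uniform(0.1, 2.0, 20))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ab = set(cs.select_coincident(a, b).analytes)
            ba = set(cs.select_coincident(b, a).analytes)
        assert ab == ba

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"a{i}" for i in range(30)]
        a = make_profile(names, rng.uniform(-0.6, 0.6, 30), rng.uniform(0.1, 2.0, 30))
        b = make_profile(names, rng.uniform(-0.6, 0.6, 30), rng.uniform(0.1, 2.0, 30))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loose = set(cs.select_coincident(a, b, cs.SignatureCriteria(0.1, 1.5)).analytes)
            tight_mean = set(cs.select_coincident(a, b, cs.SignatureCriteria(0.3, 1.5)).analytes)
            tight_cv = set(cs.select_coincident(a, b, cs.SignatureCriteria(0.1, 0.5)).analytes)
        assert tight_mean <= loose
        assert tight_cv <= loose

    def test_disjoint_profiles_error(self):
        a = make_profile(["x"], [0.5], [0.1])
        b = make_profile(["y"], [0.5], [0.1])
        with pytest.raises(PanelError, match="share"):
            cs.select_coincident(a, b)

    def test_empty_selection_warns_not_raises(self):
        a = make_profile(["x"], [0.05], [0.1])
        b = make_profile(["x"], [0.05], [0.1])
        with pytest.warns(UserWarning, match="no analyte"):
            sig = cs.select_coincident(a, b)
        assert len(sig) == 0

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            cs.SignatureCriteria(mean_threshold=0.0)


class TestReducedFit:
    def test_all_analytes_signature_reproduces_full_model(self, human_panel):
        full = cs.fit_panel(human_panel, "group", case_label="MLIV")
        sig = cs.SignatureSet(human_panel.analyte_names,
                              {a: "case-up" for a in human_panel.analyte_names})
        red = cs.reduced_fit(human_panel, sig, "group", case_label="MLIV")
        np.testing.assert_allclose(red.scores, full.scores, atol=1e-10)

    def test_single_analyte_weight_is_unit(self, human_panel):
        sig = cs.SignatureSet([human_panel.analyte_names[0]])
        red = cs.reduced_fit(human_panel, sig, "group", case_label="MLIV")
        assert abs(red.lv1_loadings[0]) == pytest.approx(1.0, abs=1e-10)

    def test_missing_analyte_error(self, human_panel):
        sig = cs.SignatureSet(["NOT-THERE"])
        with pytest.raises(PanelError, match="NOT-THERE"):
            cs.reduced_fit(human_panel, sig, "group", case_label="MLIV")

    def test_planted_signature_separates_as_well_as_full(self, human_cohort):
        panel, truth = human_cohort
        full = cs.fit_panel(panel, "group", case_label="MLIV")
        sig = cs.SignatureSet(truth.planted_analytes)
        red = cs.reduced_fit(panel, sig, "group", case_label="MLIV")
        labels = panel.groups()
        auc_full = cs.lv1_auc(full.scores[:, 0], labels, "MLIV")
        auc_red = cs.lv1_auc(red.scores[:, 0], labels, "MLIV")
        assert auc_red >= auc_full - 0.05


class TestTransfer:
    def test_transfer_onto_training_panel_reproduces_auc(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        auc_train = cs.lv1_auc(model.scores[:, 0], human_panel.groups(), "MLIV")
        res = cs.transfer_signature(model, human_panel)
        assert res.auc == auc_train
        np.testing.assert_allclose(res.scores["LV1"].to_numpy(), model.scores[:, 0],
                                   atol=1e-10)

    def test_coverage_gap_error_names_analytes(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        smaller = human_panel.subset_analytes(human_panel.analyte_names[2:])
        with pytest.raises(PanelError, match=human_panel.analyte_names[0]):
            cs.transfer_signature(model, smaller)

    def test_auc_invariant_to_positive_rescaling(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        scaled = human_panel.copy()
        scaled.concentrations.iloc[:, 0] *= 1000.0
        scaled.concentrations.iloc[:, 5] *= 0.001
        res1 = cs.transfer_signature(model, human_panel)
        res2 = cs.transfer_signature(model, scaled)
        assert res1.auc == pytest.approx(res2.auc, abs=1e-12)

    def test_map_translates_analyte_names(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        renamed = human_panel.copy()
        renamed.concentrations.columns = [f"m_{a}" for a in human_panel.analyte_names]
        amap = cs.AnalyteMap([(a, f"m_{a}") for a in human_panel.analyte_names])
        res = cs.transfer_signature(model, renamed, amap=amap)
        assert res.auc == cs.lv1_auc(model.scores[:, 0], human_panel.groups(), "MLIV")
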