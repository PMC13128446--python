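"""APEX time-course scoring and spatial deconvolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morpharm import apex
from morpharm import synthetic as syn


def brute_force_f(y, ranks, batches):
    """Independent oracle: nested-model F from explicit residual sums of
    squares using raw (non-orthogonalized) polynomial and dummy columns."""
    y = np.asarray(y, float)
    r = np.asarray(ranks, float)
    levels = sorted(set(batches))
    dummies = np.column_stack([[1.0 if b == lev else 0.0 for b in batches]
                               for lev in levels[1:]]) if len(levels) > 1 else \
        np.empty((len(y), 0))
    x_null = np.column_stack([np.ones_like(y), dummies])
    x_full = np.column_stack([x_null, r, r ** 2, r ** 3])
    def rss(x):
        beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        return float(((y - x @ beta) ** 2).sum()), rank
    rss0, rank0 = rss(x_null)
    rss1, rank1 = rss(x_full)
    d = rank1 - rank0
    df = len(y) - rank1
    f = ((rss0 - rss1) / d) / (rss1 / df)
    return f, float(stats.f.sf(f, d, df))


class TestScoreTimecourse:
    def test_matches_brute_force_oracle_to_1e10(self):
        rng = np.random.default_rng(0)
        ranks = np.tile([1, 2, 3, 4, 5], 4)
        batches = np.repeat(["b1", "b2"], 10)
        y = 20 + 0.3 * ranks + 0.05 * ranks ** 2 + rng.normal(0, 0.4, 20)
        y += np.where(batches == "b2", 0.7, 0.0)
        score = apex.score_timecourse(y, ranks, batches)
        f_ref, p_ref = brute_force_f(y, ranks, batches)
        assert score.f_stat == pytest.approx(f_ref, abs=1e-10 * max(1, f_ref))
        assert score.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_constant_series_null(self):
        ranks = np.tile([1, 2, 3, 4, 5], 2)
        score = apex.score_timecourse(np.full(10, 21.0), ranks, ["b1"] * 10)
        assert score.f_stat == pytest.approx(0.0, abs=1e-8)
        assert score.max_log2fc == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_rise_gives_exact_fc_and_huge_f(self):
        ranks = np.tile([1, 2, 3, 4, 5], 2)
        y = 20.0 + 2.0 * (ranks - 1) / 4.0  # +2 log2 units by rank 5
        score = apex.score_timecourse(y, ranks, ["b1"] * 10)
        assert score.max_log2fc == pytest.approx(2.0, abs=1e-9)
        assert score.f_stat > 1e10 or np.isinf(score.f_stat)

    def test_missing_cells_imputed_from_model(self):
        ranks = np.tile([1, 2, 3, 4, 5], 2)
        y = 20.0 + 1.0 * (ranks - 1) / 4.0
        y = y.astype(float)
        y[3] = np.nan  # one rank-4 cell missing
        score = apex.score_timecourse(y, ranks, ["b1"] * 10)
        # linear trend is inside the cubic model, so imputation is exact
        assert score.max_log2fc == pytest.approx(1.0, abs=1e-8)

    def test_all_missing_and_single_rank_flagged(self):
        ranks = np.array([1, 1, 2, 2])
        s1 = apex.score_timecourse([np.nan] * 4, ranks, ["b1"] * 4)
        assert s1.flagged
        s2 = apex.score_timecourse([1.0, 2.0, np.nan, np.nan], ranks, ["b1"] * 4)
        assert s2.flagged and "time ranks" in s2.message


class TestInteractors:
    def test_threshold_logic(self):
        scores = pd.DataFrame({
            "max_log2fc": [np.log2(1.4), 1.0, 2.0, 0.9],
            "p": [0.001, 0.04, 0.2, 0.05],
        }, index=["a", "b", "c", "d"])
        # a fails FC, b passes both, c fails p, d passes (0.9 > log2 1.5)
        assert apex.call_interactors(scores) == {"b", "d"}

    def test_constructed_set_of_three(self):
        rng = np.random.default_rng(1)
        ranks = np.tile([1, 2, 3, 4, 5], 2)
        batches = ["b1"] * 10
        rows = {}
        for i in range(7):  # null proteins
            rows[f"null{i}"] = 20 + rng.normal(0, 0.2, 10)
        for i in range(3):  # strong responders
            rows[f"resp{i}"] = 20 + 1.5 * (ranks - 1) / 4.0 + rng.normal(0, 0.1, 10)
        mat = pd.DataFrame(rows).T
        mat.columns = [f"s{i}" for i in range(10)]
        sheet = pd.DataFrame({
            "sample_id": mat.columns, "role": "mor_apex", "ligand": "DAMGO",
            "time_rank": ranks, "batch": batches,
        })
        scores = apex.score_all(mat, sheet, "DAMGO")
        assert apex.call_interactors(scores) == {"resp0", "resp1", "resp2"}


def _ref_sheet(comps, n_rep=3):
    rows = []
    for c in comps:
        for r in range(1, n_rep + 1):
            rows.append({"sample_id": f"{c}_r{r}", "role": "spatial_reference",
                         "ligand": "none", "time_rank": 0, "replicate": r,
                         "batch": "b1", "compartment": c})
    return pd.DataFrame(rows)


class TestSelectMarkers:
    def test_constructed_panel_of_two(self):
        comps = ["pm", "endo", "lyso", "cyto"]
        sheet = _ref_sheet(comps)
        rng = np.random.default_rng(2)
        base = 20.0
        rows = {}
        # two clean markers: elevated +3 in one compartment, abundant
        for name, comp in [("mk1", "pm"), ("mk2", "endo")]:
            vals = []
            for c in comps:
                mu = base + (3.0 if c == comp else 0.0)
                vals += list(mu + rng.normal(0, 0.1, 3))
            rows[name] = vals
        # flat protein and a weakly-shifted protein (below FC threshold)
        rows["flat"] = list(base + rng.normal(0, 0.1, 12))
        vals = []
        for c in comps:
            vals += list(base + (0.5 if c == "pm" else 0.0) + rng.normal(0, 0.1, 3))
        rows["weak"] = vals
        # strongly shifted but scarce: everything below the global median
        vals = []
        for c in comps:
            vals += list(10.0 + (3.0 if c == "lyso" else 0.0) + rng.normal(0, 0.1, 3))
        rows["scarce"] = vals
        rows["abundant_flat"] = list(25.0 + rng.normal(0, 0.1, 12))
        mat = pd.DataFrame(rows, index=sheet["sample_id"]).T
        panel = apex.select_markers(mat, sheet)
        assert set(panel.index) == {"mk1", "mk2"}
        assert panel.loc["mk1", "compartment"] == "pm"
        assert panel.loc["mk2", "compartment"] == "endo"

    def test_identical_compartments_give_empty_panel(self):
        sheet = _ref_sheet(["pm", "endo"])
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(20, 0.05, (5, 6)),
                           index=[f"p{i}" for i in range(5)],
                           columns=sheet["sample_id"])
        assert len(apex.select_markers(mat, sheet)) == 0

    def test_single_replicate_compartment_refused(self):
        sheet = _ref_sheet(["pm", "endo"]).iloc[:4]  # endo keeps 1 replicate
        mat = pd.DataFrame(np.ones((2, 4)) * 20, index=["a", "b"],
                           columns=sheet["sample_id"])
        with pytest.raises(ValueError, match="replicates"):
            apex.select_markers(mat, sheet)


class TestScaling:
    def test_row_scaling_rule(self):
        mat = pd.DataFrame([[100.0, 200.0, np.nan]], index=["p"],
                           columns=["a", "b", "c"])
        out = apex.scale_intensities(mat)
        assert out.loc["p"].tolist() == [0.5, 1.0, 0.0]

    def test_all_equal_row_maps_to_ones(self):
        mat = pd.DataFrame([[7.0, 7.0, 7.0]], index=["p"], columns=list("abc"))
        assert (apex.scale_intensities(mat).loc["p"] == 1.0).all()

    def test_idempotent_and_bounded(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.uniform(0, 50, (6, 8)))
        once = apex.scale_intensities(mat)
        twice = apex.scale_intensities(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())
        assert ((once.to_numpy() >= 0) & (once.to_numpy() <= 1)).all()

    def test_zero_row_dropped(self):
        mat = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["z", "p"],
                           columns=["a", "b"])
        out = apex.scale_intensities(mat)
        assert list(out.index) == ["p"]


class TestReferenceSystem:
    def test_f_is_replicate_mean_and_s_is_panel_rows(self):
        comps = ("pm", "endo")
        sheet = _ref_sheet(list(comps))
        mat = pd.DataFrame({
            "pm_r1": [0.2, 0.1], "pm_r2": [0.4, 0.1], "pm_r3": [0.6, 0.1],
            "endo_r1": [0.1, 0.8], "endo_r2": [0.1, 0.9], "endo_r3": [0.1, 1.0],
        }, index=["a", "b"])
        f_mat, s_mat = apex.build_reference_system(mat, sheet, ["b"], compartments=comps)
        assert f_mat.loc["a", "pm"] == pytest.approx(0.4)
        assert list(s_mat.index) == ["b"]
        assert list(s_mat.columns) == list(comps)

    def test_empty_panel_refused(self):
        sheet = _ref_sheet(["pm", "endo"])
        mat = pd.DataFrame(np.ones((2, 6)), index=["a", "b"], columns=sheet["sample_id"])
        with pytest.raises(ValueError, match="empty"):
            apex.build_reference_system(mat, sheet, [], compartments=("pm", "endo"))


class TestDeconvolve:
    def setup_method(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 1, (40, 4))
        s[:10, 0] += 1.0; s[10:20, 1] += 1.0; s[20:30, 2] += 1.0; s[30:, 3] += 1.0
        self.s = pd.DataFrame(np.clip(s, 0, None) / s.max(),
                              columns=["pm", "ee", "lyl", "cyt"])

    def test_pure_member_recovers_indicator(self):
        coef = apex.deconvolve_sample(self.s["pm"].to_numpy(), self.s,
                                      n_repeats=100, seed=0)
        assert coef["pm"] == pytest.approx(1.0, abs=1e-9)
        assert coef.drop("pm").abs().max() < 1e-9

    def test_mixture_recovered_to_1e6(self):
        y = 0.6 * self.s["pm"].to_numpy() + 0.4 * self.s["ee"].to_numpy()
        coef = apex.deconvolve_sample(y, self.s, n_repeats=100, seed=1)
        assert np.allclose(coef.to_numpy(), [0.6, 0.4, 0.0, 0.0], atol=1e-6)

    def test_same_seed_reproduces_medians(self):
        y = 0.5 * self.s["pm"].to_numpy() + 0.5 * self.s["cyt"].to_numpy() \
            + np.random.default_rng(9).normal(0, 0.02, len(self.s))
        a = apex.deconvolve_sample(y, self.s, n_repeats=50, seed=42)
        b = apex.deconvolve_sample(y, self.s, n_repeats=50, seed=42)
        assert (a == b).all()

    def test_nonnegative_always(self):
        rng = np.random.default_rng(6)
        y = rng.uniform(-0.1, 1.0, len(self.s))
        coef = apex.deconvolve_sample(y, self.s, n_repeats=20, seed=3)
        assert (coef >= 0).all()

    def test_dimension_mismatch_refused(self):
        with pytest.raises(ValueError):
            apex.deconvolve_sample(np.ones(7), self.s, n_repeats=5, seed=0)


class TestEndToEnd:
    def test_trafficking_recovery(self, apex_dataset):
        matrix, sheet, gt = apex_dataset
        coefs = apex.spatial_coefficients(matrix, sheet, seed=0, n_repeats=100)
        prof = apex.trafficking_profile(coefs)
        damgo = prof[prof.ligand == "DAMGO"].sort_values("time_rank")
        true_pm = [gt.params["trafficking"]["DAMGO"][r][0] for r in range(1, 6)]
        # PM occupancy declines monotonically and tracks the truth
        est = damgo["plasma_membrane_mean"].to_numpy()
        assert (np.diff(est) < 0.05).all()
        assert np.abs(est - np.array(true_pm)).max() < 0.12

    def test_replicate_permutation_leaves_means_unchanged(self, apex_dataset):
        matrix, sheet, _ = apex_dataset
        panel = apex.select_markers(matrix, sheet)
        coefs = apex.spatial_coefficients(matrix, sheet, seed=1, n_repeats=20,
                                          panel=panel)
        prof1 = apex.trafficking_profile(coefs)
        shuffled = coefs.sample(frac=1.0, random_state=0)
        prof2 = apex.trafficking_profile(shuffled)
        cols = [c for c in prof1.columns if c.endswith("_mean")]
        assert np.allclose(prof1[cols].to_numpy(), prof2[cols].to_numpy())


def test_summarize_features_drops_single_feature_proteins():
    feats = pd.DataFrame({
        "protein": ["A", "A", "A", "A", "B", "B"],
        "feature": ["f1", "f2", "f1", "f2", "f1", "f1"],
        "sample": ["s1", "s1", "s2", "s2", "s1", "s2"],
        "intensity": [100.0, 300.0, 200.0, 600.0, 50.0, 70.0],
    })
    mat = apex.summarize_features(feats)
    assert list(mat.index) == ["A"]  # B has one feature
    assert mat.loc["A", "s1"] == pytest.approx(np.log2(400.0))
    assert mat.loc["A", "s2"] == pytest.approx(np.log2(800.0))
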