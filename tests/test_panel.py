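"""Hit rates, selectivity labels, randomization, ROC, binning, predictor evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pottsthread.panel import (
    AVERAGE,
    BindingPanel,
    STRONG,
    WEAK,
    affinity_class,
    affinity_classes,
    bin_by_score,
    binned_affinity_distribution,
    evaluate_predictions,
    hit_rate,
    hit_rates,
    label_selectivity,
    most_promiscuous,
    panel_from_long,
    panel_from_wide,
    panel_to_long,
    read_panel_csv,
    read_panel_excel,
    roc_auc,
    subset_randomization,
    write_panel_csv,
)
from pottsthread.threadscore import PROMISCUOUS, SELECTIVE


def make_panel(kd, censor=10000.0, datasets=None):
    kd = np.asarray(kd, dtype=float)
    nk, ni = kd.shape
    return BindingPanel(
        kinases=[f"K{i}" for i in range(nk)],
        inhibitors=[f"I{j}" for j in range(ni)],
        datasets=datasets or ["davis"] * ni,
        kd=kd,
        censor_value=censor,
    )


def mw_auc(scores, y):
    """Mann-Whitney oracle: concordant pairs = 1, ties = 1/2."""
    pos = [s for s, t in zip(scores, y) if t]
    neg = [s for s, t in zip(scores, y) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestHitRate:
    def test_censored_values_never_count(self):
        p = make_panel([[470, 10000, 10000, 10000]])
        assert hit_rate(p, "K0") == 1

    def test_boundary_is_strict(self):
        p = make_panel([[10000.0, 9999.9]], censor=20000.0)
        # 10000 exactly at the cutoff is not a hit even though uncensored here
        assert hit_rate(p, "K0", kd_cutoff_nM=10000.0) == 1

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(1)
        kd = 10 ** rng.uniform(0, 4.5, size=(8, 20))
        kd[rng.random((8, 20)) < 0.2] = 10000.0
        p = make_panel(kd)
        hm_expected = (kd < 10000.0)
        for i, k in enumerate(p.kinases):
            assert hit_rate(p, k) == hm_expected[i].sum()

    def test_missing_pairs_excluded(self):
        kd = np.array([[50.0, np.nan, 200.0]])
        p = make_panel(kd)
        assert hit_rate(p, "K0") == 2

    def test_monotone_in_cutoff_and_subset(self):
        rng = np.random.default_rng(2)
        kd = 10 ** rng.uniform(0, 4, size=(5, 10))
        p = make_panel(kd)
        cuts = [10, 100, 1000, 10000]
        for k in p.kinases:
            rates = [hit_rate(p, k, kd_cutoff_nM=c) for c in cuts]
            assert rates == sorted(rates)
            sub = hit_rate(p, k, inhibitor_subset=p.inhibitors[:4])
            assert sub <= hit_rate(p, k)

    def test_unknown_ids_rejected(self):
        p = make_panel([[100.0, 200.0]])
        with pytest.raises(KeyError):
            hit_rate(p, "nope")
        with pytest.raises(KeyError):
            hit_rate(p, "K0", inhibitor_subset=["nope"])


class TestSelectivityLabels:
    def test_boundary_inclusive(self):
        labels = label_selectivity(pd.Series({"a": 10, "b": 11}), 10)
        assert labels["a"] == SELECTIVE
        assert labels["b"] == PROMISCUOUS

    def test_nested_across_thresholds(self):
        rng = np.random.default_rng(3)
        rates = pd.Series(rng.integers(0, 30, size=40))
        sets = [
            set(rates.index[label_selectivity(rates, t) == SELECTIVE])
            for t in (5, 10, 15)
        ]
        assert sets[0] <= sets[1] <= sets[2]


class TestSubsetRandomization:
    def test_full_pool_draw_is_degenerate(self):
        rng = np.random.default_rng(4)
        kd = 10 ** rng.uniform(1, 4.5, size=(6, 5))
        p = make_panel(kd)
        res = subset_randomization(p, k=5, iterations=50, hit_rate_ceilings=[1, 3], seed=0)
        assert np.all(res["sd_count"] == 0)
        assert np.all(res["mean_count"] == res["full_pool_count"])

    def test_matches_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(5)
        kd = 10 ** rng.uniform(2, 4.5, size=(6, 5))
        p = make_panel(kd)
        hm = (kd < 10000.0)
        ceiling = 1
        exact = []
        for combo in itertools.combinations(range(5), 2):
            rates = hm[:, list(combo)].sum(axis=1)
            exact.append((rates <= ceiling).sum())
        exact_mean = np.mean(exact)
        exact_sd = np.std(exact)
        res = subset_randomization(
            p, k=2, iterations=10000, hit_rate_ceilings=[ceiling], seed=1
        )
        se = exact_sd / np.sqrt(10000)
        assert abs(res["mean_count"].iloc[0] - exact_mean) < 3 * max(se, 1e-9)

    def test_reproducible_and_validated(self):
        p = make_panel(10 ** np.random.default_rng(6).uniform(1, 4, (4, 6)))
        a = subset_randomization(p, 3, 100, [2], seed=7)
        b = subset_randomization(p, 3, 100, [2], seed=7)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="pool"):
            subset_randomization(p, 7, 10, [2])


class TestRoc:
    def test_perfect_separation(self):
        scores = [5.0, 4.0, 3.0, 1.0, 0.5]
        labels = [SELECTIVE] * 3 + [PROMISCUOUS] * 2
        assert roc_auc(scores, labels).auc == pytest.approx(1.0)

    def test_uninformative_constant_scores(self):
        labels = [SELECTIVE, PROMISCUOUS] * 3
        assert roc_auc([2.0] * 6, labels).auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        scores = np.round(rng.normal(size=12), 1)  # rounding forces ties
        y = rng.random(12) < 0.5
        y[0], y[1] = True, False  # ensure both classes
        labels = [SELECTIVE if t else PROMISCUOUS for t in y]
        assert roc_auc(scores, labels).auc == pytest.approx(mw_auc(scores, y))

    def test_label_flip_complements_auc(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=20)
        y = rng.random(20) < 0.4
        y[0], y[1] = True, False
        labels = [SELECTIVE if t else PROMISCUOUS for t in y]
        flipped = [PROMISCUOUS if t else SELECTIVE for t in y]
        assert roc_auc(scores, labels).auc == pytest.approx(
            1.0 - roc_auc(scores, flipped).auc
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=15)
        y = rng.random(15) < 0.5
        y[0], y[1] = True, False
        labels = [SELECTIVE if t else PROMISCUOUS for t in y]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(2 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc([1.0, 2.0], [SELECTIVE, SELECTIVE])


class TestBinning:
    def test_group_count_and_partial_final_group(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.normal(size=348))
        values = pd.Series(rng.normal(size=348))
        out = bin_by_score(scores, values, 25)
        assert len(out) == 14
        assert out["n"].iloc[-1] == 23
        assert bool(out["partial"].iloc[-1]) is True
        assert not out["partial"].iloc[:-1].any()
        assert out["n"].sum() == 348

    def test_constant_values_average_to_constant(self):
        scores = pd.Series(np.arange(10.0))
        out = bin_by_score(scores, pd.Series(np.full(10, 3.5)), 4)
        assert np.allclose(out["mean_value"], 3.5)

    def test_monotone_construction_gives_monotone_group_means(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(size=60))
        values = 2.0 * scores + 1.0  # strictly monotone in score
        out = bin_by_score(scores, values, 10)
        assert np.all(np.diff(out["mean_value"]) < 0)  # sorted descending


class TestAffinityClasses:
    @pytest.mark.parametrize(
        "kd,expected",
        [(99.9, STRONG), (100.0, AVERAGE), (5000.0, AVERAGE),
         (5000.1, WEAK), (1.0, STRONG), (10000.0, WEAK)],
    )
    def test_boundaries(self, kd, expected):
        assert affinity_class(kd) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            affinity_class(0.0)

    def test_vectorized_matches_scalar_scan(self):
        rng = np.random.default_rng(13)
        kds = 10 ** rng.uniform(0, 4.5, size=50)
        vec = affinity_classes(kds)
        assert list(vec) == [affinity_class(k) for k in kds]


class TestBinnedAffinity:
    def test_all_censored_is_all_weak(self):
        kd = np.full((6, 4), 10000.0)
        p = make_panel(kd)
        scores = pd.Series(np.arange(6.0), index=p.kinases)
        out = binned_affinity_distribution(p, scores, bin_size=3)
        assert np.allclose(out["frac_weak"], 1.0)
        assert np.allclose(out["frac_strong"], 0.0)

    def test_fractions_sum_to_one_and_pairs_conserved(self):
        rng = np.random.default_rng(14)
        kd = 10 ** rng.uniform(0, 4.5, size=(20, 6))
        p = make_panel(kd)
        scores = pd.Series(rng.normal(size=20), index=p.kinases)
        out = binned_affinity_distribution(p, scores, inhibitors=p.inhibitors, bin_size=7)
        sums = out[["frac_strong", "frac_average", "frac_weak"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert out["n_pairs"].sum() == 20 * 6

    def test_strong_fraction_tracks_score_by_construction(self):
        # affinity worsens with score: top-score bins must be weak-dominated
        n = 30
        scores = pd.Series(np.linspace(10, 0, n), index=[f"K{i}" for i in range(n)])
        kd = np.tile(10 ** np.linspace(4.3, 0.5, n)[:, None], (1, 4))
        p = make_panel(kd)
        out = binned_affinity_distribution(p, scores, inhibitors=p.inhibitors, bin_size=10)
        assert out["frac_strong"].is_monotonic_increasing
        assert out["frac_weak"].iloc[0] > out["frac_weak"].iloc[-1]

    def test_default_inhibitors_are_most_promiscuous(self):
        rng = np.random.default_rng(15)
        kd = np.full((10, 6), 10000.0)
        kd[:, 2] = 50.0
        kd[:, 4] = 60.0
        kd[:5, 0] = 70.0
        kd[:2, 1] = 80.0
        p = make_panel(kd)
        assert most_promiscuous(p, n=3) == ["I2", "I4", "I0"]


class TestEvaluatePredictions:
    def _toy(self):
        rng = np.random.default_rng(16)
        kd = 10 ** rng.uniform(0, 4.5, size=(6, 4))
        return make_panel(kd)

    def test_oracle_predictor_is_perfect(self):
        t = self._toy()
        p = make_panel(t.kd.copy())
        ev = evaluate_predictions(t, p)
        assert ev.aupr == pytest.approx(1.0)
        assert np.allclose(ev.regimes["tpr_percent"].dropna(), 100.0)

    def test_constant_predictor_scores_prevalence(self):
        t = self._toy()
        p = make_panel(np.full((6, 4), 500.0))
        ev = evaluate_predictions(t, p)
        assert np.allclose(ev.precision, ev.prevalence)
        assert ev.aupr == pytest.approx(ev.prevalence)

    def test_regime_counts_match_hand_tabulation(self):
        kd_t = np.array([
            [5.0, 50.0, 2000.0, 8000.0],
            [9.0, 120.0, 4000.0, 10000.0],
            [2.0, 90.0, 300.0, 6000.0],
            [15.0, 200.0, 900.0, 7000.0],
            [8.0, 60.0, 1500.0, 9000.0],
            [3.0, 80.0, 2500.0, 10000.0],
        ])
        # predictions off by one regime for selected entries
        kd_p = kd_t.copy()
        kd_p[0, 0] = 50.0    # true <=10, predicted in (10, 100]
        kd_p[1, 3] = 100.0   # true >5000, predicted <=100
        t, p = make_panel(kd_t), make_panel(kd_p)
        ev = evaluate_predictions(t, p)
        reg = ev.regimes.set_index("regime")
        # Kd<=10: truths {5,9,2,8,3} = 5; correct = 4 (entry (0,0) moved out)
        assert reg.loc["Kd<=10", "n_true"] == 5
        assert reg.loc["Kd<=10", "n_correct"] == 4
        # Kd>5000: truths {8000,10000,6000,7000,9000,10000} = 6; one moved out
        assert reg.loc["Kd>5000", "n_true"] == 6
        assert reg.loc["Kd>5000", "n_correct"] == 5

    def test_index_mismatch_rejected(self):
        t = self._toy()
        bad = BindingPanel(
            kinases=[f"X{i}" for i in range(6)],
            inhibitors=t.inhibitors, datasets=t.datasets, kd=t.kd.copy(),
        )
        with pytest.raises(ValueError, match="X0"):
            evaluate_predictions(t, bad)


class TestPanelIO:
    def _panel(self):
        rng = np.random.default_rng(17)
        kd = 10 ** rng.uniform(0, 4.5, size=(5, 6))
        kd[kd > 9000] = 10000.0
        kd[0, 1] = np.nan
        return make_panel(kd, datasets=["davis"] * 2 + ["schrodinger"] * 4)

    def test_long_csv_round_trip(self, tmp_path):
        p = self._panel()
        f = tmp_path / "panel.csv"
        write_panel_csv(p, f)
        back = read_panel_csv(f)
        assert back.kinases == p.kinases
        assert back.inhibitors == p.inhibitors
        assert back.datasets == p.datasets
        assert np.allclose(back.kd, p.kd, equal_nan=True)
        assert np.array_equal(back.censored, p.censored)

    def test_wide_conversion(self):
        p = self._panel()
        wide = pd.DataFrame(p.kd, index=p.kinases, columns=p.inhibitors)
        back = panel_from_wide(wide, dict(zip(p.inhibitors, p.datasets)))
        assert np.allclose(back.kd, p.kd, equal_nan=True)
        assert back.datasets == p.datasets

    def test_excel_sheet_layout_round_trip(self, tmp_path):
        p = self._panel()
        xlsx = tmp_path / "panel.xlsx"
        davis_cols = [i for i, d in zip(p.inhibitors, p.datasets) if d == "davis"]
        schro_cols = [i for i, d in zip(p.inhibitors, p.datasets) if d == "schrodinger"]
        df = pd.DataFrame(p.kd, index=p.kinases, columns=p.inhibitors)
        with pd.ExcelWriter(xlsx) as xw:
            df[davis_cols].to_excel(xw, sheet_name="davis")
            df[schro_cols].to_excel(xw, sheet_name="schrodinger")
        back = read_panel_excel(xlsx, {"davis": "davis", "schrodinger": "schrodinger"})
        assert set(back.kinases) == set(p.kinases)
        orig = panel_to_long(p).sort_values(["kinase_id", "inhibitor_id"]).reset_index(drop=True)
        rt = panel_to_long(back).sort_values(["kinase_id", "inhibitor_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(orig, rt)

    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            make_panel([[0.0, 100.0]])
        with pytest.raises(ValueError, match="dataset"):
            BindingPanel(["K0"], ["I0", "I1"], ["davis"], np.array([[1.0, 2.0]]))
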