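"""Interval mapping: bridge probabilities, LOD scans, permutation
thresholds, stepwise search, support intervals, prediction."""

import numpy as np
import pandas as pd
import pytest

import gpqtl
from gpqtl import interval_mapping as im
from gpqtl.cross_sim import GeneticMap, haldane_r


@pytest.fixture(scope="module")
def planted(small_design):
    """One strong QTL (h2 = 0.8) on the small cross."""
    gm, geno, X = small_design
    cfg = gpqtl.SimulationConfig(s=1, h2=0.8, base_seed=77)
    panel = gpqtl.trait_sim.simulate_replicate(X, gm, cfg)
    grid = im.calc_genoprob(geno, gm, step_cM=1.0)
    return gm, geno, grid, panel


class TestGenoprob:
    def test_probabilities_normalized(self, planted):
        _, _, grid, _ = planted
        np.testing.assert_allclose(grid.probs.sum(axis=2), 1.0, atol=1e-10)

    def test_indicator_at_markers(self, planted):
        _, geno, grid, _ = planted
        mk = grid.positions["is_marker"].to_numpy()
        assert np.allclose(grid.probs[:, mk, :].max(axis=2), 1.0)

    def test_midpoint_closed_form(self):
        """Bridge probability between same-allele flanking markers."""
        df = pd.DataFrame({
            "marker": ["l", "r"], "chrom": ["c", "c"],
            "pos_cM": [0.0, 20.0], "pos_bp": [1, 2],
        })
        gm = GeneticMap(df)
        geno_df = pd.DataFrame({"l": ["ac"], "r": ["ac"]}, index=["o1"])
        geno = gpqtl.PhasedGenotypes(geno_df, gm)
        grid = im.calc_genoprob(geno, gm, step_cM=10.0)
        r = haldane_r(10.0)
        pa = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        mid = np.flatnonzero(
            ~grid.positions["is_marker"].to_numpy()
            & (grid.positions["pos_cM"] == 10.0).to_numpy()
        )[0]
        # class ac probability = P(a) * P(c) with both bridges identical
        assert grid.probs[0, mid, 0] == pytest.approx(pa * pa, abs=1e-12)

    def test_midpoint_matches_meiosis_simulation(self):
        """Monte-Carlo cross-check of the bridge formula."""
        cfg = gpqtl.CrossSimConfig(n_offspring=40_000, n_chromosomes=1,
                                   markers_per_chromosome=3,
                                   chrom_length_cM=30, seed=4)
        gm, geno = gpqtl.simulate_cross(cfg)
        codes = geno.class_codes()
        maternal = codes // 2
        # offspring with maternal 'a' at both flanks of the middle marker
        sel = (maternal[:, 0] == 0) & (maternal[:, 2] == 0)
        freq_a_mid = np.mean(maternal[sel, 1] == 0)
        r = haldane_r(15.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert freq_a_mid == pytest.approx(expected, abs=0.01)

    def test_bad_step_rejected(self, small_cross):
        _, gm, geno = small_cross
        with pytest.raises(ValueError):
            im.calc_genoprob(geno, gm, step_cM=0.0)


class TestScan:
    def test_constant_y_gives_zero_lod(self, planted):
        _, _, grid, _ = planted
        scan = im.scan_sim(grid, np.full(grid.probs.shape[0], 2.5))
        np.testing.assert_allclose(scan.lod, 0.0, atol=1e-10)

    def test_perfect_class_signal_capped(self, planted):
        _, geno, grid, _ = planted
        codes = geno.class_codes()
        y = codes[:, 0].astype(float)  # exact function of marker 1 classes
        with pytest.warns(UserWarning, match="capped"):
            scan = im.scan_sim(grid, y)
        j = int(np.argmax(scan.lod))
        assert grid.positions["is_marker"].iloc[j]
        assert scan.lod[j] == im.LOD_CAP

    def test_matches_explicit_regression_oracle(self, planted, rng):
        _, _, grid, _ = planted
        n = grid.probs.shape[0]
        y = rng.standard_normal(n)
        scan = im.scan_sim(grid, y)
        for j in [0, 17, grid.n_positions - 1]:
            W = np.column_stack([np.ones(n), grid.probs[:, j, :3]])
            coef, *_ = np.linalg.lstsq(W, y, rcond=None)
            rss1 = ((y - W @ coef) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            lod = n / 2 * np.log10(rss0 / rss1)
            assert scan.lod[j] == pytest.approx(lod, abs=1e-8)

    def test_peak_near_planted_qtl(self, planted):
        gm, _, grid, panel = planted
        scan = im.scan_sim(grid, panel.Y[:, 0])
        j = int(np.argmax(scan.lod))
        qtl = panel.effects.qtl_markers[0][0]
        qi = gm.marker_index([qtl])[0]
        assert grid.positions["chrom"].iloc[j] == gm.df["chrom"].iloc[qi]
        assert abs(
            grid.positions["pos_cM"].iloc[j] - gm.df["pos_cM"].iloc[qi]
        ) <= 5.0


class TestPermutationThreshold:
    def test_fwer_one_gives_min_of_maxima(self, planted, rng):
        _, _, grid, _ = planted
        y = rng.standard_normal(grid.probs.shape[0])
        thr = im.permutation_threshold(grid, y, n_perm=20, fwer=1.0, seed=3)
        thr5 = im.permutation_threshold(grid, y, n_perm=20, fwer=0.05, seed=3)
        assert 0 < thr <= thr5

    def test_monotone_in_fwer(self, planted, rng):
        _, _, grid, _ = planted
        y = rng.standard_normal(grid.probs.shape[0])
        t1 = im.permutation_threshold(grid, y, n_perm=50, fwer=0.01, seed=5)
        t5 = im.permutation_threshold(grid, y, n_perm=50, fwer=0.05, seed=5)
        assert t1 >= t5

    def test_fwer_calibration_on_null(self):
        """~5% of null scans should exceed the 5% threshold."""
        cfg = gpqtl.CrossSimConfig(n_offspring=60, n_chromosomes=5,
                                   markers_per_chromosome=12,
                                   chrom_length_cM=50, seed=21)
        gm, geno = gpqtl.simulate_cross(cfg)
        grid = im.calc_genoprob(geno, gm, step_cM=None)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(60)
        thr = im.permutation_threshold(grid, y, n_perm=500, fwer=0.05, seed=1)
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            y_null = rng.standard_normal(60)
            hits += im.scan_sim(grid, y_null).lod.max() > thr
        # binomial(200, 0.05): 4 sigma around 10
        assert 2 <= hits <= 23

    def test_too_few_permutations_rejected(self, planted, rng):
        _, _, grid, _ = planted
        with pytest.raises(ValueError):
            im.permutation_threshold(grid, rng.standard_normal(120), n_perm=5)


class TestMim:
    def test_null_data_empty_model(self, planted, rng):
        _, _, grid, _ = planted
        y = rng.standard_normal(grid.probs.shape[0])
        null_max = im.scan_sim(grid, y).lod.max()
        model = im.mim_stepwise(grid, y, penalty=null_max + 1.0,
                               n_restarts=2, seed=0)
        assert model.n_qtl == 0

    def test_max_qtl_zero_empty(self, planted):
        _, _, grid, panel = planted
        model = im.mim_stepwise(grid, panel.Y[:, 0], max_qtl=0,
                                penalty=3.0, seed=0)
        assert model.n_qtl == 0

    def test_recovers_single_strong_qtl(self, small_design):
        gm, geno, X = small_design
        grid = im.calc_genoprob(geno, gm, step_cM=None)
        found = 0
        for seed in range(10):
            cfg = gpqtl.SimulationConfig(s=1, h2=0.8, base_seed=300 + seed)
            panel = gpqtl.trait_sim.simulate_replicate(X, gm, cfg)
            thr = im.permutation_threshold(grid, panel.Y[:, 0], n_perm=50,
                                           seed=seed)
            model = im.mim_stepwise(grid, panel.Y[:, 0], max_qtl=4,
                                    penalty=thr, n_restarts=2, seed=seed)
            if model.n_qtl == 0:
                continue
            qtl = panel.effects.qtl_markers[0][0]
            qi = gm.marker_index([qtl])[0]
            tbl = model.position_table()
            ok = any(
                row["chrom"] == gm.df["chrom"].iloc[qi]
                and abs(row["pos_cM"] - gm.df["pos_cM"].iloc[qi]) <= 2.0
                for _, row in tbl.iterrows()
            )
            found += ok and model.n_qtl == 1
        assert found >= 9

    def test_sim_equals_first_forward_step(self, planted):
        """MIM restricted to one QTL peaks where the single scan peaks."""
        _, _, grid, panel = planted
        y = panel.Y[:, 0]
        scan = im.scan_sim(grid, y)
        model = im.mim_stepwise(grid, y, max_qtl=1, penalty=3.0,
                                n_restarts=1, seed=0)
        assert model.qtl_positions == [int(np.argmax(scan.lod))]


class TestSupportInterval:
    def _toy_scan(self, lods, cm=None):
        n = len(lods)
        pos = pd.DataFrame({
            "chrom": ["c"] * n,
            "pos_cM": cm if cm is not None else np.arange(n, dtype=float),
            "is_marker": [True] * n,
            "marker": [f"m{i}" for i in range(n)],
        })
        return im.LodScan(positions=pos, lod=np.asarray(lods, float))

    def test_unimodal_exact_interval(self):
        scan = self._toy_scan([0.0, 1.0, 2.5, 4.0, 3.5, 2.0, 0.5])
        lo, hi = im.lod_support_interval(scan, peak=3, drop=1.0)
        assert (lo, hi) == (3.0, 4.0)  # lod >= 3.0 holds at indices 3..4
        lo, hi = im.lod_support_interval(scan, peak=3, drop=2.0)
        assert (lo, hi) == (2.0, 5.0)  # lod >= 2.0 holds at indices 2..5

    def test_flat_curve_whole_chromosome(self):
        scan = self._toy_scan([2.0] * 5)
        lo, hi = im.lod_support_interval(scan, peak=2, drop=1.0)
        assert (lo, hi) == (0.0, 4.0)

    def test_drop_zero_degenerate(self):
        scan = self._toy_scan([0.0, 3.0, 1.0])
        lo, hi = im.lod_support_interval(scan, peak=1, drop=0.0)
        assert (lo, hi) == (1.0, 1.0)


class TestImPredict:
    def test_empty_model_predicts_mean(self, planted, rng):
        _, _, grid, _ = planted
        y = rng.standard_normal(grid.probs.shape[0])
        tr = np.arange(0, 100)
        te = np.arange(100, 120)
        preds = im.im_predict([], grid.subset(tr), y[tr], grid.subset(te))
        np.testing.assert_allclose(preds, y[tr].mean())

    def test_matches_normal_equations_oracle(self, planted, rng):
        _, _, grid, panel = planted
        y = panel.Y[:, 0]
        tr = np.arange(0, 90)
        te = np.arange(90, 120)
        positions = [3, 40]
        preds = im.im_predict(positions, grid.subset(tr), y[tr],
                              grid.subset(te))
        W_tr = np.column_stack(
            [np.ones(len(tr))] + [grid.probs[tr][:, j, :3] for j in positions]
        )
        W_te = np.column_stack(
            [np.ones(len(te))] + [grid.probs[te][:, j, :3] for j in positions]
        )
        coef = np.linalg.pinv(W_tr) @ y[tr]
        np.testing.assert_allclose(preds, W_te @ coef, atol=1e-10)

    def test_noiseless_class_means_predicted_exactly(self, small_design):
        gm, geno, X = small_design
        grid = im.calc_genoprob(geno, gm, step_cM=None)
        codes = geno.class_codes()
        y = np.array([0.0, 1.0, 2.0, 3.0])[codes[:, 10]]
        tr = np.arange(0, 90)
        te = np.arange(90, 120)
        preds = im.im_predict([10], grid.subset(tr), y[tr], grid.subset(te))
        np.testing.assert_allclose(preds, y[te], atol=1e-8)
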