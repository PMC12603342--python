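import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from odorwords import rates, synthetic
from odorwords.ensemble import (
    CellMeansTable,
    build_cell_means,
    food_within_odor_anova,
    lsd_posthoc,
    mixed_anova,
)

from helpers import make_null_tensor


# --------------------------------------------------------------------------
# independent oracle: brute-force design-matrix GLM for balanced designs
# --------------------------------------------------------------------------


def glm_splitplot_oracle(data: np.ndarray, regions: np.ndarray) -> dict[str, tuple]:
    """Split-plot F statistics via explicit design matrices (balanced only).

    Builds the full flattened observation vector and dummy design matrices
    for every between/within effect, computes each effect's sum of squares
    by sequential orthogonal projection (valid in balanced designs), and
    forms F against the matching unit-interaction error stratum.
    Returns {effect: (F, df_num, df_den)}.
    """
    N, C, T = data.shape
    region_levels = sorted(set(regions))
    a = len(region_levels)
    n = N // a
    assert all(np.sum(regions == r) == n for r in region_levels), "oracle needs balance"

    y = data.reshape(-1)  # order: unit, category, time
    rows = []
    for u in range(N):
        for c in range(C):
            for t in range(T):
                rows.append((u, region_levels.index(regions[u]), c, t))
    rows = np.asarray(rows)

    def dummies(cols):
        """Indicator design matrix for the interaction of the given columns."""
        key = rows[:, cols[0]].astype(object)
        for c in cols[1:]:
            key = key * 1000 + rows[:, c]
        levels = sorted(set(key.tolist()))
        X = np.zeros((len(key), len(levels)))
        for j, lev in enumerate(levels):
            X[key == lev, j] = 1.0
        return X

    def projection_ss(X, resid):
        beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
        fit = X @ beta
        return float(fit @ fit), fit

    # sequential orthogonal decomposition: grand mean, R, U(R), C, CR, CU(R),
    # T, TR, TU(R), CT, CTR, CTU(R)
    ss = {}
    resid = y - y.mean()
    order = [
        ("R", [1]),
        ("U", [0]),
        ("C", [2]),
        ("CR", [2, 1]),
        ("CU", [2, 0]),
        ("T", [3]),
        ("TR", [3, 1]),
        ("TU", [3, 0]),
        ("CT", [2, 3]),
        ("CTR", [2, 3, 1]),
        ("CTU", [2, 3, 0]),
    ]
    for name, cols in order:
        ss_i, fit = projection_ss(dummies(cols), resid)
        ss[name] = ss_i
        resid = resid - fit

    df = {
        "R": a - 1,
        "U": a * (n - 1),
        "C": C - 1,
        "CR": (C - 1) * (a - 1),
        "CU": (C - 1) * a * (n - 1),
        "T": T - 1,
        "TR": (T - 1) * (a - 1),
        "TU": (T - 1) * a * (n - 1),
        "CT": (C - 1) * (T - 1),
        "CTR": (C - 1) * (T - 1) * (a - 1),
        "CTU": (C - 1) * (T - 1) * a * (n - 1),
    }
    tests = {
        "REGION": ("R", "U"),
        "CAT": ("C", "CU"),
        "CAT x REGION": ("CR", "CU"),
        "TIME": ("T", "TU"),
        "TIME x REGION": ("TR", "TU"),
        "CAT x TIME": ("CT", "CTU"),
        "CAT x TIME x REGION": ("CTR", "CTU"),
    }
    out = {}
    for effect, (h, e) in tests.items():
        F = (ss[h] / df[h]) / (ss[e] / df[e])
        out[effect] = (F, df[h], df[e])
    return out


def random_cells(seed, regions, T=4, effect=0.0):
    rng = np.random.default_rng(seed)
    N = len(regions)
    data = rng.normal(size=(N, 2, T)) + rng.normal(size=(N, 1, 1))
    if effect:
        data[:, 0, :] += effect * (regions == regions[0])[:, None]
    ids = np.array([f"u{i}" for i in range(N)])
    return CellMeansTable(ids, np.asarray(regions), data, "ODOR")


class TestMixedAnovaOracle:
    @pytest.mark.parametrize("seed,effect", [(0, 0.0), (1, 0.5), (2, 1.2)])
    def test_balanced_design_matches_glm_oracle(self, seed, effect):
        """F statistics equal the explicit design-matrix GLM on balanced data."""
        regions = np.repeat(["amygdala", "hippocampus", "piriform"], 6)
        cells = random_cells(seed, regions, effect=effect)
        got = mixed_anova(cells).set_index("effect")
        want = glm_splitplot_oracle(cells.data, np.asarray(regions))
        mapping = {
            "REGION": "REGION",
            "ODOR": "CAT",
            "ODOR x REGION": "CAT x REGION",
            "TIME": "TIME",
            "TIME x REGION": "TIME x REGION",
            "ODOR x TIME": "CAT x TIME",
            "ODOR x TIME x REGION": "CAT x TIME x REGION",
        }
        for row_name, oracle_name in mapping.items():
            F, dfn, dfd = want[oracle_name]
            assert got.loc[row_name, "F"] == pytest.approx(F, abs=1e-8), row_name
            assert got.loc[row_name, "df_num"] == dfn
            assert got.loc[row_name, "df_den"] == dfd

    def test_matches_pingouin_one_within(self):
        """Collapsed over TIME, the 2-level design reproduces pingouin exactly."""
        regions = np.repeat(["amygdala", "hippocampus", "piriform"], 8)
        cells = random_cells(3, regions)
        d2 = cells.data.mean(axis=2, keepdims=True)
        cells2 = CellMeansTable(cells.unit_ids, cells.regions, d2, "ODOR")
        got = mixed_anova(cells2).set_index("effect")
        rows = []
        for i in range(len(regions)):
            for c, lab in enumerate(["in", "out"]):
                rows.append((f"u{i}", regions[i], lab, d2[i, c, 0]))
        df = pd.DataFrame(rows, columns=["unit", "region", "cat", "y"])
        ref = pg.mixed_anova(
            data=df, dv="y", within="cat", subject="unit", between="region"
        ).set_index("Source")
        assert got.loc["REGION", "F"] == pytest.approx(ref.loc["region", "F"], abs=1e-10)
        assert got.loc["ODOR", "F"] == pytest.approx(ref.loc["cat", "F"], abs=1e-10)
        assert got.loc["ODOR x REGION", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-10
        )


class TestMixedAnovaStructure:
    def test_reference_inventory_df(self):
        """195 units in the observed regional proportions give df (4, 190)."""
        regions = np.concatenate(
            [
                np.repeat(r, n)
                for r, n in synthetic.DEFAULT_UNITS_PER_REGION.items()
            ]
        )
        cells = random_cells(4, regions)
        table = mixed_anova(cells).set_index("effect")
        assert tuple(table.loc["ODOR x REGION", ["df_num", "df_den"]]) == (4, 190)
        assert tuple(table.loc["ODOR", ["df_num", "df_den"]]) == (1, 190)
        assert tuple(table.loc["ODOR x TIME x REGION", ["df_num", "df_den"]]) == (
            12,
            570,
        )

    def test_all_equal_cells_give_zero_f(self):
        regions = np.repeat(["amygdala", "piriform"], 3)
        data = np.ones((6, 2, 4))
        cells = CellMeansTable(np.array(list("abcdef")), regions, data, "ODOR")
        table = mixed_anova(cells)
        assert (table["F"] == 0.0).all()
        assert (table["p"] == 1.0).all()

    def test_shift_invariance(self):
        regions = np.repeat(["amygdala", "hippocampus"], 5)
        cells = random_cells(5, regions)
        shifted = CellMeansTable(
            cells.unit_ids, cells.regions, cells.data + 7.3, "ODOR"
        )
        pd.testing.assert_frame_equal(mixed_anova(cells), mixed_anova(shifted))

    def test_partial_eta_identity(self):
        regions = np.repeat(["amygdala", "hippocampus", "entorhinal"], 4)
        table = mixed_anova(random_cells(6, regions, effect=0.4))
        for _, row in table.iterrows():
            expected = (row["F"] * row["df_num"]) / (
                row["F"] * row["df_num"] + row["df_den"]
            )
            assert row["partial_eta_sq"] == pytest.approx(expected, abs=1e-10)

    def test_small_region_rejected(self):
        regions = np.array(["amygdala"] * 5 + ["piriform"])
        with pytest.raises(ValueError, match="piriform"):
            mixed_anova(random_cells(7, regions))

    def test_hundred_ms_resolution_preserves_category_by_region(
        self, first_presentation_trials
    ):
        """The CATEGORY x REGION F is identical at 500 ms and 100 ms windows."""
        rng = np.random.default_rng(9)
        regions = np.repeat(["amygdala", "hippocampus"], 10)
        ws = rates.WindowSet.hundred_ms()
        lam = np.full((20, 200, ws.n_windows), 4.0)
        counts = synthetic.poisson_window_counts(lam, ws.durations_s, rng)
        t100 = rates.zscore_rates(
            rates.tensor_from_counts(counts, regions, first_presentation_trials, ws)
        )
        # rebin the same counts to 500 ms windows
        ws500 = rates.WindowSet()
        c500 = np.empty((20, 200, 5))
        c500[:, :, 0] = counts[:, :, 0]
        for w in range(4):
            c500[:, :, 1 + w] = counts[:, :, 1 + 5 * w : 1 + 5 * (w + 1)].sum(axis=2)
        t500 = rates.zscore_rates(
            rates.tensor_from_counts(c500, regions, first_presentation_trials, ws500)
        )
        a100 = mixed_anova(build_cell_means(t100, "ODOR")).set_index("effect")
        a500 = mixed_anova(build_cell_means(t500, "ODOR")).set_index("effect")
        assert a100.loc["ODOR x REGION", "F"] == pytest.approx(
            a500.loc["ODOR x REGION", "F"], abs=1e-10
        )
        assert a100.loc["ODOR", "F"] == pytest.approx(
            a500.loc["ODOR", "F"], abs=1e-10
        )


class TestCellMeans:
    def test_shapes_and_exclusions(self, first_presentation_trials):
        tensor = rates.zscore_rates(
            make_null_tensor(6, first_presentation_trials, seed=2)
        )
        cells = build_cell_means(tensor, "ODOR")
        assert cells.data.shape == (6 - len(cells.excluded), 2, 4)

    def test_single_level_scheme_rejected(self, first_presentation_trials):
        tensor = rates.zscore_rates(
            make_null_tensor(4, first_presentation_trials, seed=3)
        )
        trials = tensor.trials.copy()
        trials["is_food"] = False
        tensor.trials = trials
        with pytest.raises(ValueError, match="single level"):
            build_cell_means(tensor, "FOOD")

    def test_null_category_difference_centered(self, first_presentation_trials):
        """With identical odor/control processes, cell-mean differences center on 0."""
        from scipy import stats as sps

        tensor = rates.zscore_rates(
            make_null_tensor(100, first_presentation_trials, seed=4)
        )
        cells = build_cell_means(tensor, "ODOR")
        diff = (cells.data[:, 0, :] - cells.data[:, 1, :]).mean(axis=1)
        assert sps.ttest_1samp(diff, 0.0).pvalue > 0.01


class TestLsdPosthoc:
    def test_identical_marginals_guarded(self):
        regions = np.repeat(["amygdala"], 5)
        data = np.ones((5, 2, 4))
        cells = CellMeansTable(np.array(list("abcde")), regions, data, "ODOR")
        row = lsd_posthoc(cells).iloc[0]
        assert row["p"] == 1.0 and row["cohen_d"] == 0.0

    def test_injected_difference_detected(self):
        """Mean z difference 0.019 at difference SD 0.05, 57 units: d ~ 0.38.

        The population effect size is 0.019 / 0.05 = 0.38 with ~80% power
        at alpha 0.05; both are checked across seeded replicates.
        """
        rng = np.random.default_rng(10)
        n = 57
        ds, hits = [], 0
        n_rep = 50
        for _ in range(n_rep):
            base = rng.normal(0, 0.1, size=(n, 1, 4))
            diff = rng.normal(0.019, 0.05, size=(n, 1, 1))
            data = np.concatenate([base + diff, base], axis=1)
            cells = CellMeansTable(
                np.array([f"u{i}" for i in range(n)]),
                np.repeat(["amygdala"], n),
                data,
                "ODOR",
            )
            row = lsd_posthoc(cells).iloc[0]
            ds.append(row["cohen_d"])
            hits += row["p"] < 0.05
        # sampling SD of d is ~0.135, so the mean over 50 has SE ~0.019
        assert np.mean(ds) == pytest.approx(0.38, abs=0.06)
        assert hits / n_rep > 0.6

    def test_sign_flip_symmetry(self):
        regions = np.repeat(["amygdala", "hippocampus"], 6)
        cells = random_cells(11, regions, effect=0.3)
        flipped = CellMeansTable(
            cells.unit_ids, cells.regions, cells.data[:, ::-1, :], "ODOR"
        )
        a = lsd_posthoc(cells)
        b = lsd_posthoc(flipped)
        np.testing.assert_allclose(a["p"], b["p"])
        np.testing.assert_allclose(a["cohen_d"], -b["cohen_d"])

    def test_pooled_error_variant_runs(self):
        regions = np.repeat(["amygdala", "hippocampus"], 6)
        cells = random_cells(12, regions)
        table = lsd_posthoc(cells, pooled_error=True)
        assert len(table) == 2
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_too_few_units_rejected(self):
        cells = CellMeansTable(
            np.array(["a"]), np.array(["amygdala"]), np.zeros((1, 2, 4)), "ODOR"
        )
        with pytest.raises(ValueError):
            lsd_posthoc(cells)


class TestFoodWithinOdor:
    def test_df_structure(self, first_presentation_trials):
        """57 amygdala units give a FOOD main effect with df (1, 56)."""
        tensor = rates.zscore_rates(
            make_null_tensor(57, first_presentation_trials, seed=13)
        )
        n_excluded = len(tensor.zscore_excluded)
        table = food_within_odor_anova(tensor).set_index("effect")
        assert tuple(table.loc["FOOD", ["df_num", "df_den"]]) == (
            1,
            57 - n_excluded - 1,
        )
        assert "REGION" not in table.index

    def test_identical_food_levels_give_zero_f(self):
        """Identical food/nonfood cell means per unit give a FOOD F of 0."""
        rng = np.random.default_rng(14)
        per_time = rng.normal(size=(8, 1, 4))
        data = np.concatenate([per_time, per_time], axis=1)
        cells = CellMeansTable(
            np.array([f"u{i}" for i in range(8)]),
            np.repeat(["amygdala"], 8),
            data,
            "FOOD",
        )
        table = mixed_anova(cells).set_index("effect")
        assert table.loc["FOOD", "F"] == 0.0
        assert table.loc["FOOD", "p"] == 1.0

    def test_null_calibration_uniform_p(self, first_presentation_trials):
        """FOOD main-effect p is uniform across null simulations (KS check)."""
        from scipy import stats as sps

        pvals = []
        for seed in range(60):
            tensor = rates.zscore_rates(
                make_null_tensor(12, first_presentation_trials, seed=1000 + seed)
            )
            table = food_within_odor_anova(tensor).set_index("effect")
            pvals.append(table.loc["FOOD", "p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
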