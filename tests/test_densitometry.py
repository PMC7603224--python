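import itertools

import numpy as np
import pandas as pd
import pytest

from atg8kit.densitometry import (
    bh_adjust,
    flux,
    flux_table,
    normalize,
    test_factorial,
    test_flux,
    validate_table,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["protein", "treatment", "bafA1",
                                       "replicate", "band", "intensity",
                                       "tubulin_intensity"])


@pytest.fixture
def toy_table():
    """LC3B lipidated lanes, Ctrl vs TSA, 3 paired replicates each."""
    rows = []
    with_ratios = {"Ctrl": [1.0, 1.2, 1.4], "TSA": [0.5, 0.55, 0.6]}
    without_ratios = {"Ctrl": [0.4, 0.5, 0.6], "TSA": [0.45, 0.5, 0.55]}
    for treatment in ("Ctrl", "TSA"):
        for rep in range(1, 4):
            rows.append(("LC3B", treatment, True, rep, "lipidated",
                         with_ratios[treatment][rep - 1], 1.0))
            rows.append(("LC3B", treatment, False, rep, "lipidated",
                         without_ratios[treatment][rep - 1], 1.0))
    return make_table(rows)


class TestValidate:
    def test_duplicate_rows_rejected(self):
        t = make_table([("LC3B", "Ctrl", False, 1, "lipidated", 1.0, 1.0)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            validate_table(t)

    def test_nonpositive_tubulin_rejected(self):
        t = make_table([("LC3B", "Ctrl", False, 1, "lipidated", 1.0, 0.0)])
        with pytest.raises(ValueError, match="tubulin"):
            validate_table(t)


class TestNormalize:
    def test_equal_intensities_normalize_to_one(self):
        rows = [("LC3A", tr, False, r, "total", 3.0, 1.5)
                for tr in ("Ctrl", "TSA", "Ex527") for r in (1, 2, 3)]
        out = normalize(make_table(rows))
        assert np.allclose(out["intensity"], 1.0)
        assert np.allclose(out["tubulin_intensity"], 1.0)

    def test_direct_substitution(self):
        rows = [("LC3A", "Ctrl", False, 1, "total", 0.5, 1.0),
                ("LC3A", "TSA", False, 1, "total", 2.0, 1.0)]
        out = normalize(make_table(rows))
        assert out.loc[out["treatment"] == "TSA", "intensity"].iloc[0] == pytest.approx(4.0)

    def test_missing_control_raises(self):
        rows = [("LC3C", "TSA", False, 1, "total", 1.0, 1.0)]
        with pytest.raises(ValueError, match="missing control"):
            normalize(make_table(rows))

    def test_idempotent(self, toy_table):
        once = normalize(toy_table)
        twice = normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_control_mean_maps_to_one(self, toy_table):
        out = normalize(toy_table)
        ctrl = out[(out["treatment"] == "Ctrl") & (~out["bafA1"])]
        assert ctrl["intensity"].mean() == pytest.approx(1.0)


class TestFlux:
    def test_identity_when_ratios_equal(self):
        rows = [("LC3B", "Ctrl", baf, r, "lipidated", 0.8, 1.0)
                for baf in (True, False) for r in (1, 2)]
        fr = flux(make_table(rows), "LC3B", "Ctrl")
        assert np.allclose(fr.values, 0.0)

    def test_direct_substitution(self):
        rows = [("LC3B", "Ctrl", True, 1, "lipidated", 2.0, 1.0),
                ("LC3B", "Ctrl", False, 1, "lipidated", 0.5, 1.0)]
        fr = flux(make_table(rows), "LC3B", "Ctrl")
        assert fr.values[0] == pytest.approx(1.5)

    def test_replicate_pairing_arithmetic(self, toy_table):
        fr = flux(toy_table, "LC3B", "Ctrl")
        assert np.allclose(sorted(fr.values), [0.6, 0.7, 0.8])
        assert fr.mean == pytest.approx(0.7)

    def test_scale_invariance(self, toy_table):
        scaled = toy_table.copy()
        scaled["intensity"] *= 37.0
        scaled["tubulin_intensity"] *= 37.0
        a = flux(toy_table, "LC3B", "Ctrl")
        b = flux(scaled, "LC3B", "Ctrl")
        assert np.allclose(a.values, b.values)

    def test_missing_lipidated_band_raises(self):
        rows = [("GABARAPL2", "Ctrl", True, 1, "unlipidated", 1.0, 1.0)]
        with pytest.raises(ValueError, match="missing lipidated"):
            flux(make_table(rows), "GABARAPL2", "Ctrl")

    def test_unpaired_replicates_raise(self):
        rows = [("LC3B", "Ctrl", True, 1, "lipidated", 1.0, 1.0),
                ("LC3B", "Ctrl", False, 2, "lipidated", 1.0, 1.0)]
        with pytest.raises(ValueError, match="unpaired"):
            flux(make_table(rows), "LC3B", "Ctrl")

    def test_flux_table_covers_all_groups(self, toy_table):
        out = flux_table(toy_table)
        assert set(out["treatment"]) == {"Ctrl", "TSA"}
        assert len(out) == 6


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_formula(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        out = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adj.max() <= 1.0
        assert np.all(adj >= p - 1e-12)


class TestKruskal:
    def test_identical_groups_null(self):
        rep = test_flux({"Ctrl": [1.0, 1.0], "TSA": [1.0, 1.0]})
        assert rep["H"] == 0.0
        assert rep["p"] == 1.0

    def test_hand_computed_h(self):
        rep = test_flux({"a": [1, 2, 3], "b": [10, 11, 12], "c": [20, 21, 22]})
        assert rep["H"] == pytest.approx(7.2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            test_flux({"Ctrl": [1.0, 2.0]})

    def test_posthoc_vs_control_reported(self):
        rep = test_flux({"Ctrl": [0.1, 0.2, 0.15], "TSA": [0.9, 1.0, 0.95],
                         "Ex527": [0.12, 0.22, 0.17]})
        groups = {h["group"] for h in rep["posthoc"]}
        assert groups == {"TSA", "Ex527"}
        for h in rep["posthoc"]:
            assert 0.0 <= h["p_raw"] <= h["p_adjusted"] <= 1.0


def _anova_oracle(y, a, b):
    """Balanced two-way fixed-effects sums-of-squares decomposition."""
    y = np.asarray(y, dtype=float)
    levels_a, levels_b = sorted(set(a)), sorted(set(b))
    n = len(y) / (len(levels_a) * len(levels_b))
    grand = y.mean()
    ss_a = sum((y[[x == la for x in a]].mean() - grand) ** 2
               for la in levels_a) * n * len(levels_b)
    ss_b = sum((y[[x == lb for x in b]].mean() - grand) ** 2
               for lb in levels_b) * n * len(levels_a)
    ss_cells = 0.0
    ss_err = 0.0
    for la in levels_a:
        for lb in levels_b:
            sel = np.array([(xa == la) and (xb == lb) for xa, xb in zip(a, b)])
            cell = y[sel]
            ss_cells += (cell.mean() - grand) ** 2 * len(cell)
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
    df_ab = df_a * df_b
    df_err = len(y) - len(levels_a) * len(levels_b)
    ms_err = ss_err / df_err
    return (ss_a / df_a / ms_err, ss_b / df_b / ms_err, ss_ab / df_ab / ms_err)


class TestFactorial:
    def _frame(self, y, a, b):
        return pd.DataFrame({"intensity": y, "treatment": a, "protein": b})

    def test_flat_response_null(self):
        y = [1.0] * 12
        a = ["Ctrl", "TSA"] * 6
        b = ["LC3A"] * 6 + ["LC3B"] * 6
        rep = test_factorial(self._frame(y, a, b))
        for eff in rep["effects"].values():
            assert eff["F"] == 0.0
            assert eff["p"] == 1.0

    def test_additive_effects_zero_interaction(self):
        rows = []
        for a_eff, a in ((0.0, "Ctrl"), (1.0, "TSA")):
            for b_eff, b in ((0.0, "LC3A"), (2.0, "LC3B")):
                for _ in range(3):
                    rows.append((10.0 + a_eff + b_eff, a, b))
        y, a, b = zip(*rows)
        rep = test_factorial(self._frame(list(y), list(a), list(b)))
        assert rep["effects"]["treatment:protein"]["F"] == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        a = ["Ctrl"] * 6 + ["TSA"] * 6
        b = (["LC3A"] * 3 + ["LC3B"] * 3) * 2
        effects = {"Ctrl": 0.0, "TSA": 0.7, "LC3A": 0.0, "LC3B": -0.4}
        y = [1.0 + effects[x] + effects[z] + rng.normal(0, 0.3)
             for x, z in zip(a, b)]
        rep = test_factorial(self._frame(y, a, b))
        f_a, f_b, f_ab = _anova_oracle(y, a, b)
        assert rep["effects"]["treatment"]["F"] == pytest.approx(f_a, abs=1e-8)
        assert rep["effects"]["protein"]["F"] == pytest.approx(f_b, abs=1e-8)
        assert rep["effects"]["treatment:protein"]["F"] == pytest.approx(f_ab, abs=1e-8)

    def test_empty_cell_rejected(self):
        frame = self._frame([1.0, 2.0, 1.5, 2.5],
                            ["Ctrl", "Ctrl", "TSA", "TSA"],
                            ["LC3A", "LC3A", "LC3A", "LC3A"])
        frame = pd.concat([frame, pd.DataFrame(
            {"intensity": [1.0], "treatment": ["TSA"], "protein": ["LC3B"]})])
        with pytest.raises(ValueError):
            test_factorial(frame)

    def test_contrasts_have_stars_convention(self):
        rows = []
        rng = np.random.default_rng(5)
        for tr, shift in (("Ctrl", 0.0), ("TSA", 5.0)):
            for protein in ("LC3A", "LC3B"):
                for _ in range(4):
                    rows.append((1.0 + shift + rng.normal(0, 0.1), tr, protein))
        y, a, b = zip(*rows)
        rep = test_factorial(self._frame(list(y), list(a), list(b)))
        assert all(c["stars"] in ("", "*", "**", "***") for c in rep["contrasts"])
        assert any(c["stars"] for c in rep["contrasts"])
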