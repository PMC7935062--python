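"""Discriminant axis, LD1 projection, slope regressions, Blomberg's K."""

import numpy as np
import pandas as pd
import pytest

from flpscape import morph, synthdata, trees
from flpscape.errors import (InsufficientDataError, InvalidArgumentError,
                             MissingDataError)
from flpscape.synthdata import SimulationSpec


@pytest.fixture(scope="module")
def separated_panel():
    spec = SimulationSpec(n_species=1, color_separation=80.0, seed=21)
    return synthdata.simulate_color_morphometrics(spec)


class TestTrainDiscriminant:
    def test_separated_clusters_validate_and_order(self, separated_panel):
        colors, _ = separated_panel
        ax = morph.train_discriminant(colors, "sp1")
        assert ax.validated
        assert np.linalg.norm(ax.weights) == pytest.approx(1.0)
        ld1 = morph.project_ld1(ax, colors)
        males = colors.loc[colors["sex"] == "male", "specimen"]
        class1 = colors.loc[(colors["sex"] == "female")
                            & (colors["plumage_class"] == 1), "specimen"]
        # training groups perfectly ordered, means standardized to +-1
        assert ld1.loc[males].min() > ld1.loc[class1].max()
        assert ld1.loc[males].mean() == pytest.approx(1.0, abs=1e-9)
        assert ld1.loc[class1].mean() == pytest.approx(-1.0, abs=1e-9)

    def test_zero_separation_fails_validation(self):
        spec = SimulationSpec(n_species=1, color_separation=0.0, seed=5)
        colors, _ = synthdata.simulate_color_morphometrics(spec)
        ax = morph.train_discriminant(colors, "sp1")
        assert not ax.validated
        with pytest.raises(InvalidArgumentError):
            morph.project_ld1(ax, colors)

    def test_duplicating_training_specimens_keeps_direction(self):
        # low-noise panel: the retained subspace is the same before and
        # after duplication, so scores must agree exactly
        spec = SimulationSpec(n_species=1, color_separation=150.0,
                              color_noise=1.0, seed=33)
        colors, _ = synthdata.simulate_color_morphometrics(spec)
        ax1 = morph.train_discriminant(colors, "sp1")
        doubled = pd.concat([colors, colors], ignore_index=True)
        doubled["specimen"] = [f"{s}_{i}" for i, s in
                               enumerate(doubled["specimen"])]
        ax2 = morph.train_discriminant(doubled, "sp1")
        s1 = morph.project_ld1(ax1, colors).to_numpy()
        s2 = morph.project_ld1(ax2, colors).to_numpy()
        assert np.allclose(s1, s2, atol=1e-8)

    def test_too_few_training_specimens(self, separated_panel):
        colors, _ = separated_panel
        few = colors[colors["sex"] == "male"].head(2)
        few = pd.concat([few, colors[(colors["sex"] == "female")
                                     & (colors["plumage_class"] == 1)]])
        with pytest.raises(InsufficientDataError):
            morph.train_discriminant(few, "sp1")


class TestProjection:
    def test_missing_patch_named(self, separated_panel):
        colors, _ = separated_panel
        ax = morph.train_discriminant(colors, "sp1")
        broken = colors.copy()
        broken.loc[broken.index[0], "patch03_G"] = np.nan
        with pytest.raises(MissingDataError, match="patch03_G"):
            morph.project_ld1(ax, broken)

    def test_midpoint_maps_to_zero(self, separated_panel):
        colors, _ = separated_panel
        ax = morph.train_discriminant(colors, "sp1")
        cols = ax.feature_cols
        males = colors[(colors["sex"] == "male")
                       & (colors["plumage_class"] >= 3)]
        class1 = colors[(colors["sex"] == "female")
                        & (colors["plumage_class"] == 1)]
        mid = 0.5 * (males[cols].mean() + class1[cols].mean())
        probe = pd.DataFrame([{"specimen": "mid", "species": "sp1",
                               "sex": "female", "plumage_class": 2,
                               **mid.to_dict()}])
        assert morph.project_ld1(ax, probe).iloc[0] == pytest.approx(
            0.0, abs=1e-9)


class TestRelativeMeasure:
    def test_centering(self):
        df = pd.DataFrame({"specimen": ["a", "b"], "species": "sp",
                           "sex": ["female", "male"],
                           "bill_mm": [10.0, 12.0], "wing_mm": [50.0, 50.0]})
        rel = morph.relative_measure(df, "sp", "bill")
        assert list(rel) == [-1.0, 1.0]
        assert morph.relative_measure(df, "sp", "bill_over_wing").sum() == \
            pytest.approx(0.0, abs=1e-10)

    def test_zero_wing_rejected_for_ratio(self):
        df = pd.DataFrame({"specimen": ["a", "b"], "species": "sp",
                           "sex": "female", "bill_mm": [10.0, 12.0],
                           "wing_mm": [50.0, 0.0]})
        with pytest.raises(InvalidArgumentError):
            morph.relative_measure(df, "sp", "bill_over_wing")


class TestSlopeFit:
    def test_equals_closed_form_covariance_ratio(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        y = pd.Series(2.0 * x.to_numpy() + rng.normal(size=30), index=x.index)
        res = morph.fit_morph_slope(x, y, list(x.index), alpha=0.05)
        closed = np.cov(x, y, ddof=1)[0, 1] / np.var(x.to_numpy(), ddof=1)
        assert res.slope == pytest.approx(closed, abs=1e-10)

    def test_planted_slope_recovered_within_ci(self):
        spec = SimulationSpec(n_species=1, planted_slope=-2.5, seed=17)
        colors, morpho = synthdata.simulate_color_morphometrics(spec)
        ax = morph.train_discriminant(colors, "sp1")
        ld1 = morph.project_ld1(ax, colors)
        rel = morph.relative_measure(morpho, "sp1", "bill")
        females = morpho.loc[morpho["sex"] == "female", "specimen"]
        res = morph.fit_morph_slope(ld1, rel, list(females), alpha=0.0031)
        assert abs(res.slope - (-2.5)) < 1.96 * res.se

    def test_degenerate_inputs(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        with pytest.raises(InvalidArgumentError):
            morph.fit_morph_slope(x, y, list("abc"), alpha=0.05)
        with pytest.raises(InsufficientDataError):
            morph.fit_morph_slope(x, y, ["a", "b"], alpha=0.05)


class TestBonferroni:
    def test_published_family(self):
        a = morph.bonferroni_alpha(16, 0.05)
        assert a.exact == pytest.approx(0.003125)
        assert a.rounded == pytest.approx(0.0031)

    @pytest.mark.parametrize("n,expect", [(1, 0.05), (10, 0.005)])
    def test_simple_divisions(self, n, expect):
        assert morph.bonferroni_alpha(n, 0.05).exact == pytest.approx(expect)


class TestBlombergK:
    def test_agrees_with_independent_reference(self):
        """Frozen value cross-computed with phytools::phylosig."""
        t = trees.read_newick(
            "((A:1.0,B:1.0):0.5,((C:0.6,D:0.6):0.5,E:1.1):0.4);",
            from_string=True)
        vals = {"A": 1.2, "B": 0.9, "C": -0.5, "D": -0.2, "E": 0.3}
        k, _ = morph.blomberg_k(t, vals, n_perm=99, seed=0)
        assert k == pytest.approx(1.5894266224, abs=1e-9)

    def test_affine_invariance(self):
        t = trees.simulate_yule_tree(40, 1.0, 6)
        rng = np.random.default_rng(1)
        vals = dict(zip(trees.tip_labels(t), rng.normal(size=40)))
        k1, _ = morph.blomberg_k(t, vals, n_perm=99, seed=2)
        k2, _ = morph.blomberg_k(t, {s: 3.0 * v - 7.0 for s, v in vals.items()},
                                 n_perm=99, seed=2)
        assert k1 == pytest.approx(k2, abs=1e-10)

    def test_brownian_traits_give_k_near_one(self):
        ks = []
        for s in range(40):
            t = trees.simulate_yule_tree(80, 1.0, 500 + s)
            vals = trees.simulate_brownian(t, 1.0, s)
            k, _ = morph.blomberg_k(t, vals, n_perm=1, seed=0)
            ks.append(k)
        assert 0.85 < np.mean(ks) < 1.15

    def test_shuffled_traits_lose_signal(self):
        t = trees.simulate_yule_tree(80, 1.0, 3)
        rng = np.random.default_rng(8)
        vals = trees.simulate_brownian(t, 1.0, 9)
        labels = list(vals)
        shuffled = dict(zip(labels, rng.permutation([vals[lb] for lb in labels])))
        k, p = morph.blomberg_k(t, shuffled, n_perm=199, seed=4)
        assert k < 1.0
        assert p > 0.05

    def test_constant_trait_undefined(self):
        t = trees.simulate_yule_tree(10, 1.0, 0)
        with pytest.raises(InvalidArgumentError):
            morph.blomberg_k(t, {lb: 1.0 for lb in trees.tip_labels(t)})


class TestPipelineBattery:
    def test_planted_species_flagged(self):
        """One negative- and one positive-slope species among 16 are the
        ones flagged at the Bonferroni alpha."""
        spec = SimulationSpec(n_species=16, seed=29)
        plant = {"sp1": -2.5, "sp2": 1.7}
        colors, morpho = synthdata.simulate_color_morphometrics(
            spec, slope_by_species=plant)
        table, alpha = morph.run_morph_analysis(colors, morpho)
        assert alpha.rounded == pytest.approx(0.0031)
        flagged = set(table.loc[table["significant"], "species"])
        assert flagged == {"sp1", "sp2"}
        assert table.set_index("species").loc["sp1", "slope"] < 0
        assert table.set_index("species").loc["sp2", "slope"] > 0
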