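"""Genotype-ideotype index: rescaling, factor analysis, distances, selection."""

import numpy as np
import pandas as pd
import pytest

from mgidi import (
    TraitSpec,
    TrialDataError,
    compute_index,
    fit_factor_model,
    rescale,
    select_genotypes,
    selection_differentials,
    strengths_weaknesses,
)
from mgidi.index import FactorModel, varimax


def frame(arr, traits=None, genotypes=None):
    arr = np.asarray(arr, dtype=float)
    traits = traits or [f"t{j}" for j in range(arr.shape[1])]
    genotypes = genotypes or [f"G{i:02d}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=pd.Index(genotypes, name="genotype"), columns=traits)


def specs_for(df, decrease=()):
    return [
        TraitSpec(c, "decrease" if c in decrease else "increase") for c in df.columns
    ]


def random_means(g=18, p=12, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(g, 3))
    load = rng.normal(size=(3, p))
    return frame(base @ load + 0.3 * rng.normal(size=(g, p)))


class TestRescale:
    def test_increase_maps_min_max_to_0_100(self):
        df = frame([[2.0], [4.0], [6.0]])
        rx = rescale(df, specs_for(df))
        assert rx.values["t0"].tolist() == [0.0, 50.0, 100.0]

    def test_decrease_flips_the_map(self):
        df = frame([[2.0], [4.0], [6.0]])
        rx = rescale(df, specs_for(df, decrease=["t0"]))
        assert rx.values["t0"].tolist() == [100.0, 50.0, 0.0]

    def test_affine_preserves_correlation_up_to_sign(self):
        df = random_means()
        decrease = ["t1", "t5"]
        rx = rescale(df, specs_for(df, decrease=decrease))
        for c in df.columns:
            r = np.corrcoef(df[c], rx.values[c])[0, 1]
            assert r == pytest.approx(-1.0 if c in decrease else 1.0, abs=1e-12)

    def test_every_column_attains_both_extremes(self):
        df = random_means(seed=3)
        rx = rescale(df, specs_for(df, decrease=["t0"]))
        assert np.allclose(rx.values.min(axis=0), 0.0)
        assert np.allclose(rx.values.max(axis=0), 100.0)
        assert (rx.values.to_numpy() >= 0).all() and (rx.values.to_numpy() <= 100).all()

    def test_constant_column_raises_named_error(self):
        df = frame([[1.0, 5.0], [2.0, 5.0]])
        with pytest.raises(TrialDataError, match="t1"):
            rescale(df, specs_for(df))


class TestFactorModel:
    def test_duplicate_traits_load_together(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=50)
        c = rng.normal(size=50)
        df = frame(np.column_stack([a, a, c]), traits=["a1", "a2", "c"])
        rx = rescale(df, specs_for(df))
        with pytest.warns(RuntimeWarning, match="singular"):
            model = fit_factor_model(rx)
        eigs = sorted(model.eigenvalues, reverse=True)
        # duplicated pair -> one eigenvalue ~2; rank deficiency is exact
        assert np.allclose(eigs[:2], [2.0, 1.0], atol=0.05)
        assert eigs[2] <= 1e-10
        assert model.n_factors == 1
        lead = model.loadings["FA1"]
        assert abs(lead["a1"]) > 0.9 and abs(lead["a2"]) > 0.9

    def test_scores_match_explicit_matrix_product(self):
        df = random_means(seed=5)
        rx = rescale(df, specs_for(df))
        model = fit_factor_model(rx)
        V = rx.values
        Z = ((V - V.mean()) / V.std(ddof=1)).to_numpy()
        A = model.loadings.to_numpy()
        R = model.correlation.to_numpy()
        F = Z @ (A.T @ np.linalg.inv(R)).T
        assert np.max(np.abs(F - model.scores.to_numpy())) <= 1e-10

    def test_scores_have_zero_column_means(self):
        model = fit_factor_model(rescale(random_means(seed=1), specs_for(random_means(seed=1))))
        assert np.allclose(model.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_communalities_within_unit_interval(self):
        model = fit_factor_model(rescale(random_means(seed=2), specs_for(random_means(seed=2))))
        assert ((model.communalities >= 0) & (model.communalities <= 1)).all()
        assert 1 <= model.n_factors <= 12

    def test_loading_reconstruction_on_two_factor_data(self):
        rng = np.random.default_rng(12)
        g, p = 200, 6
        f1, f2 = rng.normal(size=(2, g))
        lam = np.array(
            [[0.9, 0.0], [0.8, 0.1], [0.85, -0.05], [0.0, 0.9], [0.1, 0.85], [-0.05, 0.8]]
        )
        X = np.column_stack([f1, f2]) @ lam.T + 0.3 * rng.normal(size=(g, p))
        df = frame(X)
        model = fit_factor_model(rescale(df, specs_for(df)))
        assert model.n_factors == 2
        A = model.loadings.to_numpy()
        R = model.correlation.to_numpy()
        recon = A @ A.T
        np.fill_diagonal(recon, 1.0)  # uniquenesses fill the diagonal
        assert np.max(np.abs(recon - R)) <= 0.15

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(4)
        L = rng.normal(size=(8, 3))
        Lr = varimax(L)
        np.testing.assert_allclose((L**2).sum(axis=1), (Lr**2).sum(axis=1), atol=1e-8)


def toy_model(scores, ideotype_offset):
    """FactorModel stub with identity loadings/correlation on f factors.

    With A = R = I and unit column sds, the ideotype's score vector is just
    its standardized trait vector, so per-factor distances can be dialed in
    directly.
    """
    scores = np.asarray(scores, dtype=float)
    g, f = scores.shape
    traits = [f"t{j}" for j in range(f)]
    labels = [f"FA{j + 1}" for j in range(f)]
    mu = pd.Series(100.0 - np.asarray(ideotype_offset, dtype=float), index=traits)
    return FactorModel(
        correlation=pd.DataFrame(np.eye(f), index=traits, columns=traits),
        eigenvalues=np.ones(f),
        n_factors=f,
        loadings=pd.DataFrame(np.eye(f), index=traits, columns=labels),
        communalities=pd.Series(1.0, index=traits),
        scores=pd.DataFrame(scores, index=[f"G{i}" for i in range(g)], columns=labels),
        trait_factor=pd.Series(labels, index=traits),
        column_means=mu,
        column_sds=pd.Series(1.0, index=traits),
        r_inv=np.eye(f),
    )


class TestComputeIndex:
    def test_one_dimensional_distance(self):
        # ideotype scores (7,), genotype at 3 -> MGIDI 4
        res = compute_index(toy_model([[3.0]], ideotype_offset=[7.0]))
        assert res.mgidi.iloc[0] == pytest.approx(4.0)
        assert res.contributions.iloc[0, 0] == pytest.approx(1.0)

    def test_pythagorean_two_factor_case(self):
        # per-factor gaps (3, 4): MGIDI 5, shares (0.36, 0.64)
        res = compute_index(toy_model([[4.0, 2.0]], ideotype_offset=[7.0, 6.0]))
        assert res.mgidi.iloc[0] == pytest.approx(5.0)
        assert res.contributions.iloc[0].tolist() == pytest.approx([0.36, 0.64])

    def test_genotype_at_ideotype_scores_zero(self):
        res = compute_index(toy_model([[7.0, 6.0], [1.0, 1.0]], ideotype_offset=[7.0, 6.0]))
        assert res.mgidi.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.ranking[0] == "G0"

    def test_contribution_rows_sum_to_one(self):
        df = random_means(seed=9)
        from mgidi import run_mgidi

        res, _, _ = run_mgidi(df, specs_for(df, decrease=["t2"]))
        np.testing.assert_allclose(res.contributions.sum(axis=1), 1.0, atol=1e-10)

    def test_best_in_all_traits_ranks_first(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            df = random_means(seed=100 + rep)
            best = df.max(axis=0) + 1.0  # dominates every trait (all increase)
            df.loc["G_best"] = best
            model = fit_factor_model(rescale(df, specs_for(df)))
            res = compute_index(model)
            assert res.ranking[0] == "G_best"

    def test_permuting_rows_permutes_index(self):
        df = random_means(seed=6)
        from mgidi import run_mgidi

        specs = specs_for(df)
        res1, _, _ = run_mgidi(df, specs)
        perm = df.sample(frac=1.0, random_state=1)
        res2, _, _ = run_mgidi(perm, specs)
        pd.testing.assert_series_equal(
            res1.mgidi.sort_index(), res2.mgidi.sort_index(), atol=1e-9
        )

    def test_direction_flip_with_negated_column_is_invariant(self):
        df = random_means(seed=7)
        specs = specs_for(df)
        rx1 = rescale(df, specs)
        flipped = df.copy()
        flipped["t3"] = -flipped["t3"]
        specs2 = specs_for(df, decrease=["t3"])
        rx2 = rescale(flipped, specs2)
        pd.testing.assert_frame_equal(rx1.values, rx2.values)

    def test_brute_force_ranking_equivalence(self):
        # explicit-loop Euclidean distances reproduce the ranking on small g
        for seed in range(5):
            df = random_means(g=9, p=5, seed=30 + seed)
            model = fit_factor_model(rescale(df, specs_for(df)))
            res = compute_index(model)
            S = model.scores.to_numpy()
            ideo = res.ideotype_scores.to_numpy()
            dists = {}
            for i, gid in enumerate(model.scores.index):
                acc = 0.0
                for j in range(S.shape[1]):
                    acc += (S[i, j] - ideo[j]) ** 2
                dists[gid] = acc**0.5
            brute = sorted(dists, key=lambda k: (dists[k], str(k)))
            assert brute == res.ranking


class TestSelection:
    def test_quarter_of_eighteen_is_four(self):
        df = random_means(g=18, seed=11)
        model = fit_factor_model(rescale(df, specs_for(df)))
        res = compute_index(model)
        sel = select_genotypes(res, 0.25)
        assert len(sel) == 4
        assert sel == res.ranking[:4]

    @pytest.mark.parametrize(
        "g,prop,expected", [(10, 0.25, 2), (18, 1.0, 18), (5, 0.05, 1)]
    )
    def test_floor_rule_with_minimum_one(self, g, prop, expected):
        df = random_means(g=g, p=4, seed=g)
        res = compute_index(fit_factor_model(rescale(df, specs_for(df))))
        assert len(select_genotypes(res, prop)) == expected

    @pytest.mark.parametrize("prop", [0.0, -0.1, 1.5])
    def test_invalid_proportion_rejected(self, prop):
        df = random_means(g=6, p=3, seed=2)
        res = compute_index(fit_factor_model(rescale(df, specs_for(df))))
        with pytest.raises(ValueError):
            select_genotypes(res, prop)


class TestSelectionDifferentials:
    def test_published_grain_yield_row(self):
        # 18 genotypes, 4 selected at mean 4233.464, all-genotype mean 4067.728
        xs, xo, g, k = 4233.464, 4067.728, 18, 4
        others = (g * xo - k * xs) / (g - k)
        col = np.array([xs] * k + [others] * (g - k))
        df = frame(col[:, None], traits=["GY"])
        tab = selection_differentials(df, df.index[:k], [TraitSpec("GY")])
        row = tab.iloc[0]
        assert row["SD"] == pytest.approx(165.736, abs=1e-9)
        assert row["SD_pct"] == pytest.approx(4.074, abs=5e-4)
        assert bool(row["goal_met"])

    def test_published_proline_row(self):
        xs, xo, g, k = 1117.310, 902.279, 18, 4
        others = (g * xo - k * xs) / (g - k)
        df = frame(np.array([xs] * k + [others] * (g - k))[:, None], traits=["pc"])
        tab = selection_differentials(df, df.index[:k], [TraitSpec("pc")])
        assert tab.iloc[0]["SD"] == pytest.approx(215.031, abs=1e-9)
        assert tab.iloc[0]["SD_pct"] == pytest.approx(23.83, abs=5e-3)

    def test_no_selection_pressure_gives_zero(self):
        df = frame(np.full((6, 2), 3.0) + np.arange(6)[:, None] * 0)
        tab = selection_differentials(df, list(df.index), specs_for(df))
        assert (tab["SD"] == 0).all() and (tab["SD_pct"] == 0).all()

    def test_decrease_sense_flips_goal(self):
        df = frame(np.arange(8.0)[:, None], traits=["Na"])
        tab = selection_differentials(df, ["G00", "G01"], [TraitSpec("Na", "decrease")])
        assert tab.iloc[0]["SD"] < 0 and bool(tab.iloc[0]["goal_met"])

    def test_identity_sd_pct_times_xo(self):
        df = random_means(seed=13) + 50.0
        sel = list(df.index[:5])
        tab = selection_differentials(df, sel, specs_for(df))
        np.testing.assert_allclose(tab["SD_pct"] * tab["Xo"], 100.0 * tab["SD"], rtol=1e-10)

    def test_empty_or_unknown_selection_rejected(self):
        df = random_means(g=5, p=3, seed=1)
        with pytest.raises(ValueError):
            selection_differentials(df, [], specs_for(df))
        with pytest.raises(ValueError):
            selection_differentials(df, ["nope"], specs_for(df))


class TestStrengthsWeaknesses:
    def test_single_factor_share_is_one(self):
        res = compute_index(toy_model([[1.0], [2.0]], ideotype_offset=[5.0]))
        table = strengths_weaknesses(res)
        assert (table["FA1"] == 1.0).all()

    def test_smallest_share_flags_strongest_factor(self):
        res = compute_index(toy_model([[4.0, 2.0]], ideotype_offset=[7.0, 6.0]))
        table = strengths_weaknesses(res)
        assert table.iloc[0]["strongest_factor"] == "FA1"  # share 0.36 < 0.64

    def test_rows_sum_to_one_on_synthetic_run(self):
        df = random_means(seed=14)
        model = fit_factor_model(rescale(df, specs_for(df)))
        res = compute_index(model)
        table = strengths_weaknesses(res)
        sums = table[[c for c in table.columns if c.startswith("FA")]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
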