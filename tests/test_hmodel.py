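import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from btsel import hmodel as H
from conftest import simulate_recovery_dataset


def tiny_dataset(seed=0, q=3, n_per=4, sd_u=0.7, sd_e=0.5):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd_u, q)
    y = np.concatenate([1.0 + u[i] + rng.normal(0, sd_e, n_per) for i in range(q)])
    ids = np.repeat([f"i{j}" for j in range(q)], n_per)
    return pd.DataFrame({"individual_id": ids, "value": y})


class TestModelSpec:
    def test_default_schedule_retains_2000(self):
        assert H.ModelSpec().n_retained == 2000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"iterations": 1000, "burnin": 300, "thin": 15},  # not divisible
            {"chains": 1},
            {"formula": "banana"},
        ],
    )
    def test_invalid_specs_raise(self, kwargs):
        with pytest.raises(ValueError):
            H.ModelSpec(**kwargs)

    @pytest.mark.parametrize(
        "iterations,burnin,thin,chains",
        [(150, 30, 4, 2), (600, 100, 10, 4), (90, 10, 2, 3)],
    )
    def test_retained_draw_arithmetic(self, iterations, burnin, thin, chains):
        spec = H.ModelSpec(iterations=iterations, burnin=burnin, thin=thin,
                           chains=chains, formula="1")
        draws = H.fit_lmm(tiny_dataset(), spec)
        assert draws.n_draws == chains * (iterations - burnin) // thin == spec.n_retained


class TestDesignMatrix:
    def test_full_formula_columns(self):
        data = pd.DataFrame(
            {
                "stage": ["pre-hunt", "hunt", "post-hunt"] * 2,
                "population": ["Georgia"] * 3 + ["SouthCarolina"] * 3,
            }
        )
        X, names = H.design_matrix(data)
        assert names == H.FIXED_EFFECT_NAMES
        expected = np.array(
            [
                [1, 0, 0, 0, 0, 0],
                [1, 1, 0, 0, 0, 0],
                [1, 0, 1, 0, 0, 0],
                [1, 0, 0, 1, 0, 0],
                [1, 1, 0, 1, 1, 0],
                [1, 0, 1, 1, 0, 1],
            ],
            dtype=float,
        )
        assert np.array_equal(X, expected)

    def test_aliased_column_is_named(self):
        # hunt stage entirely absent in South Carolina => interaction aliased
        data = pd.DataFrame(
            {
                "stage": ["pre-hunt", "hunt", "pre-hunt", "post-hunt"] * 3,
                "population": ["Georgia"] * 8 + ["SouthCarolina"] * 4,
            }
        )
        data.loc[data["population"] == "SouthCarolina", "stage"] = "pre-hunt"
        with pytest.raises(ValueError, match="aliased"):
            H.design_matrix(data)


class TestSampler:
    def test_posterior_mean_matches_gls_with_fixed_variances(self):
        """With variances held fixed the beta posterior is the GLS solution."""
        data = tiny_dataset(seed=1)
        v_ind, v_e = 0.5, 0.3
        spec = H.ModelSpec(formula="1", iterations=40_300, burnin=300, thin=2,
                           chains=2, seed=4, fix_variances=(v_ind, v_e))
        draws = H.fit_lmm(data, spec)
        y = data["value"].to_numpy()
        groups = data.groupby("individual_id", sort=True)
        Z = pd.get_dummies(data["individual_id"]).to_numpy(float)
        V = v_e * np.eye(len(y)) + v_ind * Z @ Z.T
        Vi = np.linalg.inv(V)
        X = np.ones((len(y), 1))
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y).item()
        se_gls = np.sqrt(np.linalg.inv(X.T @ Vi @ X)).item()
        mc_se = draws.beta[:, 0].std() / np.sqrt(200)  # conservative ESS
        assert draws.beta[:, 0].mean() == pytest.approx(beta_gls, abs=4 * mc_se)
        assert draws.beta[:, 0].std() == pytest.approx(se_gls, rel=0.1)

    def test_recovers_simulated_variance_components(self):
        _, rec = simulate_recovery_dataset(31, n_ind=50, repeats=40)
        rec = rec.rename(columns={"std_speed": "value"})
        spec = H.ModelSpec(response="value", formula="1", iterations=2100,
                           burnin=100, thin=8, chains=2, seed=2)
        draws = H.fit_lmm(rec, spec)
        assert np.median(draws.v_ind) == pytest.approx(0.45, abs=0.15)
        assert np.median(draws.v_e) == pytest.approx(0.55, abs=0.05)
        assert draws.converged

    def test_seed_reproducibility(self):
        data = tiny_dataset()
        spec = H.ModelSpec(formula="1", iterations=300, burnin=100, thin=2,
                           chains=2, seed=9)
        a, b = H.fit_lmm(data, spec), H.fit_lmm(data, spec)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v_ind, b.v_ind)

    def test_nonconvergence_is_flagged_not_silent(self):
        # two near-identical observations per individual, almost no signal,
        # absurdly short chains: R-hat flags it
        data = tiny_dataset(seed=3, q=2, n_per=2)
        spec = H.ModelSpec(formula="1", iterations=12, burnin=4, thin=1,
                           chains=2, seed=0)
        with pytest.warns(H.ConvergenceWarning):
            draws = H.fit_lmm(data, spec)
        assert not draws.converged


class TestSummaries:
    def test_repeatability_point_identities(self):
        assert H.repeatability_from_components(1.0, 1.0) == 0.5
        assert H.repeatability_from_components(1.0, 1e-12) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            H.repeatability_from_components(-0.1, 0.5)

    def test_pd_examples(self):
        assert H.probability_of_direction([1.0, 2.0, 0.5]) == 100.0
        assert H.probability_of_direction([-1.0, -0.5, 0.5, 1.0]) == 50.0
        assert H.probability_of_direction([-0.2, 0.1, 0.3, 0.4]) == 75.0

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_pd_invariant_under_sign_flip(self, values):
        v = np.asarray(values)
        assert H.probability_of_direction(v) == pytest.approx(
            H.probability_of_direction(-v)
        )
        assert 50.0 <= H.probability_of_direction(v) <= 100.0

    def test_rope_examples(self):
        assert H.rope_percent([0.0, 0.05, -0.08]) == 100.0
        assert H.rope_percent([0.5, 0.5, 0.5]) == 0.0
        rng = np.random.default_rng(0)
        u = rng.uniform(-0.2, 0.2, 20_000)
        assert H.rope_percent(u) == pytest.approx(50.0, abs=1.5)
        with pytest.raises(ValueError):
            H.rope_percent([0.1], rope=(0.2, 0.1))

    def test_quantiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(2000)
        s = H.summarize_draw_vector(v)
        srt = np.sort(v)

        def sort_quantile(p):
            # linear-interpolation quantile computed directly from the sort
            h = p * (len(srt) - 1)
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert s.median == pytest.approx(sort_quantile(0.5))
        assert s.ci_low == pytest.approx(sort_quantile(0.025))
        assert s.ci_high == pytest.approx(sort_quantile(0.975))

    def test_constant_draws_degenerate_summary(self):
        s = H.summarize_draw_vector(np.full(100, 1.7))
        assert (s.median, s.ci_low, s.ci_high, s.pd) == (1.7, 1.7, 1.7, 100.0)

    def test_effect_table_schema(self):
        rng = np.random.default_rng(1)
        n = 40
        data = pd.DataFrame(
            {
                "individual_id": np.repeat([f"i{j}" for j in range(8)], 10),
                "stage": rng.choice(["pre-hunt", "hunt", "post-hunt"], 80),
                "population": np.repeat(["Georgia", "SouthCarolina"], 40),
                "value": rng.standard_normal(80),
            }
        )
        spec = H.ModelSpec(iterations=220, burnin=20, thin=2, chains=2, seed=0)
        draws = H.fit_lmm(data, spec)
        table = H.summarize_effects(draws)
        assert len(table) == 6 + 2 + 1
        assert (table["kind"] == "fixed").sum() == 6
        assert (table["kind"] == "variance").sum() == 2
        assert table["term"].iloc[-1] == "repeatability"
        var_rows = table[table["kind"] == "variance"]
        assert np.allclose(var_rows["median_sd_scale"] ** 2, var_rows["median"],
                           rtol=0.2)

    def test_repeatability_draws_identities(self):
        d = tiny_draws(v_ind=np.full(10, 0.3), v_e=np.full(10, 0.3))
        assert (d.repeatability_draws() == 0.5).all()
        s = H.repeatability(d)
        assert s.median == 0.5 and s.ci_low == 0.5


def tiny_draws(v_ind, v_e):
    n = len(v_ind)
    return H.PosteriorDraws(
        beta=np.zeros((n, 1)),
        v_ind=np.asarray(v_ind, float),
        v_e=np.asarray(v_e, float),
        u=np.zeros((n, 2)),
        chain=np.repeat([0, 1], n // 2),
        draw=np.tile(np.arange(n // 2), 2),
        beta_names=("intercept",),
        individual_ids=("a", "b"),
        spec=H.ModelSpec(formula="1", iterations=n // 2 * 2, burnin=0, thin=1,
                         chains=2, seed=0),
    )


class TestSplitRhat:
    def textbook_rhat(self, chains):
        """Independent implementation straight from the BDA split-R-hat recipe."""
        half = chains.shape[1] // 2
        seqs = [c[:half] for c in chains] + [c[half: 2 * half] for c in chains]
        seqs = np.array(seqs)
        m, n = seqs.shape
        means = seqs.mean(axis=1)
        B = n / (m - 1) * ((means - means.mean()) ** 2).sum()
        W = (seqs.var(axis=1, ddof=1)).mean()
        var_hat = (n - 1) / n * W + B / n
        return np.sqrt(var_hat / W)

    def test_identical_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        chains = np.vstack([x, x])
        assert H.split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.vstack(
            [rng.standard_normal(200), 10 + rng.standard_normal(200)]
        )
        assert H.split_rhat(chains) > 1.1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((3, 400)) + np.array([[0.0], [0.3], [-0.2]])
        assert H.split_rhat(chains) == pytest.approx(self.textbook_rhat(chains))

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            H.split_rhat(np.zeros((1, 100)))


class TestDrawsIO:
    def test_csv_roundtrip(self, tmp_path):
        data = tiny_dataset()
        spec = H.ModelSpec(formula="1", iterations=60, burnin=20, thin=2,
                           chains=2, seed=1)
        draws = H.fit_lmm(data, spec)
        path = tmp_path / "draws.csv"
        draws.save_csv(path)
        back = H.PosteriorDraws.load_csv(path)
        assert back.individual_ids == draws.individual_ids
        assert np.allclose(back.u, draws.u)
        assert np.allclose(back.v_ind, draws.v_ind)
        assert back.spec.thin == spec.thin
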