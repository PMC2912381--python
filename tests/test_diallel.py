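"""Half-diallel combining abilities, the GCA/SCA ANOVA partition, and
epistasis edge calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lifescreen as ls


def diallel_from_means(X, reps=2, noise=0.0, rng=None):
    """Build DiallelData with `reps` identical (or jittered) vials per cell."""
    n = X.shape[0]
    parents = [f"P{i + 1:02d}" for i in range(n)]
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        for sex in ("male", "female"):
            for v in range(reps):
                val = X[i, j]
                if noise and rng is not None:
                    val += rng.normal(0, noise)
                rows.append({"parent_i": parents[i], "parent_j": parents[j],
                             "sex": sex, "vial": f"v{v}", "value": val})
    return ls.DiallelData(pd.DataFrame(rows))


def lstsq_oracle(X):
    """Constrained least squares fit of mean + additive + interaction
    effects to a complete half-diallel of cross means (normal equations,
    minimum-norm solution recentred to the sum-to-zero parameterisation)."""
    n = X.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), 1 + n))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        A[r, 0] = 1
        A[r, 1 + i] = 1
        A[r, 1 + j] = 1
        y[r] = X[i, j]
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    mu, g = beta[0], beta[1:]
    shift = g.mean()
    mu, g = mu + 2 * shift, g - shift
    s = np.zeros((n, n))
    for r, (i, j) in enumerate(pairs):
        s[i, j] = s[j, i] = y[r] - mu - g[i] - g[j]
    return mu, g, s


class TestDiallelData:
    def test_rejects_selfs_reciprocals_small_n(self):
        base = pd.DataFrame(
            {"parent_i": ["A"], "parent_j": ["A"], "sex": ["male"],
             "vial": ["v1"], "value": [50.0]}
        )
        with pytest.raises(ValueError, match="self"):
            ls.DiallelData(base)
        recip = pd.DataFrame(
            {"parent_i": ["A", "B", "A", "B", "C"],
             "parent_j": ["B", "A", "C", "C", "D"],
             "sex": "male", "vial": "v1", "value": 50.0}
        )
        with pytest.raises(ValueError, match="orientations"):
            ls.DiallelData(recip)
        two = pd.DataFrame(
            {"parent_i": ["A"], "parent_j": ["B"], "sex": ["male"],
             "vial": ["v1"], "value": [50.0]}
        )
        with pytest.raises(ValueError, match="3 parents"):
            ls.DiallelData(two)

    def test_missing_cross_named(self):
        X = np.zeros((4, 4))
        data = diallel_from_means(X + 50)
        data.frame = data.frame[
            ~((data.frame["parent_i"] == "P01") & (data.frame["parent_j"] == "P03"))
        ]
        with pytest.raises(ValueError, match=r"P01.*P03"):
            data.check_complete()


class TestCombiningAbilities:
    def test_constant_matrix_all_effects_zero(self):
        X = np.full((5, 5), 42.0)
        ca = ls.combining_abilities(diallel_from_means(X))
        assert ca.grand_mean == pytest.approx(42.0)
        assert np.allclose(ca.gca, 0, atol=1e-12)
        assert np.allclose(ca.sca, 0, atol=1e-12)

    def test_n4_toy_matches_least_squares_oracle(self):
        X = np.zeros((4, 4))
        vals = {(0, 1): 10, (0, 2): 12, (0, 3): 14, (1, 2): 16, (1, 3): 18, (2, 3): 20}
        for (i, j), v in vals.items():
            X[i, j] = X[j, i] = v
        ca = ls.combining_abilities(diallel_from_means(X))
        mu, g, s = lstsq_oracle(X)
        assert ca.grand_mean == pytest.approx(mu)
        assert np.allclose(ca.gca.to_numpy(), g, atol=1e-10)
        assert np.allclose(ca.sca.to_numpy(), s, atol=1e-10)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_formulas_equal_least_squares_exhaustively(self, n, rng):
        for _ in range(10):
            X = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals = rng.normal(55, 8, len(iu[0]))
            X[iu] = vals
            X.T[iu] = vals
            ca = ls.combining_abilities(diallel_from_means(X))
            mu, g, s = lstsq_oracle(X)
            assert ca.grand_mean == pytest.approx(mu, abs=1e-8)
            assert np.allclose(ca.gca.to_numpy(), g, atol=1e-8)
            assert np.allclose(ca.sca.to_numpy(), s, atol=1e-8)

    def test_algebraic_identities_on_simulated_data(self, rng):
        n = 8
        g = rng.normal(0, 3, n)
        g -= g.mean()
        p = ls.DiallelSimParams(n_parents=n, gca=g, seed=13)
        data, _ = ls.simulate_diallel(p)
        ca = ls.combining_abilities(data)
        assert abs(ca.gca.sum()) < 1e-10
        assert np.abs(ca.sca.sum(axis=1)).max() < 1e-10
        for i, j in itertools.combinations(ca.parents, 2):
            x = data.cross_means().loc[i, j]
            recon = ca.grand_mean + ca.gca[i] + ca.gca[j] + ca.sca.loc[i, j]
            assert abs(x - recon) < 1e-10

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(5)
        n = 5
        X = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.normal(55, 5, len(iu[0]))
        X[iu] = vals
        X.T[iu] = vals
        ca0 = ls.combining_abilities(diallel_from_means(X))
        ca1 = ls.combining_abilities(diallel_from_means(X + shift))
        assert ca1.grand_mean == pytest.approx(ca0.grand_mean + shift, abs=1e-8)
        assert np.allclose(ca0.gca, ca1.gca, atol=1e-8)
        assert np.allclose(ca0.sca, ca1.sca, atol=1e-8)

    def test_per_sex_estimates(self, rng):
        n = 6
        sg = rng.normal(0, 2, n)
        sg -= sg.mean()
        p = ls.DiallelSimParams(n_parents=n, sex_gca=sg, sigma2_vial=0.1,
                                sigma2_error=0.1, reps_per_cross_per_sex=50, seed=7)
        data, _ = ls.simulate_diallel(p)
        ca_m = ls.combining_abilities(data, sex="male")
        ca_f = ls.combining_abilities(data, sex="female")
        # sex-interaction flips sign between sexes: female minus male ~ 2*sex_gca
        diff = (ca_f.gca - ca_m.gca).to_numpy()
        assert np.corrcoef(diff, 2 * sg)[0, 1] > 0.99


class TestDiallelAnova:
    def test_degrees_of_freedom_bookkeeping(self):
        p = ls.DiallelSimParams(n_parents=10, reps_per_cross_per_sex=2, seed=0,
                                sigma2_vial=1, sigma2_error=1)
        data, _ = ls.simulate_diallel(p)
        table = ls.diallel_anova(data).set_index("source")
        assert table.loc["GCA", "df"] == 9
        assert table.loc["SCA", "df"] == 35
        assert table.loc["GCA", "df"] + table.loc["SCA", "df"] == 44
        assert table.loc["GCA×Sex", "df"] == 9
        assert table.loc["SCA×Sex", "df"] == 35

    def test_genotype_ss_additivity(self, rng):
        # SS(G) among the cross cells = SS(GCA) + SS(SCA): the partition is
        # a projection decomposition
        from lifescreen import _design
        p = ls.DiallelSimParams(
            n_parents=6, gca=np.r_[2.0, -1, 1, -2, 0.5, -0.5],
            sigma2_vial=2, sigma2_error=2, reps_per_cross_per_sex=3, seed=21,
        )
        data, _ = ls.simulate_diallel(p)
        table = ls.diallel_anova(data).set_index("source")
        sub = data.frame
        y = sub["value"].to_numpy()
        cross = (sub["parent_i"] + "×" + sub["parent_j"]).to_numpy()
        blocks = [
            ("Intercept", np.ones((len(y), 1))),
            ("Sex", _design.dummies(sub["sex"])),
            ("G", _design.dummies(cross)),
        ]
        seq, _ = _design.sequential_ss(y, blocks)
        ss_g = float(seq.loc[seq["source"] == "G", "ss"].iloc[0])
        assert table.loc["GCA", "ss"] + table.loc["SCA", "ss"] == pytest.approx(
            ss_g, abs=1e-8
        )

    def test_no_replication_rejected(self):
        X = np.full((4, 4), 50.0)
        data = diallel_from_means(X, reps=1)
        with pytest.raises(ValueError, match="replicate"):
            ls.diallel_anova(data)

    def test_sca_test_rejects_at_alpha_under_null(self, rng):
        # sca == 0: the SCA F test rejects at ~alpha (500 simulations)
        rejections = 0
        n_sim = 500
        for k in range(n_sim):
            g = rng.normal(0, 2, 6)
            g -= g.mean()
            p = ls.DiallelSimParams(
                n_parents=6, gca=g, sigma2_vial=2, sigma2_error=2,
                reps_per_cross_per_sex=3, seed=int(rng.integers(2**31)),
            )
            data, _ = ls.simulate_diallel(p)
            table = ls.diallel_anova(data).set_index("source")
            rejections += table.loc["SCA", "P"] < 0.05
        rate = rejections / n_sim
        assert 0.03 < rate < 0.075


class TestEpistasisCalls:
    def test_zero_sca_no_edge(self):
        X = np.full((5, 5), 50.0)
        ca = ls.combining_abilities(diallel_from_means(X, reps=3, noise=1.0,
                                                       rng=np.random.default_rng(0)))
        edges = ls.sca_epistasis_calls(ca)
        # with pure noise, roughly alpha of edges may fire; signs only on
        # significant ones
        assert (edges.loc[edges["p"] >= 0.05, "sign"] == "none").all()

    def test_sign_rule(self):
        n = 5
        s = np.zeros((n, n))
        # a strong planted interaction between parents 1 and 2
        s[0, 1] = s[1, 0] = 8.0
        p = ls.DiallelSimParams(n_parents=n, sca=s, sigma2_vial=0.2,
                                sigma2_error=0.2, reps_per_cross_per_sex=8, seed=3)
        data, _ = ls.simulate_diallel(p)
        ca = ls.combining_abilities(data)
        edges = ls.sca_epistasis_calls(ca).set_index(["parent_i", "parent_j"])
        assert edges.loc[("P01", "P02"), "sign"] == "enhancing"
        s2 = -s
        p2 = ls.DiallelSimParams(n_parents=n, sca=s2, sigma2_vial=0.2,
                                 sigma2_error=0.2, reps_per_cross_per_sex=8, seed=3)
        data2, _ = ls.simulate_diallel(p2)
        edges2 = ls.sca_epistasis_calls(ls.combining_abilities(data2)).set_index(
            ["parent_i", "parent_j"]
        )
        assert edges2.loc[("P01", "P02"), "sign"] == "suppressing"

    def test_planted_edges_detected(self, rng):
        # five disjoint planted interactions whose estimable (doubly
        # centred) SCA is 5 SE: all five called as enhancing edges in at
        # least 95% of runs. (A matrix with exactly five nonzero cells
        # cannot satisfy the zero-row-sum constraint, so the planted spikes
        # are sized on the projection scale.)
        n = 10
        reps = 8
        s2 = 4.0
        planted = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]
        se_sca = np.sqrt((n - 3) / (n - 1) * s2 / (2 * reps))
        raw = np.zeros((n, n))
        for i, j in planted:
            raw[i, j] = raw[j, i] = 1.0
        T = raw.sum(axis=1)
        proj = raw - (T[:, None] + T[None, :]) / (n - 2) + T.sum() / ((n - 1) * (n - 2))
        np.fill_diagonal(proj, 0)
        s = raw * (5 * se_sca / proj[0, 1])  # planted cells sit at 5 SE post-projection
        hits = 0
        n_runs = 60
        for run in range(n_runs):
            p = ls.DiallelSimParams(
                n_parents=n, sca=s, sigma2_vial=s2 / 2, sigma2_error=s2 / 2,
                reps_per_cross_per_sex=reps, seed=1000 + run,
            )
            data, _ = ls.simulate_diallel(p)
            ca = ls.combining_abilities(data)
            edges = ls.sca_epistasis_calls(ca)
            named = {(f"P{i + 1:02d}", f"P{j + 1:02d}") for i, j in planted}
            enhancing = edges[edges["sign"] == "enhancing"]
            called = set(map(tuple, enhancing[["parent_i", "parent_j"]].to_numpy()))
            hits += named <= called
        assert hits / n_runs >= 0.95

    def test_cross_sex_sca_correlation_centred_at_zero(self, rng):
        # with no sex-interaction structure, male and female SCA estimates
        # are uncorrelated on average
        n = 10
        rs = []
        for run in range(30):
            p = ls.DiallelSimParams(n_parents=n, sigma2_vial=2, sigma2_error=2,
                                    reps_per_cross_per_sex=8, seed=600 + run)
            data, _ = ls.simulate_diallel(p)
            ca_m = ls.combining_abilities(data, sex="male")
            ca_f = ls.combining_abilities(data, sex="female")
            iu = np.triu_indices(n, 1)
            rs.append(np.corrcoef(ca_m.sca.to_numpy()[iu], ca_f.sca.to_numpy()[iu])[0, 1])
        assert abs(np.mean(rs)) < 0.1
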