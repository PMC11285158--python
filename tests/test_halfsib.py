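"""Gibbs sampler correctness, diagnostics, and the randomization machinery."""

import numpy as np
import pandas as pd
import pytest

from gmatpipe import (
    GPosterior,
    MCMCSettings,
    MixedModelSpec,
    SimConfig,
    diagnose_chain,
    extract_G,
    fit_halfsib,
    null_G_test,
    randomize_offspring,
    simulate_dataset,
)
from gmatpipe.halfsib import _rinvwishart

from conftest import small_config


def _fit(table, seed=0, burnin=400, thin=2, samples=300, **spec_kw):
    spec = MixedModelSpec(traits=table.traits, **spec_kw)
    return fit_halfsib(table, spec, MCMCSettings(n_burnin=burnin, thin=thin,
                                                 n_samples=samples, seed=seed))


class TestInvWishart:
    def test_moments_match_scipy(self):
        # cross-check the Bartlett sampler against the scipy implementation
        from scipy.stats import invwishart
        rng = np.random.default_rng(0)
        A = rng.standard_normal((3, 3))
        Psi = A @ A.T + 3 * np.eye(3)
        nu = 12.0
        ours = np.mean([_rinvwishart(nu, Psi, rng) for _ in range(4000)], axis=0)
        theirs = invwishart.mean(df=nu, scale=Psi)
        assert np.allclose(ours, theirs, rtol=0.1)

    def test_draws_symmetric_pd(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            S = _rinvwishart(8, np.eye(4), rng)
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > 0


class TestFit:
    def test_univariate_matches_anova_oracle(self):
        # balanced design with well-separated components: posterior mean of
        # the sire variance within 25% of (MS_sire - MS_dam) / (d * n)
        cfg = SimConfig(species="sp", n_blocks=10, environments=["e1"],
                        offspring_per_family_per_env=12, trait_names=["t0"],
                        Sigma_sire=np.array([[0.3]]), Sigma_dam=np.array([[0.2]]),
                        sigma2_block=0.0, Sigma_resid=np.array([[0.5]]),
                        rho_GE=1.0, seed=21)
        table = simulate_dataset(cfg)
        df = table.measured()
        d, n = 3, 12
        fam_means = df.groupby(["sire_id", "dam_id"])["t0"].mean()
        sire_means = df.groupby("sire_id")["t0"].mean()
        s = len(sire_means)
        ms_sire = n * d * np.sum((sire_means - df["t0"].mean()) ** 2) / (s - 1)
        sm = sire_means.loc[fam_means.reset_index()["sire_id"]].to_numpy()
        ms_dam = n * np.sum((fam_means.to_numpy() - sm) ** 2) / (s * (d - 1))
        anova = (ms_sire - ms_dam) / (d * n)
        post = _fit(table, burnin=800, thin=4, samples=500)
        assert abs(post.posterior_mean("sire")[0, 0] - anova) / anova < 0.25

    def test_multivariate_recovery_smoke(self):
        p = 3
        cfg = small_config(p=p, n_blocks=8, offspring_per_family_per_env=12,
                           Sigma_sire=0.05 * np.eye(p), Sigma_dam=0.05 * np.eye(p),
                           Sigma_resid=0.4 * np.eye(p), seed=22)
        post = _fit(simulate_dataset(cfg), burnin=600, thin=4, samples=300)
        diag = np.diag(post.posterior_mean("sire"))
        assert np.all(diag > 0.005) and np.all(diag < 0.2)

    def test_every_draw_symmetric_psd(self, small_table):
        post = _fit(small_table, burnin=200, thin=1, samples=150)
        for term, arr in post.Sigma.items():
            assert np.allclose(arr, np.transpose(arr, (0, 2, 1)))
            assert np.all(np.linalg.eigvalsh(arr) > -1e-10)

    def test_identical_offspring_collapse(self):
        cfg = small_config(Sigma_sire=np.zeros((2, 2)), Sigma_dam=np.zeros((2, 2)),
                           sigma2_block=0.0, Sigma_resid=np.zeros((2, 2)))
        table = simulate_dataset(cfg)
        post = _fit(table, burnin=200, thin=1, samples=150)
        # posteriors collapse toward the prior floor: scale / (N + df - p - 1)
        assert post.posterior_mean("resid").max() < 0.01
        assert post.posterior_mean("sire").max() < 1e-4

    def test_trait_relabeling_permutes_G(self, small_table):
        post = _fit(small_table, seed=5, burnin=600, thin=3, samples=400)
        swapped = small_table.data.rename(columns={"t0": "t1", "t1": "t0"})
        from gmatpipe.core_io import PhenotypeTable
        table2 = PhenotypeTable(swapped, ["t0", "t1"])  # columns swapped
        post2 = _fit(table2, seed=5, burnin=600, thin=3, samples=400)
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        a = post.posterior_mean("sire")
        b = P @ post2.posterior_mean("sire") @ P
        assert np.allclose(a, b, atol=0.01)

    def test_two_contexts_rejected(self):
        cfg = small_config(environments=["e1", "e2"])
        table = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="context"):
            _fit(table, burnin=10, samples=5)

    def test_single_sire_rejected(self):
        cfg = small_config(n_blocks=1, sires_per_block=1, dams_per_block=2)
        table = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="sires"):
            _fit(table, burnin=10, samples=5)


class TestExtractG:
    def test_scaling(self, small_table):
        post = _fit(small_table, burnin=100, thin=1, samples=50)
        G1 = extract_G(post, 1)
        G4 = extract_G(post, 4)
        assert np.allclose(G4, 4 * G1)
        # eigenvalue ordering preserved under scaling
        w1 = np.linalg.eigvalsh(G1[0])
        w4 = np.linalg.eigvalsh(G4[0])
        assert np.allclose(w4, 4 * w1)
        with pytest.raises(ValueError):
            extract_G(post, 2)

    def test_proportional_quantities_scale_invariant(self, small_table):
        from gmatpipe import eigen_G, project_through_G
        post = _fit(small_table, burnin=100, thin=1, samples=50)
        G = post.posterior_mean("sire")
        e1, e4 = eigen_G(G), eigen_G(4 * G)
        assert np.allclose(e1.proportions, e4.proportions)
        v = np.array([1.0, 1.0])
        assert np.isclose(project_through_G(v, G), project_through_G(v, 4 * G))


class TestDiagnostics:
    def _posterior_from(self, x):
        n = len(x)
        Sigma = {t: np.zeros((n, 1, 1)) for t in ("sire", "dam", "block", "resid")}
        Sigma["sire"][:, 0, 0] = x
        return GPosterior(context=("sp", "e1"), traits=["t0"], Sigma=Sigma,
                          mu=np.zeros((n, 1)), effects={},
                          settings=MCMCSettings(n_burnin=0, thin=1, n_samples=n))

    def test_independent_draws_pass(self):
        x = np.random.default_rng(0).standard_normal(2000)
        rep = diagnose_chain(self._posterior_from(x))
        row = rep[(rep.term == "sire")].iloc[0]
        assert abs(row.lag1_autocorr) < 0.05 and row["pass"]

    def test_ar1_chain_fails(self):
        rng = np.random.default_rng(1)
        x = np.zeros(2000)
        for i in range(1, 2000):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        rep = diagnose_chain(self._posterior_from(x))
        row = rep[(rep.term == "sire")].iloc[0]
        assert row.lag1_autocorr > 0.5 and not row["pass"]

    def test_deterministic_given_draws(self):
        x = np.random.default_rng(2).standard_normal(500)
        a = diagnose_chain(self._posterior_from(x))
        b = diagnose_chain(self._posterior_from(x))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            diagnose_chain(self._posterior_from(np.ones(50)))


class TestRandomization:
    def test_block_sizes_and_family_multiset_preserved(self, small_table):
        out = randomize_offspring(small_table, seed=3)
        a = small_table.data.groupby("block_id").size()
        b = out.data.groupby("block_id").size()
        pd.testing.assert_series_equal(a, b)
        for blk in a.index:
            fa = sorted(small_table.data[small_table.data.block_id == blk]
                        .groupby(["sire_id", "dam_id"]).size().tolist())
            fb = sorted(out.data[out.data.block_id == blk]
                        .groupby(["sire_id", "dam_id"]).size().tolist())
            assert fa == fb

    def test_no_row_crosses_blocks(self, small_table):
        out = randomize_offspring(small_table, seed=4)
        assert (out.data["block_id"] == small_table.data["block_id"]).all()
        # traits stay attached to their rows
        assert np.allclose(out.data[out.traits].to_numpy(),
                           small_table.data[small_table.traits].to_numpy(),
                           equal_nan=True)

    def test_single_family_block_is_identity(self):
        cfg = small_config(n_blocks=1, sires_per_block=2, dams_per_block=1,
                           n_exp_blocks=1)
        table = simulate_dataset(cfg)
        # one experimental block, two families: permutation preserves family
        # size multiset; with equal sizes contents may swap but sizes match
        out = randomize_offspring(table, seed=5)
        assert sorted(out.data.groupby(["sire_id", "dam_id"]).size()) == \
               sorted(table.data.groupby(["sire_id", "dam_id"]).size())


class TestNullGTest:
    def test_invalid_and_warning(self, small_table):
        spec = MixedModelSpec(traits=small_table.traits)
        m = MCMCSettings(n_burnin=50, thin=1, n_samples=50)
        with pytest.raises(ValueError):
            null_G_test(small_table, spec, m, n_perm=0)
        with pytest.warns(UserWarning, match="unstable"):
            null_G_test(small_table, spec, m, n_perm=3, seed=1)

    def test_strong_signal_detected(self):
        cfg = small_config(Sigma_sire=0.3 * np.eye(2), Sigma_dam=0.1 * np.eye(2),
                           Sigma_resid=0.6 * np.eye(2), n_blocks=4,
                           offspring_per_family_per_env=8, seed=31)
        table = simulate_dataset(cfg)
        spec = MixedModelSpec(traits=table.traits)
        m = MCMCSettings(n_burnin=150, thin=1, n_samples=150, seed=2)
        res = null_G_test(table, spec, m, n_perm=30, seed=7)
        assert np.diag(res["significant"]).all()
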