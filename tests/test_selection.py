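"""Direction vectors, projections through G, selection gradients, D-matrix."""

import numpy as np
import pandas as pd
import pytest

from gmatpipe import (
    DirectionVector,
    bootstrap_beta,
    compute_D,
    genotypic_selection_gradient,
    hpd_overlap,
    native_direction,
    plasticity_vector,
    project_posterior,
    project_through_G,
    selection_gradient,
)
from gmatpipe.core_io import PhenotypeTable
from gmatpipe.selection import check_selection_estimable

from conftest import random_psd


def _survival_table(n=5000, beta=(1.0, 0.0, 0.0, 0.0, 0.0), intercept=0.0, seed=0,
                    family_structure=False, n_families=100):
    """Mean-one traits with logistic survival; optionally family-clustered."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    traits = [f"t{i}" for i in range(p)]
    if family_structure:
        per = n // n_families
        fam_eff = rng.normal(0, 0.1, (n_families, p))
        X = 1.0 + np.repeat(fam_eff, per, axis=0) + rng.normal(0, 0.2, (n_families * per, p))
        sire = np.repeat([f"s{i}" for i in range(n_families)], per)
        dam = np.repeat([f"d{i}" for i in range(n_families)], per)
        n = len(X)
    else:
        X = 1.0 + rng.normal(0, 0.25, (n, p))
        sire = np.tile([f"s{i}" for i in range(20)], n // 20 + 1)[:n]
        dam = sire
    logit = intercept + (X - X.mean(axis=0)) @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    df = pd.DataFrame(X, columns=traits)
    df["individual_id"] = [f"i{k}" for k in range(n)]
    df["sire_id"], df["dam_id"] = sire, dam
    df["block_id"] = "b1"
    df["species"], df["environment"] = "sp", "e1"
    df["emerged"], df["measured"], df["survived"] = 1, 1, y
    return PhenotypeTable(df, traits)


class TestDirectionVectors:
    def test_plasticity_difference_and_antisymmetry(self):
        a = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        b = np.array([0.8, 1.2, 1.0, 1.0, 1.0])
        dv = plasticity_vector(a, b)
        assert np.allclose(dv.vector, [0.2, -0.2, 0, 0, 0])
        assert np.allclose(plasticity_vector(b, a).vector, -dv.vector)

    def test_degenerate_zero_vector_flagged(self):
        dv = plasticity_vector(np.ones(3), np.ones(3))
        assert dv.degenerate
        with pytest.raises(ValueError):
            dv.unit()

    def test_native_direction_swap(self):
        a, b = np.array([1.0, 2.0]), np.array([2.0, 1.0])
        d1 = native_direction(a, b, at_env="e", toward="A")
        d2 = native_direction(b, a, at_env="e", toward="B")
        assert np.allclose(d1.vector, -d2.vector)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            plasticity_vector(np.ones(3), np.ones(4))


class TestProjection:
    def test_gmax_projects_to_one(self, rng):
        G = random_psd(rng, 4)
        w, V = np.linalg.eigh(G)
        assert np.isclose(project_through_G(V[:, -1], G), 1.0, atol=1e-12)

    def test_eigenvector_gives_lambda_ratio(self, rng):
        for _ in range(20):
            G = random_psd(rng, 5)
            w, V = np.linalg.eigh(G)
            for k in range(5):
                assert np.isclose(project_through_G(V[:, k], G), w[k] / w[-1], atol=1e-12)

    def test_identity_isotropic(self, rng):
        v = rng.standard_normal(6)
        assert np.isclose(project_through_G(v, np.eye(6)), 1.0)

    def test_axis_example(self):
        assert np.isclose(project_through_G(np.array([0.0, 1.0]), np.diag([0.4, 0.1])), 0.25)

    def test_scale_invariance(self, rng):
        G = random_psd(rng, 3)
        v = rng.standard_normal(3)
        assert np.isclose(project_through_G(v, G), project_through_G(v, 7.3 * G))

    def test_zero_vector_and_zero_G_rejected(self):
        with pytest.raises(ValueError):
            project_through_G(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError):
            project_through_G(np.ones(2), np.zeros((2, 2)))


class TestProjectPosterior:
    def test_point_collapse(self):
        res = project_posterior(np.array([1.0, 0.0]), np.diag([0.4, 0.1]))
        assert res.mean == 1.0 and np.ptp(res.draws) == 0.0

    def test_eigenvector_mixture_hits_both_values(self):
        v_draws = np.array([[1.0, 0.0], [0.0, 1.0]] * 10)
        res = project_posterior(v_draws, np.diag([0.4, 0.1]), pairing="paired")
        assert set(np.round(res.draws, 12)) == {1.0, 0.25}

    def test_draws_bounded(self, rng):
        v_draws = rng.standard_normal((30, 3))
        G_draws = np.stack([random_psd(rng, 3) for _ in range(25)])
        for pairing in ("random", "paired", "cross"):
            res = project_posterior(v_draws, G_draws, pairing=pairing, seed=1)
            assert np.all((res.draws >= 0) & (res.draws <= 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            project_posterior(np.empty((0, 2)), np.eye(2))

    def test_hpd_overlap(self):
        a = np.random.default_rng(0).normal(0.2, 0.01, 500)
        b = np.random.default_rng(1).normal(0.8, 0.01, 500)
        assert not hpd_overlap(a, b, 0.90)
        assert hpd_overlap(a, a, 0.90)


class TestSelectionGradient:
    def test_scaling_chain_at_half_survival(self):
        # with mean survival exactly 1/2 the evaluate-at-mean transform gives
        # probability = 0.25 x logit and relative = 0.5 x logit identically
        table = _survival_table(n=4000, beta=(1.5, 0, 0, 0, 0), intercept=0.0, seed=2)
        df = table.data
        # force exactly balanced survival by construction
        y = df["survived"].to_numpy()
        idx = np.argsort(y)
        y[:] = 0.0
        y[idx[: len(y) // 2]] = 0.0
        y[idx[len(y) // 2:]] = 1.0
        df["survived"] = y
        res = selection_gradient(table, transform="at_mean")
        assert res.mean_survival == 0.5
        assert np.allclose(res.probability, 0.25 * res.logit, atol=1e-12)
        assert np.allclose(res.relative, 0.5 * res.logit, atol=1e-12)

    def test_average_gradient_close_to_quarter_when_effects_weak(self):
        table = _survival_table(n=4000, beta=(0.3, 0, 0, 0, 0), seed=3)
        res = selection_gradient(table)
        ratio = res.probability / res.logit
        assert np.allclose(ratio, 0.25, atol=0.01)

    def test_direction_recovery(self):
        table = _survival_table(n=5000, beta=(2.0, 0, 0, 0, 0), seed=4)
        res = selection_gradient(table)
        corr = res.direction[0]  # direction is unit length; e1 alignment
        assert corr > 0.95

    def test_wald_calibration_under_null(self):
        from scipy.stats import chi2
        crit = chi2.isf(0.001, df=1)
        below = total = 0
        for rep in range(60):
            table = _survival_table(n=2000, beta=(0, 0, 0, 0, 0), seed=100 + rep)
            res = selection_gradient(table)
            below += int(np.sum(res.wald_chi2 < crit))
            total += len(res.wald_chi2)
        assert below / total >= 0.95

    def test_one_class_survival_rejected(self):
        table = _survival_table(n=200, intercept=30.0, seed=5)
        with pytest.raises(ValueError):
            selection_gradient(table)

    def test_mortality_guard(self):
        table = _survival_table(n=500, intercept=5.0, seed=6)
        if 0 < table.data["survived"].mean() < 1:
            with pytest.raises(ValueError, match="mortality"):
                check_selection_estimable(table, min_mortality=0.05)


class TestGenotypicGradient:
    def test_families_of_size_one_reduce_to_individual(self):
        table = _survival_table(n=400, beta=(1.0, 0.5, 0, 0, 0), seed=7)
        df = table.data.copy()
        df["sire_id"] = [f"s{k}" for k in range(len(df))]
        df["dam_id"] = [f"d{k}" for k in range(len(df))]
        singleton = PhenotypeTable(df, table.traits)
        a = selection_gradient(table)
        g = genotypic_selection_gradient(singleton, min_families=10)
        assert abs(np.dot(a.direction, g.direction)) > 0.999

    def test_family_level_agrees_with_individual(self):
        table = _survival_table(n=2000, beta=(1.5, 0, 0, 0, 0), seed=8,
                                family_structure=True, n_families=100)
        a = selection_gradient(table)
        g = genotypic_selection_gradient(table)
        assert abs(np.dot(a.direction, g.direction)) > 0.9

    def test_relabeling_invariance(self):
        table = _survival_table(n=1000, beta=(1.0, 0, 0, 0, 0), seed=9,
                                family_structure=True, n_families=50)
        g1 = genotypic_selection_gradient(table)
        df = table.data.copy()
        mapping = {f"s{i}": f"fam_{99 - i}" for i in range(50)}
        df["sire_id"] = df["sire_id"].map(mapping)
        df["dam_id"] = df["sire_id"]
        g2 = genotypic_selection_gradient(PhenotypeTable(df, table.traits))
        assert np.allclose(g1.relative, g2.relative)

    def test_too_few_families_rejected(self):
        table = _survival_table(n=100, seed=10)
        df = table.data.copy()
        df["sire_id"] = "s1"
        df["dam_id"] = ["d1", "d2"] * 50
        with pytest.raises(ValueError):
            genotypic_selection_gradient(PhenotypeTable(df, table.traits))


class TestBootstrap:
    def test_single_draw_reproducible(self):
        table = _survival_table(n=800, beta=(1.0, 0, 0, 0, 0), seed=11)
        d1, f1 = bootstrap_beta(table, n_boot=1, seed=3)
        d2, f2 = bootstrap_beta(table, n_boot=1, seed=3)
        assert np.allclose(d1, d2) and f1 == f2 == 0

    def test_draw_count_and_mean_direction(self):
        table = _survival_table(n=5000, beta=(2.0, 0, 0, 0, 0), seed=12)
        draws, failed = bootstrap_beta(table, n_boot=60, seed=4)
        assert len(draws) == 60 - failed
        point = selection_gradient(table).relative
        mean_dir = draws.mean(axis=0)
        corr = np.dot(mean_dir, point) / (np.linalg.norm(mean_dir) * np.linalg.norm(point))
        assert corr > 0.95

    def test_invalid_n_boot(self):
        table = _survival_table(n=200, seed=13)
        with pytest.raises(ValueError):
            bootstrap_beta(table, n_boot=0)


class TestDMatrix:
    def test_equal_means_give_zero(self):
        res = compute_D([np.ones(3)] * 4)
        assert np.allclose(res.D, 0.0)

    def test_two_groups_dmax_parallel_to_difference(self):
        a, b = np.array([1.0, 2.0, 0.0]), np.array([2.0, 0.0, 1.0])
        res = compute_D([a, b])
        diff = (a - b) / np.linalg.norm(a - b)
        assert np.isclose(abs(np.dot(res.axes[:, 0], diff)), 1.0)
        assert np.isclose(res.proportions[0], 1.0)

    def test_rank_bound(self, rng):
        means = [rng.standard_normal(5) for _ in range(8)]
        res = compute_D(means)
        assert np.sum(res.eigenvalues > 1e-10) <= 7

    def test_scores_center(self, rng):
        means = [rng.standard_normal(4) for _ in range(5)]
        res = compute_D(means)
        assert np.allclose(res.scores.to_numpy().sum(axis=0), 0.0, atol=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compute_D([np.ones(2)])
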