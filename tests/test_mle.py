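import numpy as np
import pytest
from scipy import stats

from twinh2 import (DegenerateTraitError, TraitMatrix, UnsupportedDesignError,
                    ValidationError, VarCompEstimate, compute_relatedness,
                    eigendecompose, fit_mle, loglik_ae, lrt_heritability,
                    make_twin_pedigree, simulate_traits)
from twinh2.mle import _profile_loglik
from twinh2.simulate import SimulationDesign


def traits_from_values(ids, values):
    values = np.atleast_2d(values.T).T
    names = [f"t{k}" for k in range(values.shape[1])]
    return TraitMatrix(ids=list(ids), values=values, trait_names=names)


@pytest.fixture(scope="module")
def quad_structure(quad_family_pedigree):
    rel = compute_relatedness(quad_family_pedigree)
    return rel, eigendecompose(rel)


class TestLoglik:
    @pytest.mark.parametrize("h2", [0.0, 0.25, 0.6, 0.95])
    def test_matches_dense_multivariate_normal(self, quad_structure, h2):
        rel, eig = quad_structure
        rng = np.random.default_rng(42)
        y = rng.standard_normal(4)
        sp2 = 1.7
        omega = rel.values * h2 * sp2 + np.eye(4) * (1 - h2) * sp2
        dense = stats.multivariate_normal(mean=np.zeros(4), cov=omega).logpdf(y)
        z = eig.rotation.T @ y
        assert loglik_ae(h2, sp2, z, eig.eigenvalues) == pytest.approx(dense, abs=1e-10)

    def test_unrelateds_make_h2_unidentifiable(self):
        lam = np.ones(6)
        z = np.random.default_rng(1).standard_normal(6)
        vals = [loglik_ae(h2, 2.0, z, lam) for h2 in (0.0, 0.3, 0.9)]
        assert np.ptp(vals) < 1e-12

    def test_h2_zero_is_iid_normal(self):
        z = np.array([0.3, -1.2, 0.8, 2.0])
        lam = np.array([2.0, 1.5, 0.5, 0.0])
        expect = stats.norm(scale=np.sqrt(1.3)).logpdf(z).sum()
        assert loglik_ae(0.0, 1.3, z, lam) == pytest.approx(expect, abs=1e-12)

    def test_domain_errors(self):
        z = np.zeros(3)
        lam = np.ones(3)
        with pytest.raises(ValidationError):
            loglik_ae(1.2, 1.0, z, lam)
        with pytest.raises(ValidationError):
            loglik_ae(0.5, -1.0, z, lam)


@pytest.fixture(scope="module")
def sim_fit_inputs():
    ped = make_twin_pedigree(125, 125)
    rel = compute_relatedness(ped)
    eig = eigendecompose(rel)
    rng_h2 = np.linspace(0.05, 0.95, 60)
    tr = simulate_traits(ped, SimulationDesign(n_traits=60, h2_values=rng_h2, seed=21))
    return tr, eig


class TestFitAe:
    def test_grid_oracle_never_beats_fit(self, sim_fit_inputs):
        tr, eig = sim_fit_inputs
        resid = tr.values - tr.values.mean(axis=0)
        z2 = (eig.rotation.T @ resid) ** 2
        grid = np.linspace(0.0, 1.0, 1001)
        for optimizer in ("mle_a", "mle_b"):
            ests = fit_mle(tr, eig, optimizer=optimizer)
            for t, est in enumerate(ests):
                oracle = max(_profile_loglik(h, z2[:, t], eig.eigenvalues)[0]
                             for h in grid)
                assert est.loglik >= oracle - 1e-6

    def test_optimizers_agree(self, sim_fit_inputs):
        tr, eig = sim_fit_inputs
        ha = np.array([e.h2 for e in fit_mle(tr, eig, optimizer="mle_a")])
        hb = np.array([e.h2 for e in fit_mle(tr, eig, optimizer="mle_b")])
        interior = (ha > 1e-6) & (ha < 1 - 1e-6)
        assert np.abs(ha[interior] - hb[interior]).max() < 1e-4
        np.testing.assert_array_equal(ha[~interior], hb[~interior])

    def test_noise_free_h2_one_hits_boundary(self):
        ped = make_twin_pedigree(30, 30)
        rel = compute_relatedness(ped)
        eig = eigendecompose(rel)
        tr = simulate_traits(ped, SimulationDesign(
            n_traits=3, h2_values=np.ones(3), seed=8))
        for optimizer in ("mle_a", "mle_b"):
            for est in fit_mle(tr, eig, optimizer=optimizer):
                assert est.h2 == 1.0
                assert est.sigma_e2 == 0.0

    def test_null_traits_estimate_near_zero(self):
        ped = make_twin_pedigree(125, 125)
        eig = eigendecompose(compute_relatedness(ped))
        tr = simulate_traits(ped, SimulationDesign(
            n_traits=100, h2_values=np.zeros(100), seed=13))
        h2 = np.array([e.h2 for e in fit_mle(tr, eig, optimizer="mle_a")])
        assert np.median(h2) < 0.05
        assert h2.mean() < 0.08

    def test_estimate_invariants(self, sim_fit_inputs):
        tr, eig = sim_fit_inputs
        for est in fit_mle(tr, eig, optimizer="mle_a"):
            assert 0.0 <= est.h2 <= 1.0
            assert est.sigma_g2 >= 0 and est.sigma_e2 >= 0
            assert est.sigma_p2 == pytest.approx(est.sigma_g2 + est.sigma_e2)
            assert 0.0 < est.lrt_p <= 0.5 + 1e-12
            assert est.converged

    def test_degenerate_and_small_inputs(self, sim_fit_inputs):
        tr, eig = sim_fit_inputs
        flat = TraitMatrix(ids=tr.ids, values=np.ones((len(tr.ids), 1)),
                           trait_names=["flat"])
        with pytest.raises(DegenerateTraitError):
            fit_mle(flat, eig)
        with pytest.raises(ValidationError, match="at least 10"):
            ped = make_twin_pedigree(1, 1)
            rel = compute_relatedness(ped)
            tiny = simulate_traits(ped, SimulationDesign(
                n_traits=1, h2_values=np.array([0.5]), seed=0))
            fit_mle(tiny, eigendecompose(rel))


class TestAce:
    def test_recovers_shared_environment(self):
        ped = make_twin_pedigree(250, 250)
        rel = compute_relatedness(ped)
        eig = eigendecompose(rel)
        tr = simulate_traits(ped, SimulationDesign(
            n_traits=30, h2_values=np.full(30, 0.4),
            c2_values=np.full(30, 0.3), seed=30))
        ests = fit_mle(tr, eig, model="ACE", rel=rel)
        assert np.mean([e.h2 for e in ests]) == pytest.approx(0.4, abs=0.08)
        assert np.mean([e.c2 for e in ests]) == pytest.approx(0.3, abs=0.08)
        for e in ests:
            assert e.sigma_p2 == pytest.approx(
                e.sigma_g2 + e.sigma_c2 + e.sigma_e2)

    def test_ace_beats_ae_likelihood_under_shared_env(self):
        ped = make_twin_pedigree(100, 100)
        rel = compute_relatedness(ped)
        eig = eigendecompose(rel)
        tr = simulate_traits(ped, SimulationDesign(
            n_traits=5, h2_values=np.full(5, 0.2),
            c2_values=np.full(5, 0.5), seed=31))
        ae = fit_mle(tr, eig, model="AE")
        ace = fit_mle(tr, eig, model="ACE", rel=rel)
        for a, b in zip(ae, ace):
            assert b.loglik >= a.loglik - 1e-8   # AE nested in ACE

    def test_rejects_non_pair_families(self, mz_plus_sib_pedigree):
        ped = mz_plus_sib_pedigree
        rel = compute_relatedness(ped)
        eig = eigendecompose(rel)
        # pad with pairs so n >= 10
        tr = TraitMatrix(ids=rel.ids,
                         values=np.random.default_rng(0).standard_normal((5, 1)),
                         trait_names=["y"])
        with pytest.raises((UnsupportedDesignError, ValidationError)):
            fit_mle(tr, eig, model="ACE", rel=rel)


class TestLrt:
    def test_mixture_reference_values(self):
        base = VarCompEstimate(trait="y", method="mle_a", model="AE",
                               sigma_g2=0.5, sigma_e2=0.5, sigma_p2=1.0,
                               h2=0.5, loglik=-10.0)
        null = VarCompEstimate(trait="y", method="mle_a", model="AE",
                               sigma_g2=0.0, sigma_e2=1.0, sigma_p2=1.0,
                               h2=0.0, loglik=-10.0)
        stat, p = lrt_heritability(base, null)
        assert stat == 0.0 and p == 0.5          # boundary convention
        null2 = VarCompEstimate(trait="y", method="mle_a", model="AE",
                                sigma_g2=0.0, sigma_e2=1.0, sigma_p2=1.0,
                                h2=0.0, loglik=-10.0 - 2.705543 / 2)
        stat, p = lrt_heritability(base, null2)
        assert stat == pytest.approx(2.705543, abs=1e-9)
        assert p == pytest.approx(0.05, abs=1e-6)    # half the chi2_1 tail
        null3 = VarCompEstimate(trait="y", method="mle_a", model="AE",
                                sigma_g2=0.0, sigma_e2=1.0, sigma_p2=1.0,
                                h2=0.0, loglik=-60.0)
        _, p = lrt_heritability(base, null3)
        assert p < 1e-20

    def test_inadmissible_order_raises(self):
        from twinh2 import ConvergenceError
        good = VarCompEstimate(trait="y", method="mle_a", model="AE",
                               sigma_g2=0.5, sigma_e2=0.5, sigma_p2=1.0,
                               h2=0.5, loglik=-11.0)
        null = VarCompEstimate(trait="y", method="mle_a", model="AE",
                               sigma_g2=0.0, sigma_e2=1.0, sigma_p2=1.0,
                               h2=0.0, loglik=-10.0)
        with pytest.raises(ConvergenceError):
            lrt_heritability(good, null)
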