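"""Mechanism partition: structural zeros, identities, and the small-variance
closed form for growth-density covariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacoex import (
    LocalGrowthProfile,
    MetacommunityState,
    SpeciesTraits,
    SupplyField,
    delta_kappa_approx,
    invader_distribution,
    local_growth_rates,
    metacommunity_growth,
    partition_exact,
    resident_steady_state,
    single_species_equilibrium,
)
from conftest import random_traits


def exact_partition(invader, resident, field):
    res = resident_steady_state([resident], field)
    return partition_exact(invader, [resident], res.state, converged=res.converged)


def test_local_growth_hand_example():
    """r_x = -m + b p R_x + b(1-p)<R>: (0.3, 0.1) for R = (0.8, 0.4)."""
    tr = SpeciesTraits(m=0.4, b=1.0, Q=1.0, p=0.5)
    r = local_growth_rates(np.array([0.8, 0.4]), tr)
    np.testing.assert_allclose(r, [0.3, 0.1])


def test_local_growth_zero_on_break_even_field():
    tr = SpeciesTraits(m=0.4, b=1.0, Q=1.0, p=0.7)
    r = local_growth_rates(np.full(5, 0.4), tr)
    np.testing.assert_allclose(r, 0.0, atol=1e-15)


def test_metacommunity_growth_two_patch_decomposition():
    """<r nu> = <r> + cov(r, nu) with the population covariance."""
    prof = LocalGrowthProfile(
        r=np.array([0.3, 0.1]),
        nu=np.array([1.5, 0.5]),
        env_response=np.zeros(2),
        comp_response=-np.array([0.3, 0.1]),
    )
    assert metacommunity_growth(prof) == pytest.approx(0.25)


def test_metacommunity_growth_uniform_density_is_patch_mean():
    prof = LocalGrowthProfile(
        r=np.array([0.4, -0.2, 0.1]),
        nu=np.ones(3),
        env_response=np.zeros(3),
        comp_response=np.array([-0.4, 0.2, -0.1]),
    )
    assert metacommunity_growth(prof) == pytest.approx(0.1)


def test_unnormalised_density_rejected():
    with pytest.raises(ValueError, match="average to one"):
        LocalGrowthProfile(
            r=np.zeros(2), nu=np.array([1.0, 0.5]),
            env_response=np.zeros(2), comp_response=np.zeros(2),
        )


def test_resident_growth_zero_at_own_equilibrium(supply20):
    """Density-weighted mean growth of a resident on its own equilibrium
    field vanishes."""
    tr = SpeciesTraits(m=0.4, b=1.1, Q=0.8, p=0.35)
    nstar, rm = single_species_equilibrium(tr, supply20)
    prof = LocalGrowthProfile(
        r=local_growth_rates(rm, tr),
        nu=nstar / nstar.mean(),
        env_response=np.zeros_like(rm),
        comp_response=-local_growth_rates(rm, tr),
    )
    assert metacommunity_growth(prof) == pytest.approx(0.0, abs=1e-12)


def test_partition_identity_and_structural_zeros(supply20, rng):
    """dE - dC + dI + dk equals the eigenvalue invasion rate, and the
    environment, storage and relative-nonlinearity components vanish, for
    randomized invader/resident pairs."""
    for _ in range(30):
        inv, res = random_traits(rng), random_traits(rng)
        part = exact_partition(inv, res, supply20)
        assert abs(part.delta_E) < 1e-10
        assert abs(part.delta_I) < 1e-10
        assert abs(part.delta_N) < 1e-10
        assert part.r_tilde == pytest.approx(part.eigenvalue_rate, rel=1e-6, abs=1e-12)
        # dC reduces to the R* difference under q_ir = b_i/b_r
        assert part.delta_C == pytest.approx(inv.rstar - res.rstar, abs=1e-10)


def test_self_invasion_partition_is_zero(supply20):
    tr = SpeciesTraits(m=0.45, b=1.3, Q=0.9, p=0.6)
    part = exact_partition(tr, tr, supply20)
    for val in (part.delta_E, part.delta_C, part.delta_I, part.delta_kappa,
                part.r_tilde):
        assert abs(val) < 1e-8


def test_homogeneous_supply_reduces_to_rstar_comparison():
    """var(s) = 0: growth-density covariance vanishes and the invasion rate
    is R*_r - R*_i per generation."""
    field = SupplyField(S=np.full(8, 3.0))
    inv = SpeciesTraits(m=0.5, b=1.0, Q=1.0, p=0.8)
    res = SpeciesTraits(m=0.4, b=1.0, Q=1.0, p=0.2)
    part = exact_partition(inv, res, field)
    assert abs(part.delta_kappa) < 1e-12
    assert part.r_tilde == pytest.approx(res.rstar - inv.rstar, abs=1e-10)


def test_r_prime_antisymmetry(supply20):
    a = SpeciesTraits(m=0.3, b=1.0, Q=1.0, p=0.2)
    b = SpeciesTraits(m=0.6, b=1.2, Q=1.0, p=0.7)
    pab = exact_partition(a, b, supply20)
    pba = exact_partition(b, a, supply20)
    assert pab.r_prime == pytest.approx(-pba.r_prime, abs=1e-12)


def test_delta_kappa_closed_form_values():
    """var(s)(1-p_r)^2 R*_r (odds_i - odds_r): 0.1*0.25*0.5*2 = 0.025."""
    inv = SpeciesTraits(m=0.1, b=1.0, Q=1.0, p=0.75)
    res = SpeciesTraits(m=0.5, b=1.0, Q=1.0, p=0.5)
    assert delta_kappa_approx(inv, res, 0.1) == pytest.approx(0.025)
    assert delta_kappa_approx(res, res, 0.1) == 0.0
    assert delta_kappa_approx(inv, res, 0.0) == 0.0
    with pytest.raises(ValueError, match="singular"):
        delta_kappa_approx(SpeciesTraits(m=0.1, b=1, Q=1, p=1.0), res, 0.1)


def test_delta_kappa_approximation_consistency():
    """The closed form converges to the exact covariance computation as the
    supply variance shrinks (monotone ratio -> 1)."""
    rng = np.random.default_rng(42)
    shape = rng.normal(size=20)
    shape -= shape.mean()
    inv = SpeciesTraits(m=0.45, b=1.0, Q=1.0, p=0.7)
    res = SpeciesTraits(m=0.40, b=1.0, Q=1.0, p=0.4)
    ratios = []
    for eps in [0.2, 0.1, 0.05, 0.025, 0.0125]:
        field = SupplyField(S=2.0 * (1.0 + eps * shape))
        part = exact_partition(inv, res, field)
        ratios.append(delta_kappa_approx(inv, res, field.var_s) / part.delta_kappa)
    assert all(r1 > r2 for r1, r2 in zip(ratios, ratios[1:]))  # monotone
    assert abs(ratios[-1] - 1.0) < 0.01


def test_delta_kappa_sign_follows_retention_difference(supply_small):
    """Invaders keeping offspring closer than the resident gain from
    growth-density covariance; wider dispersers lose."""
    for pi in [0.1, 0.45, 0.85]:
        for pr in [0.2, 0.6]:
            if pi == pr:
                continue
            inv = SpeciesTraits(m=0.4, b=1.0, Q=1.0, p=pi)
            res = SpeciesTraits(m=0.4, b=1.0, Q=1.0, p=pr)
            part = exact_partition(inv, res, supply_small)
            assert np.sign(part.delta_kappa) == np.sign(pi - pr)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    pi=st.floats(0.0, 0.95), pr=st.floats(0.0, 0.95),
    rstar_i=st.floats(0.05, 0.95), rstar_r=st.floats(0.05, 0.95),
    bi=st.floats(0.5, 2.0), br=st.floats(0.5, 2.0),
)
def test_partition_identity_property(supply_small, pi, pr, rstar_i, rstar_r, bi, br):
    """Partition identity holds across the whole trait space."""
    inv = SpeciesTraits(m=bi * rstar_i, b=bi, Q=1.0, p=pi)
    res = SpeciesTraits(m=br * rstar_r, b=br, Q=1.0, p=pr)
    part = exact_partition(inv, res, supply_small)
    assert part.r_tilde == pytest.approx(part.eigenvalue_rate, rel=1e-6, abs=1e-12)
    assert abs(part.delta_E) < 1e-10 and abs(part.delta_I) < 1e-10
    assert abs(part.delta_N) < 1e-10


class TestInvaderDistribution:
    def test_uniform_on_homogeneous_field(self):
        tr = SpeciesTraits(m=0.3, b=1.0, Q=1.0, p=0.5)
        nu = invader_distribution(tr, np.full(6, 0.7))
        np.testing.assert_allclose(nu, 1.0, atol=1e-9)

    def test_full_retention_concentrates_on_best_patch(self):
        R = np.array([0.2, 0.9, 0.5, 0.1])
        tr = SpeciesTraits(m=0.3, b=1.0, Q=1.0, p=1.0)
        nu = invader_distribution(tr, R)
        assert nu.argmax() == 1
        assert nu.mean() == pytest.approx(1.0)

    def test_matches_rare_invader_simulation(self, supply20):
        """The eigenvector agrees with the long-run distribution of a
        renormalised rare invader on the frozen resident field."""
        from scipy.linalg import expm
        from metacoex import invasion_matrix

        res = SpeciesTraits(m=0.4, b=1.0, Q=1.0, p=0.3)
        inv = SpeciesTraits(m=0.5, b=1.2, Q=1.0, p=0.7)
        state = resident_steady_state([res], supply20).state
        A = invasion_matrix(inv, state.R)
        nu = invader_distribution(inv, state.R)
        prop = expm(A * 40.0)
        v = np.full(20, 1.0)
        for _ in range(30):
            v = prop @ v
            v /= v.mean()
        np.testing.assert_allclose(v, nu, rtol=1e-6)
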