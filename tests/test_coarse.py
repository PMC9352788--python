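"""Stationary distribution, ISA memberships and the 2-state projection."""

import numpy as np
import pytest
import scipy.linalg

import mvitc as mv
from mvitc.kinetics import RateMatrix

from conftest import BIVALENT_RATES, random_micro_rates


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        rates = mv.MicroRates(s=1, k_on=(3.0,), k_off=(7.0,))
        Q = mv.build_rate_matrix(rates, 2.0)
        pi = mv.stationary_distribution(Q)
        expected = np.array([7.0, 6.0]) / 13.0
        np.testing.assert_allclose(pi, expected, rtol=1e-12)

    def test_defining_property_on_random_chains(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rates = random_micro_rates(rng)
            Q = mv.build_rate_matrix(rates, 10 ** rng.uniform(-3, 0))
            pi = mv.stationary_distribution(Q)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.linalg.norm(Q.QT @ pi) < 1e-10 * np.abs(Q.QT).max()

    def test_printed_bivalent_rates_against_null_space_solve(self):
        Q = mv.build_rate_matrix(BIVALENT_RATES, 0.1)
        pi = mv.stationary_distribution(Q)
        ns = scipy.linalg.null_space(Q.QT)
        assert ns.shape[1] == 1
        oracle = ns[:, 0] / ns[:, 0].sum()
        np.testing.assert_allclose(pi, oracle, rtol=1e-9)

    def test_reducible_chain_rejected(self):
        Q = mv.build_rate_matrix(BIVALENT_RATES, 0.0)
        with pytest.raises(ValueError, match="irreducible"):
            mv.stationary_distribution(Q)


class TestMemberships:
    def test_rows_sum_to_one_entries_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rates = random_micro_rates(rng)
            Q = mv.build_rate_matrix(rates, 10 ** rng.uniform(-3, 0))
            chi = mv.pcca_memberships(Q).chi
            np.testing.assert_allclose(chi.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(chi >= 0) and np.all(chi <= 1)

    def test_two_state_chain_is_identity(self):
        rates = mv.MicroRates(s=1, k_on=(3.0,), k_off=(7.0,))
        Q = mv.build_rate_matrix(rates, 2.0)
        chi = mv.pcca_memberships(Q).chi
        np.testing.assert_allclose(chi, np.eye(2), atol=1e-12)

    def test_disconnected_blocks_give_crisp_split(self):
        # two uncoupled 2-state chains: memberships are exact indicators
        QT = np.zeros((4, 4))
        QT[:2, :2] = [[-1.0, 2.0], [1.0, -2.0]]
        QT[2:, 2:] = [[-5.0, 3.0], [5.0, -3.0]]
        chi = mv.pcca_memberships(RateMatrix(QT=QT, L_free=1.0)).chi
        np.testing.assert_allclose(chi[:2, 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(chi[2:, 1], 1.0, atol=1e-9)

    def test_lifted_memberships_constant_within_bond_level(self):
        Q = mv.build_rate_matrix(BIVALENT_RATES, 0.1)
        chi = mv.pcca_memberships(Q).chi
        bc = Q.space.bond_counts()
        for b in range(3):
            rows = chi[bc == b]
            assert np.all(rows == rows[0])

    def test_columns_span_observable_slow_subspace(self):
        # chi columns lie in the span of the two dominant eigenvectors of
        # the observable (bond-count) chain, lifted to the full space
        from mvitc.kinetics import build_lumped_rate_matrix

        Q = mv.build_rate_matrix(BIVALENT_RATES, 0.1)
        lump = build_lumped_rate_matrix(BIVALENT_RATES, 0.1)
        w, V = scipy.linalg.eig(lump.QT.T)
        order = np.argsort(np.abs(w.real))
        basis = V[:, order[:2]].real[Q.space.bond_counts()]
        chi = mv.pcca_memberships(Q).chi
        proj = basis @ np.linalg.lstsq(basis, chi, rcond=None)[0]
        assert np.abs(chi - proj).max() < 1e-8


class TestCoarseGrain:
    def test_identity_projection_on_two_state_chain(self):
        rates = mv.MicroRates(s=1, k_on=(3.0,), k_off=(7.0,))
        Q = mv.build_rate_matrix(rates, 2.0)
        cg = mv.coarse_grain(Q)
        np.testing.assert_allclose(cg.Qc_T, Q.QT, atol=1e-10)
        assert cg.k_on_macro == pytest.approx(3.0, rel=1e-10)
        assert cg.k_off_macro == pytest.approx(7.0, rel=1e-10)

    def test_projected_columns_sum_to_zero(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rates = random_micro_rates(rng)
            L = 10 ** rng.uniform(-3, 0)
            try:
                cg = mv.coarse_grain(mv.build_rate_matrix(rates, L))
            except ValueError:
                continue
            np.testing.assert_allclose(cg.Qc_T.sum(axis=0), 0.0, atol=1e-8)

    def test_macro_K_matches_membership_weighted_occupancies(self):
        # oracle: K * [L] must equal the chi-weighted stationary mass
        # ratio of bound over unbound, computed without the projection
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(60):
            rates = random_micro_rates(rng)
            L = 10 ** rng.uniform(-3, 0)
            Q = mv.build_rate_matrix(rates, L)
            try:
                cg = mv.coarse_grain(Q)
            except ValueError:
                continue
            chi = cg.chi.chi
            oracle = (chi[:, 1] @ cg.pi) / (chi[:, 0] @ cg.pi) / L
            assert cg.K_a_macro == pytest.approx(oracle, rel=1e-6)
            checked += 1
        assert checked > 30

    def test_crisp_occupancy_oracle_under_strong_separation(self):
        # when the observable spectral gap is wide and the metastable
        # split is bound/unbound, the projection K approaches the crisp
        # bond-count occupancy ratio
        from mvitc.coarse import lumped_generator

        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(300):
            rates = random_micro_rates(rng, s=2)
            L = 10 ** rng.uniform(-3, 0)
            Q = mv.build_rate_matrix(rates, L)
            try:
                cg = mv.coarse_grain(Q)
            except ValueError:
                continue
            wl = np.sort(np.abs(np.linalg.eigvals(lumped_generator(Q)).real))
            bc = Q.space.bond_counts()
            crisp_split = np.array_equal(np.argmax(cg.chi.chi, axis=1), bc > 0)
            if wl[2] / wl[1] < 1e3 or not crisp_split:
                continue
            crisp = cg.pi[bc > 0].sum() / cg.pi[bc == 0].sum() / L
            assert cg.K_a_macro == pytest.approx(crisp, rel=5e-2)
            checked += 1
        assert checked > 10

    def test_permutation_of_micro_states_leaves_K_unchanged(self):
        from mvitc.kinetics import BindingStateSpace

        base_space = mv.enumerate_binding_states(2)
        Q = mv.build_rate_matrix(BIVALENT_RATES, 0.05, base_space)
        base = mv.coarse_grain(Q).K_a_macro
        rng = np.random.default_rng(7)
        for _ in range(3):
            # reorder the states (keeping the unbound state first, as the
            # orientation rule requires) and rebuild the generator
            perm = np.concatenate([[0], 1 + rng.permutation(6)])
            space = BindingStateSpace(
                s=2, states=tuple(base_space.states[i] for i in perm))
            Qp = mv.build_rate_matrix(BIVALENT_RATES, 0.05, space)
            assert mv.coarse_grain(Qp).K_a_macro == pytest.approx(base, rel=1e-10)


class TestAssociationConstants:
    def test_s1_constant_across_ligand_series(self):
        rates = mv.MicroRates(s=1, k_on=(4.0,), k_off=(2.0,))
        K = mv.association_constants(rates, [0.01, 0.1, 1.0])
        np.testing.assert_allclose(K, 2.0, rtol=1e-10)

    def test_positive_along_bivalent_series(self, bivalent_conc):
        series = mv.free_ligand_series(BIVALENT_RATES, 0.3208, bivalent_conc)
        K = mv.association_constants(BIVALENT_RATES, series.L_free)
        assert K.shape == (14,)
        assert np.all(K > 0)
        # end-to-end agreement with the membership-weighted occupancy
        # oracle at every injection
        for L, Ki in zip(series.L_free, K):
            cg = mv.coarse_grain(mv.build_rate_matrix(BIVALENT_RATES, L))
            chi = cg.chi.chi
            oracle = (chi[:, 1] @ cg.pi) / (chi[:, 0] @ cg.pi) / L
            assert Ki == pytest.approx(oracle, rel=1e-6)
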