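"""Force law, combination rules, neighbour search and force balance."""

import math

import numpy as np
import pytest

from celldem import (
    InteractionMatrix,
    SimulationState,
    boundary_force,
    default_parameters,
    drag_force,
    elastic_pair_force,
    neighbor_search,
    net_forces,
    pair_coefficients,
    pair_geometry,
)
from celldem.mechanics import L0, PairCoefficients, compute_forces
from celldem.state import BoundaryObject

UM = 1e-6


def oracle_pair_force(xI, RI, pI, xJ, RJ, pJ):
    """Independent closed-form evaluation of the contact law.

    Written directly from the model definition (micrometre-unit convention
    for P): harmonic-style combinations, linear adhesion spring when
    separated, Hertz contact when overlapping, hard cutoff at the smaller
    influence radius.  Deliberately kept free of any package internals.
    """
    d = np.asarray(xJ, float) - np.asarray(xI, float)
    dist = float(np.hypot(*d))
    alpha = (RI + RJ) - dist
    delta = min(pI.delta, pJ.delta)
    if alpha < -delta:
        return np.zeros(2)
    n = d / dist
    fa = 0.0 if (pI.F_a <= 0 or pJ.F_a <= 0) else 2 * pI.F_a * pJ.F_a / (pI.F_a + pJ.F_a)
    ka = 0.0 if (pI.k_a <= 0 or pJ.k_a <= 0) else pI.k_a * pJ.k_a / (pI.k_a + pJ.k_a)
    kr = (4.0 / 3.0) / ((1 - pI.nu**2) / pI.E + (1 - pJ.nu**2) / pJ.E)
    req = RI * RJ / (RI + RJ)
    if alpha < 0.0:
        P = ka * (alpha / 1e-6)
    else:
        P = kr * math.sqrt(req / 1e-6) * (alpha / 1e-6) ** 1.5
    return (fa - P) * n


class TestPairGeometry:
    def test_overlap_direction_radius(self):
        g = pair_geometry([0.0, 0.0], 0.25 * UM, [0.4 * UM, 0.0], 0.25 * UM)
        assert g.alpha == pytest.approx(0.1 * UM)
        assert g.n == pytest.approx([1.0, 0.0])
        assert g.R_eq == pytest.approx(0.125 * UM)

    def test_equal_radii_equivalent(self):
        g = pair_geometry([0, 0], 0.3 * UM, [1e-6, 0], 0.3 * UM)
        assert g.R_eq == pytest.approx(0.15 * UM)

    def test_boundary_limit(self):
        # R_J -> infinity: equivalent radius approaches R_I
        g = pair_geometry([0, 0], 0.2 * UM, [1.0, 0], 1e6)
        assert g.R_eq == pytest.approx(0.2 * UM, rel=1e-6)

    def test_coincident_needs_rng(self):
        with pytest.raises(ValueError):
            pair_geometry([0, 0], UM, [0, 0], UM)
        rng = np.random.default_rng(0)
        g = pair_geometry([0, 0], UM, [0, 0], UM, rng=rng)
        assert np.hypot(*g.n) == pytest.approx(1.0)


class TestElasticPairForce:
    def test_zero_overlap_leaves_only_attraction(self, table2):
        pC = table2["C"]
        g = pair_geometry([0, 0], pC.R, [2 * pC.R, 0], pC.R)
        assert g.alpha == pytest.approx(0.0, abs=1e-20)
        c = pair_coefficients(pC, pC, same_type=True)
        f = elastic_pair_force(g, c, pC.delta)
        assert f == pytest.approx([pC.F_a, 0.0])

    def test_beyond_influence_radius_is_zero(self, table2):
        pC = table2["C"]
        # 3 um separation with a 2 um influence radius
        g = pair_geometry([0, 0], pC.R, [2 * pC.R + 3 * UM, 0], pC.R)
        c = pair_coefficients(pC, pC, same_type=True)
        assert elastic_pair_force(g, c, pC.delta) == pytest.approx([0.0, 0.0])

    def test_oracle_equivalence_random_draws(self):
        """1000 random parameter draws match the independent closed form."""
        rng = np.random.default_rng(42)
        from celldem.params import ParticleTypeParams

        for _ in range(1000):
            pI = ParticleTypeParams(
                R=rng.uniform(0.1, 0.5) * UM,
                F_a=rng.uniform(0, 2e-10),
                delta=rng.uniform(0.1, 3.0) * UM,
                k_a=10 ** rng.uniform(-12, -8),
                E=10 ** rng.uniform(2, 7),
                nu=rng.uniform(0.1, 0.5),
                beta=rng.uniform(0.001, 0.1),
            )
            pJ = ParticleTypeParams(
                R=rng.uniform(0.1, 0.5) * UM,
                F_a=rng.uniform(0, 2e-10),
                delta=rng.uniform(0.1, 3.0) * UM,
                k_a=10 ** rng.uniform(-12, -8),
                E=10 ** rng.uniform(2, 7),
                nu=rng.uniform(0.1, 0.5),
                beta=rng.uniform(0.001, 0.1),
            )
            xI = rng.uniform(-2, 2, 2) * UM
            xJ = xI + rng.uniform(-2, 2, 2) * UM
            if np.allclose(xI, xJ):
                continue
            g = pair_geometry(xI, pI.R, xJ, pJ.R)
            c = pair_coefficients(pI, pJ)
            ours = elastic_pair_force(g, c, min(pI.delta, pJ.delta))
            ref = oracle_pair_force(xI, pI.R, pI, xJ, pJ.R, pJ)
            assert ours == pytest.approx(ref, rel=1e-12, abs=1e-25)

    def test_newton_third_law(self, table2):
        pM, pC = table2["M"], table2["C"]
        rng = np.random.default_rng(5)
        for _ in range(200):
            xI = rng.uniform(-1, 1, 2) * UM
            xJ = xI + rng.uniform(-1, 1, 2) * UM
            gIJ = pair_geometry(xI, pM.R, xJ, pC.R)
            gJI = pair_geometry(xJ, pC.R, xI, pM.R)
            c = pair_coefficients(pM, pC)
            delta = min(pM.delta, pC.delta)
            fIJ = elastic_pair_force(gIJ, c, delta)
            fJI = elastic_pair_force(gJI, c, delta)
            np.testing.assert_allclose(fIJ, -fJI, rtol=0, atol=1e-30)


class TestDragForce:
    def test_matching_velocities_no_drag(self):
        v = np.array([1e-7, -2e-7])
        assert drag_force(v, [v, v, v], 0.05) == pytest.approx([0.0, 0.0])

    def test_two_resting_neighbours(self):
        f = drag_force([1e-6, 0.0], [np.zeros(2), np.zeros(2)], 0.05)
        assert f == pytest.approx([-5e-8, 0.0])

    def test_no_neighbours(self):
        assert drag_force([1.0, 1.0], [], 0.05) == pytest.approx([0.0, 0.0])


class TestBoundaryForce:
    def _bm(self, **kw):
        kw.setdefault("k_a", 1e-11)
        kw.setdefault("delta", 3 * UM)
        return BoundaryObject(
            "BM", point=np.zeros(2), normal=np.array([0.0, 1.0]), **kw
        )

    def test_contact_overlap(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0.0, 0.1 * UM]], "M", 0)  # R=0.15um: overlap 0.05um
        f = boundary_force(state.particle(0), self._bm(), state)
        # overlapping: net force away from the line (repulsion beats adhesion)
        assert f[1] > 0.0

    def test_separated_adhesion_pulls_toward_line(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0.0, 1.0 * UM]], "M", 0)
        f = boundary_force(state.particle(0), self._bm(), state)
        assert f[1] < 0.0

    def test_beyond_influence_radius(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0.0, 5.0 * UM]], "M", 0)
        f = boundary_force(state.particle(0), self._bm(), state)
        assert f == pytest.approx([0.0, 0.0])

    def test_disabled_species_gets_no_force(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0.0, 0.1 * UM]], "C", 0)
        f = boundary_force(state.particle(0), self._bm(), state)
        assert f == pytest.approx([0.0, 0.0])


class TestNeighborSearch:
    def test_far_apart_lists_empty(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0, 0], [50 * UM, 0]], "C", 0)
        nl = neighbor_search(state)
        assert nl == {0: [], 1: []}

    def test_matches_brute_force(self, random_gas):
        state = random_gas
        nl = neighbor_search(state)
        deltas = np.array(
            [state.type_params[l].delta for l in ("M", "C", "NM", "N")]
        )
        for i in range(state.n):
            expected = []
            for j in range(state.n):
                if j == i:
                    continue
                alpha = (
                    state.r[i] + state.r[j]
                    - np.linalg.norm(state.x[i] - state.x[j])
                )
                if alpha >= -deltas[state.species[i]]:
                    expected.append(j)
            assert nl[i] == expected

    def test_cutoff_boundary_inclusive(self, table2):
        state = SimulationState(table2)
        pC = table2["C"]
        # separation alpha exactly -delta: still a neighbour
        state.add_particles(
            [[0, 0], [2 * pC.R + pC.delta, 0]], "C", 0
        )
        nl = neighbor_search(state)
        assert nl[0] == [1] and nl[1] == [0]


class TestNetForces:
    def test_isolated_pair_action_reaction(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0, 0], [0.45 * UM, 0]], "C", 0)
        F = net_forces(state)
        np.testing.assert_allclose(F[0], -F[1], atol=1e-28)

    def test_single_particle_external_only(self, table2):
        state = SimulationState(table2)
        state.add_particles([[0, 0]], "C", 0)
        ext = {0: np.array([1e-9, -2e-9])}
        F = net_forces(state, external=ext)
        assert F[0] == pytest.approx([1e-9, -2e-9])

    def test_equilibrium_separation_balances(self, table2):
        from scipy.optimize import brentq

        pC = table2["C"]
        c = pair_coefficients(pC, pC, same_type=True)

        def net(alpha):
            if alpha < 0:
                P = c.k_a_pair * (alpha / L0)
            else:
                req = pC.R / 2
                P = c.k_r_pair * math.sqrt(req / L0) * (alpha / L0) ** 1.5
            return c.F_a_pair - P

        # the equilibrium overlap is femtometre-scale (the contact stiffens
        # steeply), so the root must be located to sub-overlap precision
        alpha_star = brentq(net, 0.0, pC.R, xtol=1e-22, rtol=1e-15)
        assert net(alpha_star) == pytest.approx(0.0, abs=1e-13)
        state = SimulationState(table2)
        state.add_particles(
            [[0, 0], [2 * pC.R - alpha_star, 0]], "C", 0
        )
        F = net_forces(state)
        assert np.abs(F).max() < 1e-13

    def test_frame_invariance(self, random_gas):
        F0 = net_forces(random_gas)
        # rigid translation leaves internal forces unchanged
        shifted = random_gas.copy()
        shifted.x = shifted.x + np.array([3.3e-6, -1.1e-6])
        np.testing.assert_allclose(net_forces(shifted), F0, rtol=1e-9, atol=1e-24)
        # rigid rotation rotates them
        th = 0.7
        Rm = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        rotated = random_gas.copy()
        rotated.x = random_gas.x @ Rm.T
        np.testing.assert_allclose(net_forces(rotated), F0 @ Rm.T, rtol=1e-7, atol=1e-22)

    def test_engine_matches_scalar_law(self, table2):
        """The vectorised kernel reproduces the scalar pair law summed by hand."""
        state = SimulationState(table2, rng_seed=2)
        rng = np.random.default_rng(9)
        state.add_particles(rng.uniform(0, 3e-6, (12, 2)), "C", 0)
        state.v[:] = 0.0
        F, _ = compute_forces(state)
        labels = ("M", "C", "NM", "N")
        expected = np.zeros_like(F)
        for i in range(state.n):
            for j in range(state.n):
                if i == j:
                    continue
                pI = table2[labels[state.species[i]]]
                pJ = table2[labels[state.species[j]]]
                expected[i] += oracle_pair_force(
                    state.x[i], state.r[i], pI, state.x[j], state.r[j], pJ
                )
        np.testing.assert_allclose(F, expected, rtol=1e-10, atol=1e-24)
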