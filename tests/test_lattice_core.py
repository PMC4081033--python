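"""Exact-solver contract: closed-form cases, brute-force agreement,
statistical-positioning physics and model validation."""

import numpy as np
import pytest

from nuclattice import (
    BruteForceTooLarge,
    InteractionRule,
    LatticeModel,
    LatticeModelError,
    LinkerCapRule,
    SpeciesSpec,
    UnwrapSpec,
    brute_force_solve,
    enumerate_configurations,
    interior_density,
    solve,
)
from nuclattice.isotherm import IsothermError, mcghee_von_hippel_activity


def assert_solutions_close(a, b, tol=1e-9):
    assert a.species_ids == b.species_ids
    for g in a.species_ids:
        np.testing.assert_allclose(a.coverage[g], b.coverage[g], atol=tol)
        np.testing.assert_allclose(a.start_prob[g], b.start_prob[g], atol=tol)
    np.testing.assert_allclose(a.free_prob, b.free_prob, atol=tol)
    assert a.log_partition == pytest.approx(b.log_partition, abs=tol)


class TestTrivialEnsembles:
    def test_zero_activity_gives_empty_lattice(self):
        model = LatticeModel(N=10, species=[SpeciesSpec("A", 3, activity=0.0)])
        sol = solve(model)
        np.testing.assert_array_equal(sol.free_prob, 1.0)
        np.testing.assert_array_equal(sol.coverage["A"], 0.0)
        assert sol.log_partition == 0.0

    def test_two_state_partition_function(self):
        # N = m = 3, a = 1: configurations {empty, one particle}, Z = 2
        model = LatticeModel(N=3, species=[SpeciesSpec("A", 3, activity=1.0)])
        sol = solve(model)
        assert sol.start_prob["A"][0] == pytest.approx(0.5)
        np.testing.assert_allclose(sol.coverage["A"], 0.5)
        assert sol.log_partition == pytest.approx(np.log(2.0))


class TestBruteForceAgreement:
    def test_single_species_hard_rods(self):
        model = LatticeModel(N=12, species=[SpeciesSpec("A", 4, activity=0.5)])
        assert_solutions_close(solve(model), brute_force_solve(model))

    def test_two_species_mixed_activities(self):
        model = LatticeModel(
            N=10,
            species=[SpeciesSpec("A", 3, activity=1.2),
                     SpeciesSpec("B", 2, activity=0.3)],
        )
        assert_solutions_close(solve(model), brute_force_solve(model))

    def test_unwrapping_with_cooperativity_and_exclusion(self):
        # unwrapping species + contact cooperativity + hard exclusion
        model = LatticeModel(
            N=14,
            species=[
                SpeciesSpec("A", 4, activity=0.8, unwrap=UnwrapSpec(2, 0.7)),
                SpeciesSpec("B", 2, activity=1.5),
            ],
            interactions=[
                InteractionRule.contact("A", "A", 5.0),
                InteractionRule.exclusion("A", "B", 2),
            ],
        )
        assert_solutions_close(solve(model), brute_force_solve(model))

    def test_linker_cap_with_vicinity(self):
        model = LatticeModel(
            N=14,
            species=[SpeciesSpec("NCP", 5, activity=1.0, is_nucleosome=True),
                     SpeciesSpec("H1", 2, activity=2.0)],
            linker_cap=LinkerCapRule("H1", "NCP", cap=1, vicinity=2,
                                     allow_free_binding=False),
        )
        assert_solutions_close(solve(model), brute_force_solve(model))

    def test_cyclic_ring_with_interactions(self):
        model = LatticeModel(
            N=12,
            species=[SpeciesSpec("A", 4, activity=0.9, unwrap=UnwrapSpec(1))],
            interactions=[InteractionRule.contact("A", "A", 3.0)],
            boundary="cyclic",
        )
        assert_solutions_close(solve(model), brute_force_solve(model))


class TestOracleEquivalence:
    """Randomized solve == brute_force_solve sweep (the primary contract)."""

    def test_randomized_instances(self, rng):
        from conftest import random_small_model

        checked = 0
        trials = 0
        while checked < 60 and trials < 400:
            trials += 1
            model = random_small_model(rng)
            if model is None:
                continue
            try:
                ref = brute_force_solve(model, max_configs=150_000)
            except BruteForceTooLarge:
                continue
            assert_solutions_close(solve(model), ref)
            checked += 1
        assert checked == 60


class TestExclusionProhibition:
    def test_zero_weight_configurations_under_exclusion(self):
        # w(L < V) = 0 assigns exactly zero weight whenever a neighbor pair
        # sits at gap < V
        V = 2
        model = LatticeModel(
            N=9,
            species=[SpeciesSpec("A", 3, activity=1.0)],
            interactions=[InteractionRule.exclusion("A", "A", V)],
        )
        seen_prohibited = 0
        for config, weight in enumerate_configurations(model):
            placements = sorted(config, key=lambda p: p[1])
            gaps = [
                b[1] - (a[1] + 3)
                for a, b in zip(placements, placements[1:])
            ]
            if any(g < V for g in gaps):
                assert weight == 0.0
                seen_prohibited += 1
            elif placements:
                assert weight > 0.0
        assert seen_prohibited > 0


class TestNormalizationAndSymmetry:
    def test_free_plus_coverage_is_one(self):
        model = LatticeModel(
            N=60,
            species=[SpeciesSpec("A", 7, activity=2.0, unwrap=UnwrapSpec(2)),
                     SpeciesSpec("B", 3, activity=0.7)],
            interactions=[InteractionRule.contact("A", "B", 2.0)],
        )
        sol = solve(model)
        np.testing.assert_allclose(
            sol.free_prob + sol.total_coverage, 1.0, atol=1e-9
        )
        assert np.all(sol.free_prob >= -1e-12)
        for g in sol.species_ids:
            assert np.all((sol.coverage[g] >= -1e-12) & (sol.coverage[g] <= 1 + 1e-12))

    def test_palindromic_landscape_gives_mirror_symmetric_solution(self):
        # affinity symmetric under the frame mirror n -> N - m - n
        N, m = 40, 5
        base = np.zeros(N)
        valid = N - m + 1
        half = 1.0 + np.sin(np.linspace(0, 2 * np.pi, valid)) ** 2
        sym = (half + half[::-1]) / 2
        base[:valid] = sym
        model = LatticeModel(N=N, species=[SpeciesSpec("A", m, activity=1.3)],
                             affinity={"A": base})
        sol = solve(model)
        np.testing.assert_allclose(
            sol.coverage["A"], sol.coverage["A"][::-1], atol=1e-9
        )

    def test_homogeneous_coverage_monotone_in_activity(self):
        covs = []
        for a in (0.1, 0.5, 2.0, 10.0):
            model = LatticeModel(N=200, species=[SpeciesSpec("A", 10, activity=a)])
            covs.append(solve(model).coverage["A"].mean())
        assert np.all(np.diff(covs) > 0)


class TestStatisticalPositioning:
    def test_boundary_oscillation_period_approaches_footprint(self):
        # Tonks-gas near a hard wall: high activity packs rods at spacing ~ m
        m = 20
        model = LatticeModel(N=600, species=[SpeciesSpec("A", m, activity=1e4)])
        cov = solve(model).coverage["A"]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(cov[:400], prominence=0.01)
        spacings = np.diff(peaks)
        assert np.all((spacings >= m) & (spacings <= m + 2))

    def test_interior_matches_isotherm_for_long_lattice(self):
        for m, a in [(2, 0.5), (10, 1.0), (147, 0.7)]:
            model = LatticeModel(N=5000, species=[SpeciesSpec("A", m, activity=a)])
            sol = solve(model)
            interior = sol.coverage["A"][2000:3000].mean() / m
            assert interior == pytest.approx(interior_density(m, a), abs=1e-4)


class TestIsotherm:
    def test_langmuir_limit(self):
        assert interior_density(1, 1.0) == pytest.approx(0.5)

    def test_dimer_matches_quadratic_closed_form(self):
        # m = 2: a = nu (1 - 2 nu)^2 / (1 - nu) ... solved independently by
        # root-finding on the quartic in closed form via numpy roots
        m, a = 2, 0.5
        nu = interior_density(m, a)
        # residual of the isotherm itself must vanish
        lhs = nu / a
        rhs = (1 - m * nu) * ((1 - m * nu) / (1 - (m - 1) * nu)) ** (m - 1)
        assert lhs == pytest.approx(rhs, rel=1e-12)
        # and against polynomial root: nu(1-nu) = a(1-2nu)^2
        roots = np.roots([4 * a + 1, -4 * a - 1, a])
        good = [r for r in roots if 0 <= r <= 0.5]
        assert nu == pytest.approx(min(good), rel=1e-10)

    def test_round_trip_activity(self):
        for m in (2, 10, 147):
            for a in (0.01, 0.7, 50.0):
                nu = interior_density(m, a)
                assert mcghee_von_hippel_activity(nu, m) == pytest.approx(a, rel=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(IsothermError):
            interior_density(0, 1.0)
        with pytest.raises(IsothermError):
            interior_density(3, -1.0)


class TestValidation:
    def test_lattice_shorter_than_footprint_rejected(self):
        with pytest.raises(LatticeModelError):
            LatticeModel(N=5, species=[SpeciesSpec("A", 10, activity=1.0)])

    def test_negative_interaction_weight_rejected(self):
        with pytest.raises(LatticeModelError):
            InteractionRule(("A", "A"), {0: -1.0})

    def test_cyclic_range_geq_N_rejected(self):
        with pytest.raises(LatticeModelError):
            LatticeModel(
                N=8,
                species=[SpeciesSpec("A", 3, activity=1.0)],
                interactions=[InteractionRule.exclusion("A", "A", 9)],
                boundary="cyclic",
            )

    def test_affinity_track_length_mismatch_rejected(self):
        with pytest.raises(LatticeModelError):
            LatticeModel(
                N=10,
                species=[SpeciesSpec("A", 3, activity=1.0)],
                affinity={"A": np.ones(9)},
            )

    def test_activity_and_constants_mutually_exclusive(self):
        with pytest.raises(LatticeModelError):
            SpeciesSpec("A", 3, activity=1.0, binding_constant=1e6,
                        concentration=1e-6)

    def test_activity_from_constant_times_concentration(self):
        sp = SpeciesSpec("A", 147, binding_constant=3e6, concentration=1e-6)
        assert sp.a == pytest.approx(3.0)
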