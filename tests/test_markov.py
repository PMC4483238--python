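"""Transition matrix, spectra, Perron-Frobenius applicability, asymptotic flux."""

import numpy as np
import pytest

from tolnet import (
    GeneratorSpec,
    MultipleRecurrentClassesError,
    SinkError,
    build_transition_matrix,
    cesaro_limit,
    check_perron_frobenius,
    eigen_spectrum,
    expected_flux_cesaro,
    generate_network,
    make_fixture,
    recurrent_classes,
    stationary_flux,
)


class TestTransitionMatrix:
    def test_uniform_over_out_edges(self, looped_star):
        T = build_transition_matrix(looped_star)
        row = T.matrix[looped_star.id_of("A") - 1]
        np.testing.assert_allclose(np.sort(row)[::-1][:3], [1 / 3] * 3)
        assert row[looped_star.id_of("S") - 1] == 0.0

    def test_sink_self_loop_row_is_unit_vector(self, chain):
        ko = chain.knockout("B")  # A becomes a sink
        T = build_transition_matrix(ko, "self_loop")
        i = ko.id_of("A") - 1
        row = np.zeros(ko.n_vertices)
        row[i] = 1.0
        np.testing.assert_array_equal(T.matrix[i], row)

    def test_sink_reject_policy_raises(self, chain):
        with pytest.raises(SinkError, match="A"):
            build_transition_matrix(chain.knockout("B"), "reject")

    @pytest.mark.parametrize("fixture", ["star_source", "looped_star", "oral_tolerance"])
    def test_rows_sum_to_one(self, fixture):
        T = build_transition_matrix(make_fixture(fixture))
        np.testing.assert_allclose(T.matrix.sum(axis=1), 1.0, atol=1e-12)


class TestSpectrum:
    def test_cycle_has_three_unit_magnitudes(self, cycle):
        # the 3-cycle subchain contributes the cube roots of unity
        mags = eigen_spectrum(build_transition_matrix(cycle)).magnitudes
        np.testing.assert_allclose(mags[:3], 1.0, atol=1e-12)

    def test_plain_star_spectrum_is_1_minus1_0(self, star):
        mags = eigen_spectrum(build_transition_matrix(star)).magnitudes
        np.testing.assert_allclose(np.sort(mags), [0, 0, 1, 1], atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_leading_magnitude_is_always_one(self, seed):
        net = generate_network(GeneratorSpec(V=8, edge_probability=0.3, seed=seed))
        mags = eigen_spectrum(build_transition_matrix(net)).magnitudes
        assert mags[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(mags) <= 1e-12)


class TestPerronFrobenius:
    def test_cycle_not_applicable_periodic(self, cycle):
        v = check_perron_frobenius(build_transition_matrix(cycle))
        assert not v.applicable and not v.aperiodic and v.unique_recurrent_class

    def test_plain_star_not_applicable_period_two(self, star):
        v = check_perron_frobenius(build_transition_matrix(star))
        assert not v.applicable and not v.aperiodic

    def test_looped_star_applicable(self, looped_star):
        v = check_perron_frobenius(build_transition_matrix(looped_star))
        assert v.applicable and v.aperiodic and v.unique_recurrent_class

    def test_two_absorbing_states_not_applicable(self, chain):
        # knocking A out of S->A->B leaves S absorbing... build explicitly:
        # S -> A, S -> B, A -> A, B -> B has two recurrent classes
        from tolnet import DirectedNetwork, Vertex

        net = DirectedNetwork(
            vertices=[Vertex(1, "S", "antigen"), Vertex(2, "A", "cellular"),
                      Vertex(3, "B", "cellular")],
            edges={(1, 2), (1, 3), (2, 2), (3, 3)},
            source_id=1,
        )
        T = build_transition_matrix(net)
        assert len(recurrent_classes(T)) == 2
        assert not check_perron_frobenius(T).applicable


class TestStationaryFlux:
    def test_looped_star_balance_solution(self, looped_star):
        pi = stationary_flux(build_transition_matrix(looped_star))
        expected = {"S": 0.0, "A": 3 / 5, "B": 1 / 5, "C": 1 / 5}
        for lab, val in expected.items():
            assert pi[looped_star.id_of(lab) - 1] == pytest.approx(val, abs=1e-10)

    def test_star_periodic_chain_still_has_unique_pi(self, star):
        pi = stationary_flux(build_transition_matrix(star))
        expected = {"S": 0.0, "A": 1 / 2, "B": 1 / 4, "C": 1 / 4}
        for lab, val in expected.items():
            assert pi[star.id_of(lab) - 1] == pytest.approx(val, abs=1e-10)

    def test_absorbing_vertex_takes_all_mass(self, chain):
        pi = stationary_flux(build_transition_matrix(chain))
        np.testing.assert_allclose(pi, [0.0, 0.0, 1.0], atol=1e-12)

    def test_multiple_recurrent_classes_raise(self):
        from tolnet import DirectedNetwork, Vertex

        net = DirectedNetwork(
            vertices=[Vertex(1, "S", "antigen"), Vertex(2, "A", "cellular"),
                      Vertex(3, "B", "cellular")],
            edges={(1, 2), (1, 3), (2, 2), (3, 3)},
            source_id=1,
        )
        with pytest.raises(MultipleRecurrentClassesError):
            stationary_flux(build_transition_matrix(net))

    def test_pi_is_a_fixed_point(self, oral):
        T = build_transition_matrix(oral)
        pi = stationary_flux(T)
        assert np.max(np.abs(pi @ T.matrix - pi)) < 1e-10
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert pi[oral.source_id - 1] == 0.0  # source is transient


class TestCesaro:
    def test_t1_is_unit_mass_on_source(self, oral):
        T = build_transition_matrix(oral)
        f = expected_flux_cesaro(T, oral.source_id, 1)
        expected = np.zeros(oral.n_vertices)
        expected[oral.source_id - 1] = 1.0
        np.testing.assert_array_equal(f, expected)

    def test_matches_naive_partial_sum(self, looped_star):
        # independent oracle: literal sum of e_s T^k
        T = build_transition_matrix(looped_star)
        e = np.zeros(4)
        e[looped_star.source_id - 1] = 1.0
        for t in (1, 2, 3, 7, 20, 33):
            acc, row = np.zeros(4), e.copy()
            for _ in range(t):
                acc += row
                row = row @ T.matrix
            np.testing.assert_allclose(
                expected_flux_cesaro(T, looped_star.source_id, t), acc / t, atol=1e-12
            )

    def test_periodic_cycle_cesaro_averages_out(self, cycle):
        T = build_transition_matrix(cycle)
        f = expected_flux_cesaro(T, cycle.source_id, 3001)
        np.testing.assert_allclose(f, [0, 1 / 3, 1 / 3, 1 / 3], atol=1e-3)

    def test_converges_to_stationary(self, looped_star):
        T = build_transition_matrix(looped_star)
        pi = stationary_flux(T)
        f = expected_flux_cesaro(T, looped_star.source_id, 2000)
        np.testing.assert_allclose(f, pi, atol=1e-2)
        # O(1/t) decay: doubling t roughly halves the gap
        g1 = np.abs(expected_flux_cesaro(T, 1, 1000) - pi).max()
        g2 = np.abs(expected_flux_cesaro(T, 1, 2000) - pi).max()
        assert g2 < 0.75 * g1

    def test_rejects_nonpositive_t(self, looped_star):
        T = build_transition_matrix(looped_star)
        with pytest.raises(ValueError):
            expected_flux_cesaro(T, 1, 0)


class TestCesaroLimit:
    def test_equals_stationary_for_single_class(self, looped_star):
        T = build_transition_matrix(looped_star)
        np.testing.assert_allclose(
            cesaro_limit(T, looped_star.source_id), stationary_flux(T), atol=1e-12
        )

    def test_splits_mass_by_absorption_probability(self):
        # S -> A (p=1/2) and S -> B (p=1/2); A, B absorbing
        from tolnet import DirectedNetwork, Vertex

        net = DirectedNetwork(
            vertices=[Vertex(1, "S", "antigen"), Vertex(2, "A", "cellular"),
                      Vertex(3, "B", "cellular")],
            edges={(1, 2), (1, 3), (2, 2), (3, 3)},
            source_id=1,
        )
        lim = cesaro_limit(build_transition_matrix(net), 1)
        np.testing.assert_allclose(lim, [0, 0.5, 0.5], atol=1e-12)

    def test_agrees_with_long_finite_cesaro_on_ko_graph(self, oral):
        # knockouts of the study network can create multi-class chains;
        # the exact limit must match the finite-t average
        ko = oral.knockout("CD103+")
        T = build_transition_matrix(ko)
        lim = cesaro_limit(T, ko.source_id)
        fin = expected_flux_cesaro(T, ko.source_id, 200_000)
        np.testing.assert_allclose(lim, fin, atol=1e-4)


@pytest.mark.parametrize("k", [10_000])
def test_matrix_power_oracle_agreement(k):
    """On aperiodic ergodic chains the rows of T^k all converge to pi."""
    found = 0
    seed = 0
    while found < 10:
        net = generate_network(
            GeneratorSpec(V=8, edge_probability=0.35, seed=seed, require_aperiodic=True)
        )
        seed += 1
        T = build_transition_matrix(net)
        if not check_perron_frobenius(T).applicable:
            continue
        found += 1
        pi = stationary_flux(T)
        Tk = np.linalg.matrix_power(T.matrix, k)
        assert np.max(np.abs(Tk - pi[None, :])) < 1e-8
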