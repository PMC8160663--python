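"""Diagonal-design construction, designation grammar, and diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from omskit import design
from omskit.design import (
    DesignSpec,
    DesignWarning,
    FactorMapping,
    build_scheme,
    direction_vectors,
    format_designation,
    optimize_diagonal_sequence,
    parse_designation,
    scheme_from_spec,
    select_test_set,
    to_concentrations,
    validate_scheme,
)


class TestDesignation:
    @pytest.mark.parametrize(
        "text, k, ds, vs, n",
        [
            ("d20v125", 2, 0, 1, 25),
            ("d30v127", 3, 0, 1, 27),
            ("d20v027", 2, 0, 0, 27),
        ],
    )
    def test_printed_examples(self, text, k, ds, vs, n):
        spec = parse_designation(text)
        assert (spec.k, spec.first_train_id, spec.first_test_id) == (k, ds, vs)
        assert spec.n_samples == n
        assert format_designation(spec) == text

    @pytest.mark.parametrize("bad", ["x20v125", "d2v125", "d0 v1", "d00v125"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_designation(bad)

    @given(
        k=st.integers(1, 9),
        ds=st.sampled_from([0, 1]),
        n_pos=st.integers(0, 400),
    )
    def test_round_trip(self, k, ds, n_pos):
        vs = 1 - ds  # exactly one subset starts at the center sample
        spec = DesignSpec(
            k=k,
            n_positions=n_pos,
            include_center=True,
            first_train_id=ds,
            first_test_id=vs,
        )
        assert parse_designation(format_designation(spec)) == spec


class TestBuildScheme:
    def test_three_factor_spiral_coordinates(self):
        """Positions 1 and 2 of the k=3 spiral produce the documented pairs."""
        scheme = build_scheme(DesignSpec(k=3, n_positions=2))
        rows = {tuple(r) for r in scheme.coords}
        assert rows == {
            (0, 0, 0),
            (1, 1, 1),
            (-1, -1, -1),
            (-2, 2, -2),
            (2, -2, 2),
        }

    def test_degenerate_center_only(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=0))
        assert scheme.n_samples == 1
        assert tuple(scheme.coords[0]) == (0, 0)
        assert scheme.ids[0] == 0

    def test_level_occupancy_d20v125(self):
        """Brute-force check: every level -12..12 occupied exactly once."""
        scheme = build_scheme(parse_designation("d20v125"))
        assert scheme.n_samples == 25
        for col in scheme.coords.T:
            assert sorted(col.tolist()) == list(range(-12, 13))

    def test_two_factor_cross_rule(self):
        """Odd positions fill the main diagonal, even ones the anti-diagonal."""
        scheme = build_scheme(DesignSpec(k=2, n_positions=4))
        by_pos = {
            p: {tuple(c) for c in scheme.coords[scheme.position == p]}
            for p in range(1, 5)
        }
        assert by_pos[1] == {(1, 1), (-1, -1)}
        assert by_pos[2] == {(2, -2), (-2, 2)}
        assert by_pos[3] == {(3, 3), (-3, -3)}
        assert by_pos[4] == {(4, -4), (-4, 4)}

    def test_errors(self):
        with pytest.raises(ValueError):
            DesignSpec(k=0, n_positions=1)
        with pytest.raises(ValueError):
            DesignSpec(k=2, n_positions=-1)
        with pytest.raises(ValueError, match="length"):
            build_scheme(DesignSpec(k=2, n_positions=3), diagonal_sequence=[0])
        with pytest.raises(ValueError, match="out of range"):
            build_scheme(DesignSpec(k=2, n_positions=2), diagonal_sequence=[0, 5])

    def test_custom_sequence_respected(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=2), diagonal_sequence=[1, 1])
        assert {tuple(c) for c in scheme.coords[scheme.position == 1]} == {
            (1, -1),
            (-1, 1),
        }

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_direction_vector_count(self, k):
        assert direction_vectors(k).shape == (2 ** (k - 1), k)


class TestTestSet:
    @pytest.mark.parametrize("n_pos", [13, 12])
    def test_every_third_position_with_edge_rule(self, n_pos):
        scheme = build_scheme(DesignSpec(k=2, n_positions=n_pos))
        marked = select_test_set(scheme)
        test_pos = sorted(set(marked.position[marked.roles == "test"]))
        assert test_pos == [1, 4, 7, 10]

    def test_single_position_edge_rule_consumes_candidate(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=1))
        marked = select_test_set(scheme)
        assert not np.any(marked.roles == "test")

    def test_four_pairs_for_13_positions(self):
        scheme = select_test_set(build_scheme(DesignSpec(k=3, n_positions=13)))
        assert np.sum(scheme.roles == "test") == 8  # four centrally symmetric pairs

    def test_errors(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=3))
        with pytest.raises(ValueError):
            select_test_set(scheme, step=0)
        with pytest.raises(ValueError):
            select_test_set(build_scheme(DesignSpec(k=2, n_positions=0)))

    def test_adjacent_test_levels_warn(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=5))
        with pytest.warns(DesignWarning):
            select_test_set(scheme, start_position=1, step=1)

    def test_vs0_marks_center_as_test(self):
        scheme = scheme_from_spec(parse_designation("d20v027"))
        roles_center = scheme.roles[scheme.position == 0]
        assert list(roles_center) == ["test"]
        test_pos = sorted(set(scheme.position[scheme.roles == "test"]) - {0})
        assert test_pos == [3, 6, 9, 12]


class TestConcentrations:
    def test_midpoint_and_boundary(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=12))
        conc = to_concentrations(scheme, FactorMapping(((1.0, 13.0), (1.0, 13.0))))
        center = conc[scheme.position == 0][0]
        assert center == pytest.approx([7.0, 7.0])
        at_max = conc[scheme.coords[:, 0] == 12, 0]
        assert at_max == pytest.approx(13.0)

    def test_column_means_are_midpoints(self):
        scheme = build_scheme(parse_designation("d20v125"))
        conc = to_concentrations(scheme, FactorMapping(((1.0, 13.0), (1.0, 13.0))))
        assert conc.mean(axis=0) == pytest.approx([7.0, 7.0])

    def test_decreasing_direction(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=2))
        mapping = FactorMapping(
            ((0.0, 4.0), (0.0, 4.0)), directions=("decreasing", "increasing")
        )
        conc = to_concentrations(scheme, mapping)
        row = conc[(scheme.coords == [1, 1]).all(axis=1)][0]
        assert row == pytest.approx([1.0, 3.0])

    def test_center_only_maps_to_midpoint(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=0))
        conc = to_concentrations(scheme, FactorMapping(((1.0, 3.0), (0.0, 10.0))))
        assert conc[0] == pytest.approx([2.0, 5.0])

    def test_mismatched_k(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=1))
        with pytest.raises(ValueError):
            to_concentrations(scheme, FactorMapping(((0.0, 1.0),)))

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            FactorMapping(((1.0, 1.0),))


class TestDiagnostics:
    def test_d20v125_correlation(self):
        """Hand-derived: r = -78/650 for the alternating two-factor scheme."""
        scheme = build_scheme(parse_designation("d20v125"))
        diag = validate_scheme(scheme)
        assert diag.latin_hypercube
        assert diag.pairwise_correlations[0, 1] == pytest.approx(-78 / 650)
        assert np.allclose(diag.pairwise_correlations, diag.pairwise_correlations.T)
        assert np.allclose(np.diag(diag.pairwise_correlations), 1.0)

    def test_d20v125_coverage(self):
        """Shoelace-derived hull area 528 over the 24x24 square."""
        scheme = build_scheme(parse_designation("d20v125"))
        assert validate_scheme(scheme).coverage == pytest.approx(528 / 576)

    def test_duplicated_level_detected(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=2))
        scheme.coords[1] = scheme.coords[3]  # violate occupancy
        assert not validate_scheme(scheme).latin_hypercube

    def test_balance_counts(self):
        scheme = build_scheme(DesignSpec(k=2, n_positions=4))
        assert validate_scheme(scheme).balance == {0: 4, 1: 4}


class TestSequenceOptimization:
    def test_k3_returns_default(self):
        spec = DesignSpec(k=3, n_positions=5)
        assert optimize_diagonal_sequence(spec) == [0, 1, 2, 3, 0]

    def test_k4_beats_or_ties_default(self):
        spec = DesignSpec(k=4, n_positions=4)
        seq = optimize_diagonal_sequence(spec)

        def max_abs_corr(sequence):
            scheme = build_scheme(spec, diagonal_sequence=sequence)
            corr = validate_scheme(scheme).pairwise_correlations
            return np.max(np.abs(corr - np.eye(4)))

        default = [(p - 1) % 8 for p in range(1, 5)]
        assert max_abs_corr(seq) <= max_abs_corr(default) + 1e-12

    def test_too_large_guard(self):
        with pytest.raises(ValueError, match="too large"):
            optimize_diagonal_sequence(
                DesignSpec(k=4, n_positions=20), max_positions=10
            )


class TestInvariants:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_central_symmetry_and_latin_hypercube(self, k):
        for L in range(0, 31, 5):
            scheme = build_scheme(DesignSpec(k=k, n_positions=L))
            assert np.all(scheme.coords.sum(axis=0) == 0)
            assert validate_scheme(scheme).latin_hypercube

    def test_test_removal_keeps_balance(self):
        """Excluding the built-in test set must not unbalance the design."""
        scheme = select_test_set(build_scheme(DesignSpec(k=3, n_positions=13)))
        train = scheme.coords[scheme.roles == "train"]
        assert np.all(train.sum(axis=0) == 0)
        train_diags = set(scheme.diagonal[(scheme.roles == "train") & (scheme.position > 0)])
        assert train_diags == set(range(4))
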