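"""Preprocessing operators: units, invariances, guards, and the search."""

import numpy as np
import pytest

from omskit import calibrate, channels, design, preprocess, simulate
from omskit.preprocess import (
    PreprocSpec,
    PreprocStep,
    augment_blocks,
    combinatorial_search,
    derivative,
    internal_normalization,
    moving_average_time,
    reference_absorbance,
    snv,
)

from conftest import make_set


class TestReferenceAbsorbance:
    def test_identity_reference_gives_zero(self):
        s = make_set(np.full((3, 5), 2.0))
        out = reference_absorbance(s, np.full(5, 2.0))
        assert np.allclose(out.X, 0.0)

    def test_tenth_of_reference_gives_unit_absorbance(self):
        s = make_set(np.full((2, 4), 0.1))
        out = reference_absorbance(s, np.ones(4))
        assert np.allclose(out.X, 1.0)

    def test_zero_intensity_names_channel(self):
        X = np.ones((2, 4))
        X[1, 2] = 0.0
        with pytest.raises(ValueError, match="channel 2"):
            reference_absorbance(make_set(X), np.ones(4))


class TestInternalNormalization:
    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.5, 2.0, size=(4, 6))
        s = make_set(X)
        out1 = internal_normalization(s, comparison_channel=3.0)
        gains = rng.uniform(0.1, 10.0, size=4)
        out2 = internal_normalization(make_set(X * gains[:, None]), 3.0)
        assert np.allclose(out1.X, out2.X)

    def test_comparison_channel_maps_to_zero(self):
        s = make_set(np.random.default_rng(1).uniform(1, 2, (3, 5)))
        out = internal_normalization(s, 2.0)
        assert np.allclose(out.X[:, 2], 0.0)

    def test_zero_comparison_reports_measurement(self):
        X = np.ones((3, 4))
        X[1, 2] = 0.0
        with pytest.raises(ValueError, match="measurement 1"):
            internal_normalization(make_set(X), 2.0)


class TestMovingAverageTime:
    def test_constant_series_unchanged(self):
        s = make_set(np.ones((20, 3)))
        assert np.allclose(moving_average_time(s, 5).X, 1.0)

    def test_window_one_is_identity(self):
        X = np.random.default_rng(2).normal(size=(15, 4))
        s = make_set(X)
        assert np.array_equal(moving_average_time(s, 1).X, X)

    def test_even_window_and_unsorted_time_rejected(self):
        s = make_set(np.ones((6, 2)))
        with pytest.raises(ValueError, match="odd"):
            moving_average_time(s, 4)
        bad = make_set(np.ones((6, 2)), time=np.array([0.0, 2, 1, 3, 4, 5]))
        with pytest.raises(ValueError, match="sorted"):
            moving_average_time(bad, 3)

    def test_interior_variance_reduction(self):
        """White noise variance drops by ~1/W at interior points."""
        rng = np.random.default_rng(3)
        W = 15
        s = make_set(rng.normal(size=(4000, 2)))
        out = moving_average_time(s, W)
        interior = out.X[W : -W, 0]
        assert interior.var() == pytest.approx(1.0 / W, rel=0.1)

    def test_row_permutation_does_not_commute(self):
        """Time smoothing is time-coupled, unlike the row-wise operators."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        s = make_set(X)
        sm_then_perm = moving_average_time(s, 3).X[perm]
        perm_then_sm = moving_average_time(make_set(X[perm]), 3).X
        assert not np.allclose(sm_then_perm, perm_then_sm)
        # snv commutes with row permutation
        assert np.allclose(snv(s).X[perm], snv(make_set(X[perm])).X)


class TestSnvAndDerivative:
    def test_snv_affine_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3, 20))
        a, b = 3.7, -1.2
        assert np.allclose(snv(make_set(X)).X, snv(make_set(a * X + b)).X)
        out = snv(make_set(X))
        assert np.allclose(out.X.mean(axis=1), 0.0)
        assert np.allclose(out.X.std(axis=1, ddof=1), 1.0)

    def test_snv_rejects_constant_spectrum(self):
        with pytest.raises(ValueError, match="constant"):
            snv(make_set(np.ones((2, 5))))

    def test_first_derivative_of_linear_spectrum_is_constant(self):
        axis = np.arange(30.0)
        s = make_set(np.tile(2.0 * axis, (3, 1)), axis=axis)
        out = derivative(s, order=1, window=7, degree=2)
        assert np.allclose(out.X, 2.0)

    def test_too_few_channels_guard_cites_count(self):
        s = make_set(np.ones((2, 7)))
        with pytest.raises(ValueError, match="7"):
            derivative(s, order=1, window=15, degree=2)


class TestAugmentBlocks:
    def test_single_block_identity(self):
        X = np.random.default_rng(6).normal(size=(4, 5))
        s = make_set(X)
        out = augment_blocks([s])
        assert np.array_equal(out.X, X)

    def test_widths_add(self):
        a = make_set(np.ones((3, 4)))
        b = make_set(np.ones((3, 6)), axis=np.arange(10.0, 16.0))
        out = augment_blocks([a, b])
        assert out.X.shape == (3, 10)
        assert list(np.unique(out.col_blocks)) == [0, 1]

    def test_unit_total_variance_scaling(self):
        rng = np.random.default_rng(7)
        a = make_set(rng.normal(size=(10, 4)))
        b = make_set(5 * rng.normal(size=(10, 6)), axis=np.arange(10.0, 16.0))
        out = augment_blocks([a, b], scaling="unit_total_variance")
        for blk in (0, 1):
            cols = out.X[:, out.col_blocks == blk]
            assert cols.var(axis=0, ddof=1).sum() == pytest.approx(1.0)

    def test_id_mismatch_rejected(self):
        a = make_set(np.ones((3, 2)))
        b = make_set(np.ones((3, 2)), ids=np.array([5, 6, 7]))
        with pytest.raises(ValueError, match="ids"):
            augment_blocks([a, b])


class TestCombinatorialSearch:
    @staticmethod
    def _validator(sset, target):
        R = channels.apply_channels(
            sset,
            [channels.Channel(550.0, 60.0), channels.Channel(900.0, 60.0)],
        )
        return calibrate.cross_val_rmse(R, sset.target(target), model_type="mlr")

    def test_single_candidate_ranks_first(self, mixture_set):
        table = combinatorial_search(
            [PreprocSpec()], mixture_set, "y_1", self._validator
        )
        assert len(table) == 1 and table.index[0] == 1

    def test_derivative_beats_identity_on_planted_baseline(self, two_components):
        """A sloping baseline uncorrelated with the target favors derivatives."""

        def full_spectrum_validator(sset, target):
            return calibrate.cross_val_rmse(
                sset.X, sset.target(target), model_type="pls", n_lv=2
            )

        wins = 0
        seeds = range(8)
        scheme = design.scheme_from_spec(design.parse_designation("d20v125"))
        conc = design.to_concentrations(
            scheme, design.FactorMapping(((1.0, 13.0), (1.0, 13.0)))
        )
        axis = np.arange(400.0, 1101.0, 5.0)
        candidates = [
            PreprocSpec(),
            PreprocSpec((PreprocStep("derivative", {"order": 1, "window": 9, "degree": 2}),)),
        ]
        for seed in seeds:
            rng = np.random.default_rng(seed)
            sset = simulate.mixture_spectra(
                conc, two_components,
                noise=simulate.NoiseHierarchy(replicate=0.001),
                seed=seed, axis=axis,
            )
            # additive linear baseline with random per-measurement slope
            slopes = rng.normal(0.0, 0.3, size=sset.n_measurements)
            lam = (axis - axis[0]) / (axis[-1] - axis[0])
            sset = sset.with_X(sset.X + slopes[:, None] * lam[None, :])
            table = combinatorial_search(
                candidates, sset, "y_1", full_spectrum_validator
            )
            if "derivative" in table.loc[1, "pipeline"]:
                wins += 1
        assert wins > len(seeds) / 2

    def test_deterministic_ranking(self, mixture_set):
        cands = [
            PreprocSpec(),
            PreprocSpec((PreprocStep("snv"),)),
        ]
        t1 = combinatorial_search(cands, mixture_set, "y_1", self._validator)
        t2 = combinatorial_search(cands, mixture_set, "y_1", self._validator)
        assert t1.equals(t2)

    def test_empty_candidates_rejected(self, mixture_set):
        with pytest.raises(ValueError):
            combinatorial_search([], mixture_set, "y_1", self._validator)
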