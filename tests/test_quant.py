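"""Reporter-ion processing: correction, normalization, rollup, permutation DE."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_matrix
from synaptomics import (
    ConfigurationError,
    Design,
    SpectrumTable,
    bh_adjust,
    impurity_correct,
    intensity_weights,
    iterative_normalize,
    permutation_de,
    preprocess_spectra,
    rollup_proteins,
    weighted_median,
)
from synaptomics.quant import PurityMatrix


def toy_spectra(values, proteins=None, channels=None, log2=False):
    values = np.asarray(values, dtype=float)
    channels = channels or [f"ch{j}" for j in range(values.shape[1])]
    ids = [f"s{i}" for i in range(values.shape[0])]
    proteins = proteins or [("A",)] * values.shape[0]
    return SpectrumTable(
        pd.DataFrame(values, index=ids, columns=channels),
        pd.Series(proteins, index=ids),
        {c: f"x{j}" for j, c in enumerate(channels)},
        log2=log2,
    )


class TestImpurityCorrect:
    def test_identity_unchanged(self):
        sp = toy_spectra([[10, 20], [30, 40]])
        out, clamped = impurity_correct(sp, PurityMatrix.identity(sp.channels))
        pd.testing.assert_frame_equal(out.intensities, sp.intensities)
        assert clamped.sum() == 0

    def test_two_by_two_inversion_by_hand(self):
        # 10% of channel 1 leaks into channel 2; observed (90, 10) -> (100, 0)
        sp = toy_spectra([[90.0, 10.0]])
        purity = PurityMatrix(["ch0", "ch1"], np.array([[0.9, 0.0], [0.1, 1.0]]))
        out, _ = impurity_correct(sp, purity)
        assert np.allclose(out.intensities.to_numpy(), [[100.0, 0.0]], atol=1e-10)

    def test_random_full_rank_round_trip(self, rng):
        from synaptomics import mix_impurities

        true = toy_spectra(rng.uniform(10, 1000, (40, 6)))
        m = np.eye(6) * 0.85
        m += rng.uniform(0, 0.02, (6, 6))
        purity = PurityMatrix(list(true.channels), m / m.sum(axis=0).max())
        mixed = mix_impurities(true, purity)
        back, _ = impurity_correct(mixed, purity)
        assert np.allclose(back.intensities.to_numpy(),
                           true.intensities.to_numpy(), atol=1e-8)

    def test_singular_matrix_rejected(self):
        sp = toy_spectra([[1.0, 1.0]])
        singular = PurityMatrix(["ch0", "ch1"], np.array([[0.5, 0.5], [0.5, 0.5]]))
        with pytest.raises(ConfigurationError):
            impurity_correct(sp, singular)

    def test_channel_mismatch_rejected(self):
        sp = toy_spectra([[1.0, 1.0]])
        with pytest.raises(ConfigurationError):
            impurity_correct(sp, PurityMatrix.identity(["other0", "other1"]))

    def test_negative_solutions_clamped_and_flagged(self):
        sp = toy_spectra([[0.0, 100.0]])
        purity = PurityMatrix(["ch0", "ch1"], np.array([[0.9, 0.0], [0.1, 1.0]]))
        out, clamped = impurity_correct(sp, purity)
        assert (out.intensities.to_numpy() >= 0).all()
        assert clamped.iloc[0] == 0  # exact solution is non-negative here
        sp2 = toy_spectra([[100.0, 0.0]])  # observed 0 in leak target -> negative x2
        out2, clamped2 = impurity_correct(sp2, purity)
        assert (out2.intensities.to_numpy() >= 0).all()
        assert clamped2.iloc[0] == 1


class TestIterativeNormalize:
    def test_balanced_matrix_fixed_point(self, rng):
        raw = rng.normal(10, 1, (50, 8))
        balanced, _ = iterative_normalize(toy_spectra(raw, log2=True))
        vals = balanced.intensities.to_numpy()
        # medians are flat after convergence ...
        assert np.ptp(np.median(vals, axis=0)) < 1e-6
        assert np.ptp(np.median(vals, axis=1)) < 1e-6
        # ... and a balanced matrix passes through unchanged
        out, _ = iterative_normalize(balanced)
        assert np.allclose(out.intensities.to_numpy(), vals, atol=1e-6)

    def test_constructed_offsets_removed(self, rng):
        raw = rng.normal(12, 0.5, (80, 6))
        base = iterative_normalize(toy_spectra(raw, log2=True))[0].intensities.to_numpy()
        offsets = np.array([1.0, -1.0, 0.5, 0.0, -0.5, 0.25])
        shifted = base + offsets[None, :]
        out, _ = iterative_normalize(toy_spectra(shifted, log2=True))
        # recovered matrix equals the balanced original up to a global constant
        diff = out.intensities.to_numpy() - base
        assert np.std(diff) < 1e-6

    def test_idempotent(self, rng):
        sp = toy_spectra(rng.uniform(100, 10000, (60, 5)))
        once, _ = iterative_normalize(sp)
        twice, n2 = iterative_normalize(once)
        assert np.allclose(once.intensities.to_numpy(),
                           twice.intensities.to_numpy(), rtol=1e-6)

    def test_all_missing_sample_named(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ConfigurationError, match="ch1"):
            iterative_normalize(toy_spectra(vals, log2=True))


class TestPreprocess:
    def test_prune_counts_and_log(self):
        proteins = [("A",)] * 7 + [("A", "B")] * 3
        sp = toy_spectra(np.full((10, 4), 8.0), proteins=proteins)
        out, counts = preprocess_spectra(sp)
        assert counts == {"n_input": 10, "n_pruned_shared": 3,
                          "n_retained": 7, "n_nonpositive_cells": 0}
        assert np.allclose(out.intensities.to_numpy(), 3.0)  # log2(8) = 3

    def test_nonpositive_become_missing(self):
        sp = toy_spectra([[4.0, 0.0, 2.0]])
        out, counts = preprocess_spectra(sp)
        assert counts["n_nonpositive_cells"] == 1
        assert np.isnan(out.intensities.iloc[0, 1])

    @given(st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_weights_monotone_in_total_intensity(self, totals):
        w = intensity_weights(np.array(totals))
        assert np.all(w > 0) and np.all(w < 1) and np.all(np.isfinite(w))
        order = np.argsort(totals)
        assert np.all(np.diff(w[order]) >= -1e-12)


class TestWeightedMedianRollup:
    @pytest.mark.parametrize(
        "values,weights,expected",
        [
            ([10, 11, 12], [1, 1, 1], 11),
            ([10, 12], [3, 1], 10),  # lower-weight convention
            ([10, 12], [1, 3], 12),
            ([5], [7], 5),
            ([1, 2, 3, 4], [1, 1, 1, 1], 2),  # even count: lower median
        ],
    )
    def test_weighted_median_convention(self, values, weights, expected):
        assert weighted_median(np.array(values, float), np.array(weights, float)) == expected

    def test_rollup_equals_median_per_sample(self):
        vals = np.log2([[1024, 2048], [2048, 4096], [4096, 8192]])
        sp = toy_spectra(vals, proteins=[("A",)] * 3, log2=True)
        sp.weights = pd.Series(1.0, index=sp.intensities.index)
        matrix, counts = rollup_proteins(sp)
        assert matrix.data.loc["A"].tolist() == [11.0, 12.0]
        assert counts["A"] == 3

    def test_missing_cells_stay_missing(self):
        vals = np.array([[3.0, np.nan]])
        sp = toy_spectra(vals, log2=True)
        sp.weights = pd.Series(1.0, index=sp.intensities.index)
        matrix, _ = rollup_proteins(sp)
        assert matrix.data.iloc[0, 0] == 3.0
        assert np.isnan(matrix.data.iloc[0, 1])

    def test_empty_table_empty_matrix(self):
        sp = toy_spectra(np.empty((0, 3)), proteins=[], log2=True)
        matrix, counts = rollup_proteins(sp)
        assert matrix.shape[0] == 0


def bh_oracle(pvals):
    """Brute-force BH step-up: q_i = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        j = m - rank_from_end
        prev = min(prev, pvals[idx] * m / j)
        q[idx] = prev
    return q


class TestBH:
    def test_worked_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=200)
    def test_matches_stepup_oracle(self, pvals):
        p = np.array(pvals)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPermutationDE:
    def test_constant_data_p_one(self, balanced_design):
        m = make_matrix(np.full((5, 16), 7.0), balanced_design)
        res = permutation_de(m, balanced_design, "TW", "TF", seed=0)
        assert (res["p"] == 1.0).all()

    def test_exhaustive_p_granularity_4v4(self, balanced_design, rng):
        m = make_matrix(rng.normal(0, 1, (50, 16)), balanced_design)
        res = permutation_de(m, balanced_design, "TW", "TF", seed=0)
        # 8-choose-4 = 70 splits; p is a multiple of 1/70, minimum 2/70
        mult = res["p"] * 70
        assert np.allclose(mult, np.round(mult), atol=1e-9)
        assert res["p"].min() >= 2 / 70 - 1e-12

    def test_exhaustive_matches_manual_enumeration(self, balanced_design):
        vals = np.zeros((1, 16))
        tw = [s.startswith("TW") for s in balanced_design.samples]
        tf = [s.startswith("TF") for s in balanced_design.samples]
        data = np.array([1.0, 3.0, 2.0, 5.0])
        vals[0, np.array(tw)] = data
        vals[0, np.array(tf)] = np.array([4.0, 6.0, 8.0, 7.0])
        m = make_matrix(vals, balanced_design)
        res = permutation_de(m, balanced_design, "TW", "TF", seed=0)
        pooled = np.concatenate([data, [4.0, 6.0, 8.0, 7.0]])
        obs = pooled[4:].mean() - pooled[:4].mean()
        count = sum(
            abs(pooled[list(set(range(8)) - set(c))].mean() - pooled[list(c)].mean())
            >= abs(obs) - 1e-12
            for c in combinations(range(8), 4)
        )
        assert res["p"].iloc[0] == pytest.approx(count / 70)

    def test_null_type_i_error_calibrated(self, balanced_design, rng):
        m = make_matrix(rng.normal(0, 1, (2000, 16)), balanced_design)
        res = permutation_de(m, balanced_design, "TW", "TF", seed=1)
        rate = (res["p"] < 0.05).mean()
        # statistic values come in complement pairs, so p takes even multiples
        # of 1/70; the achievable level below 0.05 is P(p = 2/70) = 2/70
        level = 2 / 70
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, level) / 2000
        assert lo <= rate <= hi

    def test_small_group_rejected(self):
        design = Design.balanced(2)
        m = make_matrix(np.zeros((2, 8)), design)
        res = permutation_de(m, design, "TW", "TF", seed=0)  # n=2 allowed
        design_bad = Design.balanced(4)
        with pytest.raises(ConfigurationError):
            permutation_de(make_matrix(np.zeros((2, 16)), design_bad),
                           design_bad, "TW", "XX", seed=0)
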