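"""Mutual information, MIQ scoring and mRMR forward selection."""

from collections import Counter
from math import log2

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsisort import (
    SpectrumTable,
    discretize,
    forward_select,
    miq,
    mutual_information,
    redundancy,
    relevance,
)
from hsisort.mrmr import MIQ_EPS


def brute_force_mi(a, b):
    """Independent plug-in MI: explicit sum over the empirical joint table."""
    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    total = 0.0
    for (va, vb), c in joint.items():
        pxy = c / n
        total += pxy * log2(pxy / ((pa[va] / n) * (pb[vb] / n)))
    return total


class TestMutualInformation:
    def test_identical_balanced_binary_codes_carry_one_bit(self):
        a = np.array([0, 1] * 10)
        assert mutual_information(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_is_independent_of_anything(self):
        a = np.array([0, 1, 0, 1, 1, 0])
        b = np.zeros(6, dtype=int)
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_joint_table_matches_the_brute_force_sum(self):
        # joint counts {(0,0):4, (0,1):1, (1,0):1, (1,1):4}
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([0, 0, 0, 0, 1, 0, 1, 1, 1, 1])
        expected = brute_force_mi(a.tolist(), b.tolist())
        assert expected == pytest.approx(0.2780719051126377, abs=1e-12)
        assert mutual_information(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_is_a_shape_error(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nonnegative_symmetric_and_matches_oracle(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        i_ab = mutual_information(a, b)
        assert i_ab >= -1e-15
        assert i_ab == pytest.approx(mutual_information(b, a), abs=1e-12)
        assert i_ab == pytest.approx(brute_force_mi(a.tolist(), b.tolist()),
                                     abs=1e-12)
        assert mutual_information(a, a) >= i_ab - 1e-12

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_relabelling_of_codes(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        relabel = np.array([2, 0, 3, 1])
        assert mutual_information(relabel[a], b) == pytest.approx(
            mutual_information(a, b), abs=1e-12
        )


class TestRelevanceRedundancy:
    def test_band_equal_to_labels_attains_the_label_entropy(self, rng):
        y = rng.integers(0, 2, 100)
        v = relevance(y, y)
        p = y.mean()
        entropy = -p * log2(p) - (1 - p) * log2(1 - p)
        assert v == pytest.approx(entropy, abs=1e-12)
        # no other band can be more relevant
        other = rng.integers(0, 4, 100)
        assert relevance(other, y) <= v + 1e-12

    def test_permuted_band_falls_below_the_permutation_null_tail(self, rng):
        y = np.repeat([0, 1], 100)
        band = rng.integers(0, 8, 200)  # independent of y by construction
        null = sorted(
            relevance(rng.permutation(band), y) for _ in range(99)
        )
        assert relevance(band, y) <= null[94] + 1e-9

    def test_duplicated_band_has_identical_relevance(self, rng):
        y = rng.integers(0, 2, 50)
        band = rng.integers(0, 4, 50)
        assert relevance(band, y) == relevance(band.copy(), y)

    def test_redundancy_is_the_mean_of_pairwise_mi(self, rng):
        lam = rng.integers(0, 4, 80)
        s1 = rng.integers(0, 4, 80)
        s2 = rng.integers(0, 4, 80)
        expected = 0.5 * (mutual_information(lam, s1) + mutual_information(lam, s2))
        assert redundancy(lam, [s1, s2]) == pytest.approx(expected, abs=1e-12)

    def test_redundancy_of_empty_selection_is_a_contract_error(self):
        with pytest.raises(ValueError):
            redundancy(np.array([0, 1]), [])

    def test_band_already_selected_dominates_redundancy(self, rng):
        lam = rng.integers(0, 4, 100)
        others = [rng.integers(0, 4, 100) for _ in range(5)]
        w_self = redundancy(lam, [lam])
        for z in others:
            assert redundancy(lam, [z]) <= w_self + 1e-12


class TestMiq:
    def test_zero_relevance_scores_zero(self):
        assert miq(0.0, 0.5) == 0.0

    def test_zero_redundancy_is_guarded_not_infinite(self):
        score = miq(0.7, 0.0)
        assert np.isfinite(score)
        assert score == pytest.approx(0.7 / MIQ_EPS)

    def test_plain_quotient(self):
        assert miq(0.6, 0.3) == pytest.approx(2.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            miq(-0.1, 0.2)


def toy_table(rng, n=120, n_bands=6, informative=None):
    """Random table with optional bands copied from the labels."""
    y = np.repeat([0, 1], n // 2)
    spectra = rng.uniform(0, 1, (n, n_bands))
    labels = ["broad_bean" if v else "wheat" for v in y]
    if informative is not None:
        for j in informative:
            spectra[:, j] = y + 0.01 * rng.standard_normal(n)
    wl = 400.0 + 5.0 * np.arange(n_bands)
    return SpectrumTable(spectra=spectra, wavelengths=wl, labels=labels)


def oracle_forward_select(table, n_bins, steps):
    """Brute-force greedy mRMR: exhaustive candidate scoring per step."""
    disc = discretize(table, n_bins=n_bins)
    selected = []
    picks = []
    candidates = list(range(disc.wavelengths.size))
    for _ in range(steps):
        best = None
        for j in candidates:
            if j in selected:
                continue
            v = brute_force_mi(disc.codes[:, j].tolist(), disc.labels.tolist())
            if selected:
                w = np.mean([
                    brute_force_mi(disc.codes[:, j].tolist(),
                                   disc.codes[:, z].tolist())
                    for z in selected
                ])
                crit = v / max(w, MIQ_EPS)
            else:
                crit = v
            lam = disc.wavelengths[j]
            if best is None or crit > best[0] + 1e-12 or (
                abs(crit - best[0]) <= 1e-12 and lam < best[1]
            ):
                best = (crit, lam, j)
        selected.append(best[2])
        picks.append(best[1])
    return picks


class TestForwardSelect:
    def test_single_separating_band_stops_after_one_step(self, rng):
        table = toy_table(rng, informative=[3])

        def wrapper(tbl, selected):
            return 100.0 if 415.0 in selected else 60.0

        res = forward_select(table, wrapper, target_ccr=99.0)
        assert res.selected == [415.0]
        assert res.stop_reason == "target_reached"
        assert res.trace == [100.0]

    def test_identical_copy_of_first_band_is_never_chosen_second(self):
        from conftest import balanced_pair_table

        _, table = balanced_pair_table(("broad_bean", "wheat"), lib_seed=3,
                                       stream_seed=4)
        first = forward_select(table, lambda t, s: 60.0, max_size=1).selected[0]
        # overwrite a quiet band with an exact copy of the first selection
        copy_band = 1000.0
        table.spectra[:, table.band_index(copy_band)] = \
            table.spectra[:, table.band_index(first)]
        res = forward_select(table, lambda t, s: 60.0, max_size=3)
        assert res.selected[0] == first
        assert copy_band not in res.selected[:2]

    def test_every_greedy_step_matches_the_brute_force_oracle(self, rng):
        for rep in range(5):
            table = toy_table(rng, n=150, n_bands=8, informative=[1, 5])
            expected = oracle_forward_select(table, n_bins=4, steps=4)
            res = forward_select(table, lambda t, s: 60.0, target_ccr=99.0,
                                 max_size=4, n_bins=4)
            assert res.selected == expected

    def test_tie_break_prefers_the_lower_wavelength(self, rng):
        table = toy_table(rng, informative=[2])
        table.spectra[:, 5] = table.spectra[:, 2]  # equal relevance
        res = forward_select(table, lambda t, s: 60.0, max_size=1)
        assert res.selected == [410.0]

    def test_selection_is_deterministic(self, rng):
        table = toy_table(rng, n_bands=8, informative=[1, 6])
        runs = [
            forward_select(table, lambda t, s: 60.0, max_size=5) for _ in range(2)
        ]
        assert runs[0].selected == runs[1].selected
        assert runs[0].scores == runs[1].scores

    def test_target_reached_implies_final_trace_meets_target(self, rng):
        table = toy_table(rng, informative=[0, 3])

        def wrapper(tbl, selected):
            return 80.0 + 10.0 * len(selected)

        res = forward_select(table, wrapper, target_ccr=99.0)
        assert res.stop_reason == "target_reached"
        assert res.trace[-1] >= 99.0
        assert len(res.trace) == len(res.selected)

    def test_max_size_cap(self, rng):
        table = toy_table(rng)
        res = forward_select(table, lambda t, s: 60.0, max_size=2)
        assert len(res.selected) == 2
        assert res.stop_reason == "max_size"

    def test_exhausting_all_candidates(self, rng):
        table = toy_table(rng, n_bands=3)
        res = forward_select(table, lambda t, s: 60.0, max_size=10)
        assert len(res.selected) == 3
        assert res.stop_reason == "exhausted"

    def test_invalid_target_rejected(self, rng):
        table = toy_table(rng)
        with pytest.raises(ValueError):
            forward_select(table, lambda t, s: 60.0, target_ccr=40.0)

    def test_wrapper_failure_carries_step_context(self, rng):
        table = toy_table(rng)

        def bad_wrapper(tbl, selected):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="step 1"):
            forward_select(table, bad_wrapper)


class TestDiscretize:
    def test_equal_frequency_codes_cover_the_bin_range(self, rng):
        table = toy_table(rng, n=200)
        disc = discretize(table, n_bins=8)
        assert disc.codes.min() >= 0 and disc.codes.max() < 8
        assert disc.codes.shape == table.spectra.shape
        # equal-frequency: no bin grossly over-populated on a continuous band
        counts = np.bincount(disc.codes[:, 0], minlength=8)
        assert counts.max() <= 2 * counts[counts > 0].min()

    def test_equal_width_binning(self, rng):
        table = toy_table(rng)
        disc = discretize(table, n_bins=4, binning="equal_width")
        assert disc.codes.min() >= 0 and disc.codes.max() < 4

    def test_unknown_binning_rejected(self, rng):
        with pytest.raises(ValueError):
            discretize(toy_table(rng), binning="kmeans")
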