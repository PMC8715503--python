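"""The four matching algorithms, the brute-force oracle, and their invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from cspmatch import (
    PeakList,
    PeakMatcher,
    assign_brute_force,
    assign_ra,
    assign_ras,
    assign_sd,
    assign_sds,
    recovery_fraction,
)
from cspmatch.errors import AssignmentsRequiredError, OracleSizeError
from cspmatch.matchers import solve_brute_force, solve_ra, solve_sd, solve_sds
from cspmatch.peaks_io import MatchConfig

from conftest import make_peak, random_cost_matrix

ALL_ALGORITHMS = ("sd", "sds", "ra", "ras")

GREEDY_TRAP = np.array([[1.0, 2.0], [2.0, 10.0]])


def shuffled(peaklist, rng):
    order = rng.permutation(len(peaklist))
    return dataclasses.replace(peaklist, peaks=tuple(peaklist.peaks[i] for i in order))


def scaled(peaklist, lam):
    return dataclasses.replace(
        peaklist,
        peaks=tuple(
            dataclasses.replace(p, shift_h=p.shift_h * lam, shift_het=p.shift_het * lam)
            for p in peaklist.peaks
        ),
    )


def check_partition(result, ref, tgt):
    ref_ids = {p.peak_id for p in ref}
    tgt_ids = {p.peak_id for p in tgt}
    pair_ref = [p.ref.peak_id for p in result.pairs]
    pair_tgt = [p.tgt.peak_id for p in result.pairs]
    assert len(set(pair_ref)) == len(pair_ref)  # one-to-one
    assert len(set(pair_tgt)) == len(pair_tgt)
    assert len(result.pairs) == min(len(ref), len(tgt))
    assert set(pair_ref) | {p.peak_id for p in result.unmatched_ref} == ref_ids
    assert set(pair_tgt) | {p.peak_id for p in result.unmatched_tgt} == tgt_ids
    assert not set(pair_ref) & {p.peak_id for p in result.unmatched_ref}
    assert not set(pair_tgt) & {p.peak_id for p in result.unmatched_tgt}


class TestMatrixSolvers:
    def test_greedy_falls_into_trap_optimal_escapes(self):
        """On [[1,2],[2,10]] greedy commits to the 1 and pays 11; the optimum is 4."""
        sd_pairs, sd_cost = solve_sd(GREEDY_TRAP)
        ra_pairs, ra_cost = solve_ra(GREEDY_TRAP)
        assert sd_pairs == [(0, 0), (1, 1)] and sd_cost == 11.0
        assert ra_pairs == [(0, 1), (1, 0)] and ra_cost == 4.0

    def test_brute_force_agrees_on_trap(self):
        pairs, cost = solve_brute_force(GREEDY_TRAP)
        assert pairs == [(0, 1), (1, 0)] and cost == 4.0

    def test_brute_force_single_cell(self):
        assert solve_brute_force(np.array([[0.7]])) == ([(0, 0)], 0.7)

    def test_brute_force_rejects_large_instances(self):
        with pytest.raises(OracleSizeError):
            solve_brute_force(np.ones((9, 9)))

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 7))
    def test_optimal_matches_brute_force_cost(self, seed, n):
        """RA's total cost equals the exhaustive minimum on square instances."""
        D = random_cost_matrix(np.random.default_rng(seed), n)
        _, ra_cost = solve_ra(D)
        _, bf_cost = solve_brute_force(D)
        assert ra_cost == pytest.approx(bf_cost, rel=1e-12)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6), m=st.integers(2, 6))
    def test_optimal_matches_brute_force_rectangular(self, seed, n, m):
        D = random_cost_matrix(np.random.default_rng(seed), n, m)
        _, ra_cost = solve_ra(D)
        _, bf_cost = solve_brute_force(D)
        assert ra_cost == pytest.approx(bf_cost, rel=1e-12)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 8), m=st.integers(2, 8))
    def test_greedy_never_beats_optimal(self, seed, n, m):
        D = random_cost_matrix(np.random.default_rng(seed), n, m)
        _, sd_cost = solve_sd(D)
        _, ra_cost = solve_ra(D)
        assert sd_cost >= ra_cost - 1e-12

    def test_greedy_tie_breaks_by_row_then_column(self):
        D = np.array([[5.0, 1.0, 1.0], [1.0, 5.0, 5.0]])
        pairs, _ = solve_sd(D)
        # three exact 1.0 ties; first pick must be (0, 1)
        assert (0, 1) in pairs and (1, 0) in pairs

    def test_sds_reduces_to_sd_without_sequence_neighbors(self):
        """With residues farther apart than the window, the neighborhood
        average is always zero and SDS equals SD exactly."""
        rng = np.random.default_rng(7)
        D = random_cost_matrix(rng, 6)
        residues = [10 * (i + 1) for i in range(6)]  # no pair within window 7
        sds_pairs, _, iters, converged = solve_sds(D, residues, window_k=7)
        sd_pairs, _ = solve_sd(D)
        assert sorted(sd_pairs) == sds_pairs
        assert converged and iters == 2  # pass 2 confirms pass 1


class TestIdentityAndInvariance:
    @pytest.mark.parametrize("alg", ALL_ALGORITHMS + ("brute",))
    def test_identity_recovery(self, alg, small_synthetic):
        """Matching a list against itself returns the identity with zero CSPs."""
        ref, _, _ = small_synthetic
        if alg == "brute":
            ref = dataclasses.replace(ref, peaks=ref.peaks[:6])
        result = PeakMatcher(algorithm=alg).fit_predict(ref, ref)
        assert result.pair_ids() == {(p.peak_id, p.peak_id) for p in ref}
        assert all(p.csp == 0.0 for p in result.pairs)
        check_partition(result, ref, ref)

    @pytest.mark.parametrize("alg", ALL_ALGORITHMS)
    @pytest.mark.parametrize("lam", [0.1, 3.0])
    def test_scale_invariance(self, alg, lam, small_synthetic):
        """Scaling every shift by lambda scales all distances by lambda and
        leaves the pairing of every algorithm unchanged."""
        ref, tgt, _ = small_synthetic
        base = PeakMatcher(algorithm=alg).fit_predict(ref, tgt)
        res = PeakMatcher(algorithm=alg).fit_predict(scaled(ref, lam), scaled(tgt, lam))
        assert res.pair_ids() == base.pair_ids()

    @pytest.mark.parametrize("alg", ALL_ALGORITHMS)
    def test_permutation_equivariance(self, alg, small_synthetic):
        """Reordering peaks within either list does not change the matched pairs."""
        ref, tgt, _ = small_synthetic
        rng = np.random.default_rng(5)
        base = PeakMatcher(algorithm=alg).fit_predict(ref, tgt)
        res = PeakMatcher(algorithm=alg).fit_predict(
            shuffled(ref, rng), shuffled(tgt, rng)
        )
        assert res.pair_ids() == base.pair_ids()


class TestPeakLevelAlgorithms:
    def test_rectangular_shorter_list_fully_matched(self, three_peak_list):
        tgt = PeakList("t2", three_peak_list.peaks[:2])
        tgt = dataclasses.replace(
            tgt,
            peaks=tuple(dataclasses.replace(p, peak_id="t" + p.peak_id) for p in tgt.peaks),
        )
        result = assign_sd(three_peak_list, tgt)
        assert len(result.pairs) == 2
        assert len(result.unmatched_ref) == 1
        assert len(result.unmatched_tgt) == 0
        check_partition(result, three_peak_list, tgt)

    @pytest.mark.parametrize("alg_fn", [assign_sds, assign_ras])
    def test_smart_requires_assignments(self, alg_fn):
        ref = PeakList("r", (make_peak("a", 8.0, 120.0), make_peak("b", 8.5, 122.0)))
        with pytest.raises(AssignmentsRequiredError):
            alg_fn(ref, ref)

    def test_smart_neglects_unassigned_reference_peaks(self, three_peak_list):
        ref = dataclasses.replace(
            three_peak_list,
            peaks=three_peak_list.peaks + (make_peak("extra", 6.5, 105.0),),
        )
        result = assign_sds(ref, three_peak_list)
        assert len(result.pairs) == 3
        assert "extra" in {p.peak_id for p in result.unmatched_ref}
        check_partition(result, ref, three_peak_list)

    def test_swap_case_separates_smart_from_plain(self, swap_case):
        """The planted near-neighbor swap defeats SD and RA but not SDS/RAS."""
        ref, tgt, truth = swap_case
        assert recovery_fraction(assign_sd(ref, tgt), truth) == pytest.approx(0.6)
        assert recovery_fraction(assign_ra(ref, tgt), truth) == pytest.approx(0.6)
        assert recovery_fraction(assign_sds(ref, tgt), truth) == 1.0
        assert recovery_fraction(assign_ras(ref, tgt), truth) == 1.0

    def test_swap_case_smart_converges(self, swap_case):
        ref, tgt, _ = swap_case
        for fn in (assign_sds, assign_ras):
            res = fn(ref, tgt)
            assert res.converged
            assert 1 <= res.iterations_used <= 50

    def test_ras_reported_csps_are_unscaled(self, swap_case):
        """RAS rescales distances only for the search; CSPs come from the
        physical distance matrix."""
        ref, tgt, _ = swap_case
        res = assign_ras(ref, tgt)
        by_ref = {p.ref.peak_id: p.csp for p in res.pairs}
        assert by_ref["ref4"] == pytest.approx(0.32, abs=1e-12)
        assert by_ref["ref20"] == pytest.approx(0.05, abs=1e-12)

    def test_ras_uniform_rescaling_degenerate_case(self):
        """Isolated residues give all-zero neighborhood averages; the epsilon
        floor makes the rescaling uniform, the pairing is unchanged from RA,
        and the refinement converges on round 2."""
        ref = PeakList("r", (
            make_peak("a", 7.0, 110.0, res=10),
            make_peak("b", 8.0, 120.0, res=30),
            make_peak("c", 9.0, 130.0, res=50),
        ))
        tgt = PeakList("t", (
            make_peak("x", 7.05, 110.0, res=10),
            make_peak("y", 8.05, 120.0, res=30),
            make_peak("z", 9.05, 130.0, res=50),
        ))
        ra = assign_ra(ref, tgt)
        ras = assign_ras(ref, tgt)
        assert ras.pair_ids() == ra.pair_ids()
        assert ras.converged and ras.iterations_used == 2

    def test_brute_force_agrees_with_ra_on_peaks(self, swap_case):
        ref, tgt, _ = swap_case
        assert assign_brute_force(ref, tgt).total_cost == pytest.approx(
            assign_ra(ref, tgt).total_cost
        )

    def test_recovery_under_drop_fraction(self):
        from cspmatch import SyntheticSpec, generate_pair

        ref, tgt, truth = generate_pair(SyntheticSpec(seed=9, drop_fraction=0.1))
        assert len(tgt) == 90 and len(truth) == 90
        for fn in (assign_sd, assign_ra):
            res = fn(ref, tgt)
            assert recovery_fraction(res, truth) == 1.0
            assert len(res.unmatched_ref) == 10
            check_partition(res, ref, tgt)


class TestEstimatorApi:
    def test_get_set_params_and_clone(self):
        m = PeakMatcher(algorithm="sds", het_scale=3.0, window_k=5)
        params = m.get_params()
        assert params["algorithm"] == "sds" and params["het_scale"] == 3.0
        m2 = clone(m).set_params(het_scale=5.0)
        assert m2.get_params()["het_scale"] == 5.0
        assert m.get_params()["het_scale"] == 3.0

    def test_predict_before_fit_raises(self, three_peak_list):
        with pytest.raises(AttributeError):
            PeakMatcher().predict(three_peak_list)

    def test_invalid_algorithm_rejected_at_fit(self, three_peak_list):
        with pytest.raises(ValueError):
            PeakMatcher(algorithm="hungarian").fit(three_peak_list)

    def test_config_propagates_to_distances(self, three_peak_list):
        res5 = PeakMatcher(algorithm="sd", het_scale=5.0).fit_predict(
            three_peak_list, three_peak_list
        )
        assert res5.total_cost == 0.0

    def test_sds_first_selection_matches_sd(self, small_synthetic):
        """With the all-zero seed profile, SDS's first accepted pair is the
        globally smallest distance, exactly as SD's."""
        ref, tgt, _ = small_synthetic
        from cspmatch import build_cost_matrix
        from cspmatch.matchers import _sds_pass

        D = build_cost_matrix(ref, tgt, MatchConfig())
        residues = [p.residue_index for p in ref]
        pairs, _ = _sds_pass(D, residues, {r: 0.0 for r in residues}, 7)
        sd_first = divmod(int(np.argmin(D)), D.shape[1])
        assert sd_first in pairs
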