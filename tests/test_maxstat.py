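"""Maximally-selected log-rank machinery against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from generisk.errors import (
    DegenerateGroupError,
    DomainError,
    NoEventsError,
    NoValidCutpointError,
)
from generisk.maxstat import (
    benjamini_hochberg,
    maxstat_pvalue,
    maxstat_scan,
    select_prognostic_probesets,
    standardized_logrank_stat,
)
from generisk.survival import logrank_test

from conftest import make_cohort, oracle_logrank_z, oracle_maxstat


class TestStandardizedLogrank:
    def test_hand_computed_six_patient_table(self):
        # times 1..6 all events, group = first three deaths.
        # O-E = 3 - (3/6 + 2/5 + 1/4) = 1.85; V = 0.25 + 0.24 + 0.1875.
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        group = [1, 1, 1, 0, 0, 0]
        expected = 1.85 / math.sqrt(0.6775)
        z = standardized_logrank_stat(time, event, group)
        assert z == pytest.approx(expected, abs=1e-12)

    def test_identical_copy_groups_give_zero(self):
        time = [3.0, 5.0, 8.0, 12.0] * 2
        event = [1, 0, 1, 1] * 2
        group = [1] * 4 + [0] * 4
        assert standardized_logrank_stat(time, event, group) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_square_equals_logrank_chi2(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        time = rng.exponential(12.0, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        group = rng.integers(0, 2, n).astype(bool)
        group[0], group[1] = True, False
        z = standardized_logrank_stat(time, event, group)
        chi2, df, _ = logrank_test(time, event, group.astype(int))
        assert df == 1
        assert z**2 == pytest.approx(chi2, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 25
        time = np.round(rng.exponential(12.0, n), 1) + 0.1  # force some ties
        event = rng.integers(0, 2, n)
        event[:2] = 1
        group = rng.integers(0, 2, n).astype(bool)
        group[0], group[1] = True, False
        assert standardized_logrank_stat(time, event, group) == pytest.approx(
            oracle_logrank_z(time, event, group), abs=1e-12
        )

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGroupError):
            standardized_logrank_stat([1, 2], [1, 1], [1, 1])
        with pytest.raises(NoEventsError):
            standardized_logrank_stat([1, 2], [0, 0], [1, 0])


class TestMaxstatScan:
    def test_constant_marker_has_no_cutpoint(self):
        time = np.arange(1.0, 11.0)
        event = np.ones(10, dtype=int)
        with pytest.raises(NoValidCutpointError):
            maxstat_scan(np.full(10, 5.0), time, event)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 40
        values = rng.normal(8, 1, n)
        time = rng.exponential(12, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        res = maxstat_scan(values, time, event)
        cut, stat = oracle_maxstat(values, time, event)
        assert res.cutpoint == cut
        assert res.max_stat == pytest.approx(stat, abs=1e-10)

    def test_perfect_separator_found(self):
        rng = np.random.default_rng(42)
        n = 60
        values = rng.uniform(5, 9, n)
        doomed = values > 7.0
        time = np.where(doomed, rng.uniform(1, 6, n), 60.0)
        event = doomed.astype(int)
        res = maxstat_scan(values, time, event)
        assert res.cutpoint <= 7.0
        cut, stat = oracle_maxstat(values, time, event)
        assert res.cutpoint == cut
        assert res.max_stat == pytest.approx(stat, abs=1e-10)

    def test_cutpoint_within_quantile_window(self, rng):
        values = rng.normal(0, 1, 80)
        time = rng.exponential(10, 80)
        event = np.ones(80, dtype=int)
        res = maxstat_scan(values, time, event, q_low=0.25, q_high=0.75)
        frac_le = np.mean(values <= res.cutpoint)
        assert 0.25 <= frac_le <= 0.75
        assert res.candidate_count >= 1


class TestMaxstatPvalue:
    def test_zero_statistic_clips_to_one(self):
        assert maxstat_pvalue(0.0) == 1.0
        # tiny statistics fall back to the pointwise normal-tail floor
        assert 0.9 <= maxstat_pvalue(0.1) <= 1.0

    def test_monotone_decreasing_in_statistic(self):
        assert maxstat_pvalue(4.0) < maxstat_pvalue(3.0) < maxstat_pvalue(2.0)

    def test_monotone_increasing_in_window_width(self):
        narrow = maxstat_pvalue(3.0, 0.4, 0.6)
        default = maxstat_pvalue(3.0, 0.1, 0.9)
        wide = maxstat_pvalue(3.0, 0.01, 0.99)
        assert narrow < default < wide

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            maxstat_pvalue(2.0, 0.9, 0.1)
        with pytest.raises(DomainError):
            maxstat_pvalue(-1.0)
        with pytest.raises(DomainError):
            maxstat_pvalue(2.0, 0.0, 0.9)


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert benjamini_hochberg([0.05])[0] == pytest.approx(0.05)

    def test_hand_computed_step_up(self):
        # p_(i) * 4/i = (.04, .04, .04, .04); cummin from top leaves .04.
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04] * 4)

    def test_equal_p_invariance(self):
        adj = benjamini_hochberg([0.2] * 7)
        assert adj == pytest.approx([0.2] * 7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominance_and_range(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            benjamini_hochberg([0.5, 1.5])


class TestSelection:
    def test_permutation_safety(self, rng):
        cohort = make_cohort(rng, n_patients=50, n_probes=8)
        table = select_prognostic_probesets(cohort)
        perm = rng.permutation(cohort.n_patients)
        ids = [cohort.patient_ids[i] for i in perm]
        from generisk.data import CohortDataset

        shuffled = CohortDataset(
            expression=cohort.expression.subset_patients(ids),
            survival=cohort.survival.subset(ids),
        )
        table2 = select_prognostic_probesets(shuffled)
        for a, b in zip(table.rows, table2.rows):
            assert a.probe_id == b.probe_id
            assert a.cutpoint == b.cutpoint
            assert a.max_stat == pytest.approx(b.max_stat, abs=1e-10)
        assert table.p_adj == pytest.approx(table2.p_adj, abs=1e-12)

    def test_selected_set_shrinks_with_alpha(self, rng):
        cohort = make_cohort(rng, n_patients=60, n_probes=12)
        loose = set(select_prognostic_probesets(cohort, alpha=0.5).selected_ids)
        tight = set(select_prognostic_probesets(cohort, alpha=0.05).selected_ids)
        assert tight <= loose

    def test_bh_dominance_elementwise(self, rng):
        cohort = make_cohort(rng, n_patients=50, n_probes=10)
        table = select_prognostic_probesets(cohort)
        for row, adj in zip(table.rows, table.p_adj):
            assert adj >= row.p_raw - 1e-15
            assert 0.0 <= adj <= 1.0

    def test_constant_probe_skipped_not_fatal(self, rng):
        cohort = make_cohort(rng, n_patients=40, n_probes=5)
        cohort.expression.values[2, :] = 7.0
        table = select_prognostic_probesets(cohort)
        assert cohort.expression.probe_ids[2] in table.skipped
        assert len(table.rows) == 4
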