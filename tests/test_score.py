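"""Risk-score construction, thresholding, classification and transfer."""

import math

import numpy as np
import pytest

from conftest import oracle_threshold
from generisk.data import CohortDataset, ExpressionMatrix, SurvivalData
from generisk.errors import MissingProbeError, SeparationError
from generisk.score import (
    ProbePrognostic,
    RiskScoreModel,
    apply_model,
    classify_patients,
    compute_scores,
    fit_probe_beta,
    fit_risk_score_model,
    load_model,
    optimize_score_threshold,
    save_model,
)

# Representative adverse-probe hazard ratios on the 2.6-3.7 scale typical
# of dichotomized single-gene prognostic markers.
HRS_27 = [
    3.67, 3.67, 3.46, 3.37, 3.33, 3.27, 3.25, 3.25, 3.22, 3.14, 3.12, 3.07,
    3.06, 3.00, 2.96, 2.93, 2.91, 2.90, 2.88, 2.87, 2.87, 2.78, 2.73, 2.73,
    2.66, 2.66, 2.65,
]


def _probes(betas, cut=8.0):
    return [
        ProbePrognostic(f"p{i:02d}_at", "---", cut, float(b), None)
        for i, b in enumerate(betas)
    ]


def _matrix(probes, columns):
    """columns: dict patient -> offset added to every cutpoint."""
    ids = list(columns)
    values = np.array(
        [[p.cutpoint + columns[pid] for pid in ids] for p in probes]
    )
    return ExpressionMatrix([p.probe_id for p in probes], ids, values)


class TestComputeScores:
    def test_all_below_hits_lower_bound(self):
        probes = _probes([0.5, 1.2, 0.8])
        expr = _matrix(probes, {"LO": -1.0, "HI": +1.0})
        scores = compute_scores(expr, probes)
        total = 0.5 + 1.2 + 0.8
        assert scores == pytest.approx([-total, +total])

    def test_boundary_value_counts_as_below(self):
        probes = _probes([1.0])
        expr = _matrix(probes, {"EQ": 0.0})
        assert compute_scores(expr, probes) == pytest.approx([-1.0])

    def test_single_flip_changes_score_by_twice_beta(self):
        probes = _probes([0.7, 1.1, 0.9])
        expr = _matrix(probes, {"A": -0.5, "B": -0.5})
        expr.values[1, 1] = probes[1].cutpoint + 0.5  # flip probe 1 for B
        scores = compute_scores(expr, probes)
        assert scores[1] - scores[0] == pytest.approx(2 * 1.1, abs=1e-12)

    def test_probe_order_invariance(self, rng):
        probes = _probes(rng.uniform(0.2, 1.5, 8))
        offsets = {f"P{j}": o for j, o in enumerate(rng.normal(0, 1, 12))}
        expr = _matrix(probes, offsets)
        shuffled = [probes[i] for i in rng.permutation(len(probes))]
        assert compute_scores(expr, probes) == pytest.approx(
            compute_scores(expr, shuffled), abs=1e-12
        )

    def test_printed_hr_sum_oracle(self):
        # betas from a 27-row published-style HR column; a patient above
        # every cutpoint scores the independently summed log HRs.
        betas = [math.log(hr) for hr in HRS_27]
        expected = math.fsum(betas)
        probes = _probes(betas)
        expr = _matrix(probes, {"UP": +0.1})
        assert compute_scores(expr, probes) == pytest.approx([expected], abs=1e-12)

    def test_missing_probe_listed(self):
        probes = _probes([0.5, 0.6])
        expr = _matrix(probes[:1], {"A": 0.5})
        with pytest.raises(MissingProbeError) as exc:
            compute_scores(expr, probes)
        assert "p01_at" in str(exc.value)


class TestThreshold:
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_bruteforce(self, seed):
        rng = np.random.default_rng(500 + seed)
        n = 60
        scores = np.round(rng.normal(0, 5, n), 2)
        time = rng.exponential(12, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        tau, p_high = optimize_score_threshold(scores, time, event)
        tau_o, p_o = oracle_threshold(scores, time, event)
        assert tau == tau_o
        assert p_high == p_o

    def test_perfect_separator_at_median_gap(self, rng):
        n = 80
        scores = np.concatenate([rng.uniform(-10, -5, n // 2),
                                 rng.uniform(5, 10, n // 2)])
        time = np.where(scores > 0, rng.uniform(1, 6, n), 60.0)
        event = (scores > 0).astype(int)
        tau, p_high = optimize_score_threshold(scores, time, event)
        # candidates are observed scores, so the winner is the top of the
        # low block: the lower edge of the gap between the two halves
        assert tau == np.max(scores[scores < 0])
        assert p_high == 0.5


class TestClassify:
    def _model(self, tau=0.0, p_high=0.534, mode="by_value"):
        return RiskScoreModel(
            probes=_probes([5.0, 5.0, 5.0, 5.0]),
            threshold=tau, p_high=p_high, transfer_mode=mode,
        )

    def test_by_value_all_low(self):
        model = self._model(tau=3.0)
        scored = classify_patients([-1.0, 0.0, 2.9], ["A", "B", "C"], model)
        assert (scored.labels == "low").all()

    def test_by_proportion_round_half_up(self, rng):
        model = self._model(mode="by_proportion", p_high=0.534)
        scores = rng.normal(0, 3, 100)
        scored = classify_patients(scores, [f"P{i}" for i in range(100)], model)
        assert (scored.labels == "high").sum() == 53
        # the high set is exactly the top-scoring 53
        cut = np.sort(scores)[::-1][52]
        assert set(np.flatnonzero(scored.labels == "high")) == set(
            np.flatnonzero(scores >= cut)
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_modes_agree_on_training_scores(self, seed):
        rng = np.random.default_rng(700 + seed)
        scores = rng.normal(0, 4, 90)
        time = rng.exponential(10, 90)
        event = rng.integers(0, 2, 90)
        event[0] = 1
        tau, p_high = optimize_score_threshold(scores, time, event)
        base = dict(probes=_probes([20.0] * 2), threshold=tau, p_high=p_high)
        ids = [f"P{i}" for i in range(90)]
        by_value = classify_patients(
            scores, ids, RiskScoreModel(**base, transfer_mode="by_value")
        )
        by_prop = classify_patients(
            scores, ids, RiskScoreModel(**base, transfer_mode="by_proportion")
        )
        assert np.array_equal(by_value.labels, by_prop.labels)


class TestFitProbeBeta:
    def test_null_groups_recover_unit_hazard_ratio(self, rng):
        n = 400
        values = rng.normal(8, 1, n)
        time = rng.exponential(12, n)
        event = (time < 30).astype(int)
        time = np.minimum(time, 30.0)
        _, hr = fit_probe_beta(values, 8.0, time, event)
        assert 0.8 <= hr <= 1.25

    def test_recovers_true_hazard_ratio_three(self, rng):
        n = 500
        values = rng.normal(8, 1, n)
        group = values > 8.0
        rate = np.where(group, 3.0, 1.0) / 24.0
        death = rng.exponential(1.0 / rate)
        censor = rng.exponential(1.0 / rate / 0.25)  # ~20% censoring
        time = np.minimum(death, censor)
        event = (death <= censor).astype(int)
        beta, hr = fit_probe_beta(values, 8.0, time, event)
        assert 2.4 <= hr <= 3.7
        assert hr == pytest.approx(math.exp(beta))

    def test_separation_raises(self, rng):
        values = np.concatenate([np.full(20, 9.0), np.full(20, 7.0)])
        time = np.concatenate([rng.uniform(1, 5, 20), np.full(20, 60.0)])
        event = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        with pytest.raises(SeparationError):
            fit_probe_beta(values, 8.0, time, event)


class TestModelPersistence:
    def test_roundtrip_exact(self, tmp_path):
        model = RiskScoreModel(
            probes=_probes([0.123456789012345, 1.1]),
            threshold=-0.4, p_high=0.534,
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.threshold == model.threshold
        assert back.p_high == model.p_high
        assert back.transfer_mode == model.transfer_mode
        for p, q in zip(model.probes, back.probes):
            assert (p.probe_id, p.cutpoint, p.beta) == (q.probe_id, q.cutpoint, q.beta)

    def test_threshold_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            RiskScoreModel(probes=_probes([0.5]), threshold=0.7, p_high=0.5)


def _fitted_cohort(rng, n=120):
    """Small cohort with a real prognostic probe, screened and fitted."""
    from generisk.maxstat import select_prognostic_probesets

    probes = 15
    values = rng.normal(8, 1, (probes, n))
    values[1] = values[0] * 0.9 + rng.normal(0, 0.4, n)  # co-expressed pair
    risky = values[0] > 8.0
    rate = np.where(risky, 4.0, 1.0) * np.log(2) / 24
    death = rng.exponential(1 / rate)
    time = np.minimum(death, 60.0)
    event = (death <= 60.0).astype(int)
    ids = [f"P{i:03d}" for i in range(n)]
    cohort = CohortDataset(
        expression=ExpressionMatrix(
            [f"pr{i:02d}_at" for i in range(probes)], ids, values
        ),
        survival=SurvivalData(ids, time, event),
    )
    selection = select_prognostic_probesets(cohort, alpha=0.2)
    model = fit_risk_score_model(cohort, selection)
    return cohort, model


class TestApplyModel:
    def test_training_labels_reproduced(self, rng):
        cohort, model = _fitted_cohort(rng)
        report = apply_model(model, cohort)
        scores = compute_scores(cohort.expression, model.probes)
        expected = classify_patients(scores, cohort.patient_ids, model)
        assert np.array_equal(report.scored.labels, expected.labels)
        # by_proportion was derived from tau, so labels match the tau rule
        assert np.array_equal(
            report.scored.labels == "high", scores > model.threshold
        )

    def test_missing_probe_policies(self, rng):
        cohort, model = _fitted_cohort(rng)
        keep = [p for p in cohort.expression.probe_ids if p != model.probes[0].probe_id]
        idx = [cohort.expression.probe_ids.index(p) for p in keep]
        slim = CohortDataset(
            expression=ExpressionMatrix(
                keep, cohort.patient_ids, cohort.expression.values[idx]
            ),
            survival=cohort.survival,
        )
        if len(model.probes) == 1:
            pytest.skip("model degenerated to a single probe")
        with pytest.raises(MissingProbeError):
            apply_model(model, slim)
        report = apply_model(model, slim, on_missing="drop")
        assert report.dropped_probes == [model.probes[0].probe_id]
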