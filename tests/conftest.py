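"""Shared fixtures and independent oracle implementations.

The oracles deliberately use plain scalar loops over risk sets and
candidate cutpoints, structurally unlike the vectorized implementations
they check.
"""

import math

import numpy as np
import pytest

from generisk.data import CohortDataset, ExpressionMatrix, SurvivalData


def oracle_logrank_z(time, event, group):
    """Scalar O/E/V accumulation over distinct event times (oracle)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    o = e = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        r = int(at_risk.sum())
        r1 = int((at_risk & group).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d1 = int((dying & group).sum())
        o += d1
        e += d * r1 / r
        if r > 1:
            v += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    return (o - e) / math.sqrt(v)


def oracle_maxstat(values, time, event, q_low=0.10, q_high=0.90):
    """Exhaustive brute-force dichotomy search (oracle).

    Tries every distinct observed value with empirical quantile in
    [q_low, q_high]; keeps the first (smallest) cutpoint on ties.
    Returns (cutpoint, max |z|).
    """
    values = np.asarray(values, float)
    n = values.size
    best_cut, best_stat = None, -np.inf
    for mu in np.unique(values):
        frac_le = np.count_nonzero(values <= mu) / n
        if not (q_low <= frac_le <= q_high):
            continue
        grp = values > mu
        if not grp.any() or grp.all():
            continue
        try:
            z = abs(oracle_logrank_z(time, event, grp))
        except ZeroDivisionError:
            continue
        if z > best_stat:
            best_cut, best_stat = float(mu), z
    return best_cut, best_stat


def oracle_threshold(scores, time, event):
    """Brute-force score-threshold search (oracle).

    Maximizes |z|; exact ties resolved toward the more balanced split,
    then the smaller threshold.
    """
    scores = np.asarray(scores, float)
    n = scores.size
    best = None  # (stat, balance_dev, tau)
    for tau in np.unique(scores)[:-1]:
        grp = scores > tau
        z = abs(oracle_logrank_z(time, event, grp))
        dev = abs(grp.sum() / n - 0.5)
        key = (-z, dev, tau)
        if best is None or key < best:
            best = key
    return best[2], float(np.mean(scores > best[2]))


def make_cohort(rng, n_patients=40, n_probes=6, hazard=None, horizon=36.0,
                prefix="P"):
    """Small hand-rolled cohort with exponential survival (test helper)."""
    values = rng.normal(8.0, 1.0, size=(n_probes, n_patients))
    if hazard is None:
        hazard = np.full(n_patients, np.log(2) / 12.0)
    death = rng.exponential(1.0 / hazard)
    time = np.minimum(death, horizon)
    event = (death <= horizon).astype(int)
    ids = [f"{prefix}{j:03d}" for j in range(n_patients)]
    expr = ExpressionMatrix(
        probe_ids=[f"probe_{i:03d}_at" for i in range(n_probes)],
        patient_ids=ids,
        values=values,
    )
    surv = SurvivalData(patient_ids=ids, time=time, event=event)
    return CohortDataset(expression=expr, survival=surv)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


@pytest.fixture
def small_cohort(rng):
    return make_cohort(rng)
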