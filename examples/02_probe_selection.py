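"""Screen probes for prognostic value with maximally selected log-rank
statistics and Benjamini-Hochberg FDR control.

For each probe, every candidate expression cutpoint inside the 10-90%
quantile window is tried as a dichotomy and the maximal absolute
standardized log-rank statistic is kept; its p-value corrects for the
maximization, and BH controls the false discovery rate across probes.
"""

from generisk import SimulationConfig, generate_cohort, select_prognostic_probesets

syn = generate_cohort(SimulationConfig(seed=7))
table = select_prognostic_probesets(syn.dataset, alpha=0.05)

planted = set(syn.truth.prognostic_probe_ids)
chosen = set(table.selected_ids)
print(f"probes screened: {len(table.rows)}; selected at adjusted p < .05: "
      f"{len(chosen)}")
print(f"planted probes recovered: {len(chosen & planted)}/{len(planted)}; "
      f"false positives: {len(chosen - planted)}")

best = max(table.selected, key=lambda r: r.max_stat)
print(f"strongest probe {best.probe_id}: cutpoint {best.cutpoint:.2f}, "
      f"max |z| = {best.max_stat:.2f}, raw p = {best.p_raw:.2e}")
# A selected probe means: splitting patients at the reported cutpoint
# separates their survival curves more than chance would allow, even after
# accounting for having scanned many cutpoints and many probes.
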