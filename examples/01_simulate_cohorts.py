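"""Generate a synthetic training/validation cohort pair.

Draws two cohorts from the same synthetic 'array platform': log-scale
expression for 1000 probes (25 of them noisy readouts of a latent
prognostic axis), an independent EVI1-like prognostic gene, and
right-censored overall survival in months.
"""

import numpy as np

from generisk import GeneSpec, SimulationConfig, generate_training_validation_pair

config = SimulationConfig(seed=7, gene=GeneSpec())
training, validation = generate_training_validation_pair(config, validation_n=79)

for tag, cohort in (("training", training), ("validation", validation)):
    ds = cohort.dataset
    print(f"{tag}: {ds.expression.shape[0]} probes x {ds.n_patients} patients, "
          f"event rate {ds.survival.event.mean():.2f}, "
          f"median follow-up {np.median(ds.survival.time):.1f} months")

truth = training.truth
print(f"planted prognostic probes: {len(truth.prognostic_probe_ids)} "
      f"(true per-probe log-HR {truth.config.beta_true}), "
      f"EVI1-like probe: {truth.gene_probe_id}")
# The two cohorts share probe identities and cutpoints (same platform) but
# contain independent patients, so a model trained on the first can be
# transferred to the second without information leakage.
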