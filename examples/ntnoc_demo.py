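"""Nearest-training-neighbour optimal control (NTNOC).

Solve the optimal control problem for a (small) training cohort whose
parameters are treated as known, log each patient's observation window and
optimal dose per day, then treat unseen test patients by replaying the
dose of the nearest logged same-day state.
"""

import numpy as np

from chemosched import (
    build_library,
    default_config,
    max_scores,
    run_ntnoc,
    sample_cohort,
)

cfg = default_config()
training = sample_cohort(40, k=0.20, seed=1, role="training")
library = build_library(training, cfg)
print(f"library: {library.n_entries} logged (state, dose) pairs "
      f"({len(training)} patients x {library.n_days} days)")

testing = sample_cohort(10, k=0.20, seed=2, role="testing")
sigma_max = max_scores(testing, cfg)
scaled = []
for patient in testing:
    schedule, score = run_ntnoc(library, patient, cfg)
    scaled.append(score / sigma_max[patient.id])
print("scaled NTNOC scores on 10 unseen patients:", np.round(scaled, 3))
print(f"median {np.median(scaled):.3f} -> each patient is steered by the training "
      "patient whose marrow trajectory it most resembles")
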