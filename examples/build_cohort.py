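"""Generate a seeded phantom cohort and print its ground-truth table.

Each subject is a digital thorax phantom with a known myocardial-to-rib
uptake ratio; the class column is the Perugini-like grade implied by that
ratio (0 none ... 3 greater than rib with suppressed rib uptake).
"""

from replanar import CohortSpec, make_cohort
from replanar.io import truths_to_frame

cohort = make_cohort(CohortSpec(
    n_subjects=8, class_mix={0: 2, 1: 2, 2: 2, 3: 2}, master_seed=42))

frame = truths_to_frame([t for _, _, t in cohort])
print(frame.to_string(index=False))
print("\nColumns: uptake ratio drives the class; heart centre (mm) varies "
      "with the per-subject anatomical jitter; identical master seeds "
      "reproduce this table exactly.")
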