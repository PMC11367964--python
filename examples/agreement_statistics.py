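"""Agreement statistics on simulated reader scores and paired H/CL ratios.

Simulates three readers scoring a 30-subject cohort on both modalities
with a 5% per-reading error rate, then computes the full agreement battery:
per-reader concordance counts, percent agreement, Cohen's and Fleiss's
kappa, and Bland-Altman limits for a pair of ratio series.
"""

import numpy as np

from replanar import (CohortSpec, bland_altman, cohens_kappa,
                      concordance_summary, fleiss_kappa, make_cohort,
                      pearson_regression, simulate_readers)

cohort = make_cohort(CohortSpec(master_seed=5))
truths = [t for _, _, t in cohort]
scores = simulate_readers(truths, p=0.05, seed=5)

print(concordance_summary(scores, ("conventional", "reprojected")).to_string(index=False))

for reader in scores.readers:
    res = cohens_kappa(scores.scores(reader, "conventional"),
                       scores.scores(reader, "reprojected"), seed=0)
    print(f"reader {reader}: Cohen kappa {res.kappa:.2f} "
          f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
          f"agreement {res.percent_agreement}%")

for mod in scores.modalities:
    res = fleiss_kappa(scores.rater_matrix(mod))
    print(f"{mod:>12}: Fleiss kappa {res.kappa:.2f} "
          f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")

# paired ratios with a small constant shift, as Bland-Altman sees them
rng = np.random.default_rng(0)
x = rng.uniform(1.0, 3.0, 30)
y = x + rng.normal(0.05, 0.05, 30)
ba = bland_altman(x, y)
reg = pearson_regression(x, y)
print(f"\nratios: r = {reg.r:.3f}, bias = {ba.bias:.3f}, "
      f"LoA = ({ba.loa_low:.3f}, {ba.loa_high:.3f})")
print("Kappa near 1 with tight CIs reflects the 5% reader error; the "
      "Bland-Altman bias recovers the simulated 0.05 shift.")
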