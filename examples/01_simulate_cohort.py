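"""Generate a synthetic ageing cohort with a planted brain-behaviour mediation.

The generator draws resilience and processing-speed scores with marginals
matched to a 101-subject ageing cohort, and couples resilience to the
thalamus rows of each subject's connectivity covariance through a latent
variable, so the ground truth of every downstream analysis is known.
"""

import numpy as np

from connmed import generate_cohort

cohort = generate_cohort(n_subjects=101, n_rois=90, n_volumes=240, seed=0)

pheno = cohort.phenotypes
print(f"subjects: {len(pheno)}, ROIs: {cohort.timeseries[0].n_rois}, "
      f"volumes: {cohort.timeseries[0].n_volumes}")
print(f"resilience: mean {pheno.resilience.mean():.1f}, "
      f"SD {pheno.resilience.std():.2f} (scale 0-45)")
print(f"speed:      mean {pheno.speed.mean():.1f}, SD {pheno.speed.std():.2f}")
print(f"age range:  {pheno.age.min():.0f}-{pheno.age.max():.0f}, "
      f"{(pheno.sex == 0).sum()}F/{(pheno.sex == 1).sum()}M")

truth = cohort.truth
print(f"\nplanted paths: a={truth.path_a} (resilience -> latent), "
      f"b={truth.path_b} (latent -> speed), c'={truth.path_c_prime}")
r = np.corrcoef(pheno.resilience, truth.subject_latent)[0, 1]
print(f"realised corr(resilience, latent) = {r:.2f}")
print("higher resilience lowers the thalamus connectivity modulation, and "
      "lower thalamus connectivity raises processing speed.")
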