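"""Volume-fraction deconvolution and conformer classification.

Generates a study-scale three-class hinge ensemble (158 conformers, classes
differing in inter-domain opening), synthesizes a noisy experimental SAXS
curve as an 18/76/6 mixture of one representative per class, then recovers
the volume fractions and classifies all conformers by cosine distance at
threshold 0.1.
"""

import numpy as np

from saxsemble import (
    classify_by_cosine,
    debye_profile,
    default_q_grid,
    default_study_spec,
    fit_volume_fractions,
    generate_hinge_ensemble,
    synthesize_mixture_profile,
)

ensemble, truth = generate_hinge_ensemble(default_study_spec(seed=1))
labels = truth["class_labels"]
q = default_q_grid()
profiles = [debye_profile(c, q) for c in ensemble]

# one representative per class, mixed 18% / 76% / 6% with 1% noise
refs = [profiles[int(np.flatnonzero(labels == c)[0])] for c in range(3)]
experimental = synthesize_mixture_profile(refs, [0.18, 0.76, 0.06],
                                          noise_fraction=0.01, seed=1)

fit = fit_volume_fractions(refs, experimental)
print("true fractions    :  18.0%  76.0%   6.0%")
print("recovered         : " + "  ".join(f"{100 * v:5.1f}%" for v in fit.nu))
print(f"reduced χ² of fit : {fit.chi2:.2f} (≈ 1 when residuals match the noise)")

assignment = classify_by_cosine(profiles, refs, threshold=0.1)
sizes = {lab: len(assignment.members_of(lab)) for lab in assignment.class_labels}
print(f"class sizes       : {sizes} (generator used 32 / 118 / 8)")
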