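"""Translate CYP2D6 diplotypes to activity scores and metabolizer classes.

Builds a small subject table of star-allele diplotypes, scores each one
(sum of per-allele function values times copy number), bins the scores into
gPM/gIM/gNM/gUM, and shows the NFIB rs28379954 sensitivity reclassification
moving a carrier gNM into gUM.
"""

import pandas as pd

from solmark import annotate_subjects

subjects = pd.DataFrame(
    {
        "subject_id": ["S1", "S2", "S3", "S4", "S5"],
        "diplotype": ["*4/*4", "*1/*4", "*1/*41", "*1x2/*1", "*1/*1"],
        "nfib_carrier": [False, False, False, False, True],
    }
)

print("Standard activity-score translation:")
print(annotate_subjects(subjects)[["subject_id", "diplotype", "activity_score", "phenotype"]])

print("\nWith NFIB reclassification enabled (gNM carriers -> gUM):")
print(annotate_subjects(subjects, nfib_reclass=True)[["subject_id", "diplotype", "phenotype"]])

# The activity score is additive: *4 contributes 0 per copy, *41 0.5, *1 1.0,
# and the x2 duplication doubles its haplotype's contribution, so S4 scores
# 3.0 and is ultrarapid while S1 (two null alleles) is a poor metabolizer.
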