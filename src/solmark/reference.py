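"""Published summary statistics of the solanidine biomarker cohort.

These constants describe the fasting-plasma cohort of 356 genotyped healthy
volunteers (314 retained after exclusions) on which the solanidine /
metabolite-ratio biomarker characterisation was reported: per-phenotype
geometric means with 95% CIs for solanidine (ng/mL) and the five
metabolite-to-solanidine response ratios, the printed ratio-to-gNM
contrasts, detected-subject counts per metabolite ion, and basic
demographics.  The synthetic cohort generator (:mod:`solmark.simulate`)
uses them as its default calibration; nothing in this module is computed.
"""

from __future__ import annotations

#: genotype-predicted metabolizer classes, ordered by increasing activity
PHENOTYPES = ("gPM", "gIM", "gNM", "gUM")

#: retained subjects per phenotype class (after exclusions)
GROUP_SIZES = {"gPM": 9, "gIM": 89, "gNM": 196, "gUM": 20}

N_ENROLLED = 356          # genotyped volunteers
N_INDETERMINATE = 1       # phenotype not inferable from genotype
N_BELOW_LLOQ = 41         # parent solanidine below LLOQ -> excluded
N_RETAINED = 314

SOLANIDINE_LLOQ_NG_ML = 0.01

#: endpoint -> phenotype -> (geometric mean, 95% CI low, 95% CI high).
#: "solanidine" is a concentration in ng/mL; "ratio_mz*" are semi-quantitative
#: metabolite response / solanidine concentration ratios (arbitrary units).
GEOMETRIC_MEANS = {
    "solanidine": {
        "gPM": (1.76, 0.775, 4.02),
        "gIM": (0.154, 0.119, 0.200),
        "gNM": (0.0889, 0.0746, 0.106),
        "gUM": (0.0580, 0.0333, 0.101),
    },
    "ratio_mz414": {
        "gPM": (0.00649, 0.00441, 0.00954),
        "gIM": (5.49, 4.86, 6.20),
        "gNM": (7.52, 6.92, 8.16),
        "gUM": (7.20, 5.55, 9.34),
    },
    "ratio_mz416": {
        "gPM": (0.00433, 0.00231, 0.00811),
        "gIM": (3.08, 2.53, 3.76),
        "gNM": (5.65, 4.95, 6.47),
        "gUM": (7.99, 5.23, 12.2),
    },
    "ratio_mz444": {
        "gPM": (0.00319, 0.00157, 0.00648),
        "gIM": (0.382, 0.305, 0.479),
        "gNM": (1.14, 0.979, 1.33),
        "gUM": (2.29, 1.42, 3.69),
    },
    "ratio_mz430": {
        "gPM": (0.00420, 0.00217, 0.00816),
        "gIM": (0.347, 0.281, 0.428),
        "gNM": (1.04, 0.899, 1.19),
        "gUM": (2.15, 1.38, 3.37),
    },
    "ratio_mz412": {
        "gPM": (0.00331, 0.00208, 0.00527),
        "gIM": (0.152, 0.131, 0.177),
        "gNM": (0.236, 0.214, 0.261),
        "gUM": (0.345, 0.252, 0.473),
    },
}

#: printed ratio-to-gNM contrasts (point estimates) per endpoint/class
PRINTED_RATIO_TO_GNM = {
    "solanidine": {"gPM": 19.9, "gIM": 1.74, "gUM": 0.653},
    "ratio_mz414": {"gPM": 0.000863, "gIM": 0.731, "gUM": 0.958},
    "ratio_mz416": {"gPM": 0.000765, "gIM": 0.545, "gUM": 1.41},
    "ratio_mz444": {"gPM": 0.00280, "gIM": 0.335, "gUM": 2.01},
    "ratio_mz430": {"gPM": 0.00406, "gIM": 0.335, "gUM": 2.08},
    "ratio_mz412": {"gPM": 0.0140, "gIM": 0.644, "gUM": 1.460},
}

#: overall (size-weighted) geometric mean of fasting plasma solanidine, ng/mL
POOLED_SOLANIDINE_GM = 0.110

#: subjects (of 314) with each metabolite ion measurable at S/N >= 10
METABOLITE_DETECTED = {
    "mz414": 310,
    "mz416": 308,
    "mz444": 299,
    "mz430": 296,
    "mz412": 225,
}

#: carriers of the NFIB rs28379954 T>C variant among the 196 gNM subjects
NFIB_CARRIERS_GNM = 17

MEAN_BODYWEIGHT_KG = 69.7
SD_BODYWEIGHT_KG = 12.1
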