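"""Study-condition constants for the synthetic twin cohort.

These constants pin the synthetic generator to the conditions of the
population twin study the package replicates: the cohort composition
(658 MZ, 765 same-sex DZ, 708 opposite-sex DZ complete pairs, born
1999–2003), the 17-level synaesthesia screening score (0–8 in 0.5 steps,
mean 0.76, sd 1.25), and the variance-component / correlation structure
estimated for the synaesthesia score and the three autistic-trait measures
(total A-TAC autism score and its RRBI-D and SIC sub-scales).
"""

import numpy as np

# cohort composition (complete pairs)
N_MZ = 658
N_DZ_SS = 765
N_DZ_OS = 708
N_PAIRS = N_MZ + N_DZ_SS + N_DZ_OS          # 2131
BIRTH_YEARS = (1999, 2003)
FEMALE_FRACTION = {"MZ": 413 / 658, "DZ_SS": 490 / 765}

# 17-level screening score: 0, 0.5, ..., 8
SYNAESTHESIA_LEVELS = np.arange(17) * 0.5

# Standard-normal cut points mapping a latent liability onto the 17 levels.
# Calibrated once by moment-matching a zero-inflated truncated-geometric
# marginal to mean 0.76 / sd 1.25 (scripts/calibrate_score_thresholds.py);
# the implied skewness is 2.24.
SYNAESTHESIA_THRESHOLDS = np.array([
    0.141353, 0.477893, 0.754235, 0.992987, 1.205839, 1.399784, 1.579474,
    1.748307, 1.909017, 2.064060, 2.215962, 2.367743, 2.523652, 2.690835,
    2.884294, 3.149697,
])
SYNAESTHESIA_MEAN = 0.76
SYNAESTHESIA_SD = 1.25

# screening item names; the four sequence-colour types form the
# sensitivity-analysis collapse group
SCREENING_ITEMS = [
    "letter_colour", "digit_colour", "weekday_colour", "month_colour",
    "auditory_visual", "sequence_space",
    "ordinal_linguistic_personification", "people_colour",
]
SEQUENCE_COLOUR_GROUP = SCREENING_ITEMS[:4]

# generating variance components (proportions of variance) under the
# selected AE structure: synaesthesia a2 = 0.46; the autistic-trait a2
# values are the MZ twin correlations of the constrained saturated models,
# which equal a2 under an AE structure
SYNAESTHESIA_ACE = {"a2": 0.46, "c2": 0.0, "e2": 0.54}
TRAIT_ACE = {
    "total_autistic_traits": {"a2": 0.44, "c2": 0.0, "e2": 0.56},
    "rrbid": {"a2": 0.35, "c2": 0.0, "e2": 0.65},
    "sic": {"a2": 0.47, "c2": 0.0, "e2": 0.53},
}

# cross-trait component correlations (synaesthesia vs each autistic trait)
TRAIT_CROSS = {
    "total_autistic_traits": {"r_a": 0.26, "r_c": 0.0, "r_e": 0.09},
    "rrbid": {"r_a": 0.34, "r_c": 0.0, "r_e": 0.09},
    "sic": {"r_a": 0.18, "r_c": 0.0, "r_e": 0.02},
}

# individual-level covariate effects used by the realism layer (sd units;
# the year effect is per year, centred on the 2001 cohort midpoint)
DEFAULT_SEX_EFFECT = 0.15
DEFAULT_YEAR_EFFECT = 0.02
DEFAULT_MISSING_RATE = 0.02
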