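"""Default calibration of the synthetic cohort generator.

Every number here is transcribed from the source study's printed descriptive
tables and results text for a longitudinal aging cohort measured at mean ages
~73 and ~76: per-measure wave-2 means/SDs, cross-wave stabilities, standardized
mean changes, and the standardized structural (latent) correlations between
each hippocampal biomarker and the three cognitive domains.  The provenance of
each block is recorded in machine-readable ``source`` fields so a generated
cohort is auditable back to its calibration origin.

Units: volume mm^3; percentage-of-ICV %; FA unitless; MD x10^-3 mm^2/s; T1 s;
cognitive tests in native score units; ages in days.
"""

from __future__ import annotations

DAYS_PER_YEAR = 365.25

BIOMARKERS = ("volume", "pct_icv", "fa", "md", "t1")
DOMAINS = ("verbal_memory", "working_memory", "speed")

#: indicator -> domain map for the 9-test roster
DOMAIN_INDICATORS = {
    "verbal_memory": ("logical_memory", "verbal_pairs"),
    "working_memory": ("spatial_span", "digit_backward", "letter_number"),
    "speed": ("digit_symbol", "symbol_search", "choice_rt", "inspection_time"),
}

# Wave-2 / wave-3 descriptives: (mean_w2, sd_w2, mean_w3, sd_w3).
# Source: descriptive table of the hippocampal sample (n=655 -> 469) and the
# full cognitive sample (n=866 -> ~690).
BIOMARKER_DESCRIPTIVES = {
    "volume": (6429.53, 861.22, 5634.92, 914.52),
    "pct_icv": (0.48, 0.05, 0.39, 0.06),
    "fa": (0.12, 0.01, 0.11, 0.01),
    "md": (0.88, 0.05, 0.93, 0.05),
    "t1": (1.66, 0.15, 1.44, 0.19),
}

COGNITIVE_DESCRIPTIVES = {
    "logical_memory": (74.23, 17.89, 74.58, 19.20),
    "verbal_pairs": (27.18, 9.49, 26.41, 9.56),
    "spatial_span": (14.69, 2.76, 14.62, 2.73),
    "digit_backward": (7.81, 2.29, 7.77, 2.37),
    "letter_number": (10.91, 3.08, 10.48, 2.99),
    "digit_symbol": (56.40, 12.31, 53.81, 12.93),
    "symbol_search": (24.61, 6.18, 24.60, 6.46),
    "choice_rt": (0.65, 0.09, 0.68, 0.10),
    "inspection_time": (111.22, 11.79, 110.17, 12.53),
}

#: Raw-score orientation: -1 where a larger raw value means *worse*
#: performance (choice reaction time is a latency).
COGNITIVE_SIGN = {name: 1.0 for name in COGNITIVE_DESCRIPTIVES}
COGNITIVE_SIGN["choice_rt"] = -1.0

# Cross-wave Pearson stabilities (bold diagonal of the printed full
# correlation matrix: same measure at 73 vs 76).
BIOMARKER_STABILITY = {
    "volume": 0.64,
    "pct_icv": 0.56,
    "fa": 0.67,
    "md": 0.66,
    "t1": 0.19,
}

COGNITIVE_STABILITY = {
    "logical_memory": 0.73,
    "verbal_pairs": 0.70,
    "spatial_span": 0.57,
    "digit_backward": 0.68,
    "letter_number": 0.66,
    "digit_symbol": 0.83,
    "symbol_search": 0.67,
    "choice_rt": 0.71,
    "inspection_time": 0.59,
}

# Standardized mean changes between waves, in baseline-SD units, oriented so
# that a negative value is a decline in the measure's own raw scale (MD
# increased).  Source: results text on longitudinal change.
STANDARDIZED_CHANGE = {
    "volume": -0.90,
    "pct_icv": -0.99,
    "fa": -0.56,
    "md": 1.02,
    "t1": -1.47,
    "verbal_memory": -0.12,
    "working_memory": -0.21,
    "speed": -0.40,
}

# Own-domain latent level -> change correlations (higher baseline predicting
# steeper decline), from the results text.
DOMAIN_LEVEL_CHANGE_CORR = {
    "verbal_memory": -0.047,
    "working_memory": -0.21,
    "speed": -0.18,
}

# Standardized structural path table: for each biomarker, the 12 typed
# correlations with the three cognitive domains (all with cognition oriented
# higher = better).  kinds: level_level, cog_level_bio_change,
# bio_level_cog_change, change_change; domains ordered
# (working_memory, verbal_memory, speed) as printed.
STRUCTURAL_PATHS = {
    "volume": {
        "level_level": {"working_memory": 0.123, "verbal_memory": 0.087, "speed": 0.070},
        "cog_level_bio_change": {"working_memory": 0.040, "verbal_memory": 0.088, "speed": 0.097},
        "bio_level_cog_change": {"working_memory": -0.077, "verbal_memory": 0.078, "speed": 0.096},
        "change_change": {"working_memory": 0.087, "verbal_memory": -0.008, "speed": 0.060},
    },
    "pct_icv": {
        "level_level": {"working_memory": 0.048, "verbal_memory": 0.045, "speed": -0.028},
        "cog_level_bio_change": {"working_memory": 0.040, "verbal_memory": 0.104, "speed": 0.090},
        "bio_level_cog_change": {"working_memory": -0.061, "verbal_memory": 0.101, "speed": 0.149},
        "change_change": {"working_memory": 0.094, "verbal_memory": -0.094, "speed": 0.079},
    },
    "fa": {
        "level_level": {"working_memory": 0.184, "verbal_memory": 0.085, "speed": 0.234},
        "cog_level_bio_change": {"working_memory": -0.019, "verbal_memory": -0.019, "speed": -0.016},
        "bio_level_cog_change": {"working_memory": 0.019, "verbal_memory": 0.085, "speed": 0.044},
        "change_change": {"working_memory": 0.100, "verbal_memory": -0.061, "speed": 0.012},
    },
    "md": {
        "level_level": {"working_memory": -0.159, "verbal_memory": -0.170, "speed": -0.259},
        "cog_level_bio_change": {"working_memory": -0.011, "verbal_memory": -0.040, "speed": -0.036},
        "bio_level_cog_change": {"working_memory": -0.281, "verbal_memory": -0.150, "speed": -0.197},
        "change_change": {"working_memory": 0.194, "verbal_memory": -0.011, "speed": 0.003},
    },
    "t1": {
        "level_level": {"working_memory": -0.156, "verbal_memory": -0.111, "speed": -0.174},
        "cog_level_bio_change": {"working_memory": 0.030, "verbal_memory": 0.019, "speed": 0.017},
        "bio_level_cog_change": {"working_memory": 0.039, "verbal_memory": 0.053, "speed": -0.036},
        "change_change": {"working_memory": -0.167, "verbal_memory": -0.091, "speed": -0.056},
    },
}

# Study design numbers.
N_WAVE2 = 655
N_WAVE3 = 469
AGE_W2_MEAN_YEARS = 72.50
AGE_W2_SD_YEARS = 0.71
WAVE_GAP_YEARS = 3.74  # 76.24 - 72.50
FEMALE_PROP = 309 / 655
# Mean (SD) days between cognitive testing and scanning, per wave.
TEST_SCAN_GAP_DAYS = {"w2": (65.04, 39.57), "w3": (40.29, 31.89)}
# ~19 of 1091 study members ever scored below the MMSE cutoff of 24.
MMSE_SUB24_RATE = 19 / 1091

SOURCES = {
    "descriptives": "printed descriptive-statistics table (wave 2 / wave 3 means, SDs, n)",
    "stabilities": "bold diagonal of the printed cross-wave correlation matrix",
    "standardized_changes": "results text on mean longitudinal change (SD units, z-tests)",
    "structural_paths": "printed standardized path-coefficient table (per-biomarker columns)",
    "level_change_corr": "results text: baseline level vs subsequent change correlations",
    "design": "participants section: n=655 (309F) at wave 2, 469 (218F) at wave 3",
}
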