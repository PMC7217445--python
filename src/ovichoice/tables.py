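"""Reference values from the motivating field study.

A discrete choice experiment with 370 smallholder farmers in the
northwest Ethiopian highlands elicited preferences for indigenous-sheep
traits: six binary ram attributes and seven binary ewe attributes,
effect coded, presented in four blocked choice situations of four
designed alternatives plus an opt-out.  The tables below carry the
study's published summaries — attribute definitions, rank-proportion
matrices for production objectives and selection criteria, flock
composition means, and the fitted G-MNL coefficients — and serve two
roles in this package: as default "true" parameters for the synthetic
respondent generator, and as printed inputs for the ranking and
reporting computations.
"""

from __future__ import annotations

import pandas as pd

from .design import Attribute

# --- attribute definitions (effect coded: high label = +1, low = -1) ---

RAM_ATTRIBUTES = [
    Attribute("body_size", "height and body length", "large", "small"),
    Attribute("coat_color", "predominant coat color", "brown", "white"),
    Attribute("growth_rate", "yearling live weight at breeding age", "rapid", "slow"),
    Attribute("ear_size", "size of the ears", "large", "small"),
    Attribute("horn", "presence or absence of horns", "horned", "polled"),
    Attribute("tail_type", "length and width of the fat tail", "good", "bad"),
]

EWE_ATTRIBUTES = [
    Attribute("body_size", "height and body length", "large", "small"),
    Attribute("coat_color", "predominant coat color", "brown", "white"),
    Attribute("growth_rate", "yearling live weight at breeding age", "rapid", "slow"),
    Attribute("lambing_interval", "interval between successive lambings", "short", "long"),
    Attribute("mothering_ability", "ability to nourish lambs", "good", "poor"),
    Attribute("litter_size", "lambs born per lambing", "twin", "single"),
    Attribute("tail_type", "length and width of the fat tail", "good", "bad"),
]

# --- study design and sample constants ---

N_RESPONDENTS = 370
N_SITUATIONS = 4  # one choice situation per block, four blocks per respondent
N_ALTERNATIVES = 4  # designed alternatives per situation (opt-out excluded)
RAM_OPT_OUT_RATE = 0.0047  # share of ram choice situations answered "none"
EWE_OPT_OUT_RATE = 0.004

# --- rank-proportion matrices (shares of respondents assigning rank 1-4) ---

PRODUCTION_OBJECTIVES = pd.DataFrame(
    {
        "rank1": [0.65, 0.32, 0.02, 0.00, 0.00, 0.00],
        "rank2": [0.33, 0.52, 0.08, 0.07, 0.01, 0.00],
        "rank3": [0.01, 0.14, 0.18, 0.45, 0.22, 0.01],
        "rank4": [0.01, 0.03, 0.09, 0.44, 0.42, 0.03],
    },
    index=[
        "income_generation",
        "meat_source",
        "saving_asset",
        "manure_source",
        "skin_source",
        "wool_production",
    ],
)

RAM_SELECTION_CRITERIA = pd.DataFrame(
    {
        "rank1": [0.64, 0.03, 0.03, 0.25, 0.01, 0.00, 0.01, 0.03, 0.00, 0.00, 0.00],
        "rank2": [0.21, 0.05, 0.01, 0.44, 0.04, 0.02, 0.03, 0.14, 0.00, 0.01, 0.02],
        "rank3": [0.09, 0.13, 0.05, 0.16, 0.07, 0.02, 0.10, 0.18, 0.01, 0.02, 0.02],
        "rank4": [0.02, 0.19, 0.08, 0.08, 0.08, 0.10, 0.18, 0.17, 0.01, 0.01, 0.10],
    },
    index=[
        "body_size",
        "ear_size",
        "pedigree",
        "coat_color",
        "growth_rate",
        "sexual_maturity",
        "libido",
        "tail_type",
        "adaptation",
        "wool_yield",
        "horn_status",
    ],
)

EWE_SELECTION_CRITERIA = pd.DataFrame(
    {
        "rank1": [0.63, 0.02, 0.00, 0.02, 0.02, 0.02, 0.05, 0.22, 0.01, 0.00, 0.01, 0.00, 0.00, 0.00],
        "rank2": [0.26, 0.02, 0.00, 0.04, 0.05, 0.04, 0.01, 0.41, 0.04, 0.06, 0.06, 0.00, 0.01, 0.00],
        "rank3": [0.05, 0.09, 0.01, 0.03, 0.13, 0.10, 0.03, 0.15, 0.08, 0.19, 0.08, 0.02, 0.02, 0.01],
        "rank4": [0.02, 0.12, 0.05, 0.08, 0.21, 0.07, 0.05, 0.06, 0.05, 0.12, 0.11, 0.02, 0.02, 0.00],
    },
    index=[
        "body_size",
        "litter_size",
        "lamb_survival",
        "lamb_growth",
        "lambing_interval",
        "ear_size",
        "pedigree",
        "coat_color",
        "growth_rate",
        "sexual_maturity",
        "tail_type",
        "adaptation",
        "wool_yield",
        "horn_status",
    ],
)

# --- flock size and composition (means and SDs per district and overall) ---

FLOCK_COMPOSITION = pd.DataFrame(
    {
        "estie_mean": [5.15, 0.52, 0.45, 0.62, 2.83, 0.07, 9.65],
        "estie_sd": [1.34, 0.57, 1.03, 0.94, 1.33, 0.31, 2.76],
        "farta_mean": [3.86, 0.46, 0.64, 0.79, 2.76, 0.03, 8.54],
        "farta_sd": [1.19, 0.50, 0.87, 0.92, 1.75, 0.18, 3.40],
        "lay_gayient_mean": [6.64, 0.45, 1.87, 0.68, 2.58, 0.14, 12.36],
        "lay_gayient_sd": [3.20, 0.60, 1.53, 1.15, 2.16, 0.68, 6.39],
        "overall_mean": [5.23, 0.48, 1.01, 0.70, 2.72, 0.08, 10.21],
        "overall_sd": [2.43, 0.56, 1.34, 1.01, 1.79, 0.45, 4.79],
    },
    index=[
        "breeding_ewes",
        "breeding_rams",
        "ewe_lambs",
        "ram_lambs",
        "lambs",
        "castrated",
        "total",
    ],
)

DISTRICT_COUNTS = {"estie": 117, "farta": 125, "lay_gayient": 128}

# --- fitted G-MNL coefficients (the study's point estimates and SEs) ---
# ASC for the first alternative position is the zero reference.

RAM_GMNL = {
    "asc": [0.0, 0.2863, -0.9403, 0.9929],
    "asc_se": [None, 0.117, 0.163, 0.152],
    "beta": {
        "body_size": 0.5132,
        "coat_color": 0.3237,
        "growth_rate": 0.2666,
        "ear_size": -0.1869,
        "horn": 0.2523,
        "tail_type": 0.8986,
    },
    "beta_se": {
        "body_size": 0.048,
        "coat_color": 0.039,
        "growth_rate": 0.043,
        "ear_size": 0.060,
        "horn": 0.041,
        "tail_type": 0.051,
    },
    "random_attrs": ["body_size", "tail_type"],
    "eta_sd": {"body_size": 0.001, "tail_type": 0.014},
    "eta_sd_se": {"body_size": 0.072, "tail_type": 0.318},
    "tau": 0.004,
    "tau_se": 0.13,
    "loglik": -1493.1,
    "loglik_null": -1864.1,
    "n_obs": 1473,
}

EWE_GMNL = {
    "asc": [0.0, 1.1342, 0.6060, 1.0351],
    "asc_se": [None, 0.251, 0.236, 0.241],
    "beta": {
        "body_size": 1.1287,
        "coat_color": 1.1517,
        "growth_rate": 0.9618,
        "lambing_interval": 0.9645,
        "mothering_ability": 1.3056,
        "litter_size": 0.7737,
        "tail_type": 0.8547,
    },
    "beta_se": {
        "body_size": 0.333,
        "coat_color": 0.312,
        "growth_rate": 0.254,
        "lambing_interval": 0.23,
        "mothering_ability": 0.357,
        "litter_size": 0.327,
        "tail_type": 0.240,
    },
    "random_attrs": ["body_size", "growth_rate", "lambing_interval"],
    "eta_sd": {"body_size": 0.0055, "growth_rate": 0.2086, "lambing_interval": 0.0745},
    "eta_sd_se": {"body_size": 0.07, "growth_rate": 0.244, "lambing_interval": 0.171},
    "tau": 0.7565,
    "tau_se": 0.172,
    "loglik": -1376.3,
    "loglik_null": -1894.4,
    "n_obs": 1474,
}

# --- published odds ratios with 95% Wald intervals, per attribute ---

RAM_ODDS_RATIOS = {
    "body_size": (1.67, 1.52, 1.84),
    "coat_color": (1.38, 1.28, 1.49),
    "growth_rate": (1.31, 1.20, 1.42),
    "tail_type": (2.46, 2.22, 2.71),
    "ear_size": (0.83, 0.74, 0.93),
    "horn": (1.29, 1.19, 1.40),
}

EWE_ODDS_RATIOS = {
    "body_size": (3.09, 1.61, 5.94),
    "coat_color": (3.16, 1.72, 5.83),
    "growth_rate": (2.62, 1.59, 4.31),
    "tail_type": (2.35, 1.47, 3.77),
    "lambing_interval": (2.62, 1.67, 4.12),
    "mothering_ability": (3.69, 1.83, 7.42),
    "litter_size": (2.17, 1.14, 4.12),
}
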