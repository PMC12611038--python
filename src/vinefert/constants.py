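"""Published reference constants for the '87-1' grape fertilization study.

Everything in this module is a printed input to the analysis: the orthogonal
design tables, the published per-treatment quality means, the cubic
cumulative-variance coefficients with their optimum nutrient ranges, the
stage-wise demand proportions and soil-test fertilization models, the
verification-year quality indices, and the physical fertilizer catalog.
All concentrations are mg·g⁻¹, doses kg·hm⁻², masses g unless stated.
"""

from __future__ import annotations

import pandas as pd

#: Oxide factors in design/model order.
FACTORS = ("N", "P2O5", "K2O", "CaO", "MgO")

#: Element labels used for tissue/soil concentrations.
ELEMENTS = ("N", "P", "K", "Ca", "Mg")

#: Map oxide factor -> element it supplies.
FACTOR_TO_ELEMENT = {"N": "N", "P2O5": "P", "K2O": "K", "CaO": "Ca", "MgO": "Mg"}

#: mass conversion element = oxide × factor (P = P2O5 × 0.4364 etc.)
OXIDE_TO_ELEMENT = {
    "N": 1.0,
    "P2O5": 0.4364,
    "K2O": 0.8301,
    "CaO": 0.7147,
    "MgO": 0.6030,
}

#: Phenological stages of the destructive-harvest series, in order.
HARVEST_STAGES = ("GS", "IFS", "EBS", "SDS", "VS", "MS", "DS")

#: Stages at which rhizosphere soil is sampled.
SOIL_STAGES = ("GS", "IFS", "EBS", "VS", "MS")

#: Stages at which fruit/leaf/petiole tissue is sampled.
PLANT_STAGES = ("FBS", "VS", "MS")

#: Tissues separated at destructive harvest.
HARVEST_TISSUES = (
    "roots",
    "trunk",
    "main stem",
    "shoot",
    "leaves",
    "petioles",
    "fruit",
)

#: Sampled tissues for the diagnostic survey (F = inflorescence/fruit).
PLANT_TISSUES = ("fruit", "leaf", "petiole")

#: Fertilization intervals between consecutive soil-sampled stages.
INTERVALS = ("GS-IFS", "IFS-EBS", "EBS-VS", "VS-MS", "MS-DS")

# ---------------------------------------------------------------------------
# Annual application rates per factor level (kg·hm⁻²).  Level 4 is 3/2 of
# level 3, so the K2O/CaO level-4 dose is stored at full precision 506.25.
# ---------------------------------------------------------------------------
LEVEL_DOSES = {
    "N": (0.0, 187.5, 375.0, 562.5),
    "P2O5": (0.0, 70.5, 141.0, 211.5),
    "K2O": (0.0, 168.8, 337.5, 506.25),
    "CaO": (0.0, 168.8, 337.5, 506.25),
    "MgO": (0.0, 70.5, 141.0, 211.5),
}

#: L16(4^5) treatment -> factor level assignment.
TREATMENT_LEVELS = {
    "T1": (1, 1, 1, 1, 1),
    "T2": (1, 2, 2, 2, 2),
    "T3": (1, 3, 3, 3, 3),
    "T4": (1, 4, 4, 4, 4),
    "T5": (2, 1, 2, 3, 4),
    "T6": (2, 2, 1, 4, 3),
    "T7": (2, 3, 4, 1, 2),
    "T8": (2, 4, 3, 2, 1),
    "T9": (3, 1, 3, 4, 2),
    "T10": (3, 2, 4, 3, 1),
    "T11": (3, 3, 1, 2, 4),
    "T12": (3, 4, 2, 1, 3),
    "T13": (4, 1, 4, 2, 3),
    "T14": (4, 2, 3, 1, 4),
    "T15": (4, 3, 2, 4, 1),
    "T16": (4, 4, 1, 3, 2),
}

# ---------------------------------------------------------------------------
# Published five-year treatment means (orthogonal experiment): SFW g,
# TSS %, FF g, FQI (TOPSIS closeness coefficient).
# ---------------------------------------------------------------------------
_TREATMENT_MEANS = {
    #       SFW    TSS     FF      FQI
    "T1": (4.77, 18.11, 412.62, 0.4123),
    "T2": (4.62, 17.85, 420.17, 0.4265),
    "T3": (4.64, 18.41, 399.10, 0.4064),
    "T4": (4.73, 17.89, 427.92, 0.4491),
    "T5": (5.09, 18.63, 436.88, 0.5181),
    "T6": (4.99, 18.47, 381.79, 0.3620),
    "T7": (4.75, 19.31, 419.92, 0.5221),
    "T8": (4.86, 19.26, 402.00, 0.4569),
    "T9": (4.73, 18.67, 455.11, 0.6003),
    "T10": (4.83, 18.79, 380.28, 0.3889),
    "T11": (4.83, 19.20, 430.42, 0.5435),
    "T12": (4.54, 19.90, 416.74, 0.5336),
    "T13": (4.85, 18.50, 414.53, 0.4359),
    "T14": (4.47, 20.10, 380.42, 0.4356),
    "T15": (4.60, 19.36, 404.23, 0.4694),
    "T16": (4.98, 18.22, 408.18, 0.4176),
}

_TREATMENT_SDS = {
    "T1": (0.50, 1.10, 25.71, 0.1131),
    "T2": (0.26, 1.74, 49.90, 0.2218),
    "T3": (0.49, 1.01, 52.60, 0.1478),
    "T4": (0.34, 1.97, 62.74, 0.1480),
    "T5": (0.35, 0.65, 55.16, 0.1065),
    "T6": (0.51, 1.11, 15.14, 0.1234),
    "T7": (0.43, 1.39, 61.57, 0.1584),
    "T8": (0.42, 1.16, 15.51, 0.1332),
    "T9": (0.78, 1.23, 95.64, 0.2408),
    "T10": (0.75, 1.42, 46.30, 0.2002),
    "T11": (0.67, 1.41, 44.80, 0.1867),
    "T12": (0.63, 2.26, 21.86, 0.1396),
    "T13": (0.48, 1.60, 23.05, 0.1383),
    "T14": (0.54, 2.17, 66.33, 0.1644),
    "T15": (0.48, 1.46, 27.20, 0.1614),
    "T16": (0.33, 1.33, 34.71, 0.2265),
}

#: Published level means per trait: trait -> factor -> (L1, L2, L3, L4).
PUBLISHED_LEVEL_MEANS = {
    "SFW": {
        "N": (4.68, 4.95, 4.70, 4.73),
        "P2O5": (4.85, 4.73, 4.70, 4.78),
        "K2O": (4.90, 4.70, 4.68, 4.78),
        "CaO": (4.65, 4.78, 4.88, 4.75),
        "MgO": (4.78, 4.78, 4.73, 4.78),
    },
    "TSS": {
        "N": (18.06, 18.92, 19.14, 19.04),
        "P2O5": (18.48, 18.80, 19.07, 18.81),
        "K2O": (18.50, 18.94, 19.11, 18.62),
        "CaO": (19.35, 18.70, 18.51, 18.60),
        "MgO": (18.88, 18.51, 18.82, 18.95),
    },
    "FF": {
        "N": (414.95, 410.15, 420.64, 401.84),
        "P2O5": (429.79, 390.66, 413.42, 413.71),
        "K2O": (408.25, 419.51, 409.16, 410.66),
        "CaO": (407.43, 416.78, 406.11, 417.26),
        "MgO": (399.78, 425.84, 403.04, 418.91),
    },
    "FQI": {
        "N": (0.4236, 0.4648, 0.5166, 0.4396),
        "P2O5": (0.4916, 0.4032, 0.4854, 0.4643),
        "K2O": (0.4339, 0.4869, 0.4748, 0.4490),
        "CaO": (0.4759, 0.4657, 0.4328, 0.4702),
        "MgO": (0.4319, 0.4916, 0.4345, 0.4866),
    },
}

#: Published per-level F values for each quality trait (factor order N..MgO).
PUBLISHED_F_VALUES = {
    "SFW": {"N": 0.79, "P2O5": 0.33, "K2O": 0.64, "CaO": 0.88, "MgO": 0.01},
    "TSS": {"N": 2.14, "P2O5": 0.52, "K2O": 0.70, "CaO": 1.27, "MgO": 0.32},
    "FF": {"N": 0.54, "P2O5": 2.19, "K2O": 0.23, "CaO": 0.30, "MgO": 1.32},
    "FQI": {"N": 1.17, "P2O5": 1.15, "K2O": 0.41, "CaO": 0.27, "MgO": 0.74},
}

# ---------------------------------------------------------------------------
# Cubic cumulative-variance fits: variable -> (kind, A, B, C, D, R²,
# optimum range 1 (lo, hi) or None, optimum range 2 (lo, hi) or None).
# The "_R" ratio rows ship for reporting only.
# ---------------------------------------------------------------------------
_CUBIC_ROWS = [
    # variable, kind, A, B, C, D, R2, range1, range2
    ("FBS_L_N", "plant", -61.412, 150.170, -191.270, 105.240, 0.9918, (7.192, 12.516), (7.192, 12.516)),
    ("VS_P_P", "plant", -269.760, 533.910, -368.980, 101.400, 0.9504, (3.097, 7.122), (3.097, 7.122)),
    ("FBS_F_K", "plant", 123.710, -204.390, -8.7805, 99.531, 0.9960, (18.375, 27.350), (18.375, 27.350)),
    ("FBS_F_Ca", "plant", 43.685, -50.586, -94.536, 104.110, 0.9967, (23.801, 107.960), (23.801, 107.960)),
    ("FBS_F_Mg", "plant", 110.300, -154.030, -54.098, 101.260, 0.9975, (5.166, 21.232), (5.166, 21.232)),
    ("R", "plant_ratio", -49.511, 107.220, -157.320, 101.890, 0.9920, None, None),
    ("GS_N", "soil", 28.046, -20.587, -96.761, 91.247, 0.9941, (0.017, 0.417), (0.017, 0.336)),
    ("GS_P", "soil", 36.006, -23.910, -79.894, 70.590, 0.9550, (0.036, 1.542), (0.040, 1.394)),
    ("GS_K", "soil", 8.626, 10.172, -118.340, 102.380, 0.9943, (0.126, 1.746), (0.126, 1.746)),
    ("GS_Ca", "soil", 62.153, -96.819, -59.121, 94.235, 0.9978, (3.252, 9.250), (3.530, 9.208)),
    ("GS_Mg", "soil", 59.112, -38.225, -121.360, 104.550, 0.9938, (0.339, 2.382), (0.414, 1.164)),
    ("GS_R", "soil_ratio", -36.161, 96.896, -120.170, 60.185, 0.8850, None, None),
    ("IFS_N", "soil", 164.030, -228.510, -33.682, 101.450, 0.9979, (0.012, 1.034), (0.012, 0.590)),
    # A kept at the precision of the printed function string (-B/3A check)
    ("IFS_P", "soil", 3.9675, 61.777, -166.950, 107.000, 0.9920, (0.215, 2.111), (0.249, 2.111)),
    ("IFS_K", "soil", 40.813, -40.888, -93.662, 95.866, 0.9965, (0.105, 1.696), (0.134, 1.592)),
    ("IFS_Ca", "soil", 242.910, -373.000, 35.339, 98.462, 0.9966, (2.702, 11.000), (2.702, 7.418)),
    ("IFS_Mg", "soil", 123.400, -174.270, -48.309, 101.600, 0.9980, (0.299, 1.886), (0.302, 1.208)),
    ("IFS_R", "soil_ratio", 78.171, -88.892, -77.024, 91.917, 0.9934, None, None),
    ("EBS_N", "soil", 147.110, -231.040, -8.6896, 98.115, 0.9973, (0.017, 1.160), (0.017, 1.160)),
    ("EBS_P", "soil", 109.390, -170.670, -33.997, 100.970, 0.9962, (0.112, 1.591), (0.112, 1.591)),
    ("EBS_K", "soil", -18.397, 27.472, -84.172, 76.546, 0.9736, (0.148, 1.210), (0.148, 1.210)),
    ("EBS_Ca", "soil", 73.097, -111.060, -56.813, 101.480, 0.9960, (2.686, 8.473), (2.686, 8.231)),
    ("EBS_Mg", "soil", -44.971, 100.510, -146.640, 95.082, 0.9956, (0.428, 1.277), (0.428, 1.266)),
    ("EBS_R", "soil_ratio", 137.640, -205.950, -22.919, 97.990, 0.9972, None, None),
    ("VS_N", "soil", 26.465, 4.702, -111.760, 82.782, 0.9866, (0.024, 0.966), (0.024, 0.735)),
    ("VS_P", "soil", 44.319, -37.040, -94.919, 94.100, 0.9952, (0.119, 4.143), (0.119, 2.828)),
    ("VS_K", "soil", 14.899, 10.976, -126.110, 105.480, 0.9919, (0.254, 1.212), (0.254, 1.212)),
    ("VS_Ca", "soil", 133.930, -209.960, -24.111, 101.950, 0.9974, (3.043, 7.661), (3.043, 7.095)),
    ("VS_Mg", "soil", -213.050, 404.960, -266.020, 71.346, 0.8856, (0.313, 1.197), (0.477, 1.197)),
    ("VS_R", "soil_ratio", -32.596, 88.467, -123.670, 70.449, 0.9479, None, None),
    ("MS_N", "soil", 70.275, -104.080, -51.727, 85.866, 0.9905, (0.021, 0.691), (0.021, 0.691)),
    ("MS_P", "soil", 73.229, -94.688, -69.975, 101.000, 0.9953, (0.078, 1.258), (0.155, 1.258)),
    ("MS_K", "soil", 51.873, -44.305, -98.387, 101.850, 0.9945, (0.127, 1.448), (0.249, 1.114)),
    ("MS_Ca", "soil", 31.180, -52.216, -63.023, 89.425, 0.9942, (2.659, 8.777), (2.659, 8.777)),
    ("MS_Mg", "soil", -47.682, 128.500, -165.600, 86.876, 0.9881, (0.326, 1.186), (0.391, 1.186)),
    ("MS_R", "soil_ratio", -138.770, 261.570, -166.140, 41.788, 0.5508, None, None),
]

#: Communal cutoff used for optimum range 2 (the FBS_L_N plant cutoff).
COMMUNAL_CUTOFF = 0.8151

# ---------------------------------------------------------------------------
# Stage-wise demand proportions (% of annual uptake, this study) and the
# soil-test fertilization models y = a·x + b per interval × oxide.
# ---------------------------------------------------------------------------
_STAGE_MODEL_ROWS = [
    # interval, oxide, proportion %, a, b
    ("GS-IFS", "N", 21.8, -10.5800, 3.5549),
    ("IFS-EBS", "N", 20.1, -9.0830, 5.3590),
    ("EBS-VS", "N", 31.6, -5.9055, 6.8504),
    ("VS-MS", "N", 8.8, -27.426, 20.158),
    ("MS-DS", "N", 17.7, -3.9179, 2.7073),
    ("GS-IFS", "P2O5", 18.2, -1.8744, 2.6130),
    ("IFS-EBS", "P2O5", 8.3, -0.3029, 0.6394),
    ("EBS-VS", "P2O5", 27.1, -0.6673, 1.0617),
    ("VS-MS", "P2O5", 21.6, -2.8106, 7.9485),
    ("MS-DS", "P2O5", 24.8, -2.1732, 2.7338),
    ("GS-IFS", "K2O", 21.9, -1.4583, 2.5463),
    ("IFS-EBS", "K2O", 6.7, -3.0093, 4.7907),
    ("EBS-VS", "K2O", 48.4, -2.8602, 3.4608),
    ("VS-MS", "K2O", 7.1, -21.138, 25.619),
    ("MS-DS", "K2O", 15.9, -4.2919, 4.7812),
    ("GS-IFS", "CaO", 19.7, -0.8322, 7.6625),
    ("IFS-EBS", "CaO", 2.9, -0.5010, 3.7161),
    ("EBS-VS", "CaO", 10.3, -0.4261, 3.5069),
    ("VS-MS", "CaO", 46.7, -5.3307, 37.821),
    ("MS-DS", "CaO", 20.4, -0.4413, 3.8735),
    ("GS-IFS", "MgO", 25.2, -1.1280, 1.3130),
    ("IFS-EBS", "MgO", 17.7, -1.2450, 1.5040),
    ("EBS-VS", "MgO", 15.7, -1.0095, 1.2781),
    ("VS-MS", "MgO", 3.8, -12.533, 15.002),
    ("MS-DS", "MgO", 37.6, -2.8377, 3.3656),
]

#: Fruit-to-whole-plant annual uptake ratio FR per oxide (dimensionless).
FRUIT_RATIOS = {"N": 0.2531, "P2O5": 0.1775, "K2O": 0.4465, "CaO": 0.1640, "MgO": 0.1795}

#: Whole-plant nutrient uptake per 1000 kg fruit (kg, element basis).
TOTAL_UPTAKE_PER_1000KG = {"N": 4.37, "P": 1.78, "K": 4.84, "Ca": 7.15, "Mg": 1.04}

#: Fruit nutrient uptake per 1000 kg fruit (kg, element basis).
FRUIT_UPTAKE_PER_1000KG = {"N": 1.11, "P": 0.32, "K": 2.16, "Ca": 1.17, "Mg": 0.19}

#: Literature five-stage demand ratios used by the '5416' field scheme
#: (GS-IFS : IFS-EBS : EBS-VS : VS-MS : MS-DS), distinct from the
#: proportions measured in this study (see STAGE_MODELS).
FIELD_SCHEME_RATIOS = {
    "N": (14, 18, 52, 7, 9),
    "P2O5": (4, 7, 54, 17, 18),
    "K2O": (13, 9, 60, 11, 7),
    "CaO": (7, 7, 64, 8, 14),
    "MgO": (8, 6, 64, 16, 6),
}

#: Physical fertilizer catalog: product -> oxide mass fractions.
FERTILIZER_CATALOG = {
    "calcium nitrate": {"N": 0.1186, "CaO": 0.2373},
    "potassium nitrate": {"N": 0.1386, "K2O": 0.4653},
    "urea": {"N": 0.4667},
    "potassium dihydrogen phosphate": {"P2O5": 0.5221, "K2O": 0.3456},
    "magnesium sulfate": {"MgO": 0.3333},
    "calcium acetate": {"CaO": 0.3179},
    "potassium sulfate": {"K2O": 0.5402},
    "ammonium dihydrogen phosphate": {"N": 0.1217, "P2O5": 0.6174},
}

#: Verification-year quality index per treatment (T17/T18 follow the
#: precision model; T1–T16 the orthogonal scheme).
VERIFICATION_FQI = {
    "T1": 0.4718, "T2": 0.5080, "T3": 0.4087, "T4": 0.4434, "T5": 0.2527,
    "T6": 0.5182, "T7": 0.3882, "T8": 0.4737, "T9": 0.5784, "T10": 0.7611,
    "T11": 0.2317, "T12": 0.4245, "T13": 0.5923, "T14": 0.4860, "T15": 0.5728,
    "T16": 0.4015, "T17": 0.8322, "T18": 0.8434,
}

#: TOPSIS criterion weights for SFW, TSS, FF (sum 0.4337, used as printed).
QUALITY_WEIGHTS = {"SFW": 0.0470, "TSS": 0.2089, "FF": 0.1778}

QUALITY_TRAITS = ("SFW", "TSS", "FF")


def treatment_means() -> pd.DataFrame:
    """Published treatment-mean quality table, one row per treatment."""
    df = pd.DataFrame.from_dict(
        _TREATMENT_MEANS, orient="index", columns=["SFW", "TSS", "FF", "FQI"]
    )
    df.index.name = "treatment"
    return df


def treatment_sds() -> pd.DataFrame:
    """Published within-treatment standard deviations of the quality traits."""
    df = pd.DataFrame.from_dict(
        _TREATMENT_SDS, orient="index", columns=["SFW", "TSS", "FF", "FQI"]
    )
    df.index.name = "treatment"
    return df


def cubic_table() -> pd.DataFrame:
    """Cumulative-variance cubic coefficients and optimum ranges per variable."""
    rows = []
    for var, kind, a, b, c, d, r2, r1, r2rng in _CUBIC_ROWS:
        rows.append(
            {
                "variable": var,
                "kind": kind,
                "A": a,
                "B": b,
                "C": c,
                "D": d,
                "r_squared": r2,
                "range1_low": None if r1 is None else r1[0],
                "range1_high": None if r1 is None else r1[1],
                "range2_low": None if r2rng is None else r2rng[0],
                "range2_high": None if r2rng is None else r2rng[1],
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def stage_models() -> pd.DataFrame:
    """Soil-test fertilization models and demand proportions per interval × oxide.

    ``x_max`` is the upper bound of optimum range 2 for the interval's
    start-stage soil variable; soil tests at or above it zero the dose.
    """
    cub = cubic_table()
    rows = []
    for interval, oxide, prop, a, b in _STAGE_MODEL_ROWS:
        start = interval.split("-")[0]
        var = f"{start}_{FACTOR_TO_ELEMENT[oxide]}"
        rows.append(
            {
                "interval": interval,
                "oxide": oxide,
                "proportion_pct": prop,
                "a": a,
                "b": b,
                "x_max": cub.loc[var, "range2_high"],
            }
        )
    return pd.DataFrame(rows).set_index(["interval", "oxide"])


def _check_proportions() -> None:
    # printed stage proportions must close to 100% per element
    sm = stage_models()
    sums = sm["proportion_pct"].groupby(level="oxide").sum()
    bad = sums[(sums - 100.0).abs() > 0.2]
    if len(bad):
        raise ValueError(f"demand proportions do not sum to 100%: {bad.to_dict()}")


_check_proportions()
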