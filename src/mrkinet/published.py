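"""Literature values for the membrane-clarified sugarcane juice (MCSJ)
model system: composition of the sugar/amino-acid model solution, reported
simple-order rate constants for color values and Maillard-reaction
products at 60-90 C, and the multi-response network rate constants.

These tables serve two purposes: they are the default parameterization of
the synthetic-data generator (the generator emulates the published study
conditions), and they are inputs for re-deriving downstream quantities
(activation energies, rate ratios) from the printed rate constants.

Units: rate constants h^-1; compositions g/100 mL (model system) or
mg/g DS (juice amino acids); temperatures degrees Celsius.
"""

from __future__ import annotations

TEMPERATURES_C = (60.0, 70.0, 80.0, 90.0)

#: Model-system recipe, g per 100 mL at 15 degrees Brix.
MODEL_SYSTEM_COMPOSITION = {
    "sucrose": 12.475,
    "fructose": 0.441,
    "glucose": 0.514,
    "proline": 0.45e-3,
    "histidine": 1.03e-3,
    "lysine": 0.56e-3,
}

#: Juice protein timecourse during evaporation, mg/g DS.
PROTEIN_TIMECOURSE = {
    "times_min": (0.0, 10.0, 20.0, 25.0, 30.0),
    "values": (1.3190, 1.2450, 1.0320, 0.8910, 0.8130),
}

#: Free amino acids in the juice at t = 0, mg/g DS, grouped by class.
AMINO_ACID_GROUPS_T0 = {
    "alkaline": 0.1533,            # Lys + His + Arg
    "acidic": (0.4827, 3.0179),    # Asp, Glu
    "neutral": 1.2305,             # thirteen neutral amino acids
}

#: Juice endpoint concentrations used in consumption/increase summaries.
JUICE_ENDPOINTS = {
    "glucose": {"start": 0.0343, "end": 0.0212, "unit": "g/g DS"},
    "fructose_consumption_pct": 54.42,
    "protein": {"start": 1.3190, "end": 0.8130, "unit": "mg/g DS"},
    "5-HMF": {"start": 1.367, "end": 5.485, "unit": "ug/g DS"},
}

#: Simple-order rate constants (h^-1) for the CIELAB color coordinates of
#: the model system, keyed indicator -> order -> (k60, k70, k80, k90).
COLOR_RATE_CONSTANTS = {
    "L*": {
        0: (-1.5060, -1.6950, -1.8702, -2.9322),
        1: (-0.0415, -0.0467, -0.0515, -0.0816),
        2: (0.0012, 0.0013, 0.0014, 0.0023),
    },
    "a*": {
        0: (0.4104, 0.4926, 0.5292, 0.5244),
    },
    "b*": {
        0: (0.8292, 1.4604, 1.4526, 1.5474),
        1: (0.8196, 1.2720, 1.2486, 1.3134),
        2: (-0.8214, -1.1406, -1.1070, -1.1514),
    },
    "dE*": {
        0: (1.7478, 2.3016, 2.3916, 3.3378),
    },
}

#: Reported activation energies (kJ/mol) for the color coordinates.
COLOR_ACTIVATION_ENERGIES = {
    "L*": 20.835, "a*": 8.199, "b*": 19.056, "dE*": 19.867,
}

#: Simple-order rate constants (h^-1) for the key reaction products of the
#: model system, keyed response -> order -> (k60, k70, k80, k90).
PRODUCT_RATE_CONSTANTS = {
    "GO": {
        0: (0.1476, 0.1644, 0.1770, 0.2106),
        1: (5.1860, 5.3688, 5.5398, 5.9041),
        2: (-293.1504, -293.4474, -297.0744, -300.5466),
    },
    "MGO": {
        0: (0.5694, 0.6654, 0.7308, 0.9624),
        1: (7.1154, 7.1286, 7.4682, 7.8924),
        2: (-186.4026, -173.9076, -179.5134, -176.8578),
    },
    "3-DG": {
        0: (11.5734, 13.4322, 18.7362, 24.4548),
        1: (10.9242, 10.5924, 11.1780, 11.4942),
        2: (-71.6022, -70.4520, -70.4040, -70.3302),
    },
    "5-HMF": {
        0: (0.1158, 0.1794, 0.1908, 0.2088),
        1: (5.0670, 6.0372, 6.1572, 6.3372),
        2: (-350.2164, -362.4492, -362.5248, -363.7416),
    },
    "CML": {
        0: (0.0612, 0.0642, 0.0708, 0.0744),
        1: (7.9032, 7.8348, 7.7832, 7.8954),
        2: (-2692.6134, -2622.9192, -2557.2288, -2559.3384),
    },
    "CEL": {
        0: (0.0542, 0.0593, 0.0678, 0.0750),
        1: (7.9440, 8.0424, 8.1606, 8.4744),
        2: (-3124.0776, -3073.7130, -3022.2282, -3057.0618),
    },
    "melanoidins": {
        0: (69.5022, 116.7768, 124.6932, 141.6066),
        1: (4.1634, 4.9932, 5.0064, 5.2716),
        2: (-0.3510, -0.3594, -0.3552, -0.3595),
    },
}

#: Reported activation energies (kJ/mol) for the reaction products, derived
#: from the zero-order rate-constant columns above.
PRODUCT_ACTIVATION_ENERGIES = {
    "GO": 11.464, "MGO": 16.656, "3-DG": 25.691,
    "5-HMF": 18.836, "CML": 6.972, "CEL": 11.136,
    # melanoidins reported inconsistently (22.276 in the text, 22.353 in the
    # table); recomputation from the printed k gives ~22.38
    "melanoidins": 22.276,
}

#: Multi-response network rate constants (h^-1), keyed temperature ->
#: parameter, with the reported 95% interval half-width and the
#: indeterminacy flag (True where the interval could not pin the value).
NETWORK_RATE_CONSTANTS = {
    60.0: {
        "k1": (0.0000, None, True),
        "k2": (0.0031, 0.0634, False),
        "k3": (0.0385, 0.0915, False),
        "k4": (0.0001, None, True),
        "k5": (0.0548, 0.0880, False),
        "k6": (0.0445, 0.0375, False),
        "k7": (0.0100, 0.0001, False),
        "k8": (38991.0, 37170.0, False),
        "k9": (0.2808, 0.1528, False),
        "k10": (46.4663, 29.7000, False),
        "k11": (0.0079, 0.0017, False),
        "k12": (0.0100, 0.0001, False),
        "k13": (114.1332, 87.4500, False),
        "k14": (0.0050, 0.0297, False),
        "k15": (31945.0, 26290.0, False),
    },
    70.0: {
        "k1": (0.0000, None, True),
        "k2": (0.0000, None, True),
        "k3": (0.0352, 0.0112, False),
        "k4": (0.0001, None, True),
        "k5": (0.0377, 0.0382, False),
        "k6": (0.0343, 0.0196, False),
        "k7": (0.0100, 0.0001, False),
        "k8": (20453.0, 10810.0, False),
        "k9": (0.2330, 0.1109, False),
        "k10": (46.6424, 21.4401, False),
        "k11": (0.0073, 0.0012, False),
        "k12": (0.0100, 0.0010, False),
        "k13": (147.5678, 80.5500, False),
        "k14": (0.0000, 0.0001, False),
        "k15": (23069.0, 12100.0, False),
    },
    80.0: {
        "k1": (0.0087, 0.0070, False),
        "k2": (0.0000, None, True),
        "k3": (1.8862, 0.4520, False),
        "k4": (0.0001, None, True),
        "k5": (0.6368, 0.5970, False),
        "k6": (0.5366, 0.3574, False),
        "k7": (0.0149, 0.0149, False),
        "k8": (27521.0, 21480.0, False),
        "k9": (0.2180, 0.1239, False),
        "k10": (51.9015, 29.9000, False),
        "k11": (0.0065, 0.0036, False),
        "k12": (0.0010, 0.0010, False),
        "k13": (167.6380, 116.4000, False),
        "k14": (0.0043, 0.0020, False),
        "k15": (31232.0, 24990.0, False),
    },
    90.0: {
        "k1": (0.0000, None, True),
        "k2": (0.0246, 0.0736, False),
        "k3": (0.0732, 0.0736, False),
        "k4": (0.0001, None, True),
        "k5": (0.0587, 0.0707, False),
        "k6": (0.0506, 0.0252, False),
        "k7": (0.0100, 0.0001, False),
        "k8": (28918.0, 22910.0, False),
        "k9": (0.2940, 0.2006, False),
        "k10": (56.3724, 35.2000, False),
        "k11": (0.0069, 0.0021, False),
        "k12": (0.0010, 0.0010, False),
        "k13": (172.7986, 120.0400, False),
        "k14": (0.0000, 0.0000, False),
        "k15": (28874.0, 19900.0, False),
    },
}


def network_k_values(temperature: float) -> dict[str, float]:
    """Point estimates of k1..k15 at one of the study temperatures."""
    try:
        table = NETWORK_RATE_CONSTANTS[float(temperature)]
    except KeyError:
        raise KeyError(
            f"no published constants at {temperature} C; "
            f"available: {sorted(NETWORK_RATE_CONSTANTS)}"
        ) from None
    return {name: est for name, (est, _, _) in table.items()}
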