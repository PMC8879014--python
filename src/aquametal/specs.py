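"""Calibration constants for the synthetic water-sample generator.

Each (season, water type) campaign is described by per-variable summary
statistics (min / max / mean over 80 augmented sampling sites), the pairs of
variables with a reported positive monotone association, and a smooth default
response surface mapping the four in-situ physicochemical parameters
(temperature, pH, electrical conductivity, total dissolved solids) to a
latent score for each of the eight metals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


FEATURES = ("temp", "ph", "ec", "tds")
METALS = ("cr", "cd", "fe", "mn", "zn", "ni", "pb", "cu")

UNITS = {
    "temp": "degC",
    "ph": "pH units",
    "ec": "uS/cm",
    "tds": "mg/L",
    **{m: "mg/L" for m in METALS},
}

SEASONS = ("dry", "wet")
WATER_TYPES = ("surface", "ground")

#: CSV column names in on-disk order.
CSV_COLUMNS = (
    "site_id", "season", "water_type",
    "temp_c", "ph", "ec_us_cm", "tds_mg_l",
    "cr_mg_l", "cd_mg_l", "fe_mg_l", "mn_mg_l",
    "zn_mg_l", "ni_mg_l", "pb_mg_l", "cu_mg_l",
)

VARIABLE_TO_CSV = {
    "temp": "temp_c", "ph": "ph", "ec": "ec_us_cm", "tds": "tds_mg_l",
    "cr": "cr_mg_l", "cd": "cd_mg_l", "fe": "fe_mg_l", "mn": "mn_mg_l",
    "zn": "zn_mg_l", "ni": "ni_mg_l", "pb": "pb_mg_l", "cu": "cu_mg_l",
}


@dataclass(frozen=True)
class VariableSpec:
    """Marginal summary of one variable on its natural scale."""

    name: str
    units: str
    role: str              # "feature" | "target"
    vmin: float
    vmax: float
    mean: float
    n_reference: int = 80

    def __post_init__(self) -> None:
        if self.role not in ("feature", "target"):
            raise ValueError(f"role must be feature/target, got {self.role!r}")
        if not self.vmin < self.vmax:
            raise ValueError(f"{self.name}: min must be < max")
        if not self.vmin <= self.mean <= self.vmax:
            raise ValueError(f"{self.name}: mean outside [min, max]")
        if self.n_reference <= 0:
            raise ValueError("n_reference must be positive")

    @property
    def mean_fraction(self) -> float:
        """Mean position within [vmin, vmax], in (0, 1)."""
        return (self.mean - self.vmin) / (self.vmax - self.vmin)


# (min, max, mean) per variable for each campaign; N = 80 sites each.
_DRY_SURFACE = {
    "temp": (26.0, 36.4, 30.58),
    "ph": (2.9, 9.4, 6.28),
    "ec": (130.0, 6000.0, 2617.21),
    "tds": (60.0, 3000.0, 1377.66),
    "cr": (0.00029, 0.03766, 0.01820),
    "cd": (0.00706, 0.06122, 0.04315),
    "fe": (0.45237, 2.76195, 2.32390),
    "mn": (0.00049, 11.09783, 2.07269),
    "zn": (0.00047, 9.58050, 1.69057),
    "ni": (0.00413, 0.12689, 0.10156),
    "pb": (0.00339, 0.05608, 0.03851),
    "cu": (0.02763, 17.16567, 7.67426),
}

_WET_SURFACE = {
    "temp": (26.7, 33.7, 30.26),
    "ph": (3.1, 8.4, 5.94),
    "ec": (90.0, 5380.0, 2211.00),
    "tds": (40.0, 2670.0, 1142.35),
    "cr": (0.00023, 0.03766, 0.02937),
    "cd": (0.00040, 0.06122, 0.04459),
    "fe": (0.06915, 53.01624, 21.74808),
    "mn": (0.00361, 0.01769, 0.01027),
    "zn": (0.02480, 0.07430, 0.03922),
    "ni": (0.00415, 0.12689, 0.08820),
    "pb": (0.00680, 0.05607, 0.03458),
    "cu": (0.00690, 0.20730, 0.09144),
}

_DRY_GROUND = {
    "temp": (26.3, 49.6, 37.72),
    "ph": (6.1, 7.9, 7.01),
    "ec": (80.0, 2350.0, 1140.45),
    "tds": (30.0, 1150.0, 499.12),
    "cr": (0.01733, 0.17182, 0.07527),
    "cd": (0.00055, 0.10389, 0.06879),
    "fe": (0.00038, 54.68567, 11.50116),
    "mn": (0.00009, 8.71857, 2.44137),
    "zn": (0.00098, 56.96133, 13.95211),
    "ni": (0.00013, 0.12530, 0.08955),
    "pb": (0.01560, 0.12178, 0.10676),
    "cu": (0.03711, 0.26050, 0.21542),
}

_WET_GROUND = {
    "temp": (26.2, 36.7, 30.25),
    "ph": (5.6, 7.9, 6.85),
    "ec": (20.0, 2840.0, 1185.05),
    "tds": (10.0, 1400.0, 601.20),
    "cr": (0.01638, 0.17179, 0.14767),
    "cd": (0.00055, 0.10389, 0.04458),
    "fe": (0.16390, 13.58610, 9.82432),
    "mn": (0.00405, 0.14579, 0.04089),
    "zn": (0.02480, 0.51992, 0.26563),
    "ni": (0.00101, 0.12490, 0.10005),
    "pb": (0.05496, 0.12178, 0.11831),
    "cu": (0.00690, 0.02759, 0.02257),
}

_TABLES = {
    ("dry", "surface"): _DRY_SURFACE,
    ("wet", "surface"): _WET_SURFACE,
    ("dry", "ground"): _DRY_GROUND,
    ("wet", "ground"): _WET_GROUND,
}

# Variable pairs with a reported positive monotone association.  EC-TDS is
# enforced directly in the feature copula; metal-metal pairs are realized
# through shared structure in the default response surfaces below.
POSITIVE_PAIRS = {
    "surface": [
        ("ec", "tds"), ("cr", "cd"), ("cu", "zn"),
        ("cd", "cu"), ("cd", "pb"), ("ni", "pb"),
    ],
    "ground": [
        ("ec", "tds"), ("cr", "cd"), ("cr", "ni"),
        ("cr", "pb"), ("cd", "ni"), ("cd", "pb"), ("fe", "zn"),
    ],
}

DEFAULT_PAIR_RHO = 0.6


@dataclass(frozen=True)
class ResponseSpec:
    """Smooth latent response of one metal to the standardized features.

    latent = sum_i coeffs[i] * tanh(z_i) + interaction_weight *
    tanh(z_p * z_q), where z is the vector of standardized features and
    (p, q) = interaction.  The latent score is later mapped monotonically
    onto the metal's marginal distribution, so only its ordering matters.
    """

    coeffs: tuple[float, float, float, float]
    interaction: tuple[int, int]
    interaction_weight: float


# Default response surfaces.  Metals reported as positively associated share
# closely aligned coefficient vectors so that their latent scores (and hence
# their rank correlations) co-vary; acid-mine-drainage chemistry motivates
# the negative pH loading for the dissolved-metal cluster.
DEFAULT_RESPONSES = {
    "surface": {
        "cr": ResponseSpec((0.40, -0.90, 0.60, 0.50), (1, 2), 0.30),
        "cd": ResponseSpec((0.50, -0.80, 0.60, 0.40), (0, 3), 0.30),
        "fe": ResponseSpec((0.30, 0.20, -0.70, 0.90), (2, 3), 0.40),
        "mn": ResponseSpec((-0.60, 0.90, 0.30, 0.20), (0, 1), 0.40),
        "zn": ResponseSpec((0.60, -0.70, 0.50, 0.50), (1, 3), 0.30),
        "ni": ResponseSpec((0.50, -0.75, 0.45, 0.55), (0, 2), 0.30),
        "pb": ResponseSpec((0.45, -0.80, 0.50, 0.50), (1, 2), 0.25),
        "cu": ResponseSpec((0.55, -0.75, 0.55, 0.45), (0, 1), 0.30),
    },
    "ground": {
        "cr": ResponseSpec((0.50, -0.80, 0.55, 0.50), (1, 2), 0.30),
        "cd": ResponseSpec((0.45, -0.85, 0.50, 0.55), (0, 3), 0.30),
        "fe": ResponseSpec((0.30, 0.40, 0.80, 0.60), (2, 3), 0.35),
        "mn": ResponseSpec((-0.70, 0.60, 0.30, 0.40), (0, 1), 0.40),
        "zn": ResponseSpec((0.35, 0.35, 0.75, 0.65), (2, 3), 0.30),
        "ni": ResponseSpec((0.55, -0.75, 0.50, 0.45), (0, 2), 0.30),
        "pb": ResponseSpec((0.50, -0.70, 0.60, 0.50), (1, 3), 0.25),
        "cu": ResponseSpec((0.20, 0.90, -0.40, 0.30), (0, 1), 0.35),
    },
}


def default_specs(season: str, water_type: str) -> list[VariableSpec]:
    """Return the 12 variable specs (4 features + 8 metals) for a campaign.

    Parameters
    ----------
    season : {"dry", "wet"}
    water_type : {"surface", "ground"}
    """
    key = (season, water_type)
    if key not in _TABLES:
        raise ValueError(
            f"unknown campaign {key!r}; season must be one of {SEASONS} "
            f"and water_type one of {WATER_TYPES}"
        )
    table = _TABLES[key]
    out = []
    for name in FEATURES + METALS:
        lo, hi, mean = table[name]
        role = "feature" if name in FEATURES else "target"
        out.append(VariableSpec(name, UNITS[name], role, lo, hi, mean))
    return out
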