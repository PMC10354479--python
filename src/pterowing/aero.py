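"""Body-mass scaling and an actuator-disc flight-performance model.

Body mass follows published wingspan scaling laws, with separate
equations for non-pterodactyloid pterosaurs and pterodactyloids under
two estimation approaches (Witton's and Henderson's):

    M = a * Z**b   (kg, Z in m)

The flight model is a self-contained Pennycuick-style actuator-disc
formulation.  Mechanical power at airspeed V is

    P(V) = P_ind + P_par + P_pro
    P_ind = k (M g)^2 / (2 rho V S_d),  S_d = pi Z^2 / 4   (induced)
    P_par = rho V^3 S_b C_Db / 2                           (parasite)
    P_pro = (X1 / AR) * P_am                               (profile)

where S_d is the actuator disc swept by the wings, S_b = 0.00813 M^0.666
is body frontal area, AR the wing aspect ratio, and P_am the absolute
minimum of induced + parasite power.  Profile power is held independent
of speed (the classic approximation), so the minimum-power speed has the
closed form V_mp = (A / 3B)^(1/4) with A = k (M g)^2 / (2 rho S_d) and
B = rho S_b C_Db / 2; a bounded numerical minimisation is used by the
public API and cross-checked against that closed form in tests.

Derived performance indices: total drag D = P(Vmp)/Vmp, flight
efficiency COT^-1 = Vmp M / P_BMR with basal metabolic power
P_BMR = 3.277 M^0.624, gliding sinking rate Vz = D Vmp / (M g), and
glide ratio Vmp / Vz (algebraically M g / D).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

G = 9.81  # m s^-2

MassMethod = Literal["witton", "henderson"]
MassGroup = Literal["pterodactyloid", "non_pterodactyloid"]

#: (method, group) -> (coefficient a in kg m^-b, exponent b)
MASS_EQUATIONS: dict[tuple[str, str], tuple[float, float]] = {
    ("witton", "non_pterodactyloid"): (0.681, 2.807),
    ("witton", "pterodactyloid"): (0.519, 2.550),
    ("henderson", "non_pterodactyloid"): (0.3, 2.74),
    ("henderson", "pterodactyloid"): (0.315, 2.56),
}

#: Taxonomic group of each studied taxon.
TAXON_GROUP: dict[str, MassGroup] = {
    "Rhamphorhynchus": "non_pterodactyloid",
    "anurognathids": "non_pterodactyloid",
    "Pterodactylus": "pterodactyloid",
    "Sinopterus": "pterodactyloid",
    "Pteranodon": "pterodactyloid",
}


class AeroError(ValueError):
    pass


@dataclass(frozen=True)
class MassModel:
    method: MassMethod
    group: MassGroup

    @property
    def coefficients(self) -> tuple[float, float]:
        return MASS_EQUATIONS[(self.method, self.group)]


@dataclass(frozen=True)
class AeroConfig:
    """Tunable constants of the actuator-disc model (SI units)."""

    rho: float = 1.225           # air density, kg m^-3
    k: float = 1.2               # induced-power factor
    C_Db: float = 0.1            # body drag coefficient
    body_area_coeff: float = 0.00813   # S_b = coeff * M^exponent, m^2
    body_area_exponent: float = 0.666
    X1: float = 8.4              # profile-power ratio, divided by AR
    bmr_coeff: float = 3.277     # P_BMR = coeff * M^exponent, J s^-1
    bmr_exponent: float = 0.624

    def __post_init__(self) -> None:
        if min(self.rho, self.k, self.C_Db, self.body_area_coeff, self.X1) <= 0:
            raise AeroError("aerodynamic constants must be positive")

    def body_frontal_area(self, M: float) -> float:
        return self.body_area_coeff * M**self.body_area_exponent

    def basal_metabolic_power(self, M: float) -> float:
        return self.bmr_coeff * M**self.bmr_exponent


@dataclass(frozen=True)
class FlightPerformance:
    """Flight-performance summary at one wingspan."""

    wingspan_m: float
    mass_kg: float
    wing_loading: float      # kg m^-2
    Vmp: float               # m s^-1
    drag: float              # N
    P_mech: float            # W, mechanical power at Vmp
    P_bmr: float             # J s^-1
    cot_inv: float           # kg m J^-1
    sinking_rate: float      # m s^-1
    glide_ratio: float


def body_mass(Z: float, model: MassModel) -> float:
    """Body mass (kg) from wingspan (m) under a scaling model."""
    if Z <= 0:
        raise AeroError("wingspan must be positive")
    a, b = model.coefficients
    return a * Z**b


def wing_loading(M: float, wing_area: float) -> float:
    """Wing loading M / S in kg m^-2."""
    if M <= 0 or wing_area <= 0:
        raise AeroError("mass and wing area must be positive")
    return M / wing_area


def _power_terms(
    M: float, Z: float, wing_area: float, cfg: AeroConfig
) -> tuple[float, float, float]:
    """(A, B, P_pro): P(V) = A/V + B V^3 + P_pro."""
    if min(M, Z, wing_area) <= 0:
        raise AeroError("mass, wingspan and wing area must be positive")
    S_d = np.pi * Z**2 / 4.0
    A = cfg.k * (M * G) ** 2 / (2.0 * cfg.rho * S_d)
    B = 0.5 * cfg.rho * cfg.body_frontal_area(M) * cfg.C_Db
    V_am = (A / (3.0 * B)) ** 0.25
    P_am = A / V_am + B * V_am**3
    AR = Z**2 / wing_area
    P_pro = (cfg.X1 / AR) * P_am
    return A, B, P_pro


def power_curve(
    M: float, Z: float, wing_area: float, V: float | np.ndarray,
    cfg: AeroConfig | None = None,
) -> float | np.ndarray:
    """Total mechanical power (W) at airspeed V (m s^-1)."""
    cfg = cfg or AeroConfig()
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise AeroError("airspeed must be positive")
    A, B, P_pro = _power_terms(M, Z, wing_area, cfg)
    P = A / V + B * V**3 + P_pro
    return float(P) if P.ndim == 0 else P


def minimum_power_speed(
    M: float, Z: float, wing_area: float, cfg: AeroConfig | None = None,
    bounds: tuple[float, float] = (0.1, 200.0),
) -> float:
    """Airspeed minimising P(V), by bounded scalar minimisation."""
    cfg = cfg or AeroConfig()
    A, B, P_pro = _power_terms(M, Z, wing_area, cfg)
    res = minimize_scalar(
        lambda v: A / v + B * v**3 + P_pro,
        bounds=bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    v = float(res.x)
    if v - bounds[0] < 1e-3 or bounds[1] - v < 1e-3:
        raise AeroError(
            f"minimum-power speed {v:.3f} at the search bound; "
            "configuration unphysical"
        )
    return v


def flight_indices(
    M: float, Z: float, wing_area: float, cfg: AeroConfig | None = None,
) -> FlightPerformance:
    """All flight-performance indices at one wingspan."""
    cfg = cfg or AeroConfig()
    vmp = minimum_power_speed(M, Z, wing_area, cfg)
    P = power_curve(M, Z, wing_area, vmp, cfg)
    D = P / vmp
    P_bmr = cfg.basal_metabolic_power(M)
    cot_inv = vmp * M / P_bmr
    Vz = D * vmp / (M * G)
    return FlightPerformance(
        wingspan_m=Z,
        mass_kg=M,
        wing_loading=wing_loading(M, wing_area),
        Vmp=vmp,
        drag=float(D),
        P_mech=float(P),
        P_bmr=float(P_bmr),
        cot_inv=float(cot_inv),
        sinking_rate=float(Vz),
        glide_ratio=float(vmp / Vz),
    )
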