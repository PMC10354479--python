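"""Power-law extrapolation of skeletal dimensions across a wingspan grid.

Given allometric coefficients, a skeletal element of length Y1 on a seed
specimen with wingspan Z1 extrapolates to wingspan Z2 as

    Y2 = Y1 * (Z2 / Z1) ** (b_y / b_z),

where b_y is the element's coefficient and b_z the wingspan coefficient
from the same multivariate fit.  Evaluation is done in log space, which
makes the operation an exact one-parameter group (extrapolating
Z1 -> Z2 -> Z3 equals Z1 -> Z3).

The three trunk offsets that anchor the wing outline — L1 (humeral head
to body midline), L2 (femoral head to midline) and L3 (shoulder-to-hip
distance along the midline) — are extrapolated isometrically
(b_y = b_z), i.e. proportionally to wingspan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .specimens import FORELIMB_ELEMENTS, compute_wingspan

#: Default wingspan grid endpoints and step (m).
GRID_MIN_M = 0.3
GRID_MAX_M = 7.0
GRID_STEP_M = 0.1

TRUNK_OFFSETS = ("L1", "L2", "L3")


class ExtrapolationError(ValueError):
    pass


@dataclass(frozen=True)
class SeedSpecimen:
    """The measured specimen anchoring a taxon's growth series.

    All seven forelimb elements must be present so the seed wingspan is
    computable; trunk offsets are in mm.
    """

    specimen_id: str
    measurements: Mapping[str, float]
    L1: float
    L2: float
    L3: float

    def __post_init__(self) -> None:
        missing = [d for d in FORELIMB_ELEMENTS if d not in self.measurements]
        if missing:
            raise ExtrapolationError(
                f"seed specimen {self.specimen_id!r} missing forelimb "
                f"elements: {missing}"
            )
        for name in TRUNK_OFFSETS:
            if not getattr(self, name) > 0:
                raise ExtrapolationError(f"{name} must be positive")
        for d, v in self.measurements.items():
            if not v > 0:
                raise ExtrapolationError(f"non-positive seed measurement {d}")

    @property
    def wingspan_mm(self) -> float:
        return compute_wingspan(self.measurements)


@dataclass(frozen=True)
class GrowthSeries:
    """Extrapolated dimensions over a wingspan grid.

    ``grid_m`` is strictly increasing and includes the seed wingspan;
    ``dimensions`` maps dimension name to an array of lengths (mm)
    aligned with the grid; ``L1``/``L2``/``L3`` likewise (mm).
    """

    taxon: str
    grid_m: np.ndarray
    dimensions: Mapping[str, np.ndarray]
    L1: np.ndarray
    L2: np.ndarray
    L3: np.ndarray
    seed_wingspan_m: float

    def at(self, Z: float) -> dict[str, float]:
        """Dimensions (mm) plus trunk offsets at one grid wingspan."""
        i = int(np.argmin(np.abs(self.grid_m - Z)))
        if not np.isclose(self.grid_m[i], Z, rtol=0, atol=1e-9):
            raise ExtrapolationError(f"wingspan {Z} m is not on the grid")
        out = {d: float(v[i]) for d, v in self.dimensions.items()}
        out["L1"] = float(self.L1[i])
        out["L2"] = float(self.L2[i])
        out["L3"] = float(self.L3[i])
        return out

    def to_frame(self):
        """Long-format table (taxon, wingspan_m, dimension, length_mm)."""
        import pandas as pd

        records = []
        cols = dict(self.dimensions)
        cols.update(L1=self.L1, L2=self.L2, L3=self.L3)
        for name, vals in cols.items():
            for z, v in zip(self.grid_m, vals):
                records.append((self.taxon, float(z), name, float(v)))
        return pd.DataFrame(
            records, columns=["taxon", "wingspan_m", "dimension", "length_mm"]
        )


def extrapolate_dimension(
    Y1: float, Z1: float, Z2: float, b_y: float, b_z: float
) -> float:
    """Extrapolate one element from (Y1, Z1) to wingspan Z2 in log space."""
    if min(Y1, Z1, Z2) <= 0:
        raise ExtrapolationError("lengths and wingspans must be positive")
    if b_z == 0:
        raise ExtrapolationError("wingspan coefficient b_z must be nonzero")
    return float(np.exp(np.log(Y1) + (b_y / b_z) * (np.log(Z2) - np.log(Z1))))


def default_grid(seed_wingspan_m: float) -> np.ndarray:
    """0.3-7.0 m in 0.1 m steps, with the seed wingspan spliced in."""
    grid = np.round(
        np.arange(GRID_MIN_M, GRID_MAX_M + GRID_STEP_M / 2, GRID_STEP_M), 10
    )
    if not np.any(np.isclose(grid, seed_wingspan_m, rtol=0, atol=1e-9)):
        grid = np.sort(np.append(grid, seed_wingspan_m))
    return grid


def build_growth_series(
    seed: SeedSpecimen,
    ac: Mapping[str, float],
    grid_m: np.ndarray | None = None,
    taxon: str = "",
) -> GrowthSeries:
    """Extrapolate every seed dimension over a wingspan grid.

    ``ac`` must contain a coefficient for each seed dimension (a merged
    ``wp3_4`` coefficient covers both distal phalanges) and for
    ``wingspan``.  Trunk offsets always grow isometrically.
    """
    if "wingspan" not in ac:
        raise ExtrapolationError("allometry result lacks a wingspan coefficient")
    b_z = ac["wingspan"]
    Z1_m = seed.wingspan_mm / 1000.0
    grid = default_grid(Z1_m) if grid_m is None else np.asarray(grid_m, float)
    if np.any(np.diff(grid) <= 0):
        raise ExtrapolationError("wingspan grid must be strictly increasing")

    dims: dict[str, np.ndarray] = {}
    for d, y1 in seed.measurements.items():
        if d == "wingspan":
            continue
        if d in ac:
            b_y = ac[d]
        elif d in ("wp3", "wp4") and "wp3_4" in ac:
            b_y = ac["wp3_4"]
        else:
            raise ExtrapolationError(f"no allometric coefficient for {d!r}")
        dims[d] = np.array(
            [extrapolate_dimension(y1, Z1_m, z, b_y, b_z) for z in grid]
        )
    scale = grid / Z1_m  # isometric trunk growth
    return GrowthSeries(
        taxon=taxon or seed.specimen_id,
        grid_m=grid,
        dimensions=dims,
        L1=seed.L1 * scale,
        L2=seed.L2 * scale,
        L3=seed.L3 * scale,
        seed_wingspan_m=Z1_m,
    )


def seed_from_reference(
    taxon: str,
    reference: Mapping[str, float],
    specimen_id: str | None = None,
    trunk_fractions: tuple[float, float, float] = (0.050, 0.040, 0.175),
) -> SeedSpecimen:
    """Build a seed specimen from a preset's reference lengths.

    A deterministic, noise-free stand-in for the named seed specimens of
    the published series: measurements equal the preset reference
    lengths, and trunk offsets default to fixed fractions of the summed
    forelimb spar (L1 5%, L2 4%, L3 17.5%), approximated from published
    skeletal reconstructions.
    """
    meas = {k: v for k, v in reference.items() if k != "wingspan"}
    spar = sum(meas[d] for d in FORELIMB_ELEMENTS)
    f1, f2, f3 = trunk_fractions
    return SeedSpecimen(
        specimen_id=specimen_id or f"{taxon}_seed",
        measurements=meas,
        L1=f1 * spar,
        L2=f2 * spar,
        L3=f3 * spar,
    )
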