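"""Stomatal anatomical traits from leaf-impression measurements.

A nail-polish impression of each leaf surface yields stomatal counts over
fields of view of known area plus per-stoma guard-cell dimensions measured
under the microscope:

* SL  - stomatal (complex) length, um
* SCW - stomatal complex width (two guard + two subsidiary cells), um
* PL  - pore length, um
* GCW - guard-cell (pore) width, um

Grass stomatal pores open into a rectangle, so stomatal size and maximum
pore area are rectangular products (SS = SL x SCW, PAmax = PL x GCW).
Density times pore area gives the pore area available per unit leaf area
(SPALA), and the anatomical maximum stomatal conductance to water vapor
follows from molecular diffusion through a pore of depth l = GCW/2 with a
one-end end-correction:

    gsw_max = d * SD * PAmax / ( v * ( l + (pi/2) * sqrt(PAmax/pi) ) )

with d the diffusivity of water vapor in air and v the molar volume of
air.  The public API works in the field's customary units (mm-2, um,
um2, mol m-2 s-1); conversion to SI happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AggregationError, InputError, ValidationError

SURFACES = ("adaxial", "abaxial")


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the conductance equation (SI units).

    d: diffusivity of water vapor in air, m2 s-1 (25 C).
    v: molar volume of air, m3 mol-1 (25 C).
    fov_area: microscope field-of-view area, mm2.
    pi_truncated: use pi = 3.1415 instead of full float precision, for
        matching calculations done with the truncated constant.
    """

    d: float = 2.49e-5
    v: float = 0.0245
    fov_area: float = 0.59
    pi_truncated: bool = False

    @property
    def pi(self) -> float:
        return 3.1415 if self.pi_truncated else math.pi


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass
class ImpressionRecord:
    """Raw measurements from one impression (one plant x one surface)."""

    plant_id: str
    surface: str  # "adaxial" | "abaxial"
    counts: list[int]  # stomata per field of view
    SL: list[float]  # um, per measured stoma
    SCW: list[float]
    PL: list[float]
    GCW: list[float]
    fov_area: float = 0.59  # mm2

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValidationError(f"surface must be adaxial/abaxial, got {self.surface!r}")
        if any(c < 0 for c in self.counts):
            raise ValidationError("stomatal counts must be >= 0")
        n = len(self.SL)
        if not (n and n == len(self.SCW) == len(self.PL) == len(self.GCW)):
            raise ValidationError("dimension lists must be equal length and non-empty")
        for name in ("SL", "SCW", "PL", "GCW"):
            if any(x <= 0 for x in getattr(self, name)):
                raise ValidationError(f"{name} values must be > 0")
        if any(p > s for p, s in zip(self.PL, self.SL)):
            raise ValidationError("pore length PL cannot exceed stomatal length SL")
        if any(g > s for g, s in zip(self.GCW, self.SCW)):
            raise ValidationError("guard-cell width GCW cannot exceed complex width SCW")


@dataclass
class SurfaceTraits:
    """Derived traits for one leaf surface."""

    SD: float  # mm-2
    SS: float  # um2
    PAmax: float  # um2
    SPALA: float  # um2 mm-2
    gsw_max: float  # mol m-2 s-1


@dataclass
class AnatomicalTraits:
    """Per-surface traits plus the surface aggregates used downstream.

    Totals (SD_total, SPALA_total, g_total) are adaxial + abaxial sums;
    SS_mean and PAmax_mean are arithmetic means of the two surfaces.
    """

    adaxial: SurfaceTraits
    abaxial: SurfaceTraits
    SD_total: float = field(init=False)
    SPALA_total: float = field(init=False)
    g_total: float = field(init=False)
    SS_mean: float = field(init=False)
    PAmax_mean: float = field(init=False)

    def __post_init__(self) -> None:
        if self.adaxial is None or self.abaxial is None:
            raise AggregationError("both surfaces are required for aggregation")
        self.SD_total = self.adaxial.SD + self.abaxial.SD
        self.SPALA_total = self.adaxial.SPALA + self.abaxial.SPALA
        self.g_total = self.adaxial.gsw_max + self.abaxial.gsw_max
        self.SS_mean = 0.5 * (self.adaxial.SS + self.abaxial.SS)
        self.PAmax_mean = 0.5 * (self.adaxial.PAmax + self.abaxial.PAmax)


def stomatal_density(counts: Sequence[int], fov_area: float = 0.59) -> float:
    """Stomatal density (mm-2): mean count per field of view / FOV area."""
    if len(counts) == 0:
        raise InputError("counts must be non-empty")
    if fov_area <= 0:
        raise InputError("fov_area must be > 0")
    return float(np.mean(counts)) / fov_area


def _mean_of_products(a: Sequence[float], b: Sequence[float], name: str) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise InputError(f"{name}: inputs must be equal-length and non-empty")
    if (a <= 0).any() or (b <= 0).any():
        raise InputError(f"{name}: inputs must be positive")
    return float(np.mean(a * b))


def stomatal_size(SL, SCW, *, product_of_means: bool = False) -> float:
    """Stomatal size SS = SL x SCW (um2), averaged over measured stomata.

    Default aggregation is mean of per-stoma products (the unbiased
    estimator of mean complex area); ``product_of_means`` multiplies the
    dimension means instead.
    """
    if product_of_means:
        return float(np.mean(np.asarray(SL, float)) * np.mean(np.asarray(SCW, float)))
    return _mean_of_products(np.atleast_1d(SL), np.atleast_1d(SCW), "stomatal_size")


def max_pore_area(PL, GCW, *, product_of_means: bool = False) -> float:
    """Maximum pore area PAmax = PL x GCW (um2), averaged over stomata."""
    if product_of_means:
        return float(np.mean(np.asarray(PL, float)) * np.mean(np.asarray(GCW, float)))
    return _mean_of_products(np.atleast_1d(PL), np.atleast_1d(GCW), "max_pore_area")


def spala(PAmax: float, SD: float) -> float:
    """Stomatal pore area per leaf area (um2 mm-2): PAmax x SD."""
    if PAmax < 0 or SD < 0:
        raise InputError("PAmax and SD must be non-negative")
    return PAmax * SD


def gsw_max_anatomical(
    SD: float,
    PAmax: float,
    GCW: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Anatomical maximum stomatal conductance to water vapor (mol m-2 s-1).

    Parameters are in customary units: SD in mm-2, PAmax in um2, GCW in
    um.  Pore depth is taken as half the guard-cell width.  Internally
    everything is converted to SI (SD x 1e6 -> m-2, PAmax x 1e-12 -> m2,
    l = GCW/2 x 1e-6 -> m).
    """
    if SD <= 0 or PAmax <= 0 or GCW <= 0:
        raise InputError("SD, PAmax and GCW must be positive")
    pi = constants.pi
    sd_si = SD * 1e6
    pa_si = PAmax * 1e-12
    l_si = 0.5 * GCW * 1e-6
    numerator = constants.d * sd_si * pa_si
    denominator = constants.v * (l_si + (pi / 2.0) * math.sqrt(pa_si / pi))
    return numerator / denominator


def derive_surface_traits(
    record: ImpressionRecord,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    *,
    product_of_means: bool = False,
) -> SurfaceTraits:
    """All per-surface traits from one impression record."""
    sd = stomatal_density(record.counts, record.fov_area)
    ss = stomatal_size(record.SL, record.SCW, product_of_means=product_of_means)
    pa = max_pore_area(record.PL, record.GCW, product_of_means=product_of_means)
    gcw_mean = float(np.mean(record.GCW))
    g = gsw_max_anatomical(sd, pa, gcw_mean, constants) if sd > 0 else 0.0
    return SurfaceTraits(SD=sd, SS=ss, PAmax=pa, SPALA=spala(pa, sd), gsw_max=g)


def combine_surfaces(adaxial: SurfaceTraits, abaxial: SurfaceTraits) -> AnatomicalTraits:
    """Aggregate the two leaf surfaces: sums for SD/SPALA/gsw_max, means
    for SS and PAmax.  Both surfaces must be present — there is no silent
    single-surface fallback."""
    if adaxial is None or abaxial is None:
        raise AggregationError("both adaxial and abaxial traits are required")
    return AnatomicalTraits(adaxial=adaxial, abaxial=abaxial)


def derive_plant_traits(
    records: Sequence[ImpressionRecord],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    *,
    product_of_means: bool = False,
) -> AnatomicalTraits:
    """Traits for one plant from its adaxial + abaxial impression records.

    Multiple records per surface are pooled by concatenating counts and
    dimension lists before derivation.
    """
    by_surface: dict[str, ImpressionRecord] = {}
    for surf in SURFACES:
        recs = [r for r in records if r.surface == surf]
        if not recs:
            raise AggregationError(f"no {surf} impression for plant")
        pooled = ImpressionRecord(
            plant_id=recs[0].plant_id,
            surface=surf,
            counts=[c for r in recs for c in r.counts],
            SL=[x for r in recs for x in r.SL],
            SCW=[x for r in recs for x in r.SCW],
            PL=[x for r in recs for x in r.PL],
            GCW=[x for r in recs for x in r.GCW],
            fov_area=recs[0].fov_area,
        )
        by_surface[surf] = pooled
    ad = derive_surface_traits(by_surface["adaxial"], constants,
                               product_of_means=product_of_means)
    ab = derive_surface_traits(by_surface["abaxial"], constants,
                               product_of_means=product_of_means)
    return combine_surfaces(ad, ab)
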