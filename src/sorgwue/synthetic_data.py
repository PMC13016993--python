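"""Synthetic sorghum diversity-panel generator.

Emulates the statistical structure of a field-phenotyped inbred diversity
panel (~360 accessions, 10 chromosomes) so that every analysis stage has
a ground-truth test bed:

* inbred genotypes (dosages in {0, 2}) with a uniform MAF spectrum and a
  3-SNP causal block on chromosome 1 whose alternative alleles lower
  stomatal density, assimilation and stomatal conductance while raising
  intrinsic water-use efficiency;
* plot-level field phenotypes with row/column spatial effects, batch
  weather covariates (AveT, AveH), accession random intercepts and
  residual noise;
* leaf-impression measurements with Poisson stomatal counts per field of
  view and lognormal guard-cell dimensions, negatively correlated with
  density, abaxial surfaces exceeding adaxial;
* Ball-Woodrow-Berry-generative light-response curves in which the slope
  m depends on haplotype class and water regime (classes 1-5 lose slope
  under water stress, classes 6-8 do not).

Everything is driven by one seed; the four sub-generators draw from
independent child streams so stages can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .anatomy import ImpressionRecord
from .io_formats import GasExchangeRecord, GenotypeMatrix, MarkerInfo, PhenotypeTable

#: PPFD schedule of the light-response protocol: acclimation at 1600
#: followed by stepwise descent; 11 levels per curve.
PPFD_LEVELS = (1600, 1500, 1400, 1200, 1000, 800, 600, 400, 200, 100, 50)

#: Focal 3-SNP block on chromosome 1 (positions in bp, ref/alt alleles).
CAUSAL_MARKERS = (
    ("S01_77550396", 77_550_396, "C", "T"),
    ("S01_78561058", 78_561_058, "C", "T"),
    ("S01_78619413", 78_619_413, "G", "A"),
)

#: Canonical haplotype-class ordering for the focal block: all-reference
#: (CCG) first, single-alternative classes, double, then all-alternative
#: (TTA) last.
FOCAL_HAPLOTYPE_ORDER = ("CCG", "CTG", "TCG", "CCA", "TTG", "CTA", "TCA", "TTA")

TRAITS = ("SD_total", "An", "gsw", "iWUE")


@dataclass
class TraitSpec:
    """Generative parameters for one field trait.

    ``causal_effect`` is the additive effect of one alternative-allele
    copy at each causal locus (so a homozygous-alt accession shifts by
    2 x causal_effect per locus).
    """

    mean: float
    causal_effect: float
    sigma2_accession: float
    sigma2_residual: float
    beta_avet: float  # per degree C deviation from 25 C
    beta_aveh: float  # per % RH deviation from 60 %
    sigma_row: float
    sigma_col: float


def _default_trait_specs() -> dict[str, TraitSpec]:
    return {
        # SD_total ~ 265 mm-2 (adaxial + abaxial); alt alleles reduce it
        "SD_total": TraitSpec(265.0, -6.0, 400.0, 225.0, 1.5, -0.3, 5.0, 5.0),
        "An": TraitSpec(32.0, -0.9, 6.25, 4.0, 0.4, -0.05, 0.8, 0.8),
        "gsw": TraitSpec(0.28, -0.012, 1.2e-3, 9e-4, 4e-3, -8e-4, 0.01, 0.01),
        "iWUE": TraitSpec(115.0, 4.0, 144.0, 100.0, -0.8, -0.2, 3.0, 3.0),
    }


@dataclass
class ImpressionParams:
    """Generative parameters for leaf-impression measurements."""

    fov_area: float = 0.59  # mm2
    n_fields: int = 2
    n_plants: int = 3
    n_stomata: int = 5  # stomata scored per impression
    abaxial_density_factor: float = 1.255  # abaxial / adaxial density ratio
    abaxial_dim_factors: tuple[float, float, float, float] = (1.094, 1.124, 1.089, 1.030)
    dim_means: tuple[float, float, float, float] = (35.0, 22.0, 17.0, 5.5)  # SL,SCW,PL,GCW um
    dim_cv: float = 0.08  # within-plant lognormal CV of dimensions
    density_size_corr: float = -0.3  # target corr(density, size) across accessions
    size_lognormal_sigma: float = 0.15  # accession-level size-multiplier scale
    plant_density_cv: float = 0.05


@dataclass
class BWBParams:
    """Haplotype-class x treatment parameters of the conductance model.

    ``m_ww``/``m_ws`` index by haplotype class 1..8.  Classes 1-5 are
    stomatal "spenders": high slope when well-watered, collapsing under
    water stress; classes 6-8 are conservative, slope unchanged across
    regimes.
    """

    m_ww: tuple[float, ...] = (6.5, 6.3, 6.1, 5.9, 5.7, 4.2, 4.0, 3.8)
    m_ws: tuple[float, ...] = (3.6, 3.5, 3.4, 3.3, 3.2, 4.2, 4.0, 3.8)
    g0_ww: float = 0.04  # mol m-2 s-1
    g0_ws: float = 0.03
    sigma_gsw: float = 0.02  # additive noise on gsw
    hs: float = 0.60  # leaf-surface RH fraction
    cs: float = 390.0  # leaf-surface CO2, umol mol-1
    gsw_floor: float = 0.005  # truncation of non-physical low/negative gsw


@dataclass
class LightCurveParams:
    """Non-rectangular-hyperbola light response (a standard stand-in for
    measured curves): An(Q) = [phi Q + Amax - sqrt((phi Q + Amax)^2 -
    4 theta phi Q Amax)] / (2 theta) - Rd."""

    phi: float = 0.06  # quantum yield, mol CO2 / mol photons
    theta: float = 0.7  # curvature, in (0, 1]
    amax_ww: float = 35.0  # umol m-2 s-1
    amax_ws: float = 18.0
    rd: float = 1.5  # dark respiration


@dataclass
class SimulationConfig:
    """Full generative specification of the synthetic panel."""

    n_accessions: int = 360
    n_markers: int = 5000
    n_chromosomes: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_rho: float = 0.4  # pairwise allele correlation within the block
    trait_specs: dict[str, TraitSpec] = field(default_factory=_default_trait_specs)
    n_reps: int = 3  # plots per accession (3 plants sampled per accession)
    n_rows: int | None = None  # field layout; None -> near-square auto
    n_cols: int | None = None
    batch_avet: tuple[float, ...] = (26.5, 27.8, 24.9, 22.3)  # deg C per batch
    batch_aveh: tuple[float, ...] = (62.0, 58.0, 66.0, 71.0)  # % RH per batch
    impressions: ImpressionParams = field(default_factory=ImpressionParams)
    bwb: BWBParams = field(default_factory=BWBParams)
    light_curve: LightCurveParams = field(default_factory=LightCurveParams)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.causal_rho < 1):
            raise ConfigError(f"causal_rho must be in [0, 1), got {self.causal_rho}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 < self.light_curve.theta <= 1):
            raise ConfigError(f"theta must be in (0, 1], got {self.light_curve.theta}")
        for name, ts in self.trait_specs.items():
            if ts.sigma2_accession < 0 or ts.sigma2_residual < 0:
                raise ConfigError(f"negative variance component for trait {name}")
        for name, sign in (("SD_total", -1), ("An", -1), ("gsw", -1), ("iWUE", +1)):
            ts = self.trait_specs.get(name)
            if ts is not None and ts.causal_effect * sign < 0:
                raise ConfigError(
                    f"causal effect direction for {name} must be "
                    f"{'positive' if sign > 0 else 'negative'}"
                )
        if len(self.bwb.m_ww) != 8 or len(self.bwb.m_ws) != 8:
            raise ConfigError("bwb slopes must be given for all 8 haplotype classes")

    # seeds for the four independent sub-generators
    def _child_rngs(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return [np.random.default_rng(c) for c in children]

    def rng_genotypes(self) -> np.random.Generator:
        return self._child_rngs()[0]

    def rng_field(self) -> np.random.Generator:
        return self._child_rngs()[1]

    def rng_impressions(self) -> np.random.Generator:
        return self._child_rngs()[2]

    def rng_gas_exchange(self) -> np.random.Generator:
        return self._child_rngs()[3]

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        if "trait_specs" in raw:
            raw["trait_specs"] = {
                k: TraitSpec(**v) if isinstance(v, Mapping) else v
                for k, v in raw["trait_specs"].items()
            }
        for key, typ in (("impressions", ImpressionParams), ("bwb", BWBParams),
                         ("light_curve", LightCurveParams)):
            if key in raw and isinstance(raw[key], Mapping):
                sub = dict(raw[key])
                for f_ in ("m_ww", "m_ws", "abaxial_dim_factors", "dim_means"):
                    if f_ in sub and isinstance(sub[f_], list):
                        sub[f_] = tuple(sub[f_])
                raw[key] = typ(**sub)
        for f_ in ("maf_range", "batch_avet", "batch_aveh"):
            if f_ in raw and isinstance(raw[f_], list):
                raw[f_] = tuple(raw[f_])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for downstream validation."""

    causal_marker_ids: tuple[str, ...]
    causal_effects: dict[str, float]  # per alt-allele copy, per locus
    haplotype_string: pd.Series  # accession -> e.g. "CCG"
    haplotype_class: pd.Series  # accession -> 1..8 (canonical order)
    causal_dosages: pd.DataFrame  # accession x causal marker id
    accession_values: dict[str, pd.Series] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Inbred-panel genotypes with the embedded 3-SNP causal block.

    Dosages are in {0, 2} (homozygous panel).  Alt-allele frequencies are
    uniform on ``maf_range``.  Within the causal block, alleles at the
    second and third locus copy the first with probability ``causal_rho``
    (else drawn fresh), inducing pairwise allele correlation ~rho between
    locus 1 and each of the others.
    """
    config.validate()
    rng = config.rng_genotypes()
    n = config.n_accessions
    bases = np.array(list("ACGT"))

    per_chrom = int(math.ceil(config.n_markers / config.n_chromosomes))
    markers: list[MarkerInfo] = []
    causal_cols: dict[str, int] = {}
    chrom_len = 80_000_000
    for c in range(1, config.n_chromosomes + 1):
        n_here = min(per_chrom, config.n_markers - len(markers))
        if n_here <= 0:
            break
        positions = set(
            rng.integers(1, chrom_len, size=n_here * 2).tolist()
        )
        if c == 1:
            for _, pos, _, _ in CAUSAL_MARKERS:
                positions.discard(pos)
        positions = sorted(positions)[:n_here]
        if c == 1:
            causal_pos = {pos for _, pos, _, _ in CAUSAL_MARKERS}
            positions = sorted(
                set(positions[: n_here - len(CAUSAL_MARKERS)]) | causal_pos
            )
        causal_by_pos = {pos: (mid, ref, alt) for mid, pos, ref, alt in CAUSAL_MARKERS}
        for pos in positions:
            if c == 1 and pos in causal_by_pos:
                mid, ref, alt = causal_by_pos[pos]
                causal_cols[mid] = len(markers)
            else:
                mid = f"S{c:02d}_{pos}"
                ref, alt = rng.choice(bases, size=2, replace=False)
            markers.append(MarkerInfo(mid, str(c), int(pos), str(ref), str(alt)))

    n_markers = len(markers)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_markers)
    alleles = (rng.random((n, n_markers)) < freqs).astype(np.int16)

    # causal block LD: loci 2 and 3 copy locus 1's allele with prob rho
    c1, c2, c3 = (causal_cols[mid] for mid, _, _, _ in CAUSAL_MARKERS)
    for cj in (c2, c3):
        copy_mask = rng.random(n) < config.causal_rho
        alleles[copy_mask, cj] = alleles[copy_mask, c1]

    dosages = 2 * alleles
    accession_ids = [f"ACC{i:04d}" for i in range(1, n + 1)]
    G = GenotypeMatrix(accession_ids, markers, dosages)

    causal_ids = tuple(mid for mid, _, _, _ in CAUSAL_MARKERS)
    cd = pd.DataFrame(
        dosages[:, [c1, c2, c3]], index=accession_ids, columns=list(causal_ids)
    )
    ref_alt = {mid: (ref, alt) for mid, _, ref, alt in CAUSAL_MARKERS}
    strings = cd.apply(
        lambda r: "".join(
            ref_alt[mid][1] if r[mid] == 2 else ref_alt[mid][0] for mid in causal_ids
        ),
        axis=1,
    )
    classes = strings.map({s: i + 1 for i, s in enumerate(FOCAL_HAPLOTYPE_ORDER)})
    truth = SimTruth(
        causal_marker_ids=causal_ids,
        causal_effects={t: ts.causal_effect for t, ts in config.trait_specs.items()},
        haplotype_string=strings,
        haplotype_class=classes.astype(int),
        causal_dosages=cd,
    )
    return G, truth


# ---------------------------------------------------------------------------
# field phenotypes
# ---------------------------------------------------------------------------

def simulate_field_phenotypes(
    G: GenotypeMatrix, truth: SimTruth, config: SimulationConfig
) -> tuple[PhenotypeTable, SimTruth]:
    """Plot-level phenotypes under the additive mixed-model structure.

    Per plot: trait = mean + row effect + column effect
    + beta_T (AveT - 25) + beta_H (AveH - 60) + genetic value + residual,
    where the genetic value is the causal-dosage contribution plus an
    accession random intercept.  Accessions are phenotyped in batches
    that determine their weather covariates.  Ground-truth accession
    values (mean + causal + random intercept) are stored on ``truth``.
    """
    config.validate()
    rng = config.rng_field()
    n_acc = G.n_accessions
    n_plots = n_acc * config.n_reps
    if config.n_rows is None or config.n_cols is None:
        n_rows = int(math.ceil(math.sqrt(n_plots)))
        n_cols = int(math.ceil(n_plots / n_rows))
    else:
        n_rows, n_cols = config.n_rows, config.n_cols
        if n_rows * n_cols < n_plots:
            raise ConfigError(
                f"field layout {n_rows}x{n_cols} too small for "
                f"{n_acc} accessions x {config.n_reps} plots"
            )

    # randomized plot assignment
    cells = [(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)]
    order = rng.permutation(len(cells))[:n_plots]
    plots = [cells[i] for i in order]
    acc_of_plot = np.repeat(np.arange(n_acc), config.n_reps)

    n_batches = len(config.batch_avet)
    batch_of_acc = np.arange(n_acc) % n_batches
    cd = truth.causal_dosages.to_numpy()  # (n_acc, 3)

    data = {
        "accession": [G.accession_ids[a] for a in acc_of_plot],
        "row": [plots[i][0] for i in range(n_plots)],
        "column": [plots[i][1] for i in range(n_plots)],
        "batch": [int(batch_of_acc[a]) + 1 for a in acc_of_plot],
        "AveT": [config.batch_avet[batch_of_acc[a]] for a in acc_of_plot],
        "AveH": [config.batch_aveh[batch_of_acc[a]] for a in acc_of_plot],
    }
    avet = np.asarray(data["AveT"]) - 25.0
    aveh = np.asarray(data["AveH"]) - 60.0

    for trait, ts in config.trait_specs.items():
        row_eff = rng.normal(0.0, ts.sigma_row, size=n_rows + 1)
        col_eff = rng.normal(0.0, ts.sigma_col, size=n_cols + 1)
        u = rng.normal(0.0, math.sqrt(ts.sigma2_accession), size=n_acc)
        genetic = ts.causal_effect * cd.sum(axis=1) + u
        acc_value = ts.mean + genetic
        eps = rng.normal(0.0, math.sqrt(ts.sigma2_residual), size=n_plots)
        values = (
            acc_value[acc_of_plot]
            + row_eff[[plots[i][0] for i in range(n_plots)]]
            + col_eff[[plots[i][1] for i in range(n_plots)]]
            + ts.beta_avet * avet
            + ts.beta_aveh * aveh
            + eps
        )
        data[trait] = values
        truth.accession_values[trait] = pd.Series(acc_value, index=G.accession_ids)

    df = pd.DataFrame(data)
    return PhenotypeTable(df, list(config.trait_specs)), truth


# ---------------------------------------------------------------------------
# leaf impressions
# ---------------------------------------------------------------------------

def simulate_impressions(
    accession_density_means: Mapping[str, float] | pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[ImpressionRecord]]:
    """Impression measurements per accession (``n_plants`` plants x 2 surfaces).

    ``accession_density_means`` gives the adaxial stomatal density mean
    (mm-2) per accession; abaxial densities exceed adaxial by the
    configured factor.  Counts per field of view are Poisson with mean
    density x FOV area; guard-cell dimensions are lognormal with an
    accession-level size multiplier negatively correlated with density.
    """
    p = config.impressions
    rng = rng if rng is not None else config.rng_impressions()
    dens = pd.Series(dict(accession_density_means), dtype=float)
    if (dens <= 0).any():
        raise ConfigError("accession density means must be positive")

    zd = (dens - dens.mean()) / (dens.std(ddof=0) or 1.0)
    r = p.density_size_corr
    latent = r * zd.to_numpy() + math.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(len(dens))
    size_mult = np.exp(p.size_lognormal_sigma * latent)

    sigma_dim = math.sqrt(math.log(1 + p.dim_cv**2))
    out: dict[str, list[ImpressionRecord]] = {}
    for k, (acc, d_ad) in enumerate(dens.items()):
        records: list[ImpressionRecord] = []
        for plant in range(1, p.n_plants + 1):
            plant_jitter = np.exp(rng.normal(0.0, p.plant_density_cv))
            for surface, dens_factor, dim_factors in (
                ("adaxial", 1.0, (1.0, 1.0, 1.0, 1.0)),
                ("abaxial", p.abaxial_density_factor, p.abaxial_dim_factors),
            ):
                lam = d_ad * dens_factor * plant_jitter * p.fov_area
                counts = rng.poisson(lam, size=p.n_fields).tolist()
                dims = []
                for mean_dim, f_ab in zip(p.dim_means, dim_factors):
                    mu = math.log(mean_dim * f_ab * size_mult[k]) - 0.5 * sigma_dim**2
                    dims.append(np.exp(rng.normal(mu, sigma_dim, size=p.n_stomata)))
                sl, scw, pl, gcw = dims
                pl = np.minimum(pl, sl)  # geometric constraint of the complex
                gcw = np.minimum(gcw, scw)
                records.append(
                    ImpressionRecord(
                        plant_id=f"{acc}_p{plant}", surface=surface,
                        counts=counts, SL=sl.tolist(), SCW=scw.tolist(),
                        PL=pl.tolist(), GCW=gcw.tolist(), fov_area=p.fov_area,
                    )
                )
        out[str(acc)] = records
    return out


# ---------------------------------------------------------------------------
# light-response curves
# ---------------------------------------------------------------------------

def light_response_an(q: float, amax: float, params: LightCurveParams) -> float:
    """Net assimilation at PPFD ``q`` from the non-rectangular hyperbola."""
    phi, theta, rd = params.phi, params.theta, params.rd
    s = phi * q + amax
    return (s - math.sqrt(s * s - 4.0 * theta * phi * q * amax)) / (2.0 * theta) - rd


def simulate_light_response(
    config: SimulationConfig,
    accession_id: str,
    treatment: str,
    replicate: int,
    haplotype_class: int,
    rng: np.random.Generator | None = None,
) -> list[GasExchangeRecord]:
    """One light-response curve: 11 records over the PPFD schedule.

    gsw is generated from the Ball-Woodrow-Berry relation
    gsw = m An Hs / Cs + g0 + noise, with (m, g0) set by the accession's
    haplotype class and water regime, and truncated below at the
    configured floor to avoid non-physical values.
    """
    config.validate()
    if treatment not in ("WW", "WS"):
        raise ConfigError(f"treatment must be WW or WS, got {treatment!r}")
    if not (1 <= haplotype_class <= 8):
        raise ConfigError(f"haplotype class must be 1..8, got {haplotype_class}")
    rng = rng if rng is not None else config.rng_gas_exchange()
    b, lc = config.bwb, config.light_curve
    if treatment == "WW":
        m, g0, amax = b.m_ww[haplotype_class - 1], b.g0_ww, lc.amax_ww
    else:
        m, g0, amax = b.m_ws[haplotype_class - 1], b.g0_ws, lc.amax_ws

    records = []
    for q in PPFD_LEVELS:
        an = light_response_an(q, amax, lc)
        gsw = m * an * b.hs / b.cs + g0
        if b.sigma_gsw > 0:
            gsw += rng.normal(0.0, b.sigma_gsw)
        gsw = max(gsw, b.gsw_floor)
        ci = max(b.cs - 1.6 * an / gsw, 1.0)
        records.append(
            GasExchangeRecord(
                accession_id=accession_id, treatment=treatment,
                replicate=replicate, ppfd=float(q), An=an, gsw=gsw,
                Ci=ci, Cs=b.cs, Hs=b.hs, Tleaf=28.0,
            )
        )
    return records


def simulate_gas_exchange_panel(
    config: SimulationConfig,
    panel: Mapping[str, int],
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> list[GasExchangeRecord]:
    """Curves for a growth-chamber panel: each accession (mapped to its
    haplotype class) measured under both regimes with ``n_replicates``
    biological replicates."""
    rng = rng if rng is not None else config.rng_gas_exchange()
    records: list[GasExchangeRecord] = []
    for acc, cls in panel.items():
        for treatment in ("WW", "WS"):
            for rep in range(1, n_replicates + 1):
                records.extend(
                    simulate_light_response(config, acc, treatment, rep, cls, rng=rng)
                )
    return records


def representative_panel(truth: SimTruth, max_per_class: int = 1) -> dict[str, int]:
    """Pick representative accessions, one (or more) per haplotype class
    present in the panel, for the growth-chamber experiment."""
    panel: dict[str, int] = {}
    for cls in range(1, 9):
        accs = truth.haplotype_class[truth.haplotype_class == cls].index[:max_per_class]
        for acc in accs:
            panel[str(acc)] = cls
    return panel
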