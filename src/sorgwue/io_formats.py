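"""Readers and writers for the external formats the pipeline touches.

Coordinates are 1-based inclusive everywhere (VCF/GFF3 convention).
Genotype dosages count alternative alleles per accession: 0 = homozygous
reference, 2 = homozygous alternative, 1 = heterozygous, ``MISSING`` (-1)
for uncalled genotypes.  Missingness is preserved in the matrix itself;
imputation happens only at scan time (see :mod:`sorgwue.gwas_scan`).
All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in a dosage matrix.
MISSING: int = -1

MANDATORY_PHENOTYPE_COLUMNS = ("accession", "row", "column", "AveT", "AveH")


def normalize_chromosome(name: str) -> str:
    """Strip a leading ``Chr``/``chr`` prefix and zero padding for matching.

    Original labels are preserved in the data model; this helper is used
    only when two chromosome namespaces must be compared.
    """
    s = str(name)
    s = re.sub(r"^[Cc]hr(omosome)?[_]?", "", s)
    s = s.lstrip("0") or "0"
    return s


@dataclass(frozen=True)
class MarkerInfo:
    """A biallelic SNP marker: identifier, location and alleles."""

    id: str
    chromosome: str
    position: int  # 1-based bp
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic markers with alt-allele dosages.

    ``dosages`` has shape (n_accessions, n_markers), integer values in
    {0, 1, 2, MISSING}.  Marker ids must be unique and positions strictly
    increasing within each chromosome.
    """

    accession_ids: list[str]
    markers: list[MarkerInfo]
    dosages: np.ndarray
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        n_acc, n_mark = len(self.accession_ids), len(self.markers)
        if self.dosages.shape != (n_acc, n_mark):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n_acc} accessions x {n_mark} markers"
            )
        if len(set(self.accession_ids)) != n_acc:
            raise ValidationError("accession ids are not unique")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != n_mark:
            dup = pd.Series(ids).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise ValidationError(f"duplicate marker ids: {dup[:5]}")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValidationError(f"invalid dosage values: {bad}")
        by_chrom: dict[str, int] = {}
        for m in self.markers:
            prev = by_chrom.get(m.chromosome)
            if prev is not None and m.position <= prev:
                raise ValidationError(
                    f"positions not strictly increasing on chromosome "
                    f"{m.chromosome} at {m.id}"
                )
            by_chrom[m.chromosome] = m.position

    # -- convenience accessors -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker id {marker_id!r} not in genotype matrix")

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker from non-missing dosages.

        f = mean(dosage)/2 over called genotypes; MAF = min(f, 1-f).
        Markers with no called genotypes get NaN.
        """
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            f = np.nanmean(d, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_markers(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            markers=[self.markers[i] for i in index],
            dosages=self.dosages[:, index].copy(),
            n_skipped_records=self.n_skipped_records,
        )


@dataclass
class GeneTable:
    """Annotated genes: id, chromosome, 1-based inclusive [start, end], strand."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start, end, strand

    COLUMNS = ("gene_id", "chromosome", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"gene table missing columns: {missing}")
        if len(self.table) and (self.table["end"] < self.table["start"]).any():
            bad = self.table.loc[self.table["end"] < self.table["start"], "gene_id"]
            raise ValidationError(f"gene end < start for: {bad.tolist()[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GasExchangeRecord:
    """One steady-state gas-exchange observation from a light-response curve.

    Units: ppfd in umol m-2 s-1; An in umol CO2 m-2 s-1; gsw in
    mol H2O m-2 s-1; Ci and Cs in umol mol-1; Hs a fraction in (0, 1];
    Tleaf in degrees C.
    """

    accession_id: str
    treatment: str  # "WW" or "WS"
    replicate: int
    ppfd: float
    An: float
    gsw: float
    Ci: float
    Cs: float
    Hs: float
    Tleaf: float

    def __post_init__(self) -> None:
        if self.treatment not in ("WW", "WS"):
            raise ValidationError(f"treatment must be WW or WS, got {self.treatment!r}")
        if self.gsw <= 0:
            raise ValidationError(f"gsw must be > 0, got {self.gsw}")
        if self.Cs <= 0:
            raise ValidationError(f"Cs must be > 0, got {self.Cs}")
        if not (0 < self.Hs <= 1):
            raise ValidationError(
                f"Hs must be a fraction in (0, 1], got {self.Hs}; "
                "percent RH should be divided by 100 at read time"
            )
        if self.ppfd < 0:
            raise ValidationError(f"ppfd must be >= 0, got {self.ppfd}")


@dataclass
class PhenotypeTable:
    """Plot-level phenotype records with design covariates.

    ``data`` carries one row per plot with the mandatory design columns
    (accession, row, column, AveT, AveH) plus one column per trait.
    Missing trait cells are allowed and exposed via :meth:`missing_mask`.
    """

    data: pd.DataFrame
    trait_columns: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"phenotype table missing mandatory columns: {missing}")
        if not self.trait_columns:
            raise SchemaError("phenotype table has no trait columns")

    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.trait_columns].isna()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_lite(path: str | Path) -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix` using GT fields only.

    Only biallelic SNP records are accepted; multi-allelic or non-SNP
    records are skipped and counted in ``n_skipped_records``.  ``./.``
    becomes the missing sentinel.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc

    markers: list[MarkerInfo] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        dos = np.empty(len(samples), dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            a0, a1 = gt[0], gt[1]
            dos[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        mid = var.ID or f"S{var.CHROM}_{var.POS}"
        markers.append(MarkerInfo(mid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        columns.append(dos)
    if skipped:
        logger.info("read_vcf_lite: skipped %d non-biallelic/non-SNP records", skipped)
    dosages = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), np.int16)
    )
    return GenotypeMatrix(samples, markers, dosages, n_skipped_records=skipped)


def write_vcf(G: GenotypeMatrix, path: str | Path, header_comment: str = "") -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2"]
    if header_comment:
        lines.append(f"##sorgwue={header_comment}")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(G.accession_ids)
    )
    for j, m in enumerate(G.markers):
        gts = "\t".join(gt_map[int(d)] for d in G.dosages[:, j])
        lines.append(
            f"{m.chromosome}\t{m.position}\t{m.id}\t{m.ref}\t{m.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Dosage CSV dialect (accessions x markers), for frictionless fixtures
# ---------------------------------------------------------------------------

_MARKER_ID_RE = re.compile(r"^S(\d+)_(\d+)$")


def write_dosage_csv(G: GenotypeMatrix, path: str | Path, header_comment: str = "") -> None:
    """Write an accessions-x-markers dosage CSV (missing as empty cells).

    Marker metadata beyond the column id is not preserved; ids following
    the ``S<chrom>_<pos>`` convention round-trip chromosome and position.
    """
    path = Path(path)
    df = pd.DataFrame(
        G.dosages.astype(float), index=G.accession_ids, columns=G.marker_ids
    )
    df[G.dosages == MISSING] = np.nan
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index_label="accession", float_format="%g", lineterminator="\n")


def read_dosage_csv(path: str | Path) -> GenotypeMatrix:
    """Read the dosage CSV dialect written by :func:`write_dosage_csv`.

    Column names matching ``S<chrom>_<pos>`` supply chromosome/position;
    other ids are placed on chromosome "0" at their ordinal position.
    Ref/alt alleles are not represented in this dialect and default to A/T.
    """
    df = pd.read_csv(path, comment="#", index_col="accession")
    markers = []
    for k, col in enumerate(df.columns):
        m = _MARKER_ID_RE.match(col)
        if m:
            chrom = str(int(m.group(1)))
            pos = int(m.group(2))
        else:
            chrom, pos = "0", k + 1
        markers.append(MarkerInfo(col, chrom, pos, "A", "T"))
    dos = df.to_numpy(dtype=float)
    out = np.where(np.isnan(dos), MISSING, dos).astype(np.int16)
    return GenotypeMatrix([str(a) for a in df.index], markers, out)


# ---------------------------------------------------------------------------
# Phenotype CSV
# ---------------------------------------------------------------------------

def read_phenotype_csv(path: str | Path) -> PhenotypeTable:
    """Read a plot-level phenotype CSV into a :class:`PhenotypeTable`.

    The header must contain accession, row, column, AveT, AveH and at
    least one trait column; every non-design numeric column is treated as
    a trait.  Missing trait cells are retained as NaN.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"phenotype CSV {path} missing mandatory column(s): {missing}"
        )
    design = set(MANDATORY_PHENOTYPE_COLUMNS) | {"batch", "replicate"}
    traits = [c for c in df.columns if c not in design]
    traits = [c for c in traits if pd.api.types.is_numeric_dtype(df[c])]
    if not traits:
        raise SchemaError(f"phenotype CSV {path} contains no trait columns")
    n_missing = int(df[traits].isna().to_numpy().sum())
    if n_missing:
        logger.info("read_phenotype_csv: %d missing trait cells flagged", n_missing)
    return PhenotypeTable(df, traits)


def write_phenotype_csv(
    table: PhenotypeTable, path: str | Path, header_comment: str = ""
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.data.to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> GeneTable:
    """Extract ``gene`` features from a GFF3 file into a :class:`GeneTable`.

    1-based inclusive coordinates are preserved verbatim.  A gene lacking
    an ID attribute gets a synthesized ``<chrom>:<start>-<end>`` id with a
    logged warning.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True,
            merge_strategy="create_unique", id_spec=["ID"],
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    rows = []
    for f in db.features_of_type("gene"):
        gid_attr = f.attributes.get("ID")
        if gid_attr:
            gid = gid_attr[0]
        else:
            gid = f"{f.seqid}:{f.start}-{f.end}"
            logger.warning("gene without ID at %s; synthesized id %s", gid, gid)
        if f.end < f.start:
            raise ValidationError(f"gene {gid} has end < start")
        rows.append((gid, f.seqid, int(f.start), int(f.end), f.strand or "."))
    df = pd.DataFrame(rows, columns=list(GeneTable.COLUMNS))
    return GeneTable(df)


# ---------------------------------------------------------------------------
# Gas-exchange CSV
# ---------------------------------------------------------------------------

GAS_EXCHANGE_COLUMNS = (
    "accession_id", "treatment", "replicate", "ppfd",
    "An", "gsw", "Ci", "Cs", "Hs", "Tleaf",
)


def gas_exchange_to_frame(records: Iterable[GasExchangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(GAS_EXCHANGE_COLUMNS))


def read_gas_exchange_csv(path: str | Path) -> list[GasExchangeRecord]:
    """Read LI-6800-style light-response records.

    ``Hs`` given in percent (values > 1) is converted to a fraction at
    read time, matching instrument exports that log RH in %.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in GAS_EXCHANGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"gas-exchange CSV {path} missing columns: {missing}")
    if (df["Hs"] > 1).any():
        logger.info("read_gas_exchange_csv: Hs in percent; converting to fraction")
        df = df.assign(Hs=df["Hs"] / 100.0)
    return [
        GasExchangeRecord(
            accession_id=str(r.accession_id), treatment=str(r.treatment),
            replicate=int(r.replicate), ppfd=float(r.ppfd), An=float(r.An),
            gsw=float(r.gsw), Ci=float(r.Ci), Cs=float(r.Cs), Hs=float(r.Hs),
            Tleaf=float(r.Tleaf),
        )
        for r in df.itertuples(index=False)
    ]


def write_gas_exchange_csv(
    records: Iterable[GasExchangeRecord], path: str | Path, header_comment: str = ""
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        gas_exchange_to_frame(records).to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GWAS TSV
# ---------------------------------------------------------------------------

GWAS_TSV_COLUMNS = (
    "marker_id", "chromosome", "position", "maf",
    "beta", "se", "p", "neg_log10_p", "significant",
)


def write_gwas_tsv(result, path: str | Path) -> None:
    """Write a per-marker association table (one row per tested marker).

    Column order is fixed; floats carry 17 significant digits so that a
    write-read round trip is lossless.  The header comment records the
    scan's provenance, including the single-marker substitution notice.
    """
    path = Path(path)
    df = result.table.copy()
    df["neg_log10_p"] = -np.log10(np.clip(df["p"].to_numpy(), 1e-300, None))
    df["significant"] = df["p"] < result.threshold
    df = df[list(GWAS_TSV_COLUMNS)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# trait={result.trait} alpha={result.alpha} "
                 f"n_markers_tested={result.n_markers_tested} "
                 f"threshold={result.threshold:.17g} k_pcs={result.k_pcs}\n")
        fh.write("# method=single-marker OLS with PC covariates "
                 "(FarmCPU not reimplemented)\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g",
                  lineterminator="\n")


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in GWAS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"GWAS TSV {path} missing columns: {missing}")
    return df
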