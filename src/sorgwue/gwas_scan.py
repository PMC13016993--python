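"""Single-marker genome-wide association scan with PC covariates.

The scan regresses accession-level adjusted trait values on each marker's
alt-allele dosage with the leading genotype principal components as
population-structure covariates (OLS; two-sided p from the t distribution
with n - k - 2 df).  Markers are pre-filtered at a minor-allele-frequency
cutoff (default: MAF < 3% excluded), the genome-wide significance bar is
Bonferroni alpha / n_markers_tested, and candidate genes are pulled from
windows extending 75 kb up- and downstream of significant markers.

This is a deliberately transparent substitute for multi-stage scan
algorithms (FarmCPU and kin); kinship-aware mixed-model scanning is a
non-goal.  Missing dosages are mean-imputed per marker at scan time only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io_formats import GeneTable, GenotypeMatrix, MISSING, normalize_chromosome

logger = logging.getLogger(__name__)


@dataclass
class GWASResult:
    """Per-marker association statistics plus the significance threshold."""

    table: pd.DataFrame  # marker_id, chromosome, position, maf, beta, se, p
    n_markers_tested: int
    alpha: float
    threshold: float
    k_pcs: int
    trait: str
    n_accessions: int
    zero_variance_markers: list[str]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]


def maf_filter(G: GenotypeMatrix, cutoff: float = 0.03) -> GenotypeMatrix:
    """Drop markers with minor allele frequency strictly below ``cutoff``.

    MAF is computed from non-missing dosages (f = mean/2, MAF =
    min(f, 1-f)); a marker at exactly the cutoff is retained.
    """
    maf = G.maf()
    keep = np.where(~np.isnan(maf) & (maf >= cutoff))[0]
    if keep.size == 0:
        raise InputError(f"MAF filter at {cutoff} removed all {G.n_markers} markers")
    n_removed = G.n_markers - keep.size
    if n_removed:
        logger.info("maf_filter: removed %d of %d markers", n_removed, G.n_markers)
    return G.subset_markers(keep)


def _imputed_dosages(G: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-marker mean imputation of missing cells."""
    d = G.dosages.astype(float)
    miss = G.dosages == MISSING
    if miss.any():
        d[miss] = np.nan
        col_means = np.nanmean(d, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        idx = np.where(miss)
        d[idx] = col_means[idx[1]]
    return d


def genotype_pcs(
    G: GenotypeMatrix, k: int = 3, standardize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Leading principal-component scores of the dosage matrix.

    Missing dosages are mean-imputed, columns centered (and optionally
    scaled to unit variance), and scores taken from the SVD.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    Returns (scores, proportion of variance explained).
    """
    if k >= G.n_accessions:
        raise InputError(f"k={k} PCs require more than {G.n_accessions} accessions")
    X = _imputed_dosages(G)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(min(k, Vt.shape[0])):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * S[:k]
    total_var = float((S**2).sum())
    explained = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, explained


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    """Genome-wide significance bar alpha / n_markers."""
    if not (0 < alpha < 1):
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    if n_markers < 1:
        raise InputError(f"n_markers must be >= 1, got {n_markers}")
    return alpha / n_markers


def render_threshold_3sf(alpha: float, n_markers: int) -> str:
    """The threshold as printed at 3 significant figures, e.g. '2.13e-07'."""
    return f"{bonferroni_threshold(alpha, n_markers):.2e}"


def single_marker_scan(
    G: GenotypeMatrix,
    y: pd.Series,
    pcs: np.ndarray | None = None,
    alpha: float = 0.05,
    trait: str = "",
) -> GWASResult:
    """OLS scan of y on (intercept, PCs, dosage), one marker at a time.

    ``y`` is indexed by accession id; the scan runs on the intersection
    of phenotype and genotype accessions (in genotype order) and reports
    its size.  Computation residualizes y and all dosages against the
    covariates once (Frisch-Waugh), which is numerically identical to the
    per-marker joint OLS.  Zero-variance markers get beta = 0, p = 1 and
    are flagged rather than raising.
    """
    common = [a for a in G.accession_ids if a in y.index]
    if len(common) < 3:
        raise InputError("fewer than 3 accessions shared between genotypes and phenotypes")
    if len(common) < G.n_accessions:
        logger.info(
            "single_marker_scan: %d of %d accessions have phenotypes",
            len(common), G.n_accessions,
        )
        rows = [G.accession_ids.index(a) for a in common]
        D = _imputed_dosages(G)[rows]
        if pcs is not None:
            pcs = pcs[rows]
    else:
        D = _imputed_dosages(G)
    yv = y.loc[common].to_numpy(dtype=float)
    n = len(common)

    k = 0 if pcs is None else pcs.shape[1]
    X0 = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs])
    Q, _ = np.linalg.qr(X0)
    y_r = yv - Q @ (Q.T @ yv)
    D_r = D - Q @ (Q.T @ D)

    sxx = (D_r**2).sum(axis=0)
    zero_var = sxx < 1e-12
    sxx_safe = np.where(zero_var, 1.0, sxx)
    beta = (D_r.T @ y_r) / sxx_safe
    df = n - k - 2
    if df < 1:
        raise InputError(f"no residual degrees of freedom: n={n}, k={k}")
    syy = float(y_r @ y_r)
    rss = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    se = np.sqrt(rss / df / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta[zero_var] = 0.0
    se[zero_var] = np.nan
    p[zero_var] = 1.0
    flagged = [G.markers[j].id for j in np.where(zero_var)[0]]
    if flagged:
        logger.warning("single_marker_scan: %d zero-variance markers flagged", len(flagged))

    table = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "chromosome": [m.chromosome for m in G.markers],
            "position": [m.position for m in G.markers],
            "maf": G.maf(),
            "beta": beta,
            "se": se,
            "p": p,
        }
    )
    return GWASResult(
        table=table,
        n_markers_tested=G.n_markers,
        alpha=alpha,
        threshold=bonferroni_threshold(alpha, G.n_markers),
        k_pcs=k,
        trait=trait,
        n_accessions=n,
        zero_variance_markers=flagged,
    )


def candidate_window(
    genes: GeneTable,
    chromosome: str,
    position: int,
    half_width: int = 75_000,
) -> pd.DataFrame:
    """Genes overlapping [position - half_width, position + half_width].

    Overlap is inclusive at both boundaries (a gene touching the window
    edge counts).  Chromosome names are matched after normalization; an
    unknown chromosome yields an empty result with a warning, not an
    error.  Returned in position order, with the distance from the marker
    to the nearest gene edge (0 when the marker lies inside the gene).
    """
    lo, hi = position - half_width, position + half_width
    t = genes.table
    chrom_norm = t["chromosome"].map(normalize_chromosome)
    target = normalize_chromosome(chromosome)
    on_chrom = t[chrom_norm == target]
    if on_chrom.empty and (chrom_norm == target).sum() == 0 and len(t):
        if target not in set(chrom_norm):
            logger.warning("candidate_window: chromosome %r not in gene table", chromosome)
    hits = on_chrom[(on_chrom["end"] >= lo) & (on_chrom["start"] <= hi)].copy()
    hits["distance"] = np.maximum(
        0, np.maximum(hits["start"] - position, position - hits["end"])
    )
    return hits.sort_values("start").reset_index(drop=True)


def qq_table(pvalues: np.ndarray | pd.Series) -> pd.DataFrame:
    """Expected vs observed -log10(p) quantiles for a Q-Q diagnostic."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = len(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, None))
    return pd.DataFrame({"expected": expected, "observed": observed})
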