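"""MAF filtering, genotype PCA, the single-marker scan and gene windows."""

import numpy as np
import pandas as pd
import pytest

from sorgwue.errors import InputError
from sorgwue.gwas_scan import (
    bonferroni_threshold,
    candidate_window,
    genotype_pcs,
    maf_filter,
    qq_table,
    render_threshold_3sf,
    single_marker_scan,
)
from sorgwue.io_formats import GeneTable, MISSING

from conftest import make_genotypes


def dosage_matrix_with_freqs(freqs, n=100, seed=0):
    rng = np.random.default_rng(seed)
    return 2 * (rng.random((n, len(freqs))) < np.asarray(freqs)).astype(int)


class TestMafFilter:
    def test_strictly_below_cutoff_excluded(self):
        # column freqs: 0.02 (below), 0.03 (at cutoff -> retained)
        n = 100
        d = np.zeros((n, 2), dtype=int)
        d[:2, 0] = 2  # f = 0.02
        d[:3, 1] = 2  # f = 0.03
        G = make_genotypes(d)
        kept = maf_filter(G, cutoff=0.03)
        assert kept.marker_ids == ["M1"]

    def test_hand_counted_fixture(self):
        """10 markers, 3 with MAF below 3% -> 7 retained."""
        n = 200
        freqs = [0.01, 0.02, 0.025, 0.1, 0.2, 0.3, 0.4, 0.5, 0.15, 0.05]
        d = np.zeros((n, 10), dtype=int)
        for j, f in enumerate(freqs):
            d[: int(round(f * n)), j] = 2
        kept = maf_filter(make_genotypes(d), cutoff=0.03)
        assert kept.n_markers == 7

    def test_all_removed_is_error(self):
        d = np.zeros((100, 2), dtype=int)
        d[0, 0] = 2
        with pytest.raises(InputError, match="removed all"):
            maf_filter(make_genotypes(d), cutoff=0.1)


class TestGenotypePcs:
    def test_identical_accessions_get_identical_scores(self):
        rng = np.random.default_rng(1)
        d = 2 * rng.integers(0, 2, size=(20, 50))
        d[5] = d[3]
        scores, _ = genotype_pcs(make_genotypes(d), k=3)
        np.testing.assert_allclose(scores[5], scores[3], atol=1e-10)

    def test_variance_explained_non_increasing(self):
        d = dosage_matrix_with_freqs([0.3] * 40, n=60, seed=2)
        _, ev = genotype_pcs(make_genotypes(d), k=5)
        assert all(a >= b - 1e-12 for a, b in zip(ev, ev[1:]))

    def test_two_cluster_panel_separated_on_pc1(self):
        """Allele-frequency-differentiated clusters: PC1 AUC >= 0.95."""
        rng = np.random.default_rng(3)
        n_half, m = 60, 200
        f1 = rng.uniform(0.1, 0.3, size=m)
        f2 = np.clip(f1 + rng.uniform(0.2, 0.4, size=m), 0, 0.9)
        d = np.vstack(
            [
                2 * (rng.random((n_half, m)) < f1).astype(int),
                2 * (rng.random((n_half, m)) < f2).astype(int),
            ]
        )
        scores, _ = genotype_pcs(make_genotypes(d), k=3)
        pc1 = scores[:, 0]
        labels = np.array([0] * n_half + [1] * n_half)
        ranks = pd.Series(pc1).rank().to_numpy()
        auc = (ranks[labels == 1].sum() - n_half * (n_half + 1) / 2) / n_half**2
        assert max(auc, 1 - auc) >= 0.95

    def test_k_too_large_rejected(self):
        d = dosage_matrix_with_freqs([0.3] * 10, n=5)
        with pytest.raises(InputError):
            genotype_pcs(make_genotypes(d), k=5)


class TestSingleMarkerScan:
    def test_near_noiseless_effect_recovered(self):
        rng = np.random.default_rng(4)
        d = dosage_matrix_with_freqs([0.3] * 20, n=120, seed=4)
        G = make_genotypes(d)
        y = pd.Series(
            0.5 * d[:, 7] + rng.normal(0, 1e-6, size=120), index=G.accession_ids
        )
        res = single_marker_scan(G, y, pcs=None)
        row = res.table.iloc[7]
        assert row["beta"] == pytest.approx(0.5, abs=1e-5)
        assert row["p"] < 1e-10

    def test_missing_dosages_mean_imputed(self):
        d = dosage_matrix_with_freqs([0.4] * 5, n=80, seed=5)
        d[:10, 2] = MISSING
        G = make_genotypes(d)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=80), index=G.accession_ids)
        res = single_marker_scan(G, y, pcs=None)
        assert np.isfinite(res.table["p"]).all()

    def test_zero_variance_marker_flagged(self):
        d = dosage_matrix_with_freqs([0.3, 0.4], n=60, seed=6)
        d[:, 0] = 0
        G = make_genotypes(d)
        y = pd.Series(np.random.default_rng(6).normal(size=60), index=G.accession_ids)
        res = single_marker_scan(G, y, pcs=None)
        assert res.zero_variance_markers == ["M0"]
        assert res.table.loc[0, "p"] == 1.0
        assert res.table.loc[0, "beta"] == 0.0

    def test_pcs_are_near_noop_on_structure_free_panel(self):
        """Without population structure, PC adjustment leaves effect
        estimates essentially unchanged (betas agree closely)."""
        d = dosage_matrix_with_freqs([0.3] * 300, n=300, seed=7)
        G = make_genotypes(d)
        y = pd.Series(np.random.default_rng(7).normal(size=300), index=G.accession_ids)
        pcs, _ = genotype_pcs(G, k=3)
        b0 = single_marker_scan(G, y, pcs=None).table["beta"]
        b3 = single_marker_scan(G, y, pcs).table["beta"]
        assert np.corrcoef(b0, b3)[0, 1] > 0.99
        assert np.abs(b0 - b3).mean() < 0.2 * b0.std()

    def test_threshold_identity(self):
        d = dosage_matrix_with_freqs([0.3] * 10, n=50, seed=8)
        G = make_genotypes(d)
        y = pd.Series(np.random.default_rng(8).normal(size=50), index=G.accession_ids)
        res = single_marker_scan(G, y, pcs=None, alpha=0.05)
        assert res.threshold * res.n_markers_tested == pytest.approx(0.05, rel=1e-15)

    def test_scan_uses_accession_intersection(self):
        d = dosage_matrix_with_freqs([0.3] * 10, n=50, seed=9)
        G = make_genotypes(d)
        y = pd.Series(
            np.random.default_rng(9).normal(size=40), index=G.accession_ids[:40]
        )
        res = single_marker_scan(G, y, pcs=None)
        assert res.n_accessions == 40


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 1, 0.05), (0.05, 2000, 2.5e-5)],
    )
    def test_division(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-15)

    def test_panel_scale_rendering(self):
        assert render_threshold_3sf(0.05, 234_264) == "2.13e-07"

    def test_invalid_alpha(self):
        with pytest.raises(InputError):
            bonferroni_threshold(1.5, 100)


GENES = GeneTable(
    pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "chromosome": ["1", "1", "1", "1", "2"],
            "start": [100_000, 460_000, 560_000, 700_000, 480_000],
            "end": [110_000, 470_000, 580_000, 710_000, 490_000],
            "strand": ["+"] * 5,
        }
    )
)


class TestCandidateWindow:
    def test_touching_boundary_included(self):
        # marker at 500k, window [425k, 575k]: gene starting exactly at 575k counts
        genes = GeneTable(
            pd.DataFrame(
                {"gene_id": ["edge"], "chromosome": ["1"],
                 "start": [575_000], "end": [576_000], "strand": ["+"]}
            )
        )
        hits = candidate_window(genes, "1", 500_000, 75_000)
        assert hits["gene_id"].tolist() == ["edge"]

    def test_far_gene_excluded(self):
        genes = GeneTable(
            pd.DataFrame(
                {"gene_id": ["far"], "chromosome": ["1"],
                 "start": [580_000], "end": [590_000], "strand": ["+"]}
            )
        )
        assert candidate_window(genes, "1", 500_000, 75_000).empty

    def test_hand_checked_fixture_in_position_order(self):
        """5 genes, 2 inside the +/-75 kb window around 500 kb on chr 1."""
        hits = candidate_window(GENES, "1", 500_000, 75_000)
        assert hits["gene_id"].tolist() == ["g2", "g3"]
        assert hits["distance"].tolist() == [30_000, 60_000]

    def test_chromosome_normalization(self):
        hits = candidate_window(GENES, "Chr01", 500_000, 75_000)
        assert hits["gene_id"].tolist() == ["g2", "g3"]

    def test_unknown_chromosome_empty_not_error(self):
        assert candidate_window(GENES, "99", 500_000).empty


class TestQqTable:
    def test_uniform_null_tracks_diagonal(self):
        p = np.random.default_rng(10).uniform(size=5000)
        qq = qq_table(p)
        assert np.abs(qq["expected"] - qq["observed"]).median() < 0.05
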