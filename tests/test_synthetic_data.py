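"""Generator structure: inbred coding, causal-block LD, field model,
impressions and light-response curves."""

import numpy as np
import pytest

from sorgwue import anatomy
from sorgwue.errors import ConfigError
from sorgwue.synthetic_data import (
    CAUSAL_MARKERS,
    FOCAL_HAPLOTYPE_ORDER,
    PPFD_LEVELS,
    LightCurveParams,
    SimulationConfig,
    TraitSpec,
    light_response_an,
    simulate_field_phenotypes,
    simulate_genotypes,
    simulate_impressions,
    simulate_light_response,
)


def cfg(**kw):
    defaults = dict(n_accessions=360, n_markers=60, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenotypes:
    def test_inbred_coding(self):
        G, _ = simulate_genotypes(cfg(seed=1))
        assert set(np.unique(G.dosages)) <= {0, 2}

    def test_causal_markers_present_with_stated_alleles(self):
        G, truth = simulate_genotypes(cfg(seed=2))
        by_id = {m.id: m for m in G.markers}
        for mid, pos, ref, alt in CAUSAL_MARKERS:
            assert by_id[mid].position == pos
            assert (by_id[mid].ref, by_id[mid].alt) == (ref, alt)
            assert by_id[mid].chromosome == "1"

    def test_determinism_and_stream_independence(self):
        a, _ = simulate_genotypes(cfg(seed=5))
        b, _ = simulate_genotypes(cfg(seed=5))
        c, _ = simulate_genotypes(cfg(seed=6))
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_rho_zero_gives_uncorrelated_causal_alleles(self):
        """Monte-Carlo over 20 seeds: mean pairwise allele correlation ~0."""
        corrs = []
        for seed in range(20):
            _, truth = simulate_genotypes(cfg(seed=seed, causal_rho=0.0))
            d = truth.causal_dosages.to_numpy()
            corrs.append(np.corrcoef(d[:, 0], d[:, 1])[0, 1])
        assert abs(np.mean(corrs)) < 0.1

    def test_rho_induces_positive_ld(self):
        corrs = []
        for seed in range(20):
            _, truth = simulate_genotypes(cfg(seed=seed, causal_rho=0.6))
            d = truth.causal_dosages.to_numpy()
            corrs.append(np.corrcoef(d[:, 0], d[:, 1])[0, 1])
        assert np.mean(corrs) == pytest.approx(0.6, abs=0.1)

    def test_degenerate_maf_range_bounds_frequency(self):
        """maf_range (0.5, 0.5): empirical frequencies within binomial bounds."""
        for seed in range(20):
            G, _ = simulate_genotypes(cfg(seed=seed, maf_range=(0.5, 0.5)))
            f = G.dosages.mean(axis=0) / 2
            assert ((f >= 0.4) & (f <= 0.6)).all()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigError, match="rho"):
            simulate_genotypes(cfg(causal_rho=1.0))

    def test_haplotype_classes_consistent_with_dosages(self):
        _, truth = simulate_genotypes(cfg(seed=3))
        for acc in truth.haplotype_string.index[:20]:
            s = truth.haplotype_string[acc]
            assert truth.haplotype_class[acc] == FOCAL_HAPLOTYPE_ORDER.index(s) + 1


class TestFieldPhenotypes:
    def test_noiseless_limit_equals_accession_value(self):
        c = cfg(
            n_accessions=40,
            trait_specs={
                "An": TraitSpec(30.0, -0.9, 4.0, 0.0, 0.0, 0.0, 0.0, 0.0)
            },
        )
        G, truth = simulate_genotypes(c)
        pheno, truth = simulate_field_phenotypes(G, truth, c)
        vals = pheno.data.groupby("accession")["An"].agg(["min", "max"])
        truthv = truth.accession_values["An"]
        np.testing.assert_allclose(vals["min"], truthv[vals.index], rtol=1e-12)
        np.testing.assert_allclose(vals["max"], truthv[vals.index], rtol=1e-12)

    def test_row_effect_difference_when_noise_off(self):
        c = cfg(
            n_accessions=40,
            trait_specs={"An": TraitSpec(30.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0)},
        )
        G, truth = simulate_genotypes(c)
        pheno, _ = simulate_field_phenotypes(G, truth, c)
        df = pheno.data
        # two plots of the same accession differ only through their rows;
        # plots in the same row must agree exactly
        one_row = df[df["row"] == df["row"].iloc[0]]
        by_acc = one_row.groupby("accession")["An"].nunique()
        assert (by_acc == 1).all()

    def test_accession_variance_monotone_in_sigma2(self):
        spreads = []
        for s2 in (0.1, 1.0, 10.0):
            vars_ = []
            for seed in range(20):
                c = cfg(
                    n_accessions=60, seed=seed,
                    trait_specs={"An": TraitSpec(30.0, 0.0, s2, 0.5, 0.0, 0.0, 0.0, 0.0)},
                )
                G, truth = simulate_genotypes(c)
                pheno, _ = simulate_field_phenotypes(G, truth, c)
                vars_.append(pheno.data.groupby("accession")["An"].mean().var())
            spreads.append(np.mean(vars_))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_layout_too_small_rejected(self):
        c = cfg(n_accessions=40, n_rows=5, n_cols=5)
        G, truth = simulate_genotypes(c)
        with pytest.raises(ConfigError, match="layout"):
            simulate_field_phenotypes(G, truth, c)

    def test_at_least_two_plots_per_accession(self, small_panel):
        _, _, pheno = small_panel
        assert pheno.data["accession"].value_counts().min() >= 2


class TestImpressions:
    def test_poisson_count_mean(self):
        """Density 100 mm-2 -> mean count per field ~ 59 over 1000 draws."""
        c = cfg(n_accessions=10)
        c.impressions.n_fields = 100
        c.impressions.n_plants = 1
        c.impressions.plant_density_cv = 0.0
        recs = simulate_impressions({f"A{i}": 100.0 for i in range(10)}, c)
        counts = [
            x for rs in recs.values() for r in rs if r.surface == "adaxial"
            for x in r.counts
        ]
        assert len(counts) == 1000
        assert np.mean(counts) == pytest.approx(59.0, abs=3.0)

    def test_abaxial_density_factor(self):
        """Abaxial factor 1.255 on adaxial density 100 -> abaxial ~125.5."""
        c = cfg(n_accessions=50)
        c.impressions.n_fields = 20
        c.impressions.plant_density_cv = 0.0
        recs = simulate_impressions({f"A{i}": 100.0 for i in range(50)}, c)
        ab = [
            np.mean(r.counts) / r.fov_area
            for rs in recs.values() for r in rs if r.surface == "abaxial"
        ]
        assert np.mean(ab) == pytest.approx(125.5, rel=0.03)

    def test_density_size_correlation_negative(self):
        """Target r = -0.3 across accessions -> empirical r in (-0.45, -0.15)."""
        rs = []
        for seed in range(20):
            c = cfg(n_accessions=360, seed=seed)
            dens = dict(
                zip(
                    [f"A{i}" for i in range(360)],
                    np.random.default_rng(seed).uniform(70, 200, size=360),
                )
            )
            recs = simulate_impressions(dens, c)
            ss = []
            for acc in dens:
                ad = [r for r in recs[acc] if r.surface == "adaxial"]
                ss.append(np.mean([np.mean(np.array(r.SL) * np.array(r.SCW)) for r in ad]))
            rs.append(np.corrcoef(list(dens.values()), ss)[0, 1])
        assert -0.45 < np.mean(rs) < -0.15

    def test_records_pass_type_invariants(self):
        c = cfg(n_accessions=5)
        recs = simulate_impressions({f"A{i}": 120.0 for i in range(5)}, c)
        # construction already runs ImpressionRecord validation; spot-check
        for rs in recs.values():
            for r in rs:
                assert all(p <= s for p, s in zip(r.PL, r.SL))
                assert all(g <= s for g, s in zip(r.GCW, r.SCW))


class TestLightResponse:
    def test_eleven_records_on_schedule(self):
        recs = simulate_light_response(cfg(), "A1", "WW", 1, haplotype_class=1)
        assert len(recs) == 11
        assert [r.ppfd for r in recs] == [float(q) for q in PPFD_LEVELS]

    def test_noiseless_bwb_plug_in(self):
        """m=5, g0=0.05, An=30, Hs=0.6, Cs=400 -> gsw = 0.275."""
        c = cfg()
        c.bwb.m_ww = (5.0,) * 8
        c.bwb.g0_ww = 0.05
        c.bwb.sigma_gsw = 0.0
        c.bwb.hs, c.bwb.cs = 0.6, 400.0
        recs = simulate_light_response(c, "A1", "WW", 1, haplotype_class=1)
        for r in recs:
            assert r.gsw == pytest.approx(5 * r.An * 0.6 / 400 + 0.05, rel=1e-12)
        an30 = 5 * 30 * 0.6 / 400 + 0.05
        assert an30 == pytest.approx(0.275)

    def test_dark_limit_is_respiration(self):
        lc = LightCurveParams()
        assert light_response_an(0.0, 30.0, lc) == pytest.approx(-lc.rd)

    def test_ws_lower_amax_and_spender_slope_drop(self):
        c = cfg()
        assert c.light_curve.amax_ws < c.light_curve.amax_ww
        for cls in range(1, 6):
            assert c.bwb.m_ws[cls - 1] < c.bwb.m_ww[cls - 1]
        for cls in range(6, 9):
            assert c.bwb.m_ws[cls - 1] == c.bwb.m_ww[cls - 1]

    def test_invalid_theta_rejected(self):
        c = cfg()
        c.light_curve.theta = 1.5
        with pytest.raises(ConfigError, match="theta"):
            simulate_light_response(c, "A1", "WW", 1, haplotype_class=1)

    def test_gsw_floor_enforced(self):
        c = cfg()
        c.bwb.sigma_gsw = 0.5  # large noise to trigger truncation
        recs = simulate_light_response(c, "A1", "WS", 1, haplotype_class=8)
        assert min(r.gsw for r in recs) >= c.bwb.gsw_floor


class TestConfig:
    def test_effect_direction_validated(self):
        with pytest.raises(ConfigError, match="direction"):
            SimulationConfig(
                trait_specs={"iWUE": TraitSpec(115, -4.0, 1, 1, 0, 0, 0, 0)}
            ).validate()

    def test_yaml_roundtrip(self, tmp_path):
        c = cfg(n_accessions=50, seed=9)
        c.to_yaml(tmp_path / "c.yaml")
        c2 = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert c2 == c
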