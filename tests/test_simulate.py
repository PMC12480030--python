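"""Synthetic cohort generator: determinism, marginal recovery, formats."""

import numpy as np
import pandas as pd
import pytest

from adrpgx import io
from adrpgx import simulate as sim
from adrpgx.cohort import harmonise_layers
from adrpgx.locus import load_allele_definitions, load_gene_model


def cfg_with(**kw):
    base = dict(n_samples=1000, seed=11, baseline_logit={"any": 0.0})
    base.update(kw)
    return sim.CohortConfig(**base)


class TestConfigValidation:
    def test_bad_frequency_sum(self):
        with pytest.raises(ValueError, match="sum"):
            cfg_with(haplotype_freqs={"*38": 0.9, "*2": 0.2})

    def test_probability_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cfg_with(star37_carrier_freq=1.5)

    def test_non_psd_correlation(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            cfg_with(pgs_names=("A", "B"), pgs_corr=bad)

    def test_asymmetric_correlation(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cfg_with(pgs_names=("A", "B"), pgs_corr=bad)

    def test_unknown_effect_predictor(self):
        with pytest.raises(ValueError, match="predictor"):
            cfg_with(effects={("dose:high", "any", "ALL"): 0.1})

    def test_unknown_effect_pgs(self):
        with pytest.raises(ValueError, match="unknown PGS"):
            cfg_with(effects={("pgs:NOPE", "any", "ALL"): 0.1})

    def test_unknown_outcome_code(self):
        with pytest.raises(ValueError, match="outcome"):
            cfg_with(baseline_logit={"tail_growth": 0.0})


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        a = sim.simulate_cohort(cfg_with(seed=42))
        b = sim.simulate_cohort(cfg_with(seed=42))
        assert np.array_equal(a.haplotypes.states, b.haplotypes.states)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.pgs, b.pgs)
        pd.testing.assert_frame_equal(a.cnv_segments, b.cnv_segments)

    def test_different_seed_differs(self):
        a = sim.simulate_cohort(cfg_with(seed=1))
        b = sim.simulate_cohort(cfg_with(seed=2))
        assert not np.array_equal(a.haplotypes.states, b.haplotypes.states)


class TestHaplotypes:
    def test_degenerate_distribution_all_reference(self, defs):
        cfg = cfg_with(n_samples=10, haplotype_freqs={"*38": 1.0})
        haps = sim.simulate_haplotypes(cfg, defs)
        assert (haps.labels == "*38").all()
        assert not haps.states.any()

    def test_hardy_weinberg_homozygote_fraction(self, defs):
        """*17/*17 fraction at freq 0.22 ≈ p² = 0.0484 within 3 binomial SDs."""
        n = 50_000
        cfg = cfg_with(n_samples=n, seed=1, haplotype_freqs={"*17": 0.22, "*38": 0.78})
        haps = sim.simulate_haplotypes(cfg, defs)
        hom = ((haps.labels == "*17").sum(axis=1) == 2).mean()
        p2 = 0.22**2
        assert abs(hom - p2) <= 3 * np.sqrt(p2 * (1 - p2) / n)

    def test_unknown_allele_in_freqs(self, defs):
        cfg = cfg_with(haplotype_freqs={"*38": 0.5, "*99": 0.5})
        with pytest.raises(ValueError, match="not in the table"):
            sim.simulate_haplotypes(cfg, defs)


class TestCnvSegments:
    def test_zero_carrier_frequency_no_exon_overlap(self, gene, exons15_union):
        cfg = cfg_with(n_samples=5_000, star37_carrier_freq=0.0, decoy_segment_rate=0.05)
        segments, carrier = sim.simulate_cnv_segments(cfg, gene)
        assert not carrier.any()
        for row in segments.itertuples():
            if row.svtype == "DEL":
                assert not (exons15_union & set(range(row.start, row.end)))

    def test_carrier_fraction_recovered(self, gene):
        n = 100_000
        cfg = cfg_with(n_samples=n, star37_carrier_freq=0.015)
        _, carrier = sim.simulate_cnv_segments(cfg, gene)
        sd = np.sqrt(0.015 * 0.985 / n)
        assert abs(carrier.mean() - 0.015) <= 3 * sd

    def test_carrier_deletions_cover_exons_1_to_5(self, gene):
        from adrpgx.star_alleles import call_star37

        cfg = cfg_with(n_samples=2_000, star37_carrier_freq=0.05)
        segments, carrier = sim.simulate_cnv_segments(cfg, gene)
        ids = set(np.asarray(sim._sample_ids(cfg.n_samples))[carrier])
        for sid, sub in segments.groupby("sample_id"):
            assert call_star37(sub, gene) == (sid in ids)


class TestPgs:
    def test_marginals_and_independence(self):
        cfg = cfg_with(n_samples=100_000, pgs_names=("A", "B", "C"))
        pgs = sim.simulate_pgs(cfg)
        x = pgs[["pgs_A", "pgs_B", "pgs_C"]].to_numpy()
        assert np.all(np.abs(x.mean(axis=0)) < 0.02)
        assert np.all(np.abs(x.std(axis=0) - 1) < 0.02)
        c = np.corrcoef(x.T)
        assert np.all(np.abs(c[~np.eye(3, dtype=bool)]) < 0.02)

    def test_configured_correlation_recovered(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        cfg = cfg_with(n_samples=100_000, pgs_names=("A", "B"), pgs_corr=corr)
        pgs = sim.simulate_pgs(cfg)
        r = np.corrcoef(pgs["pgs_A"], pgs["pgs_B"])[0, 1]
        assert abs(r - 0.6) < 0.02


class TestOutcomesAndRecords:
    def test_null_prevalence_half(self):
        n = 20_000
        cfg = cfg_with(n_samples=n)
        c = sim.simulate_cohort(cfg, include_records=False)
        prev = c.outcomes["any"].mean()
        assert abs(prev - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_zero_duplication_rate_harmonises_cleanly(self):
        cfg = cfg_with(n_samples=2_000, layer_duplication_rate=0.0, conflict_rate=0.0)
        c = sim.simulate_cohort(cfg)
        _, report = harmonise_layers(c.records)
        assert report["n_duplicates_removed"] == 0
        assert report["n_conflicts_resolved"] == 0

    def test_duplicates_and_conflicts_emitted(self):
        cfg = cfg_with(n_samples=2_000, layer_duplication_rate=0.2, conflict_rate=0.05)
        c = sim.simulate_cohort(cfg)
        _, report = harmonise_layers(c.records)
        assert report["n_duplicates_removed"] > 0
        assert report["n_conflicts_resolved"] > 0

    def test_metaboliser_effect_shifts_prevalence(self):
        """Poor metabolisers' prevalence responds to the configured log-OR."""
        from math import log

        cfg = sim.cyp2c19_scenario(n_samples=40_000, seed=3, poor_or=3.0)
        cfg.covariate_effects = {}
        c = sim.simulate_cohort(cfg, include_records=False)
        poor = c.true_phenotype == "poor"
        normal = c.true_phenotype == "normal"
        y = c.outcomes["any"].to_numpy()
        odds = lambda m: y[m].mean() / (1 - y[m].mean())
        assert abs(np.log(odds(poor) / odds(normal)) - log(3.0)) < 0.25

    def test_true_metaboliser_star37_rule(self):
        labels = np.array([["*38", "*38"], ["*2", "*38"], ["*2", "*17"]], dtype=object)
        carrier = np.array([True, True, True])
        assert list(sim.true_metaboliser(labels, carrier)) == [
            "intermediate",  # *37/*38
            "poor",          # *2/*37
            "poor",          # *2/*37 (replaces later-sorted *17)
        ]


class TestScenarios:
    def test_default_scenario_prevalences(self):
        """Marginal side-effect rates and pooled ~52% prevalence both hold."""
        cfg = sim.default_scenario(n_samples=30_000, seed=9)
        c = sim.simulate_cohort(cfg, include_records=False)
        t = sim.analysis_table(c, via_caller=False)
        assert abs(t["se_any"].mean() - 0.52) < 0.02
        assert abs(t["se_nausea"].mean() - 0.157) < 0.015
        assert abs(t["se_chills"].mean() - 0.008) < 0.004

    def test_cyp2c19_scenario_phenotype_mix(self):
        cfg = sim.cyp2c19_scenario(n_samples=30_000, seed=4)
        c = sim.simulate_cohort(cfg, include_records=False)
        freq = pd.Series(c.true_phenotype).value_counts(normalize=True)
        assert abs(freq["poor"] - 0.019) < 0.01
        assert abs(freq["normal"] - 0.366) < 0.03
        assert abs(freq["ultrarapid"] - 0.065) < 0.015


class TestFormats:
    def test_vcf_round_trip(self, tmp_path, defs, gene):
        cfg = cfg_with(n_samples=50)
        haps = sim.simulate_haplotypes(cfg, defs)
        path = str(tmp_path / "g.vcf")
        io.write_vcf(haps, defs, gene, path)
        text = (tmp_path / "g.vcf").read_text()
        assert "|" in text.splitlines()[-1]  # phased separator
        back = io.read_vcf_haplotypes(path, defs)
        assert back.sample_ids == haps.sample_ids
        assert np.array_equal(back.states, haps.states)

    def test_scenario_yaml_round_trip(self, tmp_path):
        cfg = sim.default_scenario(n_samples=300, seed=3)
        path = str(tmp_path / "scenario.yaml")
        io.write_scenario(cfg, path)
        back = io.read_scenario(path)
        assert back.effects == cfg.effects
        assert back.baseline_logit == cfg.baseline_logit
        a = sim.simulate_cohort(cfg, include_records=False)
        b = sim.simulate_cohort(back, include_records=False)
        assert np.array_equal(a.haplotypes.states, b.haplotypes.states)

    def test_bed_round_trip(self, tmp_path, gene):
        cfg = cfg_with(n_samples=3_000, star37_carrier_freq=0.05)
        segments, _ = sim.simulate_cnv_segments(cfg, gene)
        path = str(tmp_path / "c.bed")
        io.write_bed(segments, path)
        back = io.read_bed(path)
        assert len(back) == len(segments)
        assert (back["end"] > back["start"]).all()
        merged = back.merge(segments, on=["sample_id", "start", "end", "svtype"])
        assert len(merged) == len(segments)
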