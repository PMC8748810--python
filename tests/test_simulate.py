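"""Generator correctness: determinism, label round-trips, design recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from g4scape.intervals import k_of_n_consensus, overlap_count
from g4scape.landscape import build_integration_matrix
from g4scape.simulate import (
    SimulationConfig,
    make_toy_genome,
    simulate_coverage,
    simulate_expression,
    simulate_g4_replicates,
    simulate_g4_truth,
    simulate_histone_landscape,
)
from g4scape.stabilisation import de_category, expression_filter, weighted_linear_fit
from g4scape.tracks import binned_rpm, tss_metaprofile


def small_config(**kw) -> SimulationConfig:
    base = dict(
        seed=0,
        n_genes=200,
        chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
        n_background_peaks=50,
        n_reads=20_000,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestToyGenome:
    def test_promoters_do_not_overlap(self):
        cfg = small_config()
        sizes, genes = make_toy_genome(cfg)
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        for tsss in by_chrom.values():
            tsss.sort()
            assert min(np.diff(tsss)) >= 2 * cfg.flank + 1

    def test_deterministic_per_seed(self):
        cfg = small_config(seed=42)
        _, g1 = make_toy_genome(cfg)
        _, g2 = make_toy_genome(small_config(seed=42))
        assert g1 == g2
        _, g3 = make_toy_genome(small_config(seed=43))
        assert g1 != g3

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="too small"):
            make_toy_genome(
                SimulationConfig(n_genes=1000, chrom_sizes={"chr1": 100_000})
            )


class TestG4Replicates:
    def test_noise_free_replicates_equal_truth(self):
        cfg = small_config(jitter_sd=0.0, dropout=0.0)
        _, genes = make_toy_genome(cfg)
        truth, _ = simulate_g4_truth(cfg, genes)
        reps = simulate_g4_replicates(truth["hESC"], cfg, "hESC")
        assert len(reps) == 9
        for iset in reps.values():
            assert iset == truth["hESC"]
        by_bio = [
            k_of_n_consensus([reps[(b, t)] for t in range(3)], 2) for b in range(3)
        ]
        consensus = k_of_n_consensus(by_bio, 2)
        assert consensus == truth["hESC"].merged()

    @pytest.mark.parametrize("dropout,expected", [(0.2, 0.9697), (0.5, 0.5)])
    def test_consensus_recall_matches_two_stage_binomial(self, dropout, expected):
        """Recall = P(>=2 of 3 bio) with p_bio = P(>=2 of 3 tech present)."""
        p = 1 - dropout
        p_t = 3 * p**2 * (1 - p) + p**3
        closed_form = 3 * p_t**2 * (1 - p_t) + p_t**3
        assert closed_form == pytest.approx(expected, abs=5e-4)

        cfg = SimulationConfig(
            seed=1,
            n_genes=1000,
            chrom_sizes={"chr1": 3_000_000, "chr2": 3_000_000},
            n_background_peaks=0,
            p_g4_embryonic=1.0,  # a peak at every promoter: 1000 truth intervals
            jitter_sd=0.0,
            dropout=dropout,
        )
        _, genes = make_toy_genome(cfg)
        truth, _ = simulate_g4_truth(cfg, genes)
        reps = simulate_g4_replicates(truth["hESC"], cfg, "hESC")
        by_bio = [
            k_of_n_consensus([reps[(b, t)] for t in range(3)], 2) for b in range(3)
        ]
        consensus = k_of_n_consensus(by_bio, 2)
        recall = overlap_count(truth["hESC"], consensus) / len(truth["hESC"])
        se = np.sqrt(closed_form * (1 - closed_form) / 1000)
        assert abs(recall - closed_form) <= 3 * se


class TestHistoneLandscape:
    def test_classification_round_trip_recovers_labels(self):
        cfg = small_config()
        sizes, genes = make_toy_genome(cfg)
        truth, g4_labels = simulate_g4_truth(cfg, genes)
        k4, k27, labels = simulate_histone_landscape(cfg, genes, g4_labels)
        matrix = build_integration_matrix(genes, sizes, truth, k4, k27)
        for cell in cfg.cells:
            got = matrix[f"histone_{cell}"]
            expected = labels[f"histone_{cell}"]
            assert (got == expected).all()

    def test_identity_transition_matrix_preserves_classes(self):
        identity = {
            start: {
                g: {start: 1.0}
                for g in ("G4E+GD+", "G4E+GD-", "G4E-GD+", "G4E-GD-")
            }
            for start in ("H3K4me3", "H3K27me3", "bivalent", "other", "unmarked")
        }
        cfg = small_config(transition_matrices=identity)
        _, genes = make_toy_genome(cfg)
        _, g4_labels = simulate_g4_truth(cfg, genes)
        _, _, labels = simulate_histone_landscape(cfg, genes, g4_labels)
        assert (labels["histone_CNCC"] == labels["histone_hESC"]).all()
        assert (labels["histone_NSC"] == labels["histone_hESC"]).all()

    def test_degenerate_prior_single_class(self):
        cfg = small_config(
            histone_prior={"bivalent": 1.0, "H3K4me3": 0.0, "H3K27me3": 0.0,
                           "unmarked": 0.0, "other": 0.0}
        )
        _, genes = make_toy_genome(cfg)
        _, g4_labels = simulate_g4_truth(cfg, genes)
        _, _, labels = simulate_histone_landscape(cfg, genes, g4_labels)
        assert (labels["histone_hESC"] == "bivalent").all()


class TestG4Design:
    def test_daughter_in_embryonic_share_near_config(self):
        # P(E+|D+) = p_E*p_maintain / (p_E*p_maintain + (1-p_E)*p_gain) = 0.75
        cfg = SimulationConfig(
            seed=3,
            n_genes=4000,
            chrom_sizes={"chr1": 5_000_000, "chr2": 5_000_000},
            n_background_peaks=0,
        )
        _, genes = make_toy_genome(cfg)
        _, labels = simulate_g4_truth(cfg, genes)
        d_pos = labels["g4_CNCC"]
        share = (labels["g4_hESC"] & d_pos).sum() / d_pos.sum()
        p_d = 0.4 * 0.5 + 0.6 * 0.111
        expected = 0.4 * 0.5 / p_d
        se = np.sqrt(expected * (1 - expected) / (4000 * p_d))
        assert abs(share - expected) <= 3 * se

    def test_inter_cell_overlap_measured_by_overlap_count(self):
        cfg = small_config(seed=5, n_background_peaks=200, p_g4_embryonic=0.0,
                           p_g4_gain=0.0)
        _, genes = make_toy_genome(cfg)
        truth, _ = simulate_g4_truth(cfg, genes)
        # with promoter G4s off, sharing is purely the background design
        shared = overlap_count(truth["CNCC"], truth["hESC"])
        assert shared / len(truth["CNCC"]) == pytest.approx(
            cfg.background_shared_fraction, abs=0.08
        )


class TestExpression:
    def test_zero_sigma_group_lies_on_regression_line(self):
        cfg = small_config(
            sigma_by_group={"G4E+GD+": 0.0, "G4E+GD-": 0.0, "G4E-GD+": 0.0,
                            "G4E-GD-": 0.0},
            replicate_log2_sd=0.0,
            silent_fraction=0.0,
            expr_slope=1.3,
            expr_intercept=-0.5,
        )
        _, genes = make_toy_genome(cfg)
        _, g4_labels = simulate_g4_truth(cfg, genes)
        expr, _, _ = simulate_expression(cfg, genes, g4_labels)
        x = np.log2(expr["hESC"].median(axis=1))
        y = np.log2(expr["CNCC"].median(axis=1))
        fit = weighted_linear_fit(
            x.to_numpy(), y.to_numpy(), expr["hESC"].median(axis=1).to_numpy()
        )
        assert fit.slope == pytest.approx(1.3, abs=1e-9)
        assert fit.intercept == pytest.approx(-0.5, abs=1e-9)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_direct_label_de_exact(self):
        cfg = small_config(de_direct_labels=True)
        _, genes = make_toy_genome(cfg)
        _, g4_labels = simulate_g4_truth(cfg, genes)
        _, de, truth = simulate_expression(cfg, genes, g4_labels)
        tbl = de["CNCC"]
        cats = [de_category(r.log2fc, r.fdr) for r in tbl.itertuples()]
        expected_sig = (tbl["log2fc"].abs() > 1).sum()
        assert sum(c in ("up_hESC", "up_daughter") for c in cats) == expected_sig

    def test_strong_effects_called_by_t_test_de(self):
        cfg = small_config(
            seed=9,
            replicate_log2_sd=0.1,
            silent_fraction=0.0,
            sigma_by_group={"G4E+GD+": 3.0, "G4E+GD-": 3.0, "G4E-GD+": 3.0,
                            "G4E-GD-": 3.0},
        )
        _, genes = make_toy_genome(cfg)
        _, g4_labels = simulate_g4_truth(cfg, genes)
        _, de, truth = simulate_expression(cfg, genes, g4_labels)
        true_fc = (truth["true_log2_CNCC"] - truth["true_log2_hESC"]).to_numpy()
        strong = np.abs(true_fc) > 2
        cats = np.array(
            [de_category(r.log2fc, r.fdr) for r in de["CNCC"].itertuples()]
        )
        frac = np.isin(cats[strong], ["up_hESC", "up_daughter"]).mean()
        assert frac > 0.95

    def test_silent_genes_filtered(self):
        cfg = small_config(silent_fraction=0.3)
        _, genes = make_toy_genome(cfg)
        _, g4_labels = simulate_g4_truth(cfg, genes)
        expr, _, truth = simulate_expression(cfg, genes, g4_labels)
        e = expr["hESC"].median(axis=1).to_numpy()
        d = expr["CNCC"].median(axis=1).to_numpy()
        mask = expression_filter(e, d)
        assert (~mask).sum() == truth["silent"].sum()


class TestCoverage:
    def test_deterministic(self):
        cfg = small_config()
        _, genes = make_toy_genome(cfg)
        mask = np.zeros(len(genes), dtype=bool)
        mask[:50] = True
        r1 = simulate_coverage(cfg, genes, mask, "hESC", 0)
        r2 = simulate_coverage(cfg, genes, mask, "hESC", 0)
        assert r1 == r2

    def test_no_enrichment_flat_profile(self):
        cfg = small_config(seed=11, tss_enrichment=1.0, n_reads=60_000)
        _, genes = make_toy_genome(cfg)
        mask = np.ones(len(genes), dtype=bool)
        reads = simulate_coverage(cfg, genes, mask, "hESC", 0)
        track = binned_rpm(reads, cfg.bin_size, cfg.library_size)
        _, profile, _ = tss_metaprofile(track, genes, window=1000, stat="mean")
        # plateau/flank ratio indistinguishable from 1
        centre = profile[80:120].mean()
        flank = np.concatenate([profile[:20], profile[-20:]]).mean()
        assert centre / flank == pytest.approx(1.0, abs=0.15)

    def test_planted_enrichment_ratio_recovered(self):
        cfg = small_config(
            seed=12, tss_enrichment=5.0, tss_window=500, n_reads=150_000
        )
        _, genes = make_toy_genome(cfg)
        mask = np.ones(len(genes), dtype=bool)
        reads = simulate_coverage(cfg, genes, mask, "hESC", 0)
        track = binned_rpm(reads, cfg.bin_size, cfg.library_size)
        _, profile, _ = tss_metaprofile(track, genes, window=1000, stat="mean")
        offsets = np.arange(-1000, 1000, 10)
        centre = profile[np.abs(offsets + 5) < 400].mean()
        flank = profile[np.abs(offsets) > 700].mean()
        assert centre / flank == pytest.approx(5.0, rel=0.2)
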