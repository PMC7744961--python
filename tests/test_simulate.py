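"""Synthetic-data generator: closed forms, determinism, and self-consistency."""

import numpy as np
import pandas as pd
import pytest

from iriseq import (
    SimConfig,
    apply_iri_filters,
    build_iri_matrix,
    expected_iri,
    exonic_signal_factor,
    simulate_bundle,
    simulate_coverage,
    simulate_genome,
    simulate_ir_trajectories,
    simulate_rbp_expression,
    simulate_rbp_sites,
    write_fixture_bundle,
)
from iriseq.simulate import genome_to_fasta, genome_to_gtf

SMALL = SimConfig(n_genes=20)


class TestClosedForms:
    def test_gamma_one_reduces_to_rho(self):
        rho = np.linspace(0.05, 0.5, 5)
        np.testing.assert_allclose(expected_iri(rho, gamma=1.0), rho)

    def test_hand_arithmetic_gamma_five(self):
        # rho = 0.2 constant, gamma = 5: (0.2/5) / (0.8 + 0.2/5) = 0.0476...
        assert expected_iri(0.2, gamma=5.0) == pytest.approx(0.04 / 0.84)

    def test_exonic_signal_fall_factor(self):
        # rho rising 0.02 -> 0.4 at gamma = 5 drops the exonic signal by
        # (1 - 0.4 * 0.8) / (1 - 0.02 * 0.8) ~ 0.691
        factor = exonic_signal_factor(0.4, 5.0) / exonic_signal_factor(0.02, 5.0)
        assert factor == pytest.approx(0.6911, abs=1e-4)

    def test_gamma_one_means_no_expression_coupling(self):
        rho = np.linspace(0.02, 0.4, 5)
        np.testing.assert_allclose(exonic_signal_factor(rho, 1.0), 1.0)


class TestGenome:
    def test_deterministic_given_seed(self):
        g1 = simulate_genome(SMALL, 1)
        g2 = simulate_genome(SMALL, 1)
        assert genome_to_gtf(g1) == genome_to_gtf(g2)
        assert genome_to_fasta(g1) == genome_to_fasta(g2)

    def test_single_isoform_when_no_skipping(self):
        cfg = SimConfig(n_genes=10, skipping_fraction=0.0)
        g = simulate_genome(cfg, 2)
        assert all(len(gene.transcripts) == 1 for gene in g.genes)
        # shared introns equal the plain introns between consecutive exons
        for gene in g.genes:
            exons = next(iter(gene.transcripts.values()))
            n_introns = len(exons) - 1
            recs = [r for r in g.introns if r.gene_id == gene.gene_id]
            assert len(recs) == n_introns

    def test_skipped_exon_in_neither_shared_set(self):
        from conftest import brute_force_shared, intervals_to_bases
        from iriseq.annotation import compute_shared_regions

        cfg = SimConfig(n_genes=30, skipping_fraction=1.0)
        g = simulate_genome(cfg, 3)
        multi = [gene for gene in g.genes if len(gene.transcripts) == 2]
        assert multi, "skipping_fraction=1 should yield two-isoform genes"
        for gene in multi[:5]:
            shared = compute_shared_regions(gene)
            ex, intr = brute_force_shared(gene)
            assert intervals_to_bases(shared.shared_exonic) == ex
            assert intervals_to_bases(shared.shared_intronic) == intr
            skipped = set(next(iter(gene.transcripts.values()))) - set(
                list(gene.transcripts.values())[1]
            )
            for s, e in skipped:
                assert not (set(range(s, e)) & (ex | intr))


class TestTrajectories:
    def test_shapes_and_classes(self):
        g = simulate_genome(SMALL, 4)
        truth = simulate_ir_trajectories(SMALL, g, 4)
        cut = SMALL.retention_cutoff
        for intron_id, cls in truth.intron_class.items():
            rho = truth.rho[intron_id]
            eiri = truth.expected_iri[intron_id]
            assert len(rho) == SMALL.n_timepoints
            assert np.all(eiri >= 0) and np.all(eiri < 1)
            if cls == "up":
                assert np.all(np.diff(rho) > 0)
                assert eiri.max() >= cut
            elif cls == "down":
                assert np.all(np.diff(rho) < 0)
                assert eiri.max() >= cut
            elif cls == "stable":
                assert np.ptp(rho) == 0 and eiri.min() >= cut
            elif cls == "none":
                assert np.all(eiri < cut)

    def test_infeasible_amplitude_errors_with_bound(self):
        cfg = SimConfig(rho_stable=(0.01, 0.02), rho_high=(0.01, 0.02))
        g = simulate_genome(cfg, 1)
        with pytest.raises(ValueError, match="need rho >="):
            simulate_ir_trajectories(cfg, g, 1)

    def test_degradation_abundances(self):
        g = simulate_genome(SMALL, 5)
        truth = simulate_ir_trajectories(SMALL, g, 5)
        for gene in g.genes:
            gid = gene.gene_id
            rho = truth.rho[truth.focal_intron[gid]]
            np.testing.assert_allclose(truth.S[gid],
                                       truth.T[gid] * (1 - rho))
            np.testing.assert_allclose(truth.R[gid],
                                       truth.T[gid] * rho / SMALL.gamma)
            assert np.all(truth.S[gid] >= 0) and np.all(truth.R[gid] >= 0)


class TestCoverage:
    def test_empirical_iri_matches_closed_form(self):
        """Monte-Carlo: measured IRI tracks the generative closed form."""
        cfg = SimConfig(n_genes=25, intronic_background=0.0,
                        rho_none=(0.2, 0.3))  # keep coverage above the filter
        g = simulate_genome(cfg, 6)
        truth = simulate_ir_trajectories(cfg, g, 6)
        tracks, design = simulate_coverage(cfg, g, truth, 6)
        matrix = build_iri_matrix(tracks, g.introns)
        groups = design.groupby("group", sort=False)["sample_id"].apply(list)
        devs = []
        for intron_id in matrix.iri.index:
            for t, (_, samples) in enumerate(groups.items()):
                emp = matrix.iri.loc[intron_id, samples].mean()
                if np.isnan(emp):
                    continue
                devs.append(abs(emp - truth.expected_iri[intron_id][t]))
        assert len(devs) >= 50
        assert np.mean(devs) < 0.02

    def test_gamma_one_expression_flat_gamma_five_falls(self):
        for gamma, falls in ((1.0, False), (5.0, True)):
            cfg = SimConfig(n_genes=30, gamma=gamma)
            g = simulate_genome(cfg, 7)
            truth = simulate_ir_trajectories(cfg, g, 7)
            up_genes = [gid for gid, c in truth.gene_class.items() if c == "up"]
            for gid in up_genes:
                signal = truth.S[gid] + truth.R[gid]
                if falls:
                    assert signal[-1] < signal[0]
                else:
                    assert signal[-1] == pytest.approx(signal[0])

    def test_design_table_complete(self):
        g = simulate_genome(SMALL, 8)
        truth = simulate_ir_trajectories(SMALL, g, 8)
        tracks, design = simulate_coverage(SMALL, g, truth, 8)
        assert len(design) == SMALL.n_timepoints * SMALL.replicates
        assert set(design["sample_id"]) == set(tracks)
        assert (design["total_mapped"] > 0).all()


class TestRBPSimulation:
    def test_enrichment_detectable_null_not(self):
        from scipy import stats

        cfg = SimConfig(n_genes=60)
        g = simulate_genome(cfg, 9)
        truth = simulate_ir_trajectories(cfg, g, 9)
        sites, manifest = simulate_rbp_sites(cfg, g, truth, 9)
        assert manifest[cfg.planted_rbp]["change_intron_enrichment"] == 5.0
        from iriseq.rbp import BindingSiteIndex, binding_density

        idx = BindingSiteIndex(sites=sites)
        meta = g.introns_frame()
        change = meta[meta["true_class"].isin(["up", "down"])]
        spliced = meta[meta["true_class"] == "none"]
        for rbp, expect_sig in ((cfg.planted_rbp, True), ("RBP_D01", False)):
            d_change = binding_density(idx, change.reset_index(), rbp)["density"]
            d_none = binding_density(idx, spliced.reset_index(), rbp)["density"]
            p = stats.mannwhitneyu(d_change, d_none, alternative="greater").pvalue
            assert bool(p < 0.05) == expect_sig

    def test_empty_roster_gives_empty_bed(self):
        cfg = SimConfig(n_genes=5, n_decoy_rbps=0, rbp_base_rate=0.0)
        g = simulate_genome(cfg, 10)
        truth = simulate_ir_trajectories(cfg, g, 10)
        sites, _ = simulate_rbp_sites(cfg, g, truth, 10)
        assert len(sites) == 0

    def test_expression_tables_have_planted_drop(self):
        cfg = SimConfig()
        tables = simulate_rbp_expression(cfg, 11)
        assert set(tables) == set(cfg.rbp_models)
        dropped = 0
        for mi, model in enumerate(cfg.rbp_models):
            t = tables[model]
            reg = t[t["rbp"] == cfg.planted_rbp]
            early = reg.loc[reg["group"] == "early", "value"].mean()
            late = reg.loc[reg["group"] == "late", "value"].mean()
            if early / late > 1.5:
                dropped += 1
        assert dropped == cfg.rbp_drop_models


class TestBundle:
    def test_manifest_lists_files_with_checksums(self, small_bundle):
        manifest = small_bundle["manifest"]
        names = set(manifest["files"])
        for expected in ("annotation.gtf", "genome.fa", "design.tsv",
                         "rbp_sites.bed", "ground_truth.tsv"):
            assert expected in names
        assert all(len(v) == 64 for v in manifest["files"].values())

    def test_ground_truth_rows_equal_intron_count(self, small_bundle):
        truth_path = small_bundle["dir"] / "ground_truth.tsv"
        df = pd.read_csv(truth_path, sep="\t")
        assert len(df) == len(small_bundle["result"].genome.introns)

    def test_regenerate_byte_identical(self, tmp_path, small_bundle):
        result2 = simulate_bundle(SimConfig(n_genes=30), seed=11)
        m2 = write_fixture_bundle(result2, tmp_path / "again")
        assert m2["files"] == small_bundle["manifest"]["files"]

    def test_filters_pass_default_conditions(self):
        result = simulate_bundle(SimConfig(n_genes=20), 12, with_rbp=False)
        matrix = build_iri_matrix(result.tracks, result.genome.introns)
        _, report = apply_iri_filters(matrix)
        assert report["kept"] >= 0.9 * report["quantified"]
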