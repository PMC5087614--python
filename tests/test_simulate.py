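"""Synthetic-data generator: design shape, count model, planted truth."""

import numpy as np
import pytest
from scipy.stats import binom

from egakit.config import InvalidConfigError, ReplicateGroup, SimConfig
from egakit.simulate import (
    leutx_fixture_tfe,
    plant_motifs,
    simulate_embryo_profiles,
    simulate_experiment,
    simulate_genome_annotation,
)
from egakit.motif import scan_window
from egakit.tfe import annotate_tfes


class TestSimulateExperiment:
    def test_default_library_has_48_samples(self):
        mat, sheet, _ = simulate_experiment(SimConfig(seed=0))
        assert mat.counts.shape[1] == 48
        assert len(sheet.sample_ids) == 48
        assert len(sheet.select(gfp="negative")) == 23

    def test_null_config_has_no_truth_entries(self, small_null_config):
        mat, sheet, truth = simulate_experiment(small_null_config)
        assert all(not v for v in truth.planted_up.values())
        assert all(not v for v in truth.planted_down.values())
        assert (mat.counts.to_numpy() >= 0).all()

    def test_spike_totals_independent_of_construct(self):
        """Permutation test: spike totals carry no construct signal."""
        cfg = SimConfig(seed=5, n_tfes=500)
        mat, sheet, _ = simulate_experiment(cfg)
        totals = mat.spike_totals()
        pos = sheet.select("LEUTX_n", "positive")
        neg = sheet.select(gfp="negative")
        obs = abs(totals[pos].mean() - totals[neg].mean())
        rng = np.random.default_rng(0)
        pool = np.array(totals[pos + neg])
        n_pos = len(pos)
        null = []
        for _ in range(2000):
            rng.shuffle(pool)
            null.append(abs(pool[:n_pos].mean() - pool[n_pos:].mean()))
        p = (1 + sum(x >= obs for x in null)) / 2001
        assert p > 0.01

    def test_planted_eightfold_mean_ratio_matches_monte_carlo(self, three_v_three_design):
        """With dispersion -> 0 and lfc=+3, the spike-normalized GFP+/GFP-
        mean ratio of the planted TFE averages ~8 over replicates."""
        ratios = []
        for seed in range(1000):
            cfg = SimConfig(
                n_tfes=10, n_spikes=5, library_size_mean=20000,
                replicate_design=three_v_three_design, effect_constructs=("A",),
                frac_up=0.1, frac_down=0.0, lfc_mean=3.0, lfc_sd=0.0, lfc_min=3.0,
                dispersion=0.0, capture_efficiency_cv=0.0, base_log_sd=0.5,
                planting_min_expression=0.0, seed=seed,
            )
            mat, sheet, truth = simulate_experiment(cfg)
            (planted,) = truth.planted_up["A"]
            norm = mat.counts.loc[planted] / mat.spike_totals()
            pos, neg = sheet.select("A", "positive"), sheet.select("A", "negative")
            if norm[neg].mean() > 0:
                ratios.append(norm[pos].mean() / norm[neg].mean())
        assert np.mean(ratios) == pytest.approx(8.0, rel=0.05)

    def test_truth_consistent_with_emitted_matrix(self):
        mat, sheet, truth = simulate_experiment(SimConfig(seed=2))
        rows = set(mat.counts.index)
        for construct in truth.planted_up:
            assert truth.planted_up[construct] <= rows
            assert truth.planted_down[construct] <= rows
            assert not truth.planted_up[construct] & truth.planted_down[construct]
        assert set(truth.per_sample_capture) == set(mat.samples)
        assert set(truth.spike_concentrations) == {
            r for r in rows if r.startswith("SPIKE_")
        }

    def test_zero_replicate_design_rejected(self):
        with pytest.raises(InvalidConfigError):
            ReplicateGroup("A", "positive", 0, 75)

    def test_deterministic_under_seed(self):
        a, _, _ = simulate_experiment(SimConfig(seed=9, n_tfes=100))
        b, _, _ = simulate_experiment(SimConfig(seed=9, n_tfes=100))
        assert a.counts.equals(b.counts)


class TestGenomeAnnotation:
    def test_categories_by_construction_match_annotator(self):
        ann = simulate_genome_annotation(SimConfig(seed=1, n_tfes=300))
        bare = [t.__class__(t.id, t.chrom, t.start, t.end, t.strand, t.peak)
                for t in ann.tfes]
        recats = annotate_tfes(bare, ann.genes)
        assert all(r.category == t.category for r, t in zip(recats, ann.tfes))

    def test_promoter_windows_fit_in_contigs(self):
        ann = simulate_genome_annotation(SimConfig(seed=1, n_tfes=200), with_sequence=False)
        for _, row in ann.tss_table.iterrows():
            clen = ann.contig_lengths[row["chrom"]]
            assert row["pos"] - 2000 >= 0 and row["pos"] + 500 < clen

    def test_leutx_fixture_coordinates(self):
        rec = leutx_fixture_tfe()
        assert rec.id == "FE270433"
        assert (rec.chrom, rec.start, rec.end, rec.strand) == ("chr19", 40269482, 40269570, "+")
        assert rec.start <= rec.peak < rec.end

    def test_sequence_lengths_match_declared_contigs(self):
        ann = simulate_genome_annotation(SimConfig(seed=3, n_tfes=100))
        for c, seq in ann.sequences.items():
            assert len(seq) == ann.contig_lengths[c]


class TestPlantMotifs:
    def test_zero_rates_leave_sequences_unchanged(self, ega_pwm, random_windows):
        rng = np.random.default_rng(0)
        wins = random_windows(rng, 10)
        out, occ = plant_motifs(wins, ega_pwm, 0.0, 0.0, {w.id for w in wins}, seed=1)
        assert occ == []
        assert [w.sequence for w in out] == [w.sequence for w in wins]

    def test_rate_one_plants_and_scanner_rediscovers(self, ega_pwm, random_windows):
        rng = np.random.default_rng(1)
        wins = random_windows(rng, 10)
        out, occ = plant_motifs(wins, ega_pwm, 1.0, 0.0, {w.id for w in wins}, seed=2)
        assert len(occ) == 10
        found = {w.id: scan_window(w, ega_pwm, 1e-4) for w in out}
        for wid, offset, strand in occ:
            assert any(h.offset == offset and h.strand == strand for h in found[wid])

    def test_occurrence_count_in_binomial_interval(self, ega_pwm, random_windows):
        rng = np.random.default_rng(2)
        wins = random_windows(rng, 1000, length=100)
        _, occ = plant_motifs(wins, ega_pwm, 0.5, 0.0, {w.id for w in wins}, seed=3)
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= len(occ) <= hi

    def test_occurrences_lie_inside_windows(self, ega_pwm, random_windows):
        rng = np.random.default_rng(3)
        wins = random_windows(rng, 50, length=80)
        out, occ = plant_motifs(wins, ega_pwm, 0.8, 0.0, {w.id for w in wins}, seed=4)
        for wid, offset, _ in occ:
            assert 0 <= offset <= 80 - ega_pwm.length

    def test_invalid_rate_rejected(self, ega_pwm, random_windows):
        wins = random_windows(np.random.default_rng(0), 2)
        with pytest.raises(InvalidConfigError):
            plant_motifs(wins, ega_pwm, 1.5, 0.0, set(), seed=0)


class TestEmbryoProfiles:
    def test_zero_overlap_is_disjoint_from_targets(self):
        cfg = SimConfig(seed=4, activation_overlap=0.0, n_activated=30)
        genes = [f"G{i}" for i in range(300)]
        targets = set(genes[:50])
        _, activated = simulate_embryo_profiles(cfg, genes, targets)
        assert not activated & targets

    def test_full_overlap_with_matching_sizes(self):
        cfg = SimConfig(seed=4, activation_overlap=1.0, n_activated=50)
        genes = [f"G{i}" for i in range(300)]
        targets = set(genes[:50])
        _, activated = simulate_embryo_profiles(cfg, genes, targets)
        assert len(activated & targets) == 50

    def test_activated_genes_rise_above_fold_threshold(self):
        cfg = SimConfig(seed=5, n_activated=100)
        table, activated = simulate_embryo_profiles(cfg)
        act = sorted(activated)
        ratio = table.loc["8cell", act] / table.loc["oocyte", act]
        assert (ratio > cfg.activation_fold).mean() == 1.0
        others = [g for g in table.columns if g not in activated]
        ratio_bg = table.loc["8cell", others] / table.loc["oocyte", others]
        assert (ratio_bg > cfg.activation_fold).mean() == 0.0
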