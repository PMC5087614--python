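"""PWM construction, exact p-value table, promoter extraction, scanning,
and enrichment bookkeeping."""

import itertools
import logging

import numpy as np
import pytest

from egakit.motif import (
    MotifParseError,
    PWMModel,
    PromoterWindow,
    build_pwm,
    extract_promoters,
    motif_enrichment,
    scan_window,
    score_pvalue_table,
)
from egakit.simulate import plant_motifs
from egakit.utils import reverse_complement


def enumeration_tail(pwm: PWMModel) -> dict[int, float]:
    """Brute-force exact tail over all 4^L background sequences."""
    lo = pwm.lo_int
    bg = pwm.background
    masses: dict[int, float] = {}
    for seq in itertools.product(range(4), repeat=pwm.length):
        s = int(sum(lo[k, a] for k, a in enumerate(seq)))
        w = float(np.prod([bg[a] for a in seq]))
        masses[s] = masses.get(s, 0.0) + w
    tail, acc = {}, 0.0
    for s in sorted(masses, reverse=True):
        acc += masses[s]
        tail[s] = acc
    return tail


class TestBuildPwm:
    def test_consensus_without_pseudocount_is_deterministic(self):
        pwm = build_pwm("ACGT", pseudocount=0.0)
        assert np.allclose(np.diag(pwm.probs), 1.0)

    def test_iupac_codes_expand_uniformly(self):
        pwm = build_pwm("RN", pseudocount=0.0)
        assert np.allclose(pwm.probs[0], [0.5, 0, 0.5, 0])
        assert np.allclose(pwm.probs[1], [0.25] * 4)

    def test_uniform_pwm_has_zero_log_odds(self):
        pwm = build_pwm("NNNN", pseudocount=0.0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_alignment_frequencies(self):
        pwm = build_pwm(["AC", "AG", "AT", "AA"], pseudocount=0.0)
        assert np.allclose(pwm.probs[0], [1, 0, 0, 0])
        assert np.allclose(pwm.probs[1], [0.25] * 4)

    def test_invalid_letter_rejected(self):
        with pytest.raises(MotifParseError):
            build_pwm("ACXG")


class TestScorePvalueTable:
    @pytest.mark.parametrize("consensus,pc", [("ACGT", 0.1), ("RYSW", 0.05), ("GGATTA", 0.02)])
    def test_matches_enumeration_oracle(self, consensus, pc):
        pwm = build_pwm(consensus, pseudocount=pc)
        oracle = enumeration_tail(pwm)
        for s, p in oracle.items():
            assert pwm.pvalue_int(s) == pytest.approx(p, abs=1e-12)

    def test_threshold_below_minimum_is_one(self):
        pwm = build_pwm("ACGT", pseudocount=0.1)
        min_int, _ = pwm._tail
        assert pwm.pvalue_int(min_int - 1000) == 1.0

    def test_threshold_above_maximum_is_zero(self):
        pwm = build_pwm("ACGT", pseudocount=0.1)
        min_int, tail = pwm._tail
        assert pwm.pvalue_int(min_int + len(tail) + 5) == 0.0

    def test_table_monotone_non_increasing(self, ega_pwm):
        table = score_pvalue_table(ega_pwm)
        assert (np.diff(table["p_value"].to_numpy()) <= 1e-15).all()


class TestExtractPromoters:
    def _genome(self, n=12000, seed=0):
        rng = np.random.default_rng(seed)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return {"chr1": bases[rng.integers(0, 4, n)].tobytes().decode()}

    def test_plus_strand_window_span(self):
        g = self._genome()
        (w,) = extract_promoters([("t1", "chr1", 10000, "+")], g)
        assert (w.start, w.end) == (8000, 10500)
        assert len(w.sequence) == 2500
        assert w.sequence == g["chr1"][8000:10500]

    def test_minus_strand_is_reverse_complement_of_mirror(self):
        g = self._genome()
        (w,) = extract_promoters([("t1", "chr1", 5000, "-")], g)
        assert (w.start, w.end) == (4501, 7001)
        assert w.sequence == reverse_complement(g["chr1"][4501:7001])

    def test_clipping_at_contig_edge_warns(self, caplog):
        g = self._genome()
        with caplog.at_level(logging.WARNING):
            (w,) = extract_promoters([("t1", "chr1", 100, "+")], g)
        assert len(w.sequence) == 600
        assert "clipped" in caplog.text

    def test_missing_contig_rejected(self):
        with pytest.raises(KeyError):
            extract_promoters([("t1", "chrZ", 5000, "+")], self._genome())


class TestScanWindow:
    def test_planted_consensus_recovered_at_offset(self, ega_pwm):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seq = "".join(bases[i] for i in rng.integers(0, 4, 400))
        inst = ega_pwm.sample(rng)
        window = seq[:123] + inst + seq[123 + 36:]
        hits = scan_window(window, ega_pwm, 1e-4)
        assert any(h.offset == 123 and h.strand == "+" for h in hits)

    def test_zero_information_pwm_is_all_or_none(self):
        pwm = build_pwm("NNNN", pseudocount=0.0)
        hits_loose = scan_window("ACGTACGT", pwm, p_threshold=1.0)
        hits_tight = scan_window("ACGTACGT", pwm, p_threshold=0.5)
        assert len(hits_loose) == 2 * (8 - 4 + 1)  # every offset, both strands
        assert hits_tight == []

    def test_reverse_complement_swaps_strand_and_mirrors_offset(self, ega_pwm):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        inst = ega_pwm.sample(rng)
        window = seq[:50] + inst + seq[50 + 36:]
        fwd = scan_window(window, ega_pwm, 1e-4)
        rev = scan_window(reverse_complement(window), ega_pwm, 1e-4)
        mirrored = {(len(window) - 36 - h.offset, {"+": "-", "-": "+"}[h.strand],
                     round(h.score, 6)) for h in fwd}
        assert {(h.offset, h.strand, round(h.score, 6)) for h in rev} == mirrored

    def test_window_shorter_than_motif_yields_no_hits(self, ega_pwm):
        assert scan_window("ACGT", ega_pwm, 1.0) == []

    def test_ambiguous_bases_score_as_background(self):
        pwm = build_pwm("AC", pseudocount=0.1)
        hit_n = scan_window("NN", pwm, p_threshold=1.0)
        assert len(hit_n) == 2
        assert all(h.score == 0.0 for h in hit_n)


class TestMotifEnrichment:
    def test_identical_sets_are_not_enriched(self, ega_pwm, random_windows):
        rng = np.random.default_rng(0)
        wins = random_windows(rng, 30)
        planted, _ = plant_motifs(wins, ega_pwm, 0.5, 0.5, set(), seed=1)
        rep = motif_enrichment(planted, planted, ega_pwm, 1e-4, seed=0)
        assert rep.target_hits == rep.control_hits
        assert rep.p_value == pytest.approx(1.0)

    def test_total_hits_invariant_under_window_reverse_complement(
        self, ega_pwm, random_windows
    ):
        rng = np.random.default_rng(1)
        wins = random_windows(rng, 40)
        planted, _ = plant_motifs(wins, ega_pwm, 0.6, 0.0, {w.id for w in wins}, seed=2)
        flipped = [
            PromoterWindow(w.id, w.chrom, w.start, w.end, w.strand,
                           reverse_complement(w.sequence))
            for w in planted
        ]
        rep_a = motif_enrichment(planted, planted, ega_pwm, 1e-4, seed=0)
        rep_b = motif_enrichment(flipped, flipped, ega_pwm, 1e-4, seed=0)
        assert rep_a.target_hits == rep_b.target_hits
        assert rep_a.target_windows_with_hit == rep_b.target_windows_with_hit

    def test_sizes_equalized_by_downsampling(self, ega_pwm, random_windows):
        rng = np.random.default_rng(2)
        rep = motif_enrichment(
            random_windows(rng, 20, tag="t"), random_windows(rng, 50, tag="c"),
            ega_pwm, 1e-4, seed=5,
        )
        assert rep.n_windows == 20

    def test_sweep_curves_monotone_in_threshold(self, ega_pwm, random_windows):
        rng = np.random.default_rng(3)
        t = random_windows(rng, 30, tag="t")
        c = random_windows(rng, 30, tag="c")
        t, _ = plant_motifs(t, ega_pwm, 0.5, 0.0, {w.id for w in t}, seed=1)
        rep = motif_enrichment(t, c, ega_pwm, 1e-4, seed=0)
        for col in ("target_hits", "control_hits",
                    "target_windows_with_hit", "control_windows_with_hit"):
            assert (np.diff(rep.sweep[col].to_numpy()) >= 0).all()

    def test_empty_control_rejected(self, ega_pwm, random_windows):
        wins = random_windows(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            motif_enrichment(wins, [], ega_pwm)
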