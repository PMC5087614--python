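"""TFE clustering and genomic annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egakit.tfe import (
    GeneModel,
    TFERecord,
    annotate_tfe,
    annotate_tfes,
    cluster_tags,
    tfe_to_gene,
)


def brute_force_clusters(positions, max_gap):
    """Transitive closure over the all-pairs |pi - pj| <= max_gap graph."""
    pos = sorted(positions)
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if abs(pos[i] - pos[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(pos):
        groups.setdefault(find(i), []).append(p)
    return sorted((min(g), max(g)) for g in groups.values())


class TestClusterTags:
    def test_single_cluster_with_modal_peak(self):
        recs = cluster_tags([100, 101, 103, 100], max_gap=5)
        assert len(recs) == 1
        assert (recs[0].start, recs[0].end) == (100, 104)
        assert recs[0].peak == 100  # 100 occurs twice

    def test_gap_exceeding_threshold_splits(self):
        recs = cluster_tags([100, 200], max_gap=50)
        assert len(recs) == 2

    def test_chain_linkage_merges_across_long_span(self):
        # pairwise distant ends joined through a chain of small gaps
        recs = cluster_tags([0, 5, 10, 15, 20], max_gap=5)
        assert len(recs) == 1 and recs[0].end - recs[0].start == 21

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(42)
        positions = rng.integers(0, 5000, size=1000).tolist()
        recs = cluster_tags(positions, max_gap=20)
        got = [(r.start, r.end - 1) for r in recs]
        assert got == brute_force_clusters(positions, 20)

    def test_tie_break_is_five_prime_most_on_strand(self):
        plus = cluster_tags([10, 10, 12, 12], max_gap=5, strand="+")
        minus = cluster_tags([10, 10, 12, 12], max_gap=5, strand="-")
        assert plus[0].peak == 10
        assert minus[0].peak == 12

    def test_every_tag_covered_exactly_once(self):
        rng = np.random.default_rng(0)
        positions = rng.integers(0, 2000, size=300)
        recs = cluster_tags(positions, max_gap=10)
        for p in positions:
            owners = [r for r in recs if r.start <= p < r.end]
            assert len(owners) == 1

    def test_negative_positions_rejected(self):
        with pytest.raises(ValueError):
            cluster_tags([-1, 5], max_gap=5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 500), min_size=1, max_size=60),
        st.integers(0, 30),
    )
    def test_order_invariance_and_gap_property(self, positions, max_gap):
        a = cluster_tags(positions, max_gap)
        b = cluster_tags(list(reversed(positions)), max_gap)
        assert [(r.start, r.end, r.peak) for r in a] == [(r.start, r.end, r.peak) for r in b]
        # adjacent TFEs are separated by more than max_gap
        for r1, r2 in zip(a, a[1:]):
            assert r2.start - (r1.end - 1) > max_gap


def brute_force_category(pos, strand, chrom, models):
    """Independent per-position membership check with explicit precedence."""
    ranks = []
    for g in models:
        if g.chrom != chrom or g.strand != strand:
            continue
        if not (g.tx_start <= pos < g.tx_end):
            continue
        exonic = any(s <= pos < e for s, e in g.exons)
        if g.cds_start is not None:
            utr5 = exonic and (pos < g.cds_start if g.strand == "+" else pos >= g.cds_end)
            if utr5:
                ranks.append((0, g.gene_id))
            elif exonic:
                ranks.append((1, g.gene_id))
            else:
                ranks.append((2, g.gene_id))
        else:
            ranks.append((3, g.gene_id))
    if not ranks:
        return "intergenic_novel", None
    r, gid = min(ranks)
    return ["utr5_coding", "coding_exon", "intron", "noncoding_gene"][r], gid


class TestAnnotateTFE:
    def _tfe(self, peak, strand="+", chrom="chr1"):
        return TFERecord("T1", chrom, peak, peak + 30, strand, peak)

    def test_peak_in_utr5_of_coding_gene(self, toy_gene_plus):
        rec = annotate_tfe(self._tfe(1100), [toy_gene_plus])
        assert rec.category == "utr5_coding" and rec.gene_id == "GENEP"

    def test_minus_strand_utr5_is_high_coordinate_end(self, toy_gene_minus):
        rec = annotate_tfe(self._tfe(6800, strand="-"), [toy_gene_minus])
        assert rec.category == "utr5_coding"

    def test_antisense_peak_is_intergenic(self, toy_gene_plus):
        rec = annotate_tfe(self._tfe(1900, strand="-"), [toy_gene_plus])
        assert rec.category == "intergenic_novel" and rec.gene_id is None

    def test_precedence_utr5_beats_intron(self, toy_gene_plus):
        overlapping = GeneModel("GENEX", "chr1", "+", 900, 2000, [(900, 950), (1900, 2000)],
                                cds_start=920, cds_end=1950)
        # peak 1100: 5'UTR of GENEP, intron of GENEX
        rec = annotate_tfe(self._tfe(1100), [overlapping, toy_gene_plus])
        assert rec.category == "utr5_coding" and rec.gene_id == "GENEP"

    def test_intron_and_threeprime_exon(self, toy_gene_plus):
        assert annotate_tfe(self._tfe(1500), [toy_gene_plus]).category == "intron"
        # exonic but 3' of the coding span still counts as exon of a coding gene
        assert annotate_tfe(self._tfe(2900), [toy_gene_plus]).category == "coding_exon"

    def test_matches_brute_force_oracle(self, toy_gene_plus, toy_gene_minus):
        rng = np.random.default_rng(3)
        models = [
            toy_gene_plus,
            toy_gene_minus,
            GeneModel("NC1", "chr1", "+", 3500, 4200, [(3500, 4200)]),
            GeneModel("GENEQ", "chr2", "-", 100, 1600,
                      [(100, 600), (1000, 1600)], cds_start=300, cds_end=1400),
        ]
        for _ in range(500):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            strand = "+-"[rng.integers(2)]
            peak = int(rng.integers(0, 8000))
            rec = annotate_tfe(self._tfe(peak, strand, chrom), models)
            cat, gid = brute_force_category(peak, strand, chrom, models)
            assert rec.category == cat
            if cat == "utr5_coding":
                assert rec.gene_id == gid

    def test_intron_assignments_have_no_exonic_overlap(self, toy_gene_plus, toy_gene_minus):
        rng = np.random.default_rng(11)
        models = [toy_gene_plus, toy_gene_minus]
        tfes = [self._tfe(int(rng.integers(0, 8000)), "+-"[rng.integers(2)])
                for _ in range(200)]
        for rec in annotate_tfes(tfes, models):
            if rec.category == "intron":
                g = next(m for m in models if m.gene_id == rec.gene_id)
                assert not g.exonic(rec.peak)


class TestTfeToGene:
    def _rec(self, i, category, gene_id=None):
        return TFERecord(f"T{i}", "chr1", 10 * i, 10 * i + 5, "+", 10 * i,
                         category=category, gene_id=gene_id)

    def test_deduplicates_genes(self):
        tfes = [self._rec(1, "utr5_coding", "G1"), self._rec(2, "utr5_coding", "G1")]
        assert tfe_to_gene(tfes) == {"G1"}

    def test_all_intergenic_is_empty(self):
        tfes = [self._rec(i, "intergenic_novel") for i in range(5)]
        assert tfe_to_gene(tfes) == set()

    def test_mixed_fixture(self):
        tfes = [
            self._rec(1, "utr5_coding", "G1"),
            self._rec(2, "utr5_coding", "G1"),
            self._rec(3, "utr5_coding", "G2"),
            self._rec(4, "utr5_coding", "G3"),
            self._rec(5, "coding_exon", "G4"),
            self._rec(6, "intron", "G5"),
            self._rec(7, "noncoding_gene", "N1"),
            self._rec(8, "intergenic_novel"),
            self._rec(9, "intergenic_novel"),
            self._rec(10, "intergenic_novel"),
        ]
        assert tfe_to_gene(tfes) == {"G1", "G2", "G3"}
        assert tfe_to_gene(tfes, restrict=("utr5_coding", "coding_exon")) == {
            "G1", "G2", "G3", "G4"
        }

    def test_unannotated_input_rejected(self):
        with pytest.raises(ValueError):
            tfe_to_gene([TFERecord("T", "chr1", 0, 5, "+", 0)])
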