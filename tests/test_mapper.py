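import numpy as np
import pytest

from gpga.engine import SearchParams
from gpga.mapper import (
    ExonHit,
    ExonQuery,
    GeneMapping,
    GeneQuery,
    annotate_junctions,
    classify_mapping,
    composition_flags,
    load_genes_fasta,
    map_gene,
)
from gpga.seqio import GenomicInterval, Sequence, reverse_complement, revcomp_str

from conftest import random_dna


def _gene_with_introns(rng, n_exons=3, e_len=60, i_len=80, canonical=True):
    """Coding-strand region + exon strings + exon offsets (0-based)."""
    exons = [random_dna(rng, e_len) for _ in range(n_exons)]
    introns = []
    for _ in range(n_exons - 1):
        intron = random_dna(rng, i_len)
        if canonical:
            intron = "GT" + intron[2:-2] + "AG"
        else:
            intron = "CT" + intron[2:-2] + "AC"
        introns.append(intron)
    region = exons[0]
    offsets = [(0, e_len)]
    for intr, ex in zip(introns, exons[1:]):
        region += intr
        start = len(region)
        region += ex
        offsets.append((start, start + e_len))
    return region, exons, offsets


def _params():
    return SearchParams(pop_size=120, seed=42)


class TestMapGene:
    def test_plus_strand_planted_gene(self, rng):
        region, exons, offsets = _gene_with_introns(rng)
        Q = random_dna(rng, 300) + region + random_dna(rng, 300)
        query = Sequence("q", Q)
        gene = GeneQuery("g", tuple(ExonQuery("g", i + 1, s) for i, s in enumerate(exons)))
        m = map_gene(gene, query, _params())
        assert m.strand == "+"
        assert m.combined_similarity == 1.0
        assert m.classification == "conserved_gene"
        assert all(h.passed for h in m.hits)
        for h, (s, e) in zip(m.hits, offsets):
            assert (h.interval.start, h.interval.end) == (301 + s, 300 + e)

    def test_minus_strand_reported_in_forward_coordinates(self, rng):
        region, exons, _ = _gene_with_introns(rng)
        Qf = random_dna(rng, 300) + region + random_dna(rng, 300)
        query_minus = Sequence("q", revcomp_str(Qf))
        gene = GeneQuery("g", tuple(ExonQuery("g", i + 1, s) for i, s in enumerate(exons)))
        m_plus = map_gene(gene, Sequence("q", Qf), _params())
        m_minus = map_gene(gene, query_minus, _params())
        assert m_minus.strand == "-"
        assert m_minus.combined_similarity == m_plus.combined_similarity == 1.0
        q = len(Qf)
        mirrored = {(q - h.interval.end + 1, q - h.interval.start + 1)
                    for h in m_plus.hits}
        got = {(h.interval.start, h.interval.end) for h in m_minus.hits}
        assert got == mirrored

    def test_combined_similarity_rescues_failing_exons(self):
        # per-exon similarities 0.55, 0.58, 0.70 on 100 bp exons -> 0.61
        gene = GeneQuery("g", tuple(ExonQuery("g", i, "A" * 100) for i in (1, 2, 3)))
        hits = [
            ExonHit(gene.exons[i], GenomicInterval("q", 1 + 200 * i, 100 + 200 * i),
                    fit, fit / 100, fit / 100 >= 0.60)
            for i, fit in enumerate((55, 58, 70))
        ]
        combined = (55 + 58 + 70) / 300
        m = GeneMapping(gene, "+", hits, combined)
        m = classify_mapping(m, mode="benchmark", min_similarity=0.60)
        assert combined == pytest.approx(0.61)
        assert m.classification == "conserved_gene"

    def test_below_threshold_rejected(self):
        gene = GeneQuery("g", (ExonQuery("g", 1, "A" * 100),))
        hits = [ExonHit(gene.exons[0], GenomicInterval("q", 1, 100), 40, 0.40, False)]
        m = GeneMapping(gene, "+", hits, 0.40)
        assert classify_mapping(m, mode="benchmark").classification == "rejected"

    def test_exon_longer_than_query_names_exon(self):
        gene = GeneQuery("g", (ExonQuery("g", 1, "A" * 50),))
        with pytest.raises(ValueError, match="g.1"):
            map_gene(gene, Sequence("q", "ACGT" * 10), _params())


def _mapping_with_similarities(sims, e=100):
    gene = GeneQuery("g", tuple(ExonQuery("g", i + 1, "A" * e) for i in range(len(sims))))
    hits = [
        ExonHit(gene.exons[i], GenomicInterval("q", 1 + 200 * i, e + 200 * i),
                int(s * e), s, s >= 0.60)
        for i, s in enumerate(sims)
    ]
    total = sum(int(s * e) for s in sims) / (e * len(sims))
    return GeneMapping(gene, "+", hits, total)


class TestClassifyMapping:
    def test_all_pass_is_conserved(self):
        m = _mapping_with_similarities([0.8] * 5)
        m = classify_mapping(m, mode="conservation", L=100, P=0.70)
        assert m.classification == "conserved_gene"
        assert m.blocks == []

    def test_internal_only_is_overlapping_with_blocks(self):
        m = _mapping_with_similarities([0.5, 0.9, 0.9, 0.9, 0.5])
        m = classify_mapping(m, mode="conservation", L=100, P=0.70)
        assert m.classification == "overlapping"
        assert len(m.blocks) == 3
        assert all(b.similarity >= 0.70 for b in m.blocks)

    def test_five_prime_partial(self):
        m = _mapping_with_similarities([0.9, 0.9, 0.5])
        m = classify_mapping(m, mode="conservation", L=100, P=0.70)
        assert m.classification == "partial_5prime"

    def test_three_prime_partial(self):
        m = _mapping_with_similarities([0.5, 0.9, 0.9])
        m = classify_mapping(m, mode="conservation", L=100, P=0.70)
        assert m.classification == "partial_3prime"

    def test_none_pass_is_rejected(self):
        m = _mapping_with_similarities([0.5, 0.5])
        m = classify_mapping(m, mode="conservation", L=100, P=0.70)
        assert m.classification == "rejected"

    def test_short_exons_exempt_from_length_not_similarity(self):
        m = _mapping_with_similarities([0.9, 0.9], e=40)  # shorter than L=100
        m = classify_mapping(m, mode="conservation", L=100, P=0.70)
        assert m.classification == "conserved_gene"
        m2 = _mapping_with_similarities([0.9, 0.5], e=40)
        m2 = classify_mapping(m2, mode="conservation", L=100, P=0.70)
        assert m2.classification != "conserved_gene"

    def test_invalid_stringency_errors(self):
        m = _mapping_with_similarities([0.9])
        with pytest.raises(ValueError):
            classify_mapping(m, mode="conservation", L=0, P=0.7)
        with pytest.raises(ValueError):
            classify_mapping(m, mode="conservation", L=100, P=1.5)
        with pytest.raises(ValueError):
            classify_mapping(m, mode="nope")


def _exact_mapping_on(query_res, spans, strand="+"):
    """Build a GeneMapping whose hits are exact windows of the query."""
    q = len(query_res)
    exons = []
    hits = []
    for i, (s, e) in enumerate(spans, start=1):
        window = query_res[s - 1 : e]
        coding = window if strand == "+" else revcomp_str(window)
        x = ExonQuery("g", i, coding)
        exons.append(x)
        hits.append(ExonHit(x, GenomicInterval("q", s, e, strand), e - s + 1, 1.0, True))
    # spans are given in coding (exon_index) order for either strand
    gene = GeneQuery("g", tuple(exons))
    return GeneMapping(gene, strand, hits, 1.0, classification="conserved_gene")


class TestJunctions:
    def test_canonical_intron_flagged(self):
        q = "AAAA" + "CCCGGG" + "GT" + "TTTTT" + "AG" + "ACGACG" + "AAAA"
        #    1-4    5-10 exon1  11-19 intron     20-25 exon2
        m = _exact_mapping_on(q, [(5, 10), (20, 25)])
        m = annotate_junctions(m, Sequence("q", q))
        assert m.junctions == ["canonical_GT_AG"]

    def test_non_canonical_intron_flagged(self):
        q = "AAAA" + "CCCGGG" + "CT" + "TTTTT" + "AC" + "ACGACG" + "AAAA"
        m = _exact_mapping_on(q, [(5, 10), (20, 25)])
        m = annotate_junctions(m, Sequence("q", q))
        assert m.junctions == ["non_canonical"]

    def test_minus_strand_intron_read_on_coding_strand(self):
        coding = "CCCGGG" + "GT" + "TTTTT" + "AG" + "ACGACG"
        q = "AAAA" + revcomp_str(coding) + "AAAA"
        # forward spans of the two coding exons inside the insert
        # insert occupies forward 5..25; coding exon1 (offsets 0..6) maps to
        # forward 20..25, coding exon2 (offsets 15..21) maps to forward 5..10
        m = _exact_mapping_on(q, [(20, 25), (5, 10)], strand="-")
        m = annotate_junctions(m, Sequence("q", q))
        assert m.junctions == ["canonical_GT_AG"]

    def test_out_of_order_hits_demote_to_conserved_block(self):
        q = "A" * 60
        m = _exact_mapping_on(q, [(30, 40), (10, 20)])
        m = annotate_junctions(m, Sequence("q", q))
        assert m.junctions == []
        assert m.classification == "conserved_block"

    def test_single_exon_returns_unchanged(self):
        q = "A" * 30
        m = _exact_mapping_on(q, [(5, 12)])
        m = annotate_junctions(m, Sequence("q", q))
        assert m.junctions == []

    def test_intronless_heuristic(self):
        q = "CCCGGG" + "ATAT" + "ACGACG" + "AAAA"
        m = _exact_mapping_on(q, [(1, 6), (11, 16)])
        m = annotate_junctions(m, Sequence("q", q))
        assert m.intronless is True


class TestComposition:
    def test_gc_all(self):
        q = "GCGC" + "A" * 10
        m = _exact_mapping_on(q, [(1, 4)])
        m = composition_flags(m, Sequence("q", q))
        assert m.gc_percent == 1.0

    def test_premature_stop_detected(self):
        q = "ATGAAATAACCCGGG"  # TAA at codon 3 of 5
        m = _exact_mapping_on(q, [(1, 15)])
        m = composition_flags(m, Sequence("q", q))
        assert m.premature_stop is True

    def test_terminal_stop_not_premature(self):
        q = "ATGAAATAA"  # TAA is the final codon
        m = _exact_mapping_on(q, [(1, 9)])
        m = composition_flags(m, Sequence("q", q))
        assert m.premature_stop is False

    def test_no_stop(self):
        q = "ATGAAACCC"
        m = _exact_mapping_on(q, [(1, 9)])
        m = composition_flags(m, Sequence("q", q))
        assert m.premature_stop is False

    def test_n_excluded_from_gc_denominator(self):
        q = "GCNN" + "A" * 6
        m = _exact_mapping_on(q, [(1, 4)])
        m = composition_flags(m, Sequence("q", q))
        assert m.gc_percent == 1.0


def test_load_genes_fasta_headers(tmp_path):
    p = tmp_path / "genes.fa"
    p.write_text(
        ">gA|2 target=seq1\nCCCC\n>gA|1 target=seq1\nAAAA\n>gB|1\nGGGG\n"
    )
    genes = {g.gene_id: g for g in load_genes_fasta(p)}
    assert [x.exon_index for x in genes["gA"].exons] == [1, 2]
    assert genes["gA"].exons[0].residues == "AAAA"
    assert genes["gA"].target_seq_id == "seq1"
    assert genes["gB"].target_seq_id is None


def test_gene_query_requires_consecutive_indices():
    with pytest.raises(ValueError):
        GeneQuery("g", (ExonQuery("g", 1, "AA"), ExonQuery("g", 3, "CC")))
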