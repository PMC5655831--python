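"""Gene-level mapping: per-exon search on both strands, acceptance
thresholds, classification, junction and composition annotation.

A reference gene is an ordered set of exon sequences.  Each exon is
localized independently by the genetic search on the plus strand and on
the reverse complement of the query; the strand with the higher
combined similarity wins (combined similarity is length-weighted:
total fitness over total exon length).  A mapping is retained when the
combined similarity reaches the acceptance threshold (60% by default)
or when every exon passes individually.

Classification follows the cross-species conservation scheme: a gene is
conserved when all its exons pass the stringency; genes with only the
5' or only the 3' terminal exon passing are partial; genes where both
terminal exons fail but an internal exon passes are overlapping.
Individually passing exons of a non-conserved gene are emitted
separately as conserved blocks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

from .engine import SearchParams, search_exon
from .seqio import (
    GenomicInterval,
    Sequence,
    VALID_ALPHABET,
    minus_to_forward,
    reverse_complement,
    revcomp_str,
)

DEFAULT_MIN_SIMILARITY = 0.60

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ExonQuery:
    """One reference exon: gene id, 1-based order within the gene, sequence."""

    gene_id: str
    exon_index: int
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"exon {self.gene_id}.{self.exon_index} is empty")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"exon {self.gene_id}.{self.exon_index}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneQuery:
    """An ordered set of reference exons forming one gene.

    ``target_seq_id`` optionally names the query record this gene is a
    known homolog of (the customized-dataset association); the pipeline
    then searches only that record instead of every record.
    """

    gene_id: str
    exons: tuple[ExonQuery, ...]
    target_seq_id: str | None = None

    def __post_init__(self) -> None:
        idx = [x.exon_index for x in self.exons]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(
                f"gene {self.gene_id}: exon_index must be consecutive 1..m, got {idx}"
            )


@dataclass(frozen=True)
class ExonHit:
    exon: ExonQuery
    interval: GenomicInterval
    fitness: int
    similarity: float
    passed: bool


@dataclass
class GeneMapping:
    gene: GeneQuery
    strand: str
    hits: list[ExonHit]
    combined_similarity: float
    classification: str = "rejected"
    junctions: list[str] = field(default_factory=list)  # per inferred intron
    gc_percent: float | None = None
    premature_stop: bool | None = None
    intronless: bool | None = None  # all inferred introns < 10 bp (retroposon hint)
    blocks: list[ExonHit] = field(default_factory=list)  # conserved-block records

    @property
    def seq_id(self) -> str:
        return self.hits[0].interval.seq_id


def exon_rng_offset(gene_id: str, exon_index: int, strand: str) -> int:
    """Stable per-exon RNG stream offset (order-independent reproducibility)."""
    return zlib.crc32(f"{gene_id}|{exon_index}|{strand}".encode())


def map_gene(
    gene: GeneQuery,
    query: Sequence,
    params: SearchParams,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> GeneMapping:
    """Localize every exon of ``gene`` on both strands of ``query``.

    Returns the strand whose combined similarity is higher (tie: plus).
    The mapping is retained (classification ``conserved_gene``) when
    combined similarity >= ``min_similarity`` or every exon passes
    individually; otherwise it is ``rejected``.
    """
    q = len(query.residues)
    for x in gene.exons:
        if len(x) > q:
            raise ValueError(
                f"exon {x.gene_id}.{x.exon_index} (length {len(x)}) "
                f"longer than query {query.id} (length {q})"
            )
    rc_query = reverse_complement(query)

    candidates: dict[str, tuple[list[ExonHit], float]] = {}
    for strand, target in (("+", query), ("-", rc_query)):
        hits: list[ExonHit] = []
        total_fit = 0
        total_len = 0
        for x in gene.exons:
            best, _trace = search_exon(
                x, target, params, rng_offset=exon_rng_offset(gene.gene_id, x.exon_index, strand)
            )
            e = len(x)
            if strand == "+":
                start, end = best.position, best.position + e - 1
            else:
                start, end = minus_to_forward(best.position, e, q)
            sim = best.fitness / e
            hits.append(
                ExonHit(
                    exon=x,
                    interval=GenomicInterval(query.id, start, end, strand),
                    fitness=best.fitness,
                    similarity=sim,
                    passed=sim >= min_similarity,
                )
            )
            total_fit += best.fitness
            total_len += e
        candidates[strand] = (hits, total_fit / total_len)

    plus_sim = candidates["+"][1]
    minus_sim = candidates["-"][1]
    strand = "+" if plus_sim >= minus_sim else "-"
    hits, combined = candidates[strand]

    retained = combined >= min_similarity or all(h.passed for h in hits)
    return GeneMapping(
        gene=gene,
        strand=strand,
        hits=hits,
        combined_similarity=combined,
        classification="conserved_gene" if retained else "rejected",
    )


def classify_mapping(
    m: GeneMapping,
    mode: str = "benchmark",
    L: int = 100,
    P: float = 0.70,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> GeneMapping:
    """Classify a mapping under benchmark or conservation stringency.

    Benchmark mode applies only the combined-similarity acceptance rule
    of :func:`map_gene`.  Conservation mode applies a per-exon
    stringency (similarity >= P; exons shorter than L are exempt from
    the length criterion but not the similarity one) and assigns the
    conserved / partial / overlapping / conserved-block classes.
    Individually passing exons of a non-conserved gene are emitted as
    conserved-block records in ``blocks``.
    """
    if mode not in ("benchmark", "conservation"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "benchmark":
        retained = m.combined_similarity >= min_similarity or all(
            h.passed for h in m.hits
        )
        m.classification = "conserved_gene" if retained else "rejected"
        return m

    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 < P <= 1.0):
        raise ValueError("P must lie in (0, 1]")

    # Stringency: similarity >= P always; the length criterion (>= L) is
    # trivially met by exons of length >= L and waived for shorter ones.
    passing = [h.similarity >= P for h in m.hits]
    m.blocks = []
    if all(passing):
        m.classification = "conserved_gene"
        return m

    # passing exons of a non-conserved gene become conserved blocks
    m.blocks = [h for h, ok in zip(m.hits, passing) if ok]
    if not any(passing):
        m.classification = "rejected"
    elif passing[0] and not passing[-1]:
        m.classification = "partial_5prime"
    elif passing[-1] and not passing[0]:
        m.classification = "partial_3prime"
    elif not passing[0] and not passing[-1]:
        m.classification = "overlapping"
    else:
        # both terminal exons pass but an internal one fails: no class of
        # its own in the scheme; keep the passing pieces as blocks only
        m.classification = "conserved_block"
    return m


def _coding_positions(hit: ExonHit, q: int) -> tuple[int, int]:
    """1-based start/end of a hit on its coding strand's coordinate system."""
    if hit.interval.strand == "+":
        return hit.interval.start, hit.interval.end
    start_rc = q - hit.interval.end + 1
    end_rc = q - hit.interval.start + 1
    return start_rc, end_rc


def annotate_junctions(m: GeneMapping, query: Sequence) -> GeneMapping:
    """Flag each inferred intron as canonical GT-AG or not.

    Introns are the gaps between consecutive exon hits read along the
    coding strand.  An intron is canonical when its first two bases are
    GT and its last two are AG on the coding strand.  Hits that are out
    of order or overlap on the coding strand leave no valid introns and
    demote the gene to conserved-block status.
    """
    m.junctions = []
    if len(m.hits) < 2:
        m.intronless = None
        return m
    q = len(query.residues)
    coding_seq = (
        query.residues if m.strand == "+" else revcomp_str(query.residues)
    )
    spans = [_coding_positions(h, q) for h in m.hits]
    intron_lengths: list[int] = []
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:  # out of order or overlapping: no valid intron structure
            m.junctions = []
            m.intronless = None
            if m.classification not in ("rejected",):
                m.classification = "conserved_block"
            return m
        intron = coding_seq[e1 : s2 - 1]  # 0-based slice of (e1+1 .. s2-1)
        intron_lengths.append(len(intron))
        if len(intron) >= 4 and intron.startswith("GT") and intron.endswith("AG"):
            m.junctions.append("canonical_GT_AG")
        else:
            m.junctions.append("non_canonical")
    m.intronless = all(n < 10 for n in intron_lengths)
    return m


def composition_flags(m: GeneMapping, query: Sequence) -> GeneMapping:
    """GC fraction and premature-stop flag over the concatenated hit windows.

    Windows are read on the coding strand in exon order and concatenated;
    GC excludes N from the denominator; the stop scan reads frame 0 and
    flags TAA/TAG/TGA strictly before the final codon.
    """
    parts = []
    for h in m.hits:
        w = query.residues[h.interval.start - 1 : h.interval.end]
        parts.append(w if m.strand == "+" else revcomp_str(w))
    if m.strand == "-":
        # exon order along the coding strand is already the exon_index order
        pass
    cds = "".join(parts)
    if not cds:
        raise ValueError("empty concatenated coding sequence")
    gc = sum(cds.count(b) for b in "GC")
    acgt = sum(cds.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("concatenated coding sequence is all N")
    m.gc_percent = gc / acgt
    n_codons = len(cds) // 3
    m.premature_stop = any(
        cds[3 * i : 3 * i + 3] in _STOP_CODONS for i in range(max(n_codons - 1, 0))
    )
    return m


# ---------------------------------------------------------------------------
# Pipeline and reference-gene loading
# ---------------------------------------------------------------------------


def load_genes_fasta(path) -> list[GeneQuery]:
    """Load reference genes from a multi-FASTA with ``>geneId|exonIndex``
    headers.  A ``target=<seq_id>`` token in the description associates
    the gene with a query record."""
    from .seqio import read_fasta

    by_gene: dict[str, list[tuple[int, str]]] = {}
    targets: dict[str, str] = {}
    for rec in read_fasta(path):
        if "|" not in rec.id:
            raise ValueError(
                f"reference exon header {rec.id!r} lacks the geneId|exonIndex form"
            )
        gene_id, idx_s = rec.id.rsplit("|", 1)
        by_gene.setdefault(gene_id, []).append((int(idx_s), rec.residues))
        if rec.description:
            for tok in rec.description.split():
                if tok.startswith("target="):
                    targets[gene_id] = tok.split("=", 1)[1]
    genes = []
    for gene_id, items in by_gene.items():
        items.sort()
        genes.append(
            GeneQuery(
                gene_id=gene_id,
                exons=tuple(
                    ExonQuery(gene_id, i, res) for i, res in items
                ),
                target_seq_id=targets.get(gene_id),
            )
        )
    return genes


def load_genes_gff(gff_path, fasta_path) -> list[GeneQuery]:
    """Extract reference exon sequences from a genome FASTA + GFF3."""
    from .seqio import read_fasta

    seqs = {s.id: s for s in read_fasta(fasta_path)}
    per_gene: dict[str, list[tuple[int, int, str, str]]] = {}
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("Parent") or attrs.get("ID", "gene")
            per_gene.setdefault(gene_id, []).append(
                (int(cols[3]), int(cols[4]), cols[6], cols[0])
            )
    genes = []
    for gene_id, feats in per_gene.items():
        strand = feats[0][2]
        seq_id = feats[0][3]
        feats.sort()
        if strand == "-":
            feats = feats[::-1]  # coding order runs right-to-left on minus
        exons = []
        for i, (start, end, st, sid) in enumerate(feats, start=1):
            window = seqs[sid].residues[start - 1 : end]
            if st == "-":
                window = revcomp_str(window)
            exons.append(ExonQuery(gene_id, i, window))
        genes.append(GeneQuery(gene_id, tuple(exons), target_seq_id=seq_id))
    return genes


@dataclass
class AnnotationSummary:
    n_genes_searched: int = 0
    n_genes_retained: int = 0
    n_conserved_genes: int = 0
    n_conserved_blocks: int = 0
    n_partial_5prime: int = 0
    n_partial_3prime: int = 0
    n_overlapping: int = 0
    n_exons_retained: int = 0
    n_canonical_junctions: int = 0
    n_non_canonical_junctions: int = 0
    n_premature_stop: int = 0
    mean_gc_percent: float | None = None

    def format(self) -> str:
        lines = [
            f"genes searched              {self.n_genes_searched}",
            f"genes retained              {self.n_genes_retained}",
            f"  conserved genes           {self.n_conserved_genes}",
            f"  partial (5' matched)      {self.n_partial_5prime}",
            f"  partial (3' matched)      {self.n_partial_3prime}",
            f"  overlapping               {self.n_overlapping}",
            f"conserved blocks            {self.n_conserved_blocks}",
            f"exons in retained genes     {self.n_exons_retained}",
            f"junctions GT-AG             {self.n_canonical_junctions}",
            f"junctions non-GT-AG         {self.n_non_canonical_junctions}",
            f"premature-stop flags        {self.n_premature_stop}",
        ]
        if self.mean_gc_percent is not None:
            lines.append(f"GC%%                        {100 * self.mean_gc_percent:.2f}")
        return "\n".join(lines)


def annotate(
    queries: list[Sequence],
    genes: list[GeneQuery],
    params: SearchParams,
    mode: str = "benchmark",
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    L: int = 100,
    P: float = 0.70,
) -> tuple[list[GeneMapping], AnnotationSummary]:
    """Map every reference gene onto the query records and annotate.

    Genes with a ``target_seq_id`` are searched only on that record;
    others are searched on every record and the best combined
    similarity wins.  Returns all non-rejected mappings plus a summary.
    """
    by_id = {s.id: s for s in queries}
    results: list[GeneMapping] = []
    summary = AnnotationSummary()
    for gene in genes:
        summary.n_genes_searched += 1
        if gene.target_seq_id is not None:
            if gene.target_seq_id not in by_id:
                raise ValueError(
                    f"gene {gene.gene_id} targets unknown record {gene.target_seq_id!r}"
                )
            candidates = [by_id[gene.target_seq_id]]
        else:
            candidates = queries
        best: GeneMapping | None = None
        best_query: Sequence | None = None
        for qseq in candidates:
            m = map_gene(gene, qseq, params, min_similarity=min_similarity)
            if best is None or m.combined_similarity > best.combined_similarity:
                best, best_query = m, qseq
        assert best is not None and best_query is not None
        m = classify_mapping(best, mode=mode, L=L, P=P, min_similarity=min_similarity)
        if m.classification == "rejected" and not m.blocks:
            continue
        m = annotate_junctions(m, best_query)
        m = composition_flags(m, best_query)
        results.append(m)

        if m.classification != "rejected":
            summary.n_genes_retained += 1
            summary.n_exons_retained += len(m.hits)
        summary.n_conserved_genes += m.classification == "conserved_gene"
        summary.n_partial_5prime += m.classification == "partial_5prime"
        summary.n_partial_3prime += m.classification == "partial_3prime"
        summary.n_overlapping += m.classification == "overlapping"
        summary.n_conserved_blocks += len(m.blocks)
        summary.n_canonical_junctions += sum(
            j == "canonical_GT_AG" for j in m.junctions
        )
        summary.n_non_canonical_junctions += sum(
            j == "non_canonical" for j in m.junctions
        )
        summary.n_premature_stop += bool(m.premature_stop)
    gcs = [m.gc_percent for m in results if m.gc_percent is not None]
    if gcs:
        summary.mean_gc_percent = sum(gcs) / len(gcs)
    return results, summary
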