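"""Synthetic planted-gene genomes for offline testing and benchmarking.

The generator emulates the two benchmark regimes the method is aimed
at: single-gene genomic sequences of a few kilobases (one multi-exon
gene per record, as in curated single-gene benchmark sets) and longer
multi-gene records (several genes per record).  Each record is i.i.d.
random background at a chosen GC content with non-overlapping genes
planted on either strand; genes are ordered exons separated by introns
whose termini can be forced to the canonical GT..AG dinucleotides.

Homolog queries are derived from the planted exons by i.i.d. point
substitution at a configurable per-site divergence rate — no indels,
matching the ungapped scoring model.  The truth annotation records the
exact planted coordinates and strands, so every other module can be
evaluated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapper import ExonQuery, GeneQuery
from .seqio import GenomicInterval, Sequence, revcomp_str

_BASES = np.array(list("ACGT"))
_GAP_MARGIN = 20  # minimum background run between/around planted genes


@dataclass
class SimConfig:
    seed: int = 0
    n_sequences: int = 5
    sequence_length: int = 5000
    genes_per_sequence: float = 1.0
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (60, 200)
    intron_length: tuple[int, int] = (200, 800)
    gc_background: float = 0.45
    divergence: float = 0.0
    canonical_fraction: float = 1.0
    strand_minus_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 0.4):
            raise ValueError(
                "divergence must lie in [0, 0.4): beyond that the 60% "
                "acceptance threshold loses meaning"
            )
        if self.intron_length[0] < 4:
            raise ValueError("introns must be >= 4 bp (room for GT..AG)")
        for name in ("canonical_fraction", "strand_minus_fraction", "gc_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]  # forward coordinates, coding order
    exon_seqs: tuple[str, ...]  # coding-strand exon sequences
    canonical_introns: tuple[bool, ...]  # per intron, coding order


@dataclass
class SimBundle:
    config: SimConfig
    sequences: list[Sequence]
    genes: list[PlantedGene]
    homologs: list[GeneQuery]

    def truth_exons(self) -> list[GenomicInterval]:
        return [iv for g in self.genes for iv in g.exons]

    def write(self, out_dir: str | Path) -> None:
        from .seqio import write_fasta

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out_dir / "query.fa")
        self.write_truth_gff3(out_dir / "truth.gff3")
        self.write_homologs_fasta(out_dir / "homologs.fa")

    def write_truth_gff3(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                g_start = min(iv.start for iv in g.exons)
                g_end = max(iv.end for iv in g.exons)
                fh.write(
                    f"{g.seq_id}\tsim\tgene\t{g_start}\t{g_end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
                for i, iv in enumerate(g.exons, start=1):
                    fh.write(
                        f"{iv.seq_id}\tsim\texon\t{iv.start}\t{iv.end}\t.\t"
                        f"{iv.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    def write_homologs_fasta(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for gq in self.homologs:
                for x in gq.exons:
                    fh.write(f">{x.gene_id}|{x.exon_index} target={gq.target_seq_id}\n")
                    fh.write(x.residues + "\n")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """i.i.d. point substitution at ``rate`` per site (no indels)."""
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[str, list[tuple[int, int]], list[bool]]:
    """Coding-strand gene region, exon (start, end) offsets inside it
    (0-based half-open), and per-intron canonical flags."""
    m = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    parts: list[str] = []
    exon_offsets: list[tuple[int, int]] = []
    canonical: list[bool] = []
    pos = 0
    for i in range(m):
        e_len = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exon = _random_seq(rng, e_len, cfg.gc_background)
        parts.append(exon)
        exon_offsets.append((pos, pos + e_len))
        pos += e_len
        if i < m - 1:
            i_len = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            intron = _random_seq(rng, i_len, cfg.gc_background)
            is_canon = rng.random() < cfg.canonical_fraction
            if is_canon:
                intron = "GT" + intron[2:-2] + "AG"
            else:
                # make sure a non-canonical intron is really non-canonical
                if intron.startswith("GT"):
                    intron = "CT" + intron[2:]
                if intron.endswith("AG"):
                    intron = intron[:-2] + "AC"
            canonical.append(is_canon)
            parts.append(intron)
            pos += i_len
    return "".join(parts), exon_offsets, canonical


def generate(config: SimConfig) -> SimBundle:
    """Generate query records, planted-gene truth, and homolog queries."""
    rng = np.random.default_rng(config.seed)
    sequences: list[Sequence] = []
    planted: list[PlantedGene] = []
    homologs: list[GeneQuery] = []

    for s in range(config.n_sequences):
        seq_id = f"seq{s + 1}"
        frac = config.genes_per_sequence
        n_genes = int(frac) + (rng.random() < frac - int(frac))
        n_genes = max(n_genes, 0)

        regions = [_build_gene(rng, config) for _ in range(n_genes)]
        total_gene_len = sum(len(r[0]) for r in regions)
        n_gaps = n_genes + 1
        spare = config.sequence_length - total_gene_len - n_gaps * _GAP_MARGIN
        if spare < 0:
            raise ValueError(
                f"planted features do not fit: need at least "
                f"{total_gene_len + n_gaps * _GAP_MARGIN} bp, "
                f"sequence_length is {config.sequence_length}"
            )
        # split the spare background among the gaps
        cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1)) if n_gaps > 1 else []
        gap_extra = np.diff(np.concatenate(([0], cuts, [spare]))) if n_gaps > 1 else [spare]

        chunks: list[str] = []
        pos = 0  # 0-based forward cursor
        for k, (region, exon_offsets, canonical) in enumerate(regions):
            gap_len = _GAP_MARGIN + int(gap_extra[k])
            chunks.append(_random_seq(rng, gap_len, config.gc_background))
            pos += gap_len
            strand = "-" if rng.random() < config.strand_minus_fraction else "+"
            insert = region if strand == "+" else revcomp_str(region)
            chunks.append(insert)
            gene_id = f"{seq_id}_g{k + 1}"
            exon_ivs: list[GenomicInterval] = []
            exon_seqs: list[str] = []
            for off_s, off_e in exon_offsets:
                if strand == "+":
                    start = pos + off_s + 1
                    end = pos + off_e
                else:
                    # coding offset off_s..off_e maps to the mirrored
                    # forward window inside the inserted revcomp region
                    start = pos + len(region) - off_e + 1
                    end = pos + len(region) - off_s
                exon_ivs.append(GenomicInterval(seq_id, start, end, strand))
                exon_seqs.append(region[off_s:off_e])
            planted.append(
                PlantedGene(
                    gene_id=gene_id,
                    seq_id=seq_id,
                    strand=strand,
                    exons=tuple(exon_ivs),
                    exon_seqs=tuple(exon_seqs),
                    canonical_introns=tuple(canonical),
                )
            )
            pos += len(region)
        chunks.append(
            _random_seq(rng, _GAP_MARGIN + int(gap_extra[-1]), config.gc_background)
        )
        sequences.append(Sequence(id=seq_id, residues="".join(chunks)))

    for g in planted:
        exons = tuple(
            ExonQuery(g.gene_id, i + 1, _mutate(rng, s, config.divergence))
            for i, s in enumerate(g.exon_seqs)
        )
        homologs.append(
            GeneQuery(gene_id=g.gene_id, exons=exons, target_seq_id=g.seq_id)
        )

    return SimBundle(
        config=config, sequences=sequences, genes=planted, homologs=homologs
    )


def hmr_like(seed: int, divergence: float = 0.0, **overrides) -> SimBundle:
    """Single-gene regime: 20 records of ~7 kb, exactly one gene each."""
    cfg = SimConfig(
        seed=seed,
        n_sequences=20,
        sequence_length=7000,
        genes_per_sequence=1.0,
        exons_per_gene=(3, 5),
        exon_length=(60, 200),
        intron_length=(200, 800),
        divergence=divergence,
        **overrides,
    )
    return generate(cfg)


def sag_like(seed: int, divergence: float = 0.0, **overrides) -> SimBundle:
    """Multi-gene regime: 3 records of ~60 kb with ~4 genes each
    (scaled down from chromosome-scale records for desk runtime)."""
    cfg = SimConfig(
        seed=seed,
        n_sequences=3,
        sequence_length=60000,
        genes_per_sequence=4.0,
        exons_per_gene=(3, 5),
        exon_length=(60, 200),
        intron_length=(200, 800),
        divergence=divergence,
        **overrides,
    )
    return generate(cfg)


def duplicated_short_exon(
    seed: int, e: int = 18, q: int = 2000, positions: tuple[int, int] = (301, 1401)
) -> tuple[Sequence, ExonQuery, tuple[int, int]]:
    """A query with the same short exon planted verbatim at two sites.

    Reproduces the known failure mode of position searches for short
    exons: with two equally optimal placements the search returns one
    or the other depending on the random seed.
    """
    rng = np.random.default_rng(seed)
    exon = _random_seq(rng, e, 0.5)
    bg = list(_random_seq(rng, q, 0.5))
    for p in positions:
        bg[p - 1 : p - 1 + e] = exon
    query = Sequence(id="dup", residues="".join(bg))
    # re-plant to guarantee no accidental third exact copy is closer
    return query, ExonQuery("dup_exon", 1, exon), positions
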