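"""Sequence and annotation I/O.

Conventions used throughout the package:

* Coordinates are 1-based inclusive at every external boundary (FASTA
  headers, GFF3, TSV reports) — the convention of GFF3 and of genome
  annotation files generally.  Internal array arithmetic is 0-based
  half-open; the conversion happens only here and in the coordinate
  helpers below.
* Hits on the minus strand are reported in forward-strand coordinates
  with ``strand="-"`` so that downstream evaluation is strand-agnostic
  on positions.
* Residues are uppercased on load; anything outside ``{A,C,G,T,N}``
  (IUPAC ambiguity codes, gap characters from soft-masked sources) is
  mapped to ``N`` and counted in a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 encoding used by the scoring hot path: A,C,G,T -> 0..3, N -> 4.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
N_CODE = 4


@dataclass
class Sequence:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}; "
                "normalize with normalize_residues() first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """uint8 encoding (A,C,G,T -> 0..3, N -> 4) for fast comparison."""
        return _ENCODE[np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)]


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase ``raw`` and map non-ACGTN characters to N.

    Returns the normalized string and the number of characters replaced.
    """
    up = raw.upper()
    replaced = sum(1 for c in up if c not in VALID_ALPHABET)
    if replaced:
        up = "".join(c if c in VALID_ALPHABET else "N" for c in up)
    return up, replaced


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (multi-)FASTA file into a list of :class:`Sequence`.

    Residues are uppercased; characters outside {A,C,G,T,N} are mapped to
    N with a logged warning count.  Duplicate record ids and empty files
    are errors.
    """
    path = Path(path)
    records = list(_BioSeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out: list[Sequence] = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues, replaced = normalize_residues(str(rec.seq))
        total_replaced += replaced
        desc = rec.description[len(rec.id):].strip() or None
        out.append(Sequence(id=rec.id, residues=residues, description=desc))
    if total_replaced:
        logger.warning(
            "%s: %d non-ACGTN characters replaced with N", path, total_replaced
        )
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def reverse_complement(s: Sequence) -> Sequence:
    """Reverse complement (A<->T, C<->G, N<->N), preserving the id."""
    return Sequence(
        id=s.id,
        residues=s.residues.translate(_COMPLEMENT)[::-1],
        description=s.description,
    )


def revcomp_str(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def minus_to_forward(p_rc: int, length: int, q: int) -> tuple[int, int]:
    """Map a 1-based start on the reverse complement to forward coordinates.

    A window of ``length`` starting at ``p_rc`` on revcomp(Q) occupies
    forward positions ``q - p_rc - length + 2 .. q - p_rc + 1`` (1-based
    inclusive).
    """
    end_fwd = q - p_rc + 1
    start_fwd = end_fwd - length + 1
    return start_fwd, end_fwd


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_SOURCE = "gpga"


def _fmt_attrs(attrs: dict[str, object]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(mappings: TypingSequence, path: str | Path) -> None:
    """Write gene mappings (or bare exon hits) as GFF3.

    Accepts :class:`gpga.mapper.GeneMapping` and/or
    :class:`gpga.mapper.ExonHit` objects.  Gene features carry fitness,
    combined similarity, classification and junction counts; exon
    features carry per-exon fitness and similarity and a ``Parent``
    attribute.
    """
    from . import mapper as _mapper  # local import to avoid a cycle

    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for m in mappings:
            if isinstance(m, _mapper.ExonHit):
                fh.write(_exon_line(m, parent=None))
                continue
            hits = [h for h in m.hits]
            if not hits:
                continue
            g_start = min(h.interval.start for h in hits)
            g_end = max(h.interval.end for h in hits)
            gene_id = m.gene.gene_id
            attrs = {
                "ID": gene_id,
                "combined_similarity": f"{m.combined_similarity:.4f}",
                "classification": m.classification,
                "canonical_junctions": sum(
                    1 for j in m.junctions if j == "canonical_GT_AG"
                ),
                "non_canonical_junctions": sum(
                    1 for j in m.junctions if j == "non_canonical"
                ),
            }
            if m.gc_percent is not None:
                attrs["gc_percent"] = f"{100.0 * m.gc_percent:.2f}"
            if m.premature_stop is not None:
                attrs["premature_stop"] = str(m.premature_stop).lower()
            fh.write(
                "\t".join(
                    [
                        hits[0].interval.seq_id,
                        _GFF_SOURCE,
                        "gene",
                        str(g_start),
                        str(g_end),
                        ".",
                        m.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for h in hits:
                fh.write(_exon_line(h, parent=gene_id))


def _exon_line(hit, parent: str | None) -> str:
    attrs: dict[str, object] = {
        "ID": f"{hit.exon.gene_id}.exon{hit.exon.exon_index}",
        "fitness": hit.fitness,
        "similarity": f"{hit.similarity:.4f}",
        "passed": str(hit.passed).lower(),
    }
    if parent is not None:
        attrs["Parent"] = parent
    return (
        "\t".join(
            [
                hit.interval.seq_id,
                _GFF_SOURCE,
                "exon",
                str(hit.interval.start),
                str(hit.interval.end),
                str(hit.fitness),
                hit.interval.strand,
                ".",
                _fmt_attrs(attrs),
            ]
        )
        + "\n"
    )


def read_gff3_exons(path: str | Path) -> list[GenomicInterval]:
    """Read exon features from a GFF3 file as forward-coordinate intervals."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2] != "exon":
                continue
            strand = cols[6] if cols[6] in ("+", "-") else "+"
            out.append(
                GenomicInterval(
                    seq_id=cols[0], start=int(cols[3]), end=int(cols[4]), strand=strand
                )
            )
    return out


def write_report_tsv(mappings: TypingSequence, path: str | Path) -> None:
    """One TSV row per exon hit: seq_id, gene_id, exon_index, strand,
    start, end, fitness, e, similarity."""
    import pandas as pd

    rows = []
    for m in mappings:
        for h in m.hits:
            rows.append(
                {
                    "seq_id": h.interval.seq_id,
                    "gene_id": h.exon.gene_id,
                    "exon_index": h.exon.exon_index,
                    "strand": h.interval.strand,
                    "start": h.interval.start,
                    "end": h.interval.end,
                    "fitness": h.fitness,
                    "e": len(h.exon.residues),
                    "similarity": round(h.similarity, 4),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "gene_id",
            "exon_index",
            "strand",
            "start",
            "end",
            "fitness",
            "e",
            "similarity",
        ],
    ).to_csv(path, sep="\t", index=False)
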