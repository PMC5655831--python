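"""Exon-level prediction accuracy and substitution summaries.

Accuracy follows the Burset–Guigó exon-level convention: a predicted
exon is correct only when both of its boundaries exactly equal an
annotated exon's; a missed exon is an annotated exon with zero overlap
to any prediction; a wrong exon is a prediction with zero overlap to
any annotated exon.  Sensitivity ESn = CE/actual, specificity
ESp = CE/predicted, ME = missing/actual, WE = wrong/predicted, and
Eavg = (ESn + ESp)/2.

Strand is ignored when matching by default (benchmark annotations place
exons on the plus strand while the search considers both); pass
``strict_strand=True`` to require strand agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .seqio import GenomicInterval

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class EvalResult:
    actual_exons: int
    predicted_exons: int
    correct_exons: int
    missing_exons: int
    wrong_exons: int
    ESn: Fraction
    ESp: Fraction
    ME: Fraction
    WE: Fraction
    Eavg: Fraction
    esp_undefined: bool = False  # no predictions at all; ESp/WE reported as 0

    def as_dict(self, ndigits: int = 4) -> dict[str, float | int]:
        return {
            "actual_exons": self.actual_exons,
            "predicted_exons": self.predicted_exons,
            "correct_exons": self.correct_exons,
            "missing_exons": self.missing_exons,
            "wrong_exons": self.wrong_exons,
            "ESn": round(float(self.ESn), ndigits),
            "ESp": round(float(self.ESp), ndigits),
            "ME": round(float(self.ME), ndigits),
            "WE": round(float(self.WE), ndigits),
            "Eavg": round(float(self.Eavg), ndigits),
        }


def _key(iv: GenomicInterval, strict_strand: bool):
    return (iv.seq_id, iv.start, iv.end, iv.strand) if strict_strand else (
        iv.seq_id,
        iv.start,
        iv.end,
    )


def _overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.seq_id == b.seq_id and a.start <= b.end and b.start <= a.end


def exon_level_metrics(
    predicted: list[GenomicInterval],
    truth: list[GenomicInterval],
    strict_strand: bool = False,
) -> EvalResult:
    """Exact-boundary exon accuracy of ``predicted`` against ``truth``.

    Duplicate intervals are collapsed.  All ratios are exact
    :class:`fractions.Fraction` values.
    """
    if not truth:
        raise ValueError("truth annotation is empty: sensitivity undefined")
    truth_u = list({_key(t, strict_strand): t for t in truth}.values())
    pred_u = list({_key(p, strict_strand): p for p in predicted}.values())

    truth_keys = {_key(t, strict_strand) for t in truth_u}
    correct = sum(1 for p in pred_u if _key(p, strict_strand) in truth_keys)
    missing = sum(
        1 for t in truth_u if not any(_overlaps(t, p) for p in pred_u)
    )
    wrong = sum(1 for p in pred_u if not any(_overlaps(p, t) for t in truth_u))

    n_actual = len(truth_u)
    n_pred = len(pred_u)
    esn = Fraction(correct, n_actual)
    me = Fraction(missing, n_actual)
    if n_pred == 0:
        esp = Fraction(0)
        we = Fraction(0)
        undefined = True
    else:
        esp = Fraction(correct, n_pred)
        we = Fraction(wrong, n_pred)
        undefined = False
    return EvalResult(
        actual_exons=n_actual,
        predicted_exons=n_pred,
        correct_exons=correct,
        missing_exons=missing,
        wrong_exons=wrong,
        ESn=esn,
        ESp=esp,
        ME=me,
        WE=we,
        Eavg=(esn + esp) / 2,
        esp_undefined=undefined,
    )


@dataclass(frozen=True)
class SubstitutionSummary:
    transitions: int
    transversions: int
    codon_position_counts: tuple[int, int, int]

    @property
    def total(self) -> int:
        return self.transitions + self.transversions


def substitution_summary(
    pairs: list[tuple[str, str, int]]
) -> SubstitutionSummary:
    """Tally substitutions from (reference base, query base, codon position).

    Matching pairs are ignored.  A↔G and C↔T are transitions
    (purine↔purine, pyrimidine↔pyrimidine); every other mismatch is a
    transversion.  Codon positions are 1..3 (3 is the wobble position).
    """
    transitions = 0
    transversions = 0
    by_pos = [0, 0, 0]
    for ref, qry, pos in pairs:
        if pos not in (1, 2, 3):
            raise ValueError(f"codon position must be 1, 2 or 3, got {pos}")
        if ref not in "ACGT" or qry not in "ACGT":
            raise ValueError(f"residues must be A/C/G/T, got ({ref!r}, {qry!r})")
        if ref == qry:
            continue
        if (ref in _PURINES and qry in _PURINES) or (
            ref in _PYRIMIDINES and qry in _PYRIMIDINES
        ):
            transitions += 1
        else:
            transversions += 1
        by_pos[pos - 1] += 1
    return SubstitutionSummary(
        transitions=transitions,
        transversions=transversions,
        codon_position_counts=tuple(by_pos),
    )
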