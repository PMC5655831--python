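"""Ungapped placement fitness and the exhaustive brute-force oracle.

The fitness of placing an exon E (length e) at position p of a query Q
is the number of identical positions between E and the window
Q[p .. p+e-1], compared column by column without gaps.  Equivalently it
is the sum of the lengths of the maximal runs of consecutive matches
inside the window (F = sum(w_i)), and also e minus the Hamming distance
restricted to the window.  N never matches anything, including N.

The exhaustive scan over every placement is the independent oracle the
genetic search is tested against; it is O(q*e) and practical up to a
few hundred kilobases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import N_CODE, Sequence


@dataclass(frozen=True)
class FitnessResult:
    """Fitness of one candidate placement.

    position is the 1-based candidate start P; runs are the maximal
    match-run lengths w_i; fitness F = sum(runs); similarity = F/e.
    """

    position: int
    runs: tuple[int, ...]
    fitness: int
    similarity: float

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _match_mask(e_arr: np.ndarray, window: np.ndarray) -> np.ndarray:
    # N (code 4) never matches, not even another N
    return (e_arr == window) & (e_arr != N_CODE)


def _runs_from_mask(mask: np.ndarray) -> tuple[int, ...]:
    if not mask.any():
        return ()
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return tuple((ends - starts).tolist())


def ungapped_fitness(exon, query: Sequence, p: int) -> FitnessResult:
    """Score the placement of ``exon`` at 1-based position ``p`` of ``query``.

    ``exon`` is anything with a ``residues`` string (an ExonQuery or a
    Sequence).  Raises ValueError when p lies outside the valid
    placement interval.
    """
    e = len(exon.residues)
    q = len(query.residues)
    if e > q:
        raise ValueError(f"exon longer than query (e={e} > q={q})")
    lo, hi = 1, q - e + 1
    if not (lo <= p <= hi):
        raise ValueError(
            f"position {p} out of range: valid placements lie in [{lo}, {hi}] "
            f"(upper GA limit u = q - e = {q - e})"
        )
    e_arr = _encode(exon)
    q_arr = query.encoded()
    mask = _match_mask(e_arr, q_arr[p - 1 : p - 1 + e])
    runs = _runs_from_mask(mask)
    fitness = int(mask.sum())
    assert fitness == sum(runs)
    return FitnessResult(position=p, runs=runs, fitness=fitness, similarity=fitness / e)


def _encode(seq_like) -> np.ndarray:
    enc = getattr(seq_like, "encoded", None)
    if enc is not None:
        return enc()
    from .seqio import _ENCODE

    return _ENCODE[np.frombuffer(seq_like.residues.encode("ascii"), dtype=np.uint8)]


def all_placement_fitnesses(exon, query: Sequence) -> np.ndarray:
    """Vector of fitness values for every placement p in [1, q-e+1].

    Index i holds the fitness at position i+1.
    """
    e = len(exon.residues)
    q = len(query.residues)
    if e > q:
        raise ValueError(f"exon longer than query (e={e} > q={q})")
    e_arr = _encode(exon)
    q_arr = query.encoded()
    windows = np.lib.stride_tricks.sliding_window_view(q_arr, e)
    mask = (windows == e_arr) & (e_arr != N_CODE)
    return mask.sum(axis=1).astype(np.int64)


def exhaustive_best(exon, query: Sequence) -> FitnessResult:
    """Evaluate every placement and return the best; ties -> smallest p."""
    scores = all_placement_fitnesses(exon, query)
    best_p = int(scores.argmax()) + 1  # argmax returns the first maximum
    return ungapped_fitness(exon, query, best_p)
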