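# Methods

## Model and scope

`gpga` maps known reference exons onto unannotated genomic sequence by
ungapped placement search.  The score of placing an exon *E* (length
*e*) at position *P* of a query *Q* (length *q*) is the number of
identical columns in the window comparison of *E* against
*Q*[P..P+e−1]; equivalently the sum of the maximal match-run lengths,
and equivalently e minus the windowed Hamming distance (the
implementation asserts the run-sum and mismatch-count routes agree).
There are no gaps anywhere in the model: a homolog exon that has
suffered an insertion or deletion relative to the query can only be
matched up to the frame shift.  This is a deliberate scope boundary,
matched by the synthetic-data generator, which introduces substitutions
only.

`N` encodes uncertainty and never matches anything, including another
`N`.  Counting N–N as identity would inflate similarity toward the 60%
acceptance threshold on masked or low-quality sequence, so it is
treated as a guaranteed mismatch in both the numerator (fitness) and
retained in the denominator (e).

## The genetic search

One individual = one integer position in [l, u] = [1, q − e].  Defaults
(population 200, at most 3000 generations, stall after 200 generations
without improvement, tournament size 3, crossover and mutation
probability 1, suboptimal cutoff e/2) are the published operating
point of the method and are exposed in `SearchParams` for ablation.

Choices the operator descriptions leave open, and how this
implementation resolves them:

* **Narrowing width.** "Close to the parent" is made concrete as the
  window ±h with h = `narrow_halfwidth_factor`·e (default factor 1):
  the exon length is the natural scale of the fitness basin, since a
  placement sharing any columns with the optimum lies within ±e of it.
  Each parent gets its own window; the two parents of a crossover do
  not share one.
* **Parent pairing.** Two independent size-3 tournaments produce the
  two parents (standard tournament semantics).
* **Elitism.** The all-time best individual replaces the worst member
  of each new pool (`elite_count = 1`).  This makes the stall
  criterion well-defined on the all-time best and the per-generation
  best-fitness trace monotone.
* **Early stop.** Fitness e means the exon is found exactly; no
  improvement is possible, so the search returns immediately.
* **Tie-breaking.** Everywhere (tournaments, oracle, best tracking) a
  fitness tie is broken toward the smaller position, which makes every
  run a deterministic function of the seed.
* **RNG.** Each exon search uses a dedicated `numpy` Generator seeded
  from (`SearchParams.seed`, CRC32 of `gene|exon|strand`), so
  multi-exon and multi-strand runs are reproducible and independent of
  execution order.

The exhaustive scan over all q − e + 1 placements
(`scoring.exhaustive_best`) is kept as the independent oracle; tests
require the search to reproduce its optimum on ≥95% of seeded
planted-exon instances and never to exceed it.

## Gene assembly and classification

Combined similarity is length-weighted (Σ fitness / Σ e), not a mean of
per-exon fractions, so short exons cannot dominate the acceptance
decision.  Strand choice is winner-takes-all per gene — a gene's exons
lie on one strand — with ties going to plus.  Exon colinearity is not
enforced during search (the per-exon independence is the point of the
decomposition); it is checked at junction annotation, where hits that
are out of order or overlapping on the coding strand leave no valid
introns and demote the gene to conserved-block status.

Conservation-mode stringency takes a length L (default 100 bp) and
identity P (default 0.70).  Exons shorter than L are exempt from the
length criterion but not from P; otherwise a single short exon would
disqualify every gene containing one.  Classes: all exons pass →
conserved gene; only the 5′ (3′) terminal exon end passes → partial;
neither terminal but ≥1 internal exon passes → overlapping; passing
exons of any non-conserved gene are emitted separately as conserved
blocks.  The uncovered combination (both terminals pass, an internal
exon fails) has no class of its own and is reported as conserved
blocks only.

Junctions are canonical when the inferred intron starts GT and ends AG
on the coding strand (minus-strand introns are read on the reverse
complement).  The retroposon heuristic is reduced to two reported
flags — premature stop codon in frame 0 of the concatenated hit
windows, and an "intronless" flag when all inferred introns are
< 10 bp — and never alters classification, because no sharper
criterion is defined for it.

## Evaluation

Exon-level accuracy uses the Burset–Guigó convention: correct requires
both boundaries exact; missed/wrong use zero overlap.  Predictions
that overlap truth inexactly count toward neither.  Ratios are exact
`fractions.Fraction` values internally and are rounded to 4 decimals
only at the reporting boundary.  Strand is ignored in matching by
default (benchmark annotations conventionally place exons on the plus
strand while the mapper searches both); `strict_strand=True` is
available.

## Synthetic data

The generator emulates two benchmark regimes: `hmr_like` (20 records of
7 kb, exactly one planted gene each — the single-gene curated-benchmark
shape) and `sag_like` (3 records of 60 kb with ~4 genes each — the
multi-gene shape, scaled down from chromosome-sized records; the
methodologically relevant variable is genes-per-record, not absolute
length).  Default gene architecture: 3–5 exons of 60–200 bp separated
by introns of 200–800 bp, background GC 0.45 used for exons, introns
and intergenic alike.  Homologs are derived by i.i.d. per-site
substitution (divergence d ⇒ expected similarity 1 − d); d < 0.4 is
enforced so the 60% acceptance threshold stays meaningful.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: repeat families and low-complexity sequence
(the short-exon ambiguity failure mode is instead reproduced directly
by planting a duplicated 18 bp exon), indels, codon-structured exon
composition, splice-site motifs beyond the forced GT..AG termini, and
overlapping or nested genes.

## Problem sizes and numerical choices

The shipped tests run the oracle-equivalence battery at q = 2000 with
e ∈ {30, 60, 120} over 50 seeds, and the full pipeline on the
`hmr_like` preset (20 genes, 82–91 exons depending on seed) at homolog
divergences 0, 0.1 and 0.35; these sizes exercise every code path while
keeping a full run in minutes on one CPU.  At divergence 0.35 the
expected homolog similarity (0.65) sits ~2 standard deviations above
the 0.60 cutoff for a typical ~500 bp gene, so gene rejection there is
a possible but not guaranteed outcome of any single bundle; the margin
between measured combined similarity and the cutoff collapses from
~0.3 (divergence 0.1) to ~0.03, which is the quantitative signature of
the cutoff at moderate homology.

Known limitations: no gapped placement; per-exon search can return
either copy of a repeated short exon; runtime grows linearly in the
number of exons and strands searched; the conservation-mode length
stringency L is configurable but, by the short-exon exemption above,
only P is decisive for genes made of short exons.
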