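# Methods

This note documents the models behind each module, the parameters that
matter, the numerical conventions, and what the synthetic generators do and
do not emulate.

## Screen scoring

The scoring chain estimates a per-gene fitness effect from guide read
counts. Frequencies are computed per sample with no pseudocount
(`F = N / ΣN`); the log2 fold change of each guide compares one late
timepoint against the single plasmid reference shared by all replicates.
Multi-timepoint screens are scored once per late timepoint — the chain is
a two-sample contrast, not a trajectory fit.

**Pseudofrequency.** A guide absent from either sample makes the log ratio
infinite. By default half a read at the median sample depth
(`0.5 / median(ΣN)`) is added inside the ratio to both numerator and
denominator: it caps the fold change of zero-count guides at a value
commensurate with the depth while shifting mid-abundance guides
negligibly. It is exposed as a parameter; at `0` guides with a zero
frequency are dropped with a warning instead.

**Standardization.** z-scores use the mean and *population* standard
deviation (divisor *n*) over **all** guides of a replicate, non-targeting
controls included. Including NTCs makes the centring conservative: the
null guides participate in defining zero. Standardization refuses a
replicate with zero spread (all fold changes equal) — emitting 0/0 scores
would be fabrication; this situation only arises in degenerate inputs such
as byte-identical samples.

**Gene score.** The score of gene *g* is the grand mean of z over its
`L_g` guides and `R` replicates (one mean over the guide × replicate grid,
normalizing by `R·L_g`). NTC guides are pooled into one pseudo-gene row
and also visible individually in the guide-level output. Ranking sorts by
score descending with alphabetical tie-breaks, so output order is total
and reproducible. Guides present in the library but missing from the
counts are a hard error, never a silent zero-fill: a missing row means the
counting upstream went wrong.

**QC.** Library uniformity is the fraction of guides whose plasmid
frequency lies within a fold band `[mean/fold, mean×fold]` of the uniform
mean `1/m` (default fold 4).

## Barcode competition

Clone frequencies normalize per sample; the construct summary `M_ct` is
the grand mean over the construct's clones and replicates at each
timepoint. Two conventions: (1) a replicate in which a clone dropped out
contributes zeros, not missing values — absence is the signal in a dropout
competition; (2) a construct with no clones at a timepoint is reported
missing (NaN), because there the mean is undefined rather than zero.
Timepoint labels are ordinal strings ordered by the sample sheet (or an
explicit list), never parsed as dates.

## Repertoire networks

Vertices are unique sequences with read multiplicities; edges require
equal length and Hamming distance exactly 1 (the strict non-indel
reading). Edge construction buckets each sequence under its L
one-position-masked keys, so two sequences share a bucket iff they differ
only at the masked position — O(n·L) instead of all-pairs, but
extensionally identical to the brute-force oracle (property-tested).
Sequences containing N are kept as vertices but excluded from edge
building: a position that could be anything is not evidence of single-step
relatedness. Cluster ids order by (size descending, lexicographically
smallest member) and are therefore stable.

### CC subsampling

Cluster-enforced linkage sampling downsamples a graph to `n_target`
vertices while preserving clonal structure, in three steps per attempt:

1. **Vertex selection** — vertices are drawn without replacement with
   probability proportional to read multiplicity (clonal structure is a
   property of reads, not unique sequences; a uniform mode is available).
   A repair pass then guarantees every cluster at least one selected
   vertex by moving selections out of over-represented clusters (the
   lightest selected vertex leaves first). When `n_target` is below the
   cluster count full representation is impossible; the largest clusters
   are kept, one vertex each.
2. **Cluster-vertex migration** — within any cluster holding k ≥ 2
   selected vertices whose induced subgraph is disconnected, the selection
   is regrown as a connected set of the same size k, seeded at the
   heaviest selected vertex and preferring originally selected vertices at
   each growth step. Migration never crosses cluster boundaries, so the
   cluster count of step 1 is preserved.
3. **Total graph induction** — every original edge with both endpoints
   sampled is kept.

The procedure runs `repeats` times (default 20) and retains the attempt
whose maximum cluster size is closest to the original maximum rescaled by
the sampling fraction `n_target/|V|`; an absolute comparison against the
unsampled maximum would be unattainable by construction once `n_target`
shrinks the largest cluster. Ties go to the earliest attempt; everything
is deterministic given the seed.

### Parsimony trees

Clusters are summarized as unrooted trees whose integer branch lengths are
substitution counts. For ≤ 8 sequences every unrooted binary topology
(1, 3, 15, 105, 945, 10395 for 3–8 leaves) is scored by the Fitch
small-parsimony algorithm and a minimum kept; constant alignment columns
are dropped and repeated site patterns collapsed with weights before
scoring, which changes nothing about the optimum. Beyond 8 leaves a greedy
stepwise-addition tree (each leaf inserted on the score-minimizing edge)
is refined by nearest-neighbour interchange to a local optimum; the result
is guaranteed no worse than a star topology and empirically matches the
exhaustive optimum on clusters small enough to check. Branch lengths come
from a Fitch bottom-up pass followed by top-down refinement (keep the
parent state whenever allowed), whose edge-difference total equals the
parsimony score. Trees are exported as newick with the lexicographically
smallest leaf as the serialization root and a zero-length root edge
(`(A:d,B:0);` for two leaves).

## IgHV replacement

The stem of an annotated BCR is the suffix starting 3 bp past the V-region
end (`v_end`, 0-based half-open): the first 3 junction bases are skipped
because V-gene trimming makes their origin ambiguous. Records whose full
N-D-N-J span (`sequence[v_end:]`) is shorter than 8 nt are excluded before
pairing — such short joins can be germline-encoded and would produce
spurious stem collisions. Unique sequences (exact full-length
deduplication) are grouped by exact stem string; fuzzy stem matching is
deliberately not offered. Within a group, a pair is a replacement event
when the V calls differ, global V-region identity is below the threshold
(default 95%), and the 5′ junction strings (last 3 bp of V + N-D-N-J)
differ. Identity is matched columns over all columns of a unit-cost global
alignment (match 1, mismatch −1, gap −1, linear); arguments are
canonically ordered so the measure is symmetric, and the first optimal
alignment is used deterministically. The reported percentage divides
unique BCRs participating in ≥ 1 pair by the post-exclusion unique count —
the denominator that actually entered pairing.

## Coverage arithmetic

`cells = ⌈guides × coverage / transduced_fraction⌉` in exact rational
arithmetic (whole-cell ceiling), DNA mass at 6.6 μg per 10⁶ diploid human
cells, and a strict ceiling on reactions at the per-reaction mass cap
(default 10 μg): the cap is a maximum, so even a sub-microgram overflow
opens a new reaction. For the 6000-guide, 1000×, 30% example this gives
2×10⁷ cells, 132 μg and 14 reactions.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume; they are first-class, tested code, not fixtures.

**Screen.** The plasmid pool is a symmetric Dirichlet perturbation of the
uniform design; `plasmid_dispersion` is the reciprocal of the
per-category concentration (0.01 → concentration 100, mild
overdispersion; 0 → exactly uniform). Each guide draws an efficacy once
from Beta(6, 2) — most guides cut well, a tail does not — and evolves as
`f_i(t) ∝ f_i(0) · exp(efficacy_i · s_g · t)` with `s_g` the gene's
selection coefficient per day and `t` parsed from the timepoint label.
Sequencing is Dirichlet-multinomial with the same single dispersion knob.
Defaults: depth 5×10⁶ (about 1000× for a 6000-guide library), timepoints
d14/d28, 3 replicates. The NTC pseudo-gene is forced neutral. The planted
benchmark (`planted_screen`) uses 700 genes × 8 guides + 250 NTCs with
s = ±0.3/day for 10 genes each — at d28 an effective guide enriches
~e⁶ ≈ 400-fold, a strong but realistic dropout-screen signal. This model
is a stand-in chosen as the simplest under which the scoring chain is a
consistent estimator of the planted effects; no claim is made that the
real screens evolved this way.

**Barcodes.** Exponential competition in frequency space with the same
Dirichlet-multinomial readout; `sampling="exact"` emits noise-free
expected counts, for which two one-clone constructs follow the two-type
logistic ratio in closed form (used as an oracle test).

**Repertoire.** Each clone is a germline V (from a user-supplied or
synthetic labelled set) plus an N1-D-N2-J junction with N segments of
≥ 3 nt and a span drawn from `junction_length_range`; clone sizes are
Zipf with exponent `clone_size_distribution` (capped at 200 reads so a
single clone cannot swamp small simulations); each read receives
independent uniform per-base substitutions at `shm_rate`. Two deliberate
simplifications: SHM has no hotspot bias or indels (the downstream graph
only uses substitutions), and SHM is applied to the V region only, so the
generator contract that planted replacement partners share byte-identical
stems holds for every read. Real SHM also mutates junctions; consequently
passing recovery tests show the detector is correct for exact stem
sharing, not that real mutated-stem replacements would be found — that is
a stated limitation of the exact-grouping method itself. Replacement
partners draw a different germline V (random synthetic V pairs sit far
below the 95% identity threshold) and alter the 3 bases past the V
boundary, changing the 5′ junction while keeping the stem.

## Problem sizes in the test suite

Tests and the acceptance script run on scaled-down instances chosen to
exercise every code path with comfortable statistical margins: null
calibration uses 650-guide libraries at depth 3×10⁵ over 20 seeds; the
planted benchmark 5850 guides at depth 2×10⁶; network property tests up to
500 vertices against the brute-force oracle; parsimony oracle checks 100
clusters of ≤ 6 leaves; CC invariants 50 seeds on a ~100-vertex expanded
repertoire. These sizes are the package's own benchmark conditions; all
randomness flows from explicit seeds.

## Known limitations

- No PCR amplification bias, UMIs, or read-quality modelling in any
  generator; counts are idealized draws.
- The screen scorer computes no p-values or FDR — it is an effect-size
  ranking, not a test; no copy-number correction.
- The repertoire graph connects only equal-length sequences; an indel
  within a clone splits its cluster.
- V/D/J annotation is consumed, never computed: real data must arrive
  pre-annotated (AIRR-style TSV) from an external annotator.
- The CC retention rule compares against a rescaled, not absolute, maximum
  cluster size; other readings of "most closely represents" would retain
  different attempts.
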