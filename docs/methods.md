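# Methods

This note records the models, conventions and design decisions behind
`tlpkit`, in the order the pipeline runs. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Candidate identification

### Pattern grammar

The signature engine compiles a PROSITE-style subset: `-`-separated
elements that are single-residue literals, `x` (any residue), or `[..]`
alternative classes, each optionally carrying an `(n)` or `(n,m)` repeat.
Repeats may be written attached (`x(2,3)`) or as their own dash-separated
token (`x-(2,3)`); both occur in the literature and compile identically.
Anchors (`<`, `>`) and negated classes (`{..}`) are not part of the
subset — the thaumatin signature needs neither — and are rejected with a
parse error that names the element position, never silently ignored.
Compiled patterns carry their length bounds (`min_len = Σ min_repeat`,
`max_len = Σ max_repeat`); for the thaumatin signature these are 15 and
17.

### Matching policy

Scanning reports matches at **every** start position and matches may
overlap. For a fixed start, variable repeats are expanded shortest-first,
left to right, and the first valid expansion is reported — one match per
start, deterministic, in line with how PROSITE scanners report hits. An
`all_expansions` flag enumerates every valid expansion instead (used by
the brute-force equivalence tests). Positions are 1-based inclusive
protein coordinates throughout.

The two carbohydrate-binding octapeptides (`CQTGDCGG` canonical,
`CQTGDCQG` variant) are matched as exact substrings by a separate
operation; fuzzy motif matching is deliberately out of scope.

### The funnel

Stages run in pipeline order: (1) distinct proteins named as hit queries;
(2) e-value filter — a protein passes if its best hit passes; the
comparison is **inclusive** (`e ≤ threshold`, default `1e-10`) and the
threshold configurable, since "cutoff" conventions differ between tools;
(3) at least one complete signature match; (4) collapse to one protein
per locus keeping the longest, with equal lengths broken by the
lexicographically smallest transcript identifier (determinism over an
arbitrary but documented rule). Stage counts are recorded in a report
whose monotonicity (non-increasing) is enforced at construction.

## Protein characterization

### Molecular weight

Sum of average isotopic residue masses plus one water (18.0153 Da),
matching the ExPASy ProtParam convention; monoisotopic masses are
available behind a flag. The placeholder `X` has no defined mass and is
an error unless the caller assigns one. Report fields round to 3 decimals
in kDa; internal values keep full precision. Additivity
(`MW(a+b) = MW(a) + MW(b) − water`) is property-tested.

### Isoelectric point

Net charge is modeled per ionizable group with Henderson–Hasselbalch:
the N-terminus and H/K/R side chains contribute `+1/(1+10^(pH−pKa))`,
the C-terminus and D/E/C/Y side chains `−1/(1+10^(pKa−pH))`. The default
pKa set is Bjellqvist's (side chains D 4.05, E 4.45, C 9.0, Y 10.0,
H 5.98, K 10.0, R 12.0; generic termini 7.50/3.55) including the
residue-specific terminal adjustments (N-terminal A/M/S/P/T/V/E,
C-terminal D/E) — the set ProtParam uses, which the published barley pI
values were computed with. The set is a named, swappable configuration.
The charge curve is strictly decreasing in pH, so the pI is the unique
root, located by bisection on [0, 14] to 0.002 pH units and reported to
2 decimals. The implementation is cross-checked in the tests against
Biopython's independent port, which must be handed the full [0, 14]
bracket (its default bracket floors very acidic peptides at pH 4.05).

### Classes and assembly

Small TLPs are defined by exactly 10 cysteines (the classical full-length
class carries 16; counts up to 24 occur). Feature records enforce
`aa_length = cds_bp/3 − 1` — valid only for stop-terminated CDSs, which
is what the funnel-retained primary transcripts have — and are sorted by
gene symbol in natural numeric order. Missing annotations degrade to
"unknown"/0 rather than failing; a missing gene model is an error, since
genomic columns cannot be fabricated.

The packaged 19-gene barley reference table (`data/hvtlp_characteristics.tsv`)
is input data: published per-gene characteristics used by tests and the
acceptance script to re-derive arithmetic, grouping and distribution
claims. Its TM column is stored as printed even though the prose total
differs by one; the table is treated as authoritative.

## Gene structure

GFF3 coordinates are 1-based inclusive end-to-end; no half-open
conversion happens anywhere. Exon-count groups are I–IV for 1–4 exons;
counts above 4 map to "other" so the classifier generalizes beyond the
19-gene set instead of erroring. Protein positions map to exon ordinals
via the spliced-CDS offset `3(aa−1)+1` against cumulative per-exon CDS
lengths, walked 5′→3′ of the transcript (reverse genomic order on the
minus strand) — so the ordinal is strand-symmetric. Splice-variant
summaries report both transcripts-per-gene and additional-variants
(count − 1), because "number of splice variants" is used both ways in
the literature; ties for the maximum break lexicographically. Tandem
candidates are consecutive same-chromosome genes whose start coordinates
differ by less than a configurable 1 Mb — a pragmatic proxy for "close
proximity", not a synteny analysis.

## Phylogeny

Distances use pairwise deletion (a column is dropped for a pair if
either sequence has a gap) with `p = mismatches/compared` and, by
default, the Poisson correction `d = −ln(1−p)`; raw p-distances are the
alternative. A pair with no comparable columns, or `p = 1` under
Poisson, is an error naming the pair rather than a silent infinity.

Neighbor joining is implemented directly (Saitou–Nei Q-criterion,
standard branch-length formulas, final three-node star resolved in
closed form) because the tests need exact control of tie-breaking — the
minimal-Q pair with the smallest index pair in current matrix order wins
— and of negative-branch handling: negative length estimates are clamped
to zero with a warning, the presentation convention of common tree
viewers. The scikit-bio NJ implementation serves as an independent
topology cross-check in the tests, never as the implementation. Trees
are stored on scikit-bio `TreeNode` (rooted at a trifurcating basal
node, the standard unrooted representation) and serialized as Newick
with supports as internal-node labels.

Bootstrap resamples alignment columns with replacement; replicate *r*
derives its RNG from `seed + r`, so runs are reproducible and
embarrassingly parallel in principle. The support of each internal edge
of the full-alignment tree is the percentage of replicates whose tree
contains the same bipartition; bipartitions are canonicalized tip-name
sets, making supports invariant to taxon input order. Replicates whose
resampled columns saturate a pair (infinite Poisson distance) contribute
no splits rather than aborting the run.

Group extraction cuts the tree into *k* connected components. The
longest edges are removed greedily — ties broken by the
lexicographically smallest leaf beneath the edge — and a cut is kept
only if it increases the component count: a cut nested under earlier
cuts can otherwise empty a component, and restricting cuts to internal
edges would cap the group count at *n − 2*, whereas singleton groups
(*k = n*) are legitimate. Groups are numbered by their smallest member
label. This is an explicit algorithmic stand-in for the visual clade
grouping done by eye in the literature; *k* is the user's choice.

## Expression

FPKM values transform as `log2(x + 1)`; the pseudo-count is configurable
but unavoidable in principle because FPKM zeros exist. Row clustering is
average-linkage (UPGMA) on Euclidean distances — delegated to
`scipy.cluster.hierarchy`, whose tied-merge behaviour follows original
row index — with Pearson-correlation distance behind a flag. Tests
assert on raw log2 values and merge heights; per-row min–max scaling to
[0, 1] exists for display only. RT-PCR bands are expressed relative to a
reference (housekeeping) gene; group comparison is the classic
pooled-variance two-sample *t* with `df = n_a + n_b − 2`, two-sided, at
α = 0.05, with Welch's variant behind a flag. Identical constant samples
return `t = 0, p = 1`; constant samples with unequal means are rejected
as degenerate rather than reported as infinitely significant.

## Synthetic data

The generator's defaults are the study conditions, fixed once: 19 true
TLP loci whose isoforms total 32 transcripts, 13 decoys, protein lengths
drawn from 173–359 residues, cysteine counts from {10, 16, 17, 18, 19,
22, 24} weighted toward 10/16, two canonical-CBM and one variant-CBM
gene, 1–4 exons per gene, a four-gene tandem cluster on chromosome 5H,
and the eight-tissue panel (EMB, LEA, INF1, INF2, ROO, NOD, CAR5,
CAR15) with an 8-fold planted expression contrast at base 5 FPKM and
noise SD 1.

Signature-bearing proteins embed a concrete 15-residue signature
realization at a recorded position; backgrounds are drawn from the 19
non-cysteine residues so the total cysteine count can be set exactly by
placing cysteines outside reserved spans. Decoys plant the same
realization with its invariant aspartate mutated to lysine — TLP-like
enough that only the pattern engine (not composition) can reject them —
and every generated protein is self-verified by re-scanning, with
rejection sampling against accidental signatures or motifs. Hit-table
e-values straddle the cutoff by design: planted transcripts draw
log-uniform from [1e-50, 1e-12], half the decoys from [1e-30, 1e-11]
(passing) and half from [1e-9, 1e-3] (failing), so the e-value filter
removes 6 decoys and the signature filter must remove the other 7.

Gene models back-translate with uniform synonymous-codon choice
(standard nuclear code; codon-usage realism is out of scope), append a
stop codon, split the CDS at uniformly random nucleotide positions (not
codon boundaries), and insert GT..AG introns of 60–200 bp; minus-strand
loci are reverse-complemented with mirrored intervals, and
extract-splice-translate round-trips exactly on both strands. Extra
isoforms are C-terminal truncations sharing the locus sequence, cut
after the signature so all planted transcripts stay signature-positive;
their CDS carries no stop codon, which is why characterization tables
are built from funnel-retained primaries. Intergenic spacing is 1.2–1.5
Mb between unrelated genes and 5–50 kb within tandem clusters, so the
1 Mb adjacency rule separates them; `dense_chromosomes` shrinks the
far spacing to 20–40 kb to keep chromosome strings small for fast tests
(tandem structure is then not meaningful).

Alignments evolve a uniform-random root down a tree with a
Poisson(branch length) number of substitution events per site, each
replacing the residue with one of the other 19 uniformly — expected
substitutions per site equal branch length, so Poisson-corrected
distances estimate path lengths up to a small multiple-hit bias
(checked at 10,000 sites within three binomial standard errors). No
indels are generated, so the sequences are their own alignment.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: realistic intergenic or codon
composition, UTRs, indel evolution, alignment error from a real MSA
step, biologically structured splice variation (truncations only),
rate heterogeneity across sites, or read-level RNA-seq noise. Recovery
at recall = precision = 1.0 reflects planted effect sizes (intact vs
point-broken signatures, 8-fold expression contrasts), not performance
on borderline homologs.

## Problem sizes and tolerances

Validation runs at desk scale, chosen to keep the whole suite fast while
leaving no stochastic assertion marginal: alignments of 500 sites and
100 bootstrap replicates for split recovery, 10,000 sites for the
distance-consistency law-of-large-numbers check, additive matrices of
4–8 taxa compared at 1e-9, pI assertions at ±0.01 pH and mass at
±1e-6 Da in additivity. All randomness flows through explicit seeds;
every generator is byte-reproducible under a fixed seed.

## Known limitations

- The homology search, domain databases, MSA construction and external
  predictors (signal peptide, TM, localization) are consumed as inputs,
  never run; garbage in, garbage out.
- The pattern grammar is the subset the thaumatin signature needs;
  anchors and negated classes are rejected.
- pI values are model predictions (Bjellqvist pKa) and can differ from
  experimental isoelectric focusing by several tenths of a pH unit.
- NJ is a distance method; for deep or rate-heterogeneous divergences a
  likelihood method upstream of this package is the better tool.
- The tandem-duplicate report is a distance heuristic, not an evolutionary
  analysis.
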