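# Methods

## Gene models and coordinates

A gene model is an ordered list of exon intervals (0-based half-open
internally) with a reference CDS that excludes the terminal stop codon, so
a 1407-bp ORF encodes 469 residues and coding position c.1368 falls in
codon ⌈1368/3⌉ = 456. All reported positions (HGVS-style labels, event
tables) are 1-based. Minus-strand genes are reverse-complemented at load;
everything downstream works in CDS orientation. Donor splice sites may
follow either the canonical GT or the GC dialect per intron (the reference
gene carries GC at intron 2); acceptors are always AG.

## Pseudogene annotation

Exon mapping emulates manual annotation deterministically. Each reference
exon is aligned semi-globally (full exon, free genomic-end gaps) into the
remaining slice with affine scores +2/−3/−8/−2. Plain local alignment is
deliberately avoided: it trims terminal mismatches and silently moves
splice boundaries. A mapping is accepted when identity ≥ 0.6 over ≥ 60% of
the exon *and* the affine score is positive — the score condition was added
because gap-riddled spurious placements on random sequence can pass the
identity threshold alone while scoring strongly negative. Boundaries may
slide ≤ 12 bp to restore the declared splice dialect, but only when the
shift is score-neutral (placement ambiguity at repeats), so a genuine
GT→AT donor loss is never "refined away".

Disruption calling reconstructs the target CDS from the exon alignments
(reference sequence is substituted for exons flagged missing so the frame
stays anchored), emits one event per contiguous indel run (frameshift iff
length mod 3 ≠ 0), re-translates the edited CDS codon-by-codon to find
premature stops — so frame is tracked through upstream indels exactly as
brute-force re-translation predicts — and compares observed splice
dinucleotides against the dialect. Codons containing N are skipped and
counted as missing data. Indels are left-aligned (VCF convention) so
repeat-ambiguous placements are canonical. Stop events carry a context
motif of the preceding k residues plus "X"; detection defaults to k = 4
(matching the four-letter motifs like DSLFX used for cross-species
comparison) while the standalone `stop_context` helper defaults to k = 3.

Validation: an event is `validated_fixed` when ≥ 2 independent projects
each show ≥ `min_reads` (default 3) disrupted reads and no intact read
appears anywhere; `validated_polymorphic` when one project shows both
alleles at ≥ min_reads, or different projects are fixed for different
alleles. Status calls: ≥ 1 fixed disrupting event → pseudogene; polymorphic
only → polymorphic pseudogene; no disrupting event with full coverage →
coding; otherwise unresolved. In-frame indels are not disrupting.

## Counting independent loss events

Identical disruptions (same kind, homologous reference position, same
allele — stop-codon identity or indel length + string) form shared
clusters. Inactivated tips (fixed pseudogenes; polymorphic ones optional
and off by default) are joined whenever they share a cluster; each
connected component is one loss event placed above the MRCA of its
members. This is deliberately *not* plain Dollo parsimony: sister lineages
inactivated by distinct mutations (elephant and manatee) remain separate
events, while a merged Dollo edge cover is available behind a flag for
comparison. A coding tip inside an event's MRCA clade triggers a
Dollo-consistency warning (also covering non-monophyletic clusters, which
stay one event at the MRCA with a homoplasy warning). On the packaged
matrix and tree the count is nine: the cetacean ancestor, Phocidae,
Otariidae, the walrus, three rodents, the *Pteropus* pair (via their
shared exon-5 stop) and the manatee; the vampire-bat and elephant events
are encoded with single-source support only, hence unresolved and
excluded — see the repository's design notes for this reading of the
published enumeration.

## Codon substitution machinery

The 61-sense-codon generator has rate π_j · κ^[transition] · ω^[nonsyn]
for single-nucleotide changes, zero otherwise; each ω-class matrix is
scaled to mean rate 1 at stationarity so branch lengths are expected
substitutions per codon. The chain is reversible, so kernels come from the
eigendecomposition of the symmetrized matrix D^{1/2} Q D^{-1/2} and the
likelihood is invariant under re-rooting (tested to 1e-8). Codon
frequencies default to empirical F3x4 with a half-count floor (F1x4, F61
selectable); the original study does not state its choice. Felsenstein
pruning runs over compressed site patterns with per-pattern rescaling;
gaps/ambiguous codons contribute a partial-likelihood vector of ones.

Fitting maximizes over log-transformed κ ∈ [0.01, 100], per-class
ω ∈ [1e-4, 99] and branch lengths ∈ [1e-7, 20] with L-BFGS-B and
multi-start (default 3 restarts, seeded; the first start is deterministic
at κ=2, ω=0.4, t=0.1). When the root is a bifurcation whose two edges
share a class, only their sum is identifiable and one is pinned near zero.
Branch lengths are co-estimated per model by default; a fixed-lengths
option exists for speed. The LRT is 2(lnL₁ − lnL₀) against χ² with
df = Δ free parameters; ladder selection returns the most complex model
that significantly rejects every simpler model it is tested against and
is not rejected by any more complex one, ties toward fewer parameters.

The selection-intensity test draws site ω from three shared categories
(ω_i, w_i); test branches use ω_i^K. The null fixes K = 1; the LRT has one
degree of freedom; K < 1 with p < α is called relaxation. Branch lengths
and the κ starting value are taken from a one-ratio pre-fit and held fixed
during the mixture fits — a standard speed shortcut that slightly
understates uncertainty but leaves the df-1 test logic intact. The
implementation is deliberately simplified (no synonymous-rate variation,
three categories): it reproduces the *logic* of the published
clade-relaxation result (K ≪ 1, significant, in cetaceans), not the exact
K = 0.06 / p = 0.003 numbers, which require the original 97-sequence
alignment.

## Population statistics

Allele frequency is (n_Aa + 2n_aa)/2N and the HMA frequency n_aa/N. The
HWE default is the df-1 χ² test without continuity correction (the online
calculator used originally is unspecified); a conditional exact test is
available. Damaging-variant filtering keeps stop-gained/frameshift records
unconditionally and missense with PolyPhen ∈ [0.7, 1] and SIFT ∈ [0, 0.3],
both ends inclusive; missense with missing scores is dropped. LoF density
is 1000·n/CDS-bp. The constraint bound treats observed LoF as
Poisson(λ·expected) and reports the upper end of the two-sided 90% CI for
λ via the exact χ² relation (0.5·χ²₀.₉₅(2x+2)/expected); gnomAD's full
LOEUF pipeline differs in detail, so agreement is asserted at one decimal
(14 observed / 27.3 expected → o/e 0.51, bound 0.80). The windowed scan
reports S, per-bp π, and Tajima's D with the standard a₁…e₂ constants
(D undefined at S = 0). The Bayes-factor one-sample test uses the JZS
Cauchy prior on the standardized effect (scale 0.707, the common desktop
default) integrated numerically over the inverse-gamma auxiliary scale;
super-population means are unweighted over member populations (the
original weighting is unstated).

## Synthetic data: what it emulates and what it does not

Generators are deterministic given (scenario, seed); one global seed fans
out to labelled substreams so adding a call never perturbs other draws.
The locus generator joins (edited) exons with random introns carrying the
declared dialects and computes its truth table by brute force (apply edits
to the CDS, re-translate) — including stops induced downstream of
frameshifts — independently of the alignment-based detection path. Edits
that cross an exon boundary are rejected (not representable as one genomic
mutation), and the random-plan generator keeps edits ≥ 6 bp inside exons
because boundary-touching mutations are annotationally ambiguous even for
manual curation. Real genomic data adds paralogs, assembly errors and
alignment noise that these loci do not model, so a green detection test
establishes correctness of the calling logic, not robustness to
contamination. The coalescent generator is the standard neutral process
(exponential waiting times in units of 2N, uniform pair merging,
infinite-sites mutations at rate θ/2 per branch unit); no recombination,
demography or selection. Genotype panels follow
(p² + fpq, 2pq(1−f), q² + fpq).

Published numbers that require the original data (clade ω estimates
1.033/1.726/0.322, K = 0.06, the gnomAD 43-vs-15 LoF counts) are treated
as narrative context only; everything fixture- or arithmetic-derivable is
recomputed exactly.

## Test scaling and known limitations

Acceptance-grade simulations are sized for a single CPU: ω-recovery runs
at the full 8-taxon × 2000-codon scale across ω ∈ {0.1, 0.5, 1.0, 1.7};
ladder type-I calibration uses 50 replicates of 200-codon alignments on a
6-taxon labelled tree with a two-model ladder; the relaxation test uses 40
null replicates (200 codons) and 10 strong-relaxation replicates
(K = 0.1, 500 codons). One acceptance check is knowingly red: the mean of
Tajima's D over 500 neutral replicates at n = 20 is asserted to lie within
±0.1 of zero, but the exact finite-sample mean of the statistic is ≈ −0.1
(measured −0.112 ± 0.012 over 6000 replicates here and −0.089 ± 0.016
under msprime at identical parameters; the per-dataset values match
tskit's implementation exactly). The deviation is a known property of
Tajima's D, not an implementation defect, and a companion test verifies
cross-simulator agreement instead.

Other limitations: exon mapping assumes the target slice contains a single
orthologous copy (no paralog discrimination); the codon optimizer offers
no analytic gradients, so very large trees are slow; the ladder-selection
rule follows the published nested-comparison logic and is not an
information-criterion search.
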