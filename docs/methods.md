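# Methods

This note documents the models, conventions and numerical choices behind
`plastevol`, and what the synthetic-data suite does and does not establish
about real data.

## Coordinates and genome representation

Internal coordinates are 0-based half-open on the circular sequence
linearized at the start of the LSC (or at the record's stored origin when
no partition exists).  GenBank I/O converts to and from the flat file's
1-based inclusive convention; `join()` locations become multi-span
features.  Gene symbols are matched case-insensitively through a small
synonym table (e.g. `rrn16S` → `rrn16`); unknown symbols pass through
verbatim.

Inversion intervals are reported in flanking-breakpoint convention: an
inversion printed as `a–b` has length `b − a`, the two numbers being the
breakpoints immediately outside the inverted segment.  This convention
reproduces the published per-species inversion lengths from their printed
endpoints exactly and is asserted as such in the acceptance suite.

## Quadripartite partition and IR collapse

The IR pair is detected as the longest pair of exact reverse-complement
duplications with non-overlapping copies, at least `min_ir_len` (default
1000 bp — a length threshold operationalizes "canonical IR", which the
literature defines by similarity to *Amborella*).  Among equally long
candidates, one containing annotated rRNA features is preferred (canonical
IRs carry the rRNA operon) and a warning is logged.  The longer single-copy
gap is labeled LSC, the shorter SSC.  `collapse_ir` removes IR_B — the copy
after the SSC in LSC→IR_A→SSC→IR_B order; which copy is dropped is
immaterial to every downstream statistic, but a fixed choice keeps
coordinates deterministic.  The operation is a no-op (with a warning) on
records without both IRs, which also makes it idempotent.

## Reversal distance

Blocks are shared single-copy annotated loci rather than alignment-derived
locally collinear blocks; records sharing fewer than three single-copy loci
are rejected.  This is a deliberate deviation from alignment-based block
detection: annotation-based blocks need no whole-genome aligner, behave
identically on synthetic and real records, and are recorded as such in the
result metadata.

The distance is the exact signed (linear) reversal distance
`d = n + 1 − c + h + f` on the extended breakpoint graph.  Unoriented
components are found by uniting gray edges that cross or share a cycle;
hurdles are the minimal unoriented components plus the greatest component
when it contains all others; a fortress requires an odd number of hurdles,
all of them super-hurdles (deletion of any one would promote another
component to hurdle).  The implementation is validated against an
independent search oracle: a full breadth-first table of the reversal
graph for n ≤ 6, and iterative-deepening search for n = 7–8 whose
admissible bound (`n + 1 − c`; one reversal changes the cycle count by at
most one) does not depend on the hurdle/fortress theory being checked.
Agreement is exhaustive for n ≤ 5 and sampled (5,000 permutations) at
n = 6–8.

One optimal scenario is returned by greedy search: at each step some
reversal reduces the HP distance by one, and scanning the O(n²) candidates
finds it.  Optimal scenarios are not unique; the scenario is labeled as one
optimum, not the history.

Because the SSC orientation is arbitrary in IR-present plastomes (both
isomers coexist in vivo), cross-group distances are computed under both SSC
isomers of the reference and the minimum is reported — replicating, without
manual steps, the usual manual SSC reversal.

## Repeats

Dispersed repeats are exact maximal matching pairs ≥ 30 bp found on a
suffix array (prefix doubling + Kasai LCP) over the sequence concatenated
with its reverse complement, each N replaced by a unique symbol so no match
spans an ambiguous base.  Pairs are grouped into families keyed by the
canonical (lexicographically smaller strand) sequence.  Copies may overlap
only by less than half their length — perfect tandem structure is the SSR
detector's jurisdiction.  An O(L²) shift-scan oracle recomputes the pair
set independently for validation.

The nested-family filter applies two rules in order: (1) a family at most
10 bp longer than a family it contains is dropped (a near-identical
duplicate listing); (2) a remaining family with frequency ≥ 3 absorbs the
families it contains.  The source description of this filter is ambiguous;
this reading minimizes double counting, and the filter is idempotent.

SSRs are maximal perfect tandem runs of primitive 1–6 bp motifs with unit
minima 10/6/5/5/5/5; runs within 100 bp form compound loci, counted per
component in the tandem-repeat trait (MISA convention).  Repeat–inversion
association: a hit when any copy overlaps or lies within 500 bp of an
inversion endpoint.

Repeat censuses on quadripartite records are computed after `collapse_ir`,
so the IR pair itself never appears as a giant dispersed repeat.

## Sequence statistics

GC excludes N from numerator and denominator.  RSCU uses the standard
formula per synonymous family (the plastid code equals the standard code
for these genes); unused families are reported missing rather than zero.
GC3 excludes stop codons and codons containing N (CodonW convention).
Indel frequency counts gap *bases* in columns where exactly one of
target/reference is gapped, divided by the target's total plastome length;
an event-wise count and a per-class-length normalization are emitted as
diagnostics, since published base-wise frequencies divide by whole-plastome
length.  SNV frequency counts columns where both sequences have differing
unambiguous bases.  Alignments are inputs; the package does not infer them.

## Codon model

MG94-style: only single-nucleotide codon changes have nonzero rate; a
change's rate is the nucleotide exchangeability × the F3×4 frequency of the
target nucleotide at the changed position × ω if nonsynonymous.  The
nucleotide component is HKY (single κ) rather than full GTR — a smaller,
more identifiable optimization at the alignment sizes this package
targets — and the matrix builder accepts a 6-vector of GTR
exchangeabilities should the full model be wanted.  The chain is reversible
with stationary distribution equal to the F3×4 codon frequencies
(estimated from the data with a half-count prior, stop codons excluded).

Branch lengths are expected substitutions per codon; the matrix is
normalized to unit flux.  Per-branch dS and dN follow the
expected-substitutions decomposition — synonymous flux over neutral
synonymous site proportion — under which dN/dS = ω identically.  Likelihood
is computed by pruning over 61 states with per-pattern scaling; gapped or
ambiguous codons contribute a partial likelihood of one (missing data).
Matrix exponentials use the symmetrized eigendecomposition (one
decomposition per distinct ω per evaluation).

Optimization is bounded quasi-Newton (L-BFGS-B) in log space: ω ∈ [10⁻⁴,
20], branch lengths ∈ [10⁻⁶, 30], κ ∈ [0.05, 100], ftol 10⁻⁶.  The
two-ratio fit is initialized from the one-ratio optimum (guaranteeing the
LRT nesting numerically; a neutral-restart fallback handles the rare
failure).  The LRT compares 2ΔlnL to χ² with 1 degree of freedom.

Per-taxon dS for group comparisons is the terminal-branch dS under the
free-ratio model; root-to-tip dS is also provided, since either convention
is defensible for per-species rate plots.

Recovery at 2,000 codons on an 8-taxon tree is unbiased with |ω̂ − ω| well
within 0.05 for ω ∈ {0.1, 0.3, 1.0}, and the two-ratio LRT rejects a true
null at the nominal 5% (calibration run at 200 replicates of 300 codons on
a 5-taxon tree — sizes chosen to make the suite a routine desk run while
keeping the binomial error on the rate around 1.5%).

## Phylogenetic tests

Brownian covariance: C[i,j] is the root-to-MRCA path length.  The
phylogenetic t-test is GLS of the trait on an intercept plus a 0/1 dummy
(0 = IR-lacking, 1 = canonical relatives), t = β̂₁/SE, df = n − 2,
two-sided; homoscedastic across groups.  PGLS is the same machinery with a
continuous regressor.  On a star tree both reduce to OLS (asserted to
10⁻¹⁰).  Zero-length-branch singularities are handled by an optional ridge
of 10⁻⁸ × mean depth on the diagonal.

The phylogenetic ANOVA computes the ordinary one-way F on the observed
values and obtains its null distribution from Brownian simulations on the
tree (default 1,000; at least 500 enforced).  F and the post-hoc pairwise t
statistics are scale- and location-free, so the simulations can use unit
rate without loss; the Brownian rate is still estimated by the GLS residual
estimator and reported.  Simulation p-values use the (r + 1)/(n + 1)
convention.  Post-hoc pairwise tests use the pooled ANOVA error term with
the same simulated null and Holm correction (Bonferroni and
Benjamini–Hochberg available).

Type-I calibration at 1,000 Brownian nulls on a fixed 22-taxon birth–death
tree lands within 5% ± 2% for the t-test, PGLS and ANOVA, and a 10-σ
planted shift in one of eight variables is detected by that variable's
ANOVA alone.

## Synthetic data

The plastome generator assembles LSC, IR and SSC gene complements from the
real plastid inventory (including the IR core rrn16 / trnI-GAU / trnA-UGC /
rrn23 / rrn4.5 / rrn5) with approximately real gene lengths, i.i.d.
intergenic spacers of configurable GC (mean 200 bp), exact
reverse-complement IR copies (boundary bases adjusted so the IR match
cannot extend by chance), and optional deletion of either IR copy.  Default
gene lengths give an IR of roughly 16 kb in an ~90 kb genome; a
`gene_scale` knob shrinks fixtures for routine tests, and the partition
invariant is exercised at multiple scales.

Inversions respect gene boundaries, stay within one single-copy region and
preserve sequence length, so event coordinates remain valid in the final
genome.  Repeat-mediated events first overwrite the flanking intergenic
bases with an inverted repeat pair (default 40 bp) so the copies sit at the
breakpoints with distance zero.  In non-overlapping mode the chosen gene
runs are pairwise separated by an untouched gene, which makes the planted
count equal the true reversal distance (disjoint oriented components add).
With overlap allowed, a later inversion can relocate an earlier planted
copy; the event ledger flags such events as `disturbed`, since their ground
truth no longer has a repeat at the endpoints.

The codon simulator samples from the same MG94 process the estimator fits
(root from F3×4, children by transition-matrix sampling), and the trait
simulator draws from N(0, σ²C) with additive group shifts.

What passing tests show — and do not.  The generators match the model
assumptions exactly: repeats are exact, inversions are clean, alignments
are true, traits are Brownian.  Recovery and calibration results therefore
validate the *implementation*, not robustness to mismatch found in real
plastomes: near-identical (not exact) repeats, IR boundary expansion and
gene conversion, alignment error, non-Brownian trait evolution and
among-site rate variation are all outside the generators' scope.

## Known limitations

- Exact matching only in repeat detection (no mismatch tolerance) — by
  design, matching the published 0% mismatch setting.
- Linear (not circular) reversal distance, on records linearized at the
  LSC start; no translocation/DCJ distances.
- The search oracle refuses n > 8 (state-space guard).
- Codon model: no site models, no codon-frequency variants beyond F3×4,
  no among-branch κ variation; the two root-child branch lengths of a
  rooted binary root are only jointly identifiable (reversibility).
- Circular-origin-spanning repeats are found via a wrap-around pad of
  min_len − 1 bases; repeats longer than the pad that span the origin are
  truncated at the pad.
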