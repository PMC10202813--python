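# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic cohort generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Temporal tiering and phylogeny

Tiers are defined by the cross-tumor sharing pattern of an event within one
case: present in all tumors → early; in exactly one → late; otherwise
intermediate. A two-tumor case therefore has no intermediate tier. Tiering
is deliberately independent of the inferred tree — under a perfect
phylogeny the two coincide, and the sharing-pattern semantics stay
well-defined under homoplasy. Presence requires at least 3 supporting reads
(configurable) to absorb read noise; the threshold is a package choice, as
presence calling for cross-tumor sharing has no canonical definition.

Trees are maximum parsimony over binary presence/absence characters with an
implicit all-absent outgroup (patient normal). Fitch small parsimony is
computed with bitmask state sets vectorised over events. Search is
exhaustive over all rooted topologies of the tumors (equivalently, unrooted
topologies with the outgroup) up to 7 leaves — (2k−3)!! topologies — and
nearest-neighbour-interchange hill climbing from 10 seeded random starts
beyond that. Equally parsimonious topologies break deterministically on the
lexicographically smallest canonical newick string. Branch placement of
events uses a Fitch up-pass that prefers the parent state when ambiguous;
events needing more than one gain are flagged homoplastic with all gain
branches listed. Branch lengths, bootstrap support and rate models are out
of scope.

## Signature refitting

Spectra: SBS96 channels are ordered by substitution class (C>A, C>G, C>T,
T>A, T>C, T>G), then 5′ and 3′ base; purine-reference records are
reverse-complemented so spectra are strand-symmetric. ID83 follows the
standard indel classification (1-bp events by homopolymer length, longer
events by repeat-unit count or flanking microhomology, with microhomology
taking precedence over single-copy repeat context). RS32 crosses
clustered/non-clustered with deletion/duplication/inversion in five size
bins (1–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb, > 10 Mb) plus a size-free
translocation channel.

Refitting solves non-negative least squares (scipy `nnls`) for the
normalised spectrum against a column-stochastic catalog, then iteratively
zeroes the smallest exposure below a proportion cutoff of **0.06** and
refits, accepting each removal while the reconstruction cosine similarity
stays within **0.01** of the unpruned fit. Both constants are configurable
and mirror the documented defaults of the widely used refitting tool for
this task. Exposures are reported as proportions; late-tier refits can be
pooled per case or split per tumor (late mutations are private, so both
views are meaningful). Tiers with fewer than 20 mutations are refit but
flagged low-confidence. De novo signature extraction is out of scope;
reference catalogs are input files, and tests use synthetic catalogs.

## Rearrangements and repair inference

A breakpoint is *clustered* when the density of breakpoints from other SVs
within a 1-Mb window centred on it is at least 10× the genome-wide average
density; an SV is clustered if either breakpoint is. Both breakpoints of
the record under test are excluded from its own window count, so an
isolated SV can never cluster with itself. Window, fold and genome size are
parameters; the rule replaces the piecewise-constant segmentation used in
the literature classification because it is deterministic and directly
testable.

Repair mechanism is a pure function of junction homology length: 0–1 bp →
non-homologous end joining, 2–6 bp → microhomology-mediated (alternative)
NHEJ, > 6 bp → homologous recombination repair. SV-gene recurrence keeps
genes hit in at least ⌈fraction × n_tumors⌉ tumors (50 % of 21 → 11).
Recurrent translocations bin breakpoints into 1-Mb windows and count
distinct tumors per unordered window pair, with an arm-stratified mode at a
lower threshold.

## Copy-number selection

Events are counted at the patient level (OR over the patient's tumors;
pre- and post-treatment tumor sets each count as an entirety). The Fisher
rule tests each gene's 2×2 patient-frequency table two-sided, adjusts with
Benjamini–Hochberg across the gene universe (default: genes assayed in both
cohorts), and calls enrichment only when the adjusted P < 0.05 *and* the
frequency is higher in the cohort of interest. The ICB fold rule is
deliberately non-statistical: post frequency strictly > 2× pre and ≥ 2
post-treatment patients (a pre frequency of zero satisfies the fold
condition with any positive post frequency — the small paired cohorts make
a Fisher test uninformative there). SMG nomination takes per-gene
significance values as an input column (raw, uncorrected by design),
excludes genes with mean tumor log2CPM < 0, and bins the rest at a mean
log2CPM of 4. Bi-allelic loss requires a deletion call plus a deleterious
mutation (nonsense, frameshift, splice-site or annotated loss-of-function
missense) in the same tumor; two deleterious mutations without a deletion
are reported as "possible compound" because phasing is unavailable.

## Clonality

The CCF point estimator inverts v = ρ·CCF·m/(ρ·CNt + (1−ρ)·CNn): the
multiplicity m is the rounded allele count clamped into {1..CNt}, the CCF
the corresponding plug-in clipped to [0, 1.5]. This replaces Bayesian
multi-sample clustering because the downstream uses — the clonal/subclonal
ratio (ITH) and ΔCCF thresholds — only need a per-mutation point estimate,
which keeps recovery analytically checkable. The clonal cutoff defaults to
0.8 ("CCF approaching 1"). ΔCCF compares a mutation's CCF in the organ-A
tumor against the **mean** CCF across tumors of other organs (a max-based
reference is available behind a flag); the exact published formula is not
reproducible from text, so the mean-reference semantics are a documented
stand-in. A mutation is organ-enriched at ΔCCF > 0.2 strictly; a gene
reports for an organ at ≥ 3 patients. The estimator's sampling error is
(2/ρ)·sd(v̂), so the depth-200 recovery property (median absolute error
≤ 0.05) holds when binomial read noise is the only noise source (ρ ≈ 1);
at lower purity the error grows proportionally.

## Normal-corrected transcriptomics

log2CPM = log2((c + 0.5)/(libsize + 1) × 10⁶); the 0.5 pseudocount keeps
single-sample fold changes finite. Organ-normal signatures use a rank-sum
test per gene (one organ's NAN samples vs the rest) with BH correction,
taking the top 5 significant genes by mean difference — an internal
replacement for a count-model DE fit, validated on implanted markers.

NC-FC divides the tumor-pair fold change by the organ-matched normal-pair
fold change; NC-DEGs use cutoffs 2 and 0.5, and recurrence for an organ
requires the same direction in ≥ 30 % of that organ's comparisons *and*
≥ 3 distinct cases (the text is ambiguous about the denominator, so both
thresholds are enforced jointly). A known property of this arithmetic: for
a gene expressed only in organ B's normal tissue, the correction divides a
tumor-side ratio attenuated by purity by the full normal ratio, producing
an inverse ("up for organ A") artifact at high purity. The recurrence and
multi-case thresholds are what keep such genes out of the reported lists —
the validation study measures exactly this (see below).

Preranked GSEA uses the weighted Kolmogorov–Smirnov statistic on the
metric-sorted ranking with a gene-label permutation null; p-values
condition on the sign of the observed ES and NES divides by the mean |null
ES| of the same sign. The single-sample enrichment score is a rank-based
weighted running sum (weight exponent 0.25, ties broken by gene name),
invariant under monotone transforms of the expression vector — an internal
replacement for kernel-density ssGSEA, sufficient for argmax archetype
assignment and program scoring. NC-DGS matching is sign-aware: a set
significant in tumors and in the matched normal with the *same* direction
is removed; opposite directions are kept, since a differential gene set
carries its direction.

## Immune contexture and crosstalk

Archetype assignment is the argmax of per-set single-sample scores with a
lexicographic tie-break; composition tables are label fractions per
(organ, compartment). Ligand–receptor analysis is a transparent stand-in
for an external cell-communication model, implementing the study-design
logic: organs qualify with ≥ 4 tumor–AN and ≥ 4 tumor–NAN case pairs from
≥ 3 cases; strength is mean ligand log2CPM in the sender × mean receptor
log2CPM in the receiver (floored at 0); significance permutes compartment
labels separately for the ligand's sender enrichment and the receptor's
receiver enrichment and takes the larger p — requiring *both* partners to
be compartment-specific, without which a tumor-specific ligand alone would
make every pairing significant and the final culling (keep pairs
significant in tumor–AN but not tumor–NAN) would erase genuinely
AN-specific signalling. Each enrichment must also clear a log2 effect
floor (default 1, i.e., 2-fold): normalised bulk profiles carry small
compositional shifts between compartments (adding tumor-program mass
dilutes every other gene), and with enough samples a permutation test
declares those shifts significant; the floor keeps them out.

## Synthetic cohort generator

Defaults mirror the emulated study design: 11 cases (treatment arms split
4 MAPKi / 4 ICB / 3 both), 3 organs per case from a 6-organ pool, 2 tumors
per organ (66 tumors), one AN and one NAN sample per case-organ, mean read
depth 217, purity uniform on (0.40, 0.95) consistent with a > 30 % purity
selection. Per case a random clone tree assigns early mutations to the
trunk, intermediate to internal clades and late to leaves; default counts
per case are 400/200/150-per-tumor — scaled to hundreds rather than the
thousands seen in heavily mutated melanoma so that the full pipeline and
replicated validation studies stay light; all rules under test are
count-threshold or proportion based, so the scale does not change their
behaviour. Tier CCFs: early exactly 1, intermediate Beta(mean 0.90),
late Beta(mean 0.65) — making mean VAF fall from early to late as observed
in such cohorts. VAF = ρ·CCF·m/(ρ·CNt + (1−ρ)·2) with Poisson depth and
binomial alt reads; multiplicity is 1 except on amplified genes (uniform in
{1..CNt}). SV class mix defaults to ~67 % non-clustered translocations,
16 % deletions, 12 % inversions; early-SV repair mix is 76 % NHEJ / 18 %
alt-NHEJ / 6 % HRR, with later tiers shifting toward alt-NHEJ. Homology
lengths per mechanism — NHEJ uniform {0,1}, alt-NHEJ uniform {2..6},
HRR 7 + Geometric(0.3) — lie strictly inside the classifier's bins, so its
confusion matrix is diagonal by construction (the classifier test is a
consistency check, not evidence about real junction sequences).

Copy-number truth implants eight amplification and six deletion genes at
frequency 0.6 in the autopsy-like cohort (and in the matching
post-treatment arms) versus 0.1 background in comparators (naive n = 300;
paired MAPKi n = 28; paired ICB n = 7). Expression is a linear count-space
mixture: tumor bulk = purity × tumor program + (1 − purity) × organ-normal
profile; AN = organ normal plus at most 10 % tumor program; NAN = pure
organ normal. Organ normals carry 5 marker genes at log2FC 4; tumor
programs carry 50 organ-specific genes at log2FC 2; immune archetype
programs (12 sets of 20 genes, log2FC 2.5) ride on the mixed profile; a
liver-specific ligand/receptor pair set links tumor and AN compartments.
All randomness flows from one root seed through named substreams
(CRC32-keyed), so any artifact regenerates identically in isolation and
identical seeds give byte-identical outputs.

What the generator does **not** emulate: read-level data, germline
variation, sequencing error beyond binomial sampling, subclonal copy
number, batch effects, isoform structure, or realistic gene-gene
correlation. Passing recovery tests therefore demonstrates that the
implemented rules compute what they claim under their stated model — not
that the rules are powerful on real tissue.

## Validation studies and problem sizes

The validation suite (also run by `scripts/acceptance.py`) uses these
problem sizes, chosen to give stable estimates at interactive runtimes:
exact-test equivalence over all 2×2 tables with total count ≤ 30 and all
hypergeometric configurations with universe ≤ 25, against exact-integer
enumeration oracles; parsimony optimality on 100 random matrices (≤ 6
tumors × 30 events) against an independent all-topology Fitch oracle;
signature recovery as the mean L1 error over 200 spectra of 2,000 draws
from random 3-signature mixtures of an orthogonal catalog (the mean is the
stable statistic — the max over 200 draws reflects multinomial noise, not
the refitter); tier recovery over 20 cohorts at saturating depth and at
depth 200; normal-correction depletion over 20 cohorts configured to
isolate the correction mechanism (12 cases, two organs per case so the
inverse-correction artifact cannot reach the recurrence bar by chance,
uniform immune background, organ markers as the contamination genes);
enrichment power/size over 100 replicates at the implanted 0.6-vs-0.1
frequency shift with 12 vs 300 patients; GSEA null calibration over 200
random trials at 300 permutations. The pipeline's default permutation count
is 1,000 (configurable; published analyses of this kind use 10⁵ — the
default favours the full run completing in well under a quarter hour).

## Known limitations

The NC-FC inverse-correction artifact above is intrinsic to ratio-of-ratio
correction with impure tumors. The ICB fold rule with n = 7 pairs flags
background fluctuations by design (no multiplicity control). The
clustered-SV rule is a density heuristic, not a segmentation model.
Archetype scores on bulk tissue conflate composition and expression
change. None of the per-case analyses model shared clones across organs
beyond the tree (no migration inference).
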