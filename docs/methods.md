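# Methods

This note documents the models, defaults and numerical choices behind
each stage of the survey, what the synthetic-data generators do and do
not emulate, and the design decisions taken where the procedure was
genuinely open.

## Alignment and identification

All pairwise protein comparison in the package goes through one scoring
contract: exact Smith–Waterman local alignment with BLOSUM62 and affine
gaps costing 11 + k for a gap of length k (Biopython's `PairwiseAligner`
with `open_gap_score=-12, extend_gap_score=-1`). Significance uses a
Karlin–Altschul expect value E = K·m·n·e^(−λS) with the gapped BLOSUM62
constants λ = 0.267, K = 0.041; the screen cutoff is E ≤ 1e-5. Identity
is counted over alignment columns including gaps; coverage is the
aligned span on the longer sequence divided by its length. The "longer
sequence" denominator is used consistently for both the identification
screen (coverage ≥ 0.80) and the duplication rule, since the two share
one convention in the source procedure.

Domain confirmation replaces profile-HMM scanning with ungapped
consensus-block scoring: a 60-aa kinase-like and a 29-aa EF-hand-like
consensus are slid over the protein and windows scoring at least 60% of
the block's self-score (BLOSUM62) are reported, greedily non-overlapping
per domain. A candidate is confirmed only with ≥1 hit of *both* labels.
This keeps the published contract (two mandatory Pfam-style domains at a
stated cutoff) without re-implementing HMMER; the threshold has a wide
margin — at the generator's 10% within-domain divergence, planted blocks
score ~85–90% of self-score while random windows score below zero.
Whether one or both domains were mandatory in the original procedure is
ambiguous; the dual-domain reading is the default and the required label
set is a parameter of `confirm_members`.

Family tables name members by (chromosome label, gene start) rank.
Exact reproduction of the published numbering on real data is a
non-goal: the published table is not globally coordinate-sorted.

## Phylogeny and groups

Distances are uncorrected p-distances with pairwise deletion of gap
columns (no substitution model is specified for the original tree; at
the within-family divergences involved, p-distance orders pairs the same
way as simple corrections would). Tree building is classic Saitou–Nei
neighbor joining; a negative limb length is clamped to zero with the
deficit moved to its sister limb so the joined pair's total is
preserved. On tree-additive matrices NJ is exact, which the tests
exploit: topology and all leaf-to-leaf path lengths are recovered to
1e-9 on random 6–10-leaf trees, and the 3-leaf closed form to 1e-12.

Bootstrap supports are plain nonparametric column resamples (the
"rapid" accelerations of desktop phylogeny suites are out of scope):
support = percentage of replicate NJ trees containing the bipartition.
The default replicate count is 1000; the test suite and acceptance
script use 25–200 replicates, which is ample for the strongly separated
synthetic clades.

Group assignment roots the unrooted tree on every edge implicitly: each
edge defines the member-side component when cut; the smallest component
containing the member and at least one labeled reference leaf decides
the call (unanimous reference group → that group, mixed → ungrouped;
ties broken by sorted leaf tuple for determinism).

The multiple alignment is normally an input. The shipped fallback is a
deterministic progressive aligner — average-linkage guide tree on 3-mer
Jaccard distances, profile merges by globally aligning profile consensus
sequences and broadcasting the gap pattern — adequate for the synthetic
families, not a general-purpose MSA tool.

## Motif discovery

Each motif is a two-component mixture over all width-w windows: a
position weight matrix versus a 0-order background estimated from the
input, fitted by EM (E-step posterior per window; M-step PWM with
Dirichlet pseudocount 0.05 per cell, mixing weight = mean posterior
clipped to [1e-6, 0.3]). Convergence is a max PWM change < 1e-4 or 200
iterations. The EM objective (data log-likelihood plus the pseudocount
prior) is non-decreasing per iteration and is exposed for testing.

Sites are called where the posterior odds of the motif component exceed
10 (the original tool's internal threshold is unpublished), greedily
non-overlapping within a sequence but unlimited in number per sequence
(ANR). Widths are searched over the grid {6, 8, 10, 15, 20, 29, 50} and
selected by a BIC-like criterion, total site LLR − ½·19·w·ln(sites),
charging 19 free parameters per column; this is the E-value-like
penalty that stops flank columns from inflating wide motifs. Seeding
draws 300 random data windows, scores each as a point-mass PWM by the
summed positive LLR of its best matching windows, short-EMs the top 3,
and full-EMs the winner. Because EM on repeated patterns can converge
one or two columns out of register, the fitted PWM is phase-refined by
re-running EM from ±3-column shifts and keeping the best criterion.
After a motif is accepted its sites are masked (X) before the next
motif is sought, which guarantees disjoint site sets across motifs;
discovery stops early when no motif achieves a positive criterion with
at least two sites.

## Duplications

A member pair is duplicated when identity > 0.8 and coverage of the
longer protein > 0.8 (both strict). "Tightly linked" copies — the
unquantified collapse rule of the source procedure — are defined as
same-chromosome partners with ≤1 intervening gene or midpoints ≤100 kb
apart; both knobs are exposed. Each multi-gene tight cluster counts as
one tandem event; between distinct clusters the best-identity pair
defines one event, tandem if it itself satisfies the tight window and
segmental otherwise. Synteny-block detection is deliberately not
re-implemented: segmental means "duplicated but not tandem", matching
the binary reporting the survey design calls for. Both event counts and
duplicated-gene counts are emitted, since published tallies of this
kind are ambiguous between the two.

## Network projection and enrichment

Homologs are strict reciprocal best hits at E ≤ 1e-5 using the same
aligner (a one-way best-hit mode is available, since the source
description can be read either way); ties are broken lexicographically
with a warning. Scores are symmetric, so one score matrix serves both
search directions. Projection transfers a reference edge when both
endpoints have homolog pairs, dropping self-loops and merging
duplicates; reference edge weights are not modelled. Subnetworks are
seeds plus bounded-hop neighborhoods, with per-seed interactor counts
from the full projected network.

Enrichment is an upper-tail hypergeometric test per GO term after
true-path up-propagation, with the elim hierarchy correction: terms are
processed children-before-parents and a term significant at α = 0.05
has its genes removed from its ancestors' gene lists before they are
tested. Study and population sizes stay fixed during elimination, and
no correction beyond elim is applied, following the convention of
hierarchy-aware enrichment tools. The background universe is an
explicit required argument — the source procedure does not state
whether the whole proteome or the projected network was used, so the
choice is surfaced rather than defaulted silently.

## Expression and qPCR

FPKM(g, s) = 10⁹·c(g,s)/(N(s)·L(g)) with library sizes N as an explicit
input (defaulting to column totals only when none are supplied — for a
small gene panel the panel's column sums are not library sizes, and
using them would absorb a coordinated induction into the
normalisation). Genes are "expressed" with FPKM strictly greater than 1
in at least one sample. The heatmap transform is log2(x+1) followed by
per-gene centering and scaling by the sample standard deviation (R
`scale` semantics); zero-variance genes become all-zero rows with a
warning. Clustering is average linkage on 1−Pearson distances with the
leaf order emitted for plotting elsewhere.

Response calls compare replicate-mean FPKM per timepoint to the 0H
control: LFC = log2((m_t+1)/(m_0+1)), called up/down at |LFC| ≥ 1. The
pseudocount and the threshold are package choices (the source states no
criterion for "up-regulated") and both are configurable.

qPCR: ΔCt = Ct_target − Ct_reference per replicate, ΔΔCt = mean ΔCt(t)
− mean ΔCt(control), fold = 2^(−ΔΔCt); the control column is exactly 1
by definition. Error propagation through this estimator is what limits
recovery of planted folds: at Ct noise σ = 0.2 cycles and 3 replicates
the ΔΔCt estimate has σ ≈ 0.23, so roughly a quarter of fold estimates
fall outside ±20% of truth — the tests therefore check the observed
recovery rate against a Monte-Carlo propagation oracle rather than a
fixed high percentage.

## Synthetic data: what it emulates and what it does not

The generators produce a 16-chromosome (8 homoeologous O/P pairs)
genome with 50 family members by default: 36 founder members drawn from
four group-ancestral backbones (groups I 17, II 15, III 13, IV 5, the
tallies of the packaged family table) and 14 duplicate copies — four
2-gene tandem clusters and ten cross-homoeolog segmental pairs. Every
member carries the kinase block and a group-dependent number (1–3) of
EF-hand blocks at 10% within-domain divergence; decoys carry exactly
one of the two domains on a member-like backbone, so they survive the
homology screen and are rejected only by the domain filter.

Rates are chosen so the planted truths coincide with the rules that
detect them, which is a construction constraint rather than a tuning
knob: non-duplicate same-group members diverge at 22% per site (their
best-local identity stays ≤ ~0.76, clearly below the 0.8 duplication
rule) while duplicate copies diverge at 2% (identity ≥ ~0.96, domain
blocks copied verbatim); ortholog counterparts diverge at 6%, far
closer than any non-ortholog, so strict RBH recovers the 1:1 planted
pairs. Duplicate copies deliberately have no reference counterpart of
their own — after a lineage-specific duplication both copies share one
ortholog — which keeps the planted orthology a partial matching.

The cold time course plants 32 up-regulated members (4-fold at 30
minutes, decaying to baseline by 24 h) on negative-binomial counts
(dispersion 0.1, library sizes varying < 2×), with 3 fully silent genes
so the expressed filter has a determinate answer. Ct tables plant
per-gene ΔΔCt trajectories (one gene peaking at −5, i.e. 32-fold) with
Gaussian cycle noise.

Not emulated: codon/intron sequence content (the GFF carries
coordinates and exon counts only), read-level data, indels (all
mutation is substitution, so planted domain coordinates stay fixed),
realistic GO ontology size (a 3-namespace toy DAG with a planted
signalling enrichment), and reference-network edge weights. Passing the
recovery tests therefore demonstrates the pipeline's logic and
numerics, not robustness to alignment-breaking indels or to real
genome annotation noise.

## Problem sizes and determinism

Default synthetic conditions: 110 target proteins (50 members, 20
decoys, 40 background genes), ~80 reference proteins, a 150-edge
reference network, 8 timepoints × 3 replicates. The test suite and
acceptance script run these defaults end-to-end with 25–200 bootstrap
replicates and ≤5 motifs per discovery run — sizes chosen so the whole
suite completes in a couple of minutes on one CPU while every stage
still runs at its default thresholds. All randomness flows from a
single seed through per-stage substreams; two runs with one seed
produce byte-identical output bundles, which the suite asserts
file-by-file.

## Known limitations

- The e-value proxy uses fixed Karlin–Altschul constants; it reproduces
  BLAST-like cutoff behaviour but not BLAST's composition-adjusted
  statistics.
- The fallback progressive aligner is consensus-based and intended for
  the synthetic families; real surveys should supply a proper MSA.
- The published chromosome text ("16 chromosomes") and the packaged
  table (15 distinct chromosome labels) disagree; the fixture
  reproduces the table verbatim and the summary reports what the table
  contains.
- Group tallies differ between the packaged table (I 17, III 13, all
  50 rows grouped) and the narrative counts that exclude three
  ungrouped members (I 15, III 12); both views are derivable from the
  reported assignments, and the summary follows the table.
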