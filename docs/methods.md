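# Methods

This note documents the statistical machinery in `fusefit`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Consensus fusion catalog

Fusion callers disagree on exact breakpoint coordinates, so per-caller
calls are merged per sample by ordered gene pair with a breakpoint
tolerance (default 5 bp on each side; configurable because there is no
canonical definition of "the same transcript" across callers). Clustering
is greedy in descending junction-read order, so the representative
breakpoints always come from the best-supported call; `supporting_callers`
is the union and `max_junction_reads` the maximum. Coordinates are 1-based
inclusive: `breakpoint5` is the last retained base of the 5′ gene,
`breakpoint3` the first retained base of the 3′ gene.

Filtering keeps transcripts with (i) ≥ 2 supporting algorithms, (ii) a
maximum junction-read count ≥ 4 — the read criterion is satisfied if *any*
caller reports ≥ 4 reads, the conservative reading of a per-call
threshold — and (iii) an ordered (5′, 3′) gene pair absent from the
normal-tissue blacklist (ordered matching is the stricter choice and is
what the blacklist file encodes). Self-pairs are removed as read-through
artifacts. Every removal is logged with its reason.

When a cell line was sequenced by more than one source, only transcripts
from the highest-precedence source are taken forward. Events collapse
transcripts to one record per (cell line, gene pair); an event is labelled
in-frame if any constituent transcript is in frame. Reported percentages
round to the nearest integer, halves away from zero.

## Recurrence permutation test

The occurrence matrix is binary: entry (G, S) = 1 iff sample S carries at
least one fusion event involving gene G at either end. The null model
preserves both marginals (how often each gene is fused, how fusion-laden
each sample is) via checkerboard switches.

One subtlety matters for correctness. A chain that counts only *successful*
switches is the jump chain of the proposal process; its stationary
distribution is proportional to each matrix's number of available switches,
not uniform (and on degenerate matrices a fixed even switch count can
alias, e.g. a 2×2 identity returns to itself). Counting proposal
*attempts* as steps — failed draws are self-loops — makes the transition
kernel symmetric and the stationary distribution exactly uniform over the
margin class. `permutation_null` therefore runs a fixed number of attempt
steps per permutation (default 10× the number of 1-entries, a mixing
heuristic), while `rewire` also offers an exactly-n-successful-switches
mode with a bounded retry budget for direct matrix randomization (an
all-ones matrix, which admits no switch, is returned unchanged with a
warning).

The per-(gene, cancer type) statistic is the fused-sample count; the
empirical p uses plus-one smoothing, `p = (1 + #{null ≥ observed}) /
(1 + R)`, which can never return 0 with finite permutations. Only pairs
with an observed count ≥ 1 are tested (absent pairs have p = 1 by
construction and would only inflate the BH correction burden).
Benjamini–Hochberg is used wherever an FDR is quoted in this package.

## Expression association

For each gene fused at a given end in ≥ 3 cell lines (recurrence makes the
regression identifiable; 2 carriers leave the fusion term too close to a
leverage point), log2 RPKM is regressed on an intercept, categorical
covariates and the binary fusion indicator. Covariates: cancer type
(pan-cancer analyses only), MSI status (MSI/MSS; an unknown status would
form its own level), and the gene's copy-number category encoded as
three levels {loss, neutral, amplified} rather than a linear dose term.
Covariate levels absent from the data drop out; a rank-deficient covariate
design is an error naming the collinear columns.

The fusion-term p-value is the type-II F test. For a single term with no
interactions this equals the nested-model F comparing the full fit to the
fusion-dropped fit, which is how it is computed (from the two residual sums
of squares); the test suite verifies equality with an independently coded
type-II ANOVA to 1e-10. BH adjustment is applied within strata; a
pan-cancer run is a single stratum.

The single-event overexpression screen ranks the carrier against all
*other* lines — the carrier is excluded from its own reference set, and the
comparison uses strict inequality ("lower than"). An event is flagged when
the carrier's 3′-gene expression exceeds the 95th percentile of the others
and the carrier is not amplified for that gene (amplification would explain
the overexpression without invoking the fusion).

## Drug-response association

Stage 1 regresses each drug's log IC50 profile on tissue and MSI
covariates plus one binary CFE at a time; a CFE becomes a stage-2 covariate
for a drug iff its association passes FDR < 25 %, p < 0.001 and both Glass
deltas > 1. Stage 2 repeats the model for each recurrent fusion (≥ 2
positive screened lines) with the selected CFEs appended; the significance
gate there is FDR < 25 % with both deltas > 1. BH runs separately per
stage. Negative effect sizes mean the feature sensitizes.

Glass deltas are computed on the raw (unadjusted) IC50 groups — that is
what "the standard deviation of the two sub-populations" denotes — with the
n−1 denominator. A group of size 1 or zero spread has no usable SD; its
delta is undefined and fails the gate rather than erroring the run. Drugs
screened in one tissue lose the tissue covariate automatically (constant
dummy columns are dropped). A fusion perfectly co-occurring with a selected
CFE is collinear and reported as not-testable with the reason logged.

## Fusion essentiality score

Fold changes are used on the bias-corrected, scaled convention: per cell
line, the median guide against a non-essential reference gene sits at 0 and
against an essential reference gene at −1. `scale_to_essentials` performs
this anchoring — `scaled(x) = (x − m_ne) / (m_ne − m_e)` — and raises if a
cell line's essential median is not below its non-essential median, which
indicates a failed screen.

Guide partitioning follows the strand/side rule: a guide maps to the 5′
gene iff it cuts at or before the breakpoint on the + strand (at or after
on −), and to the 3′ gene with the rule mirrored. Ties (cut ==
breakpoint) count as mapping, a symmetric convention the data cannot
distinguish. A guide on a different chromosome than its gene's breakpoint
is excluded with a warning. The guide's position is the single cut-site
coordinate from the library table; the protospacer extent is not modelled.

Scoring: per-guide Z across all screened lines (sample SD; rows with zero
spread or fewer than two finite entries get Z = 0), per-gene mapping minus
non-mapping mean Z (zero when the gene has no non-mapping guides), averaged
over genes that have mapping guides. `raw_diff` applies the same
construction on the scaled (not Z) values pooled over both genes and feeds
the −0.45 minimum-difference filter; pooling matches the FES construction
since the threshold is stated at transcript level.

Significance: all scaled fold changes are permuted independently within
every cell line, the Z-normalization is recomputed on the permuted matrix,
and every transcript's FES is recomputed per randomization. The p-value
counts null FES **at or below** the observed (plus-one smoothed). The test
is depletion-sided because a fitness-relevant fusion depletes its mapping
guides, giving a negative FES; a "more extreme than observed" count phrased
as *higher* null FES would reward enrichment of the mapping guides, which
is not the phenotype of interest — this directional choice is deliberate
and central enough to state twice: **small p means stronger depletion**.
BH is applied per screening dataset (libraries differ between datasets, so
pooling would mix incomparable nulls); event-level significance is the
any-transcript, any-dataset rule. Hits with `raw_diff > −0.45` are removed
regardless of p.

## Pre-ranked enrichment

Items are ranked by score with a stable (score, id) tie-break so results
are reproducible. The running sum rises by `|s|^w / Σ_set |s|^w` at set
members (equal increments if all in-set weights vanish) and falls by
`1/(n_total − n_set)` otherwise; the ES is the signed maximum deviation.
The default weight exponent is 1; 0 gives the classic unweighted statistic,
invariant under monotone rescaling of scores. The p-value uses random
same-size item sets (gene permutation), one-sided and sign-matched: the
direction of enrichment is part of the hypothesis. No normalized ES across
set sizes is computed; comparisons across sets of very different sizes
should use the p-values.

## Synthetic cohort

The generator emulates the pipeline's input universe at desk scale:
60 cell lines across 4 cancer types, 120 genes on 4 chromosomes, 30 true
fusions plus 3 blacklisted pairs. Planted classes: 5 fitness-relevant
(CRISPR) fusions, 8 expression-driving fusions (log2 shifts +3 on the 3′
gene, −2 on the 5′ gene — oncogene- and TSG-like magnitudes), 3
drug-sensitizing fusions (−3 log IC50 shift in 4–6 carriers), and exactly
one *confounded* fusion. True fusions are emitted by ≥ 2 callers with ≥ 4
junction reads (each caller drops out independently at rate 0.1; the truth
manifest records per-carrier detectability), with ±2 bp breakpoint jitter;
noise calls are single-caller or low-read. Expression adds cancer-type
baselines, Gaussian residual SD 1 and ±1 copy-number shifts; IC50s add
tissue effects (SD 0.5) and unit noise; CRISPR screens use 5–10 guides per
gene, noise SD 0.25, −1 depletion of mapping guides in carrier lines, and
emit on the pre-scaled convention (an un-scaled mode with per-line anchors
exercises `scale_to_essentials`).

The confounded fixture mirrors the situation where a fusion's apparent
drug association is carried by a co-occurring driver event: the confounding
CFE has the full −3 effect, occurs in all 4 fusion-carrier lines plus 2
others, and the fusion itself has no effect. These sizes are chosen so the
*unadjusted* association is reliably significant inside the full
recurrent-fusion screen (the demonstration is vacuous otherwise) while the
stage-1 covariate removes it; the behaviour was checked across a dozen
generator seeds before freezing.

What the generator does **not** emulate: read-level data (junction reads
are counts, not alignments), linkage between copy-number breakpoints and
fusion breakpoints, heavy-tailed or batch-structured noise (a Gaussian
switch is all there is), sub-clonal fusions, guide-efficiency variation,
and cell lines screened in only a subset of assays. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to every artifact of real screens.

All generators are deterministic given the config seed; each stage draws
from its own stream derived from the seed by a fixed offset, so stages are
independently reproducible, as are pipeline stages in `run_all` (global
seed + fixed per-stage offsets, recorded in the manifest).

## Numerical and scale choices

Problem sizes in the test suite and acceptance script (e.g. 20–40 cell
lines, 100 genes, 5 guides per gene, 1000 randomizations, 25–50 replicates)
are chosen to estimate the quantities of interest — type-I error near 0.05,
detection rates near 1 — to within a few percent Monte-Carlo error; the
within-line randomization test and the rewiring null are exact conditional
procedures, so more permutations sharpen p-value granularity
(min p = 1/(R+1)) rather than validity. Degenerate inputs are handled
explicitly rather than propagated: constant fusion indicators and
insufficient group sizes are "not testable" results, zero-spread Z rows
become zeros, undefined Glass deltas fail gates, and the all-ones matrix
survives rewiring untouched with a warning.

## Known limitations

The FES treats the absent-non-mapping case by comparing against zero, i.e.
against the cross-line average behaviour of those guides; transcripts whose
partner genes are themselves essential can therefore shrink toward null.
Frame labels are taken from the callers (majority-style consensus
preferring in-frame); no reading-frame prediction is attempted. The
recurrence test is per gene, not per gene pair. Raw viability data, read
counts, copy-number bias correction of CRISPR counts and gene-level
essentiality calling are out of scope: the pipeline starts from called
fusions, RPKM matrices, fitted IC50s and corrected fold changes.
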