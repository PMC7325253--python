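# Methods

This note records the models, parameter choices and numerical conventions
behind `bilnc`, and what the synthetic-data experiments do and do not show.

## Coordinate and sequence conventions

Exon intervals are 0-based half-open internally and converted at the
GTF/GFF boundary (1-based closed). All sequences are normalised to the DNA
alphabet (U→T, uppercase) at ingest so genomic, transcript and miRNA
sequences share one alphabet; "G:U wobble" below therefore appears as G:T.
Writers emit rows sorted by identifier so outputs are diffable and runs at
a fixed seed are byte-identical.

## Identification

The candidate filter applies max-FPKM ≥ 0.5 (the maximum over all samples
— transcripts come from a merged assembly, so a transcript expressed
anywhere is a candidate), assembly coverage strictly > 1 and length
strictly > 200 nt. Coding-potential verdicts are inputs (CPC-, CNCI-,
txCdsPredict-style scores and a Pfam hit flag) with strict greater-than
thresholds (0 / 0 / 500); classification needs ≥ 3 of 4 consistent votes
and 2–2 splits are excluded from both sets rather than defaulted, because
only the ≥3 case is defined. When no verdict table is available a built-in
single-predictor stand-in is used (longest forward-frame ATG→stop ORF;
coding iff ≥ 300 nt ≈ 100 aa, a conventional proxy); it is never consulted
when verdicts are supplied. "Expressed in a line" means mean FPKM across
that line's replicates ≥ 0.5, reusing the stated cutoff.

## Expression and differential expression

FPKM = 10⁶·C/(N·L/10³). Replicate correlations are computed on
log₂(FPKM+1) (standard QC practice; a raw-scale option exists); pairs with
a constant vector are reported as undefined and excluded from the mean.

The DE test pools replicates per line and evaluates the exact conditional
binomial: conditional on k = k₁+k₂, k₁ ~ Binomial(k, N₁/(N₁+N₂)); the
two-sided p sums all outcomes with probability ≤ that of the observation
(minimum-likelihood rule), with a relative tolerance of 1e-10 so exactly
symmetric outcomes are included despite floating-point error. Above a
pooled total of 200,000 a continuity-corrected normal approximation is
used. FDR is Benjamini–Hochberg. log₂FC comes from mean FPKM with a
pseudocount ε = 0.001, which avoids ±∞ at zero expression while preserving
order. Replicate overdispersion is deliberately not modelled (the test is
a reimplementation of the pooled-count binomial approach); the
|log₂FC| ≥ 1 filter is what controls false calls from replicate
variability, and the null-configuration simulation in the test suite
measures exactly this: at FDR ≤ 0.001 the realised false-positive
proportion over 2500 independent transcripts stays ≤ 0.005.

## Target prediction

Correlations (Pearson and Spearman, both ≥ 0.6) are computed on
log₂(FPKM+1) jointly across all samples; the correlation filter precedes
both the cis and the trans branch. Positional classification is span-based
(the lncRNA's own exon structure is ignored; the mRNA's introns are derived
from its exon chain): overlap subclasses are the product
{sense, antisense} × {partial-overlap-5′, partial-overlap-3′,
lnc-complete-in-mRNA, lnc-complete-in-mRNA-intron, mRNA-complete-in-lnc},
tested in the priority order intron-containment → lnc-in-span →
span-in-lnc → partial (sided by which strand-relative mRNA end the lncRNA
overhangs). Equal spans count as lnc-complete-in-mRNA. Upstream/downstream
windows (10 kb / 20 kb) are strand-relative to the mRNA, inclusive, and
measured span-edge to span-edge; subclass labels are configurable strings.

Duplex energies use a gapless antisense nearest-neighbour model: the best
(most negative) contiguous run of RNA stacking energies over all
antiparallel registers, found by a prefix-sum scan per diagonal.
Watson–Crick stacks use a published Turner-style 10-parameter table
(kcal/mol, 37 °C); stacks involving G:U wobbles are approximated by a flat
−0.5 (+0.3 for two adjacent wobbles), and initiation/terminal terms are
omitted. This is a documented approximation of a full interaction-energy
program: it ranks complementarity correctly and a perfect ≥ 16-bp duplex
clears the −30 kcal/mol trans threshold, but absolute values are not
thermodynamic predictions. A precomputed energy table
(`energies.tsv`) overrides the scorer and is the authoritative path when
exact energies are available.

## miRNA interactions

Local alignment is exact Smith–Waterman (match +1, mismatch −2, gap −2 —
blastn-flavoured scoring) via a C implementation; heuristics are
unnecessary at these input sizes. Precursor hits require coverage ratio
(aligned precursor span / precursor length) strictly > 0.9 — the precursor
length is the denominator — and identity ≥ 0.9 (the coverage rule alone
admits low-identity covers; published hit ratios ≥ 0.919 are consistent
with near-identity). Both are configurable. When several optimal
alignments exist the aligner's first is reported deterministically.

Target scoring follows the plant small-RNA complementarity convention:
gapless antisense scan, penalty mismatch 1.0 / G:U 0.5, doubled at miRNA
positions 2–13, retained at ≤ 4.0. Edges may instead be read from a table,
which is the faithful path when the edge set comes from a companion small-
RNA study. Optional hairpin validation of precursors is off by default.

## Expression-level dominance

"Close to one parent" is operationalised as statistical non-difference at
the pipeline's own DE thresholds — the only thresholds available — so a
trio of statuses (P vs A, P vs B, A vs B) determines the call.
Betweenness for additivity follows from the two progeny–parent signs being
opposite; transgressive calls require significance against both parents.
The roman-numeral numbering within each group is fixed by an A-direction
convention (I: A<B vs XII: A>B; II/XI = ELD-A with A<B / A>B; IV/IX =
ELD-B likewise; III/VII/X and V/VI/VIII sub-indexed by A<B / A=B / A>B).
Group-level results are independent of this numbering. All 27 status
triples map deterministically; the 14 internally inconsistent triples
(e.g. P above both parents while equal to one) are "ambiguous", never an
exception, and all-ns is "no-change".

## Synthetic data: what it emulates

The generator reproduces the study design — five lines (two parents, three
progenies) × three replicates — with planted ground truth for every stage.

*Geometry.* Loci occupy fixed 50-kb slots laid out round-robin across
chromosomes, so transcripts of different slots are always separated by
more than the 20-kb window: planted pairs are the only cis geometries and
positional recovery is exact by construction. Each planted cis class is
built to satisfy its definition directly (e.g. the intron-containment
subclass places a single-exon lncRNA wholly inside intron 1 of a 3-exon
mRNA); trans pairs sit on different chromosomes and carry an engineered
60-nt antisense window copied from the partner mRNA. mRNAs have 3 exons
(250–550 nt) with 700–900 nt introns; background lncRNAs are 1–2 exons,
450–900 nt.

*Counts.* Negative binomial (gamma–Poisson) around per-line log₂ means.
The dispersion default is 0.02, calibrated so the generator reproduces the
replicate-correlation level reported for the real libraries (mean r² ≈
0.95–0.98); it is a configurable parameter, not a fitted quantity. ELD
categories are encoded on log₂ means with ``eld_effect_log2`` (default
2.0) as the minimum planted |Δlog₂| between any two groups a category
requires to differ; additivity therefore separates the parents by twice
the effect with the progeny at the midpoint, so every required difference
equals the effect. "Equal" means exactly equal means. Planted (pair and
ELD) transcripts draw baselines from 2⁷–2⁸ expected counts, matching the
mean-counts ≥ 100 condition under which recovery is assessed; background
transcripts draw from a wide lognormal (SD 1.2 log₂) emulating the dynamic
range of real libraries without letting a single transcript dominate a
miniature library. Pair correlation comes from a shared per-line standard-
normal latent factor (SD 1.5 log₂, truncated at ±2 SD): replicates of a
line see the same factor, so the pair couples across lines — as
co-regulated transcripts do — without degrading replicate correlation.
Expected per-sample totals are rescaled into a target library-size range
(30–50 k fragments by default) so every library has the same expected
composition; without this, line-level effects would shift library totals
and FPKM would acquire a composition bias that distorts planted ratios.
The no-effect configuration skips the rescaling (its composition is
already balanced) and serves as the false-discovery control.

*miRNA features.* Each precursor is a designed inverted repeat (50-nt arm,
20-nt loop, mutated complementary arm) inserted verbatim into a host
lncRNA; the mature miRNA is the 5′-arm prefix (21 nt). Three mutations at
core positions of the 3′ arm keep the hairpin itself from scoring as a
target site, so self-targeting is decided solely by the separately planted
clean sites (perfect reverse-complement insertions). The first hosts also
carry a site for their own miRNA, realising the precursor-and-target
pattern.

*What passing tests do not show.* The generator plants clean, well-
separated effects on a miniature transcriptome; real libraries add
isoform-assignment uncertainty, multi-mapping, composition shifts from
thousands of co-varying genes, and positional coincidences that the slot
layout excludes. Recovery rates on synthetic data are therefore a
correctness check of the operations, not an estimate of sensitivity or
specificity on real data; dataset-scale headline counts from real
libraries are not reproducible at this scale and are not targets of the
test suite.

## Problem sizes and determinism

Default simulations use ~90 transcripts (45 mRNA, 44 lncRNA, 16 planted
pairs, 24 ELD transcripts, 3 embedded precursors); the false-discovery
control uses 2500 independent transcripts; oracle-equivalence suites use
500 random alignment pairs and 10⁴ random geometries. All randomness flows
from a single integer seed through per-stage substreams, and the full
dataset + report bundle is byte-identical across runs at a fixed seed.
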