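# Methods

`ligandatlas` re-implements, as a reusable pipeline, the comparative
immunopeptidome analysis used for tumor target discovery: from per-sample
eluted-peptide tables and a reference proteome to tumor-exclusive antigens
and peptides, HLA class II presentation hotspots, label-free quantification
(LFQ) modulation calls, HLA population coverage, and the tetramer-staining
immunogenicity decision rule. This note documents the models, the decision
rules and their parameters, the numerical choices, and what the synthetic
cohorts do and do not emulate.

## Inputs and mapping

Peptide identifications arrive as merged per-sample lists (TSV); mass
spectrometry, database search and FDR control are upstream and out of
scope. Peptides are mapped onto the proteome by exact substring search —
one sliding window per distinct peptide length over each protein, so the
cost is O(proteome length x number of distinct lengths). Coordinates are
1-based inclusive everywhere (`protein[start-1:end] == peptide`), matching
the conventional peptide-position notation (e.g. CTSK_7-15). A peptide is a
*multi-mapper* when it occurs in more than one distinct protein; repeated
occurrences within one protein do not count. Isoleucine and leucine are
treated as distinct residues because search engines emit a single sequence
assignment; ambiguous residue codes (B, J, O, U, X, Z) are rejected rather
than skipped, so peptides are never silently lost.

## Binder annotation and QC

Binder prediction scores are consumed, never computed. A peptide is a
binder for an allotype when percentile rank <= 2 **or** SYFPEITHI score
>= 60 (both inclusive). The union of the two routes is used because each
tool serves as an independent annotation route; pairs without a score row
are conservatively non-binders (tallied in a log message). Eluate purity is
the percentage of a sample's class I peptides that bind at least one
allotype of that sample's own typing. Length histograms report the modal
length (ties break to the smaller length); normalized yield is mean unique
peptides per technical replicate divided by tissue mass in mg.

## Comparative profiling and exclusivity

Positivity is tabulated per item (source protein or peptide) across three
groups. Tumors and autologous tumor-free dura count per sample; benign
organs count per tissue: an organ is positive as soon as any of its donors
presents the item, because the published exclusivity rule is phrased in
tissues, not donors. *Tumor-exclusive* means: zero dura samples, zero
CNS-related benign organs, at most one non-CNS benign organ, and at least
two positive tumors. Dura and brain-derived organs are CNS-related and must
be completely absent — the dura comparator exists precisely to subtract
dura-associated antigens.

Curation then audits the peptide evidence behind each exclusive antigen.
Class I evidence must map to a single protein and be a binder for the
presenting patient's own typing; class II evidence must map to a single
protein and fall in a 12-25 residue window (the observed class II length
range with margins around the 13-18-mer mode; configurable). Positivity is
recomputed from surviving evidence and antigens dropping below two tumors
are discarded. Known CTA/TAA cross-referencing keeps multi-mapping peptides
in the frequency columns but excludes them from the "represented by
tumor-exclusive peptides" verdict, and omits antigens seen only on benign
tissue. WHO-grade sharing partitions items by the exact set of grades of
their positive tumors.

## Class II presentation hotspots

Class II peptides occur as nested length variants around a shared core, so
sequence-level profiling under-reports class II tumor specificity. Peptides
are grouped into connected components under "intervals overlap by >= 8
residues"; a component's core is the intersection of member intervals, or,
for chains whose extremes do not meet, the deepest-coverage run (longest,
leftmost on ties) as a single representative locus.

A hotspot is a maximal run of protein positions where (i) peptides from at
least 5 distinct patients cover every position and (ii) no position
overlaps any benign- or dura-derived peptide of that protein, with run
length >= 8. The patient threshold is enforced per position — the strictest
reading; a region-level alternative (>= 5 distinct patients anywhere in the
run) is available via `hotspot_region_level`. Benign exclusion uses
positional overlap rather than exact sequence identity (conservative;
`hotspot_exact_sequence` switches to identity). The class II peptide set
fed into hotspot detection is selected with a minimum of one tumor, because
the published class II exclusive peptide set carries no two-tumor clause —
patient support is enforced by the hotspot rule itself. Patient
multiplicity counts distinct patients: two variants from one patient
contribute one.

## LFQ modulation

For each patient with paired tumor/dura data, per-peptide replicate AUCs
are compared. Fold change is the ratio of arithmetic means of raw AUCs (the
published definition); significance is a two-sided Welch unequal-variance
t-test on log2 AUCs — the two scales are deliberately distinct. Welch on
logs is standard LFQ practice and symmetric; ordinary t and Mann-Whitney
are available via `test_method`. Degenerate rows (zero variance on both
sides) get p = 1 for equal means, p = 0 otherwise. Peptides quantified on
one side only (missing not at random) are excluded, not imputed, and
counted. Benjamini-Hochberg adjustment (step-up, implemented per the
textbook formula and oracle-tested against statsmodels) is applied per
patient pair and per HLA class; a peptide is up-modulated when q <= 0.01
and FC >= 4, down-modulated when q <= 0.01 and FC <= 0.25. An antigen is
direction-exclusive for a patient when at least one of its single-mapping
peptides is called in that direction and none in the other.

A calibration caveat: with 3 replicates per side the Welch degrees of
freedom can drop toward 2, so a plant exactly at |log2FC| = 2 sits on the
FC >= 4 gate and is recalled only ~35-55% of the time (the measured fold
change is essentially symmetric around the gate). The calibration tests
therefore report both the strict-rule recall and the significance-only
recall; the false-call rate on null data is what the thresholds control,
and it is far below the q target.

## Population coverage and saturation

Within each HLA locus, genotypes follow Hardy-Weinberg: if covered alleles
sum to frequency f, an individual carries 2/1/0 covered allotypes with
probability f^2, 2f(1-f), (1-f)^2. Loci are independent (linkage
disequilibrium ignored — the standard population-coverage assumption);
convolving per-locus distributions gives P(carry >= k covered allotypes).
Allele frequencies need not sum to 1 per locus; the remainder is uncovered
mass. The expected number of matching peptides per individual sums, over
peptides, the probability of carrying at least one restricting allotype.

Saturation of unique antigens/peptides with growing cohort size is
summarised by the mean cumulative-unique curve over random sample orderings
fitted with y(x) = y_max (1 - exp(-rate x)) — a two-parameter identifiable
choice; the asymptote is bounded below by the observed unique count, and
the attained fraction is observed/y_max. Fits use least squares
(`scipy.optimize.curve_fit`) with bounded parameters.

## Tetramer positivity

A priming culture is positive when tetramer-positive cells exceed 1% of
CD8+ cells (strict >) **and** reach at least threefold the negative-control
percentage (non-strict >=; "threefold increase" is read as signal >= 3 x
control). A zero control satisfies the fold condition vacuously. Both
comparators are configurable.

## Synthetic cohorts

The generator emulates the *structure* of the study: 33 tumors with WHO
grades in 22/9/2 proportion, 9 autologous dura samples, and a 12-organ
benign database with two CNS organs and two multi-donor organs (so
organ-level counting is exercised). Class I peptide lengths follow
{8: 0.10, 9: 0.55, 10: 0.20, 11: 0.10, 12: 0.05} (a clear nine-residue
peak); class II lengths are 12-25 peaked at 13-18. Every peptide is an
exact substring of a random proteome (~354 proteins of 200-400 residues);
a verification pass remaps all peptides and redraws any that collide, so
single-mapper status is guaranteed except for designated multi-mapper
decoys copied into a partner protein.

Planted truth: 20 exclusive antigens in 2-8 tumors with always-binder,
single-mapping evidence (5 of them also on exactly one non-CNS organ — the
allowed boundary); 300 background antigens forced into >= 2 benign organs
(every donor presents the full repertoire, so no background peptide can be
exclusive by chance) with ~85% binder probability; decoys that must never
be called (exactly 2 non-CNS organs, exactly 1 tumor, all-multi-mapper
evidence, no binding motif, class II lengths below the window, 3 antigens
present only on benign tissue); 6 class II hotspots planted as nested
variants of 5-7 patients around a 10-14-residue core with flank choices
that make the recovered region exactly the core, plus 4-patient and
benign-overlap hotspot decoys. Hotspot host proteins are themselves class
II tumor-exclusive antigens by construction, and the serialized truth
records the full per-class expectation. LFQ tables draw replicate AUCs
log-normally around per-peptide means with sigma = sqrt(ln(1 + cv^2))
(linear-scale CV equals the requested cv, default 0.1) and tumor mean =
fc x dura mean for planted peptides.

What the generator does **not** emulate: real binding-motif structure (no
sequence-score dependence), identification FDR, shared peptides between
unrelated proteins beyond the designated decoys, abundance-dependent
detectability, or inter-patient allotype-driven peptidome overlap. Passing
tests therefore demonstrate the correctness of the decision rules and
their implementations under known truth, not re-discovery of the original
biological findings.

## Problem sizes and determinism

Default problem sizes were chosen so the full suite and the acceptance
script each run in minutes on a single CPU: 100 cohort seeds for
exclusivity recovery, 200 random instances for the hotspot oracle, 100-200
simulations of 1000 peptides for LFQ calibration, 1000 random p-vectors
for the BH oracle, 200 instances for the genotype-enumeration oracle, and
200-1000 orderings for accumulation curves. One seed fans out to
independent sub-streams (proteome, repertoires, presence, scores, typing)
via `numpy.random.SeedSequence.spawn`, and all outputs are written in
sorted order with fixed float formatting, so a rerun with the same seed
reproduces every output byte for byte.
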