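# Methods

This note records the models, conventions, defaults, and known
limitations behind `duplexmut`, in the order data flows through the
pipeline.

## Coordinates and orientation conventions

All coordinates are 0-based half-open internally; BED output is written
natively in that convention and VCF output converts to 1-based. Target
sequences are stored as the plus strand. `transcribed_strand` names the
*template* strand read by RNA polymerase; "coding strand" below always
means the opposite, nontranscribed strand. Substitutions are reported in
pyrimidine space (reference C or T; purine-reference calls are
reverse-complemented), and context abundance is counted double-strandedly:
each interior position contributes its pyrimidine-oriented trinucleotide
exactly once, which makes every spectrum invariant under reverse
complement of the input — the symmetry that pyrimidine-space reporting
presumes. Whether to count 3-mers single- or double-stranded is a genuine
design choice; double-stranded is this package's convention for that
reason.

## The mutation process (synthetic truth)

Each molecule-nucleotide mutates independently; the panel-averaged
per-nucleotide rate equals the group's `mutant_frequency` (units:
mutations per nucleotide per genome copy; background tissue ≈ 1e-7,
strong mutagens 1e-6–1e-5). A 96-class signature redistributes the rate
over trinucleotide contexts and alternate alleles: for class *k* with
eligible site set *S_k*, the per-site rate is
`MF · sig[k] · n_sites / |S_k|`, so contexts that are rare in the panel
receive proportionally higher per-site rates and the aggregate rate stays
MF. Sites are drawn by these weights; counts per class are Poisson.
Classes whose context is absent from the panel contribute nothing (their
mass is not redistributed).

Transcription-coupled repair is a single factor `f ≥ 1`: any potential
mutation whose pyrimidine (lesion-carrying) base lies on the template
strand of a transcribed target has its rate divided by `f`. On the coding
strand this produces, e.g., a T→A : A→T rate ratio of `f` — the
reciprocal-substitution asymmetry the strand-bias analysis estimates.
Nontranscribed targets are untouched.

Clonal expansions are injected deterministically: `floor(cell_fraction ×
n_genomes)` molecules, lowest molecule index first (reproducibility;
ties cannot arise). A clone overrides any random mutation drawn at the
same (molecule, position).

The named signatures (`background`, `bap_like`, `enu_like`,
`urethane_like`) are synthetic, parametric constructions shaped like
classic exposure spectra (ageing/deamination, bulky-adduct G·C→T·A,
alkylator T>C/T>A, and NTG-context T>A respectively). They are inputs to
the generator, not a published catalogue, and carry no fitted values.

## The sequencing process (read families)

One family per double-stranded source fragment: a target drawn with
probability ∝ length × copy number, a genome copy drawn uniformly, a
uniform shear window (fragment length 120 bp by default, capped by the
target), and a barcode pair drawn from a generated whitelist. Whitelist
tags are 8-mers kept at pairwise Hamming distance ≥ 3 (16 tags by
default), so a single corruption is always unambiguously correctable
under the correction rule below; corruption (rate 0.01/read) introduces
1 mismatch 80% of the time, 2 mismatches otherwise, to exercise both the
corrected and rejected paths.

Per-strand read counts are zero-truncated Poisson with mean 3 — family
sizes are a protocol property no one publishes precisely, so this is a
declared convention, configurable. A strand dropout probability (0.05)
produces single-strand-only families, the case that must never yield a
duplex consensus. Sequencing errors are independent per read per base
(default 1e-3). A cigar-artifact rate (0.01/read) gives a read a
discordant cigar to exercise cigar-plurality filtering.

Single-strand damage is modelled as guanine oxidation: with probability
`damage_rate` per base, a G on the damaged strand becomes T (read as
C→A in reference orientation when the bottom strand is hit). All reads of
that strand inherit the artifact; the complementary strand never shows
it. Because top-strand artifacts need a reference G and bottom-strand
artifacts a reference C, the two strands cannot produce the same
(position, alt) — duplex consensus removes this artifact class exactly,
not merely in expectation, which is also how the artifact-suppression
contract is tested. A scalar rate with fixed chemistry is deliberately
the whole damage model; capture bias, GC bias, and enzymatic
damage-excision chemistry are out of scope.

## Consensus calling

Pipeline order: barcode correction → family grouping → quality trimming →
cigar filtering → per-strand consensus → duplex consensus → end trimming.

* **Barcode correction** accepts the whitelist tag within 1 mismatch of
  the observation provided the observation's distance to the next most
  likely tag is ≥ 2; otherwise the read is dropped (and counted).
* **Grouping** keys on (corrected barcode pair, canonicalised; target;
  shear points). Strand labels follow barcode orientation relative to the
  canonical pair — they are arbitrary but consistent within a family,
  which is all duplex calling requires.
* **Quality trimming** is the classic running-sum 3' trimmer: cut at the
  position minimising the running sum of (quality − threshold) from the
  3' end (default Q20); surviving bases below the masking quality
  (default Q20) become N. Trimmed tails are N-padded so reads stay
  column-aligned within their family.
* **Cigar filtering** keeps reads matching the family's plurality cigar;
  a tie rejects the family outright (no majority alignment = no way to
  identify the indel artifact).
* **Per-strand consensus** is per-position plurality over non-N
  observations, requiring the plurality base to hold ≥
  `min_family_agreement` (default 0.7) of them; ties and low agreement
  give N. No quality-weighted likelihood model — plurality with N on
  ambiguity is the simplest rule satisfying the duplex contract, and
  quality-aware calling is a non-goal.
* **Duplex consensus** exists only when both strands have ≥
  `min_reads_per_strand` reads (default 1); a base is emitted only where
  the two strand consensuses agree and neither is N. `end_trim` (default
  5 in the pipeline config) shrinks the mapped interval on both sides.
  The three consensus thresholds are declared defaults, configurable, not
  reproductions of any published values.

The simulator emits one full-fragment read per strand copy (fragments ≤
read length), so the end-to-end path has no overlapping mate pairs;
`clip_overlap` implements the balanced midpoint-split hard clip (left
mate keeps the odd base; a fully nested mate is dropped) for the general
paired case and is verified against a per-position coverage oracle.

## Variant calling and metrics

Pileup excludes N; depth is the per-position duplex molecule count. Any
alternate allele with count ≥ 1 is a call (a duplex base is already
double-strand-confirmed); multi-allelic positions yield one call per
allele. Only positions inside the reportable territory (target minus
10-bp-padded repeat mask, when a mask is supplied) are reported.
Germline status is a VAF threshold (default 0.3) — no published
operational rule exists, so this is a declared decision; germline calls
are excluded from MF, spectra and clonality.

MF = Σ alternate molecule counts over non-germline calls, divided by
duplex base pairs, with exact Poisson (Garwood) CIs:
`[χ²(α/2, 2k)/2, χ²(1−α/2, 2k+2)/2] / duplex_bp`. A call classified
clonal contributes 1 regardless of its molecule count when
`clone_collapse=True` (default) — the expansion is one mutagenic event;
the uncollapsed count is always reported alongside. Independent
multiplets (recurrent but not outlying) contribute their full molecule
count.

Clonality: `ClonalityModel` fits a normal to log₁₀ VAF by moments (the
MLE for a normal) over ≥ 5 non-germline calls; a call is clonal iff its
log-VAF exceeds mean + `cutoff_sd`·sd (default 3 — the outlier criterion
is unspecified in the literature this follows, so 3 sd is a declared
default) *and* its molecule count is ≥ 2. Fewer than 5 calls: warn, fit
nothing, label singlet/multiplet-independent only. Sd of exactly 0 (all
VAFs equal) flags nothing, since the outlier test is strict.

Strand bias orients all 12 substitution types to the coding strand,
normalises each count by (reference-base abundance × mean duplex depth),
and reports Clopper–Pearson CIs per side plus the reciprocal fold with a
ratio-of-bounds CI; a zero reciprocal count gives a NaN point estimate
with a finite lower bound rather than infinity. Mean per-base depth over
the target is the default depth factor. Note a structural limitation:
mononucleotide abundance correction cannot remove dinucleotide-level
composition confounding, so a single target under a context-skewed
signature shows reciprocal folds of ~1.3 even without any true bias;
transcribed-versus-nontranscribed contrasts remain an order of magnitude
larger.

Consequence annotation applies the standard genetic code to the codon
containing the call in the target's declared frame: stop gain → nonsense,
amino-acid change → missense (stop loss included), else synonymous;
noncoding targets and incomplete codons are labelled as such.

The χ² spectrum homogeneity test pools classes with expected counts
below 5 into an "other" class (repeatedly if needed) before the standard
2×k test without continuity correction.

## Clustering

Rows (samples or signatures) are compared by cosine distance; linkage is
WPGMA ("weighted") by default, with Ward on the precomputed cosine
distances available behind a flag because the two appear interchangeably
in this literature — neither is asserted as canonical, and the choice is
logged in the run manifest. Merges are deterministic; leaf order is a
deterministic smaller-subtree-first traversal (display only — an optimal
leaf-ordering algorithm would change no merge). Newick export carries
branch lengths derived from merge heights. Signature matching is plain
cosine ranking against a 96-row catalogue; no decomposition or NMF
refitting.

## Problem sizes used in tests and the acceptance script

Chosen so each check has the statistical power it needs and no more: the
artifact-suppression contrast uses 10⁵ families (~10⁷ single-strand
consensus bases, ~10⁶ duplex bases of fully covered territory at damage
rate 0.01); estimator recovery uses 10⁷ duplex bp per replicate (Poisson
means 1/10/100 at MF 1e-7/1e-6/1e-5), 25 seeds, judged by the median
estimate; clone detection uses 50 cohorts of 300 background calls at
depth ~10⁴; strand-bias recovery uses ~10⁶ molecule-sites at MF 1e-4
under factor 10; clustering uses 10 samples of ~400 mutations each from
two signatures with cosine similarity 0.17. The end-to-end pipeline
tests run a deliberately small cohort (8 samples × 500 families) to
exercise wiring, determinism, and file formats rather than statistics.

## What passing tests do and do not show

The generator reproduces the statistical structure the analyses rely on —
ultrarare Poisson mutation counts, context-shaped spectra, strand
asymmetry, discordant single-strand artifacts, clonal multiplets — but
not capture efficiency, GC or fragment-length bias, mapping error,
contamination, or indel processes (indels exist only as cigar artifacts
to be filtered; indel consensus is out of scope). Recovery results
therefore validate the estimators and the pipeline's bookkeeping under
the stated model, not performance on any particular instrument's data.
Real-data concerns that are explicitly out of scope: alignment itself
(synthetic reads carry true coordinates), interspecies decontamination,
and probe design beyond the repeat-mask subtraction rule.
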