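# Methods

This note documents the statistical model, the rules each stage
applies, the parameters that matter (with defaults and rationale), what
the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Study design and sampling model

Two small-RNA libraries (metastatic and non-metastatic xenograft lines)
are barcoded with 7-nt 5' indices, pooled, and sequenced together. Each
read is `index + insert + 3' adapter`. Per library, feature counts are
treated as one multinomial draw of fixed depth over the feature
abundance simplex; this is exactly the sampling model under which the
downstream Fisher exact test (count versus remainder, per library) is
the natural comparison. An important consequence is compositionality:
counts are proportions of a fixed total, so a genuine increase of some
features necessarily deflates the measured proportion of every other
feature. The 2-fold-change requirement of the significance rule is what
keeps modest compositional shifts from becoming calls.

## Preprocessing

* **Demultiplexing** requires an exact index match. The two 7-nt
  indices differ at ≥4 positions, so a tolerant match would add
  ambiguity without recovering meaningful reads. Reads containing `N`
  are dropped up front so tag collapsing is unambiguous.
* **Adapter trimming** cuts before the leftmost occurrence of the
  adapter's first 7 bases, allowing one mismatch — standard small-RNA
  practice. Reads without any seed occurrence are discarded and
  counted.
* **Tag filtering** keeps collapsed tags of 16–27 nt observed ≥2 times
  in *at least one* library. Surviving tags keep their exact counts
  from both libraries, including 0 and 1 — single-library features
  (later printed `N/A`) depend on this.

## Alignment and annotation

Tags are scanned ungapped against every sense-strand offset of every
stem-loop with a Hamming budget of 3. Ungapped scanning keeps the
operation exactly testable against a brute-force oracle. Multi-mapping
policy: among best-mismatch hits, hits on hairpins whose overlapped
mature annotations share one name (paralogs) collapse to the first by
(hairpin, start) and are logged; hits implying different mature names
make the tag ambiguous, which excludes it from counting — conservative,
and logged.

Classification applies, in order: **known mature** (both ends within
±2 nt of an annotated mature — the isomiR tolerance), **putative
miRNA\*** (hairpin has exactly one annotated mature and the read's
midpoint falls on the opposite side of the terminal loop), **loop**
(read contained in the loop interval), **loop without mature** (same,
hairpin unannotated), else **arm variant**. The loop interval is the
gap between the two matures; with one mature, between the mature and
its mirror image about the hairpin midpoint; with none, the central
third. The putative-star rule is positional (opposite arm) rather than
a 2-nt-overhang duplex computation: it needs no structure prediction
and matches how star fragments present in practice. Arm variants are
kept and count toward library totals, so the category partition
conserves every resolved read and normalized values sum exactly to the
scale per library.

**IsomiR clustering**: tags of one feature are grouped by start
position; the representative is the start with the largest combined
(two-library) count, ties broken by smaller |shift| then upstream. The
zero-shift (annotated-start) group is additionally reported when it is
not itself the representative, mirroring the double listing of features
whose dominant form is a one-base-shift variant. Representative
selection uses the combined count so the *same* form is compared
between libraries.

**Normalization** is counts per million hairpin-mapped tags, the
denominator being the per-library sum over all annotated groups (every
category). Using the conserved mapped total keeps normalized values an
exact partition of the scale.

## Differential expression

* Fold change is a signed ratio of normalized counts: positive =
  higher in the metastatic library, negative = higher in the
  non-metastatic library, `+1.00` for equality, `N/A` when exactly one
  side is zero (the direction then follows the nonzero side).
* The two-sided Fisher exact p sums hypergeometric probabilities of all
  tables with the observed margins whose probability is ≤ that of the
  observed table, with a 1e-12 relative slack on the comparison to
  absorb float error in equal-by-symmetry tables. It is computed in log
  space (scipy's hypergeometric log-pmf plus a log-sum-exp), so
  million-read totals are handled with the same code path as toy
  tables. An exact-rational enumeration oracle and scipy's
  `fisher_exact` serve as independent cross-checks in the tests, never
  as the implementation.
* Bonferroni: `p_adj = min(1, m·p)` with `m` = the number of tested
  rows (representatives plus annotated-start extras). The significance
  threshold (0.001) is applied to the *corrected* p — the stricter of
  the two readings of "corrected … p < 0.001" — together with the
  ≥2-fold requirement on normalized counts. Fold changes come from
  normalized counts, the exact test from raw counts: magnitude and
  evidence are deliberately separated.

## Novel-hairpin screening

Unmapped tags are filtered against known transcripts (ungapped, ≤1
mismatch), located exactly in the genome on either strand, and each
locus expanded by ±70 nt (minus-strand hits are reverse-complemented so
the tag always reads sense).

Hairpin candidacy is judged by explicit rules on a Nussinov
maximum-base-pairing fold ({AU, GC, GU} pairs, minimum loop 3,
deterministic traceback preferring pairing over bifurcation with
leftmost splits). Because the maximum-pairing structure of a true
hairpin embedded in ~100 nt of random flank never keeps a single
terminal loop, the hairpin is first *localized*: the window segment
most Watson-Crick-complementary to the tag in antiparallel register
(within a 48-nt loop distance, never overlapping the tag) marks the
putative opposite arm, and the padded span enclosing tag and partner is
folded; when the whole window is ≤150 nt it is judged as well, which
covers tags sitting mid-hairpin. Localization uses complementarity, not
fold outcomes, so no candidate is selected by how close it comes to
passing.

Pass rules (all config-exposed): exactly one terminal loop in the
traceback; ≥18 base pairs; ≥60% of tag bases paired across the loop;
≥60% of the tag WC-complementary to its opposite arm in register; tag
overlapping the terminal loop by ≤4 nt. The register rule exists
because random ~60-nt spans fold bulgy single stems with ≥18 pairs
surprisingly often; a contiguous-register match is what a real arm
provides and dinucleotide-shuffled sequence does not (shuffle null pass
rate ≤1% in the tests, versus ~10–15% without the rule). This stage is
a deliberately explicit, desk-scale surrogate for tool-based novel-miRNA
discovery; thermodynamic (minimum-free-energy) folding and learned
classifiers are out of scope.

## Microarray z-ratios and integration

Per array, unflagged log-scale intensities are standardized to
z-scores (sample sd); the per-gene z-ratio is the z difference divided
by the sample sd of all unflagged differences, with calls at ±1.96. A
probe flagged on either array is excluded from every mean/sd and
carries no call. Sample (n−1) standard deviations are used throughout
for bit-stable tests.

Targets of significant miRNAs are predicted by canonical seed matching
in 3'UTRs — reverse complements of miRNA positions 2–8 — classified as
8mer, 7mer-m8, 7mer-A1 or 6mer; a gene is a predicted target with ≥1
site of 7mer class or better. This replaces database-driven target
prediction with a fully computable stand-in. The final crossing keeps
genes regulated *exclusively* by one miRNA direction and moving the
opposite way at the mRNA level (candidate derepression, and its
mirror).

## The synthetic study generator

The generator's defaults are the study conditions under which the
pipeline's recovery guarantees are stated: 60 reference hairpins
(22-nt arms, 18-nt loops, 5% mutation on the 3' arm, 30% single-mature),
6 perfect-stem novel hairpins left out of the reference, 100 000 reads
per library, substitution error 1e-3, isomiR offset law
{0: 0.6, ±1: 0.15, ±2: 0.05} applied independently to both ends,
log-normal (σ = 1.5) baseline abundances, 5% opposite-arm (star) read
fraction on single-mature hairpins, 1% loop reads, 2% transcript
degradation reads, ten planted 10-fold changes, a 1000-gene two-array
table with 8mer sites and opposite-direction expression effects planted
for the DE miRNAs, and 5% flagged probes per array.

Choices that make the planted-truth benchmark well-posed (rather than a
test of sampling luck):

* Folds are planted on the *least* abundant features inside the
  [1e-3, 1e-2] abundance band (expected baseline ≈100 counts): high
  enough to be well measured, low enough that the compositional shift
  imposed on null features stays at a few percent — far below the
  2-fold call line.
* Planted miRNAs have mutually non-overlapping seed patterns; otherwise
  one miRNA's planted 8mer site necessarily contains another's 7mer and
  no UTR can be exclusively planted.
* Terminal loops are drawn from a two-letter non-self-pairing alphabet
  (A/C), mimicking the unstructured loop of real pre-miRNAs; a fully
  random 18-nt loop can fold an internal hairpin under max-pairing,
  which would break the single-terminal-loop property of even a perfect
  planted stem.
* Hairpins are rejection-sampled to contain no subsequence that the
  adapter trimmer could mistake for the 3' adapter — including seed
  matches completed across the insert/adapter boundary. Reads carrying
  such look-alikes are destroyed by trimming under any pipeline using
  that adapter, so the corresponding features would be unmeasurable by
  construction.
* Planted expression effects default to 6 null-sd units of the z
  difference. At 3–4 units the per-gene miss probability is 5–15% once
  the planted genes themselves inflate the z-difference sd; at 6 units
  it is ~1e-3, so the recovery bound tests the integration logic, not
  the noise.

What the generator does **not** emulate: quality scores, indels,
ligation bias, partial 3' adapters, expression-dependent sequencing
error, cross-mapping between paralogous miRNA families, and the true
(unknown) per-feature abundance law of tissue small-RNA libraries.
Passing recovery tests therefore demonstrates the pipeline's logic is
correct under its own sampling model, not that real libraries are this
clean.

## Numerical choices and problem sizes

* Fisher comparisons use a 1e-12 relative slack; p-values are summed
  via log-sum-exp.
* The Nussinov fill is O(n³), jit-compiled (numba) with a pure-Python
  fallback; sequences are capped at 300 nt.
* Deterministic tie-breaks everywhere: isomiR representatives (smaller
  |shift|, then upstream), multi-map resolution (first by hairpin id
  then start), traceback (pair before bifurcation, leftmost split),
  partner localization (nearest to the tag). Result tables are sorted
  by (feature, start), so identical inputs give byte-identical files.
* Every stochastic component takes an explicit seed and the pipeline
  derives stage seeds from one configured seed; the same seed
  reproduces byte-identical result directories.
* Calibration and recovery checks run at depth 1e5 per library with
  300–1000 features/genes and 50 replicates for null calibration —
  sizes chosen so the binomial uncertainty of each estimated rate is
  small against the bound it is compared to.
* Null-calibration replicates simulate counts directly from the
  multinomial law (the same law the read-level simulator uses) rather
  than re-running read generation and alignment per replicate;
  read-level behaviour is exercised by the end-to-end pipeline runs.

## Known limitations

* Novoalign-style gapped/quality-aware alignment is intentionally not
  reproduced; equivalence is defined against the Hamming-distance
  specification.
* The hairpin-candidacy rules are a surrogate, not a re-implementation
  of published novel-miRNA tools; absolute candidate counts from real
  data are tool- and genome-dependent and are not comparable.
* Seed matching ignores site context (AU flanking, position in UTR) and
  non-canonical sites; database-driven target prediction and pathway
  enrichment are out of scope.
* The multiplicity denominator for Bonferroni is the number of tested
  rows in the current analysis; comparisons across analyses with
  different row counts are not calibrated against each other.
* With both-end isomiR tolerance, 3' non-templated additions are not a
  separate class: they fall under the end-shift tolerance or arm
  variants.
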