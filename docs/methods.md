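# Methods

## The measurement model

The assay measures misincorporation by a polymerase of interest filling
a single-stranded region of a known 200–300 bp template (the ROI).
Each filled molecule is tagged with a 19-bp UMI, linearly amplified for
seven to ten rounds — each linear copy acquiring a 4-bp ULCI — and
sequenced in 150-bp paired-end mode with the sample barcode split
across the two reads (read 1: `[bc][UMI][ROI 5′…]`, read 2:
`[bc][ULCI][revcomp ROI 3′…]`).

The statistical core is an error taxonomy by replication level:

* a **true polymerase error** exists on the daughter strand before
  linear amplification, so it appears in every linear copy;
* a **damage/amplification artifact** arises on one linear copy and is
  independent across copies;
* a **sequencing error** arises on one read.

The two-level consensus exploits this: within a (UMI, ULCI) read group
a base call must reach 70% of informative (non-N) reads, within a UMI a
variant must reach 70% of informative copies, and molecules need at
least three distinct ULCIs. With per-copy artifact rate a ≈ 10⁻³ the
probability that three independent copies coincide on the same
alternative base is O(a³), far below polymerase error rates, while true
errors survive the consensus with probability ≈ 1.

The per-molecule, per-position structure also fixes the denominator:
opportunities are counted as covered (informative in ≥ 3 copies)
internal template positions summed over retained molecules and grouped
by trinucleotide, so partial coverage never biases frequencies.

### Alignment

Because the amplicon structure is fixed, alignment is gapless and
anchored: read 1 to the template 5′ end, reverse-complemented read 2 to
the 3′ end. Bases under Phred 20 are masked to N; where the mates
overlap and disagree the position is masked to N rather than arbitrated
by quality — the consensus layer absorbs Ns, and masking is the
conservative choice. Reads whose substitution fraction exceeds 10% of
informative positions (the symptom of an indel shifting the frame, or a
foreign sequence) or whose N fraction exceeds 50% of the covered span
are excluded; the assay analyses substitutions only, so no indel
calling is attempted. UMI/ULCI matching is exact string equality:
at 19 bp, UMI collisions are negligible at the scales analysed, and
error-tolerant clustering risks merging distinct molecules.

### Signatures and backgrounds

Error frequency is count/opportunity per (template trinucleotide, alt)
channel — 192 channels; the first and last ROI positions have no
trinucleotide and are excluded everywhere. Background subtraction
operates channel-wise in frequency space and clamps at zero: the
parental background is obtained by running the identical pipeline on
parental (unfilled template) samples, the gapping background is
consumed as a user-supplied 192-channel table (zero by default), and
counts are invalidated on the subtracted signature since they no longer
correspond to integers. Strand collapse averages each pyrimidine
channel with its reverse-complement purine channel, yielding the
COSMIC-ordered 96-channel signature; the overall error frequency is the
unweighted mean over the 192 channels, which normalizes for ROI
composition.

Cytosine classes partition internal cytosines as CpG (C followed by G),
dcm (the second C of CCAGG/CCTGG — the cytosine methylated by the
E. coli Dcm methyltransferase, methylated in every ROI since templates
are prepared in E. coli), and CpH (everything else). A C that is both
CpG and inside CCWGG is classed CpG: M.SssI methylates all CpGs, and
treating the classes as a partition keeps the class rates comparable.
Class rates computed from a 192-channel signature weight each class
position by its channel's opportunity share; note that a trinucleotide
occurring in two classes within one ROI (possible for CCA/CCT) mixes
classes at the channel level — the per-position tabulation is exact,
the channel-level class rate is an aggregate.

### Subset selection by NNLS

For each K, every size-K subset of the catalog is fitted by
Lawson–Hanson NNLS (scipy) and the lowest squared error kept; K grows
while bestError(K) ≤ 0.8 · bestError(K−1). The stopping sentence this
implements is ambiguous in the field ("the smallest K that leads to at
least a 20% decrease"); the growth reading matches the anti-overfitting
intent and is the default, while the alternative — stop at the first K
whose error drops ≥ 20% versus K−1 — is available as
`stop_at_first_drop=True`. Ties between equal-error subsets are broken
by the lexicographically smallest name set, making selection
independent of catalog column order. Exposures are reported raw; an
exhaustive search over S signatures is combinatorial, so K is bounded
by `k_max` (default 6) and catalogs beyond 30 columns trigger a
warning.

### Genome analyses

Replication domains are fixed-width 20-kb intervals annotated with fork
direction and timing; the leading-strand template is the plus strand in
left-replicating domains and the minus strand in right-replicating
ones. A mutation is assigned the class of the strand carrying its
mutated pyrimidine. Strand asymmetry is log₂ of
opportunity-normalized leading/lagging frequencies per sample; samples
with zero mutations on both strands are dropped, and a 0.5 pseudocount
on both counts keeps single-strand-zero samples finite (the analysis
keeps samples with ≥ 1 mutation on either strand, so ±∞ ratios must be
avoided somehow; the pseudocount is configurable). For CpG>TpG the two
strand classes have identical opportunity (every CpG carries one C per
strand), so the normalization cancels.

Methylation binning takes the CpG universe from the bisulfite map
(coverage ≥ 5 reads), counts a site as mutated on C>T at the site or
G>A at site+1, and reports mutated sites per (site × sample). The
MMR-region analysis restricts to methylated CpGs (β ≥ 0.9) so regional
5mC differences cannot confound the inside/outside frequency ratio.
The de novo filter implements its four clauses literally; "no other
sample shows below-threshold evidence" is read strictly as zero
alt-supporting reads elsewhere (`--max-other-alt` exposes alternatives,
since the original threshold is not quantified).

The sign test is the exact two-sided binomial(n, ½) tail with zeros
dropped; Mann–Whitney U is exact below n = 20 without ties and
normal-approximated with tie correction otherwise; Welch's t uses
unequal variances. Intervals are half-open 0-based on disk (BED),
mutations 1-based; genome context lookups accept a FASTA (pyfaidx) or
an in-memory dict so tests never download a genome.

### Rate arithmetic

Constants live in a config block: E = 4.5 × 10⁻⁵ errors per replication
per 5mCpG (wild-type), deaminationRate = 5.8 × 10⁻¹³ s⁻¹ per 5mCpG,
errorPerRepl before/after proofreading 40.23 × 10⁻⁵ / 4.52 × 10⁻⁵,
nCpGs = 53.5 × 10⁶, replicationsInADay = 0.2, and the Gregorian year
(365.2425 d). Internal values are unrounded; reports round to the
conventional precision (D to one decimal; E2, E3 to integers). Note the
main-text wild-type CpG>TpG rate is sometimes quoted as 4.52 × 10⁻⁶;
the constants above use 4.52 × 10⁻⁵, which is the value consistent with
the derived per-day counts.

## The simulator

`simulate_library` draws, per molecule: true errors from a per-position
rate matrix (a 64 × 3 channel-rate table optionally scaled by cytosine
class and methylation state), a copy count uniform on {7..10}, distinct
ULCIs per copy, independent per-copy artifacts (transition-biased, 90%
by default — deamination-like damage is C→T/G→A-heavy), and one read
pair per copy with independent per-base sequencing errors on the ROI
portions. Spike-in mutant templates carry six substitutions (three near
each ROI end) and are mixed at fixed dilutions. Identical seeds give
byte-identical FASTQ and truth tables.

Defaults are the study conditions: 7–10 linear copies, 19/4-bp
UMI/ULCI, 6-bp split sample barcode, 150-bp reads on a 250-bp ROI,
artifact and sequencing error rates 10⁻³. One read pair per linear copy
is the desk-scale default — copy-level, not read-level, redundancy is
what the consensus needs, and a single read legitimately defines a copy
(`min_reads_per_copy = 1`).

What the simulator does *not* model, and therefore what passing tests
cannot show: correlated damage shared across copies of one molecule
(real template damage is subtracted via the parental background, which
the simulator only exercises through user-supplied tables), quality
score variation (flat Phred 40), barcode-read sequencing errors (ghost
ULCIs), PCR duplicate families beyond linear copies, and indels. The
synthetic genome (10 × 2 Mb chromosomes, alternating 20-kb domains,
sawtooth timing, high/low β mixture from Beta(20,2)/Beta(2,20)) has
uniform base composition rather than realistic isochores; effects are
planted as site-weight multipliers, so recovered ratios test estimator
calibration, not biological realism.

## Evaluating the copy-number requirement

`copy_support_curve` reports the called error frequency as a function
of the number of linear copies required to *support* a variant (k
copies agreeing on the same alternative base, in molecules with ≥ k
copies). This is the quantity that isolates artifact coincidence decay:
expected artifact contributions fall like E[C(n,k)] · Σ_b p_b^k, giving
~10³× inflation at k = 1, a several-fold overestimate at k = 2, and
convergence to the true rate at k ≥ 3 under the default conditions.
The production caller instead applies the stricter published rule
(≥ 3 distinct ULCIs and ≥ 70% of informative copies); the curve is a
diagnostic, not the caller.

## Numerical choices

Consensus thresholds compare `count ≥ agreement · n_informative − 10⁻⁹`
to keep 0.7 · 10-read groups exact in floating point. Agreement
fractions are constrained to (0.5, 1], which makes within-level
conflicts (two alts both passing) impossible. Base-count ties pick the
alphabetically first base via argmax, but a tie can never reach a
> 0.5 threshold, so tie-breaking never decides a call. NNLS uses
scipy's Lawson–Hanson implementation; subset errors are compared with a
10⁻¹² strict-improvement margin so ties resolve lexicographically.
Signature TSVs round-trip bit-exactly (`float_precision="round_trip"`
on read). Degenerate inputs fail loudly: empty read groups, mixed-UMI
molecules, zero vectors in cosine similarity, all-zero signatures in
PDF scaling, all-zero differences in the sign test, degenerate
variances in t tests.

## Problem sizes

The shipped tests and the acceptance script run everything at desk
scale, chosen so each stochastic check has comfortable statistical
margin: 2 × 10⁵ molecules for the spike-in dilution validation
(lowest dilution 10⁻⁵ ⇒ ~2 expected mutant molecules; the Pearson
correlation is dominated by the well-measured upper dilutions),
1.5 × 10⁴ molecules for the copy-threshold property (~37 expected true
errors, Poisson CI ±33%), 10⁵ molecules for end-to-end signature
recovery (cosine ≥ 0.95 needs a few thousand errors spread over 192
channels), and 30 × 1 500 mutations on a 20-Mb synthetic genome for the
strand/methylation recovery checks.

## Known limitations

* The channel-level class rate mixes classes for trinucleotides shared
  between dcm and CpH contexts (see above).
* The gapping background estimator is out of scope; the subtraction
  contract is tested with supplied tables.
* Exhaustive subset NNLS does not scale past small catalogs and K — by
  design, matching the decomposition it mirrors.
* `filter_de_novo` requires externally produced calls and allele
  counts; it does not call variants.
* No indel support anywhere in the consensus path.
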