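# Methods

This note documents the models implemented in famseq, the defaults and why
they were chosen, the numerical conventions, and what the synthetic study
does and does not establish about real data.

## Coordinates

All intervals are 1-based inclusive in memory; BED files are written and
read 0-based half-open. The conversion lives in `famseq.coords` and nowhere
else. A span's length is `end − start + 1`.

## Parametric linkage by exact enumeration

The disease model is a rare autosomal-dominant locus: disease allele
frequency `q` (default 10⁻⁷) with Hardy–Weinberg founder priors and a
penetrance vector `(f0, f1, f2)` (default `(0, 1, 1)`: no phenocopies, full
penetrance). A single biallelic marker with population allele frequency `p`
is modelled jointly with the disease locus in linkage equilibrium. Each
individual's latent state is an ordered pair of two-locus haplotypes (16
states); transmissions follow Mendelian segregation with recombination
fraction θ, evaluated at θ = 0 (linked) and θ = ½ (unlinked). The
likelihood sums over all founder genotypes, phases and transmission
vectors; it is computed by factor elimination over the pedigree's Bayesian
network (children eliminated before parents), which is exact and equivalent
to the unfactorized sum — the test suite checks this equivalence against a
depth-first enumeration oracle on all its pedigrees of ≤ 8 members.
Enumeration is refused above 22 meioses; a multipoint Lander–Green HMM is
deliberately out of scope, because the single-marker exact LOD plus plateau
extraction reproduces the same decision outputs at desk scale.

Restriction before analysis: unaffected non-founders are removed (their
phenotypes would otherwise confound an incompletely ascertained dominant
trait), keeping affected individuals, all their ancestors, and nothing
else; retained unaffected connectors are re-marked "unknown" and treated as
obligate carriers of unknown genotype.

**Informative meioses and the LOD ceiling.** The ceiling is `m·log₁₀2`
where `m` counts transmissions between carriers (affected individuals or
obligate-carrier connectors), minus one per transmitting founder carrier —
a founder's phase is unknown, so one transmission is spent establishing it.
On the bundled four-generation discovery pedigree the restricted analysis
has 10 carrier-to-carrier transmissions with one founder apex, so m = 9 and
the ceiling is 9·log₁₀2 = 2.709…, displayed to one decimal as 2.7. The
exact enumeration at a fully informative co-segregating marker attains this
value (the ½ phase factor and the 2¹⁰ transmission ratio combine to exactly
2⁹), which is the package's internal cross-check between the counting rule
and the likelihood.

**Exclusion sentinel.** A LOD of −∞ (zero linked likelihood) is encoded as
the singleton `EXCLUDED`, never as a float. Note that with `q > 0` a
recombinant seen from a *founder* carrier yields a finite, strongly
negative LOD rather than exclusion, because the vanishingly improbable
homozygous-founder configuration remains consistent; exact exclusion occurs
when the carrier's phase is forced by its own genotyped parents. This is a
property of exact arithmetic, not an approximation.

**Marker QC.** Mendelian-impossible trio calls are blanked (the child call
is set missing) before filtering; markers are then removed if they are
missing in any analyzed individual (< 100% sample call rate) or have a
pedigree minor-allele frequency of 0. "Analyzed" defaults to pedigree
members of known phenotype, since unexamined connectors contribute no DNA.

**Interval extraction.** The minimum linked interval spans the contiguous
run of markers attaining the maximum LOD (ties at 10⁻⁹ tolerance); the
maximum linked interval spans the positions strictly between the nearest
flanking markers whose LOD is below the maximum, so its length is
`flank_right − flank_left − 1`. All maximal plateaus are returned, ranked
by maximum-interval length; a report-level filter (default 1 cM in the
pipeline) drops sub-centimorgan plateaus as likely genotyping errors or
ancestral haplotypes. Plateaus at a track edge have an open flank and no
maximum length.

## Capture design accounting

Targets are padded symmetrically and merged (touching intervals coalesce);
probes of fixed length (default 60 nt) are tiled from each region's start
at a fixed step while they fit, giving `floor((L − probe)/step) + 1` probes
on an unmasked region of length L. Probes overlapping any masked base are
dropped; repeat masks are inputs, not computed. Layout schemes map probes
to physical array features: `identity`, `quad` (probe and reverse
complement, each in duplicate: 4n), and `custom-subsample`
(n + Σ floor(n/j) over the subsample steps, counting from the j-th probe —
the start convention is ambiguous in the source design and this count is
not used as a check). Probe sequence content and hybridization
thermodynamics are not modelled.

## Read QC

Demultiplexing is an exact prefix match of the inline barcode (default
3 bp); one mismatch sends a read to `unassigned`, and the barcode bases are
trimmed on assignment. Duplicate marking is per sample on the single-end
key `(contig, start, strand)` — insert ends don't exist for single-end
reads — keeping the copy with the highest base-quality sum, ties broken by
input order. A read is on-target iff it overlaps at least one target base.
Coverage ladders report the fraction of targeted bases at ≥ {1, 5, 10, 20,
30, 40, 50}× depth, before and after duplicate removal; the ladder is
monotone in the threshold and dedup can only lower it.

## Read-depth CNV

Windows of 50 bp tile each merged target from its start; a trailing
remainder is dropped, and a read increments every window it overlaps.
Duplicate-removed counts are the default input. For a test sample, counts
are first scaled so all samples have equal library size (raw division would
conflate per-sample depth with copy number; the unnormalized mode is
retained as an option), then divided by the leave-one-out mean of the other
pool members (≥ 2 required) and log₂-transformed. Zero-baseline windows
are flagged and excluded; a zero test count over a live baseline is floored
at 0.5 reads to keep a finite, strongly negative ratio.

Candidate deletions are maximal runs of ≥ 5 consecutive windows with ratio
≤ −0.7; up to one flagged window inside a run is bridged; runs never cross
a gap in the tiling. The thresholds are configuration keys: the expected
heterozygous-deletion signal is log₂½ = −1 and −0.7 sits > 3 SD from
neutral noise at ≥ 50× depth, while 5 windows (250 bp) suppresses isolated
fluctuations. A mean ratio ≤ −2.5 reclassifies a segment as homozygous.
Segment length equals the span of its window bounds.

MLPA: within a sample, each probe's peak height is divided by the mean of
the control probes; that ratio is normalized by the same probe's mean ratio
across reference individuals, so 1.0 ≡ two copies. Below 0.8 calls one
copy; above 1.2 flags a possible gain. Zero or missing control peaks are
errors.

## LOH statistics

With a cell fraction `f` having lost the wild-type allele, subclones carry
the mutant allele with probability `(1+f)/2`. The default test of k/n
against ½ is the normal approximation *without* continuity correction,
two-sided (`2(1 − Φ(|z|))`); the exact binomial (doubled smaller tail,
capped at 1) is available as `exact-binomial`. The source analysis does not
name its test; the z approximation is the reconstruction adopted here
because it uniquely reproduces the printed p = 0.24 from 34/59 (the exact
test gives ≈ 0.30), and it is flagged as a reconstruction. The mixture
inversion `f̂ = 2(k/n) − 1` is unbiased before clipping; it is reported
clipped to [0, 1] with a Clopper–Pearson CI transformed through
`f = 2p − 1`. A direct lesion-vs-control two-proportion z-test is provided
as an extra; groups with n < 5 are flagged low-power.

The z test is discrete at small n: its true size at α = 0.05 is 3.6% at
n = 52 and oscillates with n. The calibration test therefore uses n = 250
subclones, where the exact null rejection rate is 4.97% — chosen from the
exact binomial null distribution, not from simulation outcomes.

## Synthetic cohorts

The generator emulates the study design: a single founder couple starts
each family, every child marries an unrelated founder and has a fixed
number of offspring (default 3 generations × 2), transmission is fair
(½ per meiosis; a mosaic founder transmits with `mosaic_fraction/2`; a
de-novo option seeds the mutation in generation 2), and affection is
carrier ∧ uniform < penetrance (default 1). The sequencing pool takes up to
two affected plus one unaffected individual per family. Defaults follow the
emulated experiment where it states them: 80 bp single-end reads, 3 bp
barcodes, ~39% off-target reads, 15 coding exons, subclone n = 52,
LOH fraction 0.69 (= 2·44/52 − 1). Desk-scale substitutions: a single
200 kb toy contig stands in for the 8.6 Mb interval, and mean target depth
defaults to 60× instead of millions of reads per sample. Duplicate rate
defaults to 0.25, a mid-range figure consistent with the pre/post-dedup
coverage drop of pooled-capture libraries.

Reads sample unique (position, strand) pairs uniformly over the target
(slightly underdispersed relative to Poisson), so a zero duplicate rate
really yields zero duplicate keys; PCR duplicates are exact-coordinate
copies appended at the configured rate; a heterozygous deletion thins
overlapping reads by ½. Injected causal variants cycle through frameshift /
nonsense / splice-acceptor classes in a shared disease gene; background
variation has two deliberately distinct components — catalog-listed
inherited SNVs shared family-wide, and *private* novel artifact calls at
cohort-unique sites (sequencing artifacts do not recur across individuals).
This makes cascade truth recovery deterministic at full penetrance; real
data additionally contain shared novel germline variants, so real candidate
sets can exceed one — the synthetic test establishes the plumbing, not the
real-data false-positive rate. Marker panels are simulated by crossover
walks (Haldane) constrained to the carrier map; the default "informative"
mode phases the disease allele onto allele 1 of a heterozygous carrier
founder with homozygous married-in founders, the classic fully informative
setting in which a co-segregating marker attains the LOD ceiling.

Not simulated: sequencing errors, base-quality structure, alignment
artifacts, GC-dependent capture bias, real genome sequence. Randomness
flows from one seed through crc32-keyed `SeedSequence` substreams, so
identical configurations are bit-identical and adding a stage never
perturbs another.

## Cascade conventions

Quality filtering is strict (> 20, the attested rule, adopted for both
protocols since the first protocol's "low confidence" rule is undefined);
support is ≥ 3 (first protocol) or > 4 (second), mode explicit. "Coding"
means overlapping CDS; splice-window variants are intronic and do *not*
pass the coding filter — consistent with the original discovery, where
splice mutations were found by follow-up sequencing rather than by the
coding intersection. Variants are matched by normalized
(contig, pos, ref, alt) — left-aligned, minimal representation — never by
overlap. The ledger records the classic table rows (total / coding / not in
catalog / shared / not in unaffected) and, because the ordering of the
novelty and sharing filters is ambiguous in the source, also a
`shared_before_novelty` column; the monotonicity invariant applies to the
main chain. Splice windows are fixed at ±2 bp (the essentially invariant
splice dinucleotides); intronic variants carry their distance to the
nearest exon.

## Known limitations

- Single-marker parametric LOD, not multipoint: between-marker information
  is not combined, and phase-unknown founders cost one meiosis that a
  multipoint analysis with dense flanking markers would recover.
- The consequence annotator handles one transcript per gene, forward or
  reverse strand, CDS-only exons (no UTRs), and classifies against a toy
  codon model.
- CNV segmentation is thresholded run-length calling, not an HMM or
  circular binary segmentation; it is calibrated for ≥ 50× pools of ≥ 3
  samples.
- The LOH z test inherits the discreteness of small n; for n ≲ 60 its true
  size is below nominal, and the exact binomial is the safer choice when
  calibration matters more than matching the published convention.
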