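# Methods

This note records the models, parameter choices and numerical decisions
behind `gbsmap`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Reference-tag model

The unit of mapping is a 64 bp tag: the flank of a PstI site (CTGCAG),
taken in the forward and the reverse direction, each beginning with the
5-base TGCAG overhang. With the motif's first base at position `p`
(0-based), the forward tag is `contig[p+1 : p+65]` and the reverse tag is
the reverse complement of `contig[p−59 : p+5]`. Including the overhang is
deliberate: categorised reads also begin with TGCAG, so reads and tags are
directly comparable end-to-end. CTGCAG is its own reverse complement, so a
single forward-strand scan finds every site; non-palindromic motifs trigger
a warning. A flank is emitted only when fully inside its contig and free of
ambiguous bases; each suppressed flank produces an exclusion record with a
reason code (`edge` / `ambiguous-base`), giving the exact conservation law
*tags + exclusions = 2 × sites* that the tests assert.

Merging additional assemblies adds a secondary tag iff no primary tag lies
within Hamming distance `min_mismatches − 1` (default 1) of it. The default
of 2 mismatches is tied to the mapper: reads tolerate one mismatch, so a
tag at distance ≥ 2 from everything else cannot capture another tag's
reads. Because tags are equal-length and alignment is ungapped, "best
full-length match with ≥ 2 mismatches" reduces to this distance test, run
through the same pigeonhole index the mapper uses. Secondary tags with no
primary counterpart at all are included by default (`include_no_hit`),
since they represent genome absent from the primary assembly.

The chloroplast screen removes tags with an ungapped full-length match to
either strand of the plastid genome at ≥ 90% identity over ≥ 64 bp — for
64 bp tags, exactly ≤ 6 mismatches. Implementation: every plastid window is
indexed by 7 chunks of the tag length; by pigeonhole any window within 6
mismatches shares at least one exact chunk with the tag, so the prefilter
is lossless and no external aligner is needed.

## Read processing

Assignment requires an exact barcode, the complete overhang, and no N in
the barcode-stripped read (the strict reading; a toggle point would be the
only alternative). Barcodes are 4–8 nt; the loader rejects sets in which
one `barcode+TGCAG` string prefixes another, and assignment matches the
joint `barcode+overhang` string longest-first, which remains unambiguous
even for nested barcodes (a pure longest-*barcode* rule would misroute a
read whose overhang completes a longer barcode's spelling — a case found
and fixed by the test suite). Quality trimming removes the maximal 3' run
of bases below Phred 20 — an internal low-quality base followed by good
bases survives — then reads are truncated to 64 bp; shorter reads are
discarded as `too-short`.

Mapping is exact-or-one-mismatch, ungapped, end-to-end; a read maps iff its
best stratum contains exactly one tag. The 1-mismatch search splits the
read into two 32-base halves (one half must be exact). Ties are never
broken; reverse-complement mapping is never attempted because the tag set
already contains both orientations and the protocol fixes read strand.
Equivalence with an exhaustive Hamming-distance oracle is asserted on
10,000-tag instances.

## Variant filtering

Candidate sites need > 3 alternative-allele reads population-wide; the
alternative allele is the most frequent non-reference base, with additional
alleles only setting a `multiallelic` flag. The cascade order and defaults
are: alt fraction ≥ 0.1; allele base-quality difference ≤ 5% (formalised as
|mean ref Q − mean alt Q| / max(·,·) × 100, the formula being a
package-level choice); site quality ≥ 20; total coverage ≥ 5 × n_samples;
heterozygous samples ≤ 2% (using provisional proportion-rule genotypes);
population alt:ref read ratio ≥ 0.5 (a segregation-balance filter; a
sample-count variant is selectable); dominant-marker removal (a tag with
zero reads in either parent is a presence/absence marker — a null allele
indistinguishable from missing data); and removal of markers whose parent
genotype is missing. Each stage is a pure per-record predicate, so the
final surviving set is order-independent even though the intermediate
ledger counts are not — both properties are tested.

The site quality score is a Phred-scaled binomial tail: the probability
that all alt-supporting reads arise from per-base error at the rate implied
by their mean base quality, capped at 3000. It is an approximation standing
in for a genotype-likelihood caller's site score; the ≥ 20 threshold is
configurable and the score's role is ranking, not calibration.

## Genotypes and the genetic map

The proportion rule calls hom-ref above 0.8, hom-alt below 0.2, het in the
closed interval between (boundaries het, since the homozygous rules are
strict inequalities), with depth floors of 3 (hom) and 6 (het) below which
calls are recoded missing. Parent replicates merge by summed depths before
calling. Markers recode to `a`/`b` by which parent carries which allele and
are dropped when a parent is missing or heterozygous or the parents agree.

Map construction collapses markers whose shared non-missing progeny calls
agree with ≥ 50% overlap (an operationalisation of "identical segregation";
exact-pattern-only mode exists), keeping the highest-quality member; drops
markers > 20% missing; groups at independence LOD ≥ 6 by single linkage,
where LOD = k·log10(2R) + (n−k)·log10(2(1−R)) for k recombinants among n
informative progeny, clamped to 0 for R ≥ 0.5; heterozygous calls are
treated as missing in pair statistics (an F11 has ≈ 0.1% residual
heterozygosity, so the information lost is negligible and the two-class
RIL likelihood stays exact). Ordering is greedy nearest-neighbour
construction polished by 2-opt segment reversal, 10 seeded starts,
minimising the sum of adjacent recombinant fractions; up to 8 markers this
provably reaches the exhaustive optimum (tested), and at population scale
the recovered orders correlate with truth at |ρ| ≥ 0.99. Distances apply
the Haldane–Waddington inverse r = R/2(1−R) and then Haldane's map function
(Kosambi selectable); gaps are capped at 50 cM with a warning. Orders and
map lengths are therefore comparable in scale to, but not bit-identical
with, tools using a proprietary maximum-likelihood distance.

"Poor fit to neighbours" is operationalised as apparent double crossovers:
a marker whose call contradicts two agreeing immediate neighbours in more
than 3 progeny is removed and the group re-ordered once. This is a stand-in
heuristic and is labelled as such in output metadata.

## QTL scanning

Haley–Knott regression replaces mixture-model interval mapping: at each
grid point (a 1 cM lattice united with the marker positions, so scans at
markers reduce exactly to marker regression — asserted) the trait is
regressed on the expected `b` dosage given flanking informative markers,
with RIL-scale transition probabilities R(d) = 2r/(1+2r), r Haldane. At RIL
information density the difference from the mixture model is negligible.
LOD = (n/2)·log10(RSS0/RSS1); variance explained = 100·(1 − RSS1/RSS0);
the effect is the fitted bb − aa difference with its OLS standard error;
zero-residual fits are flagged degenerate and capped at LOD 300.

Permutation thresholds shuffle trait values across lines (genotype vectors
stay intact, preserving marker correlation), vectorised as a correlation
matrix product, and return the (1−α) quantile of per-permutation maximum
LOD. rMQM-style scans add user-chosen (or automatically selected: the peak
marker of each significant group) cofactor markers as covariates, excluding
any cofactor within 10 cM of the test position — the window is a package
default, configurable — with the LOD taken against the cofactor-only null.
Support intervals are the widest contiguous run within `drop` LOD of the
peak. The joint model is an additive OLS over locus dosages with an F-test
of all pairwise interactions (collinear loci are reduced with a warning);
binary-trait association is the 2×2 chi-square without continuity
correction (the use-case is ranking), zero-margin tables scoring 0 with a
flag and perfect coupling flagged explicitly.

## The synthetic-data generator

The generator emulates a two-enzyme barley GBS study on an F11
single-seed-descent RIL population. Defaults are the emulated study
conditions: 7 chromosomes with lengths (140, 190, 180, 130, 190, 160, 210)
summing to 1,200 cM; 1,300 SNP marker tags placed uniformly; 200 extra
tags, 3% of them dominant (restriction site lost in one parent); 138 lines;
10 selfing meioses (residual heterozygosity (1/2)^10 ≈ 0.00098, verified
against the closed form); three height QTLs — major on chromosome 5 at
29.7 cM with per-year effects +27.5/+24.8 cm, minor on chromosome 3 at
51.6 cM (+9.7/+8.9 cm), and one on chromosome 2 at 80.5 cM (−10.1/−6.8 cm)
that also determines spike row type, with the two-row allele dominant and
two SNP markers planted in complete coupling with it. Meiosis places
crossovers with no interference (Haldane); chi-square interference is out
of scope.

Phenotypes are baseline + Σ effect × dosage + a shared line deviation +
year noise. The variance components (line SD 6.97 cm, year SD 5.73 cm,
baseline 81.5 cm) were derived in closed form from three calibration
targets — major-QTL variance fraction in the 55–62% band, between-year
correlation ≈ 0.887, heights spanning roughly 60–130 cm — and fixed.
A marker-free window (default 6 cM) sits adjacent to the major QTL,
starting 0.5 cM beyond it: this reproduces a map whose most-associated
marker lies essentially at the locus while the surrounding region is
marker-poor, the geometry characteristic of a shared parental haplotype
around an induced mutation. Placing the gap symmetrically around the QTL
instead would attenuate the peak variance below the calibrated band.

Reads are `barcode + genomic sequence from the overhang`, 100 bp, with
per-locus efficiency weights (log-normal, σ = 0.3), per-sample totals
log-normal with 2.5–97.5% range ≈ 5,000–65,000 reads — a desk-scale
default roughly 100× below a production run, adjustable via
`depth_scale` — substitution errors at 0.2%/base, Ns at 0.05%/base,
4%/3% of reads with corrupted barcodes/overhangs, and quality strings from
a pool of Illumina-like profiles including occasional low-quality 3' tails
so trimming is exercised. Parents appear in every 48-plex library at twice
the depth. Everything derives from a single seed; runs are byte-identical.

What the generator does *not* model: real barley sequence composition and
repeat structure (background sequence is random over {A,C,T} so the only
CTGCAG motifs are planted ones), paralogy and multi-mapping ambiguity
beyond duplicate tags, PCR duplicates, methylation-dependent site
filtering, indels, and quality-correlated error rates. Consequently,
passing tests demonstrate the correctness of the pipeline's logic,
bookkeeping and statistics under the stated model — not robustness to
repeat-rich genomes or heavy paralogy, where unique 1-mismatch mapping is
doing far more work.

## Problem sizes in the test suite

Map- and QTL-level checks (7 linkage groups recovered, order correlation,
permutation threshold ≈ 3.0, QTL recovery) run at the full default scale —
1,300 markers × 138 lines — directly from the generator's genotype and
phenotype layers. The read-level end-to-end run uses 520 markers × 96 lines
at ~1M reads, the package's chosen integration size: large enough that
linkage groups stay intact at LOD 6 and the minor QTLs remain detectable,
small enough to re-run routinely. At that reduced size sparse chromosome
ends can occasionally split into an extra group; the integration test
therefore asserts chromosome purity and full coverage rather than an exact
group count, which is asserted at full scale. The reference-set bookkeeping
tests run at the full count scale (343,854 sites → 802,046 tags) since they
are exact identities.

## Known limitations

* The site quality score approximates, but is not, a genotype-likelihood
  caller's score; absolute values are not comparable across tools.
* Marker ordering is heuristic; for very tightly linked markers (zero
  observed recombinants) local order within a co-segregating cluster is
  arbitrary, as it is for any method at finite population size.
* The rMQM cofactor auto-selection (peak marker per significant group) is a
  simple rule; cofactors can always be supplied explicitly.
* Dominant (presence/absence) tags are detected and removed, not
  genotyped; the pipeline is strictly co-dominant.
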