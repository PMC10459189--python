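# Methods

This note records the statistical model behind each stage of `plantsurvey`,
the default parameters and why they were chosen, and the known limits of the
approach. It is written for someone who wants to judge whether the numbers
the toolkit prints can be trusted, not as user documentation (see the README
for that).

## 1. The survey model

A genome survey estimates genome size, repeat content and heterozygosity
from short reads alone, before any assembly. The whole analysis rests on one
identity: if a genome of size `G` is sequenced to uniform depth, every
position contributes one k-mer per covering read, so the total number of
k-mer observations ("volume") above the sequencing-error noise is

```
V  ≈  G × c
```

where `c` is the depth at which single-copy k-mers pile up — the main peak
of the k-mer depth histogram. Everything else is a refinement of how `V`
and `c` are read off a real histogram.

Two practical corrections matter:

* **Read-edge losses.** A read of length `L` yields `L − k + 1` k-mers, so
  the k-mer peak sits at `c_read × (L − k + 1) / L`, not at the read depth.
  The toolkit never needs `c_read`; it works entirely in k-mer depth.
* **Contaminating volume.** Any reads that are not nuclear — organellar
  reads above all, present at high copy number in plant leaf tissue — add
  their k-mer volume to `V` and inflate `G` by (organelle volume)/`c`.
  Filtering them first is the point of this package; the pipeline can run
  both ways to show the inflation directly.

### k and canonical form

`k = 17` by default: large enough that random 17-mer collisions are
negligible against plant-genome scales (4^17 ≈ 1.7 × 10^10), small enough
that one substitution error corrupts only 17 k-mers. `k` must be odd — an
even k admits self-reverse-complementary k-mers, for which the canonical
form (lexicographic minimum of a window and its reverse complement) no
longer identifies strand-ambiguous observations uniquely, so even values
are rejected rather than silently accepted. Depths are capped at 10,000;
everything deeper accumulates in the cap bin (organelle and plastid k-mers
live there, far above any nuclear signal).

### Peak finding

The distinct-k-mer count per depth is smoothed with a centered 3-bin moving
average. The error component (k-mers created by sequencing errors) decays
from depth 1; the error cutoff `d_min` is the first local minimum of the
smoothed curve, or 1 when the curve rises from the start (error-free input).
The main peak `c` is the argmax at or beyond `d_min`; a repeat peak is the
local maximum nearest `2c` (at least 1% of the main peak height), reported
when present.

### Genome size, repeats, heterozygosity

* **Size**: `G = Σ_{d ≥ d_min} d · n(d) / c`, i.e. usable volume over peak
  depth.
* **Repeat fraction**: the unique (single-copy) component is modelled as
  `A · Poisson(d; c)` and `A` is fitted by least squares over
  `d ∈ [0.5c, 1.5c]`; the repeat fraction is `1 − A·c / V`. On a genome
  with a fraction `r` of its length in multi-copy sequence, single-copy
  k-mers carry `(1−r)·V` of the volume, so the estimator recovers `r`.
* **Heterozygosity**: alleles that differ between haplotypes put k-mer
  species at depth `c/2`. The homozygous model (`A` fitted tightly over
  `[0.75c, 1.25c]`) is subtracted from the observed species counts in the
  window `[0.35c, 0.65c]`; the excess `E` is attributed to heterozygous
  alleles. A half-peak is only *called* when the excess volume reaches 5%
  of the fitted main-peak volume — below that the excess is fit noise.
  One heterozygous site yields **two** allele k-mer species per overlapping
  window, so `E/2` counts heterozygous loci, the heterozygous locus
  fraction is `f = (E/2) / (E/2 + A)`, and the per-base rate solves
  `f = 1 − (1 − rate)^k` (a base is covered by k windows). Counting `E`
  directly instead of `E/2` would double-count alleles and report roughly
  twice the true rate on the simulator's diploid model; the choice is
  validated by the diploid recovery test (truth 0.01, estimate ≈ 0.0103).

## 2. Read QC

Fixed-cycle short reads are trimmed 8 bases from the front (adapter/quality
artifacts concentrate there) and 2 from the tail, then a read is discarded
if it is shorter than 140 bases, contains any N, or has more than 20% of
bases below Q20. The filters run in that order so reason codes are
reproducible. Pairs are dropped symmetrically (if one mate fails, both go)
to keep mate files synchronized. The headline number is the filtering
rate, `100 × (1 − clean bases / raw bases)`.

## 3. Organelle-read classification

A read is organellar when it aligns end-to-end, on either strand, to an
organelle reference (circular: the index appends the first `read_len − 1`
bases so origin-spanning placements exist) with

* gapless and ≤ 3 mismatches, or
* mismatch-free and ≤ 2 gap bases, or
* ≤ 1 gap base and ≤ 1 mismatch.

Gap bases count both inserted and deleted columns; an N in the read counts
as a mismatch against every base. The rule is a parameterized dataclass;
the defaults are deliberately strict because the cost asymmetry is strict:
a missed organelle read inflates the genome size by one read's volume,
while an over-aggressive rule would start to eat nuclear reads that happen
to resemble organelle sequence (NUMT/NUPT insertions).

**Engine.** Candidates come from non-overlapping exact seeds: with a
maximum edit budget of `e` (3 under the default rule), `e + 1` disjoint
seeds are taken from the read, so any qualifying alignment leaves at least
one seed intact (pigeonhole) and no qualifying placement can be missed.
Seeds are 32 bases — the largest length that packs into one `uint64` with
2-bit codes, which is what makes the whole lookup a vectorized binary
search; four disjoint 32-mers fit comfortably in a 140-base read, so the
pigeonhole guarantee is preserved. Candidates are verified gaplessly in
bulk; only candidates that fail gaplessly fall to a small banded dynamic
program (band = maximum gap budget) that tracks the minimum mismatch count
for every gap-base budget and diagonal offset. Leading/trailing reference
gaps are equivalent to shifting the placement and are handled by the outer
start loop; read-end insertions count as gap bases.

The tests check this engine against a structurally different oracle (full
gapless scan of every placement plus an exhaustive semi-global DP) on
randomized reads with planted edits.

## 4. GC–depth screen

After a preliminary assembly, each contig of ≥ 5,000 bases (shorter contigs
have too noisy a GC estimate) is summarized by GC fraction and mean mapped
depth. Reads are placed by the same engine under a relaxed rule (up to 5
edits) with ties between equally good placements broken randomly under a
fixed seed, so exact repeat copies share depth instead of stacking on the
first copy. Contigs are binned on a 0.01 × 5× grid; 8-connected occupied
bins form clusters, clusters holding ≥ 2% of contigs yield enrichment
centers, and the contamination flag raises when any center sits above 60%
GC — plant nuclear DNA sits far below that, while common bacterial
contaminants do not. Depth-separated centers at similar GC are annotated
as a possible heterozygosity/copy-number signal rather than contamination.

## 5. CDS variants

Alleles of a gene are compared as intron-free CDS sequences, aligned
globally with affine gap costs (match +1, mismatch −2, gap open −4, gap
extend −1 — one long gap beats scattered short ones, which is how real
indel alleles behave). Each mismatch column yields an SNV; each maximal
gap run yields one insertion or deletion. Effects under the standard code:
synonymous / missense / premature stop for SNVs by codon comparison;
indels are frameshifts unless length ≡ 0 (mod 3), and frameshifts are
scanned downstream for the first stop codon in the shifted frame.
Applying the called variants to the reference must reconstruct the
alternate sequence exactly; this round-trip is property-tested on random
mutation sets. Coordinates are 1-based with CDS position 1 at the first
base of the start codon.

## 6. Synthetic data

All validation runs on simulated data with known truth, at sizes chosen so
the full suite runs on one desktop CPU core: a 5 Mb nuclear genome stands
in for a ~1 Gb one. The simulator is deliberately simple — i.i.d.
background sequence at a target GC, exact-copy repeat units placed without
overlap, circular organelle genomes, optional diverged organelle-fragment
insertions (NUMT/NUPT mimics), diploid haplotypes by uniform substitution,
paired reads from Normal(300, 30) inserts with uniform substitution errors
and constant Phred quality. What it does *not* model (indel errors,
quality ramps, GC bias, structured repeat families) is exactly what the
estimators do not claim to correct for.

Default simulation scale: 5 Mb nuclear at 100× with 30% repeats, one
150 kb organelle at 10% of read pairs, error rate 0.001, 150 bp paired
reads. At that scale the filtered size estimate lands within ~0.5% of
truth; tests assert 5%.

## 7. Known limitations

* Genome size uses the integer peak depth; at low coverage (c ≲ 30) the
  discretization alone costs a few percent. Survey designs should aim for
  c ≥ 50 in k-mer depth.
* The repeat estimator treats everything outside the fitted Poisson as
  repeat volume, so residual organelle k-mers, contaminant k-mers, and a
  strong heterozygous half-peak all read as "repeats" if not handled first.
* The heterozygosity rate assumes isolated substitution heterozygosity
  (each het site destroys/creates whole k-mer windows independently);
  clustered variants and het indels are out of model.
* The classifier is exhaustive only within its edit budget; organelle reads
  with ≥ 4 edits (old NUMT copies, high-error reads) are deliberately left
  in the nuclear set, matching the strict acceptance rule.
* `--threads` is accepted for interface compatibility but execution is
  single-threaded; results are identical for any value.
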