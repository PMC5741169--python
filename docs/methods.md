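# Methods

This note records the models, conventions and numerical choices behind
`haplomosaic`, in the order of the pipeline.

## Cohort model and coordinates

A phased cohort is a variant table plus a {0,1} allele matrix with two
haplotype columns per sample (columns 2i, 2i+1 belong to sample i), a
panel mapping samples to populations and continents, and a per-variant
ancestral status parsed case-insensitively from the `AA=` INFO field:
`R` when the annotated ancestral allele equals the reference allele, `M`
when it equals the alternative, `X` otherwise (absent, `.`, `-`, `N`,
a third base, or an indel mismatch — the data never state how such
values should be polarized, so we decline to guess).  Multi-allelic
records are dropped because segment haplotypes are binary strings by
construction; biallelic indels are kept by default (`snp_only` disables
them).  Missing or unphased genotypes are hard errors naming the record:
the intended inputs are fully phased panels, and silently imputing phase
would corrupt every downstream string.

VCF positions are 1-based throughout.  The only 0-based construct is the
window grid of the segmentation layer: window anchors sit at 0,
`window_bp`, 2·`window_bp`, … per chromosome, and a window's segment is
the first k frequent variants with 1-based position strictly greater
than its anchor.  Anchoring the grid at zero is arbitrary but
reproducible.  Segments may extend past the next anchor ("elongation"),
so consecutive windows can produce overlapping or identical segments; a
`dedup_segments` flag collapses exact duplicates for users who prefer
counting each selection once.

"Frequent" means strictly `min(f, 1−f) > 0.25` with `f` the alternative
allele frequency over the 2n haplotypes; ties at exactly 0.25 are
excluded.

## Haplotype grouping and classes

Grouping is deliberately simple and deterministic: distinct strings are
counted exactly, ordered by (count desc, lexicographic asc), and scanned
in that order; each string joins the first existing group whose
*representative* is within 2 differences, else founds a new group.  The
founding order guarantees the representative is its group's most
frequent member, and the scan order resolves ties (a string equidistant
from two representatives joins the more frequent one).  The ≤2-difference
absorption radius exists to tolerate occasional sequencing errors; the
flip-noise recovery tests quantify exactly that.

The common-haplotype threshold is expressed both as an absolute count
(≥ 100 occurrences, appropriate for a 2184-haplotype cohort where it is
≈ 4.6%) and as a frequency (≥ 5%, used for simulated populations of
arbitrary size); exactly one must be active.

Yin/Yang pairing is greedy by rank: the most frequent unpaired CH is
paired with the most frequent other unpaired CH at Hamming distance
≥ 47, both leave the pool, and the scan repeats — so a segment can hold
several pairs.  Within a pair, Yin is the more frequent member.  The
47/50 (94%) tolerance admits a few sequencing errors or gene-conversion
"jumps" of single variants between the two backgrounds.

`min_pieces` labels each position of a haplotype Y (matches Yin only),
G (matches Yang only) or wildcard (matches both — possible wherever Yin
and Yang agree — or neither).  Wildcards never force a breakpoint:
dropping them and counting Y↔G alternations plus one is the minimum
over all wildcard resolutions, which the test suite verifies against an
exhaustive enumeration oracle on strings up to length 20.  A CH needing
≥ 12 pieces is Mosaic.  When a segment holds several Yin/Yang pairs,
Mosaic decomposition uses the top-ranked pair.

Derived-allele accounting excludes X positions from both numerator and
denominator; a haplotype whose every position is X raises a distinct
error rather than returning a number.  The one-sidedness null model
assigns each derived allele independently to Yin/Yang/neither with
configurable probabilities (defaults 0.546/0.438, the observed
genome-wide shares) and reports the fraction of replicates in which
≥ 80% land on one side; it is seeded and checked against the exact
multinomial tail at small allele counts.

## Ancestral and archaic comparison

The deduced ancestral haplotype maps R→0, M→1 and masks X.  Matching
allows ≤ 2 mismatches over unmasked positions only; segments with more
than half their positions masked are flagged ineligible because the
≤2-difference rule loses meaning there.  Abundance classes are
absent / rare (1–3) / uncommon (4–99) / common (≥ 100); the 4–99 upper
bound keeps the classes disjoint where the source conventions were
ambiguous (4–99 vs 4–100).  Specificity: rare haplotypes are
continent-specific only at 100% concentration, uncommon at strictly
> 90%; common ones instead use per-capita predominance — matches divided
by 2 × continent sample count, ties broken by the configured continent
order — because proportion rules are confounded by uneven panel sizes at
high counts.  The per-capita rate is our explicit choice of
normalization; the source only gestures at one.

Archaic genomes at frequent variants are overwhelmingly homozygous, so
diplotype codes collapse to a haplotype (0→0, 2→1; heterozygous and
unresolved positions become missing).  CH comparisons count differences
over resolved positions and require ≥ 45 of 50 resolved — our addition,
again to keep a ≤2-difference near-identity flag meaningful.

## Synthetic cohorts

The generator is constructive, not coalescent: exact ground truth beats
realism for testing.  Per segment it draws an ancestral string, plants
Yin (default 27/50 derived alleles, frequency 0.40), Yang as Yin's
complement degraded by `n_jump = 2` jumped positions (Hamming 48,
frequency 0.28), optionally a Mosaic (frequency 0.08) whose piece count
is *solved for* — the Y/G label run-structure is laid out first, the
derived-allele placement (default 12 derived, 10 matching Yin, 2
matching Yang) is derived from it, and the result is self-checked with
`min_pieces` at generation time — plus near-ancestral copies and
background haplotypes.  Jumped positions are placed on Yin-derived sites
so both pair members carry the derived allele there and the site stays
frequent.  Background columns are per-site Bernoulli draws with
probabilities chosen to pull every planted site's allele frequency
toward 0.5, clipped to [0.15, 0.85]: the clip keeps backgrounds mutually
diverse (extreme probabilities would cluster them into spurious common
haplotypes) while guaranteeing MAF > 0.25 at all 50 planted sites.
Backgrounds within 4 differences of any planted representative (or of
the ancestral string over unmasked sites) are redrawn, so noise-free
recovery is exact rather than merely probable.

Defaults emulate the study cohort: 1092 diploids (AFR 246, AMR 181,
ASN 286, EUR 379), one segment per scenario, 10% X-annotated sites
(excluded from Mosaic-derived positions so the planted split stays exact
in annotation space), flip noise ε = 0 (tests add 0.005 explicitly),
continent weights giving ancestral and Mosaic haplotypes an African
excess and Yin an African avoidance, and an archaic individual drawn
from the ancestral string with 18% derived alleles, 0.5% heterozygosity
and 2% missingness (in Mosaic scenarios the archaic equals the planted
Mosaic, emulating archaic–Mosaic near-identity).  What the generator
does *not* emulate: linkage-disequilibrium decay within segments,
recombination-rate variation, and demographic history — so passing
recovery tests demonstrates correctness of the classification machinery
under the planted architecture, not inference quality on real genomes.

## Forward simulator

The simulator is an infinite-sites abstraction on a continuous genome
[0, L): every mutation has a unique uniform position, a selection
coefficient (s > 0 deleterious, s < 0 beneficial; exponential magnitudes
with configurable means, defaults 10⁻³), and a registry entry.  Each
generation: random permanent pairs (both gametes of all α offspring of a
pair come from the same two parents; pairs are redrawn every
generation), exactly r crossovers per gamete at uniform positions with a
random starting haplotype, Poisson(μ) fresh mutations per gamete,
multiplicative co-dominant fitness (1 − hs per heterozygous, 1 − s per
homozygous mutation, floored at zero), and truncation selection keeping
the fittest N of αN/2·2 offspring with seeded random tie-breaking; α = 2
reproduces every offspring and is pure drift.  α is offspring per pair
by default (the only reading under which α = 2 means "no selection");
`alpha_per_individual` switches the convention.  Mutations reaching
count 2N are recorded as fixed and removed from the matrices; count 0 is
a loss; influx = fixations + losses + segregating holds every generation
and is asserted in tests.  A segregating-site cap (default 2·10⁶) fails
fast instead of exhausting memory.

Implementation: the population is a (2N × S) uint8 matrix over
position-sorted columns; crossovers become searchsorted toggle points
and a cumulative-sum parity per gamete, so a generation is a handful of
vectorized passes.  Runs are bit-reproducible from the seed.

Note one deliberate property of this mating scheme: with permanent pairs
and α = 2, each gene copy leaves Binomial(2, ½) descendants, so the
chance a brand-new mutation is extinct within three generations is
f(f(f(0))) ≈ 0.483 with f(s) = ((1+s)/2)², and observed diversity runs
about twice the Wright–Fisher expectation for the same N (offspring
variance ½ instead of 1).  Neutral fixation *rates* are unaffected.

## Experiment sizes

All experiment sizes are the package's own desk-scale choices.  The
neutral fixation-clock run uses N = 100, μ = 5, r = 2, 1000 burn-in +
2000 observed generations (≈ 10⁴ fixation events).  The population-size
sweep runs N ∈ {50, 100, 200, 400} under a *common budget of 1200
generations* with μ = 2 and r = 5 (preserving the r/μ ratio of the
full-scale setting), neutral α = 2: comparing populations of different
sizes after equal evolutionary time mirrors how real cohorts are
compared and is what makes the frequent-variant count grow sublinearly
(larger populations are further from mutation–drift equilibrium, as
human populations are).  Under these conditions Yin/Yang pairs are
essentially absent from panmictic populations at every size — itself the
point of the comparison.  The admixture experiment uses N = 50, μ = 2,
r = 5, 300 burn-in generations, a 500-generation separation (10·N) and a
50/50 merge, analyzed at the moment of merging against a control evolved
panmictically for the same total time; mutations privately fixed in one
lineage re-enter the merged pool at frequency ½ and are reinstated as
segregating columns.

## Known limitations

- Grouping is order-dependent by design; a different scan order is a
  different (equally defensible) partition.  Ours is documented and
  seedless.
- The derived-allele clock is linear by assumption and has no
  uncertainty model; it is arithmetic, not inference.
- The simulator's gene-free genome and truncation selection are an
  abstraction: absolute haplotype-architecture numbers depend on genome
  structure and are not comparable across implementations — only trends
  (direction of N-, r-, α-effects, admixture enrichment) are.
- The archaic comparison assumes the archaic sample is near-homozygous
  at frequent variants; heterozygous-rich archaic data would mostly be
  masked out.
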