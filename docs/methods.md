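# Methods

This note documents the models, conventions and design choices behind
`ernatlas`, in the spirit of a methods supplement: what each stage
assumes, which parameters matter, and what the synthetic generators do
and do not emulate.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); GTF input is
converted on read and chromosome names pass through verbatim.  The TSS
of a minus-strand gene is its annotated end coordinate.  Distance from
an interval to a point is 0 when the point falls inside, otherwise the
gap to the nearest edge; "within 2 kb" between intervals is measured
edge to edge.  Intervals that merely touch share no base and are not
merged.  These conventions are package choices — the workflow being
reproduced does not state its internal convention — and they are
applied uniformly so the criteria behave consistently.

## Enhancer discovery

Replicate consensus clusters peaks by single-linkage ≥1-bp overlap and
keeps clusters supported by strictly more than `min_fraction` (default
0.7) of replicates, reporting the union span.  The seven filter
criteria are conjunctive, so survivors are order-independent; the
evaluation order (1..7) only determines which failure is recorded
first.  Mark enrichment is the tag count in the 2-kb window centred on
the peak midpoint, standardised into z-scores over the population of
H3K27ac peaks that survive criteria 1–2.  The population choice is
ours (the source workflow is silent); excluding TSS-proximal peaks
keeps promoter-like outliers from dominating the mean while still
letting the five-sigma rule (criterion 3, both marks z > 5) and the
promoter-mark cap (criterion 4, z < 3 to pass) operate on one common
scale.  Criterion 4 is evaluated on the same 2-kb window as criterion
3.  Note that any peak failing criterion 3 necessarily fails criterion
4 as well (z > 5 implies z ≥ 3); provenance therefore reports the
*first* failing criterion.

## Transcription classification

log₂(n+1)-transformed tag counts are clustered with k = 2.  In one
dimension the optimal K-means partition is contiguous in sorted order,
so the implementation scans all split points using prefix sums and
returns the global optimum deterministically — no random
initialisation, no Lloyd iteration.  The tag threshold is the maximum
raw count in the weak cluster; depth correction scales the reference
threshold (30 at 245,647,806 total tags) linearly in library size, and
candidates compare as n > threshold (fractional thresholds allowed).
Tag counting uses both strands; transcription orientation uses the
stranded subsets and returns '.' on ties (including 0/0).

## Synthetic data: what is emulated

* **Genome bundle** — genes, rRNA genes and candidate peaks are laid
  out in disjoint 20-kb slots so that planted enhancers satisfy all
  seven criteria with wide margins, while each decoy class violates
  exactly the geometry or signal its criterion tests.  The
  promoter-like and high-H3K4me3 decoys need designed population
  z-scores (≈5.8 and ≈3.9); because outliers shift the population mean
  and inflate its sd, their tag counts are solved self-consistently
  against the drawn background counts.  A single decoy per class is the
  default: with one ~55-peak population the maximum attainable z for a
  lone outlier is ≈√n ≈ 7.4, and multiple extreme outliers would mask
  one another.
* **Tag mixture** — counts are round(2^x − 1) with x normal in log₂
  space, medians 123 (transcribed) and 4 (weak), transcribed fraction
  0.353.  Only the medians are externally constrained; the spreads
  (σ = 1.0 and 0.8 log₂ units) are chosen so the components overlap
  slightly and the classifier has a non-trivial boundary to find.
* **Catalogue series** — each of A candidate elements carries a
  presence rate λ and enters each cell type independently with
  probability 1 − e^(−λ).  The expected undiscovered fraction after x
  cells is E[e^(−λx)]; matching the Weibull form e^(−(x/b)^c) is a
  Laplace-transform inversion, solved by non-negative least squares on
  a fixed rate grid.  The representation is exact for shape c ≤ 1
  (complete monotonicity) and an approximation above; the default
  truth (A = 500, b = 40, c = 0.9) describes a catalogue roughly 70%
  discovered at 50 cell types.
* **SNP panels** — disease SNPs fall inside loci with probability
  fold × (locus base fraction); LD partners are placed within a block
  and carry r² drawn from per-block Beta distributions (strong blocks
  Beta(8,2), weak Beta(2,8)).  No haplotype or coalescent simulation is
  attempted: the pipeline consumes r² values only.
* **Structure cases** — perfect hairpins (Watson–Crick stem over a
  poly-A loop).  Disruptive SNVs replace a mid-stem base with one that
  cannot pair (canonically or by GU wobble) with its partner; neutral
  SNVs substitute C inside the loop.

What passing these tests shows is that each algorithm recovers planted
structure under its own generative assumptions.  Real data differ in
known ways the generators do not model: irregular peak shapes and
widths, correlated replicate noise, overdispersed tag backgrounds
outside candidates, LD that decays continuously with distance, and RNA
structures far from ideal hairpins.  Recovery rates here are therefore
upper bounds on real-data behaviour, not estimates of it.

## Master lists, saturation and fitting

Merged spans longer than 5,000 bp are split into ⌈L/5000⌉ equal-length
chunks (boundaries rounded to integers); equal chunks are a
determinism-preserving choice where the original master-list rule is
not restated.  Saturation curves draw cell-type subsets without
replacement as prefixes of random permutations — each per-x marginal
is a uniform x-subset, and one permutation yields the whole curve, so
20,000 samples stay tractable.  Subset counting operates on the
master-element decomposition (an element counts wholly once any subset
catalogue overlaps it), which is exact for catalogues built from a
shared disjoint element pool and an approximation when catalogues
partially cover elements.  The Weibull fit uses
`scipy.optimize.curve_fit` with positivity bounds; the asymptote
uncertainty `A_sd` is the linearised standard deviation from the
parameter covariance (a bootstrap could replace it, but the linearised
value is cheap and deterministic).  Constant curves yield a flagged
degenerate fit.  Consensus calling counts distinct supporting sets per
base; hit de-duplication collapses same-model hits whose ends both
shift by at most `shift_tol` (default 10 bp — "a few bases" made
concrete) against the leftmost representative.

## Expression association

FPKM = count / ((length/1000)·(total/10⁶)).  An eRNA region is
associated with the gene whose TSS is nearest to the region midpoint
(ties to the leftmost TSS) — the minimal faithful rule where the
original association is unstated.  Spearman correlation uses midranks
for ties and raises on constant vectors.  The synthetic pair generator
uses a Gaussian copula with latent Pearson r = 2·sin(πρ/6) so the
population Spearman correlation equals the target.

## Base-pair probabilities

The energy model is deliberately simple: per-pair-type energies
(GC −3.0, AU −2.0, GU −1.0 kcal/mol), a stacking bonus of −1.0 per
adjacent pair, RT = 0.616, minimum hairpin loop 3 nt, no lonely-pair
penalty.  The riboSNitch statistic compares two ensembles of the same
model, so internal consistency matters more than thermodynamic
accuracy; the model is pluggable for users who want different
parameters.  Inside–outside dynamic programming over the grammar
Z → Z·Zb | Z (last base unpaired), Zb → pair(Z inner) gives exact
probabilities in O(n³); a per-base rescaling factor is engaged
automatically when the worst-case Boltzmann mass would overflow double
precision (beyond roughly 200 nt at the default energies).  The
exhaustive enumeration oracle (guarded to 25 nt) sums the ensemble
term by term and is the independent ground truth: DP and oracle agree
elementwise to 10⁻⁹.

## riboSNitch scoring

Windows are ±200 nt around the variant, clipped (never discarded) at
sequence ends.  The distance over an interval [i, j] containing the
variant is sqrt(Σ (P_wt − P_mt)²) over all matrix entries inside the
interval, computed for all intervals via 2-D prefix sums; because the
terms are non-negative the distance is monotone under interval
inclusion, and the un-normalised default attains its maximum on the
largest admissible interval (a per-entry normalised variant is
available via a flag).  The minimum interval length defaults to 50 nt;
batch scoring clips it to the sequence length for shorter constructs.
The null distribution is the distance of random SNVs (uniform
position, uniform non-reference base) on the same sequence with the
window re-centred, and p = (1 + #{null ≥ observed})/(n_null + 1), so p
is never 0.  Distances are memoised per (position, alt): on an L-nt
sequence there are only 3L distinct null values, which makes large
null counts cheap.  Because the null is drawn from the same window,
competing strong variants (e.g. other stem positions in a hairpin)
raise each other's p-values; the distance ranking, not the p-value,
is the class separator, and p < 0.2 (strict) defines a call.

## Permutation enrichment

The null relocates length-matched, non-overlapping loci uniformly
within the supplied domain and recounts in-locus SNPs; the length
multiset of the real loci is preserved exactly.  Placement is
sequential, longest locus first (longest loci have the fewest eligible
pieces), with per-locus rejection on collision.  The add-one p-value
keeps p > 0.  Relocation within the eRNA-region domain mirrors a
comparison against "random structural ncRNA loci" while controlling
for eRNA context; genome-wide relocation is a caller choice of domain.
The Fisher test in the motif statistics is two-sided and the normal
z-transform of p-values is capped at ±8 to avoid infinities.

## Problem sizes and determinism

Default study conditions: 2,373 candidates for threshold calibration
(100 seeds, thresholds land in the low-to-mid 20s); catalogue series
with A = 500 over 50 cell types; 500 disease SNPs at fold 8 with
20,000 permutations for the enrichment bound; 100 hairpin cases for
class separation; 600 null-calibration draws with n_null = 100 for
p-value uniformity.  Saturation sampling uses 20,000 subsets by
default in the API; tests and examples use a few hundred to a few
thousand, which is already well inside the Monte-Carlo error the
assertions allow.  Every stochastic component takes an explicit seed
or `numpy` Generator, and fixed seeds reproduce outputs bit for bit.

## Known limitations

Peak calling, read alignment, covariance-model search, comparative
folding and coding-potential prediction are upstream tools whose
outputs this package consumes as inputs; their internals are out of
scope.  The structure engine ignores pseudoknots and uses a reduced
energy model, so its probabilities are not thermodynamic predictions
for real RNAs.  The master-element subset approximation overstates
coverage for partially overlapping catalogues.  The permutation null
treats SNPs as fixed and loci as relocatable; it does not model SNP
ascertainment or LD clumping within loci.
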