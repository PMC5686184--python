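# ernatlas

Enhancer RNAs (eRNAs) are non-coding transcripts produced from active
enhancers.  `ernatlas` is a Python toolkit for the computational chain
that identifies transcribed enhancer regions from histone-mark ChIP-seq
peaks and poly(A) RNA tag counts, characterises eRNA catalogues across
many cell types, and scores the impact of disease-associated single
nucleotide variants on RNA secondary structure (riboSNitches).  Every
stage ships with a synthetic-data generator that emulates the
statistical structure of real inputs, so the full pipeline is testable
end to end without any downloads.

## What it computes

**Enhancer discovery.** H3K27ac peaks are merged across replicates
(clusters kept when supported by strictly more than 70% of replicates)
and passed through seven conjunctive criteria: ≥1 kb from every
annotated TSS; no spliced EST with a 5′ end within 2 kb that spans a
TSS; not abnormally high in *both* H3K4me1 and H3K4me3 (z > 5, the
five-sigma rule) in the 2-kb window centred on the peak; H3K4me3
z < 3; an H3K4me1 peak within 2 kb; intergenic; not overlapping rRNA
genes.  The filter trace records every verdict and the first failure.

**Transcription classification.** The poly(A) tag count nᵢ in the
±1 kb window around each candidate midpoint is clustered on
log₂(nᵢ+1) by exact two-cluster 1-D K-means (global optimum via a
split-point scan).  The tag threshold is the maximum count in the weak
cluster — 30 in the reference library of N₀ = 245,647,806 tags — and
other libraries use the depth-corrected threshold 30·N/N₀.

**Catalogue characterisation.** Per-cell-type catalogues are merged
into a master list of disjoint elements (≤5,000 bp), cell specificity
is the per-element membership count, and the mean discovery curve over
random cell-type subsets is extrapolated with a Weibull saturation law
y = A·(1 − exp(−(x/b)^c)); eRNA–gene association uses the nearest TSS
and Spearman correlation of FPKM profiles.

**Structure and enrichment.** Base-pair probability matrices are
computed exactly by inside–outside dynamic programming over a simple
pair+stacking energy model (validated elementwise against an
exhaustive enumeration oracle).  An SNV's structural impact is the
maximum over intervals containing the variant of the Euclidean
distance between wild-type and mutant matrices in a ±200-nt window,
with an empirical p-value against random same-window SNVs; riboSNitch
calls use p < 0.2.  SNP-set enrichment in genomic loci uses strong-LD
expansion (r² > 0.8, one hop) and a permutation null that relocates
length-matched loci uniformly within the domain.

## Worked example

```bash
python examples/discover_and_classify.py
```

```
consensus H3K27ac peaks : 57
candidates after cascade: 50 (planted: 50)
decoys removed per criterion: c1=1, c2=1, c3=1, c4=1, c5=1, c6=1, c7=1

eRNA regions            : 17 of 50 (34.0%)
tag threshold           : 19 (max count in the weak cluster)
cluster medians         : 127 (eRNA) / 4 (weak)
corrected threshold for a 2x-deeper library: 60
```

All 50 planted enhancers survive the cascade while each decoy is
removed by exactly the criterion it was built to violate.  The
two-component tag mixture (calibrated to medians 123/4 with a 0.353
transcribed fraction) is recovered by the classifier: the eRNA cluster
median lands at 127 and the derived tag threshold at 19 for this seed.
The other examples cover saturation fitting
(`saturation_analysis.py`: fits A = 455 ± 1 against a planted
asymptote of 500), SNP enrichment (`snp_enrichment.py`: fold 9.0,
permutation p = 1.0e-4 at the add-one floor) and riboSNitch scoring
(`ribosnitch_scan.py`: stem-breaking variants rank above loop variants
with AUC 1.0).

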