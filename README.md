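# epimark

Developmental histone-modification ChIP-seq analysis for small genomes and
time courses: depth-normalized fragment-midpoint coverage, a Poisson
sliding-window enrichment caller with mock-IP control subtraction,
TSS metaprofiles, normalized interval occupancy, and classification of
genes into developmental epigenetic signatures — plus a seeded synthetic
study generator so the whole pipeline is testable without sequencing data.

## The problem

During terminal differentiation (the motivating system is the maturing
mouse retina, profiled at E17.5, PN1, PN7 and PN15), activation-associated
H3K4me2 and repression-associated H3K27me3 rearrange around transcription
start sites. Interesting gene groups include genes carrying *neither* mark
at any stage, cell-type-specific genes that gain H3K4me2 *de novo* late in
development while never acquiring H3K27me3 (the rod-photoreceptor
signature), and genes that keep high H3K27me3 with lower H3K4me2
(non-rod retinal signature). A mutant lacking the relevant cell type
(*rd1*, which loses rod photoreceptors) serves as a subtraction control.

## The model

Every uniquely mapped read is reduced to the midpoint of its inferred
190-bp fragment. Midpoints are counted in 100-bp half-open bins and
depth-normalized to 5,000,000 mapped reads. For a genomic interval of
length L kb in a library of N mapped reads with k midpoints inside,

    occupancy = k x 5,000,000 / (N x L)        [reads / kb / 5M reads]

**Enrichment calling.** Windows (default 100 bp at a 100-bp pace) are
tested against X ~ Poisson(lambda), lambda the genome-wide mean midpoint
count per window; windows with upper-tail P(X >= k) strictly below 1e-5
are significant, and overlapping/abutting significant windows merge into
regions. A region is discarded when the anti-GFP mock-IP control is itself
significantly enriched over the same span.

**No-mark screen.** The background b is the mean mock-IP occupancy over
all TSS +/- 2.5 kb windows and stages. A gene whose 8-dimensional
(2 marks x 4 stages) occupancy row has Euclidean norm below sqrt(8) x b is
a no-mark gene; with the study's b = 9.12 the cutoff is 25.80.

**Signatures.** Deterministic rules in units of b (precedence NO_MARK >
ROD_SPECIFIC > NONROD_RETINAL > UBIQUITOUS > OTHER), average-linkage
hierarchical clustering (Euclidean or uncentered correlation) as the
unsupervised alternative, and classic pooled-variance two-sample t-tests
for promoter-vs-gene-body and wt-vs-*rd1* comparisons.

## Worked example

```python
import pathlib
from epimark import (SimConfig, emit_fixture_set, load_fixture,
                     build_occupancy_matrix, interval_matrix,
                     gfp_background, classify_signatures, compare_genotypes)

workdir = pathlib.Path("demo")
emit_fixture_set(SimConfig(seed=7), workdir / "fixture")
fx = load_fixture(workdir / "fixture" / "manifest.yaml")

tss_wt = build_occupancy_matrix(fx.genotype_samples("wt"), fx.genes, "tss",
                                chrom_sizes=fx.chrom_sizes)
gfp = interval_matrix({f"GFP_{s}": c for s, c in fx.controls.items()},
                      fx.genes, "tss", chrom_sizes=fx.chrom_sizes)
b = gfp_background(gfp)
labels = classify_signatures(tss_wt, b)
print("background b =", round(b, 2))
print(labels["label"].value_counts().to_string())

tss_rd1 = build_occupancy_matrix(fx.genotype_samples("rd1"), fx.genes, "tss",
                                 chrom_sizes=fx.chrom_sizes)
rod = labels.index[labels["label"] == "ROD_SPECIFIC"]
res = compare_genotypes(tss_wt, tss_rd1, rod, "H3K4me2_PN15")
print(f"rod H3K4me2 PN15: wt/rd1 fold = {res.fold:.2f}, "
      f"t = {res.test.t:.1f}, p = {res.test.p:.2e} {res.test.stars}")
```

prints

```
background b = 313.91
label
OTHER             52
UBIQUITOUS        50
NONROD_RETINAL    50
NO_MARK           50
ROD_SPECIFIC      48
rod H3K4me2 PN15: wt/rd1 fold = 2.56, t = 37.2, p = 5.47e-58 ***
```

The synthetic cohort plants 50 genes per class (the `OTHER` bucket absorbs
the planted "down-regulated" class plus borderline genes), and the
classifier recovers them from the occupancy matrix alone. Rod-specific
genes show the expected >2-fold H3K4me2 loss in the rod-less *rd1*
genotype; b is on an arbitrary scale set by the fixture's depth.

The same steps are available from the shell:

```
epimark simulate --seed 7 --out demo/fixture
epimark occupancy --manifest demo/fixture/manifest.yaml --interval tss --out occ.tsv
epimark callpeaks --reads demo/fixture/H3K4me2_PN15_wt.bed \
    --control demo/fixture/GFP_PN15.bed \
    --chrom-sizes demo/fixture/chrom.sizes --out regions.bed
```

and `epimark run --config pipeline.yaml` orchestrates everything (tracks,
regions, matrices, labels, comparisons, metaprofile, run log).

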