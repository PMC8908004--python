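# knobscan

Heterochromatic knobs — cytologically visible blocks of 180-bp/TR-1 satellite
heterochromatin on maize chromosomes — segregate like co-dominant bi-allelic
Mendelian loci. `knobscan` treats knob presence/absence at four variable
positions (K3L, K5L, K7S, K9S; "K" + chromosome + arm) as a four-marker
genotype panel and asks whether knob constitution associates with flowering
time or genome size in a panel of inbred lines and their F1 hybrids. It is a
library for quantitative geneticists and maize cytogeneticists who want a
small, fully reproducible marker-trait pipeline: a synthetic-data generator
standing in for the field panel, entry-mean (BLUE) and heritability
estimation, an exact single-locus mixed linear model under two marker
encodings, and a permutation-based family-wise significance threshold.

## The model

Each knob locus is scored as the number of knob-presence alleles (0/1/2).
Entry means y (BLUEs; under a completely randomised design, replicate means)
enter the mixed linear model

```
y = Sα + Pβ + Kυ + ε,   υ ~ N(0, K σg²),   ε ~ N(0, σe² I)
```

where S holds the marker code under one of two encodings —

* **allele substitution (additive)**: copies of the minor allele, 0/1/2,
  testing a linear dose effect;
* **heterozygous (dis)advantage (dominance)**: 1 for heterozygotes, 0 for
  both homozygotes, testing a heterozygote-specific effect;

P holds population-structure covariates (optional principal components of
the marker matrix and, by default in mixed panels, the line/hybrid
contrast — heterosis shifts the hybrid group mean and would otherwise be
absorbed by the heterozygote indicator), and K is the VanRaden genomic
relationship matrix built from the knob counts. Variance components are
estimated by REML (eigendecomposition of K plus a one-dimensional search
over σg²/σe², re-estimated exactly for every marker by default) and each
marker gets a Wald t test on n − p degrees of freedom. Significance is
declared against a resampling threshold: phenotypes are shuffled against the
fixed genotype structure, each shuffle is rescanned, the minimum p-value is
recorded, and the 95% quantile of the best scores (the 5% quantile of the
minima) becomes the threshold.

The reference analysis of this design used the FarmCPU package; with only
four markers FarmCPU's iterative pseudo-QTN selection degenerates, so
`knobscan` implements the exact single-locus mixed model that the equation
above specifies instead.

The synthetic generator reproduces the study conditions: lines selfed to S9
from a single segregating seed (residual heterozygosity 0.5⁹ per locus),
35 hybrids crossed between 8 parent lines, a completely randomised design
with 3 replicates per line and 5 per hybrid (assay 1; assay 2 is 20 lines ×
5), one causal locus (K9S, additive −0.45/−0.51 d and dominance −1.40/−1.53 d
on male/female flowering), heterosis as a group-mean shift (hybrids flower
~7 d earlier), entry-mean heritabilities 0.51/0.41/0.26 (MF/FF/GS), a
MF–FF correlation near 0.95, and genome size with no knob effect.

## Worked example

```python
import knobscan as ks
from knobscan.phenotypes import blues_frame

params = ks.GeneratorParams(seed=1)          # assay-1 defaults
panel = ks.generate_panel(params)            # 8 lines + 35 hybrids
records = ks.simulate_phenotypes(panel, params)   # 199 plants
blues = blues_frame(records, [e.entry_id for e in panel])

spec = ks.AssociationModelSpec(encoding="dominance")
results = ks.run_scan(panel, blues["ff"], spec, trait="ff")
report = ks.permutation_threshold(panel, blues["ff"], spec,
                                  n_perm=200, seed=1, trait="ff")
print(ks.apply_threshold(results, report))
```

prints (abridged)

```
locus_id    maf  effect     se  p_value  marker_h2  significant
     K3L 0.4419  0.0247 0.4972   0.9606     0.0000        False
     K5L 0.3023 -0.3266 0.5955   0.5864     0.0014        False
     K7S 0.4419  0.8374 0.4615   0.0771     0.0106        False
     K9S 0.3488 -1.7277 0.4767   0.0008     0.0415         True
```

Only K9S — the locus the generator made causal — clears the permutation
threshold (0.0085 here): its heterozygotes flower ~1.7 d earlier than
homozygotes (generating value −1.53 d), while the three null knobs stay
non-significant. `effect` is per knob-presence allele (additive) or per
heterozygous genotype (dominance); `maf` is the minor-allele frequency, or
the heterozygote frequency in dominance rows; `marker_h2` is the fraction of
phenotypic variance the marker explains. The scripts in `examples/` walk
through panel simulation, BLUEs/heritability, both scan encodings and the
flow-cytometry genome-size arithmetic (2C pg from G0/G1 peak ratios against
an internal standard; 1 pg = 978 Mbp, so 5.6 pg ↔ 5477 Mbp and
5.4 pg ↔ 5281 Mbp).

A thin CLI wraps the same stages:

```
knobscan simulate --out-prefix run --seed 1
knobscan blues --genotypes run_genotypes.csv --phenotypes run_phenotypes.csv --out blues.tsv
knobscan scan --genotypes run_genotypes.csv --blues blues.tsv --trait ff --out scan.tsv
knobscan threshold --genotypes run_genotypes.csv --blues blues.tsv --encoding dominance --trait ff --seed 1 --out perm.tsv
knobscan report --seed 1 --out-dir out/     # full pipeline
```

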