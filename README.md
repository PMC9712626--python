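# irtax

Analysis toolkit for **cytoplasmic intron retention** in nucleus/cytoplasm
fractionated differentiation time courses, built around a spatiotemporal
taxonomy of retained introns.

During human motor neurogenesis many polyadenylated transcripts retain
specific introns, and a surprising fraction of these intron-retaining
transcripts (IRTs) is detected in the cytoplasm, not just the nucleus.
Working from percent-intron-retention (PIR) matrices quantified per intron
and sample, `irtax` provides the downstream machinery to characterise this
phenomenon:

- **IR filtering and classification** — prevalence filtering (PIR > 10 % in
  ≥ 3 nuclear samples), nuclear vs cytoplasmic IRT calls
  (NIRT: PIR<sub>nucleus</sub> > 20 % and PIR<sub>cytoplasm</sub> < 5 %;
  CIRT: PIR<sub>nucleus</sub> > 20 % and PIR<sub>cytoplasm</sub> > 15 %),
  and ΔPIR ≥ 15 event calling between conditions.
- **SVD taxonomy** — singular value decomposition of each compartment's PIR
  matrix; introns are scored against right singular vectors v⃗<sub>k</sub>
  by Pearson correlation and projection, extremes are selected per component
  by k-means, and selections are assembled into nuclear (N) and cytoplasmic
  (C) groups with distinct retention dynamics.
- **CLIP cross-link enrichment** — five 30-nt windows anchored at the splice
  sites (R1: last 30 nt of the upstream exon, R2: first 30 nt of the intron,
  R3: intron middle, R4: last 30 nt of the intron, R5: first 30 nt of the
  downstream exon); per-group enrichment = fraction of group regions with
  ≥ 1 cross-link event over the background fraction, with one-sided Fisher
  exact tests, plus Ward/Manhattan clustering of enrichment profiles.
- **Intron features** — GC content, log-length, median per-base conservation,
  per-intron cross-link enrichment against non-retained introns of the same
  gene, and a nested-model ANOVA (full vs reduced OLS F-test) relating each
  feature to maximum PIR; a premature-termination-codon scan using the 50-nt
  rule.
- **Expression gating** — per-sample two-component Gaussian mixtures on
  log2(count + 1); a gene is reliably expressed in a condition when its
  posterior probability of the non-expressed component is < 1 % in every
  sample of the condition.
- **miRNA activity inference** — Welch t-tests of predicted-target log2FC
  shifts, one-sided Fisher tests of cross-contrast sign concordance,
  hypergeometric overlap tests, and a linear mixed-effects model
  (PIR ~ genotype + (1 | patient), REML) for group-level PIR shifts between
  genotypes.
- **Synthetic data** — a generator that emulates the study design
  (DIV 0/3/7/14/21/35 × {nucleus, cytoplasm} × 4 control + 3 mutant clones)
  with nine planted PIR archetypes, a unidirectional mutant perturbation at
  DIV 14, planted regional cross-link enrichments, bimodal expression and
  planted miRNA-target shifts — with ground-truth labels for every entity,
  so each stage has a parameter-recovery test.

## Worked example

Generate a synthetic study (50 introns per archetype) and run the full
pipeline:

```bash
irtax simulate --seed 7 --out demo/ --n-introns-per-group 50
irtax run --dir demo/ --out demo_run/ --seed 7
```

which prints the stage census

```
{
 "introns": 450,
 "samples": 84,
 "prevalent": 450,
 "cirt": 300,
 "nirt": 4,
 "assigned": 416,
 "expressed_genes": 3914
}
```

i.e. all 450 introns pass the nuclear prevalence filter, 300 are called
CIRTs (the six cytoplasmic archetypes), 4 NIRTs (nuclear archetypes whose
condition-mean cytoplasmic PIR drifts under 5 %), 416 introns are assigned
to a taxonomy group, and 3914 of 5200 genes pass the expression gate
(75 % are simulated as expressed). `demo_run/manifest.json` then reports
the genotype PIR shift per recovered cytoplasmic group at DIV 14
(effect in PIR points, mixed-model p):

```
C1  +0.90  p=0.17      C4  +15.54  p=1.2e-05
C2  +4.83  p=0.0051    C5  +0.18   p=0.78
C3  -0.82  p=0.042     C6  +3.65   p=0.020
```

One recovered group (here labelled C4 — group labels enumerate SVD
component/polarity cells, not archetype names) carries the planted +15 PIR
mutant increase of the early-transient archetype, and a second group the
smaller +5 shift — the unidirectional perturbation pattern. The same
manifest lists the RBPs significantly enriched in each group's cross-link
profile (the planted RBP–group pairs are recovered), and
`demo_run/mirna_activity.tsv` shows the planted miRNA target set shifting
up in the mutant contrast (Welch p ≈ 7e-22, concordance p ≈ 4e-22) while
the negative-control set stays flat (p ≈ 0.51).

Every stage is also callable as a library function or sklearn-style
estimator:

```python
from irtax.synthetic import SimConfig, simulate_pir
from irtax.taxonomy import SpatiotemporalTaxonomy

pir, truth = simulate_pir(SimConfig(seed=1))
tax = SpatiotemporalTaxonomy(n_components=3, seed=1).fit(
    pir.subset_samples(fraction="nucleus"),
    pir.subset_samples(fraction="cytoplasm"),
)
tax.labels_.value_counts()
```

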