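# supergene

Population-genomic analysis of a non-recombining **supergene region** from
whole-genome sequences of two groups of haploid males — the study design of
the fire ant *Solenopsis invicta* social chromosome, where the SB and Sb
haplotypes behave like a young X/Y pair (SB recombines in SB/SB queens; Sb
never recombines because Sb/Sb queens die).

The package is for population geneticists who want to detect and
characterise such a region from a variant table of haploid genotypes:

* **Differentiation scan** — multilocus F<sub>ST</sub> between the groups in
  sliding windows of accessible (non-N) sequence, computed as a
  Weir–Cockerham-style two-level variance decomposition of haploid allele
  indicators, combined across sites as a ratio of sums:
  F<sub>ST</sub> = Σa / Σ(a+b), with *a* and *b* the among- and within-group
  components. Negative values are meaningful (they arise when groups are
  composed of cross-group sibling pairs) and monomorphic windows are
  *undefined*, not zero.
* **Fixed differences** — sites where all SB males carry one allele and all
  Sb males another; the region is called as consecutive windows with
  F<sub>ST</sub> > 0.25.
* **Diversity** — Nei's nucleotide diversity π per group per window,
  π = Σ (n/(n−1))(1 − Σᵢpᵢ²) / accessible bp.
* **Coding divergence** — per-gene consensus sequences for each group built
  from fixed differences, Nei–Gojobori (1986) dN/dS with Jukes–Cantor
  correction, and a McDonald–Kreitman contrast of fixed vs polymorphic
  nonsynonymous:synonymous counts.
* **Evolutionary strata** — a scan for a contiguous block of ≥30 genes with
  lower divergence than the rest, assessed against a Poisson null
  (substitutions ~ Poisson(rate × coding length), default rate 1/3000 bp)
  by the empirical rank of the minimal Welch-test p-value.
* **Robustness** — permutation tests of the group labelling, and a
  synthetic-data generator that reproduces the study's statistical structure
  (8+8 brothers, a ~1 Mb low-diversity high-differentiation region in a
  diverse background) with a full ground-truth record, so every stage is
  testable without the original sequencing data.

## Worked example

Generate a synthetic study at the default densities (1 Mb supergene region
on a 6.5 Mb genome, fixed differences at 1.4/kb, background π = 8.2×10⁻⁴,
in-region π = 6.7×10⁻⁴ for SB and 1.3×10⁻⁶ for Sb) and run the pipeline:

```python
from supergene.synthetic import SimParams, simulate_dataset
from supergene.pipeline import PipelineConfig, run_all

paths = simulate_dataset(SimParams(seed=1), "sim")
report = run_all(PipelineConfig(
    vcf=paths["vcf"], fasta=paths["fasta"], gff=paths["gff"],
    markers=paths["markers"], strs=paths["strs"], samples=paths["samples"],
    outdir="sim/out", seed=1))
print(report["region"])
print(report["supergene_region"]["fst_mean"])
print(report["background"]["pi_SB_mean"])
```

prints (seed 1):

```
{'scaffold': 'scf_1', 'start': 999637, 'end': 2005106, 'length': 1005469, ...}
0.8174803086716863
0.0008253096995255667
```

— the planted 1 Mb region is recovered to within one 30 kb window
(length ratio 1.005), its mean window F<sub>ST</sub> is ≈0.82, and the
background diversity estimate lands within 1% of the generating value.
The same report carries the fixed-difference density (1.35/kb after
filtering), the McDonald–Kreitman table for genes in the called region,
the strata-scan empirical p, and the label-permutation p-value.

The published contingency tables can be checked directly:

```bash
supergene mk-test --counts 374 417 209 490
# {"chi2": 46.345..., "df": 1, "p": 9.9e-12, "neutrality_index": 0.4756}
```

A `supergene` console script exposes each stage
(`simulate`, `filter-variants`, `map`, `windows`, `divergence`, `mk-test`,
`scan-strata`, `call-region`, `permute`, `run-all`).

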