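# inherimet

Inheritance-mode analysis of metabolite abundances and gene expression in
factorial cross designs.

## The problem

Plant breeders who sell F1 hybrid varieties need to know how a trait in the
hybrid relates to the trait in its two inbred parents: does it sit at the
midparent (additive), at one parent (dominant/recessive), or beyond the
parental range (over-dominant/over-recessive, i.e. transgressive)?  For
fruit-quality metabolites — aroma volatiles, polyphenols, soluble solids —
transgressive hybrids are the prize, and whether the cross direction
(which line is the seed parent) matters is a practical question too.

`inherimet` implements the statistical pipeline for such a study: a
factorial design of inbred parental lines and their F1 hybrids (including
reciprocal pairs), phenotyped over replicate harvests for tens of
metabolite traits, with bulk RNA-seq counts on the same samples.

## The core statistic

For each cross (parents P1, P2 and their hybrid F1) and each variable, the
mode of inheritance is classified from the **D/A ratio** (potence ratio).
With the parents oriented so the high parent is HP:

```
A = (μ_HP − μ_LP) / 2          additive component  (A ≥ 0)
D = μ_F1 − (μ_P1 + μ_P2) / 2   dominance component
```

A one-way ANOVA across the three genotypes gates the call (no significant
genotype effect at α = 0.05 → `ns`); otherwise the ratio D/A falls into
five bands:

| D/A            | mode | meaning                        |
|----------------|------|--------------------------------|
| < −1.2         | OR   | over-recessive (below low parent) |
| [−1.2, −0.8]   | R    | recessive (at low parent)      |
| (−0.8, 0.8)    | A    | additive (near midparent)      |
| [0.8, 1.2]     | D    | dominant (at high parent)      |
| > 1.2          | OD   | over-dominant (above high parent) |

Around this sit: per-trait genotype ANOVA and broad-sense heritability
h² = σ²G/(σ²G+σ²e) from REML variance components; Spearman trait
correlations and bootstrap-supported trait clustering; reciprocal-hybrid
t-tests for maternal effects; CPM filtering, TMM normalization and
differential expression across all genotype contrasts; and WGCNA-style
co-expression modules whose eigengenes are correlated with traits, with
hypergeometric annotation enrichment and gene–trait concordance reports.

A fully seeded synthetic-data generator produces factorial-design trait and
count matrices with known ground truth (true modes, heritabilities,
maternal shifts, module structure), so every stage has a recovery test.

## Worked example

```python
from inherimet.inheritance import classify_cross

call = classify_cross(
    [10.0, 10.1, 9.9],   # parent 1 replicates
    [20.0, 20.1, 19.9],  # parent 2 replicates
    [8.0, 8.1, 7.9],     # F1 replicates
)
print(f"mode={call.mode}  A={call.a_comp:.3f}  D={call.d_comp:.3f}  "
      f"D/A={call.ratio:.3f}  gate_p={call.gate_p:.2e}")
```

prints

```
mode=OR  A=5.000  D=-7.000  D/A=-1.400  gate_p=1.42e-11
```

The parents differ by 10 units (A = 5), the hybrid sits 7 units below the
midparent (D = −7), so D/A = −1.4 < −1.2: the hybrid transgresses below
the low parent — over-recessive inheritance.

From the shell, a full synthetic round trip:

```sh
inherimet simulate --seed 3 --outdir syn
inherimet inherit --design syn/design.tsv --traits syn/traits.tsv --outdir res
```

writes per-(cross, variable) calls, the per-cross stacked mode-count table
and per-variable transgression/consistency flags as TSV.  `inherimet run
--config cfg.yaml` executes every stage (traits → inheritance → maternal →
DEG → modules → concordance) and records a manifest with seeds, thresholds
and output hashes.

### Input formats

All inputs are tab-separated UTF-8 with a header row:

* **design file** — columns `genotype`, `role` (`parent`|`hybrid`),
  `female_parent`, `male_parent`, `species_class`; reciprocal pairs are
  auto-detected from swapped parent columns;
* **trait matrix** — first column sample ID, one column per trait, plus a
  sidecar `<name>.samples.tsv` with `sample`, `genotype`, `harvest`;
* **count matrix** — genes × samples of raw integer counts;
* **annotation map** — two columns (term, gene) for enrichment.

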