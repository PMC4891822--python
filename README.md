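# srnakit

Small-RNA sequencing analysis for two-condition plant miRNA studies:
from raw adapter-ligated reads to regulation calls, with a fully
synthetic, ground-truthed data generator for end-to-end validation.

The package is aimed at the classic experimental design with one sRNA
library per condition (e.g. hormone-treated vs control leaves) and no
replicates. It implements the complete analysis such studies report:

- **read cleaning** — 3' adapter trimming (seed-and-extend), 15–30 nt
  length window, poly(A)/N filters, collapsing into unique tags with
  per-library counts and a full rejection tally;
- **annotation** — substitution-only genome mapping (≤2 mismatches, both
  strands) and a mutually exclusive category cascade (miRNA > rRNA > tRNA
  > snRNA > snoRNA > repeat > exon > intron > un-annotated) that exactly
  partitions each library, plus length histograms;
- **miRNA identification** — matching against a mature-miRNA database
  (≤2 substitutions, length ±2 nt) and novel-hairpin discovery from
  un-annotated tag clusters under six qualification criteria (un-annotated
  origin; mature on one arm of the stem-loop; 2-nt 3' overhang
  mature/miRNA* duplex; ≤4 duplex mismatches and no bulge >2 nt; fold
  energy ≤ −18 kcal/mol; ≥5 supporting reads);
- **differential expression** — TPM normalisation, the exact conditional
  count test, and a five-way regulation classification;
- **target prediction** — plant-style penalty scoring (mismatch 1, G:U
  wobble 0.5, positions 2–13 doubled, cutoff 4) with per-gene collapsing;
- **qPCR validation** — stem-loop qRT-PCR ΔCt (vs the U6 control) and
  directional concordance with the sequencing fold changes;
- **simulation** — a seeded generator producing genome + GFF3 features +
  hairpin loci + two FASTQ libraries with known per-locus expected counts
  and regulation tiers.

## The statistic at the core

For a miRNA with `x` reads among `N1` clean reads in the control library
and `y` among `N2` in the treatment library, expression is compared on the
TPM scale (`count / N × 10⁶`, zeros replaced by 0.01 for fold-change
display only) and tested with the exact conditional probability

    p(y|x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1 + N2/N1)^(x+y+1) )

— the probability of observing `y` treatment counts given `x` control
counts under Poisson tag sampling (equivalently, NB(y; x+1, N1/(N1+N2))).
It is evaluated in log space via log-gamma; the default p-value is the
doubled smaller tail. Calls are classified as *significantly up/down*
(|log₂FC| ≥ 1 and p < 0.05), *slightly up/down* (0.25 ≤ |log₂FC| < 1) or
*unobviously regulated*, after removing miRNAs below 2 TPM in both
libraries.

## Worked example

```python
from srnakit.diffexpr import DiffExprPair, audic_point_mass, audic_pvalue, profile_table

N1 = N2 = 1_000_000
audic_point_mass(5, 5, N1, N2)            # 0.123046875  (= 252/2048)
audic_pvalue(DiffExprPair(100, 200, N1, N2))  # 8.01e-09

profile_table({"strong_down": (800, 150), "slight_up": (600, 840),
               "control_only": (120, 0), "flat": (500, 505)}, N1, N2)
```

prints

```
        mirna  count_c  count_t  tpm_c  tpm_t   log2fc       p_value           category exclusive_flag
 control_only      120        0  120.0   0.01 -13.5507  7.523164e-37 significantly_down   control_only
         flat      500      505  500.0 505.00   0.0144  8.996007e-01          unobvious         shared
    slight_up      600      840  600.0 840.00   0.4854  2.746727e-10        slightly_up         shared
  strong_down      800      150  800.0 150.00  -2.4150 4.869424e-108 significantly_down         shared
```

`strong_down` crosses both the fold-change and significance thresholds;
`slight_up` changes by less than two-fold, so it is a *slight* call
regardless of its p-value; `control_only` vanishes under treatment (the
0.01 TPM substitute produces the large negative log₂FC); `flat` moves by
|log₂FC| < 0.25 and is unobvious. A pair like (2, 0) shows why both
conditions matter: log₂FC = −7.6 but p = 0.25, so it is *unobvious*, not
significant.

The `examples/` directory has one short script per capability
(simulation, cleaning + annotation tables, novel-hairpin discovery,
differential expression, targets + qPCR), each printing the numbers it
computes. A thin CLI covers the file-based pipeline:

```bash
srnakit simulate --seed 7 --depth 200000 -o dataset/
srnakit all -c pipeline.yaml -o run/
```

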