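# masikit

Mutant-allele-specific-imbalance (MASI) inference for diffuse midline
glioma, H3 K27M-mutant.

In most tumors a heterozygous driver mutation sits at a 1:1 ratio with its
wild-type allele. Some tumors instead amplify the mutant allele and/or lose
the wild-type allele — mutant allele specific imbalance. For the *H3F3A*
K27M mutation that defines diffuse midline glioma, MASI shows up as a
droplet-digital-PCR variant allele frequency (VAF) well above 50%, and is
associated with higher Ki-67, lower H3K27me3 and poorer survival.

`masikit` turns the routine measurements of such a case — ddPCR droplet
counts, 10-kb binned WGS read depth, common-SNP allele counts, and
immunofluorescence cell counts — into the allelic chromosomal-structure
model of the locus that best explains them, and validates that model by
back-calculating tumor purity. It is aimed at analysts working with
low-throughput, per-case molecular pathology data.

## The model

A specimen is a mixture of one tumor clone (fraction *p*) and normal
diploid cells. The tumor clone carries an allelic configuration at the
locus: *N* total copies split *a*:*b* across the parental haplotypes
(*a* ≥ *b*), with all *M* mutant copies on one haplotype
(*W* = *N* − *M* wild-type copies). Normal cells contribute two wild-type
copies, one per haplotype. Then

```
VAF(p)  =  p·M / (p·N + 2(1 − p))                 (ddPCR observable)
BAF(p)  =  (p·a + (1 − p)) / (p·N + 2(1 − p))     (major-haplotype SNP allele frequency)
p(VAF)  =  2·VAF / (M + 2·VAF − VAF·N)            (purity back-calculation)
```

Model selection follows a two-stage screen. Candidate total copy numbers
come from the WGS segment mean (the nearest integer, plus one more copy
when the mean exceeds two or one fewer when below — normal-cell admixture
pulls the apparent copy number toward two). Every haplotype split and
mutation phasing is enumerated; the two configurations whose expected BAF
best matches the mirrored SNP-BAF band are shortlisted; among those the
configuration whose expected VAF best matches the ddPCR VAF is selected,
and its back-calculated purity is compared with the IHC tumor content
(H3 K27M-positive / DAPI-positive nuclei) for validation.

## Worked example

The observations of the strongest published case (VAF 73.2%, upper-band
BAF 91.0%, three-or-more 1q copies, tumor content 64.2%) ship with the
package:

```python
from masikit import RunConfig, run_case
from masikit.io import load_printed_cases

obs, totals = load_printed_cases()["case5"]
report = run_case(RunConfig(), observations=obs, candidate_totals=totals)
print(report["selected"])
```

prints

```
{'label': '3 mutant / 0 wild-type (total 3, split 3:0, mutant on major)',
 'total_cn': 3, 'major': 3, 'minor': 0, 'mutant_on': 'major',
 'mutant_copies': 3, 'wild_copies': 0, 'is_masi': True,
 'expected_baf_pct': 86.4, 'expected_vaf_pct': 72.9,
 'backcalc_purity_pct': 64.6, 'validated': True}
```

Read: of all one-copy-loss/gain models of 1q, three mutant copies without
the wild-type allele fits best — its expected SNP BAF (86.4%) is closest to
the observed band and its expected VAF (72.9%) is closest to the measured
73.2%; inverting the VAF relation under this model gives 64.6% tumor
content, consistent with the 64.2% counted by IHC, so the model is
validated. The same call works from raw tables (droplet amplitudes, binned
coverage, SNP counts, IHC fields), and the `masikit` command line exposes
each stage (`simulate`, `ddpcr`, `cnv`, `baf`, `model`, `cohort`).

Synthetic cases with known ground truth are first-class:

```python
from masikit import AllelicConfiguration, SyntheticTruth, simulate_case

truth = SyntheticTruth(config=AllelicConfiguration(3, 3, 0), purity=0.642, seed=7)
bundle = simulate_case(truth)   # coverage, SNPs, droplets, IHC fields
```

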