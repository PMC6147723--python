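# cmahtype

Genotype-based blood typing for the feline AB blood group system.

Domestic cats carry one of three blood types — A, B and C (the system is
historically called "AB") — determined by *CMAH*, the enzyme that converts
the sialic acid NeuAc (the B antigen) into NeuGc (the A antigen).
Mismatched transfusions and type-B queens nursing type-A/C kittens cause
hemolysis through naturally occurring anti-A alloantibodies, so breeders
and clinical laboratories need to detect the recessive `b` and `a^c`
alleles that serology cannot see in heterozygotes. `cmahtype` implements a
DNA screening workflow for this system: a catalog of the known *CMAH*
nsSNV/indel variants and their haplotype backgrounds, deterministic
genotype-to-phenotype calling, compound-heterozygote (diplotype)
resolution, concordance accounting, Hardy–Weinberg allele-frequency
estimation, Mendelian offspring prediction with neonatal-isoerythrolysis
(NI) risk, and a seeded cohort simulator.

## The model

Blood type follows a three-allele dominance hierarchy, *A* > *a^c* ≥ *b*:

| genotype | phenotype |
|---|---|
| *A/A*, *A/b*, *A/a^c* | A |
| *b/b* | B |
| *a^c/a^c*, *a^c/b* | C |

Each non-functional allele is tagged by one causal *CMAH* variant:
c.268T>A (most breeds), c.179G>T (Turkish breeds), c.1322delT (Ragdoll),
c.933delA and c.1193G>A (rare, domestic shorthair) define `b` haplotypes;
c.364C>T defines the partial-activity `a^c` haplotype (Ragdoll). The
typing rule counts alternate-allele dosage `b` over the b-associated loci
of a scheme and `ac` at c.364C>T, then calls

* **A** if `b + ac ≤ 1`, **C** if `ac ≥ 1` and `b + ac ≥ 2`, **B** otherwise,

with unresolved calls when missing genotypes leave the phenotype
undetermined. Four schemes are built in: the historical two-marker rule
(`legacy2`: c.142G>A + Δ-53), the three-marker assay panel (`snv3`), the
proposed four-variant causal panel (`scheme4`) and its six-variant
extension (`extended6`).

Under Hardy–Weinberg the phenotype frequencies are `f_B = p_b²`,
`f_C = p_ac² + 2·p_ac·p_b`, `f_A = 1 − f_B − f_C`, giving the closed-form
maximum-likelihood estimator `p_b = √(n_B/N)`,
`p_ac = √((n_B+n_C)/N) − p_b` from a phenotype count triple (an EM
estimator over latent genotypes is included as an independent check).

## Worked example

Estimate allele frequencies from the study cohort's phenotype counts
(255 A, 146 B, 20 C):

```sh
$ cmahtype estimate --counts 255,146,20
{
  "method": "closed-form HWE MLE from phenotype counts",
  "n": 421,
  "p_A": 0.3720674499510904,
  "p_b": 0.5888916276944732,
  "p_ac": 0.03904092235443635
}
```

About 59% of alleles in this (breed-biased) cohort are `b` and 4% are
`a^c`. Score a mating of a type-B queen with a homozygous type-A sire:

```sh
$ cmahtype mendel --dam b/b --sire A/A
dam b/b (type B) x sire A/A (type A)
offspring genotypes:
  A/b: 1.0000
offspring phenotypes:
  A: 1.0000
  B: 0.0000
  C: 0.0000
NI risk: YES (p_incompatible=1.0000) — type-B dam: strong anti-A alloantibodies expected
```

Every kitten is an *A/b* carrier of type A, and all of them are at NI risk
from the dam's anti-A colostral antibodies. Blood-type a genotype table
(tab-separated, two-character genotype cells such as `GA`, `T*`, `NP`):

```sh
$ cmahtype fixtures --table 3 --expand --out cohort.tsv
$ cmahtype type --scheme scheme4 --in cohort.tsv --out calls.tsv
$ cmahtype concord --scheme scheme4 --in cohort.tsv
# scheme=SCHEME4 n=353 accuracy=0.9943
...
```

The 0.9943 is the four-variant panel's accuracy on the 353 records of the
built-in genotyped A/B cohort: every cat is typed correctly except one
whose causal variant (c.1193G>A) is outside the four-variant panel and one
type-B cat with no *CMAH* variant found — a documented limit of the
scheme, not a bug.

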