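# Methods

## Genetic model

The feline AB blood group is treated as a single biallelic-per-haplotype
system with three allele classes: the functional wildtype *A*, fully
non-functional *b* alleles, and the partial-activity *a^c* allele.
Dominance is *A* > *a^c* ≥ *b*: any *A* allele gives type A, *b/b* gives
type B, and *a^c* paired with *a^c* or *b* gives type C. Each *b* or
*a^c* allele is assumed to be tagged by exactly one causal *CMAH* variant
(c.268T>A, c.179G>T, c.1322delT, c.933delA or c.1193G>A for *b*;
c.364C>T for *a^c*), and each haplotype background in the catalog carries
exactly one of them. Non-causal variants (e.g. c.142G>A, the Δ-53 indel,
c.139C>T) are catalogued with their protein effect but never drive a call;
their phase on the published backgrounds is not fully determined, so the
haplotype definitions leave them unconstrained rather than guessing.

Coordinates are cDNA positions counted from the ATG in exon 1a (GenBank
EF127684.1). The alternate exon-1b transcript numbering (all positions
shifted by −3) is recorded in the catalog's `numbering_note` only.
Deletion alleles use `*` as the alternate allele character and the 18-bp
upstream indel Δ-53 is coded presence/absence (`P`/`N`), so every genotype
is a two-character cell and the published tables transcribe verbatim.

## Typing rule

For a scheme with b-associated loci L_b and the a^c locus c.364C>T, let
`b` = total alternate-allele dosage over L_b, `ac` = dosage at c.364C>T.
The call is A if `b + ac ≤ 1`, C if `ac ≥ 1` and `b + ac ≥ 2`, else B.
The genotype label caps the combined dosage at the two available
haplotypes; a raw dosage above two (three causal alleles, observed once in
a Scottish Fold genotype) keeps the B call and attaches a
possible-cis-configuration warning. Heterozygosity for c.179G>T in an
otherwise type-A genotype attaches a "possible type C" warning — a
hypothesis about antigen co-expression, deliberately never promoted to a
C call.

**Missing data.** A call with missing scheme loci is emitted only when it
is *forced*: every completion of the missing genotypes (each missing locus
contributing 0–2 further *b* alleles; a missing c.364C>T possibly
contributing *a^c* alleles) yields the same phenotype. Otherwise the
sample is `unresolved`, which concordance accounting treats as discordant.
This is deliberately conservative: `b=2` with c.364C>T untyped is
unresolved because a hidden *a^c* allele would flip B to C.

**Legacy schemes.** The historical two-marker rule is reconstructed as
"B iff c.142G>A is homozygous alternate or Δ-53 is homozygous present";
neither marker is causal, and the rule exists to quantify the error of the
old screening practice (12 of the 243 tabulated type-A cats mis-typed).
The three-marker panel calls B iff c.268T>A is homozygous alternate, with
c.142/Δ-53 carried as divergence annotations only. A type-B cat in which
no *CMAH* variant was found is necessarily called A by every scheme; this
known false call is documented, not patched.

## Diplotype resolution

`enumerate_compatible_diplotypes` exhaustively pairs catalog haplotypes
(unordered, with replacement) and keeps pairs whose combined alleles
reproduce the observed genotype at every called causal locus; uncalled
loci are unconstrained. Strict mode places co-occurring heterozygous
causal variants in trans (compound heterozygosity), mirroring the
published backgrounds; `allow_cis` additionally enumerates the 2^6
synthetic backgrounds over the causal loci so that three-causal-allele
genotypes are explainable. A synthetic background carrying both c.364C>T
and a *b*-class variant is labeled *b* (complete loss of function
dominates partial activity); that configuration is a modeling convenience,
not an observed haplotype. The enumerator is the package's independent
oracle: over all 81 four-locus genotypes, wherever it is non-empty and
unanimous its phenotype must (and does) match the rule engine.

## Frequency estimation

Under Hardy–Weinberg, `f_B = p_b²` and `f_B + f_C = (p_b + p_ac)²` are
monotone one-to-one in `p_b` and `p_b + p_ac`, so the multinomial MLE from
a phenotype count triple is the closed form `p_b = √(n_B/N)`,
`p_ac = √((n_B+n_C)/N) − p_b`. Boundary counts give exact boundary
estimates (no continuity correction; interval estimation is delegated to
the percentile bootstrap, default 1,000 replicates, seed required). The
EM estimator apportions n_A among A/A, A/b, A/a^c and n_C among a^c/a^c,
a^c/b by current posteriors and re-counts alleles; it is retained purely
as an independent numerical check (agreement to 1e−6 is asserted in the
tests) and for its monotone log-likelihood property. Estimation is also
available by direct allele counting from rule-engine genotype labels, with
unresolved samples excluded and counted.

The cohort behind the worked example is a diagnostic-laboratory
convenience sample with deliberately over-represented B and C cats;
frequency estimates on it are illustrative of the estimator, not
population claims.

## Mendelian prediction

Offspring distributions are exact Punnett enumeration with `Fraction`
probabilities (each parent transmits either allele with probability ½,
independently). Neonatal-isoerythrolysis risk is flagged only for type-B
dams — type-B cats consistently carry strong anti-A alloantibodies — as
the probability that an offspring is type A or C. Anti-B alloantibodies
in type-A dams are rare and weak; that mating pattern yields a
low-severity note, never a flag.

## Synthetic cohorts

`simulate_cohort` draws, per cat, a breed from `breed_mix` and two
haplotypes i.i.d. from the breed's haplotype frequencies; genotypes at
every catalog locus are the allele unions (unconstrained loci default to
reference), and the true phenotype follows the dominance map. Genotyping
error, off by default, replaces a locus's genotype with one of the other
two genotypes uniformly at random — the simplest symmetric per-locus
model, provided as a robustness knob rather than an error-process claim.
The bundled breed profile is illustrative and non-biological: it
qualitatively mirrors a European case mix (b-rich British Shorthair,
*a^c* confined to Ragdolls, c.179G>T in Turkish Angora plus rare DSH
carriers). Because simulated genotypes are generated from the same causal
model the caller assumes, error-free cohorts are typed with accuracy
exactly 1.0 by the six-variant panel — this validates internal
consistency, not performance on real cats, where unknown variants (the
unexplained type-B cat above) and assay artifacts exist. Parameter
recovery and goodness-of-fit tests run at n = 10,000 with fixed seeds and
3-standard-error / p > 0.001 bands.

## Fixtures and known data inconsistency

The built-in tables are transcribed as printed. The three-marker
diplotype table's type-A counts sum to 243 (grand total 353) while the
narrative counts 241 (total 351); the package keeps the table as the
source of record and reports percentages against both denominators
(38 divergent type-A cats = 15.6% of 243 or 15.8% of 241). The full-panel
view of that cohort fills the loci not assayed there (c.179G>T, c.364C>T,
c.1322delT, c.933delA, c.1193G>A) with explicit homozygous-reference
calls except where the table's comment column states a variant — the
screened cats carried no other known causal variant — so the four- and
six-variant schemes see complete genotypes rather than missing data.

## Limitations

* The catalog is breed-panel knowledge, not discovery: a type-B or C cat
  whose causal variant is absent from the catalog will be mis-called A,
  exactly as the unexplained type-B cat in the built-in cohort is.
* Heterozygous c.179G>T as a cause of type C remains a warning-level
  hypothesis.
* No statistical phasing, pedigree inference, HWE testing or multi-breed
  joint modeling; the simulator draws haplotypes i.i.d. within breed and
  ignores linkage to non-causal variants.
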