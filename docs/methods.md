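# Methods

## Model and assumptions

The package treats each annotated alternate allele as a biallelic
autosomal marker: zygosity per individual is wt / het / hom-alt / missing,
missing is first-class and never imputed, and coordinates are 1-based
VCF-style. The disease model throughout is fully recessive with a
penetrance parameter: an individual is affected if homozygous for the
causal allele (subject to penetrance) or by an independent phenocopy draw.
X-linked, mitochondrial and dominant models are out of scope, as is
statistical phasing — phase is only ever deduced from pedigree structure.

Pedigrees are directed acyclic parentage graphs; connected components are
taken over the undirected parent–child relation, so two families joined by
a shared ancestor (as F24 and F54 are) form a single component regardless
of family labels. Mendelian consistency is checked per trio by gamete
enumeration: a child genotype is admissible iff its alt-allele dosage is
the sum of one gamete from each parent's genotype; any individual with a
missing own or parental genotype is skipped, never reported.

## The filter cascade

Stage order is fixed: coding → rare ∧ non-synonymous ∧ shared-by-affected
→ recessive zygosity → candidate genes → predicted deleterious. Design
choices where conventions differ:

* **Rarity** uses the *maximum* over populated database frequencies, and
  absent-from-all-databases passes. Novel causal alleles must not be
  discarded for lack of catalog data; a variant common in any reference
  panel is not a plausible fully penetrant recessive cause. Cutoff 5%
  (`max_af=0.05`), the conventional threshold for recessive hearing loss.
* **Sharing**: every *genotyped* affected family member must carry ≥1 alt
  allele; an affected member untyped at a site does not veto the site.
* **Compound heterozygotes**: ≥2 het variants of one gene in all affected
  members; when both parents are genotyped at both sites the pair must be
  in trans (one variant carried by exactly one parent, the other by the
  other); cis pairs are dropped; with parental genotypes unavailable the
  pair is emitted flagged `phase-unconfirmed`. The deleterious filter
  requires both variants damaging by default
  (`comphet_requires_both_damaging=False` relaxes to ≥1) — the strict
  default limits false positives; the switch documents the ambiguity.
* **Predictions**: the PolyPhen-2 category decides; other predictors are
  reported only (they disagree on one of the three reference variants, and
  PolyPhen-2 is the prioritized predictor in this workflow). Calls whose
  deciding variant has no PolyPhen-2 category fail the filter but are
  returned in an `unscored` side channel so nothing is silently lost.
* **Indels** are treated exactly like SNVs; no special-casing.
* Single-proband families are additionally screened against a
  known-pathogenic catalog keyed on (gene, HGVS c.), after the same rarity
  gate.

## Segregation verdicts

`consistent = no genotyped affected non-homozygote ∧ no genotyped
unaffected homozygote`, evaluated over individuals of known affection
only. Affected heterozygotes/wt individuals are listed as phenocopy or
second-locus candidates — in an outbred population a phenotype as common
as hearing loss frequently has environmental causes, so they weaken but do
not falsify the recessive hypothesis; unaffected homozygotes are genuine
penetrance violations. Unknown-affection individuals (e.g. late-onset or
milder phenotypes that do not match the congenital-profound case
definition) are excluded from verdict sets and listed in the notes.

## Association

Counting is on chromosomes (2 per genotyped diploid; the focal genes are
autosomal): `alt = 2·hom + het`, missing genotypes excluded from both
numerator and denominator. The two-tailed Fisher p sums hypergeometric
probabilities of all same-margin tables whose point probability is ≤ the
observed one (scipy's convention; verified against an independent
enumeration oracle to 1e-7 relative). Zero-margin tables return p = 1 by
convention with a note. Because two-sided exact-test conventions differ
between tools, results also carry the one-sided enrichment component
(`p_one_tailed`); on the 12/148 vs 4/240 reference table the two-sided
value is 0.0029 while the one-sided component reproduces the published
0.0026. The odds ratio is reported uncorrected; a zero cell degenerates it
to 0/∞ and the note carries the Haldane–Anscombe +0.5 version instead of
silently substituting it.

Relatedness bias is handled by thinning cases to one affected proband per
pedigree component; the tie-break (lexicographically smallest genotyped
affected id) is arbitrary but deterministic, chosen for reproducibility.

The exact test is conservative on discrete tables, so its type-I error
sits at or below the nominal level rather than exactly on it; under a
simulated null with a common allele (frequency 0.3, 500 chromosomes per
group, 2,000 replicates) the measured rejection rate at α = 0.05 is
≈ 0.045, inside the binomial envelope of the nominal level, and the test
suite asserts exactly that behaviour.

## Haplotype deduction

Marker states are opaque tokens compared by exact string equality —
repeat-region alleles are structural labels such as
`Q13[CAG CAA (CAG)10 del(CAG) CAA]`, never sequence-aligned. The mutant
haplotype is read off focal homozygotes (heterozygous markers there yield
`?`, which is preserved rather than resolved by frequency); heterozygous
carriers' genotypes are *subtracted* — the allele_mut state is removed at
each marker and the residual assigned to the second allele, with an
inconsistency error naming the first incompatible marker. Transmission
checks require each child allele to be assignable to a parent carrying it
(one parent: at least one child allele present). Distinct-allele counts
use exact vector equality; `?` matches nothing, so ambiguous haplotypes
are reported separately and never merged. The per-individual marker table
behind the published five-allele count was never published, so the shipped
panel fixture is a synthetic stand-in constrained to the published
allele_mut string and the published distinct count.

## Synthetic-data generator

The generator emulates the study conditions: founder-population families
ascertained through affected sibships, one planted causal missense variant
per scenario (damaging PolyPhen-2 category, absent from frequency
databases), background coding variation, environmental phenocopies
assigned independently of genotype, and a case/control cohort. Defaults:

* causal founder **carrier frequency 0.033** (the observed 4/120 control
  carrier rate), converted to an allele frequency p via 2p(1−p) = κ so the
  realized het fraction matches the configured carrier rate; penetrance 1;
  phenocopy rate 0 unless a scenario sets it (the cohort driver uses 0.05);
* **500 background variants** over a 40-gene toy map (15 recessive
  deafness candidate genes, 25 large background genes), class mix 40%
  synonymous / 35% missense / 10% non-coding / 15% other, frequency mix
  50% common (5–50%) / 35% rare / 15% novel;
* rare catalogued alleles segregate **locally at ≤1%** while their
  database labels span the whole sub-5% range: in a founder-population
  sibship two unrelated married-in parents essentially never carry the
  same rare allele, which realizes the design property that the planted
  variant is the only cascade survivor, while the rarity filter is still
  exercised across its full range;
* families with a demanded affected sibship make the sibship parents
  obligate heterozygotes and rejection-sample children and phenotypes
  until the affected count matches (cap 10,000 attempts, then a config
  error) — unconditioned founder draws at realistic frequencies would
  essentially never produce the requested families;
* database frequencies are generated at 6 significant digits, the
  precision a VCF Float survives a write/read round trip at.

Everything is driven by one integer seed (numpy `default_rng`) and output
files are byte-reproducible. Truth files record phased haplotypes, the
causal variant and phenocopy ids for oracle tests.

What the generator does **not** emulate: linkage disequilibrium,
recombination, mutation (de novo), sequencing error, coverage or
genotype-quality structure, and population stratification. Passing tests
therefore demonstrate the correctness of the filtering/segregation logic
under clean Mendelian inheritance, not robustness to genotyping artifacts.

## Problem sizes and numerical choices

The tests run the cascade sweep at 100 seeds × 500 background variants,
the phenocopy-monotonicity property at 200 seeds per rate (rates 0 / 0.1 /
0.3), Fisher-vs-enumeration agreement exhaustively for table totals ≤ 30
plus 400 sampled tables with totals ≤ 200, and the null calibration at
2,000 replicates — sizes chosen to make each property decisive while the
whole suite stays fast. Frequency comparisons after VCF round trips use
relative tolerance 1e-6; Fisher agreement uses the 1e-7 relative tolerance
the two-tailed definition is stated at.

## Known limitations

* The candidate gene list is an input; results are only as complete as it
  is (the *RAI1* variant qualifies through the OMIM-extended list).
* The compound-het path requires parental genotypes for phase; sib-pair
  phase deduction without parents is not attempted.
* Penetrance enters only the generator, not the verdict logic: a
  reduced-penetrance model would need unaffected homozygotes to be
  downgraded from violations to expectations.
* The association module tests one variant at a time; no multiple-testing
  correction is applied (single-variant confirmatory setting).
* Haplotype deduction assumes no recombination within the small flanking
  panel and no genotyping error; an inconsistency surfaces as a hard error
  rather than a probabilistic resolution.
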