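"""Hand-coded reference fixtures: the Altaian hearing-loss families.

Encodes the published genotypes of the families in which homozygous
missense mutations were found — c.5254G>A in *RAI1* (families F38, F40 and
the Sanger-screened F18, F37, F42, F43), c.1111C>G in *OTOF* (the combined
F24-F54 pedigree), and c.2168A>G in *SLC26A4* (F53) — together with a
synthetic case/control cohort whose allele-count arithmetic reproduces the
published totals (cases 24/186 chromosomes overall, 12/148 after thinning
to 74 unrelated probands; controls 4/240, i.e. 4/120 heterozygous
carriers).

Encoding notes for ambiguous individuals:

* 24-II-1 (moderate HL, drawn grey in the source pedigree, listed among the
  seven c.1111C>G heterozygotes) carries affection=unknown: the recessive
  model under test concerns congenital profound HL, and unknown-status
  individuals are excluded from segregation verdicts.
* 24-I-1 is the affected relative without the mutation (congenital profound
  HL, wt/wt).
* 38-I-1 (heterozygous mother of F38; no hearing complaints at first
  examination, moderate-to-severe HL on re-examination 11 years later)
  carries affection=unknown in the family pedigree; in the cohort she is
  represented among the four affected heterozygous patients, as the
  published count arithmetic requires.

The cohort families themselves (ids CF*, WF*, SP*, CTRL*) are synthetic:
the published material gives totals, not a per-family roster, so the
fixture realizes the smallest structure consistent with every printed
count (93 patients = 10 hom + 4 het + 79 wt in 74 pedigree components with
6 homozygous probands; 120 controls with 4 heterozygotes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set, Tuple

from .core import (
    Affection,
    FuncClass,
    Individual,
    Pedigree,
    Pp2Category,
    PredictionProfile,
    Sex,
    Variant,
    VariantKey,
    Zygosity,
)
from .haplotype import HaplotypeAllele, Marker

__all__ = ["StudyFixture", "fixture_reference_families", "fixture_rai1_haplotype_panel"]

M, F, U = Sex.MALE, Sex.FEMALE, Sex.UNKNOWN
AFF, UNAFF, UNK = Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN
WT, HET, HOM = Zygosity.WT, Zygosity.HET, Zygosity.HOM_ALT


def _variants() -> Dict[str, Variant]:
    return {
        "RAI1": Variant(
            chrom="chr17",
            pos=17701516,
            ref="G",
            alt="A",
            gene="RAI1",
            hgvs_c="c.5254G>A",
            hgvs_p="p.Gly1752Arg",
            func_class=FuncClass.MISSENSE,
            pop_freqs={"exac": 0.0001021},
            predictions=PredictionProfile(
                polyphen2_score=0.674,
                polyphen2_category=Pp2Category.POSSIBLY_DAMAGING,
                sift="tolerated",
                mutation_taster="polymorphism",
                lrt="deleterious",
                phylop=1.308,
            ),
        ),
        "OTOF": Variant(
            chrom="chr2",
            pos=26707436,
            ref="C",
            alt="G",
            gene="OTOF",
            hgvs_c="c.1111C>G",
            hgvs_p="p.Gly371Arg",
            func_class=FuncClass.MISSENSE,
            pop_freqs={},  # absent from every database (novel)
            predictions=PredictionProfile(
                polyphen2_score=1.0,
                polyphen2_category=Pp2Category.PROBABLY_DAMAGING,
                sift="damaging",
                mutation_taster="disease_causing",
                lrt="deleterious",
                phylop=7.701,
            ),
        ),
        "SLC26A4": Variant(
            chrom="chr7",
            pos=107350577,
            ref="A",
            alt="G",
            gene="SLC26A4",
            hgvs_c="c.2168A>G",
            hgvs_p="p.His723Arg",
            func_class=FuncClass.MISSENSE,
            pop_freqs={"dbsnp138": 0.0004, "1kg": 0.0009, "exac": 0.0001238},
            predictions=PredictionProfile(
                polyphen2_score=1.0,
                polyphen2_category=Pp2Category.PROBABLY_DAMAGING,
                sift="deleterious",
                mutation_taster="disease_causing",
                lrt="deleterious",
                phylop=6.299,
            ),
        ),
    }


# (iid, family, father, mother, sex, affection)
_FAMILY_ROWS: List[Tuple[str, str, str, str, Sex, Affection]] = [
    # F38 — two homozygous affected sibs, heterozygous parents
    ("38-I-1", "F38", "0", "0", F, UNK),  # see module docstring
    ("38-I-2", "F38", "0", "0", M, UNAFF),
    ("38-II-1", "F38", "38-I-2", "38-I-1", U, UNAFF),
    ("38-II-4", "F38", "38-I-2", "38-I-1", U, AFF),
    ("38-II-5", "F38", "38-I-2", "38-I-1", U, AFF),
    # F40
    ("40-I-1", "F40", "0", "0", M, UNAFF),
    ("40-I-2", "F40", "0", "0", F, UNAFF),
    ("40-II-1", "F40", "40-I-1", "40-I-2", U, AFF),
    ("40-II-3", "F40", "40-I-1", "40-I-2", U, AFF),
    # F18 — affected heterozygote (illness at 8 months)
    ("18-I-1", "F18", "0", "0", M, UNAFF),
    ("18-I-2", "F18", "0", "0", F, UNAFF),
    ("18-II-1", "F18", "18-I-1", "18-I-2", U, AFF),
    # F37 — affected heterozygote (perinatal asphyxia); carrier mother
    ("37-I-1", "F37", "0", "0", M, UNAFF),
    ("37-I-2", "F37", "0", "0", F, UNAFF),
    ("37-II-1", "F37", "37-I-1", "37-I-2", U, AFF),
    # F42 — homozygous affected, parents untested
    ("42-I-1", "F42", "0", "0", M, UNK),
    ("42-I-2", "F42", "0", "0", F, UNK),
    ("42-II-1", "F42", "42-I-1", "42-I-2", U, AFF),
    # F43 — homozygous affected grandchild; het aunt with unilateral
    # moderate adult-onset HL (otitis media) counted as affected phenocopy
    ("43-I-1", "F43", "0", "0", M, UNK),
    ("43-I-2", "F43", "0", "0", F, UNK),
    ("43-II-2", "F43", "43-I-1", "43-I-2", U, AFF),
    ("43-II-3", "F43", "43-I-1", "43-I-2", F, UNAFF),
    ("43-II-4", "F43", "0", "0", M, UNK),
    ("43-III-1", "F43", "43-II-4", "43-II-3", U, AFF),
    # F53 — single WES proband plus Sanger-confirmed sister and mother
    ("53-I-1", "F53", "0", "0", F, UNAFF),
    ("53-I-2", "F53", "0", "0", M, UNK),
    ("53-II-1", "F53", "53-I-2", "53-I-1", M, AFF),
    ("53-II-2", "F53", "53-I-2", "53-I-1", F, AFF),
    # combined F24-F54: 24-I-2 and 54-I-1 are sibs (shared untyped parents)
    ("54-0-1", "F54", "0", "0", M, UNK),
    ("54-0-2", "F54", "0", "0", F, UNK),
    ("24-I-1", "F24", "0", "0", M, AFF),
    ("24-I-2", "F24", "54-0-1", "54-0-2", F, UNAFF),
    ("24-II-1", "F24", "24-I-1", "24-I-2", M, UNK),  # moderate HL
    ("24-II-2", "F24", "24-I-1", "24-I-2", M, AFF),
    ("54-I-1", "F54", "54-0-1", "54-0-2", F, UNAFF),
    ("54-I-2", "F54", "0", "0", M, UNAFF),
    ("54-II-1", "F54", "54-I-2", "54-I-1", U, UNAFF),
    ("54-II-2", "F54", "54-I-2", "54-I-1", U, AFF),
    ("54-II-3", "F54", "54-I-2", "54-I-1", U, AFF),
    ("54-II-4", "F54", "54-I-2", "54-I-1", U, UNAFF),
    ("54-II-5", "F54", "54-I-2", "54-I-1", U, AFF),
    ("54-II-6", "F54", "54-I-2", "54-I-1", U, AFF),
    ("54-II-7", "F54", "54-I-2", "54-I-1", F, UNAFF),
    ("54-1", "F54", "0", "0", M, UNAFF),
    ("54-III-1", "F54", "54-1", "54-II-7", U, UNAFF),
]

_RAI1_GENOTYPES = {
    "38-I-1": HET,
    "38-I-2": HET,
    "38-II-1": HET,
    "38-II-4": HOM,
    "38-II-5": HOM,
    "40-I-1": HET,
    "40-I-2": HET,
    "40-II-1": HOM,
    "40-II-3": HOM,
    "18-II-1": HET,
    "37-I-2": HET,
    "37-II-1": HET,
    "42-II-1": HOM,
    "43-II-2": HET,
    "43-II-3": HET,
    "43-III-1": HOM,
    "53-II-1": WT,
    "54-II-2": WT,
    "54-II-5": WT,
}

_OTOF_GENOTYPES = {
    "24-I-1": WT,
    "24-I-2": HET,
    "24-II-1": HET,
    "24-II-2": HET,
    "54-I-1": HET,
    "54-II-1": WT,
    "54-II-2": HOM,
    "54-II-3": HOM,
    "54-II-4": HET,
    "54-II-5": HOM,
    "54-II-6": HOM,
    "54-II-7": HET,
    "54-1": WT,
    "54-III-1": HET,
    "53-II-1": WT,
    "38-II-4": WT,
    "38-II-5": WT,
    "40-II-1": WT,
    "40-II-3": WT,
}

_SLC26A4_GENOTYPES = {
    "53-I-1": HET,
    "53-II-1": HOM,
    "53-II-2": HOM,
    "38-II-4": WT,
    "38-II-5": WT,
    "40-II-1": WT,
    "40-II-3": WT,
    "54-II-2": WT,
    "54-II-5": WT,
}

#: recessive deafness candidate genes (literature list extended by OMIM
#: "hearing loss"/"deafness" search terms, which is how RAI1 qualifies)
CANDIDATE_GENES: FrozenSet[str] = frozenset(
    {
        "GJB2",
        "GJB6",
        "SLC26A4",
        "OTOF",
        "MYO7A",
        "MYO15A",
        "CDH23",
        "PCDH15",
        "TMC1",
        "TMPRSS3",
        "OTOG",
        "TECTA",
        "STRC",
        "LOXHD1",
        "RAI1",
    }
)

#: small known-pathogenic HL catalog (gene, coding change)
KNOWN_CATALOG: FrozenSet[Tuple[str, str]] = frozenset(
    {
        ("SLC26A4", "c.2168A>G"),
        ("SLC26A4", "c.919-2A>G"),
        ("GJB2", "c.35delG"),
        ("GJB2", "c.235delC"),
        ("OTOF", "c.2485C>T"),
    }
)


@dataclass
class StudyFixture:
    variants: Dict[str, Variant]
    families: Pedigree
    cohort: Pedigree
    case_ids: List[str]
    control_ids: List[str]
    candidate_genes: FrozenSet[str] = CANDIDATE_GENES
    known_catalog: FrozenSet[Tuple[str, str]] = KNOWN_CATALOG

    def variant_key(self, gene: str) -> VariantKey:
        return self.variants[gene].key

    def subpedigree(self, *family_ids: str) -> Pedigree:
        """Restriction of the family pedigree (and genotypes) to families."""
        members = [
            ind
            for ind in self.families.individuals.values()
            if ind.family_id in family_ids
        ]
        ids = {m.id for m in members}
        genotypes = {
            key: {iid: z for iid, z in table.items() if iid in ids}
            for key, table in self.families.genotypes.items()
        }
        import dataclasses

        return Pedigree([dataclasses.replace(m) for m in members], genotypes)


def _build_families(variants: Dict[str, Variant]) -> Pedigree:
    inds = [
        Individual(iid, fid, None if fa == "0" else fa, None if mo == "0" else mo, sex, aff)
        for iid, fid, fa, mo, sex, aff in _FAMILY_ROWS
    ]
    ped = Pedigree(inds)
    ped.add_genotypes(variants["RAI1"].key, _RAI1_GENOTYPES)
    ped.add_genotypes(variants["OTOF"].key, _OTOF_GENOTYPES)
    ped.add_genotypes(variants["SLC26A4"].key, _SLC26A4_GENOTYPES)
    return ped


def _build_cohort(variants: Dict[str, Variant]) -> Tuple[Pedigree, List[str], List[str]]:
    inds: List[Individual] = []
    genos: Dict[str, Zygosity] = {}
    case_ids: List[str] = []

    # 4 families: two homozygous affected sibs + one heterozygous affected
    for i in range(1, 5):
        fid = f"CF{i}"
        inds.append(Individual(f"{fid}-F", fid, sex=M, affection=UNK))
        inds.append(Individual(f"{fid}-M", fid, sex=F, affection=UNK))
        for j, z in ((1, HOM), (2, HOM), (3, HET)):
            iid = f"{fid}-{j}"
            inds.append(Individual(iid, fid, f"{fid}-F", f"{fid}-M", U, AFF))
            genos[iid] = z
            case_ids.append(iid)
    # 2 singleton homozygous patients
    for i in (5, 6):
        iid = f"CF{i}-1"
        inds.append(Individual(iid, f"CF{i}", sex=U, affection=AFF))
        genos[iid] = HOM
        case_ids.append(iid)
    # 11 families with two affected wt sibs (other causes of HL)
    for i in range(1, 12):
        fid = f"WF{i:02d}"
        inds.append(Individual(f"{fid}-F", fid, sex=M, affection=UNK))
        inds.append(Individual(f"{fid}-M", fid, sex=F, affection=UNK))
        for j in (1, 2):
            iid = f"{fid}-{j}"
            inds.append(Individual(iid, fid, f"{fid}-F", f"{fid}-M", U, AFF))
            genos[iid] = WT
            case_ids.append(iid)
    # 57 singleton wt patients
    for i in range(1, 58):
        iid = f"SP{i:02d}"
        inds.append(Individual(iid, iid, sex=U, affection=AFF))
        genos[iid] = WT
        case_ids.append(iid)
    # 120 controls, 4 heterozygous carriers
    control_ids = []
    for i in range(1, 121):
        iid = f"CTRL{i:03d}"
        inds.append(Individual(iid, iid, sex=U, affection=UNAFF))
        genos[iid] = HET if i <= 4 else WT
        control_ids.append(iid)

    ped = Pedigree(inds)
    ped.add_genotypes(variants["RAI1"].key, genos)
    return ped, case_ids, control_ids


def fixture_reference_families() -> StudyFixture:
    """Reference families, the three focal variants, and the screening cohort."""
    variants = _variants()
    families = _build_families(variants)
    cohort, case_ids, control_ids = _build_cohort(variants)
    return StudyFixture(
        variants=variants,
        families=families,
        cohort=cohort,
        case_ids=case_ids,
        control_ids=control_ids,
    )


# ---------------------------------------------------------------------------
# RAI1 flanking-marker panel (synthetic stand-in)
# ---------------------------------------------------------------------------

_RAI1_PANEL = [
    Marker("rs3803763", "snv"),
    Marker("rs11649804", "snv"),
    Marker("polyCAG", "repeat"),
    Marker("rs8067439", "snv"),
]

_Q13 = "Q13[CAG CAA (CAG)10 del(CAG) CAA]"
_Q12A = "Q12[CAG CAA (CAG)12 CAA]"
_Q13B = "Q13[CAG CAA (CAG)11 CAG CAA]"

#: the published mutant haplotype over the panel
ALLELE_MUT = HaplotypeAllele(("C", "A", _Q13, "G"), focal="mut")

_WT_ALLELES = {
    "A2": HaplotypeAllele(("T", "G", _Q12A, "A"), focal="wt"),
    "A3": HaplotypeAllele(("C", "G", _Q13B, "G"), focal="wt"),
    "A4": HaplotypeAllele(("T", "A", _Q12A, "G"), focal="wt"),
    "A5": HaplotypeAllele(("C", "A", _Q12A, "G"), focal="wt"),
}


def fixture_rai1_haplotype_panel() -> Dict:
    """Synthetic marker-panel fixture around the RAI1 mutant haplotype.

    The mutant allele C-A-Q13[...]-G matches the published read-off from
    homozygotes; the four wild-type alleles are synthetic stand-ins (the
    per-individual marker table was never published), built so that five
    distinct alleles exist in total and the F37/F43 parent-child
    transmissions confirm.
    """
    a1 = ALLELE_MUT
    a2, a3, a4, a5 = (_WT_ALLELES[k] for k in ("A2", "A3", "A4", "A5"))
    truth = {
        # homozygotes: two copies of allele_mut
        "38-II-5": (a1, a1),
        "40-II-1": (a1, a1),
        "42-II-1": (a1, a1),
        "43-III-1": (a1, a1),
        # heterozygous carriers: allele_mut plus a wild-type allele
        "37-I-2": (a1, a2),
        # 37-II-1 received allele_mut from 37-I-2; the residual allele is
        # from the untyped father
        "37-II-1": (a1, a3),
        "43-II-3": (a1, a4),
        "43-II-2": (a1, a5),
        "38-I-1": (a1, a3),
        "18-II-1": (a1, a4),
        "Alt-1": (a1, a2),
        "Alt-2": (a1, a5),
    }
    genotypes = {
        iid: {
            mk.name: tuple(sorted((h1.states[j], h2.states[j])))
            for j, mk in enumerate(_RAI1_PANEL)
        }
        for iid, (h1, h2) in truth.items()
    }
    return {
        "panel": list(_RAI1_PANEL),
        "allele_mut": a1,
        "wt_alleles": dict(_WT_ALLELES),
        "truth": truth,
        "genotypes": genotypes,
        "n_distinct_expected": 5,
    }
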