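"""Per-family variant prioritization cascade for recessive disease.

The cascade narrows all coding variants of a family down to candidate
causal calls in five fixed stages:

1. ``coding`` — variants in coding sequence;
2. ``rare_nonsyn_shared`` — non-synonymous, rare (max database frequency
   below the cutoff; variants absent from every database count as rare),
   and carried by every genotyped affected member of the family;
3. ``rare_nonsyn_shared_homozygous`` — compatible with a recessive model:
   homozygous in all genotyped affected members, or (in compound-het mode)
   two or more heterozygous variants of one gene in all affected members,
   in trans when parental genotypes allow phase deduction;
4. ``in_candidate_genes`` — restricted to a disease-gene list;
5. ``predicted_deleterious`` — PolyPhen-2 category possibly/probably
   damaging (PolyPhen-2 is the deciding predictor; SIFT, MutationTaster
   and LRT are carried along but not filtered on).

Families with a single genotyped affected member are additionally screened
against a catalog of variants already known to cause the disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .core import (
    Affection,
    CODING_CLASSES,
    DAMAGING_PP2,
    FuncClass,
    NONSYNONYMOUS_CLASSES,
    Pedigree,
    Variant,
    VariantKey,
    Zygosity,
)

__all__ = [
    "CascadeConfig",
    "CandidateCall",
    "CascadeResult",
    "STAGES",
    "filter_functional",
    "filter_rare",
    "shared_among_affected",
    "zygosity_filter",
    "candidate_gene_filter",
    "deleterious_filter",
    "known_pathogenic_screen",
    "run_cascade",
]

STAGES = (
    "coding",
    "rare_nonsyn_shared",
    "rare_nonsyn_shared_homozygous",
    "in_candidate_genes",
    "predicted_deleterious",
)


@dataclass
class CascadeConfig:
    """Tunable filter criteria.

    ``max_af`` is the rarity cutoff applied to the maximum alternate-allele
    frequency over all populated databases (default 5%). ``zygosity_mode``
    selects the recessive models considered. ``comphet_requires_both_damaging``
    controls whether a compound-het call needs both variants (default) or at
    least one predicted damaging.
    """

    max_af: float = 0.05
    functional_keep: FrozenSet[FuncClass] = NONSYNONYMOUS_CLASSES
    zygosity_mode: str = "both"  # homozygous | compound_het | both
    candidate_genes: FrozenSet[str] = frozenset()
    known_catalog: FrozenSet[Tuple[str, str]] = frozenset()
    comphet_requires_both_damaging: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_af <= 1.0:
            raise ValueError("max_af must lie in [0, 1]")
        if not self.functional_keep:
            raise ValueError("functional_keep must be nonempty")
        if self.zygosity_mode not in ("homozygous", "compound_het", "both"):
            raise ValueError(f"unknown zygosity_mode {self.zygosity_mode!r}")
        self.functional_keep = frozenset(self.functional_keep)
        self.candidate_genes = frozenset(self.candidate_genes)
        self.known_catalog = frozenset(self.known_catalog)


@dataclass(frozen=True)
class CandidateCall:
    """A gene-level candidate: one homozygous variant or a comp-het pair."""

    gene: str
    variants: Tuple[Variant, ...]
    model: str  # "homozygous" | "compound_het" | "known_pathogenic"
    flags: Tuple[str, ...] = ()

    @property
    def keys(self) -> Tuple[VariantKey, ...]:
        return tuple(v.key for v in self.variants)


@dataclass
class CascadeResult:
    """Per-family survivor sets and counts at each stage, plus final calls."""

    family_id: str
    stage_survivors: Dict[str, List[Variant]]
    final_calls: List[CandidateCall]
    unscored_calls: List[CandidateCall] = field(default_factory=list)
    known_screen_calls: List[CandidateCall] = field(default_factory=list)

    @property
    def stage_counts(self) -> Dict[str, int]:
        return {s: len(self.stage_survivors[s]) for s in STAGES}

    def check_monotone(self) -> bool:
        counts = [len(self.stage_survivors[s]) for s in STAGES]
        return all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------


def filter_functional(
    variants: Sequence[Variant], config: CascadeConfig
) -> List[Variant]:
    """Keep exactly the variants whose class is in ``functional_keep``."""
    return [v for v in variants if v.func_class in config.functional_keep]


def filter_rare(variants: Sequence[Variant], config: CascadeConfig) -> List[Variant]:
    """Keep variants rarer than ``max_af`` in every database.

    The maximum over populated frequency fields decides; variants with no
    frequency data at all are kept (novel alleles are rare by assumption).
    """
    out = []
    for v in variants:
        f = v.max_pop_freq
        if f is None or f < config.max_af:
            out.append(v)
    return out


def _genotyped_affected(ped: Pedigree, family_id: str, key: VariantKey) -> List[str]:
    return [
        i.id
        for i in ped.affected_members(family_id)
        if ped.zygosity(key, i.id) is not Zygosity.MISSING
    ]


def _any_genotyped_affected(ped: Pedigree, family_id: str) -> List[str]:
    ids = set()
    affected = [i.id for i in ped.affected_members(family_id)]
    for table in ped.genotypes.values():
        for iid in affected:
            if table.get(iid, Zygosity.MISSING) is not Zygosity.MISSING:
                ids.add(iid)
    return sorted(ids)


def shared_among_affected(
    variants: Sequence[Variant], ped: Pedigree, family_id: str
) -> List[Variant]:
    """Variants at which every genotyped affected family member carries at
    least one alternate allele. Affected members untyped at a site do not
    veto that site.
    """
    if not _any_genotyped_affected(ped, family_id):
        raise ValueError(f"family {family_id!r} has no genotyped affected member")
    affected = [i.id for i in ped.affected_members(family_id)]
    out = []
    for v in variants:
        carried = True
        for iid in affected:
            z = ped.zygosity(v.key, iid)
            if z is Zygosity.MISSING:
                continue
            if not z.carries_alt:
                carried = False
                break
        if carried:
            out.append(v)
    return out


def _hom_in_all_affected(ped: Pedigree, family_id: str, v: Variant) -> bool:
    typed = _genotyped_affected(ped, family_id, v.key)
    return bool(typed) and all(
        ped.zygosity(v.key, iid) is Zygosity.HOM_ALT for iid in typed
    )


def _het_in_all_affected(ped: Pedigree, family_id: str, v: Variant) -> bool:
    typed = _genotyped_affected(ped, family_id, v.key)
    return bool(typed) and all(
        ped.zygosity(v.key, iid) is Zygosity.HET for iid in typed
    )


def _comphet_parents(ped: Pedigree, family_id: str) -> Optional[Tuple[str, str]]:
    """Father/mother pair of the affected sibship, if shared and present."""
    parents = {
        (i.father_id, i.mother_id)
        for i in ped.affected_members(family_id)
        if i.father_id is not None and i.mother_id is not None
    }
    if len(parents) == 1:
        return next(iter(parents))
    return None


def _trans_config(
    ped: Pedigree, father: str, mother: str, v1: Variant, v2: Variant
) -> Optional[bool]:
    """True when v1/v2 are carried by different parents (trans), False when
    the parental genotypes put both on one side (cis), None when phase
    cannot be decided (a parental genotype missing).
    """
    f1, f2 = ped.zygosity(v1.key, father), ped.zygosity(v2.key, father)
    m1, m2 = ped.zygosity(v1.key, mother), ped.zygosity(v2.key, mother)
    if Zygosity.MISSING in (f1, f2, m1, m2):
        return None
    fc1, fc2 = f1.carries_alt, f2.carries_alt
    mc1, mc2 = m1.carries_alt, m2.carries_alt
    trans = (fc1 and not fc2 and mc2 and not mc1) or (
        fc2 and not fc1 and mc1 and not mc2
    )
    return trans


def zygosity_filter(
    variants: Sequence[Variant],
    ped: Pedigree,
    family_id: str,
    mode: str = "both",
) -> List[CandidateCall]:
    """Recessive-model calls among shared variants.

    Homozygous mode keeps variants homozygous-alt in every genotyped affected
    member. Compound-het mode emits gene-level calls from >=2 variants of one
    gene heterozygous in every affected member, requiring a trans
    configuration when both parents are genotyped; with parental genotypes
    unavailable the pair is emitted flagged ``phase-unconfirmed``.
    """
    calls: List[CandidateCall] = []
    if mode in ("homozygous", "both"):
        for v in variants:
            if _hom_in_all_affected(ped, family_id, v):
                calls.append(CandidateCall(v.gene, (v,), "homozygous"))
    if mode in ("compound_het", "both"):
        by_gene: Dict[str, List[Variant]] = {}
        for v in variants:
            if _het_in_all_affected(ped, family_id, v):
                by_gene.setdefault(v.gene, []).append(v)
        parent_pair = _comphet_parents(ped, family_id)
        for gene in sorted(by_gene):
            vs = by_gene[gene]
            if len(vs) < 2:
                continue
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    v1, v2 = vs[i], vs[j]
                    if parent_pair is None:
                        calls.append(
                            CandidateCall(
                                gene, (v1, v2), "compound_het", ("phase-unconfirmed",)
                            )
                        )
                        continue
                    trans = _trans_config(ped, *parent_pair, v1, v2)
                    if trans is True:
                        calls.append(CandidateCall(gene, (v1, v2), "compound_het"))
                    elif trans is None:
                        calls.append(
                            CandidateCall(
                                gene, (v1, v2), "compound_het", ("phase-unconfirmed",)
                            )
                        )
                    # cis -> no call
    return calls


def candidate_gene_filter(
    calls: Sequence[CandidateCall], config: CascadeConfig
) -> List[CandidateCall]:
    return [c for c in calls if c.gene in config.candidate_genes]


def deleterious_filter(
    calls: Sequence[CandidateCall], config: CascadeConfig
) -> Tuple[List[CandidateCall], List[CandidateCall]]:
    """Split calls into (kept, unscored).

    A homozygous call is kept when its variant is PolyPhen-2
    possibly/probably damaging. A compound-het call needs both variants
    damaging by default (``comphet_requires_both_damaging=False`` relaxes to
    at least one). Calls whose deciding variant lacks a PolyPhen-2 category
    fail the filter but are returned in the unscored side channel.
    """
    kept: List[CandidateCall] = []
    unscored: List[CandidateCall] = []
    for c in calls:
        cats = [v.predictions.polyphen2_category for v in c.variants]
        damaging = [cat in DAMAGING_PP2 for cat in cats]
        if c.model == "compound_het" and not config.comphet_requires_both_damaging:
            ok = any(damaging)
        else:
            ok = all(damaging)
        if ok:
            kept.append(c)
        elif any(cat is None for cat in cats):
            unscored.append(c)
    return kept, unscored


def known_pathogenic_screen(
    variants: Sequence[Variant],
    ped: Pedigree,
    proband_id: str,
    config: CascadeConfig,
) -> List[CandidateCall]:
    """Single-proband path: rare variants carried by the proband whose
    (gene, hgvs_c) is already catalogued as disease-causing."""
    if not config.known_catalog:
        warnings.warn("known-pathogenic catalog is empty", stacklevel=2)
        return []
    calls = []
    for v in filter_rare(variants, config):
        if (v.gene, v.hgvs_c) not in config.known_catalog:
            continue
        z = ped.zygosity(v.key, proband_id)
        if z.carries_alt:
            calls.append(
                CandidateCall(v.gene, (v,), "known_pathogenic", (f"zygosity={z.value}",))
            )
    return calls


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


def run_cascade(
    variants: Sequence[Variant],
    ped: Pedigree,
    config: CascadeConfig,
    family_ids: Optional[Sequence[str]] = None,
) -> List[CascadeResult]:
    """Run the five-stage cascade for each family.

    Families whose only genotyped affected member stands alone (no affected
    sibs with genotypes) are additionally routed through the
    known-pathogenic screen; those calls are reported separately and merged
    into ``final_calls`` (deduplicated by variant keys).
    """
    results = []
    for fam in family_ids if family_ids is not None else ped.family_ids():
        affected_typed = _any_genotyped_affected(ped, fam)
        if not affected_typed:
            raise ValueError(f"family {fam!r} has no genotyped affected member")

        coding = [v for v in variants if v.func_class in CODING_CLASSES]
        rns = shared_among_affected(
            filter_rare(filter_functional(coding, config), config), ped, fam
        )
        zyg_calls = zygosity_filter(rns, ped, fam, config.zygosity_mode)
        zyg_vars = _call_variants(zyg_calls)
        cand_calls = candidate_gene_filter(zyg_calls, config)
        cand_vars = _call_variants(cand_calls)
        final_calls, unscored = deleterious_filter(cand_calls, config)
        final_vars = _call_variants(final_calls)

        known_calls: List[CandidateCall] = []
        if len(affected_typed) == 1:
            known_calls = known_pathogenic_screen(variants, ped, affected_typed[0], config)
            seen = {c.keys for c in final_calls}
            for c in known_calls:
                if c.keys not in seen:
                    final_calls.append(c)

        results.append(
            CascadeResult(
                family_id=fam,
                stage_survivors={
                    "coding": coding,
                    "rare_nonsyn_shared": rns,
                    "rare_nonsyn_shared_homozygous": zyg_vars,
                    "in_candidate_genes": cand_vars,
                    "predicted_deleterious": final_vars,
                },
                final_calls=final_calls,
                unscored_calls=unscored,
                known_screen_calls=known_calls,
            )
        )
    return results


def _call_variants(calls: Sequence[CandidateCall]) -> List[Variant]:
    seen: Dict[VariantKey, Variant] = {}
    for c in calls:
        for v in c.variants:
            seen.setdefault(v.key, v)
    return list(seen.values())
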