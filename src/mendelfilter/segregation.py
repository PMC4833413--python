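"""Cosegregation analysis under the autosomal recessive model.

A focal variant cosegregates with the phenotype when every genotyped
affected individual is homozygous for it and no genotyped unaffected
individual is. Affected individuals who are *not* homozygous do not by
themselves falsify the recessive hypothesis — in outbred families a
phenotype as common as hearing loss can arise from environmental causes or
a second locus — so they are flagged as phenocopy candidates rather than
treated as refutations. Unaffected homozygotes, in contrast, are genuine
penetrance violations. Individuals of unknown affection status are kept
out of the verdict sets and listed in the notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

from .core import Affection, Pedigree, VariantKey, Zygosity

__all__ = ["CarrierClassification", "SegregationVerdict", "classify_carriers", "check_ar_cosegregation"]


@dataclass
class CarrierClassification:
    """Disjoint partition of all pedigree members by zygosity at one variant."""

    hom_alt_ids: List[str]
    het_ids: List[str]
    wt_ids: List[str]
    missing_ids: List[str]

    @property
    def carrier_ids(self) -> List[str]:
        return sorted(self.het_ids + self.hom_alt_ids)

    def sizes(self) -> dict:
        return {
            "hom_alt": len(self.hom_alt_ids),
            "het": len(self.het_ids),
            "wt": len(self.wt_ids),
            "missing": len(self.missing_ids),
        }


@dataclass
class SegregationVerdict:
    consistent: bool
    affected_hom: List[str]
    affected_nonhom: List[str]  # phenocopy / second-locus candidates
    unaffected_hom: List[str]  # penetrance violations
    notes: List[str] = field(default_factory=list)


def classify_carriers(ped: Pedigree, key: VariantKey) -> CarrierClassification:
    """Partition every pedigree member by zygosity; ids sorted lexicographically.

    Raises :class:`~mendelfilter.core.MissingGenotypeError` when the variant
    has no genotype data at all.
    """
    buckets = {z: [] for z in Zygosity}
    for iid in sorted(ped.individuals):
        buckets[ped.zygosity(key, iid)].append(iid)
    return CarrierClassification(
        hom_alt_ids=buckets[Zygosity.HOM_ALT],
        het_ids=buckets[Zygosity.HET],
        wt_ids=buckets[Zygosity.WT],
        missing_ids=buckets[Zygosity.MISSING],
    )


def check_ar_cosegregation(ped: Pedigree, key: VariantKey) -> SegregationVerdict:
    """Autosomal-recessive cosegregation verdict for one variant.

    Evaluated over genotyped individuals of known affection status only:
    ``consistent`` is true iff there is no genotyped affected non-homozygote
    and no genotyped unaffected homozygote.
    """
    affected_hom: List[str] = []
    affected_nonhom: List[str] = []
    unaffected_hom: List[str] = []
    notes: List[str] = []
    genotyped_affected = 0

    for iid in sorted(ped.individuals):
        z = ped.zygosity(key, iid)
        if z is Zygosity.MISSING:
            continue
        aff = ped[iid].affection
        if aff is Affection.UNKNOWN:
            notes.append(f"{iid}: unknown affection status (excluded from verdict)")
            continue
        if aff is Affection.AFFECTED:
            genotyped_affected += 1
            if z is Zygosity.HOM_ALT:
                affected_hom.append(iid)
            else:
                affected_nonhom.append(iid)
                notes.append(
                    f"{iid}: affected but {z.value} — possible phenocopy or second locus"
                )
        else:
            if z is Zygosity.HOM_ALT:
                unaffected_hom.append(iid)
                notes.append(f"{iid}: unaffected homozygote — penetrance violation")

    if genotyped_affected == 0:
        notes.append("no genotyped affected individual of known status")

    return SegregationVerdict(
        consistent=not affected_nonhom and not unaffected_hom,
        affected_hom=affected_hom,
        affected_nonhom=affected_nonhom,
        unaffected_hom=unaffected_hom,
        notes=notes,
    )
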