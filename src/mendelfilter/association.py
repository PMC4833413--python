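"""Case-control allele-frequency association.

Allele counts are tallied on chromosomes (2 per genotyped diploid
individual; the focal genes are autosomal) and compared with a two-tailed
Fisher's exact test on the 2x2 table

    =========  =========  =============
               alt        ref
    =========  =========  =============
    cases      a          b = 2n_ca - a
    controls   c          d = 2n_co - c
    =========  =========  =============

using the standard two-sided convention: the p-value sums the
hypergeometric probabilities of every table with the same margins whose
point probability does not exceed the observed table's. Related cases
inflate allele counts, so the module can first thin the case cohort to one
affected proband per connected pedigree component (deterministically the
lexicographically smallest genotyped affected id).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from scipy import stats

from .core import Affection, Pedigree, VariantKey, Zygosity

__all__ = [
    "AlleleCountTable",
    "AssociationResult",
    "allele_counts",
    "fisher_exact_two_tailed",
    "fisher_exact_one_tailed",
    "select_unrelated_probands",
    "run_association",
]


@dataclass(frozen=True)
class AlleleCountTable:
    case_alt: int
    case_total_chrom: int
    control_alt: int
    control_total_chrom: int

    def __post_init__(self) -> None:
        for alt, total in (
            (self.case_alt, self.case_total_chrom),
            (self.control_alt, self.control_total_chrom),
        ):
            if not 0 <= alt <= total:
                raise ValueError(f"alt count {alt} outside [0, {total}]")

    @property
    def cells(self) -> Tuple[int, int, int, int]:
        """(a, b, c, d) = (case alt, case ref, control alt, control ref)."""
        return (
            self.case_alt,
            self.case_total_chrom - self.case_alt,
            self.control_alt,
            self.control_total_chrom - self.control_alt,
        )


@dataclass
class AssociationResult:
    """``p_two_tailed`` is the headline test; ``p_one_tailed`` is the
    one-sided enrichment component (cases richer in the alt allele), carried
    in reporting because exact-test tools differ in their two-sided
    convention and published p-values are often the one-sided value."""

    table: AlleleCountTable
    case_freq: float
    control_freq: float
    p_two_tailed: float
    p_one_tailed: float
    odds_ratio: float
    notes: List[str] = field(default_factory=list)
    case_ids_used: List[str] = field(default_factory=list)


def allele_counts(
    ped: Pedigree, key: VariantKey, individual_ids: Sequence[str]
) -> Tuple[int, int]:
    """(alternate alleles, total chromosomes) over the genotyped subset.

    alt = 2 x #hom_alt + #het; total = 2 x #genotyped. Missing genotypes are
    excluded from both. Raises on an empty group or when nobody is genotyped.
    """
    if not individual_ids:
        raise ValueError("empty group")
    alt = total = 0
    for iid in individual_ids:
        z = ped.zygosity(key, iid)
        if z is Zygosity.MISSING:
            continue
        alt += z.alt_dosage
        total += 2
    if total == 0:
        raise ValueError("no genotyped individuals in group")
    return alt, total


def fisher_exact_two_tailed(table: AlleleCountTable) -> Tuple[float, Optional[str]]:
    """Two-tailed Fisher's exact p for the allele table.

    Any zero margin (no alt alleles anywhere, or an empty row) makes the
    table degenerate; by convention p = 1.0 with an explanatory note.
    """
    a, b, c, d = table.cells
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return 1.0, "degenerate table (zero margin); p = 1 by convention"
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0)), None


def fisher_exact_one_tailed(table: AlleleCountTable) -> float:
    """One-sided exact p for enrichment of the alt allele in cases."""
    a, b, c, d = table.cells
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(min(p, 1.0))


def select_unrelated_probands(ped: Pedigree, case_ids: Sequence[str]) -> List[str]:
    """One case per connected pedigree component.

    From each component of the parent-child graph, the lexicographically
    smallest member of ``case_ids`` that is affected is retained (case lists
    are expected to hold affected individuals; the affection check guards
    against mislabeled input). Components contributing no case are skipped;
    components whose cases are all of unknown status raise a warning and are
    skipped.
    """
    case_set = set(case_ids)
    probands: List[str] = []
    for comp in ped.components():
        members = sorted(case_set & comp)
        if not members:
            continue
        eligible = [m for m in members if ped[m].affection is Affection.AFFECTED]
        if not eligible:
            warnings.warn(
                f"component containing {members[0]!r} has no affected case; skipped",
                stacklevel=2,
            )
            continue
        probands.append(eligible[0])
    return sorted(probands)


def run_association(
    ped: Pedigree,
    key: VariantKey,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    mode: str = "all",
) -> AssociationResult:
    """Count, optionally thin cases to unrelated probands, and test.

    Odds ratio is (a*d)/(b*c); when any cell is zero the uncorrected ratio
    degenerates (0 or inf) and a note points at the Haldane-Anscombe +0.5
    correction instead of silently substituting it.
    """
    if not case_ids or not control_ids:
        raise ValueError("both groups must be nonempty")
    if mode not in ("all", "unrelated"):
        raise ValueError(f"unknown mode {mode!r}")
    notes: List[str] = []
    used = list(case_ids)
    if mode == "unrelated":
        used = select_unrelated_probands(ped, case_ids)
        notes.append(f"unrelated probands selected: {len(used)}")
    case_alt, case_total = allele_counts(ped, key, used)
    ctrl_alt, ctrl_total = allele_counts(ped, key, control_ids)
    table = AlleleCountTable(case_alt, case_total, ctrl_alt, ctrl_total)
    p, note = fisher_exact_two_tailed(table)
    p_one = fisher_exact_one_tailed(table)
    if note:
        notes.append(note)
    a, b, c, d = table.cells
    if min(a, b, c, d) == 0:
        odds = math.inf if b * c == 0 and a * d > 0 else 0.0
        notes.append(
            "zero cell in table; odds ratio degenerate — consider the "
            "Haldane-Anscombe correction "
            f"(OR+0.5 = {((a + .5) * (d + .5)) / ((b + .5) * (c + .5)):.4g})"
        )
    else:
        odds = (a * d) / (b * c)
    return AssociationResult(
        table=table,
        case_freq=case_alt / case_total,
        control_freq=ctrl_alt / ctrl_total,
        p_two_tailed=p,
        p_one_tailed=p_one,
        odds_ratio=odds,
        notes=notes,
        case_ids_used=sorted(used),
    )
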