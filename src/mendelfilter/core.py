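"""Domain types shared by every analysis stage.

The package works on a biallelic view of annotated exome variants: each
alternate allele of each site is one :class:`Variant`, each person's state at
it is one of four zygosity states (missing is first-class, never imputed),
and families are :class:`Pedigree` objects — directed acyclic parentage
graphs over :class:`Individual` records with an attached genotype table.
Coordinates are 1-based and VCF-style throughout.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

__all__ = [
    "FuncClass",
    "Zygosity",
    "Sex",
    "Affection",
    "Pp2Category",
    "PredictionProfile",
    "Variant",
    "VariantKey",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "MissingGenotypeError",
    "mendelian_violations",
    "CODING_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "DAMAGING_PP2",
]

VariantKey = Tuple[str, int, str, str]


class FuncClass(str, enum.Enum):
    """Functional consequence class of a coding (or non-coding) change."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    OTHER_CODING = "other_coding"
    NONCODING = "noncoding"


#: classes counted as "in CDS" (everything except purely non-coding)
CODING_CLASSES = frozenset(c for c in FuncClass if c is not FuncClass.NONCODING)

#: default "non-synonymous" retention set for the filter cascade
NONSYNONYMOUS_CLASSES = frozenset(
    {FuncClass.MISSENSE, FuncClass.NONSENSE, FuncClass.FRAMESHIFT, FuncClass.SPLICE}
)


class Zygosity(str, enum.Enum):
    WT = "wt"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def alt_dosage(self) -> Optional[int]:
        """Number of alternate alleles carried, or None when untyped."""
        return _DOSAGE[self]

    @property
    def carries_alt(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_ALT)


_DOSAGE = {
    Zygosity.WT: 0,
    Zygosity.HET: 1,
    Zygosity.HOM_ALT: 2,
    Zygosity.MISSING: None,
}


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    UNKNOWN = "unknown"


class Pp2Category(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


#: PolyPhen-2 categories treated as deleterious by the cascade
DAMAGING_PP2 = frozenset({Pp2Category.POSSIBLY_DAMAGING, Pp2Category.PROBABLY_DAMAGING})


@dataclass(frozen=True)
class PredictionProfile:
    """In-silico damage predictions consumed as input annotation.

    Every field may be absent (None); category/score consistency is *not*
    assumed because the values come from external annotation pipelines.
    """

    polyphen2_score: Optional[float] = None
    polyphen2_category: Optional[Pp2Category] = None
    sift: Optional[str] = None  # "tolerated" / "damaging"
    mutation_taster: Optional[str] = None  # "polymorphism" / "disease_causing"
    lrt: Optional[str] = None  # "neutral" / "deleterious"
    phylop: Optional[float] = None

    @property
    def pp2_damaging(self) -> bool:
        return self.polyphen2_category in DAMAGING_PP2


@dataclass
class Variant:
    """One annotated alternate allele at one site (biallelic view).

    ``pop_freqs`` maps a database name (e.g. ``"exac"``, ``"1kg"``) to the
    alternate-allele frequency reported there; an empty map means the allele
    is absent from every consulted database ("novel").
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    func_class: FuncClass = FuncClass.OTHER_CODING
    pop_freqs: Dict[str, float] = field(default_factory=dict)
    predictions: PredictionProfile = field(default_factory=PredictionProfile)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for db, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f!r} for {db!r} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_pop_freq(self) -> Optional[float]:
        """Maximum frequency over populated databases; None when novel."""
        return max(self.pop_freqs.values()) if self.pop_freqs else None

    def __hash__(self) -> int:  # identity by (chrom, pos, ref, alt)
        return hash(self.key)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Variant):
            return self.key == other.key
        return NotImplemented

    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    zygosity: Zygosity


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, dangling parents, dupes)."""


class MissingGenotypeError(KeyError):
    """No genotype data loaded for the requested variant key."""


class Pedigree:
    """Individuals with parent links plus a (variant, individual) genotype table.

    Parent links must resolve within the pedigree and be acyclic. Connected
    components are computed over the undirected parent-child graph, so
    families joined by a shared ancestor form one component regardless of
    their family-id labels.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        genotypes: Optional[Mapping[VariantKey, Mapping[str, Zygosity]]] = None,
    ) -> None:
        self._individuals: Dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._individuals[ind.id] = ind
        for ind in self._individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._individuals:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.id!r} not in pedigree"
                    )
        self._check_acyclic()
        self.genotypes: Dict[VariantKey, Dict[str, Zygosity]] = {}
        if genotypes:
            for key, calls in genotypes.items():
                self.add_genotypes(key, calls)

    # -- structure ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        state: Dict[str, int] = {}  # 0 visiting, 1 done

        for start in self._individuals:
            if start in state:
                continue
            stack: List[Tuple[str, Iterator[str]]] = [(start, self._parent_iter(start))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise PedigreeError(f"cyclic parentage involving {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, self._parent_iter(p)))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def _parent_iter(self, iid: str) -> Iterator[str]:
        ind = self._individuals[iid]
        return iter([p for p in (ind.father_id, ind.mother_id) if p is not None])

    @property
    def individuals(self) -> Dict[str, Individual]:
        return self._individuals

    def __contains__(self, iid: str) -> bool:
        return iid in self._individuals

    def __len__(self) -> int:
        return len(self._individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._individuals[iid]

    def members(self, family_id: str) -> List[Individual]:
        return [i for i in self._individuals.values() if i.family_id == family_id]

    def family_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for ind in self._individuals.values():
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def affected_members(self, family_id: Optional[str] = None) -> List[Individual]:
        pool = (
            self.members(family_id) if family_id is not None else list(self._individuals.values())
        )
        return [i for i in pool if i.affection is Affection.AFFECTED]

    def components(self) -> List[Set[str]]:
        """Connected components of the undirected parent-child graph.

        Deterministic: components are ordered by their lexicographically
        smallest member; ordering is stable under individual reordering.
        """
        adj: Dict[str, Set[str]] = {iid: set() for iid in self._individuals}
        for ind in self._individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    adj[ind.id].add(pid)
                    adj[pid].add(ind.id)
        seen: Set[str] = set()
        comps: List[Set[str]] = []
        for iid in sorted(self._individuals):
            if iid in seen:
                continue
            comp: Set[str] = set()
            queue = deque([iid])
            seen.add(iid)
            while queue:
                node = queue.popleft()
                comp.add(node)
                for nb in adj[node]:
                    if nb not in seen:
                        seen.add(nb)
                        queue.append(nb)
            comps.append(comp)
        comps.sort(key=lambda c: min(c))
        return comps

    # -- genotypes ---------------------------------------------------------

    def add_genotypes(
        self, key: VariantKey, calls: Mapping[str, Zygosity] | Iterable[GenotypeCall]
    ) -> None:
        table = self.genotypes.setdefault(key, {})
        items: Iterable[Tuple[str, Zygosity]]
        if isinstance(calls, Mapping):
            items = calls.items()
        else:
            items = ((c.individual_id, c.zygosity) for c in calls)
        for iid, zyg in items:
            if iid not in self._individuals:
                raise PedigreeError(f"genotype for unknown individual {iid!r}")
            table[iid] = zyg

    def zygosity(self, key: VariantKey, iid: str) -> Zygosity:
        """Zygosity of ``iid`` at ``key``; MISSING when the person is untyped.

        Raises :class:`MissingGenotypeError` when no genotype data at all is
        loaded for the variant.
        """
        if key not in self.genotypes:
            raise MissingGenotypeError(key)
        return self.genotypes[key].get(iid, Zygosity.MISSING)

    def genotyped_ids(self, key: VariantKey) -> List[str]:
        if key not in self.genotypes:
            raise MissingGenotypeError(key)
        return sorted(
            iid for iid, z in self.genotypes[key].items() if z is not Zygosity.MISSING
        )


def _gamete_dosages(zyg: Zygosity) -> Set[int]:
    if zyg is Zygosity.WT:
        return {0}
    if zyg is Zygosity.HET:
        return {0, 1}
    if zyg is Zygosity.HOM_ALT:
        return {1}
    raise ValueError("missing genotype has no gametes")


def mendelian_violations(ped: Pedigree, key: VariantKey) -> List[str]:
    """Non-founders whose zygosity is impossible under biallelic autosomal
    inheritance given both parents' genotypes.

    Individuals with a missing own genotype, an unlinked parent, or any
    missing parental genotype are never reported. Raises
    :class:`MissingGenotypeError` if no genotypes are loaded for ``key``.
    """
    if key not in ped.genotypes:
        raise MissingGenotypeError(key)
    violators: List[str] = []
    for iid in sorted(ped.individuals):
        ind = ped[iid]
        if ind.father_id is None or ind.mother_id is None:
            continue
        child = ped.zygosity(key, iid)
        pat = ped.zygosity(key, ind.father_id)
        mat = ped.zygosity(key, ind.mother_id)
        if Zygosity.MISSING in (child, pat, mat):
            continue
        possible = {
            a + b for a in _gamete_dosages(pat) for b in _gamete_dosages(mat)
        }
        if child.alt_dosage not in possible:
            violators.append(iid)
    return violators
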