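"""Pedigree-based reconstruction of the haplotype carrying a focal mutation.

The approach mirrors how founder haplotypes are deduced by hand from Sanger
genotypes at a small panel of flanking markers (SNPs plus a variable repeat
region whose alleles are opaque structural labels):

* in an individual homozygous for the focal mutation, both chromosomes
  carry the mutant haplotype, so it is read off directly — markers that are
  heterozygous there stay ambiguous ("?");
* in a heterozygous carrier, the mutant haplotype (once known) is
  *subtracted* from the unphased genotypes, assigning the residual state at
  every marker to the second, wild-type allele;
* parent-child transmissions confirm or contradict the assignments;
* distinct reconstructed alleles are enumerated by exact state-vector
  equality ("?" matches nothing, so ambiguous haplotypes are reported
  separately, never merged).

Marker states are opaque tokens compared by exact string equality; repeat
alleles like ``Q13[CAG CAA (CAG)10 del(CAG) CAA]`` are labels, not
sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import Pedigree, Zygosity

__all__ = [
    "Marker",
    "HaplotypeAllele",
    "MarkerGenotypes",
    "HaplotypeInconsistencyError",
    "TransmissionVerdict",
    "haplotype_from_homozygote",
    "subtract_mutant_haplotype",
    "confirm_by_transmission",
    "enumerate_distinct_alleles",
    "read_panel_tsv",
    "read_marker_genotypes_tsv",
]

AMBIGUOUS = "?"

#: unordered genotype at one marker: a sorted pair of state tokens
MarkerGenotypes = Mapping[str, Tuple[str, str]]


@dataclass(frozen=True)
class Marker:
    name: str
    kind: str = "snv"  # "snv" | "repeat"


@dataclass(frozen=True)
class HaplotypeAllele:
    """Ordered marker states over the panel plus the focal-mutation state."""

    states: Tuple[str, ...]
    focal: str  # "mut" | "wt"
    ambiguous_positions: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        amb = frozenset(i for i, s in enumerate(self.states) if s == AMBIGUOUS)
        object.__setattr__(self, "ambiguous_positions", amb)
        if self.focal not in ("mut", "wt"):
            raise ValueError(f"focal must be 'mut' or 'wt', got {self.focal!r}")

    @property
    def resolved(self) -> bool:
        return not self.ambiguous_positions

    def label(self) -> str:
        return "-".join(self.states) + f"-[{self.focal}]"


class HaplotypeInconsistencyError(ValueError):
    def __init__(self, marker: str, message: str):
        super().__init__(message)
        self.marker = marker


@dataclass
class TransmissionVerdict:
    status: str  # "confirmed" | "contradicted" | "uninformative"
    detail: str = ""


def _normalize(genotypes: MarkerGenotypes) -> Dict[str, Tuple[str, str]]:
    return {m: tuple(sorted(pair)) for m, pair in genotypes.items()}


def haplotype_from_homozygote(
    panel: Sequence[Marker],
    marker_genotypes: MarkerGenotypes,
    focal_zygosity: Zygosity,
) -> HaplotypeAllele:
    """Read the mutant haplotype off a focal-mutation homozygote.

    Homozygous marker states transfer directly; a heterozygous marker in the
    homozygote cannot be phased from this individual alone and yields "?".
    """
    if focal_zygosity is not Zygosity.HOM_ALT:
        raise ValueError("haplotype read-off requires a focal homozygote")
    genos = _normalize(marker_genotypes)
    states = []
    for mk in panel:
        pair = genos.get(mk.name)
        if pair is None:
            states.append(AMBIGUOUS)
        elif pair[0] == pair[1]:
            states.append(pair[0])
        else:
            states.append(AMBIGUOUS)
    return HaplotypeAllele(tuple(states), focal="mut")


def subtract_mutant_haplotype(
    panel: Sequence[Marker],
    marker_genotypes: MarkerGenotypes,
    allele_mut: HaplotypeAllele,
) -> HaplotypeAllele:
    """Residual (wild-type) haplotype of a heterozygous carrier.

    At every marker the carrier's unphased genotype must contain the mutant
    haplotype's state; the other observed state goes to the second allele.
    A genotype incompatible with ``allele_mut`` raises
    :class:`HaplotypeInconsistencyError` naming the marker.
    """
    if not allele_mut.resolved:
        raise ValueError("allele_mut must be fully resolved (no '?')")
    if allele_mut.focal != "mut":
        raise ValueError("allele_mut must carry the focal mutation")
    genos = _normalize(marker_genotypes)
    states = []
    for idx, mk in enumerate(panel):
        pair = genos.get(mk.name)
        if pair is None:
            states.append(AMBIGUOUS)
            continue
        mut_state = allele_mut.states[idx]
        if mut_state not in pair:
            raise HaplotypeInconsistencyError(
                mk.name,
                f"genotype {pair[0]}/{pair[1]} at {mk.name} does not contain "
                f"mutant-haplotype state {mut_state!r}",
            )
        residual = pair[1] if pair[0] == mut_state else pair[0]
        states.append(residual)
    return HaplotypeAllele(tuple(states), focal="wt")


def _allele_in(allele: HaplotypeAllele, pair: Tuple[HaplotypeAllele, HaplotypeAllele]) -> bool:
    return any(
        allele.states == p.states and allele.focal == p.focal for p in pair
    )


def _first_mismatch(
    panel: Sequence[Marker], child: HaplotypeAllele, parent_alleles: Iterable[HaplotypeAllele]
) -> str:
    best = None
    for p in parent_alleles:
        if p.focal != child.focal:
            continue
        for i, (a, b) in enumerate(zip(child.states, p.states)):
            if a != b:
                best = panel[i].name if best is None else best
                break
    if best is None:
        for p in parent_alleles:
            for i, (a, b) in enumerate(zip(child.states, p.states)):
                if a != b:
                    return panel[i].name
        return panel[0].name if panel else ""
    return best


def confirm_by_transmission(
    ped: Pedigree,
    child_id: str,
    haplotype_pairs: Mapping[str, Tuple[HaplotypeAllele, HaplotypeAllele]],
    panel: Sequence[Marker],
) -> TransmissionVerdict:
    """Check a child's reconstructed allele pair against its parents'.

    With both parents available, the two child alleles must be assignable
    one-per-parent, each carried by its parent. With one parent available,
    at least one child allele must be carried by that parent. With no
    parental data the verdict is uninformative.
    """
    if child_id not in haplotype_pairs:
        return TransmissionVerdict("uninformative", "child haplotypes unknown")
    child = haplotype_pairs[child_id]
    ind = ped[child_id]
    parents = [
        pid
        for pid in (ind.father_id, ind.mother_id)
        if pid is not None and pid in haplotype_pairs
    ]
    if not parents:
        return TransmissionVerdict("uninformative", "no parental haplotype data")

    if len(parents) == 2:
        p1, p2 = (haplotype_pairs[p] for p in parents)
        c1, c2 = child
        if (_allele_in(c1, p1) and _allele_in(c2, p2)) or (
            _allele_in(c2, p1) and _allele_in(c1, p2)
        ):
            return TransmissionVerdict("confirmed")
        bad = c1 if not (_allele_in(c1, p1) or _allele_in(c1, p2)) else c2
        marker = _first_mismatch(panel, bad, list(p1) + list(p2))
        return TransmissionVerdict(
            "contradicted", f"child allele unmatched in parents at marker {marker}"
        )

    pair = haplotype_pairs[parents[0]]
    if _allele_in(child[0], pair) or _allele_in(child[1], pair):
        return TransmissionVerdict("confirmed")
    marker = _first_mismatch(panel, child[0], pair)
    return TransmissionVerdict(
        "contradicted",
        f"neither child allele carried by parent {parents[0]} (first mismatch at {marker})",
    )


def enumerate_distinct_alleles(
    haplotypes: Iterable[HaplotypeAllele],
) -> Tuple[int, List[HaplotypeAllele], List[HaplotypeAllele]]:
    """(count, representatives, unresolved).

    Distinctness is exact equality of (states, focal). "?" matches nothing:
    haplotypes with ambiguous positions are returned unresolved and do not
    enter the count.
    """
    seen: Dict[Tuple[Tuple[str, ...], str], HaplotypeAllele] = {}
    unresolved: List[HaplotypeAllele] = []
    for h in haplotypes:
        if not h.resolved:
            unresolved.append(h)
            continue
        seen.setdefault((h.states, h.focal), h)
    reps = [seen[k] for k in sorted(seen)]
    return len(reps), reps, unresolved


# ---------------------------------------------------------------------------
# TSV I/O (panel: name<TAB>kind; genotypes: individual x marker, "s1/s2")
# ---------------------------------------------------------------------------


def read_panel_tsv(path: str | os.PathLike) -> List[Marker]:
    panel = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[1].strip() if len(fields) > 1 else "snv"
            panel.append(Marker(fields[0].strip(), kind))
    return panel


def read_marker_genotypes_tsv(
    path: str | os.PathLike,
) -> Dict[str, Dict[str, Tuple[str, str]]]:
    """Rows are individuals, columns markers (header row), cells "s1/s2"."""
    table: Dict[str, Dict[str, Tuple[str, str]]] = {}
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            iid = fields[0]
            genos: Dict[str, Tuple[str, str]] = {}
            for mk, cell in zip(header, fields[1:]):
                cell = cell.strip()
                if not cell or cell == "./.":
                    continue
                a, _, b = cell.partition("/")
                genos[mk] = tuple(sorted((a, b)))
            table[iid] = genos
    return table
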