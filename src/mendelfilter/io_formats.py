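"""Readers and writers for the formats the pipeline touches.

VCF 4.2 is read and written through pysam. Annotations ride in a flat INFO
schema (one scalar per key), which keeps fixtures hand-writable:

====================  =======================================================
INFO key              meaning
====================  =======================================================
``GENE``              gene symbol
``FUNC``              functional class (see :class:`~mendelfilter.core.FuncClass`)
``HGVSC`` / ``HGVSP`` coding / protein change labels
``AF_<db>``           alternate-allele frequency in database ``<db>`` (open set)
``PP2_SCORE``         PolyPhen-2 HumVar score in [0, 1]
``PP2_CAT``           PolyPhen-2 category (benign/possibly_damaging/probably_damaging)
``SIFT`` ``MT``       SIFT / MutationTaster verdicts
``LRT`` ``PHYLOP``    LRT verdict / PhyloP conservation score
====================  =======================================================

Unknown INFO keys are ignored, never fatal; missing keys yield absent fields.
Multiallelic records are decomposed into one Variant per alternate allele.
Genotypes are consumed as unphased; a phased separator is accepted and its
phase ignored.
"""

from __future__ import annotations

import csv
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pysam

from .core import (
    Affection,
    FuncClass,
    GenotypeCall,
    Individual,
    Pedigree,
    PedigreeError,
    Pp2Category,
    PredictionProfile,
    Sex,
    Variant,
    VariantKey,
    Zygosity,
)

__all__ = [
    "AnnotationSchema",
    "DEFAULT_SCHEMA",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_gene_list",
    "read_known_catalog",
    "write_variant_tsv",
    "write_summary_json",
    "SUMMARY_FORMAT_VERSION",
]

SUMMARY_FORMAT_VERSION = 1

_SCALAR_KEYS = {
    "GENE": str,
    "FUNC": str,
    "HGVSC": str,
    "HGVSP": str,
    "PP2_SCORE": float,
    "PP2_CAT": str,
    "SIFT": str,
    "MT": str,
    "LRT": str,
    "PHYLOP": float,
}


@dataclass
class AnnotationSchema:
    """Parsing rules for the flat INFO annotation encoding.

    ``af_prefix`` keys are repeatable: every INFO key starting with the
    prefix contributes one entry to ``Variant.pop_freqs`` under the
    lower-cased suffix (``AF_exac`` -> ``pop_freqs["exac"]``).
    """

    af_prefix: str = "AF_"
    scalar_keys: Mapping[str, type] = field(default_factory=lambda: dict(_SCALAR_KEYS))


DEFAULT_SCHEMA = AnnotationSchema()


class VcfParseError(ValueError):
    pass


def _scalar(value):
    """pysam returns tuples for Number=. fields; collapse singletons."""
    if isinstance(value, tuple):
        if len(value) != 1:
            return value[0]
        value = value[0]
    return value


def _parse_func(raw: Optional[str]) -> FuncClass:
    if raw is None:
        return FuncClass.OTHER_CODING
    try:
        return FuncClass(raw)
    except ValueError:
        return FuncClass.OTHER_CODING


def _parse_pp2_cat(raw: Optional[str]) -> Optional[Pp2Category]:
    if raw is None:
        return None
    try:
        return Pp2Category(raw)
    except ValueError:
        return None


def _variant_from_record(rec, alt_index: int, schema: AnnotationSchema) -> Variant:
    info = rec.info
    pop_freqs: Dict[str, float] = {}
    for key in info.keys():
        if key.startswith(schema.af_prefix):
            db = key[len(schema.af_prefix):].lower()
            try:
                pop_freqs[db] = float(_scalar(info[key]))
            except (TypeError, ValueError):
                continue

    def get_str(key: str) -> Optional[str]:
        if key in info:
            v = _scalar(info[key])
            return None if v is None else str(v)
        return None

    def get_float(key: str) -> Optional[float]:
        if key in info:
            try:
                return float(_scalar(info[key]))
            except (TypeError, ValueError):
                return None
        return None

    predictions = PredictionProfile(
        polyphen2_score=get_float("PP2_SCORE"),
        polyphen2_category=_parse_pp2_cat(get_str("PP2_CAT")),
        sift=get_str("SIFT"),
        mutation_taster=get_str("MT"),
        lrt=get_str("LRT"),
        phylop=get_float("PHYLOP"),
    )
    return Variant(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=rec.alts[alt_index],
        gene=get_str("GENE") or "",
        hgvs_c=get_str("HGVSC") or "",
        hgvs_p=get_str("HGVSP") or "",
        func_class=_parse_func(get_str("FUNC")),
        pop_freqs=pop_freqs,
        predictions=predictions,
    )


def _zygosity_from_gt(gt: Optional[Tuple], focal_allele: int) -> Zygosity:
    if gt is None or any(a is None for a in gt):
        return Zygosity.MISSING
    dose = sum(1 for a in gt if a == focal_allele)
    if dose == 0:
        return Zygosity.WT
    if dose == 1:
        return Zygosity.HET
    return Zygosity.HOM_ALT


def read_vcf(
    path: str | os.PathLike, schema: AnnotationSchema = DEFAULT_SCHEMA
) -> Tuple[List[Variant], Dict[VariantKey, List[GenotypeCall]]]:
    """Read a VCF 4.2 with GT, decomposing multiallelic records per alt.

    Returns the variants in file order and, per variant key, genotype calls
    in the sample order of the header.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header ({exc})") from exc
    variants: List[Variant] = []
    genotypes: Dict[VariantKey, List[GenotypeCall]] = {}
    samples = list(vf.header.samples)
    with vf:
        for line_no, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue
            for ai in range(len(rec.alts)):
                try:
                    v = _variant_from_record(rec, ai, schema)
                except ValueError as exc:
                    raise VcfParseError(
                        f"{path}: record {line_no} ({rec.chrom}:{rec.pos}): {exc}"
                    ) from exc
                calls = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    calls.append(GenotypeCall(s, _zygosity_from_gt(gt, ai + 1)))
                variants.append(v)
                genotypes[v.key] = calls
    return variants, genotypes


_GT_TUPLE = {
    Zygosity.WT: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
    Zygosity.MISSING: (None, None),
}


def write_vcf(
    path: str | os.PathLike,
    variants: Sequence[Variant],
    genotypes: Mapping[VariantKey, Sequence[GenotypeCall]],
    samples: Optional[Sequence[str]] = None,
    schema: AnnotationSchema = DEFAULT_SCHEMA,
) -> None:
    """Write biallelic records (one per Variant) with the flat INFO schema."""
    if samples is None:
        seen: Dict[str, None] = {}
        for calls in genotypes.values():
            for c in calls:
                seen.setdefault(c.individual_id, None)
        samples = list(seen)

    header = pysam.VariantHeader()
    contigs: Dict[str, None] = {}
    for v in variants:
        contigs.setdefault(v.chrom, None)
    for c in contigs:
        header.contigs.add(c)
    af_dbs: Dict[str, None] = {}
    for v in variants:
        for db in v.pop_freqs:
            af_dbs.setdefault(db, None)
    for key, typ in _SCALAR_KEYS.items():
        vcf_type = "Float" if typ is float else "String"
        header.info.add(key, 1, vcf_type, f"{key} annotation")
    for db in af_dbs:
        header.info.add(
            f"{schema.af_prefix}{db}", 1, "Float", f"alt allele frequency in {db}"
        )
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            info_pairs = [
                ("GENE", v.gene or None),
                ("FUNC", v.func_class.value),
                ("HGVSC", v.hgvs_c or None),
                ("HGVSP", v.hgvs_p or None),
                ("PP2_SCORE", v.predictions.polyphen2_score),
                (
                    "PP2_CAT",
                    v.predictions.polyphen2_category.value
                    if v.predictions.polyphen2_category
                    else None,
                ),
                ("SIFT", v.predictions.sift),
                ("MT", v.predictions.mutation_taster),
                ("LRT", v.predictions.lrt),
                ("PHYLOP", v.predictions.phylop),
            ]
            for db, f in v.pop_freqs.items():
                info_pairs.append((f"{schema.af_prefix}{db}", f))
            for k, val in info_pairs:
                if val is not None:
                    rec.info[k] = val
            calls = genotypes.get(v.key, ())
            by_id = {c.individual_id: c.zygosity for c in calls}
            for s in samples:
                rec.samples[s]["GT"] = _GT_TUPLE[by_id.get(s, Zygosity.MISSING)]
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_ped(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column PED (FID IID PAT MAT SEX PHENO) into a Pedigree.

    ``0`` parents become None; SEX 0 and PHENO 0/-9 map to unknown.
    Individual ids must be unique (parent links resolve by IID, so families
    sharing an ancestor merge into one connected component).
    """
    individuals: List[Individual] = []
    seen: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{line_no}: expected 6 columns, got {len(fields)}"
                )
            fid, iid, pat, mat, sex, pheno = fields[:6]
            if (fid, iid) in seen:
                raise PedigreeError(f"{path}:{line_no}: duplicate individual {iid!r} in {fid!r}")
            seen.add((fid, iid))
            if iid in (pat, mat):
                raise PedigreeError(f"{path}:{line_no}: {iid!r} is its own parent")
            individuals.append(
                Individual(
                    id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX.get(sex, Sex.UNKNOWN),
                    affection=_PHENO.get(pheno, Affection.UNKNOWN),
                )
            )
    return Pedigree(individuals)


_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}


def write_ped(path: str | os.PathLike, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for iid in ped.individuals:
            ind = ped[iid]
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        _PHENO_OUT[ind.affection],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene list / known-pathogenic catalog
# ---------------------------------------------------------------------------


def read_gene_list(path: str | os.PathLike) -> Set[str]:
    """One gene symbol per line; '#' comments and blanks skipped; case kept."""
    genes: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split()[0])
    if not genes:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return genes


def read_known_catalog(path: str | os.PathLike) -> Set[Tuple[str, str]]:
    """TSV with >=2 columns: gene symbol, coding-change label (hgvs_c)."""
    catalog: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected >=2 tab-separated columns")
            catalog.add((fields[0].strip(), fields[1].strip()))
    if not catalog:
        warnings.warn(f"known-variant catalog {path} is empty", stacklevel=2)
    return catalog


# ---------------------------------------------------------------------------
# result writers (versioned, machine-parseable)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "hgvs_c",
    "hgvs_p",
    "func_class",
    "max_pop_freq",
    "pp2_score",
    "pp2_category",
]


def write_variant_tsv(path: str | os.PathLike, variants: Iterable[Variant]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.hgvs_c,
                    v.hgvs_p,
                    v.func_class.value,
                    "" if v.max_pop_freq is None else repr(v.max_pop_freq),
                    ""
                    if v.predictions.polyphen2_score is None
                    else repr(v.predictions.polyphen2_score),
                    v.predictions.polyphen2_category.value
                    if v.predictions.polyphen2_category
                    else "",
                ]
            )


def write_summary_json(path: str | os.PathLike, payload: Mapping) -> None:
    doc = {"format_version": SUMMARY_FORMAT_VERSION}
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
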