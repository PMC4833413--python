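"""Synthetic study generator.

Produces pedigrees, Mendelian genotypes, annotations and phenotypes with
the statistical structure the downstream analyses assume, plus phased truth
for oracle tests. The generator emulates a recessive-disease exome study in
a founder population: small families ascertained through affected sibships,
one planted biallelic causal variant per scenario, background coding
variation with a mixed frequency spectrum, environmental phenocopies, and
an optional case/control cohort with a founder carrier frequency.

Founders draw alleles from the configured frequencies; non-founders inherit
one allele per parent uniformly at random. Affection = homozygous causal
(subject to penetrance) OR an independent phenocopy draw. Variants are
unlinked (no LD or recombination model — no downstream stage depends on
linkage). Everything is driven by one integer seed and is reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    Affection,
    FuncClass,
    GenotypeCall,
    Individual,
    Pedigree,
    Pp2Category,
    PredictionProfile,
    Sex,
    Variant,
    VariantKey,
    Zygosity,
)
from .io_formats import write_ped, write_vcf
from .fixtures import StudyFixture, fixture_reference_families  # noqa: F401  (re-export)

__all__ = [
    "FamilySpec",
    "CausalSpec",
    "CohortSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "SimulationError",
    "simulate_study",
    "write_study",
    "simulate_founder_haplotypes",
    "fixture_reference_families",
    "DEFAULT_GENE_MAP",
    "DEFAULT_CANDIDATE_GENES",
    "carrier_to_allele_freq",
]

MAX_REJECTION_ATTEMPTS = 10_000


class SimulationError(ValueError):
    """Requested structure cannot be realized (after bounded retries)."""


# ---------------------------------------------------------------------------
# toy gene map: (symbol, chrom, start, end, is_candidate)
# Candidate genes are recessive deafness genes; the rest are large,
# frequently-hit background genes. Coordinates are order-of-magnitude
# realistic, nothing downstream depends on them.
# ---------------------------------------------------------------------------

DEFAULT_GENE_MAP: List[Tuple[str, str, int, int, bool]] = [
    ("GJB2", "chr13", 20761609, 20767037, True),
    ("GJB6", "chr13", 20796110, 20806534, True),
    ("SLC26A4", "chr7", 107301080, 107358254, True),
    ("OTOF", "chr2", 26680071, 26781566, True),
    ("MYO7A", "chr11", 76839310, 76926284, True),
    ("MYO15A", "chr17", 18012020, 18083116, True),
    ("CDH23", "chr10", 73156691, 73575704, True),
    ("PCDH15", "chr10", 55562531, 57387702, True),
    ("TMC1", "chr9", 75136717, 75451549, True),
    ("TMPRSS3", "chr21", 43791999, 43816955, True),
    ("OTOG", "chr11", 17568850, 17672606, True),
    ("TECTA", "chr11", 120971882, 121062202, True),
    ("STRC", "chr15", 43891997, 43910994, True),
    ("LOXHD1", "chr18", 44056935, 44236996, True),
    ("RAI1", "chr17", 17584787, 17714767, True),
    ("TTN", "chr2", 179390716, 179695529, False),
    ("OBSCN", "chr1", 228395830, 228566577, False),
    ("MUC16", "chr19", 8959520, 9092018, False),
    ("SYNE1", "chr6", 152442819, 152958534, False),
    ("DNAH5", "chr5", 13690440, 13944589, False),
    ("APOB", "chr2", 21224301, 21266945, False),
    ("FLG", "chr1", 152274651, 152297679, False),
    ("AHNAK", "chr11", 62433542, 62556240, False),
    ("RYR1", "chr19", 38924340, 39078204, False),
    ("PLEC", "chr8", 144989321, 145050902, False),
    ("LRP1", "chr12", 57522276, 57607134, False),
    ("FAT1", "chr4", 187508937, 187647876, False),
    ("HMCN1", "chr1", 185703683, 186160085, False),
    ("USH2A", "chr1", 215796236, 216596738, False),
    ("DST", "chr6", 56322785, 56819426, False),
    ("MACF1", "chr1", 39546988, 39952849, False),
    ("COL6A3", "chr2", 238232646, 238323018, False),
    ("ABCA13", "chr7", 48211056, 48687091, False),
    ("SSPO", "chr7", 149483025, 149558362, False),
    ("NEB", "chr2", 152341850, 152591001, False),
    ("CSMD1", "chr8", 2792875, 4852494, False),
    ("ZFHX4", "chr8", 77593514, 77779521, False),
    ("KMT2C", "chr7", 151832010, 152133090, False),
    ("DNAH11", "chr7", 21582833, 21941457, False),
    ("PKHD1L1", "chr8", 110374635, 110543964, False),
]

DEFAULT_CANDIDATE_GENES = frozenset(g for g, *_rest, cand in DEFAULT_GENE_MAP if cand)

_BASES = ("A", "C", "G", "T")

# functional-class mix of simulated background coding variation
_CLASS_MIX: List[Tuple[FuncClass, float]] = [
    (FuncClass.SYNONYMOUS, 0.40),
    (FuncClass.MISSENSE, 0.35),
    (FuncClass.SPLICE, 0.05),
    (FuncClass.NONSENSE, 0.03),
    (FuncClass.FRAMESHIFT, 0.02),
    (FuncClass.OTHER_CODING, 0.05),
    (FuncClass.NONCODING, 0.10),
]


def carrier_to_allele_freq(carrier_freq: float) -> float:
    """Allele frequency p with het fraction 2p(1-p) equal to carrier_freq."""
    if not 0.0 <= carrier_freq < 0.5:
        raise SimulationError(f"carrier frequency {carrier_freq} outside [0, 0.5)")
    return 0.5 * (1.0 - float(np.sqrt(1.0 - 2.0 * carrier_freq)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    template: str = "sibship_with_parents"  # | three_generation | combined_two_family
    n_affected_sibs: int = 2
    n_unaffected_sibs: int = 1
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.template not in (
            "sibship_with_parents",
            "three_generation",
            "combined_two_family",
        ):
            raise SimulationError(f"unknown template {self.template!r}")
        if self.n_affected_sibs < 0 or self.n_unaffected_sibs < 0:
            raise SimulationError("sib counts must be >= 0")


@dataclass
class CausalSpec:
    gene: str = "OTOF"
    carrier_freq: float = 0.033  # founder/population het fraction
    penetrance: float = 1.0


@dataclass
class CohortSpec:
    n_case_families: int = 0
    n_controls: int = 0
    control_carrier_freq: float = 0.033


@dataclass
class SimulationConfig:
    seed: int = 0
    family_specs: List[FamilySpec] = field(default_factory=lambda: [FamilySpec()])
    causal: CausalSpec = field(default_factory=CausalSpec)
    phenocopy_rate: float = 0.0
    n_background_variants: int = 500
    background_af_mix: Tuple[float, float, float] = (0.50, 0.35, 0.15)  # common/rare/novel
    cohort: Optional[CohortSpec] = None

    def __post_init__(self) -> None:
        for r in (self.phenocopy_rate, self.causal.penetrance):
            if not 0.0 <= r <= 1.0:
                raise SimulationError(f"rate {r} outside [0, 1]")
        if self.n_background_variants < 0:
            raise SimulationError("n_background_variants must be >= 0")
        if abs(sum(self.background_af_mix) - 1.0) > 1e-9:
            raise SimulationError("background_af_mix must sum to 1")
        if self.causal.gene not in {g for g, *_ in DEFAULT_GENE_MAP}:
            raise SimulationError(f"causal gene {self.causal.gene!r} not on the gene map")


@dataclass
class SimulatedStudy:
    variants: List[Variant]  # index 0 is the causal variant
    ped: Pedigree
    causal: Variant
    truth: Dict
    config: SimulationConfig

    @property
    def causal_key(self) -> VariantKey:
        return self.causal.key


# ---------------------------------------------------------------------------
# family structures
# ---------------------------------------------------------------------------


def _structure(
    spec: FamilySpec, fid: str
) -> Tuple[List[Individual], Set[str], Set[str], List[str]]:
    """Returns (individuals in parents-first order, forced-het founder ids,
    required-het non-founder ids, designated sibship ids)."""
    inds: List[Individual] = []
    forced: Set[str] = set()
    required: Set[str] = set()
    n_sibs = spec.n_affected_sibs + spec.n_unaffected_sibs

    def add(iid, fa=None, mo=None, sex=Sex.UNKNOWN):
        inds.append(Individual(f"{fid}-{iid}", fid, fa and f"{fid}-{fa}", mo and f"{fid}-{mo}", sex))
        return f"{fid}-{iid}"

    if spec.template == "sibship_with_parents":
        fa = add("I-1", sex=Sex.MALE)
        mo = add("I-2", sex=Sex.FEMALE)
        if spec.n_affected_sibs > 0:
            forced.update({fa, mo})
        sibs = [add(f"II-{j + 1}", "I-1", "I-2") for j in range(n_sibs)]
    elif spec.template == "three_generation":
        add("I-1", sex=Sex.MALE)
        add("I-2", sex=Sex.FEMALE)
        fa = add("II-1", "I-1", "I-2", Sex.MALE)
        mo = add("II-2", sex=Sex.FEMALE)
        if spec.n_affected_sibs > 0:
            forced.update({f"{fid}-I-1", mo})
            required.add(fa)
        sibs = [add(f"III-{j + 1}", "II-1", "II-2") for j in range(n_sibs)]
    else:  # combined_two_family: two sibships whose mothers are sisters
        add("I-1", sex=Sex.MALE)
        add("I-2", sex=Sex.FEMALE)
        moA = add("II-1", "I-1", "I-2", Sex.FEMALE)
        faA = add("II-2", sex=Sex.MALE)
        moB = add("II-3", "I-1", "I-2", Sex.FEMALE)
        add("II-4", sex=Sex.MALE)
        if spec.n_affected_sibs > 0:
            forced.update({f"{fid}-I-1", faA})
            required.add(moA)
        sibs = [add(f"III-{j + 1}", "II-2", "II-1") for j in range(n_sibs)]
        add(f"III-{n_sibs + 1}", "II-4", "II-3")
        add(f"III-{n_sibs + 2}", "II-4", "II-3")
    return inds, forced, required, sibs


def _draw_causal_and_phenotypes(
    inds: List[Individual],
    forced_het: Set[str],
    required_het: Set[str],
    sibs: List[str],
    n_affected: int,
    p_allele: float,
    penetrance: float,
    phenocopy_rate: float,
    rng: np.random.Generator,
) -> Tuple[Dict[str, Tuple[int, int]], Dict[str, bool], Set[str]]:
    """Rejection-sample causal genotypes and phenotypes for one family."""
    for _ in range(MAX_REJECTION_ATTEMPTS):
        hap: Dict[str, Tuple[int, int]] = {}
        for ind in inds:
            if ind.is_founder:
                if ind.id in forced_het:
                    hap[ind.id] = (1, 0) if rng.integers(2) else (0, 1)
                else:
                    hap[ind.id] = (
                        int(rng.random() < p_allele),
                        int(rng.random() < p_allele),
                    )
            else:
                pa = hap[ind.father_id][rng.integers(2)]
                ma = hap[ind.mother_id][rng.integers(2)]
                hap[ind.id] = (pa, ma)
        if any(sum(hap[iid]) != 1 for iid in required_het):
            continue
        affected: Dict[str, bool] = {}
        phenocopies: Set[str] = set()
        for ind in inds:
            hom = sum(hap[ind.id]) == 2
            genetic = hom and (rng.random() < penetrance)
            pheno = rng.random() < phenocopy_rate
            affected[ind.id] = genetic or pheno
            if pheno and not genetic:
                phenocopies.add(ind.id)
        if sum(affected[s] for s in sibs) == n_affected:
            return hap, affected, phenocopies
    raise SimulationError(
        f"could not realize {n_affected} affected sibs in {MAX_REJECTION_ATTEMPTS} attempts"
    )


# ---------------------------------------------------------------------------
# variant panel
# ---------------------------------------------------------------------------


def _make_causal_variant(gene: str, rng: np.random.Generator) -> Variant:
    row = next(r for r in DEFAULT_GENE_MAP if r[0] == gene)
    _, chrom, start, end, _ = row
    pos = int((start + end) // 2)
    ref, alt = "G", "A"
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        hgvs_c=f"c.{pos - start}G>A",
        hgvs_p="p.Gly?Arg",
        func_class=FuncClass.MISSENSE,
        pop_freqs={},  # novel: absent from every database
        predictions=PredictionProfile(
            polyphen2_score=0.99,
            polyphen2_category=Pp2Category.PROBABLY_DAMAGING,
            sift="damaging",
            mutation_taster="disease_causing",
            lrt="deleterious",
            phylop=6.5,
        ),
    )


def _make_background_variants(
    n: int, af_mix: Tuple[float, float, float], rng: np.random.Generator
) -> Tuple[List[Variant], List[float]]:
    """Background variants plus their true segregating allele frequencies."""
    classes = [c for c, _ in _CLASS_MIX]
    class_p = np.array([w for _, w in _CLASS_MIX])
    class_p = class_p / class_p.sum()
    variants: List[Variant] = []
    sim_freqs: List[float] = []
    used: Set[VariantKey] = set()
    while len(variants) < n:
        gi = int(rng.integers(len(DEFAULT_GENE_MAP)))
        gene, chrom, start, end, _ = DEFAULT_GENE_MAP[gi]
        pos = int(rng.integers(start, end))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        key = (chrom, pos, str(ref), str(alt))
        if key in used:
            continue
        used.add(key)
        func = classes[int(rng.choice(len(classes), p=class_p))]

        # database frequencies are kept to 6 significant digits (the
        # precision VCF Float fields survive a write/read round trip at)
        sig6 = lambda x: float(f"{x:.6g}")
        bucket = rng.random()
        pop_freqs: Dict[str, float] = {}
        if bucket < af_mix[0]:  # common
            q = float(rng.uniform(0.05, 0.5))
            pop_freqs = {
                "1kg": sig6(q),
                "exac": sig6(min(1.0, q * float(rng.uniform(0.8, 1.2)))),
            }
        elif bucket < af_mix[0] + af_mix[1]:  # rare but catalogued
            # locally truly rare (<=1% segregating) so that two unrelated
            # parents almost never carry the same rare allele; the database
            # frequency spans the whole sub-cutoff range
            q = float(rng.uniform(0.0005, 0.01))
            pop_freqs = {"exac": sig6(min(0.045, q * float(rng.uniform(0.5, 4.0))))}
        else:  # novel
            q = 0.005

        preds = PredictionProfile()
        if func in (FuncClass.MISSENSE, FuncClass.OTHER_CODING):
            u = rng.random()
            if u < 0.55:
                cat, score = Pp2Category.BENIGN, float(rng.uniform(0.0, 0.4))
            elif u < 0.75:
                cat, score = Pp2Category.POSSIBLY_DAMAGING, float(rng.uniform(0.45, 0.9))
            elif u < 0.90:
                cat, score = Pp2Category.PROBABLY_DAMAGING, float(rng.uniform(0.9, 1.0))
            else:
                cat, score = None, None  # unscored
            preds = PredictionProfile(polyphen2_score=score, polyphen2_category=cat)

        variants.append(
            Variant(
                chrom=chrom,
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                gene=gene,
                hgvs_c=f"c.{pos - start}{ref}>{alt}",
                func_class=func,
                pop_freqs=pop_freqs,
                predictions=preds,
            )
        )
        sim_freqs.append(q)
    return variants, sim_freqs


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete synthetic study from a config (seeded)."""
    rng = np.random.default_rng(config.seed)
    p_causal = carrier_to_allele_freq(config.causal.carrier_freq)

    causal = _make_causal_variant(config.causal.gene, rng)
    background, bg_freqs = _make_background_variants(
        config.n_background_variants, config.background_af_mix, rng
    )
    variants = [causal] + background
    bg_q = np.array(bg_freqs)

    all_inds: List[Individual] = []
    causal_hap: Dict[str, Tuple[int, int]] = {}
    phenocopies: Set[str] = set()
    affected_map: Dict[str, bool] = {}

    for idx, spec in enumerate(config.family_specs):
        fid = spec.family_id or f"SF{idx + 1:02d}"
        inds, forced, required, sibs = _structure(spec, fid)
        hap, affected, pcs = _draw_causal_and_phenotypes(
            inds,
            forced,
            required,
            sibs,
            spec.n_affected_sibs,
            p_causal,
            config.causal.penetrance,
            config.phenocopy_rate,
            rng,
        )
        causal_hap.update(hap)
        affected_map.update(affected)
        phenocopies.update(pcs)
        all_inds.extend(inds)

    if config.cohort is not None:
        all_inds_cohort, hapc, affc, pcsc = _draw_cohort(config, rng)
        all_inds.extend(all_inds_cohort)
        causal_hap.update(hapc)
        affected_map.update(affc)
        phenocopies.update(pcsc)

    for ind in all_inds:
        ind.affection = Affection.AFFECTED if affected_map[ind.id] else Affection.UNAFFECTED

    ped = Pedigree(all_inds)

    # background genotypes: founders from q, children by inheritance
    nbg = len(background)
    bg_hap: Dict[str, np.ndarray] = {}
    for ind in all_inds:  # construction order is parents-first
        if ind.is_founder:
            bg_hap[ind.id] = (rng.random((nbg, 2)) < bg_q[:, None]).astype(np.int8)
        else:
            pa = bg_hap[ind.father_id][np.arange(nbg), rng.integers(0, 2, nbg)]
            ma = bg_hap[ind.mother_id][np.arange(nbg), rng.integers(0, 2, nbg)]
            bg_hap[ind.id] = np.stack([pa, ma], axis=1).astype(np.int8)

    zyg_of = {0: Zygosity.WT, 1: Zygosity.HET, 2: Zygosity.HOM_ALT}
    ped.add_genotypes(
        causal.key, {iid: zyg_of[sum(h)] for iid, h in causal_hap.items()}
    )
    for j, v in enumerate(background):
        ped.add_genotypes(
            v.key, {ind.id: zyg_of[int(bg_hap[ind.id][j].sum())] for ind in all_inds}
        )

    truth = {
        "seed": config.seed,
        "causal_variant": causal.label(),
        "causal_gene": causal.gene,
        "phenocopies": sorted(phenocopies),
        "haplotypes": {
            ind.id: ["|".join(map(str, causal_hap[ind.id]))]
            + ["|".join(map(str, bg_hap[ind.id][j])) for j in range(nbg)]
            for ind in all_inds
        },
        "variant_order": [v.label() for v in variants],
    }
    return SimulatedStudy(variants=variants, ped=ped, causal=causal, truth=truth, config=config)


def _draw_cohort(config: SimulationConfig, rng: np.random.Generator):
    """Affected-ascertained single-proband case families plus unaffected
    control singletons drawn at the control carrier frequency."""
    cohort = config.cohort
    inds: List[Individual] = []
    hap: Dict[str, Tuple[int, int]] = {}
    affected: Dict[str, bool] = {}
    pcs: Set[str] = set()
    p = carrier_to_allele_freq(cohort.control_carrier_freq)

    for i in range(cohort.n_case_families):
        fid = f"CASE{i + 1:03d}"
        spec = FamilySpec("sibship_with_parents", 1, 0, family_id=fid)
        fam, _forced, req, sibs = _structure(spec, fid)
        h, a, pc = _draw_causal_and_phenotypes(
            fam, set(), req, sibs, 1, p, config.causal.penetrance, config.phenocopy_rate, rng
        )
        inds.extend(fam)
        hap.update(h)
        affected.update(a)
        pcs.update(pc)

    for i in range(cohort.n_controls):
        iid = f"CTRL{i + 1:03d}"
        for _ in range(MAX_REJECTION_ATTEMPTS):
            pair = (int(rng.random() < p), int(rng.random() < p))
            hom = sum(pair) == 2
            if not (hom and rng.random() < config.causal.penetrance) and not (
                rng.random() < config.phenocopy_rate
            ):
                break
        else:
            raise SimulationError("could not draw an unaffected control")
        inds.append(Individual(iid, iid, sex=Sex.UNKNOWN))
        hap[iid] = pair
        affected[iid] = False
    return inds, hap, affected, pcs


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, out_dir: str | os.PathLike) -> Dict[str, str]:
    """Write study.vcf / study.ped / truth.json / SCENARIO.txt; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "study.vcf"),
        "ped": os.path.join(out_dir, "study.ped"),
        "truth": os.path.join(out_dir, "truth.json"),
        "scenario": os.path.join(out_dir, "SCENARIO.txt"),
    }
    samples = [iid for iid in study.ped.individuals]
    genotypes = {
        key: [GenotypeCall(iid, table.get(iid, Zygosity.MISSING)) for iid in samples]
        for key, table in study.ped.genotypes.items()
    }
    write_vcf(paths["vcf"], study.variants, genotypes, samples=samples)
    write_ped(paths["ped"], study.ped)
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg = study.config
    with open(paths["scenario"], "w") as fh:
        fh.write(
            "Synthetic recessive-disease exome study\n"
            f"seed: {cfg.seed}\n"
            f"families: {[asdict(s) for s in cfg.family_specs]}\n"
            f"causal: {asdict(cfg.causal)}\n"
            f"phenocopy_rate: {cfg.phenocopy_rate}\n"
            f"background variants: {cfg.n_background_variants} "
            f"(common/rare/novel mix {cfg.background_af_mix})\n"
            f"cohort: {asdict(cfg.cohort) if cfg.cohort else None}\n"
        )
    return paths


# ---------------------------------------------------------------------------
# founder-haplotype simulation (for the haplotype module's oracle tests)
# ---------------------------------------------------------------------------


def simulate_founder_haplotypes(
    panel_size: int,
    n_het_carriers: int,
    n_hom_carriers: int,
    n_backgrounds: int,
    seed: int,
) -> Dict:
    """Single-origin founder scenario over an opaque marker panel.

    One mutant haplotype (allele_mut) is generated; every carrier holds it,
    het carriers pair it with a random background haplotype from a pool of
    ``n_backgrounds`` distinct wild-type alleles. Returns the panel, phased
    truth pairs and the unphased genotype table.
    """
    from .haplotype import HaplotypeAllele, Marker

    rng = np.random.default_rng(seed)
    panel = []
    state_space: List[List[str]] = []
    for i in range(panel_size):
        if i == panel_size // 2:
            panel.append(Marker(f"rep{i}", "repeat"))
            states = [
                f"Q{n}[CAG CAA (CAG){n} del(CAG) CAA]" for n in (10, 12, 13, 15)
            ]
        else:
            panel.append(Marker(f"rs{1000 + i}", "snv"))
            states = list(rng.choice(_BASES, size=2, replace=False))
        state_space.append([str(s) for s in states])

    def random_allele(focal: str) -> "HaplotypeAllele":
        return HaplotypeAllele(
            tuple(str(rng.choice(st)) for st in state_space), focal=focal
        )

    allele_mut = random_allele("mut")
    pool = []
    while len(pool) < n_backgrounds:
        cand = random_allele("wt")
        if cand.states != allele_mut.states and cand not in pool:
            pool.append(cand)

    truth: Dict[str, Tuple] = {}
    genotypes: Dict[str, Dict[str, Tuple[str, str]]] = {}
    for i in range(n_hom_carriers):
        iid = f"HOM{i + 1:03d}"
        truth[iid] = (allele_mut, allele_mut)
    for i in range(n_het_carriers):
        iid = f"HET{i + 1:03d}"
        other = pool[int(rng.integers(len(pool)))]
        truth[iid] = (allele_mut, other)
    for iid, (h1, h2) in truth.items():
        genotypes[iid] = {
            mk.name: tuple(sorted((h1.states[j], h2.states[j])))
            for j, mk in enumerate(panel)
        }
    return {
        "panel": panel,
        "allele_mut": allele_mut,
        "background_pool": pool,
        "truth": truth,
        "genotypes": genotypes,
    }
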