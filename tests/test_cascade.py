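"""Filter-cascade stages against brute-force oracles and planted truth."""

import random

import pytest

from mendelfilter.cascade import (
    CascadeConfig,
    candidate_gene_filter,
    deleterious_filter,
    filter_functional,
    filter_rare,
    known_pathogenic_screen,
    run_cascade,
    shared_among_affected,
    zygosity_filter,
)
from mendelfilter.core import (
    Affection,
    FuncClass,
    Individual,
    Pedigree,
    Pp2Category,
    PredictionProfile,
    Variant,
    Zygosity,
)
from mendelfilter.fixtures import CANDIDATE_GENES
from mendelfilter.simulate import SimulationConfig, simulate_study

WT, HET, HOM = Zygosity.WT, Zygosity.HET, Zygosity.HOM_ALT


def _v(pos, gene="G1", func=FuncClass.MISSENSE, freqs=None, cat=None, chrom="chr1"):
    return Variant(
        chrom,
        pos,
        "A",
        "G",
        gene=gene,
        func_class=func,
        pop_freqs=freqs or {},
        predictions=PredictionProfile(polyphen2_category=cat),
    )


def make_family(parent_genos=None, sib_genos=(), n_sibs=2, affected_sibs=None):
    """Construct a nuclear family pedigree with per-variant genotypes.

    ``parent_genos``: {pos: (father_z, mother_z)} or None for untyped parents.
    ``sib_genos``: {pos: (z_sib1, z_sib2, ...)}.
    """
    from mendelfilter.core import Sex

    inds = [
        Individual("p1", "F1", sex=Sex.MALE, affection=Affection.UNAFFECTED),
        Individual("p2", "F1", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
    ]
    affected_sibs = list(range(n_sibs)) if affected_sibs is None else affected_sibs
    for i in range(n_sibs):
        inds.append(
            Individual(
                f"s{i + 1}",
                "F1",
                father_id="p1",
                mother_id="p2",
                affection=Affection.AFFECTED
                if i in affected_sibs
                else Affection.UNAFFECTED,
            )
        )
    ped = Pedigree(inds)
    for pos, zygs in sib_genos.items():
        table = {f"s{i + 1}": z for i, z in enumerate(zygs)}
        if parent_genos and pos in parent_genos:
            table["p1"], table["p2"] = parent_genos[pos]
        ped.add_genotypes(("chr1", pos, "A", "G"), table)
    return ped


def test_functional_filter_keeps_exactly_nonsynonymous():
    cfg = CascadeConfig()
    vs = [
        _v(1, func=FuncClass.MISSENSE),
        _v(2, func=FuncClass.SYNONYMOUS),
        _v(3, func=FuncClass.NONCODING),
        _v(4, func=FuncClass.FRAMESHIFT),
    ]
    assert [v.pos for v in filter_functional(vs, cfg)] == [1, 4]
    assert filter_functional([], cfg) == []


@pytest.mark.parametrize(
    "freqs,kept",
    [
        ({"exac": 0.0001021}, True),  # rare catalogued allele
        ({"1kg": 0.30}, False),  # common
        ({}, True),  # novel: absent from databases passes
        ({"exac": 0.001, "1kg": 0.30}, False),  # max over databases decides
        ({"exac": 0.05}, False),  # boundary: strictly below 5%
    ],
)
def test_rarity_filter_uses_max_over_databases(freqs, kept):
    cfg = CascadeConfig()
    out = filter_rare([_v(1, freqs=freqs)], cfg)
    assert bool(out) is kept


def test_shared_among_affected_intersection():
    ped = make_family(sib_genos={1: (HET, WT), 2: (HOM, HOM), 3: (HET, Zygosity.MISSING)})
    vs = [_v(1), _v(2), _v(3)]
    out = shared_among_affected(vs, ped, "F1")
    # v1 vetoed by the wt sib; v3 kept (missing genotype does not veto)
    assert [v.pos for v in out] == [2, 3]


def test_shared_matches_bruteforce_on_random_tables():
    rng = random.Random(5)
    zygs = [WT, HET, HOM, Zygosity.MISSING]
    for _ in range(25):
        n_v = rng.randint(1, 30)
        sib_genos = {
            pos: (rng.choice(zygs), rng.choice(zygs)) for pos in range(1, n_v + 1)
        }
        ped = make_family(sib_genos=sib_genos)
        vs = [_v(p) for p in sib_genos]
        got = {v.pos for v in shared_among_affected(vs, ped, "F1")}
        expected = set()
        for pos, (z1, z2) in sib_genos.items():  # independent per-variant scan
            ok = all(
                z in (HET, HOM, Zygosity.MISSING) for z in (z1, z2)
            )
            if ok:
                expected.add(pos)
        assert got == expected


def test_single_proband_degenerate_sharing():
    ped = make_family(sib_genos={1: (HET,), 2: (WT,)}, n_sibs=1)
    out = shared_among_affected([_v(1), _v(2)], ped, "F1")
    assert [v.pos for v in out] == [1]


def test_no_genotyped_affected_raises():
    ped = make_family(sib_genos={1: (HET, HET)}, affected_sibs=[])
    with pytest.raises(ValueError):
        shared_among_affected([_v(1)], ped, "F1")


def test_homozygous_zygosity_filter():
    ped = make_family(sib_genos={1: (HOM, HOM), 2: (HOM, HET)})
    calls = zygosity_filter([_v(1), _v(2)], ped, "F1", "homozygous")
    assert [c.variants[0].pos for c in calls] == [1]
    assert calls[0].model == "homozygous"


def test_compound_het_trans_called_cis_rejected():
    v1, v2 = _v(1, gene="GX"), _v(2, gene="GX")
    # trans: father carries v1 only, mother v2 only
    ped = make_family(
        parent_genos={1: (HET, WT), 2: (WT, HET)},
        sib_genos={1: (HET, HET), 2: (HET, HET)},
    )
    calls = zygosity_filter([v1, v2], ped, "F1", "compound_het")
    assert len(calls) == 1 and calls[0].model == "compound_het" and not calls[0].flags

    # cis: both variants from the father
    ped_cis = make_family(
        parent_genos={1: (HET, WT), 2: (HET, WT)},
        sib_genos={1: (HET, HET), 2: (HET, HET)},
    )
    assert zygosity_filter([v1, v2], ped_cis, "F1", "compound_het") == []


def test_compound_het_without_parents_is_phase_unconfirmed():
    ped = make_family(sib_genos={1: (HET, HET), 2: (HET, HET)})
    calls = zygosity_filter([_v(1, gene="GX"), _v(2, gene="GX")], ped, "F1", "compound_het")
    assert len(calls) == 1 and "phase-unconfirmed" in calls[0].flags


def test_candidate_and_deleterious_filters():
    cfg = CascadeConfig(candidate_genes=frozenset({"RAI1"}))
    from mendelfilter.cascade import CandidateCall

    keep = CandidateCall("RAI1", (_v(1, gene="RAI1", cat=Pp2Category.POSSIBLY_DAMAGING),), "homozygous")
    benign = CandidateCall("RAI1", (_v(2, gene="RAI1", cat=Pp2Category.BENIGN),), "homozygous")
    unscored = CandidateCall("RAI1", (_v(3, gene="RAI1"),), "homozygous")
    other = CandidateCall("TTN", (_v(4, gene="TTN", cat=Pp2Category.PROBABLY_DAMAGING),), "homozygous")

    in_cand = candidate_gene_filter([keep, benign, unscored, other], cfg)
    assert {c.variants[0].pos for c in in_cand} == {1, 2, 3}
    kept, side = deleterious_filter(in_cand, cfg)
    assert [c.variants[0].pos for c in kept] == [1]
    assert [c.variants[0].pos for c in side] == [3]  # absent prediction, reported


def test_comphet_deleterious_strictness_switch():
    from mendelfilter.cascade import CandidateCall

    pair = CandidateCall(
        "GX",
        (
            _v(1, gene="GX", cat=Pp2Category.PROBABLY_DAMAGING),
            _v(2, gene="GX", cat=Pp2Category.BENIGN),
        ),
        "compound_het",
    )
    strict = CascadeConfig(candidate_genes=frozenset({"GX"}))
    lax = CascadeConfig(candidate_genes=frozenset({"GX"}), comphet_requires_both_damaging=False)
    assert deleterious_filter([pair], strict)[0] == []
    assert len(deleterious_filter([pair], lax)[0]) == 1


def test_known_pathogenic_screen_on_single_proband(ref_fx):
    cfg = CascadeConfig(known_catalog=ref_fx.known_catalog)
    variants = list(ref_fx.variants.values())
    calls = known_pathogenic_screen(variants, ref_fx.families, "53-II-1", cfg)
    assert len(calls) == 1
    assert calls[0].gene == "SLC26A4" and "zygosity=hom_alt" in calls[0].flags

    # wt proband at every catalogued site -> empty
    assert known_pathogenic_screen(variants, ref_fx.families, "38-II-1", cfg) == []

    # a catalogued but common variant is excluded by the rarity gate
    common = Variant("chr1", 99, "A", "G", gene="GJB2", hgvs_c="c.35delG",
                     func_class=FuncClass.MISSENSE, pop_freqs={"1kg": 0.3})
    ped = make_family(sib_genos={99: (HET,)}, n_sibs=1)
    assert known_pathogenic_screen([common], ped, "s1", cfg) == []


def _bruteforce_final_homozygous(study, cfg):
    """Independent single-pass predicate for the homozygous cascade path."""
    affected = [
        i.id
        for i in study.ped.individuals.values()
        if i.family_id == "SF01" and i.affection is Affection.AFFECTED
    ]
    out = set()
    for v in study.variants:
        if v.func_class.value not in ("missense", "nonsense", "frameshift", "splice"):
            continue
        if v.pop_freqs and max(v.pop_freqs.values()) >= cfg.max_af:
            continue
        zygs = [study.ped.zygosity(v.key, i) for i in affected]
        typed = [z for z in zygs if z is not Zygosity.MISSING]
        if not typed or any(z is WT for z in typed):
            continue
        if any(z is not HOM for z in typed):
            continue
        if v.gene not in cfg.candidate_genes:
            continue
        if v.predictions.polyphen2_category is None or v.predictions.polyphen2_category.value not in (
            "possibly_damaging",
            "probably_damaging",
        ):
            continue
        out.add(v.key)
    return out


def test_cascade_equals_bruteforce_oracle(sim_study, cascade_cfg):
    cfg = CascadeConfig(
        candidate_genes=cascade_cfg.candidate_genes,
        known_catalog=cascade_cfg.known_catalog,
        zygosity_mode="homozygous",
    )
    result = run_cascade(sim_study.variants, sim_study.ped, cfg, family_ids=["SF01"])[0]
    got = {v.key for v in result.stage_survivors["predicted_deleterious"]}
    assert got == _bruteforce_final_homozygous(sim_study, cfg)


def test_planted_causal_recovered_across_seeds(cascade_cfg):
    for seed in range(20, 40):
        study = simulate_study(SimulationConfig(seed=seed, n_background_variants=200))
        r = run_cascade(study.variants, study.ped, cascade_cfg, family_ids=["SF01"])[0]
        assert len(r.final_calls) == 1
        assert r.final_calls[0].gene == study.causal.gene
        assert r.check_monotone()


def test_causal_gene_outside_candidate_list_yields_no_call(sim_study):
    cfg = CascadeConfig(candidate_genes=frozenset({"GJB2"}))
    r = run_cascade(sim_study.variants, sim_study.ped, cfg, family_ids=["SF01"])[0]
    assert r.final_calls == []
    assert r.stage_survivors["in_candidate_genes"] == []


def test_survivor_sets_independent_of_input_order(sim_study, cascade_cfg):
    rng = random.Random(0)
    shuffled = list(sim_study.variants)
    rng.shuffle(shuffled)
    a = run_cascade(sim_study.variants, sim_study.ped, cascade_cfg, family_ids=["SF01"])[0]
    b = run_cascade(shuffled, sim_study.ped, cascade_cfg, family_ids=["SF01"])[0]
    for stage in a.stage_survivors:
        assert {v.key for v in a.stage_survivors[stage]} == {
            v.key for v in b.stage_survivors[stage]
        }


def test_stage_counts_weakly_decrease_over_seeds(cascade_cfg):
    for seed in range(50, 80):
        study = simulate_study(
            SimulationConfig(seed=seed, n_background_variants=100, phenocopy_rate=0.1)
        )
        r = run_cascade(study.variants, study.ped, cascade_cfg, family_ids=["SF01"])[0]
        assert r.check_monotone(), r.stage_counts
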