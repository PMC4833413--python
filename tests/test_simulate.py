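"""Generator contracts: determinism, genotype/phenotype model, truth files."""

import hashlib
import json

import numpy as np
import pytest

from mendelfilter.core import Affection, Zygosity, mendelian_violations
from mendelfilter.simulate import (
    CausalSpec,
    CohortSpec,
    FamilySpec,
    SimulationConfig,
    SimulationError,
    carrier_to_allele_freq,
    simulate_study,
    write_study,
)


def _digests(tmpdir):
    return {
        name: hashlib.sha256((tmpdir / name).read_bytes()).hexdigest()
        for name in ("study.vcf", "study.ped", "truth.json")
    }


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=5, n_background_variants=40)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_study(simulate_study(cfg), d1)
    write_study(simulate_study(SimulationConfig(seed=5, n_background_variants=40)), d2)
    assert _digests(d1) == _digests(d2)


def test_different_seeds_differ(tmp_path):
    a = simulate_study(SimulationConfig(seed=1, n_background_variants=20))
    b = simulate_study(SimulationConfig(seed=2, n_background_variants=20))
    assert a.truth["haplotypes"] != b.truth["haplotypes"]


def test_affected_iff_homozygous_causal_without_phenocopies():
    study = simulate_study(
        SimulationConfig(
            seed=3,
            phenocopy_rate=0.0,
            n_background_variants=0,
            family_specs=[FamilySpec(n_affected_sibs=2, n_unaffected_sibs=2)],
        )
    )
    assert study.truth["phenocopies"] == []
    for iid, ind in study.ped.individuals.items():
        hom = study.ped.zygosity(study.causal_key, iid) is Zygosity.HOM_ALT
        assert (ind.affection is Affection.AFFECTED) == hom


def test_phenocopies_recorded_in_truth():
    study = simulate_study(
        SimulationConfig(
            seed=17,
            phenocopy_rate=0.5,
            n_background_variants=0,
            family_specs=[FamilySpec(n_affected_sibs=2, n_unaffected_sibs=3)],
        )
    )
    for iid in study.truth["phenocopies"]:
        assert study.ped[iid].affection is Affection.AFFECTED
        assert study.ped.zygosity(study.causal_key, iid) is not Zygosity.HOM_ALT


def test_founder_carrier_frequency_recovered_within_binomial_envelope():
    """1,000 control founders at carrier frequency 0.033: the realized het
    fraction lands within 3 binomial SDs."""
    kappa = 0.033
    study = simulate_study(
        SimulationConfig(
            seed=29,
            n_background_variants=0,
            family_specs=[],
            causal=CausalSpec(carrier_freq=kappa),
            cohort=CohortSpec(n_case_families=0, n_controls=1000, control_carrier_freq=kappa),
        )
    )
    controls = [i for i in study.ped.individuals if i.startswith("CTRL")]
    assert len(controls) == 1000
    het = sum(
        study.ped.zygosity(study.causal_key, i) is Zygosity.HET for i in controls
    )
    sd = np.sqrt(kappa * (1 - kappa) / 1000)
    assert abs(het / 1000 - kappa) < 3 * sd


def test_carrier_to_allele_freq_identity():
    for kappa in (0.01, 0.033, 0.2):
        p = carrier_to_allele_freq(kappa)
        assert 2 * p * (1 - p) == pytest.approx(kappa)


def test_truth_phases_consistent_with_genotypes():
    study = simulate_study(SimulationConfig(seed=13, n_background_variants=25))
    order = study.truth["variant_order"]
    keys = [v.key for v in study.variants]
    assert [v.label() for v in study.variants] == order
    for iid, phased in study.truth["haplotypes"].items():
        for key, hap in zip(keys, phased):
            a, b = (int(x) for x in hap.split("|"))
            dose = study.ped.zygosity(key, iid).alt_dosage
            assert a + b == dose


def test_no_mendelian_violations_for_any_seed():
    for seed in (0, 4, 8):
        study = simulate_study(SimulationConfig(seed=seed, n_background_variants=30))
        for v in study.variants:
            assert mendelian_violations(study.ped, v.key) == []


def test_impossible_structure_raises_config_error():
    # zero penetrance and zero phenocopy rate: affected sibs cannot exist
    with pytest.raises(SimulationError):
        simulate_study(
            SimulationConfig(
                seed=0,
                n_background_variants=0,
                causal=CausalSpec(penetrance=0.0),
                phenocopy_rate=0.0,
                family_specs=[FamilySpec(n_affected_sibs=1, n_unaffected_sibs=0)],
            )
        )


def test_config_validation():
    with pytest.raises(SimulationError):
        SimulationConfig(phenocopy_rate=1.5)
    with pytest.raises(SimulationError):
        SimulationConfig(causal=CausalSpec(gene="NOT_A_GENE"))
    with pytest.raises(SimulationError):
        FamilySpec(template="quartet")


def test_three_generation_and_combined_templates():
    for template in ("three_generation", "combined_two_family"):
        study = simulate_study(
            SimulationConfig(
                seed=6,
                n_background_variants=10,
                family_specs=[FamilySpec(template=template, n_affected_sibs=2, n_unaffected_sibs=1)],
            )
        )
        affected_sibs = [
            i
            for i in study.ped.individuals.values()
            if i.affection is Affection.AFFECTED and not i.is_founder
        ]
        assert len(affected_sibs) >= 2
        for v in study.variants:
            assert mendelian_violations(study.ped, v.key) == []


# -- reference-family fixtures ------------------------------------------------


def test_f53_fixture_genotypes(ref_fx):
    key = ref_fx.variant_key("SLC26A4")
    ped = ref_fx.families
    assert ped.zygosity(key, "53-II-1") is Zygosity.HOM_ALT
    assert ped.zygosity(key, "53-II-2") is Zygosity.HOM_ALT
    assert ped.zygosity(key, "53-I-1") is Zygosity.HET


def test_f54_and_f40_fixture_genotypes(ref_fx):
    otof, rai1 = ref_fx.variant_key("OTOF"), ref_fx.variant_key("RAI1")
    ped = ref_fx.families
    for iid in ("54-II-2", "54-II-3", "54-II-5", "54-II-6"):
        assert ped.zygosity(otof, iid) is Zygosity.HOM_ALT
        assert ped[iid].affection is Affection.AFFECTED
    for iid in ("54-I-1", "54-II-4", "54-II-7", "54-III-1"):
        assert ped.zygosity(otof, iid) is Zygosity.HET
        assert ped[iid].affection is Affection.UNAFFECTED
    for iid in ("54-1", "54-II-1"):
        assert ped.zygosity(otof, iid) is Zygosity.WT
    for iid in ("40-II-1", "40-II-3"):
        assert ped.zygosity(rai1, iid) is Zygosity.HOM_ALT


def test_cohort_fixture_arithmetic(ref_fx):
    assert len(ref_fx.case_ids) == 93
    assert len(ref_fx.control_ids) == 120
    key = ref_fx.variant_key("RAI1")
    z = [ref_fx.cohort.zygosity(key, i) for i in ref_fx.case_ids]
    assert z.count(Zygosity.HOM_ALT) == 10 and z.count(Zygosity.HET) == 4
    zc = [ref_fx.cohort.zygosity(key, i) for i in ref_fx.control_ids]
    assert zc.count(Zygosity.HET) == 4 and zc.count(Zygosity.HOM_ALT) == 0
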