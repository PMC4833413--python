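"""End-to-end orchestration: simulate -> cascade -> segregate -> assoc.

``run_all`` drives the stages off one config (a YAML-able dict), writes all
stage outputs under an output directory, and records a manifest with input
digests so that a rerun with identical inputs is verifiable byte-for-byte
for the deterministic stages. One global seed fans out to per-stage seeds
by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import __version__
from .association import run_association
from .core import Zygosity
from .cascade import CascadeConfig, run_cascade
from .fixtures import fixture_reference_families
from .io_formats import write_summary_json, write_variant_tsv
from .segregation import check_ar_cosegregation, classify_carriers
from .simulate import (
    CausalSpec,
    CohortSpec,
    FamilySpec,
    SimulationConfig,
    simulate_study,
    write_study,
)

__all__ = ["RunManifest", "run_all", "repro_reference", "config_from_dict", "SEED_OFFSETS"]

#: per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "cascade": 101, "assoc": 202}


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    input_digests: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_from_dict(doc: Dict, seed: Optional[int] = None) -> SimulationConfig:
    """Build a SimulationConfig from a plain (YAML-loaded) dict."""
    doc = dict(doc)
    if seed is not None:
        doc["seed"] = seed
    fams = [FamilySpec(**f) for f in doc.get("family_specs", [{}])]
    causal = CausalSpec(**doc.get("causal", {}))
    cohort = CohortSpec(**doc["cohort"]) if doc.get("cohort") else None
    return SimulationConfig(
        seed=int(doc.get("seed", 0)),
        family_specs=fams,
        causal=causal,
        phenocopy_rate=float(doc.get("phenocopy_rate", 0.0)),
        n_background_variants=int(doc.get("n_background_variants", 500)),
        background_af_mix=tuple(doc.get("background_af_mix", (0.5, 0.35, 0.15))),
        cohort=cohort,
    )


def run_all(
    config: Dict,
    out_dir: str | os.PathLike,
    seed: int = 0,
    candidate_genes=None,
    known_catalog=None,
) -> RunManifest:
    """Simulate a study and push it through cascade + segregation (+ assoc)."""
    os.makedirs(out_dir, exist_ok=True)
    sim_config = config_from_dict(config, seed=seed + SEED_OFFSETS["simulate"])
    study = simulate_study(sim_config)
    paths = write_study(study, os.path.join(out_dir, "simulated"))

    from .fixtures import CANDIDATE_GENES, KNOWN_CATALOG

    cc = CascadeConfig(
        candidate_genes=candidate_genes if candidate_genes is not None else CANDIDATE_GENES,
        known_catalog=known_catalog if known_catalog is not None else KNOWN_CATALOG,
    )
    fam_ids = [s.family_id or f"SF{i + 1:02d}" for i, s in enumerate(sim_config.family_specs)]
    results = run_cascade(study.variants, study.ped, cc, family_ids=fam_ids)
    cascade_json = os.path.join(out_dir, "cascade_summary.json")
    write_summary_json(
        cascade_json,
        {
            "families": {
                r.family_id: {
                    "stage_counts": r.stage_counts,
                    "final_calls": [
                        {"gene": c.gene, "model": c.model, "variants": [v.label() for v in c.variants]}
                        for c in r.final_calls
                    ],
                }
                for r in results
            }
        },
    )
    final_tsv = os.path.join(out_dir, "final_candidates.tsv")
    write_variant_tsv(final_tsv, [v for r in results for c in r.final_calls for v in c.variants])

    verdicts = {
        fam: dataclasses.asdict(check_ar_cosegregation_sub(study, fam))
        for fam in fam_ids
    }
    seg_json = os.path.join(out_dir, "segregation.json")
    write_summary_json(seg_json, {"causal": study.causal.label(), "verdicts": verdicts})

    outputs = {
        "cascade_summary": cascade_json,
        "final_candidates": final_tsv,
        "segregation": seg_json,
        **paths,
    }

    if sim_config.cohort is not None:
        case_ids = sorted(
            i.id
            for i in study.ped.individuals.values()
            if i.family_id.startswith("CASE") and i.affection.value == "affected"
        )
        control_ids = sorted(
            i.id for i in study.ped.individuals.values() if i.id.startswith("CTRL")
        )
        assoc = run_association(study.ped, study.causal_key, case_ids, control_ids, "all")
        assoc_json = os.path.join(out_dir, "association.json")
        write_summary_json(
            assoc_json,
            {
                "table": dataclasses.asdict(assoc.table),
                "case_freq": assoc.case_freq,
                "control_freq": assoc.control_freq,
                "p_two_tailed": assoc.p_two_tailed,
                "odds_ratio": assoc.odds_ratio if assoc.odds_ratio != float("inf") else "inf",
                "notes": assoc.notes,
            },
        )
        outputs["association"] = assoc_json

    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        input_digests={},
        outputs={k: _sha256(p) for k, p in sorted(outputs.items())},
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def check_ar_cosegregation_sub(study, family_id):
    """Cosegregation verdict for the causal variant restricted to one family."""
    from .core import Pedigree

    members = [i for i in study.ped.individuals.values() if i.family_id == family_id]
    sub = Pedigree(
        [dataclasses.replace(m) for m in members],
        {
            key: {m.id: z for m, z in ((m, table.get(m.id)) for m in members) if z is not None}
            for key, table in study.ped.genotypes.items()
        },
    )
    return check_ar_cosegregation(sub, study.causal_key)


def repro_reference(out_dir: Optional[str | os.PathLike] = None) -> Dict:
    """Run the reference family fixtures through segregation and association.

    Returns (and optionally writes) the headline table: carrier counts for
    the combined F24-F54 pedigree and the case/control allele-frequency
    comparisons for the RAI1 founder variant.
    """
    fx = fixture_reference_families()
    otof = fx.variant_key("OTOF")
    rai1 = fx.variant_key("RAI1")

    combined = fx.subpedigree("F24", "F54")
    carriers = classify_carriers(combined, otof)
    verdict = check_ar_cosegregation(combined, otof)
    assoc_all = run_association(fx.cohort, rai1, fx.case_ids, fx.control_ids, "all")
    assoc_unrel = run_association(fx.cohort, rai1, fx.case_ids, fx.control_ids, "unrelated")

    report = {
        "combined_F24_F54": {
            "het_carriers": len(carriers.het_ids),
            "hom_carriers": len(carriers.hom_alt_ids),
            "het_ids": carriers.het_ids,
            "affected_nonhom_carriers": [
                i for i in verdict.affected_nonhom if i in carriers.carrier_ids
            ],
            "consistent": verdict.consistent,
        },
        "association_all": {
            "case_alt": assoc_all.table.case_alt,
            "case_chrom": assoc_all.table.case_total_chrom,
            "case_freq": round(assoc_all.case_freq, 3),
            "control_alt": assoc_all.table.control_alt,
            "control_chrom": assoc_all.table.control_total_chrom,
            "control_freq": round(assoc_all.control_freq, 3),
            "p_two_tailed": assoc_all.p_two_tailed,
            "p_one_tailed": assoc_all.p_one_tailed,
        },
        "association_unrelated": {
            "n_probands": len(assoc_unrel.case_ids_used),
            "case_alt": assoc_unrel.table.case_alt,
            "case_chrom": assoc_unrel.table.case_total_chrom,
            "case_freq": round(assoc_unrel.case_freq, 3),
            "p_two_tailed": assoc_unrel.p_two_tailed,
            "p_one_tailed": assoc_unrel.p_one_tailed,
        },
        "control_carrier_pct": round(
            100.0
            * sum(
                1
                for iid in fx.control_ids
                if fx.cohort.zygosity(rai1, iid) is Zygosity.HET
            )
            / len(fx.control_ids),
            2,
        ),
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_summary_json(os.path.join(out_dir, "reference_tables.json"), report)
    return report
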