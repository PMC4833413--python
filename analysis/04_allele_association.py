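#!/usr/bin/env python
"""Case/control allele-frequency association for the RAI1 founder variant.

Recomputes the screening-cohort comparison: 24/186 alt chromosomes in all
93 patients vs 4/240 in 120 controls (p < 1e-5), then the bias-guarded
version on 74 unrelated probands (12/148; reported p rounds to 0.0026),
plus the 3.33% control carrier rate. Writes results/reference_tables.json.
"""

import pathlib

from mendelfilter.pipeline import repro_reference

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    report = repro_reference(OUT)
    al, au = report["association_all"], report["association_unrelated"]
    print(
        f"all patients : {al['case_alt']}/{al['case_chrom']} "
        f"(freq {al['case_freq']}) vs {al['control_alt']}/{al['control_chrom']} "
        f"(freq {al['control_freq']}); p_two={al['p_two_tailed']:.2g}"
    )
    print(
        f"unrelated    : {au['case_alt']}/{au['case_chrom']} "
        f"(freq {au['case_freq']}, {au['n_probands']} probands); "
        f"p_two={au['p_two_tailed']:.2g}, p_one={au['p_one_tailed']:.2g}"
    )
    print(f"control carriers: {report['control_carrier_pct']}%")
    cb = report["combined_F24_F54"]
    print(
        f"combined F24-F54: {cb['het_carriers']} het / {cb['hom_carriers']} hom; "
        f"affected non-hom carriers: {cb['affected_nonhom_carriers']}"
    )


if __name__ == "__main__":
    main()
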