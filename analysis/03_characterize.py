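#!/usr/bin/env python
"""Characterize the recovered counter-receptor set: share of the membrane
proteome, histone-ruler copy numbers, and N-glycosylation-site density per
Ig-like domain compared with non-counter-receptors.

Reads results/experiment/ and results/filtration/, writes
results/characterization/summary.json.
"""

import json
from pathlib import Path

from proxiglyc.characterization import (
    MembraneProteome,
    RulerConfig,
    counter_receptor_fraction,
    histone_ruler_copies,
    sequon_density_comparison,
    sequon_density_rows,
)
from proxiglyc.tables_io import (
    CCClass,
    read_annotation_table,
    read_design_table,
    read_quant_table,
    read_report,
    write_report,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    exp = BASE / "experiment"
    design = read_design_table(exp / "design.tsv")
    quant = read_quant_table(exp / "quant.tsv", design)
    ann = read_annotation_table(exp / "annotation.tsv")
    report = read_report(BASE / "filtration" / "report.json")
    final = set(report["final_set"])

    # membrane proteome: the membrane-annotated complement of the quant
    # table (in the simulated world every membrane protein is observed)
    membrane = {a.protein_id for a in ann if a.cc_class is CCClass.MEMBRANE}
    proteome = MembraneProteome(membrane, {p: [] for p in membrane})
    fraction = counter_receptor_fraction(final & membrane, proteome)

    # histone-ruler copy numbers: treat the five highest-intensity
    # non-membrane proteins of one control sample as the histone set
    sample = design[1].sample_id  # a control sample
    non_membrane = [
        (rec.intensity_by_sample.get(sample) or 0.0, rec.protein_id)
        for rec in quant.records
        if rec.protein_id not in membrane
    ]
    histones = frozenset(pid for _, pid in sorted(non_membrane, reverse=True)[:5])
    ruler = histone_ruler_copies(quant, sample, RulerConfig(histone_ids=histones))
    cr_copies = sorted(
        ruler.copies_per_cell[p] for p in final if p in ruler.copies_per_cell
    )

    density = sequon_density_comparison(sequon_density_rows(ann, final))

    summary = {
        "n_counter_receptors": len(final),
        "n_membrane_proteins": len(membrane),
        "counter_receptor_fraction_pct": fraction,
        "ruler": {
            "sample": sample,
            "n_scored": len(ruler.copies_per_cell),
            "median_cr_copies_per_cell": cr_copies[len(cr_copies) // 2]
            if cr_copies else None,
        },
        "sequon_density": density,
    }
    out = BASE / "characterization"
    out.mkdir(parents=True, exist_ok=True)
    write_report(summary, out / "summary.json")

    print(f"counter-receptors: {len(final)} of {len(membrane)} membrane "
          f"proteins = {fraction}%")
    if cr_copies:
        print(f"ruler ({sample}): median counter-receptor copy number "
              f"{cr_copies[len(cr_copies) // 2]:.3g} per cell "
              f"({len(ruler.copies_per_cell)} proteins scored)")
    for group, stats in density.items():
        if stats.get("present"):
            print(f"sequons per Ig domain [{group}]: n={stats['n']}, "
                  f"median {stats['median_density']:.2f}, "
                  f">1 site/domain in {stats['n_density_gt1']}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
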