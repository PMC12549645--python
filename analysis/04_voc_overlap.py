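"""Shared VOCs between thermokarst soil incubations and a methanogen culture.

Queries the packaged presence table of 16 KEGG-annotated compounds
detected in both systems: union-of-200 cm soil conditions against each
M. acetivorans culture temperature, the freeze-stressed 200 cm condition
against the culture union, and superclass composition of the shared set.

Writes results/voc_overlap.json.
"""

import argparse
from pathlib import Path

import pandas as pd

from thawflux import reporting, voc


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results/voc_overlap.json"))
    args = parser.parse_args()

    matrix = voc.load_shared_compound_table()
    annotations = voc.load_shared_compound_annotations()

    queries = {
        "200 cm soils (any T) ∩ culture 37 °C": voc.OverlapQuery(
            voc.BTL_200_CONDITIONS, ("MaC2A (37 °C)",)
        ),
        "200 cm soils (any T) ∩ culture 2 °C": voc.OverlapQuery(
            voc.BTL_200_CONDITIONS, ("MaC2A (2 °C)",)
        ),
        "200 cm at −4 °C ∩ culture (any T)": voc.OverlapQuery(
            ("BTL 200 cm (-4 °C)",), voc.CULTURE_CONDITIONS
        ),
    }
    payload = {"n_compounds": len(matrix.compounds), "queries": {}}
    print(f"shared-compound table: {len(matrix.compounds)} compounds × "
          f"{len(matrix.conditions)} conditions")
    for name, query in queries.items():
        count, compounds = voc.overlap_count(matrix, query)
        payload["queries"][name] = {"count": count, "compounds": compounds}
        print(f"  {name}: {count} compounds")

    counts = (
        annotations["superclass"]
        .value_counts()
        .sort_index()
    )
    payload["superclass_composition"] = counts.to_dict()
    print("superclass composition of the shared set:")
    for superclass, n in counts.items():
        print(f"  {superclass}: {n}")

    reporting.write_json_report(args.out, payload)


if __name__ == "__main__":
    main()
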