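"""Build the control reference model.

Aligns the control embryos in time (pace scaling + ABa division as time
zero) and space (extent normalization, PCA-derived A-P axis, MS-centroid
D-V axis), superimposes them by Generalized Procrustes Analysis, and stores
per-cell mean metaphase positions, mean division vectors, per-minute mean
trajectories, and control feature statistics in results/reference.json.
"""
import argparse

from lineage4d.alignment import build_reference
from lineage4d.pipeline import collect_lineages


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--out", default="results/reference.json")
    args = parser.parse_args()

    embryos = collect_lineages(args.cohort)
    controls = [e for e in embryos if e.metadata.group == "control"]
    reference = build_reference(controls)
    reference.to_json(args.out)
    print(
        f"reference from {len(controls)} controls: "
        f"{len(reference.positions)} cells, "
        f"{len(reference.division_vectors)} division vectors -> {args.out}"
    )


if __name__ == "__main__":
    main()
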