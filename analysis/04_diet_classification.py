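"""Classify specimens by diet and locomotion from mandible shape.

CVA of Procrustes coordinates per grouping, confusion tables with
leave-one-out cross-validation, Mahalanobis posteriors for the ungrouped
fossil-analog specimens, and permutation tests on between-group Procrustes
distances. Tables to results/classification/.
"""

import importlib.util
from pathlib import Path

import sciurmorph as sm

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "classification"

spec = importlib.util.spec_from_file_location(
    "step02", Path(__file__).parent / "02_superimposition_allometry.py"
)
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    _, aligned, _ = step02.load_means()

    for grouping in ("diet", "locomotion"):
        model = sm.fit_cva(aligned, grouping)
        table = sm.classify_specimens(model, aligned, grouping,
                                      cross_validate=True)
        print(f"{grouping} CVA ({len(model.groups)} groups): "
              f"{table.percent_correct:.1f}% correct, "
              f"{table.percent_correct_cv:.1f}% after cross-validation")
        table.confusion.to_csv(OUT / f"{grouping}_confusion.csv",
                               float_format="%.2f")
        table.confusion_cv.to_csv(OUT / f"{grouping}_confusion_cv.csv",
                                  float_format="%.2f")
        table.table.to_csv(OUT / f"{grouping}_posteriors.csv", index=False,
                           float_format="%.6g")

        dist, pvals = sm.group_distance_tests(aligned, grouping,
                                              n_perm=999, seed=6)
        dist.to_csv(OUT / f"{grouping}_distances.csv", float_format="%.6g")
        pvals.to_csv(OUT / f"{grouping}_distance_p.csv", float_format="%.6g")

        if grouping == "diet":
            ungrouped = table.table[
                ~table.table["true_group"].isin(model.groups)
            ]
            for _, row in ungrouped.iterrows():
                print(f"  ungrouped {row['specimen_id']}: assigned to "
                      f"{row['predicted']} "
                      f"(p = {row['p_' + row['predicted']]:.3f})")


if __name__ == "__main__":
    main()
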