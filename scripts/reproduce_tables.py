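#!/usr/bin/env python
"""Best-effort external validation on the public benchmark datasets.

The reference results for this method were reported on four public
tables — WPBC, WDBC and Heart-Cle from the UCI Machine Learning
Repository and the Colon tumor microarray set — with a dataset-specific
(alpha, beta) pair each.  Those files are not bundled (they must be
downloaded separately and converted to CSV with a header row and a label
column named ``class``); this script runs the selector on whichever of
them it finds and prints subset sizes and 10-fold CV accuracies next to
the reference values.  Exact agreement is not expected: the reference
protocol leaves fold assignment and tie handling unstated.

Usage:
    python scripts/reproduce_tables.py --data-dir path/with/csvs
"""

import argparse
import warnings
from pathlib import Path

from rumselect.data_model import SelectionConfig, normalize, read_table
from rumselect.evaluation import evaluate
from rumselect.selection import reduce

# dataset -> (filename, alpha, beta, reference subset size, reference SVM %)
BENCHMARKS = {
    "WPBC": ("wpbc.csv", 0.10, 0.25, 3, 90.00),
    "WDBC": ("wdbc.csv", 0.10, 0.10, 5, 97.37),
    "Colon": ("colon.csv", 0.10, 0.30, 4, 92.31),
    "Heart-Cle": ("heart_cle.csv", 0.35, 0.35, 5, 70.49),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("data"))
    parser.add_argument("--label", default="class")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    found_any = False
    for name, (fname, alpha, beta, ref_size, ref_svm) in BENCHMARKS.items():
        path = args.data_dir / fname
        if not path.exists():
            print(f"{name}: {path} not found, skipped")
            continue
        found_any = True
        table = normalize(read_table(path, args.label))
        cfg = SelectionConfig(alpha=alpha, beta=beta, rng_seed=args.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trace = reduce(table, cfg)
            if trace.selected:
                res = evaluate(table, trace.selected, cfg)
                acc = f"SVM {res.accuracy_svm:.2f}% / 3NN {res.accuracy_knn:.2f}%"
            else:
                acc = "no subset selected"
        positions = [table.attribute_ids.index(a) + 1 for a in trace.selected]
        print(
            f"{name}: alpha={alpha} beta={beta} -> {len(trace.selected)} attrs "
            f"{positions} ({acc}); reference: {ref_size} attrs, SVM {ref_svm:.2f}%"
        )
    if not found_any:
        print(
            "No benchmark CSVs found. Download the datasets, convert each to "
            "CSV with a header row and a 'class' label column, and place "
            "them under --data-dir as: "
            + ", ".join(v[0] for v in BENCHMARKS.values())
        )


if __name__ == "__main__":
    main()
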