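#!/usr/bin/env python
"""Fit and select the staged allometric candidate set.

Runs the staged search (singles, best-single pairs, best-pair triples) on
the full sample (mean petiole diameter >= 2 cm) and on the >= 5 cm
subset, with nested F-tests annotating each added predictor. Writes
fitted_models.csv (published-table layout), residuals.csv and
selection_report.json.
"""

import argparse
from pathlib import Path

from raphia_allometry.pipeline import run_fit_workflow


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    report = run_fit_workflow(args.data / "palms.csv", (2.0, 5.0), args.out)
    for label, sub in report["subsets"].items():
        print(f"subset {label}: n = {sub['n']}, {sub['n_candidates']} candidates")
        print(f"  best single predictor: {sub['best_single']}")
        print(f"  best overall model:    {sub['best_overall']}")


if __name__ == "__main__":
    main()
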