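#!/usr/bin/env python
"""Severe vs non-severe DILI classification.

Assembles the dynamic feature matrix (per reporter × descriptor ×
concentration course dynamics, cytotoxicity summaries, log-BMC features),
then runs the iterative procedure: stratified 80/20 splits with
training-only KS feature selection, correlation filtering, and repeated
cross-validated RBF-SVM tuning. Reports the averaged test metrics, the
per-feature selection stability, and per-compound prediction consistency.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stressdyn.annotation import load_packaged_annotations
from stressdyn.classify import ClassifierConfig, run_iterations, stability_report
from stressdyn.features import build_feature_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--condensed", type=Path, default=Path("scratch/condensed.csv"))
    ap.add_argument("--cytotox", type=Path, default=Path("results/cytotox_summary.csv"))
    ap.add_argument("--bmc", type=Path, default=Path("results/bmc.csv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--iterations", type=int, default=50,
                    help="train/test resampling iterations (200 at full scale)")
    ap.add_argument("--cv-folds", type=int, default=5)
    ap.add_argument("--cv-repeats", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    anns = load_packaged_annotations()
    cmax = {a.abbreviation: a.cmax_uM for a in anns if a.cmax_uM is not None}
    severity = pd.Series({a.abbreviation: a.severity for a in anns})

    condensed = pd.read_csv(args.condensed)
    cytotox = pd.read_csv(args.cytotox)
    bmc = pd.read_csv(args.bmc)
    x, manifest = build_feature_matrix(condensed, cytotox, bmc, cmax)
    x.to_csv(args.out / "features.csv")
    manifest.to_csv(args.out / "feature_manifest.csv", index=False)
    print(f"feature matrix: {x.shape[0]} compounds x {x.shape[1]} features")

    y = severity.loc[x.index]
    config = ClassifierConfig(cv_folds=args.cv_folds, cv_repeats=args.cv_repeats)
    runs, summary = run_iterations(
        x, y, n_iter=args.iterations, rng_seed=args.seed, config=config
    )
    (args.out / "classifier_summary.json").write_text(json.dumps(summary, indent=2))
    report = stability_report(runs, x.columns, x.index)
    stab = report.selection_counts.rename("selected").to_frame()
    stab["stable"] = stab["selected"] > 0.75 * len(runs)
    stab.sort_values("selected", ascending=False).to_csv(
        args.out / "feature_stability.csv"
    )
    report.compound_correct_fraction.rename("correct_fraction").to_csv(
        args.out / "compound_predictions.csv"
    )

    print(f"mean test ROC-AUC {summary['mean_roc_auc']:.3f}, "
          f"sensitivity {summary['mean_sensitivity']:.3f}, "
          f"specificity {summary['mean_specificity']:.3f} "
          f"over {summary['n_iterations']} iterations")
    print(f"{len(report.stable_features)} features selected in >75% of iterations:")
    for f in report.stable_features[:20]:
        print(f"  {f} ({report.selection_counts[f]}/{len(runs)})")
    consistent = (
        (report.compound_correct_fraction >= 0.9)
        | (report.compound_correct_fraction <= 0.1)
    ).sum()
    print(f"{consistent} compounds consistently predicted "
          f"(correct fraction >= 0.9 or <= 0.1)")


if __name__ == "__main__":
    main()
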