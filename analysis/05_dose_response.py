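#!/usr/bin/env python
"""Benchmark-concentration modelling and class-level potency statistics.

Fits four-parameter log-logistic curves to the max-over-time headline
descriptors (%GFP positive 2m; %GFP diff 2m for ICAM1), extracts the ±0.25
benchmark concentration per compound × reporter, and asks per reporter
whether severe-DILI compounds are more potent: a Welch t-test on
log10(BMC / C-max) and a nested linear-model ANOVA of log10 BMC on
log10 C-max with and without the severity label.
"""

import argparse
from pathlib import Path

import pandas as pd

from stressdyn.annotation import load_packaged_annotations
from stressdyn.dose_response import bmc_class_lm, bmc_class_welch, fit_bmc_table
from stressdyn.timecourse import CONTROL_COMPOUNDS, HEADLINE_DESCRIPTOR


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--summaries", type=Path, default=Path("results/max_summaries.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    anns = load_packaged_annotations()
    cmax = {a.abbreviation: a.cmax_uM for a in anns if a.cmax_uM is not None}
    severity = {a.abbreviation: a.severity for a in anns}

    summ = pd.read_csv(args.summaries)
    summ = summ[~summ["compound"].isin(CONTROL_COMPOUNDS)]
    head = summ[summ.apply(
        lambda r: HEADLINE_DESCRIPTOR.get(r["reporter"]) == r["descriptor"], axis=1
    )]
    table = fit_bmc_table(head, cmax)
    table["severity"] = table["compound"].map(severity)
    table.to_csv(args.out / "bmc.csv", index=False)

    rows = []
    for reporter, sub in table.groupby("reporter"):
        n_unc = int((~sub["censored"]).sum())
        welch = bmc_class_welch(sub["bmc_over_cmax"], sub["severity"])
        row = {"reporter": reporter, "n_uncensored": n_unc,
               **{f"welch_{k}": v for k, v in welch.items()}}
        try:
            lm = bmc_class_lm(sub["bmc_xcmax"], sub["compound"].map(cmax),
                              sub["severity"])
            row.update({f"lm_{k}": v for k, v in lm.items()})
        except ValueError as exc:
            row["lm_note"] = str(exc)
        rows.append(row)
    stats = pd.DataFrame(rows)
    stats.to_csv(args.out / "bmc_class_stats.csv", index=False)

    print(f"{(~table['censored']).sum()}/{len(table)} compound x reporter "
          f"responses reached the 0.25 departure")
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
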