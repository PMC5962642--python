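#!/usr/bin/env python
"""Well-level descriptors from single-cell records.

Converts the simulated cell table into the descriptor time series
(population mean intensity, %GFP-positive fractions, ICAM1 IQR-fence
fractions) and the cytotoxicity summaries (normalized 24-h PI fraction and
cell count / speed / nuclear size / Hoechst slopes). Full descriptor series
go to scratch/; max-over-time summaries and cytotoxicity tables to results/.
"""

import argparse
from pathlib import Path

from stressdyn.descriptors import (
    compute_cytotox_summary,
    compute_descriptor_table,
    max_summary_table,
)
from stressdyn.simulate import read_cells


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=Path, default=Path("scratch/cells.h5"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cells = read_cells(args.cells)
    desc = compute_descriptor_table(cells)
    desc.to_csv(args.scratch / "descriptors.csv", index=False)
    summ = max_summary_table(desc)
    summ.to_csv(args.out / "max_summaries.csv", index=False)
    cyto = compute_cytotox_summary(cells)
    cyto.to_csv(args.out / "cytotox_summary.csv", index=False)

    print(f"{desc['descriptor'].nunique()} descriptors x "
          f"{desc['compound'].nunique()} compounds")
    strongest = (
        summ[(summ["descriptor"] == "frac_2m") & (summ["conc_xcmax"] == 100.0)]
        .nlargest(5, "response")
    )
    print("strongest %GFP-positive-2m responses at 100x C-max:")
    print(strongest.to_string(index=False))


if __name__ == "__main__":
    main()
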