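#!/usr/bin/env python
"""Compound set overview.

Loads the packaged screen compound table (118 FDA-labelled drugs + 5
controls), derives the two-class severity grouping from the DILI-concern
labels, and writes the class composition and C-max range to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from stressdyn.annotation import class_counts, load_packaged_annotations, to_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    anns = load_packaged_annotations()
    counts = class_counts(anns)
    df = to_frame(anns)
    drugs = df[~df["is_control"]]

    rows = [{"group": f"dili_concern:{k}", "n": v}
            for k, v in counts["dili_concern"].items()]
    rows += [{"group": f"severity:{k}", "n": v} for k, v in counts["severity"].items()]
    rows.append({"group": "drugs_total", "n": len(drugs)})
    rows.append({"group": "rows_total", "n": len(df)})
    out = pd.DataFrame(rows)
    out.to_csv(args.out / "class_counts.csv", index=False)

    print(f"{len(df)} compounds screened, {len(drugs)} with DILI labels")
    print(out.to_string(index=False))
    print(
        f"C-max range: {drugs['cmax_uM'].min():g} uM "
        f"to {drugs['cmax_uM'].max() / 1000:g} mM"
    )


if __name__ == "__main__":
    main()
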