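"""Dynamic feature extraction for the severity classifier.

From each compound's condensed, scaled descriptor time courses the extractor
takes, per reporter × descriptor × concentration: the max magnitude (signed
extreme for ICAM1 difference descriptors), the time of that extreme, the area
under the curve (trapezoid, h·units), and early (0–8 h) and late (8–24 h)
OLS slopes. Cytotoxicity features per concentration — 24-h normalized cell
death fraction and the cell-count / speed / nuclear-size / Hoechst slopes —
are kept separately for the TNFα-primed (ICAM1) plates and averaged over the
other reporter plates. Each reporter contributes its benchmark concentration
on the log10 scale, both absolute (µM) and C-max-normalized, with censored
values imputed at the maximum tested concentration alongside an explicit
censoring indicator so censoring stays informative. The realized feature
catalog is written to a manifest.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .descriptors import feature_slope, max_over_time
from .timecourse import CONTROL_COMPOUNDS, HEADLINE_DESCRIPTOR

EARLY_WINDOW_H = (0.0, 8.0)
LATE_WINDOW_H = (8.0, 24.0)
CENSORED_IMPUTE_XCMAX = 100.0  # maximum tested concentration


def course_features(times, values, signed_extreme: bool = False) -> dict[str, float]:
    """Scalar dynamics of one condensed course: extreme, its time, AUC, and
    early/late slopes."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    extreme = max_over_time(values, signed_extreme=signed_extreme)
    t_of_max = float(times[int(np.argmax(np.abs(values) if signed_extreme else values))])
    auc = float(np.trapezoid(values, times))
    early = (times >= EARLY_WINDOW_H[0]) & (times <= EARLY_WINDOW_H[1])
    late = (times >= LATE_WINDOW_H[0]) & (times <= LATE_WINDOW_H[1])
    out = {"max": extreme, "t_of_max": t_of_max, "auc": auc}
    out["early_slope"] = (
        feature_slope(values[early], times[early]) if early.sum() >= 3 else 0.0
    )
    out["late_slope"] = (
        feature_slope(values[late], times[late]) if late.sum() >= 3 else 0.0
    )
    return out


def build_feature_matrix(
    condensed: pd.DataFrame,
    cytotox: pd.DataFrame,
    bmc_table: pd.DataFrame,
    cmax_by_compound: dict[str, float],
    bmc_descriptor: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the compound × feature matrix and its manifest.

    Compounds missing a course contribute 0-valued features plus a
    per-reporter missingness flag. Returns ``(X, manifest)`` with one row per
    non-control compound.
    """
    bmc_descriptor = bmc_descriptor or HEADLINE_DESCRIPTOR
    condensed = condensed[~condensed["compound"].isin(CONTROL_COMPOUNDS)]
    compounds = sorted(
        set(condensed["compound"]) | set(cytotox["compound"]) | set(bmc_table["compound"])
    )

    rows: dict[str, dict[str, float]] = {c: {} for c in compounds}

    for (compound, conc, reporter, descriptor), sub in condensed.groupby(
        ["compound", "conc_xcmax", "reporter", "descriptor"]
    ):
        signed = descriptor.startswith("icam_diff")
        sub = sub.sort_values("time_h")
        feats = course_features(sub["time_h"], sub["value"], signed_extreme=signed)
        for stat, val in feats.items():
            rows[compound][f"{reporter}.{descriptor}.c{conc:g}.{stat}"] = val

    cyto = cytotox[~cytotox["compound"].isin(CONTROL_COMPOUNDS)].copy()
    cyto["group"] = np.where(cyto["reporter"] == "ICAM1", "tnf", "plain")
    cyto_agg = (
        cyto.groupby(["compound", "conc_xcmax", "group"])
        .agg(
            death_frac=("pi_fraction_norm", "mean"),
            count_slope=("slope_cell_count", "mean"),
            speed_slope=("slope_speed", "mean"),
            nucsize_slope=("slope_nuclear_size", "mean"),
            hoechst_slope=("slope_hoechst", "mean"),
        )
        .reset_index()
    )
    for _, r in cyto_agg.iterrows():
        prefix = f"cytotox_{r['group']}.c{r['conc_xcmax']:g}"
        for stat in ("death_frac", "count_slope", "speed_slope",
                     "nucsize_slope", "hoechst_slope"):
            val = r[stat]
            rows[r["compound"]][f"{prefix}.{stat}"] = (
                float(val) if np.isfinite(val) else 0.0
            )

    bmc_head = bmc_table[
        bmc_table.apply(
            lambda r: bmc_descriptor.get(r["reporter"]) == r["descriptor"], axis=1
        )
    ]
    for _, r in bmc_head.iterrows():
        compound, reporter = r["compound"], r["reporter"]
        censored = bool(r["censored"]) or not np.isfinite(r["bmc_xcmax"])
        x = CENSORED_IMPUTE_XCMAX if censored else float(r["bmc_xcmax"])
        cmax = cmax_by_compound.get(compound, math.nan)
        rows[compound][f"{reporter}.bmc.log10_xcmax"] = math.log10(x)
        rows[compound][f"{reporter}.bmc.log10_uM"] = (
            math.log10(x * cmax) if np.isfinite(cmax) else 0.0
        )
        rows[compound][f"{reporter}.bmc.censored"] = float(censored)

    for compound in compounds:
        cmax = cmax_by_compound.get(compound, math.nan)
        rows[compound]["log10_cmax_uM"] = (
            math.log10(cmax) if np.isfinite(cmax) else 0.0
        )

    x_df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    # per-reporter missingness flags, then zero-impute absent courses
    reporters = sorted(condensed["reporter"].unique())
    for reporter in reporters:
        cols = [
            c for c in x_df.columns
            if c.startswith(f"{reporter}.") and not c.startswith(f"{reporter}.bmc")
        ]
        x_df[f"missing_{reporter}"] = (
            x_df[cols].isna().all(axis=1).astype(float) if cols else 0.0
        )
    x_df = x_df.fillna(0.0)
    if not np.isfinite(x_df.to_numpy()).all():
        raise ValueError("feature matrix contains non-finite values")

    manifest = pd.DataFrame(
        {
            "feature": x_df.columns,
            "family": [c.split(".")[0] for c in x_df.columns],
        }
    )
    return x_df, manifest
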