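"""Well-level descriptor time series and cytotoxicity summaries from
single-cell records.

For each plate, vehicle-control wells (DMSO; TNFα + DMSO on ICAM1 plates) set
per-timepoint background statistics. Reporter activity descriptors are then:

* ``intensity_mean`` — cell-population mean GFP intensity;
* ``frac_2m`` / ``frac_3m`` — fraction of cells above 2× / 3× the control
  mean ("%GFP positive 2m/3m");
* ``frac_m3sd`` — fraction above control mean + 3 sd;
* ICAM1 only: ``icam_up_k`` / ``icam_down_k`` / ``icam_diff_k`` for
  k ∈ {1.5, 2, 3} — fractions of cells beyond the control interquartile
  fences Q3 + k·IQR (up) and Q1 − k·IQR (down), and their difference
  ("%GFP diff. k m"). The IQR fences accommodate the skewed ICAM1 intensity
  distribution.

Cytotoxicity summaries use the 24-h PI stain (a cell is dead when its
PI/nucleus overlap is at least 10% of the nuclear area) and per-plate linear
regression slopes over time of cell count, cell speed, nuclear size, and
Hoechst intensity, averaged over plates.

Intensity descriptors are min-max scaled to [0, 1] within a replicate
(per reporter); ICAM1 intensity is scaled to [−1, 1] around the matched
control trajectory; fraction descriptors are already fractions and bypass
scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ICAM_KS = (1.5, 2.0, 3.0)
PI_DEAD_RATIO = 0.10  # inclusive: "at least 10% of the cell size"

FRACTION_DESCRIPTORS = frozenset(
    {"frac_2m", "frac_3m", "frac_m3sd"}
    | {f"icam_{kind}_{k:g}" for kind in ("up", "down", "diff") for k in ICAM_KS}
)


@dataclass(frozen=True)
class ControlStats:
    """Background statistics of one plate's control wells at one timepoint."""

    plate_id: str
    control_kind: str  # "DMSO" or "TNFa_DMSO"
    mean_gfp: float
    sd_gfp: float
    q1_gfp: float
    q3_gfp: float
    pi_positive_fraction: float = float("nan")

    @property
    def iqr_gfp(self) -> float:
        return self.q3_gfp - self.q1_gfp


def compute_control_stats(
    control_cells: pd.DataFrame, timepoint: float, min_cells: int = 20
) -> ControlStats:
    """Background statistics from one plate's control wells at a timepoint.

    Quartiles use linear interpolation between order statistics. The PI
    fraction is only defined at the final frame (where PI was recorded).
    """
    if control_cells.empty:
        raise ValueError("plate has no control wells")
    at_t = control_cells[control_cells["time_h"] == timepoint]
    if len(at_t) < min_cells:
        raise ValueError(
            f"only {len(at_t)} control cells at t={timepoint} (need >= {min_cells})"
        )
    gfp = at_t["gfp_intensity"].to_numpy(dtype=float)
    pi = at_t["pi_overlap_area_px"].to_numpy(dtype=float)
    if np.isfinite(pi).any():
        dead = pi_flag(at_t)
        pi_frac = float(np.mean(dead))
    else:
        pi_frac = float("nan")
    return ControlStats(
        plate_id=str(at_t["plate_id"].iloc[0]),
        control_kind=str(at_t["control_kind"].iloc[0]),
        mean_gfp=float(np.mean(gfp)),
        sd_gfp=float(np.std(gfp, ddof=1)) if len(gfp) > 1 else 0.0,
        q1_gfp=float(np.quantile(gfp, 0.25)),
        q3_gfp=float(np.quantile(gfp, 0.75)),
        pi_positive_fraction=pi_frac,
    )


def frac_positive(gfp_values, control: ControlStats, rule: str) -> float:
    """Fraction of cells whose GFP exceeds the control-derived threshold.

    rule ``2m``: > 2 × control mean; ``3m``: > 3 × control mean;
    ``m3sd``: > control mean + 3 × control sd.
    """
    gfp = np.asarray(gfp_values, dtype=float)
    if gfp.size == 0:
        raise ValueError("empty cell set")
    if rule == "2m":
        thr = 2.0 * control.mean_gfp
    elif rule == "3m":
        thr = 3.0 * control.mean_gfp
    elif rule == "m3sd":
        thr = control.mean_gfp + 3.0 * control.sd_gfp
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return float(np.mean(gfp > thr))


def icam_fractions(gfp_values, control: ControlStats, k: float) -> tuple[float, float, float]:
    """ICAM1 up/down fractions beyond the TNFα control IQR fences.

    up = fraction above Q3 + k·IQR; down = fraction below Q1 − k·IQR;
    diff = up − down ∈ [−1, 1].
    """
    if control.control_kind != "TNFa_DMSO":
        raise ValueError("ICAM1 fractions require TNFα + DMSO control statistics")
    gfp = np.asarray(gfp_values, dtype=float)
    if gfp.size == 0:
        raise ValueError("empty cell set")
    iqr = control.iqr_gfp
    up = float(np.mean(gfp > control.q3_gfp + k * iqr))
    down = float(np.mean(gfp < control.q1_gfp - k * iqr))
    return up, down, up - down


def pi_flag(cells: pd.DataFrame | pd.Series) -> np.ndarray | bool:
    """Alive/dead flag from the PI/nucleus overlap ratio (dead ⇔ ratio ≥ 0.10)."""
    if isinstance(cells, pd.Series):
        if not np.isfinite(cells["pi_overlap_area_px"]):
            raise ValueError("PI overlap missing (not the final timepoint)")
        return bool(
            cells["pi_overlap_area_px"] / cells["nucleus_area_px"] >= PI_DEAD_RATIO
        )
    pi = cells["pi_overlap_area_px"].to_numpy(dtype=float)
    if not np.isfinite(pi).all():
        raise ValueError("PI overlap missing (not the final timepoint)")
    return pi / cells["nucleus_area_px"].to_numpy(dtype=float) >= PI_DEAD_RATIO


def pi_fraction_normalized(treated_fraction: float, control: ControlStats) -> float:
    """Treated PI-positive fraction minus the plate-control fraction."""
    return treated_fraction - control.pi_positive_fraction


def feature_slope(values, times_h) -> float:
    """Ordinary-least-squares slope (per hour) of a well-level series."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 timepoints for a slope")
    return float(np.polyfit(times, values, 1)[0])


def scale_minmax(values, x_min: float, x_max: float):
    """Min-max scale to [0, 1]; degenerate range returns zeros with a warning."""
    values = np.asarray(values, dtype=float)
    if x_max <= x_min:
        warnings.warn("degenerate scaling range (max == min); returning zeros")
        return np.zeros_like(values)
    return (values - x_min) / (x_max - x_min)


def max_over_time(values, signed_extreme: bool = False) -> float:
    """Scalar time-course summary: the maximum, or for ICAM1 difference
    descriptors the signed extreme (largest magnitude, keeping its sign)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if signed_extreme:
        return float(values[np.argmax(np.abs(values))])
    return float(values.max())


# ---------------------------------------------------------------------------
# table-level drivers


def _control_stats_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per (plate, timepoint) background statistics of the control wells."""
    ctrl = cells[cells["control_kind"] != ""]
    if ctrl.empty:
        raise ValueError("cell table has no control wells")
    g = ctrl.groupby(["plate_id", "time_h"])["gfp_intensity"]
    stats = g.agg(
        ctrl_mean="mean",
        ctrl_sd=lambda v: np.std(v, ddof=1),
        ctrl_q1=lambda v: np.quantile(v, 0.25),
        ctrl_q3=lambda v: np.quantile(v, 0.75),
    ).reset_index()
    stats["ctrl_iqr"] = stats["ctrl_q3"] - stats["ctrl_q1"]
    return stats


def compute_descriptor_table(cells: pd.DataFrame, include_controls: bool = True) -> pd.DataFrame:
    """Long descriptor table from a cell table.

    One row per (compound, concentration, reporter, replicate, descriptor,
    timepoint). Control wells are evaluated against their own plate background
    and emitted under their control kind (``DMSO`` / ``TNFa_DMSO``) with one
    curve per control well (replicate key ``rep:plate:well``) so they can
    serve as the comparison group for whole-curve testing.

    Intensity descriptors are min-max scaled within (reporter, replicate)
    across compounds, concentrations and times — 0–1 for the up reporters,
    −1–1 around the plate-control trajectory for ICAM1 — with the realized
    raw min/max recorded; fraction descriptors are fractions already and
    bypass scaling.
    """
    stats = _control_stats_table(cells)
    df = cells.merge(stats, on=["plate_id", "time_h"], how="left")
    if df["ctrl_mean"].isna().any():
        raise ValueError("wells without matching plate controls")
    if not include_controls:
        df = df[df["control_kind"] == ""]

    is_ctrl = df["control_kind"] != ""
    df = df.assign(
        compound=np.where(is_ctrl, df["control_kind"], df["compound_abbrev"]),
        replicate=np.where(
            is_ctrl,
            df["replicate_id"].astype(str) + ":" + df["plate_id"] + ":" + df["well_id"],
            df["replicate_id"].astype(str),
        ),
    )

    gfp = df["gfp_intensity"]
    df = df.assign(
        above_2m=(gfp > 2.0 * df["ctrl_mean"]).astype(float),
        above_3m=(gfp > 3.0 * df["ctrl_mean"]).astype(float),
        above_m3sd=(gfp > df["ctrl_mean"] + 3.0 * df["ctrl_sd"]).astype(float),
    )
    for k in ICAM_KS:
        df[f"up_{k:g}"] = (gfp > df["ctrl_q3"] + k * df["ctrl_iqr"]).astype(float)
        df[f"down_{k:g}"] = (gfp < df["ctrl_q1"] - k * df["ctrl_iqr"]).astype(float)

    keys = ["compound", "conc_xcmax", "reporter", "replicate", "time_h"]
    agg = {"gfp_intensity": "mean", "ctrl_mean": "mean", "above_2m": "mean",
           "above_3m": "mean", "above_m3sd": "mean"}
    for k in ICAM_KS:
        agg[f"up_{k:g}"] = "mean"
        agg[f"down_{k:g}"] = "mean"
    well = df.groupby(keys, sort=True).agg(agg).reset_index()
    well["base_replicate"] = well["replicate"].str.split(":").str[0]

    records = []
    is_icam = well["reporter"] == "ICAM1"

    def _emit(sub: pd.DataFrame, descriptor: str, values, scaled: bool,
              raw_min=np.nan, raw_max=np.nan) -> None:
        rec = sub[keys].copy()
        rec["descriptor"] = descriptor
        rec["value"] = np.asarray(values, dtype=float)
        rec["scaled"] = scaled
        rec["raw_min"] = raw_min
        rec["raw_max"] = raw_max
        records.append(rec)

    # intensity: scaled within (reporter, replicate) across everything else
    for (reporter, _rep), sub in well.groupby(["reporter", "base_replicate"]):
        raw = sub["gfp_intensity"].to_numpy(dtype=float)
        if reporter == "ICAM1":
            # deviation from the matched plate-control trajectory, in [-1, 1]
            diff = raw - sub["ctrl_mean"].to_numpy(dtype=float)
            denom = float(np.max(np.abs(diff)))
            denom = denom if denom > 0 else 1.0
            _emit(sub, "intensity_mean", diff / denom, True,
                  raw_min=float(diff.min()), raw_max=float(diff.max()))
        else:
            rmin, rmax = float(raw.min()), float(raw.max())
            _emit(sub, "intensity_mean", scale_minmax(raw, rmin, rmax), True,
                  raw_min=rmin, raw_max=rmax)

    up_sub = well[~is_icam]
    for desc, col in (("frac_2m", "above_2m"), ("frac_3m", "above_3m"),
                      ("frac_m3sd", "above_m3sd")):
        _emit(up_sub, desc, up_sub[col], False)
    icam_sub = well[is_icam]
    if not icam_sub.empty:
        for k in ICAM_KS:
            up = icam_sub[f"up_{k:g}"].to_numpy(dtype=float)
            down = icam_sub[f"down_{k:g}"].to_numpy(dtype=float)
            _emit(icam_sub, f"icam_up_{k:g}", up, False)
            _emit(icam_sub, f"icam_down_{k:g}", down, False)
            _emit(icam_sub, f"icam_diff_{k:g}", up - down, False)

    out = pd.concat(records, ignore_index=True)
    return out.sort_values(
        ["reporter", "compound", "conc_xcmax", "replicate", "descriptor", "time_h"]
    ).reset_index(drop=True)


def max_summary_table(descriptor_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean max-over-time summaries for concentration–response fits.

    Per (compound, concentration, reporter, descriptor): take each replicate's
    time-course maximum (signed extreme for ICAM1 difference descriptors),
    then average over replicates. Output columns: compound, reporter,
    descriptor, conc_xcmax, response.
    """
    df = descriptor_table.copy()
    df["replicate"] = df["replicate"].astype(str)  # robust to re-parsed tables
    signed = df["descriptor"].str.startswith("icam_diff")
    # for signed-extreme descriptors rank by magnitude, keep the signed value
    df["_rank"] = np.where(signed, df["value"].abs(), df["value"])
    keys = ["compound", "reporter", "descriptor", "conc_xcmax", "replicate"]
    idx = df.groupby(keys)["_rank"].idxmax()
    per_rep = df.loc[idx, keys + ["value"]].rename(columns={"value": "response"})
    return (
        per_rep.groupby(["compound", "reporter", "descriptor", "conc_xcmax"])["response"]
        .mean()
        .reset_index()
    )


def _speed_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean cell speed (px/h) per well and timepoint from frame-to-frame
    displacements of tracked cell ids."""
    df = cells.sort_values(["plate_id", "well_id", "cell_id", "time_h"])
    grp = df.groupby(["plate_id", "well_id", "cell_id"])
    dx = grp["x_px"].diff()
    dy = grp["y_px"].diff()
    dt = grp["time_h"].diff()
    speed = np.hypot(dx, dy) / dt
    out = df.assign(speed=speed).dropna(subset=["speed"])
    return (
        out.groupby(["plate_id", "well_id", "time_h"])["speed"]
        .mean()
        .rename("speed")
        .reset_index()
    )


def compute_cytotox_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Per (compound, concentration, reporter) cytotoxicity summaries.

    ``pi_fraction_norm`` is the 24-h PI-positive fraction minus the matched
    plate-control fraction, averaged over replicate plates; the four slope
    features are per-plate OLS slopes over time (cell count as a fraction of
    the initial count) averaged over plates.
    """
    final_t = cells["time_h"].max()
    final = cells[cells["time_h"] == final_t].copy()
    final["dead"] = pi_flag(final)

    well_keys = ["plate_id", "well_id", "compound_abbrev", "conc_xcmax",
                 "reporter", "replicate_id", "control_kind"]
    pi_frac = final.groupby(well_keys)["dead"].mean().rename("pi_fraction").reset_index()
    ctrl_pi = (
        pi_frac[pi_frac["control_kind"] != ""]
        .groupby("plate_id")["pi_fraction"]
        .mean()
        .rename("ctrl_pi")
    )
    treated_pi = pi_frac[pi_frac["control_kind"] == ""].merge(
        ctrl_pi, on="plate_id", how="left"
    )
    treated_pi["pi_fraction_norm"] = treated_pi["pi_fraction"] - treated_pi["ctrl_pi"]

    treated = cells[cells["control_kind"] == ""]
    per_t = (
        treated.groupby(well_keys + ["time_h"])
        .agg(
            n_cells=("cell_id", "size"),
            nucleus=("nucleus_area_px", "mean"),
            hoechst=("hoechst_intensity", "mean"),
        )
        .reset_index()
    )
    speed = _speed_table(treated)
    per_t = per_t.merge(speed, on=["plate_id", "well_id", "time_h"], how="left")

    rows = []
    for key, sub in per_t.groupby(well_keys):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(dtype=float)
        n0 = float(sub["n_cells"].iloc[0])
        row = dict(zip(well_keys, key))
        row["slope_cell_count"] = feature_slope(sub["n_cells"] / n0, t)
        row["slope_nuclear_size"] = feature_slope(sub["nucleus"], t)
        row["slope_hoechst"] = feature_slope(sub["hoechst"], t)
        sp = sub.dropna(subset=["speed"])
        row["slope_speed"] = (
            feature_slope(sp["speed"], sp["time_h"]) if len(sp) >= 3 else np.nan
        )
        rows.append(row)
    slopes = pd.DataFrame(rows)

    merged = slopes.merge(
        treated_pi[well_keys + ["pi_fraction_norm"]], on=well_keys, how="left"
    )
    out = (
        merged.groupby(["compound_abbrev", "conc_xcmax", "reporter"])
        .agg(
            pi_fraction_norm=("pi_fraction_norm", "mean"),
            slope_cell_count=("slope_cell_count", "mean"),
            slope_speed=("slope_speed", "mean"),
            slope_nuclear_size=("slope_nuclear_size", "mean"),
            slope_hoechst=("slope_hoechst", "mean"),
        )
        .reset_index()
        .rename(columns={"compound_abbrev": "compound"})
    )
    return out
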