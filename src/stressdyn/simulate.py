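"""Synthetic high-content reporter screen generator.

Emulates the screen design downstream analysis assumes: 384-well plates laid
out as one reporter cell line × one concentration (1/5/10/50/100 × C-max),
hourly single-cell GFP and Hoechst measurements over 24 h, propidium-iodide
(PI) staining at the final frame only, vehicle controls on every plate
(TNFα + DMSO on ICAM1 plates), and at least two replicate plates per
condition.

The generator works at the level of per-cell feature records (the image
analysis producing them is upstream of this package). Drug effects are
encoded per compound × reporter as a latent concentration–response:

* SRXN1 / CHOP / P21 ("up" reporters): the population mean scaled response is
  ``m(t, x) = emax * x^h / (x^h + bmc^h) * 1 / (1 + exp(-k (t - t50)))`` —
  a Hill curve in concentration ``x`` (in C-max multiples) with a logistic
  onset in time. A cell's GFP is ``baseline * (1 + gain * m)`` times
  mean-one lognormal noise.
* ICAM1: all wells are TNFα-primed, so the control follows a saturating ramp
  ``r(t) = r0 + amp * t / (t + tau)``; a compound multiplies the ramp part by
  ``1 + (mult - 1) * Hill(x)`` with ``mult < 1`` suppression, ``> 1``
  enhancement.

Severe-DILI compounds draw their true benchmark concentration from a
lower-mean log-normal than non-severe compounds, so potency (BMC / C-max)
carries the class signal the dose-response and classifier stages look for.
Cytotoxicity enters through a saturating concentration effect that raises the
per-cell death probability, slows growth and motility, shrinks nuclei, and
condenses chromatin (raising Hoechst intensity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .annotation import CompoundAnnotation

REPORTERS = ("SRXN1", "CHOP", "P21", "ICAM1")
UP_REPORTERS = ("SRXN1", "CHOP", "P21")
CONCENTRATIONS = (1.0, 5.0, 10.0, 50.0, 100.0)

CELL_COLUMNS = [
    "plate_id",
    "well_id",
    "compound_abbrev",
    "conc_xcmax",
    "reporter",
    "replicate_id",
    "control_kind",
    "time_h",
    "cell_id",
    "gfp_intensity",
    "hoechst_intensity",
    "nucleus_area_px",
    "pi_overlap_area_px",
    "x_px",
    "y_px",
]


@dataclass(frozen=True)
class ReporterEffect:
    """Latent response of one compound in one reporter line."""

    responsive: bool
    emax: float
    bmc_true_xcmax: float
    hill: float
    t50_h: float
    onset_rate: float
    icam_multiplier: float = 1.0  # ICAM1 only; <1 suppression, >1 enhancement

    def __post_init__(self) -> None:
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError("emax must lie in [0, 1]")
        if self.bmc_true_xcmax <= 0:
            raise ValueError("bmc_true_xcmax must be positive")
        if self.icam_multiplier <= 0:
            raise ValueError("icam_multiplier must be positive")


@dataclass(frozen=True)
class SimCompoundParams:
    """Per-compound simulation truth: one ReporterEffect per reporter plus a
    cytotoxicity threshold (C-max multiples; ``inf`` = non-cytotoxic)."""

    abbreviation: str
    effects: Mapping[str, ReporterEffect]
    tox_conc_xcmax: float


@dataclass
class EffectConfig:
    """Distributions the per-compound latent parameters are drawn from.

    The class-dependent log10 BMC/C-max normals are the central study
    condition: severe mean 0.9 vs non-severe mean 1.6 (sd 0.4), truncated to
    [0, 2.3] so every true point of departure sits inside the tested
    1–100 × C-max decade range.
    """

    mu_log10_bmc: dict = field(
        default_factory=lambda: {"severe": 0.9, "non_severe": 1.6}
    )
    sd_log10_bmc: float = 0.4
    log10_bmc_bounds: tuple = (0.0, 2.3)
    responsive_prob: dict = field(
        default_factory=lambda: {
            "severe": {"SRXN1": 0.85, "CHOP": 0.8, "P21": 0.3, "ICAM1": 0.8},
            "non_severe": {"SRXN1": 0.35, "CHOP": 0.3, "P21": 0.15, "ICAM1": 0.4},
        }
    )
    emax_range: tuple = (0.5, 0.9)
    hill_range: tuple = (1.5, 3.0)
    t50_range_h: tuple = (6.0, 16.0)
    onset_range: tuple = (0.4, 1.0)
    icam_suppress_prob: float = 0.6
    icam_suppress_range: tuple = (0.2, 0.7)
    icam_enhance_range: tuple = (1.5, 3.0)
    tox_prob: dict = field(
        default_factory=lambda: {"severe": 0.6, "non_severe": 0.3}
    )
    mu_log10_tox: dict = field(
        default_factory=lambda: {"severe": 1.5, "non_severe": 2.2}
    )
    sd_log10_tox: float = 0.4
    # cell-level observation model
    noise_cv: float = 0.3
    baseline_gfp: float = 100.0
    gain: float = 4.0
    tnf_r0: float = 0.3
    tnf_amp: float = 2.0
    tnf_tau_h: float = 6.0
    hoechst_baseline: float = 500.0
    hoechst_cv: float = 0.2
    hoechst_tox_drift: float = 0.3
    nucleus_area_px: float = 180.0
    nucleus_area_cv: float = 0.25
    nucleus_tox_shrink: float = 0.3
    growth_rate_per_h: float = 0.02
    death_hazard_per_h: float = 0.06
    step_px_per_h: float = 15.0
    motility_tox_slowdown: float = 0.8
    field_px: float = 2048.0


@dataclass
class LayoutConfig:
    """Plate layout: one plate per reporter × concentration × replicate."""

    reporters: tuple = REPORTERS
    concentrations: tuple = CONCENTRATIONS
    n_replicates: int = 3
    n_control_wells: int = 2
    n_cells_0: int = 200
    hours: tuple = tuple(float(h) for h in range(25))


def hill(x, bmc: float, h: float):
    """Fraction of maximal response at concentration ``x`` (0 at x=0)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x**h / (x**h + bmc**h), 0.0)
    return float(out) if out.ndim == 0 else out


def onset_logistic(t, t50: float, rate: float):
    return 1.0 / (1.0 + np.exp(-rate * (np.asarray(t, dtype=float) - t50)))


def tnf_ramp(t, config: EffectConfig):
    """TNFα-induced control trajectory factor (relative to GFP baseline)."""
    t = np.asarray(t, dtype=float)
    return config.tnf_r0 + config.tnf_amp * t / (t + config.tnf_tau_h)


def mean_scaled_response(effect: ReporterEffect, t, x):
    """Population mean scaled response m(t, x) for an up reporter.

    Half-maximal in concentration at x = bmc_true; for emax = 0.8 the late-time
    response at x = bmc_true is 0.4.
    """
    if not effect.responsive:
        shape = np.broadcast(np.asarray(t, dtype=float), np.asarray(x, dtype=float)).shape
        return 0.0 if shape == () else np.zeros(shape)
    return (
        effect.emax
        * hill(x, effect.bmc_true_xcmax, effect.hill)
        * onset_logistic(t, effect.t50_h, effect.onset_rate)
    )


def mean_gfp_factor(effect: ReporterEffect | None, reporter: str, t, x, config: EffectConfig):
    """Mean GFP level in units of ``baseline_gfp``. ``effect=None`` → control."""
    t = np.asarray(t, dtype=float)
    if reporter == "ICAM1":
        ramp = config.tnf_amp * t / (t + config.tnf_tau_h)
        if effect is None or not effect.responsive:
            mult = np.zeros_like(t)
        else:
            mult = (effect.icam_multiplier - 1.0) * hill(
                x, effect.bmc_true_xcmax, effect.hill
            ) * np.ones_like(t)
        return config.tnf_r0 + ramp * (1.0 + mult)
    if effect is None:
        return np.ones_like(t)
    return 1.0 + config.gain * mean_scaled_response(effect, t, x)


def tox_saturation(x: float, tox_conc: float) -> float:
    """Saturating cytotoxic load in [0, 1); 1/2 at x = tox_conc."""
    if not math.isfinite(tox_conc) or x <= 0:
        return 0.0
    r = (x / tox_conc) ** 2
    return r / (1.0 + r)


def death_probability(x: float, tox_conc: float, config: EffectConfig, t_end: float = 24.0) -> float:
    lam = config.death_hazard_per_h * tox_saturation(x, tox_conc)
    return 1.0 - math.exp(-lam * t_end)


def _truncnorm_draw(rng, mu: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mu, lo), hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def draw_compound_params(
    annotation: CompoundAnnotation,
    effect_config: EffectConfig,
    rng_seed,
) -> SimCompoundParams:
    """Draw one compound's latent simulation truth, class-dependently.

    log10(BMC/C-max) per reporter ~ truncated N(mu_class, sd); responsiveness
    per reporter is Bernoulli with class-dependent probability. Deterministic
    given ``rng_seed`` (int or ``numpy.random.Generator``).
    """
    if annotation.is_control:
        raise ValueError("controls carry no latent drug effect")
    rng = np.random.default_rng(rng_seed)
    cfg = effect_config
    sev = annotation.severity
    effects: dict[str, ReporterEffect] = {}
    for reporter in REPORTERS:
        responsive = bool(rng.random() < cfg.responsive_prob[sev][reporter])
        log_bmc = _truncnorm_draw(
            rng, cfg.mu_log10_bmc[sev], cfg.sd_log10_bmc, *cfg.log10_bmc_bounds
        )
        emax = float(rng.uniform(*cfg.emax_range))
        h = float(rng.uniform(*cfg.hill_range))
        t50 = float(rng.uniform(*cfg.t50_range_h))
        rate = float(rng.uniform(*cfg.onset_range))
        if reporter == "ICAM1" and responsive:
            if rng.random() < cfg.icam_suppress_prob:
                mult = float(rng.uniform(*cfg.icam_suppress_range))
            else:
                mult = float(rng.uniform(*cfg.icam_enhance_range))
        else:
            mult = 1.0
        effects[reporter] = ReporterEffect(
            responsive=responsive,
            emax=emax,
            bmc_true_xcmax=10.0**log_bmc,
            hill=h,
            t50_h=t50,
            onset_rate=rate,
            icam_multiplier=mult,
        )
    if rng.random() < cfg.tox_prob[sev]:
        tox = 10.0 ** _truncnorm_draw(
            rng, cfg.mu_log10_tox[sev], cfg.sd_log10_tox, 0.5, 3.5
        )
    else:
        tox = math.inf
    return SimCompoundParams(
        abbreviation=annotation.abbreviation, effects=effects, tox_conc_xcmax=tox
    )


def _lognormal_noise(rng, shape, cv: float):
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def simulate_well(
    params: SimCompoundParams | None,
    conc_xcmax: float,
    reporter: str,
    n_cells_0: int,
    hours: Sequence[float],
    rng_seed,
    config: EffectConfig | None = None,
    *,
    plate_id: str = "plate",
    well_id: str = "well",
    replicate_id: int = 1,
    control_kind: str = "",
) -> pd.DataFrame:
    """Simulate all cell records of one well over the imaging session.

    ``params=None`` simulates a control well (DMSO, or TNFα + DMSO on ICAM1
    plates). PI overlap is recorded only at the final frame; dead cells there
    carry an overlap of at least 10% of the nuclear area.
    """
    if n_cells_0 <= 0:
        raise ValueError("n_cells_0 must be positive")
    if reporter not in REPORTERS:
        raise ValueError(f"unknown reporter {reporter!r}")
    config = config or EffectConfig()
    rng = np.random.default_rng(rng_seed)
    hours = np.asarray(hours, dtype=float)
    n_t = hours.size

    effect = params.effects[reporter] if params is not None else None
    tox = params.tox_conc_xcmax if params is not None else math.inf
    s_tox = tox_saturation(conc_xcmax, tox)

    # deterministic population size: growth suppressed (and reversed) by tox
    g_eff = config.growth_rate_per_h * (1.0 - 2.0 * s_tox)
    n_at = np.maximum(1, np.round(n_cells_0 * np.exp(g_eff * hours))).astype(int)
    n_max = int(n_at.max())

    mean_factor = mean_gfp_factor(effect, reporter, hours, conc_xcmax, config)  # (n_t,)
    gfp = (
        config.baseline_gfp
        * mean_factor[None, :]
        * _lognormal_noise(rng, (n_max, n_t), config.noise_cv)
    )
    hoechst_drift = 1.0 + config.hoechst_tox_drift * s_tox * hours / 24.0
    hoechst = (
        config.hoechst_baseline
        * hoechst_drift[None, :]
        * _lognormal_noise(rng, (n_max, n_t), config.hoechst_cv)
    )
    area_shrink = 1.0 - config.nucleus_tox_shrink * s_tox * hours / 24.0
    area = (
        config.nucleus_area_px
        * area_shrink[None, :]
        * _lognormal_noise(rng, (n_max, n_t), config.nucleus_area_cv)
    )

    # random-walk positions; step size reduced under toxicity
    step = config.step_px_per_h * (1.0 - config.motility_tox_slowdown * s_tox)
    dt = np.diff(hours, prepend=hours[0])
    steps_x = rng.normal(0.0, 1.0, size=(n_max, n_t)) * step * np.sqrt(np.maximum(dt, 0.0))
    steps_y = rng.normal(0.0, 1.0, size=(n_max, n_t)) * step * np.sqrt(np.maximum(dt, 0.0))
    steps_x[:, 0] = 0.0
    steps_y[:, 0] = 0.0
    x0 = rng.uniform(0.0, config.field_px, size=n_max)
    y0 = rng.uniform(0.0, config.field_px, size=n_max)
    xs = x0[:, None] + np.cumsum(steps_x, axis=1)
    ys = y0[:, None] + np.cumsum(steps_y, axis=1)

    # PI at the final frame: per-cell death Bernoulli with tox-dependent rate
    p_dead = death_probability(conc_xcmax, tox, config, t_end=float(hours[-1]))
    dead = rng.random(n_max) < p_dead
    final_area = area[:, -1]
    pi_final = np.where(
        dead,
        rng.uniform(0.10, 0.60, size=n_max) * final_area,
        np.where(
            rng.random(n_max) < 0.05,
            rng.uniform(0.0, 0.08, size=n_max) * final_area,
            0.0,
        ),
    )

    present = np.arange(n_max)[:, None] < n_at[None, :]  # (n_max, n_t)
    cell_idx, t_idx = np.nonzero(present)
    n_rec = cell_idx.size
    pi_col = np.full(n_rec, np.nan)
    at_end = t_idx == n_t - 1
    pi_col[at_end] = pi_final[cell_idx[at_end]]

    return pd.DataFrame(
        {
            "plate_id": np.repeat(plate_id, n_rec),
            "well_id": np.repeat(well_id, n_rec),
            "compound_abbrev": np.repeat(
                params.abbreviation if params is not None else control_kind or "DMSO",
                n_rec,
            ),
            "conc_xcmax": np.repeat(float(conc_xcmax), n_rec),
            "reporter": np.repeat(reporter, n_rec),
            "replicate_id": np.repeat(int(replicate_id), n_rec),
            "control_kind": np.repeat(control_kind, n_rec),
            "time_h": hours[t_idx],
            "cell_id": cell_idx,
            "gfp_intensity": gfp[cell_idx, t_idx],
            "hoechst_intensity": hoechst[cell_idx, t_idx],
            "nucleus_area_px": area[cell_idx, t_idx],
            "pi_overlap_area_px": pi_col,
            "x_px": xs[cell_idx, t_idx],
            "y_px": ys[cell_idx, t_idx],
        },
        columns=CELL_COLUMNS,
    )


def draw_screen_params(
    annotations: Iterable[CompoundAnnotation],
    effect_config: EffectConfig,
    rng_seed: int,
) -> dict[str, SimCompoundParams]:
    """Latent truth for every non-control compound, substreamed per compound."""
    params = {}
    for i, ann in enumerate(a for a in annotations if not a.is_control):
        params[ann.abbreviation] = draw_compound_params(
            ann, effect_config, np.random.default_rng([rng_seed, 7919, i])
        )
    return params


def truth_table(params: Mapping[str, SimCompoundParams]) -> pd.DataFrame:
    """One row per (compound, reporter) of the latent simulation truth."""
    rows = []
    for abb, p in params.items():
        for reporter, eff in p.effects.items():
            rows.append(
                {
                    "compound_abbrev": abb,
                    "reporter": reporter,
                    "responsive": eff.responsive,
                    "emax": eff.emax,
                    "bmc_true_xcmax": eff.bmc_true_xcmax,
                    "hill": eff.hill,
                    "t50_h": eff.t50_h,
                    "onset_rate": eff.onset_rate,
                    "icam_multiplier": eff.icam_multiplier,
                    "tox_conc_xcmax": p.tox_conc_xcmax,
                }
            )
    return pd.DataFrame(rows)


def simulate_screen(
    annotations: Iterable[CompoundAnnotation],
    effect_config: EffectConfig | None = None,
    layout_config: LayoutConfig | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full screen: one plate per reporter × concentration ×
    replicate, each holding one well per compound plus control wells.

    Returns the concatenated cell table and the latent truth table. Plate
    random streams are derived deterministically from the master seed, so the
    output is byte-identical across runs with the same inputs.
    """
    effect_config = effect_config or EffectConfig()
    layout = layout_config or LayoutConfig()
    annotations = list(annotations)
    compounds = [a for a in annotations if not a.is_control]
    params = draw_screen_params(compounds, effect_config, rng_seed)

    frames: list[pd.DataFrame] = []
    plate_index = 0
    for reporter in layout.reporters:
        control_kind = "TNFa_DMSO" if reporter == "ICAM1" else "DMSO"
        for conc in layout.concentrations:
            for rep in range(1, layout.n_replicates + 1):
                plate_index += 1
                plate_id = f"{reporter}_c{conc:g}_r{rep}"
                well = 0
                for c in range(layout.n_control_wells):
                    well += 1
                    frames.append(
                        simulate_well(
                            None,
                            0.0,
                            reporter,
                            layout.n_cells_0,
                            layout.hours,
                            np.random.default_rng([rng_seed, plate_index, well]),
                            effect_config,
                            plate_id=plate_id,
                            well_id=f"W{well:03d}",
                            replicate_id=rep,
                            control_kind=control_kind,
                        )
                    )
                for ann in compounds:
                    well += 1
                    frames.append(
                        simulate_well(
                            params[ann.abbreviation],
                            conc,
                            reporter,
                            layout.n_cells_0,
                            layout.hours,
                            np.random.default_rng([rng_seed, plate_index, well]),
                            effect_config,
                            plate_id=plate_id,
                            well_id=f"W{well:03d}",
                            replicate_id=rep,
                        )
                    )
    cells = pd.concat(frames, ignore_index=True)
    return cells, truth_table(params)


def noiseless_config(base: EffectConfig | None = None) -> EffectConfig:
    """Copy of a configuration with all cell-level noise and cytotoxicity off;
    used for parameter-recovery checks."""
    cfg = replace(
        base or EffectConfig(),
        noise_cv=0.0,
        hoechst_cv=0.0,
        nucleus_area_cv=0.0,
        tox_prob={"severe": 0.0, "non_severe": 0.0},
    )
    return cfg


def strong_separation_config(base: EffectConfig | None = None) -> EffectConfig:
    """Configuration with a strongly class-separated screen: severe compounds
    respond in almost every reporter at low BMC/C-max and are cytotoxic, while
    non-severe compounds rarely respond. Used for positive-control runs of the
    classifier, where near-perfect separation is the expected outcome."""
    return replace(
        base or EffectConfig(),
        mu_log10_bmc={"severe": 0.5, "non_severe": 1.9},
        sd_log10_bmc=0.15,
        responsive_prob={
            "severe": {"SRXN1": 0.95, "CHOP": 0.95, "P21": 0.6, "ICAM1": 0.95},
            "non_severe": {"SRXN1": 0.1, "CHOP": 0.1, "P21": 0.05, "ICAM1": 0.1},
        },
        tox_prob={"severe": 0.8, "non_severe": 0.05},
        mu_log10_tox={"severe": 1.2, "non_severe": 2.5},
        noise_cv=0.2,
    )


def analytic_intensity_bmc(
    effect: ReporterEffect,
    config: EffectConfig,
    raw_min: float,
    raw_max: float,
    delta: float = 0.25,
    t_end: float = 24.0,
    conc_range: tuple = (1.0, 100.0),
) -> float:
    """Ground-truth benchmark concentration of the noiseless scaled
    mean-intensity curve of an up reporter.

    After min-max scaling the late-time summary is an exact log-logistic in
    concentration, so the +0.25 departure point solves in closed form:
    ``Hill(x*) = q`` with ``q = delta * (raw_max - raw_min) /
    (baseline * gain * emax * L(t_end))``. Returns ``nan`` when the plateau
    never departs by ``delta`` or the crossing falls outside the tested range.
    """
    if not effect.responsive:
        return math.nan
    l_end = float(onset_logistic(t_end, effect.t50_h, effect.onset_rate))
    beta = config.baseline_gfp * config.gain * effect.emax * l_end
    q = delta * (raw_max - raw_min) / beta
    if not 0 < q < 1:
        return math.nan
    x = effect.bmc_true_xcmax * (q / (1.0 - q)) ** (1.0 / effect.hill)
    if not conc_range[0] <= x <= conc_range[1]:
        return math.nan
    return float(x)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV (``.csv``) or HDF5 (``.h5``/``.hdf5``)."""
    path = Path(path)
    if path.suffix == ".csv":
        cells.to_csv(path, index=False)
    elif path.suffix in (".h5", ".hdf5"):
        cells.to_hdf(path, key="cells", mode="w", format="table")
    else:
        raise ValueError(f"unsupported cell-table extension: {path.suffix}")


def read_cells(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        cells = pd.read_csv(path).astype({"time_h": float, "conc_xcmax": float})
    elif path.suffix in (".h5", ".hdf5"):
        cells = pd.read_hdf(path, key="cells")
    else:
        raise ValueError(f"unsupported cell-table extension: {path.suffix}")
    # empty control_kind marks a treated well; never NaN
    cells["control_kind"] = cells["control_kind"].fillna("")
    return cells
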