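"""Condensation, hypothesis testing, and clustering of descriptor time courses.

Replicate time courses are condensed with natural cubic spline regression
(8 degrees of freedom) evaluated on 24 equidistant timepoints and averaged
across replicates. Whole-curve treatment-vs-control comparisons use a
permutation ANOVA for functional data on 100-point linearly interpolated
curves: the statistic integrates the standardized squared difference between
group mean curves over the grid, and its null distribution comes from
permuting replicate labels (exhaustively when the number of distinct
assignments is small, by random draws otherwise). Up reporters are tested
one-sided for upregulation; ICAM1 two-sided. Benjamini–Hochberg controls the
false discovery rate across curves, with significance called at q < 0.01.

Multi-reporter clustering takes the mean over reporters of pairwise Manhattan
(L1) distances between condensed course vectors and feeds it to Ward
agglomerative linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FunctionalAnovaResult:
    statistic: float
    p_value: float
    direction: str
    n_permutations: int
    exhaustive: bool


@lru_cache(maxsize=256)
def _spline_design(times_key: tuple, grid_key: tuple, df: int):
    """Natural cubic spline basis on observed times and the evaluation grid
    (cached: every course of a screen shares the same time grid)."""
    times = np.asarray(times_key, dtype=float)
    grid = np.asarray(grid_key, dtype=float)
    design = dmatrix("cr(t, df=dof)", {"t": times, "dof": df})
    (basis_grid,) = build_design_matrices([design.design_info], {"t": grid, "dof": df})
    return np.asarray(design), np.asarray(basis_grid)


def condense_course(
    replicate_series: list[tuple[np.ndarray, np.ndarray]],
    n_points: int = 24,
    df: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Natural-cubic-spline condensation of replicate time courses.

    Each replicate ``(times, values)`` is fit by natural cubic spline basis
    regression with ``df`` degrees of freedom and evaluated on ``n_points``
    equidistant timepoints spanning the common observed range; replicates are
    then averaged pointwise. Constant and linear courses are reproduced
    exactly (natural splines contain the linear functions).
    """
    if not replicate_series:
        raise ValueError("no replicate series given")
    t_lo = max(np.min(t) for t, _ in replicate_series)
    t_hi = min(np.max(t) for t, _ in replicate_series)
    grid = np.linspace(t_lo, t_hi, n_points)
    fits = []
    for times, values in replicate_series:
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.size < df + 1:
            raise ValueError(
                f"{times.size} timepoints cannot support a df={df} spline basis"
            )
        design, basis_grid = _spline_design(
            tuple(times.tolist()), tuple(grid.tolist()), df
        )
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        fits.append(basis_grid @ coef)
    return grid, np.mean(fits, axis=0)


def interpolate_100(times, values, n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear resampling onto equidistant timepoints.

    Dense linear interpolation retains the original noise structure of the
    course; knot values are preserved wherever a grid point coincides with an
    observed timepoint.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 timepoints to interpolate")
    grid = np.linspace(times.min(), times.max(), n_points)
    return grid, np.interp(grid, times, values)


def _fanova_statistic(curves: np.ndarray, idx_a: np.ndarray, direction: str,
                      eps: float) -> np.ndarray:
    """Integrated standardized mean-difference statistic for one or many
    group-A index sets. ``curves``: (n, T); ``idx_a``: (B, nA)."""
    n, n_t = curves.shape
    n_a = idx_a.shape[1]
    n_b = n - n_a
    total = curves.sum(axis=0)  # (T,)
    sum_a = curves[idx_a].sum(axis=1)  # (B, T)
    mean_a = sum_a / n_a
    mean_b = (total[None, :] - sum_a) / n_b
    diff = mean_a - mean_b
    if direction == "up":
        diff = np.maximum(diff, 0.0)
    elif direction == "down":
        diff = np.minimum(diff, 0.0)
    # pooled pointwise variance of the permuted groups
    sq = curves**2
    sq_a = sq[idx_a].sum(axis=1)
    ss_a = sq_a - n_a * mean_a**2
    ss_b = (sq.sum(axis=0)[None, :] - sq_a) - n_b * mean_b**2
    dof = max(n - 2, 1)
    pooled = (ss_a + ss_b) / dof
    return np.mean(diff**2 / (pooled + eps), axis=1)


def functional_anova(
    treated_curves,
    control_curves,
    direction: str = "up",
    n_perm: int = 1999,
    rng_seed=0,
    eps: float = 1e-12,
) -> FunctionalAnovaResult:
    """Permutation one-way ANOVA for functional data.

    ``treated_curves`` and ``control_curves`` are lists/arrays of replicate
    curves on a common grid (e.g. the 100-point interpolation). The statistic
    is the grid mean of the squared group-mean difference standardized by the
    pooled pointwise variance; for ``direction='up'`` (``'down'``) only
    positive (negative) pointwise differences contribute. The p-value comes
    from permutation of replicate labels: exhaustive over all distinct
    assignments when there are at most ``n_perm`` of them, otherwise
    ``n_perm`` random assignments plus the observed one.
    """
    treated = np.atleast_2d(np.asarray(treated_curves, dtype=float))
    control = np.atleast_2d(np.asarray(control_curves, dtype=float))
    if treated.shape[0] < 2 or control.shape[0] < 2:
        raise ValueError("need at least 2 replicate curves per group")
    if treated.shape[1] != control.shape[1]:
        raise ValueError("curves must share a common grid")
    if direction not in ("up", "down", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    curves = np.vstack([treated, control])
    n, n_a = curves.shape[0], treated.shape[0]

    obs = float(_fanova_statistic(curves, np.arange(n_a)[None, :], direction, eps)[0])
    if obs == 0.0:
        return FunctionalAnovaResult(0.0, 1.0, direction, 0, True)

    n_distinct = comb(n, n_a)
    if n_distinct <= n_perm:
        idx = np.array(list(combinations(range(n), n_a)), dtype=int)
        stats = _fanova_statistic(curves, idx, direction, eps)
        p = float(np.mean(stats >= obs - 1e-12))
        return FunctionalAnovaResult(obs, p, direction, n_distinct, True)
    rng = np.random.default_rng(rng_seed)
    idx = np.array([rng.permutation(n)[:n_a] for _ in range(n_perm)], dtype=int)
    stats = _fanova_statistic(curves, idx, direction, eps)
    p = float((1 + np.sum(stats >= obs - 1e-12)) / (1 + n_perm))
    return FunctionalAnovaResult(obs, p, direction, n_perm, False)


def fdr_adjust(p_values, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg q-values and significance flags at q < alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < alpha


def multireporter_distance(courses_by_reporter: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean-over-reporters Manhattan distance matrix between items.

    Each value is a DataFrame indexed by item (compound) whose row is the
    concatenated condensed course vector for that reporter. Items missing a
    reporter contribute the mean over the reporters available to both items
    of a pair (pairwise-complete).
    """
    if not courses_by_reporter:
        raise ValueError("no reporter course tables given")
    widths = {df.shape[1] for df in courses_by_reporter.values()}
    if len(widths) > 1:
        raise ValueError(f"course vector dimension mismatch across reporters: {widths}")
    items = sorted(set().union(*(set(df.index) for df in courses_by_reporter.values())))
    n = len(items)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for reporter, df in courses_by_reporter.items():
        present = [i for i, it in enumerate(items) if it in df.index]
        if not present:
            continue
        vals = df.loc[[items[i] for i in present]].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"NaN course values for reporter {reporter}")
        d = np.abs(vals[:, None, :] - vals[None, :, :]).sum(axis=2)
        ii = np.asarray(present)
        acc[np.ix_(ii, ii)] += d
        cnt[np.ix_(ii, ii)] += 1
    if (cnt == 0).any():
        missing = [items[i] for i in range(n) if cnt[i, i] == 0]
        raise ValueError(f"items with no reporter courses: {missing}")
    out = acc / cnt
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=items, columns=items)


def ward_cluster(
    distance: pd.DataFrame | np.ndarray, k: int | None = None, height: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ward agglomerative clustering of a precomputed distance matrix.

    Returns (labels, linkage matrix). Cut either at ``k`` clusters or at a
    merge ``height``; with neither, every item gets its own label and only the
    merge tree is informative.
    """
    if isinstance(distance, pd.DataFrame):
        dmat = distance.to_numpy(dtype=float)
    else:
        dmat = np.asarray(distance, dtype=float)
    if dmat.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(dmat, dmat.T):
        raise ValueError("distance matrix must be symmetric")
    z = linkage(squareform(dmat, checks=False), method="ward")
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(z, t=height, criterion="distance")
    else:
        labels = np.arange(1, dmat.shape[0] + 1)
    return labels, z


HEADLINE_DESCRIPTOR = {
    "SRXN1": "frac_2m",
    "CHOP": "frac_2m",
    "P21": "frac_2m",
    "ICAM1": "icam_diff_2",
}
CONTROL_COMPOUNDS = ("DMSO", "TNFa_DMSO")


def condense_descriptor_table(
    descriptor_table: pd.DataFrame, n_points: int = 24, df: int = 8
) -> pd.DataFrame:
    """Condense every (compound, concentration, reporter, descriptor) course.

    Per-replicate spline fits are averaged; output is a long table with
    ``n_points`` equidistant timepoints per key.
    """
    descriptor_table = descriptor_table.assign(
        replicate=descriptor_table["replicate"].astype(str)
    )
    rows = []
    for (compound, conc, reporter, descriptor), sub in descriptor_table.groupby(
        ["compound", "conc_xcmax", "reporter", "descriptor"]
    ):
        series = [
            (rep_sub["time_h"].to_numpy(), rep_sub["value"].to_numpy())
            for _, rep_sub in sub.groupby("replicate")
        ]
        grid, values = condense_course(series, n_points=n_points, df=df)
        rows.append(
            pd.DataFrame(
                {
                    "compound": compound,
                    "conc_xcmax": conc,
                    "reporter": reporter,
                    "descriptor": descriptor,
                    "time_h": grid,
                    "value": values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def anova_table(
    descriptor_table: pd.DataFrame,
    headline: dict[str, str] | None = None,
    n_perm: int = 1999,
    rng_seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Whole-curve treatment-vs-control tests for every compound × concentration.

    For each reporter's headline descriptor, the treated replicate curves are
    compared against the pooled control-well curves of the same reporter
    (DMSO; TNFα + DMSO for ICAM1) on a common 100-point linear interpolation
    grid. Up reporters are tested for upregulation, ICAM1 two-sided.
    Benjamini–Hochberg q-values are appended with significance at q < alpha.
    """
    headline = headline or HEADLINE_DESCRIPTOR
    descriptor_table = descriptor_table.assign(
        replicate=descriptor_table["replicate"].astype(str)
    )
    rows = []
    for reporter, descriptor in headline.items():
        sub = descriptor_table[
            (descriptor_table["reporter"] == reporter)
            & (descriptor_table["descriptor"] == descriptor)
        ]
        if sub.empty:
            continue
        ctrl_name = "TNFa_DMSO" if reporter == "ICAM1" else "DMSO"
        ctrl = sub[sub["compound"] == ctrl_name]
        if ctrl.empty:
            raise ValueError(f"no {ctrl_name} control curves for reporter {reporter}")
        ctrl_curves = [
            interpolate_100(g["time_h"], g["value"])[1]
            for _, g in ctrl.groupby("replicate")
        ]
        direction = "two_sided" if reporter == "ICAM1" else "up"
        treated = sub[~sub["compound"].isin(CONTROL_COMPOUNDS)]
        for i, ((compound, conc), g) in enumerate(
            treated.groupby(["compound", "conc_xcmax"])
        ):
            curves = [
                interpolate_100(r["time_h"], r["value"])[1]
                for _, r in g.groupby("replicate")
            ]
            res = functional_anova(
                curves, ctrl_curves, direction=direction, n_perm=n_perm,
                rng_seed=np.random.default_rng(
                    [rng_seed, sum(ord(ch) for ch in reporter), i]
                ),
            )
            rows.append(
                {
                    "compound": compound,
                    "conc_xcmax": conc,
                    "reporter": reporter,
                    "descriptor": descriptor,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "direction": res.direction,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        q, sig = fdr_adjust(out["p"], alpha=alpha)
        out["q"] = q
        out["significant"] = sig
    return out


def courses_by_reporter(
    condensed: pd.DataFrame, descriptor_by_reporter: dict[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Reshape a condensed table into per-reporter item × feature matrices.

    Each compound's row concatenates its condensed courses over all
    concentrations (sorted), giving the time-course vectors whose Manhattan
    distances drive the multi-reporter clustering.
    """
    descriptor_by_reporter = descriptor_by_reporter or HEADLINE_DESCRIPTOR
    out = {}
    for reporter, descriptor in descriptor_by_reporter.items():
        sub = condensed[
            (condensed["reporter"] == reporter)
            & (condensed["descriptor"] == descriptor)
            & ~condensed["compound"].isin(CONTROL_COMPOUNDS)
        ]
        if sub.empty:
            continue
        wide = sub.pivot_table(
            index="compound", columns=["conc_xcmax", "time_h"], values="value"
        ).sort_index(axis=1)
        out[reporter] = wide
    return out


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Encode a linkage merge tree as a Newick string (branch lengths are
    merge-height differences)."""
    tree = to_tree(z)

    def _rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = _rec(node.left, node.dist)
        right = _rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return _rec(tree, tree.dist) + ";"
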