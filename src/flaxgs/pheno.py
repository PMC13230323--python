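"""Two-stage multi-environment trial (MET) analysis of plot-level records.

Stage 1 fits, per experiment, the fixed-effects model
value = line + block + error and reports least-squares (adjusted) line means;
in balanced RCBDs these equal raw line means.  Stage 2 combines stage-1 means
across experiments with the mixed model
mean = mu + experiment (fixed) + line (random, sigma_g2) + residual,
estimating variance components by profiled REML and returning per-line BLUPs (on
the trait scale, i.e. grand mean + shrunken deviation).  Shared check lines
are what connect experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PhenoError(ValueError):
    pass


class EstimabilityError(PhenoError):
    pass


class RemlConvergenceError(RuntimeError):
    def __init__(self, msg, trajectory):
        super().__init__(msg)
        self.trajectory = trajectory


@dataclass
class LineValues:
    """Per-line estimates from a stage of the MET analysis."""

    table: pd.DataFrame  # line, estimate, se (se may be nan)
    kind: str  # stage1 | blup | merged
    variance_components: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def lines(self) -> pd.Series:
        return self.table["line"]

    def as_series(self) -> pd.Series:
        return self.table.set_index("line")["estimate"]


def _check_records(records: pd.DataFrame) -> None:
    required = {"line", "experiment", "block", "value"}
    missing = required - set(records.columns)
    if missing:
        raise PhenoError(f"records missing columns {sorted(missing)}")
    if not np.isfinite(records["value"]).all():
        raise PhenoError("non-finite phenotype values")
    if records.duplicated(["line", "experiment", "block"]).any():
        raise PhenoError("duplicate (line, experiment, block) rows")


def _connected_components(lines: pd.Series, blocks: pd.Series) -> list[set]:
    """Components of the line-block incidence graph (union-find)."""
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for ln, bl in zip(lines, blocks):
        a, b = ("L", ln), ("B", bl)
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        union(a, b)
    comps: dict = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return list(comps.values())


def stage1_adjusted_means(records: pd.DataFrame, experiment: str) -> LineValues:
    """Least-squares line means within one experiment, adjusting for blocks.

    lsmean_i = mu + line_i + average block effect; with complete blocks this
    reduces to the raw line mean.  Disconnected designs are rejected with the
    orphan lines named.
    """
    _check_records(records)
    sub = records[records["experiment"] == experiment]
    if sub.empty:
        raise PhenoError(f"no records for experiment {experiment!r}")
    comps = _connected_components(sub["line"], sub["block"])
    if len(comps) > 1:
        comps.sort(key=len, reverse=True)
        orphans = sorted(
            n for comp in comps[1:] for kind, n in comp if kind == "L"
        )
        raise EstimabilityError(
            f"design for {experiment!r} is disconnected; orphan lines: {orphans}"
        )
    lines = sorted(sub["line"].unique())
    blocks = sorted(sub["block"].unique())
    li = {l: k for k, l in enumerate(lines)}
    bi = {b: k for k, b in enumerate(blocks)}
    n = len(sub)
    # treatment coding: intercept, line dummies (ref = first), block dummies
    X = np.zeros((n, 1 + len(lines) - 1 + len(blocks) - 1))
    X[:, 0] = 1.0
    for r, (ln, bl) in enumerate(zip(sub["line"], sub["block"])):
        if li[ln] > 0:
            X[r, li[ln]] = 1.0
        if bi[bl] > 0:
            X[r, len(lines) - 1 + bi[bl]] = 1.0
    y = sub["value"].to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = n - rank
    resid = y - X @ beta
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    block_avg = np.zeros(X.shape[1])
    block_avg[len(lines) - 1 + 1 : len(lines) - 1 + len(blocks)] = 1.0 / len(blocks)
    rows = []
    for ln in lines:
        contrast = block_avg.copy()
        contrast[0] = 1.0
        if li[ln] > 0:
            contrast[li[ln]] = 1.0
        est = float(contrast @ beta)
        se = float(np.sqrt(max(sigma2 * contrast @ XtX_inv @ contrast, 0.0)))
        rows.append((ln, est, se if dof > 0 else np.nan))
    return LineValues(
        table=pd.DataFrame(rows, columns=["line", "estimate", "se"]),
        kind="stage1",
        variance_components={"sigma_e2": sigma2},
        meta={"experiment": experiment, "n_plots": n, "n_blocks": len(blocks)},
    )


def stage1_all_experiments(records: pd.DataFrame) -> pd.DataFrame:
    """Stage-1 means for every experiment, stacked (line, experiment,
    estimate, se)."""
    out = []
    for exp in pd.unique(records["experiment"]):
        lv = stage1_adjusted_means(records, exp)
        t = lv.table.copy()
        t.insert(1, "experiment", exp)
        out.append(t)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Stage 2: EM-REML mixed model
# ---------------------------------------------------------------------------

def _reml_one_random(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    fix_sigma_g2: float | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray, list]:
    """REML for one random effect: V = sigma_g2 * ZZ' + sigma_e2 * I.

    The likelihood is profiled over the variance ratio delta = sigma_e2 /
    sigma_g2 on the eigenbasis of ZZ' and maximized by bounded scalar search
    (EM stalls sublinearly when sigma_g2 sits near its boundary, so the
    profiled search is used throughout; the boundary itself maps to the edge
    of the delta range and is reported as sigma_g2 = 0).  Returns
    (sigma_g2, sigma_e2, b, u, trajectory of evaluated candidates).
    """
    from scipy.optimize import minimize_scalar

    n, q = len(y), Z.shape[1]
    rank_x = np.linalg.matrix_rank(X)
    traj: list = []

    def ols():
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        se2 = float((y - X @ b) @ (y - X @ b) / (n - rank_x))
        return b, se2

    if fix_sigma_g2 is not None and fix_sigma_g2 <= 0.0:
        b, se2 = ols()
        return 0.0, se2, b, np.zeros(q), traj

    K = Z @ Z.T
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    def profile(log_delta: float) -> tuple[float, np.ndarray, float]:
        delta = np.exp(log_delta)
        w = d + delta
        Xw = Xt / w[:, None]
        b = np.linalg.lstsq(Xw.T @ Xt, Xw.T @ yt, rcond=None)[0]
        r = yt - Xt @ b
        quad = float(r @ (r / w))
        sg2 = quad / (n - rank_x)
        _, logdet_xx = np.linalg.slogdet(Xt.T @ (Xt / w[:, None]))
        neg2l = (n - rank_x) * np.log(max(sg2, 1e-300)) + np.log(w).sum() + logdet_xx
        return neg2l, b, sg2

    if fix_sigma_g2 is not None:
        # only sigma_e2 free: 1-D search over delta at fixed sigma_g2
        def obj(log_delta):
            delta = np.exp(log_delta)
            w = d + delta
            Xw = Xt / w[:, None]
            b = np.linalg.lstsq(Xw.T @ Xt, Xw.T @ yt, rcond=None)[0]
            r = yt - Xt @ b
            quad = float(r @ (r / w)) / fix_sigma_g2
            _, logdet_xx = np.linalg.slogdet(Xt.T @ (Xt / w[:, None]))
            return (
                (n - rank_x) * np.log(fix_sigma_g2)
                + np.log(w).sum()
                + logdet_xx
                + quad
            )

        res = minimize_scalar(
            obj, bounds=(-20.0, 20.0), method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        delta = float(np.exp(res.x))
        sg2, se2 = float(fix_sigma_g2), float(fix_sigma_g2 * delta)
    else:
        def obj(log_delta):
            neg2l, _, sg2 = profile(log_delta)
            traj.append((float(np.exp(log_delta)), sg2))
            return neg2l

        res = minimize_scalar(
            obj, bounds=(-20.0, 20.0), method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        if not res.success:
            raise RemlConvergenceError(
                f"REML search failed after {max_iter} evaluations", traj
            )
        delta = float(np.exp(res.x))
        _, _, sg2 = profile(res.x)
        se2 = sg2 * delta
        if delta >= np.exp(19.0):  # boundary: no genetic variance
            b, se2 = ols()
            return 0.0, se2, b, np.zeros(q), traj

    w = d + delta
    Xw = Xt / w[:, None]
    b = np.linalg.lstsq(Xw.T @ Xt, Xw.T @ yt, rcond=None)[0]
    u = Z.T @ (U @ ((yt - Xt @ b) / w))
    return float(sg2), float(se2), b, u, traj


def stage2_blup(
    stage1_tables: pd.DataFrame,
    fix_sigma_g2: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LineValues:
    """Across-experiment BLUPs from stacked stage-1 means.

    Input columns: line, experiment, estimate (se optional, unused by
    default).  Returns estimates on the trait scale: experiment-adjusted
    grand mean plus the shrunken line deviation.
    """
    df = stage1_tables
    for col in ("line", "experiment", "estimate"):
        if col not in df.columns:
            raise PhenoError(f"stage-1 table missing column {col!r}")
    lines = sorted(df["line"].unique())
    exps = sorted(df["experiment"].unique())
    li = {l: k for k, l in enumerate(lines)}
    ei = {e: k for k, e in enumerate(exps)}
    n = len(df)
    X = np.zeros((n, len(exps)))  # cell-means coding for experiments
    Z = np.zeros((n, len(lines)))
    for r, (ln, ex) in enumerate(zip(df["line"], df["experiment"])):
        X[r, ei[ex]] = 1.0
        Z[r, li[ln]] = 1.0
    y = df["estimate"].to_numpy(dtype=float)
    sg2, se2, b, u, traj = _reml_one_random(
        y, X, Z, tol=tol, max_iter=max_iter, fix_sigma_g2=fix_sigma_g2
    )
    grand = float(np.mean(b))  # average over experiment means
    table = pd.DataFrame(
        {"line": lines, "estimate": grand + u, "se": np.nan, "blup_deviation": u}
    )
    return LineValues(
        table=table,
        kind="blup",
        variance_components={
            "sigma_g2": sg2,
            "sigma_e2": se2,
            "n_iterations": len(traj),
        },
        meta={"n_experiments": len(exps), "grand_mean": grand},
    )


def combine_sources(
    a: LineValues, b: LineValues
) -> tuple[LineValues, float | None]:
    """Merge two independent estimate sets (e.g. dual seed sources).

    Returns the merged LineValues (inverse-variance weighted where SEs are
    available, else equal weights) and the Pearson correlation on shared
    lines (None, flagged, when either source is constant).
    """
    ta = a.table.set_index("line")
    tb = b.table.set_index("line")
    shared = ta.index.intersection(tb.index)
    if len(shared) == 0:
        raise PhenoError("no lines shared between sources")
    xa = ta.loc[shared, "estimate"].to_numpy()
    xb = tb.loc[shared, "estimate"].to_numpy()
    r: float | None
    if np.std(xa) == 0 or np.std(xb) == 0:
        r = None
        merged_vals = xb if np.std(xa) == 0 else xa
        merged = pd.DataFrame(
            {"line": shared, "estimate": merged_vals, "se": np.nan}
        )
    else:
        r = float(np.corrcoef(xa, xb)[0, 1])
        sa = ta.loc[shared, "se"].to_numpy() if "se" in ta else np.full_like(xa, np.nan)
        sb = tb.loc[shared, "se"].to_numpy() if "se" in tb else np.full_like(xb, np.nan)
        if np.isnan(sa).any() or np.isnan(sb).any() or (sa == 0).any() or (sb == 0).any():
            wa = wb = np.ones_like(xa)
        else:
            wa, wb = 1.0 / sa**2, 1.0 / sb**2
        merged = pd.DataFrame(
            {
                "line": shared,
                "estimate": (wa * xa + wb * xb) / (wa + wb),
                "se": np.nan,
            }
        )
    out = LineValues(
        table=merged.reset_index(drop=True),
        kind="merged",
        meta={"cross_source_r": r, "constant_source": r is None},
    )
    return out, r
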