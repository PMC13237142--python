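"""Hill-curve fitting of titration profiles and the fit-acceptance cascade.

The measured quantity per protein is the reporter abundance across an
11-channel concentration series. Each biological replicate is
max-normalized per protein (its titration vector divided by its own
maximum), replicates that are not fully quantified are excluded, and
proteins fully quantified in at least ``min_replicates`` replicates are
averaged channel-wise (mean +/- SEM). The mean profile is fit with the
Hill-like model

    R(c) = b + (t - b) * c**h / (c**h + K**h),    t >= b >= 0, h > 0,

which is finite at c = 0 so the zero control enters the fit directly. K is
reported as the apparent dissociation constant KD_app (uM). A fit is
accepted only if it clears three gates: R^2 >= 0.9, an extra-sum-of-squares
F-test against the constant-mean null at p <= 0.05, and log2 fold-change
>= 1 between the top-concentration and zero-control channels. Pearson
tiers (moderate/good/perfect at r > 0.90/0.95/0.99) are descriptive
annotations only. Accepted binders are placed into affinity classes by
strict KD_app cutoffs (< 1, < 5, < 25 uM).

Numerically the fit profiles out (b, t): for any (K, h) the optimal
baseline/plateau solve a 2x2 constrained linear least-squares problem, so
the nonlinear search runs over (log10 K, h) only -- a vectorized coarse
grid scan (24 log-spaced K values x 9 slopes) seeds a bounded
trust-region polish. K is constrained to [c_min_nonzero/20, c_max*20] and
h to (0, 10].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import TitrationDesign
from .io import QuantTable

log = logging.getLogger(__name__)

PEARSON_TIERS = (("perfect", 0.99), ("good", 0.95), ("moderate", 0.90))
AFFINITY_CLASSES = (("sub1", 1.0), ("sub5", 5.0), ("sub25", 25.0))


@dataclass(frozen=True)
class QCThresholds:
    """Fit-acceptance gates and affinity-class cutoffs (all configurable)."""

    r2_min: float = 0.9
    f_p_max: float = 0.05
    log2fc_min: float = 1.0
    pearson_tiers: Tuple[Tuple[str, float], ...] = PEARSON_TIERS
    affinity_cutoffs: Tuple[float, float, float] = (1.0, 5.0, 25.0)

    def __post_init__(self) -> None:
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")
        if not 0 < self.f_p_max <= 1:
            raise ValueError("f_p_max must lie in (0, 1]")
        cut = tuple(float(c) for c in self.affinity_cutoffs)
        if list(cut) != sorted(cut) or len(cut) != 3:
            raise ValueError("affinity_cutoffs must be three ascending values")
        object.__setattr__(self, "affinity_cutoffs", cut)


@dataclass
class NormalizedProfile:
    """Replicate-merged titration profile (channel means, SEMs, n)."""

    mean: pd.DataFrame  # rows (protein, probe, fraction, metal) x channels
    sem: pd.DataFrame
    n_replicates: pd.Series


@dataclass
class HillFitResult:
    protein_id: str
    probe: str
    fraction: str
    metal: str
    n_replicates: int
    baseline: float = np.nan
    plateau: float = np.nan
    hill_slope: float = np.nan
    kd_app: float = np.nan
    r_squared: float = np.nan
    pearson_r: float = np.nan
    pearson_tier: str = "none"
    f_stat: float = np.nan
    f_pvalue: float = np.nan
    log2fc_endpoints: float = np.nan
    converged: bool = False
    boundary: bool = False
    pass_r2: bool = False
    pass_f: bool = False
    pass_fc: bool = False
    pass_all: bool = False
    affinity_class: str = ""


# ---------------------------------------------------------------------------
# normalization and replicate merging

def normalize_replicate(
    table: QuantTable, mode: str = "per_protein"
) -> pd.DataFrame:
    """Max-normalize each fully quantified titration vector.

    ``per_protein`` (default) divides every protein's channel vector by its
    own within-replicate maximum, making replicate curves commensurable
    before averaging; ``per_sample`` divides each channel column by the
    column maximum instead. Rows with any missing channel are dropped (the
    protein is not "fully quantified" in that replicate); all-zero rows are
    excluded with a logged reason.
    """
    data = table.data
    complete = data.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        log.info("normalize_replicate: dropped %d not-fully-quantified rows", dropped)
    data = data.loc[complete]
    if mode == "per_protein":
        maxima = data.max(axis=1)
        zero = maxima <= 0
        if zero.any():
            log.info("normalize_replicate: excluded %d all-zero profiles", int(zero.sum()))
            data, maxima = data.loc[~zero], maxima.loc[~zero]
        return data.div(maxima, axis=0)
    if mode == "per_sample":
        maxima = data.max(axis=0)
        return data.div(maxima.where(maxima > 0), axis=1)
    raise ValueError(f"unknown normalization mode {mode!r}")


def merge_replicates(
    normalized: pd.DataFrame, min_replicates: int = 2
) -> NormalizedProfile:
    """Average normalized replicates; keep proteins with >= min_replicates.

    SEM is the channel-wise standard error over the qualifying replicates
    (0 where only identical replicates contribute).
    """
    group_cols = ["protein_id", "probe", "fraction", "metal"]
    grouped = normalized.groupby(level=group_cols, sort=True)
    n = grouped.size()
    keep = n[n >= min_replicates].index
    log.info(
        "merge_replicates: retained %d of %d profiles at the >=%d-replicate gate",
        len(keep), len(n), min_replicates,
    )
    mean = grouped.mean().loc[keep]
    sd = grouped.std(ddof=1).loc[keep]
    sem = sd.div(np.sqrt(n.loc[keep]), axis=0)
    return NormalizedProfile(mean=mean, sem=sem, n_replicates=n.loc[keep])


# ---------------------------------------------------------------------------
# Hill fit

def _solve_linear(f: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Optimal (b, t) for R = b(1-f) + t f subject to t >= b >= 0.

    Returns (b, t, ss). Solved analytically from the 2x2 normal equations;
    constraint violations fall back to the best boundary solution.
    """
    u = 1.0 - f
    uu, uv, vv = u @ u, u @ f, f @ f
    uy, vy = u @ y, f @ y
    det = uu * vv - uv * uv
    candidates: List[Tuple[float, float]] = []
    if det > 1e-14 * max(uu * vv, 1e-300):
        b = (uy * vv - vy * uv) / det
        t = (vy * uu - uy * uv) / det
        if t >= b >= 0:
            res = y - (b * u + t * f)
            return b, t, float(res @ res)
    # boundary: t == b (constant model)
    m = max(float(np.mean(y)), 0.0)
    candidates.append((m, m))
    # boundary: b == 0
    if vv > 0:
        t0 = max(vy / vv, 0.0)
        candidates.append((0.0, t0))
    best = None
    for b, t in candidates:
        if not t >= b >= 0:
            continue
        res = y - (b * u + t * f)
        ss = float(res @ res)
        if best is None or ss < best[2]:
            best = (b, t, ss)
    return best  # type: ignore[return-value]


def _fraction_bound(c: np.ndarray, log10_kd: float, h: float) -> np.ndarray:
    f = np.zeros_like(c)
    nz = c > 0
    # compute in log space for numerical stability at extreme K, h
    z = h * (np.log10(c[nz]) - log10_kd)
    f[nz] = 1.0 / (1.0 + 10.0 ** (-z))
    return f


def _grid_best(
    c: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> Tuple[float, float]:
    """Coarse vectorized (log10 K, h) scan used to seed the local polish.

    The baseline/plateau pair is profiled out at every grid node by the
    same constrained linear solve the polish uses; ties prefer smaller h.
    """
    logk = np.linspace(lo, hi, 24)
    hs = np.array([0.3, 0.5, 0.8, 1.0, 1.3, 1.8, 2.5, 4.0, 7.0])
    K, H = np.meshgrid(logk, hs, indexing="ij")
    K, H = K.ravel(), H.ravel()
    logc = np.where(c > 0, np.log10(np.where(c > 0, c, 1.0)), 0.0)
    z = H[:, None] * (logc[None, :] - K[:, None])
    f = np.where(c[None, :] > 0, 1.0 / (1.0 + 10.0 ** (-z)), 0.0)
    u = 1.0 - f
    uu = np.einsum("ij,ij->i", u, u)
    uv = np.einsum("ij,ij->i", u, f)
    vv = np.einsum("ij,ij->i", f, f)
    uy = u @ y
    vy = f @ y
    det = uu * vv - uv * uv
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(det > 0, (uy * vv - vy * uv) / det, np.nan)
        t = np.where(det > 0, (vy * uu - uy * uv) / det, np.nan)
    valid = np.isfinite(b) & (b >= 0) & (t >= b)
    # fallback candidates where the unconstrained solution is infeasible
    m = max(float(np.mean(y)), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t0 = np.where(vv > 0, np.maximum(vy / vv, 0.0), 0.0)
    b_c = np.where(valid, b, 0.0)
    t_c = np.where(valid, t, t0)
    res = y[None, :] - (b_c[:, None] * u + t_c[:, None] * f)
    ss = np.einsum("ij,ij->i", res, res)
    res_const = y - m
    ss_const = float(res_const @ res_const)
    ss = np.where(valid, ss, np.minimum(ss, ss_const))
    # prefer smaller h on (near-)ties
    order = np.lexsort((H, K, np.round(ss, 14)))
    best = order[0]
    return float(K[best]), float(H[best])


def fit_hill(
    y: np.ndarray,
    design: TitrationDesign,
    thresholds: QCThresholds = QCThresholds(),
) -> Dict[str, object]:
    """Fit the Hill-like model to one mean titration profile.

    ``y`` is the vector of channel means aligned with the design. Returns a
    dict of fitted parameters, fit statistics, and cascade flags. Requires
    at least 5 usable concentration points (4 parameters + 1); never raises
    on non-convergence -- failed fits come back flagged instead.
    """
    c = np.asarray(design.channel_concentrations, dtype=float)
    y = np.asarray(y, dtype=float)
    usable = np.isfinite(y)
    c, y = c[usable], y[usable]
    n = len(y)
    out: Dict[str, object] = {k: np.nan for k in (
        "baseline", "plateau", "hill_slope", "kd_app", "r_squared", "pearson_r",
        "f_stat", "f_pvalue", "log2fc_endpoints")}
    out.update(converged=False, boundary=False, pearson_tier="none",
               pass_r2=False, pass_f=False, pass_fc=False, pass_all=False,
               affinity_class="")
    if n < 5:
        return out

    cmin, cmax = c[c > 0].min(), c.max()
    lo, hi = np.log10(cmin / 20.0), np.log10(cmax * 20.0)
    bounds = ([lo, 1e-2], [hi, 10.0])

    def residuals(x: np.ndarray) -> np.ndarray:
        f = _fraction_bound(c, x[0], x[1])
        b, t, _ = _solve_linear(f, y)
        return y - (b * (1.0 - f) + t * f)

    best: Optional[Tuple[float, np.ndarray]] = None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    gk, gh = _grid_best(c, y, lo, hi)
    starts = [(gk, gh)]
    if gh != 1.0:
        starts.append((gk, 1.0))
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0=list(x0), bounds=bounds,
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=60,
            )
        except Exception:  # pragma: no cover - optimizer robustness guard
            continue
        ss = float(sol.fun @ sol.fun)
        if best is None or ss < best[0] - 1e-15 or (
            abs(ss - best[0]) <= 1e-15 and sol.x[1] < best[1][1]
        ):
            best = (ss, sol.x)
        if ss <= 1e-14 * max(ss_tot, 1e-300):
            break  # essentially perfect fit; further starts cannot improve
    if best is None:
        return out

    ss_res, x = best
    f = _fraction_bound(c, x[0], x[1])
    b, t, _ = _solve_linear(f, y)
    fitted = b * (1.0 - f) + t * f
    kd = 10.0 ** x[0]

    out["baseline"], out["plateau"], out["hill_slope"], out["kd_app"] = b, t, float(x[1]), float(kd)
    out["converged"] = True
    out["boundary"] = bool(
        x[0] - lo < 1e-6 or hi - x[0] < 1e-6 or x[1] - 1e-2 < 1e-6 or 10.0 - x[1] < 1e-6
    )

    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    out["r_squared"] = float(r2)
    if np.std(fitted) > 0 and np.std(y) > 0:
        out["pearson_r"] = float(np.corrcoef(fitted, y)[0, 1])
    tier = "none"
    for name, cutoff in thresholds.pearson_tiers:
        if np.isfinite(out["pearson_r"]) and out["pearson_r"] > cutoff:
            tier = name
            break
    out["pearson_tier"] = tier

    # extra-sum-of-squares F against the constant-mean null (3 extra df)
    df1, df2 = 3, n - 4
    if ss_tot <= 0:  # constant profile: null and full model coincide
        f_stat, f_p = 0.0, 1.0
    elif ss_res <= 0:
        f_stat, f_p = np.inf, 0.0
    elif ss_tot <= ss_res:
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat = ((ss_tot - ss_res) / df1) / (ss_res / df2)
        f_p = float(stats.f.sf(f_stat, df1, df2))
    out["f_stat"], out["f_pvalue"] = float(f_stat), float(f_p)

    # endpoint fold-change with an epsilon floor of half the minimum
    # positive mean, so a zero control cannot produce an infinite ratio
    positive = y[y > 0]
    eps = 0.5 * positive.min() if len(positive) else 1.0
    y_top, y_zero = max(y[-1], eps), max(y[0], eps)
    out["log2fc_endpoints"] = float(np.log2(y_top / y_zero))

    out["pass_r2"] = bool(r2 >= thresholds.r2_min)
    out["pass_f"] = bool(f_p <= thresholds.f_p_max)
    out["pass_fc"] = bool(out["log2fc_endpoints"] >= thresholds.log2fc_min)
    out["pass_all"] = out["pass_r2"] and out["pass_f"] and out["pass_fc"]
    if out["pass_all"]:
        out["affinity_class"] = classify_affinity(kd, thresholds)
    return out


def classify_affinity(kd_app: float, thresholds: QCThresholds = QCThresholds()) -> str:
    """Strict-inequality affinity class: sub1 / sub5 / sub25 / weak."""
    if not np.isfinite(kd_app) or kd_app <= 0:
        raise ValueError("classify_affinity requires a positive fitted KD_app")
    c1, c5, c25 = thresholds.affinity_cutoffs
    if kd_app < c1:
        return "sub1"
    if kd_app < c5:
        return "sub5"
    if kd_app < c25:
        return "sub25"
    return "weak"


def fit_profiles(
    profiles: NormalizedProfile,
    design: TitrationDesign,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Fit every merged profile; one result row per (protein, probe, condition)."""
    rows = []
    for key, y in profiles.mean.iterrows():
        res = fit_hill(y.to_numpy(), design, thresholds)
        pid, probe, fraction, metal = key
        rows.append(
            {
                "protein_id": pid, "probe": probe, "fraction": fraction,
                "metal": metal, "n_replicates": int(profiles.n_replicates.loc[key]),
                "baseline": res["baseline"], "plateau": res["plateau"],
                "hill_slope": res["hill_slope"], "kd_app_uM": res["kd_app"],
                "r_squared": res["r_squared"], "pearson_r": res["pearson_r"],
                "pearson_tier": res["pearson_tier"], "f_stat": res["f_stat"],
                "f_pvalue": res["f_pvalue"],
                "log2fc_endpoints": res["log2fc_endpoints"],
                "converged": res["converged"], "boundary": res["boundary"],
                "pass_r2": res["pass_r2"], "pass_f": res["pass_f"],
                "pass_fc": res["pass_fc"], "pass_all": res["pass_all"],
                "affinity_class": res["affinity_class"],
            }
        )
    return pd.DataFrame(rows)


def run_dose_response(
    table: QuantTable,
    thresholds: QCThresholds = QCThresholds(),
    min_replicates: int = 2,
    normalization: str = "per_protein",
) -> pd.DataFrame:
    """Normalize, merge and fit a full quantification table."""
    normalized = normalize_replicate(table, mode=normalization)
    profiles = merge_replicates(normalized, min_replicates=min_replicates)
    return fit_profiles(profiles, table.design, thresholds)


# ---------------------------------------------------------------------------
# binder-set overlap summaries

def binder_overlap(
    sets: Mapping[str, Mapping[str, float]],
    mode: str = "all",
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Pairwise overlap between binder sets.

    ``sets`` maps a set label to {protein_id: kd_app}. Mode ``all`` uses
    the full sets; ``top_n_by_kd`` ranks each set ascending by kd_app
    (ties broken by protein id) and truncates to ``top_n`` before
    intersecting. The fraction of A found in B is reported per ordered
    pair; empty sets yield defined=False rather than NaN arithmetic.
    """
    if len(sets) < 2:
        raise ValueError("binder_overlap needs at least two sets")
    if mode not in ("all", "top_n_by_kd"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "top_n_by_kd" and not top_n:
        raise ValueError("top_n_by_kd mode requires top_n")
    members: Dict[str, set] = {}
    for name, kds in sets.items():
        if mode == "top_n_by_kd":
            ranked = sorted(kds.items(), key=lambda kv: (kv[1], kv[0]))[:top_n]
            members[name] = {pid for pid, _ in ranked}
        else:
            members[name] = set(kds)
    rows = []
    names = list(sets)
    for a in names:
        for b in names:
            if a == b:
                continue
            inter = len(members[a] & members[b])
            defined = len(members[a]) > 0
            rows.append(
                {
                    "set_a": a, "set_b": b,
                    "size_a": len(members[a]), "size_b": len(members[b]),
                    "intersection": inter,
                    "frac_a_in_b": inter / len(members[a]) if defined else None,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)
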