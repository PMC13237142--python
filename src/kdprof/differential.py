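"""Single-concentration differential enrichment and the compound-specificity screen.

Probe-vs-probe comparisons use the one channel closest to 33.3 uM extracted
across multiplexes. Intensities are log2-transformed (zeros already treated
as missing upstream), median-normalized across samples, and tested with a
per-protein linear model whose residual variances are shrunk by empirical
Bayes: the prior (d0, s0^2) is estimated by moment matching on the log
residual variances (digamma/trigamma relations), the posterior variance is
s~^2 = (d0*s0^2 + d*s^2) / (d0 + d), and the moderated t has d0 + d degrees
of freedom. Significance uses the dual threshold |log2FC| > 1 and p < 0.05
(static mode) or distribution-derived thresholds at median +/- 2.5*MAD
(dynamic mode).

The compound-specificity screen imputes left-censored missing values with a
minimal-probability (MinProb) draw near the detection limit, runs a
main-effects three-way ANOVA (compound, fraction, treatment) per protein
with per-factor Benjamini-Hochberg FDR, selects proteins with a significant
compound effect but no significant fraction or treatment effect, z-scores
the selected rows, and clusters rows and columns (Euclidean distance,
complete linkage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import QuantTable

log = logging.getLogger(__name__)


@dataclass
class IntensityMatrix:
    """Proteins x samples log2 intensities plus sample annotations.

    ``values``: DataFrame, rows protein ids, columns sample labels.
    ``samples``: DataFrame indexed by sample label with columns
    probe, fraction, metal, replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample annotation must match value columns")


def build_intensity_matrix(
    table: QuantTable, concentration: float = 100.0 / 3.0
) -> IntensityMatrix:
    """Extract the channel nearest ``concentration`` and log2-transform."""
    conc = np.asarray(table.design.channel_concentrations)
    channel = int(np.argmin(np.abs(conc - concentration)))
    wide = table.data[channel].unstack(["probe", "fraction", "metal", "replicate"])
    labels = [f"{p}_{f}-{m}_rep{r}" for p, f, m, r in wide.columns]
    samples = pd.DataFrame(
        [(p, f, m, r) for p, f, m, r in wide.columns],
        columns=["probe", "fraction", "metal", "replicate"],
        index=pd.Index(labels, name="sample"),
    )
    values = pd.DataFrame(np.log2(wide.to_numpy()), index=wide.index, columns=labels)
    return IntensityMatrix(values=values, samples=samples)


def filter_min_replicates(
    matrix: IntensityMatrix, min_n: int = 2, groups: Optional[Sequence[str]] = None
) -> IntensityMatrix:
    """Keep proteins quantified in >= min_n replicates of >= 1 condition.

    A condition is one combination of the grouping columns (default probe,
    fraction, metal).
    """
    groups = list(groups or ["probe", "fraction", "metal"])
    observed = matrix.values.notna()
    keep = pd.Series(False, index=matrix.values.index)
    for _, cols in matrix.samples.groupby(groups).groups.items():
        keep |= observed[list(cols)].sum(axis=1) >= min_n
    log.info("filter_min_replicates: retained %d of %d proteins", int(keep.sum()), len(keep))
    return IntensityMatrix(matrix.values.loc[keep], matrix.samples)


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Shift each sample so its median equals the median of sample medians.

    Samples with fewer than two observed values are left unshifted with a
    warning; missing values are ignored in the medians.
    """
    values = matrix.values.copy()
    medians = values.median(axis=0, skipna=True)
    counts = values.notna().sum(axis=0)
    target = float(medians[counts >= 2].median())
    for col in values.columns:
        if counts[col] < 2:
            warnings.warn(f"sample {col!r} has < 2 observed values; left unshifted")
            continue
        values[col] = values[col] - medians[col] + target
    return IntensityMatrix(values, matrix.samples)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> Tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Uses the standard empirical-Bayes relations on z = log s^2:
    E[z] and Var[z] are digamma/trigamma functions of the degrees of
    freedom, so the excess spread of z over its sampling noise identifies
    d0 and the recentered mean identifies s0^2. When the observed spread
    does not exceed sampling noise, d0 = inf (complete pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    n = len(e)
    ebar = e.mean()
    evar = ((e - ebar) ** 2).sum() / (n - 1)
    if evar <= 1e-12 * (1.0 + ebar**2):
        # variances are literally identical: pooling to that common value
        # makes moderation an exact no-op
        return np.inf, float(np.exp(np.mean(z)))
    excess = evar - polygamma(1, d / 2.0).mean()
    if excess <= 0:
        # spread no larger than sampling noise: complete pooling with the
        # chi-square bias correction (the documented moment estimate)
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(float(excess))
    s0_sq = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def squeeze_variances(
    s2: np.ndarray, df: np.ndarray, d0: float, s0_sq: float
) -> np.ndarray:
    """Posterior variances s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


def moderated_test(
    matrix: IntensityMatrix,
    contrast: Tuple[str, str],
    group_by: str = "probe",
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    mode: str = "static",
) -> pd.DataFrame:
    """Two-group moderated t-test between contrast levels of ``group_by``.

    log2FC is mean(A) - mean(B). Proteins need >= 2 observations in at
    least one side; sides with a single observation contribute no variance
    and are flagged ``pooled_only``. BH adjustment is applied across all
    tested proteins.
    """
    a_label, b_label = contrast
    for lab in contrast:
        if lab not in set(matrix.samples[group_by]):
            raise ValueError(f"contrast level {lab!r} not found in {group_by!r}")
    if mode not in ("static", "dynamic"):
        raise ValueError(f"unknown cutoff mode {mode!r}")
    cols_a = matrix.samples.index[matrix.samples[group_by] == a_label]
    cols_b = matrix.samples.index[matrix.samples[group_by] == b_label]
    A = matrix.values[cols_a].to_numpy()
    B = matrix.values[cols_b].to_numpy()
    na = np.isfinite(A).sum(axis=1)
    nb = np.isfinite(B).sum(axis=1)
    tested = (na + nb >= 3) & (na >= 1) & (nb >= 1) & ((na >= 2) | (nb >= 2))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
        var_a = np.nanvar(A, axis=1, ddof=1)
        var_b = np.nanvar(B, axis=1, ddof=1)
    var_a = np.where(na >= 2, var_a, 0.0)
    var_b = np.where(nb >= 2, var_b, 0.0)
    df_res = np.maximum(na - 1, 0) + np.maximum(nb - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df_res > 0, (var_a * np.maximum(na - 1, 0) + var_b * np.maximum(nb - 1, 0)) / np.where(df_res > 0, df_res, 1), np.nan)

    d0, s0_sq = estimate_prior(s2[tested], df_res[tested])
    s2_post = squeeze_variances(s2, df_res, d0, s0_sq)
    se = np.sqrt(s2_post * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
    log2fc = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t = log2fc / se
    df_total = np.where(np.isinf(d0), np.inf, d0 + df_res)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    res = pd.DataFrame(
        {
            "protein_id": matrix.values.index,
            "contrast": f"{a_label}_vs_{b_label}",
            "log2fc": log2fc,
            "moderated_t": t,
            "p_value": p,
            "pooled_only": (na < 2) | (nb < 2),
        }
    ).loc[tested]
    res = res.reset_index(drop=True)
    res["adj_p"] = multipletests(res["p_value"], method="fdr_bh")[1]
    if mode == "dynamic":
        lo, hi, fallback = dynamic_cutoff(res["log2fc"].to_numpy())
        if fallback:
            mode = "static"
        else:
            res["significant"] = ((res["log2fc"] > hi) | (res["log2fc"] < lo)) & (
                res["p_value"] < p_threshold
            )
    if mode == "static":
        res["significant"] = (res["log2fc"].abs() > fc_threshold) & (
            res["p_value"] < p_threshold
        )
    res["cutoff_mode"] = mode
    res.attrs["d0"] = d0
    res.attrs["s0_sq"] = s0_sq
    return res


def dynamic_cutoff(
    log2fc: np.ndarray, n_mads: float = 2.5, min_results: int = 50
) -> Tuple[float, float, bool]:
    """Distribution-derived fold-change thresholds at median +/- n_mads*MAD.

    Returns (lower, upper, fallback). Degenerate inputs (< min_results
    values or MAD == 0) fall back to static thresholds with a warning.
    """
    x = np.asarray(log2fc, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_results:
        warnings.warn("too few results for a dynamic cutoff; falling back to static")
        return np.nan, np.nan, True
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        warnings.warn("MAD of log2FC distribution is 0; falling back to static")
        return np.nan, np.nan, True
    return med - n_mads * mad, med + n_mads * mad, False


# ---------------------------------------------------------------------------
# imputation, three-way ANOVA, clustering

def minprob_impute(
    matrix: IntensityMatrix,
    q: float = 0.01,
    tune_sigma: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> IntensityMatrix:
    """Impute left-censored missing values near the detection limit.

    Each missing entry of sample j is drawn from Normal(mu_j, sigma_j)
    where mu_j is the q-quantile of the sample's observed values and
    sigma_j is tune_sigma times the median per-protein standard deviation
    (computed across samples) over proteins observed in sample j. Samples
    with no observed values raise an error naming the sample.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    arr = values.to_numpy()
    if not np.isnan(arr).any():
        return IntensityMatrix(values, matrix.samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_sd = np.nanstd(arr, axis=1, ddof=1)
    for j, col in enumerate(values.columns):
        colvals = arr[:, j]
        observed = np.isfinite(colvals)
        if not observed.any():
            raise ValueError(f"sample {col!r} has no observed values to impute from")
        missing = ~observed
        if not missing.any():
            continue
        mu = np.nanquantile(colvals[observed], q)
        sds = row_sd[observed]
        sds = sds[np.isfinite(sds)]
        sigma = tune_sigma * (float(np.median(sds)) if len(sds) else float(np.nanstd(colvals[observed])))
        arr[missing, j] = rng.normal(mu, max(sigma, 0.0), size=int(missing.sum()))
    return IntensityMatrix(pd.DataFrame(arr, index=values.index, columns=values.columns), matrix.samples)


_FACTORS = ("compound", "fraction", "treatment")
_FACTOR_COLUMNS = {"compound": "probe", "fraction": "fraction", "treatment": "metal"}


def _dummies(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    if len(cats.categories) < 2:
        raise ValueError("factor needs >= 2 levels")
    return pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)


def three_way_anova(matrix: IntensityMatrix, fdr: float = 0.05) -> pd.DataFrame:
    """Main-effects ANOVA (compound + fraction + treatment) per protein.

    Requires a completed (imputed) matrix with every factor level present.
    Per-factor F-tests compare the full main-effects model to the model
    without that factor; BH-FDR is applied per factor across proteins.
    compound_specific is true when q_compound < fdr while q_fraction and
    q_treatment are both >= fdr.
    """
    Y = matrix.values.to_numpy()
    if np.isnan(Y).any():
        raise ValueError("three_way_anova requires a completed (imputed) matrix")
    info = matrix.samples
    blocks: Dict[str, np.ndarray] = {}
    for factor in _FACTORS:
        col = _FACTOR_COLUMNS[factor]
        if info[col].nunique() < 2:
            raise ValueError(f"factor {factor!r} ({col}) has a missing level")
        blocks[factor] = _dummies(info[col])
    n = Y.shape[1]
    intercept = np.ones((n, 1))

    def rss(X: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(X)
        fitted = (Y @ Q) @ Q.T
        return np.sum((Y - fitted) ** 2, axis=1)

    X_full = np.hstack([intercept] + [blocks[f] for f in _FACTORS])
    p_full = X_full.shape[1]
    rss_full = rss(X_full)
    df_resid = n - p_full
    out = pd.DataFrame({"protein_id": matrix.values.index})
    for factor in _FACTORS:
        X_red = np.hstack([intercept] + [blocks[f] for f in _FACTORS if f != factor])
        df_f = blocks[factor].shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            F = ((rss(X_red) - rss_full) / df_f) / (rss_full / df_resid)
        F = np.where(rss_full <= 0, np.inf, np.maximum(F, 0.0))
        p = stats.f.sf(F, df_f, df_resid)
        out[f"F_{factor}"] = F
        out[f"p_{factor}"] = p
        out[f"q_{factor}"] = multipletests(p, method="fdr_bh")[1]
    out["compound_specific"] = (
        (out["q_compound"] < fdr)
        & (out["q_fraction"] >= fdr)
        & (out["q_treatment"] >= fdr)
    )
    return out


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: List[str]
    col_order: List[str]
    excluded: List[str]


def cluster_heatmap_input(values: pd.DataFrame) -> ClusterResult:
    """Row z-scoring plus complete-linkage Euclidean clustering.

    Rows are standardized to mean 0 and sample SD (n-1) of 1; zero-variance
    rows are excluded from clustering and listed in ``excluded``. Row and
    column dendrogram leaf orders and merge heights are returned.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs >= 2 proteins and >= 2 samples")
    sd = values.std(axis=1, ddof=1)
    excluded = list(values.index[(sd == 0) | ~np.isfinite(sd)])
    kept = values.loc[~values.index.isin(excluded)]
    if kept.shape[0] < 2:
        raise ValueError("fewer than 2 rows with variance; nothing to cluster")
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[kept.index], axis=0)
    row_link = hierarchy.linkage(z.to_numpy(), method="complete", metric="euclidean")
    col_link = hierarchy.linkage(z.to_numpy().T, method="complete", metric="euclidean")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(z, row_link, col_link, row_order, col_order, excluded)
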