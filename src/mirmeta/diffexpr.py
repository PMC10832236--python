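"""Per-study sex-stratified differential expression.

A single group-means linear model over the four sex x condition groups
(control-F, AD-F, control-M, AD-M) is fitted per study, and the two
contrasts of interest — AD female minus control female, AD male minus
control male — are estimated from it, so both sexes share one residual
variance pool.  RNA-seq counts are first converted to log2
counts-per-million with per-observation precision weights derived from
a lowess fit of residual sqrt-standard-deviation against average
log-count (weight = predicted sqrt-sd to the power -4, i.e. inverse
predicted variance).  Per-miRNA residual variances are then shrunk
toward a prior estimated across miRNAs by moment matching of
log-variances (digamma/trigamma inversion), giving moderated
t-statistics on augmented degrees of freedom, with Benjamini-Hochberg
adjustment within each study x contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .ingest import StudyBundle

logger = logging.getLogger("mirmeta")

GROUP_ORDER = ("control_female", "ad_female", "control_male", "ad_male")

CONTRASTS = {
    # AD minus control within each sex, over the four groups in GROUP_ORDER
    "female": np.array([-1.0, 1.0, 0.0, 0.0]),
    "male": np.array([0.0, 0.0, -1.0, 1.0]),
}

LOWESS_SPAN = 0.5  # span for the mean-variance trend
MIN_MIRNAS_FOR_TREND = 50  # below this, fall back to a flat trend


@dataclass
class DEResult:
    """Differential-expression table for one contrast in one study."""

    study_id: str
    tissue: str
    contrast: str  # "female" or "male"
    table: pd.DataFrame  # index mirna_id: logFC, se, t_mod, df_total, p, adj_p, zero_var
    n_samples: dict = field(default_factory=dict)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def group_labels(samples: pd.DataFrame) -> pd.Series:
    cond = samples["condition"].str.lower().map({"control": "control", "ad": "ad"})
    return cond + "_" + samples["sex"]


def build_design(samples: pd.DataFrame):
    """One-hot group-means design over the four groups, plus contrast specs.

    Returns ``(design, contrasts)`` where design has one column per group
    (zero-sample groups dropped) and ``contrasts`` maps contrast name to
    its coefficient vector over the retained columns; a contrast touching
    an absent group is disabled (omitted) for this study.
    """
    g = group_labels(samples)
    design = pd.DataFrame(
        {grp: (g == grp).astype(float) for grp in GROUP_ORDER}, index=samples.index
    )
    present = [c for c in design.columns if design[c].sum() > 0]
    if len(present) < 2:
        raise ValueError("fewer than 2 distinct sex x condition groups")
    design = design[present]
    contrasts = {}
    for name, full in CONTRASTS.items():
        vec = pd.Series(full, index=GROUP_ORDER)
        touched = [grp for grp in GROUP_ORDER if vec[grp] != 0]
        if all(t in present for t in touched):
            contrasts[name] = vec[present].to_numpy()
        else:
            logger.info("contrast %r disabled: group(s) %s absent", name,
                        [t for t in touched if t not in present])
    return design, contrasts


def count_transform(
    counts: pd.DataFrame,
    libsizes: np.ndarray | None = None,
    design: pd.DataFrame | None = None,
):
    """Counts -> (log2-CPM matrix, precision weights, trend table).

    logcpm = log2((count + 0.5) / (libsize + 1) * 1e6).  Residual
    sqrt-standard-deviations from a group-means fit are smoothed against
    average log2-count by lowess; each observation's weight is the trend
    prediction at its fitted log-count raised to the power -4.
    """
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise ValueError("count matrix must contain non-negative integers")
    if libsizes is None:
        libsizes = vals.sum(axis=0)
    libsizes = np.asarray(libsizes, dtype=float)
    if (libsizes <= 0).any():
        bad = counts.columns[libsizes <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")

    logcpm = np.log2((vals + 0.5) / (libsizes + 1.0) * 1e6)
    n = vals.shape[1]
    if design is None:
        X = np.ones((n, 1))
    else:
        X = design.to_numpy(dtype=float)
    # unweighted fit for the trend; one-hot designs make this group means
    beta, *_ = np.linalg.lstsq(X, logcpm.T, rcond=None)
    fitted = (X @ beta).T
    resid = logcpm - fitted
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the trend fit")
    s = np.sqrt((resid**2).sum(axis=1) / df_resid)  # residual sd per miRNA
    sqrt_sd = np.sqrt(s)

    # x axis: average log2 count, reconstructed from mean log-CPM
    offset = np.mean(np.log2(libsizes + 1.0)) - np.log2(1e6)
    avg_logcount = logcpm.mean(axis=1) + offset

    if len(sqrt_sd) >= MIN_MIRNAS_FOR_TREND and np.ptp(avg_logcount) > 1e-8:
        tr = lowess(sqrt_sd, avg_logcount, frac=LOWESS_SPAN, return_sorted=True)
        tx, ty = tr[:, 0], np.maximum(tr[:, 1], 1e-4)
    else:
        tx = np.array([avg_logcount.min() - 1, avg_logcount.max() + 1])
        ty = np.full(2, max(float(sqrt_sd.mean()), 1e-4))

    fitted_logcount = fitted + (np.log2(libsizes + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)
    weights = pred**-4.0
    logcpm_df = pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)
    w_df = pd.DataFrame(weights, index=counts.index, columns=counts.columns)
    trend = pd.DataFrame({"avg_logcount": tx, "sqrt_sd": ty})
    return logcpm_df, w_df, trend


def trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Models s2 ~ s0^2 * F(df, d0) and matches mean and variance of
    log s2 using digamma/trigamma identities; returns (inf, geometric
    mean variance) when the observed spread of log-variances does not
    exceed the sampling spread.  Falls back to a median-based prior
    (d0 = 10, s0^2 = median s2) if the inversion misbehaves on tiny
    inputs.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) == 0:
        raise ValueError("no positive residual variances to estimate a prior from")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if len(s2) < 2:
        return np.inf, float(np.exp(emean))
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    try:
        d0 = float(2.0 * trigamma_inverse(np.array([evar]))[0])
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        if not (np.isfinite(d0) and d0 > 0 and np.isfinite(s02) and s02 > 0):
            raise FloatingPointError
    except (FloatingPointError, ZeroDivisionError):
        logger.warning("variance-prior inversion failed; using median-based fallback")
        d0, s02 = 10.0, float(np.median(s2))
    return d0, s02


def fit_moderated(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    contrast: np.ndarray,
    weights: pd.DataFrame | None = None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Weighted least squares per miRNA + empirical-Bayes moderated t.

    ``prior_df``/``prior_var`` override the estimated prior (prior_df=0
    gives ordinary t-statistics).  Returns a table indexed by miRNA with
    logFC, se, t_mod, df_total, p, adj_p and a zero_var flag.
    """
    Y = expr.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    c = np.asarray(contrast, dtype=float)
    G, n = Y.shape
    p_cols = X.shape[1]
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("design matrix is rank deficient")
    df_resid = n - p_cols
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    W = np.ones_like(Y) if weights is None else weights.to_numpy(dtype=float)
    if (W <= 0).any() or not np.isfinite(W).all():
        raise ValueError("precision weights must be positive and finite")

    # batched WLS: A_g = X' W_g X, b_g = X' W_g y_g
    A = np.einsum("gs,sp,sq->gpq", W, X, X)
    b = np.einsum("gs,sp->gp", W * Y, X)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    # unscaled variance of the contrast: c' A^-1 c
    Ainv_c = np.linalg.solve(A, np.broadcast_to(c, (G, p_cols))[..., None])[..., 0]
    v = np.einsum("gp,p->g", Ainv_c, c)
    logfc = beta @ c
    resid = Y - beta @ X.T
    s2 = np.einsum("gs,gs->g", W, resid**2) / df_resid

    zero_var = s2 <= 1e-300
    if prior_df is None or prior_var is None:
        if np.all(zero_var):
            raise ValueError("all miRNAs have zero residual variance")
        d0_est, s02_est = estimate_prior(s2[~zero_var], df_resid)
        d0 = d0_est if prior_df is None else prior_df
        s02 = s02_est if prior_var is None else prior_var
    else:
        d0, s02 = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full(G, s02)
        df_total = np.full(G, np.inf)
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = np.full(G, d0 + df_resid)
    se = np.sqrt(s2_post * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    pval = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_total),
    )
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "se": se,
            "t_mod": t,
            "df_total": df_total,
            "p": pval,
            "adj_p": bh_adjust(pval),
            "zero_var": zero_var,
        },
        index=expr.index,
    )
    out.attrs["prior_df"] = float(d0)
    out.attrs["prior_var"] = float(s02)
    out.attrs["df_resid"] = float(df_resid)
    return out


def run_de(bundle: StudyBundle) -> list[DEResult]:
    """All active sex-stratified contrasts for one preprocessed study."""
    design, contrasts = build_design(bundle.samples)
    if bundle.platform == "rnaseq":
        logcpm, weights, _trend = count_transform(bundle.expr, design=design)
        expr, w = logcpm, weights
    else:
        expr, w = bundle.expr, None
    g = group_labels(bundle.samples)
    n_samples = g.value_counts().to_dict()
    results = []
    for name, cvec in contrasts.items():
        table = fit_moderated(expr, design, cvec, weights=w)
        results.append(
            DEResult(
                study_id=bundle.study_id,
                tissue=bundle.tissue,
                contrast=name,
                table=table,
                n_samples=n_samples,
            )
        )
    return results


def write_de_results(results: list[DEResult], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in results:
        r.table.rename_axis("mirna_id").to_csv(
            out / f"de_{r.study_id}_{r.contrast}.tsv", sep="\t"
        )
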