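"""Ranking-transfer functional enrichment of meta-analysis profiles.

Every analyzed miRNA (significant or not) receives a signed index,
by default sign(mu_hat) * (-log10 p); the index is transferred to
target genes through a miRNA->gene map (gene score = mean index over
the miRNAs that target it) and the gene scores are rank-transformed to
standard-normal quantiles.  Each GO Biological Process term within the
configured size bounds is then tested with a univariate logistic model
of term membership on the normalized gene index; the fitted slope is
the log odds ratio (lor) and its Wald test yields the p-value, with
Benjamini-Hochberg adjustment across tested terms.  The background
universe is the set of genes reachable from the target map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diffexpr import bh_adjust
from .meta import MetaResult

logger = logging.getLogger("mirmeta")

DEFAULT_SIZE_BOUNDS = (10, 500)


@dataclass
class RankedGeneIndex:
    """Per-gene signed ranking score transferred from miRNA statistics."""

    raw: pd.Series  # gene_id -> mean miRNA index
    normalized: pd.Series  # gene_id -> standard-normal quantile of the raw rank
    n_mirnas: pd.Series  # gene_id -> number of contributing miRNAs


def load_target_map(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for m, g in zip(df["mirna_id"], df["gene_id"]):
        out.setdefault(m, set()).add(g)
    return {m: gs for m, gs in out.items() if gs}


def load_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "go_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(need)}")
    if "go_name" not in df.columns:
        df["go_name"] = df["go_id"]
    return df[["gene_id", "go_id", "go_name"]]


def mirna_index(meta_table: pd.DataFrame, transform: str = "signed_logp") -> pd.Series:
    """Signed per-miRNA ranking index from a meta-analysis table.

    ``signed_logp``: sign(mu_hat) * (-log10 p);  ``signed_z``: the z
    statistic itself.  Zero p-values are clamped to the smallest
    positive float with a warning.
    """
    p = meta_table["p"].to_numpy(dtype=float)
    if (p <= 0).any():
        logger.warning("clamping %d zero p-values for the ranking index",
                       int((p <= 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    if transform == "signed_logp":
        idx = np.sign(meta_table["mu_hat"].to_numpy()) * (-np.log10(p))
    elif transform == "signed_z":
        idx = meta_table["z"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown index transform {transform!r}")
    return pd.Series(idx, index=meta_table.index, name="index")


def transfer_to_genes(
    index: pd.Series, targets: dict[str, set[str]], aggregate: str = "mean"
) -> RankedGeneIndex:
    """Propagate the miRNA index to target genes and rank-normalize.

    A gene's raw score aggregates (default: mean) the indices of the
    indexed miRNAs that target it; genes targeted by no indexed miRNA
    are absent.  Normalized scores are standard-normal quantiles of the
    mid-offset ranks, so hub genes are comparable to sparsely targeted
    ones.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    indexed = index.dropna()
    for m, val in indexed.items():
        for g in targets.get(m, ()):
            sums[g] = sums.get(g, 0.0) + float(val)
            counts[g] = counts.get(g, 0) + 1
    if not sums:
        raise ValueError("no overlap between indexed miRNAs and the target map")
    genes = sorted(sums)
    n_mirnas = pd.Series({g: counts[g] for g in genes}, name="n_mirnas")
    if aggregate == "mean":
        raw = pd.Series({g: sums[g] / counts[g] for g in genes}, name="raw")
    elif aggregate == "sum":
        raw = pd.Series({g: sums[g] for g in genes}, name="raw")
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    ranks = stats.rankdata(raw.to_numpy(), method="average")
    normalized = pd.Series(
        stats.norm.ppf((ranks - 0.5) / len(ranks)), index=raw.index, name="normalized"
    )
    return RankedGeneIndex(raw=raw, normalized=normalized, n_mirnas=n_mirnas)


def _score_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rao score test of slope 0 in a univariate logistic model."""
    ybar = y.mean()
    xc = x - x.mean()
    u = float((y - ybar) @ x)
    var = float(ybar * (1 - ybar) * (xc**2).sum())
    if var <= 0:
        return 0.0, 1.0
    z = u / np.sqrt(var)
    return z, float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))


def logistic_gsa(
    index: RankedGeneIndex,
    annotation: pd.DataFrame,
    size_bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS,
) -> pd.DataFrame:
    """Logistic gene-set test per GO term over the indexed-gene universe.

    For each term with an in-universe annotated gene count inside
    ``size_bounds``, fits membership ~ normalized index; ``lor`` is the
    slope and ``p`` its Wald test.  Complete separation or a failed fit
    falls back to the score test (``flagged`` column).  Terms outside
    the bounds are skipped and counted in ``result.attrs['n_skipped']``.
    """
    x = index.normalized
    universe = x.index
    ann = annotation[annotation["gene_id"].isin(universe)]
    names = ann.drop_duplicates("go_id").set_index("go_id")["go_name"]
    xv = x.to_numpy()
    X = sm.add_constant(xv)
    rows = []
    n_skipped = 0
    for go_id, genes in ann.groupby("go_id")["gene_id"]:
        members = set(genes)
        n_genes = len(members)
        if not (size_bounds[0] <= n_genes <= size_bounds[1]):
            n_skipped += 1
            continue
        y = np.asarray(universe.isin(members), dtype=float)
        lor, p, flagged = np.nan, np.nan, False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            lor = float(fit.params[1])
            p = float(fit.pvalues[1])
            if not (np.isfinite(lor) and np.isfinite(p) and fit.bse[1] < 1e3):
                raise ValueError("unstable fit")
        except Exception:
            z, p = _score_test(xv, y)
            lor = z  # sign-carrying fallback statistic
            flagged = True
        p = float(min(max(p, np.finfo(float).tiny), 1.0))
        rows.append((go_id, names.get(go_id, go_id), n_genes, lor, p, flagged))
    out = pd.DataFrame(
        rows, columns=["go_id", "go_name", "n_genes", "lor", "p", "flagged"]
    ).set_index("go_id")
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["direction"] = np.where(out["lor"] > 0, "up", "down")
        out = out.sort_values("p")
    else:
        out["adj_p"] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=object)
    out.attrs["n_skipped"] = n_skipped
    return out


def target_frequency(
    significant_mirnas: set[str] | list[str], targets: dict[str, set[str]]
) -> pd.DataFrame:
    """Genes ranked by how many of the given miRNAs target them."""
    counts: dict[str, int] = {}
    for m in significant_mirnas:
        for g in targets.get(m, ()):
            counts[g] = counts.get(g, 0) + 1
    out = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "n_mirnas"],
    )
    return out


@dataclass
class EnrichmentResult:
    gsa: pd.DataFrame
    gene_index: RankedGeneIndex
    freq: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_enrichment(
    meta_results: dict[tuple[str, str], MetaResult],
    targets: dict[str, set[str]],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    size_bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS,
    transform: str = "signed_logp",
) -> dict[tuple[str, str], EnrichmentResult]:
    """One enrichment per meta-analysis, run on the full profile.

    The logistic gene-set analysis always uses every analyzed miRNA; the
    companion target-frequency report uses only the significant set
    (empty report when nothing is significant).
    """
    out = {}
    for stratum, mr in meta_results.items():
        if mr.table.empty:
            logger.warning("stratum %s: empty meta table; enrichment skipped", stratum)
            continue
        idx = mirna_index(mr.table, transform=transform)
        gi = transfer_to_genes(idx, targets)
        gsa = logistic_gsa(gi, annotation, size_bounds=size_bounds)
        sig = set(mr.table.index[mr.table["adj_p"] < alpha])
        freq = target_frequency(sig, targets)
        out[stratum] = EnrichmentResult(gsa=gsa, gene_index=gi, freq=freq)
    return out


def write_enrichment(results: dict, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (tissue, sex), r in results.items():
        r.gsa.rename_axis("go_id").to_csv(out / f"gsa_{tissue}_{sex}.tsv", sep="\t")
        r.freq.to_csv(out / f"target_frequency_{tissue}_{sex}.tsv", sep="\t", index=False)
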