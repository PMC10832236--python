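"""Random-effects (DerSimonian-Laird) integration of per-study logFCs.

Per tissue x sex stratum, each miRNA observed in at least two studies
contributes its per-study effect y_i (logFC) with sampling variance
v_i (se^2).  The DL moment estimator gives the between-study variance

    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),  w_i = 1/v_i,

with Cochran's Q computed under fixed-effect weights; the combined
effect is the inverse-(v_i + tau2)-weighted mean with normal-theory
z inference and a 95% CI, plus I^2 = max(0, (Q-(k-1))/Q) * 100.
Benjamini-Hochberg adjustment is applied within each of the four
meta-analyses (blood-F, blood-M, brain-F, brain-M) separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, bh_adjust

logger = logging.getLogger("mirmeta")

STRATA = (("blood", "female"), ("blood", "male"), ("brain", "female"), ("brain", "male"))


@dataclass
class MetaResult:
    """One stratum's combined table plus the per-study inputs behind it."""

    tissue: str
    sex: str
    table: pd.DataFrame  # index mirna_id: k, mu_hat, se_mu, ci_low, ci_high, z, p, adj_p, Q, tau2, I2, direction
    inputs: pd.DataFrame  # long: mirna_id, study_id, y, v  (forest-plot export)


def dl_combine(y, v) -> dict:
    """DerSimonian-Laird combination of effects ``y`` with variances ``v``."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("need at least 2 studies to combine")
    if (v <= 0).any():
        raise ValueError("all sampling variances must be > 0")
    w = 1.0 / v
    sw = w.sum()
    y_fe = float((w * y).sum() / sw)
    Q = float((w * (y - y_fe) ** 2).sum())
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (v + tau2)
    swr = wr.sum()
    mu = float((wr * y).sum() / swr)
    se = float(swr**-0.5)
    z = mu / se
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    zcrit = stats.norm.ppf(0.975)
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return {
        "k": k,
        "mu_hat": mu,
        "se_mu": se,
        "ci_low": mu - zcrit * se,
        "ci_high": mu + zcrit * se,
        "z": z,
        "p": p,
        "Q": Q,
        "tau2": tau2,
        "I2": i2,
    }


def assemble_inputs(
    de_results: list[DEResult], tissue: str, sex: str, min_studies: int = 2
) -> pd.DataFrame:
    """Long (mirna, study, y, v) table for one stratum, >=min_studies only."""
    frames = []
    for r in de_results:
        if r.tissue != tissue or r.contrast != sex:
            continue
        t = r.table
        frames.append(
            pd.DataFrame(
                {
                    "mirna_id": t.index,
                    "study_id": r.study_id,
                    "y": t["logFC"].to_numpy(),
                    "v": (t["se"] ** 2).to_numpy(),
                }
            )
        )
    if len(frames) < min_studies:
        raise ValueError(
            f"stratum {tissue}-{sex}: only {len(frames)} studies; "
            f"need at least {min_studies}"
        )
    long = pd.concat(frames, ignore_index=True)
    counts = long.groupby("mirna_id")["study_id"].nunique()
    keep = counts.index[counts >= min_studies]
    if len(keep) == 0:
        logger.warning("stratum %s-%s: no miRNAs shared by >=%d studies",
                       tissue, sex, min_studies)
    return long[long["mirna_id"].isin(keep)].reset_index(drop=True)


def meta_table(inputs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """DL combination per miRNA over a long input table + BH across miRNAs."""
    rows = {}
    for mirna, grp in inputs.groupby("mirna_id", sort=True):
        rows[mirna] = dl_combine(grp["y"].to_numpy(), grp["v"].to_numpy())
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        return pd.DataFrame(
            columns=["k", "mu_hat", "se_mu", "ci_low", "ci_high", "z", "p",
                     "adj_p", "Q", "tau2", "I2", "direction", "significant"]
        )
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.where(table["mu_hat"] > 0, "up", "down")
    table["significant"] = table["adj_p"] < alpha
    table.index.name = "mirna_id"
    return table


def run_meta(
    de_results: list[DEResult],
    alpha: float = 0.05,
    min_studies: int = 2,
    strata: tuple = STRATA,
) -> dict[tuple[str, str], MetaResult]:
    """One meta-analysis per requested (tissue, sex) stratum with DE data."""
    available = {(r.tissue, r.contrast) for r in de_results}
    out = {}
    for tissue, sex in strata:
        if (tissue, sex) not in available:
            continue
        inputs = assemble_inputs(de_results, tissue, sex, min_studies)
        table = meta_table(inputs, alpha=alpha)
        n_k2 = int((table["k"] == 2).sum()) if len(table) else 0
        if n_k2:
            # k=2 strata are allowed; their tau2 is noisy but still reported
            logger.info("stratum %s-%s: %d miRNAs combined from only 2 studies",
                        tissue, sex, n_k2)
        out[(tissue, sex)] = MetaResult(tissue=tissue, sex=sex, table=table, inputs=inputs)
    if not out:
        raise ValueError("no stratum had differential-expression results")
    return out


def significant_sets(result: MetaResult, alpha: float = 0.05) -> set[tuple[str, str]]:
    """Set of (mirna_id, direction) pairs significant at adj_p < alpha."""
    t = result.table
    sig = t[t["adj_p"] < alpha]
    return set(zip(sig.index, sig["direction"]))


def write_meta_results(results: dict, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (tissue, sex), r in results.items():
        r.table.rename_axis("mirna_id").to_csv(out / f"meta_{tissue}_{sex}.tsv", sep="\t")
        r.inputs.to_csv(out / f"forest_{tissue}_{sex}.tsv", sep="\t", index=False)
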