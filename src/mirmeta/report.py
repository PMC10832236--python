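"""Exploratory QC, cross-sex comparison and result export.

All figures are backed by exported TSVs so downstream checks assert on
data, not pixels.  PCA runs on centered (unscaled) log-expression with
samples as observations; sample clustering is average-linkage on
correlation distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .ingest import StudyBundle
from .meta import MetaResult

logger = logging.getLogger("mirmeta")


@dataclass
class SignatureIntersection:
    """Partition of two direction-aware signatures into exclusive/common."""

    exclusive_a: set
    exclusive_b: set
    common: set

    def sizes(self) -> tuple[int, int, int]:
        return len(self.exclusive_a), len(self.common), len(self.exclusive_b)

    def by_direction(self, direction: str) -> "SignatureIntersection":
        f = lambda s: {e for e in s if e[1] == direction}
        return SignatureIntersection(
            f(self.exclusive_a), f(self.exclusive_b), f(self.common)
        )


def qc_study(bundle: StudyBundle) -> dict:
    """Counts, per-sample quartiles, top-2 PCA and sample clustering."""
    counts = (
        bundle.samples.groupby(["sex", "condition"]).size().rename("n").reset_index()
    )
    q = bundle.expr.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    q.index = ["min", "q1", "median", "q3", "max"]
    quartiles = q.T.rename_axis("sample_id")

    out = {"counts": counts, "quartiles": quartiles, "pca": None,
           "explained": None, "linkage": None, "order": None}

    X = bundle.expr.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < 3:
        logger.warning("%s: fewer than 3 samples; PCA skipped", bundle.study_id)
    else:
        Xc = X - X.mean(axis=0)
        _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[:2].T
        var = s**2 / max(n - 1, 1)
        total = var.sum()
        out["pca"] = pd.DataFrame(
            scores, index=bundle.expr.columns, columns=["PC1", "PC2"]
        )
        out["explained"] = (var[:2] / total * 100.0) if total > 0 else np.zeros(2)
    if n >= 2:
        d = pdist(X, metric="correlation")
        # constant samples have undefined correlation; treat as uncorrelated
        d = np.where(np.isfinite(d), d, 1.0)
        d = np.clip(d, 0.0, None)  # guard tiny negative rounding
        link = hierarchy.linkage(d, method="average")
        out["linkage"] = link
        out["order"] = [
            bundle.expr.columns[i] for i in hierarchy.leaves_list(link)
        ]
    return out


def intersect_signatures(set_a, set_b) -> SignatureIntersection:
    """Exact direction-aware partition of two (mirna, direction) sets."""
    a, b = set(set_a), set(set_b)
    return SignatureIntersection(exclusive_a=a - b, exclusive_b=b - a, common=a & b)


def cross_sex_profile(
    meta_f: MetaResult, meta_m: MetaResult, mirnas, alpha: float = 0.05
) -> pd.DataFrame:
    """Side-by-side female/male effects for a miRNA set, with discordance flag.

    A miRNA is flagged discordant when it is significant in one sex while
    its combined effect in the other sex has the opposite sign — the
    pattern where a miRNA drops significantly in males yet shows no such
    change in females.  MiRNAs missing from one stratum keep their row
    with missing cells.
    """
    cols = ["mu_hat", "ci_low", "ci_high", "adj_p"]
    rows = []
    for m in mirnas:
        row: dict = {"mirna_id": m}
        for label, mr in (("female", meta_f), ("male", meta_m)):
            if m in mr.table.index:
                for c in cols:
                    row[f"{label}_{c}"] = float(mr.table.loc[m, c])
            else:
                for c in cols:
                    row[f"{label}_{c}"] = np.nan
        sig_f = row["female_adj_p"] < alpha if np.isfinite(row["female_adj_p"]) else False
        sig_m = row["male_adj_p"] < alpha if np.isfinite(row["male_adj_p"]) else False
        opp_fm = (
            np.isfinite(row["male_mu_hat"])
            and np.isfinite(row["female_mu_hat"])
            and np.sign(row["male_mu_hat"]) == -np.sign(row["female_mu_hat"])
            and np.sign(row["female_mu_hat"]) != 0
        )
        row["discordant"] = bool((sig_f or sig_m) and opp_fm)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna_id")


def export_volcano(
    meta: MetaResult, out_prefix: str | Path | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Volcano data (mu_hat vs -log10 adjusted p) with threshold annotation."""
    t = meta.table
    data = pd.DataFrame(
        {
            "mu_hat": t["mu_hat"],
            "neg_log10_adj_p": -np.log10(np.maximum(t["adj_p"], np.finfo(float).tiny)),
            "significant": t["adj_p"] < alpha,
            "direction": t["direction"],
        },
        index=t.index,
    ).rename_axis("mirna_id")
    data.attrs["threshold"] = -np.log10(alpha)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        data.to_csv(out_prefix.with_suffix(".tsv"), sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        sig = data["significant"]
        ax.scatter(data.loc[~sig, "mu_hat"], data.loc[~sig, "neg_log10_adj_p"],
                   s=8, c="grey", label="n.s.")
        up = sig & (data["direction"] == "up")
        dn = sig & (data["direction"] == "down")
        ax.scatter(data.loc[up, "mu_hat"], data.loc[up, "neg_log10_adj_p"],
                   s=10, c="tab:orange", label="up")
        ax.scatter(data.loc[dn, "mu_hat"], data.loc[dn, "neg_log10_adj_p"],
                   s=10, c="tab:blue", label="down")
        ax.axhline(-np.log10(alpha), ls="--", c="grey", lw=1)
        ax.set_xlabel("combined logFC (AD - control)")
        ax.set_ylabel("-log10 adjusted p")
        ax.set_title(f"{meta.tissue} / {meta.sex}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_prefix.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return data


def write_qc(qc: dict, study_id: str, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc["counts"].to_csv(out / f"qc_counts_{study_id}.tsv", sep="\t", index=False)
    qc["quartiles"].to_csv(out / f"qc_quartiles_{study_id}.tsv", sep="\t")
    if qc["pca"] is not None:
        qc["pca"].to_csv(out / f"qc_pca_{study_id}.tsv", sep="\t")


def write_summary(
    meta_results: dict[tuple[str, str], MetaResult],
    out_dir: str | Path,
    alpha: float = 0.05,
) -> Path:
    """Markdown summary stitching all strata: counts, Venn partitions, volcanos."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Meta-analysis summary", ""]
    lines.append("| stratum | miRNAs analyzed | up (adj p<%.2g) | down |" % alpha)
    lines.append("|---|---|---|---|")
    sigsets: dict[tuple[str, str], set] = {}
    for (tissue, sex), mr in sorted(meta_results.items()):
        t = mr.table
        sig = t[t["adj_p"] < alpha]
        up = int((sig["direction"] == "up").sum())
        down = int((sig["direction"] == "down").sum())
        lines.append(f"| {tissue}-{sex} | {len(t)} | {up} | {down} |")
        sigsets[(tissue, sex)] = set(zip(sig.index, sig["direction"]))
        export_volcano(mr, out / f"volcano_{tissue}_{sex}", alpha=alpha)
    for tissue in sorted({t for t, _ in meta_results}):
        kf, km = (tissue, "female"), (tissue, "male")
        if kf in sigsets and km in sigsets:
            inter = intersect_signatures(sigsets[kf], sigsets[km])
            ea, common, eb = inter.sizes()
            lines += [
                "",
                f"## {tissue}: female vs male significant signatures",
                f"- exclusive to females: {ea}",
                f"- common: {common}",
                f"- exclusive to males: {eb}",
            ]
    path = out / "summary.md"
    path.write_text("\n".join(lines) + "\n")
    return path
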