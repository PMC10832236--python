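"""Study ingestion and preprocessing.

Reads per-study expression matrices and sample metadata, keeps only
control and AD samples with known sex, harmonizes feature identifiers to
mature miRBase-style IDs, collapses duplicate features by keeping the
row with the highest mean expression, and applies the shift-and-log2
normalization: a matrix whose minimum is negative is shifted up by
|min| so its minimum becomes zero, and array matrices that are not yet
on the log scale get a log2(x + 1) transform.  RNA-seq count matrices
are left as counts here; they are converted to log-CPM with precision
weights inside the differential-expression stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mirmeta")

VALID_CONDITIONS = ("control", "AD")


@dataclass
class StudyBundle:
    """One study's expression matrix plus sample metadata.

    ``expr`` is features x samples; ``samples`` is indexed by sample_id
    with columns ``sex`` (female/male) and ``condition`` (control/AD).
    ``logged`` records whether values are already on the log2 scale.
    """

    study_id: str
    tissue: str
    platform: str
    logged: bool
    expr: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> None:
        if set(self.expr.columns) != set(self.samples.index):
            raise ValueError(f"{self.study_id}: expr columns != sample ids")
        if self.samples.index.duplicated().any():
            raise ValueError(f"{self.study_id}: duplicate sample ids")


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    manifest["_base"] = path.parent
    return manifest


def load_study(entry: dict, base_dir: str | Path = ".") -> StudyBundle:
    """Load one manifest entry into a raw StudyBundle.

    Samples whose condition is neither control nor AD (e.g. MCI arms) are
    dropped, as are samples with missing sex; expression columns and
    metadata rows must otherwise match exactly.
    """
    base = Path(base_dir)
    expr = pd.read_csv(base / entry["expr"], sep="\t", index_col=0)
    samples = pd.read_csv(base / entry["samples"], sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    expr.columns = expr.columns.astype(str)

    missing_in_meta = sorted(set(expr.columns) - set(samples.index))
    missing_in_expr = sorted(set(samples.index) - set(expr.columns))
    if missing_in_meta or missing_in_expr:
        raise ValueError(
            f"{entry['study_id']}: sample-id mismatch between expression and "
            f"metadata; only in expression: {missing_in_meta}; "
            f"only in metadata: {missing_in_expr}"
        )

    keep = samples["condition"].isin(VALID_CONDITIONS)
    n_cond = int((~keep).sum())
    if n_cond:
        logger.info(
            "%s: dropped %d samples with condition outside %s",
            entry["study_id"], n_cond, VALID_CONDITIONS,
        )
    sex_known = samples["sex"].isin(("female", "male"))
    n_sex = int((keep & ~sex_known).sum())
    if n_sex:
        logger.warning(
            "%s: dropped %d samples with missing/unknown sex", entry["study_id"], n_sex
        )
    keep &= sex_known
    samples = samples.loc[keep]
    if samples.empty:
        raise ValueError(f"{entry['study_id']}: no control/AD samples with known sex")
    expr = expr.loc[:, samples.index]

    bundle = StudyBundle(
        study_id=entry["study_id"],
        tissue=entry["tissue"],
        platform=entry["platform"],
        logged=bool(entry["logged"]),
        expr=expr,
        samples=samples,
    )
    bundle.validate()
    return bundle


def load_idmap(path: str | Path) -> pd.Series:
    """Two-column TSV (source_id, mature_id) -> Series source -> mature."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.iloc[:, :2]
    df.columns = ["source_id", "mature_id"]
    if df["source_id"].duplicated().any():
        dupes = df.loc[df["source_id"].duplicated(), "source_id"].tolist()
        raise ValueError(f"id map is not a function; duplicated source ids: {dupes[:5]}")
    return df.set_index("source_id")["mature_id"]


def harmonize_ids(bundle: StudyBundle, idmap: pd.Series) -> StudyBundle:
    """Rename features to mature ids; drop features without a mature mapping."""
    mapped = bundle.expr.index.to_series().map(idmap)
    keep = mapped.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("%s: removed %d features with no mature-id mapping",
                    bundle.study_id, n_drop)
    expr = bundle.expr.loc[keep].copy()
    expr.index = mapped[keep].to_numpy()
    if expr.empty:
        raise ValueError(f"{bundle.study_id}: no features left after mature-id filtering")
    return replace(bundle, expr=expr)


def collapse_duplicates(bundle: StudyBundle) -> StudyBundle:
    """Keep, per duplicated feature id, the row with highest mean expression.

    Ties keep the first row in input order (logged).
    """
    expr = bundle.expr
    if not expr.index.duplicated().any():
        return bundle
    means = expr.mean(axis=1).to_numpy()
    order = pd.DataFrame(
        {"id": expr.index, "mean": means, "pos": np.arange(len(expr))}
    )
    # stable sort: highest mean first, earliest input position breaks ties
    best = (
        order.sort_values(["mean", "pos"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("id")
        .sort_values("pos")
    )
    n_ties = int(
        order.groupby("id")["mean"].transform("max").eq(order["mean"]).groupby(
            order["id"].values
        ).sum().gt(1).sum()
    )
    if n_ties:
        logger.info("%s: %d duplicate groups had tied means; kept first occurrence",
                    bundle.study_id, n_ties)
    out = expr.iloc[best["pos"].to_numpy()]
    logger.info("%s: collapsed %d duplicate rows", bundle.study_id, len(expr) - len(out))
    return replace(bundle, expr=out)


def shift_and_log(bundle: StudyBundle) -> StudyBundle:
    """Shift negative matrices to non-negative; log2(x+1) unlogged array data."""
    expr = bundle.expr
    vals = expr.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError(f"{bundle.study_id}: non-finite expression values")
    m = vals.min()
    if m < 0:
        expr = expr - m  # shift by |min| so the new minimum is exactly 0
        logger.info("%s: shifted matrix up by %.4g to remove negatives",
                    bundle.study_id, -m)
    logged = bundle.logged
    if not logged and bundle.platform == "array":
        expr = np.log2(expr + 1.0)
        logged = True
    return replace(bundle, expr=expr, logged=logged)


def preprocess(bundle: StudyBundle, idmap: pd.Series | None = None) -> StudyBundle:
    """Full ingest chain: harmonize (if a map is given), collapse, shift+log."""
    if idmap is not None:
        bundle = harmonize_ids(bundle, idmap)
    bundle = collapse_duplicates(bundle)
    bundle = shift_and_log(bundle)
    bundle.validate()
    return bundle


def load_all(manifest: dict, idmap: pd.Series | None = None) -> list[StudyBundle]:
    base = manifest.get("_base", ".")
    if idmap is None and manifest.get("idmap"):
        idmap = load_idmap(Path(base) / manifest["idmap"])
    return [preprocess(load_study(e, base), idmap) for e in manifest["studies"]]
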