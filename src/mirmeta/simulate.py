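"""Multi-study miRNA expression simulator with known ground truth.

Generates per-study expression matrices (Gaussian log2-scale for array
platforms, negative-binomial counts for RNA-seq platforms) carrying
planted disease effects that are shared between sexes or exclusive to
one sex, with controllable between-study heterogeneity.  The realized
per-study effect for a non-null miRNA is drawn once per (miRNA, study)
from Normal(mu_class, tau2) and applied to the AD samples of the sexes
the class touches, so the downstream random-effects machinery can be
validated by parameter recovery.

A miRNA->gene target map and a gene->GO annotation table are generated
alongside, with a subset of GO terms planted as enriched: their member
genes are preferentially drawn from the pool of genes targeted by
non-null miRNAs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ingest import StudyBundle

GROUPS = ("control_female", "ad_female", "control_male", "ad_male")

# effect classes a miRNA can belong to
CLASSES = ("null", "shared", "female_only", "male_only")


@dataclass
class SimulationConfig:
    """Study-design and effect-model parameters for the simulator.

    Effect sizes are on the log2 scale; ``tau2`` is the between-study
    variance of the realized effects (log2^2 units) and ``sigma2`` the
    within-study residual variance for array platforms.
    """

    n_studies: int = 6
    platform_per_study: list[str] | None = None
    tissue_per_study: list[str] | None = None
    n_mirnas: int = 300
    # (control-F, AD-F, control-M, AD-M); a single 4-tuple applies to all
    # studies, or give one 4-tuple per study.  Female groups are larger by
    # default, matching the sex imbalance typical of AD cohorts.
    samples_per_group: tuple | list = (12, 12, 8, 8)
    mu_shared: float = 1.0
    mu_female_only: float = 1.0
    mu_male_only: float = 1.0
    tau2: float = 0.05
    sigma2: float = 0.25
    nb_dispersion: float = 0.1
    frac_shared: float = 0.10
    frac_female_only: float = 0.05
    frac_male_only: float = 0.05
    n_genes: int = 2000
    targets_per_mirna: int = 20
    n_go_terms: int = 50
    genes_per_term: int = 40
    n_enriched_terms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform_per_study is None:
            # mirrors a realistic mix: mostly arrays plus sequencing studies
            base = ["array", "array", "rnaseq", "rnaseq", "array", "rnaseq"]
            self.platform_per_study = [base[i % 6] for i in range(self.n_studies)]
        if self.tissue_per_study is None:
            # four brain studies then blood, recycling for other sizes
            base = ["brain", "brain", "brain", "brain", "blood", "blood"]
            self.tissue_per_study = [base[i % 6] for i in range(self.n_studies)]
        self.validate()

    def validate(self) -> None:
        if self.n_studies < 1 or self.n_mirnas < 1:
            raise ValueError("n_studies and n_mirnas must be positive")
        if len(self.platform_per_study) != self.n_studies:
            raise ValueError("platform_per_study length must equal n_studies")
        if len(self.tissue_per_study) != self.n_studies:
            raise ValueError("tissue_per_study length must equal n_studies")
        for p in self.platform_per_study:
            if p not in ("array", "rnaseq"):
                raise ValueError(f"unknown platform {p!r}")
        fracs = (self.frac_shared, self.frac_female_only, self.frac_male_only)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("effect-class fractions must be >=0 and sum to <=1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        for spg in self._groups_matrix():
            if any(int(n) <= 0 for n in spg):
                raise ValueError(
                    "every study needs at least one sample in each of the four "
                    "sex x condition groups; got counts "
                    f"{tuple(int(n) for n in spg)}"
                )

    def _groups_matrix(self) -> list[tuple[int, int, int, int]]:
        spg = self.samples_per_group
        if len(spg) == 4 and np.isscalar(spg[0]):
            return [tuple(int(x) for x in spg)] * self.n_studies
        if len(spg) != self.n_studies:
            raise ValueError("samples_per_group must be one 4-vector or one per study")
        return [tuple(int(x) for x in row) for row in spg]


@dataclass
class GroundTruth:
    """Planted truth recorded by :func:`simulate_multistudy`."""

    mirna_class: dict[str, str]
    # (mirna_id, study_id) -> realized log2 effect (0.0 for null miRNAs)
    study_effects: dict[tuple[str, str], float]
    target_map: dict[str, set[str]]
    enriched_terms: set[str]
    go_names: dict[str, str] = field(default_factory=dict)


def _mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-{i + 1:04d}-5p" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n)]


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    ids = _mirna_ids(cfg.n_mirnas)
    n_sh = int(round(cfg.frac_shared * cfg.n_mirnas))
    n_f = int(round(cfg.frac_female_only * cfg.n_mirnas))
    n_m = int(round(cfg.frac_male_only * cfg.n_mirnas))
    perm = rng.permutation(cfg.n_mirnas)
    classes = {}
    for pos, idx in enumerate(perm):
        if pos < n_sh:
            cls = "shared"
        elif pos < n_sh + n_f:
            cls = "female_only"
        elif pos < n_sh + n_f + n_m:
            cls = "male_only"
        else:
            cls = "null"
        classes[ids[idx]] = cls
    return {m: classes[m] for m in ids}


def _build_targets_and_go(
    cfg: SimulationConfig, classes: dict[str, str], rng: np.random.Generator
) -> tuple[dict[str, set[str]], pd.DataFrame, set[str], dict[str, str]]:
    genes = np.array(_gene_ids(cfg.n_genes))
    # non-null miRNAs draw targets from a concentrated pool so that planted
    # GO terms (built from the same pool) are genuinely enriched among the
    # genes they regulate
    pool_size = max(cfg.targets_per_mirna, cfg.genes_per_term, cfg.n_genes // 8)
    pool = genes[:pool_size]
    target_map: dict[str, set[str]] = {}
    for m, cls in classes.items():
        src = pool if cls != "null" else genes
        k = min(cfg.targets_per_mirna, len(src))
        target_map[m] = set(rng.choice(src, size=k, replace=False))

    rows = []
    enriched: set[str] = set()
    go_names: dict[str, str] = {}
    for t in range(cfg.n_go_terms):
        go_id = f"GO:{t + 1:07d}"
        planted = t < cfg.n_enriched_terms
        src = pool if planted else genes
        members = rng.choice(src, size=min(cfg.genes_per_term, len(src)), replace=False)
        name = ("planted process " if planted else "background process ") + str(t + 1)
        go_names[go_id] = name
        if planted:
            enriched.add(go_id)
        for g in members:
            rows.append((g, go_id, name))
    annotation = pd.DataFrame(rows, columns=["gene_id", "go_id", "go_name"])
    return target_map, annotation, enriched, go_names


def _sample_table(counts: tuple[int, int, int, int], study_id: str) -> pd.DataFrame:
    rows = []
    specs = [
        ("female", "control", counts[0]),
        ("female", "AD", counts[1]),
        ("male", "control", counts[2]),
        ("male", "AD", counts[3]),
    ]
    i = 0
    for sex, cond, n in specs:
        for _ in range(n):
            rows.append((f"{study_id}_s{i:03d}", sex, cond))
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "sex", "condition"]).set_index(
        "sample_id"
    )


def _effect_matrix(
    classes: dict[str, str],
    realized: np.ndarray,
    samples: pd.DataFrame,
) -> np.ndarray:
    """Per-(miRNA, sample) additive log2 shift implied by the planted effects."""
    ids = list(classes)
    cls = np.array([classes[m] for m in ids])
    ad_f = ((samples["condition"] == "AD") & (samples["sex"] == "female")).to_numpy()
    ad_m = ((samples["condition"] == "AD") & (samples["sex"] == "male")).to_numpy()
    hit_f = np.isin(cls, ("shared", "female_only"))
    hit_m = np.isin(cls, ("shared", "male_only"))
    eff = np.zeros((len(ids), len(samples)))
    eff[np.ix_(hit_f, ad_f)] = realized[hit_f, None]
    eff[np.ix_(hit_m, ad_m)] = realized[hit_m, None]
    return eff


def simulate_multistudy(
    config: SimulationConfig,
) -> tuple[list[StudyBundle], GroundTruth]:
    """Simulate one StudyBundle per configured study plus full ground truth.

    The global seed expands into independent per-study substreams (study
    ``i`` uses ``default_rng([seed, i])``) plus one truth substream, so
    appending a study leaves earlier studies' data bit-identical.
    """
    config.validate()
    rng_truth = np.random.default_rng([config.seed, 1_000_003])
    classes = _assign_classes(config, rng_truth)
    target_map, annotation, enriched, go_names = _build_targets_and_go(
        config, classes, rng_truth
    )
    mu_by_class = {
        "null": 0.0,
        "shared": config.mu_shared,
        "female_only": config.mu_female_only,
        "male_only": config.mu_male_only,
    }
    ids = list(classes)
    nonnull = np.array([classes[m] != "null" for m in ids])
    mu_vec = np.array([mu_by_class[classes[m]] for m in ids])

    bundles: list[StudyBundle] = []
    study_effects: dict[tuple[str, str], float] = {}
    groups = config._groups_matrix()
    for i in range(config.n_studies):
        study_id = f"SIM{i + 1:03d}"
        rng = np.random.default_rng([config.seed, i])
        samples = _sample_table(groups[i], study_id)
        # realized effect per miRNA for this study: Normal(mu_class, tau2);
        # exactly zero for null miRNAs
        realized = np.where(
            nonnull,
            mu_vec + np.sqrt(config.tau2) * rng.standard_normal(len(ids)),
            0.0,
        )
        for m, e in zip(ids, realized):
            study_effects[(m, study_id)] = float(e)
        eff = _effect_matrix(classes, realized, samples)
        platform = config.platform_per_study[i]
        if platform == "array":
            baseline = rng.normal(8.0, 2.0, size=len(ids))
            mat = (
                baseline[:, None]
                + eff
                + np.sqrt(config.sigma2)
                * rng.standard_normal((len(ids), len(samples)))
            )
            expr = pd.DataFrame(mat, index=ids, columns=samples.index)
            logged = True
        else:
            base_log2 = rng.normal(6.0, 2.0, size=len(ids))
            # library-size factors within 2x of each other
            libfac = rng.uniform(1.0, 2.0, size=len(samples))
            mean = 2.0 ** (base_log2[:, None] + eff) * libfac[None, :]
            phi = config.nb_dispersion
            if phi > 0:
                lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
            else:
                lam = mean
            counts = rng.poisson(lam)
            expr = pd.DataFrame(counts, index=ids, columns=samples.index, dtype=int)
            logged = False
        bundles.append(
            StudyBundle(
                study_id=study_id,
                tissue=config.tissue_per_study[i],
                platform=platform,
                logged=logged,
                expr=expr,
                samples=samples,
            )
        )

    truth = GroundTruth(
        mirna_class=classes,
        study_effects=study_effects,
        target_map=target_map,
        enriched_terms=enriched,
        go_names=go_names,
    )
    truth.annotation = annotation  # convenience: flat gene->GO table
    return bundles, truth


def targets_frame(target_map: dict[str, set[str]]) -> pd.DataFrame:
    rows = [(m, g) for m, gs in target_map.items() for g in sorted(gs)]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id"])


def write_fixture(
    bundles: list[StudyBundle],
    truth: GroundTruth,
    dir_path: str | Path,
    config: SimulationConfig | None = None,
) -> Path:
    """Serialize bundles + truth to TSVs and a YAML manifest; returns manifest path."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for b in bundles:
        expr_path = out / f"expr_{b.study_id}.tsv"
        meta_path = out / f"meta_{b.study_id}.tsv"
        b.expr.rename_axis("mirna_id").to_csv(expr_path, sep="\t")
        b.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")
        entries.append(
            {
                "study_id": b.study_id,
                "tissue": b.tissue,
                "platform": b.platform,
                "logged": bool(b.logged),
                "expr": expr_path.name,
                "samples": meta_path.name,
            }
        )
    targets_frame(truth.target_map).to_csv(out / "targets.tsv", sep="\t", index=False)
    getattr(truth, "annotation", pd.DataFrame(columns=["gene_id", "go_id", "go_name"])).to_csv(
        out / "go_annotation.tsv", sep="\t", index=False
    )
    # identity id map lets the full preprocess chain run on the fixture
    idmap = pd.DataFrame(
        {"source_id": list(truth.mirna_class), "mature_id": list(truth.mirna_class)}
    )
    idmap.to_csv(out / "idmap.tsv", sep="\t", index=False)

    study_ids = [b.study_id for b in bundles]
    tt = pd.DataFrame(
        {
            "mirna_id": list(truth.mirna_class),
            "class": list(truth.mirna_class.values()),
        }
    )
    for sid in study_ids:
        tt[f"effect_{sid}"] = [
            truth.study_effects[(m, sid)] for m in truth.mirna_class
        ]
    tt.to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame({"go_id": sorted(truth.enriched_terms)}).to_csv(
        out / "truth_enriched_terms.tsv", sep="\t", index=False
    )

    manifest = {
        "studies": entries,
        "targets": "targets.tsv",
        "go_annotation": "go_annotation.tsv",
        "idmap": "idmap.tsv",
        "truth": "truth.tsv",
    }
    if config is not None:
        manifest["config"] = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dataclasses.asdict(config).items()
        }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
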