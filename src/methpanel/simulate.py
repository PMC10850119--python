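"""Synthetic multi-project methylation cohorts with known ground truth.

The generator emulates the structure of a multi-cancer HM450-style
beta-value dataset at desk scale:

* several cancer projects, each with tumor and paired-normal samples;
* within each project, tumors split into 4-7 methylation clusters
  whose overall methylation levels are evenly spaced, so clusters are
  orderable (MC1 = most methylated);
* planted cancer-specific hypermethylated marker probes (high beta in
  the target cancer's tumors, low everywhere else);
* planted "shared" probes hypermethylated in a cancer's tumors AND its
  paired normals (the pancreatic-cancer-like behaviour where a marker
  does not discriminate tumor from adjacent tissue);
* bimodal background probes (low ~0.1 / high ~0.8 modes shared across
  projects), a fraction of which are cluster-informative;
* sex-chromosome probes, duplicated probe ids and sprinkled missing
  values to exercise the filtering rules;
* liver-metastasis columns that conserve their source primary's
  profile up to a small perturbation;
* cell-free DNA columns drawn as tumor/leukocyte mixtures with a known
  tumor fraction f.

All values are drawn from a beta distribution parameterized by its
mean and a concentration phi (shape pair ``(mean*phi, (1-mean)*phi)``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    GroupSpec,
    ValidationError,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
)

EPS = 1e-3  # mean clamp before parameterizing the beta draw


@dataclass
class ProjectConfig:
    """Per-cancer-project generator settings."""

    n_tumor: int = 40
    n_normal: int = 10
    n_clusters: int = 5
    cluster_mix: tuple[float, ...] | None = None  # uniform if None
    n_marker_probes: int = 50
    marker_mean: float = 0.7
    offtarget_mean: float = 0.05
    n_shared_probes: int = 0
    marker_clusters: tuple[int, ...] | None = None  # 1-based; all if None
    n_metastasis: int = 0

    def __post_init__(self) -> None:
        if not 4 <= self.n_clusters <= 7:
            raise ValidationError("n_clusters must be in [4, 7]")
        if self.marker_mean - self.offtarget_mean <= 0:
            raise ValidationError("marker_mean must exceed offtarget_mean")
        if self.cluster_mix is not None:
            if len(self.cluster_mix) != self.n_clusters:
                raise ValidationError("cluster_mix length != n_clusters")
            if abs(sum(self.cluster_mix) - 1.0) > 1e-9:
                raise ValidationError("cluster_mix must sum to 1")
        if self.n_metastasis > self.n_tumor:
            raise ValidationError("n_metastasis cannot exceed n_tumor")


@dataclass
class CohortConfig:
    """Whole-cohort generator settings (the study conditions)."""

    projects: dict[str, ProjectConfig] = field(default_factory=dict)
    n_background_probes: int = 2000
    n_sexchrom_probes: int = 50
    n_duplicate_probes: int = 5
    missing_fraction: float = 0.005  # fraction of probes carrying missing cells
    precision: float = 30.0  # beta concentration phi
    cluster_informative_fraction: float = 0.5
    cluster_level_range: tuple[float, float] = (0.25, 0.65)
    cluster_spread: float = 0.2  # per-probe deviation around the cluster level
    metastasis_noise: float = 0.05
    cfdna_samples: tuple[tuple[str | None, float], ...] = ()  # (source project, f)
    dataset: str = "identification"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValidationError("precision phi must be > 0")
        for _, f in self.cfdna_samples:
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"cfDNA tumor fraction {f} outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    marker_probes: dict[str, tuple[str, ...]]
    shared_probes: dict[str, tuple[str, ...]]
    cluster_of: dict[str, int]  # tumor sample -> 1-based cluster index
    cluster_levels: dict[str, tuple[float, ...]]
    metastasis_source: dict[str, str]
    cfdna_fraction: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "marker_probes": {k: list(v) for k, v in self.marker_probes.items()},
            "shared_probes": {k: list(v) for k, v in self.shared_probes.items()},
            "cluster_of": self.cluster_of,
            "cluster_levels": {k: list(v) for k, v in self.cluster_levels.items()},
            "metastasis_source": self.metastasis_source,
            "cfdna_fraction": self.cfdna_fraction,
        }


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default seven-project roster used throughout the analyses.

    Cluster counts per project lie in the observed 4-7 range; each
    project plants 50 cancer-specific markers with tumor mean 0.7
    against 0.05 elsewhere; PAAD and LUAD additionally plant probes
    hypermethylated in their normals. Metastases derive from PAAD and
    BRCA; cfDNA includes three healthy donors and six patients.
    """
    n_clusters = {
        "BRCA": 7, "CHOL": 4, "CRC": 4, "LIHC": 6, "LUAD": 5, "PAAD": 5, "STAD": 6,
    }
    projects = {}
    for name, k in n_clusters.items():
        projects[name] = ProjectConfig(
            n_clusters=k,
            n_shared_probes=5 if name in ("PAAD", "LUAD") else 0,
            n_metastasis=5 if name in ("PAAD", "BRCA") else 0,
        )
    cfdna = tuple(
        [(None, 0.0)] * 3 + [("CRC", 0.6)] * 3 + [("BRCA", 0.6)] * 3
    )
    cfg = CohortConfig(projects=projects, cfdna_samples=cfdna, seed=seed)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def sample_beta(mean, precision: float, rng: np.random.Generator, size=None):
    """Draw beta values with the given mean(s) and concentration phi.

    Means at the boundary are clamped to ``[1e-3, 1 - 1e-3]`` before
    parameterization; draws are kept inside the open interval (0, 1).
    """
    if precision <= 0:
        raise ValidationError("precision phi must be > 0")
    mean = np.clip(np.asarray(mean, dtype=float), EPS, 1.0 - EPS)
    a = mean * precision
    b = (1.0 - mean) * precision
    draws = rng.beta(a, b, size=size if size is not None else mean.shape or None)
    return np.clip(draws, 1e-6, 1.0 - 1e-6)


def _bimodal_means(n: int, rng: np.random.Generator) -> np.ndarray:
    """Probe base means from the genome-wide bimodal methylation pattern."""
    low = np.clip(rng.normal(0.10, 0.03, size=n), 0.02, 0.30)
    high = np.clip(rng.normal(0.80, 0.05, size=n), 0.50, 0.95)
    pick_high = rng.random(n) < 0.5
    return np.where(pick_high, high, low)


def _cluster_assignment(pcfg: ProjectConfig) -> np.ndarray:
    """Deterministic largest-remainder partition of tumors among clusters."""
    mix = pcfg.cluster_mix or tuple([1.0 / pcfg.n_clusters] * pcfg.n_clusters)
    raw = np.array(mix) * pcfg.n_tumor
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: pcfg.n_tumor - counts.sum()]:
        counts[i] += 1
    return np.repeat(np.arange(1, pcfg.n_clusters + 1), counts)


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate (beta matrix, sample sheet, probe annotation, truth).

    Metastasis and cfDNA columns, when configured, are always labelled
    ``dataset=verification`` (they are evaluation-only material); primary
    tumors and normals carry ``cfg.dataset``.
    """
    rng = np.random.default_rng(cfg.seed)
    projects = list(cfg.projects)

    # --- probe roster ------------------------------------------------
    probe_ids: list[str] = []
    marker_probes: dict[str, tuple[str, ...]] = {}
    shared_probes: dict[str, tuple[str, ...]] = {}
    counter = 0

    def _new_probes(n: int) -> tuple[str, ...]:
        nonlocal counter
        ids = tuple(f"cg{counter + i:08d}" for i in range(n))
        counter += n
        probe_ids.extend(ids)
        return ids

    for p in projects:
        marker_probes[p] = _new_probes(cfg.projects[p].n_marker_probes)
    for p in projects:
        shared_probes[p] = _new_probes(cfg.projects[p].n_shared_probes)
    background = _new_probes(cfg.n_background_probes)
    sexchrom = _new_probes(cfg.n_sexchrom_probes)

    base_mean = pd.Series(0.0, index=pd.Index(probe_ids, name="probe_id"))
    base_mean[list(background)] = _bimodal_means(len(background), rng)
    base_mean[list(sexchrom)] = _bimodal_means(len(sexchrom), rng)

    n_informative = int(round(cfg.cluster_informative_fraction * len(background)))
    informative = set(
        rng.choice(np.array(background), size=n_informative, replace=False)
    )

    # --- samples and per-sample probe means --------------------------
    lo, hi = cfg.cluster_level_range
    cluster_of: dict[str, int] = {}
    cluster_levels: dict[str, tuple[float, ...]] = {}
    sample_ids: list[str] = []
    sheet_rows: list[dict] = []
    mean_cols: dict[str, np.ndarray] = {}

    informative_mask = base_mean.index.isin(informative)
    for p in projects:
        pcfg = cfg.projects[p]
        levels = np.linspace(hi, lo, pcfg.n_clusters)  # cluster 1 most methylated
        cluster_levels[p] = tuple(float(x) for x in levels)
        assignment = _cluster_assignment(pcfg)
        marker_cl = set(pcfg.marker_clusters or range(1, pcfg.n_clusters + 1))
        # Each informative probe has its own methylation level per cluster,
        # centred on the cluster's overall level: subtypes share an ordering
        # by mean methylation but differ probe-by-probe, as real MCs do.
        informative_means = np.clip(
            levels[None, :]
            + rng.normal(0.0, cfg.cluster_spread,
                         size=(int(informative_mask.sum()), pcfg.n_clusters)),
            0.05,
            0.95,
        )

        for i in range(pcfg.n_tumor):
            sid = f"{p}_T{i:02d}"
            cluster = int(assignment[i])
            cluster_of[sid] = cluster
            mu = np.full(len(base_mean), pcfg.offtarget_mean)
            mu[~informative_mask & (base_mean.to_numpy() > 0)] = base_mean.to_numpy()[
                ~informative_mask & (base_mean.to_numpy() > 0)
            ]
            mu[informative_mask] = informative_means[:, cluster - 1]
            own = base_mean.index.isin(marker_probes[p])
            mu[own] = pcfg.marker_mean if cluster in marker_cl else pcfg.offtarget_mean
            mu[base_mean.index.isin(shared_probes[p])] = pcfg.marker_mean
            mean_cols[sid] = mu
            sample_ids.append(sid)
            sheet_rows.append(
                dict(sample_id=sid, project=p, tissue_class="tumor",
                     dataset=cfg.dataset, ffpe=False)
            )
        for i in range(pcfg.n_normal):
            sid = f"{p}_N{i:02d}"
            mu = np.where(
                base_mean.to_numpy() > 0, base_mean.to_numpy(), pcfg.offtarget_mean
            )
            mu[base_mean.index.isin(shared_probes[p])] = pcfg.marker_mean
            mean_cols[sid] = mu
            sample_ids.append(sid)
            sheet_rows.append(
                dict(sample_id=sid, project=p, tissue_class="normal",
                     dataset=cfg.dataset, ffpe=False)
            )

    means = np.column_stack([mean_cols[s] for s in sample_ids])
    values = sample_beta(means, cfg.precision, rng)
    m = pd.DataFrame(values, index=base_mean.index.copy(), columns=sample_ids)

    # --- missing values and duplicated probe ids ---------------------
    n_missing_probes = int(round(cfg.missing_fraction * m.shape[0]))
    if n_missing_probes:
        rows = rng.choice(m.shape[0], size=n_missing_probes, replace=False)
        for r in rows:
            cols = rng.choice(m.shape[1], size=rng.integers(1, 4), replace=False)
            m.iloc[r, cols] = np.nan
    if cfg.n_duplicate_probes:
        dup_ids = list(background[: cfg.n_duplicate_probes])
        dup_rows = m.loc[dup_ids].copy()
        noise = sample_beta(
            np.clip(base_mean[dup_ids].to_numpy(), 0.02, 0.98)[:, None]
            * np.ones((1, m.shape[1])),
            cfg.precision,
            rng,
        )
        dup_rows.iloc[:, :] = noise
        m = pd.concat([m, dup_rows])

    # --- annotation --------------------------------------------------
    autosome = rng.choice(np.array([str(i) for i in range(1, 23)]), size=len(base_mean))
    ann = pd.Series(autosome, index=base_mean.index.copy(), name="chromosome")
    sex_labels = np.where(np.arange(len(sexchrom)) % 2 == 0, "X", "Y")
    ann[list(sexchrom)] = sex_labels

    # --- metastases --------------------------------------------------
    metastasis_source: dict[str, str] = {}
    for p in projects:
        pcfg = cfg.projects[p]
        if pcfg.n_metastasis == 0:
            continue
        sources = [f"{p}_T{i:02d}" for i in range(pcfg.n_metastasis)]
        met_cols = simulate_metastases(
            m[sources], cfg.metastasis_noise, cfg.precision, rng
        )
        met_cols.columns = [f"{p}_M{i:02d}" for i in range(pcfg.n_metastasis)]
        for mid, src in zip(met_cols.columns, sources):
            metastasis_source[mid] = src
            sheet_rows.append(
                dict(sample_id=mid, project=p, tissue_class="metastasis",
                     dataset="verification", ffpe=False)
            )
        m = pd.concat([m, met_cols], axis=1)

    # --- cfDNA -------------------------------------------------------
    leukocyte = np.where(
        base_mean.to_numpy() > 0, base_mean.to_numpy(), 0.05
    )  # planted probes unmethylated in blood
    leukocyte = pd.Series(
        np.concatenate([leukocyte, leukocyte[: cfg.n_duplicate_probes]])
        if cfg.n_duplicate_probes
        else leukocyte,
        index=m.index.copy(),
    )
    cfdna_fraction: dict[str, float] = {}
    for j, (source, f) in enumerate(cfg.cfdna_samples):
        sid = f"CF{j:02d}_{source or 'healthy'}"
        if source is None:
            tumor_profile = leukocyte
        else:
            tumor_ids = [s for s in m.columns if s.startswith(f"{source}_T")]
            tumor_profile = m[tumor_ids].mean(axis=1)
        col = simulate_cfdna(tumor_profile, leukocyte, f, cfg.precision, rng)
        m[sid] = col
        cfdna_fraction[sid] = f
        sheet_rows.append(
            dict(sample_id=sid, project=source or "healthy",
                 tissue_class="cfdna", dataset="verification", ffpe=False)
        )

    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    truth = SyntheticTruth(
        marker_probes=marker_probes,
        shared_probes=shared_probes,
        cluster_of=cluster_of,
        cluster_levels=cluster_levels,
        metastasis_source=metastasis_source,
        cfdna_fraction=cfdna_fraction,
    )
    return m, sheet, ann, truth


def simulate_metastases(
    primary: pd.DataFrame,
    noise: float,
    precision: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Metastasis columns conserving their source primaries.

    Each metastasis takes its source column's realized betas as probe
    means, perturbs each by a uniform ``+/- noise``, truncates to (0, 1)
    and redraws via :func:`sample_beta`. No missing values are emitted.
    """
    means = primary.to_numpy(dtype=float)
    filled = np.where(np.isnan(means), 0.5, means)
    perturbed = filled + rng.uniform(-noise, noise, size=filled.shape)
    perturbed = np.clip(perturbed, EPS, 1.0 - EPS)
    values = sample_beta(perturbed, precision, rng)
    return pd.DataFrame(values, index=primary.index, columns=primary.columns)


def simulate_cfdna(
    tumor_profile: pd.Series,
    background_profile: pd.Series,
    f: float,
    precision: float,
    rng: np.random.Generator,
) -> pd.Series:
    """One cfDNA column: per-probe mean ``f*tumor + (1-f)*background``."""
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"cfDNA tumor fraction {f} outside [0, 1]")
    tumor = tumor_profile.to_numpy(dtype=float)
    bg = background_profile.reindex(tumor_profile.index).to_numpy(dtype=float)
    mix = f * np.where(np.isnan(tumor), bg, tumor) + (1.0 - f) * bg
    return pd.Series(
        sample_beta(mix, precision, rng), index=tumor_profile.index
    )


def tumor_group(sheet: pd.DataFrame, project: str) -> GroupSpec:
    ids = sheet.index[
        (sheet["project"] == project) & (sheet["tissue_class"] == "tumor")
    ]
    return GroupSpec(name=f"{project}_tumor", sample_ids=tuple(ids))


def write_cohort(
    out_dir: str | Path,
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    ann: pd.Series,
    truth: SyntheticTruth,
) -> None:
    """Write beta TSV, sample CSV, annotation CSV and truth JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(m, out / "beta.tsv")
    write_sample_sheet(sheet, out / "samples.csv")
    write_probe_annotation(ann, out / "annotation.csv")
    (out / "truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=1, sort_keys=True)
    )


def config_from_yaml(path: str | Path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    projects = {
        name: ProjectConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in (pc or {}).items()
        })
        for name, pc in raw.pop("projects", {}).items()
    }
    if "cfdna_samples" in raw:
        raw["cfdna_samples"] = tuple(
            (s if s != "healthy" else None, float(f)) for s, f in raw["cfdna_samples"]
        )
    for key in ("cluster_level_range",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortConfig(projects=projects, **raw)


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(x) for x in obj]
    if isinstance(obj, (list,)):
        return [_listify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def config_to_yaml(cfg: CohortConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["cfdna_samples"] = [
        [s if s is not None else "healthy", f] for s, f in cfg.cfdna_samples
    ]
    Path(path).write_text(yaml.safe_dump(_listify(d)))
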