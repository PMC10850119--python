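"""End-to-end discovery runs: non-clustered, clustered, verification.

The non-clustered run treats each cancer project's tumors (and each
project's normals) as one group, performs all pairwise
differential-methylation comparisons, intersects the target-positive
significant probes per cancer, applies the strict (fallback: relaxed)
selection tier, annotates against paired normals, builds a greedy
panel per cancer and evaluates it on the identification cohort.

The clustered run first partitions each project's tumors into
methylation clusters; each cluster is a group, clusters of the same
cancer are never compared against each other, candidates are selected
per cluster and merged per cancer (recording in how many clusters a
probe was found) before panel building.

Verification evaluates frozen panels on an independent cohort's
primary tumors, liver metastases and cfDNA without touching the
panels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GroupSpec,
    ValidationError,
    drop_ffpe,
    filter_probes,
    merge_projects,
    normal_groups,
    tumor_groups,
)
from .dmr import (
    CandidateProbe,
    DMRThresholds,
    SelectionThresholds,
    clustered_plan,
    dmr_compare,
    intersect_significant,
    mc_groups,
    merge_mc_candidates,
    nonclustered_plan,
    select_candidates,
    verify_in_normals,
)
from .panels import (
    Panel,
    PanelConstraints,
    PanelMetrics,
    build_panel,
    evaluate_cfdna,
    evaluate_metastasis_panel,
    evaluate_panel,
    metrics_table,
)
from .rpmm import MCAssignment, rpmm_cluster


@dataclass
class RunConfig:
    """All knobs of a discovery run (defaults = the study constants)."""

    approach: str = "non-clustered"
    k: int = 5000  # most-variable probes used for clustering
    seed: int = 0
    max_depth: int = 4
    min_cluster_size: int = 5
    dmr: DMRThresholds = field(default_factory=DMRThresholds)
    selection: SelectionThresholds = field(default_factory=SelectionThresholds)
    constraints: PanelConstraints = field(default_factory=PanelConstraints)
    relaxed_fallback_min: int = 2  # fall back to relaxed below this many strict hits
    project_merge: dict = field(default_factory=dict)  # e.g. {"COAD": "CRC", ...}

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    approach: str
    panels: dict[str, Panel]
    candidates: dict[str, list[CandidateProbe]]
    metrics: dict[str, PanelMetrics]
    assignments: dict[str, MCAssignment]
    n_comparisons: int
    n_probes_in: int
    n_probes_filtered: int
    manifest: dict


def _hash_frame(obj) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(obj, index=True).to_numpy().tobytes())
    return h.hexdigest()


def _manifest(cfg: RunConfig, m: pd.DataFrame, sheet: pd.DataFrame) -> dict:
    return {
        "config": cfg.to_json_dict(),
        "seed": cfg.seed,
        "beta_hash": _hash_frame(m),
        "sheet_hash": _hash_frame(sheet.astype(str)),
    }


def prepare_inputs(
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    ann: pd.Series,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project merging, FFPE exclusion and probe filtering."""
    sheet = drop_ffpe(merge_projects(sheet, cfg.project_merge))
    sheet = sheet[sheet.index.isin(m.columns)]
    m = m[list(sheet.index)]
    filtered = filter_probes(m, ann)
    return filtered, sheet


def _comparison_tables(
    m: pd.DataFrame,
    plan: list[tuple[GroupSpec, GroupSpec]],
    thresholds: DMRThresholds,
) -> dict[tuple[str, str], pd.DataFrame]:
    return {
        (g1.name, g2.name): dmr_compare(m, g1, g2, thresholds) for g1, g2 in plan
    }


def _oriented(
    tables: dict[tuple[str, str], pd.DataFrame], target: str, comparator: str
) -> pd.DataFrame:
    """The comparison table with ``target`` as g1, flipping if stored reversed."""
    if (target, comparator) in tables:
        return tables[(target, comparator)]
    t = tables[(comparator, target)]
    flipped = t.rename(columns={"mean_g1": "mean_g2", "mean_g2": "mean_g1"}).copy()
    flipped["delta"] = -t["delta"]
    return flipped


def _tiered_candidates(
    m: pd.DataFrame,
    target: GroupSpec,
    comparators: list[GroupSpec],
    intersected: set[str],
    cfg: RunConfig,
) -> list[CandidateProbe]:
    """Strict tier, falling back to relaxed when too few probes survive."""
    strict = select_candidates(m, target, comparators, intersected, "strict",
                               cfg.selection)
    if len(strict) >= cfg.relaxed_fallback_min:
        return strict
    relaxed = select_candidates(m, target, comparators, intersected, "relaxed",
                                cfg.selection)
    strict_ids = {c.probe_id for c in strict}
    return strict + [c for c in relaxed if c.probe_id not in strict_ids]


def run_nonclustered(
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    ann: pd.Series,
    cfg: RunConfig | None = None,
) -> RunResult:
    """The non-clustered discovery pipeline on the identification data."""
    cfg = cfg or RunConfig(approach="non-clustered")
    n_in = m.shape[0]
    m, sheet = prepare_inputs(m, sheet, ann, cfg)
    tumors = tumor_groups(sheet)
    normals = normal_groups(sheet)
    plan = nonclustered_plan(tumors, normals)
    tables = _comparison_tables(m, plan, cfg.dmr)

    normal_by_project = {g.name.rsplit("_", 1)[0]: g for g in normals}
    panels: dict[str, Panel] = {}
    candidates: dict[str, list[CandidateProbe]] = {}
    metrics: dict[str, PanelMetrics] = {}
    for target_group in tumors:
        project = target_group.name.rsplit("_", 1)[0]
        comparators = [g for g in tumors if g.name != target_group.name]
        oriented = [
            _oriented(tables, target_group.name, c.name) for c in comparators
        ]
        intersected = intersect_significant(oriented)
        cands = _tiered_candidates(m, target_group, comparators, intersected, cfg)
        cands = verify_in_normals(
            cands, m, normals, normal_by_project.get(project),
            call_cutoff=cfg.constraints.cutoff,
        )
        candidates[project] = cands
        if not cands:
            continue
        panel = build_panel(cands, m, sheet, project, cfg.constraints,
                            approach="non-clustered")
        panels[project] = panel
        metrics[project] = evaluate_panel(panel, m, sheet)[1]

    return RunResult(
        approach="non-clustered",
        panels=panels,
        candidates=candidates,
        metrics=metrics,
        assignments={},
        n_comparisons=len(plan),
        n_probes_in=n_in,
        n_probes_filtered=m.shape[0],
        manifest=_manifest(cfg, m, sheet),
    )


def run_clustered(
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    ann: pd.Series,
    cfg: RunConfig | None = None,
) -> RunResult:
    """The clustered discovery pipeline (per-project RPMM first)."""
    cfg = cfg or RunConfig(approach="clustered")
    n_in = m.shape[0]
    m, sheet = prepare_inputs(m, sheet, ann, cfg)
    tumors = tumor_groups(sheet)
    normals = normal_groups(sheet)
    normal_by_project = {g.name.rsplit("_", 1)[0]: g for g in normals}

    project_seeds = np.random.SeedSequence(cfg.seed).spawn(len(tumors))
    assignments: dict[str, MCAssignment] = {}
    for group, ss in zip(tumors, project_seeds):
        project = group.name.rsplit("_", 1)[0]
        assignments[project] = rpmm_cluster(
            m, group, project=project, k=cfg.k, max_depth=cfg.max_depth,
            min_cluster_size=cfg.min_cluster_size,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )

    plan = clustered_plan(assignments, normals)
    tables = _comparison_tables(m, plan, cfg.dmr)

    all_mc: dict[str, list[GroupSpec]] = {
        p: mc_groups(a) for p, a in assignments.items()
    }
    panels: dict[str, Panel] = {}
    candidates: dict[str, list[CandidateProbe]] = {}
    metrics: dict[str, PanelMetrics] = {}
    for project, target_mcs in all_mc.items():
        comparators = [
            g for p, groups in all_mc.items() if p != project for g in groups
        ]
        per_mc: dict[str, list[CandidateProbe]] = {}
        for mc_group in target_mcs:
            oriented = [
                _oriented(tables, mc_group.name, c.name) for c in comparators
            ]
            intersected = intersect_significant(oriented)
            per_mc[mc_group.name] = _tiered_candidates(
                m, mc_group, comparators, intersected, cfg
            )
        cancer_tumors = next(g for g in tumors if g.name == f"{project}_tumor")
        merged = merge_mc_candidates(per_mc, m, cancer_tumors)
        merged = verify_in_normals(
            merged, m, normals, normal_by_project.get(project),
            call_cutoff=cfg.constraints.cutoff,
        )
        candidates[project] = merged
        if not merged:
            continue
        panel = build_panel(merged, m, sheet, project, cfg.constraints,
                            approach="clustered")
        panels[project] = panel
        metrics[project] = evaluate_panel(panel, m, sheet)[1]

    return RunResult(
        approach="clustered",
        panels=panels,
        candidates=candidates,
        metrics=metrics,
        assignments=assignments,
        n_comparisons=len(plan),
        n_probes_in=n_in,
        n_probes_filtered=m.shape[0],
        manifest=_manifest(cfg, m, sheet),
    )


@dataclass
class VerificationResult:
    primary_metrics: dict[str, PanelMetrics]
    metastasis_metrics: dict[str, PanelMetrics]
    cfdna_calls: dict[str, pd.DataFrame]
    comparison: pd.DataFrame  # identification vs verification sensitivity


def run_verification(
    panels: dict[str, Panel],
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    identification_metrics: dict[str, PanelMetrics] | None = None,
) -> VerificationResult:
    """Evaluate frozen panels on a verification cohort.

    ``m``/``sheet`` hold the verification samples (primary tumors and
    normals with ``dataset=verification``, plus any metastasis and
    cfDNA columns). Panels are used exactly as given.
    """
    frozen = {t: hash(p.probes) for t, p in panels.items()}
    primary: dict[str, PanelMetrics] = {}
    mets: dict[str, PanelMetrics] = {}
    cfdna: dict[str, pd.DataFrame] = {}
    records = []
    met_projects = set(
        sheet.loc[sheet["tissue_class"] == "metastasis", "project"]
    )
    for target, panel in panels.items():
        missing = [p for p in panel.probes if p not in m.index]
        if missing:
            raise ValidationError(
                f"panel {target!r} probes missing from verification matrix: {missing}"
            )
        primary[target] = evaluate_panel(panel, m, sheet, scope="verification")[1]
        if target in met_projects:
            mets[target] = evaluate_metastasis_panel(panel, m, sheet)[1]
        table = evaluate_cfdna(panel, m, sheet)
        if len(table):
            cfdna[target] = table
        records.append(
            {
                "target": target,
                "identification_sensitivity": (
                    identification_metrics[target].sensitivity
                    if identification_metrics and target in identification_metrics
                    else None
                ),
                "verification_sensitivity": primary[target].sensitivity,
            }
        )
    assert all(hash(panels[t].probes) == h for t, h in frozen.items())
    return VerificationResult(
        primary_metrics=primary,
        metastasis_metrics=mets,
        cfdna_calls=cfdna,
        comparison=pd.DataFrame.from_records(records).set_index("target"),
    )


def write_run(result: RunResult, out_dir: str | Path) -> None:
    """Write panels, candidate lists, metric tables and the manifest."""
    out = Path(out_dir)
    (out / "panels").mkdir(parents=True, exist_ok=True)
    (out / "candidates").mkdir(exist_ok=True)
    for target, panel in sorted(result.panels.items()):
        (out / "panels" / f"{target}.json").write_text(
            json.dumps(panel.to_json_dict(), indent=1, sort_keys=True)
        )
    for target, cands in sorted(result.candidates.items()):
        (out / "candidates" / f"{target}.json").write_text(
            json.dumps([c.to_json_dict() for c in cands], indent=1, sort_keys=True)
        )
    if result.assignments:
        (out / "assignments").mkdir(exist_ok=True)
        for project, a in sorted(result.assignments.items()):
            (out / "assignments" / f"{project}.json").write_text(
                json.dumps(a.to_json_dict(), indent=1, sort_keys=True)
            )
    metrics_table(result.metrics).to_csv(out / "metrics.tsv", sep="\t")
    manifest = dict(result.manifest)
    manifest.update(
        approach=result.approach,
        n_comparisons=result.n_comparisons,
        n_probes_in=result.n_probes_in,
        n_probes_filtered=result.n_probes_filtered,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
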