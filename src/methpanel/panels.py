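"""Diagnostic panel construction and evaluation.

A *panel* is a small ordered set of hypermethylated probes for one
cancer type. A sample is called positive when its maximum beta over
the panel's probes strictly exceeds the call cutoff (default 0.3; a
value of exactly 0.3 is negative).

Five statistics summarize a panel on a cohort of primary tumors and
normal tissues:

* sensitivity              - target-cancer tumors called positive;
* cancer specificity       - target-cancer paired normals called negative;
* tumor-samples specificity- all non-target tumor samples called negative;
* all-samples specificity  - all non-target samples called negative
  (non-target tumors plus every normal, including the target's);
* diagnostic accuracy      - (true positives + true negatives) / all.

All reported percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GroupSpec, ValidationError


def round_half_up_percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to one decimal."""
    frac = Decimal(numerator) * Decimal(100) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Panel:
    """An ordered probe panel for one target cancer."""

    target: str
    probes: tuple[str, ...]
    cutoff: float = 0.3
    approach: str = "non-clustered"

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValidationError("panel needs at least one probe")
        if len(set(self.probes)) != len(self.probes):
            raise ValidationError("panel probes must be unique")
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError("cutoff must lie in (0, 1)")

    def to_json_dict(self) -> dict:
        return {
            "target": self.target,
            "approach": self.approach,
            "cutoff": self.cutoff,
            "probes": list(self.probes),
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "Panel":
        d = json.loads(Path(path).read_text())
        return cls(
            target=d["target"], probes=tuple(d["probes"]),
            cutoff=d["cutoff"], approach=d["approach"],
        )


@dataclass
class PanelCounts:
    """The confusion counts underlying the five panel statistics."""

    target_pos: int
    target_n: int
    paired_normal_neg: int
    paired_normal_n: int
    other_ts_neg: int
    other_ts_n: int
    other_all_neg: int
    other_all_n: int
    total_n: int


@dataclass
class PanelMetrics:
    """Counts plus the five percentage statistics (half-up, one decimal).

    A statistic whose denominator is zero is ``None`` (not applicable).
    """

    counts: PanelCounts
    sensitivity: float | None
    cancer_specificity: float | None
    ts_specificity: float | None
    all_samples_specificity: float | None
    accuracy: float | None

    def to_json_dict(self) -> dict:
        return {
            "counts": vars(self.counts),
            "sensitivity": self.sensitivity,
            "cancer_specificity": self.cancer_specificity,
            "ts_specificity": self.ts_specificity,
            "all_samples_specificity": self.all_samples_specificity,
            "accuracy": self.accuracy,
        }


def metrics_from_counts(c: PanelCounts) -> PanelMetrics:
    """The five statistics from confusion counts.

    sensitivity = target_pos/target_n, cancer specificity =
    paired_normal_neg/paired_normal_n, tumor-samples specificity =
    other_ts_neg/other_ts_n, all-samples specificity =
    other_all_neg/other_all_n, accuracy =
    (target_pos + other_all_neg)/total_n; percentages half-up, one
    decimal. Zero denominators yield ``None``.
    """
    for pos, n in (
        (c.target_pos, c.target_n),
        (c.paired_normal_neg, c.paired_normal_n),
        (c.other_ts_neg, c.other_ts_n),
        (c.other_all_neg, c.other_all_n),
    ):
        if pos < 0 or n < 0 or pos > n:
            raise ValidationError(f"invalid counts: {pos}/{n}")

    def pct(num: int, den: int) -> float | None:
        return round_half_up_percent(num, den) if den > 0 else None

    return PanelMetrics(
        counts=c,
        sensitivity=pct(c.target_pos, c.target_n),
        cancer_specificity=pct(c.paired_normal_neg, c.paired_normal_n),
        ts_specificity=pct(c.other_ts_neg, c.other_ts_n),
        all_samples_specificity=pct(c.other_all_neg, c.other_all_n),
        accuracy=pct(c.target_pos + c.other_all_neg, c.total_n)
        if c.total_n > 0
        else None,
    )


def call_sample(panel: Panel, betas: pd.Series) -> tuple[float, bool]:
    """Max beta over the panel's probes and the strict-> cutoff call."""
    missing = [p for p in panel.probes if p not in betas.index]
    if missing:
        raise ValidationError(
            f"sample {betas.name!r} lacks panel probes {missing}"
        )
    values = betas[list(panel.probes)].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"sample {betas.name!r} has missing panel betas")
    max_beta = float(values.max())
    return max_beta, max_beta > panel.cutoff


def call_table(panel: Panel, m: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Per-sample max beta and call over the panel (vectorized)."""
    missing = [p for p in panel.probes if p not in m.index]
    if missing:
        raise ValidationError(f"matrix lacks panel probes {missing}")
    sub = m.loc[list(panel.probes), sample_ids]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValidationError(f"missing panel betas for samples {bad[:5]}")
    max_beta = sub.max(axis=0)
    return pd.DataFrame(
        {"max_beta": max_beta, "call": max_beta > panel.cutoff},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def evaluate_panel(
    panel: Panel,
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    scope: str = "identification",
) -> tuple[pd.DataFrame, PanelMetrics]:
    """Evaluate a panel on one dataset's primary tumors and normals."""
    in_scope = sheet[
        sheet["tissue_class"].isin(["tumor", "normal"])
        & (sheet["dataset"] == scope)
        & ~sheet["ffpe"]
    ]
    in_scope = in_scope[in_scope.index.isin(m.columns)]
    target_tumors = in_scope[
        (in_scope["project"] == panel.target) & (in_scope["tissue_class"] == "tumor")
    ].index
    if len(target_tumors) == 0:
        raise ValidationError(
            f"target cancer {panel.target!r} absent from scope {scope!r}"
        )
    calls = call_table(panel, m, list(in_scope.index))
    positive = calls["call"]

    paired_normals = in_scope[
        (in_scope["project"] == panel.target) & (in_scope["tissue_class"] == "normal")
    ].index
    other_ts = in_scope[
        (in_scope["project"] != panel.target) & (in_scope["tissue_class"] == "tumor")
    ].index
    other_all = in_scope.index.difference(target_tumors)

    counts = PanelCounts(
        target_pos=int(positive[target_tumors].sum()),
        target_n=len(target_tumors),
        paired_normal_neg=int((~positive[paired_normals]).sum()),
        paired_normal_n=len(paired_normals),
        other_ts_neg=int((~positive[other_ts]).sum()),
        other_ts_n=len(other_ts),
        other_all_neg=int((~positive[other_all]).sum()),
        other_all_n=len(other_all),
        total_n=len(in_scope),
    )
    return calls, metrics_from_counts(counts)


def evaluate_metastasis_panel(
    panel: Panel,
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    scope: str = "verification",
) -> tuple[pd.DataFrame, PanelMetrics]:
    """Evaluate a frozen panel on liver metastases.

    Sensitivity is over the target cancer's metastases; "cancer"
    specificity becomes metastasis specificity (other cancers'
    metastases called negative); tumor-samples specificity covers all
    primary tumors plus other metastases; all-samples specificity and
    accuracy cover everything in scope except the target metastases.
    """
    in_scope = sheet[
        sheet["tissue_class"].isin(["tumor", "normal", "metastasis"])
        & (sheet["dataset"] == scope)
        & ~sheet["ffpe"]
    ]
    in_scope = in_scope[in_scope.index.isin(m.columns)]
    is_met = in_scope["tissue_class"] == "metastasis"
    target_mets = in_scope[is_met & (in_scope["project"] == panel.target)].index
    if len(target_mets) == 0:
        raise ValidationError(f"no {panel.target!r} metastases in scope {scope!r}")
    calls = call_table(panel, m, list(in_scope.index))
    positive = calls["call"]

    other_mets = in_scope[is_met & (in_scope["project"] != panel.target)].index
    ts = in_scope[(in_scope["tissue_class"] == "tumor")].index.union(other_mets)
    other_all = in_scope.index.difference(target_mets)

    counts = PanelCounts(
        target_pos=int(positive[target_mets].sum()),
        target_n=len(target_mets),
        paired_normal_neg=int((~positive[other_mets]).sum()),
        paired_normal_n=len(other_mets),
        other_ts_neg=int((~positive[ts]).sum()),
        other_ts_n=len(ts),
        other_all_neg=int((~positive[other_all]).sum()),
        other_all_n=len(other_all),
        total_n=len(in_scope),
    )
    return calls, metrics_from_counts(counts)


def evaluate_cfdna(
    panel: Panel, m: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-cfDNA-sample probe betas, max beta and call (no aggregates)."""
    cf = sheet[sheet["tissue_class"] == "cfdna"]
    cf = cf[cf.index.isin(m.columns)]
    if len(cf) == 0:
        return pd.DataFrame(columns=[*panel.probes, "max_beta", "call"])
    sub = m.loc[list(panel.probes), list(cf.index)].T
    out = sub.copy()
    out["max_beta"] = sub.max(axis=1)
    out["call"] = out["max_beta"] > panel.cutoff
    out.index.name = "sample_id"
    return out


@dataclass
class PanelConstraints:
    """Greedy panel-builder settings."""

    min_cancer_specificity: float = 90.0  # percent, on paired normals
    all_spec_slack: float = 2.0  # allowed per-step drop, percentage points
    min_new_target_samples: int = 1  # minimum sensitivity gain per step
    cutoff: float = 0.3
    exhaustive: bool = False  # enumerate subsets (pools of <= 12 only)
    max_probes: int | None = None


def build_panel(
    cands,
    m: pd.DataFrame,
    sheet: pd.DataFrame,
    target: str,
    constraints: PanelConstraints = PanelConstraints(),
    approach: str = "non-clustered",
    scope: str = "identification",
) -> Panel:
    """Greedy forward selection of a small high-sensitivity panel.

    Candidates are ranked by (clusters detected, target mean, probe
    id); at each step the ranked candidate giving the largest
    sensitivity gain is added, subject to the paired-normal
    specificity floor and a bounded drop in all-samples specificity;
    the search stops when no addition detects new target samples. The
    result is the shortest prefix of the selection order achieving the
    final sensitivity. When the candidate pool contains only probes
    shared with the target's normal tissue, the paired-normal floor is
    not enforced (such panels are reported as non-discriminating).
    """
    if not cands:
        raise ValidationError(f"no candidates for target {target!r}")
    in_scope = sheet[
        sheet["tissue_class"].isin(["tumor", "normal"])
        & (sheet["dataset"] == scope)
        & ~sheet["ffpe"]
    ]
    in_scope = in_scope[in_scope.index.isin(m.columns)]
    target_tumors = in_scope[
        (in_scope["project"] == target) & (in_scope["tissue_class"] == "tumor")
    ].index
    paired_normals = in_scope[
        (in_scope["project"] == target) & (in_scope["tissue_class"] == "normal")
    ].index
    other_all = in_scope.index.difference(target_tumors)
    if len(target_tumors) == 0:
        raise ValidationError(f"target cancer {target!r} absent from scope")

    ranked = sorted(cands, key=lambda c: (-c.n_target_mcs, -c.target_mean, c.probe_id))
    probes = [c.probe_id for c in ranked]
    calls = m.loc[probes, list(in_scope.index)] > constraints.cutoff

    enforce_normals = len(paired_normals) > 0 and any(
        c.normal_status != "shared_with_normal" for c in ranked
    )

    def stats(subset: list[str]) -> tuple[int, float, float]:
        pos = calls.loc[subset].any(axis=0)
        sens_n = int(pos[target_tumors].sum())
        cancer_spec = (
            100.0 * float((~pos[paired_normals]).mean())
            if len(paired_normals)
            else 100.0
        )
        all_spec = 100.0 * float((~pos[other_all]).mean()) if len(other_all) else 100.0
        return sens_n, cancer_spec, all_spec

    if constraints.exhaustive:
        if len(probes) > 12:
            raise ValidationError("exhaustive mode limited to <= 12 candidates")
        best = None
        for r in range(1, len(probes) + 1):
            for combo in itertools.combinations(probes, r):
                sens_n, cancer_spec, all_spec = stats(list(combo))
                if enforce_normals and cancer_spec < constraints.min_cancer_specificity:
                    continue
                key = (sens_n, -len(combo), all_spec)
                if best is None or key > best[0]:
                    best = (key, combo)
        if best is None:  # no subset meets the floor; fall back to best single
            best = max(
                ((stats([p])[0], -1, stats([p])[2]), (p,)) for p in probes
            )
        return Panel(target=target, probes=best[1],
                     cutoff=constraints.cutoff, approach=approach)

    selected: list[str] = []
    current_sens, _, current_all_spec = 0, 100.0, 100.0
    remaining = list(probes)
    while remaining:
        if constraints.max_probes and len(selected) >= constraints.max_probes:
            break
        best_choice = None
        for p in remaining:
            sens_n, cancer_spec, all_spec = stats(selected + [p])
            if enforce_normals and cancer_spec < constraints.min_cancer_specificity:
                continue
            if all_spec < current_all_spec - constraints.all_spec_slack:
                continue
            gain = sens_n - current_sens
            if best_choice is None or gain > best_choice[0]:
                best_choice = (gain, p, sens_n, all_spec)
        if best_choice is None or best_choice[0] < constraints.min_new_target_samples:
            break
        _, p, current_sens, current_all_spec = best_choice
        selected.append(p)
        remaining.remove(p)
    if not selected:
        selected = [probes[0]]  # never return an empty panel
        current_sens = stats(selected)[0]
    # shortest prefix of the selection order reaching the final sensitivity
    for cut in range(1, len(selected) + 1):
        if stats(selected[:cut])[0] >= current_sens:
            selected = selected[:cut]
            break
    return Panel(target=target, probes=tuple(selected),
                 cutoff=constraints.cutoff, approach=approach)


def metrics_table(rows: dict[str, PanelMetrics]) -> pd.DataFrame:
    """Tabular report mirroring the counts-then-percentages layout."""
    records = []
    for name, pm in rows.items():
        c = pm.counts
        records.append(
            {
                "panel": name,
                "target_pos": c.target_pos,
                "target_n": c.target_n,
                "paired_normal_neg": c.paired_normal_neg,
                "paired_normal_n": c.paired_normal_n,
                "other_ts_neg": c.other_ts_neg,
                "other_ts_n": c.other_ts_n,
                "other_all_neg": c.other_all_neg,
                "other_all_n": c.other_all_n,
                "total_n": c.total_n,
                "sensitivity": pm.sensitivity,
                "cancer_specificity": pm.cancer_specificity,
                "ts_specificity": pm.ts_specificity,
                "all_samples_specificity": pm.all_samples_specificity,
                "accuracy": pm.accuracy,
            }
        )
    return pd.DataFrame.from_records(records).set_index("panel")
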