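"""Pairwise differential-methylation testing and candidate selection.

For every pair of sample groups, each probe is scored by the
difference in mean beta and a two-sided Wilcoxon rank-sum p-value,
Benjamini-Hochberg adjusted within the comparison; a probe is
*significant* when ``|delta| >= 0.2`` and adjusted p <= 0.05.

Cancer-specific hypermethylated candidates are then the probes
significant with positive delta in EVERY comparison of the target
group against the other cancers, intersected, and filtered by the
selection tiers:

* strict  - delta > 0.3 against every comparator and every comparator
  mean < 0.1;
* relaxed - delta > 0.2 and comparator mean < 0.15 (both required by
  default; an OR mode is available).

Candidates are finally annotated against the target's paired normal
tissue: a paired-normal mean below the 0.3 call cutoff marks the probe
``normal_discriminating``, otherwise ``shared_with_normal`` (the
pancreatic-cancer-like case). No candidate is removed by this step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GroupSpec, ValidationError
from .rpmm import MCAssignment

EXACT_MAX_N = 12  # exact rank-sum enumeration up to this group size


@dataclass
class DMRThresholds:
    min_delta: float = 0.2
    max_adjusted_p: float = 0.05


@dataclass
class SelectionThresholds:
    strict_delta: float = 0.3
    strict_comparator_mean: float = 0.1
    relaxed_delta: float = 0.2
    relaxed_comparator_mean: float = 0.15
    relaxed_mode: str = "and"  # "and" (default) or "or"


@dataclass
class CandidateProbe:
    """A cancer-specific hypermethylated probe and how it was selected."""

    probe_id: str
    target_group: str
    target_mean: float
    comparator_means: dict[str, float]
    min_delta: float
    tier: str  # strict | relaxed
    normal_status: str | None = None  # normal_discriminating | shared_with_normal
    normal_means: dict[str, float] = field(default_factory=dict)
    n_target_mcs: int = 1

    def to_json_dict(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "target_group": self.target_group,
            "target_mean": self.target_mean,
            "comparator_means": self.comparator_means,
            "min_delta": self.min_delta,
            "tier": self.tier,
            "normal_status": self.normal_status,
            "normal_means": self.normal_means,
            "n_target_mcs": self.n_target_mcs,
        }


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration when both groups have at most 12 values and
    there are no ties, otherwise the normal approximation with tie and
    continuity correction. The fully degenerate all-tied case is
    defined as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires non-empty groups")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    ties = np.unique(combined).size < combined.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise rank-sum p-values for probe x sample blocks.

    ``x`` is (probes, n1), ``y`` is (probes, n2). Applies the same
    exact / asymptotic rule as :func:`rank_sum_test` per row.
    """
    n1, n2 = x.shape[1], y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    degenerate = np.all(combined == combined[:, :1], axis=1)
    has_ties = np.array(
        [np.unique(row).size < row.size for row in combined]
    )
    p = np.ones(x.shape[0])
    small = n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N
    exact_rows = small & ~has_ties & ~degenerate
    asym_rows = ~degenerate & ~exact_rows
    if exact_rows.any():
        p[exact_rows] = stats.mannwhitneyu(
            x[exact_rows], y[exact_rows], alternative="two-sided",
            method="exact", axis=1,
        ).pvalue
    if asym_rows.any():
        p[asym_rows] = stats.mannwhitneyu(
            x[asym_rows], y[asym_rows], alternative="two-sided",
            method="asymptotic", axis=1,
        ).pvalue
    return np.minimum(p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dmr_compare(
    m: pd.DataFrame,
    g1: GroupSpec,
    g2: GroupSpec,
    thresholds: DMRThresholds = DMRThresholds(),
) -> pd.DataFrame:
    """Per-probe differential methylation of ``g1`` (target) vs ``g2``.

    Returns a probe-indexed table with columns mean_g1, mean_g2, delta,
    p_value, p_adjusted, significant. BH adjustment is within this one
    comparison.
    """
    overlap = set(g1.sample_ids) & set(g2.sample_ids)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    x = m[list(g1.sample_ids)].to_numpy(dtype=float)
    y = m[list(g2.sample_ids)].to_numpy(dtype=float)
    mean1 = x.mean(axis=1)
    mean2 = y.mean(axis=1)
    p = rank_sum_pvalues(x, y)
    p_adj = bh_adjust(p)
    delta = mean1 - mean2
    significant = (np.abs(delta) >= thresholds.min_delta) & (
        p_adj <= thresholds.max_adjusted_p
    )
    return pd.DataFrame(
        {
            "mean_g1": mean1,
            "mean_g2": mean2,
            "delta": delta,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": significant,
        },
        index=m.index,
    )


def intersect_significant(tables: list[pd.DataFrame]) -> set[str]:
    """Probes significant AND hypermethylated (delta > 0) in every table.

    Each table must be oriented with the target group as g1.
    """
    if not tables:
        raise ValidationError("need at least one comparator table")
    kept: set[str] | None = None
    for t in tables:
        positive = set(t.index[t["significant"] & (t["delta"] > 0)])
        kept = positive if kept is None else kept & positive
    return kept


def select_candidates(
    m: pd.DataFrame,
    target: GroupSpec,
    comparators: list[GroupSpec],
    intersected: set[str],
    tier: str,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[CandidateProbe]:
    """Apply the strict or relaxed selection tier to intersected probes.

    Output is sorted by target mean, descending.
    """
    if tier == "strict":
        min_delta, max_comp, mode = (
            thresholds.strict_delta, thresholds.strict_comparator_mean, "and",
        )
    elif tier == "relaxed":
        min_delta, max_comp, mode = (
            thresholds.relaxed_delta,
            thresholds.relaxed_comparator_mean,
            thresholds.relaxed_mode,
        )
    else:
        raise ValidationError(f"unknown tier {tier!r}")
    probes = [p for p in intersected if p in m.index]
    missing = set(intersected) - set(probes)
    if missing:
        raise ValidationError(f"intersected probes absent from matrix: {missing}")
    if not probes:
        return []
    target_mean = m.loc[probes, list(target.sample_ids)].mean(axis=1)
    comp_means = {
        c.name: m.loc[probes, list(c.sample_ids)].mean(axis=1) for c in comparators
    }
    out: list[CandidateProbe] = []
    for probe in probes:
        tmean = float(target_mean[probe])
        cmeans = {name: float(s[probe]) for name, s in comp_means.items()}
        deltas = [tmean - v for v in cmeans.values()]
        delta_ok = min(deltas) > min_delta
        comp_ok = max(cmeans.values()) < max_comp
        passed = (delta_ok and comp_ok) if mode == "and" else (delta_ok or comp_ok)
        if passed:
            out.append(
                CandidateProbe(
                    probe_id=probe,
                    target_group=target.name,
                    target_mean=tmean,
                    comparator_means=cmeans,
                    min_delta=float(min(deltas)),
                    tier=tier,
                )
            )
    out.sort(key=lambda c: (-c.target_mean, c.probe_id))
    return out


def verify_in_normals(
    cands: list[CandidateProbe],
    m: pd.DataFrame,
    normal_groups: list[GroupSpec],
    paired_normal: GroupSpec | None,
    call_cutoff: float = 0.3,
) -> list[CandidateProbe]:
    """Annotate candidates against normal tissues (removes nothing).

    A candidate whose paired-normal mean is below the call cutoff is
    ``normal_discriminating``; otherwise it is ``shared_with_normal``.
    Per-normal-group means are recorded either way.
    """
    out = []
    for c in cands:
        normal_means = {
            g.name: float(m.loc[c.probe_id, list(g.sample_ids)].mean())
            for g in normal_groups
            if c.probe_id in m.index
        }
        if paired_normal is None:
            status = "normal_discriminating"
        else:
            paired_mean = float(
                m.loc[c.probe_id, list(paired_normal.sample_ids)].mean()
            )
            status = (
                "normal_discriminating"
                if paired_mean < call_cutoff
                else "shared_with_normal"
            )
        out.append(replace(c, normal_status=status, normal_means=normal_means))
    return out


# --- comparison plans ------------------------------------------------


def nonclustered_plan(
    tumor_groups: list[GroupSpec], normal_groups: list[GroupSpec]
) -> list[tuple[GroupSpec, GroupSpec]]:
    """All pairwise comparisons among tumor and normal project groups."""
    groups = list(tumor_groups) + list(normal_groups)
    return list(itertools.combinations(groups, 2))


def mc_groups(assignment: MCAssignment) -> list[GroupSpec]:
    """One GroupSpec per methylation cluster of a project."""
    return [
        GroupSpec(
            name=f"{assignment.project}_MC{mc}",
            sample_ids=assignment.members(mc),
        )
        for mc in sorted(assignment.cluster_means)
    ]


def clustered_plan(
    assignments: dict[str, MCAssignment], normal_groups: list[GroupSpec]
) -> list[tuple[GroupSpec, GroupSpec]]:
    """All pairwise comparisons among MC and normal groups, excluding
    pairs of clusters from the same cancer type."""
    project_of: dict[str, str] = {}
    groups: list[GroupSpec] = []
    for project, assignment in sorted(assignments.items()):
        for g in mc_groups(assignment):
            groups.append(g)
            project_of[g.name] = project
    groups += list(normal_groups)
    plan = []
    for g1, g2 in itertools.combinations(groups, 2):
        if (
            g1.name in project_of
            and g2.name in project_of
            and project_of[g1.name] == project_of[g2.name]
        ):
            continue
        plan.append((g1, g2))
    return plan


def merge_mc_candidates(
    per_mc: dict[str, list[CandidateProbe]],
    m: pd.DataFrame,
    cancer_tumors: GroupSpec,
) -> list[CandidateProbe]:
    """Merge a cancer's per-cluster candidates, counting the MCs that
    selected each probe and re-expressing the target mean over the
    cancer's full tumor group (used by the panel builder's ranking)."""
    by_probe: dict[str, list[CandidateProbe]] = {}
    for cands in per_mc.values():
        for c in cands:
            by_probe.setdefault(c.probe_id, []).append(c)
    tier_rank = {"strict": 0, "relaxed": 1}
    merged = []
    for probe, copies in by_probe.items():
        best = min(copies, key=lambda c: tier_rank[c.tier])
        tmean = float(m.loc[probe, list(cancer_tumors.sample_ids)].mean())
        merged.append(
            replace(
                best,
                target_group=cancer_tumors.name,
                target_mean=tmean,
                n_target_mcs=len(copies),
            )
        )
    merged.sort(key=lambda c: (-c.n_target_mcs, -c.target_mean, c.probe_id))
    return merged
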