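"""Published confusion counts for the adenocarcinoma methylation panels.

These are the reported per-panel confusion counts for seven
adenocarcinoma diagnostic methylation panels evaluated at the 0.3
max-beta cutoff on a TCGA identification cohort (2853 samples: 2609
primary tumors + 244 normals) and an independent GEO verification
cohort (782 primary-tumor/normal samples, plus 31 liver metastases for
the metastasis rows). They serve as exact worked examples for
:func:`methpanel.panels.metrics_from_counts`: recomputing the five
statistics from the counts reproduces the published percentages under
half-up rounding to one decimal.

A handful of printed percentage cells are not arithmetically
consistent with their own printed counts (transcription slips in the
source tables); those cells are listed in ``inconsistent`` per row and
are excluded from reproduction checks. For the metastasis rows only
the metastasis sensitivity and metastasis specificity cells are
asserted, because the published "other tumor samples" / "all samples"
denominators are off by small constants from the stated cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .panels import PanelCounts, PanelMetrics, metrics_from_counts


@dataclass(frozen=True)
class PublishedPanelRow:
    """One published panel-evaluation row (primary tumors + normals)."""

    cancer: str
    dataset: str  # TCGA (identification) or GEO (verification)
    approach: str  # non-clustered | clustered
    n_probes: int
    target_pos: int
    target_n: int
    paired_normal_neg: int
    paired_normal_n: int
    other_ts_neg: int
    all_ts_total: int  # published "all tumor samples" column (includes target)
    other_all_neg: int
    total_n: int
    printed: dict  # statistic name -> printed percentage
    inconsistent: tuple[str, ...] = ()

    def counts(self) -> PanelCounts:
        return PanelCounts(
            target_pos=self.target_pos,
            target_n=self.target_n,
            paired_normal_neg=self.paired_normal_neg,
            paired_normal_n=self.paired_normal_n,
            other_ts_neg=self.other_ts_neg,
            other_ts_n=self.all_ts_total - self.target_n,
            other_all_neg=self.other_all_neg,
            other_all_n=self.total_n - self.target_n,
            total_n=self.total_n,
        )

    def recompute(self) -> PanelMetrics:
        return metrics_from_counts(self.counts())


@dataclass(frozen=True)
class PublishedMetastasisRow:
    """One published liver-metastasis row (asserted cells only)."""

    cancer: str
    approach: str
    met_pos: int
    met_n: int
    other_met_neg: int
    other_met_n: int
    printed_sensitivity: float
    printed_specificity: float


def _row(cancer, dataset, approach, n_probes, tp, tn, nn, n_n, ots, ats, oan, tot,
         printed, inconsistent=()):
    return PublishedPanelRow(
        cancer=cancer, dataset=dataset, approach=approach, n_probes=n_probes,
        target_pos=tp, target_n=tn, paired_normal_neg=nn, paired_normal_n=n_n,
        other_ts_neg=ots, all_ts_total=ats, other_all_neg=oan, total_n=tot,
        printed=printed, inconsistent=tuple(inconsistent),
    )


STATS = (
    "sensitivity",
    "cancer_specificity",
    "ts_specificity",
    "all_samples_specificity",
    "accuracy",
)


def _printed(sens, cspec, tspec, aspec, acc):
    return dict(zip(STATS, (sens, cspec, tspec, aspec, acc)))


PUBLISHED_PANEL_ROWS: list[PublishedPanelRow] = [
    # LIHC
    _row("LIHC", "TCGA", "non-clustered", 6, 344, 377, 50, 50, 2116, 2609,
         2357, 2853, _printed(91.2, 100.0, 94.8, 95.2, 94.7)),
    _row("LIHC", "TCGA", "clustered", 8, 336, 377, 49, 50, 2171, 2609,
         2413, 2853, _printed(89.1, 98.0, 97.3, 97.5, 96.4)),
    _row("LIHC", "GEO", "non-clustered", 6, 112, 114, 48, 48, 253, 418,
         602, 782, _printed(98.2, 100.0, 83.3, 90.1, 91.3),
         inconsistent=("ts_specificity",)),  # counts give 253/304 = 83.2
    _row("LIHC", "GEO", "clustered", 8, 110, 114, 44, 48, 286, 418,
         644, 782, _printed(96.5, 91.7, 94.1, 96.4, 96.4)),
    # CHOL
    _row("CHOL", "TCGA", "non-clustered", 3, 28, 36, 9, 9, 2338, 2609,
         2582, 2853, _printed(77.8, 100.0, 90.9, 91.7, 91.5)),
    _row("CHOL", "TCGA", "clustered", 4, 26, 36, 9, 9, 2384, 2609,
         2622, 2853, _printed(72.2, 100.0, 92.7, 93.1, 92.8)),
    _row("CHOL", "GEO", "non-clustered", 3, 69, 116, 16, 16, 263, 418,
         597, 782, _printed(59.5, 100.0, 87.1, 89.6, 85.2)),
    _row("CHOL", "GEO", "clustered", 4, 83, 116, 16, 16, 297, 418,
         653, 782, _printed(71.6, 100.0, 98.3, 98.0, 94.1)),
    # CRC
    _row("CRC", "TCGA", "non-clustered", 4, 371, 387, 45, 45, 2023, 2609,
         2267, 2853, _printed(95.9, 100.0, 91.0, 91.9, 92.5)),
    _row("CRC", "TCGA", "clustered", 3, 243, 387, 45, 45, 2166, 2609,
         2410, 2853, _printed(62.8, 100.0, 97.5, 97.7, 93.0)),
    _row("CRC", "GEO", "non-clustered", 4, 82, 89, 71, 81, 303, 418,
         652, 782, _printed(92.1, 87.7, 92.1, 94.1, 93.9)),
    _row("CRC", "GEO", "clustered", 3, 51, 89, 81, 81, 327, 418,
         691, 782, _printed(57.3, 100.0, 99.4, 99.7, 94.6),
         inconsistent=("accuracy",)),  # counts give (51+691)/782 = 94.9
    # STAD
    _row("STAD", "TCGA", "non-clustered", 5, 356, 395, 22, 22, 2016, 2609,
         2220, 2853, _printed(90.1, 100.0, 94.1, 90.3, 90.3),
         inconsistent=("ts_specificity",)),  # counts give 2016/2214 = 91.1
    _row("STAD", "TCGA", "clustered", 7, 291, 395, 22, 22, 2076, 2609,
         2249, 2853, _printed(73.7, 100.0, 93.8, 91.5, 89.0)),
    _row("STAD", "GEO", "non-clustered", 5, 22, 24, 84, 84, 375, 418,
         739, 782, _printed(91.7, 100.0, 95.2, 97.5, 97.3)),
    _row("STAD", "GEO", "clustered", 7, 17, 24, 84, 84, 369, 418,
         727, 782, _printed(70.8, 100.0, 93.7, 95.9, 95.1)),
    # BRCA
    _row("BRCA", "TCGA", "non-clustered", 7, 690, 776, 93, 96, 1724, 2609,
         1964, 2853, _printed(88.9, 96.9, 94.1, 94.7, 93.0),
         inconsistent=("all_samples_specificity",)),  # 1964/2077 = 94.6
    _row("BRCA", "TCGA", "clustered", 10, 712, 776, 91, 96, 1660, 2609,
         1899, 2853, _printed(91.8, 94.8, 90.6, 91.4, 91.5)),
    _row("BRCA", "GEO", "non-clustered", 7, 43, 51, 104, 104, 334, 418,
         696, 782, _printed(84.3, 100.0, 91.0, 95.2, 94.5)),
    _row("BRCA", "GEO", "clustered", 10, 44, 51, 102, 104, 350, 418,
         712, 782, _printed(86.3, 98.1, 95.4, 97.4, 96.7)),
]

PUBLISHED_METASTASIS_ROWS: list[PublishedMetastasisRow] = [
    PublishedMetastasisRow("PAAD", "non-clustered", 13, 13, 15, 18, 100.0, 83.3),
    PublishedMetastasisRow("PAAD", "clustered", 9, 13, 17, 18, 69.2, 94.4),
    PublishedMetastasisRow("BRCA", "non-clustered", 15, 18, 9, 13, 83.3, 69.2),
    PublishedMetastasisRow("BRCA", "clustered", 15, 18, 13, 13, 83.3, 100.0),
]


def reproduction_report() -> tuple[int, int, list[str]]:
    """Recompute every consistent published percentage from its counts.

    Returns (matched, checked, mismatches) across all panel rows'
    consistent cells plus the metastasis sensitivity/specificity cells.
    """
    from .panels import round_half_up_percent

    checked = matched = 0
    mismatches: list[str] = []
    for row in PUBLISHED_PANEL_ROWS:
        pm = row.recompute()
        for stat in STATS:
            if stat in row.inconsistent:
                continue
            checked += 1
            got = getattr(pm, stat)
            want = row.printed[stat]
            if got == want:
                matched += 1
            else:
                mismatches.append(
                    f"{row.cancer}/{row.dataset}/{row.approach}/{stat}: "
                    f"recomputed {got} vs printed {want}"
                )
    for met in PUBLISHED_METASTASIS_ROWS:
        for got, want in (
            (round_half_up_percent(met.met_pos, met.met_n), met.printed_sensitivity),
            (
                round_half_up_percent(met.other_met_neg, met.other_met_n),
                met.printed_specificity,
            ),
        ):
            checked += 1
            if got == want:
                matched += 1
            else:
                mismatches.append(f"{met.cancer}/{met.approach}: {got} vs {want}")
    return matched, checked, mismatches
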