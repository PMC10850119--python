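"""Panel calling, the five statistics, greedy building, metastases, cfDNA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methpanel.core import GroupSpec, ValidationError
from methpanel.dmr import CandidateProbe
from methpanel.panels import (
    Panel,
    PanelConstraints,
    PanelCounts,
    build_panel,
    call_sample,
    evaluate_cfdna,
    evaluate_metastasis_panel,
    evaluate_panel,
    metrics_from_counts,
    round_half_up_percent,
)


class TestCallSample:
    @pytest.mark.parametrize(
        "betas,expected_max,expected_call",
        [
            ({"p1": 0.10, "p2": 0.29}, 0.29, False),
            ({"p1": 0.10, "p2": 0.31}, 0.31, True),
            ({"p1": 0.30}, 0.30, False),  # exactly the cutoff is negative
        ],
    )
    def test_max_beta_and_strict_cutoff(self, betas, expected_max, expected_call):
        panel = Panel(target="LIHC", probes=tuple(betas))
        max_beta, call = call_sample(panel, pd.Series(betas, name="S1"))
        assert max_beta == pytest.approx(expected_max)
        assert call is expected_call

    def test_missing_probe_error_names_probe_and_sample(self):
        panel = Panel(target="LIHC", probes=("p1", "p2"))
        with pytest.raises(ValidationError, match="S9.*p2"):
            call_sample(panel, pd.Series({"p1": 0.5}, name="S9"))


class TestMetricsFromCounts:
    def test_perfect_classifier_scores_hundred_everywhere(self):
        pm = metrics_from_counts(
            PanelCounts(10, 10, 5, 5, 20, 20, 25, 25, 35)
        )
        assert (
            pm.sensitivity, pm.cancer_specificity, pm.ts_specificity,
            pm.all_samples_specificity, pm.accuracy,
        ) == (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_large_cohort_worked_example(self):
        # 377-target cohort inside 2853 samples
        pm = metrics_from_counts(
            PanelCounts(344, 377, 50, 50, 2116, 2232, 2357, 2476, 2853)
        )
        assert pm.sensitivity == 91.2
        assert pm.cancer_specificity == 100.0
        assert pm.ts_specificity == 94.8
        assert pm.all_samples_specificity == 95.2
        assert pm.accuracy == 94.7

    def test_small_target_worked_example(self):
        pm = metrics_from_counts(
            PanelCounts(28, 36, 9, 9, 2338, 2573, 2582, 2817, 2853)
        )
        assert pm.sensitivity == 77.8
        assert pm.ts_specificity == 90.9
        assert pm.all_samples_specificity == 91.7
        assert pm.accuracy == 91.5

    def test_zero_denominator_reported_not_applicable(self):
        pm = metrics_from_counts(PanelCounts(5, 5, 0, 0, 3, 3, 3, 3, 8))
        assert pm.cancer_specificity is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_counts(PanelCounts(6, 5, 0, 0, 0, 0, 0, 0, 5))
        with pytest.raises(ValidationError):
            metrics_from_counts(PanelCounts(-1, 5, 0, 0, 0, 0, 0, 0, 5))

    @pytest.mark.parametrize(
        "num,den,expected",
        [(93, 96, 96.9), (695, 800, 86.9), (253, 304, 83.2), (1, 3, 33.3)],
    )
    def test_half_up_rounding_to_one_decimal(self, num, den, expected):
        assert round_half_up_percent(num, den) == expected


def _cohort(matrix, projects, classes, dataset="identification"):
    samples = list(matrix.columns)
    sheet = pd.DataFrame(
        {
            "project": projects,
            "tissue_class": classes,
            "dataset": [dataset] * len(samples),
            "ffpe": [False] * len(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return matrix, sheet


class TestEvaluatePanel:
    def test_separable_toy_scores_hundred(self):
        m = pd.DataFrame(
            [[0.99, 0.99, 0.01, 0.01, 0.01]], index=["p1"],
            columns=["T1", "T2", "O1", "O2", "N1"],
        )
        m, sheet = _cohort(m, ["AAA", "AAA", "BBB", "BBB", "AAA"],
                           ["tumor", "tumor", "tumor", "tumor", "normal"])
        _, pm = evaluate_panel(Panel("AAA", ("p1",)), m, sheet)
        assert pm.sensitivity == pm.accuracy == 100.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_per_sample_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        m = pd.DataFrame(
            rng.random((6, n)), index=[f"p{i}" for i in range(6)],
            columns=[f"S{i}" for i in range(n)],
        )
        projects = rng.choice(["AAA", "BBB", "CCC"], size=n)
        classes = rng.choice(["tumor", "normal"], size=n, p=[0.8, 0.2])
        if not ((projects == "AAA") & (classes == "tumor")).any():
            projects[0], classes[0] = "AAA", "tumor"
        m, sheet = _cohort(m, projects, classes)
        panel = Panel("AAA", ("p0", "p3"))
        _, pm = evaluate_panel(panel, m, sheet)

        counts = dict(tp=0, tn_nt=0, nt=0, tn_ots=0, ots=0, tn_all=0, alln=0)
        for s in sheet.index:
            call = max(m.loc["p0", s], m.loc["p3", s]) > 0.3
            is_target = sheet.loc[s, "project"] == "AAA"
            is_tumor = sheet.loc[s, "tissue_class"] == "tumor"
            if is_target and is_tumor:
                counts["tp"] += call
            else:
                counts["alln"] += 1
                counts["tn_all"] += not call
                if is_tumor:
                    counts["ots"] += 1
                    counts["tn_ots"] += not call
                if is_target and not is_tumor:
                    counts["nt"] += 1
                    counts["tn_nt"] += not call
        assert pm.counts.target_pos == counts["tp"]
        assert pm.counts.paired_normal_neg == counts["tn_nt"]
        assert pm.counts.other_ts_neg == counts["tn_ots"]
        assert pm.counts.other_all_neg == counts["tn_all"]
        assert pm.counts.other_all_n == counts["alln"]

    def test_invariant_to_sample_and_probe_order(self, rng):
        m = pd.DataFrame(
            rng.random((4, 12)), index=[f"p{i}" for i in range(4)],
            columns=[f"S{i}" for i in range(12)],
        )
        projects = ["AAA"] * 6 + ["BBB"] * 6
        classes = ["tumor"] * 5 + ["normal"] + ["tumor"] * 5 + ["normal"]
        m1, sheet1 = _cohort(m, projects, classes)
        perm = rng.permutation(12)
        m2 = m.iloc[::-1, perm]
        sheet2 = sheet1.iloc[perm]
        panel = Panel("AAA", ("p1", "p2"))
        assert (
            evaluate_panel(panel, m1, sheet1)[1].to_json_dict()
            == evaluate_panel(panel, m2, sheet2)[1].to_json_dict()
        )

    def test_absent_target_rejected(self, rng):
        m = pd.DataFrame([[0.5, 0.5]], index=["p1"], columns=["S0", "S1"])
        m, sheet = _cohort(m, ["BBB", "BBB"], ["tumor", "tumor"])
        with pytest.raises(ValidationError, match="absent"):
            evaluate_panel(Panel("AAA", ("p1",)), m, sheet)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_adding_probe_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(
            rng.random((5, 20)), index=[f"p{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(20)],
        )
        projects = ["AAA"] * 10 + ["BBB"] * 10
        classes = (["tumor"] * 8 + ["normal"] * 2) * 2
        m, sheet = _cohort(m, projects, classes)
        small = evaluate_panel(Panel("AAA", ("p0",)), m, sheet)[1]
        large = evaluate_panel(Panel("AAA", ("p0", "p1", "p2")), m, sheet)[1]
        assert large.sensitivity >= small.sensitivity
        assert large.cancer_specificity <= small.cancer_specificity
        assert large.ts_specificity <= small.ts_specificity
        assert large.all_samples_specificity <= small.all_samples_specificity


class TestEvaluateMetastasisPanel:
    def _scope(self):
        # 13 target mets (all called), 18 other mets (15 negative), plus
        # primaries and normals
        rng = np.random.default_rng(0)
        cols, projects, classes, rows = [], [], [], []
        for i in range(13):
            cols.append(f"PM{i}"); projects.append("PAAD"); classes.append("metastasis")
            rows.append(0.9)
        for i in range(18):
            cols.append(f"BM{i}"); projects.append("BRCA"); classes.append("metastasis")
            rows.append(0.9 if i < 3 else 0.05)
        for i in range(10):
            cols.append(f"T{i}"); projects.append("CRC"); classes.append("tumor")
            rows.append(0.05)
        for i in range(4):
            cols.append(f"N{i}"); projects.append("PAAD"); classes.append("normal")
            rows.append(0.05)
        m = pd.DataFrame([rows], index=["p1"], columns=cols)
        return _cohort(m, projects, classes, dataset="verification")

    def test_published_style_counts(self):
        m, sheet = self._scope()
        _, pm = evaluate_metastasis_panel(Panel("PAAD", ("p1",)), m, sheet)
        assert pm.sensitivity == 100.0  # 13/13 target metastases called
        assert pm.cancer_specificity == 83.3  # 15/18 other metastases negative
        assert pm.counts.other_ts_n == 10 + 18  # primaries + other metastases

    def test_no_target_called_gives_zero_sensitivity(self):
        m, sheet = self._scope()
        m.loc["p1", [c for c in m.columns if c.startswith("PM")]] = 0.05
        _, pm = evaluate_metastasis_panel(Panel("PAAD", ("p1",)), m, sheet)
        assert pm.sensitivity == 0.0

    def test_no_other_metastases_reports_not_applicable(self):
        m = pd.DataFrame(
            [[0.9, 0.9, 0.05]], index=["p1"], columns=["PM0", "PM1", "T0"]
        )
        m, sheet = _cohort(m, ["PAAD", "PAAD", "CRC"],
                           ["metastasis", "metastasis", "tumor"],
                           dataset="verification")
        _, pm = evaluate_metastasis_panel(Panel("PAAD", ("p1",)), m, sheet)
        assert pm.cancer_specificity is None


def _candidates(probes, means=None, mcs=None):
    return [
        CandidateProbe(
            probe_id=p, target_group="AAA_tumor",
            target_mean=(means or {}).get(p, 0.8),
            comparator_means={}, min_delta=0.5, tier="strict",
            normal_status="normal_discriminating",
            n_target_mcs=(mcs or {}).get(p, 1),
        )
        for p in probes
    ]


class TestBuildPanel:
    def test_single_perfect_candidate_gives_one_probe(self):
        m = pd.DataFrame(
            [[0.9] * 5 + [0.05] * 5, [0.9] * 5 + [0.05] * 5],
            index=["p1", "p2"],
            columns=[f"S{i}" for i in range(10)],
        )
        m, sheet = _cohort(m, ["AAA"] * 5 + ["BBB"] * 5, ["tumor"] * 10)
        panel = build_panel(_candidates(["p1", "p2"]), m, sheet, "AAA")
        assert len(panel.probes) == 1

    def test_disjoint_coverage_selects_both(self):
        cols = [f"S{i}" for i in range(12)]
        m = pd.DataFrame(
            [
                [0.9] * 3 + [0.05] * 3 + [0.05] * 6,  # first target half
                [0.05] * 3 + [0.9] * 3 + [0.05] * 6,  # second target half
            ],
            index=["p1", "p2"], columns=cols,
        )
        m, sheet = _cohort(m, ["AAA"] * 6 + ["BBB"] * 6, ["tumor"] * 12)
        panel = build_panel(_candidates(["p1", "p2"]), m, sheet, "AAA")
        assert set(panel.probes) == {"p1", "p2"}
        _, pm = evaluate_panel(panel, m, sheet)
        assert pm.sensitivity == 100.0

    def test_empty_candidate_list_rejected(self):
        m = pd.DataFrame([[0.5]], index=["p1"], columns=["S0"])
        m, sheet = _cohort(m, ["AAA"], ["tumor"])
        with pytest.raises(ValidationError, match="no candidates"):
            build_panel([], m, sheet, "AAA")

    @pytest.mark.parametrize("seed", list(range(6)))
    def test_greedy_within_five_points_of_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n_probes, n_target, n_other, n_normal = 8, 15, 15, 5
        cols = (
            [f"T{i}" for i in range(n_target)]
            + [f"O{i}" for i in range(n_other)]
            + [f"N{i}" for i in range(n_normal)]
        )
        target_block = rng.choice([0.7, 0.05], p=[0.45, 0.55],
                                  size=(n_probes, n_target))
        other_block = rng.choice([0.7, 0.05], p=[0.08, 0.92],
                                 size=(n_probes, n_other + n_normal))
        m = pd.DataFrame(
            np.hstack([target_block, other_block]),
            index=[f"p{i}" for i in range(n_probes)], columns=cols,
        )
        projects = ["AAA"] * n_target + ["BBB"] * n_other + ["AAA"] * n_normal
        classes = ["tumor"] * (n_target + n_other) + ["normal"] * n_normal
        m, sheet = _cohort(m, projects, classes)
        cands = _candidates(list(m.index))

        # identical constraint set for both searches: the paired-normal
        # specificity floor (the slack rule is a greedy-path heuristic)
        greedy = build_panel(
            cands, m, sheet, "AAA", PanelConstraints(all_spec_slack=100.0)
        )
        exhaustive = build_panel(
            cands, m, sheet, "AAA", PanelConstraints(exhaustive=True)
        )
        sens_greedy = evaluate_panel(greedy, m, sheet)[1].sensitivity
        sens_best = evaluate_panel(exhaustive, m, sheet)[1].sensitivity
        assert sens_greedy >= sens_best - 5.0

    def test_shared_with_normal_pool_skips_normal_floor(self):
        # every candidate is hypermethylated in the paired normals too
        cols = ["T0", "T1", "N0", "N1", "O0", "O1"]
        m = pd.DataFrame(
            [[0.9, 0.9, 0.8, 0.8, 0.05, 0.05]], index=["p1"], columns=cols
        )
        m, sheet = _cohort(
            m, ["AAA", "AAA", "AAA", "AAA", "BBB", "BBB"],
            ["tumor", "tumor", "normal", "normal", "tumor", "tumor"],
        )
        cands = _candidates(["p1"])
        cands[0].normal_status = "shared_with_normal"
        panel = build_panel(cands, m, sheet, "AAA")
        _, pm = evaluate_panel(panel, m, sheet)
        assert pm.sensitivity == 100.0
        assert pm.cancer_specificity == 0.0  # reported, not enforced


class TestEvaluateCfdna:
    def test_healthy_negative_patient_positive(self):
        m = pd.DataFrame(
            {"CF_healthy": [0.02, 0.04], "CF_patient": [0.45, 0.10]},
            index=["p1", "p2"],
        )
        m, sheet = _cohort(m, ["healthy", "CRC"], ["cfdna", "cfdna"],
                           dataset="verification")
        table = evaluate_cfdna(Panel("CRC", ("p1", "p2")), m, sheet)
        assert not table.loc["CF_healthy", "call"]
        assert table.loc["CF_patient", "call"]
        assert table.loc["CF_patient", "max_beta"] == pytest.approx(0.45)

    def test_no_cfdna_samples_yields_empty_table(self):
        m = pd.DataFrame([[0.5]], index=["p1"], columns=["T0"])
        m, sheet = _cohort(m, ["AAA"], ["tumor"])
        assert len(evaluate_cfdna(Panel("AAA", ("p1",)), m, sheet)) == 0


class TestPanelType:
    def test_rejects_empty_duplicate_or_bad_cutoff(self):
        with pytest.raises(ValidationError):
            Panel("AAA", ())
        with pytest.raises(ValidationError):
            Panel("AAA", ("p1", "p1"))
        with pytest.raises(ValidationError):
            Panel("AAA", ("p1",), cutoff=1.5)

    def test_json_roundtrip(self, tmp_path):
        panel = Panel("AAA", ("p1", "p2"), cutoff=0.3, approach="clustered")
        path = tmp_path / "panel.json"
        import json

        path.write_text(json.dumps(panel.to_json_dict()))
        assert Panel.from_json(path) == panel
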