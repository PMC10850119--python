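"""Evaluate the frozen panels on the verification cohort.

Takes the non-clustered panels from 03_discover_panels.py and
evaluates them, unchanged, on the independent verification cohort:
primary tumors and normals, liver metastases, and cfDNA samples.
Writes the metric tables and cfDNA call tables under
results/verification/.
"""

from pathlib import Path

from methpanel.core import (
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
)
from methpanel.panels import Panel, metrics_table
from methpanel.pipeline import RunConfig, prepare_inputs, run_verification

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = ROOT / "cohorts" / "verification"
    m = read_beta_matrix(cohort / "beta.tsv")
    sheet = read_sample_sheet(cohort / "samples.csv")
    ann = read_probe_annotation(cohort / "annotation.csv")
    m2, sheet2 = prepare_inputs(m, sheet, ann, RunConfig())

    panel_dir = ROOT / "runs" / "non_clustered" / "panels"
    panels = {
        path.stem: Panel.from_json(path)
        for path in sorted(panel_dir.glob("*.json"))
    }
    ver = run_verification(panels, m2, sheet2)

    out = ROOT / "verification"
    out.mkdir(parents=True, exist_ok=True)
    metrics_table(ver.primary_metrics).to_csv(out / "primary_metrics.tsv", sep="\t")
    if ver.metastasis_metrics:
        metrics_table(ver.metastasis_metrics).to_csv(
            out / "metastasis_metrics.tsv", sep="\t"
        )
    for target, table in ver.cfdna_calls.items():
        table.to_csv(out / f"cfdna_calls_{target}.tsv", sep="\t")

    for target in sorted(ver.primary_metrics):
        pm = ver.primary_metrics[target]
        line = f"{target}: verification sensitivity {pm.sensitivity}%"
        if target in ver.metastasis_metrics:
            line += (f", metastasis sensitivity "
                     f"{ver.metastasis_metrics[target].sensitivity}%")
        print(line)
    healthy_positive = sum(
        int(t.loc[t.index.str.contains("healthy"), "call"].sum())
        for t in ver.cfdna_calls.values()
    )
    patient_positive = sum(
        int(t.loc[~t.index.str.contains("healthy"), "call"].sum())
        for t in ver.cfdna_calls.values()
    )
    print(f"cfDNA: {healthy_positive} positive calls in healthy donors, "
          f"{patient_positive} positive panel calls in patients")


if __name__ == "__main__":
    main()
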