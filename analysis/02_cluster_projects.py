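"""Cluster each project's tumors into methylation clusters (MCs).

Reads the identification cohort written by 01_simulate_cohorts.py,
runs the recursive beta-mixture clustering per project on the 5000
most variable probes, and reports the recovered cluster count and the
adjusted Rand index against the generator's planted truth. Writes
per-project assignment JSONs under results/clustering/.
"""

import json
from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from methpanel.core import (
    GroupSpec,
    filter_probes,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
)
from methpanel.rpmm import rpmm_cluster

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    cohort = ROOT / "cohorts" / "identification"
    m = read_beta_matrix(cohort / "beta.tsv")
    sheet = read_sample_sheet(cohort / "samples.csv")
    ann = read_probe_annotation(cohort / "annotation.csv")
    truth = json.loads((cohort / "truth.json").read_text())
    mf = filter_probes(m, ann)

    out = ROOT / "clustering"
    out.mkdir(parents=True, exist_ok=True)
    for project in sorted(sheet["project"].unique()):
        ids = tuple(
            sheet.index[(sheet["project"] == project)
                        & (sheet["tissue_class"] == "tumor")]
        )
        if not ids:
            continue
        a = rpmm_cluster(mf, GroupSpec(f"{project}_tumor", ids),
                         project=project, seed=SEED)
        ari = adjusted_rand_score(
            [truth["cluster_of"][s] for s in ids], [a.labels[s] for s in ids]
        )
        (out / f"{project}.json").write_text(
            json.dumps(a.to_json_dict(), indent=1, sort_keys=True)
        )
        print(f"{project}: {a.n_clusters()} clusters, ARI vs truth {ari:.3f}")


if __name__ == "__main__":
    main()
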