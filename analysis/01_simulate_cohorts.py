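"""Generate the identification and verification cohorts.

Writes the default seven-project synthetic roster (280 primary tumors,
70 normals, 10 liver metastases, 9 cfDNA samples over ~2400 probes)
and an independent verification cohort drawn from the same generative
parameters with a fresh seed, under results/cohorts/.
"""

from pathlib import Path

from methpanel.simulate import default_config, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
IDENTIFICATION_SEED = 1
VERIFICATION_SEED = 101


def main() -> None:
    for name, seed, dataset in (
        ("identification", IDENTIFICATION_SEED, "identification"),
        ("verification", VERIFICATION_SEED, "verification"),
    ):
        cfg = default_config(seed=seed, dataset=dataset)
        m, sheet, ann, truth = simulate_cohort(cfg)
        write_cohort(OUT / name, m, sheet, ann, truth)
        counts = sheet["tissue_class"].value_counts().to_dict()
        print(f"{name}: {m.shape[0]} probes x {m.shape[1]} samples, {counts}")


if __name__ == "__main__":
    main()
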