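"""Beta-value matrices, sample sheets and probe annotations.

Methylation levels are represented as beta values: the fraction of
methylated signal at a CpG probe, in [0, 1] (0 = unmethylated,
1 = fully methylated). A cohort is a probe x sample matrix of betas
(a :class:`pandas.DataFrame` with probe ids as the index and sample
ids as columns, ``NaN`` for missing), a sample sheet mapping samples
to project / tissue class / dataset, and a probe annotation giving
each probe's chromosome.

The filtering rules applied before any analysis are:

* probes on the X and Y chromosomes are removed (avoids sex effects),
* probes with any missing value in the loaded matrix are removed,
* probes whose id occurs more than once are removed entirely (all
  copies; a duplicated measurement cannot be disambiguated),
* FFPE-flagged samples are excluded via the sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("tumor", "normal", "metastasis", "cfdna")
DATASETS = ("identification", "verification")

AUTOSOMES = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = ("X", "Y")


class ValidationError(ValueError):
    """An input violates the format or value contracts."""


@dataclass(frozen=True)
class GroupSpec:
    """A named set of sample ids used as one side of a comparison."""

    name: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise ValidationError(f"group {self.name!r} has no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"group {self.name!r} has duplicate sample ids")


def validate_beta_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check value range and sample-id uniqueness; return ``m`` unchanged."""
    if m.columns.duplicated().any():
        dupes = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    values = m.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {values[i, j]!r} outside [0, 1] "
            f"at probe {m.index[i]!r}, sample {m.columns[j]!r}"
        )
    return m


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated beta matrix (rows = probes, header = samples).

    Missing values are encoded as ``NA``. Raises :class:`ValidationError`
    for non-numeric cells, values outside [0, 1] or duplicate sample ids.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise ValidationError(f"duplicate sample ids: {dupes}")
    m = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
        dtype=str,
    )
    m.index = m.index.astype(str)
    m.index.name = "probe_id"
    m.columns = m.columns.astype(str)
    out = pd.DataFrame(index=m.index, columns=m.columns, dtype=float)
    for col in m.columns:
        converted = pd.to_numeric(m[col], errors="coerce")
        bad = converted.isna() & m[col].notna()
        if bad.any():
            probe = m.index[bad][0]
            raise ValidationError(
                f"non-numeric beta value {m.loc[probe, col]!r} "
                f"at probe {probe!r}, sample {col!r}"
            )
        out[col] = converted
    return validate_beta_matrix(out)


def write_beta_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV (sample_id, project, tissue_class, dataset, ffpe)."""
    s = pd.read_csv(path, dtype=str)
    required = ["sample_id", "project", "tissue_class", "dataset", "ffpe"]
    missing = [c for c in required if c not in s.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    s = s.set_index("sample_id")
    s["ffpe"] = s["ffpe"].str.lower().map({"true": True, "false": False})
    if s["ffpe"].isna().any():
        raise ValidationError("ffpe column must be 'true' or 'false'")
    return validate_sample_sheet(s)


def validate_sample_sheet(s: pd.DataFrame) -> pd.DataFrame:
    if s.index.duplicated().any():
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in sheet: {dupes}")
    unknown = set(s["tissue_class"]) - set(TISSUE_CLASSES)
    if unknown:
        raise ValidationError(
            f"unknown tissue_class {sorted(unknown)}; allowed: {list(TISSUE_CLASSES)}"
        )
    unknown = set(s["dataset"]) - set(DATASETS)
    if unknown:
        raise ValidationError(
            f"unknown dataset {sorted(unknown)}; allowed: {list(DATASETS)}"
        )
    return s


def write_sample_sheet(s: pd.DataFrame, path: str | Path) -> None:
    out = s.copy()
    out["ffpe"] = out["ffpe"].map({True: "true", False: "false"})
    out.to_csv(path, index_label="sample_id")


def read_probe_annotation(path: str | Path) -> pd.Series:
    """Read a probe annotation CSV (probe_id, chromosome) as a Series."""
    ann = pd.read_csv(path, dtype=str)
    if "probe_id" not in ann.columns or "chromosome" not in ann.columns:
        raise ValidationError("annotation must have columns probe_id, chromosome")
    return ann.set_index("probe_id")["chromosome"]


def write_probe_annotation(ann: pd.Series, path: str | Path) -> None:
    ann.rename("chromosome").to_csv(path, index_label="probe_id")


def filter_probes(m: pd.DataFrame, ann: pd.Series) -> pd.DataFrame:
    """Apply the probe-exclusion rules; retained values are untouched.

    Keeps exactly the probes that are autosomal, have no missing value
    in any sample of ``m``, and whose id occurs exactly once. All copies
    of a duplicated id are removed.
    """
    probe_ids = m.index
    unannotated = probe_ids[~probe_ids.isin(ann.index)].unique().tolist()
    if unannotated:
        raise ValidationError(f"probes without annotation: {unannotated[:5]}")
    duplicated = probe_ids[probe_ids.duplicated(keep=False)]
    keep = ~probe_ids.isin(duplicated)
    keep &= ann.reindex(probe_ids).isin(AUTOSOMES).to_numpy()
    keep &= m.notna().all(axis=1).to_numpy()
    out = m.loc[keep]
    if out.shape[0] == 0:
        raise ValidationError("no probes survive filtering")
    return out


def merge_projects(s: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Relabel projects (e.g. ``{"COAD": "CRC", "READ": "CRC"}``); idempotent."""
    for old, new in mapping.items():
        if not new:
            raise ValidationError(f"project {old!r} mapped to empty label")
    out = s.copy()
    out["project"] = out["project"].replace(dict(mapping))
    return out


def drop_ffpe(s: pd.DataFrame) -> pd.DataFrame:
    """Exclude FFPE-flagged samples (no analysis sees them)."""
    return s.loc[~s["ffpe"]]


def subset_samples(m: pd.DataFrame, sample_ids: Iterable[str]) -> pd.DataFrame:
    ids = [sid for sid in sample_ids if sid in m.columns]
    return m[ids]


def tumor_groups(s: pd.DataFrame, dataset: str = "identification") -> list[GroupSpec]:
    """One group per project of that project's primary tumor samples."""
    return _class_groups(s, "tumor", dataset, suffix="tumor")


def normal_groups(s: pd.DataFrame, dataset: str = "identification") -> list[GroupSpec]:
    """One group per project of that project's normal tissue samples."""
    return _class_groups(s, "normal", dataset, suffix="normal")


def _class_groups(
    s: pd.DataFrame, tissue_class: str, dataset: str, suffix: str
) -> list[GroupSpec]:
    sub = s[(s["tissue_class"] == tissue_class) & (s["dataset"] == dataset)]
    groups = []
    for project in sorted(sub["project"].unique()):
        ids = tuple(sub.index[sub["project"] == project])
        groups.append(GroupSpec(name=f"{project}_{suffix}", sample_ids=ids))
    return groups
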