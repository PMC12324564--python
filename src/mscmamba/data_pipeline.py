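"""Dataset-side I/O and math for ROI-level BOLD time series.

File conventions
----------------
* per-subject time series: delimited text (CSV/TSV), rows = time points,
  columns = regions, optional header row of region names, '.' decimal;
* phenotype table: TSV with mandatory columns ``subject_id``, ``site``,
  ``label``, ``age``, ``sex`` and optional ``education``, ``quality``;
* dataset manifest: YAML naming the phenotype file and the time-series
  directory (one ``<subject_id>.csv`` per subject).

The quality column is a precomputed per-subject scalar (e.g. the spatial
correlation of a subject's ReHo map with the group mean); image-level QC is
out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SubjectRecord", "ExclusionCriteria", "ConnectivityMatrix",
           "SubjectDataset", "load_subject_timeseries", "write_subject_timeseries",
           "load_phenotypes", "apply_exclusions", "roi_average", "fc_matrix",
           "fisher_z", "write_fc_matrix", "write_manifest", "load_dataset"]

LABELS = ("control", "patient")  # class 0, class 1


@dataclass
class SubjectRecord:
    """One subject's T×C ROI time series plus phenotype fields."""

    subject_id: str
    site: str
    label: str  # "patient" or "control"
    timeseries: np.ndarray
    age: float = np.nan
    sex: str = ""
    education: float | None = None
    region_names: list | None = None

    def __post_init__(self):
        ts = np.asarray(self.timeseries, dtype=np.float64)
        if ts.ndim != 2 or ts.shape[0] < 2 or ts.shape[1] < 2:
            raise ValueError("timeseries must be T×C with T >= 2, C >= 2")
        if not np.all(np.isfinite(ts)):
            raise ValueError("timeseries contains NaN/Inf")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        self.timeseries = ts

    @property
    def T(self) -> int:
        return self.timeseries.shape[0]

    @property
    def C(self) -> int:
        return self.timeseries.shape[1]

    @property
    def y(self) -> int:
        return LABELS.index(self.label)


@dataclass
class ExclusionCriteria:
    """Phenotype/QC exclusion rules applied by :func:`apply_exclusions`."""

    age_min: float = 18.0
    age_max: float = 65.0
    required_fields: tuple = ("age", "sex", "education")
    min_site_count_per_group: int = 10
    quality_threshold: float = 0.6

    def __post_init__(self):
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")


@dataclass
class ConnectivityMatrix:
    """C×C symmetric Fisher-z functional connectivity, zero diagonal."""

    values: np.ndarray
    region_names: list | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v


class SubjectDataset:
    """List of :class:`SubjectRecord` with array views for model training."""

    def __init__(self, records: list):
        if not records:
            raise ValueError("dataset is empty")
        self.records = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def X(self) -> np.ndarray:
        return np.stack([r.timeseries for r in self.records])

    @property
    def y(self) -> np.ndarray:
        return np.array([r.y for r in self.records], dtype=int)

    @property
    def sites(self) -> np.ndarray:
        return np.array([r.site for r in self.records])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_subject_timeseries(path, expected_regions: int | None = None,
                            subject_id: str | None = None, site: str = "",
                            label: str = "control", **pheno) -> SubjectRecord:
    """Load one subject's T×C delimited time-series file.

    Non-numeric cells, ragged rows or NaNs raise a load error naming the
    offending row/column (0-based, header excluded); all-zero (zero-variance)
    regions trigger a warning listing the column indices, mirroring the
    exclusion of acquisitions with no signal in part of the atlas.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = first.iloc[0].apply(
        lambda v: isinstance(v, str) and not _is_number(v)).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     float_precision="round_trip")
    region_names = [str(c) for c in df.columns] if has_header else None
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                if not _is_number(arr[i, j]):
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i}, column {j}")
        arr = arr.astype(np.float64)
    bad = np.argwhere(~np.isfinite(arr.astype(np.float64)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: NaN/Inf at row {i}, column {j}")
    arr = arr.astype(np.float64)
    if expected_regions is not None and arr.shape[1] != expected_regions:
        raise ValueError(
            f"{path}: expected {expected_regions} regions, found {arr.shape[1]}")
    zero_var = np.nonzero(arr.std(axis=0) == 0.0)[0]
    if zero_var.size:
        warnings.warn(f"{path.name}: zero-variance region column(s) "
                      f"{zero_var.tolist()}", stacklevel=2)
    return SubjectRecord(subject_id=subject_id or path.stem, site=site,
                         label=label, timeseries=arr,
                         region_names=region_names, **pheno)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_subject_timeseries(record: SubjectRecord, path) -> Path:
    """Write a record's time series as CSV (17 significant digits, so a
    write/read round trip is bit-exact)."""
    path = Path(path)
    cols = record.region_names or [f"roi_{i}" for i in range(record.C)]
    df = pd.DataFrame(record.timeseries, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"subject_id", "site", "label", "age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

def apply_exclusions(phenotypes: pd.DataFrame,
                     crit: ExclusionCriteria = ExclusionCriteria()):
    """Apply the subject/site exclusion rules in order and report removals.

    Order: (1) age bounds, inclusive at both ends (keep age_min ≤ age ≤
    age_max); (2) subjects with missing required fields; (3) quality scalar
    below the threshold (only when a ``quality`` column exists); (4) sites
    with fewer than ``min_site_count_per_group`` subjects in either class.
    Returns (kept table, report dict of per-rule removal counts).
    """
    required = {"subject_id", "site", "label"} | set(
        f for f in crit.required_fields if f in ("age", "sex", "education"))
    missing_cols = required - set(phenotypes.columns)
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")
    df = phenotypes.copy()
    report = {}
    n0 = len(df)
    keep = (df["age"] >= crit.age_min) & (df["age"] <= crit.age_max)
    df = df[keep]
    report["age_bounds"] = n0 - len(df)

    n0 = len(df)
    cols = [f for f in crit.required_fields if f in df.columns]
    mask = np.ones(len(df), dtype=bool)
    for c in cols:
        col = df[c]
        mask &= col.notna().to_numpy()
        if col.dtype == object:
            mask &= (col.astype(str).str.strip() != "").to_numpy()
    df = df[mask]
    report["missing_fields"] = n0 - len(df)

    n0 = len(df)
    if "quality" in df.columns:
        df = df[df["quality"] >= crit.quality_threshold]
    report["quality"] = n0 - len(df)

    n0 = len(df)
    ok_sites = []
    for s, grp in df.groupby("site"):
        counts = grp["label"].value_counts()
        if all(counts.get(lbl, 0) >= crit.min_site_count_per_group
               for lbl in LABELS):
            ok_sites.append(s)
    df = df[df["site"].isin(ok_sites)]
    report["site_minimum"] = n0 - len(df)
    report["kept"] = len(df)
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# ROI averaging + functional connectivity
# ---------------------------------------------------------------------------

def roi_average(voxel_series: np.ndarray, labels) -> np.ndarray:
    """Average voxel time series within each atlas region.

    ``voxel_series`` is T×V; ``labels`` assigns every voxel a region in
    1..C.  Column c−1 of the result is the per-time-point mean over voxels
    with label c.  An empty region is an error naming the region.
    """
    vs = np.asarray(voxel_series, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if vs.ndim != 2 or labels.shape[0] != vs.shape[1]:
        raise ValueError("labels length must equal the number of voxels")
    C = labels.max()
    if labels.min() < 1:
        raise ValueError("labels must be in 1..C")
    out = np.empty((vs.shape[0], C))
    for c in range(1, C + 1):
        idx = labels == c
        if not idx.any():
            raise ValueError(f"region {c} has no voxels")
        out[:, c - 1] = vs[:, idx].mean(axis=1)
    return out


_R_CLAMP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing z = arctanh(r), with r clamped to ±(1−1e−7)."""
    return np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))


def fc_matrix(timeseries: np.ndarray, region_names=None,
              on_zero_variance: str = "warn") -> ConnectivityMatrix:
    """Fisher-z Pearson functional connectivity of a T×C series.

    Zero-variance columns produce zero rows/columns with a warning
    (``on_zero_variance="error"`` raises instead).  Diagonal is 0
    (arctanh(1) is undefined).
    """
    ts = np.asarray(timeseries, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be T×C with T >= 3")
    sd = ts.std(axis=0)
    dead = np.nonzero(sd == 0.0)[0]
    if dead.size:
        if on_zero_variance == "error":
            raise ValueError(f"zero-variance column(s): {dead.tolist()}")
        warnings.warn(f"zero-variance column(s) {dead.tolist()}; "
                      "corresponding connectivity set to 0", stacklevel=2)
    live = np.nonzero(sd > 0.0)[0]
    C = ts.shape[1]
    z = np.zeros((C, C))
    if live.size >= 2:
        r = np.corrcoef(ts[:, live], rowvar=False)
        zl = fisher_z(r)
        np.fill_diagonal(zl, 0.0)
        z[np.ix_(live, live)] = zl
    return ConnectivityMatrix(values=z, region_names=region_names)


def write_fc_matrix(cm: ConnectivityMatrix, path) -> Path:
    """Write a connectivity matrix as CSV, with region names as the header
    when available."""
    path = Path(path)
    cols = cm.region_names or [f"roi_{i}" for i in range(cm.values.shape[0])]
    pd.DataFrame(cm.values, columns=cols).to_csv(path, index=False,
                                                 float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(out_dir, phenotype_file: str = "phenotypes.tsv",
                   timeseries_dir: str = "timeseries") -> Path:
    out_dir = Path(out_dir)
    manifest = {"phenotypes": phenotype_file, "timeseries_dir": timeseries_dir}
    p = out_dir / "manifest.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return p


def load_dataset(manifest_path) -> SubjectDataset:
    """Load a full dataset (phenotypes + per-subject CSVs) from a manifest."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    pheno = load_phenotypes(root / manifest["phenotypes"])
    ts_dir = root / manifest["timeseries_dir"]
    records = []
    for row in pheno.itertuples(index=False):
        rec = load_subject_timeseries(
            ts_dir / f"{row.subject_id}.csv",
            subject_id=str(row.subject_id), site=str(row.site),
            label=str(row.label), age=float(row.age), sex=str(row.sex),
            education=float(getattr(row, "education", np.nan)))
        records.append(rec)
    return SubjectDataset(records)
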