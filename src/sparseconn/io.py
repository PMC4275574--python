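"""Plain-text I/O for time-series, manifests, matrices, models and reports.

Formats:

* regional time-series: TSV, rows = time-points, header row of region labels;
* motion parameters: whitespace-delimited text, n_t rows x 6 columns (the
  SPM ``rp_*.txt`` dialect);
* subject manifest: TSV with columns ``subject_id``, ``group`` (+1/-1) and
  optional ``timeseries``/``motion`` file paths;
* connectivity matrices and weight vectors: TSV with region labels, feature
  rows keyed ``regionA|regionB``;
* cross-validation reports: JSON plus a one-row TSV summary with the
  Accuracy / Sensitivity / Specificity / Sparsity / Stability columns;
* discriminative networks: edge-list TSV, node-degree TSV and optionally a
  BrainNet Viewer ``.node``/``.edge`` pair;
* voxel input: NIfTI-1 4-D image plus integer label volume (via nibabel).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import TrainedLinearModel
from .dataset import StudyData
from .preprocess import RawTimeSeries, RegionalTimeSeries, clean_timeseries, regional_means
from .selection import CVReport
from .synthdata import GroundTruth, SimulationSpec

__all__ = [
    "read_timeseries_tsv", "write_timeseries_tsv", "read_motion_params",
    "read_manifest", "write_manifest", "write_matrix_tsv", "read_matrix_tsv",
    "write_model", "read_model", "report_to_dict", "write_report",
    "summary_row", "write_network", "write_brainnet",
    "write_dataset", "load_dataset", "load_nifti_subject",
    "write_ground_truth", "read_simulation_spec",
]


# -- time-series and motion -------------------------------------------------

def read_timeseries_tsv(path, tr_seconds: float = 2.0, subject_id: str = "",
                        group: int = 0) -> RawTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RawTimeSeries(df.to_numpy(dtype=float), tr_seconds,
                         subject_id or Path(path).stem, group)


def write_timeseries_tsv(path, ts: RawTimeSeries | RegionalTimeSeries,
                         region_labels=None) -> None:
    labels = region_labels or [f"region{r:03d}" for r in range(ts.n_p)]
    pd.DataFrame(ts.data, columns=labels).to_csv(path, sep="\t", index=False,
                                                 float_format="%.10g")


def read_motion_params(path) -> np.ndarray:
    mo = np.loadtxt(path)
    if mo.ndim != 2 or mo.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    return mo


# -- manifest ---------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df or "group" not in df:
        raise ValueError("manifest needs 'subject_id' and 'group' columns")
    if not set(df["group"].astype(int)) <= {-1, 1}:
        raise ValueError("manifest groups must be coded +1 (patient) / -1")
    return df


def write_manifest(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- matrices and models ----------------------------------------------------

def write_matrix_tsv(path, mat: np.ndarray, region_labels=None) -> None:
    labels = region_labels or [f"region{r:03d}" for r in range(mat.shape[0])]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_model(path_prefix, model: TrainedLinearModel, index_map,
                region_labels=None) -> None:
    """Weights as TSV (pair id, weight) plus a JSON sidecar of metadata."""
    prefix = Path(path_prefix)
    labels = region_labels or [
        f"region{r:03d}"
        for r in range(max(max(i, j) for i, j in index_map) + 1)]
    rows = [{"pair": f"{labels[i]}|{labels[j]}", "weight": w}
            for (i, j), w in zip(index_map, model.weights)]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".weights.tsv"), sep="\t",
                              index=False, float_format="%.12g")
    side = {"penalty": model.penalty, "C": model.C, "eps": model.eps,
            "meta": {k: v for k, v in model.meta.items()
                     if isinstance(v, (str, int, float, bool, type(None)))}}
    prefix.with_suffix(".model.json").write_text(json.dumps(side, indent=2))


def read_model(path_prefix) -> TrainedLinearModel:
    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".weights.tsv"), sep="\t")
    side = json.loads(prefix.with_suffix(".model.json").read_text())
    return TrainedLinearModel(df["weight"].to_numpy(dtype=float),
                              side["penalty"], side["C"], side["eps"],
                              side.get("meta", {}))


# -- reports ----------------------------------------------------------------

def report_to_dict(report: CVReport) -> dict:
    return {
        "feature_kind": report.feature_kind,
        "penalty": report.penalty,
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "sparsity_mean": report.sparsity_mean,
        "sparsity_sd": report.sparsity_sd,
        "stability_mean": report.stability_mean,
        "stability_sd": report.stability_sd,
        "confusion": dataclasses.asdict(report.confusion),
        "folds": [{
            "fold": f.fold,
            "test_subjects": list(f.test_subjects),
            "chosen_C": f.chosen_C,
            "chosen_lambda": f.chosen_lambda,
            "y_true": list(f.y_true),
            "y_pred": list(f.y_pred),
            "sparsity": f.sparsity,
            "inner_stability": f.inner_stability,
        } for f in report.folds],
    }


def write_report(path, report: CVReport, extra: dict | None = None) -> None:
    d = report_to_dict(report)
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, default=float))


def summary_row(report: CVReport, p_value: float | None = None) -> dict:
    """One table row: Accuracy %, p, Sensitivity %, Specificity %,
    Sparsity % mean +- sd, Stability % mean +- sd."""
    def _pm(mean, sd, scale=100.0):
        if mean is None:
            return "-"
        return f"{scale * mean:.2f} ± {scale * sd:.2f}"

    return {
        "Features": report.feature_kind,
        "Penalty": report.penalty.upper(),
        "Accuracy (%)": round(report.accuracy, 2),
        "Accuracy p-value": p_value if p_value is not None else "-",
        "Sensitivity (%)": round(report.sensitivity, 2),
        "Specificity (%)": round(report.specificity, 2),
        "Sparsity (%)": _pm(report.sparsity_mean, report.sparsity_sd),
        "Stability (%)": _pm(report.stability_mean, report.stability_sd),
    }


# -- discriminative network -------------------------------------------------

def write_network(path_prefix, network) -> None:
    prefix = Path(path_prefix)
    network.edges.to_csv(prefix.with_suffix(".edges.tsv"), sep="\t",
                         index=False, float_format="%.12g")
    network.node_degrees.rename_axis("region").reset_index().to_csv(
        prefix.with_suffix(".degrees.tsv"), sep="\t", index=False)


def write_brainnet(path_prefix, network, coordinates: dict | None = None) -> None:
    """BrainNet Viewer ``.node``/``.edge`` pair for the significant edges.

    ``coordinates`` maps region label -> (x, y, z); regions without an entry
    are placed at the origin.
    """
    prefix = Path(path_prefix)
    sig = network.edges[network.edges["significant"]]
    regions = sorted(set(sig["region_i"]) | set(sig["region_j"]))
    coords = coordinates or {}
    deg = network.node_degrees
    with open(prefix.with_suffix(".node"), "w") as fh:
        for r in regions:
            x, y, z = coords.get(r, (0.0, 0.0, 0.0))
            fh.write(f"{x:.1f}\t{y:.1f}\t{z:.1f}\t1\t"
                     f"{int(deg.get(r, 0))}\t{r}\n")
    idx = {r: k for k, r in enumerate(regions)}
    M = np.zeros((len(regions), len(regions)))
    for _, row in sig.iterrows():
        a, b = idx[row["region_i"]], idx[row["region_j"]]
        M[a, b] = M[b, a] = row["weight"]
    np.savetxt(prefix.with_suffix(".edge"), M, fmt="%.6g", delimiter="\t")


# -- datasets ---------------------------------------------------------------

def write_dataset(out_dir, subjects: list[RawTimeSeries],
                  motions: dict[str, np.ndarray],
                  truth: GroundTruth | None = None) -> Path:
    """Write per-subject TSVs, motion files, a manifest and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        ts_path = out / f"{ts.subject_id}.tsv"
        write_timeseries_tsv(ts_path, ts)
        row = {"subject_id": ts.subject_id, "group": ts.group,
               "timeseries": ts_path.name, "tr_seconds": ts.tr_seconds}
        if ts.subject_id in motions:
            mo_path = out / f"rp_{ts.subject_id}.txt"
            np.savetxt(mo_path, motions[ts.subject_id], fmt="%.8g")
            row["motion"] = mo_path.name
        rows.append(row)
    write_manifest(out / "manifest.tsv", pd.DataFrame(rows))
    if truth is not None:
        write_ground_truth(out / "ground_truth.json", truth)
    return out / "manifest.tsv"


def write_ground_truth(path, truth: GroundTruth) -> None:
    d = {
        "precision_a": truth.precision_a.tolist(),
        "precision_b": truth.precision_b.tolist(),
        "base_support": [list(e) for e in truth.base_support],
        "planted_edges": [list(e) for e in truth.planted_edges],
        "spec": dataclasses.asdict(truth.spec),
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(np.array(d["precision_a"]), np.array(d["precision_b"]),
                       [tuple(e) for e in d["base_support"]],
                       [tuple(e) for e in d["planted_edges"]],
                       SimulationSpec(**d["spec"]))


def read_simulation_spec(path) -> SimulationSpec:
    """Simulation spec from a flat ``key = value`` text file (or JSON)."""
    text = Path(path).read_text()
    fields = {f.name: f.type for f in dataclasses.fields(SimulationSpec)}
    if text.lstrip().startswith("{"):
        return SimulationSpec(**json.loads(text))
    kv = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in fields:
            raise ValueError(f"unknown simulation parameter {key!r}")
        kv[key] = type(getattr(SimulationSpec(), key))(val.strip())
    return SimulationSpec(**kv)


def load_dataset(manifest_path, cutoff_seconds: float = 128.0,
                 dct_k: int | None = None,
                 preprocess: bool = True) -> StudyData:
    """Read a manifest, clean every subject and assemble a `StudyData`."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    cleaned: list[RegionalTimeSeries] = []
    for _, row in df.iterrows():
        tr = float(row.get("tr_seconds", 2.0))
        raw = read_timeseries_tsv(base / row["timeseries"], tr,
                                  row["subject_id"], int(row["group"]))
        motion = None
        if "motion" in row and isinstance(row["motion"], str) and row["motion"]:
            motion = read_motion_params(base / row["motion"])
        if preprocess:
            cleaned.append(clean_timeseries(raw, motion, cutoff_seconds, dct_k))
        else:
            cleaned.append(RegionalTimeSeries(raw.data - raw.data.mean(axis=0),
                                              tr, raw.subject_id, raw.group,
                                              ["centered"]))
    return StudyData.from_timeseries(cleaned)


def load_nifti_subject(image_path, parcellation_path, tr_seconds: float = 2.0,
                       subject_id: str = "", group: int = 0) -> RawTimeSeries:
    """Regional mean series from a 4-D NIfTI image and an integer label volume."""
    import nibabel as nib

    img = nib.load(str(image_path))
    labels = nib.load(str(parcellation_path))
    return regional_means(np.asanyarray(img.dataobj, dtype=float),
                          np.asanyarray(labels.dataobj).astype(int),
                          tr_seconds, subject_id or Path(image_path).stem,
                          group)
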