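"""Delimited-text and JSON input/output.

One documented dialect everywhere: comma-separated, header row, UTF-8.
Datasets are a manifest table (event_id, specimen_id, class_label, n_scans,
location_tag) plus one long scan table (event_id, scan_index, bin_index,
intensity). Models serialize to a single versioned JSON archive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureAnnotation
from .pcalda import PCALDAClassifier
from .simulate import EventDataset, SamplingEvent

__all__ = [
    "write_dataset", "read_dataset",
    "write_binned_matrix", "read_binned_matrix",
    "write_qc_log",
    "save_model", "load_model",
    "read_annotations", "write_annotations",
    "read_mzml_events",
]

MODEL_SCHEMA_VERSION = 1


def write_dataset(dataset: EventDataset, directory) -> tuple[Path, Path]:
    """Write manifest.csv and scans.csv for a dataset of sampling events."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    scan_frames = []
    for e in dataset.events:
        manifest_rows.append({"event_id": e.event_id,
                              "specimen_id": e.specimen_id,
                              "class_label": e.class_label,
                              "n_scans": e.n_scans,
                              "location_tag": e.location_tag})
        scans = np.asarray(e.scans, dtype=float)
        scan_idx, bin_idx = np.nonzero(scans)
        scan_frames.append(pd.DataFrame({
            "event_id": e.event_id,
            "scan_index": scan_idx,
            "bin_index": bin_idx,
            "intensity": scans[scan_idx, bin_idx],
        }))
    manifest_path = directory / "manifest.csv"
    scans_path = directory / "scans.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.concat(scan_frames, ignore_index=True).to_csv(scans_path, index=False)
    (directory / "meta.json").write_text(json.dumps({
        "n_bins": dataset.n_bins, "n_events": len(dataset.events)}))
    return manifest_path, scans_path


def read_dataset(directory) -> EventDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    scans = pd.read_csv(directory / "scans.csv")
    meta = json.loads((directory / "meta.json").read_text())
    n_bins = int(meta["n_bins"])
    grouped = {eid: g for eid, g in scans.groupby("event_id", sort=False)}
    events = []
    for row in manifest.itertuples(index=False):
        n_scans = int(row.n_scans)
        mat = np.zeros((n_scans, n_bins))
        g = grouped.get(row.event_id)
        if g is not None:
            mat[g["scan_index"].to_numpy(), g["bin_index"].to_numpy()] = \
                g["intensity"].to_numpy()
        events.append(SamplingEvent(
            event_id=str(row.event_id), specimen_id=str(row.specimen_id),
            class_label=str(row.class_label), scans=mat,
            location_tag="" if pd.isna(row.location_tag) else str(row.location_tag)))
    return EventDataset(events=events, n_bins=n_bins)


def write_binned_matrix(path, X, event_ids, labels=None, specimens=None) -> Path:
    """Events-by-bins matrix as delimited text with identifier columns."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(X, dtype=float),
                      columns=[f"bin_{i}" for i in range(np.asarray(X).shape[1])])
    df.insert(0, "event_id", event_ids)
    if labels is not None:
        df.insert(1, "class_label", labels)
    if specimens is not None:
        df.insert(1, "specimen_id", specimens)
    df.to_csv(path, index=False)
    return path


def read_binned_matrix(path):
    """Return (X, event_ids, labels, specimens); missing columns are None."""
    df = pd.read_csv(path)
    bins = [c for c in df.columns if c.startswith("bin_")]
    X = df[bins].to_numpy(dtype=float)
    labels = df["class_label"].to_numpy(dtype=str) if "class_label" in df else None
    specimens = df["specimen_id"].to_numpy(dtype=str) if "specimen_id" in df else None
    return X, df["event_id"].to_numpy(dtype=str), labels, specimens


def write_qc_log(path, qc_log: pd.DataFrame) -> Path:
    path = Path(path)
    qc_log.to_csv(path, index=False)
    return path


def save_model(model: PCALDAClassifier, path, config_hash: str | None = None) -> Path:
    """Serialize a fitted model to a versioned single-file JSON archive."""
    model._check_fitted()
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config_hash": config_hash,
        "params": model.get_params(),
        "classes": [str(c) for c in model.classes_],
        "n_features_in": int(model.n_features_in_),
        "feature_subset": None if model.feature_subset_ is None
        else model.feature_subset_.tolist(),
        "mean": model.mean_.tolist(),
        "pca_loadings": model.pca_loadings_.tolist(),
        "pca_eigenvalues": model.pca_eigenvalues_.tolist(),
        "total_variance": model.total_variance_,
        "ld_axes": model.ld_axes_.tolist(),
        "ld_eigenvalues": model.ld_eigenvalues_.tolist(),
        "n_pc": int(model.n_pc_),
        "n_ld": int(model.n_ld_),
        "centroids": model.centroids_.tolist(),
        "covariances": [c.tolist() for c in model.covariances_],
        "priors": model.priors_.tolist(),
        "training_summary": model.training_summary_,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model(path) -> PCALDAClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {doc.get('schema_version')}")
    params = doc["params"]
    if params.get("feature_subset") is not None:
        params["feature_subset"] = list(params["feature_subset"])
    model = PCALDAClassifier(**params)
    model.classes_ = np.array(doc["classes"])
    model.n_features_in_ = int(doc["n_features_in"])
    model.feature_subset_ = None if doc["feature_subset"] is None \
        else np.array(doc["feature_subset"], dtype=int)
    model.mean_ = np.array(doc["mean"])
    model.pca_loadings_ = np.array(doc["pca_loadings"])
    model.pca_eigenvalues_ = np.array(doc["pca_eigenvalues"])
    model.total_variance_ = float(doc["total_variance"])
    model.ld_axes_ = np.array(doc["ld_axes"])
    model.ld_eigenvalues_ = np.array(doc["ld_eigenvalues"])
    model.n_pc_ = int(doc["n_pc"])
    model.n_ld_ = int(doc["n_ld"])
    model.centroids_ = np.array(doc["centroids"])
    model.covariances_ = [np.array(c) for c in doc["covariances"]]
    model._chol = [np.linalg.cholesky(c) for c in model.covariances_]
    model.log_dets_ = np.array([2.0 * float(np.sum(np.log(np.diag(L))))
                                for L in model._chol])
    model.priors_ = np.array(doc["priors"])
    model.training_summary_ = doc["training_summary"]
    return model


def write_annotations(path, annotations) -> Path:
    path = Path(path)
    pd.DataFrame([{"bin_index": a.bin_index,
                   "representative_mz": a.representative_mz,
                   "status": a.status, "note": a.note}
                  for a in annotations]).to_csv(path, index=False)
    return path


def read_annotations(path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        mz = None if pd.isna(row.representative_mz) else float(row.representative_mz)
        out.append(FeatureAnnotation(bin_index=int(row.bin_index),
                                     representative_mz=mz,
                                     status=str(row.status),
                                     note="" if pd.isna(row.note) else str(row.note)))
    return out


def read_mzml_events(path, binning, manifest: pd.DataFrame) -> EventDataset:
    """Optional mzML reader: each spectrum maps to one scan.

    The manifest assigns consecutive spectra to events through its n_scans
    column (same manifest dialect as :func:`write_dataset`).
    """
    from pyteomics import mzml  # deferred: only needed for mzML input

    from .preprocessing import bin_spectrum

    spectra = []
    with mzml.read(str(path)) as reader:
        for spec in reader:
            peaks = np.column_stack([spec["m/z array"], spec["intensity array"]])
            spectra.append(bin_spectrum(peaks, binning).values)
    events = []
    cursor = 0
    for row in manifest.itertuples(index=False):
        n = int(row.n_scans)
        chunk = spectra[cursor:cursor + n]
        cursor += n
        if len(chunk) < n:
            raise ValueError("mzML file has fewer spectra than the manifest "
                             "n_scans total")
        events.append(SamplingEvent(
            event_id=str(row.event_id), specimen_id=str(row.specimen_id),
            class_label=str(row.class_label), scans=np.vstack(chunk),
            location_tag=getattr(row, "location_tag", "") or ""))
    return EventDataset(events=events, n_bins=binning.n_bins)
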