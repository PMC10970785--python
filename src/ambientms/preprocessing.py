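"""Binning, quality control and normalization of sampling-event spectra.

Raw per-scan peak lists are collapsed into fixed-width m/z bins (default
100 mDa), summed into one fingerprint per sampling event, passed through
label-blind quality checkpoints (minimum scan count, raw-intensity floor,
optional expected-peak and replicate-similarity checks) and normalized.
QC always runs on pre-normalization intensities: the >1e3 intensity floor
is a raw-signal criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import EventDataset, SamplingEvent

__all__ = [
    "BinningSpec",
    "QCCriteria",
    "BinnedSpectrum",
    "bin_spectrum",
    "aggregate_event",
    "qc_filter",
    "normalize",
    "normalize_matrix",
    "replicate_similarity",
    "PreparedData",
    "prepare_dataset",
]

#: pseudocount added before log transforms, small enough not to distort
#: non-zero bins at typical intensity scales
LOG_EPSILON = 1e-9


@dataclass(frozen=True)
class BinningSpec:
    """Fixed-width, half-open, left-closed m/z bins anchored at ``mz_min``."""

    mz_min: float = 100.0
    mz_max: float = 1000.0
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.mz_max - self.mz_min) / self.bin_width))

    def bin_index(self, mz) -> np.ndarray:
        return np.floor((np.asarray(mz, dtype=float) - self.mz_min)
                        / self.bin_width).astype(int)

    def bin_center(self, index) -> np.ndarray:
        return self.mz_min + (np.asarray(index, dtype=float) + 0.5) * self.bin_width


@dataclass(frozen=True)
class QCCriteria:
    """Label-blind data-quality checkpoints applied to every event.

    ``min_total_intensity`` applies to the summed raw event TIC over all
    scans (per-event interpretation; set ``per_scan=True`` for the stricter
    per-scan reading).
    """

    min_scans: int = 3
    min_total_intensity: float = 1e3
    per_scan: bool = False
    required_bins: tuple[int, ...] | None = None
    min_cosine: float | None = None
    max_cv: float | None = None

    def __post_init__(self) -> None:
        if self.min_scans < 1:
            raise ValueError("min_scans must be >= 1")
        if self.min_total_intensity < 0:
            raise ValueError("min_total_intensity must be >= 0")
        if self.min_cosine is not None and not 0.0 <= self.min_cosine <= 1.0:
            raise ValueError("min_cosine must lie in [0, 1]")


@dataclass
class BinnedSpectrum:
    """Intensity-per-bin vector plus its binning and normalization state."""

    values: np.ndarray
    binning: BinningSpec | None = None
    normalization: str = "none"
    event_id: str | None = None
    dropped_peaks: int = 0  # out-of-range peaks discarded during binning

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[0])

    def total_intensity(self) -> float:
        return float(self.values.sum())


def bin_spectrum(peaks, spec: BinningSpec, event_id: str | None = None) -> BinnedSpectrum:
    """Collapse a peak list into fixed-width bins.

    ``peaks`` is an (n, 2) array-like of (m/z, intensity). Bin index is
    floor((mz - mz_min)/width); co-binned intensities are summed, so total
    in-range intensity is conserved. Out-of-range peaks are dropped and
    counted, not raised.
    """
    values = np.zeros(spec.n_bins)
    peaks = np.asarray(peaks, dtype=float).reshape(-1, 2)
    if peaks.shape[0] == 0:
        return BinnedSpectrum(values=values, binning=spec, event_id=event_id)
    idx = spec.bin_index(peaks[:, 0])
    in_range = (idx >= 0) & (idx < spec.n_bins)
    np.add.at(values, idx[in_range], peaks[in_range, 1])
    return BinnedSpectrum(values=values, binning=spec, event_id=event_id,
                          dropped_peaks=int((~in_range).sum()))


def aggregate_event(event: SamplingEvent, spec: BinningSpec | None = None) -> BinnedSpectrum:
    """Sum an event's scans bin-wise into one fingerprint (one data point
    per sampling event).

    Scans stored as binned vectors are summed directly; scans stored as
    (m/z, intensity) peak lists are binned first (``spec`` required).
    """
    if event.n_scans < 1:
        raise ValueError(f"event {event.event_id} has no scans")
    scans = event.scans
    if isinstance(scans, np.ndarray) and scans.ndim == 2 and (
            spec is None or scans.shape[1] == spec.n_bins):
        return BinnedSpectrum(values=scans.sum(axis=0), binning=spec,
                              event_id=event.event_id)
    if spec is None:
        raise ValueError("peak-list scans require a BinningSpec")
    total = np.zeros(spec.n_bins)
    dropped = 0
    for scan in scans:
        b = bin_spectrum(scan, spec)
        total += b.values
        dropped += b.dropped_peaks
    return BinnedSpectrum(values=total, binning=spec, event_id=event.event_id,
                          dropped_peaks=dropped)


def qc_filter(event: SamplingEvent, binned: BinnedSpectrum,
              criteria: QCCriteria = QCCriteria()) -> tuple[str, tuple[str, ...]]:
    """Evaluate the quality checkpoints for one event.

    Returns ("pass" | "fail", reasons); reasons list every violated
    criterion. Never raises on data content — QC is an accounting step and
    every attempt is logged for duty-cycle calculation.
    """
    reasons: list[str] = []
    if event.n_scans < criteria.min_scans:
        reasons.append("min_scans")
    if criteria.per_scan:
        scan_tics = np.asarray(event.scans).sum(axis=1)
        low = bool((scan_tics <= criteria.min_total_intensity).any())
    else:
        low = binned.total_intensity() <= criteria.min_total_intensity
    if low:
        reasons.append("min_total_intensity")
    if criteria.required_bins:
        if np.any(binned.values[list(criteria.required_bins)] == 0):
            reasons.append("required_bins")
    if (criteria.min_cosine is not None or criteria.max_cv is not None) \
            and event.n_scans >= 2:
        scans = np.asarray(event.scans, dtype=float)
        replicates = [BinnedSpectrum(values=s, binning=binned.binning) for s in scans]
        cosine, cv = replicate_similarity(replicates)
        if criteria.min_cosine is not None and cosine < criteria.min_cosine:
            reasons.append("min_cosine")
        if criteria.max_cv is not None and cv > criteria.max_cv:
            reasons.append("max_cv")
    return ("fail" if reasons else "pass"), tuple(reasons)


def _normalize_vector(values: np.ndarray, method: str,
                      reference: np.ndarray | None) -> np.ndarray:
    if method == "none":
        return values.copy()
    if method == "tic":
        total = values.sum()
        if total <= 0:
            raise ValueError("cannot TIC-normalize an all-zero spectrum")
        return values / total
    if method == "nonzero_median":
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return values / np.median(positive)
    if method == "median_fold_change":
        if reference is None:
            raise ValueError("median_fold_change requires a reference spectrum")
        mask = (reference > 0) & (values > 0)
        if not mask.any():
            raise ValueError("no shared non-zero bins with the reference")
        fold = np.median(values[mask] / reference[mask])
        return np.log(values / fold + LOG_EPSILON)
    raise ValueError(f"unknown normalization method: {method!r}")


def normalize(binned: BinnedSpectrum, method: str = "tic",
              reference: BinnedSpectrum | None = None) -> BinnedSpectrum:
    """Return a normalized copy of a binned spectrum.

    tic: divide by total ion intensity (result sums to 1).
    nonzero_median: divide by the median of strictly positive bins.
    median_fold_change: divide by the median fold ratio to the reference
    (typically the dataset median spectrum), then log-transform.
    """
    ref = reference.values if reference is not None else None
    out = _normalize_vector(np.asarray(binned.values, dtype=float), method, ref)
    return replace(binned, values=out, normalization=method)


def normalize_matrix(X: np.ndarray, method: str = "tic",
                     reference: np.ndarray | None = None) -> np.ndarray:
    """Row-wise normalization of an events x bins intensity matrix."""
    X = np.asarray(X, dtype=float)
    if method == "none":
        return X.copy()
    return np.vstack([_normalize_vector(row, method, reference) for row in X])


def replicate_similarity(replicates) -> tuple[float, float]:
    """Mean pairwise cosine similarity and median per-bin CV of replicates.

    CV = SD/mean per bin over replicates, summarized as the median over bins
    with non-zero mean; cosine lies in [0, 1] for nonnegative spectra.
    """
    vectors = [np.asarray(r.values if isinstance(r, BinnedSpectrum) else r,
                          dtype=float) for r in replicates]
    if len(vectors) < 2:
        raise ValueError("replicate_similarity needs >= 2 replicates")
    M = np.vstack(vectors)
    norms = np.linalg.norm(M, axis=1)
    cosines = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            denom = norms[i] * norms[j]
            cosines.append(float(M[i] @ M[j] / denom) if denom > 0 else 0.0)
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    nz = mean != 0
    median_cv = float(np.median(sd[nz] / mean[nz])) if nz.any() else 0.0
    return float(np.mean(cosines)), median_cv


@dataclass
class PreparedData:
    """QC-filtered event fingerprints ready for modeling.

    ``X`` holds raw (pre-normalization) aggregated intensities for passing
    events; normalization belongs to the model pipeline so that sparse
    re-fits can re-normalize within their restricted bin set.
    """

    X: np.ndarray               # (n_pass, n_bins) raw binned fingerprints
    y: np.ndarray               # class labels per passing event
    specimens: np.ndarray
    event_ids: np.ndarray
    qc_log: pd.DataFrame        # every attempt: event_id, status, reasons
    n_total: int

    @property
    def n_pass(self) -> int:
        return int(self.X.shape[0])


def prepare_dataset(dataset: EventDataset,
                    criteria: QCCriteria = QCCriteria(),
                    binning: BinningSpec | None = None) -> PreparedData:
    """Aggregate, QC-filter and tabulate a dataset of sampling events.

    All attempts are logged (event_id, specimen, class, n_scans, TIC, status,
    reasons) so duty-cycle accounting can include QC exclusions.
    """
    rows = []
    kept_values, kept_y, kept_spec, kept_ids = [], [], [], []
    for event in dataset.events:
        binned = aggregate_event(event, binning)
        status, reasons = qc_filter(event, binned, criteria)
        event.qc_status = status
        event.qc_reasons = reasons
        rows.append({"event_id": event.event_id,
                     "specimen_id": event.specimen_id,
                     "class_label": event.class_label,
                     "n_scans": event.n_scans,
                     "total_intensity": binned.total_intensity(),
                     "qc_status": status,
                     "qc_reasons": ";".join(reasons)})
        if status == "pass":
            kept_values.append(binned.values)
            kept_y.append(event.class_label)
            kept_spec.append(event.specimen_id)
            kept_ids.append(event.event_id)
    X = np.vstack(kept_values) if kept_values else np.zeros((0, dataset.n_bins))
    return PreparedData(X=X, y=np.array(kept_y), specimens=np.array(kept_spec),
                        event_ids=np.array(kept_ids),
                        qc_log=pd.DataFrame(rows), n_total=len(dataset.events))
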