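"""Loading-plot feature shortlisting, annotation-based exclusion and
sparse model re-fitting.

A fitted model ranks bins by their contribution to class discrimination;
the top of that list (default 100) is carried to offline identification.
Annotations are an input table — identification itself (MS2, database
lookup) happens outside this package. Features flagged as artifacts (for
example an exogenous contaminant that discriminates classes for
non-biological reasons) are never allowed into a sparse model; the sparse
re-fit restricts the pipeline, including normalization, to the retained
bins, which makes it insensitive to whatever happens in excluded bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pcalda import PCALDAClassifier, loading_ranks

__all__ = [
    "FeatureAnnotation",
    "select_top_features",
    "apply_annotations",
    "fit_sparse",
    "representative_mz",
]

IDENTIFIED = "identified_biological"
UNIDENTIFIED = "unidentified"
FLAGGED = "flagged_artifact"
_STATUSES = (IDENTIFIED, UNIDENTIFIED, FLAGGED)


@dataclass(frozen=True)
class FeatureAnnotation:
    """Offline identity/provenance call for one bin."""

    bin_index: int
    representative_mz: float | None = None
    status: str = UNIDENTIFIED
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown annotation status: {self.status!r}")


def select_top_features(model: PCALDAClassifier, n: int = 100):
    """Top-n bins by discrimination importance, rank order preserved.

    Ties in importance break by ascending bin index; deterministic given
    the model.
    """
    ranks = loading_ranks(model)
    if n > len(ranks):
        raise ValueError(f"requested {n} features but the model has only "
                         f"{len(ranks)} bins")
    return ranks[:n]


def apply_annotations(features, annotations, keep: str = "all_unflagged",
                      strict: bool = True):
    """Filter a ranked feature list through annotations.

    keep="identified_only" retains bins annotated identified_biological;
    keep="all_unflagged" drops only flagged_artifact bins. Flagged bins are
    removed under both policies. Rank order is preserved. In strict mode an
    annotation referencing a bin absent from the feature list raises; with
    strict=False such annotations are ignored (useful when one annotation
    table serves several shortlists).
    """
    if keep not in ("identified_only", "all_unflagged"):
        raise ValueError(f"unknown keep policy: {keep!r}")
    bins = [int(b) for b, _ in features]
    bin_set = set(bins)
    status_by_bin: dict[int, str] = {}
    for ann in annotations:
        if ann.bin_index not in bin_set:
            if strict:
                raise ValueError(
                    f"annotation references unknown bin {ann.bin_index}")
            continue
        status_by_bin[int(ann.bin_index)] = ann.status
    retained = []
    for b, imp in features:
        status = status_by_bin.get(int(b), UNIDENTIFIED)
        if status == FLAGGED:
            continue
        if keep == "identified_only" and status != IDENTIFIED:
            continue
        retained.append((int(b), imp))
    return retained


def fit_sparse(X, y, retained_features, specimens=None,
               **model_params) -> PCALDAClassifier:
    """Re-fit the PCA-LDA pipeline on a retained bin subset.

    The identical pipeline runs on the reduced bin set: normalization is
    recomputed within the subset and the PC cap re-derives from the reduced
    dimensionality. ``retained_features`` is a sequence of bin indices or of
    (bin, importance) pairs.
    """
    bins = [int(f[0]) if isinstance(f, (tuple, list)) else int(f)
            for f in retained_features]
    if len(bins) < 2:
        raise ValueError("sparse analysis needs at least 2 retained features")
    subset = sorted({int(b) for b in bins})
    model = PCALDAClassifier(feature_subset=subset, **model_params)
    return model.fit(X, y, specimens=specimens)


def representative_mz(bin_index: int, binning=None, peaks=None) -> float | None:
    """Human-readable m/z for a bin.

    With per-peak training data, the intensity-weighted mean m/z of peaks
    falling in the bin; otherwise the bin centre from the binning spec.
    """
    if peaks is not None and binning is not None:
        peaks = np.asarray(peaks, dtype=float).reshape(-1, 2)
        idx = binning.bin_index(peaks[:, 0])
        mask = idx == bin_index
        weight = peaks[mask, 1].sum()
        if weight > 0:
            return float((peaks[mask, 0] * peaks[mask, 1]).sum() / weight)
    if binning is not None:
        return float(binning.bin_center(bin_index))
    return None
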