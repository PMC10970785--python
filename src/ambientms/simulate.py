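"""Seeded synthetic generator for ambient-MS sampling-event datasets.

The generator emulates the statistical structure that the modeling workflow
assumes: a common baseline fingerprint, sparse class-specific intensity
offsets (inter-class variance), specimen-level random effects (intra-class
variance), event-level noise, optional poor-quality events that violate the
QC defaults, and an optional high-intensity contaminant confined to a subset
of classes. Fingerprints are generated directly in binned space; per-peak
(m/z, intensity) export assigns bin-centre m/z values.

Noise is additive truncated normal (clipped at zero). The baseline is kept
roughly ten noise SDs above zero so clipping is negligible and the nominal
variance components are recovered empirically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SyntheticConfig",
    "SamplingEvent",
    "EventDataset",
    "generate_dataset",
    "scenario_preset",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the hierarchical fingerprint generator.

    ``class_separation`` is the Euclidean distance between any two class mean
    fingerprints expressed in units of ``event_sd`` (event-level noise SD per
    bin). ``specimen_sd`` and ``event_sd`` are intensity-unit SDs of the
    specimen random effect and the per-event noise.
    """

    n_classes: int = 3
    specimens_per_class: int = 10
    events_per_specimen: int = 44
    scans_per_event: int = 10
    n_bins: int = 500
    class_separation: float = 6.0
    specimen_sd: float = 4.0
    event_sd: float = 5.0
    baseline_intensity: float = 50.0
    informative_fraction: float = 0.1
    poor_quality_fraction: float = 0.0
    contaminant_bin: int | None = None
    contaminant_classes: tuple[str, ...] = ()
    contaminant_intensity: float = 30000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "specimens_per_class", "events_per_specimen",
                     "scans_per_event", "n_bins"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("class_separation", "specimen_sd", "event_sd",
                     "baseline_intensity", "contaminant_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.poor_quality_fraction <= 1.0:
            raise ValueError("poor_quality_fraction must lie in [0, 1]")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if self.contaminant_bin is not None and not (
                0 <= self.contaminant_bin < self.n_bins):
            raise ValueError("contaminant_bin must be < n_bins")
        unknown = set(self.contaminant_classes) - set(self.class_labels())
        if unknown:
            raise ValueError(f"unknown contaminant classes: {sorted(unknown)}")

    def class_labels(self) -> list[str]:
        return [f"class_{chr(ord('A') + i)}" for i in range(self.n_classes)]

    @property
    def n_events(self) -> int:
        return self.n_classes * self.specimens_per_class * self.events_per_specimen


@dataclass
class SamplingEvent:
    """One probe interrogation: a short stack of per-scan binned spectra."""

    event_id: str
    specimen_id: str
    class_label: str
    scans: np.ndarray  # (n_scans, n_bins) nonnegative intensities
    location_tag: str = ""
    qc_status: str = "untested"  # untested | pass | fail
    qc_reasons: tuple[str, ...] = ()

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def n_bins(self) -> int:
        if isinstance(self.scans, np.ndarray) and self.scans.ndim == 2:
            return int(self.scans.shape[1])
        raise AttributeError("peak-list scans have no fixed bin count")

    def total_intensity(self) -> float:
        if isinstance(self.scans, np.ndarray):
            return float(self.scans.sum())
        return float(sum(i for scan in self.scans for _, i in scan))


@dataclass
class EventDataset:
    """A generated (or loaded) collection of sampling events.

    ``informative_bins`` maps each class label to the bins carrying that
    class's mean offset (ground truth for feature-selection tests); it is
    ``None`` for datasets read back from disk.
    """

    events: list[SamplingEvent]
    n_bins: int
    config: SyntheticConfig | None = None
    class_means: dict[str, np.ndarray] | None = None
    informative_bins: dict[str, np.ndarray] | None = None
    baseline: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.events)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.class_label for e in self.events])

    @property
    def specimens(self) -> np.ndarray:
        return np.array([e.specimen_id for e in self.events])

    @property
    def event_ids(self) -> np.ndarray:
        return np.array([e.event_id for e in self.events])

    def relabelled(self, labels) -> "EventDataset":
        """Copy of the dataset with per-event class labels replaced."""
        labels = list(labels)
        if len(labels) != len(self.events):
            raise ValueError("label count does not match event count")
        events = [replace(e, class_label=str(lab))
                  for e, lab in zip(self.events, labels)]
        return EventDataset(events=events, n_bins=self.n_bins, config=self.config,
                            class_means=None, informative_bins=None,
                            baseline=self.baseline)


def _class_offsets(cfg: SyntheticConfig, rng: np.random.Generator):
    """Sparse nonnegative per-class mean offsets on disjoint bin sets.

    Offsets are scaled so that every pairwise distance between class means
    equals class_separation * event_sd exactly.
    """
    labels = cfg.class_labels()
    pool_size = min(cfg.n_bins,
                    max(cfg.n_classes, round(cfg.informative_fraction * cfg.n_bins)))
    per_class = max(1, pool_size // cfg.n_classes)
    pool = rng.choice(cfg.n_bins, size=per_class * cfg.n_classes, replace=False)
    informative: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    target = cfg.class_separation * cfg.event_sd / math.sqrt(2.0)
    for i, lab in enumerate(labels):
        bins = np.sort(pool[i * per_class:(i + 1) * per_class])
        raw = rng.uniform(0.5, 1.5, size=per_class)
        norm = np.linalg.norm(raw)
        vec = np.zeros(cfg.n_bins)
        if norm > 0 and target > 0:
            vec[bins] = raw * (target / norm)
        informative[lab] = bins
        offsets[lab] = vec
    return informative, offsets


def generate_dataset(config: SyntheticConfig) -> EventDataset:
    """Draw a full dataset of sampling events under the hierarchical model.

    Event fingerprint = class mean + specimen effect + event noise, clipped
    at zero; scans partition the fingerprint so that per-scan noise sums to
    the event-level noise SD. Identical config (including seed) gives
    bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mu = math.log(cfg.baseline_intensity) - 0.125 if cfg.baseline_intensity > 0 else 0.0
    baseline = rng.lognormal(mean=mu, sigma=0.5, size=cfg.n_bins) \
        if cfg.baseline_intensity > 0 else np.zeros(cfg.n_bins)
    informative, offsets = _class_offsets(cfg, rng)

    events: list[SamplingEvent] = []
    class_means: dict[str, np.ndarray] = {}
    n_scans_nominal = cfg.scans_per_event
    scan_sd = cfg.event_sd / math.sqrt(n_scans_nominal)
    for lab in cfg.class_labels():
        mean_c = baseline + offsets[lab]
        if cfg.contaminant_bin is not None and lab in cfg.contaminant_classes:
            mean_c = mean_c.copy()
            mean_c[cfg.contaminant_bin] += cfg.contaminant_intensity
        class_means[lab] = mean_c
        for s in range(cfg.specimens_per_class):
            specimen_id = f"{lab}_sp{s:02d}"
            spec_eff = rng.normal(0.0, cfg.specimen_sd, size=cfg.n_bins)
            for e in range(cfg.events_per_specimen):
                poor = rng.random() < cfg.poor_quality_fraction
                mean_event = mean_c + spec_eff
                if poor:
                    # Below both QC defaults: < 3 scans and TIC <= 1e3.
                    n_scans = int(rng.integers(1, 3))
                    total = float(mean_event.sum())
                    scale = (400.0 / total) if total > 0 else 0.0
                    per_scan_mean = scale * mean_event / n_scans
                    noise = rng.normal(0.0, scale * scan_sd + 1e-12,
                                       size=(n_scans, cfg.n_bins))
                else:
                    n_scans = n_scans_nominal
                    per_scan_mean = mean_event / n_scans
                    noise = rng.normal(0.0, scan_sd, size=(n_scans, cfg.n_bins))
                scans = np.clip(per_scan_mean[None, :] + noise, 0.0, None)
                loc = f"x{rng.integers(0, 100):02d}y{rng.integers(0, 100):02d}"
                events.append(SamplingEvent(
                    event_id=f"{specimen_id}_e{e:03d}",
                    specimen_id=specimen_id,
                    class_label=lab,
                    scans=scans,
                    location_tag=loc,
                ))
    return EventDataset(events=events, n_bins=cfg.n_bins, config=cfg,
                        class_means=class_means, informative_bins=informative,
                        baseline=baseline)


#: Documented scenario presets exercised throughout the test battery.
SCENARIO_NAMES = ("distinct_classes", "pseudo_class_single_tissue",
                  "contaminated", "heterogeneous")


def scenario_preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Fixed study-condition presets.

    distinct_classes
        Three well-separated classes with modest specimen effects — the
        regime of a multi-organ demonstration model (high CV accuracy,
        saturating learning curve). Shaped like a three-organ study: 10
        independent specimens per class, ~44 sampling events each.
    pseudo_class_single_tissue
        One homogeneous class (~410 events from 10 specimens) intended to be
        relabelled into pseudo-classes downstream; chance-level baseline.
    contaminated
        distinct_classes-like biology plus a dominant exogenous contaminant
        bin present in one class only — the false-discovery scenario.
    heterogeneous
        Large specimen-level variance relative to class separation; the hard,
        molecularly similar regime.
    """
    if name == "distinct_classes":
        return SyntheticConfig(n_classes=3, specimens_per_class=10,
                               events_per_specimen=44, class_separation=6.0,
                               specimen_sd=4.0, event_sd=5.0, seed=seed)
    if name == "pseudo_class_single_tissue":
        return SyntheticConfig(n_classes=1, specimens_per_class=10,
                               events_per_specimen=41, class_separation=0.0,
                               specimen_sd=4.0, event_sd=5.0, seed=seed)
    if name == "contaminated":
        return SyntheticConfig(n_classes=3, specimens_per_class=10,
                               events_per_specimen=22, class_separation=6.0,
                               specimen_sd=4.0, event_sd=5.0,
                               contaminant_bin=450,
                               contaminant_classes=("class_A",),
                               contaminant_intensity=30000.0, seed=seed)
    if name == "heterogeneous":
        return SyntheticConfig(n_classes=3, specimens_per_class=20,
                               events_per_specimen=11, class_separation=3.0,
                               specimen_sd=8.0, event_sd=5.0, seed=seed)
    raise ValueError(f"unknown scenario preset: {name!r}")
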