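"""Parametric representation of the identification pipeline.

Every stage of the pipeline — channel selection, common average referencing,
Butterworth band-pass filtering, overlapped segmentation, Burg AR feature
extraction and classification — is driven by a single validated
:class:`PipelineConfig`.  A configuration sweep over (filter order,
frequency sub-band) pairs is described by :class:`SweepSpec`; expanding a
sweep yields one configuration per grid cell, each with a stable id, so
that downstream results can always be traced back to the parameters that
produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "STANDARD_19_CHANNELS",
    "CANONICAL_BANDS",
    "ClassifierSpec",
    "PipelineConfig",
    "SweepSpec",
    "ConfigError",
    "load_config",
    "expand_sweep",
    "config_id",
]

#: Conventional 19-electrode subset of the 10-20 system.
STANDARD_19_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Named canonical EEG frequency bands (Hz).
CANONICAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

_CLASSIFIER_KINDS = ("knn", "naive_bayes", "decision_tree", "lda")
_FILTER_VARIANTS = ("causal", "zero_phase")


class ConfigError(ValueError):
    """A configuration file or object violates an invariant."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier closes the pipeline.

    ``neighbors`` and ``distance`` only apply to ``kind='knn'``.
    """

    kind: str = "knn"
    neighbors: int = 1
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.kind not in _CLASSIFIER_KINDS:
            raise ConfigError(
                f"classifier.kind must be one of {_CLASSIFIER_KINDS}, got {self.kind!r}"
            )
        if self.distance != "euclidean":
            raise ConfigError(f"classifier.distance must be 'euclidean', got {self.distance!r}")
        if int(self.neighbors) < 1:
            raise ConfigError(f"classifier.neighbors must be >= 1, got {self.neighbors}")


@dataclass(frozen=True)
class PipelineConfig:
    """All input parameters of the identification pipeline, in processing order.

    Parameters
    ----------
    channel_set
        Ordered channel labels (H channels); CAR needs at least two.
    filter_order
        Butterworth filter order ``O``.
    band
        Pass band ``(low, high)`` in Hz, strictly inside (0, Nyquist).
    filter_variant
        ``'causal'`` (single forward pass) or ``'zero_phase'``
        (forward-backward application of the same design).
    sampling_rate
        Sampling frequency ``fs`` in Hz.
    segment_length
        Segment duration ``v`` in seconds.
    overlap
        Overlap fraction ``alpha`` in [0, 1).
    ar_order
        AR model order ``Q``; the feature dimension is ``d = H * Q``.
    classifier
        Classifier specification.
    kfold
        Number of cross-validation folds.
    duration
        Recording duration ``V`` in seconds.
    car_over_selected
        If True (default) the common average is computed over the selected
        channel set; if False it is computed over all channels present in
        the recording before selection.
    """

    channel_set: tuple[str, ...] = STANDARD_19_CHANNELS
    filter_order: int = 2
    band: tuple[float, float] = CANONICAL_BANDS["gamma"]
    filter_variant: str = "causal"
    sampling_rate: float = 160.0
    segment_length: float = 5.0
    overlap: float = 0.4
    ar_order: int = 12
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    kfold: int = 3
    duration: float = 60.0
    car_over_selected: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_set", tuple(self.channel_set))
        object.__setattr__(self, "band", (float(self.band[0]), float(self.band[1])))
        if len(self.channel_set) < 2:
            raise ConfigError("channel_set: need H >= 2 channels (common average undefined)")
        if len(set(self.channel_set)) != len(self.channel_set):
            raise ConfigError("channel_set: duplicate channel labels")
        if int(self.filter_order) < 1:
            raise ConfigError(f"filter_order must be >= 1, got {self.filter_order}")
        if self.filter_variant not in _FILTER_VARIANTS:
            raise ConfigError(
                f"filter_variant must be one of {_FILTER_VARIANTS}, got {self.filter_variant!r}"
            )
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be positive, got {self.sampling_rate}")
        low, high = self.band
        nyquist = self.sampling_rate / 2.0
        if not (0.0 < low < high):
            raise ConfigError(f"band: need 0 < low < high, got ({low}, {high})")
        if high >= nyquist:
            raise ConfigError(
                f"band: high edge {high} Hz must be below the Nyquist frequency {nyquist} Hz"
            )
        if not (0.0 < self.segment_length <= self.duration):
            raise ConfigError(
                f"segment_length must satisfy 0 < v <= duration "
                f"({self.segment_length} vs {self.duration})"
            )
        if not (0.0 <= self.overlap < 1.0):
            raise ConfigError(f"overlap must lie in [0, 1), got {self.overlap}")
        if int(self.ar_order) < 1:
            raise ConfigError(f"ar_order must be >= 1, got {self.ar_order}")
        if int(self.kfold) < 2:
            raise ConfigError(f"kfold must be >= 2, got {self.kfold}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_set)

    @property
    def feature_dim(self) -> int:
        """d = H * Q."""
        return self.n_channels * self.ar_order

    def to_dict(self) -> dict:
        return {
            "channel_set": list(self.channel_set),
            "filter_order": int(self.filter_order),
            "band_hz": [self.band[0], self.band[1]],
            "filter_variant": self.filter_variant,
            "sampling_rate_hz": float(self.sampling_rate),
            "segment_length_s": float(self.segment_length),
            "overlap_fraction": float(self.overlap),
            "ar_order": int(self.ar_order),
            "classifier": {
                "kind": self.classifier.kind,
                "neighbors": int(self.classifier.neighbors),
                "distance": self.classifier.distance,
            },
            "kfold": int(self.kfold),
            "duration_s": float(self.duration),
            "car_over_selected": bool(self.car_over_selected),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {
            "channel_set", "filter_order", "band_hz", "filter_variant",
            "sampling_rate_hz", "segment_length_s", "overlap_fraction",
            "ar_order", "classifier", "kfold", "duration_s", "car_over_selected",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline field(s): {sorted(unknown)}")
        kwargs = {}
        if "classifier" in data:
            c = dict(data.pop("classifier"))
            unknown_c = set(c) - {"kind", "neighbors", "distance"}
            if unknown_c:
                raise ConfigError(f"unknown classifier field(s): {sorted(unknown_c)}")
            kwargs["classifier"] = ClassifierSpec(**c)
        rename = {
            "band_hz": "band",
            "sampling_rate_hz": "sampling_rate",
            "segment_length_s": "segment_length",
            "overlap_fraction": "overlap",
            "duration_s": "duration",
        }
        for key, value in data.items():
            kwargs[rename.get(key, key)] = value
        if "band" in kwargs:
            kwargs["band"] = tuple(kwargs["band"])
        return cls(**kwargs)


def _parse_band(entry) -> tuple[float, float]:
    if isinstance(entry, str):
        if entry not in CANONICAL_BANDS:
            raise ConfigError(
                f"unknown band name {entry!r}; known: {sorted(CANONICAL_BANDS)}"
            )
        return CANONICAL_BANDS[entry]
    low, high = entry
    return (float(low), float(high))


@dataclass(frozen=True)
class SweepSpec:
    """Grid of target parameters: filter orders S1 and sub-bands S2."""

    orders: tuple[int, ...]
    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "orders", tuple(int(o) for o in self.orders))
        object.__setattr__(self, "bands", tuple(_parse_band(b) for b in self.bands))
        if not self.orders or not self.bands:
            raise ConfigError("sweep: orders and bands must be non-empty")
        if len(set(self.orders)) != len(self.orders):
            raise ConfigError("sweep: duplicate filter orders")
        if len(set(self.bands)) != len(self.bands):
            raise ConfigError("sweep: duplicate bands")

    @property
    def size(self) -> int:
        return len(self.orders) * len(self.bands)


def config_id(order: int, band: tuple[float, float]) -> str:
    """Stable id for one (filter order, band) grid cell, e.g. ``o2_b30-50``."""

    def fmt(x: float) -> str:
        return f"{x:g}".replace(".", "p")

    return f"o{int(order)}_b{fmt(band[0])}-{fmt(band[1])}"


def expand_sweep(base: PipelineConfig, sweep: SweepSpec) -> list[PipelineConfig]:
    """All grid configurations, order-major then band, differing from
    ``base`` only in (filter_order, band)."""
    configs = []
    for order in sweep.orders:
        for band in sweep.bands:
            configs.append(replace(base, filter_order=order, band=band))
    return configs


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a pipeline configuration from a YAML file.

    The file may either contain the pipeline fields at the top level or
    nest them under a ``pipeline`` key (the layout used by full-run files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    if "pipeline" in data:
        data = data["pipeline"]
    return PipelineConfig.from_dict(data)


def load_sweep(data: dict) -> SweepSpec:
    unknown = set(data) - {"orders", "bands"}
    if unknown:
        raise ConfigError(f"unknown sweep field(s): {sorted(unknown)}")
    return SweepSpec(orders=tuple(data["orders"]), bands=tuple(data["bands"]))


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Serialize a pipeline configuration; round-trips losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump({"pipeline": cfg.to_dict()}, fh, sort_keys=False)
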