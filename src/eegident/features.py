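"""Burg autoregressive features and the labeled feature space.

Each segment is summarised by the concatenation of per-channel AR(Q)
coefficients estimated with Burg's method, giving one d = H*Q dimensional
ID vector per segment.  Stacking the vectors of all subjects yields the
feature space on which enrollment is simulated.

Coefficients follow the prediction convention

    x_t = a_1 x_{t-1} + ... + a_Q x_{t-Q} + e_t

i.e. the returned ``a`` directly predict the next sample.  Burg's method
estimates no intercept; segments are mean-centered before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, config_id
from .preprocessing import EEGRecording, SegmentSet, bandpass, car_filter, segment

__all__ = [
    "FeatureVector",
    "FeatureSpace",
    "burg_ar",
    "extract_features",
    "build_feature_space",
]


@dataclass
class FeatureVector:
    """One segment's ID vector (d = H*Q) with its subject label."""

    values: np.ndarray
    subject_label: int


@dataclass
class FeatureSpace:
    """The (E*N) x d matrix of ID vectors for a whole cohort.

    ``config_id`` records the (filter order, band) pair that produced the
    space so metric reports can be traced back to their configuration.
    """

    matrix: np.ndarray
    labels: np.ndarray
    config_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per feature row required")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.labels)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=[f"a{i}" for i in range(self.dim)])
        df.insert(0, "label", self.labels)
        df.insert(1, "config_id", self.config_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureSpace":
        df = pd.read_csv(path)
        cid = str(df["config_id"].iloc[0]) if len(df) else ""
        coeff_cols = [c for c in df.columns if c.startswith("a")]
        return cls(
            matrix=df[coeff_cols].to_numpy(float),
            labels=df["label"].to_numpy(int),
            config_id=cid,
        )


def burg_ar(series: np.ndarray, order: int) -> np.ndarray:
    """Estimate AR(order) coefficients by Burg's method.

    The recursion minimises the sum of forward and backward prediction
    error powers at each stage and propagates the coefficients with a
    Levinson-type update.  Returns the ``order`` coefficients in the
    prediction convention (see module docstring).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if n <= order:
        raise ValueError(f"need more samples than the AR order ({n} <= {order})")
    x = x - x.mean()
    if not np.any(x):
        raise ValueError("zero-variance series: AR coefficients undefined")

    # error-filter polynomial convention internally: a[0] = 1
    a = np.array([1.0])
    f = x.copy()  # forward prediction errors
    b = x.copy()  # backward prediction errors
    for _ in range(order):
        fk = f[1:]
        bk = b[:-1]
        den = fk @ fk + bk @ bk
        if den <= 0.0:
            raise ValueError("prediction error vanished; series has degenerate structure")
        k = -2.0 * (fk @ bk) / den  # reflection coefficient
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        f = fk + k * bk
        b = bk + k * fk
    return -a[1:]


def extract_features(segs: SegmentSet, order: int) -> list[FeatureVector]:
    """One ID vector per segment: per-channel Burg coefficients concatenated
    in channel order."""
    vectors = []
    for s_idx in range(segs.n_segments):
        blocks = []
        for c_idx in range(segs.segments.shape[1]):
            try:
                blocks.append(burg_ar(segs.segments[s_idx, c_idx], order))
            except ValueError as exc:
                label = (
                    segs.channel_labels[c_idx]
                    if c_idx < len(segs.channel_labels)
                    else str(c_idx)
                )
                raise ValueError(
                    f"AR estimation failed for segment {s_idx}, channel {label}: {exc}"
                ) from exc
        vectors.append(
            FeatureVector(values=np.concatenate(blocks), subject_label=segs.subject_label)
        )
    return vectors


def build_feature_space(
    cohort: list[EEGRecording], cfg: PipelineConfig
) -> FeatureSpace:
    """Run channel selection -> CAR -> band-pass -> segmentation -> Burg
    extraction for every subject and stack the labeled ID vectors.

    Rows are grouped by subject in cohort order; the configuration id of
    the (filter order, band) pair is recorded on the result.
    """
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for rec in cohort:
        try:
            if cfg.car_over_selected:
                sub = rec.select_channels(cfg.channel_set)
                sub = car_filter(sub)
            else:
                sub = car_filter(rec).select_channels(cfg.channel_set)
            filt = bandpass(sub, cfg.filter_order, cfg.band, cfg.filter_variant)
            segs = segment(filt, cfg.segment_length, cfg.overlap)
            vectors = extract_features(segs, cfg.ar_order)
        except (ValueError, KeyError) as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {rec.subject_label}: {exc}"
            ) from exc
        for vec in vectors:
            rows.append(vec.values)
            labels.append(vec.subject_label)
    return FeatureSpace(
        matrix=np.vstack(rows),
        labels=np.asarray(labels),
        config_id=config_id(cfg.filter_order, cfg.band),
    )
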