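"""Self-relative degradation metrics over openness-accuracy trajectories.

Given a mean openness-accuracy vector OAm = (acc_1 ... acc_R):

* LRL (local relative loss): mean relative accuracy drop between
  successive steps, each drop measured against the previous step.
* GRL (global relative loss): mean relative accuracy drop of every step
  against the first step, capturing the cumulative effect of openness.
* Power of a target parameter: max/min ratio of the marginal mean GRL
  across that parameter's values — how strongly the parameter diversifies
  identity-information quality.
* DMM (decision-making metric): step accuracy divided by GRL (percent
  scale); maximised to pick the configuration that is simultaneously
  accurate and stable under enrollment.

Both loss metrics honour the degradation condition: steps where accuracy
does not drop contribute zero by default ("clamped"); alternatively only
the degrading steps are averaged ("degrading_only").  Either way the
metrics are ratios of accuracies and therefore invariant to a common
rescaling of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import json

import numpy as np
import pandas as pd

from .config import SweepSpec, config_id
from .evaluation import OpennessAccuracy

__all__ = [
    "DegradationUndefined",
    "SelfRelativeReport",
    "lrl",
    "grl",
    "power",
    "dmm",
    "grid_report",
]


class DegradationUndefined(ValueError):
    """Raised when a metric needs a nonzero degradation (GRL = 0)."""


def _loss_terms(reference: np.ndarray, acc: np.ndarray) -> np.ndarray:
    if np.any(reference <= 0.0):
        raise ValueError("reference accuracies must be positive")
    return np.maximum((reference - acc) / reference, 0.0)


def _finish(terms: np.ndarray, drops: np.ndarray, mode: str) -> float:
    if mode == "clamped":
        return float(100.0 * terms.mean())
    if mode == "degrading_only":
        degrading = terms[drops > 0]
        return float(100.0 * degrading.mean()) if degrading.size else 0.0
    raise ValueError(f"mode must be 'clamped' or 'degrading_only', got {mode!r}")


def _check_vector(oam) -> np.ndarray:
    oam = np.asarray(oam, dtype=float)
    if oam.ndim != 1 or oam.size < 2:
        raise ValueError("need an accuracy vector with at least 2 steps")
    if np.any(oam < 0) or np.any(oam > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    return oam


def lrl(oam, mode: str = "clamped") -> float:
    """Local relative loss in percent: mean over steps j >= 2 of
    (acc_{j-1} - acc_j)/acc_{j-1}, counted only when accuracy drops."""
    oam = _check_vector(oam)
    drops = (oam[:-1] - oam[1:]) / np.where(oam[:-1] > 0, oam[:-1], np.nan)
    if np.any(~np.isfinite(drops)):
        raise ValueError("LRL undefined: a reference step has zero accuracy")
    terms = np.maximum(drops, 0.0)
    return _finish(terms, drops, mode)


def grl(oam, mode: str = "clamped") -> float:
    """Global relative loss in percent: mean over steps j >= 2 of
    (acc_1 - acc_j)/acc_1, counted only when accuracy drops below the
    first step."""
    oam = _check_vector(oam)
    if oam[0] <= 0.0:
        raise ValueError("GRL undefined: first-step accuracy is zero")
    drops = (oam[0] - oam[1:]) / oam[0]
    terms = np.maximum(drops, 0.0)
    return _finish(terms, drops, mode)


def power(values) -> float:
    """Diversification power: max/min ratio of marginal mean GRL values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one GRL mean")
    if np.any(values <= 0.0):
        raise ValueError("power requires strictly positive GRL means")
    return float(values.max() / values.min())


def dmm(accuracy: float, grl_percent: float) -> float:
    """Decision-making metric: step accuracy times 1/GRL (percent scale)."""
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    if grl_percent <= 0.0:
        raise DegradationUndefined(
            "no degradation (GRL = 0): DMM is undefined — the configuration is "
            "perfectly stable and should be ranked by accuracy alone"
        )
    return float(accuracy / grl_percent)


@dataclass
class SelfRelativeReport:
    """Self-relative metrics over a (filter order x band) configuration grid.

    ``table`` holds one row per configuration (OAm endpoints, LRL, GRL,
    DMM at the last step); ``order_marginals`` / ``band_marginals`` hold
    the mean GRL per parameter value with the parameter's Power ratio;
    ``best_config_id`` is the argmax-DMM configuration, where zero-GRL
    (perfectly stable) configurations outrank all degrading ones and tie-
    break by last-step accuracy.
    """

    table: pd.DataFrame
    order_marginals: pd.DataFrame
    band_marginals: pd.DataFrame
    order_power: float
    band_power: float
    best_config_id: str
    oam: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def best_band(self) -> tuple[float, float]:
        row = self.table.loc[self.table["config_id"] == self.best_config_id].iloc[0]
        return (float(row["band_low_hz"]), float(row["band_high_hz"]))

    @property
    def best_order(self) -> int:
        row = self.table.loc[self.table["config_id"] == self.best_config_id].iloc[0]
        return int(row["filter_order"])

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "metrics.csv", index=False)
        self.order_marginals.to_csv(out_dir / "grl_by_order.csv", index=False)
        self.band_marginals.to_csv(out_dir / "grl_by_band.csv", index=False)
        summary = {
            "best_config_id": self.best_config_id,
            "best_filter_order": self.best_order,
            "best_band_hz": list(self.best_band),
            "order_power": None if np.isnan(self.order_power) else self.order_power,
            "band_power": None if np.isnan(self.band_power) else self.band_power,
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)


def grid_report(
    results: Mapping[str, OpennessAccuracy], sweep: SweepSpec, mode: str = "clamped"
) -> SelfRelativeReport:
    """Compute LRL/GRL/DMM per grid cell plus marginal GRL means and Power.

    ``results`` maps each configuration id of the sweep to its openness
    accuracy.  Power is reported as NaN when a parameter has a single
    value (the ratio is uninformative) and the marginal means must all be
    positive for it to be defined.
    """
    missing = []
    rows = []
    oam_store: dict[str, np.ndarray] = {}
    for order in sweep.orders:
        for band in sweep.bands:
            cid = config_id(order, band)
            if cid not in results:
                missing.append(cid)
                continue
            oa = results[cid]
            oam = np.asarray(oa.mean, dtype=float)
            oam_store[cid] = oam
            grl_val = grl(oam, mode=mode)
            try:
                dmm_val = dmm(oam[-1], grl_val)
            except DegradationUndefined:
                dmm_val = np.inf
            rows.append(
                {
                    "config_id": cid,
                    "filter_order": order,
                    "band_low_hz": band[0],
                    "band_high_hz": band[1],
                    "acc_first": oam[0],
                    "acc_last": oam[-1],
                    "lrl_percent": lrl(oam, mode=mode),
                    "grl_percent": grl_val,
                    "dmm_last": dmm_val,
                }
            )
    if missing:
        raise KeyError(f"missing openness results for grid cell(s): {missing}")
    table = pd.DataFrame(rows)

    order_marg = (
        table.groupby("filter_order", as_index=False)["grl_percent"]
        .mean()
        .rename(columns={"grl_percent": "mean_grl_percent"})
    )
    band_marg = (
        table.groupby(["band_low_hz", "band_high_hz"], as_index=False)["grl_percent"]
        .mean()
        .rename(columns={"grl_percent": "mean_grl_percent"})
    )

    def marginal_power(values: np.ndarray) -> float:
        if values.size < 2 or np.any(values <= 0.0):
            return float("nan")
        return power(values)

    order_power = marginal_power(order_marg["mean_grl_percent"].to_numpy())
    band_power = marginal_power(band_marg["mean_grl_percent"].to_numpy())

    # argmax DMM; inf (zero-GRL) cells outrank all, ties broken by acc_last
    ranked = table.sort_values(
        ["dmm_last", "acc_last"], ascending=False, kind="mergesort"
    )
    best = str(ranked.iloc[0]["config_id"])

    return SelfRelativeReport(
        table=table,
        order_marginals=order_marg,
        band_marginals=band_marg,
        order_power=order_power,
        band_power=band_power,
        best_config_id=best,
        oam=oam_store,
    )
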