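"""Model-vs-measurement comparison across (concentration, well size) conditions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CompareReport", "compare_report"]

_KEYS = ["concentration_M", "well_diameter_m"]


@dataclass(frozen=True)
class CompareReport:
    """Per-condition model radius vs measured mean radius plus trend flags.

    ``trends`` maps each well diameter to the sign of the model's
    concentration dependence ('increasing' / 'flat' / 'decreasing').
    """

    table: pd.DataFrame
    trends: dict[float, str]


def _trend(values: np.ndarray, rel_tol: float = 1e-6) -> str:
    if len(values) < 2:
        return "flat"
    span = values[-1] - values[0]
    scale = max(abs(values).max(), 1e-300)
    if span > rel_tol * scale:
        return "increasing"
    if span < -rel_tol * scale:
        return "decreasing"
    return "flat"


def compare_report(sweep_table: pd.DataFrame, measured: pd.DataFrame) -> CompareReport:
    """Join the kinetic-model sweep with measured synthetic distributions.

    ``sweep_table`` is the output of the model sweep (``r_g_m`` per
    concentration and well diameter); ``measured`` needs the same two key
    columns plus ``mean_radius_um``. Raises if either table is empty or the
    condition keys do not match one-to-one.
    """
    if len(sweep_table) == 0:
        raise ValueError("model sweep table is empty")
    if len(measured) == 0:
        raise ValueError("measurement table is empty")
    for col in _KEYS + ["r_g_m"]:
        if col not in sweep_table.columns:
            raise ValueError(f"sweep table missing column {col!r}")
    for col in _KEYS + ["mean_radius_um"]:
        if col not in measured.columns:
            raise ValueError(f"measurement table missing column {col!r}")

    model_keys = set(map(tuple, sweep_table[_KEYS].itertuples(index=False)))
    meas_keys = set(map(tuple, measured[_KEYS].itertuples(index=False)))
    if model_keys != meas_keys:
        missing = sorted(model_keys - meas_keys)
        extra = sorted(meas_keys - model_keys)
        raise ValueError(
            f"condition keys differ; model-only: {missing}, measurement-only: {extra}"
        )

    merged = sweep_table.merge(measured[_KEYS + ["mean_radius_um"]], on=_KEYS)
    merged = merged.sort_values(_KEYS).reset_index(drop=True)
    merged["model_r_g_um"] = merged["r_g_m"] * 1e6
    merged["discrepancy_um"] = merged["mean_radius_um"] - merged["model_r_g_um"]

    trends: dict[float, str] = {}
    for diam, grp in merged.groupby("well_diameter_m"):
        grp = grp.sort_values("concentration_M")
        trends[float(diam)] = _trend(grp["model_r_g_um"].to_numpy())
    return CompareReport(table=merged, trends=trends)
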