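"""Stability-activity phase plane and fitness-energetics correlations.

Each variant is a point in the plane spanned by its native-state stability
perturbation ddG0_NI (x, positive = destabilized) and its catalytic
barrier perturbation ddG_act(kcat) (y, negative = faster enzyme), colored
by its selection coefficient.  Quadrants therefore read:

    lower-right : destabilized, faster   (where most beneficial mutants sit)
    upper-right : destabilized, slower
    lower-left  : stabilized,  faster
    upper-left  : stabilized,  slower

A variant whose coordinate is within its own SE of zero is treated as
sitting on that axis (WT-like band) rather than forced into a quadrant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, norm

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

WT_BAND = "wt-band"


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def quadrant(
    ddG_NI: float,
    ddG_cat: float,
    *,
    ni_band: float = 0.0,
    cat_band: float = 0.0,
) -> str:
    """Quadrant label for one (stability, activity) point.

    ``ni_band`` / ``cat_band`` are half-widths (typically the SEs) inside
    which a coordinate counts as WT-like; such points get the label
    ``"wt-band"`` instead of a quadrant.
    """
    if abs(ddG_NI) <= ni_band or abs(ddG_cat) <= cat_band:
        return WT_BAND
    horiz = "right" if ddG_NI > 0 else "left"
    vert = "lower" if ddG_cat < 0 else "upper"
    return f"{vert}-{horiz}"


def assemble_phase_plane(
    stability: pd.DataFrame,
    kinetics: pd.DataFrame,
    fitness: pd.DataFrame,
) -> pd.DataFrame:
    """Join the three per-variant result tables into phase-plane points.

    Inputs are tidy tables keyed by ``variant_id``: ``stability`` with
    ddG_NI (+ optional ddG_NI_se, ddG_IU, ddG_IU_se), ``kinetics`` with
    ddG_cat (+ optional se and kcat/Km/Keff/ddG_eff columns), ``fitness``
    with s_norm.  Variants missing from any table are excluded with a
    logged warning.  The join is a pure function of the input sets: row
    order of the output is sorted by variant id.
    """
    for name, df, col in (
        ("stability", stability, "ddG_NI"),
        ("kinetics", kinetics, "ddG_cat"),
        ("fitness", fitness, "s_norm"),
    ):
        if "variant_id" not in df.columns or col not in df.columns:
            raise InvalidInputError(f"{name} table needs variant_id and {col} columns")

    merged = (
        stability.merge(kinetics, on="variant_id", how="outer", suffixes=("", "_kin"))
        .merge(fitness, on="variant_id", how="outer", suffixes=("", "_fit"))
        .sort_values("variant_id", kind="stable")
        .reset_index(drop=True)
    )
    complete = merged[["ddG_NI", "ddG_cat", "s_norm"]].notna().all(axis=1)
    for vid in merged.loc[~complete, "variant_id"]:
        logger.warning("variant %s missing from one or more stages; excluded", vid)
    merged = merged.loc[complete].reset_index(drop=True)

    ni_se = merged.get("ddG_NI_se", pd.Series(0.0, index=merged.index)).fillna(0.0)
    cat_se = merged.get("ddG_cat_se", pd.Series(0.0, index=merged.index)).fillna(0.0)
    merged["quadrant"] = [
        quadrant(x, y, ni_band=bx, cat_band=by)
        for x, y, bx, by in zip(merged["ddG_NI"], merged["ddG_cat"], ni_se, cat_se)
    ]
    return merged


def correlate(x, y, *, level: float = 0.95) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero variance in one of the vectors")
    res = pearsonr(x, y)
    r = float(res.statistic)
    n = len(x)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = norm.ppf(0.5 + level / 2.0)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    else:
        lo, hi = r, r
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n, p_value=float(res.pvalue))
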