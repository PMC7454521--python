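"""Growth-competition fitness: rate constants, slopes, selection coefficients.

A tryptophan-auxotrophic yeast strain complemented by an enzyme variant
grows exponentially in selective medium; competition against the reference
(wild-type) strain is tracked as the log2 mutant:WT abundance ratio over
6-10 timepoints.  For exponential growth this trajectory is linear with
slope w = (k_MT - k_WT) / ln 2 in log2 units per hour.

The normalized selection coefficient maps the fitness slope affinely so
that the wild-type reference sits at s = 0 and the vector-only (null,
uncomplemented) control sits at s = -1:

    s_norm = (w_i - w_WT) / |w_vector - w_WT|

The equivalent rate-ratio form s = log2(k_MT / k_WT) is exposed as a
cross-check; on noiseless exponential data the two agree exactly once the
slope is converted back to a rate ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .kinetics import _ols_slope

LN2 = float(np.log(2.0))


@dataclass
class GrowthDataset:
    """Competition or growth time series.

    ``data`` columns: ``variant_id``, ``time_hr``, plus ``log2_ratio``
    (competition mode) or ``abundance`` (per-culture mode); optional
    ``replicate``, ``is_vector_control``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"variant_id", "time_hr"}
        missing = need - set(self.data.columns)
        if missing:
            raise InvalidInputError(f"growth data missing columns: {sorted(missing)}")
        if not ({"log2_ratio", "abundance"} & set(self.data.columns)):
            raise InvalidInputError("growth data needs a log2_ratio or abundance column")


@dataclass
class FitnessResult:
    variant_id: str
    w: float               # fitness slope, log2 units / hr
    w_se: float
    s_norm: float | None = None
    s_norm_se: float | None = None
    k: float | None = None  # growth rate constant, 1/hr (per-culture mode)
    k_se: float | None = None


def growth_rate(time_hr, abundance) -> tuple[float, float]:
    """Exponential growth rate constant k (1/hr) from a per-culture series.

    Least-squares slope of ln(abundance) versus time; returns (k, se).
    """
    t = np.asarray(time_hr, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if len(t) < 2:
        raise InvalidInputError("need >= 2 timepoints")
    if np.any(a <= 0):
        raise InvalidInputError("abundance must be positive to take logs")
    return _ols_slope(t, np.log(a))


def fitness_slope(time_hr, log2_ratio, *, doubling_time_hr: float | None = None):
    """Fitness w as the slope of log2(mutant:WT abundance) versus time.

    Returns (w, se) in log2 units per hour, or per WT doubling when
    ``doubling_time_hr`` is given (slope multiplied by the doubling time).
    """
    t = np.asarray(time_hr, dtype=float)
    r = np.asarray(log2_ratio, dtype=float)
    if len(t) < 2:
        raise InvalidInputError("need >= 2 timepoints")
    w, se = _ols_slope(t, r)
    if doubling_time_hr is not None:
        if doubling_time_hr <= 0:
            raise InvalidInputError("doubling time must be positive")
        w, se = w * doubling_time_hr, se * doubling_time_hr
    return w, se


def selection_coefficient(
    w_i: float,
    w_wt: float,
    w_vector: float,
    *,
    w_i_se: float = 0.0,
    w_wt_se: float = 0.0,
    w_vector_se: float = 0.0,
) -> tuple[float, float]:
    """Vector-normalized selection coefficient and its SE.

    Affine map anchored at the two controls: a WT-like slope gives 0, the
    vector-only (null) slope gives -1, and variants slower than WT come
    out negative.  SE by first-order propagation of the three slope SEs.
    """
    denom = w_wt - w_vector
    if abs(denom) < 1e-12 * max(1.0, abs(w_wt), abs(w_vector)):
        raise InvalidInputError("degenerate normalizer: vector and WT slopes coincide")
    # the vector control must anchor the slow end; |denom| with the sign
    # convention "slower than WT < 0" reduces to dividing by (w_wt - w_vector)
    s = (w_i - w_wt) / denom
    ds_dwi = 1.0 / denom
    ds_dwwt = -(1.0 + s) / denom
    ds_dwv = s / denom
    se = float(
        np.sqrt(
            (ds_dwi * w_i_se) ** 2
            + (ds_dwwt * w_wt_se) ** 2
            + (ds_dwv * w_vector_se) ** 2
        )
    )
    return float(s), se


def selection_from_rates(k_mt: float, k_wt: float) -> float:
    """Rate-ratio selection coefficient s = log2(k_MT / k_WT).

    Cross-check form: 0 for WT-like growth, positive for beneficial.
    """
    if k_mt <= 0 or k_wt <= 0:
        raise InvalidInputError("growth rate constants must be positive")
    return float(np.log2(k_mt / k_wt))


def rate_from_slope(w: float, k_wt: float) -> float:
    """Invert the competition slope: k_MT = k_WT + w*ln2 (w in log2/hr)."""
    return k_wt + w * LN2


def analyze_competition(
    dataset: GrowthDataset,
    *,
    wt_id: str = "WT",
    vector_id: str | None = None,
    doubling_time_hr: float | None = None,
) -> list[FitnessResult]:
    """Per-variant fitness slopes and normalized selection coefficients.

    Slopes are fit per replicate and averaged; SEs are SD/sqrt(n) over
    replicates (single-replicate series fall back to the regression SE).
    The vector control is found via the ``is_vector_control`` flag or
    ``vector_id``.
    """
    df = dataset.data
    if "log2_ratio" not in df.columns:
        raise InvalidInputError("competition analysis needs a log2_ratio column")

    def _slope_stats(sub: pd.DataFrame) -> tuple[float, float]:
        groups = (
            [g for _, g in sub.groupby("replicate")]
            if "replicate" in sub.columns
            else [sub]
        )
        ws, ses = [], []
        for g in groups:
            w, se = fitness_slope(g["time_hr"], g["log2_ratio"])
            ws.append(w)
            ses.append(se)
        if len(ws) > 1:
            return float(np.mean(ws)), float(np.std(ws, ddof=1) / np.sqrt(len(ws)))
        return ws[0], ses[0]

    slopes: dict[str, tuple[float, float]] = {}
    for vid, sub in df.groupby("variant_id", sort=True):
        slopes[str(vid)] = _slope_stats(sub)

    if vector_id is None:
        if "is_vector_control" in df.columns and df["is_vector_control"].any():
            vector_id = str(df.loc[df["is_vector_control"], "variant_id"].iloc[0])
        else:
            raise InvalidInputError("no vector control flagged and no vector_id given")
    if wt_id not in slopes:
        raise InvalidInputError(f"WT reference '{wt_id}' absent from dataset")
    if vector_id not in slopes:
        raise InvalidInputError(f"vector control '{vector_id}' absent from dataset")

    w_wt, w_wt_se = slopes[wt_id]
    w_vec, w_vec_se = slopes[vector_id]

    results = []
    for vid, (w, w_se) in slopes.items():
        s, s_se = selection_coefficient(
            w, w_wt, w_vec, w_i_se=w_se, w_wt_se=w_wt_se, w_vector_se=w_vec_se
        )
        if vid == wt_id:
            s, s_se = 0.0, 0.0  # the reference defines the origin exactly
        w_out, w_out_se = w, w_se
        if doubling_time_hr is not None:
            w_out, w_out_se = w * doubling_time_hr, w_se * doubling_time_hr
        results.append(
            FitnessResult(variant_id=vid, w=w_out, w_se=w_out_se, s_norm=s, s_norm_se=s_se)
        )
    return results
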