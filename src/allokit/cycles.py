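"""Thermodynamic double-mutant cycles, abundance normalization, flux model.

For a physical property P (a folding free energy, or an activation free
energy derived from kcat or Keff) measured on wild type, two single
mutants and the corresponding double mutant, the interaction energy is
the deviation from additivity

    delta = dP_DM - (dP_M1 + dP_M2),     dP_X = perturbation of X vs WT.

delta = 0 means the two sites act independently; a nonzero delta is
energetic coupling (epistasis) between them.  Whether a measured delta is
distinguishable from zero is decided by a z-score rule with an absolute
floor: |delta| > z*SE is called nonadditive, |delta| <= z*SE but above
the floor stays inconclusive, and small-|delta| values are additive.

Intracellular protein abundance from quantitative Western blots is
normalized to a loading control and expressed as fold versus wild type.
The flux-dynamics model maps effective functional capacity (abundance x
kcat) to the selection coefficient:

    s = a * [E]_i * kcat / (b + kcat)

with environment-dependent constants a and b (b > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .errors import FitFailureError, InvalidInputError

#: Property labels accepted by cycle operations.
CYCLE_PROPERTIES = ("ddG_NI", "ddG_IU", "ddG_cat", "ddG_eff")

ADDITIVE, NONADDITIVE, INCONCLUSIVE = "additive", "nonadditive", "inconclusive"


@dataclass
class CycleResult:
    property: str
    single1: str
    single2: str
    double: str
    delta: float
    delta_se: float
    call: str


@dataclass
class AbundanceRecord:
    variant_id: str
    fold_vs_wt: float
    fold_se: float
    n_replicates: int


@dataclass
class FluxFit:
    a: float
    a_se: float
    b: float
    b_se: float
    predicted: pd.DataFrame   # variant_id, s_obs, s_pred, residual
    positive_trend: bool      # fitness rises with abundance*kcat capacity
    converged: bool


def interaction_energy(
    dP1: float,
    dP2: float,
    dPD: float,
    *,
    se1: float = 0.0,
    se2: float = 0.0,
    seD: float = 0.0,
) -> tuple[float, float]:
    """delta = dPD - (dP1 + dP2); SE by quadrature of the three SEs.

    Symmetric in the two single-mutant perturbations, and flips sign
    coherently if all three inputs flip sign convention together.
    """
    delta = dPD - (dP1 + dP2)
    se = float(np.sqrt(se1 ** 2 + se2 ** 2 + seD ** 2))
    return float(delta), se


def classify_additivity(
    delta: float,
    se: float,
    *,
    z_threshold: float = 1.96,
    floor: float = 0.1,
) -> str:
    """Three-way additivity call from the interaction energy and its SE.

    ``floor`` (kcal/mol) guards against calling a cycle additive merely
    because the measurement is noisy: a |delta| above the floor that is
    not significant stays inconclusive.
    """
    if se <= 0:
        raise InvalidInputError("SE must be positive to classify")
    if abs(delta) > z_threshold * se:
        return NONADDITIVE
    if abs(delta) > floor:
        return INCONCLUSIVE
    return ADDITIVE


def mutant_cycle(
    property: str,
    perturbations: dict[str, tuple[float, float]],
    single1: str,
    single2: str,
    double: str,
    *,
    z_threshold: float = 1.96,
    floor: float = 0.1,
) -> CycleResult:
    """Build one cycle result from per-variant (value, SE) perturbations.

    ``perturbations`` maps variant id -> (dP vs WT, SE) for the named
    property; all three variants must be present.
    """
    if property not in CYCLE_PROPERTIES:
        raise InvalidInputError(
            f"unknown property '{property}'; expected one of {CYCLE_PROPERTIES}"
        )
    for vid in (single1, single2, double):
        if vid not in perturbations:
            raise InvalidInputError(f"variant '{vid}' missing from perturbation table")
    dP1, se1 = perturbations[single1]
    dP2, se2 = perturbations[single2]
    dPD, seD = perturbations[double]
    delta, se = interaction_energy(dP1, dP2, dPD, se1=se1, se2=se2, seD=seD)
    call = classify_additivity(delta, se, z_threshold=z_threshold, floor=floor) if se > 0 else (
        ADDITIVE if abs(delta) <= floor else NONADDITIVE
    )
    return CycleResult(property, single1, single2, double, delta, se, call)


def abundance_fold(
    records: pd.DataFrame,
    *,
    wt_id: str = "WT",
) -> list[AbundanceRecord]:
    """Loading-normalized abundance fold versus wild type, per variant.

    ``records`` columns: ``variant_id``, ``igps_intensity``,
    ``loading_intensity``, optional ``replicate``.  Per replicate the
    band ratio igps/loading is formed; fold = mean ratio / mean WT ratio,
    with the SE combining both relative replicate errors in quadrature.
    """
    need = {"variant_id", "igps_intensity", "loading_intensity"}
    missing = need - set(records.columns)
    if missing:
        raise InvalidInputError(f"abundance table missing columns: {sorted(missing)}")
    if (records["igps_intensity"] <= 0).any() or (records["loading_intensity"] <= 0).any():
        raise InvalidInputError("band intensities must be positive")
    ratios = records.assign(ratio=records["igps_intensity"] / records["loading_intensity"])
    by_var = ratios.groupby("variant_id")["ratio"]
    means = by_var.mean()
    sems = by_var.sem().fillna(0.0)
    counts = by_var.count()
    if wt_id not in means.index:
        raise InvalidInputError(f"WT reference '{wt_id}' absent from abundance table")
    wt_mean, wt_sem = float(means[wt_id]), float(sems[wt_id])
    out = []
    for vid in means.index:
        fold = float(means[vid] / wt_mean)
        rel = np.sqrt((sems[vid] / means[vid]) ** 2 + (wt_sem / wt_mean) ** 2)
        out.append(
            AbundanceRecord(
                variant_id=str(vid),
                fold_vs_wt=fold,
                fold_se=float(fold * rel),
                n_replicates=int(counts[vid]),
            )
        )
    return out


def flux_model(abundance, kcat, a, b):
    """s = a * [E] * kcat / (b + kcat)."""
    A = np.asarray(abundance, dtype=float)
    k = np.asarray(kcat, dtype=float)
    return a * A * k / (b + k)


def fit_flux_model(
    s_values,
    abundance_folds,
    kcat_values,
    *,
    variant_ids=None,
) -> FluxFit:
    """Fit the two flux-model constants (a, b) by nonlinear least squares.

    b is constrained positive.  Also reports whether fitness shows the
    expected positive trend with functional capacity (abundance x kcat),
    as a Pearson correlation sign check.
    """
    s = np.asarray(s_values, dtype=float)
    A = np.asarray(abundance_folds, dtype=float)
    k = np.asarray(kcat_values, dtype=float)
    if not (len(s) == len(A) == len(k)):
        raise InvalidInputError("s, abundance and kcat vectors must align")
    if len(s) < 3:
        raise InvalidInputError("need >= 3 variants to fit the flux model")
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(len(s))]

    capacity = A * k
    r_trend = pearsonr(capacity, s).statistic if np.std(capacity) > 0 and np.std(s) > 0 else 0.0

    def resid(theta):
        return flux_model(A, k, theta[0], theta[1]) - s

    b0 = float(np.median(k))
    with np.errstate(divide="ignore", invalid="ignore"):
        a_guess = np.median(s / (A * k / (b0 + k)))
    a0 = float(a_guess) if np.isfinite(a_guess) and a_guess != 0 else 0.1
    theta0 = np.array([a0, b0])
    best = None
    for scale in (1.0, 0.1, 10.0):
        try:
            sol = least_squares(
                resid,
                theta0 * np.array([1.0, scale]),
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("flux-model fit did not converge")

    a_hat, b_hat = best.x
    # covariance from the Jacobian at the optimum (Gauss-Newton approximation)
    dof = max(len(s) - 2, 1)
    sigma2 = 2.0 * best.cost / dof
    try:
        JTJ = best.jac.T @ best.jac
        cov = sigma2 * np.linalg.inv(JTJ)
        a_se, b_se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        a_se = b_se = float("nan")

    pred = flux_model(A, k, a_hat, b_hat)
    table = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "s_obs": s,
            "s_pred": pred,
            "residual": s - pred,
        }
    )
    return FluxFit(
        a=float(a_hat),
        a_se=float(a_se),
        b=float(b_hat),
        b_se=float(b_se),
        predicted=table,
        positive_trend=bool(r_trend > 0),
        converged=True,
    )
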