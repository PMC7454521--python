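"""Michaelis-Menten analysis and activation-energy perturbations.

Initial velocities v0 measured at a series of substrate concentrations are
fit by nonlinear least squares to

    v0 = Vmax * [S] / ([S] + Km),        Vmax = kcat * [E]0

(never a linearized transform), giving kcat, Km and the catalytic
efficiency Keff = kcat / Km.  Transition-state theory, kcat = k0 *
exp(-dG_act / RT), converts rate-constant ratios between a mutant and the
reference enzyme into activation free-energy perturbations

    ddG_act = -RT * ln(k_mut / k_ref)

where the prefactor k0 cancels; negative values mean the mutation lowers
the barrier (faster enzyme).  Applied to kcat this gives ddG_cat, applied
to Keff it gives ddG_eff.

Raw plate-reader traces are fluorescence (RFU) versus time; a calibration
factor (RFU per uM product) converts slopes to uM/s.  Without it, fits are
reported in relative (RFU-based) units and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE_K, rt
from .errors import FitFailureError, InvalidInputError


@dataclass
class KineticsDataset:
    """Initial-velocity observations for one variant.

    ``data`` columns: ``substrate_uM``, ``v0`` and optionally
    ``replicate``.  ``progress`` (optional) holds raw traces with columns
    ``substrate_uM``, ``time_s``, ``rfu``.  ``calib`` is RFU per uM
    product; when present, velocities are in uM/s and kcat in 1/s.
    """

    variant_id: str
    E0: float  # uM enzyme
    data: pd.DataFrame
    progress: pd.DataFrame | None = None
    calib: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise InvalidInputError("enzyme concentration E0 must be positive")
        if "substrate_uM" in self.data.columns and (self.data["substrate_uM"] < 0).any():
            raise InvalidInputError("substrate concentrations must be nonnegative")


@dataclass
class KineticsFit:
    variant_id: str
    Vmax: float
    Vmax_se: float
    Km: float
    Km_se: float
    kcat: float
    kcat_se: float
    Keff: float            # kcat/Km in 1/(s*uM)
    Keff_se: float
    relative_units: bool   # True when no RFU->uM calibration was available
    temperature: float
    n_obs: int
    bootstrap: np.ndarray | None = None  # (B, 2) columns (Vmax, Km)
    ddG_cat: float | None = None
    ddG_cat_se: float | None = None
    ddG_eff: float | None = None
    ddG_eff_se: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def Keff_per_M(self) -> float:
        """Catalytic efficiency in 1/(s*M)."""
        return self.Keff * 1e6

    def predict(self, substrate) -> np.ndarray:
        s = np.asarray(substrate, dtype=float)
        return self.Vmax * s / (s + self.Km)


def michaelis_menten(substrate, Vmax, Km):
    s = np.asarray(substrate, dtype=float)
    return Vmax * s / (s + Km)


def initial_velocity(
    time_s,
    rfu,
    *,
    amplitude_fraction: float = 0.10,
    min_points: int = 15,
    calib: float | None = None,
) -> tuple[float, float]:
    """Initial velocity as the OLS slope of the early linear window.

    The window is the first ``amplitude_fraction`` of the total signal
    amplitude or the first ``min_points`` samples, whichever is larger.
    Returns (v0, se); in uM/s when ``calib`` (RFU per uM) is given,
    otherwise RFU/s.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 4:
        raise InvalidInputError("need >= 4 (time, rfu) points")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]

    amp = y.max() - y.min()
    if amp <= 0:
        raise InvalidInputError("trace has no amplitude; no linear window")
    rising = y[-1] >= y[0]
    target = y[0] + amplitude_fraction * amp if rising else y[0] - amplitude_fraction * amp
    within = np.nonzero(y <= target if rising else y >= target)[0]
    n_amp = within[-1] + 1 if len(within) else 0
    n_win = max(n_amp, min(min_points, len(t)))
    n_win = max(n_win, 4)
    if y[0] == y.max() and y[0] == y[n_win - 1]:
        raise InvalidInputError("saturated trace: no early linear window")
    tw, yw = t[:n_win], y[:n_win]

    slope, se = _ols_slope(tw, yw)
    if calib is not None:
        if calib <= 0:
            raise InvalidInputError("calibration factor must be positive")
        slope, se = slope / calib, se / calib
    return slope, se


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and its standard error (0 for a 2-point fit)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise InvalidInputError("degenerate abscissa: all x values equal")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    if n > 2:
        sigma2 = float((resid ** 2).sum()) / (n - 2)
        se = float(np.sqrt(sigma2 / sxx))
    else:
        se = 0.0
    return slope, se


def fit_mm(
    data: KineticsDataset,
    *,
    bootstrap: int = 200,
    seed: int = 0,
) -> KineticsFit:
    """Fit the Michaelis-Menten equation to one variant's velocities.

    SEs come from a seeded bootstrap over replicates when replicate labels
    are present (mirroring biological-replicate error propagation), else
    over individual observations.
    """
    df = data.data
    s = df["substrate_uM"].to_numpy(float)
    v = df["v0"].to_numpy(float)
    keep = np.isfinite(s) & np.isfinite(v)
    s, v = s[keep], v[keep]
    if len(np.unique(s[s > 0])) < 3:
        raise InvalidInputError("need >= 3 nonzero substrate levels")

    popt, _ = _mm_curve_fit(s, v)
    Vmax, Km = popt
    warnings_: list[str] = []
    s_pos_max = s[s > 0].max()
    if Km > 5 * s_pos_max:
        warnings_.append(
            f"Km ({Km:.3g} uM) far above the highest substrate level "
            f"({s_pos_max:.3g} uM); poorly constrained"
        )

    boot = None
    ses = np.full(2, np.nan)
    if bootstrap and bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = (
            df.loc[keep, "replicate"].to_numpy()
            if "replicate" in df.columns
            else np.arange(len(s))
        )
        unique_reps = np.unique(reps)
        thetas = np.full((bootstrap, 2), np.nan)
        for b in range(bootstrap):
            if len(unique_reps) > 1:
                chosen = rng.choice(unique_reps, size=len(unique_reps), replace=True)
                idx = np.concatenate([np.nonzero(reps == c)[0] for c in chosen])
            else:
                idx = rng.integers(0, len(s), size=len(s))
            try:
                p_b, _ = _mm_curve_fit(s[idx], v[idx], p0=popt)
                thetas[b] = p_b
            except Exception:
                pass
        boot = thetas[np.all(np.isfinite(thetas), axis=1)]
        if len(boot) >= 10:
            ses = boot.std(axis=0, ddof=1)

    kcat = Vmax / data.E0
    kcat_se = ses[0] / data.E0
    Keff = kcat / Km
    # first-order propagation, treating Vmax and Km bootstrap scatter jointly
    if boot is not None and len(boot) >= 10:
        keff_boot = (boot[:, 0] / data.E0) / boot[:, 1]
        Keff_se = float(keff_boot.std(ddof=1))
    else:
        Keff_se = float("nan")

    return KineticsFit(
        variant_id=data.variant_id,
        Vmax=float(Vmax),
        Vmax_se=float(ses[0]),
        Km=float(Km),
        Km_se=float(ses[1]),
        kcat=float(kcat),
        kcat_se=float(kcat_se),
        Keff=float(Keff),
        Keff_se=Keff_se,
        relative_units=data.calib is None and data.progress is not None,
        temperature=data.temperature,
        n_obs=len(s),
        bootstrap=boot,
        warnings=warnings_,
    )


def _mm_curve_fit(s, v, p0=None):
    if p0 is None:
        vmax0 = max(v.max(), 1e-12)
        pos = s > 0
        km0 = float(np.median(s[pos])) if pos.any() else 1.0
        p0 = (vmax0, km0)
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            s,
            v,
            p0=p0,
            bounds=([1e-12, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"Michaelis-Menten fit failed: {exc}") from exc
    return popt, pcov


def activation_ddG(
    k_mut: float,
    k_ref: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Barrier perturbation ddG_act = -RT ln(k_mut/k_ref), kcal/mol.

    Negative = the mutant's barrier is lower (faster catalysis).
    """
    if k_mut <= 0 or k_ref <= 0:
        raise InvalidInputError("rate constants must be positive")
    return -rt(temperature) * float(np.log(k_mut / k_ref))


def activation_ddG_se(
    k_mut: float, k_mut_se: float, k_ref: float, k_ref_se: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """First-order SE of activation_ddG from the two rate SEs."""
    RT = rt(temperature)
    return float(RT * np.hypot(k_mut_se / k_mut, k_ref_se / k_ref))


def compare_to_reference(fit: KineticsFit, ref: KineticsFit) -> KineticsFit:
    """Fill ddG_cat / ddG_eff (and SEs) of ``fit`` relative to ``ref``.

    Returns the same object for chaining.  Both fits must share units:
    mixing a calibrated fit with a relative-units fit is rejected.
    """
    if fit.relative_units != ref.relative_units:
        raise InvalidInputError("cannot compare fits with mismatched units")
    T = fit.temperature
    fit.ddG_cat = activation_ddG(fit.kcat, ref.kcat, T)
    fit.ddG_eff = activation_ddG(fit.Keff, ref.Keff, T)
    if np.isfinite(fit.kcat_se) and np.isfinite(ref.kcat_se):
        fit.ddG_cat_se = activation_ddG_se(fit.kcat, fit.kcat_se, ref.kcat, ref.kcat_se, T)
    if np.isfinite(fit.Keff_se) and np.isfinite(ref.Keff_se):
        fit.ddG_eff_se = activation_ddG_se(fit.Keff, fit.Keff_se, ref.Keff, ref.Keff_se, T)
    return fit
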