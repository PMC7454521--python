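"""Global three-state equilibrium unfolding analysis.

Chemical denaturation of a TIM-barrel protein monitored by far-UV CD is
described by a three-state equilibrium, N <=> I <=> U, with linear
extrapolation of each free-energy difference in denaturant:

    dG_X(urea) = dG0_X - m_X * [urea],      X in {NI, IU}
    K_X        = exp(-dG_X / RT)

so the species populations at any urea concentration follow from the
partition function 1 + K_NI + K_NI*K_IU.  The observed CD signal is the
population-weighted sum of linear species baselines.  A global fit shares
the four thermodynamic parameters (dG0_NI, m_NI, dG0_IU, m_IU) across all
wavelengths while each wavelength carries its own baselines; because the
baselines enter linearly, they are profiled out exactly at every step of
the nonlinear optimization (variable projection), which keeps the search
four-dimensional and fast.

The intermediate baseline is constant in urea by default: I is populated
over a narrow urea window, so a free slope is poorly determined.

Uncertainties come from a seeded residual-resampling bootstrap; mutational
stability perturbations ddG0 = dG0(WT) - dG0(mutant) use the convention
that positive values mean the mutant is destabilized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import DEFAULT_TEMPERATURE_K, rt
from .errors import FitFailureError, InvalidInputError

logger = logging.getLogger(__name__)

#: Species order used everywhere in this module.
SPECIES = ("N", "I", "U")

#: Thermodynamic parameter order in vectors and bootstrap arrays.
PARAM_NAMES = ("dG_NI", "m_NI", "dG_IU", "m_IU")

_LOWER_BOUNDS = np.array([-12.0, 0.02, -12.0, 0.02])
_UPPER_BOUNDS = np.array([25.0, 6.0, 25.0, 6.0])


@dataclass
class MeltDataset:
    """Urea-denaturation observations for one variant.

    ``data`` is long-format with columns ``urea_M``, ``wavelength_nm``,
    ``signal`` and optionally ``replicate``.
    """

    variant_id: str
    data: pd.DataFrame
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        missing = {"urea_M", "wavelength_nm", "signal"} - set(self.data.columns)
        if missing:
            raise InvalidInputError(f"melt data missing columns: {sorted(missing)}")
        if (self.data["urea_M"] < 0).any():
            raise InvalidInputError("urea concentrations must be nonnegative")


@dataclass
class ThreeStateFit:
    """Result of a global three-state fit.

    Thermodynamic parameters are shared across wavelengths; ``baselines``
    has one row per (wavelength, species) with ``intercept`` and ``slope``
    (slope in signal units per molar urea).  ``bootstrap`` holds the
    resampled parameter vectors (B x 4, column order ``PARAM_NAMES``).
    """

    variant_id: str
    dG_NI: float
    m_NI: float
    dG_IU: float
    m_IU: float
    dG_NI_se: float
    m_NI_se: float
    dG_IU_se: float
    m_IU_se: float
    baselines: pd.DataFrame
    rms: float
    n_obs: int
    temperature: float
    bootstrap: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.dG_NI, self.m_NI, self.dG_IU, self.m_IU])

    def ci(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Percentile bootstrap confidence interval for one parameter."""
        if self.bootstrap is None or len(self.bootstrap) == 0:
            raise InvalidInputError("fit carries no bootstrap replicates")
        j = PARAM_NAMES.index(param)
        alpha = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(self.bootstrap[:, j], [alpha, 100.0 - alpha])
        return float(lo), float(hi)

    def fractions(self, urea) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return species_fractions(
            self.dG_NI, self.m_NI, self.dG_IU, self.m_IU, urea, rt(self.temperature)
        )

    def predict(self, urea, wavelength: float) -> np.ndarray:
        return predict_signal(self, urea, wavelength)


@dataclass
class StabilityPerturbation:
    """Mutational change in stability, positive = destabilized."""

    variant_id: str
    ddG_NI: float
    ddG_NI_se: float
    ddG_IU: float
    ddG_IU_se: float


def species_fractions(dG_NI, m_NI, dG_IU, m_IU, urea, RT: float | None = None):
    """Equilibrium fractions (fN, fI, fU) at the given urea concentration(s).

    Computed through a log-sum-exp-normalized partition function so that
    strongly folded or unfolded limits do not overflow.  The three
    fractions sum to one at machine precision.
    """
    if RT is None:
        RT = rt()
    if RT <= 0:
        raise InvalidInputError("RT must be positive")
    u = np.asarray(urea, dtype=float)
    gN = np.zeros_like(u)
    gI = -(dG_NI - m_NI * u) / RT          # ln K_NI
    gU = gI - (dG_IU - m_IU * u) / RT      # ln (K_NI * K_IU)
    g = np.stack([gN, gI, gU])
    g -= g.max(axis=0)
    w = np.exp(g)
    f = w / w.sum(axis=0)
    return f[0], f[1], f[2]


def _baseline_row(fit_baselines: pd.DataFrame, wavelength: float, species: str):
    sel = fit_baselines[
        (fit_baselines["wavelength_nm"] == wavelength)
        & (fit_baselines["species"] == species)
    ]
    if len(sel) == 0:
        raise InvalidInputError(
            f"no fitted baseline for wavelength {wavelength} nm (species {species})"
        )
    row = sel.iloc[0]
    return float(row["intercept"]), float(row["slope"])


def predict_signal(fit: ThreeStateFit, urea, wavelength: float) -> np.ndarray:
    """Model signal at (urea, wavelength): population-weighted baselines."""
    u = np.asarray(urea, dtype=float)
    fN, fI, fU = fit.fractions(u)
    out = np.zeros_like(u)
    for frac, sp in zip((fN, fI, fU), SPECIES):
        a, b = _baseline_row(fit.baselines, wavelength, sp)
        out = out + frac * (a + b * u)
    return out


def _design_matrix(fN, fI, fU, u, i_slope: bool) -> np.ndarray:
    cols = [fN, fN * u, fI]
    if i_slope:
        cols.append(fI * u)
    cols += [fU, fU * u]
    return np.column_stack(cols)


class _GlobalProblem:
    """Precomputed per-wavelength views of one melt for fast residuals."""

    def __init__(self, df: pd.DataFrame, RT: float, i_slope: bool):
        self.RT = RT
        self.i_slope = i_slope
        self.groups: list[tuple[float, np.ndarray, np.ndarray]] = []
        for wl, sub in df.groupby("wavelength_nm", sort=True):
            sub = sub.sort_values("urea_M", kind="stable")
            self.groups.append(
                (float(wl), sub["urea_M"].to_numpy(float), sub["signal"].to_numpy(float))
            )
        self.n_obs = sum(len(u) for _, u, _ in self.groups)

    def solve_baselines(self, theta, y_per_group=None):
        """For fixed thermodynamics, solve each wavelength's linear baselines.

        Returns (betas, residuals, sse).  Rank-deficient designs (a species
        never populated) are handled by the minimum-norm least-squares
        solution.
        """
        betas, resid = [], []
        sse = 0.0
        for k, (wl, u, y) in enumerate(self.groups):
            if y_per_group is not None:
                y = y_per_group[k]
            fN, fI, fU = species_fractions(*theta, u, self.RT)
            X = _design_matrix(fN, fI, fU, u, self.i_slope)
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            betas.append(beta)
            resid.append(r)
            sse += float(r @ r)
        return betas, resid, sse

    def residuals(self, theta, y_per_group=None) -> np.ndarray:
        _, resid, _ = self.solve_baselines(theta, y_per_group)
        return np.concatenate(resid)


def _apparent_fraction_proxy(problem: _GlobalProblem) -> tuple[np.ndarray, np.ndarray]:
    """Rough fraction-unfolded curve averaged over wavelengths, for starts."""
    curves = []
    u_ref = None
    for _, u, y in problem.groups:
        lo = np.mean(y[:3]) if len(y) >= 3 else y[0]
        hi = np.mean(y[-3:]) if len(y) >= 3 else y[-1]
        denom = hi - lo
        if abs(denom) < 1e-12:
            continue
        curves.append((y - lo) / denom)
        u_ref = u
    if not curves or u_ref is None:
        raise FitFailureError("signal shows no urea dependence; cannot initialize fit")
    n = min(len(c) for c in curves)
    f = np.mean([c[:n] for c in curves], axis=0)
    return u_ref[:n], f


def _initial_midpoints(u: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Guess the two transition midpoints from the steepest regions of a
    smoothed apparent-fraction curve."""
    if len(f) >= 5:
        kernel = np.ones(3) / 3.0
        f = np.convolve(f, kernel, mode="same")
    df = np.abs(np.gradient(f, u))
    order = np.argsort(df)[::-1]
    c1 = u[order[0]]
    c2 = None
    for idx in order[1:]:
        if abs(u[idx] - c1) >= 1.0:
            c2 = u[idx]
            break
    if c2 is None:  # single visible transition: bracket it
        c2 = c1 + 1.5
        c1 = max(c1 - 1.5, 0.5)
    return (min(c1, c2), max(c1, c2))


def fit_three_state(
    data: MeltDataset,
    *,
    i_baseline_slope: bool = False,
    n_starts: int = 10,
    bootstrap: int = 200,
    seed: int = 0,
    temperature: float | None = None,
    max_nfev: int = 400,
) -> ThreeStateFit:
    """Globally fit a three-state linear-extrapolation model to one melt.

    Thermodynamic parameters are shared across all wavelengths; baselines
    are per wavelength and profiled out linearly.  ``n_starts`` jittered
    restarts guard against local minima; parameter SEs and CIs come from
    ``bootstrap`` residual-resampling refits.  Fully deterministic for a
    fixed ``seed``.
    """
    if temperature is None:
        temperature = data.temperature
    RT = rt(temperature)

    df = data.data
    finite = np.isfinite(df["signal"].to_numpy(float))
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropping %d non-finite signal rows for %s", n_dropped, data.variant_id)
        df = df.loc[finite]
    warnings_: list[str] = []
    n_urea = df["urea_M"].nunique()
    if n_urea < 8:
        raise InvalidInputError(
            f"need >= 8 distinct urea concentrations, got {n_urea}"
        )

    problem = _GlobalProblem(df, RT, i_baseline_slope)
    u_proxy, f_proxy = _apparent_fraction_proxy(problem)
    c1, c2 = _initial_midpoints(u_proxy, f_proxy)
    m1_0, m2_0 = 1.5, 1.0
    theta0 = np.array([m1_0 * c1, m1_0, m2_0 * c2, m2_0])
    theta0 = np.clip(theta0, _LOWER_BOUNDS + 1e-6, _UPPER_BOUNDS - 1e-6)

    rng = np.random.default_rng(seed)
    jitter_scale = np.array([1.0, 0.4, 1.0, 0.3])

    best = None
    for start in range(max(1, n_starts)):
        theta_s = theta0.copy()
        if start > 0:
            theta_s = theta0 + rng.normal(0.0, jitter_scale)
            theta_s = np.clip(theta_s, _LOWER_BOUNDS + 1e-6, _UPPER_BOUNDS - 1e-6)
        try:
            sol = least_squares(
                problem.residuals,
                theta_s,
                bounds=(_LOWER_BOUNDS, _UPPER_BOUNDS),
                method="trf",
                max_nfev=max_nfev,
            )
        except Exception:  # singular step, overflow in a bad corner, ...
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError(f"three-state fit failed for {data.variant_id}: no start converged")

    theta_hat = best.x
    betas, resid_groups, sse = problem.solve_baselines(theta_hat)
    resid = np.concatenate(resid_groups)
    yhat_groups = [y - r for (_, _, y), r in zip(problem.groups, resid_groups)]
    rms = float(np.sqrt(sse / problem.n_obs))

    _, _, fU_max = species_fractions(*theta_hat, df["urea_M"].max(), RT)
    if fU_max < 0.9:
        warnings_.append(
            "urea range may not span the second transition "
            f"(fU at max urea = {fU_max:.2f})"
        )
    if species_fractions(*theta_hat, df["urea_M"].min(), RT)[0] < 0.9:
        warnings_.append("urea range may not capture the native baseline")

    boot = None
    ses = np.full(4, np.nan)
    if bootstrap and bootstrap > 0:
        boot_rng = np.random.default_rng(seed + 1)
        thetas = np.empty((bootstrap, 4))
        n = problem.n_obs
        sizes = [len(u) for _, u, _ in problem.groups]
        offsets = np.cumsum([0] + sizes)
        for b in range(bootstrap):
            r_b = boot_rng.choice(resid, size=n, replace=True)
            y_b = [
                yhat_groups[k] + r_b[offsets[k]: offsets[k + 1]]
                for k in range(len(sizes))
            ]
            try:
                sol_b = least_squares(
                    problem.residuals,
                    theta_hat,
                    args=(y_b,),
                    bounds=(_LOWER_BOUNDS, _UPPER_BOUNDS),
                    method="trf",
                    max_nfev=max_nfev // 2,
                )
                thetas[b] = sol_b.x
            except Exception:
                thetas[b] = np.nan
        boot = thetas[np.all(np.isfinite(thetas), axis=1)]
        if len(boot) >= 10:
            ses = boot.std(axis=0, ddof=1)
        else:
            warnings_.append("bootstrap produced too few valid replicates for SEs")

    species_rows = []
    for (wl, _, _), beta in zip(problem.groups, betas):
        if i_baseline_slope:
            aN, bN, aI, bI, aU, bU = beta
        else:
            aN, bN, aI, aU, bU = beta
            bI = 0.0
        for sp, a, bsl in (("N", aN, bN), ("I", aI, bI), ("U", aU, bU)):
            species_rows.append(
                {"wavelength_nm": wl, "species": sp, "intercept": a, "slope": bsl}
            )

    return ThreeStateFit(
        variant_id=data.variant_id,
        dG_NI=float(theta_hat[0]),
        m_NI=float(theta_hat[1]),
        dG_IU=float(theta_hat[2]),
        m_IU=float(theta_hat[3]),
        dG_NI_se=float(ses[0]),
        m_NI_se=float(ses[1]),
        dG_IU_se=float(ses[2]),
        m_IU_se=float(ses[3]),
        baselines=pd.DataFrame(species_rows),
        rms=rms,
        n_obs=problem.n_obs,
        temperature=temperature,
        bootstrap=boot,
        warnings=warnings_,
    )


def fraction_unfolded_apparent(
    data: MeltDataset, fit: ThreeStateFit, wavelength: float
) -> pd.DataFrame:
    """Baseline-normalized apparent fraction unfolded at one wavelength.

    F_app = (Y - Y_N(urea)) / (Y_U(urea) - Y_N(urea)); noisy points may
    fall slightly outside [0, 1] and are deliberately not clipped.
    """
    sub = data.data[data.data["wavelength_nm"] == wavelength]
    if len(sub) == 0:
        raise InvalidInputError(f"no observations at wavelength {wavelength} nm")
    u = sub["urea_M"].to_numpy(float)
    y = sub["signal"].to_numpy(float)
    aN, bN = _baseline_row(fit.baselines, wavelength, "N")
    aU, bU = _baseline_row(fit.baselines, wavelength, "U")
    yN = aN + bN * u
    yU = aU + bU * u
    denom = yU - yN
    scale = max(np.abs(y).max(), 1.0)
    if np.median(np.abs(denom)) < 1e-9 * scale:
        raise InvalidInputError("degenerate baselines: Y_U ~ Y_N at this wavelength")
    return pd.DataFrame({"urea_M": u, "F_app": (y - yN) / denom})


def stability_perturbation(wt: ThreeStateFit, mut: ThreeStateFit) -> StabilityPerturbation:
    """ddG0 = dG0(WT) - dG0(mutant) per transition, SEs in quadrature.

    Positive values mean the mutation destabilizes that transition.
    """
    return StabilityPerturbation(
        variant_id=mut.variant_id,
        ddG_NI=wt.dG_NI - mut.dG_NI,
        ddG_NI_se=float(np.hypot(wt.dG_NI_se, mut.dG_NI_se)),
        ddG_IU=wt.dG_IU - mut.dG_IU,
        ddG_IU_se=float(np.hypot(wt.dG_IU_se, mut.dG_IU_se)),
    )
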