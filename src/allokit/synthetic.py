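"""Ground-truth-known synthetic datasets for every pipeline stage.

Each generator emulates the statistical structure its downstream fitting
stage assumes, so parameter recovery can be tested without any external
data: urea melts are species-population-weighted linear baselines plus
additive Gaussian noise on the CD signal; Michaelis-Menten velocities
carry multiplicative Gaussian noise (a constant coefficient of
variation); competition trajectories are linear in log2 ratio with
additive Gaussian noise; Western-blot abundances are lognormal around the
true fold.  All randomness flows through explicitly passed integer seeds
(no global state), so identical seeds reproduce byte-identical datasets.

Default parameter values describe a moderately stable thermophilic
TIM-barrel enzyme assayed at 30 degC: dG0_NI = 5.5 kcal/mol with
m_NI = 1.8 kcal/(mol*M) (first transition midpoint near 3 M urea),
dG0_IU = 5.0 kcal/mol with m_IU = 1.0 (second midpoint near 5 M),
kcat = 9.5 1/s and Km = 359 uM at 1 uM enzyme, and a wild-type doubling
time of 4.5 hr (k = ln2/4.5 per hr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, rt
from .errors import InvalidInputError
from .fitness import LN2, GrowthDataset
from .kinetics import KineticsDataset, michaelis_menten
from .unfolding import MeltDataset, species_fractions

#: Default urea grid: 0-9 M in 0.25 M steps (37 points).
DEFAULT_UREA_GRID = tuple(np.round(np.arange(0.0, 9.0 + 1e-9, 0.25), 4))

#: Default CD wavelengths (nm): a small band on the alpha-helical shoulder.
DEFAULT_WAVELENGTHS = (218.0, 221.0, 224.0, 227.0, 230.0)

#: Default substrate grid (uM): 12 levels from 0 to 1500.
DEFAULT_SUBSTRATE_GRID = (
    0.0, 25.0, 50.0, 100.0, 150.0, 250.0, 400.0, 600.0, 800.0, 1000.0, 1250.0, 1500.0
)

#: Properties a cycle scenario may perturb; "dGcat" acts on kcat through
#: the activation barrier.
CYCLE_SCENARIO_PROPERTIES = ("dG_NI", "dG_IU", "dGcat")


def default_baselines(wavelengths=DEFAULT_WAVELENGTHS) -> dict:
    """Realistic per-wavelength CD baselines (mean residue ellipticity,
    10^-3 deg cm^2/dmol) for the three species; N and U slope with urea,
    the intermediate baseline is flat.  The intermediate's spectral shape
    differs from a simple N/U mixture -- its position between the native
    and unfolded signals shifts across the band -- which is what gives a
    multi-wavelength global fit its power to separate the two
    transitions."""
    out = {}
    for wl in wavelengths:
        d = wl - 218.0
        a_n, a_u = -14.0 + 0.25 * d, -3.5 + 0.12 * d
        frac_i = 0.25 + 0.05 * d  # I sits 25% (218 nm) to 85% (230 nm) of the way to U
        out[float(wl)] = {
            "N": (a_n, 0.02),
            "I": (a_n + frac_i * (a_u - a_n), 0.0),
            "U": (a_u, -0.06),
        }
    return out


@dataclass
class GroundTruth:
    """True parameters for one simulated variant across all assays."""

    variant_id: str = "WT"
    dG_NI: float = 5.5                 # kcal/mol
    m_NI: float = 1.8                  # kcal/(mol*M)
    dG_IU: float = 5.0                 # kcal/mol
    m_IU: float = 1.0                  # kcal/(mol*M)
    baselines: dict | None = None      # wavelength -> species -> (intercept, slope)
    kcat: float = 9.5                  # 1/s
    Km: float = 359.0                  # uM
    E0: float = 1.0                    # uM
    growth_rate: float = LN2 / 4.5     # 1/hr  (4.5 hr doubling time)
    abundance_fold: float = 1.0        # relative to WT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_NI <= 0 or self.m_IU <= 0:
            raise InvalidInputError("m-values must be positive")
        if self.Km <= 0 or self.E0 <= 0:
            raise InvalidInputError("Km and E0 must be positive")
        if self.abundance_fold <= 0:
            raise InvalidInputError("abundance fold must be positive")

    def baselines_for(self, wavelengths) -> dict:
        base = self.baselines if self.baselines is not None else default_baselines(wavelengths)
        missing = [wl for wl in wavelengths if float(wl) not in base]
        if missing:
            raise InvalidInputError(f"no baselines for wavelengths {missing}")
        return base

    def melt_signal(self, urea, wavelength: float, temperature: float = DEFAULT_TEMPERATURE_K):
        """Noiseless model signal: the same population-weighted-baseline
        expression the unfolding stage fits."""
        u = np.asarray(urea, dtype=float)
        fN, fI, fU = species_fractions(
            self.dG_NI, self.m_NI, self.dG_IU, self.m_IU, u, rt(temperature)
        )
        b = self.baselines_for([wavelength])[float(wavelength)]
        return (
            fN * (b["N"][0] + b["N"][1] * u)
            + fI * (b["I"][0] + b["I"][1] * u)
            + fU * (b["U"][0] + b["U"][1] * u)
        )


def simulate_melt(
    truth: GroundTruth,
    urea_grid=DEFAULT_UREA_GRID,
    wavelengths=DEFAULT_WAVELENGTHS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> MeltDataset:
    """Simulate an equilibrium urea melt observed by CD.

    Additive Gaussian noise of SD ``noise_sd`` (signal units) on every
    (urea, wavelength) observation.
    """
    urea = np.asarray(urea_grid, dtype=float)
    wls = [float(w) for w in wavelengths]
    if urea.size == 0 or len(wls) == 0:
        raise InvalidInputError("urea grid and wavelength list must be non-empty")
    if (urea < 0).any() or np.any(np.diff(urea) < 0):
        raise InvalidInputError("urea grid must be nonnegative and ascending")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for wl in wls:
        y = truth.melt_signal(urea, wl, temperature)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        for u, s in zip(urea, y):
            rows.append((u, wl, s))
    df = pd.DataFrame(rows, columns=["urea_M", "wavelength_nm", "signal"])
    df["replicate"] = 1
    df["variant_id"] = truth.variant_id
    return MeltDataset(variant_id=truth.variant_id, data=df, temperature=temperature)


def simulate_kinetics(
    truth: GroundTruth,
    substrate_grid=DEFAULT_SUBSTRATE_GRID,
    noise_cv: float = 0.0,
    calib: float | None = None,
    seed: int | None = None,
    replicates: int = 3,
    progress: bool = False,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> KineticsDataset:
    """Simulate initial velocities (uM/s) for a Michaelis-Menten enzyme.

    Noise is multiplicative Gaussian with coefficient of variation
    ``noise_cv``.  With ``progress=True`` and a ``calib`` factor, early
    saturating progress curves in RFU are emitted as well.
    """
    s = np.asarray(substrate_grid, dtype=float)
    if s.size == 0:
        raise InvalidInputError("substrate grid must be non-empty")
    if (s < 0).any():
        raise InvalidInputError("substrate concentrations must be nonnegative")
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be nonnegative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    vmax = truth.kcat * truth.E0
    rows = []
    for rep in range(1, replicates + 1):
        v_true = michaelis_menten(s, vmax, truth.Km)
        v = v_true.copy()
        if noise_cv > 0:
            v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
        for si, vi in zip(s, v):
            rows.append((si, rep, vi))
    data = pd.DataFrame(rows, columns=["substrate_uM", "replicate", "v0"])
    data["variant_id"] = truth.variant_id

    prog = None
    if progress:
        if calib is None or calib <= 0:
            raise InvalidInputError("progress curves require a positive calib (RFU/uM)")
        t = np.arange(0.0, 120.0, 2.0)
        prows = []
        for si in s[s > 0]:
            v0 = michaelis_menten(si, vmax, truth.Km)
            amp = 0.9 * si                       # product approached at completion
            k_exp = v0 / amp                     # initial slope = v0 exactly
            p_um = amp * (1.0 - np.exp(-k_exp * t))
            y = calib * p_um
            if noise_cv > 0:
                y = y + rng.normal(0.0, noise_cv * calib * max(amp, 1.0) * 0.01, size=y.shape)
            for ti, yi in zip(t, y):
                prows.append((si, ti, yi))
        prog = pd.DataFrame(prows, columns=["substrate_uM", "time_s", "rfu"])

    return KineticsDataset(
        variant_id=truth.variant_id,
        E0=truth.E0,
        data=data,
        progress=prog,
        calib=calib,
        temperature=temperature,
    )


def simulate_competition(
    k_WT: float,
    k_MT: float,
    k_vector: float = 0.0,
    timepoints=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    mutant_id: str = "MT",
) -> GrowthDataset:
    """Simulate log2 mutant:WT competition trajectories.

    Exponential growth makes log2(N_MT/N_WT) linear in time with slope
    (k_MT - k_WT)/ln2 per hour.  The dataset includes the mutant, a flat
    WT self-ratio reference, and a vector-only control (growth rate
    ``k_vector``; 0 = lethal in selective medium).  Additive Gaussian
    noise of ``noise_sd`` log2 units per observation.
    """
    if timepoints is None:
        timepoints = np.linspace(0.0, 31.5, 8)  # ~7 WT doublings at 4.5 hr
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 2:
        raise InvalidInputError("need >= 2 timepoints")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    tracks = [
        (mutant_id, (k_MT - k_WT) / LN2, False),
        ("WT", 0.0, False),
        ("vector", (k_vector - k_WT) / LN2, True),
    ]
    for vid, slope, is_vec in tracks:
        for rep in range(1, replicates + 1):
            y = slope * t
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=y.shape)
            for ti, yi in zip(t, y):
                rows.append((vid, rep, ti, yi, is_vec))
    df = pd.DataFrame(
        rows, columns=["variant_id", "replicate", "time_hr", "log2_ratio", "is_vector_control"]
    )
    df.insert(0, "sample_id", df["variant_id"] + "_r" + df["replicate"].astype(str))
    return GrowthDataset(data=df)


def simulate_abundance(
    folds: dict[str, float],
    *,
    replicates: int = 3,
    noise_cv: float = 0.15,
    seed: int = 0,
    wt_level: float = 1000.0,
    loading_level: float = 500.0,
) -> pd.DataFrame:
    """Simulate Western-blot band intensities with a loading control.

    ``folds`` maps variant id -> true abundance fold versus WT (the
    observed range in this system is roughly 1-2.5x).  Band intensities
    are lognormal around their expectation with coefficient of variation
    ``noise_cv``.
    """
    if "WT" not in folds:
        folds = {"WT": 1.0, **folds}
    if any(f <= 0 for f in folds.values()):
        raise InvalidInputError("abundance folds must be positive")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0
    rows = []
    for vid, fold in folds.items():
        for rep in range(1, replicates + 1):
            mu_igps = wt_level * fold
            igps = mu_igps * rng.lognormal(-0.5 * sigma ** 2, sigma) if sigma else mu_igps
            load = loading_level * (rng.lognormal(-0.5 * sigma ** 2, sigma) if sigma else 1.0)
            rows.append((vid, rep, igps, load))
    return pd.DataFrame(
        rows, columns=["variant_id", "replicate", "igps_intensity", "loading_intensity"]
    )


def _apply_effects(base: GroundTruth, variant_id: str, effects: dict[str, float], seed: int) -> GroundTruth:
    out = replace(base, variant_id=variant_id, seed=seed)
    for prop, delta in effects.items():
        if prop not in CYCLE_SCENARIO_PROPERTIES:
            raise InvalidInputError(
                f"unknown property '{prop}'; expected one of {CYCLE_SCENARIO_PROPERTIES}"
            )
        # effects use the downstream perturbation convention: positive =
        # destabilized (ddG = dG_WT - dG_mut) or higher barrier (slower kcat)
        if prop == "dG_NI":
            out = replace(out, dG_NI=out.dG_NI - delta)
        elif prop == "dG_IU":
            out = replace(out, dG_IU=out.dG_IU - delta)
        else:  # dGcat: a barrier increase of delta slows kcat by exp(-delta/RT)
            out = replace(out, kcat=out.kcat * math.exp(-delta / rt()))
    return out


def simulate_cycle_scenario(
    base: GroundTruth,
    effect_M1: dict[str, float],
    effect_M2: dict[str, float],
    injected_delta: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, GroundTruth]:
    """Four ground truths (WT, M1, M2, DM) for a double-mutant cycle.

    Effects and the injected interaction energy are free-energy deltas in
    kcal/mol on the properties in ``CYCLE_SCENARIO_PROPERTIES``; the
    double mutant carries effect_M1 + effect_M2 + injected_delta, so a
    zero injected delta yields an exactly additive cycle.
    """
    injected_delta = injected_delta or {}
    for d in (effect_M1, effect_M2, injected_delta):
        for prop in d:
            if prop not in CYCLE_SCENARIO_PROPERTIES:
                raise InvalidInputError(
                    f"unknown property '{prop}'; expected one of {CYCLE_SCENARIO_PROPERTIES}"
                )
    dm_effects: dict[str, float] = {}
    for prop in CYCLE_SCENARIO_PROPERTIES:
        total = effect_M1.get(prop, 0.0) + effect_M2.get(prop, 0.0) + injected_delta.get(prop, 0.0)
        if total != 0.0:
            dm_effects[prop] = total
    return {
        "WT": replace(base, variant_id="WT", seed=seed),
        "M1": _apply_effects(base, "M1", effect_M1, seed + 1),
        "M2": _apply_effects(base, "M2", effect_M2, seed + 2),
        "DM": _apply_effects(base, "DM", dm_effects, seed + 3),
    }
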