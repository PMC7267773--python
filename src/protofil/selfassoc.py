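"""Sedimentation-equilibrium monomer-dimer self-association analysis.

At sedimentation equilibrium a single ideal species of molar mass M
distributes exponentially in the squared radius,

    c(r) = c(r0) * exp[ sigma * (r^2 - r0^2) / 2 ],
    sigma = M (1 - vbar * rho) * omega^2 / (R T)          [cm^-2]

with omega the rotor angular velocity, vbar the partial specific volume
and rho the solvent density (cgs units internally: cm, g, erg).  For a
monomer-dimer equilibrium with dissociation constant K_D = [M]^2 / [D],
mass action ties the dimer profile to the square of the monomer profile:

    signal(r) = eps * ( m(r) + 2 d(r) ),
    m(r) = m0 exp[sigma (r^2 - r0^2)/2],
    d(r) = (m0^2 / K_D) exp[2 sigma (r^2 - r0^2)/2],

in molar monomer-equivalents (the dimer carries two monomer signals).
The per-profile reference concentration m0 is fixed by conservation of
mass over the sector-shaped cell (radial weight proportional to r).

``fit_kd`` performs the global fit used to extract K_D from a multi-speed,
multi-loading experiment: one shared K_D across all profiles plus one
reference concentration per profile, by nonlinear least squares.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq, least_squares

__all__ = [
    "SelfAssocParams",
    "SedEqProfile",
    "FitResult",
    "reduced_buoyant_sigma",
    "monomer_dimer_fractions",
    "simulate_profiles",
    "fit_kd",
    "mgml_to_molar",
    "write_profiles_csv",
    "read_profiles_csv",
]

R_GAS_ERG = 8.314462618e7  # erg mol^-1 K^-1


@dataclass(frozen=True)
class SelfAssocParams:
    """Physical parameters of the self-associating species.

    monomer_mass g/mol; vbar mL/g; solvent_density g/mL; temperature K;
    kd molar (K_D = [M]^2/[D]); extinction_factor signal per molar
    monomer-equivalent.
    """

    monomer_mass: float
    vbar: float = 0.73
    solvent_density: float = 1.005
    temperature: float = 277.0
    kd: float | None = None
    extinction_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("monomer_mass", "vbar", "solvent_density", "temperature",
                     "extinction_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kd is not None and self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass(frozen=True)
class SedEqProfile:
    rpm: float
    radii: np.ndarray  # cm, strictly increasing
    signal: np.ndarray
    loading: float  # molar monomer-equivalent
    meniscus: float
    base: float

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if r.ndim != 1 or r.shape != s.shape:
            raise ValueError("radii and signal must be equal-length 1-D arrays")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing")
        if r[0] < self.meniscus - 1e-9 or r[-1] > self.base + 1e-9:
            raise ValueError("radii outside [meniscus, base]")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class FitResult:
    kd_hat: float
    kd_interval: tuple[float, float]
    rms_residual: float
    converged: bool
    reference_concentrations: tuple[float, ...]
    n_profiles: int
    message: str = ""


def mgml_to_molar(c_mgml: float, monomer_mass: float) -> float:
    """mg/mL loading to molar monomer-equivalent concentration.

    mg/mL equals g/L, so dividing by the molar mass in g/mol gives mol/L.
    """
    return c_mgml / monomer_mass


def reduced_buoyant_sigma(params: SelfAssocParams, rpm: float) -> float:
    """Reduced buoyant molar mass sigma = M(1 - vbar rho) omega^2 / (R T), cm^-2.

    The dimer exponent is 2 * sigma.  A buoyancy factor <= 0 (vbar*rho >= 1)
    is physically permitted and returned as sigma <= 0.
    """
    omega = rpm * 2.0 * np.pi / 60.0
    return params.monomer_mass * (1.0 - params.vbar * params.solvent_density) * omega**2 / (
        R_GAS_ERG * params.temperature
    )


def monomer_dimer_fractions(c_total: float, kd: float) -> tuple[float, float]:
    """Monomer and dimer-bound fractions of total monomer-equivalent concentration.

    Solves [M] + 2 [M]^2 / kd = c_total for [M] >= 0 (positive quadratic
    root); returns ([M]/c_total, 2[D]/c_total), which sum to 1.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if c_total < 0:
        raise ValueError("c_total must be >= 0")
    if c_total == 0:
        return 1.0, 0.0
    # 2 m^2 / kd + m - c = 0  ->  m = kd/4 * (sqrt(1 + 8 c / kd) - 1)
    m = 0.25 * kd * (np.sqrt(1.0 + 8.0 * c_total / kd) - 1.0)
    fm = m / c_total
    return float(fm), float(1.0 - fm)


def _profile_signal(
    radii: np.ndarray,
    m0: float,
    sigma: float,
    kd: float,
    r0: float,
    eps: float,
) -> np.ndarray:
    e = np.exp(sigma * (radii**2 - r0**2) / 2.0)
    return eps * (m0 * e + 2.0 * (m0**2 / kd) * e**2)


def _sector_mean(radii: np.ndarray, conc: np.ndarray) -> float:
    """Sector-weighted (r-weighted) mean concentration over the column."""
    return float(simpson(conc * radii, x=radii) / simpson(radii, x=radii))


def _solve_m0(
    radii: np.ndarray, sigma: float, kd: float, r0: float, loading: float
) -> float:
    """Reference monomer concentration enforcing conservation of mass."""

    def mass_gap(m0: float) -> float:
        e = np.exp(sigma * (radii**2 - r0**2) / 2.0)
        total = m0 * e + 2.0 * (m0**2 / kd) * e**2
        return _sector_mean(radii, total) - loading

    lo, hi = 0.0, max(loading, 1e-12)
    for _ in range(200):
        if mass_gap(hi) >= 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"could not bracket reference concentration (loading {loading:.3g} M, "
            f"sigma {sigma:.3g} cm^-2)"
        )
    return brentq(mass_gap, lo, hi, xtol=1e-18, rtol=1e-14)


def simulate_profiles(
    params: SelfAssocParams,
    speeds_rpm: list[float],
    loadings_molar: list[float],
    n_points: int = 120,
    meniscus: float = 6.0,
    base: float = 6.4,
    noise_sd: float = 0.0,
    relative_noise: float | None = None,
    seed: int | None = None,
) -> list[SedEqProfile]:
    """Simulate one equilibrium profile per (speed, loading) combination.

    ``noise_sd`` is an absolute Gaussian standard deviation in signal
    units; ``relative_noise`` instead scales the noise to that fraction of
    each profile's mean signal.  The reference radius is the meniscus and
    the reference concentration is solved per profile so the sector-
    weighted mean monomer-equivalent concentration equals the loading.
    """
    if params.kd is None:
        raise ValueError("params.kd must be set to simulate")
    rng = np.random.default_rng(seed)
    radii = np.linspace(meniscus, base, n_points)
    out: list[SedEqProfile] = []
    for rpm in speeds_rpm:
        sigma = reduced_buoyant_sigma(params, rpm)
        for loading in loadings_molar:
            m0 = _solve_m0(radii, sigma, params.kd, meniscus, loading)
            clean = _profile_signal(radii, m0, sigma, params.kd, meniscus,
                                    params.extinction_factor)
            sd = noise_sd
            if relative_noise is not None:
                sd = relative_noise * float(np.mean(clean))
            noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
            out.append(
                SedEqProfile(
                    rpm=rpm,
                    radii=radii.copy(),
                    signal=noisy,
                    loading=loading,
                    meniscus=meniscus,
                    base=base,
                )
            )
    return out


def fit_kd(
    profiles: list[SedEqProfile],
    params_known: SelfAssocParams,
    kd_init: float = 1e-4,
    confidence_sigma: float = 1.0,
) -> FitResult:
    """Global monomer-dimer fit: one K_D shared across profiles.

    Free parameters are log K_D plus one log reference (meniscus) monomer
    concentration per profile; M, vbar, rho and T are held fixed.  The
    interval is the ``confidence_sigma``-sigma linearized confidence range
    on K_D from the Jacobian at the optimum.  Non-convergence is reported,
    never silently ignored.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    sigmas = [reduced_buoyant_sigma(params_known, p.rpm) for p in profiles]
    eps = params_known.extinction_factor

    m0_init = []
    for p, sg in zip(profiles, sigmas):
        try:
            m0_init.append(_solve_m0(p.radii, sg, kd_init, p.meniscus, p.loading))
        except RuntimeError:
            m0_init.append(p.loading)

    x0 = np.log(np.concatenate([[kd_init], m0_init]))

    def residuals(x: np.ndarray) -> np.ndarray:
        kd = np.exp(x[0])
        res = []
        for k, (p, sg) in enumerate(zip(profiles, sigmas)):
            m0 = np.exp(x[1 + k])
            model = _profile_signal(p.radii, m0, sg, kd, p.meniscus, eps)
            res.append(model - p.signal)
        return np.concatenate(res)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000)
    kd_hat = float(np.exp(sol.x[0]))
    refs = tuple(float(v) for v in np.exp(sol.x[1:]))
    rms = float(np.sqrt(np.mean(sol.fun**2)))

    # linearized confidence interval on log kd
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        sd_log = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        sd_log = np.inf
    lo = kd_hat * np.exp(-confidence_sigma * sd_log)
    hi = kd_hat * np.exp(confidence_sigma * sd_log)
    converged = bool(sol.success)
    return FitResult(
        kd_hat=kd_hat,
        kd_interval=(float(lo), float(hi)),
        rms_residual=rms,
        converged=converged,
        reference_concentrations=refs,
        n_profiles=len(profiles),
        message=str(sol.message),
    )


def write_profiles_csv(profiles: list[SedEqProfile], path: str | Path) -> Path:
    """Profiles as a flat CSV (radius_cm, signal, rpm, loading_molar, meniscus, base)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["radius_cm", "signal", "rpm", "loading_molar", "meniscus_cm", "base_cm"])
        for p in profiles:
            for r, s in zip(p.radii, p.signal):
                w.writerow([f"{r:.6f}", f"{s:.10e}", f"{p.rpm:g}", f"{p.loading:.10e}",
                            f"{p.meniscus:.4f}", f"{p.base:.4f}"])
    return path


def read_profiles_csv(path: str | Path) -> list[SedEqProfile]:
    rows: dict[tuple[float, float], list[tuple[float, float, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            key = (float(rec["rpm"]), float(rec["loading_molar"]))
            rows.setdefault(key, []).append(
                (float(rec["radius_cm"]), float(rec["signal"]),
                 float(rec["meniscus_cm"]), float(rec["base_cm"]))
            )
    out = []
    for (rpm, loading), data in rows.items():
        data.sort(key=lambda d: d[0])
        radii = np.array([d[0] for d in data])
        signal = np.array([d[1] for d in data])
        out.append(SedEqProfile(rpm=rpm, radii=radii, signal=signal, loading=loading,
                                meniscus=data[0][2], base=data[0][3]))
    return out
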