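"""Two-step covalent binding kinetics.

An irreversible covalent inhibitor binds its target in two steps: fast,
reversible recognition of the protein (characterised by the dissociation
constant ``K_I = k_-1 / k_1``) followed by the chemical, bond-forming step
from the noncovalent complex (first-order rate ``k_inact``)::

    E + I  <=== k_1 / k_-1 ===>  E.I  --- k_inact --->  E-I

Under rapid pre-equilibrium and excess inhibitor the loss of unlabelled
enzyme is pseudo-first-order with the hyperbolic observed rate

    k_obs(c) = k_inact * c / (K_I + c)

which saturates at ``k_inact`` and whose low-concentration slope is the
second-order efficiency ``k_inact / K_I``.  This module provides the
analytic observables and the full mass-action ODE used to validate the
rapid-equilibrium approximation.

Internal unit system is strict SI: concentrations in M, times in s,
rates in s^-1 (first order) or M^-1 s^-1 (second order).  Micromolar and
hours appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "TwoStepParams",
    "OccupancyTimeCourse",
    "SpeciesTrajectory",
    "analytic_kobs",
    "occupancy_curve",
    "simulate_two_step_ode",
]


@dataclass(frozen=True)
class TwoStepParams:
    """Kinetic identity of one compound-protein pair.

    Parameters
    ----------
    K_I : float
        Dissociation constant of the reversible complex (M); > 0.
    k_inact : float
        First-order rate of the covalent step (s^-1); >= 0.
    k_1, k_minus1 : float, optional
        Microscopic association (M^-1 s^-1) and dissociation (s^-1)
        rates.  When both are given they must be consistent with
        ``K_I = k_minus1 / k_1``.
    """

    K_I: float
    k_inact: float
    k_1: float | None = None
    k_minus1: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.K_I) or self.K_I <= 0:
            raise ValueError(f"K_I must be positive and finite, got {self.K_I}")
        if not np.isfinite(self.k_inact) or self.k_inact < 0:
            raise ValueError(f"k_inact must be >= 0, got {self.k_inact}")
        if (self.k_1 is None) != (self.k_minus1 is None):
            raise ValueError("k_1 and k_minus1 must be given together")
        if self.k_1 is not None and self.k_minus1 is not None:
            if self.k_1 <= 0 or self.k_minus1 < 0:
                raise ValueError("microscopic rates must be positive")
            implied = self.k_minus1 / self.k_1
            if not np.isclose(implied, self.K_I, rtol=1e-9, atol=0.0):
                raise ValueError(
                    f"inconsistent microscopic rates: k_minus1/k_1 = {implied:g} "
                    f"but K_I = {self.K_I:g}"
                )

    @property
    def efficiency(self) -> float:
        """Second-order efficiency k_inact / K_I (M^-1 s^-1)."""
        return self.k_inact / self.K_I


@dataclass(frozen=True)
class OccupancyTimeCourse:
    """One MS target-engagement experiment: fractional covalent occupancy
    of the protein sampled over time at a single inhibitor concentration.
    """

    compound_id: str
    conc: float  # M
    times: np.ndarray  # s, strictly increasing, >= 0
    occupancy: np.ndarray  # fractions in [0, 1]
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "occupancy", occ)
        if self.conc < 0:
            raise ValueError("concentration must be >= 0")
        if times.ndim != 1 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("times must be 1-D, nonnegative and strictly increasing")
        if occ.shape != times.shape:
            raise ValueError("occupancy and times must have matching shapes")
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancy values must lie in [0, 1]")


@dataclass(frozen=True)
class SpeciesTrajectory:
    """Mass-action trajectory of the two-step scheme.

    Concentrations (M) of free enzyme E, free inhibitor I, the
    noncovalent complex EI, and the covalent adduct E-I at each time.
    """

    times: np.ndarray
    E: np.ndarray
    I: np.ndarray
    EI: np.ndarray
    EI_cov: np.ndarray
    E0: float = field(default=0.0)

    def __post_init__(self) -> None:
        total = self.E + self.EI + self.EI_cov
        e0 = self.E0 if self.E0 > 0 else total[0]
        if np.any(np.abs(total - e0) > 1e-6 * e0):
            raise ValueError("enzyme mass not conserved to 1e-6 relative")
        for name in ("E", "I", "EI", "EI_cov"):
            if np.any(getattr(self, name) < -1e-15):
                raise ValueError(f"negative concentration in {name}")

    @property
    def adduct_fraction(self) -> np.ndarray:
        """Covalent occupancy: adduct as a fraction of total enzyme."""
        e0 = self.E0 if self.E0 > 0 else (self.E + self.EI + self.EI_cov)[0]
        return self.EI_cov / e0

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (columns time_s, E_M, EI_M, EI_cov_M, I_M)."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "E_M": self.E,
                "EI_M": self.EI,
                "EI_cov_M": self.EI_cov,
                "I_M": self.I,
            }
        )


def analytic_kobs(params: TwoStepParams, conc: float | np.ndarray) -> float | np.ndarray:
    """Pseudo-first-order inactivation rate at inhibitor concentration ``conc``.

    k_obs = k_inact * c / (K_I + c): hyperbolic in c, saturating at
    k_inact, with initial slope k_inact / K_I.

    Parameters
    ----------
    params : TwoStepParams
    conc : float or ndarray
        Inhibitor concentration(s) in M; must be >= 0.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = params.k_inact * c / (params.K_I + c)
    return float(out) if np.isscalar(conc) else out


def occupancy_curve(
    k_obs: float, plateau: float, times: np.ndarray | float
) -> np.ndarray | float:
    """One-phase association of covalent occupancy toward a plateau.

    occupancy(t) = plateau * (1 - exp(-k_obs * t)); the protein starts
    fully unlabelled, so occupancy(0) = 0.  Equivalently the unlabelled
    fraction decays exponentially ("one-phase decay").

    Parameters
    ----------
    k_obs : float
        Pseudo-first-order labelling rate (s^-1); >= 0.
    plateau : float
        Saturation occupancy, in (0, 1].
    times : array-like
        Times (s).
    """
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    if not 0 < plateau <= 1:
        raise ValueError("plateau must lie in (0, 1]")
    t = np.asarray(times, dtype=float)
    out = plateau * -np.expm1(-k_obs * t)
    return float(out) if np.isscalar(times) else out


def simulate_two_step_ode(
    k_1: float,
    k_minus1: float,
    k_inact: float,
    E0: float,
    I0: float,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SpeciesTrajectory:
    """Integrate the mass-action ODE of the two-step scheme.

        dE/dt    = -k_1 E I + k_minus1 EI
        dI/dt    = -k_1 E I + k_minus1 EI
        dEI/dt   =  k_1 E I - (k_minus1 + k_inact) EI
        dEIc/dt  =  k_inact EI

    Inhibitor depletion is modelled explicitly; no excess assumption is
    made.  An adaptive stiff solver is used because the pre-equilibration
    transient (timescale 1/(k_1 I0 + k_minus1)) can be orders of
    magnitude faster than inactivation.

    Parameters
    ----------
    k_1 : float
        Association rate (M^-1 s^-1).
    k_minus1, k_inact : float
        Dissociation and inactivation rates (s^-1).
    E0, I0 : float
        Initial free enzyme and inhibitor (M); > 0.
    times : array-like
        Output times (s), strictly increasing, >= 0.
    """
    for name, v in (("k_1", k_1), ("k_minus1", k_minus1), ("k_inact", k_inact),
                    ("E0", E0), ("I0", I0)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if E0 <= 0 or I0 <= 0:
        raise ValueError("E0 and I0 must be > 0")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be 1-D, nonnegative, strictly increasing")

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        E, I, EI, _EIc = y
        assoc = k_1 * E * I
        return [
            -assoc + k_minus1 * EI,
            -assoc + k_minus1 * EI,
            assoc - (k_minus1 + k_inact) * EI,
            k_inact * EI,
        ]

    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1.0)
    sol = solve_ivp(
        rhs,
        t_span,
        [E0, I0, 0.0, 0.0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    E, I, EI, EIc = np.clip(sol.y, 0.0, None)
    return SpeciesTrajectory(times=t, E=E, I=I, EI=EI, EI_cov=EIc, E0=E0)
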