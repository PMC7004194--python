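"""Power-law surface-dissolution kinetics of pure CuO nanoparticles.

The release of Cu2+ follows

    dc/dt = k_Cu * c_s(t)^m * c_AA(t)^n

where c_s = k_site * A(t) is the surface copper concentration,
A(t) = A0 * (1 - c/c_tot)^(2/3) the active surface area of shrinking
monodisperse spheres at constant particle number, and
c_AA(t) = c_AA0 - nu * c(t) the free amino acid remaining after 1:nu
complexation (nu = 2 at physiological pH).  Dissolution is complete:
the curve tends to the total copper molarity while ligand lasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .particles import Inventory, MediumSpec, ParticleSystem, copper_inventories

__all__ = [
    "PureKineticParams",
    "ReleaseCurve",
    "simulate_pure_release",
    "amino_acid_remaining",
    "WrongModelError",
    "SolverFailure",
    "StoichiometryError",
]

#: default relative tolerance of the ODE integrator
ODE_RTOL = 1e-8


class WrongModelError(ValueError):
    """The condition's phase does not match the requested model."""


class SolverFailure(RuntimeError):
    """The ODE integrator failed or produced an inadmissible state."""


class StoichiometryError(ValueError):
    """Complexation bookkeeping drove the free amino acid negative."""


@dataclass(frozen=True)
class PureKineticParams:
    """Rate parameters of the power-law dissolution of pure CuO.

    ``k_cu`` carries the units fixed by the orders: with concentrations
    in mol m^-3 its units are mol^(1-m-n) m^(3(m+n-1)) s^-1.
    """

    k_cu: float
    m: float = 1.75
    n: float = 2.0
    k_site: float = 1.66e-5  # mol m^-2

    def __post_init__(self) -> None:
        if not (self.k_cu > 0):
            raise ValueError("k_cu must be positive")
        if not (self.m > 0):
            raise ValueError("m must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not (self.k_site > 0):
            raise ValueError("k_site must be positive")


@dataclass
class ReleaseCurve:
    """Cumulative dissolved Cu2+ versus time for one condition.

    times are seconds, concentrations mol m^-3.  ``condition`` carries
    free-form metadata (particle, medium, label); ``meta`` carries the
    molar inventories the mass-balance audit needs.
    """

    times: np.ndarray
    c_cu: np.ndarray
    condition: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_cu = np.asarray(self.c_cu, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.c_cu.shape:
            raise ValueError("times and c_cu must be 1-D arrays of equal length")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def label(self) -> str:
        return str(self.condition.get("label", "curve"))

    def to_frame(self):
        """Lab-facing table: hours and mM (1 mol m^-3 == 1 mM)."""
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times / 3600.0, "cu_mM": self.c_cu}
        )

    def plot(self, ax=None, **kwargs):
        """Release curve on logarithmic time (hours vs mM)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pos = self.times > 0
        ax.semilogx(self.times[pos] / 3600.0, self.c_cu[pos],
                    label=kwargs.pop("label", self.label), **kwargs)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("dissolved Cu$^{2+}$ (mM)")
        return ax


def _integrate_power_law(
    k_cu: float,
    m: float,
    n: float,
    cs_of_c: Callable[[float], float],
    cap: float,
    medium: MediumSpec,
    times: np.ndarray,
    rtol: float = ODE_RTOL,
) -> np.ndarray:
    """Integrate dc/dt = k * c_s(c)^m * c_AA(c)^n up to the cap.

    Shared by the pure model (c_s from shrinking spheres) and the doped
    burst (c_s from the finite surface inventory).  States are clamped
    at zero and integration stops when copper or amino acid runs out.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(times < 0) or (len(times) > 1 and not np.all(np.diff(times) > 0)):
        raise ValueError("times must be non-negative and strictly increasing")

    c_aa0, nu, excess = medium.c_aa0, medium.nu, medium.excess
    if not excess:
        cap = min(cap, c_aa0 / nu)
    if cap <= 0 or (not excess and c_aa0 <= 0):
        return np.zeros_like(times)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c = min(max(y[0], 0.0), cap)
        cs = max(cs_of_c(c), 0.0)
        caa = c_aa0 if excess else max(c_aa0 - nu * c, 0.0)
        if cs == 0.0 or caa == 0.0:
            return [0.0]
        return [k_cu * cs**m * caa**n]

    def exhausted(t: float, y: np.ndarray) -> float:
        return cap - y[0]

    exhausted.terminal = True
    exhausted.direction = -1

    t_end = float(times[-1])
    if t_end == 0.0:
        return np.zeros_like(times)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=rtol * max(cap, 1e-30) * 1e-3,
        events=exhausted,
    )
    if sol.status == -1:
        raise SolverFailure(f"ODE integration failed: {sol.message}")
    c = np.full_like(times, cap)
    c[: len(sol.y[0])] = sol.y[0]
    c = np.minimum(np.maximum.accumulate(np.maximum(c, 0.0)), cap)
    if np.any(~np.isfinite(c)):
        raise SolverFailure("non-finite state in release curve")
    return c


def simulate_pure_release(
    particle: ParticleSystem,
    medium: MediumSpec,
    params: PureKineticParams,
    times: np.ndarray,
    rtol: float = ODE_RTOL,
) -> ReleaseCurve:
    """Forward-simulate complete dissolution of pure CuO.

    Raises
    ------
    WrongModelError
        If the particle is iron-doped; use the doped two-step model.
    """
    if particle.f_fe0 > 0:
        raise WrongModelError(
            "particle has f_fe0 > 0; use cuokinetics.doped.simulate_doped_release"
        )
    inv: Inventory = copper_inventories(particle, params.k_site)
    c_tot = inv.total_cu_molarity
    cs0 = inv.surface_site_molarity

    def cs_of_c(c: float) -> float:
        if c_tot == 0.0:
            return 0.0
        # shrinking spheres: area ~ (remaining volume)^(2/3) at fixed N_p
        return cs0 * max(1.0 - c / c_tot, 0.0) ** (2.0 / 3.0)

    c = _integrate_power_law(params.k_cu, params.m, params.n, cs_of_c, c_tot, medium, times, rtol)
    return ReleaseCurve(
        times=np.asarray(times, dtype=float),
        c_cu=c,
        condition={
            "label": f"pure-{medium.amino_acid}",
            "amino_acid": medium.amino_acid,
            "f_fe0": 0.0,
            "d0": particle.d0,
            "mass_conc": particle.mass_conc,
            "c_aa0": medium.c_aa0,
        },
        meta={
            "model": "pure",
            "total_cu_molarity": c_tot,
            "surface_site_molarity": cs0,
            "remaining_cu_final": c_tot - float(c[-1]),
            "params": params,
        },
    )


def amino_acid_remaining(
    curve: ReleaseCurve, medium: MediumSpec, tol: float = 1e-9
) -> np.ndarray:
    """Free amino acid c_AA(t) = c_AA0 - nu * c_Cu(t), mol m^-3.

    Raises StoichiometryError if any value is below -tol (relative to
    the initial pool): more copper complexed than ligand available.
    """
    remaining = medium.c_aa0 - medium.nu * curve.c_cu
    if np.any(remaining < -tol * max(medium.c_aa0, 1.0)):
        raise StoichiometryError(
            "released copper exceeds the amino-acid pool at nu = "
            f"{medium.nu}: min free amino acid {remaining.min():.3e} mol m^-3"
        )
    return remaining
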