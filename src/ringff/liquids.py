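"""Liquid-phase thermodynamic observables from simulation time series.

Implements the finite-difference and fluctuation estimators used to validate
organic-liquid force-field parameters:

* density rho with 5-block averaging,
* enthalpy of vaporisation  dHvap = (Epot_gas + RT) - Epot_liquid/n,
* thermal expansion         alpha_P = -d(ln rho)/dT          (finite diff.),
* classical isobaric heat capacity  C_P = dU/dT per molecule,
* isothermal compressibility kappa_T = d(ln rho)/dP  (positive convention),
* static dielectric constant from box-dipole fluctuations with a
  running-average convergence check,
* the total-energy drift quality criterion in J/(mol ns DoF).

Units follow the GROMOS/GROMACS convention: kJ/mol, nm^3, bar, K, e.nm.
kappa_T is returned in 1/GPa and C_P in J/(mol K), the units liquid
benchmarks print.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as const

__all__ = [
    "EnergyVolumeSeries", "BlockAverage",
    "block_average", "density", "enthalpy_of_vaporization",
    "thermal_expansion", "heat_capacity", "isothermal_compressibility",
    "dielectric_constant", "energy_drift",
    "ENERGY_DRIFT_THRESHOLD",
]

#: QC threshold on total-energy drift, J/(mol ns DoF).
ENERGY_DRIFT_THRESHOLD = 0.5

_BAR_PER_GPA = 1.0e4
_E_NM = const.e * 1e-9  # 1 e.nm in C.m


@dataclass
class EnergyVolumeSeries:
    """Scalar observables of one simulation.

    All energies are totals for the whole box in kJ/mol; ``box_dipole`` rows
    are the instantaneous total box dipole M in e.nm (optional).
    """

    time: np.ndarray                      # ps, strictly increasing
    n_molecules: int
    Epot: np.ndarray | None = None        # kJ/mol (total system)
    Etot: np.ndarray | None = None        # kJ/mol (potential + kinetic)
    volume: np.ndarray | None = None      # nm^3
    pressure: np.ndarray | None = None    # bar
    temperature: np.ndarray | None = None  # K
    box_dipole: np.ndarray | None = None  # (n, 3) e.nm
    n_degrees_of_freedom: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size == 0:
            raise ValueError("series is empty")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        for name in ("Epot", "Etot", "volume", "pressure", "temperature"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise ValueError(f"{name} length does not match time")
                setattr(self, name, v)
        if self.box_dipole is not None:
            self.box_dipole = np.asarray(self.box_dipole, dtype=float)
            if self.box_dipole.shape != (self.time.size, 3):
                raise ValueError("box_dipole must be (n_frames, 3)")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class BlockAverage:
    """Mean and between-block SD over contiguous equal-length blocks."""

    mean: float
    sd: float
    n_blocks: int


def block_average(values, n_blocks: int = 5) -> BlockAverage:
    """Average over ``n_blocks`` contiguous equal blocks; remainder frames are
    dropped from the tail so the result is deterministic."""
    v = np.asarray(values, dtype=float)
    if v.size < n_blocks:
        raise ValueError(f"{v.size} samples cannot form {n_blocks} blocks")
    per = v.size // n_blocks
    blocks = v[: per * n_blocks].reshape(n_blocks, per)
    means = blocks.mean(axis=1)
    sd = float(means.std(ddof=1)) if n_blocks > 1 else 0.0
    return BlockAverage(mean=float(means.mean()), sd=sd, n_blocks=n_blocks)


def density(series: EnergyVolumeSeries, molar_mass: float, n_blocks: int = 5) -> BlockAverage:
    """Per-frame rho = n_mol * M / (N_A * V), block-averaged, in g/cm^3."""
    if series.volume is None:
        raise ValueError("series has no volume column")
    if np.any(series.volume <= 0):
        raise ValueError("non-positive volume encountered")
    v_cm3 = series.volume * 1e-21  # nm^3 -> cm^3
    rho = series.n_molecules * molar_mass / (const.N_A * v_cm3)
    return block_average(rho, n_blocks=n_blocks)


def enthalpy_of_vaporization(epot_gas: float, epot_liquid: float,
                             n_molecules: int, T: float = 298.15) -> float:
    """dHvap = (Epot_gas + RT) - Epot_liquid / n_molecules, kJ/mol.

    ``epot_gas`` is the per-molecule gas-phase mean; ``epot_liquid`` the total
    liquid-box mean (kJ/mol).  RT is 2.479 kJ/mol at 298.15 K.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rt = const.R * T / 1000.0
    return (epot_gas + rt) - epot_liquid / n_molecules


def thermal_expansion(rho_T1: float, rho_T2: float, T1: float, T2: float) -> float:
    """alpha_P = -(ln rho(T2) - ln rho(T1)) / (T2 - T1), in 1/K.

    Symmetric under swapping the two states.  With the bracketing states
    (T-10, T+10) this is the central difference at T.
    """
    if T1 == T2:
        raise ValueError("T1 and T2 must differ")
    if rho_T1 <= 0 or rho_T2 <= 0:
        raise ValueError("densities must be positive")
    return -(np.log(rho_T2) - np.log(rho_T1)) / (T2 - T1)


def heat_capacity(U_T1: float, U_T2: float, T1: float, T2: float,
                  n_molecules: int) -> float:
    """Classical isobaric heat capacity C_P = dU/dT per molecule, J/(mol K).

    ``U_*`` are total-box mean energies (potential + kinetic) in kJ/mol.  The
    classical estimator carries no quantum corrections and is known to
    overestimate experimental C_P.
    """
    if T1 == T2:
        raise ValueError("T1 and T2 must differ")
    return (U_T2 - U_T1) / ((T2 - T1) * n_molecules) * 1000.0


def isothermal_compressibility(rho_P1: float, rho_P2: float,
                               P1: float, P2: float) -> float:
    """kappa_T = (ln rho(P2) - ln rho(P1)) / (P2 - P1), in 1/GPa.

    Sign convention: density rising with pressure gives kappa_T > 0 (the
    physically positive compressibility; recasting -1/V dV/dP in terms of
    rho cancels the minus sign).  Pressures are in bar.
    """
    if P1 == P2:
        raise ValueError("P1 and P2 must differ")
    if rho_P1 <= 0 or rho_P2 <= 0:
        raise ValueError("densities must be positive")
    per_bar = (np.log(rho_P2) - np.log(rho_P1)) / (P2 - P1)
    return per_bar * _BAR_PER_GPA


def dielectric_constant(series: EnergyVolumeSeries, volume_nm3: float,
                        T: float = 298.15, convergence_window: float = 0.2,
                        convergence_tol: float = 0.02):
    """Static dielectric constant from box-dipole fluctuations.

    eps = 1 + (<M^2> - <M>^2) / (3 eps0 V kB T), conducting ("tin-foil")
    boundary formula; no reaction-field finite-size correction is applied.

    Returns ``(eps, running_average_curve, converged)`` where the curve is the
    running estimate over frames and ``converged`` flags a relative change
    below ``convergence_tol`` across the final ``convergence_window`` fraction
    of the trace.
    """
    if series.box_dipole is None:
        raise ValueError("series has no box-dipole column")
    if volume_nm3 <= 0 or T <= 0:
        raise ValueError("V and T must be positive")
    M = series.box_dipole * _E_NM  # C.m
    n = M.shape[0]
    csum = np.cumsum(M, axis=0)
    csum2 = np.cumsum((M ** 2).sum(axis=1))
    counts = np.arange(1, n + 1)
    mean2 = (csum ** 2).sum(axis=1) / counts ** 2   # |<M>|^2 running
    m2 = csum2 / counts                             # <M^2> running
    fluct = m2 - mean2
    denom = 3.0 * const.epsilon_0 * (volume_nm3 * 1e-27) * const.k * T
    curve = 1.0 + fluct / denom
    eps = float(curve[-1])
    tail = curve[int(np.floor(n * (1.0 - convergence_window))):]
    if tail.size >= 2 and eps != 0:
        converged = bool(np.max(np.abs(tail - eps)) / abs(eps) < convergence_tol)
    else:
        converged = False
    return eps, curve, converged


def energy_drift(series: EnergyVolumeSeries):
    """Total-energy drift: |OLS slope| of Etot vs time, in J/(mol ns DoF).

    Returns ``(drift, passes)`` where ``passes`` compares against the
    0.5 J/(mol ns DoF) quality threshold.  Requires >= 10 samples.
    """
    if series.Etot is None:
        raise ValueError("series has no total-energy column")
    if series.n_degrees_of_freedom is None:
        raise ValueError("series has no n_degrees_of_freedom")
    if len(series) < 10:
        raise ValueError("energy drift needs at least 10 samples")
    t = series.time
    slope = np.polyfit(t, series.Etot, 1)[0]  # kJ/mol per ps
    drift = abs(slope) * 1e6 / series.n_degrees_of_freedom  # -> J/(mol ns DoF)
    return float(drift), bool(drift < ENERGY_DRIFT_THRESHOLD)
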