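"""Synthetic-data generators with known ground truth.

Every estimator in this toolkit normally consumes the output of a molecular
dynamics or quantum chemistry engine.  These generators stand in for those
engines: they draw data directly in configuration/observable space from the
stated model (two-state Markov H-bond kinetics, exponential-in-T/P liquid
volumes, polynomial TI integrands, cosine-series torsion profiles, geometric
hydration shells) and return the generating parameters alongside, so tests
and acceptance checks recover known truth instead of re-deriving it.  No
dynamics integrator is involved.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hbonds import HBondTimeSeries, Water
from .io import AtomRecord, MoleculeTopology, TrajectoryFrame
from .liquids import EnergyVolumeSeries
from .ti import TICurve, default_lambda_stage
from .torsions import DihedralParams, TorsionProfile, evaluate_dihedral

__all__ = [
    "MarkovHBondFixture", "LiquidStateFixture", "TICurveFixture",
    "HydrationShellFixture",
    "gen_hbond_markov", "gen_liquid_series", "gen_dipole_series",
    "gen_ti_curve", "gen_hydration_shell", "gen_uniform_gas",
    "gen_torsion_profile", "gen_toy_molecule",
]


# ---------------------------------------------------------------------------
# two-state Markov H-bond series
# ---------------------------------------------------------------------------

@dataclass
class MarkovHBondFixture:
    series: HBondTimeSeries
    bound_intervals: np.ndarray  # ps, completed bound dwells (continuous)
    free_intervals: np.ndarray   # ps
    tau_bound: float
    tau_free: float
    occupancy: float             # stationary P(bound) = tau_b / (tau_b + tau_f)


def gen_hbond_markov(tau_bound: float, tau_free: float, dt: float = 2.0,
                     duration_ns: float = 250.0, seed: int = 0) -> MarkovHBondFixture:
    """Alternating-renewal (two-state continuous-time Markov) bond indicator.

    Dwell times are exponential with means ``tau_bound``/``tau_free`` (ps);
    the indicator is discretised at the save interval ``dt``.  The continuous
    completed bound intervals are returned as well, since sub-``dt`` kinetics
    are invisible in the discretised series.
    """
    if tau_bound <= 0 or tau_free <= 0 or dt <= 0 or duration_ns <= 0:
        raise ValueError("all times must be positive")
    if dt > min(tau_bound, tau_free) / 2.0:
        warnings.warn(
            f"save interval dt={dt} ps aliases dwell times "
            f"(min tau = {min(tau_bound, tau_free)} ps)", UserWarning, stacklevel=2
        )
    rng = np.random.default_rng(seed)
    total = duration_ns * 1000.0  # ps
    p_bound = tau_bound / (tau_bound + tau_free)
    state0 = bool(rng.random() < p_bound)
    # alternate exponential dwells, drawn per state and interleaved, until the
    # cumulative time covers the run
    mean_cycle = tau_bound + tau_free
    dwell_chunks, state_chunks = [], []
    t_acc = 0.0
    while t_acc < total:
        n_cyc = max(8, int(1.3 * (total - t_acc) / mean_cycle) + 8)
        first = rng.exponential(tau_bound if state0 else tau_free, size=n_cyc)
        second = rng.exponential(tau_free if state0 else tau_bound, size=n_cyc)
        chunk = np.empty(2 * n_cyc)
        chunk[0::2], chunk[1::2] = first, second
        st = np.empty(2 * n_cyc, dtype=bool)
        st[0::2], st[1::2] = state0, not state0
        dwell_chunks.append(chunk)
        state_chunks.append(st)
        t_acc += float(chunk.sum())  # even-length chunks keep the phase of state0
    dwells = np.concatenate(dwell_chunks)
    states = np.concatenate(state_chunks)
    # truncate to the first dwell crossing the run length
    cum = np.cumsum(dwells)
    n_keep = int(np.searchsorted(cum, total, side="right")) + 1
    dwells = dwells[:n_keep]
    states = states[:n_keep]
    edges = np.concatenate([[0.0], np.cumsum(dwells)])
    # completed intervals exclude the final (censored) dwell
    bound_iv = dwells[:-1][states[:-1]]
    free_iv = dwells[:-1][~states[:-1]]
    # discretise: state at sample times k*dt
    tsamp = np.arange(0.0, total, dt)
    idx = np.searchsorted(edges, tsamp, side="right") - 1
    idx = np.clip(idx, 0, states.size - 1)
    counts = states[idx].astype(int)
    series = HBondTimeSeries(site_label="markov", role="both", counts=counts, dt=dt)
    return MarkovHBondFixture(
        series=series, bound_intervals=bound_iv, free_intervals=free_iv,
        tau_bound=tau_bound, tau_free=tau_free, occupancy=p_bound,
    )


# ---------------------------------------------------------------------------
# liquid-state observable series
# ---------------------------------------------------------------------------

@dataclass
class LiquidStateFixture:
    """Series per (T, P) state plus the generating parameters."""

    states: dict  # (T, P) -> EnergyVolumeSeries
    rho0: float         # g/cm^3 at (T0, P0)
    alpha_true: float   # 1/K
    kappa_true: float   # 1/GPa
    cp_true: float      # J/(mol K) per molecule
    molar_mass: float   # g/mol
    n_molecules: int
    T0: float
    P0: float


def gen_liquid_series(rho0: float = 0.88, alpha_true: float = 1.0e-3,
                      kappa_true: float = 1.0, cp_true: float = 200.0,
                      molar_mass: float = 78.11, n_molecules: int = 1000,
                      T0: float = 298.15, P0: float = 1.0,
                      dT: float = 10.0, dP: float = 0.1,
                      noise_volume: float = 0.0, noise_energy: float = 0.0,
                      n_frames: int = 2500, seed: int = 0) -> LiquidStateFixture:
    """Volume/energy series for the (T-dT, T, T+dT) x P0 and T0 x (P0-dP,
    P0, P0+dP) state points.

    V(T, P) = V0 exp(alpha (T - T0)) exp(-kappa (P - P0)) with kappa in 1/GPa
    and P in bar; U(T) is linear in T with per-molecule slope ``cp_true``
    J/(mol K).  Gaussian noise of the stated SDs is added per frame.
    """
    from scipy import constants as const

    rng = np.random.default_rng(seed)
    v0 = n_molecules * molar_mass / (const.N_A * rho0) * 1e21  # nm^3
    u0 = -30.0 * n_molecules  # arbitrary baseline, kJ total
    t_grid = np.arange(n_frames) * 2.0  # ps
    states = {}
    points = [(T0 - dT, P0), (T0, P0), (T0 + dT, P0),
              (T0, P0 - dP), (T0, P0 + dP)]
    for T, P in points:
        v_mean = v0 * np.exp(alpha_true * (T - T0)) * np.exp(-kappa_true * 1e-4 * (P - P0))
        u_mean = u0 + cp_true * n_molecules * (T - T0) / 1000.0  # kJ total
        vol = v_mean + rng.normal(0.0, noise_volume, size=n_frames)
        etot = u_mean + rng.normal(0.0, noise_energy, size=n_frames)
        states[(T, P)] = EnergyVolumeSeries(
            time=t_grid, n_molecules=n_molecules, volume=vol, Etot=etot,
            Epot=etot, temperature=np.full(n_frames, float(T)),
            pressure=np.full(n_frames, float(P)),
        )
    return LiquidStateFixture(
        states=states, rho0=rho0, alpha_true=alpha_true, kappa_true=kappa_true,
        cp_true=cp_true, molar_mass=molar_mass, n_molecules=n_molecules,
        T0=T0, P0=P0,
    )


def gen_dipole_series(sigma: float, n_samples: int = 30000,
                      seed: int = 0) -> tuple[EnergyVolumeSeries, float]:
    """Box-dipole series with i.i.d. normal components (mean 0, SD ``sigma``
    e.nm); returns the series and sigma for closed-form dielectric checks."""
    rng = np.random.default_rng(seed)
    M = rng.normal(0.0, sigma, size=(n_samples, 3))
    series = EnergyVolumeSeries(
        time=np.arange(n_samples, dtype=float) + 1.0, n_molecules=1, box_dipole=M,
    )
    return series, sigma


# ---------------------------------------------------------------------------
# TI curves
# ---------------------------------------------------------------------------

@dataclass
class TICurveFixture:
    curve: TICurve
    exact_integral: float
    coefficients: tuple


def gen_ti_curve(coefficients=(2.0, -3.0, 0.5, 4.0), sem: float = 0.0,
                 lambdas=None) -> TICurveFixture:
    """Polynomial <dH/dlambda> curve (coefficients low order first) on the
    default 25-window stage, with its exact integral over [0, 1]."""
    lam = np.asarray(default_lambda_stage() if lambdas is None else lambdas, dtype=float)
    coef = np.asarray(coefficients, dtype=float)
    vals = np.polynomial.polynomial.polyval(lam, coef)
    exact = float(sum(c / (k + 1) for k, c in enumerate(coef)))
    curve = TICurve(lambdas=lam, dHdl_mean=vals,
                    dHdl_sem=np.full_like(lam, float(sem)))
    return TICurveFixture(curve=curve, exact_integral=exact, coefficients=tuple(coef))


# ---------------------------------------------------------------------------
# hydration shells
# ---------------------------------------------------------------------------

_SPC_OH = 0.1          # nm
_SPC_HOH = 109.47      # degrees


def _spc_water(o_pos: np.ndarray, axis: np.ndarray, rng) -> np.ndarray:
    """O/H1/H2 coordinates of a rigid SPC water at ``o_pos`` whose dipole
    (O -> H-bisector) points along ``axis``."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the dipole axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    spin = rng.uniform(0.0, 2.0 * np.pi)
    perp = np.cos(spin) * perp + np.sin(spin) * np.cross(axis, perp)
    half = np.radians(_SPC_HOH / 2.0)
    h1 = o_pos + _SPC_OH * (np.cos(half) * axis + np.sin(half) * perp)
    h2 = o_pos + _SPC_OH * (np.cos(half) * axis - np.sin(half) * perp)
    return np.vstack([o_pos, h1, h2])


@dataclass
class HydrationShellFixture:
    frames: list
    ref_atom: int                 # 1-based index of the solute atom
    waters: list                  # Water index records
    n_shell: int
    obd: float
    orientation_mode: str
    box: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 3.0]))


def gen_hydration_shell(n_waters: int = 200, obd: float = 0.28,
                        orientation_mode: str = "inward", n_shell: int = 4,
                        n_frames: int = 20, box_edge: float = 3.0,
                        seed: int = 0) -> HydrationShellFixture:
    """Frames of one solute atom at the box centre surrounded by
    ``n_shell`` waters at the shell radius ``obd`` and bulk waters beyond.

    ``orientation_mode``: "inward" points every water dipole (hence both
    hydrogens) at the solute, "outward" away from it, "random" draws
    isotropic orientations.
    """
    if orientation_mode not in ("inward", "outward", "random"):
        raise ValueError("orientation_mode must be inward, outward or random")
    rng = np.random.default_rng(seed)
    box = np.array([box_edge] * 3)
    center = box / 2.0
    n_bulk = n_waters - n_shell
    if n_bulk < 0:
        raise ValueError("n_shell exceeds n_waters")
    frames = []
    waters = [Water(O=2 + 3 * i, H1=3 + 3 * i, H2=4 + 3 * i) for i in range(n_waters)]
    for k in range(n_frames):
        coords = [center[None, :]]  # solute atom, index 1
        dirs = rng.normal(size=(n_shell, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        radii = np.abs(rng.normal(obd, 0.004, size=n_shell))
        for d, rr in zip(dirs, radii):
            o_pos = center + rr * d
            if orientation_mode == "inward":
                axis = -d
            elif orientation_mode == "outward":
                axis = d
            else:
                axis = rng.normal(size=3)
            coords.append(_spc_water(o_pos, axis, rng))
        # bulk waters uniform, kept outside twice the shell radius
        placed = 0
        while placed < n_bulk:
            cand = rng.uniform(0.0, box_edge, size=(n_bulk - placed, 3))
            dist = np.linalg.norm(cand - center, axis=1)
            cand = cand[dist > 2.0 * obd]
            for o_pos in cand:
                axis = rng.normal(size=3)
                coords.append(_spc_water(o_pos, axis, rng))
                placed += 1
                if placed == n_bulk:
                    break
        frames.append(TrajectoryFrame(time=float(k), coordinates=np.vstack(coords), box=box))
    return HydrationShellFixture(
        frames=frames, ref_atom=1, waters=waters, n_shell=n_shell, obd=obd,
        orientation_mode=orientation_mode, box=box,
    )


def gen_uniform_gas(n_waters: int = 3000, n_frames: int = 100,
                    box_edge: float = 4.5, seed: int = 0):
    """Ideal-gas point 'waters' (O sites only) around a central reference
    atom: g(r) must be flat at 1.  Returns (frames, ref_atom, selection)."""
    rng = np.random.default_rng(seed)
    box = np.array([box_edge] * 3)
    frames = []
    for k in range(n_frames):
        coords = np.vstack([box[None, :] / 2.0,
                            rng.uniform(0.0, box_edge, size=(n_waters, 3))])
        frames.append(TrajectoryFrame(time=float(k), coordinates=coords, box=box))
    return frames, 1, list(range(2, n_waters + 2))


# ---------------------------------------------------------------------------
# torsion profiles and toy molecules
# ---------------------------------------------------------------------------

def gen_torsion_profile(params: DihedralParams, noise: float = 0.0,
                        step_deg: float = 30.0, seed: int = 0) -> TorsionProfile:
    """Sample a dihedral potential on a regular grid (default the scan's
    30-degree steps over [-180, 180])."""
    rng = np.random.default_rng(seed)
    angles = np.arange(-180.0, 180.0 + step_deg / 2, step_deg)
    e = evaluate_dihedral(params, angles)
    if noise > 0:
        e = e + rng.normal(0.0, noise, size=angles.size)
    return TorsionProfile(angles=angles, energies=np.asarray(e, dtype=float))


def gen_toy_molecule(kind: str = "diatomic", seed: int = 0) -> tuple[MoleculeTopology, TrajectoryFrame]:
    """Small analytic molecules for charge/dipole fixtures.

    "diatomic": two atoms 0.1 nm apart with charges -0.2/+0.2 e;
    "planar4": four atoms in a plane, one neutral charge group;
    "benzene_like": hexagonal C6H6, six CH charge groups each summing to 0.
    """
    rng = np.random.default_rng(seed)
    if kind == "diatomic":
        pos = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]])
        atoms = [
            AtomRecord(1, "A1", "C", pos[0], -0.2, 1, 12.011),
            AtomRecord(2, "A2", "C", pos[1], +0.2, 1, 12.011),
        ]
        mol = MoleculeTopology("diatomic", atoms, bonds=[(1, 2)])
    elif kind == "planar4":
        pos = np.array([
            [0.0, 0.0, 0.0], [0.14, 0.0, 0.0], [0.14, 0.14, 0.0], [0.0, 0.14, 0.0],
        ]) + rng.normal(0.0, 0.005, size=(4, 3)) * np.array([1.0, 1.0, 0.0])
        q = rng.normal(0.0, 0.15, size=4)
        q -= q.mean()
        atoms = [AtomRecord(i + 1, f"A{i + 1}", "C", pos[i], float(q[i]), 1, 12.011)
                 for i in range(4)]
        mol = MoleculeTopology("planar4", atoms,
                               bonds=[(1, 2), (2, 3), (3, 4), (4, 1)])
    elif kind == "benzene_like":
        r_c, r_h = 0.139, 0.247
        rows = []
        for i in range(6):
            th = np.pi / 3.0 * i
            rows.append((r_c * np.cos(th), r_c * np.sin(th)))
            rows.append((r_h * np.cos(th), r_h * np.sin(th)))
        pos = np.array([[x, y, 0.0] for x, y in rows])
        atoms = []
        for i in range(6):
            atoms.append(AtomRecord(2 * i + 1, f"C{i + 1}", "C", pos[2 * i], -0.1, i + 1, 12.011))
            atoms.append(AtomRecord(2 * i + 2, f"H{i + 1}", "H", pos[2 * i + 1], +0.1, i + 1, 1.008))
        bonds = [(2 * i + 1, 2 * i + 2) for i in range(6)]
        bonds += [(2 * i + 1, 2 * ((i + 1) % 6) + 1) for i in range(6)]
        mol = MoleculeTopology("benzene_like", atoms, bonds=bonds)
    else:
        raise ValueError(f"unknown toy-molecule kind {kind!r}")
    frame = TrajectoryFrame(time=0.0, coordinates=mol.positions(),
                            box=np.array([5.0, 5.0, 5.0]))
    return mol, frame
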