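"""Dipole-constrained partial-charge assignment.

The electrostatic signature of a small aromatic ring in a fixed-charge force
field is its molecular dipole.  This module computes point-charge dipoles,
measures the angle theta between a reference (QM) dipole and the model (MM)
dipole, and adjusts MM partial charges — under GROMOS charge-group integer-sum
constraints — so the point-charge dipole reproduces a target dipole vector.

The adjustment is posed as an equality-constrained linear least-squares
problem on the dipole *vector* difference, which penalises direction and
magnitude error simultaneously.  Among least-squares minimisers the
minimal-norm charge shift is returned, making the result deterministic even
when the system is underdetermined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MoleculeTopology

__all__ = [
    "DEBYE_PER_E_NM",
    "DipoleVector",
    "ChargeFitSpec",
    "ChargeFitResult",
    "ConstraintError",
    "compute_dipole",
    "dipole_angle",
    "fit_charges_to_dipole",
]

#: 1 e.nm in Debye.
DEBYE_PER_E_NM = 48.0321


class ConstraintError(ValueError):
    """The charge-constraint system is infeasible."""


@dataclass
class DipoleVector:
    """Molecular dipole in e.nm with its magnitude in Debye."""

    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (3,):
            raise ValueError("dipole needs 3 components")

    @property
    def magnitude_e_nm(self) -> float:
        return float(np.linalg.norm(self.components))

    @property
    def magnitude_debye(self) -> float:
        return DEBYE_PER_E_NM * self.magnitude_e_nm


@dataclass
class ChargeFitSpec:
    """Targets and constraints for a charge fit.

    group_charge_targets maps charge_group_id -> integer total charge (e).
    overlap_memberships lists atoms that additionally belong to a second,
    superimposed group: {group_id: [1-based atom indices]}; those atoms'
    charges then appear in both groups' sum constraints.
    """

    target_dipole: DipoleVector
    frozen_atom_indices: tuple[int, ...] = ()
    group_charge_targets: dict[int, int] | None = None
    overlap_memberships: dict[int, list[int]] = field(default_factory=dict)
    max_charge_shift: float = 0.5

    @property
    def overlap_atom_indices(self) -> tuple[int, ...]:
        out: list[int] = []
        for members in self.overlap_memberships.values():
            out.extend(members)
        return tuple(sorted(set(out)))


@dataclass
class ChargeFitResult:
    charges: np.ndarray
    theta_deg: float
    dipole_mm: DipoleVector
    residual_norm: float
    shift_exceeded: bool = False


def _origin(mol: MoleculeTopology, origin: str) -> np.ndarray:
    pos = mol.positions()
    if origin == "center_of_geometry":
        return pos.mean(axis=0)
    if origin == "center_of_mass":
        m = mol.masses()
        if m.sum() <= 0:
            raise ValueError("center_of_mass requires positive masses")
        return (pos * m[:, None]).sum(axis=0) / m.sum()
    raise ValueError(f"unknown origin {origin!r}")


def compute_dipole(mol: MoleculeTopology, origin: str = "center_of_geometry") -> DipoleVector:
    """Point-charge dipole mu = sum_i q_i (r_i - r_origin), in e.nm.

    For a neutral molecule the result is origin-independent; for ions the
    declared origin matters and is the caller's responsibility.
    """
    pos = mol.positions()
    q = mol.charges()
    r0 = _origin(mol, origin)
    return DipoleVector((q[:, None] * (pos - r0)).sum(axis=0))


def dipole_angle(a: DipoleVector, b: DipoleVector) -> float:
    """Angle between two dipoles in degrees, in [0, 180]."""
    na, nb = a.magnitude_e_nm, b.magnitude_e_nm
    if na <= 1e-12 or nb <= 1e-12:
        raise ValueError("dipole angle undefined for a (near-)zero vector")
    c = float(np.dot(a.components, b.components) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _constraint_system(mol: MoleculeTopology, spec: ChargeFitSpec):
    """Build A q = b rows: per-group sums (with overlap memberships) and
    frozen atoms."""
    n = mol.n_atoms
    groups = mol.charge_groups()
    targets = spec.group_charge_targets
    if targets is None:
        # default: current rounded group sums (conserve what the topology declares)
        targets = {}
        for gid, members in groups.items():
            targets[gid] = int(round(sum(mol.atoms[i - 1].partial_charge for i in members)))
    missing = set(groups) - set(targets)
    if missing:
        raise ConstraintError(f"no charge target for groups {sorted(missing)}")
    rows, b = [], []
    for gid in sorted(groups):
        members = set(groups[gid]) | set(spec.overlap_memberships.get(gid, ()))
        row = np.zeros(n)
        for idx in members:
            row[idx - 1] = 1.0
        rows.append(row)
        b.append(float(targets[gid]))
    q0 = mol.charges()
    for idx in spec.frozen_atom_indices:
        row = np.zeros(n)
        row[idx - 1] = 1.0
        rows.append(row)
        b.append(q0[idx - 1])
    return np.vstack(rows), np.array(b)


def fit_charges_to_dipole(mol: MoleculeTopology, spec: ChargeFitSpec) -> ChargeFitResult:
    """Adjust partial charges to reproduce a target dipole.

    Minimises ||mu(q) - mu_target||^2 subject to (i) per-group integer charge
    sums (overlap atoms contribute to both groups' rows), (ii) frozen atoms
    unchanged.  The |q_i - q_i0| <= max_charge_shift box is checked a
    posteriori: violation warns and sets ``shift_exceeded``.

    Underdetermined systems return the minimal-norm charge shift;
    inconsistent constraints raise :class:`ConstraintError`.
    """
    pos = mol.positions()
    q0 = mol.charges()
    r0 = _origin(mol, "center_of_geometry")
    D = (pos - r0).T  # 3 x n, mu = D @ q
    A, b = _constraint_system(mol, spec)

    # feasibility: rank([A|b]) must equal rank(A)
    rank_a = np.linalg.matrix_rank(A, tol=1e-10)
    rank_ab = np.linalg.matrix_rank(np.hstack([A, b[:, None]]), tol=1e-10)
    if rank_ab > rank_a:
        raise ConstraintError(
            "inconsistent charge constraints (group targets conflict with "
            "frozen atoms / overlap memberships)"
        )

    # shift variables: q = q0 + d, A d = c
    c = b - A @ q0
    d_part = np.linalg.pinv(A) @ c  # minimal-norm particular solution
    # orthonormal nullspace basis of A
    _u, s, vt = np.linalg.svd(A)
    tol = max(A.shape) * (s[0] if s.size else 1.0) * np.finfo(float).eps
    null = vt[np.sum(s > tol):].T  # n x k
    r = spec.target_dipole.components - D @ (q0 + d_part)
    if null.shape[1] > 0:
        # minimal-norm z -> minimal-norm shift; absolute singular-value cutoff
        # so directions in which the dipole is (numerically) immovable under
        # the constraints produce zero shift instead of blowing up
        dn = D @ null
        u2, s2, vt2 = np.linalg.svd(dn, full_matrices=False)
        cutoff = 1e-10 * max(1.0, float(np.abs(D).max()))
        s_inv = np.where(s2 > cutoff, 1.0 / np.where(s2 > cutoff, s2, 1.0), 0.0)
        z = vt2.T @ (s_inv * (u2.T @ r))
        d = d_part + null @ z
    else:
        d = d_part

    q = q0 + d
    exceeded = bool(np.any(np.abs(d) > spec.max_charge_shift + 1e-12))
    if exceeded:
        warnings.warn(
            f"charge shift exceeds max_charge_shift={spec.max_charge_shift} e "
            f"(max |shift| = {np.abs(d).max():.3f} e)", UserWarning, stacklevel=2
        )
    mu = DipoleVector(D @ q)
    try:
        theta = dipole_angle(mu, spec.target_dipole)
    except ValueError:
        theta = 0.0  # both (near) zero: direction trivially conserved
    return ChargeFitResult(
        charges=q,
        theta_deg=theta,
        dipole_mm=mu,
        residual_norm=float(np.linalg.norm(mu.components - spec.target_dipole.components)),
        shift_exceeded=exceeded,
    )
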