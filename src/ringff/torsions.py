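"""Fitting of periodic dihedral potentials to a torsion-energy profile.

The target of the fit is the difference between a reference (QM) torsion scan
and the molecular-mechanics profile computed with the fitted dihedral zeroed
(the "background").  The model is the GROMOS proper-dihedral form

    V(phi) = sum_n k_n * (1 + cos(n*phi - phi0_n)),   k_n >= 0,
    n in {1..6}, phi0_n in {0, 180} degrees.

Because (1 + cos(n*phi - 180)) = (1 - cos(n*phi)), the two allowed phases of
one multiplicity are a sign choice on a single cosine coefficient: the fit is
plain linear least squares on {cos(n*phi)} plus an intercept, and a negative
coefficient maps to the opposite-phase positive-k term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KT_298", "TorsionProfile", "DihedralTerm", "DihedralParams",
    "evaluate_dihedral", "fit_torsion", "classify_rotamer_spread",
    "barrier_height", "itp_parameter_lines",
]

#: kT at 298.15 K in kJ/mol, the rotamer-localisation scale.
KT_298 = 2.479

ALLOWED_MULTIPLICITIES = frozenset(range(1, 7))


@dataclass
class TorsionProfile:
    """A sampled torsion profile: angles (deg, strictly increasing within one
    period) and energies (kJ/mol)."""

    angles: np.ndarray
    energies: np.ndarray
    zero_convention: str = "raw"  # or "min-shifted"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.shape != self.energies.shape or self.angles.ndim != 1:
            raise ValueError("angles and energies must be matching 1-D arrays")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[-1] - self.angles[0] > 360.0 + 1e-9:
            raise ValueError("profile spans more than one period")

    def min_shifted(self) -> "TorsionProfile":
        return TorsionProfile(self.angles, self.energies - self.energies.min(),
                              zero_convention="min-shifted")


@dataclass(frozen=True)
class DihedralTerm:
    force_constant: float  # kJ/mol, >= 0
    multiplicity: int
    phase_deg: float  # 0 or 180

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.multiplicity not in ALLOWED_MULTIPLICITIES:
            raise ValueError(f"multiplicity must be in {sorted(ALLOWED_MULTIPLICITIES)}")
        if self.phase_deg not in (0.0, 180.0):
            raise ValueError("phase must be 0 or 180 degrees")


@dataclass
class DihedralParams:
    terms: list[DihedralTerm] = field(default_factory=list)
    #: constant offset (kJ/mol) between the min-shifted target and the model;
    #: reported for bookkeeping, not part of the potential.
    offset: float = 0.0

    def __post_init__(self) -> None:
        mults = [t.multiplicity for t in self.terms]
        if len(set(mults)) != len(mults):
            raise ValueError("multiplicities must be unique within one dihedral")


def evaluate_dihedral(params: DihedralParams, phi_deg) -> np.ndarray | float:
    """V(phi) = sum_n k_n (1 + cos(n phi - phi0)) in kJ/mol."""
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    v = np.zeros_like(phi)
    for t in params.terms:
        v = v + t.force_constant * (1.0 + np.cos(t.multiplicity * phi - np.radians(t.phase_deg)))
    return float(v) if np.isscalar(phi_deg) else v


def fit_torsion(target: TorsionProfile, mm_background: TorsionProfile,
                multiplicities=(1, 2, 3, 6)) -> tuple[DihedralParams, float]:
    """Fit dihedral terms to (target - background), both min-shifted.

    Returns the parameters and the RMSD (kJ/mol) of the fit on the input
    grid.  Raises on grid mismatch or a rank-deficient design matrix (too few
    distinct angles for the requested multiplicities).
    """
    mults = sorted(set(int(n) for n in multiplicities))
    bad = [n for n in mults if n not in ALLOWED_MULTIPLICITIES]
    if bad:
        raise ValueError(f"illegal multiplicities {bad}; allowed 1..6")
    if target.angles.shape != mm_background.angles.shape or \
            not np.allclose(target.angles, mm_background.angles):
        raise ValueError("target and background must share the same angle grid")
    if len(target.angles) < len(mults) + 1:
        raise ValueError(
            f"{len(target.angles)} points cannot determine {len(mults)} terms + offset"
        )
    y = target.min_shifted().energies - mm_background.min_shifted().energies
    phi = np.radians(target.angles)
    # columns: intercept, cos(n phi) per requested n
    X = np.column_stack([np.ones_like(phi)] + [np.cos(n * phi) for n in mults])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design matrix: angle grid cannot resolve the "
            f"requested multiplicities {mults}"
        )
    coef, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rmsd = float(np.sqrt(np.mean((fitted - y) ** 2)))
    terms = []
    for n, c in zip(mults, coef[1:]):
        # c*cos(n phi) == |c|*(1 + cos(n phi - phi0)) - |c|, phi0 = 0 or 180
        terms.append(DihedralTerm(force_constant=abs(float(c)),
                                  multiplicity=n,
                                  phase_deg=0.0 if c >= 0 else 180.0))
    total_k = sum(t.force_constant for t in terms)
    params = DihedralParams(terms=terms, offset=float(coef[0]) - total_k)
    return params, rmsd


def classify_rotamer_spread(params: DihedralParams, kT: float = KT_298) -> str:
    """Classify the rotamer distribution the potential induces.

    A 1-degree grid scan gives the barrier height (max - min); barriers below
    2.5 kJ/mol (~kT) let the dihedral distribution spread over transient
    states rather than localise in wells.
    """
    grid = np.arange(0.0, 360.0, 1.0)
    v = evaluate_dihedral(params, grid)
    barrier = float(np.max(v) - np.min(v))
    return "spread" if barrier < 2.5 else "localized"


def barrier_height(params: DihedralParams, step_deg: float = 1.0) -> float:
    """Barrier height (kJ/mol) on a dense grid scan."""
    grid = np.arange(0.0, 360.0, step_deg)
    v = evaluate_dihedral(params, grid)
    return float(np.max(v) - np.min(v))


def itp_parameter_lines(params: DihedralParams, atoms=(1, 2, 3, 4)) -> list[str]:
    """Render ITP [dihedrals] parameter lines (function type 1), one per term."""
    i, j, k, l = atoms
    return [
        f"{i:5d} {j:5d} {k:5d} {l:5d}  1  {t.phase_deg:8.2f} {t.force_constant:10.5f} {t.multiplicity:3d}"
        for t in params.terms
    ]
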