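"""Hydrogen-bond and solvation-shell analysis of a solute in water.

Produces, per heteroatom site, the full interaction fingerprint a
ring-in-water simulation yields: average H-bond count and occupancy
percentage, residence time and lifetime of the bond, the Eyring free energy
of H-bond breakage, the radial-distribution-function-derived optimal binding
distance (OBD) and coordination number (CN), and the mean orientation of the
surrounding waters.

Geometry criterion (the common analysis-tool default): a donor D with
covalent hydrogen H is bonded to acceptor A when r(D, A) <= 0.35 nm and the
angle H-D-A <= 30 degrees, with minimum-image distances on orthorhombic
boxes.

Kinetics: the residence time tau is the time constant of a single-exponential
fit to the survival function of uninterrupted bonded intervals; the lifetime
column is 1/tau by definition.  The breakage free energy is the
transition-state (Eyring) inversion of the rate 1/tau:

    dG = RT * ln(tau * kB*T / h),   tau in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as const
from scipy.signal import find_peaks

from .io import REPORT_COLUMNS, TrajectoryFrame

__all__ = [
    "HBondCriteria", "HBondTimeSeries", "Occupancy", "ResidenceTime",
    "RDFCurve", "ShellAnalysis", "Water",
    "detect_hbonds", "occupancy", "intervals_from_series", "residence_time",
    "hbond_free_energy", "rdf", "obd_and_cn", "orientation", "site_report",
    "render_report_row",
]


@dataclass
class HBondCriteria:
    """Geometric H-bond criterion: donor-acceptor cutoff (nm) and maximum
    hydrogen-donor-acceptor angle (degrees)."""

    r_donor_acceptor_max: float = 0.35
    angle_hda_max: float = 30.0

    def __post_init__(self) -> None:
        if self.r_donor_acceptor_max <= 0 or self.angle_hda_max <= 0:
            raise ValueError("criteria must be positive")


@dataclass
class Water:
    """A rigid 3-site water: 1-based indices of O, H1, H2 in the frame."""

    O: int
    H1: int
    H2: int


@dataclass
class HBondTimeSeries:
    """Per-frame H-bond count for one site."""

    site_label: str
    role: str  # donor | acceptor | both
    counts: np.ndarray
    dt: float  # ps between frames

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor", "both"):
            raise ValueError("role must be donor, acceptor or both")
        self.counts = np.asarray(self.counts)
        if self.counts.size < 2:
            raise ValueError("series needs at least 2 frames")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class Occupancy:
    aver: float     # mean bond count
    sd: float       # per-frame SD
    percent: float  # % frames with >= 1 bond
    block_aver: np.ndarray = field(default_factory=lambda: np.empty(0))
    block_percent: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ResidenceTime:
    tau: float        # ps (nan when undefined)
    lifetime: float   # 1/ps, = 1/tau
    n_events: int
    flag: str = "ok"  # ok | insufficient | short-lived | non-decaying


@dataclass
class RDFCurve:
    """g(r) on bin centers with the bulk number density used to normalise."""

    r: np.ndarray
    g: np.ndarray
    number_density: float  # 1/nm^3

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.shape != self.g.shape:
            raise ValueError("r and g must match")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be increasing")
        if np.any(self.g < -1e-12):
            raise ValueError("g must be >= 0")


@dataclass
class ShellAnalysis:
    obd: float      # nm
    cn: float
    r_min: float    # first-minimum radius bounding the shell (nm)
    qualified: bool  # False -> no structured first shell


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _frame_bond_matrix(frame: TrajectoryFrame, donor_pairs, acceptors,
                       criteria: HBondCriteria) -> np.ndarray:
    """Boolean (n_pairs, n_acceptors) bond matrix for one frame."""
    xyz, box = frame.coordinates, frame.box
    d_idx = np.array([p[0] for p in donor_pairs], dtype=int) - 1
    h_idx = np.array([p[1] for p in donor_pairs], dtype=int) - 1
    a_idx = np.asarray(acceptors, dtype=int) - 1
    rd, rh, ra = xyz[d_idx], xyz[h_idx], xyz[a_idx]
    da = _min_image(ra[None, :, :] - rd[:, None, :], box)      # (nd, na, 3)
    dist = np.linalg.norm(da, axis=-1)
    dh = _min_image(rh - rd, box)                              # (nd, 3)
    nh = np.linalg.norm(dh, axis=-1)
    cosang = np.einsum("ij,ikj->ik", dh, da) / np.maximum(nh[:, None] * dist, 1e-30)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bonded = (dist <= criteria.r_donor_acceptor_max) & (ang <= criteria.angle_hda_max)
    # a donor never bonds its own atoms
    bonded &= (a_idx[None, :] != d_idx[:, None]) & (a_idx[None, :] != h_idx[:, None])
    return bonded


def detect_hbonds(frames, donors, hydrogens, acceptors,
                  criteria: HBondCriteria | None = None, dt: float | None = None,
                  site_label: str = "site", role: str = "both") -> HBondTimeSeries:
    """Count H-bonds per frame between the given donor-hydrogen pairs and
    acceptor atoms (1-based indices into the frame coordinates).

    ``donors`` and ``hydrogens`` must pair up one-to-one (a hydrogen without
    a parent donor is a topology error).
    """
    donors, hydrogens = list(donors), list(hydrogens)
    if len(donors) != len(hydrogens):
        raise ValueError(
            f"{len(hydrogens)} hydrogens for {len(donors)} donors: every "
            "hydrogen needs a parent donor"
        )
    criteria = criteria or HBondCriteria()
    frames = list(frames)
    if dt is None:
        dt = frames[1].time - frames[0].time if len(frames) > 1 and \
            frames[1].time > frames[0].time else 1.0
    counts = np.zeros(len(frames), dtype=int)
    if donors and len(list(acceptors)):
        pairs = list(zip(donors, hydrogens))
        for i, fr in enumerate(frames):
            counts[i] = int(_frame_bond_matrix(fr, pairs, acceptors, criteria).sum())
    return HBondTimeSeries(site_label=site_label, role=role, counts=counts, dt=dt)


# ---------------------------------------------------------------------------
# occupancy and kinetics
# ---------------------------------------------------------------------------

def occupancy(series: HBondTimeSeries, n_blocks: int = 5) -> Occupancy:
    """Mean bond count (with per-frame SD) and the percentage of frames with
    at least one bond; per-block values retained for derived uncertainties."""
    c = series.counts.astype(float)
    per = c.size // n_blocks
    if per >= 1:
        blocks = c[: per * n_blocks].reshape(n_blocks, per)
        block_aver = blocks.mean(axis=1)
        block_pct = 100.0 * (blocks >= 1).mean(axis=1)
    else:
        block_aver = np.array([c.mean()])
        block_pct = np.array([100.0 * (c >= 1).mean()])
    return Occupancy(
        aver=float(c.mean()),
        sd=float(c.std(ddof=0)),
        percent=float(100.0 * (c >= 1).mean()),
        block_aver=block_aver,
        block_percent=block_pct,
    )


def intervals_from_series(series: HBondTimeSeries) -> np.ndarray:
    """Durations (ps) of uninterrupted bonded stretches (count >= 1).

    Stretches touching either end of the series are censored and dropped.
    """
    bonded = np.concatenate([[0], (series.counts >= 1).astype(int), [0]])
    diff = np.diff(bonded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    lengths = ends - starts
    keep = np.ones(lengths.size, dtype=bool)
    if lengths.size:
        if starts[0] == 0:
            keep[0] = False
        if ends[-1] == series.counts.size:
            keep[-1] = False
    return lengths[keep] * series.dt


def residence_time(intervals, dt: float | None = None, min_events: int = 20,
                   survival_floor: float = 0.05) -> ResidenceTime:
    """Residence time from a single-exponential fit to the interval survival
    function; lifetime = 1/tau.

    ``intervals`` are bonded-interval durations in ps.  Fewer than
    ``min_events`` completed intervals flags insufficient sampling (the
    dash cells of sparse sites).  If every interval is at or below the frame
    spacing ``dt`` the site is flagged short-lived with tau <= dt.
    """
    iv = np.sort(np.asarray(intervals, dtype=float))
    n = iv.size
    if n < min_events:
        return ResidenceTime(tau=float("nan"), lifetime=float("nan"),
                             n_events=n, flag="insufficient")
    if dt is not None and iv.max() <= dt + 1e-12:
        tau = float(iv.mean())
        return ResidenceTime(tau=tau, lifetime=1.0 / tau, n_events=n, flag="short-lived")
    # empirical survival S(t) = P(duration > t) on a uniform grid up to the
    # quantile where S hits the floor, then log-linear least squares.
    t_max = float(np.quantile(iv, 1.0 - survival_floor))
    if t_max <= 0:
        return ResidenceTime(tau=float("nan"), lifetime=float("nan"),
                             n_events=n, flag="non-decaying")
    grid = np.linspace(0.0, t_max, 50)
    surv = 1.0 - np.searchsorted(iv, grid, side="right") / n
    ok = surv > 0
    if ok.sum() < 3:
        return ResidenceTime(tau=float("nan"), lifetime=float("nan"),
                             n_events=n, flag="non-decaying")
    slope, _ = np.polyfit(grid[ok], np.log(surv[ok]), 1)
    if slope >= 0:
        return ResidenceTime(tau=float("nan"), lifetime=float("nan"),
                             n_events=n, flag="non-decaying")
    tau = float(-1.0 / slope)
    return ResidenceTime(tau=tau, lifetime=1.0 / tau, n_events=n, flag="ok")


def hbond_free_energy(tau_ps: float, T: float = 298.15) -> float:
    """Eyring inversion of the breakage rate: dG = RT ln(tau kB T / h), kJ/mol.

    tau is the residence time in ps; the fixed point dG = 0 sits at
    tau = h/(kB T) ~ 1.6e-4 ps.  Strictly increasing in tau.
    """
    if not tau_ps > 0:
        raise ValueError("tau must be positive")
    rt = const.R * T / 1000.0
    return float(rt * np.log(tau_ps * 1e-12 * const.k * T / const.h))


# ---------------------------------------------------------------------------
# solvation structure
# ---------------------------------------------------------------------------

def rdf(frames, ref_atom: int, selection, bin_width: float = 0.002,
        r_max: float | None = None) -> RDFCurve:
    """Radial distribution function of ``selection`` atoms around one
    reference atom (1-based indices), shell-histogram estimator normalised by
    the ideal-gas count at the bulk number density; minimum-image distances.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("rdf needs at least one frame")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    box = frames[0].box
    if bin_width > box.min() / 4.0:
        raise ValueError("bin width larger than box/4")
    if r_max is None:
        r_max = float(box.min() / 2.0)
    sel = np.asarray(selection, dtype=int) - 1
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    vol = 0.0
    for fr in frames:
        delta = _min_image(fr.coordinates[sel] - fr.coordinates[ref_atom - 1], fr.box)
        d = np.linalg.norm(delta, axis=1)
        counts += np.histogram(d, bins=edges)[0]
        vol += float(np.prod(fr.box))
    vol /= len(frames)
    rho = sel.size / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / len(frames) / (rho * shell)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFCurve(r=centers, g=g, number_density=rho)


def obd_and_cn(curve: RDFCurve, prominence_ratio: float = 1.05) -> ShellAnalysis:
    """Optimal binding distance and coordination number from an RDF.

    OBD is the first local maximum with g > 1 whose height is at least
    ``prominence_ratio`` times the following minimum; CN integrates
    rho * 4 pi r^2 g(r) out to that minimum.  Without a qualifying peak the
    global maximum is reported with a warning and ``qualified=False``.
    """
    r, g = curve.r, curve.g
    peaks, _ = find_peaks(g)
    chosen = None
    for p in peaks:
        if g[p] <= 1.0:
            continue
        rest = g[p:]
        mins, _ = find_peaks(-rest)
        m = p + (mins[0] if mins.size else rest.size - 1)
        if g[p] >= prominence_ratio * max(g[m], 1e-12):
            chosen = (p, m)
            break
    qualified = chosen is not None
    if not qualified:
        warnings.warn("no structured first shell: using global maximum as OBD",
                      UserWarning, stacklevel=2)
        p = int(np.argmax(g))
        rest = g[p:]
        mins, _ = find_peaks(-rest)
        m = p + (mins[0] if mins.size else rest.size - 1)
    else:
        p, m = chosen
    mask = r <= r[m]
    integrand = 4.0 * np.pi * r[mask] ** 2 * g[mask]
    cn = float(curve.number_density * np.trapezoid(integrand, r[mask]))
    return ShellAnalysis(obd=float(r[p]), cn=cn, r_min=float(r[m]), qualified=qualified)


def orientation(frames, ref_atom: int, waters, shell_radius: float,
                threshold: float = 0.25, min_observations: int = 100) -> tuple[str, float]:
    """Mean orientation of shell waters around an atom.

    For every water whose oxygen lies within ``shell_radius`` of the
    reference atom, cos(theta) is taken between the water dipole direction
    (O -> bisector of the two O-H vectors, rigid 3-site water) and the
    oxygen -> reference-atom vector.  Classification on the mean:
    >= +threshold "H-oriented", <= -threshold "O-oriented", else "Undefined".

    Returns (label, mean_cos).
    """
    for w in waters:
        if not isinstance(w, Water):
            raise TypeError("waters must be rigid 3-site Water records")
    o_idx = np.array([w.O for w in waters], dtype=int) - 1
    h1_idx = np.array([w.H1 for w in waters], dtype=int) - 1
    h2_idx = np.array([w.H2 for w in waters], dtype=int) - 1
    cos_vals = []
    for fr in frames:
        xyz, box = fr.coordinates, fr.box
        to_ref = _min_image(xyz[ref_atom - 1] - xyz[o_idx], box)
        dist = np.linalg.norm(to_ref, axis=1)
        inside = dist <= shell_radius
        if not inside.any():
            continue
        d1 = _min_image(xyz[h1_idx[inside]] - xyz[o_idx[inside]], box)
        d2 = _min_image(xyz[h2_idx[inside]] - xyz[o_idx[inside]], box)
        dip = d1 + d2
        nd = np.linalg.norm(dip, axis=1) * dist[inside]
        cos_vals.append(np.einsum("ij,ij->i", dip, to_ref[inside]) / np.maximum(nd, 1e-30))
    if not cos_vals:
        raise ValueError("empty solvation shell: no water oxygen inside the radius")
    c = np.concatenate(cos_vals)
    if c.size < min_observations:
        raise ValueError(
            f"only {c.size} in-shell water observations (< {min_observations})"
        )
    mean = float(c.mean())
    if mean >= threshold:
        return "H-oriented", mean
    if mean <= -threshold:
        return "O-oriented", mean
    return "Undefined", mean


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _pm(mean: float, sd: float, prec: int = 2) -> str:
    return f"{mean:.{prec}f} ± {sd:.{prec}f}"

_DASH = "–"


def site_report(molecule: str, series: HBondTimeSeries, intervals,
                rdf_curves, orientation_label: str, n_blocks: int = 5,
                T: float = 298.15, min_events: int = 20) -> dict:
    """Assemble one report row for a site.

    ``intervals`` are completed bonded-interval durations (ps) over the whole
    run; ``rdf_curves`` is either one RDFCurve or a per-block list, whose
    scatter provides the CN/OBD uncertainties.  Kinetic and thermodynamic
    uncertainties come from splitting the intervals into ``n_blocks``
    consecutive chunks (the trajectory's contiguous time blocks).  Sites with
    fewer than ``min_events`` completed intervals render dash cells.
    """
    occ = occupancy(series, n_blocks=n_blocks)
    iv = np.asarray(intervals, dtype=float)
    res = residence_time(iv, dt=series.dt, min_events=min_events)

    if res.flag == "insufficient" or not np.isfinite(res.tau):
        tau_s = lt_s = dg_s = _DASH
    else:
        chunks = [c for c in np.array_split(iv, n_blocks) if c.size >= max(3, min_events // n_blocks)]
        taus = [residence_time(c, dt=series.dt, min_events=3).tau for c in chunks]
        taus = np.array([t for t in taus if np.isfinite(t)])
        tau_sd = float(taus.std(ddof=1)) if taus.size > 1 else 0.0
        dgs = np.array([hbond_free_energy(t, T=T) for t in taus]) if taus.size else np.empty(0)
        dg_sd = float(dgs.std(ddof=1)) if dgs.size > 1 else 0.0
        lt_sd = tau_sd / res.tau ** 2  # first-order propagation of 1/tau
        tau_s = _pm(res.tau, tau_sd)
        lt_s = _pm(res.lifetime, lt_sd)
        dg_s = _pm(hbond_free_energy(res.tau, T=T), dg_sd)

    curves = rdf_curves if isinstance(rdf_curves, (list, tuple)) else [rdf_curves]
    shells = [obd_and_cn(c) for c in curves]
    obds = np.array([s.obd for s in shells])
    cns = np.array([s.cn for s in shells])
    obd_sd = float(obds.std(ddof=1)) if obds.size > 1 else 0.0
    cn_sd = float(cns.std(ddof=1)) if cns.size > 1 else 0.0

    row = {
        "Molecule": molecule,
        "Atom": series.site_label,
        "Aver_HB": _pm(occ.aver, occ.sd),
        "tau_HB": tau_s,
        "lifetime_HB": lt_s,
        "dG_HB": dg_s,
        "Percent": round(occ.percent, 2),
        "CN": _pm(float(cns.mean()), cn_sd),
        "OBD_HB": _pm(float(obds.mean()), obd_sd),
        "Orientation": orientation_label,
    }
    assert list(row) == REPORT_COLUMNS
    return row


def render_report_row(row: dict) -> str:
    return "\t".join(str(row[c]) for c in REPORT_COLUMNS)
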