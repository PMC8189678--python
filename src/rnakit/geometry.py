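"""Per-nucleotide geometric descriptors of RNA chains.

For every nucleotide the module computes, from atomic coordinates alone:

* the six backbone torsion angles alpha..zeta and the glycosidic torsion chi
  with its syn/anti class;
* the five endocyclic ribose torsions nu0..nu4 and the derived
  Altona-Sundaralingam pseudorotation phase P, amplitude nu_max and the
  36-degree sugar-pucker conformer bin;
* the pseudotorsion pairs (eta, theta) over P/C4' virtual bonds,
  (eta', theta') over P/C1', and (eta'', theta'') over P/base-center.

All angles are reported in degrees on [0, 360).  Undefined values (missing
atoms, chain termini, unresolved neighbors, degenerate geometry) are NaN for
angles and ``None`` for labels; sentinel numbers are never used.  Helix-form
labels (A/B/Z) are *ingested* from external annotation files by the dataset
module, never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import Residue, RnaChain

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

#: 36-degree pseudorotation-wheel bins, in order from P = 0.
PUCKER_BINS = [
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
]

#: Quadruples (atom, residue offset) defining each backbone torsion.
BACKBONE_TORSION_ATOMS = {
    "alpha": (("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)),
    "beta": (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),
    "gamma": (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),
    "delta": (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),
    "epsilon": (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)),
    "zeta": (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)),
}

#: Quadruples defining the five endocyclic ribose torsions.
NU_TORSION_ATOMS = {
    "nu0": ("C4'", "O4'", "C1'", "C2'"),
    "nu1": ("O4'", "C1'", "C2'", "C3'"),
    "nu2": ("C1'", "C2'", "C3'", "C4'"),
    "nu3": ("C2'", "C3'", "C4'", "O4'"),
    "nu4": ("C3'", "C4'", "O4'", "C1'"),
}

BASE_RING_ATOMS_PURINE = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
BASE_RING_ATOMS_PYRIMIDINE = ("N1", "C2", "N3", "C4", "C5", "C6")

_ANGLE_FIELDS = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi",
    "nu0", "nu1", "nu2", "nu3", "nu4",
    "eta", "theta", "eta_prime", "theta_prime", "eta_pprime", "theta_pprime",
    "phase", "amplitude",
)


@dataclass
class GeometricDescriptors:
    """All per-nucleotide geometric descriptors, NaN/None where undefined."""

    index: int
    alpha: float = math.nan
    beta: float = math.nan
    gamma: float = math.nan
    delta: float = math.nan
    epsilon: float = math.nan
    zeta: float = math.nan
    chi: float = math.nan
    chi_class: str | None = None
    nu0: float = math.nan
    nu1: float = math.nan
    nu2: float = math.nan
    nu3: float = math.nan
    nu4: float = math.nan
    eta: float = math.nan
    theta: float = math.nan
    eta_prime: float = math.nan
    theta_prime: float = math.nan
    eta_pprime: float = math.nan
    theta_pprime: float = math.nan
    phase: float = math.nan
    amplitude: float = math.nan
    pucker_label: str | None = None
    form_label: str | None = None  # ingested (A/B/Z), never computed here

    def defined_angles(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in _ANGLE_FIELDS
            if not math.isnan(getattr(self, name))
        }


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of the four points, in degrees on [0, 360).

    The angle is measured between plane(p1,p2,p3) and plane(p2,p3,p4) about
    the p2->p3 axis, positive clockwise looking down the axis (IUPAC
    convention).  Invariant under rigid motion.  Degenerate geometry
    (coincident points, collinear triples) yields NaN rather than raising.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return math.nan
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    return math.degrees(math.atan2(y, x)) % 360.0


def wrap_degrees(angle: float) -> float:
    """Reduce any angle in degrees to [0, 360)."""
    return angle % 360.0


def signed_degrees(angle: float) -> float:
    """Convert an angle on [0, 360) to the signed range (-180, 180]."""
    wrapped = angle % 360.0
    return wrapped - 360.0 if wrapped > 180.0 else wrapped


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth point ``d`` from internal coordinates (NeRF).

    ``d`` is at distance ``bond`` from ``c``, with angle(b, c, d) =
    ``angle_deg`` and dihedral(a, b, c, d) = ``torsion_deg``.  This is the
    inverse of :func:`dihedral` and serves as ground-truth construction for
    fixtures and tests.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _atom(chain: RnaChain, i: int, name: str) -> np.ndarray | None:
    """Atom ``name`` of 1-based residue i, or None if absent/out of range."""
    if i < 1 or i > len(chain.residues):
        return None
    return chain.residues[i - 1].atoms.get(name)


def _dihedral_or_nan(*points) -> float:
    if any(p is None for p in points):
        return math.nan
    return dihedral(*points)


def chi_torsion(residue: Residue) -> tuple[float, str | None]:
    """Glycosidic torsion chi and its syn/anti class.

    Purines use O4'-C1'-N9-C4, pyrimidines O4'-C1'-N1-C2.  The syn window is
    chi in [0, 90) or [270, 360); everything else is anti.
    """
    if residue.parent_base in PURINES:
        names = ("O4'", "C1'", "N9", "C4")
    elif residue.parent_base in PYRIMIDINES:
        names = ("O4'", "C1'", "N1", "C2")
    else:
        return math.nan, None
    pts = [residue.atoms.get(n) for n in names]
    chi = _dihedral_or_nan(*pts)
    if math.isnan(chi):
        return chi, None
    is_syn = chi < 90.0 or chi >= 270.0
    return chi, ("syn" if is_syn else "anti")


def backbone_torsions(chain: RnaChain, i: int) -> dict[str, float | str | None]:
    """Backbone torsions alpha..zeta plus chi/chi_class for residue i.

    Angles whose defining atoms are missing (termini, unresolved neighbors)
    are NaN.  An unresolved residue yields all-undefined.
    """
    res = chain.residues[i - 1]
    out: dict[str, float | str | None] = {}
    if not res.resolved:
        for name in BACKBONE_TORSION_ATOMS:
            out[name] = math.nan
        out["chi"], out["chi_class"] = math.nan, None
        return out
    for name, quad in BACKBONE_TORSION_ATOMS.items():
        pts = [_atom(chain, i + off, atom) for atom, off in quad]
        out[name] = _dihedral_or_nan(*pts)
    out["chi"], out["chi_class"] = chi_torsion(res)
    return out


def base_center(residue: Residue) -> np.ndarray | None:
    """Centroid of the base ring heavy atoms, or None when incomplete."""
    if residue.parent_base in PURINES:
        names = BASE_RING_ATOMS_PURINE
    elif residue.parent_base in PYRIMIDINES:
        names = BASE_RING_ATOMS_PYRIMIDINE
    else:
        return None
    pts = [residue.atoms.get(n) for n in names]
    if any(p is None for p in pts):
        return None
    return np.mean(np.array(pts), axis=0)


def pseudotorsions(chain: RnaChain, i: int) -> dict[str, float]:
    """The three pseudotorsion pairs for residue i.

    eta(i)  = torsion(C4'(i-1), P(i), C4'(i), P(i+1))
    theta(i) = torsion(P(i), C4'(i), P(i+1), C4'(i+1))

    Primed variants substitute C1' for C4'; double-primed variants
    substitute the base-center point.  Angles lacking a neighbor atom are
    NaN (the eta family is always undefined at the first residue, the theta
    family at the last).
    """
    res = chain.residues[i - 1]
    out = {k: math.nan for k in (
        "eta", "theta", "eta_prime", "theta_prime", "eta_pprime", "theta_pprime")}
    if not res.resolved:
        return out

    def anchor(j: int, kind: str) -> np.ndarray | None:
        if kind == "pp":
            if j < 1 or j > len(chain.residues):
                return None
            return base_center(chain.residues[j - 1])
        return _atom(chain, j, kind)

    for suffix, kind in (("", "C4'"), ("_prime", "C1'"), ("_pprime", "pp")):
        out["eta" + suffix] = _dihedral_or_nan(
            anchor(i - 1, kind), _atom(chain, i, "P"), anchor(i, kind), _atom(chain, i + 1, "P")
        )
        out["theta" + suffix] = _dihedral_or_nan(
            _atom(chain, i, "P"), anchor(i, kind), _atom(chain, i + 1, "P"), anchor(i + 1, kind)
        )
    return out


_PUCKER_DENOM = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))


def sugar_pucker(
    nu0: float, nu1: float, nu2: float, nu3: float, nu4: float
) -> tuple[float, float, str | None]:
    """Altona-Sundaralingam pseudorotation from five endocyclic torsions.

    Torsions are taken on the signed scale internally (inputs may be given
    either signed or on [0, 360)).  Returns ``(phase, amplitude, label)``
    with phase on [0, 360), amplitude >= 0 and the 36-degree conformer bin
    label; a planar ring (all-zero torsions) yields amplitude 0 and label
    ``None``.  The two-argument arctangent keeps nu2 ~ 0 well-defined.
    """
    nus = [signed_degrees(v) for v in (nu0, nu1, nu2, nu3, nu4)]
    if any(math.isnan(v) for v in nus):
        return math.nan, math.nan, None
    v0, v1, v2, v3, v4 = nus
    num = (v4 + v1) - (v3 + v0)  # proportional to nu_max * sin(P)
    den = v2 * _PUCKER_DENOM     # proportional to nu_max * cos(P)
    sin_part = num / _PUCKER_DENOM
    amplitude = math.hypot(v2, sin_part)
    if amplitude < 1e-12:
        return math.nan, 0.0, None
    phase = math.degrees(math.atan2(num, den)) % 360.0
    return phase, amplitude, pucker_label(phase)


def pucker_label(phase: float) -> str:
    """Name of the 36-degree pseudorotation bin containing ``phase``."""
    return PUCKER_BINS[int(wrap_degrees(phase) // 36.0) % 10]


def ribose_torsions(residue: Residue) -> dict[str, float]:
    out = {}
    for name, quad in NU_TORSION_ATOMS.items():
        pts = [residue.atoms.get(a) for a in quad]
        out[name] = _dihedral_or_nan(*pts)
    return out


def annotate_residue(chain: RnaChain, i: int) -> GeometricDescriptors:
    res = chain.residues[i - 1]
    desc = GeometricDescriptors(index=i)
    if not res.resolved:
        return desc
    bb = backbone_torsions(chain, i)
    desc.chi_class = bb.pop("chi_class")
    for name, val in bb.items():
        setattr(desc, name, val)
    for name, val in ribose_torsions(res).items():
        setattr(desc, name, val)
    for name, val in pseudotorsions(chain, i).items():
        setattr(desc, name, val)
    desc.phase, desc.amplitude, desc.pucker_label = sugar_pucker(
        desc.nu0, desc.nu1, desc.nu2, desc.nu3, desc.nu4
    )
    return desc


def annotate_chain(chain: RnaChain) -> list[GeometricDescriptors]:
    """One :class:`GeometricDescriptors` per residue, in chain order.

    Unresolved residues yield fully undefined records; per-residue geometry
    failures degrade to NaN fields rather than aborting the chain.
    """
    return [annotate_residue(chain, i) for i in range(1, len(chain.residues) + 1)]
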