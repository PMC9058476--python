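"""Point-charge electrostatic-potential models and their error measures.

A set of net atomic charges can be judged by how well its Coulomb potential
reproduces a reference molecular electrostatic potential (MEP) on a shell
between 1.4 and 2.0 times the atomic van der Waals radii — the region that
matters for intermolecular interactions.  The error is reported as RRMSE,
the RMSE of the charge model as a percentage of the RMSE of the all-zero
charge model, so 0% is a perfect model and 100% is no better than no
charges at all.  The molecular dipole error Delta-mu is reported alongside;
adding per-atom point dipoles can reproduce the molecular dipole exactly.

Units: coordinates and radii in bohr, charges in e, dipoles in atomic
units, potentials in kcal mol^-1 e^-1 (1 hartree/e = 627.509474).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._elements import atomic_number
from .errors import DegenerateGeometryError, ValidationError

#: hartree -> kcal/mol
HARTREE_TO_KCAL = 627.509474

DEFAULT_INNER = 1.4
DEFAULT_OUTER = 2.0
DEFAULT_SPACING = 0.4  # bohr


@dataclass
class Molecule:
    """Elements, Cartesian coordinates (bohr), and per-atom vdW radii (bohr)."""

    elements: list[str]
    coordinates: np.ndarray   # (n, 3) bohr
    radii: np.ndarray         # (n,) bohr
    net_charge: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if len(self.elements) != len(self.coordinates) or \
                len(self.radii) != len(self.coordinates):
            raise ValidationError("elements, coordinates, radii length mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates must be finite")
        if np.any(self.radii <= 0):
            raise ValidationError("vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([atomic_number(e) for e in self.elements], dtype=float)


@dataclass
class ESPGrid:
    """Shell grid points (bohr) with optional reference potentials."""

    points: np.ndarray                     # (m, 3) bohr
    reference: np.ndarray | None = None    # (m,) kcal/mol/e
    inner: float = DEFAULT_INNER
    outer: float = DEFAULT_OUTER
    spacing: float = DEFAULT_SPACING

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class ESPResult:
    """RMSE/RRMSE of a charge model plus its molecular dipole error."""

    rmse: float          # kcal/mol
    rmse_zero: float     # kcal/mol, zero-charge model
    rrmse: float         # percent
    mu_model: np.ndarray  # au, vector
    mu_model_magnitude: float
    delta_mu: float | None   # percent, None when no reference dipole given


def read_xyz_with_radii(path) -> Molecule:
    """Read an XYZ-style file with a 5th per-atom column of vdW radii (bohr)."""
    lines = [ln.split() for ln in open(path, encoding="utf-8")
             if ln.strip() and not ln.startswith("#")]
    # optional atom-count / comment header as in plain xyz
    start = 0
    if len(lines[0]) == 1 and lines[0][0].isdigit():
        start = 2 if len(lines) > 1 and len(lines[1]) != 5 else 1
    rows = lines[start:]
    elements = [r[0] for r in rows]
    coords = np.array([[float(v) for v in r[1:4]] for r in rows])
    radii = np.array([float(r[4]) for r in rows])
    return Molecule(elements, coords, radii)


def read_esp_grid(path) -> ESPGrid:
    """Read a whitespace-delimited ``x y z V_ref`` reference grid (bohr, kcal/mol/e)."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 4:
        raise ValidationError("grid file must have 4 columns: x y z V_ref")
    return ESPGrid(points=data[:, :3], reference=data[:, 3])


def build_vdw_shell_grid(mol: Molecule,
                         inner: float = DEFAULT_INNER,
                         outer: float = DEFAULT_OUTER,
                         spacing: float = DEFAULT_SPACING) -> ESPGrid:
    """Uniform cubic lattice filtered to the vdW shell.

    A lattice aligned with the axes and centered at the molecule's geometric
    center is clipped to points p with |p - r_a| >= inner * R_a for *every*
    atom and |p - r_a| <= outer * R_a for at least one atom.  Point order is
    lexicographic in the lattice indices, so the grid is deterministic.
    """
    if not 0 < inner < outer:
        raise ValidationError("require 0 < inner < outer")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    center = mol.coordinates.mean(axis=0)
    reach = np.max(np.linalg.norm(mol.coordinates - center, axis=1)
                   + outer * mol.radii)
    n = int(np.ceil(reach / spacing))
    idx = np.arange(-n, n + 1)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    pts = center + spacing * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)

    d = np.linalg.norm(pts[:, None, :] - mol.coordinates[None, :, :], axis=2)
    keep = np.all(d >= inner * mol.radii, axis=1) & \
        np.any(d <= outer * mol.radii, axis=1)
    points = pts[keep]
    if len(points) == 0:
        raise ValidationError("spacing too coarse: no grid points in shell")
    return ESPGrid(points=points, inner=inner, outer=outer, spacing=spacing)


def point_charge_potential(mol: Molecule, charges, points) -> np.ndarray:
    """Coulomb potential of point charges: V(p) = C * sum_a q_a / |p - r_a|.

    Distances in bohr; returns kcal mol^-1 e^-1.
    """
    q = np.asarray(charges, dtype=float)
    if len(q) != mol.n_atoms:
        raise ValidationError("one charge per atom required")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(pts[:, None, :] - mol.coordinates[None, :, :], axis=2)
    if np.any(d == 0):
        raise ValidationError("grid point coincides with an atom")
    return HARTREE_TO_KCAL * (q / d).sum(axis=1)


def molecular_dipole(mol: Molecule, charges,
                     atomic_dipoles=None) -> np.ndarray:
    """Dipole (au) of the point-charge (+ atomic dipole) model.

    mu = sum_a q_a * (r_a - r_0) + sum_a d_a.  For a neutral model the
    origin r_0 is irrelevant; for ions it is fixed at the center of nuclear
    charge so the value is well defined.
    """
    q = np.asarray(charges, dtype=float)
    if abs(q.sum()) > 1e-9:
        z = mol.atomic_numbers
        origin = (z[:, None] * mol.coordinates).sum(axis=0) / z.sum()
    else:
        origin = np.zeros(3)
    mu = (q[:, None] * (mol.coordinates - origin)).sum(axis=0)
    if atomic_dipoles is not None:
        mu = mu + np.asarray(atomic_dipoles, dtype=float).reshape(-1, 3).sum(axis=0)
    return mu


def esp_errors(model_values, reference_values, mol: Molecule, charges,
               mu_ref: float | np.ndarray | None = None,
               atomic_dipoles=None) -> ESPResult:
    """RMSE, RRMSE (% of the zero-charge model), dipole and Delta-mu.

    ``mu_ref`` may be a magnitude or a 3-vector (au); Delta-mu = 100 *
    (|mu_model| - |mu_ref|) / |mu_ref|.
    """
    model = np.asarray(model_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if model.shape != ref.shape:
        raise ValidationError("model and reference value lengths differ")
    rmse = float(np.sqrt(np.mean((model - ref) ** 2)))
    rmse_zero = float(np.sqrt(np.mean(ref ** 2)))
    if rmse_zero == 0:
        raise ValidationError("zero reference potential: RRMSE undefined")
    rrmse = 100.0 * rmse / rmse_zero

    mu_model = molecular_dipole(mol, charges, atomic_dipoles)
    mu_mag = float(np.linalg.norm(mu_model))
    delta_mu = None
    if mu_ref is not None:
        ref_mag = float(np.linalg.norm(np.atleast_1d(np.asarray(mu_ref, float))))
        if ref_mag == 0:
            raise ValidationError("|mu_ref| must be > 0 for Delta-mu")
        delta_mu = 100.0 * (mu_mag - ref_mag) / ref_mag
    return ESPResult(rmse, rmse_zero, rrmse, mu_model, mu_mag, delta_mu)


def triatomic_dipole_charges(mol: Molecule, mu_ref,
                             net_charge: float = 0.0,
                             tol: float = 1e-8) -> np.ndarray:
    """Charges of a bent symmetric A-B-A molecule from its dipole moment.

    For a C2v triatomic (central atom B, equivalent terminals A) the charge
    pattern (q_A, q_B, q_A) is uniquely fixed by q_B + 2 q_A = Q and the
    dipole along the symmetry axis.  Linear geometries leave the dipole
    insensitive to the charges and raise; so does a reference dipole with a
    component off the symmetry axis.

    Atom order must be terminal, center, terminal.  Returns (q_A, q_B, q_A).
    """
    if mol.n_atoms != 3:
        raise ValidationError("need exactly 3 atoms (A-B-A order: A, B, A)")
    a1, b, a2 = mol.coordinates
    e1, eb, e2 = mol.elements
    if e1 != e2 or not np.isclose(np.linalg.norm(a1 - b),
                                  np.linalg.norm(a2 - b), rtol=1e-6):
        raise ValidationError("terminal atoms are not symmetry-equivalent")

    midpoint = (a1 + a2) / 2.0
    axis = b - midpoint
    axis_len = np.linalg.norm(axis)
    scale = max(np.linalg.norm(a1 - b), 1.0)
    if axis_len < tol * scale:
        raise DegenerateGeometryError(
            "linear geometry: dipole does not determine the charges")
    u = axis / axis_len

    mu = np.atleast_1d(np.asarray(mu_ref, dtype=float))
    if mu.size == 1:
        mu_axis = float(mu[0])
    else:
        off = mu - (mu @ u) * u
        if np.linalg.norm(off) > max(tol, 1e-6 * max(np.linalg.norm(mu), 1.0)):
            raise ValidationError("reference dipole has an off-axis component")
        mu_axis = float(mu @ u)

    # neutral-model origin cancels on-axis; solve the 2x2 system
    # q_B + 2 q_A = Q ; q_B (r_B . u) + q_A ((r_A1 + r_A2) . u) = mu_axis
    coeff = np.array([[2.0, 1.0],
                      [(a1 + a2) @ u, b @ u]])
    rhs = np.array([net_charge, mu_axis])
    det = np.linalg.det(coeff)
    if abs(det) < tol:
        raise DegenerateGeometryError("charge system is singular")
    q_a, q_b = np.linalg.solve(coeff, rhs)
    return np.array([q_a, q_b, q_a])
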