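"""Potential grids, skin masks and the Hodgkin electrostatic similarity index.

Electrostatic potentials are represented on a regular 3-D grid (the
convention of finite-difference Poisson-Boltzmann solvers such as APBS,
whose OpenDX output this module reads and writes).  Two potentials are
compared with the Hodgkin index

    SI(a, b) = 2 <a, b> / (<a, a> + <b, b>)

evaluated either over the full grid or restricted to a "skin": a shell
of grid points lying 3-7 Angstrom outside the van der Waals surface of a
structure, where the potential is shape-sensitive but not dominated by
interior singularities.  Pairwise comparisons use the intersection of
the two structures' skins.

A naive Coulomb generator over explicit point charges is included so
that grid families with known ground truth can be produced without an
external Poisson-Boltzmann run; it is a test/synthetic-data facility,
not a physical solvent model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrices import LabeledSquareMatrix

__all__ = [
    "GridGeometry",
    "PotentialGrid",
    "SkinMask",
    "ChargeSystem",
    "default_geometry",
    "hodgkin_index",
    "compute_skin_mask",
    "intersect_masks",
    "coulomb_potential",
    "pairwise_similarity",
    "read_dx",
    "write_dx",
    "charge_system_from_pdb",
    "VDW_RADII",
]

logger = logging.getLogger(__name__)

# Bondi-style van der Waals radii (Angstrom) for elements common in
# protein structures; unknown elements fall back to 1.7 A with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "CA": 2.31, "MG": 1.73, "NA": 2.27, "K": 2.75,
    "FE": 1.94, "MN": 1.93, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.7


@dataclass(frozen=True)
class GridGeometry:
    """Origin (A), per-axis spacing (A) and shape of a regular grid."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if any(s < 2 for s in self.shape):
            raise ValueError(f"grid shape components must be >= 2, got {self.shape}")
        if any(h <= 0 for h in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def points(self) -> np.ndarray:
        """All grid-point coordinates, shape (n_points, 3), z fastest."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def default_geometry(center=(0.0, 0.0, 0.0), shape=(65, 65, 65), spacing=1.5) -> GridGeometry:
    """A 65x65x65 grid at 1.5 A spacing centred on ``center``.

    These are the dimensions typically used for whole-domain protein
    electrostatics comparisons; the grid is placed symmetrically about
    the requested centre (e.g. the common centre of mass of a set of
    superposed structures).
    """
    spacing3 = (spacing, spacing, spacing) if np.isscalar(spacing) else tuple(spacing)
    origin = tuple(
        float(center[k]) - spacing3[k] * (shape[k] - 1) / 2.0 for k in range(3)
    )
    return GridGeometry(origin, spacing3, tuple(shape))


def _require_same_geometry(g1: GridGeometry, g2: GridGeometry, what: str) -> None:
    names = ("origin", "spacing", "shape")
    for name in names:
        a, b = getattr(g1, name), getattr(g2, name)
        if not np.allclose(a, b, atol=1e-9):
            raise ValueError(f"{what}: grid {name} differs ({a} vs {b})")


@dataclass(frozen=True)
class PotentialGrid:
    """A scalar field sampled on a regular grid (potential units as produced upstream)."""

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid shape {self.geometry.shape}"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SkinMask:
    """Boolean flags on a grid selecting the comparison shell."""

    geometry: GridGeometry
    flags: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.shape != self.geometry.shape:
            raise ValueError(
                f"flags shape {flags.shape} does not match grid shape {self.geometry.shape}"
            )
        object.__setattr__(self, "flags", flags)

    @property
    def n_selected(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class ChargeSystem:
    """Point charges with positions (A), charges (e) and vdW radii (A)."""

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        r = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if pos.shape != (len(q), 3) or len(r) != len(q):
            raise ValueError("positions, charges and radii must have equal lengths")
        if len(q) == 0:
            raise ValueError("charge system must contain at least one atom")
        if (r <= 0).any():
            raise ValueError("van der Waals radii must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return len(self.charges)


def hodgkin_index(a: PotentialGrid, b: PotentialGrid, mask: SkinMask | None = None) -> float:
    """Hodgkin similarity 2<a,b> / (|a|^2 + |b|^2) over the masked points.

    Returns 1 for identical potentials, 0 for orthogonal ones and -1 for
    anti-correlated ones; the value is bounded in [-1, 1] by the AM-GM
    inequality.  With ``mask=None`` the full grid is used.
    """
    _require_same_geometry(a.geometry, b.geometry, "hodgkin_index")
    if mask is not None:
        _require_same_geometry(a.geometry, mask.geometry, "hodgkin_index mask")
        va = a.values[mask.flags]
        vb = b.values[mask.flags]
    else:
        va = a.values.ravel()
        vb = b.values.ravel()
    denom = float(va @ va + vb @ vb)
    if denom == 0.0:
        raise ValueError(
            "both potentials are identically zero on the comparison region (0/0)"
        )
    si = 2.0 * float(va @ vb) / denom
    return float(np.clip(si, -1.0, 1.0))


def compute_skin_mask(
    structure: ChargeSystem,
    geometry: GridGeometry,
    inner: float = 3.0,
    thickness: float = 4.0,
    chunk: int = 65536,
) -> SkinMask:
    """Grid points whose distance to the vdW surface lies in [inner, inner+thickness].

    The distance of a point p to the van der Waals surface is
    approximated as min_k (|p - r_k| - radius_k) over atoms k: negative
    inside an atom, positive outside all of them.  With the defaults
    (3 A offset, 4 A thickness) the skin is the closed shell 3-7 A away
    from the surface.
    """
    if inner < 0:
        raise ValueError("inner offset must be >= 0")
    if thickness <= 0:
        raise ValueError("skin thickness must be > 0")
    pts = geometry.points()
    surf = np.empty(len(pts))
    # chunked so 65^3-point grids against large structures stay in memory
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - structure.positions[None, :, :], axis=2)
        surf[start : start + chunk] = (d - structure.radii[None, :]).min(axis=1)
    flags = (surf >= inner) & (surf <= inner + thickness)
    return SkinMask(geometry, flags.reshape(geometry.shape))


def intersect_masks(masks: list[SkinMask]) -> SkinMask:
    """Pointwise AND of one or more skin masks sharing a geometry."""
    if not masks:
        raise ValueError("need at least one mask")
    flags = masks[0].flags.copy()
    for m in masks[1:]:
        _require_same_geometry(masks[0].geometry, m.geometry, "intersect_masks")
        flags &= m.flags
    return SkinMask(masks[0].geometry, flags)


def coulomb_potential(
    system: ChargeSystem,
    geometry: GridGeometry,
    clamp: float | None = None,
    chunk: int = 65536,
) -> PotentialGrid:
    """Unscreened Coulomb sum V(p) = sum_k q_k / max(|p - r_k|, clamp).

    The distance clamp (default half the smallest grid spacing) bounds
    values near charge positions so grids are finite everywhere; this is
    a fixture-generation convenience, not a dielectric model.  The field
    is linear in the charges.
    """
    if clamp is None:
        clamp = 0.5 * min(geometry.spacing)
    pts = geometry.points()
    vals = np.empty(len(pts))
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - system.positions[None, :, :], axis=2)
        np.maximum(d, clamp, out=d)
        vals[start : start + chunk] = (system.charges[None, :] / d).sum(axis=1)
    return PotentialGrid(geometry, vals.reshape(geometry.shape))


def pairwise_similarity(
    grids: list[PotentialGrid],
    masks: list[SkinMask] | None = None,
    labels: list[str] | None = None,
) -> LabeledSquareMatrix:
    """All-pairs Hodgkin similarity matrix over n(n-1)/2 grid comparisons.

    When masks are supplied, pair (i, j) is compared over the
    intersection of skin i and skin j; otherwise over the full grid.
    """
    n = len(grids)
    if n < 2:
        raise ValueError("need at least two grids")
    if masks is not None and len(masks) != n:
        raise ValueError("need one mask per grid")
    if labels is None:
        labels = [f"grid{i:03d}" for i in range(n)]
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = None
            if masks is not None:
                mask = intersect_masks([masks[i], masks[j]])
            sim[i, j] = sim[j, i] = hodgkin_index(grids[i], grids[j], mask)
    return LabeledSquareMatrix(tuple(labels), sim, "similarity")


# ---------------------------------------------------------------------------
# OpenDX I/O (APBS dialect).  In-file data order follows the OpenDX
# convention: the z index varies fastest, then y, then x — which matches
# C-order raveling of an (nx, ny, nz) array.

def write_dx(grid: PotentialGrid, path, comment: str = "written by cmclust") -> None:
    nx, ny, nz = grid.geometry.shape
    ox, oy, oz = grid.geometry.origin
    hx, hy, hz = grid.geometry.spacing
    flat = grid.values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.12g} {oy:.12g} {oz:.12g}\n")
        fh.write(f"delta {hx:.12g} 0 0\n")
        fh.write(f"delta 0 {hy:.12g} 0\n")
        fh.write(f"delta 0 0 {hz:.12g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.9e}" for v in flat[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> PotentialGrid:
    """Read an OpenDX regular-grid scalar file (as written by APBS)."""
    shape = None
    origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    reading_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if reading_data:
                if line.startswith(("attribute", "object", "component")):
                    reading_data = False
                    continue
                try:
                    values.extend(float(tok) for tok in line.split())
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed data line {line!r}")
                continue
            if line.startswith("object") and "gridpositions" in line:
                toks = line.split()
                try:
                    shape = tuple(int(t) for t in toks[-3:])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed gridpositions counts")
            elif line.startswith("origin"):
                origin = tuple(float(t) for t in line.split()[1:4])
            elif line.startswith("delta"):
                deltas.append([float(t) for t in line.split()[1:4]])
            elif line.startswith("object") and "class array" in line:
                toks = line.split()
                try:
                    n_items = int(toks[toks.index("items") + 1])
                except (ValueError, IndexError):
                    raise ValueError(f"{path}:{lineno}: malformed array header")
                reading_data = True
    if shape is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path}: incomplete OpenDX header")
    d = np.asarray(deltas)
    if not np.allclose(d, np.diag(np.diag(d))):
        raise ValueError(f"{path}: only axis-aligned (diagonal delta) grids are supported")
    spacing = tuple(np.diag(d))
    expected = shape[0] * shape[1] * shape[2]
    if n_items != expected or len(values) != expected:
        raise ValueError(
            f"{path}: data count mismatch (header {n_items}, read {len(values)}, "
            f"shape implies {expected})"
        )
    geometry = GridGeometry(origin, spacing, shape)
    return PotentialGrid(geometry, np.asarray(values).reshape(shape, order="C"))


# ---------------------------------------------------------------------------
# PDB input (coordinates and elements only; structures assumed pre-superposed)

def charge_system_from_pdb(path, charges: np.ndarray | None = None) -> ChargeSystem:
    """Build a ChargeSystem (for skin masks) from the first model of a PDB file.

    Charges default to zero — the PDB is consulted only for atom
    positions and elements; radii come from the built-in vdW table.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    model = next(structure.get_models())
    positions, radii = [], []
    unknown: set[str] = set()
    for atom in model.get_atoms():
        positions.append(atom.coord)
        elem = (atom.element or "").strip().upper()
        if elem in VDW_RADII:
            radii.append(VDW_RADII[elem])
        else:
            unknown.add(elem or atom.get_name())
            radii.append(DEFAULT_VDW_RADIUS)
    if unknown:
        logger.warning(
            "unknown elements %s assigned default vdW radius %.2f A",
            sorted(unknown), DEFAULT_VDW_RADIUS,
        )
    if not positions:
        raise ValueError(f"{path}: no atoms found")
    positions = np.asarray(positions, dtype=float)
    if charges is None:
        charges = np.zeros(len(positions))
    return ChargeSystem(positions, charges, np.asarray(radii))
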