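"""Voxelization: molecules to electron-density and electrostatic-potential grids.

Molecules are sampled onto a centered cubic lattice (default 64 voxels per
side, 0.5 Angstrom step).  The built-in electron density is promolecular — a
sum of normalized isotropic atom-centered Gaussians, one per atom, each
integrating to the element's electron count::

    rho(r) = sum_a  Z_a * (alpha_a / pi)^(3/2) * exp(-alpha_a * |r - r_a|^2)

with the width ``alpha_a`` set so the Gaussian standard deviation equals the
element's covalent radius.  The electrostatic potential is a softened Coulomb
sum over per-atom partial charges::

    V(r) = sum_a  q_a / sqrt(|r - r_a|^2 + eps^2)

in proportional units of e/Angstrom; ``eps`` (default 0.5 A, one voxel)
removes the singularity at the nuclei.  Any quantum backend can replace
either field through the ``backend`` callable arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .chemio import ELEMENTS, Molecule

__all__ = [
    "GridSpec",
    "DensityGrid",
    "ESPGrid",
    "DecoratedVolume",
    "VoxelizeParams",
    "COVALENT_RADIUS",
    "center_molecule",
    "compute_density_grid",
    "compute_esp_grid",
    "dilate_sparse",
    "decorate",
    "assign_gasteiger_charges",
]

# covalent radii in Angstrom (Cordero et al. consensus values)
COVALENT_RADIUS: dict[str, float] = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57}


@dataclass(frozen=True)
class GridSpec:
    """Cubic voxel lattice centered on the origin.

    Voxel-center coordinate of index ``i`` along an axis is
    ``(i - (n_voxels - 1) / 2) * step`` Angstrom.
    """

    n_voxels: int = 64
    step: float = 0.5

    def __post_init__(self):
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def extent(self) -> float:
        """Physical edge length of the box in Angstrom."""
        return self.n_voxels * self.step

    def axis_coords(self) -> np.ndarray:
        n = self.n_voxels
        return (np.arange(n) - (n - 1) / 2.0) * self.step

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self.axis_coords()
        return np.meshgrid(c, c, c, indexing="ij")


@dataclass
class DensityGrid:
    spec: GridSpec
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.spec.n_voxels
        if self.values.shape != (n, n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n},{n},{n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite density values")
        if np.any(self.values < 0):
            raise ValueError("electron density must be non-negative")

    def integral(self) -> float:
        """Grid estimate of the electron count: sum(values) * step^3."""
        return float(self.values.sum() * self.spec.step ** 3)


@dataclass
class ESPGrid:
    spec: GridSpec
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.spec.n_voxels
        if self.values.shape != (n, n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n},{n},{n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite ESP values")


@dataclass
class DecoratedVolume:
    """Electron density decorated channel-wise with its electrostatic potential."""

    spec: GridSpec
    channels: tuple

    @property
    def array(self) -> np.ndarray:
        """(2, n, n, n) stack: channel 0 = ED, channel 1 = ESP."""
        return np.stack([self.channels[0].values, self.channels[1].values])


@dataclass
class VoxelizeParams:
    alphas: dict = field(default_factory=lambda: {
        el: 1.0 / (2.0 * COVALENT_RADIUS[el] ** 2) for el in COVALENT_RADIUS})
    esp_softening: float = 0.5   # Angstrom; ~one voxel at the default step
    margin: float = 2.0          # Angstrom; atoms closer to the wall warn
    cutoff_sigmas: float = 8.0   # Gaussian evaluation cutoff


def center_molecule(mol: Molecule) -> Molecule:
    """Translate so the unweighted geometric center of the atoms is the origin."""
    if mol.n_atoms == 0:
        raise ValueError("cannot center an empty molecule")
    centered = mol.coords - mol.coords.mean(axis=0)
    return Molecule(elements=list(mol.elements), coords=centered,
                    charges=None if mol.charges is None else mol.charges.copy(),
                    smiles=mol.smiles)


def _check_inside(mol: Molecule, spec: GridSpec, margin: float, provenance: dict) -> None:
    half = spec.extent / 2.0
    outside = np.abs(mol.coords).max(axis=1) > half - margin
    if np.any(outside):
        idx = np.nonzero(outside)[0].tolist()
        msg = (f"{len(idx)} atom(s) within {margin} A of the grid boundary "
               f"(extent {spec.extent} A): indices {idx}")
        provenance["boundary_warning"] = msg
        warnings.warn(msg, stacklevel=3)


def compute_density_grid(mol: Molecule, spec: GridSpec,
                         params: VoxelizeParams | None = None,
                         backend: Callable | None = None) -> DensityGrid:
    """Promolecular Gaussian electron density sampled at voxel centers.

    ``backend`` may be any callable ``(mol, spec) -> (n,n,n) array`` to swap in
    a quantum-chemistry density.
    """
    params = params or VoxelizeParams()
    prov: dict = {"model": "promolecular-gaussian"}
    _check_inside(mol, spec, params.margin, prov)
    if backend is not None:
        vals = np.asarray(backend(mol, spec), dtype=np.float64)
        return DensityGrid(spec=spec, values=vals,
                           provenance={"model": "backend", **prov})
    ax = spec.axis_coords()
    n = spec.n_voxels
    vals = np.zeros((n, n, n), dtype=np.float64)
    for el, pos in zip(mol.elements, mol.coords):
        if el not in params.alphas:
            raise ValueError(f"no Gaussian width configured for element {el!r}")
        alpha = params.alphas[el]
        z = ELEMENTS[el]
        # separable Gaussian: exp(-a|r-ra|^2) = gx ⊗ gy ⊗ gz
        cutoff = params.cutoff_sigmas / np.sqrt(2 * alpha)
        gs = []
        for d in range(3):
            dist2 = (ax - pos[d]) ** 2
            g = np.where(dist2 < cutoff ** 2, np.exp(-alpha * dist2), 0.0)
            gs.append(g)
        amp = z * (alpha / np.pi) ** 1.5
        vals += amp * gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
    return DensityGrid(spec=spec, values=vals, provenance=prov)


def compute_esp_grid(mol: Molecule, spec: GridSpec,
                     params: VoxelizeParams | None = None,
                     backend: Callable | None = None) -> ESPGrid:
    """Softened Coulomb electrostatic potential from per-atom partial charges."""
    params = params or VoxelizeParams()
    if backend is not None:
        vals = np.asarray(backend(mol, spec), dtype=np.float64)
        return ESPGrid(spec=spec, values=vals, provenance={"model": "backend"})
    if mol.charges is None:
        raise ValueError(
            "molecule has no partial charges; assign them first "
            "(e.g. voxelize.assign_gasteiger_charges) or supply a charge column")
    x, y, z = spec.voxel_centers()
    vals = np.zeros_like(x)
    eps2 = params.esp_softening ** 2
    for q, pos in zip(mol.charges, mol.coords):
        r2 = (x - pos[0]) ** 2 + (y - pos[1]) ** 2 + (z - pos[2]) ** 2
        vals += q / np.sqrt(r2 + eps2)
    return ESPGrid(spec=spec, values=vals,
                   provenance={"model": "softened-coulomb",
                               "softening_A": params.esp_softening})


def dilate_sparse(points: np.ndarray, values: np.ndarray, spec: GridSpec,
                  radius_voxels: float) -> ESPGrid:
    """Spread sparse point samples onto the grid by nearest-source dilation.

    Every voxel whose center lies within ``radius_voxels`` (Euclidean, voxel
    units) of at least one source point takes the value of its nearest source
    (ties broken toward the smallest point index); all other voxels are zero.
    Points are Cartesian Angstrom coordinates.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be non-negative")
    n = spec.n_voxels
    out = np.zeros((n, n, n), dtype=np.float64)
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    values = np.asarray(values, dtype=np.float64).ravel()
    if points.shape[0] == 0:
        return ESPGrid(spec=spec, values=out)
    # voxel-space coordinates of sources and voxel centers
    pvox = points / spec.step + (n - 1) / 2.0
    idx = np.arange(n, dtype=np.float64)
    vx, vy, vz = np.meshgrid(idx, idx, idx, indexing="ij")
    centers = np.stack([vx, vy, vz], axis=-1).reshape(-1, 3)
    d2 = ((centers[:, None, :] - pvox[None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=1)               # first minimum = smallest index
    within = d2[np.arange(d2.shape[0]), nearest] <= radius_voxels ** 2 + 1e-12
    flat = out.reshape(-1)
    flat[within] = values[nearest[within]]
    return ESPGrid(spec=spec, values=out)


def decorate(ed: DensityGrid, esp: ESPGrid) -> DecoratedVolume:
    """Stack an ED grid and its ESP grid as a two-channel volume."""
    if ed.spec != esp.spec:
        raise ValueError(f"grid specs differ: {ed.spec} vs {esp.spec}")
    return DecoratedVolume(spec=ed.spec, channels=(ed, esp))


def assign_gasteiger_charges(mol: Molecule) -> Molecule:
    """Gasteiger partial charges (electronegativity equalization) via RDKit.

    Requires ``mol.smiles``; charges are mapped onto the existing atom order
    by matching the heavy-atom/hydrogen layout of the embedded structure.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if mol.smiles is None:
        raise ValueError("SMILES required for Gasteiger charge assignment")
    rd = Chem.MolFromSmiles(mol.smiles)
    if rd is None:
        raise ValueError(f"unparseable SMILES {mol.smiles!r}")
    rd = Chem.AddHs(rd)
    AllChem.ComputeGasteigerCharges(rd)
    qs = np.array([float(a.GetProp("_GasteigerCharge")) for a in rd.GetAtoms()])
    syms = [a.GetSymbol() for a in rd.GetAtoms()]
    if syms != list(mol.elements):
        # fall back to matching by element multiset order
        order: dict[str, list[int]] = {}
        for i, s in enumerate(syms):
            order.setdefault(s, []).append(i)
        try:
            qs = np.array([qs[order[e].pop(0)] for e in mol.elements])
        except (KeyError, IndexError):
            raise ValueError("atom layout of SMILES does not match molecule") from None
    return Molecule(elements=list(mol.elements), coords=mol.coords.copy(),
                    charges=qs, smiles=mol.smiles)
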