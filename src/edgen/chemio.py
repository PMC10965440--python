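"""File formats and core records: molecules, run configuration, volumetric I/O.

Reads and writes the on-disk formats used across the pipeline: XYZ geometries,
Gaussian cube volumes, one-per-line SMILES lists, chunked HDF5 datasets of
(volume, SMILES) training pairs, and the JSON run configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "Molecule",
    "RunConfig",
    "ParseError",
    "FormatError",
    "ELEMENTS",
    "read_xyz",
    "write_xyz",
    "read_cube",
    "write_cube",
    "read_smiles_list",
    "write_smiles_list",
    "dataset_write",
    "dataset_iter",
    "dataset_len",
]

# atomic numbers for the supported (QM9-scale) elements
ELEMENTS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9}
_SYMBOL_OF = {z: s for s, z in ELEMENTS.items()}

BOHR_PER_ANGSTROM = 1.8897259886


class ParseError(ValueError):
    """Malformed text input (carries a file/line context in the message)."""


class FormatError(ValueError):
    """Structurally invalid volumetric or dataset file."""


@dataclass
class Molecule:
    """Atoms in 3D: element symbols, Cartesian coordinates in Angstrom,
    optional per-atom partial charges (elementary charge) and a SMILES string."""

    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    smiles: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.coords)} coordinate rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for el in self.elements:
            if el not in ELEMENTS:
                raise ValueError(f"unsupported element symbol {el!r}")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=np.float64).ravel()
            if len(self.charges) != len(self.elements):
                raise ValueError("charges length does not match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ELEMENTS[e] for e in self.elements], dtype=np.int64)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum())


@dataclass
class RunConfig:
    """JSON-serializable configuration shared by the CLI subcommands."""

    n_voxels: int = 16
    step: float = 0.5
    latent_dim: int = 32
    # model hyper-parameters
    vae_channels: tuple = (8, 16, 32)
    vae_beta: float = 1e-3
    esp_channels: int = 8
    esp_layers: int = 4
    d_model: int = 64
    n_heads: int = 2
    n_blocks: int = 2
    max_len: int = 32
    # training
    epochs: int = 100
    batch_size: int = 8
    train_lr: float = 1e-3
    # latent optimizer
    population: int = 16
    learning_rate: float = 0.05
    max_iter: int = 500
    lam: float = 0.5
    stage1_max_iter: int = 100
    plateau_tol: float = 1e-3
    plateau_window: int = 20
    rng_seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_voxels < 8 or self.n_voxels % 2 != 0:
            raise ValueError("n_voxels must be an even integer >= 8")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if not (isinstance(self.rng_seed, (int, np.integer)) and self.rng_seed >= 0):
            raise ValueError("rng_seed must be a non-negative integer")
        if self.plateau_window < 2:
            raise ValueError("plateau_window must be >= 2")
        self.vae_channels = tuple(self.vae_channels)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(path) -> Molecule:
    """Parse a standard XYZ file (count line, comment, ``El x y z`` rows, Angstrom).

    A fifth numeric column, when present on every atom row, is read as a
    per-atom partial charge.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: malformed atom-count line {lines[0]!r}") from None
    body = lines[2:2 + n]
    if len(body) < n:
        raise ParseError(f"{path}: count line says {n} atoms but only "
                         f"{len(body)} atom rows present")
    elements, coords, charges = [], [], []
    for i, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{i}: expected 'El x y z', got {line!r}")
        el = parts[0]
        if el not in ELEMENTS:
            raise ParseError(f"{path}:{i}: unknown element symbol {el!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}:{i}: non-numeric coordinate in {line!r}") from None
        elements.append(el)
        coords.append(xyz)
        if len(parts) >= 5:
            try:
                charges.append(float(parts[4]))
            except ValueError:
                charges.append(np.nan)
    q = np.asarray(charges) if len(charges) == n else None
    if q is not None and not np.all(np.isfinite(q)):
        q = None
    return Molecule(elements=elements, coords=np.asarray(coords), charges=q)


def write_xyz(mol: Molecule, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{comment}\n")
        for i, el in enumerate(mol.elements):
            x, y, z = mol.coords[i]
            row = f"{el} {x:.6f} {y:.6f} {z:.6f}"
            if mol.charges is not None:
                row += f" {mol.charges[i]:.6f}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Gaussian cube
#
# Layout: two comment lines; natoms + origin; three axis lines (count, axis
# vector); one line per atom (Z, charge, x, y, z); values in z-fastest order.
# Negative voxel counts mark Angstrom units (positive would mean Bohr).


def write_cube(grid, molecule: Molecule | None, path) -> None:
    """Write a cubic grid (``grid.values`` n^3, ``grid.spec``) as a Gaussian cube."""
    spec = grid.spec
    n = spec.n_voxels
    h = spec.step
    origin = -(n - 1) / 2.0 * h
    mol = molecule if molecule is not None else Molecule(elements=[], coords=np.zeros((0, 3)))
    with open(path, "w") as fh:
        fh.write("edgen volumetric grid\n")
        fh.write("lengths in Angstrom (negative voxel counts)\n")
        fh.write(f"{max(mol.n_atoms, 0):5d} {origin:12.6f} {origin:12.6f} {origin:12.6f}\n")
        fh.write(f"{-n:5d} {h:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{-n:5d} {0.0:12.6f} {h:12.6f} {0.0:12.6f}\n")
        fh.write(f"{-n:5d} {0.0:12.6f} {0.0:12.6f} {h:12.6f}\n")
        for i, el in enumerate(mol.elements):
            x, y, z = mol.coords[i]
            q = mol.charges[i] if mol.charges is not None else 0.0
            fh.write(f"{ELEMENTS[el]:5d} {q:12.6f} {x:12.6f} {y:12.6f} {z:12.6f}\n")
        vals = np.asarray(grid.values, dtype=np.float64).reshape(n, n, n)
        flat = vals.reshape(-1)  # C order == z fastest
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v: .5E}" for v in flat[start:start + 6]) + "\n")


def read_cube(path):
    """Read a Gaussian cube written by :func:`write_cube` (or any cubic cube file).

    Returns ``(values, spec, molecule)``; values are n^3 z-fastest.  Positive
    voxel counts are interpreted as Bohr units and converted to Angstrom.
    """
    from .voxelize import GridSpec  # local import to avoid a cycle

    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated cube header")
    natoms = int(lines[2].split()[0])
    axes = []
    for k in range(3):
        parts = lines[3 + k].split()
        axes.append((int(parts[0]), [float(p) for p in parts[1:4]]))
    counts = [abs(a[0]) for a in axes]
    in_angstrom = axes[0][0] < 0
    if len(set(counts)) != 1:
        raise FormatError(f"{path}: non-cubic grid {counts}")
    n = counts[0]
    steps = [axes[0][1][0], axes[1][1][1], axes[2][1][2]]
    off = [axes[0][1][1], axes[0][1][2], axes[1][1][0], axes[1][1][2],
           axes[2][1][0], axes[2][1][1]]
    if any(abs(o) > 1e-9 for o in off):
        raise FormatError(f"{path}: non-axis-aligned cube axes")
    if abs(steps[0] - steps[1]) > 1e-9 or abs(steps[0] - steps[2]) > 1e-9:
        raise FormatError(f"{path}: anisotropic voxel step {steps}")
    h = steps[0] if in_angstrom else steps[0] / BOHR_PER_ANGSTROM
    scale = 1.0 if in_angstrom else 1.0 / BOHR_PER_ANGSTROM
    elements, coords, charges = [], [], []
    for row in lines[6:6 + natoms]:
        parts = row.split()
        z = int(parts[0])
        if z not in _SYMBOL_OF:
            raise FormatError(f"{path}: unsupported atomic number {z}")
        elements.append(_SYMBOL_OF[z])
        charges.append(float(parts[1]))
        coords.append([float(p) * scale for p in parts[2:5]])
    mol = None
    if natoms:
        mol = Molecule(elements=elements, coords=np.asarray(coords),
                       charges=np.asarray(charges))
    vals = np.array(" ".join(lines[6 + natoms:]).split(), dtype=np.float64)
    if vals.size != n ** 3:
        raise FormatError(f"{path}: expected {n**3} values, found {vals.size}")
    spec = GridSpec(n_voxels=n, step=h)
    return vals.reshape(n, n, n), spec, mol


# ---------------------------------------------------------------------------
# SMILES lists


def read_smiles_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_smiles_list(smiles: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(smiles) + ("\n" if smiles else ""))


# ---------------------------------------------------------------------------
# record-oriented (volume, SMILES) datasets — chunked HDF5


def dataset_write(pairs: Sequence[tuple[np.ndarray, str]], path,
                  spec=None, attrs: dict | None = None) -> None:
    """Write (volume, smiles) pairs; volumes must share one shape.

    Volumes are stored as float32, channels-last, shape (N, n, n, n, C);
    plain 3D arrays are stored with a single channel.
    """
    vols = []
    for v, _ in pairs:
        a = np.asarray(v, dtype=np.float32)
        if a.ndim == 3:
            a = a[..., None]
        vols.append(a)
    if vols:
        shape0 = vols[0].shape
        for i, a in enumerate(vols):
            if a.shape != shape0:
                raise FormatError(f"pair {i} has grid shape {a.shape}, expected {shape0}")
    smiles = [s for _, s in pairs]
    with h5py.File(path, "w") as f:
        if vols:
            f.create_dataset("volumes", data=np.stack(vols), chunks=(1,) + shape0,
                             dtype=np.float32)
        else:
            f.create_dataset("volumes", shape=(0, 0, 0, 0, 1), dtype=np.float32)
        dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("smiles", data=np.array(smiles, dtype=object), dtype=dt)
        if spec is not None:
            f.attrs["n_voxels"] = spec.n_voxels
            f.attrs["step"] = spec.step
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def dataset_iter(path) -> Iterator[tuple[np.ndarray, str]]:
    """Iterate (volume, smiles) in write order."""
    with h5py.File(path, "r") as f:
        n = f["smiles"].shape[0]
        for i in range(n):
            vol = f["volumes"][i] if f["volumes"].shape[0] else None
            s = f["smiles"][i]
            yield vol, s.decode("utf-8") if isinstance(s, bytes) else str(s)


def dataset_len(path) -> int:
    with h5py.File(path, "r") as f:
        return int(f["smiles"].shape[0])
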