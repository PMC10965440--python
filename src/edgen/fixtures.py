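"""Deterministic synthetic molecules, toy hosts and training pairs.

Generates QM9-scale molecules (up to 9 heavy atoms of C/N/O/F plus
hydrogens) from four structural families — linear alkanes, primary and
secondary amines, ethers and small carbocycles/heterocycles — with 3D
coordinates from seeded distance-geometry embedding and Gasteiger partial
charges.  Also builds analytic "toy hosts": hollow density shells with a
dipolar ESP pattern at the cavity mouths, standing in for container
molecules (which exceed the 9-heavy-atom generative scope).  Ingestion of
the public QM9 dataset from a local copy is an optional path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemio import Molecule
from .smiles_codec import canonicalize
from .voxelize import (DensityGrid, ESPGrid, GridSpec, center_molecule,
                       compute_density_grid, compute_esp_grid)

__all__ = [
    "FixtureSpec",
    "FAMILIES",
    "family_smiles",
    "toy_molecule_library",
    "make_training_pairs",
    "toy_host",
    "qm9_ingest",
    "embed_molecule",
]

FAMILIES = ("alkanes", "primary_amines", "secondary_amines", "ethers", "rings")


@dataclass
class FixtureSpec:
    family: str = "alkanes"
    size_range: tuple = (1, 4)     # heavy-atom counts, inclusive
    count: int = 16
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(n_voxels=16, step=0.5))

    def __post_init__(self):
        if self.family not in FAMILIES and self.family != "all":
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        lo, hi = self.size_range
        if lo > hi or hi > 9:
            raise ValueError("size_range must satisfy lo <= hi <= 9 heavy atoms")
        if self.family == "rings" and hi < 3:
            raise ValueError("ring family needs at least 3 heavy atoms")


def family_smiles(family: str, size_range: tuple) -> list[str]:
    """Enumerate the SMILES of one structural family over a heavy-atom range."""
    lo, hi = size_range
    out: list[str] = []
    if family in ("alkanes", "all"):
        out += ["C" * k for k in range(max(lo, 1), hi + 1)]
    if family in ("primary_amines", "all"):
        out += ["N" + "C" * k for k in range(max(lo - 1, 1), hi)]
    if family in ("secondary_amines", "all"):
        for total in range(max(lo, 3), hi + 1):
            for a in range(1, total - 1):
                b = total - 1 - a
                if a <= b:
                    out.append("C" * a + "N" + "C" * b)
    if family in ("ethers", "all"):
        for total in range(max(lo, 3), hi + 1):
            for a in range(1, total - 1):
                b = total - 1 - a
                if a <= b:
                    out.append("C" * a + "O" + "C" * b)
    if family in ("rings", "all"):
        for k in range(max(lo, 3), hi + 1):
            out.append("C1" + "C" * (k - 2) + "C1")
            if k >= 4:
                out.append("C1" + "C" * (k - 3) + "OC1")
    if not out:
        raise ValueError(f"family {family!r} is unsatisfiable on size range {size_range}")
    # canonical, deduplicated, stable order
    seen: dict[str, None] = {}
    for s in out:
        seen.setdefault(canonicalize(s) or s, None)
    return list(seen)


def embed_molecule(smiles: str, seed: int = 0) -> Molecule:
    """3D geometry by seeded ETKDG distance-geometry embedding + Gasteiger charges."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(rd, maxIters=200)
    AllChem.ComputeGasteigerCharges(rd)
    conf = rd.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(rd.GetNumAtoms())])
    mol = Molecule(
        elements=[a.GetSymbol() for a in rd.GetAtoms()],
        coords=coords,
        charges=np.array([float(a.GetProp("_GasteigerCharge")) for a in rd.GetAtoms()]),
        smiles=canonicalize(smiles))
    return center_molecule(mol)


def toy_molecule_library(spec: FixtureSpec) -> list[Molecule]:
    """Deterministic library of embedded molecules for one family (or ``all``).

    The same ``spec`` (family, sizes, count, seed) always yields the same
    coordinates; the enumeration is truncated or cycled to ``count``.
    """
    smiles = family_smiles(spec.family, spec.size_range)
    mols = []
    for i in range(spec.count):
        s = smiles[i % len(smiles)]
        # distinct seeds for repeated SMILES give distinct conformers
        mols.append(embed_molecule(s, seed=spec.seed + 1000 * (i // len(smiles)) + i))
    return mols


def make_training_pairs(molecules, spec: GridSpec, decorated: bool = True,
                        out_path=None):
    """Voxelize molecules into (volume, canonical SMILES) training pairs.

    Volumes are ``(n, n, n)`` plain ED or ``(n, n, n, 2)`` ED+ESP channels.
    Molecules whose atoms fall outside the grid extent are skipped with a
    warning; the skip count is returned in the second element.
    """
    half = spec.extent / 2.0
    pairs = []
    skipped = 0
    for mol in molecules:
        mol = center_molecule(mol)
        if np.abs(mol.coords).max() > half:
            skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary-margin warnings at desk scale
            ed = compute_density_grid(mol, spec)
            if decorated:
                esp = compute_esp_grid(mol, spec)
                vol = np.stack([ed.values, esp.values], axis=-1)
            else:
                vol = ed.values
        pairs.append((vol.astype(np.float32), mol.smiles or ""))
    if skipped:
        warnings.warn(f"skipped {skipped} molecule(s) exceeding the grid extent")
    if out_path is not None:
        from .chemio import dataset_write

        dataset_write(pairs, out_path, spec=spec)
    return pairs, skipped


def toy_host(kind: str, spec: GridSpec, radius: float | None = None,
             wall_width: float = 0.5, amplitude: float = 1.0,
             esp_amplitude: float = 0.5) -> tuple[DensityGrid, ESPGrid]:
    """Analytic host: hollow density with a balanced dipolar ESP at the mouths.

    ``hollow_shell`` is a spherical Gaussian shell of radius ``radius``;
    ``torus`` is a Gaussian tube around a circle in the xy-plane.  Both have
    a zero-density central cavity.  The ESP is a +/- pair of Gaussian rings
    above and below the cavity (point-antisymmetric in z, integrating to ~0),
    mimicking the two dipolar carbonyl portals of a cucurbituril.
    """
    if kind not in ("hollow_shell", "torus"):
        raise ValueError(f"unknown host kind {kind!r}")
    half = spec.extent / 2.0
    R = radius if radius is not None else 0.6 * half
    w = wall_width
    if R + 3 * w > half:
        raise ValueError(f"cavity radius {R} + walls exceeds grid half-extent {half}")
    x, y, z = spec.voxel_centers()
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    s = np.sqrt(x ** 2 + y ** 2)
    if kind == "hollow_shell":
        ed = amplitude * np.exp(-((r - R) ** 2) / (2 * w ** 2))
    else:
        ed = amplitude * np.exp(-(((s - R) ** 2) + z ** 2) / (2 * w ** 2))
    ed[ed < 1e-8 * amplitude] = 0.0
    ed[r < R - 2.5 * w] = 0.0  # guaranteed-empty cavity
    # portal charges: a +q ring above and a -q ring below the cavity mouth,
    # as softened point-charge Coulomb sums, so the field reaches the cavity
    ring_r, ring_z, n_ring = 0.6 * R, 0.8 * R, 8
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    pts = []
    qs = []
    for sign, zz in ((+1.0, ring_z), (-1.0, -ring_z)):
        for a in ang:
            pts.append([ring_r * np.cos(a), ring_r * np.sin(a), zz])
            qs.append(sign * esp_amplitude / n_ring)
    ring_mol = Molecule(elements=["H"] * len(pts), coords=np.asarray(pts),
                        charges=np.asarray(qs))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        esp = compute_esp_grid(ring_mol, spec).values
    return (DensityGrid(spec=spec, values=ed, provenance={"model": f"toy-{kind}"}),
            ESPGrid(spec=spec, values=esp, provenance={"model": "toy-dipolar-rings"}))


def dipole_pairs(n: int, spec: GridSpec, seed: int = 0,
                 separation: tuple = (1.2, 2.4), charge: float = 0.4):
    """Idealized diatomic-dipole (ED, ESP) training pairs for the ESP net.

    Each pair is an H-F-like diatomic at a random orientation and bond
    length: a small and a large promolecular peak carrying opposite partial
    charges, so the density unambiguously encodes the potential's sign
    pattern.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        d = rng.uniform(*separation)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        coords = np.array([-u * d / 2, u * d / 2])
        mol = Molecule(elements=["H", "F"], coords=coords,
                       charges=np.array([charge, -charge]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ed = compute_density_grid(mol, spec)
            esp = compute_esp_grid(mol, spec)
        out.append((ed, esp))
    return out


# ---------------------------------------------------------------------------
# optional QM9 ingestion (local files only)


def _parse_qm9_xyz(text: str):
    lines = text.splitlines()
    n = int(lines[0].split()[0])
    atoms = lines[2:2 + n]
    elements, coords = [], []
    for row in atoms:
        parts = row.replace("*^", "e").split()
        elements.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    smiles_line = lines[2 + n + 1].split()
    smiles = smiles_line[-1] if smiles_line else None
    return Molecule(elements=elements, coords=np.asarray(coords), smiles=smiles)


def qm9_ingest(path, limit: int | None = None, max_heavy: int = 9) -> list[Molecule]:
    """Read QM9-format ``.xyz`` files from a local directory.

    Molecules with more than ``max_heavy`` heavy atoms (there are none in
    genuine QM9) are dropped; ordering follows sorted filenames so repeated
    ingestion is identical.
    """
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(f"QM9 path {path} does not exist")
    files = sorted(root.glob("*.xyz"))
    mols = []
    for f in files:
        if limit is not None and len(mols) >= limit:
            break
        mol = _parse_qm9_xyz(f.read_text())
        heavy = sum(1 for e in mol.elements if e != "H")
        if heavy > max_heavy:
            continue
        mols.append(center_molecule(mol))
    return mols
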