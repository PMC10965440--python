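"""Library-level quality metrics for generated SMILES sets.

Deduplication (by canonical SMILES), validity, novelty against a training
corpus, and internal/external Tanimoto similarity profiles over Morgan
(ECFP4-style) fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .smiles_codec import canonicalize, is_valid

__all__ = [
    "LibraryReport",
    "dedupe",
    "novelty",
    "similarity_profile",
    "validity_rate",
    "build_report",
]


@dataclass
class LibraryReport:
    n_raw: int
    n_unique: int
    multiplicity_histogram: dict
    validity_fraction: float
    novelty_fraction: float
    internal_similarity: dict
    external_similarity: dict
    per_string: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_unique > self.n_raw:
            raise ValueError("n_unique cannot exceed n_raw")

    def to_dict(self) -> dict:
        return asdict(self)


def dedupe(smiles_list: Sequence[str]) -> tuple[list[str], dict]:
    """Unique canonical SMILES (first-seen order) and a multiplicity map.

    Unparseable strings are grouped under their raw string, keyed with a
    ``!`` prefix so the flag survives in the map; multiplicities always sum
    to the input length.
    """
    unique: list[str] = []
    mult: dict[str, int] = {}
    for s in smiles_list:
        canon = canonicalize(s)
        key = canon if canon is not None else "!" + s
        if key not in mult:
            mult[key] = 0
            unique.append(key)
        mult[key] += 1
    return unique, mult


def novelty(generated_unique: Sequence[str], training_corpus: Sequence[str]) -> float:
    """Fraction of generated canonical SMILES absent from the training corpus."""
    train = {canonicalize(s) or s for s in training_corpus}
    gen = [canonicalize(s) or s for s in generated_unique]
    if not gen:
        return 0.0
    return sum(1 for s in gen if s not in train) / len(gen)


def _fingerprints(smiles: Sequence[str], radius: int = 2, n_bits: int = 2048):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps, skipped = [], 0
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            skipped += 1
            continue
        fps.append(gen.GetFingerprint(mol))
    return fps, skipped


def similarity_profile(set_a: Sequence[str], set_b: Sequence[str] | None = None,
                       radius: int = 2, n_bits: int = 2048) -> dict:
    """Pairwise Tanimoto similarity summary (mean/median/max).

    Internal mode (``set_b is None``) uses all unordered pairs of ``set_a``
    excluding self-pairs; external mode uses the full cross product.
    Unparseable strings are excluded and counted.
    """
    from rdkit import DataStructs

    fps_a, skip_a = _fingerprints(set_a, radius, n_bits)
    sims: list[float] = []
    if set_b is None:
        skipped = skip_a
        for i in range(len(fps_a)):
            for j in range(i + 1, len(fps_a)):
                sims.append(DataStructs.TanimotoSimilarity(fps_a[i], fps_a[j]))
    else:
        fps_b, skip_b = _fingerprints(set_b, radius, n_bits)
        skipped = skip_a + skip_b
        for fa in fps_a:
            sims.extend(DataStructs.BulkTanimotoSimilarity(fa, fps_b))
    if not sims:
        return {"n_pairs": 0, "skipped": skipped,
                "mean": None, "median": None, "max": None}
    arr = np.asarray(sims)
    return {"n_pairs": len(sims), "skipped": skipped,
            "mean": float(arr.mean()), "median": float(np.median(arr)),
            "max": float(arr.max())}


def validity_rate(smiles_list: Sequence[str]) -> tuple[float, list]:
    """Fraction passing :func:`smiles_codec.is_valid`, plus per-string reasons."""
    if not smiles_list:
        return 0.0, []
    flags = []
    n_ok = 0
    for s in smiles_list:
        ok, reason = is_valid(s)
        flags.append({"smiles": s, "valid": ok, "reason": reason})
        n_ok += int(ok)
    return n_ok / len(smiles_list), flags


def build_report(generated: Sequence[str], training_corpus: Sequence[str]) -> LibraryReport:
    """Full LibraryReport for a generated set against a training corpus."""
    unique, mult = dedupe(generated)
    counts = np.array(list(mult.values()))
    hist = {int(k): int((counts == k).sum()) for k in np.unique(counts)}
    val_frac, flags = validity_rate(list(generated))
    parseable_unique = [u for u in unique if not u.startswith("!")]
    nov = novelty(parseable_unique, training_corpus)
    return LibraryReport(
        n_raw=len(generated), n_unique=len(unique), multiplicity_histogram=hist,
        validity_fraction=val_frac, novelty_fraction=nov,
        internal_similarity=similarity_profile(parseable_unique),
        external_similarity=similarity_profile(parseable_unique, list(training_corpus)),
        per_string=flags)
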