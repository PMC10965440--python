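"""SMILES tokenization, vocabulary handling and chemical-validity checks.

The token granularity is character-level over the QM9 alphabet (C, N, O, F,
H, aromatic forms, bonds, ring-closure digits, branches, stereo marks) with
bracket atoms such as ``[NH3+]`` kept as single tokens.  Sequences are
wrapped in START/END and padded with PAD (always index 0).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PAD", "START", "END", "UNK",
    "Vocabulary",
    "TokenSequence",
    "split_smiles",
    "tokenize",
    "detokenize",
    "is_valid",
    "canonicalize",
    "DEFAULT_FILTERS",
]

PAD, START, END, UNK = "<pad>", "<s>", "</s>", "<unk>"

_TOKEN_RE = re.compile(r"\[[^\]]+\]|.")

# single characters admissible outside brackets for QM9-scale SMILES
_CHAR_ALPHABET = set("CNOFHcnos=#-+()123456789/\\@.%")


class TokenizationError(ValueError):
    pass


def split_smiles(smiles: str, strict: bool = True) -> list[str]:
    """Greedy longest-match split: bracket atoms as one token, else characters."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    out = []
    for tok in _TOKEN_RE.findall(smiles):
        if len(tok) == 1 and tok not in _CHAR_ALPHABET:
            if strict:
                raise TokenizationError(f"character {tok!r} outside the SMILES alphabet")
            tok = UNK
        out.append(tok)
    return out


@dataclass
class Vocabulary:
    """Ordered token list with PAD at index 0 and contiguous indices."""

    tokens: list[str]
    index: dict = field(init=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        if self.tokens[0] != PAD:
            raise ValueError("PAD must be the first token (index 0)")
        for special in (START, END, UNK):
            if special not in self.tokens:
                raise ValueError(f"vocabulary missing special token {special!r}")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for s in corpus:
            for t in split_smiles(s):
                seen.setdefault(t, None)
        return cls(tokens=[PAD, START, END, UNK] + sorted(seen))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def start_id(self) -> int:
        return self.index[START]

    @property
    def end_id(self) -> int:
        return self.index[END]

    @property
    def unk_id(self) -> int:
        return self.index[UNK]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"tokens": self.tokens}, indent=2))

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        return cls(tokens=json.loads(Path(path).read_text())["tokens"])


@dataclass
class TokenSequence:
    indices: list[int]
    max_len: int

    def __post_init__(self):
        if len(self.indices) > self.max_len:
            raise ValueError(f"sequence length {len(self.indices)} exceeds "
                             f"max_len {self.max_len}")


def tokenize(smiles: str, vocab: Vocabulary, max_len: int = 64,
             strict: bool = True) -> TokenSequence:
    """Encode a SMILES string as [START, tokens..., END] indices.

    With ``strict`` (the training-data policy) an out-of-alphabet or
    out-of-vocabulary token raises; otherwise it maps to UNK.
    """
    toks = split_smiles(smiles, strict=strict)
    ids = [vocab.start_id]
    for t in toks:
        if t in vocab.index:
            ids.append(vocab.index[t])
        elif strict:
            raise TokenizationError(f"token {t!r} not in vocabulary")
        else:
            ids.append(vocab.unk_id)
    ids.append(vocab.end_id)
    return TokenSequence(indices=ids, max_len=max_len)


def detokenize(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> str:
    """Concatenate tokens between START and the first END; ignore the rest."""
    ids = seq.indices if isinstance(seq, TokenSequence) else list(seq)
    out = []
    for i in ids:
        if not 0 <= i < len(vocab):
            raise ValueError(f"token index {i} outside vocabulary of size {len(vocab)}")
        tok = vocab.tokens[i]
        if tok == END:
            break
        if tok in (START, PAD):
            continue
        out.append(tok)
    return "".join(out)


# ---------------------------------------------------------------------------
# validity

# default structural filters (SMARTS deny-list), editable via config:
# heavily strained motifs that string-level generators commonly emit
DEFAULT_FILTERS: list[tuple[str, str]] = [
    ("triple bond in ring", "[R]#[R]"),
    ("cumulated diene in ring", "[R]=[R;X2]=[R]"),
]

_ALLOWED_ELEMENTS = {"H", "C", "N", "O", "F"}


def is_valid(smiles: str, filters: list[tuple[str, str]] | None = None,
             allowed_elements: set[str] | None = None) -> tuple[bool, str]:
    """Parseability plus structural-filter screen.

    Returns ``(ok, reason)``; ``reason`` is empty for valid strings.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    if not smiles:
        return False, "empty string"
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        return False, "parse failure"
    allowed = allowed_elements if allowed_elements is not None else _ALLOWED_ELEMENTS
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in allowed:
            return False, f"disallowed element {atom.GetSymbol()}"
    for name, smarts in (filters if filters is not None else DEFAULT_FILTERS):
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.HasSubstructMatch(patt):
            return False, f"structural filter: {name}"
    return True, ""


def canonicalize(smiles: str) -> str | None:
    """RDKit canonical form, or None if the string does not parse."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)
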