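"""Circular-fingerprint Tanimoto similarity for compound-set heterogeneity.

Thin, deterministic wrapper around RDKit's Morgan generator (radius 3 /
2048 bits by default, i.e. ECFP6-style binary fingerprints) with a plain
bit-vector Tanimoto and a symmetric pairwise matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from rdkit import Chem, rdBase
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "SimilarityMatrix",
    "SmilesParseError",
    "circular_fingerprint",
    "tanimoto",
    "similarity_matrix",
]


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed; position is 0-based if known."""

    def __init__(self, smiles: str, position: Optional[int] = None, detail: str = ""):
        self.smiles = smiles
        self.position = position
        where = f" near position {position}" if position is not None else ""
        msg = f"could not parse SMILES {smiles!r}{where}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # uint8 0/1 vector
    radius: int
    n_bits: int
    source_structure: str  # canonical SMILES

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class SimilarityMatrix:
    labels: List[str]
    values: np.ndarray

    def max_offdiagonal(self) -> float:
        """Heterogeneity summary: largest pairwise similarity."""
        m = self.values.copy()
        np.fill_diagonal(m, -np.inf)
        return float(m.max())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# characters legal in SMILES outside bracket atoms ('l'/'r' only occur in
# Cl/Br; accepting them standalone keeps this a best-effort diagnostic)
_SMILES_CHARS = frozenset("BCNOPSFIbcnops*lr=#$:/\\~.-+0123456789%@()[]")


def _diagnose_smiles(smiles: str):
    """Best-effort (position, reason) for an unparseable SMILES string."""
    paren_stack = []
    open_rings = {}
    in_bracket = False
    bracket_start = 0
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if in_bracket:
            if ch == "]":
                in_bracket = False
        elif ch == "[":
            in_bracket = True
            bracket_start = i
        elif ch == "(":
            paren_stack.append(i)
        elif ch == ")":
            if not paren_stack:
                return i, "unmatched ')'"
            paren_stack.pop()
        elif ch == "%":
            i += 2  # two-digit ring label
        elif ch.isdigit():
            if ch in open_rings:
                open_rings.pop(ch)
            else:
                open_rings[ch] = i
        elif ch not in _SMILES_CHARS:
            return i, f"unexpected character {ch!r}"
        i += 1
    if in_bracket:
        return bracket_start, "unclosed bracket atom"
    if paren_stack:
        return paren_stack[-1], "unmatched '('"
    if open_rings:
        return min(open_rings.values()), "unclosed ring bond"
    return None, "rejected by the parser"


def _parse_smiles(smiles: str) -> Chem.Mol:
    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        return mol
    position, detail = _diagnose_smiles(smiles)
    raise SmilesParseError(smiles, position=position, detail=detail)


def circular_fingerprint(
    structure: str, radius: int = 3, n_bits: int = 2048
) -> Fingerprint:
    """Hashed Morgan (circular) fingerprint of a SMILES string.

    Canonicalization-invariant: different SMILES spellings of the same
    molecule give identical bit vectors.
    """
    mol = _parse_smiles(structure)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(
        bits=bits,
        radius=radius,
        n_bits=n_bits,
        source_structure=Chem.MolToSmiles(mol),
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Bit-set intersection over union; 0 (with a warning) if both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0", stacklevel=2)
        return 0.0
    return inter / union


def similarity_matrix(
    structures: Sequence[str],
    radius: int = 3,
    n_bits: int = 2048,
    labels: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """Symmetric pairwise Tanimoto matrix with unit diagonal."""
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    fps: List[Fingerprint] = []
    errors: List[str] = []
    for i, s in enumerate(structures):
        try:
            fps.append(circular_fingerprint(s, radius=radius, n_bits=n_bits))
        except SmilesParseError as exc:
            errors.append(f"entry {i}: {exc}")
    if errors:
        raise ValueError("unparseable structures:\n" + "\n".join(errors))
    n = len(fps)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    if labels is None:
        labels = [str(i + 1) for i in range(n)]
    return SimilarityMatrix(labels=list(labels), values=m)
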