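"""Substitution matrices for protein local alignment.

BLOSUM62 ships with the package verbatim in NCBI plain-text format and is
the default scoring model. One deliberate deviation from the published
matrix: the ambiguity code X scores 0 against every residue (the published
X column carries small negative values), so ambiguous positions neither
reward nor penalize an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

__all__ = ["SubstitutionMatrix", "load_matrix"]

#: Matrices bundled under ``mimicryscan/data``.
BUNDLED = ("BLOSUM62",)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric integer substitution matrix over the residue alphabet."""

    name: str
    alphabet: str
    scores: np.ndarray  # (k, k) int64, symmetric
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.alphabet)}
        )
        if self.scores.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError(f"matrix {self.name!r} is not symmetric")

    def score(self, a: str, b: str) -> int:
        """Score of aligning residue ``a`` against residue ``b``."""
        return int(self.scores[self._index[a], self._index[b]])

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to row indices of the score matrix."""
        try:
            return np.fromiter(
                (self._index[c] for c in residues), dtype=np.int64,
                count=len(residues),
            )
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise ValueError(f"residue {exc.args[0]!r} not in matrix alphabet")


def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a bundled substitution matrix by name.

    The matrix is restricted to the 20 standard residues plus X, with the
    X row/column zeroed (see module docstring). Unknown names raise
    ``ValueError``.
    """
    if name not in BUNDLED:
        raise ValueError(
            f"unknown matrix {name!r}; bundled matrices: {', '.join(BUNDLED)}"
        )
    path = resources.files("mimicryscan").joinpath(f"data/{name}")
    with resources.as_file(path) as p:
        raw = substitution_matrices.read(str(p))
    from .types import AMINO_ACIDS

    alphabet = AMINO_ACIDS + "X"
    k = len(alphabet)
    scores = np.zeros((k, k), dtype=np.int64)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if a == "X" or b == "X":
                scores[i, j] = 0
            else:
                scores[i, j] = int(raw[a, b])
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=scores)
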