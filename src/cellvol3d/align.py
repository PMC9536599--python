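"""Global protein alignment with affine gap penalties (Needleman-Wunsch/Gotoh).

Percent identity is computed over the full alignment length including gap
columns (NCBI convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")

_NEG = -1e9


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    alignment_length: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.alignment_length


def _validate(seq: str, name: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in AA_ALPHABET:
            raise ValueError(f"invalid residue {ch!r} at position {i} of {name}")


def load_blosum62():
    return substitution_matrices.load("BLOSUM62")


def needleman_wunsch(a: str, b: str, substitution=None,
                     gap_open: float = 11.0, gap_extend: float = 1.0) -> AlignmentResult:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    A gap of length L costs ``gap_open + L * gap_extend``.  Traceback
    tie-breaking prefers match/mismatch over a gap in ``b`` over a gap in
    ``a``, which makes the result deterministic.
    """
    a, b = a.upper(), b.upper()
    _validate(a, "a")
    _validate(b, "b")
    if substitution is None:
        substitution = load_blosum62()
    n, m = len(a), len(b)

    sub = np.empty((n, m))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            sub[i, j] = substitution[x][y]

    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a (consume b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - i * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - j * gap_extend

    for i in range(1, n + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        curM, curX, curY = M[i], X[i], Y[i]
        srow = sub[i - 1]
        for j in range(1, m + 1):
            best_prev = max(prevM[j - 1], prevX[j - 1], prevY[j - 1])
            curM[j] = best_prev + srow[j - 1]
            curX[j] = max(prevM[j] - gap_open - gap_extend,
                          prevX[j] - gap_extend,
                          prevY[j] - gap_open - gap_extend)
            curY[j] = max(curM[j - 1] - gap_open - gap_extend,
                          curX[j - 1] - gap_open - gap_extend,
                          curY[j - 1] - gap_extend)

    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback
    out_a, out_b = [], []
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick_state(M, X, Y, i, j, target)
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            i -= 1
            if abs(M[i, j] - gap_open - gap_extend - val) < 1e-6:
                state = "M"
            elif abs(X[i, j] - gap_extend - val) < 1e-6:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] - gap_open - gap_extend - val) < 1e-6:
                state = "M"
            elif abs(Y[i, j] - gap_extend - val) < 1e-6:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return AlignmentResult(aligned_a, aligned_b, float(score), matches, len(aligned_a))


def _pick_state(M, X, Y, i, j, target):
    for s, mat in (("M", M), ("X", X), ("Y", Y)):
        if abs(mat[i, j] - target) < 1e-6:
            return s
    raise RuntimeError("traceback failed")


def load_propeptide_sequences() -> tuple[str, str]:
    """The bundled mouse/human 100-residue propeptide pair (mouse, human)."""
    path = resources.files("cellvol3d.data") / "prospc_propeptides.fasta"
    with resources.as_file(path) as p:
        records = list(SeqIO.parse(str(p), "fasta"))
    return str(records[0].seq), str(records[1].seq)


def propeptide_identity(gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Percent identity of the bundled propeptide pair."""
    mouse, human = load_propeptide_sequences()
    return needleman_wunsch(mouse, human, gap_open=gap_open,
                            gap_extend=gap_extend).percent_identity
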