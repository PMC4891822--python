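"""RNA secondary-structure prediction backends.

The hairpin-qualification stage needs a deterministic fold with a
defensible energy scale, so the built-in reference backend is a
maximum-weight base-pairing dynamic program (Nussinov-style) over a fixed
per-pair energy table:

    G:C  -3 kcal/mol
    A:U  -2 kcal/mol
    G:U  -1 kcal/mol

plus a helix-stacking bonus of -1 kcal/mol for every pair stacked directly
on another (the dominant stabilising term of real RNA thermodynamics; it
makes contiguous stems strictly better than the same number of scattered
pairs, which keeps folds of designed stem-loops unambiguous). Minimum
hairpin-loop size is 3 nt; unpaired bases carry no penalty. The reported
free energy is minus the total weight. A thermodynamic backend (ViennaRNA,
when importable) is available behind the same contract for production use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sequtils import encode

MIN_LOOP = 3

# pair weight matrix indexed by the A=0 C=1 G=2 T=3 codes (kcal/mol, negated)
_PAIR_W = np.zeros((5, 5), dtype=np.int64)
_PAIR_W[2, 1] = _PAIR_W[1, 2] = 3  # G:C
_PAIR_W[0, 3] = _PAIR_W[3, 0] = 2  # A:U
_PAIR_W[2, 3] = _PAIR_W[3, 2] = 1  # G:U


@dataclass
class FoldResult:
    """A predicted secondary structure.

    ``structure`` is the dot-bracket string, ``energy`` the backend's free
    energy estimate in kcal/mol, and ``pairs[i]`` the partner index of
    position ``i`` (or -1 when unpaired).
    """

    structure: str
    energy: float
    pairs: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.structure) != len(self.pairs):
            raise ValueError("structure/pairs length mismatch")


NEG = -(10**9)
STACK_BONUS = 1


@njit(cache=True)
def _nussinov_fill(codes, pair_w, min_loop, stack):  # pragma: no cover - jit
    n = codes.shape[0]
    W = np.zeros((n, n), dtype=np.int64)
    V = np.full((n, n), NEG, dtype=np.int64)  # best score with (i,j) paired
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            w = pair_w[codes[i], codes[j]]
            if w > 0:
                inner = W[i + 1, j - 1]
                if V[i + 1, j - 1] + stack > inner:
                    inner = V[i + 1, j - 1] + stack
                V[i, j] = w + inner
            best = W[i + 1, j]
            if W[i, j - 1] > best:
                best = W[i, j - 1]
            if V[i, j] > best:
                best = V[i, j]
            for k in range(i + 1, j):
                v = W[i, k] + W[k + 1, j]
                if v > best:
                    best = v
            W[i, j] = best
    return W, V


@njit(cache=True)
def _nussinov_traceback(W, V, codes, pair_w, min_loop, stack):  # pragma: no cover - jit
    n = codes.shape[0]
    pairs = np.full(n, -1, dtype=np.int64)
    stack_i = np.empty(2 * n + 4, dtype=np.int64)
    stack_j = np.empty(2 * n + 4, dtype=np.int64)
    stack_m = np.empty(2 * n + 4, dtype=np.int64)  # 0 = W state, 1 = V state
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    stack_m[top] = 0
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        m = stack_m[top]
        if i >= j:
            continue
        if m == 1:
            pairs[i] = j
            pairs[j] = i
            w = pair_w[codes[i], codes[j]]
            # prefer continuing the helix (stacked inner pair) when optimal
            if V[i + 1, j - 1] > NEG and V[i, j] == w + V[i + 1, j - 1] + stack:
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                stack_m[top] = 1
                top += 1
            else:
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                stack_m[top] = 0
                top += 1
            continue
        if j - i <= min_loop:
            continue
        if V[i, j] > NEG and W[i, j] == V[i, j]:
            stack_i[top] = i
            stack_j[top] = j
            stack_m[top] = 1
            top += 1
        elif W[i, j] == W[i + 1, j]:
            stack_i[top] = i + 1
            stack_j[top] = j
            stack_m[top] = 0
            top += 1
        elif W[i, j] == W[i, j - 1]:
            stack_i[top] = i
            stack_j[top] = j - 1
            stack_m[top] = 0
            top += 1
        else:
            for k in range(i + 1, j):
                if W[i, j] == W[i, k] + W[k + 1, j]:
                    stack_i[top] = i
                    stack_j[top] = k
                    stack_m[top] = 0
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j
                    stack_m[top] = 0
                    top += 1
                    break
    return pairs


def _pairs_to_dotbracket(pairs: np.ndarray) -> str:
    out = []
    for i, p in enumerate(pairs):
        out.append("." if p < 0 else ("(" if p > i else ")"))
    return "".join(out)


class ReferenceFold:
    """Deterministic maximum-weight pairing fold (the test/acceptance backend)."""

    name = "reference"

    def fold(self, seq: str) -> FoldResult:
        seq = seq.upper().replace("U", "T")
        if not seq or any(c not in "ACGT" for c in seq):
            raise ValueError("fold_rna requires a non-empty ACGU/T sequence")
        codes = encode(seq).astype(np.int64)
        W, V = _nussinov_fill(codes, _PAIR_W, MIN_LOOP, STACK_BONUS)
        pairs = _nussinov_traceback(W, V, codes, _PAIR_W, MIN_LOOP, STACK_BONUS)
        energy = -float(W[0, len(seq) - 1]) + 0.0 if len(seq) > 1 else 0.0
        return FoldResult(_pairs_to_dotbracket(pairs), energy, pairs)


class ViennaFold:
    """Thermodynamic MFE fold via the ViennaRNA bindings (optional)."""

    name = "vienna"

    def __init__(self):
        import RNA  # noqa: F401 - deferred, optional

        self._rna = RNA

    def fold(self, seq: str) -> FoldResult:
        seq = seq.upper().replace("T", "U")
        if not seq or any(c not in "ACGU" for c in seq):
            raise ValueError("fold_rna requires a non-empty ACGU/T sequence")
        structure, mfe = self._rna.fold(seq)
        pairs = np.full(len(seq), -1, dtype=np.int64)
        stack: list[int] = []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pairs[i], pairs[j] = j, i
        return FoldResult(structure, float(mfe), pairs)


def get_backend(name: str = "reference"):
    if name == "reference":
        return ReferenceFold()
    if name == "vienna":
        return ViennaFold()
    raise ValueError(f"unknown fold backend: {name!r}")


def fold_rna(seq: str, backend: str = "reference") -> FoldResult:
    """Fold a precursor-scale sequence (intended range ~40-400 nt)."""
    return get_backend(backend).fold(seq)
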