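"""Shared low-level sequence helpers.

All sequences are handled internally in the DNA alphabet (U normalised to T
at every ingest boundary); RNA is only produced again when writing
structures or duplexes for display.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte codes used by the numeric kernels: A=0 C=1 G=2 T=3, anything else 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3


def normalize(seq: str) -> str:
    """Upper-case and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA/RNA string to uint8 codes (A=0 C=1 G=2 T/U=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul-Erikson style: build the multigraph whose edges are the
    observed dinucleotides, draw a random Eulerian path with the original
    first/last vertices, and read the shuffled sequence off the path.
    """
    if len(seq) < 3:
        return seq
    # edge multiset per source vertex
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # Pick, for every non-terminal vertex, the edge it will traverse LAST so
    # that those edges form an arborescence toward the terminal vertex; any
    # walk then consumes every edge (Eulerian path with original endpoints).
    non_terminal = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen, w = {v}, last_edge[v]
            while w != last:
                if w in seen or w not in last_edge:
                    ok = False
                    break
                seen.add(w)
                w = last_edge[w]
            if not ok:
                break
        if ok:
            break
    pools: dict[str, list[str]] = {}
    for v, es in edges.items():
        rest = list(es)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        pools[v] = rest[::-1]  # pop() from the end = traverse in order
    out = [seq[0]]
    v = seq[0]
    while pools.get(v):
        v = pools[v].pop()
        out.append(v)
    return "".join(out)


def write_fasta(path, records) -> None:
    """Write (name, seq) pairs as FASTA, 70-column wrapped."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name→sequence dict (U normalised to T)."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize(str(rec.seq))
    return out
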