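"""Plant miRNA target prediction by complementarity penalty scoring.

Each transcript window of miRNA length is scored against the miRNA with
the classic plant convention: mismatch 1.0, G:U wobble 0.5, per-position
penalties doubled in the core (miRNA positions 2-13, 1-based from the 5'
end), no gaps; windows scoring at or below the cutoff (default 4.0) are
reported as target sites. The miRNA binds the site antiparallel, so miRNA
position i (5'->3') pairs transcript position site_end-1-i.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from .sequtils import normalize

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ScoringScheme:
    mismatch: float = 1.0
    wobble: float = 0.5
    core_start: int = 2  # 1-based, inclusive
    core_end: int = 13
    core_multiplier: float = 2.0
    cutoff: float = 4.0


@dataclass(frozen=True)
class TargetHit:
    mirna: str
    transcript: str
    start: int  # 0-based half-open site interval on the transcript
    end: int
    score: float
    alignment: str  # per miRNA position: '|' pair, 'o' G:U wobble, '.' mismatch

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("negative score")


def _position_penalty(mirna_base: str, target_base: str, scheme: ScoringScheme) -> float:
    if _COMP.get(mirna_base) == target_base:
        return 0.0
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return scheme.wobble
    return scheme.mismatch


def score_duplex(mirna: str, site: str, scheme: ScoringScheme | None = None):
    """Penalty score and alignment string of a miRNA against one site.

    ``site`` is the transcript window in transcript orientation (5'->3');
    its length must equal the miRNA length.
    """
    scheme = scheme or ScoringScheme()
    mirna = normalize(mirna)
    site = normalize(site)
    if len(site) != len(mirna):
        raise ValueError("site window length must equal miRNA length")
    total = 0.0
    align = []
    for i, mb in enumerate(mirna):
        tb = site[len(site) - 1 - i]
        pen = _position_penalty(mb, tb, scheme)
        if scheme.core_start <= i + 1 <= scheme.core_end:
            pen *= scheme.core_multiplier
        total += pen
        align.append("|" if pen == 0 else ("o" if _is_wobble(mb, tb) else "."))
    return total, "".join(align)


def _is_wobble(mb: str, tb: str) -> bool:
    return (mb, tb) in (("G", "T"), ("T", "G"))


def predict_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    cutoff: float | None = None,
    scheme: ScoringScheme | None = None,
) -> list[TargetHit]:
    """Slide the miRNA over every transcript window and keep scoring hits.

    Hits are sorted by (score, transcript id, position), one per
    (transcript, position).
    """
    scheme = scheme or ScoringScheme()
    if cutoff is None:
        cutoff = scheme.cutoff
    mirna_seq = normalize(mirna_seq)
    L = len(mirna_seq)
    # precompute per-position penalty lookup in site orientation:
    # miRNA position i pairs site position L-1-i
    hits: list[TargetHit] = []
    for tid in sorted(transcripts):
        seq = normalize(transcripts[tid])
        for pos in range(0, len(seq) - L + 1):
            site = seq[pos : pos + L]
            total = 0.0
            for i in range(L):
                pen = _position_penalty(mirna_seq[i], site[L - 1 - i], scheme)
                if scheme.core_start <= i + 1 <= scheme.core_end:
                    pen *= scheme.core_multiplier
                total += pen
                if total > cutoff:
                    break
            if total <= cutoff:
                score, align = score_duplex(mirna_seq, site, scheme)
                hits.append(TargetHit(mirna_id, tid, pos, pos + L, score, align))
    hits.sort(key=lambda h: (h.score, h.transcript, h.start))
    return hits


def predict_targets_bruteforce(mirna_id, mirna_seq, transcripts, cutoff=4.0, scheme=None):
    """All-windows oracle without the early-exit pruning (tests)."""
    scheme = scheme or ScoringScheme()
    mirna_seq = normalize(mirna_seq)
    L = len(mirna_seq)
    hits = []
    for tid in sorted(transcripts):
        seq = normalize(transcripts[tid])
        for pos in range(0, len(seq) - L + 1):
            score, align = score_duplex(mirna_seq, seq[pos : pos + L], scheme)
            if score <= cutoff:
                hits.append(TargetHit(mirna_id, tid, pos, pos + L, score, align))
    hits.sort(key=lambda h: (h.score, h.transcript, h.start))
    return hits


def summarize_targets_per_mirna(hits, gene_map: dict[str, str] | None = None) -> dict[str, int]:
    """Collapse transcript-level hits to distinct target-gene counts."""
    genes: dict[str, set] = defaultdict(set)
    mirnas = set()
    for h in hits:
        mirnas.add(h.mirna)
        if gene_map is not None and h.transcript not in gene_map:
            warnings.warn(f"transcript {h.transcript} has no gene mapping; counted as its own gene")
        gene = gene_map.get(h.transcript, h.transcript) if gene_map is not None else h.transcript
        genes[h.mirna].add(gene)
    return {m: len(genes.get(m, ())) for m in sorted(mirnas)}


def hits_table(hits, gene_map=None):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mirna": h.mirna,
                "transcript": h.transcript,
                "gene": (gene_map or {}).get(h.transcript, h.transcript),
                "start": h.start,
                "end": h.end,
                "score": h.score,
                "alignment": h.alignment,
            }
            for h in hits
        ]
    )
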