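"""Genome mapping of small-RNA tags and category annotation.

Tags are aligned to the genome with a substitution-only model (no indels;
short tags make gapped alignment unnecessary) and each tag is assigned to
exactly one annotation category by a fixed precedence cascade:

    known miRNA > rRNA > tRNA > snRNA > snoRNA > repeat
    > exon (sense/antisense) > intron (sense/antisense) > un-annotated

Ties within a tier are broken by longest feature overlap, then by
lexicographic feature ID; multimapping tags are classified once from their
best alignment (fewest mismatches) so that category totals exactly
partition the library.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sequtils import encode, revcomp

CATEGORY_ORDER = [
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
]

#: Table-style display order for category summaries
TABLE_ORDER = [
    "Total",
    "Exon antisense",
    "Exon sense",
    "Intron antisense",
    "Intron sense",
    "miRNA",
    "rRNA",
    "repeat",
    "snRNA",
    "snoRNA",
    "tRNA",
    "Un-annotated",
]

_DISPLAY = {
    "exon_antisense": "Exon antisense",
    "exon_sense": "Exon sense",
    "intron_antisense": "Intron antisense",
    "intron_sense": "Intron sense",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "repeat": "repeat",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "tRNA": "tRNA",
    "unannotated": "Un-annotated",
}

_FEATURE_PRECEDENCE = ["rRNA", "tRNA", "snRNA", "snoRNA", "repeat_region", "exon", "intron"]


@dataclass(frozen=True)
class Feature:
    """One annotation interval (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    fid: str


@dataclass(frozen=True)
class GenomicAlignment:
    """Ungapped placement of a tag on the genome.

    ``strand == '-'`` means the tag sequence matches the reverse complement
    of ``genome[start:end]``.
    """

    tag: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int


def read_gff3(path) -> list[Feature]:
    """Load features from GFF3 (1-based closed converted to 0-based half-open)."""
    import pyranges

    df = pyranges.read_gff3(str(path), as_df=True)
    feats = []
    for row in df.itertuples(index=False):
        fid = getattr(row, "ID", None) or f"{row.Feature}_{row.Start}"
        feats.append(
            Feature(str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand), str(row.Feature), str(fid))
        )
    return feats


def write_gff3(path, features: list[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tsrnakit\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\tID={f.fid}\n"
            )


class FeatureIndex:
    """Interval lookup over annotation features, per chromosome."""

    def __init__(self, features: list[Feature]):
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in features:
            if f.end > f.start:
                self.trees[f.chrom].addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        return [iv.data for iv in self.trees.get(chrom, IntervalTree()).overlap(start, end)]


class GenomeIndex:
    """Seed-and-verify substring index of a (multi-)FASTA genome.

    Exact matches use a fixed-length seed table; mismatch search (≤2
    substitutions) uses the pigeonhole principle over three tag pieces, so
    it is exhaustive for the supported mismatch range.
    """

    def __init__(self, genome: dict[str, str] | str, seed_len: int = 12):
        if isinstance(genome, str):
            genome = {"chr1": genome}
        self.genome = {c: s.upper().replace("U", "T") for c, s in genome.items()}
        if not any(self.genome.values()):
            raise ValueError("empty genome")
        self.seed_len = seed_len
        self._seed_tables: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        tab = self._seed_tables.get(k)
        if tab is None:
            tab = defaultdict(list)
            for chrom, seq in self.genome.items():
                for i in range(len(seq) - k + 1):
                    tab[seq[i : i + k]].append((chrom, i))
            self._seed_tables[k] = tab
        return tab

    def _verify(self, query: str, chrom: str, pos: int, max_mm: int) -> int | None:
        seq = self.genome[chrom]
        if pos < 0 or pos + len(query) > len(seq):
            return None
        mm = 0
        window = seq[pos : pos + len(query)]
        if max_mm == 0:
            return 0 if window == query else None
        for a, b in zip(query, window):
            if a != b:
                mm += 1
                if mm > max_mm:
                    return None
        return mm

    def _search_oriented(self, query: str, max_mm: int) -> list[tuple[str, int, int]]:
        L = len(query)
        hits: dict[tuple[str, int], int] = {}
        if max_mm == 0:
            k = min(self.seed_len, L)
            for chrom, pos in self._table(k).get(query[:k], ()):  # seed at offset 0
                mm = self._verify(query, chrom, pos, 0)
                if mm is not None:
                    hits[(chrom, pos)] = mm
        else:
            # pigeonhole: with <=2 mismatches one of three pieces is exact
            n_pieces = max_mm + 1
            size = L // n_pieces
            for p in range(n_pieces):
                off = p * size
                piece = query[off : off + size] if p < n_pieces - 1 else query[off:]
                k = len(piece)
                for chrom, pos in self._table(k).get(piece, ()):
                    start = pos - off
                    if (chrom, start) in hits:
                        continue
                    mm = self._verify(query, chrom, start, max_mm)
                    if mm is not None:
                        hits[(chrom, start)] = mm
        return [(c, p, mm) for (c, p), mm in hits.items()]


def map_tags(
    tags, genome: dict[str, str] | str, max_mismatch: int = 0, index: GenomeIndex | None = None
) -> dict[str, list[GenomicAlignment]]:
    """Align tag sequences to the genome on both strands.

    Returns every placement with at most ``max_mismatch`` substitutions per
    tag; tags absent from the result dictionary are unmapped.
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    idx = index if index is not None else GenomeIndex(genome)
    out: dict[str, list[GenomicAlignment]] = {}
    seqs = [t.sequence if hasattr(t, "sequence") else t for t in tags]
    for seq in seqs:
        alns = []
        for chrom, pos, mm in idx._search_oriented(seq, max_mismatch):
            alns.append(GenomicAlignment(seq, chrom, pos, pos + len(seq), "+", mm))
        rc = revcomp(seq)
        for chrom, pos, mm in idx._search_oriented(rc, max_mismatch):
            alns.append(GenomicAlignment(seq, chrom, pos, pos + len(seq), "-", mm))
        if alns:
            alns.sort(key=lambda a: (a.mismatches, a.chrom, a.start, a.strand))
            out[seq] = alns
    return out


def brute_force_map(tag: str, genome: dict[str, str] | str, max_mismatch: int) -> list[GenomicAlignment]:
    """Exhaustive sliding-window alignment oracle (vectorised, small genomes)."""
    if isinstance(genome, str):
        genome = {"chr1": genome}
    out = []
    L = len(tag)
    for chrom, seq in genome.items():
        g = encode(seq)
        if len(seq) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        for strand, q in (("+", tag), ("-", revcomp(tag))):
            mm = (windows != encode(q)).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                out.append(GenomicAlignment(tag, chrom, int(pos), int(pos) + L, strand, int(mm[pos])))
    out.sort(key=lambda a: (a.mismatches, a.chrom, a.start, a.strand))
    return out


def _category_of_alignment(aln: GenomicAlignment, features: FeatureIndex) -> tuple:
    """Best (precedence_rank, -overlap, fid) category for one alignment."""
    best = None
    for f in features.overlapping(aln.chrom, aln.start, aln.end):
        try:
            rank = _FEATURE_PRECEDENCE.index(f.ftype)
        except ValueError:
            continue
        if f.ftype == "exon":
            cat = "exon_sense" if f.strand == aln.strand else "exon_antisense"
        elif f.ftype == "intron":
            cat = "intron_sense" if f.strand == aln.strand else "intron_antisense"
        elif f.ftype == "repeat_region":
            cat = "repeat"
        else:
            cat = f.ftype
        overlap = min(aln.end, f.end) - max(aln.start, f.start)
        key = (rank, -overlap, f.fid, cat)
        if best is None or key < best:
            best = key
    if best is None:
        return (len(_FEATURE_PRECEDENCE), 0, "", "unannotated")
    return best


def classify_tag(
    tag: str,
    alignments: list[GenomicAlignment] | None,
    features: FeatureIndex,
    known_mirna_hit: bool = False,
) -> str:
    """Assign exactly one category to a tag.

    Known-miRNA assignment takes precedence over every genomic feature;
    among alignments only those with the fewest mismatches are considered.
    """
    if known_mirna_hit:
        return "miRNA"
    if not alignments:
        return "unannotated"
    best_mm = min(a.mismatches for a in alignments)
    keys = [_category_of_alignment(a, features) for a in alignments if a.mismatches == best_mm]
    return min(keys)[3]


def classify_all(
    tags, alignments: dict[str, list[GenomicAlignment]], features: FeatureIndex, known_hits: set[str]
) -> dict[str, str]:
    """Classify a collection of tags; returns sequence→category."""
    return {
        t.sequence: classify_tag(t.sequence, alignments.get(t.sequence), features, t.sequence in known_hits)
        for t in tags
    }


@dataclass
class CategorySummary:
    """Per-library unique/total tallies across annotation categories."""

    table: pd.DataFrame = field(repr=False)

    def percent(self, category: str, kind: str = "total") -> float:
        return float(self.table.loc[category, f"{kind}_pct"])


def _pct(x: float, total: float) -> float:
    return round(100.0 * x / total, 2) if total else 0.0


def summarize_categories(tags, categories: dict[str, str], library: str) -> CategorySummary:
    """Tally unique tags and total reads per category for one library.

    ``library`` selects which per-tag count field to use ('control' uses
    ``count_c``, 'treatment' ``count_t``); a tag is unique in a library only
    if it was observed there.
    """
    uniq = Counter()
    total = Counter()
    for t in tags:
        n = t.count_c if library == "control" else t.count_t
        if n <= 0:
            continue
        cat = categories[t.sequence]
        uniq[cat] += 1
        total[cat] += n
    grand_u, grand_t = sum(uniq.values()), sum(total.values())
    if grand_t == 0:
        raise ValueError(f"library {library!r} has zero total reads")
    rows = {
        "Total": (grand_u, 100.0, grand_t, 100.0),
    }
    for cat in CATEGORY_ORDER:
        if cat == "miRNA" or cat in _DISPLAY:
            name = _DISPLAY.get(cat, cat)
            rows[name] = (
                uniq.get(cat, 0),
                _pct(uniq.get(cat, 0), grand_u),
                total.get(cat, 0),
                _pct(total.get(cat, 0), grand_t),
            )
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["unique", "unique_pct", "total", "total_pct"]
    ).reindex(TABLE_ORDER)
    return CategorySummary(df)


def length_distribution(tags, min_len: int = 15, max_len: int = 30) -> pd.DataFrame:
    """Unique/total read counts and percentages per insert length, per library.

    Every length bin in [min_len, max_len] is reported, including empty ones.
    """
    if not tags:
        raise ValueError("no tags")
    idx = range(min_len, max_len + 1)
    df = pd.DataFrame(
        0, index=idx, columns=["unique_c", "total_c", "unique_t", "total_t"], dtype=np.int64
    )
    for t in tags:
        L = len(t.sequence)
        if L < min_len or L > max_len:
            continue
        if t.count_c > 0:
            df.loc[L, "unique_c"] += 1
            df.loc[L, "total_c"] += t.count_c
        if t.count_t > 0:
            df.loc[L, "unique_t"] += 1
            df.loc[L, "total_t"] += t.count_t
    for col in ["unique_c", "total_c", "unique_t", "total_t"]:
        tot = df[col].sum()
        df[col + "_pct"] = [round(100.0 * v / tot, 2) if tot else 0.0 for v in df[col]]
    df.index.name = "length"
    return df
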