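"""Raw read cleaning and collapsing into unique tags.

An sRNA insert is shorter than the sequencing read, so every genuine read
carries (a prefix of) the 3' adapter; reads with no detectable 3' adapter
are discarded as artifacts and reported in the rejection tally. Adapter
localisation is seed-and-extend: the first ``seed_len`` adapter bases are
scanned left to right allowing ``seed_mismatch`` mismatches, then the match
is extended over the remaining read with at most ``max_adapter_mismatch``
total mismatches over the matched adapter prefix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .sequtils import normalize

#: 5'/3' adapters of the standard small-RNA library protocol (DNA alphabet)
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class CleanReadPolicy:
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    min_len: int = 15
    max_len: int = 30
    max_adapter_mismatch: int = 2
    discard_polyA: bool = True
    polya_frac: float = 0.8
    seed_len: int = 8
    seed_mismatch: int = 1

    def __post_init__(self):
        self.adapter3 = normalize(self.adapter3)
        self.adapter5 = normalize(self.adapter5)
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.adapter3:
            raise ValueError("3' adapter must be non-empty")


@dataclass
class SmallRNATag:
    """A unique cleaned insert with its per-library read counts."""

    sequence: str
    count_c: int = 0
    count_t: int = 0

    def __post_init__(self):
        if self.count_c < 0 or self.count_t < 0:
            raise ValueError("negative tag count")

    @property
    def total(self) -> int:
        return self.count_c + self.count_t


def _seed_matches(seq: str, pos: int, seed: str, max_mm: int) -> bool:
    mm = 0
    for a, b in zip(seed, seq[pos : pos + len(seed)]):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def find_adapter(seq: str, policy: CleanReadPolicy) -> int | None:
    """Leftmost start of the 3' adapter in ``seq``, or None.

    At least ``seed_len`` adapter bases must be present in the read; the
    total mismatch count over the matched adapter prefix must not exceed
    ``max_adapter_mismatch``.
    """
    ad = policy.adapter3
    k = min(policy.seed_len, len(ad))
    seed = ad[:k]
    last = len(seq) - k
    if last < 0:
        return None

    def _extends(pos: int) -> bool:
        overlap = min(len(ad), len(seq) - pos)
        mm = sum(a != b for a, b in zip(ad[:overlap], seq[pos : pos + overlap]))
        return mm <= policy.max_adapter_mismatch

    # fast path: the leftmost exact seed occurrence; positions before it can
    # only hold mismatched seeds, so re-scan just that prefix. If the exact
    # hit fails extension, fall through to a plain scan of the remainder.
    exact = seq.find(seed)
    if exact != -1 and exact <= last:
        for pos in range(exact):
            if _seed_matches(seq, pos, seed, policy.seed_mismatch) and _extends(pos):
                return pos
        if _extends(exact):
            return exact
        start = exact + 1
    else:
        start = 0
    for pos in range(start, last + 1):
        if _seed_matches(seq, pos, seed, policy.seed_mismatch) and _extends(pos):
            return pos
    return None


def trim_and_filter(reads, policy: CleanReadPolicy | None = None):
    """Clean an iterable of raw read sequences.

    Returns ``(inserts, tally)`` where ``tally`` counts the input reads by
    outcome: accepted, no_adapter, too_short, too_long, polyA, has_N.
    Accepted + rejected always equals the input read count.
    """
    policy = policy or CleanReadPolicy()
    inserts: list[str] = []
    tally = Counter(accepted=0, no_adapter=0, too_short=0, too_long=0, polyA=0, has_N=0)
    for read in reads:
        seq = normalize(read)
        pos = find_adapter(seq, policy)
        if pos is None:
            tally["no_adapter"] += 1
            continue
        insert = seq[:pos]
        if "N" in insert:
            tally["has_N"] += 1
            continue
        if len(insert) < policy.min_len:
            tally["too_short"] += 1
            continue
        if len(insert) > policy.max_len:
            tally["too_long"] += 1
            continue
        if policy.discard_polyA and insert.count("A") >= policy.polya_frac * len(insert):
            tally["polyA"] += 1
            continue
        tally["accepted"] += 1
        inserts.append(insert)
    return inserts, dict(tally)


def clean_fastq(path, policy: CleanReadPolicy | None = None):
    """Run :func:`trim_and_filter` over a FASTQ file (Phred+33)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    def _reads():
        with open(path) as fh:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                try:
                    rec = next(it, None)
                except ValueError as exc:
                    raise ValueError(f"malformed FASTQ record at index {i} in {path}: {exc}") from exc
                if rec is None:
                    return
                yield rec[1]
                i += 1

    return trim_and_filter(_reads(), policy)


def collapse_tags(inserts_c, inserts_t) -> list[SmallRNATag]:
    """Collapse cleaned inserts from the two libraries into unique tags.

    One tag per distinct sequence; counts are per-library multiplicities.
    Deterministic order: descending combined count, then sequence.
    """
    cc = Counter(inserts_c)
    ct = Counter(inserts_t)
    tags = [SmallRNATag(seq, cc.get(seq, 0), ct.get(seq, 0)) for seq in set(cc) | set(ct)]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def tags_to_fasta(path, tags) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags, 1):
            fh.write(f">tag{i}_x{t.total}\n{t.sequence}\n")


def tags_to_tsv(path, tags) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount_c\tcount_t\n")
        for t in tags:
            fh.write(f"{t.sequence}\t{t.count_c}\t{t.count_t}\n")


def read_tags_tsv(path) -> list[SmallRNATag]:
    tags = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"unexpected tag TSV header in {path}")
        for line in fh:
            seq, c, t = line.rstrip("\n").split("\t")
            tags.append(SmallRNATag(seq, int(c), int(t)))
    return tags


def tally_to_tsv(path, tally_c: dict, tally_t: dict) -> None:
    keys = ["accepted", "no_adapter", "too_short", "too_long", "polyA", "has_N"]
    with open(path, "w") as fh:
        fh.write("outcome\tcontrol\ttreatment\n")
        for k in keys:
            fh.write(f"{k}\t{tally_c.get(k, 0)}\t{tally_t.get(k, 0)}\n")
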