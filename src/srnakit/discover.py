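"""Known-miRNA matching and novel hairpin-miRNA discovery.

Novel candidates are qualified by six criteria: (1) un-annotated genomic
origin, (2) a stem-loop fold with the mature wholly on one arm, (3) a
mature/miRNA* duplex with 2-nt 3' overhangs, (4) no large internal loops
or bulges in the duplex (quantified: at most ``max_duplex_mismatch``
unpaired mature positions and no asymmetric bulge longer than
``max_bulge``), (5) fold free energy at or below ``max_energy`` kcal/mol,
and (6) at least ``min_reads`` supporting reads. A candidate passes only
if all six hold; support (criterion 6) is evaluated first so that genuinely
unsupported windows are never folded.

Expression of a mature miRNA is counted with the end-tolerant rule: a tag
contributes when it matches the mature exactly over the core (mature
positions 4..L-3, 1-based) and accumulates at most three
mismatching/overhanging nucleotides over the two terminal 3-nt windows
combined.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .annotate import GenomicAlignment
from .fold import FoldResult, get_backend
from .sequtils import encode, revcomp


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    sequence: str
    origin: str = "known"  # known | novel
    precursor_id: str | None = None

    def __post_init__(self):
        if not 15 <= len(self.sequence) <= 30:
            raise ValueError(f"mature {self.name}: implausible length {len(self.sequence)}")


@dataclass
class HairpinCriteria:
    """Thresholds of the six novel-miRNA qualifications."""

    max_energy: float = -18.0
    min_reads: int = 5
    max_duplex_mismatch: int = 4
    max_bulge: int = 2


@dataclass
class HairpinCandidate:
    """A precursor window evaluated against the six qualifications."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor_seq: str
    structure: str
    energy: float
    mature_arm: str  # 5p | 3p | "?"
    mature_interval: tuple[int, int]  # window-relative, oriented 5'->3'
    star_interval: tuple[int, int] | None
    supporting_reads: int
    flags: dict[str, bool] = field(default_factory=dict)
    mature_seq: str = ""
    name: str = ""
    count_c: int = 0
    count_t: int = 0

    @property
    def passed(self) -> bool:
        return len(self.flags) == 6 and all(self.flags.values())


FLAG_NAMES = [
    "unannotated_origin",
    "mature_one_arm",
    "overhang_2nt",
    "duplex_quality",
    "energy",
    "read_support",
]


# ---------------------------------------------------------------------------
# known-miRNA matching


def match_known(tags, mature_db, max_mismatch: int = 2):
    """Assign tags to known mature miRNAs.

    A tag is assigned to the mature with the fewest substitutions when the
    lengths differ by at most 2 nt and the 5'-anchored comparison over the
    overlap has at most ``max_mismatch`` mismatches. Ties go to the first
    mature in name order. Returns sequence→(name, mismatches).

    ``mature_db`` is a name→sequence mapping (or list of MatureMiRNA).
    """
    if not mature_db:
        raise ValueError("empty mature miRNA database")
    if hasattr(mature_db, "items"):
        db = sorted(mature_db.items())
    else:
        db = sorted((m.name, m.sequence) for m in mature_db)
    seqs = [t.sequence if hasattr(t, "sequence") else t for t in tags]
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        by_len[len(s)].append(i)
    mats = {L: np.array([encode(seqs[i]) for i in idx]) for L, idx in by_len.items()}
    best_mm = np.full(len(seqs), max_mismatch + 1, dtype=np.int64)
    best_name = np.full(len(seqs), -1, dtype=np.int64)
    for name_idx, (_, mseq) in enumerate(db):
        mcodes = encode(mseq)
        Lm = len(mseq)
        for L in range(Lm - 2, Lm + 3):
            idx = by_len.get(L)
            if not idx:
                continue
            ov = min(L, Lm)
            mm = (mats[L][:, :ov] != mcodes[:ov]).sum(axis=1)
            rows = np.asarray(idx)
            better = mm < best_mm[rows]
            best_mm[rows[better]] = mm[better]
            best_name[rows[better]] = name_idx
    out = {}
    for i, s in enumerate(seqs):
        if best_name[i] >= 0 and best_mm[i] <= max_mismatch:
            out[s] = (db[best_name[i]][0], int(best_mm[i]))
    return out


def match_known_bruteforce(tag: str, mature_db: dict[str, str], max_mismatch: int = 2):
    """Plain Hamming-scan oracle for :func:`match_known` (tests)."""
    best = None
    for name in sorted(mature_db):
        mseq = mature_db[name]
        if abs(len(tag) - len(mseq)) > 2:
            continue
        ov = min(len(tag), len(mseq))
        mm = sum(a != b for a, b in zip(tag[:ov], mseq[:ov]))
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (name, mm)
    return best


# ---------------------------------------------------------------------------
# precursor windows


@dataclass
class TagCluster:
    chrom: str
    strand: str
    start: int
    end: int
    #: (sequence, start, end, count_c, count_t) of member alignments
    members: list[tuple[str, int, int, int, int]] = field(default_factory=list)

    def dominant(self):
        """Most abundant member (ties: leftmost, then lexicographic)."""
        return min(self.members, key=lambda m: (-(m[3] + m[4]), m[1], m[0]))

    def support(self, shift_tol: int = 3):
        """Reads stacked at (within ``shift_tol`` nt of) the dominant member."""
        dom = self.dominant()
        n = 0
        for seq, s, e, c, t in self.members:
            if abs(s - dom[1]) <= shift_tol and abs(e - dom[2]) <= shift_tol:
                n += c + t
        return n


def cluster_alignments(items, cluster_gap: int = 10) -> list[TagCluster]:
    """Merge aligned tags into clusters with inter-tag gaps <= ``cluster_gap``.

    ``items`` yields (alignment, count_c, count_t) triples; clustering is
    per (chromosome, strand).
    """
    by_key: dict[tuple[str, str], list] = defaultdict(list)
    for aln, c, t in items:
        by_key[(aln.chrom, aln.strand)].append((aln.start, aln.end, aln.tag, c, t))
    clusters = []
    for (chrom, strand), rows in sorted(by_key.items()):
        rows.sort()
        cur: TagCluster | None = None
        for s, e, seq, c, t in rows:
            if cur is not None and s - cur.end <= cluster_gap:
                cur.end = max(cur.end, e)
                cur.members.append((seq, s, e, c, t))
            else:
                cur = TagCluster(chrom, strand, s, e, [(seq, s, e, c, t)])
                clusters.append(cur)
    return clusters


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool = False


def extract_precursor_windows(anchor_start, anchor_end, chrom, strand, genome_length, flank: int = 300):
    """Candidate precursor windows around an anchor tag interval.

    Emits the symmetric window plus the two asymmetric ones (anchor at
    either end of the window, kept off the exact terminus by a small pad so
    the fold is not forced to close on an anchor base), deduplicated;
    windows running off the chromosome are clipped and flagged.
    """
    pad = min(10, flank)
    raw = [
        (anchor_start - flank, anchor_end + flank),
        (anchor_start - pad, anchor_end + 2 * flank - pad),
        (anchor_start - 2 * flank + pad, anchor_end + pad),
    ]
    out, seen = [], set()
    for s, e in raw:
        cs, ce = max(0, s), min(genome_length, e)
        if (cs, ce) in seen or ce - cs < anchor_end - anchor_start:
            continue
        seen.add((cs, ce))
        out.append(CandidateWindow(chrom, cs, ce, strand, clipped=(cs != s or ce != e)))
    return out


# ---------------------------------------------------------------------------
# hairpin evaluation

_PARTNERS = {"A": "T", "C": "G", "G": "CT", "T": "AG"}  # Watson-Crick + G:U


def _pairs(a: str, b: str) -> bool:
    return b in _PARTNERS[a]


def find_duplex(window: str, m0: int, m1: int, criteria: HairpinCriteria, min_loop: int = 3):
    """Best mature/miRNA* duplex for a mature at [m0, m1) in the window.

    Searches every antiparallel placement of the mature's paired span
    (positions 0..L-3; the last two bases are the mature 3' overhang)
    against the window, ungapped first, then with one internal bulge of at
    most ``max_bulge`` nt. A placement is valid when the implied star
    interval (partner span plus the 2-nt star 3' overhang) lies wholly on
    one side of the mature, separated by at least ``min_loop`` nt.

    Returns (mismatches, bulge, star_lo, star_hi, arm) of the best valid
    duplex with mismatches <= max_duplex_mismatch, or None. Star intervals
    clipped by the window edge are still reported (flagged by the caller).
    """
    L = m1 - m0
    core = L - 2
    mature = window[m0:m1]
    n = len(window)
    max_mm = criteria.max_duplex_mismatch
    candidates = []  # (mm, |bulge|, distance-from-mature, q, star_lo, star_hi, arm)

    def _valid_geometry(star_lo: int, star_hi: int):
        if star_hi <= m0 - min_loop:
            return "3p", m0 - star_hi
        if star_lo >= m1 + min_loop:
            return "5p", star_lo - m1
        return None, 0

    near_miss = []
    for q in range(core - 1, n):
        star_lo, star_hi = q - core + 1, q + 3
        arm, dist = _valid_geometry(star_lo, star_hi)
        if arm is None:
            continue
        mm = 0
        for i in range(core):
            p = q - i
            if p >= n or not _pairs(mature[i], window[p]):
                mm += 1
                if mm > max_mm + 2 * criteria.max_bulge:
                    break
        else:
            if mm <= max_mm:
                candidates.append((mm, 0, dist, q, star_lo, star_hi, arm))
                continue
            near_miss.append((q, arm, dist))
    # one-bulge rescue only around nearly-pairing placements
    for q, arm, dist in near_miss:
        best_b = None
        for k in range(3, core - 3):  # bulge position within the duplex
            head = sum(0 if _pairs(mature[i], window[q - i]) else 1 for i in range(k))
            if head > max_mm:
                continue
            for b in (-criteria.max_bulge, -1, 1, criteria.max_bulge):
                mm = head
                ok = True
                for i in range(k, core):
                    p = q - i - b
                    if p < 0 or p >= len(window):
                        ok = False
                        break
                    if not _pairs(mature[i], window[p]):
                        mm += 1
                        if mm > max_mm:
                            ok = False
                            break
                if ok and mm <= max_mm:
                    lo = min(q - core + 1 - b, q - core + 1)
                    hi = q + 3
                    a2, d2 = _valid_geometry(lo, hi)
                    if a2 == arm and (best_b is None or (mm, abs(b)) < best_b[:2]):
                        best_b = (mm, abs(b), d2, q, lo, hi, arm)
        if best_b is not None:
            candidates.append(best_b)
    if not candidates:
        return None
    mm, bulge, _, q, star_lo, star_hi, arm = min(candidates)
    return mm, bulge, star_lo, star_hi, arm


def evaluate_hairpin(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    fold: FoldResult,
    supporting_reads: int,
    criteria: HairpinCriteria | None = None,
    unannotated_origin: bool = True,
    chrom: str = "chr1",
    window_start: int = 0,
    strand: str = "+",
    backend=None,
) -> HairpinCandidate:
    """Score one folded window against the six qualifications.

    ``mature_offset`` is the mature start within ``window_seq`` (both
    oriented 5'->3' on the transcribed strand). ``backend`` is used only
    for the precursor-span re-fold of criterion 2 and defaults to the
    reference folder.
    """
    crit = criteria or HairpinCriteria()
    m0, m1 = mature_offset, mature_offset + mature_len
    if not 0 <= m0 < m1 <= len(window_seq):
        raise ValueError("mature interval not contained in window")
    flags = dict.fromkeys(FLAG_NAMES, False)
    flags["unannotated_origin"] = bool(unannotated_origin)
    flags["read_support"] = supporting_reads >= crit.min_reads
    flags["energy"] = fold.energy <= crit.max_energy

    # criterion 2: the mature must sit wholly on one arm of the predicted
    # structure (paired, no internal pairs, partners all on one side) - the
    # strongest discriminator against non-hairpin windows
    def _one_arm(pairs, a0, a1):
        partners = [int(pairs[i]) for i in range(a0, a1) if pairs[i] >= 0]
        if not partners or any(a0 <= p < a1 for p in partners):
            return "?"
        if all(p >= a1 for p in partners):
            return "5p"
        if all(p < a0 for p in partners):
            return "3p"
        return "?"

    # the mature's own 2-nt 3' overhang is unpaired in the duplex and free
    # to pair elsewhere; criterion 2 applies to the duplex-forming span
    fold_arm = _one_arm(fold.pairs, m0, m1 - 2)

    # criteria 3 and 4 from a direct mature/miRNA* duplex search, which is
    # robust to co-optimal-structure ambiguity in the fold traceback
    arm = fold_arm
    star: tuple[int, int] | None = None
    duplex = find_duplex(window_seq, m0, m1, crit)
    if duplex is not None:
        mm, bulge, s_lo, s_hi, duplex_arm = duplex
        if fold_arm == duplex_arm:
            arm = duplex_arm
            flags["duplex_quality"] = True  # find_duplex enforces mm/bulge limits
            if 0 <= s_lo and s_hi <= len(window_seq):
                flags["overhang_2nt"] = True
                star = (s_lo, s_hi)
    flags["mature_one_arm"] = fold_arm != "?"

    return HairpinCandidate(
        chrom=chrom,
        start=window_start,
        end=window_start + len(window_seq),
        strand=strand,
        precursor_seq=window_seq,
        structure=fold.structure,
        energy=fold.energy,
        mature_arm=arm,
        mature_interval=(m0, m1),
        star_interval=star,
        supporting_reads=supporting_reads,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# expression counting


def tag_contributes(tag: str, mature: str, offset: int) -> bool:
    """End-tolerant expression-counting rule for one tag at a fixed offset.

    ``offset`` is tag start minus mature start. The tag must cover and
    exactly match the mature core (positions 4..L-3, 1-based); mismatches at
    the two terminal 3-nt windows plus nucleotides overhanging either mature
    end must total <= 3.
    """
    L = len(mature)
    lo, hi = 3, L - 3  # core = [lo, hi)
    t0, t1 = offset, offset + len(tag)
    if t0 > lo or t1 < hi:
        return False
    for p in range(lo, hi):
        if tag[p - t0] != mature[p]:
            return False
    budget = max(0, -t0) + max(0, t1 - L)  # overhanging nt
    for p in list(range(0, lo)) + list(range(hi, L)):
        if t0 <= p < t1 and tag[p - t0] != mature[p]:
            budget += 1
    return budget <= 3


def best_offset(tag: str, mature: str, search: int = 3) -> int | None:
    """Smallest-|offset| placement under which the tag contributes."""
    for off in sorted(range(-search, search + 1), key=lambda o: (abs(o), o)):
        if tag_contributes(tag, mature, off):
            return off
    return None


def count_mirna_expression(mature: str, tags, offsets: dict[str, int] | None = None):
    """Per-library expression of a mature miRNA under the end-tolerant rule.

    ``tags`` are SmallRNATag-like; ``offsets`` optionally fixes each tag's
    alignment offset (tag start - mature start), e.g. from genomic
    coordinates; otherwise the best |offset| <= 3 placement is searched.
    Each tag contributes at most once. Returns (count_c, count_t, tags used).
    """
    cc = ct = 0
    used = []
    for t in tags:
        off = offsets.get(t.sequence) if offsets is not None else best_offset(t.sequence, mature)
        if off is None:
            continue
        if tag_contributes(t.sequence, mature, off):
            cc += t.count_c
            ct += t.count_t
            used.append(t.sequence)
    return cc, ct, used


# ---------------------------------------------------------------------------
# discovery orchestration


@dataclass
class DiscoveryParams:
    flank: int = 300
    #: tighter window sets tried alongside the full flank; short windows
    #: recover clean stem-loops that wide windows can obscure with flanking
    #: co-folds (the minimal set brackets a bare precursor-sized window)
    short_flank: int = 75
    min_flank: int = 25
    cluster_gap: int = 10
    max_fold_len: int = 360
    shift_tol: int = 3
    #: read mounds examined per cluster (background bridging can merge
    #: several independent loci into one cluster)
    max_loci_per_cluster: int = 8
    criteria: HairpinCriteria = field(default_factory=HairpinCriteria)
    fold_backend: str = "reference"


def _trim_window(win: CandidateWindow, m_start: int, m_end: int, max_len: int):
    """Clip a window to ``max_len`` while keeping the mature inside."""
    if win.end - win.start <= max_len:
        return win.start, win.end
    mid = (m_start + m_end) // 2
    s = max(win.start, min(mid - max_len // 2, win.end - max_len))
    return s, s + max_len


def evaluate_anchor(
    genome: dict[str, str],
    chrom: str,
    strand: str,
    anchor_start: int,
    anchor_end: int,
    support: int,
    params: DiscoveryParams,
    backend=None,
    unannotated_origin: bool = True,
) -> HairpinCandidate | None:
    """Evaluate every candidate window around one anchor tag interval.

    Windows are drawn at both the full and the short flank; the first
    passing candidate wins, otherwise the best-failing one (most criteria
    met) is returned for reporting.
    """
    backend = backend or get_backend(params.fold_backend)
    glen = len(genome[chrom])
    best: HairpinCandidate | None = None
    windows = []
    for flank in (params.min_flank, params.short_flank, params.flank):
        windows.extend(extract_precursor_windows(anchor_start, anchor_end, chrom, strand, glen, flank))
    seen = set()
    for win in windows:
        ws, we = _trim_window(win, anchor_start, anchor_end, params.max_fold_len)
        if (ws, we) in seen or not (ws <= anchor_start and anchor_end <= we):
            continue
        seen.add((ws, we))
        seq = genome[chrom][ws:we]
        if strand == "+":
            offset = anchor_start - ws
        else:
            seq = revcomp(seq)
            offset = we - anchor_end
        cand = evaluate_hairpin(
            seq,
            offset,
            anchor_end - anchor_start,
            backend.fold(seq),
            support,
            params.criteria,
            unannotated_origin=unannotated_origin,
            chrom=chrom,
            window_start=ws,
            strand=strand,
            backend=backend,
        )
        if cand.passed:
            return cand
        if best is None or sum(cand.flags.values()) > sum(best.flags.values()):
            best = cand
    return best


def discover_novel(
    unannotated,
    genome: dict[str, str] | str,
    params: DiscoveryParams | None = None,
) -> list[HairpinCandidate]:
    """Hairpin discovery over un-annotated aligned tags.

    ``unannotated`` yields (GenomicAlignment, count_c, count_t) for the best
    alignment of every un-annotated tag. Clusters whose dominant read stack
    is below the support threshold are rejected before folding. Returns one
    candidate per evaluated cluster (passing or best-failing); passing
    candidates carry per-library expression counts.
    """
    p = params or DiscoveryParams()
    if isinstance(genome, str):
        genome = {"chr1": genome}
    backend = get_backend(p.fold_backend)
    out: list[HairpinCandidate] = []
    n_novel = 0
    for cluster in cluster_alignments(unannotated, p.cluster_gap):
        members = list(cluster.members)
        for _round in range(p.max_loci_per_cluster):
            if not members:
                break
            dom_seq, dom_s, dom_e, dom_c, dom_t = min(
                members, key=lambda m: (-(m[3] + m[4]), m[1], m[0])
            )
            mound = [
                m
                for m in members
                if abs(m[1] - dom_s) <= p.shift_tol and abs(m[2] - dom_e) <= p.shift_tol
            ]
            support = sum(m[3] + m[4] for m in mound)
            if support < p.criteria.min_reads:
                break
            best = evaluate_anchor(
                genome, cluster.chrom, cluster.strand, dom_s, dom_e, support, p, backend
            )
            if best is not None:
                best.mature_seq = dom_seq
            removed = set(id(m) for m in mound)
            if best is not None and best.passed:
                n_novel += 1
                best.name = f"novel_cand_{n_novel}"
                from .cleaning import SmallRNATag

                member_tags = [SmallRNATag(s, c, t) for s, _, _, c, t in members]
                if cluster.strand == "+":
                    offsets = {s: st - dom_s for s, st, _, _, _ in members}
                else:
                    offsets = {s: dom_e - en for s, _, en, _, _ in members}
                best.count_c, best.count_t, _ = count_mirna_expression(dom_seq, member_tags, offsets)
                if best.star_interval is not None:
                    # also retire reads from the star arm of this precursor
                    if cluster.strand == "+":
                        g_lo = best.start + best.star_interval[0]
                        g_hi = best.start + best.star_interval[1]
                    else:
                        g_lo = best.end - best.star_interval[1]
                        g_hi = best.end - best.star_interval[0]
                    for m in members:
                        if m[1] < g_hi and g_lo < m[2]:
                            removed.add(id(m))
            if best is not None:
                out.append(best)
            members = [m for m in members if id(m) not in removed]
    out.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return out
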