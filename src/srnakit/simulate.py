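"""Two-condition small-RNA-seq simulator with known ground truth.

The generator emulates the structure of a plant sRNA sequencing experiment:
a random-background genome carrying planted rRNA/tRNA/snRNA/snoRNA/repeat
and exon/intron features, hairpin miRNA loci (known and novel) whose mature
and star arms form a designed near-perfect stem-loop with 2-nt 3'
overhangs, decoy loci (dinucleotide-shuffled precursors), and two read
libraries (control vs treatment) whose per-locus counts follow planted
log2 fold-change effects across the three regulation tiers
(|log2FC| >= 1, 0.25 <= |log2FC| < 1, < 0.25).

Reads are insert + 3' adapter + random fill, with 21/24-nt insert-length
modes, a 5'-U bias on mature miRNAs, Poisson (optionally negative-binomial)
count noise and a small per-base substitution error rate. Everything is
driven by a single seeded generator, so an identical configuration yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import Feature, write_gff3
from .sequtils import dinucleotide_shuffle, revcomp, write_fasta

_BASES = np.array(list("ACGT"))

#: read-budget share per annotation category (Table-1-like composition)
DEFAULT_CATEGORY_WEIGHTS = {
    "miRNA": 0.11,
    "rRNA": 0.075,
    "tRNA": 0.015,
    "snRNA": 0.0004,
    "snoRNA": 0.0001,
    "repeat": 0.155,
    "exon": 0.045,
    "intron": 0.12,
    "unannotated": 0.48,
}

#: number and length range of planted features per type
DEFAULT_FEATURE_PLAN = {
    "rRNA": (4, 800, 2000),
    "tRNA": (8, 70, 90),
    "snRNA": (4, 100, 200),
    "snoRNA": (4, 80, 150),
    "repeat_region": (10, 200, 600),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 120_000
    n_known_mirna: int = 25
    n_novel_mirna: int = 20
    n_decoy_loci: int = 10
    library_depths: tuple[int, int] = (200_000, 200_000)
    #: probability mass of the 21-nt and 24-nt insert classes; the residual
    #: mass is spread uniformly over the other lengths in [15, 30]
    length_mode_weights: dict[int, float] = field(default_factory=lambda: {21: 0.22, 24: 0.45})
    five_prime_u_prob: float = 0.8
    #: explicit (locus_id, log2FC) effects; auto-assigned across the three
    #: regulation tiers when None
    de_effects: list[tuple[str, float]] | None = None
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    noise: float = 0.002
    count_noise: str = "poisson"  # "poisson" | "nb"
    nb_dispersion: float = 0.2
    read_length: int = 50
    mature_lengths: tuple[int, ...] = (20, 21, 21, 21, 22)
    loop_len: int = 8
    n_genes: int = 8
    #: floor on the expected control-library read count of every planted
    #: miRNA locus, so each locus is sequencable at the default depths
    min_locus_expected: float = 25.0
    n_background_loci: int = 400
    singleton_frac: float = 0.5
    isomir_shift_prob: float = 0.08
    category_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))

    def validate(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if any(d <= 0 for d in self.library_depths):
            raise ValueError("library depths must be > 0")
        for p in [self.five_prime_u_prob, self.noise, self.singleton_frac, self.isomir_shift_prob]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if sum(self.length_mode_weights.values()) > 1.0 + 1e-9:
            raise ValueError("length_mode_weights mass exceeds 1")
        if self.count_noise not in ("poisson", "nb"):
            raise ValueError("count_noise must be 'poisson' or 'nb'")


@dataclass
class TruthLocus:
    """Ground truth for one planted locus."""

    locus_id: str
    origin: str  # known | novel | decoy
    mature_seq: str
    star_seq: str
    chrom: str
    precursor_start: int
    precursor_end: int
    strand: str
    mature_start: int
    mature_end: int
    expected_count_c: float = 0.0
    expected_count_t: float = 0.0
    true_log2fc: float = 0.0
    tier: str = "null"

    def __post_init__(self):
        if self.origin != "decoy":
            if not (self.precursor_start <= self.mature_start < self.mature_end <= self.precursor_end):
                raise ValueError("mature must lie within the precursor interval")


@dataclass
class GroundTruth:
    loci: dict[str, TruthLocus] = field(default_factory=dict)

    def add(self, locus: TruthLocus) -> None:
        if locus.locus_id in self.loci:
            raise ValueError(f"duplicate locus id {locus.locus_id}")
        self.loci[locus.locus_id] = locus

    def mirna_loci(self) -> list[TruthLocus]:
        return [l for l in self.loci.values() if l.origin in ("known", "novel")]

    def by_tier(self, tier: str) -> list[TruthLocus]:
        return [l for l in self.mirna_loci() if l.tier == tier]


@dataclass
class SyntheticGenome:
    chrom: str
    sequence: str
    features: list[Feature]
    truth: GroundTruth
    background_loci: list[tuple[int, int]]
    #: fixed per-locus weight shares used to split category read budgets
    locus_weights: dict[str, np.ndarray] = field(default_factory=dict)


def _tier_of(lfc: float) -> str:
    a = abs(lfc)
    if a >= 1.0:
        return "strong"
    if a >= 0.25:
        return "slight"
    return "null"


def _auto_effects(locus_ids: list[str], rng: np.random.Generator) -> list[tuple[str, float]]:
    """Cycle strong/slight/null effects over the miRNA loci.

    Magnitudes are drawn inside each tier, away from the 0.25 and 1.0
    boundaries, so that tier membership is unambiguous under count noise.
    """
    out = []
    for i, lid in enumerate(locus_ids):
        kind = i % 3
        sign = -1.0 if (i // 3) % 2 else 1.0
        if kind == 0:
            mag = rng.uniform(1.3, 2.3)
        elif kind == 1:
            mag = rng.uniform(0.35, 0.85)
        else:
            mag = rng.uniform(0.0, 0.15)
        out.append((lid, sign * mag))
    return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _folds_as_designed(precursor: str, m_off: int, mlen: int) -> bool:
    """True when the precursor's fold keeps the mature wholly on one arm.

    Matures with substantial self-complementarity can make the designed
    stem-loop non-optimal (the mature pairs with itself); such constructs
    are rejected at generation so every planted locus is a genuine hairpin.
    """
    from .fold import fold_rna

    pairs = fold_rna(precursor).pairs
    partners = [int(pairs[i]) for i in range(m_off, m_off + mlen) if pairs[i] >= 0]
    if not partners or any(m_off <= p < m_off + mlen for p in partners):
        return False
    return all(p >= m_off + mlen for p in partners) or all(p < m_off for p in partners)


def _nonpairing_base(neighbors: str, rng: np.random.Generator) -> str:
    """A base that neither Watson-Crick- nor wobble-pairs any neighbor base."""
    partners = {"A": "T", "C": "G", "G": "CT", "T": "AG"}
    ok = [b for b in "AC" if not any(n in partners[b] for n in neighbors)]
    return ok[0] if ok else "A"


class _Placer:
    """Non-overlapping interval placement with a safety margin."""

    def __init__(self, genome_length: int, rng: np.random.Generator, margin: int = 60):
        self.L = genome_length
        self.rng = rng
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, length: int, tries: int = 2000) -> int:
        for _ in range(tries):
            s = int(self.rng.integers(self.margin, self.L - length - self.margin))
            if all(s + length + self.margin <= a or s >= b + self.margin for a, b in self.taken):
                self.taken.append((s, s + length))
                return s
        raise ValueError("genome too short to place all requested features")


def design_precursor(mature: str, loop_len: int, arm: str, rng: np.random.Generator):
    """Build a stem-loop precursor around a mature sequence.

    The star arm is the reverse complement of all but the last two mature
    bases plus a 2-nt extension, giving the mature/star duplex 2-nt 3'
    overhangs on both ends by construction; the terminal loop is >= 4 nt of
    non-pairing bases. Returns (precursor, star, mature_offset).
    """
    if not 20 <= len(mature) <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if loop_len < 4:
        raise ValueError("terminal loop must be >= 4 nt")
    core = revcomp(mature[:-2])
    overhang = "".join(_nonpairing_base(mature[:2] + mature[-2:], rng) for _ in range(2))
    star = core + overhang
    loop_base = _nonpairing_base(mature[-3:] + star[:3], rng)
    loop = loop_base * loop_len
    if arm == "5p":
        return mature + loop + star, star, 0
    return star + loop + mature, star, len(star) + loop_len


def plant_hairpin_locus(
    genome: np.ndarray,
    placer: _Placer,
    mature: str,
    rng: np.random.Generator,
    arm: str | None = None,
    loop_len: int = 8,
    shuffle: bool = False,
):
    """Insert a precursor into the genome buffer; returns a TruthLocus shell.

    ``shuffle=True`` plants a dinucleotide-shuffled copy of the precursor
    (a decoy that should fail hairpin qualification).
    """
    arm = arm or ("5p" if rng.random() < 0.5 else "3p")
    precursor, star, m_off = design_precursor(mature, loop_len, arm, rng)
    if shuffle:
        precursor = dinucleotide_shuffle(precursor, rng)
        m_off = int(rng.integers(0, len(precursor) - len(mature) + 1))
        mature = precursor[m_off : m_off + len(mature)]
        star = ""
    start = placer.place(len(precursor))
    genome[start : start + len(precursor)] = list(precursor)
    return mature, star, start, start + len(precursor), start + m_off, start + m_off + len(mature)


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build the genome, annotation features and planted-locus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genome = _BASES[rng.integers(0, 4, L)].copy()
    placer = _Placer(L, rng)
    features: list[Feature] = []
    chrom = "chr1"

    # ncRNA / repeat features
    for ftype, (n, lo, hi) in DEFAULT_FEATURE_PLAN.items():
        for i in range(n):
            flen = int(rng.integers(lo, hi + 1))
            start = placer.place(flen)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(chrom, start, start + flen, strand, ftype, f"{ftype}_{i + 1}"))

    # genes: exon-intron-exon blocks
    for g in range(config.n_genes):
        e1 = int(rng.integers(150, 401))
        intr = int(rng.integers(200, 601))
        e2 = int(rng.integers(150, 401))
        start = placer.place(e1 + intr + e2)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{g + 1}"
        features.append(Feature(chrom, start, start + e1, strand, "exon", f"{gid}_exon1"))
        features.append(Feature(chrom, start + e1, start + e1 + intr, strand, "intron", f"{gid}_intron1"))
        features.append(Feature(chrom, start + e1 + intr, start + e1 + intr + e2, strand, "exon", f"{gid}_exon2"))

    truth = GroundTruth()
    plan = (
        [("known", i) for i in range(config.n_known_mirna)]
        + [("novel", i) for i in range(config.n_novel_mirna)]
        + [("decoy", i) for i in range(config.n_decoy_loci)]
    )
    for origin, i in plan:
        mlen = int(rng.choice(config.mature_lengths))
        arm = "5p" if rng.random() < 0.5 else "3p"
        for _ in range(100):  # reject matures whose precursor would misfold
            mature = _random_seq(rng, mlen)
            if rng.random() < config.five_prime_u_prob:
                mature = "T" + mature[1:]
            prec, _, m_off = design_precursor(mature, config.loop_len, arm, rng)
            if _folds_as_designed(prec, m_off, mlen):
                break
        mature, star, ps, pe, ms, me = plant_hairpin_locus(
            genome, placer, mature, rng, arm=arm, loop_len=config.loop_len, shuffle=(origin == "decoy")
        )
        lid = f"{origin}_mir_{i + 1}" if origin != "decoy" else f"decoy_{i + 1}"
        truth.add(
            TruthLocus(lid, origin, mature, star, chrom, ps, pe, "+", ms, me)
        )

    # discrete background source loci for the un-annotated class
    background = []
    for _ in range(config.n_background_loci):
        blen = int(rng.integers(30, 151))
        try:
            s = placer.place(blen, tries=200)
        except ValueError:
            continue
        background.append((s, s + blen))

    # per-locus budget shares, fixed once per genome
    lw: dict[str, np.ndarray] = {}
    for ftype in DEFAULT_FEATURE_PLAN:
        n = sum(1 for f in features if f.ftype == ftype)
        w = rng.lognormal(0.0, 1.0, n)
        lw[ftype] = w / w.sum()
    for part in ("exon", "intron"):
        n = sum(1 for f in features if f.ftype == part)
        w = rng.lognormal(0.0, 1.0, n)
        lw[part] = w / w.sum()
    w = rng.lognormal(0.0, 1.2, max(len(background), 1))
    lw["background"] = w / w.sum()
    mir = truth.mirna_loci()
    w = rng.lognormal(0.0, 1.2, max(len(mir), 1))
    lw["mirna"] = w / w.sum()
    w = rng.uniform(10, 40, max(config.n_decoy_loci, 1))
    lw["decoy_counts"] = w

    # planted differential-expression effects and expected counts
    effects = (
        config.de_effects
        if config.de_effects is not None
        else _auto_effects([l.locus_id for l in mir], rng)
    )
    eff = dict(effects)
    unknown = set(eff) - set(truth.loci)
    if unknown:
        raise ValueError(f"de_effects reference unknown loci: {sorted(unknown)}")
    d1, d2 = config.library_depths
    mir_budget = config.category_weights["miRNA"] / sum(config.category_weights.values()) * d1
    for locus, share in zip(mir, lw["mirna"]):
        lfc = eff.get(locus.locus_id, 0.0)
        locus.true_log2fc = lfc
        locus.tier = _tier_of(lfc)
        locus.expected_count_c = max(share * mir_budget, config.min_locus_expected)
        locus.expected_count_t = locus.expected_count_c * (2.0**lfc) * (d2 / d1)
    for locus, ec in zip((l for l in truth.loci.values() if l.origin == "decoy"), lw["decoy_counts"]):
        locus.expected_count_c = float(ec)
        locus.expected_count_t = float(ec) * (d2 / d1)
        locus.tier = "decoy"

    return SyntheticGenome(chrom, "".join(genome), features, truth, background, lw)


def _insert_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    u = rng.random()
    acc = 0.0
    for length, w in config.length_mode_weights.items():
        acc += w
        if u < acc:
            return length
    others = [l for l in range(15, 31) if l not in config.length_mode_weights]
    return int(others[rng.integers(0, len(others))])


def _draw_count(mean: float, config: SimulationConfig, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if config.count_noise == "poisson":
        return int(rng.poisson(mean))
    # negative binomial with variance mean + dispersion * mean^2
    r = 1.0 / config.nb_dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _locus_insert(lo: int, hi: int, config, rng) -> tuple[int, int]:
    """(start, length) of a random insert window inside a source locus [lo, hi)."""
    L = min(_insert_length(config, rng), hi - lo)
    p = int(rng.integers(lo, hi - L + 1))
    return p, L


def simulate_libraries(genome: SyntheticGenome, config: SimulationConfig):
    """Draw the control and treatment read libraries.

    Returns ``(reads_c, reads_t)``: lists of raw read strings
    (insert + 3' adapter + random fill, truncated to ``read_length``).
    Deterministic given the configuration; uses a generator seeded
    independently of genome construction (seed + 1) so the same genome can
    be re-sequenced.
    """
    rng = np.random.default_rng(config.seed + 1)
    seq = genome.sequence
    cw = config.category_weights
    wsum = sum(cw.values())
    libraries = []
    for lib_idx, depth in enumerate(config.library_depths):
        inserts: list[str] = []
        # planted miRNA loci
        for locus in genome.truth.mirna_loci():
            mean = locus.expected_count_c if lib_idx == 0 else locus.expected_count_t
            n = _draw_count(mean, config, rng)
            for _ in range(n):
                s, e = locus.mature_start, locus.mature_end
                if rng.random() < config.isomir_shift_prob:
                    shift = int(rng.integers(-1, 2))
                    e = min(max(e + shift, s + 15), len(seq))
                ins = seq[s:e]
                inserts.append(ins if locus.strand == "+" else revcomp(ins))
        # decoy loci: reads from the decoy "mature" position
        for locus in (l for l in genome.truth.loci.values() if l.origin == "decoy"):
            mean = locus.expected_count_c if lib_idx == 0 else locus.expected_count_t
            for _ in range(_draw_count(mean, config, rng)):
                inserts.append(seq[locus.mature_start : locus.mature_end])
        # feature-derived background
        by_type: dict[str, list[Feature]] = {}
        for f in genome.features:
            by_type.setdefault(f.ftype, []).append(f)
        for ftype, budget_key in [
            ("rRNA", "rRNA"),
            ("tRNA", "tRNA"),
            ("snRNA", "snRNA"),
            ("snoRNA", "snoRNA"),
            ("repeat_region", "repeat"),
            ("exon", "exon"),
            ("intron", "intron"),
        ]:
            feats = by_type.get(ftype, [])
            if not feats:
                continue
            budget = cw[budget_key] / wsum * depth
            weights = genome.locus_weights[ftype]
            counts = rng.poisson(weights * budget)
            for f, n in zip(feats, counts):
                for _ in range(int(n)):
                    p, L = _locus_insert(f.start, f.end, config, rng)
                    ins = seq[p : p + L]
                    if f.strand == "-":
                        ins = revcomp(ins)
                    if rng.random() < 0.4:  # antisense transcription noise
                        ins = revcomp(ins)
                    inserts.append(ins)
        # un-annotated background: discrete loci + uniform singletons
        un_budget = cw["unannotated"] / wsum * depth
        n_single = int(un_budget * config.singleton_frac)
        loci_budget = un_budget - n_single
        counts = rng.poisson(genome.locus_weights["background"] * loci_budget)
        for (lo, hi), n in zip(genome.background_loci, counts):
            for _ in range(int(n)):
                p, L = _locus_insert(lo, hi, config, rng)
                inserts.append(seq[p : p + L])
        for _ in range(rng.poisson(n_single)):
            L = _insert_length(config, rng)
            p = int(rng.integers(0, len(seq) - L))
            ins = seq[p : p + L]
            inserts.append(ins if rng.random() < 0.5 else revcomp(ins))

        # shuffle read order, apply sequencing errors, add adapter + fill
        order = rng.permutation(len(inserts))
        reads = []
        for i in order:
            ins = inserts[i]
            nerr = rng.binomial(len(ins), config.noise) if config.noise > 0 else 0
            if nerr:
                chars = list(ins)
                for p in rng.choice(len(ins), size=nerr, replace=False):
                    chars[p] = _BASES[(("ACGT".index(chars[p])) + int(rng.integers(1, 4))) % 4]
                ins = "".join(chars)
            read = ins + config.adapter3
            if len(read) < config.read_length:
                read += _random_seq(rng, config.read_length - len(read))
            reads.append(read[: config.read_length])
        libraries.append(reads)
    return libraries[0], libraries[1]


def write_fastq(path, reads, prefix: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{prefix}_{i + 1:07d}\n{r}\n+\n{'I' * len(r)}\n")


def truth_table(truth: GroundTruth):
    """Ground-truth table as a pandas DataFrame (spec'd columns first)."""
    import pandas as pd

    rows = []
    for l in truth.loci.values():
        rows.append(
            {
                "locus_id": l.locus_id,
                "mature_seq": l.mature_seq,
                "expected_count_c": round(l.expected_count_c, 3),
                "expected_count_t": round(l.expected_count_t, 3),
                "true_log2fc": round(l.true_log2fc, 4),
                "tier": l.tier,
                "origin": l.origin,
                "chrom": l.chrom,
                "precursor_start": l.precursor_start,
                "precursor_end": l.precursor_end,
                "strand": l.strand,
                "mature_start": l.mature_start,
                "mature_end": l.mature_end,
                "star_seq": l.star_seq,
            }
        )
    return pd.DataFrame(rows)


def known_mature_db(truth: GroundTruth) -> dict[str, str]:
    """The synthetic 'known mature miRNA' reference database."""
    return {l.locus_id: l.mature_seq for l in truth.loci.values() if l.origin == "known"}


def write_dataset(outdir, genome: SyntheticGenome, reads_c, reads_t) -> dict[str, str]:
    """Write genome FASTA, GFF3, mature DB, FASTQ pair and truth TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "features.gff3"),
        "mature_db": os.path.join(outdir, "known_mature.fa"),
        "fastq_c": os.path.join(outdir, "control.fastq"),
        "fastq_t": os.path.join(outdir, "treatment.fastq"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(paths["genome"], [(genome.chrom, genome.sequence)])
    write_gff3(paths["gff3"], genome.features)
    write_fasta(paths["mature_db"], sorted(known_mature_db(genome.truth).items()))
    write_fastq(paths["fastq_c"], reads_c, "c")
    write_fastq(paths["fastq_t"], reads_t, "t")
    truth_table(genome.truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_transcripts(
    truth: GroundTruth, rng: np.random.Generator, n_transcripts: int = 30, site_mirnas: int = 10
):
    """Synthetic transcript set with planted miRNA target sites.

    Transcripts are grouped two-per-gene; the first ``site_mirnas`` miRNA
    loci get a perfect complementary site planted in one or more
    transcripts. Returns (transcripts dict, transcript→gene map,
    mirna→set of target genes truth).
    """
    transcripts: dict[str, str] = {}
    gene_map: dict[str, str] = {}
    site_truth: dict[str, set[str]] = {}
    for i in range(n_transcripts):
        tid = f"tx_{i + 1}"
        gene_map[tid] = f"g_{i // 2 + 1}"
        transcripts[tid] = _random_seq(rng, int(rng.integers(500, 1200)))
    tids = list(transcripts)
    for locus in truth.mirna_loci()[:site_mirnas]:
        n_sites = int(rng.integers(1, 4))
        site_truth[locus.locus_id] = set()
        for _ in range(n_sites):
            tid = tids[int(rng.integers(0, len(tids)))]
            seq = transcripts[tid]
            site = revcomp(locus.mature_seq)
            p = int(rng.integers(0, len(seq) - len(site)))
            transcripts[tid] = seq[:p] + site + seq[p + len(site) :]
            site_truth[locus.locus_id].add(gene_map[tid])
    return transcripts, gene_map, site_truth


def simulate_qpcr_table(
    log2fcs: dict[str, float], rng: np.random.Generator, n_discordant: int = 0, n_replicates: int = 3
):
    """Synthetic stem-loop qPCR Ct table consistent with given fold changes.

    Ct scales as -log2(expression); a planted subset of assays is flipped to
    emulate discordant validation. Returns (DataFrame, set of flipped ids).
    """
    import pandas as pd

    rows = []
    ids = sorted(log2fcs)
    flipped = set(ids[:n_discordant])
    for mid in ids:
        lfc = log2fcs[mid]
        if mid in flipped:
            lfc = -lfc if lfc != 0 else 1.0
        base = rng.uniform(22, 30)
        for cond, dct in (("control", 0.0), ("treatment", -lfc)):
            ct_u6 = 18.0
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "mirna": mid,
                        "condition": cond,
                        "replicate": rep,
                        "ct_target": round(base + dct + rng.normal(0, 0.05), 3),
                        "ct_u6": round(ct_u6 + rng.normal(0, 0.05), 3),
                    }
                )
    return pd.DataFrame(rows), flipped
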