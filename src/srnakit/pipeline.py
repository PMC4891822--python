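"""End-to-end orchestration: clean → annotate → identify → diffexpr → targets.

`analyze` runs the whole analysis on in-memory inputs and returns a
Results bundle; `run_pipeline` wraps it with file input/output, report
rendering and a machine-readable run manifest. Stages log to stderr;
report files never interleave with logs, and reruns with the same
configuration and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    FeatureIndex,
    GenomeIndex,
    TABLE_ORDER,
    classify_all,
    length_distribution,
    map_tags,
    read_gff3,
    summarize_categories,
)
from .cleaning import CleanReadPolicy, clean_fastq, collapse_tags, tags_to_fasta, tags_to_tsv, tally_to_tsv
from .diffexpr import Thresholds, category_tally, profile_table
from .discover import DiscoveryParams, count_mirna_expression, discover_novel, match_known
from .qpcr import concordance_rate, concordance_table, records_from_table
from .sequtils import read_fasta
from .targets import ScoringScheme, hits_table, predict_targets, summarize_targets_per_mirna

log = logging.getLogger("srnakit")


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str):
        super().__init__(f"stage {stage!r} failed: {context}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genome: str = ""
    gff3: str = ""
    mature_db: str = ""
    transcripts: str = ""
    fastq_c: str = ""
    fastq_t: str = ""
    qpcr_table: str = ""
    policy: CleanReadPolicy = field(default_factory=CleanReadPolicy)
    max_mismatch: int = 0
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    alternative: str = "two-sided"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "policy":
                v = CleanReadPolicy(**v)
            elif f.name == "discovery":
                v = DiscoveryParams(**v)
            elif f.name == "thresholds":
                v = Thresholds(**v)
            elif f.name == "scoring":
                v = ScoringScheme(**v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def require_paths(self, *names) -> None:
        for n in names:
            p = getattr(self, n)
            if not p or not os.path.exists(p):
                raise FileNotFoundError(f"config path {n!r} missing or does not exist: {p!r}")


@dataclass
class Results:
    tags: list
    tally_c: dict
    tally_t: dict
    n_clean_c: int
    n_clean_t: int
    categories: dict[str, str]
    summary_c: object
    summary_t: object
    length_dist: pd.DataFrame
    known_hits: dict
    candidates: list
    mirna_counts: dict[str, tuple[int, int]]
    profiles: pd.DataFrame
    profiles_filtered: pd.DataFrame
    tallies: pd.DataFrame
    target_hits: list = field(default_factory=list)
    target_gene_counts: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def known_mirna_expression(tags, known_hits, mature_db) -> dict[str, tuple[int, int]]:
    """Per-library counts for each known mature, end-tolerant rule.

    Tags are grouped by their match_known assignment, then counted against
    the assigned mature; each tag contributes to at most one mature.
    """
    grouped: dict[str, list] = {}
    for t in tags:
        hit = known_hits.get(t.sequence)
        if hit:
            grouped.setdefault(hit[0], []).append(t)
    out = {}
    for name, members in grouped.items():
        cc, ct, _ = count_mirna_expression(mature_db[name], members)
        if cc or ct:
            out[name] = (cc, ct)
    return out


def analyze(
    genome: dict[str, str] | str,
    features: list,
    mature_db: dict[str, str],
    reads_c,
    reads_t,
    transcripts: dict[str, str] | None = None,
    gene_map: dict[str, str] | None = None,
    policy: CleanReadPolicy | None = None,
    max_mismatch: int = 0,
    discovery: DiscoveryParams | None = None,
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
    alternative: str = "two-sided",
) -> Results:
    """Run the full in-memory analysis on raw read iterables."""
    from .cleaning import trim_and_filter

    policy = policy or CleanReadPolicy()
    discovery = discovery or DiscoveryParams()
    thresholds = thresholds or Thresholds()

    inserts_c, tally_c = trim_and_filter(reads_c, policy)
    inserts_t, tally_t = trim_and_filter(reads_t, policy)
    n1, n2 = len(inserts_c), len(inserts_t)
    tags = collapse_tags(inserts_c, inserts_t)
    del inserts_c, inserts_t

    index = GenomeIndex(genome)
    alignments = map_tags(tags, genome, max_mismatch, index=index)
    known_hits = match_known(tags, mature_db) if mature_db else {}
    fidx = FeatureIndex(features)
    categories = classify_all(tags, alignments, fidx, set(known_hits))
    summary_c = summarize_categories(tags, categories, "control")
    summary_t = summarize_categories(tags, categories, "treatment")
    ldist = length_distribution(tags, policy.min_len, policy.max_len)

    unannot = [
        (alignments[t.sequence][0], t.count_c, t.count_t)
        for t in tags
        if categories[t.sequence] == "unannotated" and t.sequence in alignments
    ]
    candidates = discover_novel(unannot, index.genome, discovery)

    counts = known_mirna_expression(tags, known_hits, mature_db) if mature_db else {}
    for cand in candidates:
        if cand.passed:
            counts[cand.name] = (cand.count_c, cand.count_t)
    profiles = profile_table(counts, max(n1, 1), max(n2, 1), thresholds, alternative)
    if len(profiles):
        keep = profiles[["tpm_c", "tpm_t"]].max(axis=1) >= thresholds.min_tpm
        filtered = profiles[keep].reset_index(drop=True)
    else:
        filtered = profiles
    tallies = category_tally(filtered)

    target_hits: list = []
    gene_counts: dict = {}
    if transcripts:
        mature_seqs = dict(mature_db)
        for cand in candidates:
            if cand.passed:
                mature_seqs[cand.name] = cand.mature_seq
        profiled = set(filtered["mirna"]) if len(filtered) else set()
        for name in sorted(profiled):
            target_hits.extend(
                predict_targets(name, mature_seqs[name], transcripts, scheme=scoring or ScoringScheme())
            )
        gene_counts = summarize_targets_per_mirna(target_hits, gene_map)

    return Results(
        tags=tags,
        tally_c=tally_c,
        tally_t=tally_t,
        n_clean_c=n1,
        n_clean_t=n2,
        categories=categories,
        summary_c=summary_c,
        summary_t=summary_t,
        length_dist=ldist,
        known_hits=known_hits,
        candidates=candidates,
        mirna_counts=counts,
        profiles=profiles,
        profiles_filtered=filtered,
        tallies=tallies,
        target_hits=target_hits,
        target_gene_counts=gene_counts,
    )


def render_table1(summary_c, summary_t) -> pd.DataFrame:
    """Two-library category table in the fixed report row order."""
    rows = []
    for cat in TABLE_ORDER:
        rc = summary_c.table.loc[cat]
        rt = summary_t.table.loc[cat]
        rows.append(
            {
                "category": cat,
                "unique_c": int(rc["unique"]),
                "unique_pct_c": f"{rc['unique_pct']:.2f}",
                "total_c": int(rc["total"]),
                "total_pct_c": f"{rc['total_pct']:.2f}",
                "unique_t": int(rt["unique"]),
                "unique_pct_t": f"{rt['unique_pct']:.2f}",
                "total_t": int(rt["total"]),
                "total_pct_t": f"{rt['total_pct']:.2f}",
            }
        )
    return pd.DataFrame(rows)


def _write_candidates(outdir, candidates) -> None:
    rows = []
    with open(os.path.join(outdir, "novel_candidates.fa"), "w") as fa, open(
        os.path.join(outdir, "novel_candidates.str"), "w"
    ) as st:
        for c in candidates:
            rows.append(
                {
                    "name": c.name or "-",
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "strand": c.strand,
                    "arm": c.mature_arm,
                    "energy": c.energy,
                    "supporting_reads": c.supporting_reads,
                    "passed": c.passed,
                    **{f"flag_{k}": v for k, v in c.flags.items()},
                    "count_c": c.count_c,
                    "count_t": c.count_t,
                    "mature_seq": c.mature_seq,
                }
            )
            if c.passed:
                star = (
                    c.precursor_seq[c.star_interval[0] : c.star_interval[1]] if c.star_interval else ""
                )
                fa.write(f">{c.name}_precursor\n{c.precursor_seq}\n")
                fa.write(f">{c.name}_mature\n{c.mature_seq}\n")
                if star:
                    fa.write(f">{c.name}_star\n{star}\n")
                st.write(f">{c.name}\n{c.precursor_seq}\n{c.structure}\n")
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "novel_candidates.tsv"), sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage from files and write the report directory."""
    os.makedirs(outdir, exist_ok=True)
    config.require_paths("genome", "gff3", "mature_db", "fastq_c", "fastq_t")

    @_stage("clean")
    def _clean():
        ic, tc = clean_fastq(config.fastq_c, config.policy)
        it, tt = clean_fastq(config.fastq_t, config.policy)
        return ic, tc, it, tt

    inserts_c, tally_c, inserts_t, tally_t = _clean()
    tags = collapse_tags(inserts_c, inserts_t)
    n1, n2 = len(inserts_c), len(inserts_t)
    tags_to_tsv(os.path.join(outdir, "tags.tsv"), tags)
    tags_to_fasta(os.path.join(outdir, "tags.fa"), tags)
    tally_to_tsv(os.path.join(outdir, "clean_tally.tsv"), tally_c, tally_t)

    genome = read_fasta(config.genome)
    features = read_gff3(config.gff3)
    mature_db = read_fasta(config.mature_db)
    transcripts = read_fasta(config.transcripts) if config.transcripts else None

    @_stage("annotate")
    def _annotate():
        index = GenomeIndex(genome)
        alignments = map_tags(tags, genome, config.max_mismatch, index=index)
        known_hits = match_known(tags, mature_db)
        fidx = FeatureIndex(features)
        cats = classify_all(tags, alignments, fidx, set(known_hits))
        return index, alignments, known_hits, cats

    index, alignments, known_hits, categories = _annotate()
    summary_c = summarize_categories(tags, categories, "control")
    summary_t = summarize_categories(tags, categories, "treatment")
    render_table1(summary_c, summary_t).to_csv(
        os.path.join(outdir, "category_summary.tsv"), sep="\t", index=False
    )
    length_distribution(tags, config.policy.min_len, config.policy.max_len).to_csv(
        os.path.join(outdir, "length_histogram.tsv"), sep="\t"
    )

    @_stage("identify")
    def _identify():
        unannot = [
            (alignments[t.sequence][0], t.count_c, t.count_t)
            for t in tags
            if categories[t.sequence] == "unannotated" and t.sequence in alignments
        ]
        return discover_novel(unannot, index.genome, config.discovery)

    candidates = _identify()
    _write_candidates(outdir, candidates)

    @_stage("diffexpr")
    def _diffexpr():
        counts = known_mirna_expression(tags, known_hits, mature_db)
        for cand in candidates:
            if cand.passed:
                counts[cand.name] = (cand.count_c, cand.count_t)
        profiles = profile_table(counts, max(n1, 1), max(n2, 1), config.thresholds, config.alternative)
        return counts, profiles

    counts, profiles = _diffexpr()
    profiles.to_csv(os.path.join(outdir, "expression_profiles.tsv"), sep="\t", index=False)
    if len(profiles):
        keep = profiles[["tpm_c", "tpm_t"]].max(axis=1) >= config.thresholds.min_tpm
        filtered = profiles[keep].reset_index(drop=True)
    else:
        filtered = profiles
    filtered.to_csv(os.path.join(outdir, "expression_profiles_filtered.tsv"), sep="\t", index=False)
    category_tally(filtered).to_csv(os.path.join(outdir, "category_tally.tsv"), sep="\t", index=False)
    for flag in ("control_only", "treatment_only"):
        sub = filtered[filtered["exclusive_flag"] == flag] if len(filtered) else filtered
        sub.to_csv(os.path.join(outdir, f"{flag}.tsv"), sep="\t", index=False)

    if transcripts:

        @_stage("targets")
        def _targets():
            hits = []
            mature_seqs = dict(mature_db)
            for cand in candidates:
                if cand.passed:
                    mature_seqs[cand.name] = cand.mature_seq
            for name in sorted(set(filtered["mirna"]) if len(filtered) else ()):
                hits.extend(predict_targets(name, mature_seqs[name], transcripts, scheme=config.scoring))
            return hits

        hits = _targets()
        hits_table(hits).to_csv(os.path.join(outdir, "target_hits.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(summarize_targets_per_mirna(hits).items()), columns=["mirna", "n_target_genes"]
        ).to_csv(os.path.join(outdir, "target_gene_counts.tsv"), sep="\t", index=False)

    if config.qpcr_table:

        @_stage("qpcr")
        def _qpcr():
            df = pd.read_csv(config.qpcr_table, sep="\t")
            records = records_from_table(df)
            lfcs = dict(zip(profiles["mirna"], profiles["log2fc"])) if len(profiles) else {}
            table = concordance_table(records, lfcs)
            qdir = {r.mirna: r.direction for r in records}
            rdir = {
                m: (0 if v == 0 else (1 if v > 0 else -1)) for m, v in lfcs.items()
            }
            rate = concordance_rate(qdir, rdir)
            return table, rate

        qtable, rate = _qpcr()
        qtable.to_csv(os.path.join(outdir, "qpcr_concordance.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "qpcr_summary.txt"), "w") as fh:
            fh.write(f"concordance_pct\t{rate:.2f}\n")

    manifest = {
        "package": "srnakit",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_clean_reads": [n1, n2],
        "n_tags": len(tags),
        "n_known_mirnas_detected": len({v[0] for v in known_hits.values()}),
        "n_novel_candidates_passing": sum(1 for c in candidates if c.passed),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
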