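"""Recovery metrics of a pipeline run against simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass

_TIER_FROM_CATEGORY = {
    "significantly_up": ("strong", 1),
    "significantly_down": ("strong", -1),
    "slightly_up": ("slight", 1),
    "slightly_down": ("slight", -1),
    "unobvious": ("null", 0),
}


def _expected_category(lfc: float) -> str:
    a = abs(lfc)
    if a >= 1.0:
        return "significantly_up" if lfc > 0 else "significantly_down"
    if a >= 0.25:
        return "slightly_up" if lfc > 0 else "slightly_down"
    return "unobvious"


@dataclass
class RecoveryReport:
    n_novel_planted: int
    n_novel_recovered: int
    novel_recovery_pct: float
    n_strong: int
    n_strong_correct: int
    strong_tier_accuracy_pct: float
    matched_novel: dict[str, str]  # truth locus id -> candidate name


def match_candidates_to_truth(candidates, truth) -> dict[str, str]:
    """Match passing hairpin candidates to planted novel loci by overlap."""
    matched = {}
    for locus in truth.mirna_loci():
        if locus.origin != "novel":
            continue
        for c in candidates:
            if not c.passed or c.chrom != locus.chrom:
                continue
            if c.start < locus.precursor_end and locus.precursor_start < c.end:
                matched[locus.locus_id] = c.name
                break
    return matched


def recovery_report(candidates, profiles, truth) -> RecoveryReport:
    """Score novel-locus recovery and regulation-tier assignment.

    A planted novel locus counts as recovered when a passing candidate
    overlaps its precursor. Tier accuracy is judged over every planted
    miRNA locus with true |log2FC| >= 1 (known loci are looked up by id,
    novel loci through their matched candidate); an unrecovered or
    unprofiled strong locus counts as incorrect.
    """
    matched = match_candidates_to_truth(candidates, truth)
    novel = [l for l in truth.mirna_loci() if l.origin == "novel"]
    n_rec = len(matched)

    cat_by_name = dict(zip(profiles["mirna"], profiles["category"])) if len(profiles) else {}
    strong = [l for l in truth.mirna_loci() if abs(l.true_log2fc) >= 1.0]
    n_ok = 0
    for locus in strong:
        name = locus.locus_id if locus.origin == "known" else matched.get(locus.locus_id)
        if name is None:
            continue
        if cat_by_name.get(name) == _expected_category(locus.true_log2fc):
            n_ok += 1
    return RecoveryReport(
        n_novel_planted=len(novel),
        n_novel_recovered=n_rec,
        novel_recovery_pct=round(100.0 * n_rec / len(novel), 2) if novel else 100.0,
        n_strong=len(strong),
        n_strong_correct=n_ok,
        strong_tier_accuracy_pct=round(100.0 * n_ok / len(strong), 2) if strong else 100.0,
        matched_novel=matched,
    )
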