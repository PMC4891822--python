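"""Synthetic-data generator: determinism, geometry, count calibration."""

import numpy as np
import pytest

from srnakit.sequtils import dinucleotide_shuffle, revcomp
from srnakit.simulate import (
    SimulationConfig,
    design_precursor,
    generate_genome,
    known_mature_db,
    simulate_libraries,
    truth_table,
)


def _cfg(**kw):
    base = dict(
        seed=2,
        genome_length=50_000,
        n_known_mirna=3,
        n_novel_mirna=2,
        n_decoy_loci=1,
        library_depths=(5_000, 5_000),
        n_background_loci=40,
        n_genes=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_is_byte_identical():
    a_cfg, b_cfg = _cfg(), _cfg()
    ga, gb = generate_genome(a_cfg), generate_genome(b_cfg)
    assert ga.sequence == gb.sequence
    assert ga.features == gb.features
    ra = simulate_libraries(ga, a_cfg)
    rb = simulate_libraries(gb, b_cfg)
    assert ra == rb


def test_different_seed_differs():
    ga = generate_genome(_cfg(seed=2))
    gb = generate_genome(_cfg(seed=3))
    assert ga.sequence != gb.sequence


def test_empty_planting_gives_background_plus_features_only():
    g = generate_genome(_cfg(n_known_mirna=0, n_novel_mirna=0, n_decoy_loci=0))
    assert not g.truth.loci
    assert any(f.ftype == "rRNA" for f in g.features)


def test_planted_precursor_intervals_do_not_overlap():
    g = generate_genome(_cfg(n_known_mirna=3, n_novel_mirna=2, genome_length=50_000))
    ivs = sorted((l.precursor_start, l.precursor_end) for l in g.truth.loci.values())
    assert len(ivs) == 6  # incl. decoy
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2
    for f in g.features:  # features never overlap planted loci
        for s, e in ivs:
            assert not (f.start < e and s < f.end)


def test_genome_too_short_raises():
    with pytest.raises(ValueError):
        generate_genome(_cfg(genome_length=10_000, n_known_mirna=200))


def test_designed_precursor_duplex_geometry():
    rng = np.random.default_rng(0)
    mature = "TGAGGTAGTAGGTTGTATAGT"  # 21 nt
    for arm in ("5p", "3p"):
        prec, star, off = design_precursor(mature, 8, arm, rng)
        assert prec[off : off + 21] == mature
        # star core is the reverse complement of mature[:-2]: exact 2-nt
        # 3' overhangs on both duplex ends by construction
        assert star[:-2] == revcomp(mature[:-2])
        assert len(star) == len(mature)
        assert star in prec and mature in prec


def test_mature_length_bounds_enforced():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        design_precursor("ACGT" * 5 + "ACGTACGT", 8, "5p", rng)  # 28 nt
    with pytest.raises(ValueError):
        design_precursor("ACGTACGTACGTACG", 8, "5p", rng)  # 15 nt


def test_five_prime_u_bias_degenerate():
    g = generate_genome(_cfg(five_prime_u_prob=1.0))
    for locus in g.truth.mirna_loci():
        assert locus.mature_seq[0] == "T"


def test_truth_conservation_expected_counts_within_depth():
    cfg = _cfg()
    g = generate_genome(cfg)
    for i, key in enumerate(["expected_count_c", "expected_count_t"]):
        total = sum(getattr(l, key) for l in g.truth.mirna_loci())
        assert total <= cfg.library_depths[i]


def test_null_effects_count_ratios_centered_on_depth_ratio():
    # >= 100 loci, all with log2FC = 0: per-locus count ratios average ~N2/N1
    cfg = _cfg(
        genome_length=120_000,
        n_known_mirna=60,
        n_novel_mirna=60,
        n_decoy_loci=0,
        n_background_loci=20,
        library_depths=(30_000, 30_000),
        noise=0.0,
        isomir_shift_prob=0.0,
    )
    cfg.de_effects = []  # no effects: every locus defaults to log2FC 0
    g = generate_genome(cfg)
    rc, rt = simulate_libraries(g, cfg)
    from collections import Counter

    strip = lambda reads: Counter(r[: r.find(cfg.adapter3)] for r in reads)
    counts_c, counts_t = strip(rc), strip(rt)
    ratios = []
    for l in g.truth.mirna_loci():
        x, y = counts_c[l.mature_seq], counts_t[l.mature_seq]
        if x and y:
            ratios.append(np.log2(y / x))
    assert len(ratios) >= 100
    assert abs(np.mean(ratios)) < 0.1


def test_planted_depletion_recovers_expected_log2fc():
    # every locus planted at log2FC -2 with expected >= 200 control reads:
    # the empirical log2FC of the mature tag should sit near -2
    cfg = _cfg(
        n_known_mirna=6,
        n_novel_mirna=6,
        n_decoy_loci=0,
        min_locus_expected=200.0,
        library_depths=(30_000, 30_000),
        noise=0.0,
        isomir_shift_prob=0.0,
    )
    cfg.de_effects = None
    g = generate_genome(cfg)
    for l in g.truth.mirna_loci():
        l.true_log2fc = -2.0
        l.expected_count_t = l.expected_count_c / 4.0
        l.tier = "strong"
    rc, rt = simulate_libraries(g, cfg)
    from collections import Counter

    strip = lambda reads: Counter(r[: r.find(cfg.adapter3)] for r in reads)
    counts_c, counts_t = strip(rc), strip(rt)
    lfcs = [
        np.log2(counts_t[l.mature_seq] / counts_c[l.mature_seq]) for l in g.truth.mirna_loci()
    ]
    assert abs(np.mean(lfcs) - (-2.0)) < 0.3


def test_reads_carry_adapter_and_fixed_length():
    cfg = _cfg()
    g = generate_genome(cfg)
    rc, rt = simulate_libraries(g, cfg)
    for r in rc[:200] + rt[:200]:
        assert len(r) == cfg.read_length
        assert cfg.adapter3[:8] in r  # at least the adapter seed survives


def test_truth_table_columns_and_known_db():
    g = generate_genome(_cfg())
    df = truth_table(g.truth)
    assert list(df.columns[:6]) == [
        "locus_id",
        "mature_seq",
        "expected_count_c",
        "expected_count_t",
        "true_log2fc",
        "tier",
    ]
    db = known_mature_db(g.truth)
    assert len(db) == 3
    assert all(15 <= len(s) <= 30 for s in db.values())


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(genome_length=5000).validate()
    with pytest.raises(ValueError):
        SimulationConfig(library_depths=(0, 10)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(five_prime_u_prob=1.5).validate()
    with pytest.raises(ValueError):
        generate_genome(_cfg(de_effects=[("nonexistent", 1.0)]))


def test_dinucleotide_shuffle_preserves_composition():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 150))
    sh = dinucleotide_shuffle(seq, rng)
    assert sh != seq
    assert len(sh) == len(seq)
    from collections import Counter

    assert Counter(zip(seq, seq[1:])) == Counter(zip(sh, sh[1:]))
    assert sh[0] == seq[0] and sh[-1] == seq[-1]
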