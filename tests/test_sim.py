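"""Synthetic-data generators: determinism, truth fidelity, rate fidelity."""

import numpy as np
import pandas as pd
import pytest

from manihot import dna
from manihot.sim.config import SimulationConfig, stage_rng
from manihot.sim.genome import (
    CapacityError,
    apply_variants,
    diverge_lineages,
    generate_ancestral_genome,
    make_diploid,
)
from manihot.sim.mites import plant_mites
from manihot.sim.expression import simulate_expression
from manihot.sim.reads import simulate_bac_and_fpc, simulate_reads


# --- ancestral genome -------------------------------------------------------


def test_gene_packing_and_orf_validity(small_config, small_genome):
    """Genes are non-overlapping with promoter clearance and are clean ORFs
    (translate-and-scan oracle)."""
    genome, genes = small_genome
    spans = sorted((g.start, g.end) for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 - e1 >= small_config.upstream_window
    for g in genes:
        prot = dna.translate(g.cds(genome))
        assert prot[0] == "M"
        assert prot[-1] == "*"
        assert "*" not in prot[:-1]


def test_no_internal_stops_in_large_gene_cohort():
    """1,000 simulated genes contain zero internal stop codons."""
    cfg = SimulationConfig(genome_length=1_300_000, n_genes=1000, gene_length=300)
    genome, genes = generate_ancestral_genome(cfg, stage_rng(3, "genome"))
    internal_stops = 0
    for g in genes:
        internal_stops += dna.translate(g.cds(genome))[:-1].count("*")
    assert internal_stops == 0


def test_generator_determinism(small_config):
    a, ga = generate_ancestral_genome(small_config, stage_rng(9, "genome"))
    b, gb = generate_ancestral_genome(small_config, stage_rng(9, "genome"))
    assert np.array_equal(a, b)
    assert [(g.id, g.start, g.end, g.strand) for g in ga] == [
        (g.id, g.start, g.end, g.strand) for g in gb
    ]


def test_infeasible_packing_raises():
    with pytest.raises((CapacityError, ValueError)):
        SimulationConfig(genome_length=10_000, n_genes=20, gene_length=900)


# --- diploid haplotypes -----------------------------------------------------


def test_zero_rates_give_identical_haplotypes(small_genome, rng):
    genome, _ = small_genome
    hap2, truth = make_diploid(genome, 0.0, 0.0, rng)
    assert np.array_equal(hap2, genome)
    assert len(truth) == 0


def test_het_event_count_within_poisson_bounds():
    """Planted SNV count lies within 3 Poisson SDs of rate * length."""
    genome = dna.random_seq(2_000_000, np.random.default_rng(4))
    _, truth = make_diploid(genome, 3.8, 0.0, np.random.default_rng(5))
    expected = 3.8 * 2_000_000 / 1000.0
    n = (truth.vtype == "SNV").sum()
    assert abs(n - expected) <= 3 * np.sqrt(expected)


def test_truth_positions_differ_and_others_match(small_genome, rng):
    """Every truth SNV position differs between haplotypes; every non-event
    position matches (position-wise oracle, SNV-only so coordinates align)."""
    genome, _ = small_genome
    hap2, truth = make_diploid(genome, 2.0, 0.0, rng)
    assert len(hap2) == len(genome)
    snv_pos = set(truth.pos)
    diff = np.flatnonzero(hap2 != genome)
    assert set(diff.tolist()) == snv_pos


def test_apply_variants_roundtrip_lift(rng):
    seq = dna.random_seq(500, rng)
    variants = pd.DataFrame(
        [
            (50, dna.decode(seq[50:51]), "A" if seq[50] != 0 else "C", "SNV", "x"),
            (100, "", "TTT", "INS", "x"),
            (200, dna.decode(seq[200:204]), "", "DEL", "x"),
        ],
        columns=["pos", "ref", "alt", "vtype", "lineage"],
    )
    out, lift = apply_variants(seq, variants)
    assert len(out) == 500 + 3 - 4
    # positions after the insertion shift right, after the deletion left
    assert lift(99) == 99
    assert lift(150) == 153
    assert lift(300) == 299
    assert np.array_equal(out[lift(300) : lift(310)], seq[300:310])


# --- lineage divergence -----------------------------------------------------


def test_zero_divergence_reproduces_ancestor(small_genome):
    genome, genes = small_genome
    cfg = SimulationConfig(
        genome_length=120_000,
        n_genes=30,
        gene_length=900,
        divergence_snv_rate=0.0,
        divergence_indel_rate=0.0,
        coding_subs_per_gene=0.0,
        pav_fraction=0.0,
        cnv_fraction=0.0,
    )
    lp = diverge_lineages(genome, genes, cfg, stage_rng(2, "divergence"))
    assert np.array_equal(lp.wild, genome)
    assert np.array_equal(lp.cultivar, genome)
    assert len(lp.variant_truth) == 0


def test_pav_count_binomial():
    """~10% PAV over 200 genes -> about 20 genes absent in one lineage."""
    cfg = SimulationConfig(
        genome_length=500_000,
        n_genes=200,
        gene_length=900,
        pav_fraction=0.10,
        cnv_fraction=0.0,
        coding_subs_per_gene=0.0,
    )
    genome, genes = generate_ancestral_genome(cfg, stage_rng(6, "genome"))
    lp = diverge_lineages(genome, genes, cfg, stage_rng(6, "divergence"))
    n_pav = (lp.gene_truth.pav_lineage != "").sum()
    expected, sd = 20.0, np.sqrt(200 * 0.1 * 0.9)
    assert abs(n_pav - expected) <= 3 * sd
    # deleted genes are absent from exactly one lineage's gene list
    wild_ids = {g.id for g in lp.wild_genes}
    cult_ids = {g.id for g in lp.cultivar_genes}
    for row in lp.gene_truth.itertuples():
        if row.pav_lineage == "wild":
            assert row.gene_id not in wild_ids and row.gene_id in cult_ids
        elif row.pav_lineage == "cultivar":
            assert row.gene_id in wild_ids and row.gene_id not in cult_ids


def test_positive_regime_truth_has_kaks_above_one(small_genome, small_lineages):
    """Genes planted under the positive regime show NG86 Ka/Ks > 1 against
    the ancestor (and the negative regime < 1)."""
    from manihot.selection import align_codons, compute_ka_ks

    genome, genes = small_genome
    lp = small_lineages
    anc = {g.id: g.cds(genome) for g in genes}
    cult = {g.id: g for g in lp.cultivar_genes}
    checked = 0
    for row in lp.gene_truth.itertuples():
        if row.pav_lineage or row.regime not in ("positive", "negative"):
            continue
        if row.na_planted == 0 or row.ns_planted == 0 or row.gene_id not in cult:
            continue
        cols = align_codons(anc[row.gene_id], cult[row.gene_id].cds(lp.cultivar))
        res = compute_ka_ks(cols)
        ratio = res.ka / res.ks
        assert (ratio > 1) == (row.regime == "positive")
        checked += 1
    assert checked >= 5


# --- MITE planting ----------------------------------------------------------


def test_plant_probability_zero_leaves_genome_unchanged(small_genome, rng):
    genome, genes = small_genome
    out, out_genes, truth = plant_mites(genome, genes, rng, insertion_prob=0.0)
    assert np.array_equal(out, genome)
    assert len(truth) == 0


def test_planted_element_tir_and_tsd_structure(small_genome, rng):
    genome, genes = small_genome
    out, out_genes, truth = plant_mites(genome, genes, rng, insertion_prob=1.0)
    planted = truth[truth.note == ""]
    assert len(planted) >= 25
    for row in planted.itertuples():
        elem = out[row.start : row.end]
        tir5 = elem[: row.tir_len]
        tir3 = elem[-row.tir_len :]
        assert np.array_equal(tir5, dna.revcomp(tir3))
        tsd = dna.encode(row.tsd)
        assert np.array_equal(out[row.start - len(tsd) : row.start], tsd)
        assert np.array_equal(out[row.end : row.end + len(tsd)], tsd)


def test_insertion_count_binomial():
    """Probability 0.3 over 100 windows -> ~30 insertions in truth."""
    cfg = SimulationConfig(genome_length=250_000, n_genes=100, gene_length=900)
    genome, genes = generate_ancestral_genome(cfg, stage_rng(8, "genome"))
    _, _, truth = plant_mites(genome, genes, stage_rng(8, "mites"), insertion_prob=0.3)
    n = (truth.note == "").sum()
    assert abs(n - 30) <= 3 * np.sqrt(100 * 0.3 * 0.7)


# --- read simulation --------------------------------------------------------


def test_read_count_matches_coverage(rng):
    genome = dna.random_seq(200_000, rng)
    rp = simulate_reads((genome,), 30.0, 300, 30, 100, 0.0, rng)
    assert abs(2 * len(rp) - 30 * 200_000 / 100) / (30 * 200_000 / 100) < 0.05


def test_error_free_reads_are_substrings(rng):
    """Error rate 0: every read occurs verbatim in a haplotype (substring
    oracle)."""
    hap1 = dna.random_seq(30_000, rng)
    hap2, _ = make_diploid(hap1, 3.0, 0.5, rng)
    rp = simulate_reads((hap1, hap2), 2.0, 400, 40, 80, 0.0, rng)
    h1, h2 = dna.decode(hap1), dna.decode(hap2)
    for i in range(len(rp)):
        r1 = dna.decode(rp.r1[i])
        r2 = dna.revcomp_str(dna.decode(rp.r2[i]))  # inward mate, flip back
        assert r1 in h1 or r1 in h2
        assert r2 in h1 or r2 in h2


def test_read_simulation_deterministic():
    genome = dna.random_seq(50_000, np.random.default_rng(3))
    a = simulate_reads((genome,), 5.0, 300, 30, 100, 0.01, np.random.default_rng(7))
    b = simulate_reads((genome,), 5.0, 300, 30, 100, 0.01, np.random.default_rng(7))
    assert np.array_equal(a.r1, b.r1) and np.array_equal(a.r2, b.r2)


def test_insert_precondition():
    genome = dna.random_seq(10_000, np.random.default_rng(0))
    with pytest.raises(ValueError):
        simulate_reads((genome,), 1.0, 150, 10, 100, 0.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        simulate_reads((genome,), 1.0, 20_000, 10, 100, 0.0, np.random.default_rng(0))


# --- BAC library and clone map ----------------------------------------------


def test_ten_genome_equivalents_clone_count():
    """10 genome equivalents of a 1-Mb genome at 115-kb inserts ~ 87 clones."""
    cfg = SimulationConfig(genome_length=1_000_000, n_genes=10, gene_length=300)
    assert cfg.bac_clone_count == 87


def test_fpc_order_monotone_and_end_spacing(rng):
    genome = dna.random_seq(400_000, rng)
    bac, fpc = simulate_bac_and_fpc(genome, 40, 115_000, 8_000, 500, rng)
    mids = {
        cid: (s + e) / 2 for cid, s, e in zip(bac.clone_ids, bac.start, bac.end)
    }
    for mc, clones in fpc.contigs.items():
        order_mids = [mids[c] for c in clones]
        assert order_mids == sorted(order_mids)
    # end reads map ~ insert length apart on the source (mapping oracle)
    g = dna.decode(genome)
    for i in range(0, len(bac.clone_ids), 7):
        p1 = g.find(dna.decode(bac.end1[i]))
        p2 = g.find(dna.revcomp_str(dna.decode(bac.end2[i])))
        assert p1 >= 0 and p2 >= 0
        span = (p2 + 500) - p1
        assert abs(span - (bac.end[i] - bac.start[i])) <= 1


# --- expression -------------------------------------------------------------


def test_expression_null_means_close(rng):
    ids = [f"g{i}" for i in range(400)]
    counts, truth = simulate_expression(ids, [False] * 400, 0.0, 0.05, 10, rng)
    wild = counts.filter(like="wild").mean(axis=1)
    cult = counts.filter(like="cultivar").mean(axis=1)
    # equal-mean model: per-gene group means differ only by sampling noise
    rel = ((wild - cult) / truth.wild_mean).abs()
    assert rel.median() < 0.15


def test_suppression_shifts_cultivar_mean(rng):
    ids = ["a", "b"]
    counts, truth = simulate_expression(
        ids, [True, False], -2.0, 0.0, 4000, rng, base_mean=400.0, mean_sigma=0.0
    )
    assert truth.loc["a", "cultivar_mean"] == pytest.approx(100.0)
    assert counts.loc["a"].filter(like="cultivar").mean() == pytest.approx(100.0, rel=0.05)


def test_nb_moments_match_dispersion(rng):
    """Across many null genes the empirical variance follows
    var = mu + dispersion * mu^2 (moment-matching oracle)."""
    ids = [f"g{i}" for i in range(1000)]
    disp = 0.1
    counts, truth = simulate_expression(
        ids, [False] * 1000, 0.0, disp, 50, rng, mean_sigma=0.0, base_mean=300.0
    )
    x = counts.to_numpy()
    mu = x.mean()
    implied_disp = (x.var() - mu) / mu**2
    assert implied_disp == pytest.approx(disp, rel=0.15)
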