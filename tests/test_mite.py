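"""MITE detection, cross-genome presence, DE and association."""

import numpy as np
import pandas as pd
import pytest

from manihot import dna
from manihot.mite import (
    associate,
    association_permutation_pvalue,
    compare_presence,
    detect_in_regions,
    detect_mites,
    diff_expression,
    extract_upstream,
)
from manihot.sim.config import SimulationConfig, stage_rng
from manihot.sim.expression import simulate_expression
from manihot.sim.genome import GeneModel, generate_ancestral_genome
from manihot.sim.mites import plant_mites


# --- upstream extraction -----------------------------------------------------


def test_plus_strand_window_arithmetic(rng):
    genome = dna.random_seq(10_000, rng)
    gene = GeneModel("g", 5_000, 5_300, "+")
    (region,) = extract_upstream([gene], genome, "x")
    assert (region.start, region.end) == (4_000, 5_000)
    assert np.array_equal(region.seq, genome[4_000:5_000])
    assert not region.truncated


def test_truncation_at_contig_edge(rng):
    genome = dna.random_seq(2_000, rng)
    gene = GeneModel("g", 300, 600, "+")
    (region,) = extract_upstream([gene], genome, "x")
    assert len(region) == 300 and region.truncated


def test_minus_strand_window_is_revcomp(rng):
    genome = dna.random_seq(10_000, rng)
    gene = GeneModel("g", 5_000, 5_300, "-")
    (region,) = extract_upstream([gene], genome, "x")
    assert (region.start, region.end) == (5_300, 6_300)
    assert np.array_equal(region.seq, dna.revcomp(genome[5_300:6_300]))


# --- structural detection ----------------------------------------------------


def _constructed_region(rng, tir_len=15, elem_len=200, at=400):
    """A 1-kb region with one planted element: TA + TIR..rc(TIR) + TA."""
    region = dna.random_seq(1000, rng)
    tir = dna.random_seq(tir_len, rng)
    body = dna.random_seq(elem_len - 2 * tir_len, rng)
    elem = np.concatenate([tir, body, dna.revcomp(tir)])
    ta = dna.encode("TA")
    region[at - 2 : at] = ta
    region[at + elem_len : at + elem_len + 2] = ta
    region[at : at + elem_len] = elem
    return region, at, at + elem_len


def test_planted_element_detected_at_exact_coordinates(rng):
    region, start, end = _constructed_region(rng)
    hits = detect_mites(region)
    assert any(h.start == start and h.end == end for h in hits)
    h = next(h for h in hits if h.start == start)
    assert h.tir_len >= 15 and h.tsd == "TA"


def test_candidate_without_tsd_rejected(rng):
    region, start, end = _constructed_region(rng)
    # destroy both TSD copies
    region[start - 2 : start] = dna.encode("CC")
    region[end : end + 2] = dna.encode("GG")
    hits = detect_mites(region)
    assert not any(abs(h.start - start) < 5 for h in hits)


def test_short_tir_rejected(rng):
    region, start, end = _constructed_region(rng, tir_len=6, elem_len=100)
    hits = detect_mites(region, min_tir=10)
    assert not any(abs(h.start - start) < 5 for h in hits)


def test_detector_cohort_precision_recall():
    """>= 0.9 precision and recall over a 100-window planted cohort,
    allowing boundary jitter up to the TSD length (palindromic TA motifs
    make the outermost TIR column ambiguous)."""
    cfg = SimulationConfig(genome_length=300_000, n_genes=100, gene_length=300)
    genome, genes = generate_ancestral_genome(cfg, stage_rng(21, "genome"))
    planted_genome, planted_genes, truth = plant_mites(
        genome, genes, stage_rng(21, "mites"), insertion_prob=1.0
    )
    regions = extract_upstream(planted_genes, planted_genome, "t")
    hits = detect_in_regions(regions)
    reg = {r.gene_id: r for r in regions}
    det = []
    for h in hits:
        r = reg[h.gene_id]
        gs, ge = (
            (r.start + h.start, r.start + h.end)
            if r.strand == "+"
            else (r.end - h.end, r.end - h.start)
        )
        det.append((h.gene_id, gs, ge))
    tr = [(t.gene_id, t.start, t.end) for t in truth[truth.note == ""].itertuples()]

    def matches(x, pool):
        return any(
            x[0] == y[0] and abs(x[1] - y[1]) <= 6 and abs(x[2] - y[2]) <= 6
            for y in pool
        )

    precision = sum(matches(d, tr) for d in det) / len(det)
    recall = sum(matches(t, det) for t in tr) / len(tr)
    assert precision >= 0.9
    assert recall >= 0.9


def test_false_call_rate_on_shuffled_sequence():
    """Dinucleotide-shuffled 1-kb windows: < 0.05 false calls per kb."""
    rng = np.random.default_rng(77)
    calls = 0
    n_kb = 1000
    for _ in range(n_kb):
        seq = dna.random_seq(1000, rng)
        pairs = seq[:1000].reshape(-1, 2)
        shuffled = pairs[rng.permutation(len(pairs))].reshape(-1)
        calls += len(detect_mites(shuffled))
    assert calls / n_kb < 0.05


# --- presence comparison -----------------------------------------------------


def test_presence_labels_shared_and_specific():
    cfg = SimulationConfig(genome_length=160_000, n_genes=50, gene_length=300)
    genome, genes = generate_ancestral_genome(cfg, stage_rng(22, "genome"))
    mrng = stage_rng(22, "mites")
    from manihot.sim.mites import make_element

    plan_a, plan_b, expect = {}, {}, {}
    for i, g in enumerate(genes):
        if i % 5 == 0:  # shared: same element at the homologous offset
            entry = (make_element(mrng)[0], mrng.random())
            plan_a[g.id] = entry
            plan_b[g.id] = entry
            expect[g.id] = "shared"
        elif i % 5 == 1:  # cultivar-specific
            plan_b[g.id] = (make_element(mrng)[0], mrng.random())
            expect[g.id] = "cult-specific"
    ga, genes_a, _ = plant_mites(genome, genes, stage_rng(23, "mites"), plan=plan_a)
    gb, genes_b, _ = plant_mites(genome, genes, stage_rng(24, "mites"), plan=plan_b)
    ra = extract_upstream(genes_a, ga, "wild")
    rb = extract_upstream(genes_b, gb, "cult")
    ia = detect_in_regions(ra)
    ib = detect_in_regions(rb)
    table = compare_presence(
        [(g.id, g.id) for g in genes],
        {r.gene_id: r for r in ra},
        {r.gene_id: r for r in rb},
        ia,
        ib,
        labels=("wild", "cult"),
    )
    by_gene = table.groupby("gene_a").label.agg(set).to_dict()
    n_shared = n_spec = 0
    for gid, want in expect.items():
        got = by_gene.get(gid, set())
        if want == "shared" and got == {"shared"}:
            n_shared += 1
        if want == "cult-specific" and got == {"cult-specific"}:
            n_spec += 1
    assert n_shared >= 0.9 * sum(v == "shared" for v in expect.values())
    assert n_spec >= 0.9 * sum(v == "cult-specific" for v in expect.values())


def test_presence_counts_exact_on_clean_cohort():
    """30 planted cultivar-specific + 20 shared -> exact label counts."""
    cfg = SimulationConfig(genome_length=180_000, n_genes=60, gene_length=300)
    genome, genes = generate_ancestral_genome(cfg, stage_rng(25, "genome"))
    mrng = stage_rng(25, "mites")
    from manihot.sim.mites import make_element

    plan_a, plan_b = {}, {}
    for i, g in enumerate(genes[:50]):
        entry = (make_element(mrng)[0], mrng.random())
        if i < 20:
            plan_a[g.id] = entry
            plan_b[g.id] = entry
        else:
            plan_b[g.id] = entry
    ga, genes_a, ta = plant_mites(genome, genes, stage_rng(26, "mites"), plan=plan_a)
    gb, genes_b, tb = plant_mites(genome, genes, stage_rng(27, "mites"), plan=plan_b)
    assert (ta.note == "").sum() == 20 and (tb.note == "").sum() == 50
    ra = extract_upstream(genes_a, ga, "a")
    rb = extract_upstream(genes_b, gb, "b")
    table = compare_presence(
        [(g.id, g.id) for g in genes],
        {r.gene_id: r for r in ra},
        {r.gene_id: r for r in rb},
        detect_in_regions(ra),
        detect_in_regions(rb),
        labels=("wild", "cult"),
    )
    spec_genes = set(table[table.label == "cult-specific"].gene_b)
    shared_genes = set(table[table.label == "shared"].gene_b)
    want_spec = {g.id for g in genes[20:50]}
    want_shared = {g.id for g in genes[:20]}
    assert len(spec_genes ^ want_spec) <= 2
    assert len(shared_genes ^ want_shared) <= 2


# --- differential expression -------------------------------------------------


def test_null_duplicated_columns_no_calls(rng):
    counts = pd.DataFrame(
        rng.poisson(200, size=(300, 4)),
        index=[f"g{i}" for i in range(300)],
        columns=["a", "b", "c", "d"],
    )
    dup = pd.concat([counts, counts], axis=1)
    dup.columns = [f"w{i}" for i in range(4)] + [f"c{i}" for i in range(4)]
    de = diff_expression(dup, ["w"] * 4 + ["c"] * 4)
    assert (de.call == "none").all()


def test_planted_suppression_called_lower(rng):
    ids = [f"g{i}" for i in range(200)]
    flags = [i < 20 for i in range(200)]
    counts, _ = simulate_expression(ids, flags, -2.0, 0.05, 5, rng, base_mean=400.0)
    de = diff_expression(counts, ["wild"] * 5 + ["cultivar"] * 5)
    called_lower = de.loc[[f"g{i}" for i in range(20)]].call == "lower"
    assert called_lower.mean() >= 0.9
    null_calls = (de.loc[[f"g{i}" for i in range(20, 200)]].call != "none").mean()
    assert null_calls <= 0.05


def test_type_one_error_controlled(rng):
    """Across null genes the significant fraction stays near alpha."""
    ids = [f"g{i}" for i in range(2000)]
    counts, _ = simulate_expression(ids, [False] * 2000, 0.0, 0.05, 5, rng)
    de = diff_expression(counts, ["w"] * 5 + ["c"] * 5, alpha=0.05)
    frac = (de.call != "none").mean()
    # BH on null data controls FDR; with no true positives nearly nothing passes
    assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 2000)


# --- association -------------------------------------------------------------


def test_association_counts_conserve(rng):
    ids = [f"g{i}" for i in range(100)]
    flags = [i < 10 for i in range(100)]
    counts, _ = simulate_expression(ids, flags, -2.0, 0.05, 5, rng)
    de = diff_expression(counts, ["w"] * 5 + ["c"] * 5)
    summary = associate([f"g{i}" for i in range(10)], de)
    assert summary.n_specific == 10
    assert summary.n_lower + summary.n_higher <= summary.n_specific
    assert summary.frac_lower == pytest.approx(summary.n_lower / 10)


def test_association_empty_summary():
    de = pd.DataFrame({"log2fc": [], "pvalue": [], "padj": [], "call": []})
    s = associate([], de)
    assert s.n_specific == 0 and s.frac_lower == 0.0


def test_permutation_detects_planted_association(rng):
    ids = [f"g{i}" for i in range(300)]
    flags = [i < 30 for i in range(300)]
    counts, _ = simulate_expression(ids, flags, -2.0, 0.05, 5, rng)
    de = diff_expression(counts, ["w"] * 5 + ["c"] * 5)
    p = association_permutation_pvalue(de, [f"g{i}" for i in range(30)], rng)
    assert p <= 0.01
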