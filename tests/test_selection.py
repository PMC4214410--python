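"""NG86 Ka/Ks, codon alignment, orthologue clustering, selection classes."""

import itertools
import warnings

import numpy as np
import pytest

from manihot import dna
from manihot.selection import (
    align_codons,
    alignment_score,
    classify_selection,
    codon_path_differences,
    codon_site_counts,
    compute_ka_ks,
    find_orthologues,
    ng86_site_counts,
    selection_scan,
)

# --- independent NG86 oracle -------------------------------------------------

_CODE = {
    c: a
    for c, a in __import__("manihot.dna", fromlist=["CODON_TABLE"]).CODON_TABLE.items()
}


def _oracle_sites(codon):
    """Per-codon synonymous site fraction by direct enumeration."""
    s = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _CODE[alt] == _CODE[codon]:
                s += 1 / 3
    return s


def _oracle_path_diffs(a, b):
    """Pathway-averaged (syn, nonsyn) differences by explicit enumeration,
    skipping stop-codon intermediates when possible."""
    diff = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, stop = a, 0, 0, False
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            stop = stop or _CODE[nxt] == "*"
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((stop, sd, nd))
    ok = [(s, n) for st, s, n in results if not st] or [
        (s, n) for _, s, n in results
    ]
    return sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok)


def test_site_counts_match_enumeration_oracle():
    for codon in dna.SENSE_CODONS:
        s, n = codon_site_counts(codon)
        assert s == pytest.approx(_oracle_sites(codon), abs=1e-12)
        assert s + n == pytest.approx(3.0)


def test_pathway_differences_match_oracle_all_pairs():
    """All 61x61 sense-codon pairs agree with the enumeration oracle to
    1e-9."""
    for a in dna.SENSE_CODONS:
        for b in dna.SENSE_CODONS:
            sd, nd = codon_path_differences(a, b)
            osd, ond = _oracle_path_diffs(a, b)
            assert abs(sd - osd) < 1e-9 and abs(nd - ond) < 1e-9
            ndiff = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(ndiff)


def test_ka_ks_matches_biopython_ng86(rng):
    """Whole-CDS Ka/Ks agrees with Biopython's independent NG86
    implementation on random diverged pairs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    sense = [c for c in dna.SENSE_CODONS]
    for trial in range(3):
        a = "ATG" + "".join(rng.choice(sense, 50))
        b = list(a)
        muts = 0
        while muts < 10:
            i = int(rng.integers(1, 51))
            pi = int(rng.integers(3))
            codon = "".join(b[3 * i : 3 * i + 3])
            cand = codon[:pi] + "ACGT"[int(rng.integers(4))] + codon[pi + 1 :]
            if cand != codon and cand not in dna.STOP_CODONS:
                b[3 * i + pi] = cand[pi]
                muts += 1
        b = "".join(b)
        cols = [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
        res = compute_ka_ks(cols)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert res.ka == pytest.approx(dn, abs=1e-9)
        assert res.ks == pytest.approx(ds, abs=1e-9)


# --- Ka/Ks basics ------------------------------------------------------------


def test_identical_sequences_zero():
    cols = [("GCT", "GCT"), ("AAA", "AAA"), ("CGA", "CGA")] * 4
    res = compute_ka_ks(cols)
    assert res.ka == 0.0 and res.ks == 0.0


def test_single_synonymous_difference_exact_value():
    """TTT->TTC (Phe->Phe): Ka = 0 and Ks equals the hand-derived
    JC-corrected value from the oracle counts."""
    cols = [("TTT", "TTT")] * 11 + [("TTT", "TTC")]
    res = compute_ka_ks(cols)
    assert res.ka == 0.0 and res.ks > 0.0
    S = sum(
        (_oracle_sites(a) + _oracle_sites(b)) / 2 for a, b in cols
    )
    ps = 1.0 / S
    expected = -0.75 * np.log(1 - 4 * ps / 3)
    assert res.ks == pytest.approx(expected, abs=1e-12)


def test_single_nonsynonymous_difference_sign():
    cols = [("GCT", "GCT")] * 11 + [("GCT", "GTT")]
    res = compute_ka_ks(cols)
    assert res.ks == 0.0 and res.ka > 0.0


def test_minimum_column_requirement():
    with pytest.raises(ValueError):
        compute_ka_ks([("ATG", "ATG")] * 9)


def test_symmetry_in_sequence_order(rng):
    sense = list(dna.SENSE_CODONS)
    cols = []
    for _ in range(40):
        a = sense[int(rng.integers(61))]
        pi = int(rng.integers(3))
        b = a[:pi] + "ACGT"[int(rng.integers(4))] + a[pi + 1 :]
        if b in dna.STOP_CODONS:
            b = a
        cols.append((a, b))
    r1 = compute_ka_ks(cols)
    r2 = compute_ka_ks([(b, a) for a, b in cols])
    assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
    assert r1.ks == pytest.approx(r2.ks, abs=1e-12)


# --- classification ----------------------------------------------------------


@pytest.mark.parametrize(
    "ka,ks,expected",
    [
        (0.3, 0.1, "positive"),
        (0.1, 0.3, "negative"),
        (0.0, 0.0, "no-divergence"),
        (0.0, 0.2, "Ks-only"),
        (0.2, 0.0, "Ka-only"),
        (0.205, 0.2, "neutral"),
        (0.3, 0.2, "positive"),
    ],
)
def test_classification_rules(ka, ks, expected):
    assert classify_selection(ka, ks) == expected


def test_classification_scale_free(rng):
    for _ in range(50):
        ka, ks = rng.uniform(0.01, 1.0, 2)
        c = rng.uniform(0.1, 10.0)
        assert classify_selection(ka, ks) == classify_selection(c * ka, c * ks)


# --- codon alignment ---------------------------------------------------------


def test_identical_cds_align_without_gaps():
    cds = "ATG" + "GCT" * 20 + "TAA"
    cols = align_codons(cds, cds)
    assert len(cols) == 21
    assert all(a == b for a, b in cols)


def test_inserted_codon_creates_single_gap():
    base = ["ATG"] + ["GAA", "CCT", "TGG", "TAT", "GGC", "AAA", "CAT", "CGA", "GAC", "TTG"] * 2
    a = "".join(base)
    b_codons = base[:7] + ["GTG"] + base[7:]
    b = "".join(b_codons)
    cols = align_codons(a, b)
    assert len(cols) == len(base)  # the inserted codon column is excluded


def test_alignment_score_matches_dp_oracle(rng):
    """Affine-gap protein alignment score equals an independent DP oracle on
    short pairs."""
    def oracle(p, q, blosum, open_=-11.0, ext=-1.0):
        n, m = len(p), len(q)
        NEG = -1e18
        M = np.full((n + 1, m + 1), NEG)
        X = np.full((n + 1, m + 1), NEG)  # gap in q
        Y = np.full((n + 1, m + 1), NEG)  # gap in p
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = open_ + (i - 1) * ext
        for j in range(1, m + 1):
            Y[0, j] = open_ + (j - 1) * ext
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = blosum[p[i - 1], q[j - 1]]
                M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
                X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
                Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
        return max(M[n, m], X[n, m], Y[n, m])

    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    sense = [c for c in dna.SENSE_CODONS]
    for _ in range(5):
        a = "ATG" + "".join(rng.choice(sense, int(rng.integers(8, 25))))
        b = "ATG" + "".join(rng.choice(sense, int(rng.integers(8, 25))))
        score = alignment_score(a, b)
        assert score == pytest.approx(oracle(dna.translate(a), dna.translate(b), blosum))


def test_low_identity_pair_skipped():
    rng = np.random.default_rng(0)
    sense = [c for c in dna.SENSE_CODONS]
    a = "ATG" + "".join(rng.choice(sense, 40))
    b = "ATG" + "".join(rng.choice(sense, 40))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cols = align_codons(a, b)
    # two random CDS usually fall under 30% identity; accept either outcome
    assert cols is None or len(cols) > 0


# --- orthologue clustering ---------------------------------------------------


def _cds(rng, n=40):
    sense = [c for c in dna.SENSE_CODONS]
    return "ATG" + "".join(rng.choice(sense, n)) + "TAA"


def test_shared_cluster_across_three_genomes(rng):
    cds = _cds(rng)
    sets = {"g1": {"a1": cds}, "g2": {"b1": cds}, "g3": {"c1": cds}}
    clusters = find_orthologues(sets)
    assert len(clusters) == 1
    cl = clusters[0]
    assert cl.copy_number == {"g1": 1, "g2": 1, "g3": 1}
    assert cl.status(["g1", "g2", "g3"]) == "shared"


def test_unique_gene_cluster(rng):
    sets = {"wild": {"w1": _cds(rng)}, "cult": {"c1": _cds(rng)}}
    clusters = find_orthologues(sets)
    stats = sorted(cl.status(["wild", "cult"]) for cl in clusters)
    assert stats == ["cult-unique", "wild-unique"]


def test_duplicated_gene_copy_number(rng):
    cds = _cds(rng)
    sets = {"wild": {"w1": cds}, "cult": {"c1": cds, "c2": cds}}
    clusters = find_orthologues(sets)
    assert len(clusters) == 1
    assert clusters[0].copy_number == {"wild": 1, "cult": 2}


def test_duplicate_ids_rejected(rng):
    cds = _cds(rng)
    with pytest.raises(ValueError):
        find_orthologues({"a": {"x": cds}, "b": {"x": cds}})


# --- selection scan ----------------------------------------------------------


def test_empty_scan_all_zero():
    records, counts = selection_scan([], "a", "b", {"a": {}, "b": {}})
    assert records == []
    assert all(v == 0 for v in counts.values())


def test_scan_conservation(small_genome, small_lineages):
    genome, genes = small_genome
    lp = small_lineages
    gene_sets = {
        "wild": {f"w_{g.id}": g.cds(lp.wild) for g in lp.wild_genes},
        "cultivar": {f"c_{g.id}": g.cds(lp.cultivar) for g in lp.cultivar_genes},
    }
    clusters = find_orthologues(gene_sets)
    records, counts = selection_scan(clusters, "wild", "cultivar", gene_sets)
    class_total = sum(
        counts[k]
        for k in ("positive", "negative", "neutral", "no-divergence", "Ka-only", "Ks-only")
    )
    assert class_total == len(records)
    assert class_total + counts["multi-copy"] + counts["not-paired"] + counts["skipped"] == len(clusters)
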