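"""Orthologue matching, NG86 Ka/Ks and selection classification.

Ka and Ks follow Nei–Gojobori (1986) counting: per-codon synonymous site
fractions, averaging of synonymous/nonsynonymous differences over all
minimal mutational pathways between two codons (pathways through stop
codons are excluded when any stop-free pathway exists), and Jukes–Cantor
correction of the difference proportions.  Changes creating a stop codon
count as nonsynonymous in the site fractions.

Orthologue clusters are built from reciprocal-best protein matches joined by
single linkage, with within-genome near-identical copies attached so that
copy-number variation is visible per cluster.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import dna

# ---------------------------------------------------------------------------
# NG86 counting


@cache
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = dna.CODON_TABLE[codon]
    if aa == "*":
        raise ValueError("site counts undefined for stop codons")
    s = 0.0
    for i in range(3):
        syn = 0
        for b in dna.BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if dna.CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """Total (synonymous, nonsynonymous) sites of an in-frame CDS,
    skipping stop codons."""
    S = N = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if dna.CODON_TABLE.get(codon, "*") == "*":
            continue
        s, n = codon_site_counts(codon)
        S += s
        N += n
    return S, N


@cache
def codon_path_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over minimal mutational pathways (stop-free when possible)."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if dna.CODON_TABLE[nxt] == "*":
                through_stop = True
            if dna.CODON_TABLE[nxt] == dna.CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    clean = [(s, n) for stop, s, n in paths if not stop]
    if not clean:
        clean = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a difference proportion."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    pn: float
    ps: float
    saturated: bool = False
    ks_undefined: bool = False

    def __iter__(self):
        return iter((self.ka, self.ks))


def compute_ka_ks(codon_pairs: list[tuple[str, str]]) -> KaKsResult:
    """NG86 Ka/Ks over an aligned list of codon column pairs.

    Columns containing gaps, ambiguity codes or stop codons must already be
    excluded (``align_codons`` does this).  Requires >= 10 codon columns.
    """
    if len(codon_pairs) < 10:
        raise ValueError("need at least 10 ungapped codon columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_path_differences(ca, cb)
        Sd += sd
        Nd += nd
    pn = Nd / N if N > 0 else 0.0
    if S <= 0:
        return KaKsResult(jukes_cantor(pn), float("nan"), N, S, pn, float("nan"), ks_undefined=True)
    ps = Sd / S
    saturated = ps >= 0.75 or pn >= 0.75
    ka = jukes_cantor(pn) if pn < 0.75 else float("nan")
    ks = jukes_cantor(ps) if ps < 0.75 else float("nan")
    return KaKsResult(ka, ks, N, S, pn, ps, saturated=saturated)


# ---------------------------------------------------------------------------
# codon-aware alignment

_aligner = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        _aligner = a
    return _aligner


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and dna.CODON_TABLE.get(cds[-3:]) == "*":
        return cds[:-3]
    return cds


def align_codons(cds_a: str, cds_b: str) -> list[tuple[str, str]] | None:
    """Codon alignment via global protein alignment back-translation.

    Returns codon column pairs with gap- or N-containing columns removed, or
    ``None`` (with a warning) when translated identity falls below 30%.
    """
    cds_a, cds_b = _strip_terminal_stop(cds_a), _strip_terminal_stop(cds_b)
    pa, pb = dna.translate(cds_a), dna.translate(cds_b)
    if "*" in pa or "*" in pb:
        raise ValueError("internal stop codon in CDS")
    aln = _protein_aligner().align(pa, pb)[0]
    cols: list[tuple[str, str]] = []
    ident = 0
    n_cols = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            n_cols += 1
            if pa[i] == pb[j]:
                ident += 1
            ca = cds_a[3 * i : 3 * i + 3]
            cb = cds_b[3 * j : 3 * j + 3]
            if "N" in ca or "N" in cb:
                continue
            cols.append((ca, cb))
    if n_cols == 0 or ident / n_cols < 0.30:
        warnings.warn("translated alignment identity < 30%; pair skipped")
        return None
    return cols


def alignment_score(cds_a: str, cds_b: str) -> float:
    """Global protein alignment score (affine gaps, BLOSUM62)."""
    pa, pb = dna.translate(_strip_terminal_stop(cds_a)), dna.translate(_strip_terminal_stop(cds_b))
    return float(_protein_aligner().score(pa, pb))


# ---------------------------------------------------------------------------
# selection classification


def classify_selection(ka: float, ks: float, tolerance: float = 0.1) -> str:
    """Selection class of one orthologue pair.

    Ka=Ks=0 -> ``no-divergence``; Ka=0,Ks>0 -> ``Ks-only``; Ka>0,Ks=0 ->
    ``Ka-only``; otherwise the ratio is compared with 1 within a relative
    tolerance (``neutral``) or falls ``positive`` / ``negative``.
    """
    if ka < 0 or ks < 0:
        raise ValueError("Ka and Ks must be >= 0")
    if ka == 0 and ks == 0:
        return "no-divergence"
    if ka == 0:
        return "Ks-only"
    if ks == 0:
        return "Ka-only"
    ratio = ka / ks
    if abs(ratio - 1.0) <= tolerance:
        return "neutral"
    return "positive" if ratio > 1.0 else "negative"


# ---------------------------------------------------------------------------
# orthologue clustering


@dataclass
class OrthologueCluster:
    """Matched gene models across genomes."""

    cluster_id: str
    members: dict[str, list[str]]  # genome label -> gene ids

    @property
    def copy_number(self) -> dict[str, int]:
        return {g: len(ids) for g, ids in self.members.items()}

    def status(self, genomes: list[str]) -> str:
        present = [g for g in genomes if self.members.get(g)]
        if len(present) == len(genomes):
            return "shared"
        if len(present) == 1:
            return f"{present[0]}-unique"
        return "partial"


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _identity_coverage(pa: str, pb: str) -> tuple[float, float]:
    aln = _protein_aligner().align(pa, pb)[0]
    ident = cols = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            cols += 1
            if pa[i] == pb[j]:
                ident += 1
    shorter = min(len(pa), len(pb))
    if shorter == 0:
        return 0.0, 0.0
    return (ident / shorter, cols / shorter)


def _seed_candidates(prots: dict[str, dict[str, str]], seed_len: int = 6) -> set[tuple]:
    """Pairs of genes sharing at least one exact protein seed word."""
    index: dict[str, list[tuple[str, str]]] = {}
    for genome, genes in prots.items():
        for gid, p in genes.items():
            for i in range(0, max(1, len(p) - seed_len + 1), 2):
                index.setdefault(p[i : i + seed_len], []).append((genome, gid))
    cands: set[tuple] = set()
    for hits in index.values():
        if len(hits) > 50:  # low-complexity word
            continue
        for a, b in itertools.combinations(hits, 2):
            if a != b:
                cands.add((min(a, b), max(a, b)))
    return cands


def find_orthologues(
    gene_sets: dict[str, dict[str, str]],
    min_identity: float = 0.35,
    min_coverage: float = 0.5,
) -> list[OrthologueCluster]:
    """Cluster genes across 2-3 genomes into orthologue groups.

    ``gene_sets`` maps genome label to ``{gene_id: CDS}``.  Cross-genome
    links require reciprocal best matches at the identity/coverage
    thresholds; within-genome links at the same thresholds attach duplicated
    copies.  Unmatched genes become singleton clusters.
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    all_ids = [gid for genes in gene_sets.values() for gid in genes]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("duplicate gene ids across gene sets")
    prots = {
        g: {gid: dna.translate(_strip_terminal_stop(cds)) for gid, cds in genes.items()}
        for g, genes in gene_sets.items()
    }
    cands = _seed_candidates(prots)
    scores: dict[tuple, tuple[float, float]] = {}
    for (ga, ia), (gb, ib) in cands:
        ident, cov = _identity_coverage(prots[ga][ia], prots[gb][ib])
        if ident >= min_identity and cov >= min_coverage:
            scores[((ga, ia), (gb, ib))] = (ident, cov)
    # reciprocal best across genomes
    best: dict[tuple, dict[str, tuple]] = {}
    for (a, b), (ident, _) in scores.items():
        if a[0] != b[0]:
            for x, y in ((a, b), (b, a)):
                cur = best.setdefault(x, {}).get(y[0])
                if cur is None or ident > cur[1] or (ident == cur[1] and y < cur[0]):
                    best[x][y[0]] = (y, ident)
    uf = _UnionFind()
    for genes in gene_sets.values():
        for gid in genes:
            uf.find(gid)
    for (a, b), (ident, _) in scores.items():
        if a[0] == b[0]:
            uf.union(a[1], b[1])  # within-genome duplicate
        else:
            if best.get(a, {}).get(b[0], (None,))[0] == b and best.get(b, {}).get(a[0], (None,))[0] == a:
                uf.union(a[1], b[1])
    groups: dict[str, list[tuple[str, str]]] = {}
    for genome, genes in gene_sets.items():
        for gid in genes:
            groups.setdefault(uf.find(gid), []).append((genome, gid))
    clusters = []
    for i, root in enumerate(sorted(groups)):
        members: dict[str, list[str]] = {g: [] for g in gene_sets}
        for genome, gid in sorted(groups[root]):
            members[genome].append(gid)
        clusters.append(OrthologueCluster(cluster_id=f"OC{i:05d}", members=members))
    return clusters


# ---------------------------------------------------------------------------
# genome-pair selection scan


@dataclass
class SelectionRecord:
    cluster_id: str
    gene_a: str
    gene_b: str
    ka: float
    ks: float
    ratio: float  # nan when undefined
    selection_class: str


def selection_scan(
    clusters: list[OrthologueCluster],
    genome_a: str,
    genome_b: str,
    gene_sets: dict[str, dict[str, str]],
    neutral_tolerance: float = 0.1,
) -> tuple[list[SelectionRecord], dict[str, int]]:
    """Ka/Ks selection classes over single-copy orthologue pairs.

    Clusters with exactly one member in each of the two genomes are scanned;
    multi-copy and partial clusters are tallied under ``multi-copy`` /
    ``not-paired``.  Returns per-cluster records and class counts.
    """
    records: list[SelectionRecord] = []
    counts = {
        "positive": 0,
        "negative": 0,
        "neutral": 0,
        "no-divergence": 0,
        "Ka-only": 0,
        "Ks-only": 0,
        "multi-copy": 0,
        "not-paired": 0,
        "skipped": 0,
    }
    for cl in clusters:
        ma = cl.members.get(genome_a, [])
        mb = cl.members.get(genome_b, [])
        if len(ma) == 0 or len(mb) == 0:
            counts["not-paired"] += 1
            continue
        if len(ma) > 1 or len(mb) > 1:
            counts["multi-copy"] += 1
            continue
        cds_a = gene_sets[genome_a][ma[0]]
        cds_b = gene_sets[genome_b][mb[0]]
        cols = align_codons(cds_a, cds_b)
        if cols is None or len(cols) < 10:
            counts["skipped"] += 1
            continue
        res = compute_ka_ks(cols)
        if res.saturated or np.isnan(res.ka) or np.isnan(res.ks):
            counts["skipped"] += 1
            continue
        cls = classify_selection(res.ka, res.ks, neutral_tolerance)
        ratio = res.ka / res.ks if res.ks > 0 else float("nan")
        records.append(
            SelectionRecord(cl.cluster_id, ma[0], mb[0], res.ka, res.ks, ratio, cls)
        )
        counts[cls] += 1
    return records, counts
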