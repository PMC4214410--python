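"""Planting MITEs into promoter windows.

A planted element follows the canonical structural model of a miniature
inverted-repeat transposable element: perfect terminal inverted repeats
(10-30 bp) around a random internal body (total length 50-800 bp), flanked
by a target-site duplication created from the host bases at the insertion
point (TA-dinucleotide sites preferred, as for Stowaway/Tourist-like
families).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .. import dna
from .genome import GeneModel

MITE_TRUTH_COLUMNS = [
    "gene_id",
    "start",
    "end",
    "element_len",
    "tir_len",
    "tsd",
    "note",
]


def make_element(
    rng: np.random.Generator,
    tir_range: tuple[int, int] = (10, 30),
    len_range: tuple[int, int] = (50, 800),
) -> tuple[np.ndarray, int]:
    """Random MITE body: TIR + internal + revcomp(TIR).  Returns the
    encoded element and its TIR length."""
    tir_len = int(rng.integers(tir_range[0], tir_range[1] + 1))
    total = int(rng.integers(max(len_range[0], 2 * tir_len + 4), len_range[1] + 1))
    tir = dna.random_seq(tir_len, rng)
    internal = dna.random_seq(total - 2 * tir_len, rng)
    return np.concatenate([tir, internal, dna.revcomp(tir)]), tir_len


def _upstream_span(gene: GeneModel, genome_len: int, window: int) -> tuple[int, int]:
    """Genomic span of the promoter window (strand-aware), truncated at the
    sequence edge."""
    if gene.strand == "+":
        return max(0, gene.start - window), gene.start
    return gene.end, min(genome_len, gene.end + window)


def _pick_insertion_site(
    genome: np.ndarray, lo: int, hi: int, tsd_len: int, rng: np.random.Generator
) -> int:
    """Insertion point inside [lo, hi): prefer a TA dinucleotide (the
    classical target site), else any position; returns the index of the
    first TSD base."""
    lo, hi = lo + 2, hi - tsd_len - 2
    if hi <= lo:
        return -1
    seg = genome[lo:hi]
    ta = np.flatnonzero((seg[:-1] == dna.T) & (seg[1:] == dna.A))
    if tsd_len == 2 and len(ta):
        return lo + int(ta[rng.integers(len(ta))])
    return lo + int(rng.integers(hi - lo))


def plant_mites(
    genome: np.ndarray,
    genes: list[GeneModel],
    rng: np.random.Generator,
    insertion_prob: float = 0.3,
    window: int = 1000,
    tsd_len: int = 2,
    plan: dict[str, tuple[np.ndarray, float]] | None = None,
) -> tuple[np.ndarray, list[GeneModel], pd.DataFrame]:
    """Insert MITEs into promoter windows of one genome.

    With probability ``insertion_prob`` per window the element is inserted
    after a target-site motif which is duplicated on both flanks.  An
    explicit ``plan`` of gene id -> (element, site fraction) overrides the
    random draws; planting the same plan entry into two genomes puts the
    element at the homologous window offset in both, which is how ancestral
    (shared) insertions are simulated.  Returns the modified genome, lifted
    gene models and a truth table in modified-genome coordinates.  Windows
    shorter than the element are skipped with a truth note.
    """
    if not 0 <= insertion_prob <= 1:
        raise ValueError("insertion_prob must lie in [0, 1]")
    placements = []  # (site, element, gene_id, tir_len)
    rows = []
    for gene in sorted(genes, key=lambda g: g.start):
        site_u = None
        if plan is not None:
            entry = plan.get(gene.id)
            if entry is None:
                continue
            element, site_u = entry
            tir_len = _infer_tir_len(element)
        else:
            if rng.random() >= insertion_prob:
                continue
            element, tir_len = make_element(rng)
        lo, hi = _upstream_span(gene, len(genome), window)
        if hi - lo < len(element):
            rows.append((gene.id, -1, -1, len(element), tir_len, "", "window-too-short"))
            continue
        # constrain the site so the element (plus flanking TSD copies) still
        # lies inside the 1-kb window measured from the *shifted* gene start
        if gene.strand == "+":
            lo2 = max(lo, hi + len(element) + tsd_len - window)
            hi2 = hi
        else:
            lo2 = lo
            hi2 = min(hi, lo + window - len(element) - 2 * tsd_len)
        if hi2 - lo2 < tsd_len + 6:
            rows.append((gene.id, -1, -1, len(element), tir_len, "", "window-too-short"))
            continue
        if site_u is not None:
            # planned placement at a fixed window fraction (homologous
            # offset across genomes); no target-site preference
            site = lo2 + 2 + int(site_u * (hi2 - lo2 - tsd_len - 4))
        else:
            site = _pick_insertion_site(genome, lo2, hi2, tsd_len, rng)
        if site < 0:
            rows.append((gene.id, -1, -1, len(element), tir_len, "", "window-too-short"))
            continue
        placements.append((site, element, gene.id, tir_len))

    placements.sort(key=lambda t: t[0])
    # splice in ascending site order, accumulating the coordinate shift
    parts = []
    cur = 0
    shift_at = []
    shifts = []
    total_shift = 0
    for site, element, gene_id, tir_len in placements:
        if site < cur:  # two promoter windows sharing the same span
            rows.append((gene_id, -1, -1, len(element), tir_len, "", "window-collision"))
            continue
        tsd = genome[site : site + tsd_len]
        parts.append(genome[cur : site + tsd_len])
        parts.append(element)
        parts.append(tsd)
        cur = site + tsd_len
        start_mod = site + tsd_len + total_shift  # element start in output
        rows.append(
            (
                gene_id,
                start_mod,
                start_mod + len(element),
                len(element),
                tir_len,
                dna.decode(tsd),
                "",
            )
        )
        total_shift += len(element) + tsd_len
        shift_at.append(cur)
        shifts.append(total_shift)
    parts.append(genome[cur:])
    new_genome = np.concatenate(parts) if parts else genome.copy()

    def lift(x: int) -> int:
        i = np.searchsorted(shift_at, x, side="right") - 1
        return x + (shifts[i] if i >= 0 else 0)

    new_genes = []
    for g in genes:
        ng = replace(g)
        ng.start, ng.end = lift(g.start), lift(g.end)
        new_genes.append(ng)
    truth = pd.DataFrame(rows, columns=MITE_TRUTH_COLUMNS)
    truth = truth.sort_values(["start", "gene_id"], kind="mergesort").reset_index(drop=True)
    return new_genome, new_genes, truth


def _infer_tir_len(element: np.ndarray) -> int:
    rc = dna.revcomp(element)
    n = 0
    half = len(element) // 2
    while n < half and element[n] == rc[n]:
        n += 1
    return n
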