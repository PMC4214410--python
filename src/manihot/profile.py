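"""K-mer genome profiling and variant discovery.

Covers the read-based side of the comparative analysis: canonical k-mer
spectra and the spectrum-based genome-size estimate, heterozygous SNV/InDel
calling from unique-seed pileups of a diploid's own reads, base-level
comparison of two diverged assemblies via unique-anchor chaining, and Venn
partitions of variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import edlib
import numpy as np
import pandas as pd

from . import dna
from .mapping import INDEL, OK, SINGLE, SeedIndex, map_reads
from .sim.reads import ReadPairs

# ---------------------------------------------------------------------------
# k-mer spectrum and genome size


@dataclass
class KmerSpectrum:
    k: int
    histogram: np.ndarray  # histogram[d] = number of distinct k-mers at depth d
    error_cutoff: int | None = None
    peak_depth: int | None = None

    def total_kmers(self, min_depth: int = 1) -> int:
        d = np.arange(len(self.histogram))
        return int((d[min_depth:] * self.histogram[min_depth:]).sum())


class SpectrumError(RuntimeError):
    """No usable homozygous peak in a k-mer spectrum."""


def _iter_read_blocks(reads) -> list[np.ndarray]:
    if isinstance(reads, np.ndarray):
        return [reads if reads.ndim == 2 else reads[None, :]]
    blocks = []
    for item in reads:
        if isinstance(item, ReadPairs):
            blocks.append(item.r1)
            blocks.append(item.r2)
        else:
            blocks.append(item if item.ndim == 2 else item[None, :])
    return blocks


def kmer_spectrum(reads, k: int = 17, chunk: int = 200_000) -> KmerSpectrum:
    """Depth histogram of distinct canonical k-mers over read sets.

    ``reads`` may be a 2-D encoded read array, a list of such arrays, or a
    list of :class:`ReadPairs`.  K-mers containing N are skipped.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    parts: list[np.ndarray] = []
    for block in _iter_read_blocks(reads):
        n, L = block.shape
        if L < k:
            raise ValueError("reads shorter than k")
        for lo in range(0, n, chunk):
            sub = block[lo : lo + chunk]
            m = sub.shape[0]
            codes = np.zeros((m, L - k + 1), dtype=np.uint64)
            a = sub.astype(np.uint64)
            for j in range(k):
                codes <<= np.uint64(2)
                codes |= a[:, j : j + L - k + 1] & np.uint64(3)
            flat = codes.ravel()
            hasn = sub >= 4
            if hasn.any():
                bad = np.zeros((m, L - k + 1), dtype=bool)
                for j in range(k):
                    bad |= hasn[:, j : j + L - k + 1]
                flat = flat[~bad.ravel()]
            parts.append(dna.canonical_codes(flat, k))
    if not parts:
        raise ValueError("no reads")
    allc = np.concatenate(parts)
    del parts
    allc.sort(kind="stable")
    boundaries = np.flatnonzero(np.diff(allc) != 0)
    counts = np.diff(np.concatenate([[-1], boundaries, [len(allc) - 1]]))
    hist = np.bincount(counts)
    hist[0] = 0
    return KmerSpectrum(k=k, histogram=hist)


@dataclass
class GenomeSizeEstimate:
    size_bp: float
    peak_depth: int  # modal histogram bin
    peak_refined: float  # centroid around the mode; used for the size
    error_cutoff: int
    het_peak_depth: int | None = None


def estimate_genome_size(spectrum: KmerSpectrum) -> GenomeSizeEstimate:
    """Genome size = (k-mer instances above the error cutoff) / peak depth.

    The error cutoff is the first local minimum of the depth histogram (1
    when the histogram rises monotonically, i.e. error-free reads); the peak
    is the modal depth above the cutoff, guarded so the cutoff is at most a
    third of the peak.  A half-depth heterozygous shoulder, when present as
    a distinct local maximum, is reported but never double-counted.
    """
    h = spectrum.histogram.astype(np.int64)
    if len(h) < 3 or h.sum() == 0:
        raise SpectrumError("empty spectrum")
    cutoff = 1
    if len(h) > 2 and h[1] > h[2]:
        d = 2
        while d + 1 < len(h) and h[d + 1] <= h[d]:
            d += 1
        if d + 1 >= len(h):
            raise SpectrumError("no local minimum: histogram decays monotonically")
        cutoff = d
    peak = int(cutoff + np.argmax(h[cutoff:]))
    if peak <= cutoff or h[peak] == 0:
        raise SpectrumError("no homozygous peak above the error cutoff")
    if cutoff > peak / 3:
        raise SpectrumError("error cutoff exceeds a third of the peak depth")
    total = spectrum.total_kmers(min_depth=cutoff)
    # integer-mode discretisation biases the size by up to half a depth
    # unit; a count-weighted centroid around the mode removes it
    lo, hi = max(cutoff, peak - 3), min(len(h), peak + 4)
    d = np.arange(lo, hi)
    peak_refined = float((d * h[lo:hi]).sum() / h[lo:hi].sum())
    size = total / peak_refined
    het = None
    half = peak // 2
    if half > cutoff + 1:
        lo, hi = max(cutoff + 1, half - peak // 6), half + peak // 6 + 1
        seg = h[lo:hi]
        if len(seg):
            cand = lo + int(np.argmax(seg))
            if 0 < cand < 0.75 * peak and h[cand] > h[(cand + peak) // 2]:
                het = cand
    spectrum.error_cutoff = cutoff
    spectrum.peak_depth = peak
    return GenomeSizeEstimate(
        size_bp=size,
        peak_depth=peak,
        peak_refined=peak_refined,
        error_cutoff=cutoff,
        het_peak_depth=het,
    )


# ---------------------------------------------------------------------------
# heterozygous variant calling from the individual's own reads


@dataclass
class RateSummary:
    snv_per_kb: float
    indel_per_kb: float
    callable_bp: int


VARIANT_CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "zygosity", "depth", "alt_fraction"]


def _gapped_pileup(
    ref: np.ndarray,
    oriented: np.ndarray,
    starts_left: np.ndarray,
    starts_right: np.ndarray,
    counts: np.ndarray,
    indel_votes: dict,
    pad: int = 12,
) -> None:
    """Edlib-refined pileup contribution of reads whose anchors disagree
    (putative InDel spanning reads)."""
    L = oriented.shape[1]
    for i in range(oriented.shape[0]):
        w0 = int(min(starts_left[i], starts_right[i])) - pad
        w1 = int(max(starts_left[i], starts_right[i])) + L + pad
        w0 = max(0, w0)
        w1 = min(len(ref), w1)
        query = dna.decode(oriented[i])
        target = dna.decode(ref[w0:w1])
        res = edlib.align(query, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["cigar"]:
            continue
        rpos = w0 + res["locations"][0][0]
        qpos = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            ln = int(num)
            num = ""
            if ch == "=" or ch == "X":
                block = oriented[i, qpos : qpos + ln]
                np.add.at(counts, (np.arange(rpos, rpos + ln), block), 1)
                rpos += ln
                qpos += ln
            elif ch == "I":  # bases present in read, absent from reference
                seq = dna.decode(oriented[i, qpos : qpos + ln])
                indel_votes[(rpos, "INS", seq)] = indel_votes.get((rpos, "INS", seq), 0) + 1
                qpos += ln
            elif ch == "D":
                seq = dna.decode(ref[rpos : rpos + ln])
                indel_votes[(rpos, "DEL", seq)] = indel_votes.get((rpos, "DEL", seq), 0) + 1
                rpos += ln


def call_het_variants(
    assembly: np.ndarray,
    read_sets: list[ReadPairs] | ReadPairs,
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
    max_alt_fraction: float = 0.8,
    max_indel_len: int = 10,
    k: int = 31,
    chrom: str = "chr1",
    chunk: int = 200_000,
) -> tuple[pd.DataFrame, RateSummary]:
    """Heterozygous SNV/InDel calls from the individual's own reads.

    Reads are placed by unique-seed anchors; anchor-consistent reads feed an
    ungapped pileup, anchor-inconsistent reads (InDel signal) are realigned
    with edlib and contribute gapped evidence.  A het SNV is a position with
    depth >= ``min_depth`` whose best non-reference allele has a fraction in
    [``min_alt_fraction``, ``max_alt_fraction``]; het InDels are called the
    same way from gapped-read votes.  Rates are per callable kb.
    """
    if isinstance(read_sets, ReadPairs):
        read_sets = [read_sets]
    index = SeedIndex.build(assembly, k=k)
    L_ref = len(assembly)
    counts = np.zeros((L_ref, 4), dtype=np.int32)
    indel_votes: dict = {}
    max_ungapped_mismatch = 6
    for rp in read_sets:
        for block in (rp.r1, rp.r2):
            n, L = block.shape
            for lo in range(0, n, chunk):
                sub = block[lo : lo + chunk]
                pl = map_reads(index, sub)
                ok = pl.status == OK
                if ok.any():
                    oriented = np.where(
                        pl.fwd[ok, None], sub[ok], dna.revcomp_rows(sub[ok])
                    )
                    pos = pl.start[ok][:, None] + np.arange(L)[None, :]
                    # an InDel between the outermost anchor and the read end
                    # leaves consistent diagonals but a misaligned segment:
                    # verify the whole read before trusting the placement
                    mism = (oriented != assembly[pos]).sum(axis=1)
                    clean = mism <= max_ungapped_mismatch
                    posc = pos[clean]
                    orc = oriented[clean]
                    flat = posc.ravel() * 4 + orc.ravel()
                    counts_flat = np.bincount(flat, minlength=L_ref * 4)
                    counts += counts_flat.reshape(L_ref, 4).astype(np.int32)
                    gap_mask = np.zeros(len(sub), dtype=bool)
                    gap_mask[np.flatnonzero(ok)[~clean]] = True
                else:
                    gap_mask = np.zeros(len(sub), dtype=bool)
                gap_mask |= (pl.status == INDEL) | (pl.status == SINGLE)
                if gap_mask.any():
                    oriented = np.where(
                        pl.fwd[gap_mask, None], sub[gap_mask], dna.revcomp_rows(sub[gap_mask])
                    )
                    _gapped_pileup(
                        assembly,
                        oriented,
                        pl.start[gap_mask],
                        pl.start_right[gap_mask],
                        counts,
                        indel_votes,
                    )
    depth = counts.sum(axis=1)
    callable_bp = int((depth >= min_depth).sum())
    if callable_bp == 0:
        raise RuntimeError("zero callable bases")
    ref_codes = assembly.astype(np.int64)
    nonref = counts.copy()
    nonref[np.arange(L_ref), ref_codes] = 0
    alt_code = nonref.argmax(axis=1)
    alt_count = nonref.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    snv_mask = (
        (depth >= min_depth)
        & (af >= min_alt_fraction)
        & (af <= max_alt_fraction)
        & (alt_count > 0)
    )
    rows = []
    bases = "ACGT"
    for p in np.flatnonzero(snv_mask):
        rows.append(
            (
                chrom,
                int(p),
                bases[ref_codes[p]],
                bases[alt_code[p]],
                "SNV",
                "het",
                int(depth[p]),
                float(af[p]),
            )
        )
    # gapped aligners place equivalent InDels at slightly different anchors;
    # merge votes of the same type within a small window before calling
    merged_votes: list[tuple[tuple[int, str, str], int]] = []
    for (p, vtype, seq), support in sorted(indel_votes.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2])):
        if merged_votes:
            (mp, mt, ms), msup = merged_votes[-1]
            if mt == vtype and abs(p - mp) <= 3:
                best = (p, vtype, seq) if support > msup else (mp, mt, ms)
                merged_votes[-1] = (best, msup + support)
                continue
        merged_votes.append(((p, vtype, seq), support))
    for (p, vtype, seq), support in merged_votes:
        if not 1 <= len(seq) <= max_indel_len:
            continue
        d = int(depth[p]) if p < L_ref else 0
        if d < min_depth:
            continue
        frac = support / d
        if min_alt_fraction <= frac <= max_alt_fraction:
            if vtype == "INS":
                rows.append((chrom, int(p), "", seq, "insertion", "het", d, float(frac)))
            else:
                rows.append((chrom, int(p), seq, "", "deletion", "het", d, float(frac)))
    calls = pd.DataFrame(rows, columns=VARIANT_CALL_COLUMNS)
    n_snv = int((calls.vtype == "SNV").sum())
    n_indel = len(calls) - n_snv
    summary = RateSummary(
        snv_per_kb=1000.0 * n_snv / callable_bp,
        indel_per_kb=1000.0 * n_indel / callable_bp,
        callable_bp=callable_bp,
    )
    return calls, summary


# ---------------------------------------------------------------------------
# assembly-vs-assembly comparison


def _lis_chain(q: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly increasing subsequence of ``q``."""
    import bisect

    tails: list[int] = []  # value of smallest tail per length
    tails_idx: list[int] = []
    prev = np.full(len(q), -1, dtype=np.int64)
    for i, v in enumerate(q):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    cur = tails_idx[-1] if tails_idx else -1
    while cur >= 0:
        out.append(cur)
        cur = prev[cur]
    return np.array(out[::-1], dtype=np.int64)


_seg_aligner = None


def _segment_aligner():
    """Affine-gap DNA aligner for inter-anchor segments; affine costs keep
    multi-base InDels as single contiguous events."""
    global _seg_aligner
    if _seg_aligner is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.match_score = 1.0
        a.mismatch_score = -2.0
        a.open_gap_score = -6.0
        a.extend_gap_score = -0.5
        a.mode = "global"
        _seg_aligner = a
    return _seg_aligner


def _segment_variants(rseg: str, qseg: str, r0: int, q0: int) -> list[tuple]:
    """Variant rows from a global affine-gap alignment of two segments."""
    rows: list[tuple] = []
    if rseg == qseg:
        return rows
    if len(rseg) == 0:
        if qseg:
            rows.append((r0, q0, "", qseg, "INS"))
        return rows
    if len(qseg) == 0:
        rows.append((r0, q0, rseg, "", "DEL"))
        return rows
    aln = _segment_aligner().align(rseg, qseg)[0]
    tb, qb = aln.aligned
    pt = pq = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        if ts > pt:
            rows.append((r0 + pt, q0 + pq, rseg[pt:ts], "", "DEL"))
        if qs > pq:
            rows.append((r0 + ts, q0 + pq, "", qseg[pq:qs], "INS"))
        for i in range(te - ts):
            if rseg[ts + i] != qseg[qs + i]:
                rows.append(
                    (r0 + ts + i, q0 + qs + i, rseg[ts + i], qseg[qs + i], "SNV")
                )
        pt, pq = te, qe
    if pt < len(rseg):
        rows.append((r0 + pt, q0 + pq, rseg[pt:], "", "DEL"))
    if pq < len(qseg):
        rows.append((r0 + len(rseg), q0 + pq, "", qseg[pq:], "INS"))
    return rows


COMPARISON_COLUMNS = ["pos", "qpos", "ref", "alt", "vtype"]


def compare_assemblies(
    query: np.ndarray,
    reference: np.ndarray,
    k: int = 31,
    anchor_spacing: int = 150,
) -> tuple[pd.DataFrame, RateSummary]:
    """Base-level variants between two collinear assemblies.

    K-mers unique in both genomes define anchors; a longest-increasing-
    subsequence chain keeps the collinear subset, and the inter-anchor
    segments are globally aligned (edlib) to yield SNVs and short InDels.
    Rates are normalised by aligned reference bases (anchored span).
    """
    cq, vq = dna.kmer_codes(query, k)
    cr, vr = dna.kmer_codes(reference, k)

    def _unique(codes, valid):
        v = np.flatnonzero(valid)
        c = codes[v]
        order = np.argsort(c, kind="stable")
        cs, ps = c[order], v[order]
        first = np.ones(len(cs), dtype=bool)
        first[1:] = cs[1:] != cs[:-1]
        last = np.ones(len(cs), dtype=bool)
        last[:-1] = cs[1:] != cs[:-1]
        u = first & last
        return cs[u], ps[u]

    ucq, upq = _unique(cq, vq)
    ucr, upr = _unique(cr, vr)
    common, iq, ir = np.intersect1d(ucq, ucr, return_indices=True)
    if len(common) == 0:
        import warnings

        warnings.warn("no shared unique anchors between assemblies")
        return (
            pd.DataFrame(columns=COMPARISON_COLUMNS),
            RateSummary(0.0, 0.0, 0),
        )
    qpos = upq[iq]
    rpos = upr[ir]
    order = np.argsort(rpos, kind="stable")
    qpos, rpos = qpos[order], rpos[order]
    # thin anchors to a minimum spacing along the reference
    keep = [0]
    last = rpos[0]
    for i in range(1, len(rpos)):
        if rpos[i] >= last + anchor_spacing:
            keep.append(i)
            last = rpos[i]
    qpos, rpos = qpos[np.array(keep)], rpos[np.array(keep)]
    chain = _lis_chain(qpos)
    qpos, rpos = qpos[chain], rpos[chain]

    rows: list[tuple] = []
    for i in range(len(rpos) - 1):
        r0, r1 = int(rpos[i] + k), int(rpos[i + 1])
        q0, q1 = int(qpos[i] + k), int(qpos[i + 1])
        if r1 < r0 or q1 < q0:  # overlapping anchors (closer than k)
            continue
        rows.extend(
            _segment_variants(
                dna.decode(reference[r0:r1]), dna.decode(query[q0:q1]), r0, q0
            )
        )
    calls = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    aligned_bp = int(rpos[-1] + k - rpos[0])
    n_snv = int((calls.vtype == "SNV").sum()) if len(calls) else 0
    n_ind = len(calls) - n_snv
    summary = RateSummary(
        snv_per_kb=1000.0 * n_snv / aligned_bp if aligned_bp else 0.0,
        indel_per_kb=1000.0 * n_ind / aligned_bp if aligned_bp else 0.0,
        callable_bp=aligned_bp,
    )
    return calls, summary


# ---------------------------------------------------------------------------
# Venn partition of variant sets


def variant_venn(
    variant_sets: dict[str, pd.DataFrame], position_tolerance: int = 0
) -> dict[frozenset, int]:
    """Partition counts over every intersection region of 2-3 variant sets.

    Variants are matched by (sequence, position, alleles); a positive
    tolerance first snaps same-allele variants within that distance onto a
    shared cluster position.  Region counts sum to the union cardinality.
    """
    keyed: dict[str, set] = {}
    if position_tolerance > 0:
        # cluster same-allele variants across sets by greedy position chaining
        pooled: list[tuple] = []
        for label, df in variant_sets.items():
            for r in df.itertuples():
                chrom = getattr(r, "chrom", "ref")
                pooled.append(((chrom, r.ref, r.alt), int(r.pos), label))
        pooled.sort(key=lambda t: (t[0], t[1]))
        keyed = {label: set() for label in variant_sets}
        cluster_id = -1
        prev_key, prev_pos = None, None
        for key, pos, label in pooled:
            if key != prev_key or pos - prev_pos > position_tolerance:
                cluster_id += 1
            keyed[label].add((key, cluster_id))
            prev_key, prev_pos = key, pos
    else:
        for label, df in variant_sets.items():
            s = set()
            for r in df.itertuples():
                chrom = getattr(r, "chrom", "ref")
                s.add((chrom, int(r.pos), r.ref, r.alt))
            keyed[label] = s
    labels = sorted(keyed)
    out: dict[frozenset, int] = {}
    universe = set().union(*keyed.values()) if keyed else set()
    for n in range(1, len(labels) + 1):
        for combo in combinations(labels, n):
            inside = set.intersection(*(keyed[l] for l in combo))
            outside = set().union(*(keyed[l] for l in labels if l not in combo)) if n < len(labels) else set()
            out[frozenset(combo)] = len(inside - outside)
    assert sum(out.values()) == len(universe)
    return out
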