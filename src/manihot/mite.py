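"""MITE detection in promoter windows and expression association.

The structural detector looks for the canonical MITE signature inside 1-kb
upstream regions: terminal inverted repeats (an exact >=``min_tir`` bp
complementary core at the element boundaries, extensible with a bounded
number of mismatches) flanked by a duplicated target-site motif, with the
element length in a plausible MITE range.  Cross-genome presence is decided
by matching flanking anchors of orthologous windows, and lineage-specific
insertions are tested for association with expression suppression via a
normalised t-type test with Benjamini-Hochberg correction and a label-
permutation contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import dna
from .sim.genome import GeneModel


@dataclass
class UpstreamRegion:
    """Promoter window, 5'->3' toward the gene start on the gene's strand."""

    gene_id: str
    genome: str
    seq: np.ndarray
    start: int  # genomic span (forward-strand coordinates)
    end: int
    strand: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.seq)


def extract_upstream(
    genes: list[GeneModel],
    genome: np.ndarray,
    genome_label: str = "",
    window: int = 1000,
) -> list[UpstreamRegion]:
    """Strand-aware promoter windows, truncated (and flagged) at edges."""
    out = []
    for g in genes:
        if not 0 <= g.start <= g.end <= len(genome):
            raise ValueError(f"gene {g.id} outside genome bounds")
        if g.strand == "+":
            lo, hi = max(0, g.start - window), g.start
            seq = genome[lo:hi].copy()
        else:
            lo, hi = g.end, min(len(genome), g.end + window)
            seq = dna.revcomp(genome[lo:hi])
        out.append(
            UpstreamRegion(
                gene_id=g.id,
                genome=genome_label,
                seq=seq,
                start=lo,
                end=hi,
                strand=g.strand,
                truncated=(hi - lo) < window,
            )
        )
    return out


# ---------------------------------------------------------------------------
# structural detection


@dataclass
class MITEInsertion:
    gene_id: str
    genome: str
    start: int  # within-region coordinates (0-based half-open)
    end: int
    tir_len: int
    tir_mismatches: int
    tsd: str


def _tir_stats(region: np.ndarray, x0: int, y0: int, max_mm: int, mismatch_penalty: int = 3) -> tuple[int, int]:
    """Extend the TIR inward from the element boundaries.

    Returns (tir_len, mismatches) of the best mismatch-penalised extension;
    mismatches beyond the exact core are tolerated only when compensated by
    extra matching length (score = matches - penalty * mismatches).
    """
    comp = 3 - region[x0 : x0 + (y0 - x0) // 2]
    other = region[y0 - len(comp) : y0][::-1]
    match = comp == other
    best_len, best_score, best_mm = 0, 0, 0
    mm = 0
    score = 0
    for i in range(len(match)):
        if match[i]:
            score += 1
        else:
            mm += 1
            if mm > max_mm:
                break
            score -= mismatch_penalty
        if score > best_score:
            best_score, best_len, best_mm = score, i + 1, mm
    return best_len, best_mm


def detect_mites(
    region: np.ndarray | UpstreamRegion,
    min_tir: int = 10,
    max_tir_mismatch: int = 2,
    len_range: tuple[int, int] = (50, 800),
    tsd_range: tuple[int, int] = (2, 10),
) -> list[MITEInsertion]:
    """Structural MITE candidates in one region.

    Candidate boundaries come from exact ``min_tir``-mer matches between the
    region and its reverse complement (the TIR core); a candidate is kept
    when the boundary-anchored TIR reaches ``min_tir`` net score with at
    most ``max_tir_mismatch`` mismatches, the element length is in range,
    and a duplicated target-site motif flanks both ends.  Overlapping
    candidates are resolved longest-TIR-first, then leftmost.
    """
    meta = None
    if isinstance(region, UpstreamRegion):
        meta = region
        region = region.seq
    L = len(region)
    lo_len, hi_len = len_range
    if L < lo_len:
        return []
    s = min_tir
    codes, valid = dna.kmer_codes(region, s)
    rc = dna.revcomp(region)
    rcodes, rvalid = dna.kmer_codes(rc, s)
    fwd: dict[int, list[int]] = {}
    for p in np.flatnonzero(valid):
        fwd.setdefault(int(codes[p]), []).append(int(p))
    # each seed match is a putative exact TIR core anchored at the element
    # boundaries: region[x0:x0+s] == revcomp(region[y0-s:y0])
    pairs: set[tuple[int, int]] = set()
    for m in np.flatnonzero(rvalid):
        for x in fwd.get(int(rcodes[m]), ()):
            y0 = L - int(m)
            x0 = int(x)
            if lo_len <= y0 - x0 <= hi_len and y0 <= L:
                pairs.add((x0, y0))
    candidates: list[MITEInsertion] = []
    for x0, y0 in sorted(pairs):
        tir_len, mm = _tir_stats(region, x0, y0, max_tir_mismatch)
        if tir_len - 3 * mm < min_tir:
            continue
        tsd = ""
        for t in range(tsd_range[1], tsd_range[0] - 1, -1):
            if x0 - t < 0 or y0 + t > L:
                continue
            if np.array_equal(region[x0 - t : x0], region[y0 : y0 + t]):
                tsd = dna.decode(region[x0 - t : x0])
                break
        if not tsd:
            continue
        candidates.append(
            MITEInsertion(
                gene_id=meta.gene_id if meta else "",
                genome=meta.genome if meta else "",
                start=x0,
                end=y0,
                tir_len=tir_len,
                tir_mismatches=mm,
                tsd=tsd,
            )
        )
    # non-overlap resolution: longest TIR, then leftmost
    candidates.sort(key=lambda c: (-c.tir_len, c.start, c.end))
    chosen: list[MITEInsertion] = []
    for c in candidates:
        if all(c.end <= o.start or c.start >= o.end for o in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


def detect_in_regions(regions: list[UpstreamRegion], **kwargs) -> list[MITEInsertion]:
    out = []
    for r in regions:
        out.extend(detect_mites(r, **kwargs))
    return out


# ---------------------------------------------------------------------------
# cross-genome presence


def compare_presence(
    gene_pairs: list[tuple[str, str]],
    regions_a: dict[str, UpstreamRegion],
    regions_b: dict[str, UpstreamRegion],
    insertions_a: list[MITEInsertion],
    insertions_b: list[MITEInsertion],
    flank_match: int = 20,
    max_flank_ed: int = 4,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Label each insertion in orthologous windows shared / genome-specific.

    An insertion is shared when the orthologous window carries an insertion
    whose upstream flanking anchor (``flank_match`` bp) aligns to this
    insertion's flank within ``max_flank_ed`` edits; otherwise it is
    specific to its genome.
    """
    by_gene_a: dict[str, list[MITEInsertion]] = {}
    for m in insertions_a:
        by_gene_a.setdefault(m.gene_id, []).append(m)
    by_gene_b: dict[str, list[MITEInsertion]] = {}
    for m in insertions_b:
        by_gene_b.setdefault(m.gene_id, []).append(m)
    rows = []
    for ga, gb in gene_pairs:
        ra, rb = regions_a.get(ga), regions_b.get(gb)
        ins_a = by_gene_a.get(ga, [])
        ins_b = by_gene_b.get(gb, [])
        matched_b: set[int] = set()
        for m in ins_a:
            shared = False
            if ra is not None and rb is not None:
                flank = ra.seq[max(0, m.start - flank_match) : m.start]
                for bi, mb in enumerate(ins_b):
                    if bi in matched_b:
                        continue
                    bflank = rb.seq[max(0, mb.start - flank_match) : mb.start]
                    if len(flank) == 0 or len(bflank) == 0:
                        continue
                    ed = edlib.align(dna.decode(flank), dna.decode(bflank), mode="NW")[
                        "editDistance"
                    ]
                    if ed <= max_flank_ed:
                        shared = True
                        matched_b.add(bi)
                        break
            rows.append(
                (ga, gb, labels[0], m.start, m.end, "shared" if shared else f"{labels[0]}-specific")
            )
        for bi, mb in enumerate(ins_b):
            if bi in matched_b:
                rows.append((ga, gb, labels[1], mb.start, mb.end, "shared"))
            else:
                rows.append((ga, gb, labels[1], mb.start, mb.end, f"{labels[1]}-specific"))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "genome", "start", "end", "label"]
    )


# ---------------------------------------------------------------------------
# differential expression


def _median_of_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalisation by the median-of-ratios method."""
    log_counts = np.log(counts.where(counts > 0))
    log_gm = log_counts.mean(axis=1)
    ok = np.isfinite(log_gm)
    if ok.sum() == 0:
        return counts.astype(float)
    sf = np.exp((log_counts.loc[ok].sub(log_gm[ok], axis=0)).median(axis=0))
    sf = sf / np.exp(np.log(sf).mean())
    return counts / sf


def diff_expression(
    counts: pd.DataFrame,
    groups: list[str] | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene expression contrast between two groups.

    Median-of-ratios normalisation, Welch t-test on log2(normalised + 1),
    Benjamini-Hochberg adjustment; the call is ``lower`` / ``higher`` (the
    second group relative to the first) at adjusted p <= alpha, else
    ``none``.
    """
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    if min((groups == g).sum() for g in names) < 2:
        raise ValueError("need >= 2 replicates per group")
    norm = _median_of_ratios(counts)
    logn = np.log2(norm + 1.0)
    a = logn.loc[:, groups == names[0]].to_numpy()
    b = logn.loc[:, groups == names[1]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    reject, padj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    call = np.where(~reject, "none", np.where(log2fc < 0, "lower", "higher"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": p,
            "padj": padj,
            "call": call,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# association


@dataclass
class AssociationSummary:
    n_specific: int
    n_lower: int
    n_higher: int
    frac_lower: float
    frac_higher: float
    alpha: float


def associate(
    specific_genes: list[str], de: pd.DataFrame, alpha: float = 0.05
) -> AssociationSummary:
    """Tally expression calls among genes carrying a lineage-specific
    promoter insertion."""
    sub = de.loc[[g for g in specific_genes if g in de.index]]
    n = len(sub)
    n_lower = int((sub.call == "lower").sum())
    n_higher = int((sub.call == "higher").sum())
    return AssociationSummary(
        n_specific=n,
        n_lower=n_lower,
        n_higher=n_higher,
        frac_lower=n_lower / n if n else 0.0,
        frac_higher=n_higher / n if n else 0.0,
        alpha=alpha,
    )


def association_permutation_pvalue(
    de: pd.DataFrame,
    specific_genes: list[str],
    rng: np.random.Generator,
    n_permutations: int = 199,
) -> float:
    """One-sided permutation p-value that genes with a lineage-specific
    insertion are called ``lower`` more often than a random gene set of the
    same size (insertion labels permuted over genes)."""
    flags = de.index.isin(specific_genes)
    k = int(flags.sum())
    if k == 0:
        return 1.0
    lower = (de.call == "lower").to_numpy()
    observed = lower[flags].mean()
    n = len(de)
    more_extreme = 0
    for _ in range(n_permutations):
        perm = rng.choice(n, size=k, replace=False)
        if lower[perm].mean() >= observed:
            more_extreme += 1
    return (1 + more_extreme) / (1 + n_permutations)
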