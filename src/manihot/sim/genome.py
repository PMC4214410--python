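"""Ancestral genome synthesis, diploid haplotypes and lineage divergence.

The simulated chromosome is a single sequence carrying non-overlapping
protein-coding genes, each guaranteed a promoter-sized clearance on its own
strand.  Within-individual heterozygosity (a second haplotype) and
between-lineage divergence (a wild and a cultivated descendant of one
ancestor) are planted as explicit event lists that double as truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .. import dna
from .config import SimulationConfig

#: minimum spacing enforced between planted events, > the longest InDel,
#: so that events never overlap and truth positions stay unambiguous
MIN_EVENT_SPACING = 13

MAX_INDEL_LEN = 10

VARIANT_COLUMNS = ["pos", "ref", "alt", "vtype", "lineage"]

#: target Ka/Ks planted for each selection regime
REGIME_TARGET = {"positive": 3.0, "negative": 0.2, "neutral": 1.0}


class CapacityError(ValueError):
    """Raised when genes cannot be packed into the requested genome."""


@dataclass
class GeneModel:
    """A coding gene: CDS span on the simulated chromosome."""

    id: str
    start: int  # 0-based, half-open span of the CDS in genome coordinates
    end: int
    strand: str
    regime: str | None = None

    def cds(self, genome: np.ndarray) -> str:
        seg = genome[self.start : self.end]
        if self.strand == "-":
            seg = dna.revcomp(seg)
        return dna.decode(seg)

    @property
    def length(self) -> int:
        return self.end - self.start


class CoordinateLift:
    """Piecewise-constant coordinate shift from a source genome to a
    descendant produced by :func:`apply_variants`."""

    def __init__(self, breakpoints: np.ndarray, shifts: np.ndarray):
        self._bp = breakpoints  # sorted source positions
        self._shift = shifts  # cumulative shift applying at/after each bp

    def __call__(self, pos):
        idx = np.searchsorted(self._bp, np.asarray(pos), side="right") - 1
        base = np.where(idx >= 0, self._shift[np.maximum(idx, 0)], 0)
        return np.asarray(pos) + base


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(columns=VARIANT_COLUMNS).astype(
        {"pos": int, "ref": str, "alt": str, "vtype": str, "lineage": str}
    )


def apply_variants(seq: np.ndarray, variants: pd.DataFrame) -> tuple[np.ndarray, CoordinateLift]:
    """Apply SNV/INS/DEL events (source coordinates, non-overlapping) to a
    sequence.  Insertions are placed before ``pos``; deletions remove
    ``len(ref)`` bases starting at ``pos``.  Returns the derived sequence and
    a lift mapping source coordinates to derived coordinates."""
    if len(variants) == 0:
        return seq.copy(), CoordinateLift(np.array([0]), np.array([0]))
    v = variants.sort_values("pos", kind="mergesort")
    out = seq.copy()
    snv = v[v.vtype == "SNV"]
    if len(snv):
        out[snv.pos.to_numpy()] = [dna.encode(a)[0] for a in snv.alt]
    indels = v[v.vtype != "SNV"]
    if len(indels) == 0:
        return out, CoordinateLift(np.array([0]), np.array([0]))
    parts: list[np.ndarray] = []
    bps: list[int] = [0]
    shifts: list[int] = [0]
    cur = 0
    shift = 0
    for row in indels.itertuples():
        if row.vtype == "INS":
            parts.append(out[cur : row.pos])
            parts.append(dna.encode(row.alt))
            cur = row.pos
            shift += len(row.alt)
            bps.append(row.pos)
            shifts.append(shift)
        elif row.vtype == "DEL":
            dl = len(row.ref)
            parts.append(out[cur : row.pos])
            cur = row.pos + dl
            shift -= dl
            bps.append(cur)
            shifts.append(shift)
        else:  # pragma: no cover - guarded upstream
            raise ValueError(f"unknown variant type {row.vtype}")
    parts.append(out[cur:])
    return np.concatenate(parts), CoordinateLift(np.array(bps), np.array(shifts))


# ---------------------------------------------------------------------------
# ancestral genome


def generate_ancestral_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[GeneModel]]:
    """Random chromosome with packed, clearance-separated ORFs.

    Every gene is a valid open reading frame (ATG start, sense codons, one
    terminal stop) on a random strand, and consecutive gene spans are
    separated by at least ``config.upstream_window`` bases so each promoter
    window is intergenic.
    """
    L, n, glen, w = (
        config.genome_length,
        config.n_genes,
        config.gene_length,
        config.upstream_window,
    )
    needed = n * (glen + w)
    if L < needed:
        raise CapacityError(
            f"genome of {L} bp cannot hold {n} genes of {glen} bp "
            f"with {w} bp clearance (needs {needed} bp)"
        )
    genome = dna.random_seq(L, rng)
    extra = L - needed
    # distribute the slack uniformly over the n+1 inter-gene gaps
    splits = rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1)))
    stops = sorted(dna.STOP_CODONS)
    sense = [c for c in dna.SENSE_CODONS]
    genes: list[GeneModel] = []
    cursor = 0
    n_mid = glen // 3 - 2
    for i in range(n):
        cursor += w + int(splits[i])
        start = cursor
        mid = rng.choice(len(sense), size=n_mid)
        cds = dna.START_CODON + "".join(sense[j] for j in mid) + stops[rng.integers(len(stops))]
        strand = "+" if rng.random() < 0.5 else "-"
        if i == n - 1 and int(splits[n]) < w:
            strand = "+"  # keep the trailing promoter window inside the genome
        seg = dna.encode(cds)
        if strand == "-":
            seg = dna.revcomp(seg)
        genome[start : start + glen] = seg
        genes.append(GeneModel(id=f"g{i:05d}", start=start, end=start + glen, strand=strand))
        cursor += glen
    return genome, genes


# ---------------------------------------------------------------------------
# event sampling helpers


def _spaced_positions(
    n: int, candidates: np.ndarray, rng: np.random.Generator, spacing: int = MIN_EVENT_SPACING
) -> np.ndarray:
    """Sample ``n`` positions from ``candidates`` with a minimum pairwise
    spacing, by rejection resampling."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n > len(candidates) // max(spacing, 1):
        raise ValueError("too many events for the available sequence")
    chosen = np.sort(rng.choice(candidates, size=n, replace=False))
    for _ in range(200):
        bad = np.zeros(len(chosen), dtype=bool)
        close = np.diff(chosen) < spacing
        bad[1:][close] = True
        if not bad.any():
            return chosen
        keep = chosen[~bad]
        extra = rng.choice(candidates, size=int(bad.sum()), replace=False)
        chosen = np.sort(np.unique(np.concatenate([keep, extra])))
        while len(chosen) < n:  # collapse of duplicate draws
            more = rng.choice(candidates, size=n - len(chosen), replace=False)
            chosen = np.sort(np.unique(np.concatenate([chosen, more])))
    raise RuntimeError("could not satisfy event spacing; sequence too dense")


def _random_snv_events(
    seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, str, str, str]]:
    events = []
    bases = "ACGT"
    offs = rng.integers(1, 4, size=len(positions))
    for p, o in zip(positions, offs):
        ref = int(seq[p])
        events.append((int(p), bases[ref], bases[(ref + int(o)) % 4], "SNV"))
    return events


def _random_indel_events(
    seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, str, str, str]]:
    events = []
    bases = "ACGT"
    for p in positions:
        length = int(min(MAX_INDEL_LEN, rng.geometric(0.45)))
        if rng.random() < 0.5:
            ins = "".join(bases[b] for b in rng.integers(0, 4, size=length))
            events.append((int(p), "", ins, "INS"))
        else:
            ref = dna.decode(seq[p : p + length])
            events.append((int(p), ref, "", "DEL"))
    return events


def make_diploid(
    haplotype: np.ndarray,
    het_snv_rate: float,
    het_indel_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Second haplotype of a diploid individual.

    Heterozygous SNVs and short InDels are planted at Poisson-distributed
    counts matching the per-kb rates; the returned truth table records every
    event in first-haplotype coordinates.
    """
    if het_snv_rate < 0 or het_indel_rate < 0:
        raise ValueError("rates must be >= 0")
    L = len(haplotype)
    n_snv = int(rng.poisson(L * het_snv_rate / 1000.0))
    n_ind = int(rng.poisson(L * het_indel_rate / 1000.0))
    candidates = np.arange(MIN_EVENT_SPACING, L - MIN_EVENT_SPACING)
    pos = _spaced_positions(n_snv + n_ind, candidates, rng)
    which = rng.permutation(n_snv + n_ind) < n_snv
    events = _random_snv_events(haplotype, pos[which], rng)
    events += _random_indel_events(haplotype, pos[~which], rng)
    truth = pd.DataFrame(events, columns=["pos", "ref", "alt", "vtype"])
    truth["lineage"] = "hap2"
    truth = truth.sort_values("pos", kind="mergesort").reset_index(drop=True)
    hap2, _ = apply_variants(haplotype, truth)
    return hap2, truth


# ---------------------------------------------------------------------------
# lineage divergence with selection regimes


def _site_counts(cds: str) -> tuple[float, float]:
    """NG86 synonymous / nonsynonymous site counts of one CDS (local import
    to avoid a module cycle)."""
    from ..selection import ng86_site_counts

    return ng86_site_counts(cds)


def _plant_coding_changes(
    cds: list[str],
    target_ratio: float,
    n_total: int,
    rng: np.random.Generator,
) -> tuple[list[str], int, int, bool]:
    """Rejection-sample ``n_total`` codon substitutions whose NG86-counted
    synonymous/nonsynonymous split matches ``target_ratio`` as closely as the
    integer quota allows.  Returns mutated codons, realized (na, ns) and a
    flag set when the quota could not be met (gene too short)."""
    S, A = 0.0, 0.0
    for c in cds:
        s, a = _site_counts_codon(c)
        S += s
        A += a

    def _jc(p: float) -> float:
        return -0.75 * np.log1p(-4.0 * p / 3.0)

    # search nearby totals for the integer (na, ns) split whose corrected
    # Ka/Ks lands closest to the target regime
    best = None
    n_total = min(n_total, max(2, len(cds) // 2))
    for n in range(max(2, n_total - 3), n_total + 4):
        if n > len(cds):
            continue
        for ns in range(1, n):
            na = n - ns
            ratio = _jc(na / A) / _jc(ns / S)
            score = abs(np.log(ratio / target_ratio))
            if best is None or score < best[0]:
                best = (score, na, ns)
    if best is None:
        return list(cds), 0, 0, True
    _, quota_na, quota_ns = best
    codons = list(cds)
    mutated: set[int] = set()  # one substitution per codon: NG86 counts stay exact
    na = ns = 0
    attempts = 0
    max_attempts = 400 * max(1, n_total)
    while (na < quota_na or ns < quota_ns) and attempts < max_attempts:
        attempts += 1
        ci = int(rng.integers(len(codons)))
        pi = int(rng.integers(3))
        if ci in mutated:
            continue
        codon = codons[ci]
        old = codon[pi]
        new = "ACGT"[int(rng.integers(4))]
        if new == old:
            continue
        cand = codon[:pi] + new + codon[pi + 1 :]
        if cand in dna.STOP_CODONS or codon == dna.START_CODON and ci == 0:
            continue
        syn = dna.CODON_TABLE[cand] == dna.CODON_TABLE[codon]
        if syn and ns < quota_ns:
            ns += 1
        elif not syn and na < quota_na:
            na += 1
        else:
            continue
        codons[ci] = cand
        mutated.add(ci)
    return codons, na, ns, (na < quota_na or ns < quota_ns)


def _site_counts_codon(codon: str) -> tuple[float, float]:
    from ..selection import codon_site_counts

    return codon_site_counts(codon)


@dataclass
class LineagePair:
    """A wild and a cultivated genome diverged from one ancestor, with truth."""

    ancestor: np.ndarray
    ancestor_genes: list[GeneModel]
    wild: np.ndarray
    wild_genes: list[GeneModel]
    cultivar: np.ndarray
    cultivar_genes: list[GeneModel]
    variant_truth: pd.DataFrame  # ancestor coordinates; lineage column
    gene_truth: pd.DataFrame


def diverge_lineages(
    ancestor: np.ndarray,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LineagePair:
    """Derive a wild and a cultivated genome from one ancestor.

    ``divergence_snv_rate`` is the genome-wide pairwise rate: coding
    substitutions planted under the selection regimes count toward it and
    the intergenic quota makes up the remainder.  Every event lands in
    exactly one lineage, so the wild-versus-cultivar difference density
    equals the configured per-kb rates.  InDels are intergenic to keep all
    reading frames intact.  A configurable fraction of genes is deleted in
    one lineage (presence/absence truth) or duplicated (copy-number truth).
    """
    L = len(ancestor)
    genes = [replace(g) for g in genes]
    # --- regime assignment
    order = rng.permutation(len(genes))
    regimes: list[str | None] = [None] * len(genes)
    cursor = 0
    for frac, regime in config.selection_profile:
        cnt = int(round(frac * len(genes)))
        for j in order[cursor : cursor + cnt]:
            regimes[j] = regime
        cursor += cnt
    for g, r in zip(genes, regimes):
        g.regime = r

    # --- coding substitutions (cultivar lineage)
    cult_events: list[tuple[int, str, str, str]] = []
    gene_rows = []
    n_coding_total = 0
    for g in genes:
        if g.regime is None:
            gene_rows.append((g.id, None, 0, 0, False))
            continue
        n_total = int(rng.poisson(config.coding_subs_per_gene))
        if n_total == 0:
            gene_rows.append((g.id, g.regime, 0, 0, False))
            continue
        # exclude the terminal stop codon from mutable codons
        codons = [g.cds(ancestor)[i : i + 3] for i in range(0, g.length - 3, 3)]
        new_codons, na, ns, skipped = _plant_coding_changes(
            codons, REGIME_TARGET[g.regime], n_total, rng
        )
        # convert codon-space substitutions back to genome coordinates
        for ci, (old, new) in enumerate(zip(codons, new_codons)):
            if old == new:
                continue
            for pi in range(3):
                if old[pi] == new[pi]:
                    continue
                if g.strand == "+":
                    gpos = g.start + 3 * ci + pi
                    ref, alt = old[pi], new[pi]
                else:
                    gpos = g.end - 1 - (3 * ci + pi)
                    ref = dna.revcomp_str(old[pi])
                    alt = dna.revcomp_str(new[pi])
                cult_events.append((gpos, ref, alt, "SNV"))
        n_coding_total += na + ns
        gene_rows.append((g.id, g.regime, na, ns, skipped))
    gene_truth = pd.DataFrame(
        gene_rows, columns=["gene_id", "regime", "na_planted", "ns_planted", "regime_skipped"]
    )

    # --- presence/absence and copy-number events
    pav_mask = rng.random(len(genes)) < config.pav_fraction
    cnv_mask = (rng.random(len(genes)) < config.cnv_fraction) & ~pav_mask
    pav_lineage = {}
    cnv_lineage = {}
    for i, g in enumerate(genes):
        if pav_mask[i]:
            pav_lineage[g.id] = "wild" if rng.random() < 0.5 else "cultivar"
        if cnv_mask[i]:
            cnv_lineage[g.id] = "wild" if rng.random() < 0.5 else "cultivar"
    gene_truth["pav_lineage"] = [pav_lineage.get(g.id, "") for g in genes]
    gene_truth["cnv_lineage"] = [cnv_lineage.get(g.id, "") for g in genes]

    # --- intergenic events
    genic = np.zeros(L, dtype=bool)
    for g in genes:
        genic[max(0, g.start - MIN_EVENT_SPACING) : g.end + MIN_EVENT_SPACING] = True
    genic[: MIN_EVENT_SPACING] = True
    genic[L - MIN_EVENT_SPACING :] = True
    intergenic = np.flatnonzero(~genic)
    n_snv_target = int(rng.poisson(L * config.divergence_snv_rate / 1000.0))
    n_snv_inter = max(0, n_snv_target - n_coding_total)
    n_ind = int(rng.poisson(L * config.divergence_indel_rate / 1000.0))
    pos = _spaced_positions(n_snv_inter + n_ind, intergenic, rng)
    which = rng.permutation(n_snv_inter + n_ind) < n_snv_inter
    inter_events = _random_snv_events(ancestor, pos[which], rng)
    inter_events += _random_indel_events(ancestor, pos[~which], rng)
    to_wild = rng.random(len(inter_events)) < 0.5

    wild_rows = [e for e, w in zip(inter_events, to_wild) if w]
    cult_rows = [e for e, w in zip(inter_events, to_wild) if not w] + cult_events
    wild_truth = pd.DataFrame(wild_rows, columns=["pos", "ref", "alt", "vtype"])
    wild_truth["lineage"] = "wild"
    cult_truth = pd.DataFrame(cult_rows, columns=["pos", "ref", "alt", "vtype"])
    cult_truth["lineage"] = "cultivar"
    variant_truth = (
        pd.concat([wild_truth, cult_truth], ignore_index=True)
        .sort_values("pos", kind="mergesort")
        .reset_index(drop=True)
    )

    out = {}
    for lineage, truth in (("wild", wild_truth), ("cultivar", cult_truth)):
        seq = ancestor.copy()
        lineage_genes = []
        # PAV: overwrite the lost gene's span with random sequence (length-
        # preserving so downstream coordinates stay comparable)
        for g in genes:
            if pav_lineage.get(g.id) == lineage:
                seq[g.start : g.end] = dna.random_seq(g.length, rng)
            else:
                lineage_genes.append(replace(g))
        seq, lift = apply_variants(seq, truth)
        for g in lineage_genes:
            g.start, g.end = int(lift(g.start)), int(lift(g.end))
        # CNV: append duplicated copies beyond the chromosome end
        total = len(seq)
        dup_parts = [seq]
        for g in genes:
            if cnv_lineage.get(g.id) == lineage and pav_lineage.get(g.id) != lineage:
                src = next((x for x in lineage_genes if x.id == g.id), None)
                if src is None:
                    continue
                cds_seq = dna.encode(src.cds(seq))
                dup_parts.append(dna.random_seq(500, rng))
                start = total + 500
                dup_parts.append(cds_seq)
                lineage_genes.append(
                    GeneModel(id=f"{g.id}_dup", start=start, end=start + len(cds_seq), strand="+", regime=g.regime)
                )
                total = start + len(cds_seq)
        seq = np.concatenate(dup_parts) if len(dup_parts) > 1 else seq
        out[lineage] = (seq, lineage_genes)

    return LineagePair(
        ancestor=ancestor,
        ancestor_genes=genes,
        wild=out["wild"][0],
        wild_genes=out["wild"][1],
        cultivar=out["cultivar"][0],
        cultivar_genes=out["cultivar"][1],
        variant_truth=variant_truth,
        gene_truth=gene_truth,
    )


# ---------------------------------------------------------------------------
# genome shredding (assembly-stage inputs)


def shred_overlapping(
    genome: np.ndarray, piece_len: int, overlap: int
) -> tuple[list[tuple[str, np.ndarray]], pd.DataFrame]:
    """Cut a genome into consecutive pieces with fixed suffix/prefix overlap
    (error-free contig input for the merge stage).  Returns contigs and a
    truth layout table."""
    if overlap >= piece_len:
        raise ValueError("overlap must be smaller than piece length")
    step = piece_len - overlap
    contigs = []
    rows = []
    i = 0
    start = 0
    while start < len(genome):
        end = min(len(genome), start + piece_len)
        contigs.append((f"frag{i:05d}", genome[start:end].copy()))
        rows.append((f"frag{i:05d}", start, end))
        if end == len(genome):
            break
        start += step
        i += 1
    return contigs, pd.DataFrame(rows, columns=["id", "start", "end"])


def shred_gapped(
    genome: np.ndarray,
    mean_len: int,
    sd_len: int,
    gap_mean: int,
    gap_sd: int,
    rng: np.random.Generator,
    big_gap_prob: float = 0.0,
    big_gap_mean: int = 0,
) -> tuple[list[tuple[str, np.ndarray]], pd.DataFrame]:
    """Cut a genome into ordered contigs separated by unsequenced gaps
    (scaffolding-stage input).  With probability ``big_gap_prob`` a gap is
    drawn around ``big_gap_mean`` instead — larger than any insert tier, so
    only map-guided ordering can bridge it.  The truth table records each
    contig's source interval; truth orientation is always '+'."""
    contigs = []
    rows = []
    pos = 0
    i = 0
    while pos < len(genome) - mean_len // 2:
        clen = max(200, int(rng.normal(mean_len, sd_len)))
        end = min(len(genome), pos + clen)
        cid = f"ctg{i:05d}"
        contigs.append((cid, genome[pos:end].copy()))
        rows.append((cid, pos, end))
        if big_gap_prob > 0 and rng.random() < big_gap_prob:
            gap = max(20, int(rng.normal(big_gap_mean, big_gap_mean / 10)))
        else:
            gap = max(20, int(rng.normal(gap_mean, gap_sd)))
        pos = end + gap
        i += 1
    return contigs, pd.DataFrame(rows, columns=["id", "start", "end"])
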