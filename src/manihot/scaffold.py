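"""Mate-pair scaffolding and physical-map-guided mega-scaffolding.

Scaffolds are built tier by tier from inward-oriented paired libraries,
smallest insert first, by greedy joining of unambiguous high-support end
links; a later tier never breaks an earlier join.  Scaffolds are then
ordered and oriented along map contigs of a clone-order (FPC-style)
physical map using BAC end reads, and emitted as pseudomolecules whose
scaffold joins are fixed 500-N gaps.  The conflict policy is
clone-map order > BAC links > mate-pair tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dna
from .mapping import OK, SINGLE, SeedIndex, map_reads
from .sim.reads import BacLibrary, ReadPairs

HEAD, TAIL = "H", "T"


@dataclass
class LinkBundle:
    """Aggregated read-pair evidence joining two oriented contig ends."""

    a_id: str
    a_end: str  # H(ead)=sequence start, T(ail)=sequence end
    b_id: str
    b_end: str
    support: int
    gap_estimate: float
    tier: str = ""


@dataclass
class Scaffold:
    """Ordered, oriented contigs with estimated gaps.

    ``parts`` holds (contig_id, orientation, gap_after_bp); the last part's
    gap is ignored.  Negative gap estimates are preserved here and clamped
    only at sequence emission.
    """

    id: str
    parts: list[tuple[str, str, float]]
    tier_history: list[str] = field(default_factory=list)

    def reverse(self) -> "Scaffold":
        new_parts = []
        n = len(self.parts)
        for i in range(n - 1, -1, -1):
            cid, orient, _ = self.parts[i]
            gap_after = self.parts[i - 1][2] if i > 0 else 0.0
            new_parts.append((cid, "-" if orient == "+" else "+", gap_after))
        return Scaffold(id=self.id, parts=new_parts, tier_history=list(self.tier_history))

    @property
    def contig_ids(self) -> list[str]:
        return [c for c, _, _ in self.parts]


@dataclass
class FPCMap:
    """Clone-order physical map: map contigs of ordered clone ids."""

    contigs: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mc, clones in self.contigs.items():
            for c in clones:
                if c in seen:
                    raise ValueError(f"clone {c} appears twice in the map")
                seen.add(c)

    def order_index(self) -> dict[str, tuple[str, int]]:
        out = {}
        for mc, clones in self.contigs.items():
            for i, c in enumerate(clones):
                out[c] = (mc, i)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FPCMap":
        contigs: dict[str, list[str]] = {}
        for mc, sub in df.sort_values("order_index").groupby("map_contig", sort=True):
            contigs[mc] = list(sub.clone_id)
        return cls(contigs=contigs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, mc, i)
            for mc, clones in self.contigs.items()
            for i, c in enumerate(clones)
        ]
        return pd.DataFrame(rows, columns=["clone_id", "map_contig", "order_index"])


def scaffold_sequence(
    scaffold: Scaffold, contigs: dict[str, np.ndarray], min_gap: int = 1
) -> np.ndarray:
    """Concatenated scaffold sequence with gaps printed as N runs
    (negative estimates clamped to ``min_gap``)."""
    parts = []
    for i, (cid, orient, gap) in enumerate(scaffold.parts):
        seq = contigs[cid]
        parts.append(dna.revcomp(seq) if orient == "-" else seq)
        if i < len(scaffold.parts) - 1:
            parts.append(np.full(max(min_gap, int(round(gap))), dna.N, dtype=np.uint8))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# link evidence


def collect_link_evidence(
    contigs: list[tuple[str, np.ndarray]],
    pairs: ReadPairs,
    tier: str = "",
    k: int = 31,
    chunk: int = 250_000,
    index: SeedIndex | None = None,
) -> list[LinkBundle]:
    """Aggregate mate pairs into oriented end-to-end link bundles.

    Reads are placed by unique seeds; a pair whose mates land on two
    different contigs votes for joining the contig ends the fragment runs
    off, with per-pair gap = insert mean - distance_a - distance_b.
    """
    if index is None:
        index = SeedIndex.build(contigs, k=k)
    lengths = index.lengths
    L = pairs.read_length
    votes: dict[tuple, list[float]] = {}
    n = len(pairs)
    for lo in range(0, n, chunk):
        p1 = map_reads(index, pairs.r1[lo : lo + chunk])
        p2 = map_reads(index, pairs.r2[lo : lo + chunk])
        good = (
            ((p1.status == OK) | (p1.status == SINGLE))
            & ((p2.status == OK) | (p2.status == SINGLE))
            & (p1.seq_idx != p2.seq_idx)
            & (p1.seq_idx >= 0)
            & (p2.seq_idx >= 0)
        )
        for i in np.flatnonzero(good):
            ends = []
            dists = []
            for pl in (p1, p2):
                si = int(pl.seq_idx[i])
                local = int(pl.start[i] - index.starts[si])
                if pl.fwd[i]:
                    # fragment continues to the right: links the tail
                    ends.append((index.ids[si], TAIL))
                    dists.append(int(lengths[si]) - local)
                else:
                    ends.append((index.ids[si], HEAD))
                    dists.append(local + L)
            gap = pairs.insert_mean - dists[0] - dists[1]
            # a true pair's implied gap is bounded by the insert geometry;
            # wildly negative or over-insert gaps are chimera/mismap noise
            if gap > pairs.insert_mean or gap < -(2 * L + 4 * pairs.insert_sd):
                continue
            (aid, aend), (bid, bend) = ends
            if (bid, bend) < (aid, aend):
                (aid, aend), (bid, bend) = (bid, bend), (aid, aend)
            votes.setdefault((aid, aend, bid, bend), []).append(gap)
    bundles = [
        LinkBundle(a, ae, b, be, len(g), float(np.mean(g)), tier)
        for (a, ae, b, be), g in sorted(votes.items())
    ]
    return bundles


def build_scaffold_graph(
    bundles: list[LinkBundle], min_support: int = 3
) -> list[LinkBundle]:
    """Filter bundles into scaffold-graph edges.

    Bundles below ``min_support`` are dropped; when several bundles link the
    same contig pair with incompatible end combinations, only the majority
    (highest-support) bundle survives.  Surviving edges are returned ranked
    by support (descending), ready for greedy joining.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    by_pair: dict[tuple, LinkBundle] = {}
    for b in bundles:
        if b.support < min_support:
            continue
        key = (b.a_id, b.b_id)
        cur = by_pair.get(key)
        if cur is None or b.support > cur.support:
            by_pair[key] = b
    edges = sorted(
        by_pair.values(), key=lambda b: (-b.support, b.a_id, b.a_end, b.b_id, b.b_end)
    )
    return edges


# ---------------------------------------------------------------------------
# greedy joining


def _greedy_join(
    scaffolds: list[Scaffold], edges: list[LinkBundle], tier: str
) -> tuple[list[Scaffold], list[str]]:
    """Join scaffolds along unambiguous, non-conflicting edges.

    Each scaffold end may be used once; edges creating cycles or touching an
    already-used end are rejected (logged).  Accepted edges are applied in
    support order, so a conflicting lower-support edge always loses.
    """
    log: list[str] = []
    by_id = {s.id: s for s in scaffolds}
    used_end: set[tuple[str, str]] = set()
    parent: dict[str, str] = {s.id: s.id for s in scaffolds}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted: list[LinkBundle] = []
    for e in edges:
        if e.a_id not in by_id or e.b_id not in by_id:
            log.append(f"reject {e.a_id}-{e.b_id}: unknown scaffold")
            continue
        ka, kb = (e.a_id, e.a_end), (e.b_id, e.b_end)
        if ka in used_end or kb in used_end:
            log.append(f"reject {e.a_id}{e.a_end}-{e.b_id}{e.b_end}: end already joined")
            continue
        if find(e.a_id) == find(e.b_id):
            log.append(f"reject {e.a_id}-{e.b_id}: would close a cycle")
            continue
        used_end.add(ka)
        used_end.add(kb)
        parent[find(e.a_id)] = find(e.b_id)
        accepted.append(e)

    # build adjacency over ends and walk linear chains
    adj: dict[tuple[str, str], tuple[str, str, float]] = {}
    for e in accepted:
        adj[(e.a_id, e.a_end)] = (e.b_id, e.b_end, e.gap_estimate)
        adj[(e.b_id, e.b_end)] = (e.a_id, e.a_end, e.gap_estimate)
    visited: set[str] = set()
    out: list[Scaffold] = []

    def other_end(end: str) -> str:
        return HEAD if end == TAIL else TAIL

    for s in scaffolds:
        if s.id in visited:
            continue
        # find a chain terminus: walk left from this scaffold
        cur, entry = s.id, HEAD
        seen_walk = {s.id}
        while (cur, entry) in adj:
            nxt_id, nxt_end, _ = adj[(cur, entry)]
            if nxt_id in seen_walk:
                break
            cur, entry = nxt_id, other_end(nxt_end)
            seen_walk.add(cur)
        # cur's `entry` side is free: chain starts here
        chain: list[tuple[str, str, float]] = []  # (scaffold_id, enter_end, gap_before)
        chain.append((cur, entry, 0.0))
        visited.add(cur)
        while (cur, other_end(entry)) in adj:
            nxt_id, nxt_end, gap = adj[(cur, other_end(entry))]
            if nxt_id in visited:
                break
            chain.append((nxt_id, nxt_end, gap))
            visited.add(nxt_id)
            cur, entry = nxt_id, nxt_end
        if len(chain) == 1:
            out.append(by_id[cur])
            continue
        parts: list[tuple[str, str, float]] = []
        hist: list[str] = []
        for i, (sid, enter, gap_before) in enumerate(chain):
            sc = by_id[sid]
            oriented = sc if enter == HEAD else sc.reverse()
            if i > 0 and parts:
                cid, orient, _ = parts[-1]
                parts[-1] = (cid, orient, gap_before)
            parts.extend(oriented.parts)
            hist.extend(oriented.tier_history)
        out.append(
            Scaffold(id=chain[0][0], parts=parts, tier_history=sorted(set(hist + [tier])))
        )
    return out, log


def hierarchical_scaffold(
    contigs: list[tuple[str, np.ndarray]],
    tier_reads: list[ReadPairs],
    min_support: int = 3,
    k: int = 31,
) -> tuple[list[Scaffold], list[str]]:
    """Scaffold contigs tier by tier, smallest insert first.

    Every contig appears in exactly one output scaffold (singletons
    included).  Tiers must be supplied sorted by ascending insert size; each
    tier links the *current* scaffolds, so later (larger-insert) tiers can
    only bridge across earlier joins, never undo them.
    """
    means = [rp.insert_mean for rp in tier_reads]
    if means != sorted(means):
        raise ValueError("tiers must be sorted by ascending insert size")
    contig_dict = {cid: seq for cid, seq in contigs}
    scaffolds = [Scaffold(id=cid, parts=[(cid, "+", 0.0)]) for cid, _ in contigs]
    log: list[str] = []
    for rp in tier_reads:
        seqs = [(s.id, scaffold_sequence(s, contig_dict)) for s in scaffolds]
        bundles = collect_link_evidence(seqs, rp, tier=rp.tier, k=k)
        if not bundles:
            log.append(f"tier {rp.tier}: zero mapped linking pairs")
        edges = build_scaffold_graph(bundles, min_support=min_support)
        scaffolds, tier_log = _greedy_join(scaffolds, edges, rp.tier)
        log.extend(f"tier {rp.tier}: {m}" for m in tier_log)
    return scaffolds, log


# ---------------------------------------------------------------------------
# mega-scaffolding along the clone-order map


@dataclass
class MegaScaffold:
    id: str
    components: list[tuple[Scaffold, str]]  # (scaffold, orientation)
    map_contig: str | None = None


def mega_scaffold(
    scaffolds: list[Scaffold],
    contigs: dict[str, np.ndarray],
    bac: BacLibrary,
    fpc: FPCMap,
    k: int = 31,
    min_clone_hits: int = 1,
) -> tuple[list[MegaScaffold], list[str]]:
    """Order and orient scaffolds along the physical map.

    Each scaffold is assigned to the map contig contributing the majority of
    its BAC-end hits, ordered by the median clone order index, and oriented
    by the sign of the correlation between hit position and clone order.
    BAC links between scaffolds are validated against the resulting order;
    contradicting links are rejected (the map wins).  Unplaced scaffolds
    pass through as singleton mega-scaffolds.
    """
    log: list[str] = []
    seqs = [(s.id, scaffold_sequence(s, contigs)) for s in scaffolds]
    index = SeedIndex.build(seqs, k=k)
    order_of = fpc.order_index()
    # clone end hits per scaffold: (position in scaffold, map contig, order)
    hits: dict[str, list[tuple[float, str, int]]] = {s.id: [] for s in scaffolds}
    clone_scaffolds: dict[str, set[str]] = {}
    for end_block in (bac.end1, bac.end2):
        pl = map_reads(index, end_block)
        for i in np.flatnonzero((pl.status == OK) | (pl.status == SINGLE)):
            cid = bac.clone_ids[i]
            if cid not in order_of:
                continue
            si = int(pl.seq_idx[i])
            sid = index.ids[si]
            local = float(pl.start[i] - index.starts[si])
            mc, oi = order_of[cid]
            hits[sid].append((local, mc, oi))
            clone_scaffolds.setdefault(cid, set()).add(sid)
    placed: dict[str, tuple[str, float, str]] = {}  # sid -> (map contig, median order, orient)
    for s in scaffolds:
        h = hits[s.id]
        if len(h) < min_clone_hits:
            log.append(f"{s.id}: unplaced (no clone hits)")
            continue
        mc_votes: dict[str, int] = {}
        for _, mc, _ in h:
            mc_votes[mc] = mc_votes.get(mc, 0) + 1
        top = sorted(mc_votes.items(), key=lambda t: (-t[1], t[0]))
        if len(top) > 1 and top[0][1] == top[1][1]:
            log.append(f"{s.id}: unplaced (tied between map contigs {top[0][0]}/{top[1][0]})")
            continue
        mc = top[0][0]
        sub = [(local, oi) for local, m, oi in h if m == mc]
        med = float(np.median([oi for _, oi in sub]))
        orient = "+"
        if len(sub) >= 3:
            x = np.array([l for l, _ in sub])
            y = np.array([oi for _, oi in sub], dtype=float)
            if np.std(x) > 0 and np.std(y) > 0:
                r = np.corrcoef(x, y)[0, 1]
                if r < -0.3:  # weak correlations keep the default
                    orient = "-"
        placed[s.id] = (mc, med, orient)

    # validate BAC links (two ends on different scaffolds) against map order
    for cid in sorted(clone_scaffolds):
        pair = sorted(clone_scaffolds[cid])
        if len(pair) != 2:
            continue
        a, b = pair
        if a in placed and b in placed:
            mca, oa, _ = placed[a]
            mcb, ob, _ = placed[b]
            if mca != mcb:
                log.append(f"bac link {cid} ({a}-{b}): rejected, spans map contigs")
    by_mc: dict[str, list[tuple[float, str]]] = {}
    for sid, (mc, med, orient) in placed.items():
        by_mc.setdefault(mc, []).append((med, sid))
    sdict = {s.id: s for s in scaffolds}
    megas: list[MegaScaffold] = []
    for i, mc in enumerate(sorted(by_mc)):
        comps = []
        for med, sid in sorted(by_mc[mc], key=lambda t: (t[0], t[1])):
            comps.append((sdict[sid], placed[sid][2]))
        megas.append(MegaScaffold(id=f"MS{i:04d}", components=comps, map_contig=mc))
    n = len(megas)
    for s in scaffolds:
        if s.id not in placed:
            megas.append(MegaScaffold(id=f"MS{n:04d}", components=[(s, "+")], map_contig=None))
            n += 1
    return megas, log


# ---------------------------------------------------------------------------
# pseudomolecule emission and stats

PSEUDOMOLECULE_GAP = 500


def emit_pseudomolecule(
    mega: MegaScaffold,
    contigs: dict[str, np.ndarray],
    gap_len: int = PSEUDOMOLECULE_GAP,
    min_gap: int = 1,
    name: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pseudomolecule sequence plus its AGP v2.1 table.

    Consecutive scaffolds are joined by exactly ``gap_len`` N bases;
    within-scaffold evidence gaps keep their (clamped) estimated size and are
    written as linkage gaps.  The AGP reconstructs the sequence exactly.
    """
    if not mega.components:
        raise ValueError("empty mega-scaffold")
    name = name or mega.id
    rows = []
    parts = []
    pos = 0  # 0-based running length
    part_no = 0

    def add_component(cid: str, orient: str) -> None:
        nonlocal pos, part_no
        seq = contigs[cid]
        part_no += 1
        rows.append(
            (name, pos + 1, pos + len(seq), part_no, "W", cid, 1, len(seq), orient)
        )
        parts.append(dna.revcomp(seq) if orient == "-" else seq)
        pos += len(seq)

    def add_gap(n: int, gap_type: str, linkage: str, evidence: str) -> None:
        nonlocal pos, part_no
        part_no += 1
        rows.append((name, pos + 1, pos + n, part_no, "N", n, gap_type, linkage, evidence))
        parts.append(np.full(n, dna.N, dtype=np.uint8))
        pos += n

    for ci, (scaf, sorient) in enumerate(mega.components):
        sc = scaf.reverse() if sorient == "-" else scaf
        for pi, (cid, orient, gap) in enumerate(sc.parts):
            add_component(cid, orient)
            if pi < len(sc.parts) - 1:
                add_gap(max(min_gap, int(round(gap))), "scaffold", "yes", "paired-ends")
        if ci < len(mega.components) - 1:
            add_gap(gap_len, "contig", "no", "na")
    agp = pd.DataFrame(
        rows,
        columns=[
            "object",
            "object_beg",
            "object_end",
            "part_number",
            "component_type",
            "component_id",
            "component_beg",
            "component_end",
            "orientation",
        ],
    )
    return np.concatenate(parts), agp


def reconstruct_from_agp(agp: pd.DataFrame, contigs: dict[str, np.ndarray]) -> np.ndarray:
    """Rebuild a pseudomolecule sequence from its AGP rows."""
    parts = []
    for r in agp.itertuples():
        if r.component_type == "W":
            seq = contigs[r.component_id][int(r.component_beg) - 1 : int(r.component_end)]
            parts.append(dna.revcomp(seq) if r.orientation == "-" else seq)
        else:
            parts.append(np.full(int(r.component_id), dna.N, dtype=np.uint8))
    return np.concatenate(parts)


@dataclass
class AssemblyStats:
    total_bp: int
    contig_count: int
    n50: int
    non_gapped_fraction: float


def assembly_stats(seqs: list[np.ndarray]) -> AssemblyStats:
    """N50 and gap statistics of a sequence set."""
    if not seqs:
        raise ValueError("empty sequence set")
    lengths = np.sort(np.array([len(s) for s in seqs]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2.0)])
    non_n = sum(int((s != dna.N).sum()) for s in seqs)
    return AssemblyStats(
        total_bp=total,
        contig_count=len(seqs),
        n50=n50,
        non_gapped_fraction=non_n / total if total else 0.0,
    )
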