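"""Hybrid contig-set integration: redundancy filtering and OLC merging.

Two contig sets (long-read-derived and short-read-derived assemblies of the
same genome) are integrated by (1) discarding secondary contigs already
contained in the primary set and (2) merging contigs connected by
unambiguous suffix-prefix (dovetail) overlaps, overlap-layout-consensus
style.  Overlap discovery is seed-and-extend: shared fixed-size k-mers
propose a dovetail shift which is verified by edit-distance alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from . import dna

HEAD, TAIL = "H", "T"


@dataclass
class Contig:
    id: str
    seq: np.ndarray
    source: str = ""
    mean_depth: float | None = None

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"empty contig {self.id}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Overlap:
    """Dovetail overlap joining ``a_end`` of contig a to ``b_end`` of b.

    ``orientation`` is ``same`` when both contigs overlap on the same
    strand (tail-to-head) and ``reverse`` when one must be flipped
    (tail-tail or head-head).  Records are canonical: ``a_id < b_id``.
    """

    a_id: str
    b_id: str
    a_end: str
    b_end: str
    orientation: str
    length: int
    identity: float


def _seed_index(contigs: list[Contig], k: int, max_occ: int = 50) -> dict[int, list[tuple[int, int]]]:
    index: dict[int, list[tuple[int, int]]] = {}
    for ci, c in enumerate(contigs):
        codes, valid = dna.kmer_codes(c.seq, k)
        for p in np.flatnonzero(valid):
            code = int(codes[p])
            lst = index.get(code)
            if lst is None:
                index[code] = [(ci, int(p))]
            elif len(lst) <= max_occ:
                lst.append((ci, int(p)))
    return {c: l for c, l in index.items() if len(l) <= max_occ}


def _identity_of(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    ed = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - ed / max(len(a), len(b))


# ---------------------------------------------------------------------------
# redundancy filtering


@dataclass
class FilterDecision:
    contig_id: str
    removed: bool
    best_primary: str | None
    identity: float


def filter_redundant_contigs(
    primary: list[Contig],
    secondary: list[Contig],
    min_identity: float = 0.95,
    min_containment: float = 0.90,
    k: int = 15,
) -> tuple[list[Contig], list[FilterDecision]]:
    """Drop secondary contigs contained in the primary set.

    A secondary contig is removed when it aligns (infix, either strand) to a
    primary contig with effective identity >= ``min_identity`` over at least
    ``min_containment`` of its length — assessed as edit distance <=
    ``len * (1 - min_identity * min_containment)`` of the full contig against
    its best seed-supported primary candidate.  Decisions are logged with
    the best hit.  An empty primary set retains everything.
    """
    if not 0 < min_identity <= 1 or not 0 < min_containment <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    decisions: list[FilterDecision] = []
    if not primary:
        for c in secondary:
            decisions.append(FilterDecision(c.id, False, None, 0.0))
        return list(secondary), decisions
    index = _seed_index(primary, k)
    retained = []
    for c in secondary:
        candidates: dict[int, int] = {}
        for query in (c.seq, dna.revcomp(c.seq)):
            codes, valid = dna.kmer_codes(query, k)
            for p in np.flatnonzero(valid)[::3]:
                for ci, _ in index.get(int(codes[p]), ()):
                    candidates[ci] = candidates.get(ci, 0) + 1
        best_id = None
        best_ident = 0.0
        q = dna.decode(c.seq)
        qr = dna.revcomp_str(q)
        for ci, _votes in sorted(candidates.items(), key=lambda t: -t[1])[:3]:
            target = dna.decode(primary[ci].seq)
            for qq in (q, qr):
                res = edlib.align(qq, target, mode="HW")
                if res["editDistance"] < 0:
                    continue
                ident = 1.0 - res["editDistance"] / len(qq)
                if ident > best_ident:
                    best_ident, best_id = ident, primary[ci].id
        removed = best_ident >= min_identity * min_containment
        decisions.append(FilterDecision(c.id, removed, best_id, best_ident))
        if not removed:
            retained.append(c)
    return retained, decisions


# ---------------------------------------------------------------------------
# overlap discovery


def compute_overlaps(
    contigs: list[Contig],
    min_overlap_len: int = 50,
    max_error_rate: float = 0.02,
    k: int = 15,
) -> list[Overlap]:
    """All dovetail (suffix-prefix) overlaps of length >= ``min_overlap_len``
    with error <= ``max_error_rate``, both strands, stored once per pair of
    oriented ends in canonical id order."""
    if min_overlap_len < k:
        raise ValueError("min_overlap_len must be >= seed size")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids")
    index = _seed_index(contigs, k)
    # candidate shifts per (i, j, orientation); i < j
    votes: dict[tuple[int, int, str], dict[int, int]] = {}
    for cj, c in enumerate(contigs):
        for strand in ("+", "-"):
            query = c.seq if strand == "+" else dna.revcomp(c.seq)
            codes, valid = dna.kmer_codes(query, k)
            for p in np.flatnonzero(valid):
                for ci, q in index.get(int(codes[p]), ()):
                    if ci == cj:
                        continue
                    # shift of query start relative to contigs[ci] start
                    shift = int(q) - int(p)
                    if ci < cj:
                        key = (ci, cj, "same" if strand == "+" else "reverse")
                        d = shift
                    else:
                        if strand == "+":
                            key = (cj, ci, "same")
                            d = -shift
                        else:
                            # rc(c_cj) at shift s on c_ci  <=>  rc(c_ci) at
                            # shift s + len_cj - len_ci on c_cj
                            key = (cj, ci, "reverse")
                            d = shift + len(contigs[cj]) - len(contigs[ci])
                    votes.setdefault(key, {}).setdefault(d, 0)
                    votes[key][d] += 1
    overlaps: dict[tuple, Overlap] = {}
    for (i, j, orient), ds in votes.items():
        a, b = contigs[i], contigs[j]
        bseq = b.seq if orient == "same" else dna.revcomp(b.seq)
        for d, _cnt in sorted(ds.items(), key=lambda t: -t[1])[:4]:
            # b (oriented) starts at offset d on a's coordinates
            if d > 0:
                olen = min(len(a) - d, len(bseq))
                a_sub, b_sub = a.seq[d : d + olen], bseq[:olen]
                a_end = TAIL
                b_entry = HEAD  # entering b at its oriented start
            elif d < 0:
                olen = min(len(bseq) + d, len(a))
                a_sub, b_sub = a.seq[:olen], bseq[-d : -d + olen]
                a_end = HEAD
                b_entry = TAIL
            else:
                continue  # containment / identical start: not a dovetail
            if olen < min_overlap_len or olen >= len(a) or olen >= len(bseq):
                continue
            ed = edlib.align(dna.decode(a_sub), dna.decode(b_sub), mode="NW")["editDistance"]
            if ed > max_error_rate * olen:
                continue
            b_end = b_entry if orient == "same" else (TAIL if b_entry == HEAD else HEAD)
            key = (a.id, b.id, a_end, b_end)
            ov = Overlap(a.id, b.id, a_end, b_end, orient, int(olen), 1.0 - ed / olen)
            cur = overlaps.get(key)
            if cur is None or ov.identity > cur.identity or (
                ov.identity == cur.identity and ov.length > cur.length
            ):
                overlaps[key] = ov
    return sorted(overlaps.values(), key=lambda o: (o.a_id, o.b_id, o.a_end, o.b_end))


# ---------------------------------------------------------------------------
# overlap-layout-consensus merge


def _consensus_join(
    left: np.ndarray,
    right: np.ndarray,
    olen: int,
    depth_left: float,
    depth_right: float,
) -> np.ndarray:
    """Join two oriented sequences over an overlap of ``olen`` columns.

    Disagreeing overlap columns take the base of the deeper contig, then the
    lexicographically smaller base — deterministic majority-of-two.
    """
    l_ov = left[len(left) - olen :]
    r_ov = right[:olen]
    if depth_left > depth_right:
        cons = l_ov
    elif depth_right > depth_left:
        cons = r_ov
    else:
        cons = np.minimum(l_ov, r_ov)
    return np.concatenate([left[: len(left) - olen], cons, right[olen:]])


def olc_merge(
    contigs: list[Contig], overlaps: list[Overlap]
) -> tuple[list[Contig], list[str]]:
    """Merge maximal unambiguous overlap chains.

    An overlap edge is usable only when both contig ends it joins have no
    other incident overlap (degree one): branch points are never merged
    through.  Cycles among unambiguous edges are broken at the lowest-
    identity overlap.  Total merged length equals the summed contig lengths
    minus the used overlap lengths.
    """
    log: list[str] = []
    by_id = {c.id: c for c in contigs}
    degree: dict[tuple[str, str], int] = {}
    for ov in overlaps:
        degree[(ov.a_id, ov.a_end)] = degree.get((ov.a_id, ov.a_end), 0) + 1
        degree[(ov.b_id, ov.b_end)] = degree.get((ov.b_id, ov.b_end), 0) + 1
    usable = [
        ov
        for ov in overlaps
        if degree[(ov.a_id, ov.a_end)] == 1 and degree[(ov.b_id, ov.b_end)] == 1
    ]
    # break cycles: union-find, reject the weakest edge closing a loop
    usable.sort(key=lambda o: (-o.identity, -o.length, o.a_id, o.b_id))
    parent = {c.id: c.id for c in contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted = []
    for ov in usable:
        if find(ov.a_id) == find(ov.b_id):
            log.append(
                f"cycle broken at {ov.a_id}-{ov.b_id} (identity {ov.identity:.4f})"
            )
            continue
        parent[find(ov.a_id)] = find(ov.b_id)
        accepted.append(ov)
    adj: dict[tuple[str, str], tuple[str, str, int]] = {}
    for ov in accepted:
        adj[(ov.a_id, ov.a_end)] = (ov.b_id, ov.b_end, ov.length)
        adj[(ov.b_id, ov.b_end)] = (ov.a_id, ov.a_end, ov.length)

    def other(end: str) -> str:
        return HEAD if end == TAIL else TAIL

    visited: set[str] = set()
    merged: list[Contig] = []
    for c in contigs:
        if c.id in visited:
            continue
        # walk to a terminus
        cur, entry = c.id, HEAD
        seen = {cur}
        while (cur, entry) in adj:
            nid, nend, _ = adj[(cur, entry)]
            if nid in seen:
                break
            cur, entry = nid, other(nend)
            seen.add(cur)
        chain: list[tuple[str, str, int]] = [(cur, entry, 0)]
        visited.add(cur)
        while (cur, other(entry)) in adj:
            nid, nend, olen = adj[(cur, other(entry))]
            if nid in visited:
                break
            chain.append((nid, nend, olen))
            visited.add(nid)
            cur, entry = nid, nend
        if len(chain) == 1:
            merged.append(c)
            continue
        seq = None
        depth = 0.0
        names = []
        for cid, enter, olen in chain:
            part = by_id[cid]
            oriented = part.seq if enter == HEAD else dna.revcomp(part.seq)
            names.append(cid)
            pd_ = part.mean_depth or 0.0
            if seq is None:
                seq = oriented.copy()
                depth = pd_
            else:
                seq = _consensus_join(seq, oriented, olen, depth, pd_)
                depth = max(depth, pd_)
        merged.append(
            Contig(id=f"merge_{names[0]}", seq=seq, source="merged", mean_depth=depth or None)
        )
        log.append(f"merged {len(names)} contigs: {'+'.join(names)}")
    return merged, log
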