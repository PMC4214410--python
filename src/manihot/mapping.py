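"""Unique exact-seed read placement.

Reads are located on a reference by 31-mer anchors that are unique in the
reference across both strands (canonical-k-mer uniqueness).  Three anchor
columns per read (left, middle, right) give strand, a diagonal consistency
check, and an InDel signal when the left and right diagonals disagree.
The mapper is deterministic and fully vectorised; it deliberately has no
scoring model — ambiguous or unanchored reads are simply dropped, which is
the conservative choice for evidence collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dna

#: placement status codes
UNMAPPED, OK, INDEL, SINGLE = 0, 1, 2, 3


@dataclass
class SeedIndex:
    """Canonical-unique k-mer index over a set of sequences."""

    ids: list[str]
    lengths: np.ndarray
    starts: np.ndarray  # global start of each sequence in the concatenation
    k: int
    _codes: np.ndarray  # sorted canonical codes, unique across both strands
    _pos: np.ndarray  # global position of each unique k-mer
    _fwd: np.ndarray  # True where the genome k-mer equals its canonical form

    @classmethod
    def build(cls, seqs: list[tuple[str, np.ndarray]] | np.ndarray, k: int = 31) -> "SeedIndex":
        if isinstance(seqs, np.ndarray):
            seqs = [("seq0", seqs)]
        ids = [s[0] for s in seqs]
        lengths = np.array([len(s[1]) for s in seqs], dtype=np.int64)
        sep = np.array([dna.N], dtype=np.uint8)
        chunks = []
        starts = np.zeros(len(seqs), dtype=np.int64)
        pos = 0
        for i, (_, arr) in enumerate(seqs):
            starts[i] = pos
            chunks.append(arr)
            pos += len(arr)
            if i < len(seqs) - 1:
                chunks.append(sep)
                pos += 1
        concat = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
        codes, valid = dna.kmer_codes(concat, k)
        ccodes = dna.canonical_codes(codes, k)
        vpos = np.flatnonzero(valid)
        vc = ccodes[vpos]
        order = np.argsort(vc, kind="stable")
        vc_s = vc[order]
        vpos_s = vpos[order]
        # canonical k-mers occurring exactly once across both strands
        is_first = np.ones(len(vc_s), dtype=bool)
        is_first[1:] = vc_s[1:] != vc_s[:-1]
        is_last = np.ones(len(vc_s), dtype=bool)
        is_last[:-1] = vc_s[1:] != vc_s[:-1]
        uniq = is_first & is_last
        upos = vpos_s[uniq]
        ucodes = vc_s[uniq]
        ufwd = codes[upos] == ucodes
        return cls(
            ids=ids,
            lengths=lengths,
            starts=starts,
            k=k,
            _codes=ucodes,
            _pos=upos,
            _fwd=ufwd,
        )

    def locate(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Look up raw (forward) k-mer codes.

        Returns ``(hit, gpos, fwd)``: whether the k-mer is a unique anchor,
        its global position, and whether the query matches the reference
        forward strand there.
        """
        cc = dna.canonical_codes(codes, self.k)
        idx = np.searchsorted(self._codes, cc)
        idx = np.minimum(idx, len(self._codes) - 1) if len(self._codes) else idx
        hit = len(self._codes) > 0
        if not hit:
            z = np.zeros(len(codes), dtype=bool)
            return z, np.zeros(len(codes), dtype=np.int64), z
        hitm = self._codes[idx] == cc
        gpos = np.where(hitm, self._pos[idx], -1)
        fwd = np.where(hitm, self._fwd[idx], False) == (codes == cc)
        return hitm, gpos, fwd

    def to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global concatenation position -> (sequence index, local offset)."""
        si = np.searchsorted(self.starts, gpos, side="right") - 1
        return si, gpos - self.starts[si]


@dataclass
class Placements:
    """Vectorised read placements (global reference coordinates)."""

    status: np.ndarray  # UNMAPPED / OK / INDEL / SINGLE
    fwd: np.ndarray  # read aligns to the forward strand
    start: np.ndarray  # footprint start (left-anchor diagonal)
    start_right: np.ndarray  # right-anchor diagonal (== start unless INDEL)
    seq_idx: np.ndarray  # reference sequence index (-1 if unmapped)


def map_reads(
    index: SeedIndex, reads: np.ndarray, offsets: tuple[int, ...] | None = None
) -> Placements:
    """Place a (n, L) block of encoded reads on the reference.

    Each anchor offset contributes a (strand, diagonal) vote; reads whose
    anchors disagree on strand are dropped, equal diagonals give ``OK``,
    differing left/right diagonals give ``INDEL`` (a gapped aligner should
    refine those), and a lone anchor gives ``SINGLE``.
    """
    n, L = reads.shape
    k = index.k
    if offsets is None:
        offsets = (0, (L - k) // 2, L - k)
    offsets = tuple(sorted(set(o for o in offsets if 0 <= o <= L - k)))
    m = len(offsets)
    hits = np.zeros((m, n), dtype=bool)
    diags = np.zeros((m, n), dtype=np.int64)
    fwds = np.zeros((m, n), dtype=bool)
    for j, o in enumerate(offsets):
        codes = dna.row_kmer_code(reads, o, k)
        hit, gpos, fwd = index.locate(codes)
        hits[j] = hit
        fwds[j] = fwd
        # forward: read offset o sits at gpos -> footprint start gpos - o
        # reverse: the read's reverse complement carries this k-mer at
        # offset L-k-o, so the footprint starts at gpos - (L-k-o)
        diags[j] = np.where(fwd, gpos - o, gpos - (L - k - o))
    nhit = hits.sum(axis=0)
    status = np.full(n, UNMAPPED, dtype=np.int8)
    start = np.full(n, -1, dtype=np.int64)
    start_r = np.full(n, -1, dtype=np.int64)
    fwd_out = np.zeros(n, dtype=bool)

    any_hit = nhit > 0
    # strand consensus: all hitting anchors must agree
    n_fwd = (hits & fwds).sum(axis=0)
    agree = any_hit & ((n_fwd == nhit) | (n_fwd == 0))
    fwd_out[agree] = n_fwd[agree] > 0

    big = np.int64(1) << 60
    d_min = np.where(hits, diags, big).min(axis=0)
    d_max = np.where(hits, diags, -big).max(axis=0)
    single = agree & (nhit == 1)
    multi = agree & (nhit >= 2)
    same = multi & (d_min == d_max)
    diff = multi & (d_min != d_max)
    status[single] = SINGLE
    status[same] = OK
    status[diff] = INDEL
    start[agree] = d_min[agree]
    # leftmost/rightmost *hitting* anchor diagonals for the INDEL case
    first_j = np.argmax(hits, axis=0)
    last_j = m - 1 - np.argmax(hits[::-1], axis=0)
    rows = np.arange(n)
    start[agree] = diags[first_j[agree], rows[agree]]
    start_r[agree] = diags[last_j[agree], rows[agree]]

    # bounds: footprint must stay within one reference sequence
    mapped = status > 0
    si = np.full(n, -1, dtype=np.int64)
    if mapped.any():
        s_i, local = index.to_local(start[mapped])
        ok_bounds = (local >= 0) & (local + L <= index.lengths[s_i])
        mm = np.flatnonzero(mapped)
        bad = mm[~ok_bounds]
        status[bad] = UNMAPPED
        si[mm[ok_bounds]] = s_i[ok_bounds]
    return Placements(status=status, fwd=fwd_out, start=start, start_right=start_r, seq_idx=si)
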