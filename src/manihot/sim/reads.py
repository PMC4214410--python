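"""Paired-read and BAC/FPC resource simulation.

Read pairs are drawn uniformly from the two haplotypes of a diploid (or a
single haplotype), in inward orientation with normally distributed insert
sizes, a uniform per-base error rate and optional chimeric pairs.  BAC
clones emulate a large-insert library whose two Sanger-style end reads and
clone-order map drive mega-scaffolding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import dna


@dataclass
class ReadPairs:
    """One simulated paired library, kept as encoded arrays.

    ``r1``/``r2`` are (n, read_length) uint8 arrays; mate 2 is already
    reverse-complemented (inward orientation, as sequenced).
    """

    r1: np.ndarray
    r2: np.ndarray
    insert_mean: float
    insert_sd: float
    tier: str = "pe"
    # truth (fragment start/end on the source haplotype, haplotype index)
    frag_start: np.ndarray | None = None
    frag_end: np.ndarray | None = None
    haplotype: np.ndarray | None = None

    def __len__(self) -> int:
        return self.r1.shape[0]

    @property
    def read_length(self) -> int:
        return self.r1.shape[1]

    def names(self) -> list[str]:
        return [f"{self.tier}_{i:08d}" for i in range(len(self))]


def _extract(hap: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    idx = starts[:, None] + np.arange(length)[None, :]
    return hap[idx]


def _add_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    mask = rng.random(reads.shape) < error_rate
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        reads[mask] = (reads[mask] + shift) % 4


def simulate_reads(
    haplotypes: tuple[np.ndarray, ...] | np.ndarray,
    coverage: float,
    insert_mean: float,
    insert_sd: float,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    tier: str = "pe",
    chimera_rate: float = 0.0,
    chunk: int = 250_000,
) -> ReadPairs:
    """Simulate one inward-oriented paired library at the given coverage.

    Pairs are drawn uniformly over both haplotypes; requested coverage is
    realized exactly up to rounding of the pair count.  ``chimera_rate``
    replaces that fraction of mates with reads from an unrelated locus.
    """
    if isinstance(haplotypes, np.ndarray):
        haplotypes = (haplotypes,)
    if insert_mean <= 2 * read_length:
        raise ValueError("insert mean must exceed twice the read length")
    glen = min(len(h) for h in haplotypes)
    if insert_mean >= glen:
        raise ValueError("insert size exceeds genome length")
    n_pairs = int(round(coverage * glen / (2.0 * read_length)))
    out1 = np.empty((n_pairs, read_length), dtype=np.uint8)
    out2 = np.empty((n_pairs, read_length), dtype=np.uint8)
    fs = np.empty(n_pairs, dtype=np.int64)
    fe = np.empty(n_pairs, dtype=np.int64)
    hp = rng.integers(0, len(haplotypes), size=n_pairs)
    for lo in range(0, n_pairs, chunk):
        hi = min(n_pairs, lo + chunk)
        m = hi - lo
        ins = rng.normal(insert_mean, insert_sd, size=m)
        ins = np.clip(ins, 2 * read_length + 2, None).astype(np.int64)
        for h_idx, hap in enumerate(haplotypes):
            sel = np.flatnonzero(hp[lo:hi] == h_idx)
            if len(sel) == 0:
                continue
            ins_h = np.minimum(ins[sel], len(hap) - 1)
            starts = rng.integers(0, len(hap) - ins_h + 1)
            ends = starts + ins_h
            out1[lo + sel] = _extract(hap, starts, read_length)
            out2[lo + sel] = dna.revcomp_rows(_extract(hap, ends - read_length, read_length))
            fs[lo + sel] = starts
            fe[lo + sel] = ends
    if chimera_rate > 0:
        n_chi = int(round(chimera_rate * n_pairs))
        if n_chi:
            which = rng.choice(n_pairs, size=n_chi, replace=False)
            hap0 = haplotypes[0]
            alt = rng.integers(0, len(hap0) - read_length + 1, size=n_chi)
            out2[which] = dna.revcomp_rows(_extract(hap0, alt, read_length))
    _add_errors(out1, error_rate, rng)
    _add_errors(out2, error_rate, rng)
    return ReadPairs(
        r1=out1,
        r2=out2,
        insert_mean=float(insert_mean),
        insert_sd=float(insert_sd),
        tier=tier,
        frag_start=fs,
        frag_end=fe,
        haplotype=hp,
    )


def simulate_tiers(
    haplotypes,
    tiers: tuple[tuple[int, int, float], ...],
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    chimera_rate: float = 0.0,
) -> list[ReadPairs]:
    """All configured insert tiers, smallest insert first."""
    out = []
    for mean, sd, cov in sorted(tiers, key=lambda t: t[0]):
        out.append(
            simulate_reads(
                haplotypes,
                cov,
                mean,
                sd,
                read_length,
                error_rate,
                rng,
                tier=f"ins{mean}",
                chimera_rate=chimera_rate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BAC clones and the clone-order (FPC-style) map


@dataclass
class BacLibrary:
    """BAC clones with their two end reads (inward orientation)."""

    clone_ids: list[str]
    end1: np.ndarray  # (n, end_read_length) uint8
    end2: np.ndarray
    insert_mean: float
    # truth
    start: np.ndarray = field(default=None)
    end: np.ndarray = field(default=None)


def simulate_bac_and_fpc(
    genome: np.ndarray,
    n_clones: int,
    bac_insert_mean: int,
    bac_insert_sd: int,
    end_read_length: int,
    rng: np.random.Generator,
):
    """BAC end-read pairs plus a clone-order physical map.

    Clone starts are uniform over the genome.  The map abstracts the
    fingerprinting step: clones are grouped into map contigs wherever clone
    coverage is contiguous and ordered by true insert midpoint, which is the
    only information the downstream ordering step consumes.  Returns
    ``(BacLibrary, FPCMap)``.
    """
    from ..scaffold import FPCMap

    glen = len(genome)
    if bac_insert_mean >= glen:
        raise ValueError("BAC insert exceeds genome length")
    ins = rng.normal(bac_insert_mean, bac_insert_sd, size=n_clones)
    ins = np.clip(ins, 2 * end_read_length + 10, glen - 1).astype(np.int64)
    starts = rng.integers(0, glen - ins + 1)
    ends = starts + ins
    ids = [f"bac{i:06d}" for i in range(n_clones)]
    end1 = _extract(genome, starts, end_read_length)
    end2 = dna.revcomp_rows(_extract(genome, ends - end_read_length, end_read_length))
    lib = BacLibrary(
        clone_ids=ids,
        end1=end1,
        end2=end2,
        insert_mean=float(bac_insert_mean),
        start=starts,
        end=ends,
    )
    mid = (starts + ends) / 2.0
    order = np.argsort(mid, kind="stable")
    map_contigs: list[list[str]] = []
    current: list[str] = []
    covered_to = -1
    for j in order:
        if current and starts[j] > covered_to:
            map_contigs.append(current)
            current = []
        current.append(ids[j])
        covered_to = max(covered_to, int(ends[j]))
    if current:
        map_contigs.append(current)
    fpc = FPCMap(
        contigs={f"mc{i:04d}": list(clones) for i, clones in enumerate(map_contigs)}
    )
    return lib, fpc
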