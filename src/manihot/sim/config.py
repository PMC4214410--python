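"""Simulation configuration and seed fan-out."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: default insert-size tiers: (mean bp, sd bp, coverage x) per library,
#: smallest first; the short tier is an ordinary paired-end library, the
#: larger two emulate mate-pair jumping libraries.
DEFAULT_TIERS: tuple[tuple[int, int, float], ...] = (
    (300, 30, 30.0),
    (3000, 300, 10.0),
    (8000, 800, 5.0),
)

#: default gene selection regimes: fraction of genes, target Ka/Ks regime
DEFAULT_SELECTION: tuple[tuple[float, str], ...] = (
    (0.2, "positive"),
    (0.1, "negative"),
    (0.7, "neutral"),
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated wild/cultivar study.

    Rates are events per kb, as reported for the modelled system: within-
    individual heterozygosity of 3.8 (wild) / 3.4 (cultivar) SNVs per kb,
    and wild-versus-reference divergence of 6.9 SNVs and 0.8 InDels per kb.
    BAC clones default to a 115-kb mean insert with the clone count sized to
    about ten genome equivalents.
    """

    genome_length: int = 1_000_000
    n_genes: int = 200
    gene_length: int = 900
    het_snv_rate: float = 3.8
    het_indel_rate: float = 0.6
    divergence_snv_rate: float = 6.9
    divergence_indel_rate: float = 0.8
    selection_profile: tuple[tuple[float, str], ...] = DEFAULT_SELECTION
    coding_subs_per_gene: float = 30.0
    pav_fraction: float = 0.05
    cnv_fraction: float = 0.03
    mite_insertion_prob: float = 0.3
    mite_shared_prob: float = 0.2
    suppression_log2fc: float = -2.0
    nb_dispersion: float = 0.05
    expression_mean: float = 400.0
    n_replicates: int = 5
    upstream_window: int = 1000
    read_length: int = 100
    error_rate: float = 0.001
    insert_tiers: tuple[tuple[int, int, float], ...] = DEFAULT_TIERS
    bac_insert_mean: int = 115_000
    bac_insert_sd: int = 10_000
    bac_end_read_length: int = 700
    n_bac_clones: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.het_snv_rate,
            self.het_indel_rate,
            self.divergence_snv_rate,
            self.divergence_indel_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be >= 0")
        if not 0 <= self.mite_insertion_prob <= 1:
            raise ValueError("mite_insertion_prob must be in [0, 1]")
        if not 0 <= self.mite_shared_prob <= 1:
            raise ValueError("mite_shared_prob must be in [0, 1]")
        fracs = [f for f, _ in self.selection_profile]
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("selection_profile fractions must lie in [0,1] and sum <= 1")
        if any(cov <= 0 for _, _, cov in self.insert_tiers):
            raise ValueError("tier coverage must be > 0")
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")
        if self.genome_length < self.n_genes * (self.gene_length + self.upstream_window):
            raise ValueError(
                "genome too short to place "
                f"{self.n_genes} genes of {self.gene_length} bp with "
                f"{self.upstream_window} bp clearance"
            )

    @property
    def bac_clone_count(self) -> int:
        """Clone count; defaults to ten genome equivalents of coverage."""
        if self.n_bac_clones is not None:
            return self.n_bac_clones
        return max(1, round(10 * self.genome_length / self.bac_insert_mean))

    def to_dict(self) -> dict:
        return asdict(self)


_STAGES = (
    "genome",
    "diploid",
    "divergence",
    "mites",
    "reads",
    "bac",
    "expression",
    "other",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from one global seed.

    The derivation is ``SeedSequence(seed, spawn_key=(stage_index,))``, so
    changing the seed of one stage never perturbs another stage's stream.
    """
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}; known: {_STAGES}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)
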