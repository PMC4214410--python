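"""Negative-binomial expression counts with MITE-linked suppression."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _nb_draw(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB2 draw: variance = mean + dispersion * mean^2; Poisson when the
    dispersion is zero."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_expression(
    gene_ids: list[str],
    suppressed: np.ndarray | list[bool],
    suppression_log2fc: float,
    nb_dispersion: float,
    n_replicates: int,
    rng: np.random.Generator,
    base_mean: float = 400.0,
    mean_sigma: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts table (genes x samples) for a wild and a cultivar group.

    ``suppressed`` flags genes carrying a cultivar-specific promoter MITE:
    their cultivar mean is shifted by ``suppression_log2fc`` (a log2 fold
    change, negative = suppression); all other genes share equal means in
    the two groups.  Per-gene baseline means are log-normal around
    ``base_mean``.  Returns the count table and a truth table with per-gene
    means and the planted fold change.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    suppressed = np.asarray(suppressed, dtype=bool)
    if len(suppressed) != len(gene_ids):
        raise ValueError("flag vector length must match gene list")
    n = len(gene_ids)
    base = base_mean * np.exp(rng.normal(0.0, mean_sigma, size=n) - mean_sigma**2 / 2)
    cult = base * np.where(suppressed, 2.0**suppression_log2fc, 1.0)
    cols = {}
    for r in range(n_replicates):
        cols[f"wild_{r + 1}"] = _nb_draw(base, nb_dispersion, rng)
    for r in range(n_replicates):
        cols[f"cultivar_{r + 1}"] = _nb_draw(cult, nb_dispersion, rng)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "wild_mean": base,
            "cultivar_mean": cult,
            "log2fc": np.where(suppressed, suppression_log2fc, 0.0),
        }
    ).set_index("gene_id")
    return counts, truth
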