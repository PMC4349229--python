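"""Signal-to-gene assignment, gene ranking and top-1% outlier calling.

A point signal (iHS core) belongs to a gene when it lies within 1 kb
upstream of the transcription start through 1 kb downstream of the
transcription stop; a window signal (PBS bin) is assigned on >= 1 bp span
overlap with that flanked region. Each gene keeps its strongest signal;
genes are ranked by that score and the top 1% — anchored to the full
annotated-gene universe, not just the genes that received signals — are
called outliers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sweepscan.io import GeneModel

logger = logging.getLogger(__name__)


def gene_flank_region(gene: GeneModel, flank: int = 1000) -> tuple[int, int]:
    """Half-open [start, stop) region of the gene extended by ``flank`` bp
    upstream of the transcription start and downstream of the stop.

    Both flanks are the same length, so the region is strand-symmetric;
    strand determines which end is "upstream" but not the span.
    """
    return gene.start - flank, gene.stop + flank


def assign_signals_to_genes(
    signals: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 1000,
) -> pd.DataFrame:
    """Map signals to genes; a signal may hit several overlapping genes.

    ``signals`` needs columns ``chrom``, ``start_pos``, ``stop_pos``
    (half-open; a point signal has stop = start + 1) and ``score``.
    Returns the signal rows replicated per assigned gene with a
    ``gene_id`` column.
    """
    out = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        sig = signals[signals["chrom"].astype(str) == str(chrom)]
        if sig.empty:
            continue
        starts = sig["start_pos"].to_numpy()
        stops = sig["stop_pos"].to_numpy()
        for g in chrom_genes:
            lo, hi = gene_flank_region(g, flank)
            hit = (starts < hi) & (stops > lo)  # >= 1 bp overlap
            if hit.any():
                sub = sig.loc[hit].copy()
                sub["gene_id"] = g.gene_id
                out.append(sub)
    if not out:
        return pd.DataFrame(
            columns=[*signals.columns, "gene_id"]
        )
    return pd.concat(out, ignore_index=True)


def best_signal_per_gene(assigned: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: the strongest assigned signal (max score)."""
    if assigned.empty:
        return assigned
    idx = assigned.groupby("gene_id")["score"].idxmax()
    best = assigned.loc[idx].reset_index(drop=True)
    return best


def rank_and_call_outliers(
    gene_scores: pd.DataFrame,
    universe_size: int,
    percentile: float = 0.01,
) -> pd.DataFrame:
    """Rank genes by best score and flag the top-``percentile`` outliers.

    The outlier count is ``round(percentile * universe_size)`` — anchored
    to the full annotated-gene universe (19,990 genes -> 200 outliers) —
    not to the number of genes that happened to receive signals. Ties at
    the cutoff are broken by genomic position (earlier chromosome, then
    earlier coordinate, then gene id).

    ``gene_scores`` needs ``gene_id``, ``score`` and, for tie-breaking,
    ``chrom`` and ``start_pos``.
    """
    n_out = int(round(percentile * universe_size))
    if len(gene_scores) < n_out:
        raise ValueError(
            f"only {len(gene_scores)} ranked genes but the top-"
            f"{percentile:.0%} cutoff on a universe of {universe_size} "
            f"requires {n_out}"
        )
    cols = ["score"]
    ascending = [False]
    for c in ("chrom", "start_pos", "gene_id"):
        if c in gene_scores.columns:
            cols.append(c)
            ascending.append(True)
    ranked = gene_scores.sort_values(
        cols, ascending=ascending, kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked["outlier"] = ranked["rank"] <= n_out
    if n_out and len(ranked) > n_out:
        if ranked.loc[n_out - 1, "score"] == ranked.loc[n_out, "score"]:
            logger.info(
                "tie at the top-%s cutoff broken by genomic position",
                f"{percentile:.0%}",
            )
    return ranked


def overlap_between_breeds(
    set_a: set[str],
    set_b: set[str],
    universe: list[str],
    n_replicates: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[set[str], float]:
    """Observed intersection of two outlier gene sets and its resampling
    p-value.

    The null draws ``n_replicates`` pairs of same-size gene sets uniformly
    without replacement from the universe and counts intersections at least
    as large as observed, with the (r + 1)/(B + 1) correction.
    """
    if not universe:
        raise ValueError("empty gene universe")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    shared = set_a & set_b
    observed = len(shared)
    g = len(universe)
    k_a, k_b = len(set_a), len(set_b)
    exceed = 0
    for _ in range(n_replicates):
        draw_a = rng.choice(g, size=k_a, replace=False, shuffle=False)
        mask = np.zeros(g, dtype=bool)
        mask[draw_a] = True
        draw_b = rng.choice(g, size=k_b, replace=False, shuffle=False)
        if int(mask[draw_b].sum()) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_replicates + 1)
    return shared, p
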