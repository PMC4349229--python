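"""Windowed three-population branch-statistic scan.

Per window and population pair, Hudson-style F_ST = 1 - pi_w / pi_t with
pi_w = (n1 pi1 + n2 pi2) / (n1 + n2); the -log(1 - F_ST) transform turns each
pairwise F_ST into an effective divergence time T, and the three T values are
combined into per-population branch lengths:

    PBS_1 = (T_12 + T_13 - T_23) / 2   (and cyclic permutations)

so that PBS_1 + PBS_2 + PBS_3 = (T_12 + T_13 + T_23) / 2 identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan.core import nucleotide_diversity
from sweepscan.io import HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    fst: float  # clamped to [0, 1]
    fst_raw: float  # unclamped Hudson estimate (may be negative)
    pi_w: float
    pi_t: float
    defined: bool  # False when pi_t == 0 (window monomorphic across the pair)


def hudson_fst(pop1: np.ndarray, pop2: np.ndarray) -> FstResult:
    """Hudson-style F_ST = 1 - pi_w/pi_t for one window of two populations.

    Negative estimates are clamped to 0 (the raw value is retained) so that
    the downstream divergence-time transform stays non-negative.
    """
    n1, n2 = pop1.shape[0], pop2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 haplotypes")
    pi1 = nucleotide_diversity(pop1)
    pi2 = nucleotide_diversity(pop2)
    pi_w = (n1 * pi1 + n2 * pi2) / (n1 + n2)
    pi_t = nucleotide_diversity(np.vstack([pop1, pop2]))
    if pi_t == 0.0:
        return FstResult(math.nan, math.nan, pi_w, pi_t, defined=False)
    raw = 1.0 - pi_w / pi_t
    return FstResult(max(raw, 0.0), raw, pi_w, pi_t, defined=True)


def divergence_time(fst: float, n_total: int | None = None) -> float:
    """T = -ln(1 - F_ST); F_ST = 1 is capped via 1 - 1/(2 n_total)."""
    if not 0.0 <= fst <= 1.0:
        raise ValueError(f"F_ST outside [0, 1]: {fst}")
    if fst == 1.0:
        if n_total is None:
            raise ValueError("F_ST = 1 requires n_total to compute the cap")
        fst = 1.0 - 1.0 / (2 * n_total)
    return -math.log(1.0 - fst)


def pbs(t_12: float, t_13: float, t_23: float) -> tuple[float, float, float]:
    """Branch lengths (PBS_1, PBS_2, PBS_3) from the three pairwise T values.

    Indices: T_12 between populations 1 and 2, etc. Values may be negative
    and are reported as computed.
    """
    for t in (t_12, t_13, t_23):
        if t < 0:
            raise ValueError("divergence times must be non-negative")
    pbs_1 = (t_12 + t_13 - t_23) / 2.0
    pbs_2 = (t_12 + t_23 - t_13) / 2.0
    pbs_3 = (t_13 + t_23 - t_12) / 2.0
    return pbs_1, pbs_2, pbs_3


def window_starts(n_snps: int, window_snps: int, step_snps: int) -> list[int]:
    """Full-window start indices 0, step, 2*step, ...; partial trailing
    windows are dropped, giving floor((N - window)/step) + 1 windows."""
    if n_snps < window_snps:
        return []
    return list(range(0, n_snps - window_snps + 1, step_snps))


def window_scan(
    haps: HaplotypeSet,
    breed1: str,
    breed2: str,
    outgroup: str,
    window_snps: int = 200,
    step_snps: int = 50,
) -> pd.DataFrame:
    """Sliding-window PBS scan over sites variable in the combined
    three-population sample.

    Returns one row per window with per-population pi, the three pairwise
    F_ST / T values and the three PBS branch lengths. Population 1 = breed1,
    2 = breed2, 3 = outgroup.
    """
    pops = (breed1, breed2, outgroup)
    rows = {p: haps.rows_for(p) for p in pops}
    keep = np.isin(haps.populations, pops)
    sub = haps.alleles[keep]
    counts = sub.sum(axis=0, dtype=np.int64)
    seg = np.flatnonzero((counts > 0) & (counts < sub.shape[0]))
    n_total = sub.shape[0]

    records = []
    for chrom in dict.fromkeys(haps.chrom.tolist()):
        snp_idx = seg[haps.chrom[seg] == chrom]
        starts = window_starts(snp_idx.size, window_snps, step_snps)
        if not starts:
            logger.info(
                "chromosome %s: %d SNPs < window %d, skipped",
                chrom, snp_idx.size, window_snps,
            )
            continue
        for s in starts:
            idx = snp_idx[s : s + window_snps]
            win = {p: rows[p][:, idx] for p in pops}
            rec: dict = {
                "chrom": chrom,
                "first_snp": int(idx[0]),
                "last_snp": int(idx[-1]),
                "start_pos": int(haps.positions[idx[0]]),
                "stop_pos": int(haps.positions[idx[-1]]) + 1,
            }
            for p in pops:
                rec[f"n_{p}"] = win[p].shape[0]
                rec[f"pi_{p}"] = nucleotide_diversity(win[p])
            pairs = {
                "12": (breed1, breed2),
                "13": (breed1, outgroup),
                "23": (breed2, outgroup),
            }
            t: dict[str, float] = {}
            defined = True
            for key, (a, b) in pairs.items():
                res = hudson_fst(win[a], win[b])
                rec[f"fst_{key}"] = res.fst
                rec[f"fst_raw_{key}"] = res.fst_raw
                if not res.defined:
                    defined = False
                else:
                    t[key] = divergence_time(
                        res.fst, win[a].shape[0] + win[b].shape[0]
                    )
            rec["defined"] = defined
            if defined:
                rec["T_12"], rec["T_13"], rec["T_23"] = t["12"], t["13"], t["23"]
                p1, p2, p3 = pbs(t["12"], t["13"], t["23"])
                rec[f"pbs_{breed1}"] = p1
                rec[f"pbs_{breed2}"] = p2
                rec[f"pbs_{outgroup}"] = p3
            else:
                for k in ("T_12", "T_13", "T_23"):
                    rec[k] = math.nan
                for p in pops:
                    rec[f"pbs_{p}"] = math.nan
            records.append(rec)
    if not records:
        logger.warning("no chromosome had >= %d SNPs; empty scan", window_snps)
        return pd.DataFrame()
    return pd.DataFrame.from_records(records)
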