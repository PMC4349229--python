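"""Per-site and per-window diversity primitives.

Nucleotide diversity pi is the mean number of pairwise differences over all
unordered haplotype pairs; the vectorized per-site form used here,
sum_j c_j (n - c_j) / C(n, 2), is identical to explicit pair enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan.io import HaplotypeSet


@dataclass
class SiteAnnotation:
    """Per-site allele counts, frequencies and outgroup polarization.

    ``derived_is_alt`` holds, per breed, which allele is treated as derived
    (True: alt, False: ref) under the outgroup minor-allele rule;
    ``ambiguous`` flags sites where the outgroup frequency is exactly 0.5.
    """

    positions: np.ndarray
    chrom: np.ndarray
    alt_count: dict[str, np.ndarray]
    n_hap: dict[str, int]
    alt_freq: dict[str, np.ndarray]
    maf: dict[str, np.ndarray]
    derived_is_alt: np.ndarray
    ambiguous: np.ndarray

    def derived_freq(self, breed: str) -> np.ndarray:
        """Derived-allele frequency in ``breed`` (NaN where ambiguous)."""
        f = np.where(
            self.derived_is_alt, self.alt_freq[breed], 1.0 - self.alt_freq[breed]
        )
        return np.where(self.ambiguous, np.nan, f)

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"chrom": self.chrom, "pos": self.positions}
        for pop in self.alt_freq:
            data[f"alt_freq_{pop}"] = self.alt_freq[pop]
            data[f"maf_{pop}"] = self.maf[pop]
        data["derived_is_alt"] = self.derived_is_alt
        data["ambiguous"] = self.ambiguous
        return pd.DataFrame(data)


def nucleotide_diversity(haps: np.ndarray) -> float:
    """Mean pairwise difference over all unordered haplotype pairs.

    Parameters
    ----------
    haps : (n_hap, n_sites) 0/1 matrix (a window slice of one or more
        populations).
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity requires >= 2 haplotypes")
    c = haps.sum(axis=0, dtype=np.int64)
    # per-site pair differences c*(n-c), summed, over total pairs
    return float((c * (n - c)).sum() / (n * (n - 1) / 2))


def annotate_sites(
    haps: HaplotypeSet, outgroup: str, breeds: list[str] | None = None
) -> SiteAnnotation:
    """Compute per-population counts/frequencies/MAF and polarize against
    the outgroup.

    The allele that is minor (frequency < 0.5) or absent in the outgroup is
    designated derived; an exact 0.5 outgroup frequency is flagged ambiguous
    and such sites are excluded from iHS cores downstream.
    """
    pops = haps.population_labels
    if outgroup not in pops:
        raise KeyError(f"outgroup {outgroup!r} not among populations {pops}")
    if breeds is None:
        breeds = [p for p in pops if p != outgroup]
    alt_count: dict[str, np.ndarray] = {}
    n_hap: dict[str, int] = {}
    alt_freq: dict[str, np.ndarray] = {}
    maf: dict[str, np.ndarray] = {}
    for pop in pops:
        rows = haps.rows_for(pop)
        alt_count[pop] = rows.sum(axis=0, dtype=np.int64)
        n_hap[pop] = rows.shape[0]
        alt_freq[pop] = alt_count[pop] / n_hap[pop]
        maf[pop] = np.minimum(alt_freq[pop], 1.0 - alt_freq[pop])
    total = sum(alt_count[p] for p in pops)
    if np.any((total == 0) | (total == haps.n_hap)):
        raise ValueError(
            "sites monomorphic across all populations present; "
            "restrict to segregating sites first"
        )
    f_out = alt_freq[outgroup]
    derived_is_alt = f_out < 0.5
    ambiguous = f_out == 0.5
    return SiteAnnotation(
        positions=haps.positions,
        chrom=haps.chrom,
        alt_count=alt_count,
        n_hap=n_hap,
        alt_freq=alt_freq,
        maf=maf,
        derived_is_alt=derived_is_alt,
        ambiguous=ambiguous,
    )


def polarize_against_outgroup(
    outgroup_alt_freq: float,
) -> tuple[str | None, bool]:
    """Return (derived allele designation, ambiguous flag) for one site.

    The designation is ``"alt"`` when the alt allele is minor or absent in
    the outgroup, ``"ref"`` when it is major, and ``None`` with the ambiguous
    flag set when the outgroup frequency is exactly 0.5.
    """
    if not 0.0 <= outgroup_alt_freq <= 1.0:
        raise ValueError("frequency outside [0, 1]")
    if outgroup_alt_freq == 0.5:
        return None, True
    return ("alt" if outgroup_alt_freq < 0.5 else "ref"), False


def count_distinct_haplotypes(haps: np.ndarray) -> int:
    """Number of distinct haplotype strings over the given window slice."""
    haps = np.ascontiguousarray(haps, dtype=np.uint8)
    if haps.shape[0] < 1:
        raise ValueError("need at least one haplotype")
    return len({h.tobytes() for h in haps})


def h_windows(
    haps: HaplotypeSet,
    population: str,
    window_snps: int = 30,
    step_snps: int | None = None,
) -> pd.DataFrame:
    """Distinct-haplotype counts H in windows of ``window_snps`` sites that
    are variable within ``population``.

    Windows are non-overlapping by default (step = window size); they never
    span chromosomes, and trailing partial windows are dropped.
    """
    if step_snps is None:
        step_snps = window_snps
    rows = haps.rows_for(population)
    if rows.shape[0] < 2:
        raise ValueError("population needs >= 2 haplotypes")
    c = rows.sum(axis=0, dtype=np.int64)
    variable = (c > 0) & (c < rows.shape[0])
    records = []
    for chrom in dict.fromkeys(haps.chrom.tolist()):
        on_chrom = np.flatnonzero((haps.chrom == chrom) & variable)
        n = on_chrom.size
        for start in range(0, n - window_snps + 1, step_snps):
            idx = on_chrom[start : start + window_snps]
            records.append(
                {
                    "chrom": chrom,
                    "first_snp": int(idx[0]),
                    "last_snp": int(idx[-1]),
                    "start_pos": int(haps.positions[idx[0]]),
                    "stop_pos": int(haps.positions[idx[-1]]) + 1,
                    "H": count_distinct_haplotypes(rows[:, idx]),
                }
            )
    if not records:
        raise ValueError(
            f"no window of {window_snps} variable sites in {population!r}"
        )
    return pd.DataFrame.from_records(records)


def h_distribution(
    haps: HaplotypeSet,
    population: str,
    window_snps: int = 30,
    step_snps: int | None = None,
) -> pd.Series:
    """Histogram of H over all eligible windows (index: H, values: counts)."""
    win = h_windows(haps, population, window_snps, step_snps)
    return win["H"].value_counts().sort_index()
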