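"""EHH / iHH / iHS haplotype-length scan within one breed.

For each eligible core SNP the decay of extended haplotype homozygosity
(EHH) is traced outward site by site on both flanks, separately for the
carriers of the derived and the ancestral core allele. EHH over a span is
the probability that two randomly chosen carrier haplotypes are identical
across it:

    EHH = sum_h C(n_h, 2) / C(n_c, 2)

over distinct extended haplotypes h among the n_c carriers. Each curve is
integrated over physical distance (trapezoids, linear interpolation to the
0.05 crossing) to give iHH; the raw score is ln(iHH_A / iHH_D) and is
standardized within derived-allele-frequency classes to mean 0, variance 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sweepscan.core import SiteAnnotation, annotate_sites
from sweepscan.io import HaplotypeSet

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05


@dataclass
class EhhCurve:
    """EHH decay from one core allele: per-flank offsets (bp, increasing
    away from the core, starting at 0) and EHH values (starting at 1)."""

    core_idx: int
    core_allele: str  # "ancestral" | "derived" (or raw "0"/"1")
    left_offsets: list[float] = field(default_factory=list)
    left_ehh: list[float] = field(default_factory=list)
    right_offsets: list[float] = field(default_factory=list)
    right_ehh: list[float] = field(default_factory=list)
    left_truncation: str = "edge"  # "cutoff" | "edge"
    right_truncation: str = "edge"

    @property
    def edge_truncated(self) -> bool:
        return self.left_truncation == "edge" or self.right_truncation == "edge"


def _flank(
    carriers: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    direction: int,
    cutoff: float,
    max_extension: float | None,
) -> tuple[list[float], list[float], str]:
    """Trace EHH outward in one direction. Returns (offsets, ehh, reason)."""
    n_c = carriers.shape[0]
    denom = n_c * (n_c - 1)
    group = np.zeros(n_c, dtype=np.int64)
    offsets = [0.0]
    values = [1.0]
    j = core_idx + direction
    reason = "edge"
    n_sites = carriers.shape[1]
    core_pos = positions[core_idx]
    while 0 <= j < n_sites:
        dist = abs(float(positions[j]) - float(core_pos))
        if max_extension is not None and dist > max_extension:
            break
        group = np.unique(group * 2 + carriers[:, j], return_inverse=True)[1]
        counts = np.bincount(group)
        e = float((counts * (counts - 1)).sum()) / denom
        offsets.append(dist)
        values.append(e)
        if e < cutoff:
            reason = "cutoff"
            break
        j += direction
    return offsets, values, reason


def ehh(
    haps: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    core_allele: int,
    cutoff: float = EHH_CUTOFF,
    max_extension: float | None = None,
    allele_label: str | None = None,
) -> EhhCurve:
    """EHH decay curve for carriers of ``core_allele`` at ``core_idx``.

    ``haps`` is the haplotype matrix of one breed on one chromosome; all
    linked SNPs, whatever their frequency, participate in the extension.
    """
    carriers = haps[haps[:, core_idx] == core_allele]
    if carriers.shape[0] < 2:
        raise ValueError("fewer than 2 carriers of the core allele")
    lo, lv, lr = _flank(carriers, positions, core_idx, -1, cutoff, max_extension)
    ro, rv, rr = _flank(carriers, positions, core_idx, +1, cutoff, max_extension)
    return EhhCurve(
        core_idx=core_idx,
        core_allele=allele_label if allele_label is not None else str(core_allele),
        left_offsets=lo,
        left_ehh=lv,
        right_offsets=ro,
        right_ehh=rv,
        left_truncation=lr,
        right_truncation=rr,
    )


def _integrate_flank(
    offsets: list[float], values: list[float], cutoff: float
) -> float:
    """Trapezoidal integral of one flank, linearly interpolated to the
    ``cutoff`` crossing when the last point dips below it."""
    if len(offsets) < 2:
        return 0.0
    off = np.asarray(offsets)
    val = np.asarray(values)
    if val[-1] < cutoff:
        # replace the last point by the interpolated crossing
        e0, e1 = val[-2], val[-1]
        d0, d1 = off[-2], off[-1]
        d_cross = d0 + (e0 - cutoff) * (d1 - d0) / (e0 - e1)
        off = np.append(off[:-1], d_cross)
        val = np.append(val[:-1], cutoff)
    return float(np.trapezoid(val, off))


def ihh(curve: EhhCurve, cutoff: float = EHH_CUTOFF) -> float:
    """Integrated EHH: trapezoid areas of both flanks summed (bp units)."""
    total = _integrate_flank(curve.left_offsets, curve.left_ehh, cutoff)
    total += _integrate_flank(curve.right_offsets, curve.right_ehh, cutoff)
    if total == 0.0:
        raise ValueError("degenerate EHH curve: no extension on either flank")
    return total


def select_cores(
    haps: HaplotypeSet,
    annotation: SiteAnnotation,
    breed: str,
    maf_min: float = 0.2,
) -> np.ndarray:
    """Indices of eligible core sites: breed MAF strictly above ``maf_min``,
    unambiguous outgroup polarization, and >= 2 carriers of each allele."""
    maf = annotation.maf[breed]
    count = annotation.alt_count[breed]
    n = annotation.n_hap[breed]
    mask = (
        (maf > maf_min)
        & ~annotation.ambiguous
        & (count >= 2)
        & (n - count >= 2)
    )
    return np.flatnonzero(mask)


def ihs_scan(
    haps: HaplotypeSet,
    breed: str,
    outgroup: str,
    maf_min: float = 0.2,
    cutoff: float = EHH_CUTOFF,
    max_extension: float | None = None,
    annotation: SiteAnnotation | None = None,
) -> pd.DataFrame:
    """Raw (unstandardized) iHS for every eligible core in ``breed``.

    One row per scored core with iHH_A, iHH_D, the raw score
    ln(iHH_A/iHH_D), the derived-allele frequency, and an
    ``edge_truncated`` flag (EHH never reached the cutoff before the
    chromosome end on some flank).
    """
    if annotation is None:
        annotation = annotate_sites(haps, outgroup)
    cores = select_cores(haps, annotation, breed, maf_min)
    rows = haps.rows_for(breed)
    records = []
    for chrom in dict.fromkeys(haps.chrom.tolist()):
        chrom_sites = np.flatnonzero(haps.chrom == chrom)
        sub = rows[:, chrom_sites]
        pos = haps.positions[chrom_sites]
        # map global site index -> local index on this chromosome
        local = {int(g): i for i, g in enumerate(chrom_sites)}
        for g_idx in cores:
            if int(g_idx) not in local:
                continue
            c_idx = local[int(g_idx)]
            derived_allele = 1 if annotation.derived_is_alt[g_idx] else 0
            try:
                curve_d = ehh(
                    sub, pos, c_idx, derived_allele, cutoff, max_extension,
                    allele_label="derived",
                )
                curve_a = ehh(
                    sub, pos, c_idx, 1 - derived_allele, cutoff, max_extension,
                    allele_label="ancestral",
                )
                ihh_d = ihh(curve_d, cutoff)
                ihh_a = ihh(curve_a, cutoff)
            except ValueError:
                continue
            records.append(
                {
                    "chrom": chrom,
                    "site": int(g_idx),
                    "pos": int(haps.positions[g_idx]),
                    "derived_freq": float(
                        annotation.derived_freq(breed)[g_idx]
                    ),
                    "ihh_a": ihh_a,
                    "ihh_d": ihh_d,
                    "raw_ihs": math.log(ihh_a / ihh_d),
                    "edge_truncated": curve_d.edge_truncated
                    or curve_a.edge_truncated,
                }
            )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "chrom", "site", "pos", "derived_freq",
            "ihh_a", "ihh_d", "raw_ihs", "edge_truncated",
        ],
    )
    logger.info(
        "iHS scan %s: %d cores scored (%d edge-truncated)",
        breed, len(df), int(df["edge_truncated"].sum()) if len(df) else 0,
    )
    return df


def _merge_small_classes(
    class_of: np.ndarray, min_class_size: int
) -> np.ndarray:
    """Merge frequency classes with fewer than ``min_class_size`` members
    into the nearest (by bin index) neighbouring class."""
    classes = sorted(set(class_of.tolist()))
    counts = {c: int((class_of == c).sum()) for c in classes}
    while len(counts) > 1:
        small = [c for c in counts if counts[c] < min_class_size]
        if not small:
            break
        c = min(small, key=lambda c: counts[c])
        others = [o for o in counts if o != c]
        target = min(others, key=lambda o: (abs(o - c), o))
        class_of = np.where(class_of == c, target, class_of)
        counts[target] += counts.pop(c)
    return class_of


def standardize(
    records: pd.DataFrame,
    n_bins: int = 20,
    min_class_size: int = 10,
    keep_truncated: bool = False,
) -> pd.DataFrame:
    """Standardize raw scores within derived-allele-frequency classes.

    Cores are partitioned into ``n_bins`` equal-width frequency bins on
    (0, 1); classes with fewer than ``min_class_size`` members are merged
    with the nearest class. Within each class the standardized score is
    (raw - class mean) / class standard deviation, so every class has
    sample mean 0 and variance 1 (population ddof). Edge-truncated cores
    are excluded from standardization and ranking unless
    ``keep_truncated``; a class whose scores are all identical is flagged
    and left unstandardized.
    """
    df = records.copy()
    df["ihs"] = np.nan
    df["abs_ihs"] = np.nan
    df["freq_class"] = -1
    df["zero_variance"] = False
    usable = df.index[
        df["raw_ihs"].notna()
        & (df["edge_truncated"] == False if not keep_truncated else True)  # noqa: E712
    ]
    if len(usable) == 0:
        logger.warning("no usable cores to standardize")
        return df
    freq = df.loc[usable, "derived_freq"].to_numpy()
    bins = np.clip((freq * n_bins).astype(int), 0, n_bins - 1)
    bins = _merge_small_classes(bins, min_class_size)
    df.loc[usable, "freq_class"] = bins
    raw = df.loc[usable, "raw_ihs"].to_numpy()
    z = np.full(raw.shape, np.nan)
    zero_var = np.zeros(raw.shape, dtype=bool)
    for c in np.unique(bins):
        sel = bins == c
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=0)
        if sd == 0.0:
            zero_var[sel] = True
            logger.warning("frequency class %d has zero score variance", c)
            continue
        z[sel] = (raw[sel] - mu) / sd
    df.loc[usable, "ihs"] = z
    df.loc[usable, "zero_variance"] = zero_var
    df["abs_ihs"] = df["ihs"].abs()
    return df
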