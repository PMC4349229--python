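"""Haplotype substrate and readers/writers for the standard formats the
pipeline touches.

Coordinate convention: everything in memory is 0-based half-open. VCF input
(1-based) is converted on read; gene tables are BED-like and taken as native
0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

QTL_CATEGORIES = ("production", "reproduction", "exterior", "health")


class HaplotypeSetError(ValueError):
    pass


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotype matrix with site metadata and population labels.

    Attributes
    ----------
    alleles : (n_hap, n_sites) uint8 array with entries in {0, 1}
    chrom : (n_sites,) array of chromosome ids
    positions : (n_sites,) int array, strictly increasing within a chromosome
        (0-based)
    populations : (n_hap,) array of population labels, one per haplotype row;
        two consecutive rows form one diploid sample
    ref, alt : (n_sites,) allele character arrays
    """

    alleles: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    populations: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    sample_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.chrom = np.asarray(self.chrom)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.populations = np.asarray(self.populations)
        if self.ref is None:
            self.ref = np.full(self.n_sites, "A")
        if self.alt is None:
            self.alt = np.full(self.n_sites, "T")
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.validate()

    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise HaplotypeSetError("alleles must be a 2-D matrix")
        n_hap, n_sites = self.alleles.shape
        if self.positions.shape != (n_sites,) or self.chrom.shape != (n_sites,):
            raise HaplotypeSetError("site metadata length mismatch")
        if self.populations.shape != (n_hap,):
            raise HaplotypeSetError("population label length mismatch")
        if n_sites and self.alleles.max(initial=0) > 1:
            raise HaplotypeSetError("alleles must be in {0, 1}")
        for c in dict.fromkeys(self.chrom.tolist()):
            pos = self.positions[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise HaplotypeSetError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def population_labels(self) -> list[str]:
        return list(dict.fromkeys(self.populations.tolist()))

    def rows_for(self, population: str) -> np.ndarray:
        """Haplotype-row matrix for one population."""
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"unknown population label {population!r}")
        return self.alleles[mask]

    def take_sites(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return HaplotypeSet(
            alleles=self.alleles[:, index],
            chrom=self.chrom[index],
            positions=self.positions[index],
            populations=self.populations,
            ref=self.ref[index],
            alt=self.alt[index],
            sample_ids=self.sample_ids,
        )

    def segregating_mask(self) -> np.ndarray:
        """Sites variable in the combined sample."""
        counts = self.alleles.sum(axis=0)
        return (counts > 0) & (counts < self.n_hap)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # transcription start (0-based)
    stop: int  # transcription stop (half-open)
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"gene {self.gene_id}: start must be < stop")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class QtlInterval:
    chrom: str
    start: int
    stop: int
    category: str
    subcategory: str = ""
    size_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("QTL interval: start must be < stop")
        if self.category not in QTL_CATEGORIES:
            raise ValueError(
                f"unknown QTL category {self.category!r}; "
                f"expected one of {QTL_CATEGORIES}"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_phased_vcf(haps: HaplotypeSet, path: str) -> None:
    """Write a minimal phased VCF 4.2 with one diploid sample per row pair."""
    n_hap = haps.n_hap
    if n_hap % 2:
        raise HaplotypeSetError("odd number of haplotype rows; need diploids")
    n_samp = n_hap // 2
    if haps.sample_ids is not None and len(haps.sample_ids) == n_samp:
        samples = [str(s) for s in haps.sample_ids]
    else:
        samples = [f"{haps.populations[2 * i]}_{i}" for i in range(n_samp)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in dict.fromkeys(haps.chrom.tolist()):
            length = int(haps.positions[haps.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={max(length, 1)}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(haps.n_sites):
            gts = "\t".join(
                f"{haps.alleles[2 * i, j]}|{haps.alleles[2 * i + 1, j]}"
                for i in range(n_samp)
            )
            fh.write(
                f"{haps.chrom[j]}\t{haps.positions[j] + 1}\t.\t"
                f"{haps.ref[j]}\t{haps.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: str, population_map: dict[str, str]) -> HaplotypeSet:
    """Read phased biallelic SNP records into a :class:`HaplotypeSet`.

    Multiallelic, unphased or missing-genotype records are dropped and
    counted in the log. ``population_map`` maps every VCF sample id to its
    population label.
    """
    samples: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                unknown = [s for s in samples if s not in population_map]
                if unknown:
                    raise KeyError(
                        f"samples missing from population_map: {unknown}"
                    )
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValueError(f"malformed VCF record: {line[:80]!r}")
            chrom, pos, _, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            if "GT" not in fmt:
                raise ValueError("record without GT field")
            gt_idx = fmt.index("GT")
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                n_dropped += 1
                continue
            col = np.empty(2 * len(samples), dtype=np.uint8)
            ok = True
            for i, cell in enumerate(parts[9:]):
                gt = cell.split(":")[gt_idx]
                if "|" not in gt:
                    ok = False
                    break
                a, b = gt.split("|")
                if a not in ("0", "1") or b not in ("0", "1"):
                    ok = False
                    break
                col[2 * i] = int(a)
                col[2 * i + 1] = int(b)
            if not ok:
                n_dropped += 1
                continue
            chroms.append(chrom)
            positions.append(int(pos) - 1)  # to 0-based
            refs.append(ref)
            alts.append(alt)
            columns.append(col)
    if not samples:
        raise ValueError(f"no #CHROM header found in {path}")
    if not columns:
        raise ValueError(f"no usable phased biallelic records in {path}")
    logger.info(
        "read %d phased biallelic records from %s (%d dropped)",
        len(columns), path, n_dropped,
    )
    populations = np.repeat([population_map[s] for s in samples], 2)
    hs = HaplotypeSet(
        alleles=np.column_stack(columns),
        chrom=np.array(chroms),
        positions=np.array(positions),
        populations=populations,
        ref=np.array(refs),
        alt=np.array(alts),
        sample_ids=np.array(samples),
    )
    hs.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return hs


# ---------------------------------------------------------------------------
# Internal haplotype text format: one header line, then one row per haplotype
# ---------------------------------------------------------------------------


def write_haplotype_text(haps: HaplotypeSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#sweepscan-haps\t"
            + ",".join(str(c) for c in haps.chrom)
            + "\t"
            + ",".join(str(p) for p in haps.positions)
            + "\t"
            + ",".join(str(r) for r in haps.ref)
            + "\t"
            + ",".join(str(a) for a in haps.alt)
            + "\n"
        )
        for i in range(haps.n_hap):
            row = "".join(str(x) for x in haps.alleles[i])
            fh.write(f"{haps.populations[i]}\t{row}\n")


def read_haplotype_text(path: str) -> HaplotypeSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#sweepscan-haps"):
            raise ValueError(f"{path}: not a sweepscan haplotype file")
        _, chrom_s, pos_s, ref_s, alt_s = header.split("\t")
        pops: list[str] = []
        rows: list[np.ndarray] = []
        for line in fh:
            pop, row = line.rstrip("\n").split("\t")
            pops.append(pop)
            rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
    return HaplotypeSet(
        alleles=np.vstack(rows),
        chrom=np.array(chrom_s.split(",")),
        positions=np.array([int(p) for p in pos_s.split(",")]),
        populations=np.array(pops),
        ref=np.array(ref_s.split(",")),
        alt=np.array(alt_s.split(",")),
    )


# ---------------------------------------------------------------------------
# Gene (BED-like) and QTL tables
# ---------------------------------------------------------------------------


def write_gene_table(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.stop}\t{g.gene_id}\t.\t{g.strand}\n")


def read_gene_table(path: str) -> list[GeneModel]:
    """Read a BED-like gene table: chrom, start, stop, gene id, score, strand."""
    genes: list[GeneModel] = []
    seen: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"gene table row too short: {line!r}")
            strand = parts[5] if len(parts) > 5 else "+"
            g = GeneModel(
                gene_id=parts[3],
                chrom=parts[0],
                start=int(parts[1]),
                stop=int(parts[2]),
                strand=strand,
            )
            if g.gene_id in seen:
                if seen[g.gene_id] != g:
                    raise ValueError(
                        f"conflicting duplicate gene id {g.gene_id!r}"
                    )
                continue
            seen[g.gene_id] = g
            genes.append(g)
    if not genes:
        warnings.warn(f"empty gene table: {path}", stacklevel=2)
    return genes


def write_qtl_table(qtls: list[QtlInterval], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tstop\tcategory\tsubcategory\tsize_cm\n")
        for q in qtls:
            cm = "" if q.size_cm is None else f"{q.size_cm:g}"
            fh.write(
                f"{q.chrom}\t{q.start}\t{q.stop}\t{q.category}\t"
                f"{q.subcategory}\t{cm}\n"
            )


def read_qtl_table(path: str, max_cm: float = 5.0) -> list[QtlInterval]:
    """Read a tab-separated QTL table, applying the size filter and
    collapsing exact duplicates.

    Intervals with a reported size >= ``max_cm`` centimorgans are excluded.
    When no cM size is reported the physical span is converted with the
    1 cM ~= 1 Mbp approximation.
    """
    qtls: list[QtlInterval] = []
    seen: set[tuple] = set()
    n_excluded = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"QTL table row too short: {line!r}")
            chrom, start, stop, category = parts[:4]
            subcategory = parts[4] if len(parts) > 4 else ""
            size_cm = (
                float(parts[5]) if len(parts) > 5 and parts[5] != "" else None
            )
            q = QtlInterval(
                chrom=chrom,
                start=int(start),
                stop=int(stop),
                category=category,
                subcategory=subcategory,
                size_cm=size_cm,
            )
            eff_cm = q.size_cm if q.size_cm is not None else (q.stop - q.start) / 1e6
            if eff_cm >= max_cm:
                n_excluded += 1
                continue
            key = (q.chrom, q.start, q.stop, q.subcategory)
            if key in seen:
                continue  # redundant locus
            seen.add(key)
            qtls.append(q)
    logger.info(
        "read %d QTL intervals from %s (%d excluded by %g cM filter)",
        len(qtls), path, n_excluded, max_cm,
    )
    if not qtls:
        warnings.warn(f"no QTL intervals retained from {path}", stacklevel=2)
    return qtls
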