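"""Domain containers and I/O: populations, SNPs, frequency tables, haplotype
panels, SNP-to-gene assignment and LD-based variant collapsing.

Conventions: all genomic coordinates are 1-based inclusive (VCF convention);
frequency tables store the frequency of ``allele_b`` with NaN for missing;
haplotype matrices are binary with 0 = ancestral and 1 = derived.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Population",
    "SNPRecord",
    "FrequencyTable",
    "GeneAnnotation",
    "HaplotypePanel",
    "LDResult",
    "read_frequency_table",
    "write_frequency_table",
    "read_populations",
    "write_populations",
    "read_gene_annotations",
    "write_gene_annotations",
    "frequencies_from_genotypes",
    "haplotypes_from_vcf",
    "average_maf",
    "assign_snps_to_genes",
    "ld_r2",
    "collapse_by_ld",
]

UPSTREAM_WINDOW = 500  # bp upstream of the TSS counted as part of a gene


@dataclass(frozen=True)
class Population:
    """A sampled population with its geographic location."""

    id: str
    latitude: float
    longitude: float
    n_individuals: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP; ``ancestral`` is one of the alleles or 'unknown'."""

    id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    ancestral: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"alleles identical for {self.id}")
        if self.ancestral not in (self.allele_a, self.allele_b, "unknown"):
            raise ValueError(
                f"ancestral {self.ancestral!r} is neither allele of {self.id}"
            )

    @property
    def polarized(self) -> bool:
        return self.ancestral != "unknown"

    def derived_frequency(self, freq_b: float) -> float:
        """Frequency of the derived allele given the allele_b frequency."""
        if not self.polarized:
            raise ValueError(f"SNP {self.id} has unknown ancestral state")
        return 1.0 - freq_b if self.ancestral == self.allele_b else freq_b


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcribed interval of a gene, 1-based inclusive, with strand."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"tx_start > tx_end for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class LDResult:
    snp_i: str
    snp_j: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")


@dataclass
class FrequencyTable:
    """SNP x population matrix of allele_b frequencies.

    ``freq`` has shape (n_snps, n_pops) with NaN for missing cells;
    ``counts`` optionally holds the number of non-missing allele calls behind
    each frequency.
    """

    snps: list[SNPRecord]
    populations: list[Population]
    freq: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.snps), len(self.populations)):
            raise ValueError(
                f"freq shape {self.freq.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.populations)} populations"
            )
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        pids = [p.id for p in self.populations]
        if len(set(pids)) != len(pids):
            raise ValueError("duplicate population ids")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bad = (self.freq < 0) | (self.freq > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"frequency {self.freq[i, j]} outside [0, 1] "
                f"(SNP {ids[i]}, population {pids[j]})"
            )
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.freq.shape:
                raise ValueError("counts shape does not match freq")
        self._snp_index = {s: k for k, s in enumerate(ids)}

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def population_ids(self) -> list[str]:
        return [p.id for p in self.populations]

    def snp_index(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def subset_snps(self, snp_ids: list[str]) -> "FrequencyTable":
        idx = [self.snp_index(s) for s in snp_ids]
        return FrequencyTable(
            snps=[self.snps[i] for i in idx],
            populations=self.populations,
            freq=self.freq[idx],
            counts=None if self.counts is None else self.counts[idx],
        )

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency matrix; requires full polarization."""
        out = np.empty_like(self.freq)
        for i, snp in enumerate(self.snps):
            if not snp.polarized:
                raise ValueError(f"SNP {snp.id} has unknown ancestral state")
            out[i] = 1.0 - self.freq[i] if snp.ancestral == snp.allele_b else self.freq[i]
        return out


_META_COLS = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "ancestral"]


def write_frequency_table(table: FrequencyTable, path) -> None:
    """Write a TSV with SNP metadata columns then one column per population."""
    df = pd.DataFrame(
        {
            "snp_id": table.snp_ids,
            "chrom": [s.chrom for s in table.snps],
            "pos": [s.pos for s in table.snps],
            "allele_a": [s.allele_a for s in table.snps],
            "allele_b": [s.allele_b for s in table.snps],
            "ancestral": [s.ancestral for s in table.snps],
        }
    )
    for j, pid in enumerate(table.population_ids):
        df[pid] = table.freq[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_frequency_table(
    path, populations: list[Population] | None = None
) -> FrequencyTable:
    """Read a frequency TSV written by :func:`write_frequency_table`.

    If ``populations`` is not given, placeholder Population records (equator,
    n=1) are created from the header so the matrix is still usable for purely
    frequency-based statistics.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no SNPs (empty file)") from None
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no SNPs")
    pop_cols = [c for c in df.columns if c not in _META_COLS]
    if not pop_cols:
        raise ValueError(f"{path}: no population columns")
    snps = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            snps.append(
                SNPRecord(
                    id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    allele_a=str(row.allele_a),
                    allele_b=str(row.allele_b),
                    ancestral=str(row.ancestral),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
    freq = df[pop_cols].to_numpy(dtype=float)
    if populations is None:
        populations = [Population(c, 0.0, 0.0, 1) for c in pop_cols]
    else:
        by_id = {p.id: p for p in populations}
        try:
            populations = [by_id[c] for c in pop_cols]
        except KeyError as exc:
            raise ValueError(f"{path}: population {exc} not in metadata") from exc
    return FrequencyTable(snps=snps, populations=populations, freq=freq)


def write_populations(populations: list[Population], path) -> None:
    pd.DataFrame(
        {
            "population_id": [p.id for p in populations],
            "latitude": [p.latitude for p in populations],
            "longitude": [p.longitude for p in populations],
            "n_individuals": [p.n_individuals for p in populations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_populations(path) -> list[Population]:
    df = pd.read_csv(path, sep="\t")
    return [
        Population(str(r.population_id), float(r.latitude), float(r.longitude),
                   int(r.n_individuals))
        for r in df.itertuples(index=False)
    ]


def write_gene_annotations(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "tx_start": [g.tx_start for g in genes],
            "tx_end": [g.tx_end for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_annotations(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tx_start),
                       int(r.tx_end), str(r.strand))
        for r in df.itertuples(index=False)
    ]


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes for one population over one chromosome.

    ``alleles`` has shape (n_haplotypes, n_sites), coded 0 = ancestral,
    1 = derived; ``positions`` are strictly increasing 1-based coordinates.
    """

    population_id: str
    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("alleles columns do not match positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary 0/1")
        if self.alleles.shape[0] < 4:
            raise ValueError("need at least 4 haplotypes")
        if self.snp_ids is not None and len(self.snp_ids) != self.positions.size:
            raise ValueError("snp_ids length does not match positions")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_index(self, snp_id: str) -> int:
        if self.snp_ids is None:
            raise ValueError("panel carries no SNP ids")
        return self.snp_ids.index(snp_id)

    def derived_frequency(self, site: int) -> float:
        return float(self.alleles[:, site].mean())


# ---------------------------------------------------------------------------
# VCF ingestion (cyvcf2)

def _iter_biallelic(vcf_path):
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%s", variant.CHROM, variant.POS
            )
            continue
        yield samples, variant


def frequencies_from_genotypes(
    vcf_path, pop_map: dict[str, str], populations: list[Population] | None = None
) -> FrequencyTable:
    """Per-population ALT-allele frequencies from a VCF.

    ``pop_map`` maps sample name -> population id and must cover every sample
    in the file.  Multi-allelic records are skipped with a warning; a
    population with no called genotype at a SNP gets a missing (NaN) cell.
    """
    pop_ids: list[str] = []
    for pid in pop_map.values():
        if pid not in pop_ids:
            pop_ids.append(pid)
    snps: list[SNPRecord] = []
    freqs: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    sample_pops: list[int] | None = None
    for samples, variant in _iter_biallelic(vcf_path):
        if sample_pops is None:
            absent = [s for s in samples if s not in pop_map]
            if absent:
                raise ValueError(f"samples absent from pop_map: {absent}")
            sample_pops = [pop_ids.index(pop_map[s]) for s in samples]
        alt_counts = np.zeros(len(pop_ids))
        call_counts = np.zeros(len(pop_ids))
        for s_idx, gt in enumerate(variant.genotypes):
            for allele in gt[:-1]:  # last entry is the phasing flag
                if allele < 0:
                    continue
                call_counts[sample_pops[s_idx]] += 1
                alt_counts[sample_pops[s_idx]] += allele
        with np.errstate(invalid="ignore"):
            f = np.where(call_counts > 0, alt_counts / np.maximum(call_counts, 1), np.nan)
        aa = (variant.INFO.get("AA") or "unknown").upper()
        ancestral = aa if aa in (variant.REF, variant.ALT[0]) else "unknown"
        snps.append(
            SNPRecord(
                id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                chrom=variant.CHROM,
                pos=variant.POS,
                allele_a=variant.REF,
                allele_b=variant.ALT[0],
                ancestral=ancestral,
            )
        )
        freqs.append(f)
        counts.append(call_counts)
    if not snps:
        raise ValueError(f"{vcf_path}: no biallelic SNPs")
    if populations is None:
        populations = [Population(p, 0.0, 0.0, 1) for p in pop_ids]
    else:
        by_id = {p.id: p for p in populations}
        populations = [by_id[p] for p in pop_ids]
    return FrequencyTable(
        snps=snps, populations=populations,
        freq=np.vstack(freqs), counts=np.vstack(counts),
    )


def haplotypes_from_vcf(vcf_path, population_id: str) -> HaplotypePanel:
    """Read phased biallelic genotypes into a HaplotypePanel.

    Alleles are polarized with the INFO/AA tag when present (derived = the
    non-ancestral allele); records without AA are polarized REF=ancestral.
    All records must be phased and on one chromosome.
    """
    positions, columns, ids = [], [], []
    chrom = None
    for _, variant in _iter_biallelic(vcf_path):
        if chrom is None:
            chrom = variant.CHROM
        elif variant.CHROM != chrom:
            raise ValueError("haplotype panel spans multiple chromosomes")
        gts = np.asarray(variant.genotypes)
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"missing genotype at {variant.CHROM}:{variant.POS}")
        if not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {variant.CHROM}:{variant.POS}")
        col = gts[:, :2].reshape(-1)
        aa = (variant.INFO.get("AA") or variant.REF).upper()
        if aa == variant.ALT[0]:
            col = 1 - col
        positions.append(variant.POS)
        columns.append(col)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not positions:
        raise ValueError(f"{vcf_path}: no biallelic SNPs")
    return HaplotypePanel(
        population_id=population_id,
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=np.column_stack(columns),
        snp_ids=ids,
    )


# ---------------------------------------------------------------------------
# Per-SNP statistics

def average_maf(table: FrequencyTable, snp: int) -> float:
    """Minor-allele frequency of one SNP, folded from the unweighted mean of
    per-population allele_b frequencies over non-missing populations."""
    row = table.freq[snp]
    valid = ~np.isnan(row)
    if not valid.any():
        raise ValueError(f"SNP {table.snps[snp].id}: all populations missing")
    mean = float(row[valid].mean())
    return min(mean, 1.0 - mean)


def average_maf_all(table: FrequencyTable) -> np.ndarray:
    """Vectorized :func:`average_maf` over every SNP."""
    if np.all(np.isnan(table.freq), axis=1).any():
        raise ValueError("table contains an all-missing SNP")
    mean = np.nanmean(table.freq, axis=1)
    return np.minimum(mean, 1.0 - mean)


def assign_snps_to_genes(
    snps: list[SNPRecord], genes: list[GeneAnnotation],
    upstream: int = UPSTREAM_WINDOW,
) -> dict[str, list[str]]:
    """Map gene_id -> SNP ids within the transcript or the strand-aware
    ``upstream``-bp window before the TSS.  A SNP may land in several
    overlapping genes; genes with no SNP are omitted."""
    out: dict[str, list[str]] = {}
    by_chrom: dict[str, list[SNPRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for gene in genes:
        if gene.strand == "+":
            lo, hi = gene.tx_start - upstream, gene.tx_end
        else:
            lo, hi = gene.tx_start, gene.tx_end + upstream
        hits = [s.id for s in by_chrom.get(gene.chrom, []) if lo <= s.pos <= hi]
        if hits:
            out[gene.gene_id] = sorted(hits)
    return out


def ld_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared Pearson correlation of two binary haplotype vectors."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic site")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def collapse_by_ld(
    snp_ids: list[str],
    r2_fn,
    threshold: float = 0.4,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Collapse SNPs in LD into single loci, keeping one per linked pair.

    A single greedy pass in the given (genomic) order: each candidate is
    compared against the retained set; on a conflict (r² ≥ threshold) one of
    the two is chosen at random under ``seed``.  If the candidate wins it
    replaces the conflicting SNP only when it is itself conflict-free against
    the rest of the retained set, so the output always satisfies the pairwise
    r² < threshold audit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    retained: list[str] = []
    for cand in snp_ids:
        conflicts = [k for k, kept in enumerate(retained) if r2_fn(kept, cand) >= threshold]
        if not conflicts:
            retained.append(cand)
            continue
        if len(conflicts) == 1 and rng.random() < 0.5:
            retained[conflicts[0]] = cand  # candidate randomly wins the pair
    return retained
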