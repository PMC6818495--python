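"""Readers, writers, and in-memory containers for the formats the pipeline touches.

Coordinate conventions: VCF and all internal coordinates are 1-based
inclusive; BED is 0-based half-open on disk only and converted on read.
Genotypes are additive alt-allele counts in {0, 1, 2}, stored as float
with NaN for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = np.nan


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant. ``pos`` is 1-based; ``id`` is an optional rsID."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> str:
        """Positional key ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass
class GenotypeMatrix:
    """Samples x variants additive genotype codes with per-sample population labels.

    ``codes`` is a float array of shape (n_samples, n_variants) holding
    {0, 1, 2} or NaN for missing calls.
    """

    variants: list[VariantRecord]
    samples: list[str]
    codes: np.ndarray
    pop_labels: list[str] | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample IDs must be unique")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype codes must be 0, 1 or 2")
        if self.pop_labels is not None and len(self.pop_labels) != len(self.samples):
            raise ValueError("pop_labels length must match samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=int)

    def population_indices(self, label: str) -> np.ndarray:
        if self.pop_labels is None:
            raise ValueError("matrix carries no population labels")
        idx = np.array([i for i, l in enumerate(self.pop_labels) if l == label], dtype=int)
        if idx.size == 0:
            raise ValueError(f"population label {label!r} not present")
        return idx

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing genotypes."""
        return np.mean(~np.isfinite(self.codes), axis=0)


def allele_frequency(matrix: GenotypeMatrix, group: Sequence[str] | np.ndarray | None = None) -> np.ndarray:
    """Per-variant alt-allele frequency over a sample subset.

    ``group`` may be sample names or integer indices; None means all samples.
    Frequency = alt alleles / (2 x non-missing genotypes); a variant with no
    typed genotype in the group gets NaN.
    """
    if group is None:
        idx = np.arange(matrix.n_samples)
    elif len(group) == 0:
        raise ValueError("group must be non-empty")
    elif all(isinstance(g, (int, np.integer)) for g in group):
        idx = np.asarray(group, dtype=int)
    else:
        idx = matrix.sample_indices(group)
    sub = matrix.codes[idx]
    typed = np.isfinite(sub)
    n_typed = typed.sum(axis=0)
    alt = np.where(typed, sub, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_typed > 0, alt / (2.0 * n_typed), np.nan)
    return freq


def read_vcf(path: str | Path, region: tuple[str, int, int] | None = None) -> GenotypeMatrix:
    """Read a VCF with GT fields into a GenotypeMatrix.

    Multi-allelic records are skipped (counted in the log); any genotype with
    an unknown or non-{0,1} allele, including half-calls, maps to missing.
    ``region`` is an optional (chrom, start, end) 1-based inclusive filter
    applied while streaming, so no tabix index is required.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    prev: tuple[str, int] | None = None
    sorted_ok = True
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if region is not None:
            chrom, start, end = region
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        if prev is not None and v.CHROM == prev[0] and v.POS < prev[1]:
            sorted_ok = False
        prev = (v.CHROM, v.POS)
        codes = np.full(len(samples), MISSING)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a in (0, 1) and b in (0, 1):
                codes[i] = a + b
        variants.append(
            VariantRecord(v.CHROM, v.POS, v.REF, v.ALT[0], v.ID if v.ID not in (None, ".") else None)
        )
        rows.append(codes)
    vcf.close()
    if n_multi:
        log.warning("skipped %d multi-allelic record(s) in %s", n_multi, path)
    if not sorted_ok:
        log.info("input VCF %s is not coordinate-sorted", path)
    codes = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(variants, samples, codes)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 with GT-only genotypes."""
    code_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples) + "\n")
        for j, var in enumerate(matrix.variants):
            gts = [code_to_gt.get(c, "./.") if np.isfinite(c) else "./." for c in matrix.codes[:, j]]
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id or '.'}\t{var.ref_allele}\t{var.alt_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class IntervalTrack:
    """A list of intervals; internally 1-based inclusive (BED on disk only)."""

    records: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for r in self.records:
            out.setdefault(r.chrom, []).append(r)
        for lst in out.values():
            lst.sort(key=lambda r: (r.start, r.end))
        return out


def read_interval_track(path: str | Path) -> IntervalTrack:
    """Read a BED3+ file; disk coordinates 0-based half-open become 1-based inclusive."""
    records: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else None
            records.append(Interval(chrom, start + 1, end, name))
    return IntervalTrack(records)


def write_interval_track(track: IntervalTrack, path: str | Path) -> None:
    """Write a track back to BED (converting to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in track.records:
            cols = [r.chrom, str(r.start - 1), str(r.end)]
            if r.name is not None:
                cols.append(r.name)
            fh.write("\t".join(cols) + "\n")


class KnownSet:
    """Membership set of known variants queryable by rsID or positional key."""

    def __init__(self, keys: Iterable[str] = ()):
        self._keys: set[str] = set()
        for k in keys:
            self.add(k)

    def add(self, key: str) -> None:
        self._keys.add(key.strip())

    def __contains__(self, item) -> bool:
        if isinstance(item, VariantRecord):
            return (item.id is not None and item.id in self._keys) or item.key in self._keys
        return item in self._keys

    def __len__(self) -> int:
        return len(self._keys)


def read_known_set(path: str | Path) -> KnownSet:
    """Read a plain-text list of rsIDs and/or chrom:pos:ref:alt keys (one per line)."""
    ks = KnownSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ks.add(line)
    return ks


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV (sample, sex, then trait columns) indexed by sample.

    Quantitative traits are numeric with NaN for missing; binary traits may
    use case/control/missing strings.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ValueError("phenotype table must have a 'sample' column")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample IDs in phenotype table")
    return df.set_index("sample")


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample")
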