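"""Weir & Cockerham (1984) per-site Fst between two populations.

The estimator decomposes allele-frequency variance into three components:
``a`` among populations, ``b`` among individuals within populations, and
``c`` within individuals (heterozygosity); theta = a / (a + b + c).
Negative estimates are retained (no clamping), matching common
VCFtools-style output, and sites monomorphic in the pooled sample yield an
undefined (NaN) theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, VariantRecord


@dataclass
class FstComponents:
    """Per-site WC variance components. All fields may be arrays or scalars."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _wc_components(n1, p1, h1, n2, p2, h2) -> FstComponents:
    """Vectorised WC (1984) a, b, c for r=2 populations.

    n_i: (possibly real-valued) number of typed individuals per population;
    p_i: alt-allele frequency; h_i: observed heterozygote frequency.
    """
    n1, p1, h1 = np.asarray(n1, float), np.asarray(p1, float), np.asarray(h1, float)
    n2, p2, h2 = np.asarray(n2, float), np.asarray(p2, float), np.asarray(h2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return FstComponents(a=a, b=b, c=c)


def site_fst_from_counts(
    genotype_counts_pop1: tuple[float, float, float],
    genotype_counts_pop2: tuple[float, float, float],
) -> FstComponents:
    """WC components from per-population genotype counts (n_AA, n_Aa, n_aa).

    Counts may be real-valued (HWE-expected counts are allowed). Each
    population must contribute at least two typed individuals. A site
    monomorphic in both populations has theta NaN (a = b = c = 0).
    """
    out = []
    for counts in (genotype_counts_pop1, genotype_counts_pop2):
        nAA, nAa, naa = (float(x) for x in counts)
        if min(nAA, nAa, naa) < 0:
            raise ValueError("genotype counts must be non-negative")
        n = nAA + nAa + naa
        if n < 2:
            raise ValueError("each population needs >= 2 typed individuals")
        # allele A is treated as the counted allele
        p = (2 * nAA + nAa) / (2 * n)
        h = nAa / n
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out
    return _wc_components(n1, p1, h1, n2, p2, h2)


def site_fst_from_frequencies(p1: float, n1: float, p2: float, n2: float) -> FstComponents:
    """Convenience path for frequency-only inputs via HWE-expected genotype counts."""
    return site_fst_from_counts(
        (n1 * p1**2, 2 * n1 * p1 * (1 - p1), n1 * (1 - p1) ** 2),
        (n2 * p2**2, 2 * n2 * p2 * (1 - p2), n2 * (1 - p2) ** 2),
    )


@dataclass
class FstScanResult:
    """Genome-wide per-site theta plus the empirical-tail summary."""

    variants: list[VariantRecord]
    theta: np.ndarray  # NaN where undefined or site excluded
    mean_theta: float  # over defined sites, negatives included
    n_defined: int
    cutoff: float | None  # empirical cutoff at tail_p, None if not requested/undefined
    tail_p: float | None
    top_variants: list[VariantRecord] = field(default_factory=list)
    n_excluded_missing: int = 0
    n_skipped: int = 0  # fewer than 2 typed individuals in a population

    def empirical_p(self) -> np.ndarray:
        """Per-site empirical P = #{theta_j >= theta_i} / N over defined sites."""
        vals = self.theta
        defined = np.isfinite(vals)
        p = np.full(vals.shape, np.nan)
        if defined.sum():
            v = vals[defined]
            order = np.sort(v)
            # #{>= x} = N - (number strictly below x)
            p[defined] = (v.size - np.searchsorted(order, v, side="left")) / v.size
        return p


def empirical_cutoff(theta_values: np.ndarray, tail_p: float) -> float | None:
    """Smallest observed theta whose empirical tail probability is < tail_p.

    Empirical P of x = #{theta >= x} / N. Returns None when no observed
    value qualifies (e.g. all values equal).
    """
    vals = np.asarray(theta_values, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite theta values")
    if not (0.0 < tail_p < 1.0):
        raise ValueError("tail_p must be in (0, 1)")
    order = np.sort(vals)
    n = vals.size
    # empirical P of order[i] = (n - first index of order[i]) / n
    first_idx = np.searchsorted(order, order, side="left")
    tailprob = (n - first_idx) / n
    qualifying = order[tailprob < tail_p]
    if qualifying.size == 0:
        return None
    return float(qualifying[0])


def fst_scan(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    max_missing_rate: float = 0.5,
    tail_p: float | None = None,
) -> FstScanResult:
    """Per-site WC theta over all variants between two labeled populations.

    Sites with pooled missing rate strictly above ``max_missing_rate`` are
    excluded; theta is computed from observed genotype counts. Indels are
    carried through with NaN theta (the scan is SNV-only). The mean is taken
    over defined thetas, negatives included.
    """
    ia = matrix.population_indices(pop_a)
    ib = matrix.population_indices(pop_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("each population needs >= 2 samples")
    sub = matrix.codes[np.concatenate([ia, ib])]
    miss_rate = np.mean(~np.isfinite(sub), axis=0)
    snv = np.array([v.is_snv for v in matrix.variants], dtype=bool)

    theta = np.full(matrix.n_variants, np.nan)
    n_skipped = 0
    usable = (miss_rate <= max_missing_rate) & snv
    ga, gb = matrix.codes[ia], matrix.codes[ib]

    def pop_stats(g):
        typed = np.isfinite(g)
        n = typed.sum(axis=0).astype(float)
        alt = np.where(typed, g, 0.0).sum(axis=0)
        het = np.where(typed, g == 1.0, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, het / n, np.nan)
        return n, p, h

    n1, p1, h1 = pop_stats(ga)
    n2, p2, h2 = pop_stats(gb)
    ok = usable & (n1 >= 2) & (n2 >= 2)
    n_skipped = int((usable & ~ok).sum())
    if ok.any():
        comp = _wc_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
        theta[ok] = comp.theta

    defined = np.isfinite(theta)
    mean_theta = float(np.mean(theta[defined])) if defined.any() else float("nan")
    cutoff = None
    top: list[VariantRecord] = []
    if tail_p is not None and defined.any():
        cutoff = empirical_cutoff(theta[defined], tail_p)
        if cutoff is not None:
            top = [v for v, t in zip(matrix.variants, theta) if np.isfinite(t) and t >= cutoff]
    return FstScanResult(
        variants=matrix.variants,
        theta=theta,
        mean_theta=mean_theta,
        n_defined=int(defined.sum()),
        cutoff=cutoff,
        tail_p=tail_p,
        top_variants=top,
        n_excluded_missing=int((miss_rate > max_missing_rate).sum()),
        n_skipped=n_skipped,
    )


def scan_to_frame(result: FstScanResult):
    """Tabular (chrom, pos, id, theta, empirical_p) view of a scan."""
    import pandas as pd

    p = result.empirical_p()
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in result.variants],
            "pos": [v.pos for v in result.variants],
            "id": [v.id or "." for v in result.variants],
            "theta": result.theta,
            "empirical_p": p,
        }
    )
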