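"""Enhancer-promoter linking from DNase I hypersensitivity across cell types.

A distal DHS is linked to a gene when the Pearson correlation of its signal
with a promoter DHS of that gene across cell types exceeds 0.7 (strict) and
the two sites lie within +/-500 kb (midpoint-to-midpoint, inclusive).
Variants falling inside a linked distal DHS inherit its candidate target
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VariantRecord

META_COLUMNS = ("chrom", "start", "end", "site_class", "gene", "name")


@dataclass(frozen=True)
class DHSLink:
    distal_index: int
    promoter_index: int
    gene: str
    r: float
    distance: int
    distal_chrom: str
    distal_start: int
    distal_end: int


def _validate_matrix(matrix: pd.DataFrame) -> list[str]:
    for col in META_COLUMNS:
        if col == "name":
            continue  # optional site label
        if col not in matrix.columns:
            raise ValueError(f"DHS matrix missing column {col!r}")
    signal_cols = [c for c in matrix.columns if c not in META_COLUMNS]
    if len(signal_cols) < 2:
        raise ValueError("need >= 2 cell-type signal columns")
    bad = set(matrix["site_class"]) - {"promoter", "distal"}
    if bad:
        raise ValueError(f"unknown site classes: {sorted(bad)}")
    return signal_cols


def link_dhs(
    matrix: pd.DataFrame,
    window: int = 500_000,
    r_min: float = 0.7,
    zscore: bool = False,
) -> list[DHSLink]:
    """Emit (distal, promoter) links with Pearson r > r_min within the window.

    ``matrix`` rows are DHS sites (columns chrom, start, end, site_class,
    gene, then one signal column per cell type). Promoter rows must carry a
    gene label. Pairs with a zero-variance signal vector are skipped.
    ``zscore`` optionally standardises each site's signal first (this does
    not change Pearson r but mirrors normalised-signal inputs).
    """
    signal_cols = _validate_matrix(matrix)
    sig = matrix[signal_cols].to_numpy(float)
    if zscore:
        sd = sig.std(axis=1, keepdims=True)
        sig = np.where(sd > 0, (sig - sig.mean(axis=1, keepdims=True)) / sd, sig)
    mid = ((matrix["start"].to_numpy() + matrix["end"].to_numpy()) / 2.0)
    is_prom = (matrix["site_class"] == "promoter").to_numpy()
    links: list[DHSLink] = []
    for di in np.flatnonzero(~is_prom):
        for pi in np.flatnonzero(is_prom):
            if matrix["chrom"].iat[di] != matrix["chrom"].iat[pi]:
                continue
            dist = abs(mid[di] - mid[pi])
            if dist > window:
                continue
            x, y = sig[di], sig[pi]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if r > r_min:
                gene = matrix["gene"].iat[pi]
                if gene is None or (isinstance(gene, float) and np.isnan(gene)):
                    raise ValueError(f"promoter row {pi} lacks a gene label")
                links.append(
                    DHSLink(
                        distal_index=int(di),
                        promoter_index=int(pi),
                        gene=str(gene),
                        r=r,
                        distance=int(round(dist)),
                        distal_chrom=str(matrix["chrom"].iat[di]),
                        distal_start=int(matrix["start"].iat[di]),
                        distal_end=int(matrix["end"].iat[di]),
                    )
                )
    return links


def map_snps_to_links(
    snps: list[VariantRecord], links: list[DHSLink]
) -> pd.DataFrame:
    """Assign SNPs falling inside a linked distal DHS to that link's gene.

    One output row per (SNP, link); a SNP inside a distal DHS linked to two
    promoters yields two candidate genes. Also reports the SNP-to-promoter
    distance (SNP position to the link's recorded midpoint distance anchor
    is approximated by the link distance). The summary mean distance is the
    mean over assignment rows.
    """
    rows = []
    for snp in snps:
        for ln in links:
            if snp.chrom == ln.distal_chrom and ln.distal_start <= snp.pos <= ln.distal_end:
                rows.append(
                    {
                        "snp": snp.id or snp.key,
                        "chrom": snp.chrom,
                        "pos": snp.pos,
                        "gene": ln.gene,
                        "r": ln.r,
                        "distance": ln.distance,
                    }
                )
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "gene", "r", "distance"])
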