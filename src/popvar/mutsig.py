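"""Mutational-signature analysis of novel singleton SNVs.

Workflow: extract variants carried by exactly one cohort member, well
supported by reads and absent from the known-variant database; classify
each into one of the 96 pyrimidine-centered trinucleotide contexts; refit
the per-sample 96-count vectors against a reference signature catalogue by
non-negative least squares (de novo NMF is available as an alternative);
compare signature proportions between groups and regress a signature load
on genotypes genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix, KnownSet, VariantRecord

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 96 context labels, substitution-major then upstream then downstream base
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{up}[{sub}]{down}" for sub in SUBSTITUTIONS for up in BASES for down in BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def classify_context(snv: VariantRecord, trinucleotide: str) -> str:
    """Map an SNV plus its reference trinucleotide to one of the 96 class labels.

    Purine-centered mutations are reverse-complemented into the
    pyrimidine-centered convention. Raises ValueError for ambiguous (non-ACGT)
    bases; callers typically skip and count those.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3:
        raise ValueError(f"trinucleotide must have length 3, got {trinucleotide!r}")
    ref, alt = snv.ref_allele.upper(), snv.alt_allele.upper()
    if any(b not in BASES for b in tri) or alt not in BASES:
        raise ValueError(f"ambiguous base in context {tri} or alt {alt}")
    if tri[1] != ref:
        raise ValueError(f"context middle base {tri[1]} != ref allele {ref}")
    if ref in ("G", "A"):  # purine-centered: flip strand
        tri = reverse_complement(tri)
        ref = COMPLEMENT[snv.ref_allele.upper()]
        alt = COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


@dataclass
class SingletonSet:
    """Per-sample novel singleton SNVs with read support."""

    by_sample: dict[str, list[tuple[VariantRecord, int]]]
    n_dropped_shared: int = 0
    n_dropped_support: int = 0
    n_dropped_known: int = 0

    def sample_counts(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.by_sample.items()}


def extract_novel_singletons(
    calls: dict[str, list[tuple[VariantRecord, int]]],
    known: KnownSet,
    min_support: int = 11,
) -> SingletonSet:
    """Keep variants carried by exactly one sample, supported by at least
    ``min_support`` reads ("more than 10" => >= 11) and absent from the
    known-variant set.
    """
    carriers: dict[str, list[str]] = {}
    for sample, lst in calls.items():
        for var, _support in lst:
            carriers.setdefault(var.key, []).append(sample)
    out: dict[str, list[tuple[VariantRecord, int]]] = {s: [] for s in calls}
    n_shared = n_support = n_known = 0
    for sample, lst in calls.items():
        for var, support in lst:
            if len(carriers[var.key]) != 1:
                n_shared += 1
                continue
            if support < min_support:
                n_support += 1
                continue
            if var in known:
                n_known += 1
                continue
            out[sample].append((var, support))
    return SingletonSet(out, n_shared, n_support, n_known)


@dataclass
class MutationContextMatrix:
    """Samples x 96 non-negative context counts."""

    samples: list[str]
    counts: np.ndarray  # (n_samples, 96) ints
    n_skipped_ambiguous: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), 96):
            raise ValueError("counts must be n_samples x 96")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=list(CONTEXT_LABELS))


def build_context_matrix(
    singletons: SingletonSet, reference: dict[str, str]
) -> MutationContextMatrix:
    """Tally each sample's singletons into the 96 context classes.

    ``reference`` maps chromosome name to its sequence (1-based positions
    index ``seq[pos - 1]``). Variants with an ambiguous (N) context are
    skipped and counted; row sums equal per-sample singleton counts minus
    skips.
    """
    samples = sorted(singletons.by_sample)
    counts = np.zeros((len(samples), 96), dtype=int)
    skipped = 0
    for i, sample in enumerate(samples):
        for var, _support in singletons.by_sample[sample]:
            if var.chrom not in reference:
                raise KeyError(f"chromosome {var.chrom} not in reference ({var.key})")
            seq = reference[var.chrom]
            if not (2 <= var.pos <= len(seq) - 1):
                raise IndexError(f"variant {var.key} context outside reference")
            tri = seq[var.pos - 2 : var.pos + 1].upper()
            try:
                label = classify_context(var, tri)
            except ValueError:
                skipped += 1
                continue
            counts[i, _LABEL_INDEX[label]] += 1
    return MutationContextMatrix(samples, counts, n_skipped_ambiguous=skipped)


@dataclass
class SignatureMatrix:
    """96 x K reference profiles; every column sums to 1."""

    names: list[str]
    profiles: np.ndarray  # (96, K)

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, float)
        if self.profiles.shape != (96, len(self.names)):
            raise ValueError("profiles must be 96 x K")
        if (self.profiles < 0).any():
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature columns must sum to 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        df = df.reindex(list(CONTEXT_LABELS))
        if df.isna().any().any():
            raise ValueError("signature table missing context rows")
        return cls(list(df.columns), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=list(CONTEXT_LABELS), columns=self.names)


@dataclass
class ExposureMatrix:
    """Samples x K non-negative signature loads (attributed mutation counts)."""

    samples: list[str]
    signatures: list[str]
    loads: np.ndarray  # (n_samples, K)
    residuals: np.ndarray  # per-sample residual norm
    zero_samples: list[str] = field(default_factory=list)

    @property
    def proportions(self) -> np.ndarray:
        totals = self.loads.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.loads / totals, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loads, index=self.samples, columns=self.signatures)


def refit_exposures(counts: MutationContextMatrix, reference: SignatureMatrix) -> ExposureMatrix:
    """Per-sample NNLS refit: minimise ||m - S e||_2 subject to e >= 0."""
    S = reference.profiles
    if np.linalg.matrix_rank(S) < S.shape[1]:
        import logging

        logging.getLogger(__name__).warning("signature columns are linearly dependent")
    loads = np.zeros((len(counts.samples), S.shape[1]))
    resid = np.zeros(len(counts.samples))
    zeros = []
    for i, row in enumerate(counts.counts):
        if row.sum() == 0:
            zeros.append(counts.samples[i])
            continue
        loads[i], resid[i] = optimize.nnls(S, row.astype(float))
    return ExposureMatrix(counts.samples, list(reference.names), loads, resid, zeros)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def denovo_nmf(
    counts: MutationContextMatrix,
    rank: int,
    reference: SignatureMatrix | None = None,
    restarts: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, float]] | None]:
    """Best-of-restarts NMF of the count matrix into (exposures, signatures).

    Returns (W, H) with W samples x rank and H rank x 96 (rows L1-normalised,
    exposures rescaled to compensate), plus, when a reference catalogue is
    given, each factor's best cosine match as (name, similarity).
    """
    from sklearn.decomposition import NMF

    if not (1 <= rank <= min(len(counts.samples), 96)):
        raise ValueError(f"rank {rank} out of range")
    X = counts.counts.astype(float)
    best = None
    for r in range(restarts):
        model = NMF(
            n_components=rank,
            init="random",
            random_state=seed + r,
            max_iter=2000,
            tol=1e-8,
        )
        W = model.fit_transform(X)
        H = model.components_
        err = np.linalg.norm(X - W @ H)
        if best is None or err < best[0]:
            best = (err, W, H)
    _, W, H = best
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    H = H / scale[:, None]
    W = W * scale[None, :]
    matches = None
    if reference is not None:
        matches = []
        for k in range(rank):
            sims = [cosine_similarity(H[k], reference.profiles[:, j]) for j in range(len(reference.names))]
            j = int(np.argmax(sims))
            matches.append((reference.names[j], float(sims[j])))
    return W, H, matches


def compare_signature_loads(
    proportions: np.ndarray, groups: np.ndarray | list
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum P per signature between two groups.

    ``proportions`` is samples x K (row-normalised exposures); ``groups`` a
    two-level label vector. Exact P when combined n <= 20, normal
    approximation with continuity correction otherwise.
    """
    proportions = np.asarray(proportions, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {list(levels)}")
    ga = proportions[groups == levels[0]]
    gb = proportions[groups == levels[1]]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(ga) + len(gb)) <= 20 else "asymptotic"
    pvals = np.empty(proportions.shape[1])
    for k in range(proportions.shape[1]):
        try:
            res = stats.mannwhitneyu(ga[:, k], gb[:, k], alternative="two-sided", method=method)
        except ValueError:  # ties prevent the exact method
            res = stats.mannwhitneyu(ga[:, k], gb[:, k], alternative="two-sided", method="asymptotic")
        pvals[k] = min(res.pvalue, 1.0)
    return pvals


def signature_load_gwas(
    matrix: GenotypeMatrix,
    load: np.ndarray,
    maf_min: float = 0.05,
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Per-SNP simple linear regression of a signature load on additive genotype.

    SNPs with minor-allele frequency below ``maf_min`` or monomorphic are
    excluded. Returns a table with slope, standard error, P and a
    ``significant`` flag at ``alpha``.
    """
    load = np.asarray(load, float)
    if load.shape[0] != matrix.n_samples:
        raise ValueError("load must have one value per sample")
    if np.nanstd(load) == 0:
        raise ValueError("signature load has zero variance")
    rows = []
    for j, var in enumerate(matrix.variants):
        g = matrix.codes[:, j]
        keep = np.isfinite(g) & np.isfinite(load)
        g_, y_ = g[keep], load[keep]
        if g_.size < 3 or np.all(g_ == g_[0]):
            continue
        af = g_.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf < maf_min:
            continue
        slope, se, p = _ols_slope(g_, y_)
        rows.append(
            {
                "chrom": var.chrom,
                "pos": var.pos,
                "id": var.id or ".",
                "maf": maf,
                "slope": slope,
                "se": se,
                "p": p,
                "n": g_.size,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "maf", "slope", "se", "p", "n", "significant"]
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, SE and two-sided P of simple OLS y ~ x."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        return np.nan, np.nan, np.nan
    slope = ((x - xm) * (y - ym)).sum() / sxx
    resid = y - ym - slope * (x - xm)
    dof = n - 2
    if dof <= 0:
        return slope, np.nan, np.nan
    s2 = (resid**2).sum() / dof
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return slope, 0.0, 0.0 if slope != 0 else 1.0
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(slope), float(se), float(p)
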