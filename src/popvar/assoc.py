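"""Genotype-phenotype association and trait-catalog enrichment.

Quantitative traits are rank-inverse-normal transformed (Blom offsets) and
regressed on additive genotype by per-SNP OLS; binary traits use logistic
regression with separation detection. Sex effects are handled by
stratification rather than covariates. Gene-set enrichment uses the
one-sided hypergeometric upper tail with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix


def normalize_trait(values: np.ndarray | pd.Series, method: str = "blom") -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    z_i = Phi^{-1}((rank_i - 3/8) / (n + 1/4)) over non-missing values;
    missing entries are preserved as NaN. ``method='zscore'`` standardises
    instead. A constant trait is an error.
    """
    v = np.asarray(values, float)
    mask = np.isfinite(v)
    x = v[mask]
    if x.size < 3:
        raise ValueError("need >= 3 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("trait is constant")
    out = np.full(v.shape, np.nan)
    if method == "blom":
        ranks = stats.rankdata(x, method="average")
        out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))
    elif method == "zscore":
        out[mask] = (x - x.mean()) / x.std(ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


@dataclass(frozen=True)
class AssocRow:
    snp_id: str
    effect: float
    se: float
    p: float
    n: int
    flag: str | None = None


def _stratum_indices(matrix: GenotypeMatrix, stratum) -> np.ndarray:
    if stratum is None:
        return np.arange(matrix.n_samples)
    if isinstance(stratum, np.ndarray) and stratum.dtype == bool:
        return np.flatnonzero(stratum)
    return matrix.sample_indices(stratum)


def quantitative_assoc(
    matrix: GenotypeMatrix,
    trait: np.ndarray,
    stratum=None,
) -> pd.DataFrame:
    """Per-SNP OLS of a (normalised) quantitative trait on additive genotype.

    ``stratum`` restricts the samples used (names, indices, or boolean
    mask); SNPs monomorphic within the stratum are skipped. At least 10
    typed samples with the trait are required.
    """
    trait = np.asarray(trait, float)
    idx = _stratum_indices(matrix, stratum)
    y = trait[idx]
    G = matrix.codes[idx]
    if np.isfinite(y).sum() < 10:
        raise ValueError("stratum needs >= 10 samples with the trait")
    rows = []
    for j, var in enumerate(matrix.variants):
        g = G[:, j]
        keep = np.isfinite(g) & np.isfinite(y)
        g_, y_ = g[keep], y[keep]
        if g_.size < 3 or np.all(g_ == g_[0]):
            continue
        slope, se, p = _ols(g_, y_)
        rows.append({"id": var.id or var.key, "effect": slope, "se": se, "p": p, "n": int(g_.size)})
    return pd.DataFrame(rows, columns=["id", "effect", "se", "p", "n"])


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    resid = y - ym - slope * (x - xm)
    dof = n - 2
    s2 = (resid**2).sum() / dof if dof > 0 else np.nan
    se = np.sqrt(s2 / sxx)
    if not np.isfinite(se) or se == 0:
        return float(slope), float(se), np.nan
    t = slope / se
    return float(slope), float(se), float(2 * stats.t.sf(abs(t), dof))


def binary_assoc(
    matrix: GenotypeMatrix,
    status: np.ndarray,
    stratum=None,
) -> pd.DataFrame:
    """Per-SNP logistic regression of case/control status on additive genotype.

    ``status`` is 0/1 (NaN missing). Requires >= 5 cases and >= 5 controls
    in the stratum. Complete separation is flagged and leaves no finite
    estimate.
    """
    import statsmodels.api as sm

    status = np.asarray(status, float)
    idx = _stratum_indices(matrix, stratum)
    y = status[idx]
    G = matrix.codes[idx]
    ok = np.isfinite(y)
    n_case, n_ctrl = int((y[ok] == 1).sum()), int((y[ok] == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("stratum contains a single outcome class")
    if n_case < 5 or n_ctrl < 5:
        raise ValueError("need >= 5 cases and >= 5 controls")
    rows = []
    for j, var in enumerate(matrix.variants):
        g = G[:, j]
        keep = np.isfinite(g) & np.isfinite(y)
        g_, y_ = g[keep], y[keep]
        if g_.size < 3 or np.all(g_ == g_[0]):
            continue
        X = sm.add_constant(g_)
        flag = None
        logodds = se = p = np.nan
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y_, X).fit(disp=0, maxiter=100)
            logodds, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            if not fit.mle_retvals.get("converged", True) or abs(logodds) > 15 or se > 100:
                flag = "separation"
                logodds = se = p = np.nan
        except Exception:
            flag = "separation"
        rows.append(
            {"id": var.id or var.key, "effect": logodds, "se": se, "p": p,
             "n": int(g_.size), "flag": flag}
        )
    return pd.DataFrame(rows, columns=["id", "effect", "se", "p", "n", "flag"])


def genotype_stratified_test(
    trait: np.ndarray, genotypes: np.ndarray, group_codes: set | tuple = (2,)
) -> tuple[float, float]:
    """Welch two-sided t-test of a trait between genotype groups.

    ``group_codes`` defines the first group (e.g. {2} for the homozygous-alt
    vs other split); the second group is everything else. Identical groups
    (zero pooled variance, equal means) give (0.0, 1.0).
    """
    trait = np.asarray(trait, float)
    genotypes = np.asarray(genotypes, float)
    keep = np.isfinite(trait) & np.isfinite(genotypes)
    t_, g_ = trait[keep], genotypes[keep]
    in_a = np.isin(g_, list(group_codes))
    a, b = t_[in_a], t_[~in_a]
    if a.size < 2 or b.size < 2:
        raise ValueError("both genotype groups need >= 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def trait_enrichment(
    input_genes: set[str],
    catalog: dict[str, set[str]],
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of an input gene set against a trait catalog.

    For each term with gene set T in a background universe of size M, the
    one-sided upper-tail P is P(X >= |input & T|) with X ~
    Hypergeom(M, |T|, |input|). BH correction is applied across terms.
    ``background`` defaults to the union of all catalog gene sets.
    """
    from statsmodels.stats.multitest import multipletests

    if background is None:
        background = set().union(*catalog.values()) if catalog else set()
    if not input_genes <= background:
        raise ValueError("input genes must be a subset of the background")
    M = len(background)
    n = len(input_genes)
    rows = []
    for term, genes in sorted(catalog.items()):
        if not genes <= background:
            raise ValueError(f"term {term!r} has genes outside the background")
        K = len(genes)
        k = len(input_genes & genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "n_input": k, "n_background": K, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "n_input", "n_background", "p"])
    if not df.empty:
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_bh"] = []
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)
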