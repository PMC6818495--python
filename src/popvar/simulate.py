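"""Synthetic data generators mirroring the statistical structure of a
two-population WGS cohort study.

The defaults emulate the study conditions the pipeline targets: a cohort of
339 + 116 diploid individuals from two subpopulations, per-site
differentiation under the Balding-Nichols model (F is the target Fst),
novel singleton SNVs drawn from known signature mixtures, SV truth sets
with per-sample breakpoint jitter, additive heritable phenotypes, and DHS
signal matrices with planted enhancer-promoter correlations. Every
generator is a pure function of its config: the same seed reproduces the
same data, and each dataset returns its generating truth alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Interval, IntervalTrack, KnownSet, VariantRecord
from .mutsig import BASES, CONTEXT_LABELS, SignatureMatrix, reverse_complement
from .sv import SVCall


@dataclass
class SimConfig:
    """Parameters for all generators; ``seed`` drives every random draw."""

    seed: int
    n_pop1: int = 339
    n_pop2: int = 116
    n_sites: int = 2000
    F: float = 0.0015
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    pop_names: tuple[str, str] = ("NH", "SH")
    # singletons
    mutations_per_sample: int = 1000
    reference_length: int = 60_000
    known_fraction: float = 0.0
    shared_fraction: float = 0.0
    min_support: int = 11
    # SVs
    sv_jitter_sd: float = 0.0
    # phenotypes
    phenotype_noise_sd: float = 1.0
    # DHS
    n_cell_types: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.F < 1.0):
            raise ValueError("F must be in [0, 1)")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_two_pop_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Balding-Nichols two-population genotypes.

    Per site: ancestral p ~ Uniform(range); per-population frequencies
    p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (p_i = p when F = 0); genotypes ~
    Binomial(2, p_i). Optional missingness is masked uniformly at random.
    """
    rng = _rng(config, 1)
    lo, hi = config.ancestral_af_range
    p_anc = rng.uniform(lo, hi, config.n_sites)
    if config.F == 0.0:
        p1 = p2 = p_anc
    else:
        a = p_anc * (1 - config.F) / config.F
        b = (1 - p_anc) * (1 - config.F) / config.F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    g1 = rng.binomial(2, p1, size=(config.n_pop1, config.n_sites)).astype(float)
    g2 = rng.binomial(2, p2, size=(config.n_pop2, config.n_sites)).astype(float)
    codes = np.vstack([g1, g2])
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = np.nan
    variants = [
        VariantRecord("chr1", 1000 + 10 * j, "A", "G", id=f"sim{j}")
        for j in range(config.n_sites)
    ]
    samples = [f"{config.pop_names[0]}_{i:04d}" for i in range(config.n_pop1)] + [
        f"{config.pop_names[1]}_{i:04d}" for i in range(config.n_pop2)
    ]
    labels = [config.pop_names[0]] * config.n_pop1 + [config.pop_names[1]] * config.n_pop2
    truth = {
        "config": asdict(config),
        "ancestral_af": p_anc.tolist(),
        "pop1_af": np.asarray(p1).tolist(),
        "pop2_af": np.asarray(p2).tolist(),
    }
    return GenotypeMatrix(variants, samples, codes, labels), truth


def simulate_outgroup_panel(
    config: SimConfig, n_specific: int = 10, n_null: int = 90, gap: float = 0.4
) -> tuple[pd.DataFrame, dict]:
    """Outgroup frequency panel with ``n_specific`` sites passing the
    population-specific screen by construction (cohort AF exceeds every
    outgroup by ``gap``) and ``n_null`` sites that do not.
    """
    rng = _rng(config, 2)
    rows, planted = [], []
    for i in range(n_specific + n_null):
        rsid = f"rs{900000 + i}"
        if i < n_specific and gap > 0:
            cas = rng.uniform(max(gap, 0.5), 1.0)
            outs = {g: rng.uniform(0.0, cas - gap) for g in ("sas", "afr", "amr", "eur")}
            planted.append(rsid)
        else:
            cas = rng.uniform(0.0, 1.0)
            outs = {g: rng.uniform(0.0, 1.0) for g in ("sas", "afr", "amr", "eur")}
            # pin one outgroup within 0.25 of the cohort so neither allele
            # orientation can reach the 0.3 gap on all four outgroups
            outs["sas"] = float(np.clip(cas + rng.uniform(-0.25, 0.25), 0.0, 1.0))
        rows.append(
            {
                "id": rsid,
                "chrom": "chr2",
                "pos": 5000 + 10 * i,
                "allele": "T",
                "af_cas": cas,
                "af_eas": min(1.0, max(0.0, cas + rng.normal(0, 0.02))),
                **{f"af_{g}": v for g, v in outs.items()},
            }
        )
    truth = {"planted": planted, "gap": gap}
    return pd.DataFrame(rows), truth


def simulate_singletons(
    config: SimConfig, signatures: SignatureMatrix, weights: np.ndarray, n_samples: int = 10
) -> tuple[dict[str, list[tuple[VariantRecord, int]]], dict[str, str], KnownSet, dict]:
    """Per-sample singleton SNV calls drawn from a signature mixture.

    A random reference chromosome is generated; each sample draws mutation
    context classes from sum_k w_k s_k and positions whose reference
    trinucleotide matches (pyrimidine-centered or its reverse complement).
    Read support is drawn at or above ``min_support``. A configurable
    fraction of calls is planted into the known set or duplicated into a
    second sample to exercise the singleton filters. Returns (calls,
    reference, known set, truth).
    """
    weights = np.asarray(weights, float)
    if len(weights) != len(signatures.names):
        raise ValueError("one weight per signature required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    rng = _rng(config, 3)
    seq = "".join(rng.choice(list(BASES), config.reference_length))
    reference = {"chrS": seq}
    # index positions by pyrimidine-centered trinucleotide class
    index: dict[str, list[int]] = {}
    for pos in range(2, len(seq)):  # 1-based center positions 2..L-1
        tri = seq[pos - 2 : pos + 1]
        if tri[1] in ("C", "T"):
            index.setdefault(tri, []).append(pos)
        else:
            index.setdefault(reverse_complement(tri), []).append(pos)
    mixture = signatures.profiles @ weights
    mixture = mixture / mixture.sum()
    calls: dict[str, list[tuple[VariantRecord, int]]] = {}
    known = KnownSet()
    samples = [f"S{i:03d}" for i in range(n_samples)]
    used_positions: set[int] = set()
    truth_contexts: dict[str, list[str]] = {}
    for s_i, sample in enumerate(samples):
        calls.setdefault(sample, [])
        truth_contexts[sample] = []
        classes = rng.choice(96, size=config.mutations_per_sample, p=mixture)
        for cls in classes:
            label = CONTEXT_LABELS[cls]
            up, sub, down = label[0], label[2:5], label[6]
            tri = up + sub[0] + down
            candidates = index.get(tri, [])
            pos = None
            for _ in range(50):
                cand = int(candidates[rng.integers(len(candidates))])
                if cand not in used_positions:
                    pos = cand
                    break
            if pos is None:
                continue
            used_positions.add(pos)
            ref_base = seq[pos - 1]
            alt_base = sub[2]
            if ref_base != sub[0]:  # purine strand: emit the reverse complement
                alt_base = reverse_complement(sub[2])
            support = int(rng.integers(config.min_support, config.min_support + 30))
            var = VariantRecord("chrS", pos, ref_base, alt_base)
            u = rng.random()
            if u < config.known_fraction:
                known.add(var.key)
            elif u < config.known_fraction + config.shared_fraction and n_samples > 1:
                other = samples[(s_i + 1) % n_samples]
                calls.setdefault(other, []).append((var, support))
            else:
                truth_contexts[sample].append(label)
            calls[sample].append((var, support))
    truth = {
        "weights": weights.tolist(),
        "signatures": list(signatures.names),
        "contexts": truth_contexts,
    }
    return calls, reference, known, truth


def simulate_sv_calls(
    config: SimConfig,
    truth_svs: list[tuple[str, int, int, str]] | None = None,
    n_samples: int = 10,
    carriers_per_sv: int = 3,
    n_decoys: int = 5,
) -> tuple[list[SVCall], dict]:
    """Per-sample SV call lists around a truth set with breakpoint jitter.

    Each truth SV is assigned to a random carrier subset; per-carrier
    breakpoints are jittered with SD ``config.sv_jitter_sd``. Decoy calls
    violating the intake size filters (below 50 bp or above the caller cap)
    are injected.
    """
    rng = _rng(config, 4)
    if truth_svs is None:
        truth_svs = [
            ("chr3", int(10_000 + 20_000 * k), int(10_000 + 20_000 * k + rng.integers(200, 2000)), "deletion")
            for k in range(5)
        ]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    calls: list[SVCall] = []
    truth_records = []
    for chrom, start, end, sv_type in truth_svs:
        carriers = sorted(rng.choice(samples, size=min(carriers_per_sv, n_samples), replace=False))
        truth_records.append(
            {"chrom": chrom, "start": start, "end": end, "sv_type": sv_type, "carriers": carriers}
        )
        for sample in carriers:
            js = int(round(rng.normal(0, config.sv_jitter_sd))) if config.sv_jitter_sd else 0
            je = int(round(rng.normal(0, config.sv_jitter_sd))) if config.sv_jitter_sd else 0
            caller = "pindel" if rng.random() < 0.5 else "crest"
            calls.append(
                SVCall(chrom, start + js, max(start + js + 49, end + je), sv_type, sample,
                       caller=caller, support=int(rng.integers(3, 30)))
            )
    for d in range(n_decoys):
        sample = samples[int(rng.integers(n_samples))]
        if d % 2 == 0:  # too short
            s = int(rng.integers(1_000, 5_000))
            calls.append(SVCall("chr3", s, s + int(rng.integers(1, 49)), "deletion", sample, "pindel"))
        else:  # over the pindel cap
            s = int(rng.integers(200_000, 300_000))
            calls.append(SVCall("chr3", s, s + 12_000, "deletion", sample, "pindel"))
    truth = {"svs": truth_records, "n_samples": n_samples, "n_decoys": n_decoys}
    return calls, truth


def simulate_phenotypes(
    config: SimConfig,
    matrix: GenotypeMatrix,
    causal: dict[int, float] | None = None,
    male_only: bool = False,
    trait_name: str = "trait",
) -> tuple[pd.DataFrame, dict]:
    """Additive quantitative phenotype: trait = sum_j b_j g_j + N(0, sd^2).

    ``causal`` maps variant index -> effect size per alt allele. Sex is
    assigned Bernoulli(0.5); ``male_only`` restricts the genetic effect to
    males, emulating a sex-specific association.
    """
    rng = _rng(config, 5)
    causal = causal or {}
    n = matrix.n_samples
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    genetic = np.zeros(n)
    for j, b in causal.items():
        g = np.nan_to_num(matrix.codes[:, j])
        genetic += b * g
    if male_only:
        genetic = np.where(sex == "male", genetic, 0.0)
    trait = genetic + rng.normal(0.0, config.phenotype_noise_sd, n)
    df = pd.DataFrame({"sample": matrix.samples, "sex": sex, trait_name: trait}).set_index("sample")
    truth = {"causal": {int(k): float(v) for k, v in causal.items()}, "male_only": male_only}
    return df, truth


def simulate_dhs(
    config: SimConfig,
    n_planted: int = 3,
    n_null: int = 7,
    target_r: float = 0.95,
) -> tuple[pd.DataFrame, dict]:
    """DHS matrix with ``n_planted`` correlated (distal, promoter) pairs.

    Planted pairs share a latent factor scaled so the expected Pearson r
    across cell types is ``target_r``; null pairs are independent noise.
    All sites sit within the linking window on one chromosome.
    """
    rng = _rng(config, 6)
    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must be in (0, 1)")
    lam = target_r / np.sqrt(1.0 - target_r**2)  # signal-to-noise for corr target_r
    rows, planted = [], []
    pos = 10_000
    for i in range(n_planted + n_null):
        shared = rng.normal(size=config.n_cell_types)
        if i < n_planted:
            distal_sig = lam * shared + rng.normal(size=config.n_cell_types)
            prom_sig = lam * shared + rng.normal(size=config.n_cell_types)
            planted.append((f"D{i}", f"G{i}"))
        else:
            distal_sig = rng.normal(size=config.n_cell_types)
            prom_sig = rng.normal(size=config.n_cell_types)
        rows.append({"chrom": "chr9", "start": pos, "end": pos + 200, "site_class": "distal",
                     "gene": None, "name": f"D{i}",
                     **{f"ct{c}": distal_sig[c] for c in range(config.n_cell_types)}})
        rows.append({"chrom": "chr9", "start": pos + 5_000, "end": pos + 5_200,
                     "site_class": "promoter", "gene": f"G{i}", "name": f"P{i}",
                     **{f"ct{c}": prom_sig[c] for c in range(config.n_cell_types)}})
        pos += 2_000_000  # separate pairs beyond the window
    truth = {"planted": planted, "target_r": target_r}
    return pd.DataFrame(rows), truth


def write_gap_track(path, intervals: list[tuple[str, int, int]]) -> IntervalTrack:
    """Convenience: build and write a BED gap/repeat track (1-based inclusive input)."""
    from .io import write_interval_track

    track = IntervalTrack([Interval(c, s, e) for c, s, e in intervals])
    write_interval_track(track, path)
    return track
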