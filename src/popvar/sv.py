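"""Structural-variant consensus merging.

Intake keeps calls of at least 50 bp and below the per-caller size cap.
Within each sample, calls of the same chromosome and type whose reciprocal
overlap exceeds 80% are merged greedily (highest overlap first, coordinate
tie-breaks), with the merged breakpoints set to the mean of the members'
(rounded half-up). Across samples the same procedure runs at a 50%
threshold, producing non-redundant consensus SVs with carrier sets and
allele frequency = carriers / cohort size. Insertions are point-like, so
they are matched by breakpoint distance (<= 100 bp) instead of reciprocal
overlap. Consensus SVs covered > 80% by assembly gaps are removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Interval, IntervalTrack

INSERTION_MAX_BREAKPOINT_DISTANCE = 100


@dataclass(frozen=True)
class SVCall:
    """One per-sample SV call, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    sv_type: str  # deletion | insertion | inversion
    sample: str
    caller: str = "unknown"
    support: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConsensusSV:
    """A merged, non-redundant SV with its carrier set and allele frequency."""

    chrom: str
    start: int
    end: int
    sv_type: str
    carriers: frozenset[str]
    af: float
    members: list[SVCall] = field(default_factory=list)
    support: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def intake_filter(
    calls: list[SVCall],
    caller_max_size: dict[str, int] | None = None,
    min_size: int = 50,
) -> tuple[list[SVCall], dict[str, int]]:
    """Apply the size filters: length >= min_size and <= the caller's cap.

    Default caps: pindel 10 kb, crest 50 kb. Returns (kept, drop counts per
    reason).
    """
    if caller_max_size is None:
        caller_max_size = {"pindel": 10_000, "crest": 50_000}
    kept = []
    dropped = {"too_short": 0, "over_caller_cap": 0}
    for c in calls:
        if c.length < min_size:
            dropped["too_short"] += 1
            continue
        cap = caller_max_size.get(c.caller.lower())
        if cap is not None and c.length > cap:
            dropped["over_caller_cap"] += 1
            continue
        kept.append(c)
    return kept, dropped


def reciprocal_overlap(a: SVCall | ConsensusSV, b: SVCall | ConsensusSV) -> float:
    """Minimum over both intervals of (intersection length / interval length).

    Intervals are 1-based inclusive; zero when the calls differ in
    chromosome or type, or do not intersect.
    """
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _sort_key(c):
    return (c.chrom, c.start, c.end, getattr(c, "sample", ""), getattr(c, "caller", ""))


def _pair_score(a, b, min_overlap: float) -> float | None:
    """Merge priority for a pair, or None if they do not qualify.

    Deletions/inversions: reciprocal overlap, qualifying when strictly above
    ``min_overlap``. Insertions: breakpoint distance <= 100 bp, scored so
    closer pairs merge first.
    """
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return None
    if a.sv_type == "insertion":
        dist = abs(a.start - b.start)
        if dist > INSERTION_MAX_BREAKPOINT_DISTANCE:
            return None
        return 1.0 - dist / (INSERTION_MAX_BREAKPOINT_DISTANCE + 1)
    ro = reciprocal_overlap(a, b)
    return ro if ro > min_overlap else None


def _greedy_merge(items: list, min_overlap: float, combine) -> list:
    """Repeatedly merge the qualifying pair with the highest score.

    Ties break on the sorted coordinate order of the pair, which makes the
    result invariant to input ordering.
    """
    pool = sorted(items, key=_sort_key)
    while True:
        best = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                score = _pair_score(pool[i], pool[j], min_overlap)
                if score is None:
                    continue
                key = (-score, _sort_key(pool[i]), _sort_key(pool[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            return pool
        _, i, j = best
        merged = combine(pool[i], pool[j])
        pool = [x for k, x in enumerate(pool) if k not in (i, j)]
        pool.append(merged)
        pool.sort(key=_sort_key)


def merge_within_sample(calls: list[SVCall], min_overlap: float = 0.8) -> list[SVCall]:
    """Merge one sample's calls whose reciprocal overlap exceeds ``min_overlap``.

    The merged call takes the mean start/end of its members (rounded
    half-up) and the summed read support.
    """
    samples = {c.sample for c in calls}
    if len(samples) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(samples)}")

    def combine(a: SVCall, b: SVCall) -> SVCall:
        # mean over all original members, tracked via _members
        mem = getattr(a, "_members", [a]) + getattr(b, "_members", [b])
        start = _round_half_up(sum(m.start for m in mem) / len(mem))
        end = _round_half_up(sum(m.end for m in mem) / len(mem))
        merged = SVCall(
            a.chrom, start, end, a.sv_type, a.sample,
            caller="+".join(sorted({m.caller for m in mem})),
            support=sum(m.support for m in mem),
        )
        object.__setattr__(merged, "_members", mem)
        return merged

    out = _greedy_merge(list(calls), min_overlap, combine)
    for c in out:
        if hasattr(c, "_members"):
            object.__delattr__(c, "_members")
    return out


def merge_across_samples(
    per_sample_calls: list[SVCall], cohort_size: int, min_overlap: float = 0.5
) -> list[ConsensusSV]:
    """Merge within-sample-merged calls across samples into consensus SVs.

    Same greedy procedure at the cross-sample threshold; every input call
    ends up in exactly one consensus record, whose AF is
    |carrier samples| / cohort_size.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    seeds = [
        ConsensusSV(
            c.chrom, c.start, c.end, c.sv_type,
            carriers=frozenset([c.sample]), af=0.0, members=[c], support=c.support,
        )
        for c in per_sample_calls
    ]

    def combine(a: ConsensusSV, b: ConsensusSV) -> ConsensusSV:
        mem = a.members + b.members
        start = _round_half_up(sum(m.start for m in mem) / len(mem))
        end = _round_half_up(sum(m.end for m in mem) / len(mem))
        return ConsensusSV(
            a.chrom, start, end, a.sv_type,
            carriers=a.carriers | b.carriers, af=0.0,
            members=mem, support=a.support + b.support,
        )

    merged = _greedy_merge(seeds, min_overlap, combine)
    return [replace(m, af=len(m.carriers) / cohort_size) for m in merged]


def _union_coverage(start: int, end: int, intervals: list[Interval]) -> int:
    """Bases of [start, end] covered by the union of the intervals."""
    clipped = sorted(
        (max(start, iv.start), min(end, iv.end))
        for iv in intervals
        if iv.start <= end and iv.end >= start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered


def filter_gap_overlap(
    consensus: list[ConsensusSV], gaps: IntervalTrack, max_frac: float = 0.8
) -> list[ConsensusSV]:
    """Drop consensus SVs whose fraction covered by assembly gaps exceeds ``max_frac``.

    Coverage is the union of all gap intervals over the SV, as a fraction of
    the SV's length.
    """
    by_chrom = gaps.by_chrom()
    out = []
    for sv in consensus:
        ivs = by_chrom.get(sv.chrom, [])
        frac = _union_coverage(sv.start, sv.end, ivs) / sv.length
        if frac <= max_frac:
            out.append(sv)
    return out


def af_spectrum(
    consensus: list[ConsensusSV],
    bin_edges: list[float] = (0.0, 0.005, 0.05, 0.5, 1.0),
) -> pd.DataFrame:
    """Allele-frequency spectrum, per SV type and overall, over right-open bins.

    The last bin is closed on the right so AF = 1 is counted.
    """
    if not consensus:
        raise ValueError("empty consensus list")
    edges = list(bin_edges)
    labels = [f"[{edges[i]}, {edges[i+1]})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]}, {edges[-1]}]")
    types = sorted({sv.sv_type for sv in consensus}) + ["all"]
    table = pd.DataFrame(0, index=labels, columns=types)
    for sv in consensus:
        i = np.searchsorted(edges, sv.af, side="right") - 1
        i = min(max(i, 0), len(labels) - 1)
        table.loc[labels[i], sv.sv_type] += 1
        table.loc[labels[i], "all"] += 1
    fracs = table / table.sum(axis=0).replace(0, np.nan)
    fracs.columns = [f"frac_{c}" for c in fracs.columns]
    return pd.concat([table, fracs], axis=1)


def annotate_repeat_overlap(
    consensus: list[ConsensusSV], repeats: IntervalTrack
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag SVs overlapping repeat classes (>= 1 bp) and summarise per type.

    ``repeats`` records must carry the repeat class in their name field
    (e.g. "tandem" or "interspersed"). Returns (per-SV flags, summary).
    The summary holds per-type fractions of SVs overlapping each class and
    the mean SV length per repeat-complexity stratum (which classes an SV
    touches).
    """
    classes = sorted({iv.name or "repeat" for iv in repeats})
    by_chrom = repeats.by_chrom()
    rows = []
    for sv in consensus:
        hit = {cls: False for cls in classes}
        for iv in by_chrom.get(sv.chrom, []):
            if iv.start <= sv.end and iv.end >= sv.start:
                hit[iv.name or "repeat"] = True
        stratum = "+".join(sorted(c for c, h in hit.items() if h)) or "none"
        rows.append(
            {"chrom": sv.chrom, "start": sv.start, "end": sv.end, "sv_type": sv.sv_type,
             "length": sv.length, "stratum": stratum, **{f"in_{c}": hit[c] for c in classes}}
        )
    flags = pd.DataFrame(rows)
    if flags.empty:
        return flags, pd.DataFrame()
    frac = flags.groupby("sv_type")[[f"in_{c}" for c in classes]].mean()
    mean_len = flags.groupby("stratum")["length"].mean().rename("mean_length")
    summary = pd.concat([frac.stack().rename("fraction_overlapping").reset_index(),
                         mean_len.reset_index()], axis=1)
    return flags, summary
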