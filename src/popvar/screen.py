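"""Population-specific variant screen against outgroup allele-frequency panels.

A variant passes when one of its two alleles is at a frequency in the study
cohort at least ``delta`` (default 0.3) above that allele's frequency in
every outgroup panel (South Asian, African, Admixed American, European).
The East Asian panel is recorded but not thresholded — the screen targets
variants at high frequency in the cohort and shared with East Asians, so
EAS is excluded from the outgroups. Both alleles are tested, making the
screen invariant to which allele the panel designates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, allele_frequency

OUTGROUPS = ("sas", "afr", "amr", "eur")
PANEL_COLUMNS = ("af_cas", "af_eas", "af_sas", "af_afr", "af_amr", "af_eur")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one variant."""

    passed: bool
    focal_allele: str | None  # "designated" or "other" (the complement)
    min_gap: float | None  # minimum cohort-minus-outgroup gap for the focal allele
    reason: str | None = None


def screen_variant(
    af_cas: float,
    af_eas: float | None,
    af_sas: float,
    af_afr: float,
    af_amr: float,
    af_eur: float,
    delta: float = 0.3,
    tolerance: float = 1e-9,
) -> ScreenResult:
    """Screen a single biallelic site from its per-population frequencies.

    Frequencies must all refer to the same designated allele; the
    complementary allele (1 - f) is tested too. EAS may be None (recorded
    only). Passing requires min over outgroups of (cohort - outgroup) >=
    delta - tolerance for at least one allele orientation.
    """
    outs = {"sas": af_sas, "afr": af_afr, "amr": af_amr, "eur": af_eur}
    for name, f in list(outs.items()) + [("cas", af_cas)]:
        if f is None or not np.isfinite(f):
            return ScreenResult(False, None, None, reason=f"missing {name} frequency")
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"allele frequency {name}={f} outside [0, 1]")
    if af_eas is not None and np.isfinite(af_eas) and not (0.0 <= af_eas <= 1.0):
        raise ValueError(f"allele frequency eas={af_eas} outside [0, 1]")

    best: tuple[float, str] | None = None
    for orientation, flip in (("designated", False), ("other", True)):
        cas = 1.0 - af_cas if flip else af_cas
        gaps = [cas - ((1.0 - f) if flip else f) for f in outs.values()]
        min_gap = min(gaps)
        if best is None or min_gap > best[0]:
            best = (min_gap, orientation)
    min_gap, orientation = best
    passed = min_gap >= delta - tolerance
    return ScreenResult(passed, orientation if passed else None, float(min_gap))


def screen_panel(
    panel: pd.DataFrame, delta: float = 0.3, tolerance: float = 1e-9
) -> pd.DataFrame:
    """Apply the screen to every row of a frequency panel.

    ``panel`` needs columns af_cas, af_eas, af_sas, af_afr, af_amr, af_eur
    (af_eas may be absent or NaN). Returns the panel plus ``pass``,
    ``focal_allele`` and ``min_gap`` columns.
    """
    missing = [c for c in PANEL_COLUMNS if c != "af_eas" and c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    results = [
        screen_variant(
            row["af_cas"],
            row.get("af_eas", np.nan),
            row["af_sas"],
            row["af_afr"],
            row["af_amr"],
            row["af_eur"],
            delta=delta,
            tolerance=tolerance,
        )
        for _, row in panel.iterrows()
    ]
    out = panel.copy()
    out["pass"] = [r.passed for r in results]
    out["focal_allele"] = [r.focal_allele for r in results]
    out["min_gap"] = [r.min_gap for r in results]
    return out


def screen_cohort(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    delta: float = 0.3,
    tolerance: float = 1e-9,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen cohort variants whose cohort AF is computed from the genotype matrix.

    ``panel`` must carry outgroup frequency columns plus ``id`` (rsID) and/or
    a positional ``key`` column; matrix variants are matched by either.
    Returns the screened table and pass counts by variant class
    ({"snv": ..., "indel": ...}).
    """
    cohort_af = allele_frequency(matrix)
    rows = []
    panel_by_id = panel.set_index("id") if "id" in panel.columns else None
    panel_by_key = panel.set_index("key") if "key" in panel.columns else None
    for var, af in zip(matrix.variants, cohort_af):
        prow = None
        if panel_by_id is not None and var.id is not None and var.id in panel_by_id.index:
            prow = panel_by_id.loc[var.id]
        elif panel_by_key is not None and var.key in panel_by_key.index:
            prow = panel_by_key.loc[var.key]
        if prow is None:
            continue
        rows.append(
            {
                "id": var.id,
                "key": var.key,
                "class": "snv" if var.is_snv else "indel",
                "af_cas": af,
                "af_eas": prow.get("af_eas", np.nan),
                "af_sas": prow["af_sas"],
                "af_afr": prow["af_afr"],
                "af_amr": prow["af_amr"],
                "af_eur": prow["af_eur"],
            }
        )
    if not rows:
        raise ValueError("no overlap between genotype matrix and frequency panel")
    table = screen_panel(pd.DataFrame(rows), delta=delta, tolerance=tolerance)
    counts = (
        table[table["pass"]].groupby("class").size().reindex(["snv", "indel"], fill_value=0)
    )
    return table, {"snv": int(counts["snv"]), "indel": int(counts["indel"])}


def intersect_with_catalog(screen: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Annotate passing variants with trait-catalog entries (inner join on rsID).

    ``catalog`` needs columns id (rsID), trait, gene; one output row per
    (variant, trait) pair. An empty intersection is allowed.
    """
    passing = screen[screen["pass"]] if "pass" in screen.columns else screen
    if passing.empty or catalog.empty:
        return pd.DataFrame(columns=list(passing.columns) + ["trait", "gene"])
    return passing.merge(catalog[["id", "trait", "gene"]], on="id", how="inner")
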