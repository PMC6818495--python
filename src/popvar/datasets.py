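"""Small bundled reference tables used by examples and validation.

``metabolic_snp_frequencies`` holds published per-population allele
frequencies for 17 metabolism-associated SNPs in a Han Chinese cohort
(CAS column) alongside the 1000 Genomes super-population panels (EAS, SAS,
AFR, AMR, EUR). One SNP (rs820430) is reported under two blood-pressure
traits, so the table has 18 rows and 17 distinct rsIDs.

``north_south_differentiated_snps`` holds the reported allele frequencies
and sample sizes for strongly north-south differentiated missense variants
in the same cohort (northern n = 339, southern n = 116).
"""

from __future__ import annotations

import pandas as pd

_METABOLIC_ROWS = [
    # trait, rsid, effect_allele, af_cas, af_eas, af_sas, af_afr, af_amr, af_eur, gene
    ("waist_circumference", "rs13210323", "A", 0.64, 0.69, 0.31, 0.34, 0.31, 0.28, "ANKS1A"),
    ("waist_circumference", "rs1549293", "T", 0.92, 0.88, 0.14, 0.09, 0.38, 0.38, "KAT8"),
    ("waist_circumference", "rs3791679", "A", 0.78, 0.77, 0.25, 0.03, 0.24, 0.23, "EFEMP1"),
    ("waist_circumference", "rs806794", "A", 0.77, 0.76, 0.45, 0.38, 0.45, 0.30, "HIST1H2BF"),
    ("type_2_diabetes", "rs11257655", "T", 0.58, 0.54, 0.24, 0.24, 0.26, 0.23, "CDC123/CAMK1D"),
    ("type_2_diabetes", "rs231356", "T", 0.79, 0.79, 0.48, 0.25, 0.43, 0.30, "KCNQ1OT1"),
    ("type_2_diabetes", "rs62481355", "T", 0.65, 0.69, 0.32, 0.01, 0.25, 0.31, "LOC100506682/GCC1"),
    ("type_2_diabetes", "rs806215", "C", 0.63, 0.66, 0.26, 0.27, 0.24, 0.22, "FSCN3"),
    ("fasting_plasma_glucose", "rs733331", "A", 0.52, 0.52, 0.18, 0.00, 0.15, 0.04, "PDK1/RAPGEF4-AS1"),
    ("hypertension", "rs2398162", "A", 0.65, 0.67, 0.28, 0.04, 0.34, 0.21, "NR2F2-AS1"),
    ("systolic_blood_pressure", "rs820430", "A", 0.70, 0.67, 0.38, 0.02, 0.37, 0.39, "SLC4A7/EOMES"),
    ("systolic_blood_pressure", "rs13359291", "A", 0.62, 0.59, 0.29, 0.14, 0.27, 0.17, "PRDM6"),
    ("systolic_blood_pressure_smoking", "rs1792738", "G", 0.79, 0.78, 0.44, 0.05, 0.43, 0.34, "LINC01539/TXNL1"),
    ("diastolic_blood_pressure", "rs820430", "A", 0.70, 0.67, 0.38, 0.02, 0.37, 0.39, "SLC4A7/EOMES"),
    ("triglycerides", "rs11649653", "G", 0.93, 0.90, 0.17, 0.02, 0.41, 0.39, "CTF1/FBXL19-AS1"),
    ("hdl_cholesterol", "rs759819", "C", 0.81, 0.72, 0.29, 0.07, 0.36, 0.31, "LILRA3/LILRA5"),
    ("hdl_cholesterol", "rs2967605", "T", 0.64, 0.60, 0.30, 0.22, 0.24, 0.19, "RAB11B"),
    ("hdl_cholesterol", "rs386000", "C", 0.84, 0.65, 0.15, 0.17, 0.43, 0.19, "MIR4752/LILRA3"),
]


def metabolic_snp_frequencies() -> pd.DataFrame:
    """Published frequency panel for 17 metabolism-associated SNPs (18 rows)."""
    return pd.DataFrame(
        _METABOLIC_ROWS,
        columns=["trait", "id", "allele", "af_cas", "af_eas", "af_sas",
                 "af_afr", "af_amr", "af_eur", "gene"],
    )


def north_south_differentiated_snps() -> pd.DataFrame:
    """Reported north/south allele frequencies for differentiated missense SNPs."""
    rows = [
        # rsid, gene, allele, af_north, n_north, af_south, n_south, reported_fst
        ("rs1801133", "MTHFR", "A", 0.578, 339, 0.379, 116, 0.0729),
        ("rs75680863", "TCN2", "T", 0.195, 339, 0.065, 116, None),
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "gene", "allele", "af_north", "n_north", "af_south", "n_south",
                 "reported_fst"],
    )
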