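"""Reference values from the pan-cancer TCGA glucose-metabolism screen.

Three small, public summary tables are bundled so the screening machinery
can be exercised without downloading any cohort data:

* :data:`COHORT_SIZES` — normal-control and cancer-patient counts for the
  12 TCGA cancer types that satisfy the N_normal >= 10 and N_cancer >= 10
  admission rule.
* :data:`PAN_CANCER_LOG2FC` — normalized log2 fold-changes (cancer over
  matched normal) for the ten glucose-metabolism genes whose fold-change
  direction is concordant across the cohorts.  ``None`` marks a gene that
  is not quantified in a cohort (PDHA2 in BLCA).
* :data:`CONSISTENT_PAIRS` — the five gene pairs whose correlation-change
  category is identical in every cohort, with their category codes.
"""

from __future__ import annotations

import pandas as pd

#: TCGA cancer-type code -> (description, n_normal, n_cancer)
COHORT_SIZES: list[tuple[str, str, int, int]] = [
    ("BLCA", "Bladder urothelial carcinoma", 19, 414),
    ("BRCA", "Breast invasive carcinoma", 113, 1102),
    ("COAD", "Colon adenocarcinoma", 41, 471),
    ("ESCA", "Esophageal carcinoma", 11, 159),
    ("HNSC", "Head and neck squamous cell carcinoma", 13, 127),
    ("KIRC", "Kidney renal clear cell carcinoma", 72, 538),
    ("LIHC", "Liver hepatocellular carcinoma", 50, 371),
    ("LUAD", "Lung adenocarcinoma", 59, 533),
    ("PRAD", "Prostate adenocarcinoma", 52, 498),
    ("STAD", "Stomach adenocarcinoma", 32, 375),
    ("THCA", "Thyroid carcinoma", 58, 502),
    ("UCEC", "Uterine corpus endometrial carcinoma", 23, 551),
]

#: Cohort codes in canonical order.
CANCER_TYPES: list[str] = [row[0] for row in COHORT_SIZES]

#: gene -> per-cohort normalized log2 fold-change (cancer / normal).
PAN_CANCER_LOG2FC: dict[str, dict[str, float | None]] = {
    "ADH1B": dict(zip(CANCER_TYPES, [-4.40, -4.86, -4.06, -2.15, -3.41, -2.67,
                                     -1.16, -3.19, -1.66, -1.83, -3.44, -7.03])),
    "ALDH2": dict(zip(CANCER_TYPES, [-1.64, -2.10, -0.26, -0.17, -0.65, -0.75,
                                     -1.02, -1.19, -0.81, -0.23, -0.84, -0.36])),
    "ENO1": dict(zip(CANCER_TYPES, [0.96, 0.33, 1.00, 1.48, 1.14, 0.64,
                                    1.27, 1.22, 0.19, 1.12, 0.17, 1.53])),
    "EPM2A": dict(zip(CANCER_TYPES, [-2.45, -0.96, -1.21, -0.79, -0.99, -1.30,
                                     -0.30, -1.17, -0.94, -1.10, -0.82, -2.00])),
    "GAPDH": dict(zip(CANCER_TYPES, [0.67, 1.05, 0.90, 1.29, 0.56, 1.50,
                                     1.35, 1.72, 0.08, 0.64, 0.44, 1.45])),
    "LDHA": dict(zip(CANCER_TYPES, [0.62, 0.56, 0.72, 1.50, 1.31, 1.71,
                                    0.05, 1.36, 0.42, 0.85, 0.07, 1.38])),
    "MPC1": dict(zip(CANCER_TYPES, [-0.62, -0.38, -0.96, -0.69, -0.82, -1.56,
                                    -0.85, -0.37, -0.19, -0.42, -0.79, -0.38])),
    "PDHA2": dict(zip(CANCER_TYPES, [None, 1.13, 1.88, 2.99, 1.65, 2.27,
                                     3.72, 3.43, 0.73, 2.92, 1.35, 1.73])),
    "PFKFB4": dict(zip(CANCER_TYPES, [2.39, 1.26, 0.84, 1.15, 1.65, 2.45,
                                      2.43, 0.81, 0.21, 0.11, 0.18, 2.33])),
    "PHKG2": dict(zip(CANCER_TYPES, [0.71, 1.12, 0.48, 0.95, 1.01, 0.28,
                                     0.86, 0.86, 0.26, 0.96, 0.31, 1.01])),
}

#: The five pan-cohort consistent decoupling pairs and their categories.
CONSISTENT_PAIRS: list[tuple[str, str, str]] = [
    ("ADH6", "GYC1", "neg_less_neg"),
    ("ADPGK", "SLC2A4", "neg_less_neg"),
    ("ENO1", "PPP2R1A", "pos_less_pos"),
    ("MDH2", "SLC25A11", "pos_less_pos"),
    ("PGM2", "PPP2CA", "pos_less_pos"),
]


def cohort_size_frame() -> pd.DataFrame:
    """The cohort-size table as a DataFrame (type, description, n_normal, n_cancer)."""
    return pd.DataFrame(
        COHORT_SIZES, columns=["cancer_type", "description", "n_normal", "n_cancer"]
    )


def pan_cancer_log2fc_records() -> pd.DataFrame:
    """The log2FC grid in long form, one row per (gene, cohort).

    Columns match the differential-screen record contract
    (``gene, cancer_type, log2fc, p_value, available``).  The grid carries
    no p-values (they were screened upstream of the published grid), so
    ``p_value`` is NaN throughout and downstream screens treat the p
    criterion as already satisfied.
    """
    rows = []
    for gene, per_cohort in PAN_CANCER_LOG2FC.items():
        for cancer_type in CANCER_TYPES:
            value = per_cohort[cancer_type]
            rows.append(
                {
                    "gene": gene,
                    "cancer_type": cancer_type,
                    "log2fc": float("nan") if value is None else value,
                    "p_value": float("nan"),
                    "available": value is not None,
                }
            )
    return pd.DataFrame(rows)
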