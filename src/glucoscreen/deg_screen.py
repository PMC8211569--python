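"""Per-cohort differential expression and the two cross-cohort gene screens.

The per-gene statistic is a two-group Poisson likelihood-ratio test on
library-normalized, rounded expression values, referred to a chi-square
distribution with one degree of freedom; the effect size is the
normalized log2 fold-change of group means with a small pseudocount.
Two screens aggregate the per-cohort records:

* the *trend* screen asks for a strictly consistent fold-change sign
  across every cohort in which the gene is quantified, and
* the *differential* screen applies the |log2FC| >= 1, p < 0.05 cut-off
  in every such cohort.

Record contract: a long-form DataFrame with columns
``gene, cancer_type, log2fc, p_value, available``.  A gene missing from
one cohort contributes a row with ``available=False`` and NaN
statistics; screens ignore such rows rather than imputing them.  A NaN
``p_value`` on an available row means no p-value accompanies the
fold-change (as in published fold-change grids); the p criterion is then
treated as satisfied and the screen output notes the waiver.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .io_model import CohortPair, ExpressionMatrix

__all__ = [
    "normalize_library",
    "compute_log2fc",
    "lrt_two_group",
    "deg_table",
    "screen_trend",
    "screen_differential",
    "log2fc_grid",
]

RECORD_COLUMNS = ["gene", "cancer_type", "log2fc", "p_value", "available"]

DEFAULT_PSEUDOCOUNT = 1e-3


def normalize_library(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every sample column to the median column sum.

    The median over an even number of column sums is the arithmetic mean
    of the two middle values.  An all-zero sample carries no usable
    library and is an error.
    """
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(f"all-zero sample column: {m.sample_ids[zero[0]]!r}")
    target = float(np.median(colsums))
    return ExpressionMatrix(m.gene_ids, m.sample_ids, m.values * (target / colsums))


def _normalized_arms(pair: CohortPair) -> tuple[np.ndarray, np.ndarray]:
    """Jointly library-normalize both arms (shared median target) and split."""
    combined = np.concatenate([pair.normal.values, pair.cancer.values], axis=1)
    em = normalize_library(
        ExpressionMatrix(
            pair.gene_ids,
            pair.normal.sample_ids + pair.cancer.sample_ids,
            combined,
        )
    )
    n = pair.n_normal
    return em.values[:, :n], em.values[:, n:]


def compute_log2fc(
    pair: CohortPair, gene: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Normalized log2 fold-change of a gene, cancer over normal.

    ``log2((mean_cancer + c) / (mean_normal + c))`` on jointly
    library-normalized values; positive means upregulated in cancer.
    Returns NaN when the gene is absent from the cohort (the screening
    layer treats that as an unavailable record, not an error).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if gene not in pair.gene_ids:
        return float("nan")
    row = pair.gene_ids.index(gene)
    normal, cancer = _normalized_arms(pair)
    return float(
        np.log2((cancer[row].mean() + pseudocount) / (normal[row].mean() + pseudocount))
    )


def lrt_two_group(
    count_a: Sequence[float], count_b: Sequence[float]
) -> tuple[float, float]:
    """Two-group Poisson likelihood-ratio test on rounded expression values.

    H0: both groups share one Poisson mean; H1: each group has its own.
    Returns ``(statistic, p_value)`` with the statistic ``2 * (l1 - l0)``
    and the p-value from chi-square with 1 degree of freedom.  Identical
    group means give statistic 0 and p = 1; two all-zero groups are the
    degenerate case of that and are flagged with a warning.
    """
    a = np.rint(np.asarray(count_a, dtype=float))
    b = np.rint(np.asarray(count_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("expression values must be nonnegative")
    sa, sb = a.sum(), b.sum()
    na, nb = a.size, b.size
    if sa == 0 and sb == 0:
        warnings.warn("both groups are all-zero; LRT is degenerate", stacklevel=2)
        return 0.0, 1.0
    ma, mb = sa / na, sb / nb
    if ma == mb:
        return 0.0, 1.0
    m0 = (sa + sb) / (na + nb)

    def profile_ll(s: float, n: int, mu: float) -> float:
        # Poisson log-likelihood at its MLE, dropping the x!-terms that
        # cancel in the ratio.
        return float(xlogy(s, mu) - n * mu)

    stat = 2.0 * (
        profile_ll(sa, na, ma) + profile_ll(sb, nb, mb) - profile_ll(sa + sb, na + nb, m0)
    )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def deg_table(
    pair: CohortPair,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene log2FC and Poisson-LRT p-value for one cohort.

    ``genes`` (default: the cohort's own genes) fixes the record universe;
    requested genes absent from the cohort yield ``available=False`` rows.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    normal, cancer = _normalized_arms(pair)
    fc = np.log2(
        (cancer.mean(axis=1) + pseudocount) / (normal.mean(axis=1) + pseudocount)
    )
    rows = []
    row_of = {g: i for i, g in enumerate(pair.gene_ids)}
    for gene in genes if genes is not None else pair.gene_ids:
        i = row_of.get(gene)
        if i is None:
            rows.append((gene, pair.cancer_type, np.nan, np.nan, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero genes are expected in screens
            _, p = lrt_two_group(normal[i], cancer[i])
        rows.append((gene, pair.cancer_type, float(fc[i]), p, True))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"record table missing columns: {sorted(missing)}")
    return records


def screen_trend(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-cohort sign-consistency screen.

    A gene is trend-consistent when every available log2FC is strictly
    positive (direction ``up``) or strictly negative (``down``); a zero
    fold-change counts as neither.  Unavailable cohorts are ignored.
    Genes available in no cohort are excluded and listed in
    ``result.attrs["excluded_genes"]``.
    """
    _validate_records(records)
    rows = []
    excluded = []
    for gene, sub in records.groupby("gene", sort=True):
        avail = sub.loc[sub["available"], "log2fc"].to_numpy()
        if avail.size == 0:
            excluded.append(gene)
            continue
        if np.all(avail > 0):
            direction = "up"
        elif np.all(avail < 0):
            direction = "down"
        else:
            direction = "mixed"
        rows.append(
            {
                "gene": gene,
                "n_cohorts_available": int(avail.size),
                "direction": direction,
                "trend_consistent": direction in ("up", "down"),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_cohorts_available", "direction",
                                      "trend_consistent"])
    out.attrs["excluded_genes"] = excluded
    if excluded:
        warnings.warn(f"{len(excluded)} gene(s) available in no cohort were excluded",
                      stacklevel=2)
    return out


def screen_differential(
    records: pd.DataFrame,
    fc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    require_all: bool = True,
    adjust: str = "none",
) -> tuple[list[str], pd.DataFrame]:
    """Fold-change + significance screen across cohorts.

    A gene passes a cohort iff it is available there, |log2FC| >=
    ``fc_cutoff`` and p < ``p_cutoff``; rows whose p-value is NaN have the
    p criterion treated as satisfied (fold-change-grid mode), which is
    flagged in ``table.attrs["p_criterion_waived"]``.  With
    ``require_all`` a hit must pass every cohort in which it is
    available.  ``adjust="bh"`` applies Benjamini-Hochberg within each
    cohort before thresholding.

    Returns ``(hit_genes, per_gene_table)`` with the table sorted by
    ``n_cohorts_differential`` descending then gene symbol.
    """
    if fc_cutoff < 0:
        raise ValueError("fc_cutoff must be >= 0")
    if not (0 < p_cutoff <= 1):
        raise ValueError("p_cutoff must lie in (0, 1]")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    records = _validate_records(records).copy()

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        for _, idx in records.groupby("cancer_type").groups.items():
            mask = records.loc[idx, "available"] & records.loc[idx, "p_value"].notna()
            sel = records.loc[idx][mask.to_numpy()].index
            if len(sel):
                records.loc[sel, "p_value"] = multipletests(
                    records.loc[sel, "p_value"].to_numpy(), method="fdr_bh"
                )[1]

    waived = bool((records["available"] & records["p_value"].isna()).any())
    p_ok = records["p_value"].isna() | (records["p_value"] < p_cutoff)
    records["passes"] = (
        records["available"]
        & (records["log2fc"].abs() >= fc_cutoff)
        & p_ok
    )
    grouped = records.groupby("gene", sort=True).agg(
        n_cohorts_available=("available", "sum"),
        n_cohorts_differential=("passes", "sum"),
    )
    grouped = grouped[grouped["n_cohorts_available"] > 0]
    grouped["differential_in_all"] = (
        grouped["n_cohorts_differential"] == grouped["n_cohorts_available"]
    )
    table = (
        grouped.reset_index()
        .sort_values(["n_cohorts_differential", "gene"],
                     ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    table.attrs["p_criterion_waived"] = waived
    if require_all:
        hits = table.loc[table["differential_in_all"], "gene"].tolist()
    else:
        hits = table.loc[table["n_cohorts_differential"] > 0, "gene"].tolist()
    return sorted(hits), table


def log2fc_grid(records: pd.DataFrame, na_rep: str = "N/A") -> pd.DataFrame:
    """Gene x cohort grid of log2FC values, unavailable cells as ``na_rep``."""
    _validate_records(records)
    grid = records.pivot(index="gene", columns="cancer_type", values="log2fc")
    return grid.astype(object).where(grid.notna(), na_rep)
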