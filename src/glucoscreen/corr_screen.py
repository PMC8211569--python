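"""Pairwise correlation matrices, the six-category change classifier, and
the cross-cohort consistency screen.

For each cohort, Pearson correlation matrices are computed separately on
the normal and cancer arms (on log2(x+1)-transformed expression by
default).  Every gene pair's (r_normal, r_cancer) is classified into one
of six transitions —

    positive -> more positive   (``pos_more_pos``)
    positive -> less positive   (``pos_less_pos``)
    positive -> negative        (``pos_to_neg``)
    negative -> more negative   (``neg_more_neg``)
    negative -> less negative   (``neg_less_neg``)
    negative -> positive        (``neg_to_pos``)

— or ``undefined`` (starting correlation inside the +/- sign_tau dead
zone) or ``null_change`` (|r_normal - r_cancer| below delta_min).  A pair
whose category is identical, and one of the six real transitions, in
every cohort is a consistency hit; with ``require_all`` it must also be
defined in every cohort.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionMatrix

__all__ = [
    "CATEGORIES",
    "CATEGORY_LABELS",
    "ScreenConfig",
    "CorrelationMatrix",
    "correlation_matrix",
    "classify_change",
    "classify_change_array",
    "pair_change_table",
    "screen_consistent_pairs",
    "fisher_z_difference",
    "render_corr_dotplot",
]

#: The six real correlation-change transitions, in canonical order.
CATEGORIES = (
    "pos_more_pos",
    "pos_less_pos",
    "pos_to_neg",
    "neg_more_neg",
    "neg_less_neg",
    "neg_to_pos",
)

#: Human-readable labels used in hit tables.
CATEGORY_LABELS = {
    "pos_more_pos": "Positive → More positive",
    "pos_less_pos": "Positive → Less positive",
    "pos_to_neg": "Positive → Negative",
    "neg_more_neg": "Negative → More negative",
    "neg_less_neg": "Negative → Less negative",
    "neg_to_pos": "Negative → Positive",
}


@dataclasses.dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the change classifier.

    sign_tau : half-width of the dead zone around zero inside which the
        starting correlation has no usable sign (default 0.1).
    delta_min : minimum |r_normal - r_cancer| to call any change at all
        (default 0.1).
    transform : expression transform applied before Pearson correlation,
        ``"log2p1"`` (log2(x+1), default) or ``"none"``.
    """

    sign_tau: float = 0.1
    delta_min: float = 0.1
    transform: str = "log2p1"

    def __post_init__(self) -> None:
        if not (0 <= self.sign_tau < 1):
            raise ValueError("sign_tau must lie in [0, 1)")
        if not (0 <= self.delta_min < 2):
            raise ValueError("delta_min must lie in [0, 2)")
        if self.transform not in ("log2p1", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclasses.dataclass
class CorrelationMatrix:
    """Pearson correlations with an explicit defined mask.

    ``r[i, j]`` is NaN wherever ``defined_mask[i, j]`` is False (either
    gene has zero variance); defined entries lie in [-1, 1] and the
    defined diagonal is exactly 1.
    """

    gene_ids: list[str]
    r: np.ndarray
    n_samples: int
    defined_mask: np.ndarray


def correlation_matrix(
    m: ExpressionMatrix, transform: str = "log2p1"
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of all genes across samples."""
    if len(m.sample_ids) < 3:
        raise ValueError(
            f"need >= 3 samples for a correlation matrix, got {len(m.sample_ids)}"
        )
    if transform == "log2p1":
        x = np.log2(m.values + 1.0)
    elif transform == "none":
        x = m.values
    else:
        raise ValueError(f"unknown transform {transform!r}")

    n_genes = len(m.gene_ids)
    defined_genes = x.std(axis=1) > 0
    r = np.full((n_genes, n_genes), np.nan)
    idx = np.flatnonzero(defined_genes)
    if idx.size >= 1:
        sub = np.corrcoef(x[idx])
        sub = np.atleast_2d(sub)
        sub = np.clip((sub + sub.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(sub, 1.0)
        r[np.ix_(idx, idx)] = sub
    mask = np.outer(defined_genes, defined_genes)
    return CorrelationMatrix(list(m.gene_ids), r, len(m.sample_ids), mask)


def classify_change(r_normal: float, r_cancer: float, cfg: ScreenConfig) -> str:
    """Classify one pair's correlation transition from normal to cancer.

    Boundary conventions: the starting sign is strict (``r_normal``
    exactly at +/- sign_tau is undefined); ``|r_normal - r_cancer| <
    delta_min`` is null_change; a cancer correlation landing exactly on
    the far dead-zone boundary counts as "less", not as sign-crossing.
    """
    for name, v in (("r_normal", r_normal), ("r_cancer", r_cancer)):
        if not np.isfinite(v) or not (-1.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a defined correlation in [-1, 1], got {v}")
    if -cfg.sign_tau <= r_normal <= cfg.sign_tau:
        return "undefined"
    if abs(r_normal - r_cancer) < cfg.delta_min:
        return "null_change"
    if r_normal > cfg.sign_tau:
        if r_cancer > r_normal:
            return "pos_more_pos"
        if r_cancer < -cfg.sign_tau:
            return "pos_to_neg"
        return "pos_less_pos"
    if r_cancer < r_normal:
        return "neg_more_neg"
    if r_cancer > cfg.sign_tau:
        return "neg_to_pos"
    return "neg_less_neg"


def classify_change_array(
    r_normal: np.ndarray, r_cancer: np.ndarray, cfg: ScreenConfig
) -> np.ndarray:
    """Vectorized :func:`classify_change` over parallel arrays."""
    rn = np.asarray(r_normal, dtype=float)
    rc = np.asarray(r_cancer, dtype=float)
    cat = np.full(rn.shape, "null_change", dtype=object)
    pos = rn > cfg.sign_tau
    neg = rn < -cfg.sign_tau
    cat[~(pos | neg)] = "undefined"
    changed = np.abs(rn - rc) >= cfg.delta_min
    p = pos & changed
    cat[p & (rc > rn)] = "pos_more_pos"
    cat[p & ~(rc > rn) & (rc < -cfg.sign_tau)] = "pos_to_neg"
    cat[p & ~(rc > rn) & ~(rc < -cfg.sign_tau)] = "pos_less_pos"
    n = neg & changed
    cat[n & (rc < rn)] = "neg_more_neg"
    cat[n & ~(rc < rn) & (rc > cfg.sign_tau)] = "neg_to_pos"
    cat[n & ~(rc < rn) & ~(rc > cfg.sign_tau)] = "neg_less_neg"
    return cat


def pair_change_table(
    cm_normal: CorrelationMatrix,
    cm_cancer: CorrelationMatrix,
    cfg: ScreenConfig,
    cancer_type: str,
) -> pd.DataFrame:
    """Per-pair change records for one cohort.

    One row per unordered gene pair defined in both arms, columns
    ``gene_a, gene_b, cancer_type, r_normal, r_cancer, category`` with
    ``gene_a < gene_b`` lexicographically.  Pairs undefined in either arm
    contribute no row (missingness, not a category).
    """
    if cm_normal.gene_ids != cm_cancer.gene_ids:
        raise ValueError("normal and cancer correlation matrices must share genes")
    genes = cm_normal.gene_ids
    iu, ju = np.triu_indices(len(genes), k=1)
    defined = cm_normal.defined_mask[iu, ju] & cm_cancer.defined_mask[iu, ju]
    iu, ju = iu[defined], ju[defined]
    rn = cm_normal.r[iu, ju]
    rc = cm_cancer.r[iu, ju]
    names_i = np.array(genes, dtype=object)[iu]
    names_j = np.array(genes, dtype=object)[ju]
    swap = names_i > names_j
    gene_a = np.where(swap, names_j, names_i)
    gene_b = np.where(swap, names_i, names_j)
    return pd.DataFrame(
        {
            "gene_a": gene_a,
            "gene_b": gene_b,
            "cancer_type": cancer_type,
            "r_normal": rn,
            "r_cancer": rc,
            "category": classify_change_array(rn, rc, cfg),
        }
    )


def screen_consistent_pairs(
    records: pd.DataFrame,
    require_all: bool = True,
    cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Pairs whose change category is identical across cohorts.

    A pair is a hit iff every cohort in which it is defined assigns it the
    same category and that category is one of the six real transitions.
    With ``require_all`` (the pan-cohort reading) the pair must be defined
    in every cohort of ``cohorts`` (default: all cohorts present in the
    records).  Output is sorted by ``gene_a`` then ``gene_b`` and carries
    a human-readable ``label`` column.
    """
    needed = {"gene_a", "gene_b", "cancer_type", "category"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"pair records missing columns: {sorted(missing)}")
    cohort_set = set(cohorts) if cohorts is not None else set(records["cancer_type"])
    rows = []
    for (a, b), sub in records.groupby(["gene_a", "gene_b"], sort=True):
        cats = set(sub["category"])
        if len(cats) != 1:
            continue
        category = cats.pop()
        if category not in CATEGORIES:
            continue
        if require_all and set(sub["cancer_type"]) != cohort_set:
            continue
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "category": category,
                "label": CATEGORY_LABELS[category],
                "n_cohorts": sub["cancer_type"].nunique(),
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "category", "label",
                                       "n_cohorts"])


def fisher_z_difference(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Two-sample Fisher z-test for equality of two Pearson correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.  An optional significance filter on top of
    the categorical change classifier; not applied by default.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("both sample sizes must be >= 4")
    for name, r in (("r1", r1), ("r2", r2)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
    if r1 == r2:
        return 0.0, 1.0
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((np.arctanh(r1) - np.arctanh(r2)) / se)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def render_corr_dotplot(
    cm_normal: CorrelationMatrix,
    cm_cancer: CorrelationMatrix,
    out: str | Path,
    max_dot_area: float = 60.0,
) -> None:
    """Side-by-side correlation dot matrices (normal | cancer).

    Blue dots are positive correlations, red dots negative; dot area is
    proportional to |r|; undefined cells are left blank.
    """
    if cm_normal.gene_ids != cm_cancer.gene_ids:
        raise ValueError("normal and cancer correlation matrices must share genes")
    from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: F401
    from matplotlib.figure import Figure

    n = len(cm_normal.gene_ids)
    fig = Figure(figsize=(max(4.0, n * 0.25) * 2 + 1, max(4.0, n * 0.25)))
    for ax, cm, title in zip(
        fig.subplots(1, 2), (cm_normal, cm_cancer), ("normal", "cancer")
    ):
        ii, jj = np.nonzero(cm.defined_mask)
        r = cm.r[ii, jj]
        colors = np.where(r >= 0, "tab:blue", "tab:red")
        ax.scatter(jj, ii, s=np.abs(r) * max_dot_area, c=colors, linewidths=0)
        ax.set_xlim(-0.5, n - 0.5)
        ax.set_ylim(n - 0.5, -0.5)
        ax.set_aspect("equal")
        ax.set_title(title)
        ticks = range(n) if n <= 30 else range(0, n, max(1, n // 30))
        ax.set_xticks(list(ticks))
        ax.set_xticklabels([cm.gene_ids[t] for t in ticks], rotation=90, fontsize=5)
        ax.set_yticks(list(ticks))
        ax.set_yticklabels([cm.gene_ids[t] for t in ticks], fontsize=5)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
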