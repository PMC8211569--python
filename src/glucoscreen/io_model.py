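"""Expression-matrix data model, plain-text readers/writers, and cohort bookkeeping.

The on-disk dialect is deliberately strict: expression tables are UTF-8
TSV with a ``gene`` header column followed by sample ids, one gene per
row, and every cell a finite nonnegative number.  Missing-cell markers
("." or "NA") are errors — a gene that was not quantified in a cohort is
modeled as an absent per-cohort record at the screening layer, never as
an imputed cell.  Gene identity is the exact symbol string,
case-sensitive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortPair",
    "CohortManifest",
    "CohortAdmissionError",
    "read_expression_table",
    "write_expression_table",
    "read_gene_list",
    "read_group_map",
    "write_group_map",
    "restrict_to_gene_list",
    "build_cohort_pair",
    "summarize_cohorts",
    "write_manifest",
]

GROUP_LABELS = ("normal", "cancer")


class CohortAdmissionError(ValueError):
    """A cohort failed the minimum-sample admission check."""

    def __init__(self, cancer_type: str, n_normal: int, n_cancer: int,
                 min_normal: int, min_cancer: int):
        self.n_normal = n_normal
        self.n_cancer = n_cancer
        super().__init__(
            f"cohort {cancer_type!r} rejected: n_normal={n_normal} "
            f"(need >= {min_normal}), n_cancer={n_cancer} (need >= {min_cancer})"
        )


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples matrix of nonnegative FPKM-like expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, cols])


@dataclasses.dataclass
class CohortPair:
    """One cancer type's matched normal and cancer expression matrices."""

    cancer_type: str
    normal: ExpressionMatrix
    cancer: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.normal.gene_ids != self.cancer.gene_ids:
            raise ValueError(
                f"cohort {self.cancer_type!r}: normal and cancer arms must share "
                "an identical gene list in identical order"
            )
        overlap = set(self.normal.sample_ids) & set(self.cancer.sample_ids)
        if overlap:
            raise ValueError(
                f"cohort {self.cancer_type!r}: sample ids shared between arms: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.normal.gene_ids

    @property
    def n_normal(self) -> int:
        return len(self.normal.sample_ids)

    @property
    def n_cancer(self) -> int:
        return len(self.cancer.sample_ids)


@dataclasses.dataclass
class CohortManifest:
    """Per-cancer-type sample bookkeeping: (cancer_type, n_normal, n_cancer)."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        _check_unique([e[0] for e in self.entries], "cancer_type")
        for ct, n_normal, n_cancer in self.entries:
            if n_normal < 0 or n_cancer < 0:
                raise ValueError(f"negative sample count for cohort {ct!r}")

    @property
    def total_normal(self) -> int:
        return sum(e[1] for e in self.entries)

    @property
    def total_cancer(self) -> int:
        return sum(e[2] for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["cancer_type", "n_normal", "n_cancer"])


def read_expression_table(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The first header cell is the gene-column label; the remaining header
    cells are sample ids.  Duplicate gene rows, duplicate sample columns,
    non-numeric cells (including "NA" and ".") and negative values are
    all hard errors.
    """
    if format != "tsv":
        raise ValueError(f"unsupported expression-table format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    df.index = df.index.astype(str)
    _check_unique(list(df.index), "gene")
    _check_unique(list(df.columns), "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in expression table {path}: {exc}") from exc
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the strict-dialect TSV; round-trips bit-exactly through repr floats."""
    df = m.to_frame()
    df.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    genes: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise ValueError(f"gene list {path} contains no symbols")
    return genes


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>group`` with group in {normal, cancer}."""
    groups: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
        sample, group = parts
        if lineno == 1 and group not in GROUP_LABELS:
            continue  # header row
        if group not in GROUP_LABELS:
            raise ValueError(f"{path}:{lineno}: unknown group {group!r}")
        if sample in groups:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        groups[sample] = group
    if not groups:
        raise ValueError(f"group map {path} is empty")
    return groups


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def restrict_to_gene_list(
    m: ExpressionMatrix, genes: Sequence[str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Subset a matrix to a gene list, in gene-list order.

    Returns the restricted matrix and the list of requested symbols absent
    from the matrix.  An empty intersection is an error — silently
    producing an empty screen would mask an identifier mismatch.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    wanted = list(dict.fromkeys(genes))
    row_of = {g: i for i, g in enumerate(m.gene_ids)}
    present = [g for g in wanted if g in row_of]
    absent = [g for g in wanted if g not in row_of]
    if not present:
        raise ValueError("gene list shares no symbols with the expression matrix")
    rows = [row_of[g] for g in present]
    return ExpressionMatrix(present, m.sample_ids, m.values[rows, :]), absent


def build_cohort_pair(
    cancer_type: str,
    matrix: ExpressionMatrix,
    groups: Mapping[str, str],
    min_normal: int = 10,
    min_cancer: int = 10,
) -> CohortPair:
    """Split a combined matrix into normal/cancer arms and apply the admission rule.

    Every sample must be mapped; cohorts with fewer than ``min_normal``
    normal or ``min_cancer`` cancer samples are rejected with
    :class:`CohortAdmissionError` (defaults 10/10, the pan-cancer
    admission criterion).
    """
    unmapped = [s for s in matrix.sample_ids if s not in groups]
    if unmapped:
        raise ValueError(
            f"cohort {cancer_type!r}: samples missing from group map: {unmapped[:5]}"
        )
    bad = {s: g for s, g in groups.items()
           if s in matrix.sample_ids and g not in GROUP_LABELS}
    if bad:
        raise ValueError(f"cohort {cancer_type!r}: unknown group labels: {bad}")
    normal_ids = [s for s in matrix.sample_ids if groups[s] == "normal"]
    cancer_ids = [s for s in matrix.sample_ids if groups[s] == "cancer"]
    if len(normal_ids) < min_normal or len(cancer_ids) < min_cancer:
        raise CohortAdmissionError(cancer_type, len(normal_ids), len(cancer_ids),
                                   min_normal, min_cancer)
    return CohortPair(
        cancer_type=cancer_type,
        normal=matrix.select_samples(normal_ids),
        cancer=matrix.select_samples(cancer_ids),
    )


def summarize_cohorts(
    pairs: Iterable[CohortPair],
) -> tuple[CohortManifest, tuple[int, int]]:
    """Manifest plus exact (total_normal, total_cancer) sums."""
    entries = [(p.cancer_type, p.n_normal, p.n_cancer) for p in pairs]
    if not entries:
        raise ValueError("no cohorts to summarize")
    manifest = CohortManifest(entries)
    return manifest, (manifest.total_normal, manifest.total_cancer)


def write_manifest(manifest: CohortManifest, path: str | Path,
                   descriptions: Mapping[str, str] | None = None) -> None:
    df = manifest.to_frame()
    df.insert(1, "description",
              [(descriptions or {}).get(ct, "") for ct in df["cancer_type"]])
    df.to_csv(path, sep="\t", index=False)
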