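"""Synthetic paired normal/cancer cohorts with planted ground truth.

Expression is lognormal: each value is ``exp(z)`` for a latent Gaussian
``z`` with a per-gene baseline mean and a common within-group standard
deviation.  The generator plants two kinds of signal against an
independent background:

* **differential genes** — the cancer arm's latent mean is shifted by
  ``log2fc * ln 2``, which makes the population log2 fold-change of
  group means exactly the requested value in every cohort;
* **decoupling pairs** — the two genes' latent noise is drawn from a
  bivariate Gaussian with the target correlation, separately per arm
  (a Gaussian copula), so the realized log-scale Pearson correlation
  concentrates on the target.  No gene participates in two planted
  pairs, keeping the planted covariance block-diagonal and valid.

One global seed expands into independent substreams keyed by
``(cohort index, arm)`` — adding a cohort never perturbs the data of
earlier cohorts — and every run is bit-reproducible given the spec.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import tcga_reference
from .io_model import CohortPair, ExpressionMatrix, write_expression_table, write_group_map

__all__ = [
    "PlantedPair",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohorts",
    "paper_shaped_spec",
    "small_spec",
    "write_dataset",
]

LN2 = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class PlantedPair:
    """A gene pair with per-arm target correlations and its intended category."""

    i: int
    j: int
    r_normal: float
    r_cancer: float
    category: str


@dataclasses.dataclass
class SyntheticSpec:
    """Study-shape parameters of a synthetic pan-cancer dataset.

    ``n_normal`` / ``n_cancer`` are either one count shared by all
    cohorts or per-cohort sequences of length ``k_cohorts``.  Latent
    scale: gene baselines are spread uniformly over ``base_log_mean +/-
    gene_baseline_spread`` (natural-log units) and within-group noise has
    standard deviation ``base_log_sd``.
    """

    n_genes: int = 127
    k_cohorts: int = 12
    n_normal: int | Sequence[int] = 50
    n_cancer: int | Sequence[int] = 200
    planted_degs: list[tuple[int, float]] = dataclasses.field(default_factory=list)
    planted_pairs: list[PlantedPair] = dataclasses.field(default_factory=list)
    base_log_mean: float = 3.0
    base_log_sd: float = 0.5
    gene_baseline_spread: float = 1.0
    cancer_types: list[str] | None = None
    seed: int = 0

    def resolved_counts(self) -> tuple[list[int], list[int]]:
        def expand(x) -> list[int]:
            if isinstance(x, (int, np.integer)):
                return [int(x)] * self.k_cohorts
            xs = [int(v) for v in x]
            if len(xs) != self.k_cohorts:
                raise ValueError("per-cohort sample counts must have k_cohorts entries")
            return xs

        return expand(self.n_normal), expand(self.n_cancer)

    def resolved_cancer_types(self) -> list[str]:
        if self.cancer_types is None:
            return [f"C{i:02d}" for i in range(self.k_cohorts)]
        if len(self.cancer_types) != self.k_cohorts:
            raise ValueError("cancer_types must have k_cohorts entries")
        return list(self.cancer_types)

    def validate(self) -> None:
        if self.n_genes < 1 or self.k_cohorts < 1:
            raise ValueError("n_genes and k_cohorts must be positive")
        n_normal, n_cancer = self.resolved_counts()
        if min(n_normal) < 4 or min(n_cancer) < 4:
            raise ValueError("every cohort needs >= 4 samples per arm")
        if self.base_log_sd <= 0:
            raise ValueError("base_log_sd must be positive")
        for idx, fc in self.planted_degs:
            if not (0 <= idx < self.n_genes):
                raise ValueError(f"planted DEG index {idx} out of range")
            if not np.isfinite(fc):
                raise ValueError("planted log2fc must be finite")
        used: set[int] = set()
        for p in self.planted_pairs:
            if p.i == p.j:
                raise ValueError("planted pair indices must be distinct")
            if not (0 <= p.i < self.n_genes and 0 <= p.j < self.n_genes):
                raise ValueError(f"planted pair ({p.i}, {p.j}) out of range")
            if not (abs(p.r_normal) < 1 and abs(p.r_cancer) < 1):
                raise ValueError("planted |r| targets must be < 1")
            if p.i in used or p.j in used:
                raise ValueError("a gene may participate in only one planted pair")
            used.update((p.i, p.j))
        self.resolved_cancer_types()


@dataclasses.dataclass
class GroundTruth:
    """What was planted, per cohort and overall; written beside every dataset."""

    cohort_sizes: pd.DataFrame  # cancer_type, n_normal, n_cancer
    degs: pd.DataFrame          # gene, log2fc
    pairs: pd.DataFrame         # gene_a, gene_b, r_normal, r_cancer, category


def _gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n_genes)]


def _arm_latent(
    spec: SyntheticSpec,
    baselines: np.ndarray,
    cohort_idx: int,
    arm: str,
    n_samples: int,
) -> np.ndarray:
    """Latent Gaussian draws for one cohort arm, from its own substream."""
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(1, cohort_idx, 0 if arm == "normal" else 1))
    )
    eps = rng.standard_normal((spec.n_genes, n_samples))
    for p in spec.planted_pairs:
        r = p.r_normal if arm == "normal" else p.r_cancer
        eps[p.j] = r * eps[p.i] + np.sqrt(1.0 - r * r) * rng.standard_normal(n_samples)
    z = baselines[:, None] + spec.base_log_sd * eps
    if arm == "cancer":
        for idx, fc in spec.planted_degs:
            z[idx] += fc * LN2
    return z


def generate_cohorts(spec: SyntheticSpec) -> tuple[list[CohortPair], GroundTruth]:
    """Generate all cohorts of a spec, plus the planted-truth manifest."""
    spec.validate()
    genes = _gene_ids(spec.n_genes)
    n_normal, n_cancer = spec.resolved_counts()
    types = spec.resolved_cancer_types()

    base_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    baselines = spec.base_log_mean + spec.gene_baseline_spread * (
        2.0 * base_rng.random(spec.n_genes) - 1.0
    )

    pairs: list[CohortPair] = []
    for c, cancer_type in enumerate(types):
        z_normal = _arm_latent(spec, baselines, c, "normal", n_normal[c])
        z_cancer = _arm_latent(spec, baselines, c, "cancer", n_cancer[c])
        normal = ExpressionMatrix(
            genes,
            [f"{cancer_type}-N{k:04d}" for k in range(n_normal[c])],
            np.exp(z_normal),
        )
        cancer = ExpressionMatrix(
            genes,
            [f"{cancer_type}-T{k:04d}" for k in range(n_cancer[c])],
            np.exp(z_cancer),
        )
        pairs.append(CohortPair(cancer_type, normal, cancer))

    truth = GroundTruth(
        cohort_sizes=pd.DataFrame(
            {"cancer_type": types, "n_normal": n_normal, "n_cancer": n_cancer}
        ),
        degs=pd.DataFrame(
            [{"gene": genes[i], "log2fc": fc} for i, fc in spec.planted_degs],
            columns=["gene", "log2fc"],
        ),
        pairs=pd.DataFrame(
            [
                {
                    "gene_a": min(genes[p.i], genes[p.j]),
                    "gene_b": max(genes[p.i], genes[p.j]),
                    "r_normal": p.r_normal,
                    "r_cancer": p.r_cancer,
                    "category": p.category,
                }
                for p in spec.planted_pairs
            ],
            columns=["gene_a", "gene_b", "r_normal", "r_cancer", "category"],
        ),
    )
    return pairs, truth


def paper_shaped_spec(seed: int = 0) -> SyntheticSpec:
    """A spec shaped like the pan-cancer glucose-metabolism study.

    12 cohorts with the real TCGA sample counts, 127 genes, two
    direction-consistent differential genes (one strongly down at log2FC
    -3, one up at +2) and five decoupling pairs — three positive pairs
    weakening (r 0.9 -> 0.2) and two negative pairs weakening (-0.9 ->
    -0.2), matching the published category split.  Strong-to-weak targets
    are set well apart so the planted transition is identifiable even in
    the smallest normal arm (n = 11).
    """
    sizes = tcga_reference.cohort_size_frame()
    return SyntheticSpec(
        n_genes=127,
        k_cohorts=12,
        n_normal=sizes["n_normal"].tolist(),
        n_cancer=sizes["n_cancer"].tolist(),
        planted_degs=[(0, -3.0), (1, 2.0)],
        planted_pairs=[
            PlantedPair(10, 11, 0.9, 0.2, "pos_less_pos"),
            PlantedPair(12, 13, 0.9, 0.2, "pos_less_pos"),
            PlantedPair(14, 15, 0.9, 0.2, "pos_less_pos"),
            PlantedPair(16, 17, -0.9, -0.2, "neg_less_neg"),
            PlantedPair(18, 19, -0.9, -0.2, "neg_less_neg"),
        ],
        cancer_types=sizes["cancer_type"].tolist(),
        seed=seed,
    )


def small_spec(seed: int = 0) -> SyntheticSpec:
    """A three-cohort miniature for fast end-to-end smoke runs."""
    return SyntheticSpec(
        n_genes=40,
        k_cohorts=3,
        n_normal=30,
        n_cancer=60,
        planted_degs=[(0, -3.0), (1, 2.0)],
        planted_pairs=[
            PlantedPair(5, 6, 0.9, 0.2, "pos_less_pos"),
            PlantedPair(7, 8, -0.9, -0.2, "neg_less_neg"),
        ],
        cancer_types=["AAA", "BBB", "CCC"],
        seed=seed,
    )


def write_dataset(
    pairs: list[CohortPair], truth: GroundTruth, spec: SyntheticSpec, outdir: str | Path
) -> None:
    """Write one expression + group-map TSV per cohort, the planted-truth
    tables, a gene-list file, and a machine-readable spec echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        combined = ExpressionMatrix(
            pair.gene_ids,
            pair.normal.sample_ids + pair.cancer.sample_ids,
            np.concatenate([pair.normal.values, pair.cancer.values], axis=1),
        )
        write_expression_table(combined, outdir / f"{pair.cancer_type}_expression.tsv")
        groups = {s: "normal" for s in pair.normal.sample_ids}
        groups.update({s: "cancer" for s in pair.cancer.sample_ids})
        write_group_map(groups, outdir / f"{pair.cancer_type}_groups.tsv")
    (outdir / "gene_list.txt").write_text(
        "\n".join(pairs[0].gene_ids) + "\n", encoding="utf-8"
    )
    truth.cohort_sizes.to_csv(outdir / "ground_truth_cohorts.tsv", sep="\t", index=False)
    truth.degs.to_csv(outdir / "ground_truth_degs.tsv", sep="\t", index=False)
    truth.pairs.to_csv(outdir / "ground_truth_pairs.tsv", sep="\t", index=False)
    echo = dataclasses.asdict(spec)
    echo["planted_pairs"] = [dataclasses.asdict(p) for p in spec.planted_pairs]
    (outdir / "spec.json").write_text(json.dumps(echo, indent=2), encoding="utf-8")
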