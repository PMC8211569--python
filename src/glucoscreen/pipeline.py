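"""End-to-end orchestration of the screen from a declarative config file.

``run_screen`` executes cohort loading -> differential-expression
screens -> correlation-change screens -> (optional) PPI neighborhood
extraction, writing every stage table plus a Markdown summary report
that echoes all effective thresholds and conventions.  Outputs are
deterministic: the same config on the same inputs produces byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .corr_screen import (
    ScreenConfig,
    correlation_matrix,
    pair_change_table,
    render_corr_dotplot,
    screen_consistent_pairs,
)
from .deg_screen import deg_table, log2fc_grid, screen_differential, screen_trend
from .io_model import (
    build_cohort_pair,
    read_expression_table,
    read_gene_list,
    read_group_map,
    restrict_to_gene_list,
    summarize_cohorts,
    write_manifest,
)
from .ppi import degree_report, direct_neighborhood, export_graph, parse_biogrid_tab

__all__ = ["CohortInput", "RunConfig", "load_config", "run_screen", "regenerate_report"]


@dataclasses.dataclass
class CohortInput:
    cancer_type: str
    expression: Path
    groups: Path


@dataclasses.dataclass
class RunConfig:
    """Validated screen configuration (one YAML file)."""

    cohorts: list[CohortInput]
    gene_list: Path
    out_dir: Path
    fc_cutoff: float = 1.0
    p_cutoff: float = 0.05
    sign_tau: float = 0.1
    delta_min: float = 0.1
    transform: str = "log2p1"
    pseudocount: float = 1e-3
    min_normal: int = 10
    min_cancer: int = 10
    require_all: bool = True
    biogrid: Path | None = None
    plots: bool = True
    seed: int = 0

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(self.sign_tau, self.delta_min, self.transform)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cohorts"] = [
            {"cancer_type": c.cancer_type, "expression": str(c.expression),
             "groups": str(c.groups)}
            for c in self.cohorts
        ]
        for key in ("gene_list", "out_dir", "biogrid"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; all referenced paths must exist."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    cohorts = []
    for entry in raw.get("cohorts", []):
        cohorts.append(
            CohortInput(
                cancer_type=str(entry["cancer_type"]),
                expression=resolve(entry["expression"]),
                groups=resolve(entry["groups"]),
            )
        )
    if not cohorts:
        raise ValueError(f"config {path} lists no cohorts")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    extra = {
        k: v for k, v in raw.items() if k in known and k not in ("cohorts", "gene_list", "out_dir", "biogrid")
    }
    cfg = RunConfig(
        cohorts=cohorts,
        gene_list=resolve(raw["gene_list"]),
        out_dir=resolve(raw["out_dir"]),
        biogrid=resolve(raw["biogrid"]) if raw.get("biogrid") else None,
        **extra,
    )
    for c in cfg.cohorts:
        for p in (c.expression, c.groups):
            if not Path(p).exists():
                raise ValueError(f"config error: path does not exist: {p}")
    if not Path(cfg.gene_list).exists():
        raise ValueError(f"config error: path does not exist: {cfg.gene_list}")
    if cfg.biogrid is not None and not Path(cfg.biogrid).exists():
        raise ValueError(f"config error: path does not exist: {cfg.biogrid}")
    if not (0 < cfg.p_cutoff <= 1) or cfg.fc_cutoff < 0:
        raise ValueError("config error: cut-offs out of range")
    cfg.screen_config()  # validates sign_tau / delta_min / transform
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True),
                          encoding="utf-8")


def run_screen(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full screen and write the report bundle to ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_list = read_gene_list(cfg.gene_list)

    cohort_pairs = []
    absent_report: dict[str, list[str]] = {}
    for entry in sorted(cfg.cohorts, key=lambda c: c.cancer_type):
        matrix = read_expression_table(entry.expression)
        restricted, absent = restrict_to_gene_list(matrix, gene_list)
        if absent:
            absent_report[entry.cancer_type] = absent
        groups = read_group_map(entry.groups)
        cohort_pairs.append(
            build_cohort_pair(entry.cancer_type, restricted, groups,
                              cfg.min_normal, cfg.min_cancer)
        )

    manifest, (total_normal, total_cancer) = summarize_cohorts(cohort_pairs)
    write_manifest(manifest, out / "cohort_manifest.tsv")

    records = pd.concat(
        [deg_table(p, cfg.pseudocount, genes=gene_list) for p in cohort_pairs],
        ignore_index=True,
    )
    records.to_csv(out / "deg_records.tsv", sep="\t", index=False)
    log2fc_grid(records).to_csv(out / "log2fc_grid.tsv", sep="\t")
    trend = screen_trend(records)
    trend.to_csv(out / "trend_screen.tsv", sep="\t", index=False)
    deg_hits, diff_table = screen_differential(
        records, cfg.fc_cutoff, cfg.p_cutoff, require_all=cfg.require_all
    )
    diff_table.to_csv(out / "differential_screen.tsv", sep="\t", index=False)

    screen_cfg = cfg.screen_config()
    pair_records = []
    for pair in cohort_pairs:
        cm_normal = correlation_matrix(pair.normal, cfg.transform)
        cm_cancer = correlation_matrix(pair.cancer, cfg.transform)
        pair_records.append(
            pair_change_table(cm_normal, cm_cancer, screen_cfg, pair.cancer_type)
        )
        if cfg.plots:
            render_corr_dotplot(cm_normal, cm_cancer,
                                out / f"corr_{pair.cancer_type}.png")
    pair_records = pd.concat(pair_records, ignore_index=True)
    pair_records.to_csv(out / "pair_records.tsv", sep="\t", index=False,
                        float_format="%.6f")
    hits = screen_consistent_pairs(
        pair_records, require_all=cfg.require_all,
        cohorts=[p.cancer_type for p in cohort_pairs],
    )
    hits.to_csv(out / "consistent_pairs.tsv", sep="\t", index=False)

    ppi_summary = None
    if cfg.biogrid is not None and len(hits):
        graph, parse_report = parse_biogrid_tab(cfg.biogrid)
        seeds = sorted(set(hits["gene_a"]) | set(hits["gene_b"]))
        seeds_present = [s for s in seeds if s in graph]
        if seeds_present:
            nbhd = direct_neighborhood(graph, seeds, reference_list=gene_list)
            degree_report(nbhd).to_csv(out / "ppi_degrees.tsv", sep="\t", index=False)
            export_graph(nbhd.subgraph, "sif", out / "ppi_subnetwork.sif")
            export_graph(nbhd.subgraph, "graphml", out / "ppi_subnetwork.graphml")
            ppi_summary = {
                "n_direct_interactions": nbhd.n_direct_interactions,
                "n_partners": nbhd.n_partners,
                "n_partners_in_reference_list": nbhd.n_partners_in_reference_list,
                "n_duplicate_lines_collapsed": parse_report.n_duplicate_edges,
                "n_self_loops_removed": parse_report.n_self_loops,
            }

    results = {
        "manifest": manifest,
        "totals": (total_normal, total_cancer),
        "records": records,
        "trend": trend,
        "deg_hits": deg_hits,
        "differential_table": diff_table,
        "pair_records": pair_records,
        "consistent_pairs": hits,
        "ppi_summary": ppi_summary,
        "absent_genes": absent_report,
    }
    _write_report(cfg, results, out / "report.md")
    return results


def _md_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    rows = [[str(v) for v in row] for row in df.itertuples(index=False, name=None)]
    widths = [max(len(c), *(len(r[i]) for r in rows)) if rows else len(c)
              for i, c in enumerate(cols)]
    def fmt(cells: list[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    sep = "| " + " | ".join("-" * w for w in widths) + " |"
    return "\n".join([fmt(cols), sep, *(fmt(r) for r in rows)])


def _write_report(cfg: RunConfig, results: dict[str, Any], path: Path) -> None:
    manifest = results["manifest"]
    trend = results["trend"]
    hits = results["consistent_pairs"]
    p_waived = bool(results["differential_table"].attrs.get("p_criterion_waived", False))
    lines = [
        "# Glucose-metabolism co-expression screen report",
        "",
        f"- tool version: glucoscreen {__version__}",
        f"- config hash: {cfg.config_hash()}",
        f"- cohorts: {len(manifest.entries)} "
        f"({results['totals'][0]} normal, {results['totals'][1]} cancer samples)",
        "",
        "## Effective thresholds and conventions",
        "",
        f"- fold-change cut-off |log2FC| >= {cfg.fc_cutoff}",
        f"- p-value cut-off p < {cfg.p_cutoff} (raw, per cohort)"
        + (" — WAIVED for records carrying no p-value" if p_waived else ""),
        f"- correlation transform: {cfg.transform}",
        f"- classifier dead zone sign_tau = {cfg.sign_tau}, "
        f"minimum change delta_min = {cfg.delta_min}",
        f"- pseudocount {cfg.pseudocount}; admission n_normal >= {cfg.min_normal}, "
        f"n_cancer >= {cfg.min_cancer}; require_all = {cfg.require_all}",
        "",
        "## Cohort manifest",
        "",
        _md_table(manifest.to_frame()),
        "",
        "## Trend screen",
        "",
        f"{int(trend['trend_consistent'].sum())} of {len(trend)} genes are "
        "sign-consistent across their available cohorts.",
        "",
        "## Differential screen",
        "",
        f"Hits (pass in every available cohort): {', '.join(results['deg_hits']) or 'none'}",
        "",
        "## Consistent correlation-change pairs",
        "",
        _md_table(hits[["gene_a", "gene_b", "label"]])
        if len(hits)
        else "none",
        "",
    ]
    if results["ppi_summary"]:
        s = results["ppi_summary"]
        lines += [
            "## PPI neighborhood of hit genes",
            "",
            f"- direct interactions: {s['n_direct_interactions']}",
            f"- distinct non-seed partners: {s['n_partners']}",
            f"- partners in the reference gene list: {s['n_partners_in_reference_list']}",
            "",
        ]
    if results["absent_genes"]:
        lines += [
            "## Gene-list symbols absent from cohorts",
            "",
            *(f"- {ct}: {', '.join(genes)}" for ct, genes in
              sorted(results["absent_genes"].items())),
            "",
        ]
    path.write_text("\n".join(lines), encoding="utf-8")


def regenerate_report(cfg: RunConfig) -> Path:
    """Rebuild ``report.md`` from the stage TSVs already in ``out_dir``."""
    out = Path(cfg.out_dir)
    needed = ["cohort_manifest.tsv", "deg_records.tsv", "trend_screen.tsv",
              "differential_screen.tsv", "pair_records.tsv", "consistent_pairs.tsv"]
    for name in needed:
        if not (out / name).exists():
            raise ValueError(f"stage output missing, run the screen first: {out / name}")
    from .io_model import CohortManifest

    mdf = pd.read_csv(out / "cohort_manifest.tsv", sep="\t")
    manifest = CohortManifest(
        list(mdf[["cancer_type", "n_normal", "n_cancer"]].itertuples(index=False, name=None))
    )
    records = pd.read_csv(out / "deg_records.tsv", sep="\t")
    diff_table = pd.read_csv(out / "differential_screen.tsv", sep="\t")
    diff_table.attrs["p_criterion_waived"] = bool(
        (records["available"] & records["p_value"].isna()).any()
    )
    hits = pd.read_csv(out / "consistent_pairs.tsv", sep="\t")
    if hits.empty:
        hits = hits.reindex(columns=["gene_a", "gene_b", "category", "label", "n_cohorts"])
    results = {
        "manifest": manifest,
        "totals": (manifest.total_normal, manifest.total_cancer),
        "records": records,
        "trend": pd.read_csv(out / "trend_screen.tsv", sep="\t"),
        "deg_hits": diff_table.loc[diff_table["differential_in_all"], "gene"].tolist(),
        "differential_table": diff_table,
        "pair_records": pd.read_csv(out / "pair_records.tsv", sep="\t"),
        "consistent_pairs": hits,
        "ppi_summary": None,
        "absent_genes": {},
    }
    _write_report(cfg, results, out / "report.md")
    return out / "report.md"
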