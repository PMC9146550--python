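"""End-to-end orchestration: screen -> cluster -> prioritize -> mixture -> expression.

One config drives all stages; every stage writes its artifacts plus
provenance (input hashes, parameters, funnel counts) into the output
directory, and the final report is reconstructible from the per-stage
artifacts alone.  Reruns with the same config and inputs are
byte-identical: nothing time- or path-dependent enters any output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog, clustering, ddct, doseresponse, mixture, prioritize, screen, simulate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline settings in one validated, serializable object."""

    # inputs (optional when simulating)
    list_presence: str | None = None
    keyword_map: str | None = None
    assay_summary: str | None = None
    viability: str | None = None
    qpcr_ct: str | None = None
    # screening
    endpoint_name: str = "ATG_PPARg_TRANS_up"
    z_threshold: float = 2.0
    missing_z_policy: str = "pass_with_flag"
    # catalog
    min_categories: int = 2
    unmapped_policy: str = "drop_with_warning"
    # clustering
    linkage: str = "ward"
    k_max: int = 34
    selection_rule: str = "first_silhouette_peak"
    # prioritization
    required_categories: list[str] = field(default_factory=list)
    # mixture / dose-response
    i_values: list[float] = field(default_factory=lambda: [1.0, 0.5, 0.2])
    fallback_um: float = 1000.0
    tested_range_um: list[float] = field(default_factory=lambda: [0.0, 2000.0])
    # expression
    housekeeping: list[str] = field(default_factory=lambda: ["GAPDH"])
    control_label: str = "vehicle"
    test_method: str = "welch"
    # reproducibility
    seed: int = 1

    def validate(self) -> None:
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be >= 0")
        if self.min_categories < 1:
            raise ValueError("min_categories must be >= 1")
        if self.linkage not in clustering.LINKAGE_METHODS:
            raise ValueError(f"linkage must be one of {clustering.LINKAGE_METHODS}")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.selection_rule not in clustering.SELECTION_RULES:
            raise ValueError(f"selection_rule must be one of {clustering.SELECTION_RULES}")
        if not self.i_values or any(i <= 0 for i in self.i_values):
            raise ValueError("i_values must be non-empty and positive")
        if len(self.tested_range_um) != 2 or self.tested_range_um[1] <= self.tested_range_um[0]:
            raise ValueError("tested_range_um must be (low, high)")
        if self.test_method not in {"welch", "student"}:
            raise ValueError("test_method must be 'welch' or 'student'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path, *, do_simulate: bool = False,
                 make_heatmap: bool = False) -> dict:
    """Run every stage in order, writing artifacts and a report to ``outdir``.

    With ``do_simulate`` the synthetic fixture suite is generated first
    (under ``outdir/inputs``) and the report compares planted truth with
    recovered structure.  Returns a provenance dictionary (also written
    as ``provenance.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth: simulate.SyntheticTruth | None = None
    if do_simulate:
        paths = simulate.simulate_all(config.seed, outdir / "inputs")
        config.list_presence = str(paths["list_presence"])
        config.keyword_map = str(paths["keyword_map"])
        config.assay_summary = str(paths["assay_summary"])
        config.viability = str(paths["viability"])
        config.qpcr_ct = str(paths["qpcr_ct"])
        truth = simulate.SyntheticTruth.from_json(paths["truth"])

    for name in ("list_presence", "keyword_map", "assay_summary", "viability", "qpcr_ct"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p}")

    prov: dict = {
        "config": asdict(config),
        "inputs": {
            name: {"file": Path(getattr(config, name)).name,
                   "sha256": _sha256(Path(getattr(config, name)))}
            for name in ("list_presence", "keyword_map", "assay_summary", "viability", "qpcr_ct")
        },
        "stages": {},
    }
    report: list[str] = ["Co-occurring chemical mixture prioritization report", "=" * 51, ""]

    # stage 1: exposure catalog
    records = catalog.load_list_presence(config.list_presence)
    mapping = catalog.load_keyword_map(config.keyword_map)
    pairs = catalog.map_keywords(records, mapping, config.unmapped_policy)
    matrix = catalog.build_presence_matrix(pairs)
    filt = catalog.filter_min_categories(matrix, config.min_categories)
    catalog.write_presence_matrix(filt.matrix, outdir / "presence_matrix.tsv",
                                  filt.provenance())
    prov["stages"]["catalog"] = {
        "n_records": len(records),
        "n_keywords": len({r.keyword for r in records}),
        "n_pairs": len(pairs),
        **filt.provenance(),
    }
    report += [
        "Exposure catalog",
        f"  list-presence records: {len(records)}",
        f"  distinct keywords: {len({r.keyword for r in records})}"
        f" -> categories: {matrix.shape[1]}",
        f"  chemicals with >= {config.min_categories} categories: {filt.matrix.shape[0]}",
        "",
    ]

    # stage 2: bioactivity screen
    assay = screen.load_assay_summary(config.assay_summary, config.endpoint_name)
    result = screen.filter_active_noncytotoxic(assay, config.z_threshold,
                                               config.missing_z_policy)
    result.to_json(outdir / "screen.json")
    screened = screen.intersect_with_exposure(result, filt.matrix, config.min_categories)
    catalog.write_presence_matrix(screened.matrix, outdir / "screened_matrix.tsv",
                                  screened.provenance())
    prov["stages"]["screen"] = {**result.stage_counts,
                                "active_and_exposed": int(screened.matrix.shape[0])}
    report += [
        f"Bioactivity screen (endpoint {config.endpoint_name}, Z > {config.z_threshold:g})",
        f"  records screened: {result.stage_counts['input']}",
        f"  hit call 1: {result.stage_counts['hit_call_1']}",
        f"  active below cytotoxicity: {result.stage_counts['hit_and_noncytotoxic']}",
        f"  active with exposure data (>= {config.min_categories} categories): "
        f"{screened.matrix.shape[0]}",
        "",
    ]

    # stage 3: co-occurrence clustering
    sol = clustering.assign_clusters(screened.matrix, linkage=config.linkage,
                                     k_max_rows=config.k_max, k_max_cols=config.k_max,
                                     selection_rule=config.selection_rule)
    sol.assignments_frame().to_csv(outdir / "cluster_assignments.tsv", sep="\t", index=False)
    sol.row_profile.as_frame().to_csv(outdir / "k_profile_chemicals.csv", index=False)
    sol.col_profile.as_frame().to_csv(outdir / "k_profile_categories.csv", index=False)
    ordered, row_b, col_b = clustering.biclustered_layout(screened.matrix, sol)
    ordered.to_csv(outdir / "biclustered_matrix.tsv", sep="\t")
    (outdir / "cluster_boundaries.json").write_text(
        json.dumps({"row_boundaries": row_b, "col_boundaries": col_b}, sort_keys=True) + "\n"
    )
    if make_heatmap:
        clustering.plot_heatmap(screened.matrix, sol, str(outdir / "heatmap.png"))
    prov["stages"]["clustering"] = {
        "linkage": config.linkage,
        "k_max": config.k_max,
        "selection_rule": config.selection_rule,
        "chemical_clusters": sol.n_row_clusters,
        "category_clusters": sol.n_col_clusters,
    }
    report += [
        f"Co-occurrence clustering (Jaccard distance, {config.linkage} linkage, "
        f"k by {config.selection_rule} over 2..{config.k_max})",
        f"  chemical clusters: {sol.n_row_clusters}",
        f"  category clusters: {sol.n_col_clusters}",
    ]
    if truth is not None:
        planted_rows = len(set(truth.row_blocks.values()))
        planted_cols = len(set(truth.col_blocks.values()))
        report += [
            f"  planted chemical blocks: {planted_rows} "
            f"(recovered {sol.n_row_clusters})",
            f"  planted category blocks: {planted_cols} "
            f"(recovered {sol.n_col_clusters})",
        ]
    report.append("")

    # stage 4: cluster prioritization
    summaries = prioritize.summarize_clusters(screened.matrix, sol)
    ranked = prioritize.prioritize_cluster(summaries, config.required_categories or None)
    ranked.to_json(outdir / "clusters_ranked.json")
    sel = ranked.selected
    pd.DataFrame(
        {"chemical_id": sel.members,
         "n_categories": [sel.category_counts[c] for c in sel.members]}
    ).to_csv(outdir / "selected_cluster_members.csv", index=False)
    stats = prioritize.breadth_stats(summaries)
    prov["stages"]["prioritization"] = {
        "selected_cluster": sel.cluster,
        "n_members": sel.n_members,
        "mean_categories": sel.mean_categories,
        **stats,
    }
    report += [
        "Cluster prioritization (mean exposure-source count)",
        f"  selected cluster {sel.cluster}: {sel.n_members} chemicals, "
        f"mean {sel.mean_categories:.2f} categories "
        f"(all-cluster mean {stats['overall_mean']:.2f}, "
        f"min {stats['min']:.2f}, max {stats['max']:.2f})",
        "",
    ]

    # stage 5: dose-response AC90s
    via = pd.read_csv(config.viability)
    lo, hi = config.tested_range_um
    ac90s, fits = doseresponse.ac90_table_from_viability(
        via, (lo, hi), config.fallback_um
    )
    ac90_frame = pd.DataFrame(
        [{"chemical": e.chemical, "casrn": e.casrn, "ac90_um": e.ac90_um,
          "status": e.status} for e in ac90s.ordered()]
    )
    ac90_frame.to_csv(outdir / "ac90_table.csv", index=False)
    (outdir / "fit_report.json").write_text(
        json.dumps(
            {c: {"top": f.top, "bottom": f.bottom, "midpoint_um": f.midpoint_um,
                 "hill": f.hill, "rss": f.rss, "n_obs": f.n_obs}
             for c, f in sorted(fits.items())},
            indent=2, sort_keys=True) + "\n"
    )
    prov["stages"]["dose_response"] = {
        "n_chemicals": len(ac90s),
        "n_fallback": sum(e.status == mixture.STATUS_FALLBACK for e in ac90s.values()),
    }
    report += ["Dose-response AC90 estimation"]
    for e in ac90s.ordered():
        note = " (fallback: 90% never reached in tested range)" \
            if e.status == mixture.STATUS_FALLBACK else ""
        report.append(f"  {e.chemical}: AC90 = {e.ac90_um:.4g} µM{note}")
    report.append("")

    # stage 6: mixture design
    sheet = mixture.mixture_sheet(ac90s, config.i_values, outdir / "mixture_sheet.csv")
    report += ["Proportional-AC90 mixture design"]
    for spec in mixture.mixture_series(ac90s, config.i_values):
        report.append(f"  C_{spec.i:g}: total {spec.total_um:.4g} µM "
                      f"({len(spec.components_um)} components)")
    report.append("")
    prov["stages"]["mixture"] = {
        "i_values": list(config.i_values),
        "totals_um": {f"{s.i:g}": s.total_um
                      for s in mixture.mixture_series(ac90s, config.i_values)},
    }

    # stage 7: expression ddCt
    ct = pd.read_csv(config.qpcr_ct)
    expr = ddct.ddct_analysis(ct, config.control_label,
                              housekeeping=set(config.housekeeping),
                              test_method=config.test_method)
    expr.write(outdir / "expression_summary.csv")
    expr.write_replicates(outdir / "expression_replicates.csv")
    prov["stages"]["expression"] = {
        "n_conditions": int(expr.summary["condition"].nunique()),
        "genes": sorted(expr.summary["gene"].unique()),
        "test_method": config.test_method,
    }
    report += [f"Gene expression (ddCt vs {config.control_label}, "
               f"{config.test_method} test)"]
    for _, row in expr.summary.iterrows():
        if row["condition"] == config.control_label:
            continue
        p = f", p = {row['p_value']:.3g}" if pd.notna(row["p_value"]) else ""
        report.append(f"  {row['condition']} / {row['gene']}: "
                      f"log2FC = {row['mean_log2fc']:.3g}{p}")
    report.append("")

    (outdir / "provenance.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True) + "\n")
    config.to_yaml(outdir / "config.yaml")
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return prov
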