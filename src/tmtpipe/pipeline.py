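"""Configuration-driven orchestration of the full analysis.

The default configuration simulates the emulated study: four datasets (two
brain regions x two nicotine regimens), each a 2-plex TMT 10-plex design
with pooled reference channels. Per dataset the stages run in order:
simulate (or load) -> row filters -> normalization (IRS for the
high-coverage chronic-VTA-style dataset, least-squares linear batch
correction for the others) -> QC -> the three pairwise moderated tests ->
cross-dataset overlap accounting -> over-representation analysis ->
score-thresholded network + MCODE complexes. Every numeric artifact is
written as TSV with a fixed float format, so identical config + seed gives
byte-identical outputs; a JSON manifest records parameters, seeds and row
counts at every filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, enrichment, mcode, normalize, overlap, simulate, stats
from .containers import IntensityMatrix
from .errors import ConfigError, StageError

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

STAGES = ("simulate", "normalize", "qc", "compare", "overlap", "enrich",
          "cluster", "run")


@dataclass
class DatasetConfig:
    """One brain-region x regimen dataset."""

    name: str
    batch_method: str = "linear_model"      # irs | linear_model
    anova_enabled: bool = True
    n_proteins: int = 500
    protein_groups: str | None = None       # read instead of simulate when set
    design: str | None = None

    def __post_init__(self):
        if self.batch_method not in ("irs", "linear_model"):
            raise ConfigError(f"dataset {self.name}: invalid batch_method "
                              f"{self.batch_method!r}")


def _default_datasets():
    # coverage ratios mirror the emulated study (chronic VTA the deepest,
    # and the only one batch-corrected by IRS without the ANOVA prefilter)
    return [
        DatasetConfig("subchronic_vta", "linear_model", True, 450),
        DatasetConfig("subchronic_nac", "linear_model", True, 400),
        DatasetConfig("chronic_vta", "irs", False, 800),
        DatasetConfig("chronic_nac", "linear_model", True, 460),
    ]


@dataclass
class PipelineConfig:
    """Everything run_all needs; see the packaged default config."""

    outdir: str = "tmtpipe_out"
    seed: int = 0
    datasets: list = field(default_factory=_default_datasets)
    test: stats.TestConfig = field(default_factory=stats.TestConfig)
    synthetic: dict = field(default_factory=dict)   # SyntheticDesign overrides
    gmt_path: str | None = None                     # None -> synthetic gene sets
    edges_path: str | None = None                   # None -> synthetic PPI edges
    edges_score_scale: str = "unit"
    min_score: float = 0.7
    mcode: mcode.MCODEParams = field(default_factory=mcode.MCODEParams)
    enrichment_top_k: int = 5
    enrichment_q_cutoff: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        datasets = d.pop("datasets", None)
        test = d.pop("test", None)
        mcode_d = d.pop("mcode", None)
        cfg = cls(**d)
        if datasets is not None:
            cfg.datasets = [DatasetConfig(**ds) if isinstance(ds, dict) else ds
                            for ds in datasets]
        if test is not None:
            cfg.test = stats.TestConfig(**test) if isinstance(test, dict) else test
        if mcode_d is not None:
            cfg.mcode = mcode.MCODEParams(**mcode_d) if isinstance(mcode_d, dict) \
                else mcode_d
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate_paths(self) -> None:
        """Pre-flight check before any compute."""
        for p in (self.gmt_path, self.edges_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")
        for ds in self.datasets:
            for p in (ds.protein_groups, ds.design):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"dataset {ds.name}: missing input {p}")


def _subseed(seed: int, name: str) -> int:
    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2 ** 31)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# per-dataset processing
# ---------------------------------------------------------------------------

def _load_or_simulate(config: PipelineConfig, ds: DatasetConfig, outdir: Path):
    if ds.protein_groups is not None:
        matrix = core_io.read_protein_groups(ds.protein_groups, ds.design)
        return matrix, None
    design = simulate.SyntheticDesign(
        n_proteins=ds.n_proteins, seed=_subseed(config.seed, ds.name),
        **config.synthetic)
    matrix, truth = simulate.generate_dataset(design)
    core_io.write_protein_groups(matrix, outdir / f"{ds.name}_protein_groups.tsv",
                                 outdir / f"{ds.name}_design.tsv")
    simulate.write_truth(truth, outdir / f"{ds.name}_truth.tsv")
    return matrix, truth


def _process_dataset(config: PipelineConfig, ds: DatasetConfig, outdir: Path,
                     manifest: dict):
    entry = {"name": ds.name, "batch_method": ds.batch_method,
             "anova_enabled": ds.anova_enabled}
    matrix, truth = _load_or_simulate(config, ds, outdir)
    entry["n_rows_input"] = matrix.n_proteins

    filtered = core_io.filter_rows(matrix)
    entry["n_dropped_flagged"] = filtered.meta.get("n_dropped_flagged", 0)
    entry["n_dropped_missing"] = filtered.meta.get("n_dropped_missing", 0)
    entry["n_rows_filtered"] = filtered.n_proteins

    norm, factors = normalize.normalize_pipeline(filtered,
                                                 batch_method=ds.batch_method)
    entry["n_dropped_irs"] = norm.meta.get("n_dropped_irs", 0)
    entry["n_rows_normalized"] = norm.n_proteins
    _write(norm.values, outdir / f"{ds.name}_normalized_log2.tsv")

    qc = normalize.qc_report(norm)
    _write(qc.channel_quartiles, outdir / f"{ds.name}_qc_quartiles.tsv")
    _write(qc.pearson, outdir / f"{ds.name}_qc_pearson.tsv")
    _write(qc.pca_scores, outdir / f"{ds.name}_qc_pca.tsv")
    _write(qc.group_mean_cv.to_frame("mean_cv_pct"),
           outdir / f"{ds.name}_qc_cv.tsv")
    entry["group_mean_cv_pct"] = {k: round(float(v), 4)
                                  for k, v in qc.group_mean_cv.items()}

    test_cfg = dataclasses.replace(config.test,
                                   anova_enabled=ds.anova_enabled,
                                   seed=_subseed(config.seed, ds.name + "/test"))
    results, anova_table = stats.run_pairwise_suite(norm, test_cfg)
    if anova_table is not None:
        _write(anova_table, outdir / f"{ds.name}_anova.tsv")
        entry["n_rows_after_anova"] = int(anova_table["keep"].sum())
    for label, res in results.items():
        _write(stats.volcano_table(res), outdir / f"{ds.name}_{label}.tsv")
    _write(stats.summary_counts(results), outdir / f"{ds.name}_summary.tsv")
    entry["comparisons"] = {label: res.counts() for label, res in results.items()}

    manifest["datasets"].append(entry)
    return norm, results, truth


# ---------------------------------------------------------------------------
# cross-dataset stages
# ---------------------------------------------------------------------------

def default_overlap_plan(dataset_names) -> list:
    """Pairings of the overlap analysis across regimens and sexes."""
    plan = []
    regions = sorted({n.split("_", 1)[1] for n in dataset_names
                      if "_" in n})
    for region in regions:
        a, b = f"subchronic_{region}", f"chronic_{region}"
        if a in dataset_names and b in dataset_names:
            for label in ("MC_vs_FC", "FN_vs_FC", "MN_vs_MC"):
                plan.append((f"{region}_{label}_across_regimen",
                             f"{a}:{label}", f"{b}:{label}"))
    for name in dataset_names:
        plan.append((f"{name}_treatment_across_sex",
                     f"{name}:FN_vs_FC", f"{name}:MN_vs_MC"))
    return plan


def run_overlap(all_results: dict, plan=None) -> pd.DataFrame:
    keyed = {f"{ds}:{label}": res
             for ds, results in all_results.items()
             for label, res in results.items()}
    plan = plan if plan is not None else default_overlap_plan(list(all_results))
    return overlap.overlap_matrix(keyed, plan)


# ---------------------------------------------------------------------------
# run_all / run_stage
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "datasets": [],
                "test": dataclasses.asdict(config.test),
                "mcode": dataclasses.asdict(config.mcode),
                "min_score": config.min_score, "outputs": []}

    all_results, truths, norms = {}, {}, {}
    for ds in config.datasets:
        try:
            norm, results, truth = _process_dataset(config, ds, outdir, manifest)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(f"dataset:{ds.name}", str(exc)) from exc
        all_results[ds.name] = results
        truths[ds.name] = truth
        norms[ds.name] = norm

    try:
        overlap_table = run_overlap(all_results)
        _write(overlap_table, outdir / "overlap_summary.tsv", index=False)
    except Exception as exc:
        raise StageError("overlap", str(exc)) from exc

    try:
        _run_enrichment(config, all_results, norms, truths, outdir, manifest)
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc

    try:
        _run_clusters(config, all_results, truths, outdir, manifest)
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc

    manifest["outputs"] = sorted(
        {p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _gene_universe(norm: IntensityMatrix) -> set:
    return {str(g).upper() for g in norm.records["gene_name"] if g}


def _collection_for(config: PipelineConfig, ds_name: str, truth):
    if config.gmt_path is not None:
        return core_io.read_gmt(config.gmt_path)
    if truth is None:
        raise ConfigError("no GMT configured and no simulation truth available")
    return simulate.generate_gene_sets(truth,
                                       seed=_subseed(config.seed, ds_name + "/gmt"))


def _run_enrichment(config, all_results, norms, truths, outdir, manifest):
    rows = []
    for ds_name, results in all_results.items():
        universe = _gene_universe(norms[ds_name])
        collection = _collection_for(config, ds_name, truths[ds_name])
        for label, res in results.items():
            reports = enrichment.enrich_comparison(
                res, universe, collection, k=config.enrichment_top_k,
                q_cutoff=config.enrichment_q_cutoff)
            for direction, (_full, top) in reports.items():
                for _, r in top.iterrows():
                    rows.append({"dataset": ds_name, "comparison": label,
                                 "direction": direction, **r.to_dict()})
    table = pd.DataFrame(rows)
    _write(table, outdir / "enrichment_top.tsv", index=False)
    manifest["n_enriched_rows"] = len(table)


def _run_clusters(config, all_results, truths, outdir, manifest):
    rows = []
    for ds_name, results in all_results.items():
        if config.edges_path is not None:
            edges = core_io.read_edge_table(config.edges_path,
                                            config.edges_score_scale)
        else:
            if truths[ds_name] is None:
                raise ConfigError("no edge table configured and no simulation "
                                  "truth available")
            edges = simulate.generate_ppi_edges(
                truths[ds_name], seed=_subseed(config.seed, ds_name + "/ppi"))
        for label, res in results.items():
            sig_genes = {str(g).upper() for g in res.significant["gene_name"] if g}
            f = edges.frame
            sub = f[f["protein_a"].str.upper().isin(sig_genes)
                    & f["protein_b"].str.upper().isin(sig_genes)]
            from .containers import EdgeTable
            if sub.empty:
                continue
            G = mcode.build_network(EdgeTable(sub.reset_index(drop=True)),
                                    min_score=config.min_score)
            clusters = mcode.mcode_find_clusters(G, config.mcode)
            for c in clusters:
                rows.append({"dataset": ds_name, "comparison": label,
                             "rank": c.rank, "score": c.score,
                             "n_nodes": c.n_nodes, "n_edges": c.n_edges,
                             "members": ";".join(c.members)})
    table = pd.DataFrame(rows)
    _write(table, outdir / "ppi_clusters.tsv", index=False)
    manifest["n_clusters"] = len(table)


def run_stage(config: PipelineConfig, stage: str, **inputs):
    """Run one stage from on-disk inputs; mirrors the matching run_all slice."""
    if stage == "run":
        return run_all(config)
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if stage == "simulate":
        ds = config.datasets[0]
        matrix, truth = _load_or_simulate(config, ds, outdir)
        return {"n_proteins": matrix.n_proteins}

    if stage in ("normalize", "qc", "compare"):
        pg = inputs.get("protein_groups")
        design = inputs.get("design")
        batch_method = inputs.get("batch_method", config.datasets[0].batch_method)
        if pg is None or design is None:
            raise ConfigError(f"stage {stage!r} needs protein_groups and design")
        matrix = core_io.read_protein_groups(pg, design)
        filtered = core_io.filter_rows(matrix)
        norm, _factors = normalize.normalize_pipeline(filtered,
                                                      batch_method=batch_method)
        if stage == "normalize":
            _write(norm.values, outdir / "normalized_log2.tsv")
            return {"n_proteins": norm.n_proteins}
        if stage == "qc":
            qc = normalize.qc_report(norm)
            _write(qc.pearson, outdir / "qc_pearson.tsv")
            _write(qc.group_mean_cv.to_frame("mean_cv_pct"), outdir / "qc_cv.tsv")
            return {"min_pearson": float(np.min(qc.pearson.to_numpy()))}
        test_cfg = dataclasses.replace(config.test,
                                       seed=_subseed(config.seed, "stage/test"))
        results, _anova = stats.run_pairwise_suite(norm, test_cfg)
        for label, res in results.items():
            _write(stats.volcano_table(res), outdir / f"compare_{label}.tsv")
        return {label: res.counts() for label, res in results.items()}

    if stage == "overlap":
        a, b = inputs.get("comparison_a"), inputs.get("comparison_b")
        if a is None or b is None:
            raise ConfigError("stage 'overlap' needs comparison_a and comparison_b")
        lists = {}
        for key, path in (("a", a), ("b", b)):
            t = pd.read_csv(path, sep="\t", index_col=0)
            sig = t[t["significant"]]
            idents = np.where(sig["gene_name"].fillna("") != "",
                              sig["gene_name"].fillna(""), sig.index)
            lists[key] = list(dict(zip([str(i).upper() for i in idents],
                                       sig["direction"])).items())
        s = overlap.overlap_summary(lists["a"], lists["b"], label="overlap")
        _write(pd.DataFrame([s.to_row()]), outdir / "overlap_summary.tsv",
               index=False)
        return s.to_row()

    if stage == "enrich":
        comparison, gmt = inputs.get("comparison"), inputs.get("gmt",
                                                               config.gmt_path)
        if comparison is None or gmt is None:
            raise ConfigError("stage 'enrich' needs comparison and gmt")
        t = pd.read_csv(comparison, sep="\t", index_col=0)
        collection = core_io.read_gmt(gmt)
        universe = {str(g).upper() for g in t["gene_name"].dropna() if g}
        sig = t[t["significant"]]
        rows = []
        for direction in ("up", "down"):
            genes = {str(g).upper() for g in
                     sig.loc[sig["direction"] == direction, "gene_name"].dropna()
                     if g}
            if not genes:
                continue
            table = enrichment.enrich(genes, universe, collection)
            top = enrichment.top_k_report(table, k=config.enrichment_top_k,
                                          q_cutoff=config.enrichment_q_cutoff)
            top.insert(0, "direction", direction)
            rows.append(top)
        table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        _write(table, outdir / "enrichment_top.tsv", index=False)
        return {"n_rows": len(table)}

    if stage == "cluster":
        comparison = inputs.get("comparison")
        edges_path = inputs.get("edges", config.edges_path)
        if comparison is None or edges_path is None:
            raise ConfigError("stage 'cluster' needs comparison and edges")
        t = pd.read_csv(comparison, sep="\t", index_col=0)
        sig = t[t["significant"]]
        sig_genes = {str(g).upper() for g in sig["gene_name"].dropna() if g}
        edges = core_io.read_edge_table(edges_path, config.edges_score_scale)
        f = edges.frame
        sub = f[f["protein_a"].str.upper().isin(sig_genes)
                & f["protein_b"].str.upper().isin(sig_genes)]
        from .containers import EdgeTable
        clusters = []
        if not sub.empty:
            G = mcode.build_network(EdgeTable(sub.reset_index(drop=True)),
                                    min_score=config.min_score)
            clusters = mcode.mcode_find_clusters(G, config.mcode)
        _write(mcode.clusters_frame(clusters), outdir / "ppi_clusters.tsv",
               index=False)
        return {"n_clusters": len(clusters)}

    raise ConfigError(f"unhandled stage {stage!r}")
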