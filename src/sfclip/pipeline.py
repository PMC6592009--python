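"""End-to-end orchestration: from inputs to a ranked splicing-factor list.

Stage order: splicing regions -> ExS matrix -> (optional) similarity
network -> path expression -> event expression filter -> PSI ->
differential-splicing test (built-in or imported) -> event selection ->
CLIP enrichment -> gene filter + differential expression -> ranking.
Every stage logs its counts into a run report mirroring the analysis
funnel (events loaded / quantified / passing filter / selected; RBPs
tested / passing).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clip, enrichment, events as ev_mod, exs as exs_mod
from . import similarity as sim_mod, splicing
from .simulate import SimulatedDataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline inputs and parameters; every method constant is a default.

    Exactly one of ``top_n`` / ``p_threshold`` chooses the event-selection
    mode. Paths may be None when running on an in-memory bundle.
    """

    event_table: str | None = None
    peak_metadata: str | None = None
    tx_expr: str | None = None
    gene_expr: str | None = None
    design: str | None = None
    event_stats: str | None = None  # imported differential-splicing p-values
    output_dir: str | None = None

    window_nt: int = 400
    strand_policy: str = "ignore"
    top_n: int | None = 1000
    p_threshold: float | None = None
    q_event: float = 0.1
    sample_frac: float = 0.75
    q_gene: float = 0.25
    p_clip_max: float = 0.05
    p_expr_max: float = 0.05
    lfc_min: float = 0.58
    r_min: float = 0.46
    q_max: float = 0.1
    combine: str = "none"
    run_similarity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.top_n is None) == (self.p_threshold is None):
            raise ValueError("set exactly one of top_n / p_threshold")
        for name, lo, hi in (
            ("q_event", 0, 1), ("sample_frac", 0, 1), ("q_gene", 0, 1),
            ("p_clip_max", 0, 1), ("p_expr_max", 0, 1), ("q_max", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    exs: exs_mod.ExSMatrix
    network: sim_mod.SimilarityNetwork | None
    path_expression: splicing.PathExpression
    psi: pd.DataFrame
    kept_events: set[str]
    event_stats: pd.DataFrame
    selected_events: set[str]
    enrichment: pd.DataFrame
    de: pd.DataFrame | None
    ranking: pd.DataFrame
    candidates: pd.DataFrame
    report: dict[str, int]


def _stage(report: dict, name: str, value: int) -> None:
    report[name] = int(value)
    logger.info("stage %-28s %d", name, value)


def run_stages(
    event_list: list[ev_mod.SplicingEvent],
    peaks: list[clip.ClipPeak],
    tx_expr: pd.DataFrame,
    design: pd.Series,
    cfg: RunConfig,
    gene_expr: pd.DataFrame | None = None,
    imported_stats: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full method on in-memory inputs."""
    report: dict[str, int] = {}
    _stage(report, "events_loaded", len(event_list))

    regions = [
        ev_mod.derive_splicing_region(ev, cfg.window_nt) for ev in event_list
    ]
    peak_sets = clip.consolidate_rbp_peaks(peaks)
    _stage(report, "rbps_loaded", len(peak_sets))
    exs = exs_mod.build_exs(regions, peak_sets, strand_policy=cfg.strand_policy)

    network = None
    if cfg.run_similarity:
        edges = sim_mod.pairwise_rbp_similarity(exs)
        network = sim_mod.build_similarity_network(
            edges, r_min=cfg.r_min, q_max=cfg.q_max
        )
        _stage(report, "similarity_edges", len(network.edges))

    pe = splicing.compute_path_expression(tx_expr, event_list)
    _stage(report, "events_quantified", len(pe.event_ids))
    kept = splicing.filter_events_by_expression(
        pe, q=cfg.q_event, sample_frac=cfg.sample_frac
    )
    _stage(report, "events_pass_expression_filter", len(kept))

    psi = splicing.compute_psi(pe)
    builtin = splicing.differential_splicing_test(psi, pe, design)
    if imported_stats is not None:
        stats_df = splicing.merge_event_stats(imported_stats, builtin)
    else:
        stats_df = builtin
    stats_kept = stats_df[stats_df["event_id"].isin(kept)].reset_index(drop=True)

    if cfg.top_n is not None:
        selected = splicing.select_top_events(stats_kept, cfg.top_n)
    else:
        selected = splicing.select_events_by_p(stats_kept, cfg.p_threshold)
    _stage(report, "events_selected", len(selected))

    tested = sorted(set(stats_kept["event_id"]))
    enr = enrichment.clip_enrichment(exs, sorted(selected), tested)
    _stage(report, "rbps_tested", len(enr))

    de = None
    if gene_expr is not None:
        kept_genes = splicing.filter_genes_by_expression(gene_expr, q=cfg.q_gene)
        _stage(report, "genes_pass_expression_filter", len(kept_genes))
        de = enrichment.differential_expression_test(
            gene_expr.loc[sorted(kept_genes)], design
        )

    ranking = enrichment.rank_splicing_factors(
        enr,
        de,
        p_clip_max=cfg.p_clip_max,
        p_expr_max=cfg.p_expr_max,
        lfc_min=cfg.lfc_min,
        combine=cfg.combine,
    )
    candidates = enrichment.candidate_list(ranking)
    _stage(report, "rbps_passing_filters", len(candidates))

    return PipelineResult(
        exs=exs,
        network=network,
        path_expression=pe,
        psi=psi,
        kept_events=kept,
        event_stats=stats_kept,
        selected_events=selected,
        enrichment=enr,
        de=de,
        ranking=ranking,
        candidates=candidates,
        report=report,
    )


def run_on_bundle(bundle: SimulatedDataset, cfg: RunConfig) -> PipelineResult:
    """Run the pipeline directly on a simulated bundle."""
    return run_stages(
        bundle.events,
        bundle.peaks,
        bundle.tx_expr,
        bundle.design,
        cfg,
        gene_expr=bundle.gene_expr,
    )


def _load_design(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: design needs columns sample, group")
    bad = set(df["group"]) - {"reference", "condition"}
    if bad:
        raise ValueError(f"{path}: groups must be reference/condition, got {bad}")
    return pd.Series(df["group"].to_numpy(), index=df["sample"], name="group")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Load inputs from the paths in ``cfg``, run, and write outputs.

    Any stage failure aborts with the stage name in the exception context.
    """
    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if cfg.event_table is None or cfg.peak_metadata is None:
        raise ValueError("event_table and peak_metadata paths are required")
    if cfg.tx_expr is None or cfg.design is None:
        raise ValueError("tx_expr and design paths are required")

    event_list = stage("load_events", ev_mod.load_event_table, cfg.event_table)
    peaks = stage("load_peaks", clip.load_peak_collection, cfg.peak_metadata)
    tx_expr = stage(
        "load_tx_expr", pd.read_csv, cfg.tx_expr, sep="\t", index_col=0
    )
    design = stage("load_design", _load_design, cfg.design)
    gene_expr = (
        stage("load_gene_expr", pd.read_csv, cfg.gene_expr, sep="\t", index_col=0)
        if cfg.gene_expr
        else None
    )
    imported = (
        stage(
            "load_event_stats",
            splicing.import_event_stats,
            cfg.event_stats,
            [ev.event_id for ev in event_list],
        )
        if cfg.event_stats
        else None
    )

    result = run_stages(
        event_list, peaks, tx_expr, design, cfg,
        gene_expr=gene_expr, imported_stats=imported,
    )

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        exs_mod.write_exs(result.exs, out / "exs")
        if result.network is not None:
            sim_mod.write_network(result.network, out / "similarity")
        splicing.write_event_stats(result.event_stats, out / "event_stats.tsv")
        result.psi.to_csv(out / "psi.tsv", sep="\t")
        result.ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
        result.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(result.report, indent=1, sort_keys=True)
        )
    return result
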