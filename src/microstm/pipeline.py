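"""Orchestration of the full workflow from a single declarative config.

Stages run in order prep -> fit -> effects -> functions -> pathway model ->
(optional) timeseries.  Every output file is listed in a manifest with its
SHA-256 content hash, so reruns with an identical configuration and seed
can be verified bit-for-bit.  All stage randomness derives from the global
seed via stage-name-keyed sub-seeds: adding a stage never perturbs the
random streams of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_prep, stm_core, topic_effects, topic_functions, pathway_model, timeseries

logger = logging.getLogger("microstm")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Flat configuration for the full pipeline (mirrors CLI flags)."""

    # inputs
    otu_table: str = ""
    table_format: str = "tsv"            # or "biom-json"
    otus_in_rows: bool = True
    taxonomy: str | None = None
    metadata: str | None = None
    copy_numbers: str | None = None
    gene_content: str | None = None
    hierarchy: str | None = None
    # prep
    min_sample_reads: float = 1000
    min_otu_total: float = 10
    min_prevalence: float = 0.0
    require_phylum: bool = True
    # model
    covariates: list = field(default_factory=list)   # [[column, transform(, arg)], ...]
    k: int = 3
    max_em_iter: int = 500
    rel_tol: float = 1e-5
    init: str = "spectral"
    # effects
    effect_covariate: str | None = None
    effect_draws: int = 200
    effect_level: float = 0.95
    group_R: int = 100
    group_I: int = 20
    group_threshold: float = 0.99
    # functions / pathway model
    constant: int = 10000
    pathway_level: int = 3
    allowed_level2: list | None = None
    chains: int = 2
    warmup: int = 400
    samples: int = 400
    interaction_level: float = 0.80
    # timeseries (optional)
    day_column: str | None = None
    corr_cutoff: float = 0.05
    corr_draws: int = 200
    timeline_draws: int = 200
    min_dominance: float = 0.5
    # run
    outdir: str = "microstm_out"
    seed: int = 0

    def validate(self) -> None:
        for name in ("otu_table", "taxonomy", "metadata", "copy_numbers",
                     "gene_content", "hierarchy"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file: {p}")
        if not self.otu_table:
            raise ValueError("config.otu_table is required")


def load_config(path) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)


def _stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _covariate_spec(cfg: PipelineConfig):
    spec = []
    for entry in cfg.covariates:
        if len(entry) == 2:
            spec.append((entry[0], entry[1]))
        else:
            spec.append((entry[0], (entry[1], int(entry[2]))))
    return spec


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict.

    Any stage failure aborts with the stage name and cause; outputs written
    so far are kept and a ``failed/MARKER`` file names the failing stage.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "prep"

    def _emit(name: str, path: Path):
        artifacts[name] = _sha256(path)

    try:
        # ---- prep -------------------------------------------------------
        t = io_prep.read_otu_table(cfg.otu_table, format=cfg.table_format,
                                   taxonomy_path=cfg.taxonomy,
                                   metadata_path=cfg.metadata,
                                   otus_in_rows=cfg.otus_in_rows)
        if cfg.copy_numbers:
            t = io_prep.copy_number_normalize(t, io_prep.read_copy_numbers(cfg.copy_numbers))
        t, report = io_prep.filter_table(
            t, min_sample_reads=cfg.min_sample_reads, min_otu_total=cfg.min_otu_total,
            min_otu_prevalence_frac=cfg.min_prevalence, require_phylum=cfg.require_phylum)
        ftab = out / "filtered_table.tsv"
        io_prep.write_otu_table(t, ftab)
        _emit("filtered_table", ftab)
        frep = out / "filter_report.tsv"
        with open(frep, "w") as fh:
            fh.write("reason\tid\n")
            for reason, ids in sorted(report.items()):
                for i in ids:
                    fh.write(f"{reason}\t{i}\n")
        _emit("filter_report", frep)

        X = None
        if cfg.covariates:
            X = io_prep.build_design_matrix(t.metadata, _covariate_spec(cfg))

        # ---- fit --------------------------------------------------------
        stage = "fit"
        stm_cfg = stm_core.StmConfig(K=cfg.k, max_em_iter=cfg.max_em_iter,
                                     rel_tol=cfg.rel_tol, init=cfg.init,
                                     seed=_stage_seed(cfg.seed, "fit"))
        fit = stm_core.fit_stm(t, X, stm_cfg)
        farch = out / "stm_fit.json"
        stm_core.save_fit(fit, farch)
        _emit("stm_fit", farch)
        disp = stm_core.residual_dispersion(fit, t)

        # ---- effects ----------------------------------------------------
        stage = "effects"
        groups = {k: "none" for k in range(fit.K)}
        if cfg.effect_covariate and X is not None:
            seed_e = _stage_seed(cfg.seed, "effects")
            effects = topic_effects.estimate_topic_effects(
                fit, X, cfg.effect_covariate, n_draws=cfg.effect_draws,
                level=cfg.effect_level, seed=seed_e)
            groups = topic_effects.high_ranking_topics(effects)
            eff_tab = out / "topic_effects.tsv"
            pd.DataFrame(
                [(e.topic, e.point, e.lower, e.upper, groups[e.topic]) for e in effects],
                columns=["topic", "estimate", "lower", "upper", "group"],
            ).to_csv(eff_tab, sep="\t", index=False, float_format="%.8g")
            _emit("topic_effects", eff_tab)
            gf = topic_effects.posterior_group_frequencies(
                fit, groups, R=cfg.group_R, I=cfg.group_I,
                library_sizes=t.library_sizes(), seed=seed_e + 1)
            gtab = out / "group_frequencies.tsv"
            gf.frame().to_csv(gtab, sep="\t", float_format="%.8g",
                              index_label="otu_id")
            _emit("group_frequencies", gtab)
            group_otus = topic_effects.select_group_otus(gf, cfg.group_threshold)
            series = topic_effects.group_abundance_series(t, group_otus)
            stab = out / "group_abundance.tsv"
            pd.DataFrame(series, index=t.sample_ids).to_csv(
                stab, sep="\t", float_format="%.8g", index_label="sample_id")
            _emit("group_abundance", stab)

        # ---- functions + pathway model -----------------------------------
        y = None
        if cfg.gene_content:
            stage = "functions"
            gc = topic_functions.read_gene_content(cfg.gene_content,
                                                   hierarchy_path=cfg.hierarchy)
            pseudo = topic_functions.topics_to_pseudocounts(fit.beta, cfg.constant)
            genes = topic_functions.predict_functions(pseudo, gc, fit.vocabulary)
            allowed = set(cfg.allowed_level2) if cfg.allowed_level2 else None
            y, labels, parents = topic_functions.collapse_pathways(
                genes, gc, level=cfg.pathway_level, allowed_level2=allowed)
            ytab = out / "topic_pathway_counts.tsv"
            pd.DataFrame(y, columns=labels,
                         index=[f"T{k + 1}" for k in range(fit.K)]).to_csv(
                ytab, sep="\t", index_label="topic")
            _emit("topic_pathway_counts", ytab)

            stage = "pathway_model"
            spec = pathway_model.PathwayModelSpec(
                chains=cfg.chains, warmup=cfg.warmup, samples=cfg.samples,
                seed=_stage_seed(cfg.seed, "pathway_model"))
            post = pathway_model.fit_pathway_model(y, spec)
            ptab = out / "pathway_posterior.tsv"
            df = post.summary_frame(cfg.interaction_level)
            df["pathway"] = [labels[i % len(labels)] for i in range(len(df))]
            df.to_csv(ptab, sep="\t", index=False, float_format="%.8g")
            _emit("pathway_posterior", ptab)
            sig = pathway_model.significant_interactions(post, cfg.interaction_level)
            stabf = out / "significant_interactions.tsv"
            with open(stabf, "w") as fh:
                fh.write("topic\tpathway\tsign\n")
                for k, c, s in sorted(sig):
                    fh.write(f"T{k + 1}\t{labels[c]}\t{'+' if s > 0 else '-'}\n")
            _emit("significant_interactions", stabf)

        # ---- timeseries ---------------------------------------------------
        if cfg.day_column:
            stage = "timeseries"
            seed_t = _stage_seed(cfg.seed, "timeseries")
            graph = timeseries.topic_correlation_graph(
                fit, cutoff=cfg.corr_cutoff, n_draws=cfg.corr_draws, seed=seed_t)
            etab = out / "topic_graph_edges.tsv"
            with open(etab, "w") as fh:
                fh.write("topic_a\ttopic_b\tcorrelation\n")
                for u, v, w in sorted(graph.edge_list()):
                    fh.write(f"T{u + 1}\tT{v + 1}\t{w:.8g}\n")
            _emit("topic_graph_edges", etab)
            import networkx as nx
            gml = out / "topic_graph.graphml"
            nx.write_graphml(graph.graph, gml)
            _emit("topic_graph", gml)
            day = pd.to_numeric(t.metadata[cfg.day_column]).to_numpy(dtype=float)
            tl = timeseries.cluster_day_frequencies(
                fit, graph, day, n_draws=cfg.timeline_draws, seed=seed_t + 1)
            ttab = out / "cluster_timeline.tsv"
            rows = []
            for i, d in enumerate(tl.days):
                for j, lab in enumerate(tl.labels):
                    rows.append((d, lab, tl.mean[i, j], tl.lower[i, j], tl.upper[i, j]))
            pd.DataFrame(rows, columns=["day", "cluster", "mean", "lower", "upper"]).to_csv(
                ttab, sep="\t", index=False, float_format="%.8g")
            _emit("cluster_timeline", ttab)
            ev = timeseries.detect_events(tl, min_dominance=cfg.min_dominance)
            evtab = out / "events.tsv"
            with open(evtab, "w") as fh:
                fh.write("change_day\n")
                for d in ev:
                    fh.write(f"{d:g}\n")
            _emit("events", evtab)
    except Exception as e:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "MARKER").write_text(f"stage: {stage}\nerror: {e}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "dispersion_statistic": round(float(disp), 10),
        "converged": bool(fit.converged),
        "artifacts": dict(sorted(artifacts.items())),
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
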