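"""End-to-end orchestration: filter -> normalize -> log10 -> test -> select
-> multivariate -> genomic cluster summaries, with a JSON run report.

Configuration is a flat key-value mapping (YAML on disk). Logs go to
standard error, one line per stage with its parameters; results only to
files, so runs compose in shell pipelines. Identical config + seed produces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from mirdeq import counts_io, diffexp, multivariate, normalization
from mirdeq.genomic_clusters import group_loci, summarize_cluster_deregulation

logger = logging.getLogger("mirdeq")


@dataclass
class RunConfig:
    counts: str
    samples: str
    out_dir: str
    gff: str | None = None
    min_mean: float = 5.0
    pseudocount: float = 1.0
    method: str = "quantile"  # "quantile" | "scale"
    alpha: float = 0.05
    family_size: int | None = None  # None = number of miRNAs tested
    fc_min: float = 2.0
    diff_min: float = 100.0
    max_gap: int = 10_000
    min_significant: int = 2
    metric: str = "pearson"
    n_components: int = 2
    welch: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("family_size") in ("auto", ""):
            raw["family_size"] = None
        return cls(**raw)


@dataclass
class PipelineResult:
    normalized: normalization.NormalizedMatrix
    logged: normalization.NormalizedMatrix
    records: list
    signature: list
    clustering_set: list
    pca: multivariate.PCAResult | None
    dendrogram: multivariate.Dendrogram | None
    cluster_summaries: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that broke."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # re-raise with stage context
        raise StageError(name, exc) from exc


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in asdict(config).items()}}

    cm = _stage("read_counts", counts_io.read_count_matrix, config.counts)
    samples = _stage("read_samples", counts_io.read_sample_table, config.samples)
    logger.info("read_counts: %d miRNAs x %d samples", cm.n_mirnas, cm.n_samples)
    report["n_input_mirnas"] = cm.n_mirnas
    report["n_samples"] = cm.n_samples
    report["group_sizes"] = samples.group_sizes()

    filtered = _stage(
        "filter", normalization.filter_low_expression, cm, config.min_mean
    )
    logger.info(
        "filter: min_mean=%s retained %d/%d miRNAs",
        config.min_mean, filtered.n_mirnas, cm.n_mirnas,
    )
    report["n_retained_mirnas"] = filtered.n_mirnas

    linear = _stage(
        "normalize", normalization.normalize_counts, filtered, config.method
    )
    logger.info("normalize: method=%s", config.method)
    logged = _stage(
        "log10", normalization.log10_transform, linear, config.pseudocount
    )
    logger.info("log10: pseudocount=%s", config.pseudocount)
    linear.to_frame().to_csv(out / "normalized.tsv", sep="\t",
                             index_label="mirna_id", float_format="%.12g")

    records = _stage(
        "diffexp",
        diffexp.make_de_records,
        linear, logged, samples,
        family_size=config.family_size,
        welch=config.welch,
    )
    m = config.family_size if config.family_size else len(records)
    logger.info("diffexp: tested %d miRNAs, family_size=%d", len(records), m)
    report["n_tested"] = len(records)
    report["family_size"] = m
    counts_io.write_results_table(records, out / "de.tsv")

    signature = _stage(
        "signature", diffexp.select_signature, records, config.alpha
    )
    logger.info("signature: alpha=%s selected %d", config.alpha, len(signature))
    report["n_signature"] = len(signature)
    counts_io.write_results_table(signature, out / "signature.tsv")

    clustering_set = _stage(
        "clustering_set",
        diffexp.select_clustering_set,
        records, config.fc_min, config.diff_min,
    )
    logger.info(
        "clustering_set: fc_min=%s diff_min=%s selected %d",
        config.fc_min, config.diff_min, len(clustering_set),
    )
    report["n_clustering_set"] = len(clustering_set)

    pca = None
    dendro = None
    if logged.values.shape[1] >= 2 and logged.values.shape[0] >= 1:
        n_comp = min(config.n_components, *logged.values.T.shape)
        pca = _stage("pca", multivariate.pca_scores, logged, n_comp)
        _write_pca(pca, out / "pca_scores.tsv")
        logger.info("pca: %d components", n_comp)
    keep_ids = {r.mirna_id for r in clustering_set}
    if len(keep_ids) >= 2:
        subset = normalization.NormalizedMatrix(
            [i for i in logged.mirna_ids if i in keep_ids],
            list(logged.sample_ids),
            logged.values[[i in keep_ids for i in logged.mirna_ids]],
            "log10",
        )
        dendro = _stage(
            "cluster_samples", multivariate.hierarchical_cluster, subset,
            config.metric,
        )
        (out / "dendrogram.json").write_text(dendro.to_json(), encoding="utf-8")
        report["dendrogram_misclassified"] = multivariate.two_group_purity(
            dendro, samples
        )
        logger.info(
            "cluster_samples: metric=%s misclassified=%d",
            config.metric, report["dendrogram_misclassified"],
        )
    else:
        logger.info("cluster_samples: skipped (<2 miRNAs in clustering set)")

    summaries = []
    if config.gff:
        loci = _stage("read_gff", counts_io.read_mirna_annotations, config.gff)
        clusters = _stage("group_loci", group_loci, loci, config.max_gap)
        summaries = _stage(
            "cluster_summary",
            summarize_cluster_deregulation,
            clusters, records, config.alpha, config.min_significant,
        )
        logger.info(
            "cluster_summary: %d loci -> %d clusters, %d reported",
            len(loci), len(clusters), len(summaries),
        )
        report["n_genomic_clusters"] = len(clusters)
        report["n_reported_clusters"] = len(summaries)
        _write_cluster_table(summaries, out / "clusters.tsv")

    report_path = out / "report.json"
    report_path.write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("report: %s", report_path)
    return PipelineResult(
        normalized=linear,
        logged=logged,
        records=records,
        signature=signature,
        clustering_set=clustering_set,
        pca=pca,
        dendrogram=dendro,
        cluster_summaries=summaries,
        report=report,
    )


def _write_pca(pca: multivariate.PCAResult, path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        pca.scores,
        index=pca.sample_ids,
        columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
    )
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def _write_cluster_table(summaries, path: Path) -> None:
    import pandas as pd

    rows = []
    for s in summaries:
        folds = [
            "N/A" if f is None else f"{f:.1f}" for f in s.significant_folds
        ]
        rows.append(
            {
                "cluster_id": s.cluster.cluster_id,
                "chrom": s.cluster.chrom,
                "strand": s.cluster.strand,
                "span_start": s.cluster.span[0],
                "span_end": s.cluster.span[1],
                "n_members": s.cluster.n_members,
                "n_significant": s.n_significant,
                "direction": s.consensus_direction,
                "member_ids": ",".join(s.cluster.member_ids),
                "significant_folds": ",".join(folds),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "strand", "span_start", "span_end",
            "n_members", "n_significant", "direction", "member_ids",
            "significant_folds",
        ],
    ).to_csv(path, sep="\t", index=False)
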