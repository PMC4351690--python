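"""Synthetic input generators with planted, recoverable structure.

Every on-disk format the pipeline consumes can be generated here with known
ground truth: negative-binomial count matrices with planted two-group fold
changes and heterogeneous sequencing depths, miRBase-dialect GFF3 annotation
with planted polycistronic clusters, replicate CT tables with planted qPCR
folds, and UTR FASTA files with planted seed sites. All generators are
deterministic given (config, seed).

The count model is NB with variance ``mean + dispersion * mean**2``
(``dispersion=0`` falls back to Poisson). Per-sample expected totals are
drawn uniformly from the configured depth range to stress normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mirdeq.counts_io import CountMatrix, SampleTable
from mirdeq.rtpcr import CTMeasurement
from mirdeq.seed_targets import SITE_CLASSES, reverse_complement, scan_seed_sites

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_counts",
    "simulate_annotations",
    "simulate_ct",
    "simulate_utrs",
]


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults emulate a 24-vs-14 deep-sequencing
    design with ~700 expressed miRNAs and per-sample totals of 0.4M-7.9M."""

    # count matrix
    n_tumor: int = 24
    n_normal: int = 14
    n_mirna: int = 707
    n_low: int = 50
    depth_min: float = 393_305.0
    depth_max: float = 7_906_634.0
    de_fraction: float = 0.0
    lfc: float = 2.0          # |log2 fold| planted on DE features
    frac_up: float = 0.6
    nb_dispersion: float = 0.2
    base_mean_min: float = 30.0
    base_mean_max: float = 30_000.0
    de_base_mean_min: float = 200.0  # eligibility floor for planted DE
    # annotation geometry
    n_clusters: int = 7
    cluster_size: int = 3
    n_singletons: int = 10
    intra_cluster_gap: int = 1_000
    inter_cluster_gap: int = 50_000
    hairpin_length: int = 80
    # qPCR
    ct_fold: float = 4.0
    ct_noise: float = 0.1
    ct_n_tumor: int = 19
    ct_n_normal: int = 4
    ct_replicates: int = 3
    ct_baseline_dct: float = 5.0
    # UTRs
    utr_length: int = 200
    mirna_seq: str = "ACTCTTTCCCTGTTGCACTAC"

    def validate(self) -> None:
        positive = [
            ("n_tumor", self.n_tumor), ("n_normal", self.n_normal),
            ("n_mirna", self.n_mirna), ("depth_min", self.depth_min),
            ("depth_max", self.depth_max), ("n_clusters", self.n_clusters),
            ("cluster_size", self.cluster_size),
            ("intra_cluster_gap", self.intra_cluster_gap),
            ("inter_cluster_gap", self.inter_cluster_gap),
            ("ct_replicates", self.ct_replicates),
            ("utr_length", self.utr_length),
        ]
        for name, value in positive:
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")
        if self.n_low < 0 or self.nb_dispersion < 0 or self.ct_noise < 0:
            raise ValueError("n_low, nb_dispersion and ct_noise must be >= 0")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must be <= depth_max")
        if not np.isfinite(self.lfc):
            raise ValueError("lfc must be finite")
        if self.intra_cluster_gap >= self.inter_cluster_gap:
            raise ValueError(
                "intra_cluster_gap must be smaller than inter_cluster_gap"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulationTruth:
    """Planted ground truth; ids are subsets of the generated identifiers."""

    de: dict[str, tuple[str, float]] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)
    ct_folds: dict[tuple[str, str], float] = field(default_factory=dict)
    seed_sites: dict[str, tuple[int, int, str]] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion == 0.0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    config: SimulationConfig, seed: int
) -> tuple[CountMatrix, SampleTable, SimulationTruth]:
    """Two-group NB count matrix with planted fold changes.

    Expressed features draw log-uniform baseline means; ``n_low`` extra
    features sit far below the mean-5 filter so the retained set has a known
    size. ``round(de_fraction * n_mirna)`` features (among those with
    baseline >= ``de_base_mean_min``) get their tumor mean multiplied or
    divided by ``2**lfc``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_expr, n_low = config.n_mirna, config.n_low
    n_feat = n_expr + n_low

    log_lo, log_hi = np.log10(config.base_mean_min), np.log10(config.base_mean_max)
    base = 10 ** rng.uniform(log_lo, log_hi, size=n_expr)
    # low features: expected count stays < 2 even at the deepest sample, so
    # their realized mean across samples sits far below the mean-5 filter
    rel_total = base.sum()
    low_cap = 2.0 * rel_total / config.depth_max
    low = rng.uniform(0.1, 0.9, size=n_low) * low_cap

    mirna_ids = [f"sim-miR-{i + 1:04d}" for i in range(n_expr)] + [
        f"sim-low-{i + 1:03d}" for i in range(n_low)
    ]
    mu = np.concatenate([base, low])

    truth = SimulationTruth()
    n_de = int(round(config.de_fraction * n_expr))
    tumor_mu = mu.copy()
    if n_de:
        eligible = np.flatnonzero(base >= config.de_base_mean_min)
        if len(eligible) < n_de:
            raise ValueError("not enough high-expression features to plant DE")
        chosen = rng.choice(eligible, size=n_de, replace=False)
        n_up = int(np.ceil(config.frac_up * n_de))
        factor = 2.0**config.lfc
        for rank, idx in enumerate(chosen):
            if rank < n_up:
                tumor_mu[idx] = mu[idx] * factor
                truth.de[mirna_ids[idx]] = ("up", factor)
            else:
                tumor_mu[idx] = mu[idx] / factor
                truth.de[mirna_ids[idx]] = ("down", factor)

    sample_ids = [f"T{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(config.n_normal)
    ]
    groups = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    depths = rng.uniform(config.depth_min, config.depth_max, size=len(sample_ids))

    counts = np.zeros((n_feat, len(sample_ids)), dtype=np.int64)
    for j, group in enumerate(groups):
        group_mu = tumor_mu if group == "tumor" else mu
        col_mean = group_mu * (depths[j] / group_mu.sum())
        counts[:, j] = _nb_draw(rng, col_mean, config.nb_dispersion)

    cm = CountMatrix(mirna_ids, sample_ids, counts)
    stages = (["early"] * 7 + ["advanced"] * 17)[: config.n_tumor]
    stages += [""] * max(config.n_tumor - 24, 0)
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "stage": stages[: config.n_tumor] + [""] * config.n_normal,
            }
        )
    )
    return cm, table, truth


def simulate_annotations(
    config: SimulationConfig, seed: int
) -> tuple[str, SimulationTruth]:
    """miRBase-dialect GFF3 text with planted polycistronic clusters.

    ``n_clusters`` clusters of ``cluster_size`` precursors (consecutive gaps
    < ``intra_cluster_gap``) separated by > ``inter_cluster_gap``, plus
    ``n_singletons`` isolated precursors. Every precursor emits a -5p and a
    -3p mature record. Coordinates are written 1-based inclusive.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    truth = SimulationTruth()
    chrom = "chrS"
    pos = 10_000
    hp = config.hairpin_length

    def emit(precursor: str, start0: int) -> list[str]:
        end0 = start0 + hp
        pid = f"MI-{precursor}"
        rows = [
            f"{chrom}\t.\tmiRNA_primary_transcript\t{start0 + 1}\t{end0}\t.\t+\t."
            f"\tID={pid};Name={precursor}"
        ]
        arms = []
        for arm, (a0, a1) in (
            ("5p", (start0, start0 + 22)),
            ("3p", (end0 - 22, end0)),
        ):
            name = f"{precursor}-{arm}"
            rows.append(
                f"{chrom}\t.\tmiRNA\t{a0 + 1}\t{a1}\t.\t+\t."
                f"\tID=MIMAT-{name};Name={name};Derives_from={pid}"
            )
            arms.append(name)
        emit.last_arms = arms  # type: ignore[attr-defined]
        return rows

    for c in range(config.n_clusters):
        members: list[str] = []
        for k in range(config.cluster_size):
            precursor = f"sim-mir-c{c + 1}-{k + 1}"
            lines.extend(emit(precursor, pos))
            members.extend(emit.last_arms)  # type: ignore[attr-defined]
            gap = int(rng.integers(1, config.intra_cluster_gap))
            pos += hp + gap
        truth.clusters[f"cluster-{c + 1}"] = members
        pos += config.inter_cluster_gap + int(rng.integers(1, 10_000))
    for s in range(config.n_singletons):
        precursor = f"sim-mir-s{s + 1}"
        lines.extend(emit(precursor, pos))
        pos += hp + config.inter_cluster_gap + int(rng.integers(1, 10_000))
    return "\n".join(lines) + "\n", truth


def simulate_ct(
    config: SimulationConfig, seed: int, target_assay: str = "sim-miR-t",
    control_assay: str = "U6"
) -> tuple[pd.DataFrame, str, SimulationTruth]:
    """Replicate CT table with a planted tumor fold change.

    Control CT ~ Normal(20, 0.1^2); per replicate the target CT is the
    control replicate plus a baseline dCT, minus log2 of the planted fold,
    plus Normal(0, ct_noise^2). Tumor samples carry ``ct_fold``; normal
    samples fold 1. Returns (table, calibrator sample id, truth); the
    calibrator is the first normal sample.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    rows = []
    sample_folds = [(f"CT-T{i + 1:02d}", config.ct_fold) for i in range(config.ct_n_tumor)]
    sample_folds += [(f"CT-N{i + 1:02d}", 1.0) for i in range(config.ct_n_normal)]
    calibrator = f"CT-N01"
    for sample, fold in sample_folds:
        control_cts = rng.normal(20.0, 0.1, size=config.ct_replicates)
        noise = (
            rng.normal(0.0, config.ct_noise, size=config.ct_replicates)
            if config.ct_noise > 0
            else np.zeros(config.ct_replicates)
        )
        target_cts = (
            control_cts + config.ct_baseline_dct - np.log2(fold) + noise
        )
        for ct in control_cts:
            rows.append({"sample_id": sample, "assay_id": control_assay, "ct": ct})
        for ct in target_cts:
            rows.append({"sample_id": sample, "assay_id": target_assay, "ct": ct})
        truth.ct_folds[(sample, target_assay)] = fold
    return pd.DataFrame(rows), calibrator, truth


def _random_background(
    rng: np.random.Generator, length: int, forbidden: list[str]
) -> str:
    """Random DNA avoiding every forbidden substring."""
    for _ in range(500):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError("could not generate a clean background sequence")


def simulate_utrs(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, str], SimulationTruth]:
    """UTR sequences with one planted site per canonical class plus one
    site-free control UTR; backgrounds are screened against chance matches.

    Returns (utr_id -> sequence, truth) where truth maps each UTR id to the
    planted (start, end, class); the control UTR maps to ``None`` entries
    being absent.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    m = config.mirna_seq.upper().replace("U", "T")
    if len(m) < 8:
        raise ValueError("mirna_seq must be >= 8 nt")
    core6 = reverse_complement(m[1:7])
    core7 = reverse_complement(m[1:8])
    m8_comp = reverse_complement(m[7])
    non_a = "C"
    not_m8 = "G" if m8_comp != "G" else "C"
    planted_seq = {
        "6mer": not_m8 + core6 + non_a,
        "7mer-A1": not_m8 + core6 + "A",
        "7mer-m8": core7 + non_a,
        "8mer": core7 + "A",
    }
    truth = SimulationTruth()
    utrs: dict[str, str] = {}
    for cls in SITE_CLASSES:
        insert = planted_seq[cls]
        for _ in range(200):
            pos = int(rng.integers(10, config.utr_length - len(insert) - 10))
            left = _random_background(rng, pos, [core6])
            right = _random_background(
                rng, config.utr_length - pos - len(insert), [core6]
            )
            seq = left + insert + right
            sites = scan_seed_sites(seq, m)
            if len(sites) == 1 and sites[0].site_class == cls:
                utr_id = f"utr-{cls}"
                utrs[utr_id] = seq
                truth.seed_sites[utr_id] = (sites[0].start, sites[0].end, cls)
                break
        else:
            raise RuntimeError(f"failed to plant a clean {cls} site")
    utrs["utr-empty"] = _random_background(rng, config.utr_length, [core6])
    return utrs, truth
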