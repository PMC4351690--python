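import numpy as np
import pandas as pd
import pytest

from mirdeq.counts_io import CountMatrix, SampleTable
from mirdeq.diffexp import DERecord
from mirdeq.examples import CLUSTER_TABLE
from mirdeq.synthetic_data import SimulationConfig


@pytest.fixture
def tiny_cm() -> CountMatrix:
    return CountMatrix(
        ["miR-a", "miR-b"], ["s1", "s2"], np.array([[5, 0], [1, 7]])
    )


@pytest.fixture
def two_group_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {"sample_id": ["s1", "s2"], "group": ["tumor", "normal"]}
        )
    )


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig()


def make_sample_table(tumor_ids, normal_ids) -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": list(tumor_ids) + list(normal_ids),
                "group": ["tumor"] * len(tumor_ids)
                + ["normal"] * len(normal_ids),
            }
        )
    )


def published_cluster_records() -> list[DERecord]:
    """DE records reconstructed from the bundled per-cluster summary table."""
    records = []
    for info in CLUSTER_TABLE.values():
        for mirna_id, p_raw, direction, fold in info["members"]:
            if fold is None:
                mean_t, mean_n = (50.0, 0.0) if direction == "up" else (0.0, 50.0)
            elif direction == "up":
                mean_t, mean_n = 100.0 * fold, 100.0
            else:
                mean_t, mean_n = 100.0, 100.0 * fold
            records.append(
                DERecord(
                    mirna_id=mirna_id,
                    mean_tumor=mean_t,
                    mean_normal=mean_n,
                    t=0.0,
                    p_raw=p_raw,
                    p_adj=min(1.0, p_raw * 145),
                    direction=direction,
                    fold_change=fold,
                    mean_diff=abs(mean_t - mean_n),
                )
            )
    # an isolated significant miRNA outside any cluster
    records.append(
        DERecord("hsa-miR-215", 3.0, 92.0, 0.0, 3.21e-08, 4.66e-06,
                 "down", 92.0 / 3.0, 89.0)
    )
    return records


def published_cluster_gff() -> str:
    """GFF3 text placing each bundled cluster's matures on its chromosome."""
    from mirdeq.genomic_clusters import strip_arm

    lines = ["##gff-version 3"]
    for info in CLUSTER_TABLE.values():
        pos = 1_000
        by_precursor: dict[str, list[str]] = {}
        for mirna_id, *_ in info["members"]:
            by_precursor.setdefault(strip_arm(mirna_id), []).append(mirna_id)
        for precursor, matures in by_precursor.items():
            for k, name in enumerate(matures):
                start1 = pos + 30 * k + 1
                lines.append(
                    f"{info['chrom']}\t.\tmiRNA\t{start1}\t{start1 + 21}\t.\t+"
                    f"\t.\tID=MIMAT-{name};Name={name}"
                )
            pos += 600
    # the singleton, alone on its own chromosome
    lines.append(
        "chr1b\t.\tmiRNA\t5001\t5022\t.\t+\t.\tID=MIMAT-215;Name=hsa-miR-215"
    )
    return "\n".join(lines) + "\n"
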