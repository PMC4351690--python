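"""Readers and writers for on-disk artifacts.

Formats: tab-separated count matrices and result tables (UTF-8, header row),
sample metadata tables (TSV/CSV), and miRNA locus annotations in the miRBase
GFF3 dialect (feature types ``miRNA_primary_transcript`` / ``miRNA``,
``Name=`` attributes). GFF3 coordinates are 1-based inclusive on disk and are
converted to 0-based half-open internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = ("tumor", "normal")
VALID_STAGES = ("early", "advanced")

#: default mapping from AJCC stage strings to the two-level stage factor
AJCC_STAGE_MAP = {
    "I": "early",
    "II": "early",
    "IIA": "early",
    "IIB": "early",
    "III": "advanced",
    "IIIA": "advanced",
    "IIIB": "advanced",
    "IIIC": "advanced",
}

# float format giving 12 significant digits, enough for lossless round-trips
_FLOAT_FMT = "%.12g"


class CountMatrixError(ValueError):
    """Raised on malformed count-matrix input."""


@dataclass
class CountMatrix:
    """Non-negative integer read counts, miRNAs x samples."""

    mirna_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D array")
        n_mir, n_samp = self.counts.shape
        if n_mir != len(self.mirna_ids) or n_samp != len(self.sample_ids):
            raise CountMatrixError(
                f"dimension mismatch: counts {self.counts.shape} vs "
                f"{len(self.mirna_ids)} miRNAs / {len(self.sample_ids)} samples"
            )
        for name, ids in (("miRNA", self.mirna_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise CountMatrixError(f"duplicate {name} id: {dup!r}")
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise CountMatrixError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise CountMatrixError(
                f"negative count at miRNA {self.mirna_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.mirna_ids, columns=self.sample_ids
        )

    def subset_rows(self, keep: np.ndarray) -> "CountMatrix":
        """Row subset preserving order; ``keep`` is a boolean or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.mirna_ids[i] for i in keep],
            list(self.sample_ids),
            self.counts[keep],
        )


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Parse a TSV count matrix (first column: miRNA ids; header row: samples).

    Raises :class:`CountMatrixError` naming the offending row/column on
    duplicate identifiers and negative or non-numeric cells. ``.`` is not
    accepted as a numeric cell.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise CountMatrixError(f"{path}: no columns found")
    mirna_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    dup = _first_duplicate(mirna_ids)
    if dup is not None:
        raise CountMatrixError(f"{path}: duplicate miRNA id: {dup!r}")
    n = len(mirna_ids)
    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(df.columns[1:]):
        for i, cell in enumerate(df[col]):
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise CountMatrixError(
                    f"{path}: non-numeric count {cell!r} at miRNA "
                    f"{mirna_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if value < 0:
                raise CountMatrixError(
                    f"{path}: negative count {value} at miRNA "
                    f"{mirna_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            counts[i, j] = value
    return CountMatrix(mirna_ids, sample_ids, counts)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="mirna_id")


@dataclass
class SampleTable:
    """Per-sample metadata: group label and optional stage / pairing."""

    frame: pd.DataFrame  # columns: sample_id, group, [stage], [pair_id]

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" not in df.columns or "group" not in df.columns:
            raise ValueError("sample table needs 'sample_id' and 'group' columns")
        dup = _first_duplicate(df["sample_id"].tolist())
        if dup is not None:
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad = set(df["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group label: {sorted(bad)[0]!r}")
        if "stage" in df.columns:
            bad = {s for s in df["stage"].dropna() if s != ""} - set(VALID_STAGES)
            if bad:
                raise ValueError(f"unknown stage label: {sorted(bad)[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id, "group"]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]

    def ids_in_group(self, group: str) -> list[str]:
        return self.frame.loc[self.frame["group"] == group, "sample_id"].tolist()

    def group_sizes(self) -> dict[str, int]:
        return self.frame["group"].value_counts().to_dict()


def map_ajcc_stage(stage: str, mapping: dict[str, str] | None = None) -> str:
    """Collapse an AJCC stage string (e.g. ``IIA``) to early/advanced."""
    mapping = AJCC_STAGE_MAP if mapping is None else mapping
    key = stage.strip().upper()
    if key not in mapping:
        raise ValueError(f"unknown AJCC stage: {stage!r}")
    return mapping[key]


def read_sample_table(path: str | Path, sep: str = "\t") -> SampleTable:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


@dataclass
class MiRNALocus:
    """Genomic interval of a mature miRNA, 0-based half-open internally."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    context: str | None = None
    precursor_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.mirna_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.mirna_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


_GFF_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    return {k.strip(): v for k, v in _GFF_ATTR_RE.findall(text)}


def read_mirna_annotations(path: str | Path) -> list[MiRNALocus]:
    """Load mature miRNA loci from a miRBase-dialect GFF3 file.

    Only ``miRNA`` feature lines produce loci; ``miRNA_primary_transcript``
    lines are used to resolve ``Derives_from`` references into precursor
    names. On-disk coordinates (1-based inclusive) become 0-based half-open.
    """
    primaries: dict[str, str] = {}  # ID -> Name
    raw: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line "
                    f"({len(fields)} columns, expected 9)"
                )
            raw.append((lineno, fields))
            if fields[2] == "miRNA_primary_transcript":
                attrs = _parse_gff_attributes(fields[8])
                if "ID" in attrs:
                    primaries[attrs["ID"]] = attrs.get("Name", attrs["ID"])
    loci: list[MiRNALocus] = []
    for lineno, fields in raw:
        if fields[2] != "miRNA":
            continue
        chrom, _, _, start_s, end_s, _, strand, _, attr_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if end1 < start1:
            raise ValueError(f"{path}:{lineno}: end {end1} < start {start1}")
        attrs = _parse_gff_attributes(attr_s)
        name = attrs.get("Name") or attrs.get("ID")
        if not name:
            raise ValueError(f"{path}:{lineno}: miRNA record without Name/ID")
        derives = attrs.get("Derives_from")
        precursor = primaries.get(derives, derives) if derives else None
        loci.append(
            MiRNALocus(
                mirna_id=name,
                chrom=chrom,
                start=start1 - 1,  # to 0-based half-open
                end=end1,
                strand=strand,
                context=attrs.get("context"),
                precursor_id=precursor,
            )
        )
    return loci


RESULT_COLUMNS = [
    "mirna_id",
    "mean_tumor",
    "mean_normal",
    "t",
    "p_raw",
    "p_adj",
    "direction",
    "fold_change",
    "mean_diff",
]

_NA_TOKEN = "N/A"  # the only serialized token for undefined fold change


def write_results_table(records: Iterable, path: str | Path) -> None:
    """Serialize DE records as TSV; undefined fold change becomes ``N/A``."""
    rows = []
    for r in records:
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "mean_tumor": _FLOAT_FMT % r.mean_tumor,
                "mean_normal": _FLOAT_FMT % r.mean_normal,
                "t": _FLOAT_FMT % r.t,
                "p_raw": _FLOAT_FMT % r.p_raw,
                "p_adj": _FLOAT_FMT % r.p_adj,
                "direction": r.direction,
                "fold_change": (
                    _NA_TOKEN if r.fold_change is None else _FLOAT_FMT % r.fold_change
                ),
                "mean_diff": _FLOAT_FMT % r.mean_diff,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> list:
    """Inverse of :func:`write_results_table`."""
    from mirdeq.diffexp import DERecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        fc = None if row["fold_change"] == _NA_TOKEN else float(row["fold_change"])
        records.append(
            DERecord(
                mirna_id=row["mirna_id"],
                mean_tumor=float(row["mean_tumor"]),
                mean_normal=float(row["mean_normal"]),
                t=float(row["t"]),
                p_raw=float(row["p_raw"]),
                p_adj=float(row["p_adj"]),
                direction=row["direction"],
                fold_change=fc,
                mean_diff=float(row["mean_diff"]),
            )
        )
    return records
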