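"""Seed-region complementarity scanning of 3'-UTRs.

Canonical site taxonomy over strict Watson-Crick pairs (no G:U wobble):

* 6mer     — UTR reverse-complement match to miRNA positions 2-7
* 7mer-A1  — 6mer plus an A in the UTR opposite miRNA position 1
* 7mer-m8  — reverse-complement match to miRNA positions 2-8
* 8mer     — 7mer-m8 plus the A1 adenosine

Coordinates are 0-based half-open on the UTR read 5'->3'. At each match
locus only the longest applicable class is reported. RNA and DNA alphabets
are accepted interchangeably (U == T); the internal alphabet is DNA and
sequence output mirrors the input alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_DNA_COMP = str.maketrans("ACGT", "TGCA")
# transversions only (purine <-> pyrimidine), to maximally disrupt pairing
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class AlphabetError(ValueError):
    pass


def _to_dna(seq: str, label: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise AlphabetError(f"{label}: invalid nucleotide {sorted(bad)[0]!r}")
    return s


def reverse_complement(seq: str) -> str:
    return _to_dna(seq, "sequence").translate(_DNA_COMP)[::-1]


@dataclass
class SeedSite:
    """A seed complementarity match inside a 3'-UTR."""

    utr_id: str
    start: int
    end: int
    site_class: str
    matched_seed: str

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.end - self.start not in (6, 7, 8):
            raise ValueError("site length must be 6, 7 or 8")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def scan_seed_sites(
    utr: str, mirna: str, utr_id: str = "utr"
) -> list[SeedSite]:
    """All canonical seed sites for ``mirna`` (5'->3', length >= 8) in ``utr``.

    Matches are strict Watson-Crick reverse complements; overlapping classes
    at one locus collapse to the longest. Sites are returned in ascending
    coordinate order; ``matched_seed`` is the UTR substring in the input
    alphabet.
    """
    u = _to_dna(utr, "UTR")
    m = _to_dna(mirna, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA must be >= 8 nt to define seed positions 2-8")
    core6 = reverse_complement(m[1:7])  # pairs miRNA positions 2-7
    m8_comp = m[7].translate(_DNA_COMP)  # UTR base pairing miRNA position 8
    sites: list[SeedSite] = []
    pos = u.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and u[pos - 1] == m8_comp
        has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
        if has_m8 and has_a1:
            cls, start, end = "8mer", pos - 1, pos + 7
        elif has_m8:
            cls, start, end = "7mer-m8", pos - 1, pos + 6
        elif has_a1:
            cls, start, end = "7mer-A1", pos, pos + 7
        else:
            cls, start, end = "6mer", pos, pos + 6
        sites.append(SeedSite(utr_id, start, end, cls, utr[start:end]))
        pos = u.find(core6, pos + 1)
    return sorted(sites, key=lambda s: (s.start, s.end))


def mutate_site(
    utr: str,
    site: SeedSite,
    mirna: str,
    n_mutations: int = 3,
    seed: int = 0,
) -> str:
    """Disrupt a seed site with exactly ``n_mutations`` substitutions.

    Mutations are transversions confined to the site interval, at least one
    of them inside the 6mer core so pairing is broken; the result is
    verified by re-scanning (no site may overlap the original interval).
    Deterministic given ``seed``; bases outside the site are never touched.
    """
    if n_mutations < 1:
        raise ValueError("cannot disrupt a site with zero mutations")
    length = site.end - site.start
    if n_mutations > length:
        raise ValueError(f"n_mutations={n_mutations} exceeds site length {length}")
    if not (0 <= site.start < site.end <= len(utr)):
        raise ValueError("site does not lie within the UTR")
    is_rna = "U" in utr.upper() or "u" in utr
    # the 6mer core sits one base inside the site for m8-anchored classes
    core_start = site.start + 1 if site.site_class in ("7mer-m8", "8mer") else site.start
    core_positions = list(range(core_start, core_start + 6))
    other_positions = [
        p for p in range(site.start, site.end) if p not in core_positions
    ]
    rng = np.random.default_rng(seed)
    for _ in range(200):
        n_core = min(n_mutations, 6)
        chosen = list(rng.choice(core_positions, size=n_core, replace=False))
        if n_mutations > n_core:
            chosen += list(
                rng.choice(other_positions, size=n_mutations - n_core, replace=False)
            )
        mutated = list(utr)
        for p in chosen:
            base = _to_dna(utr[p], "UTR")
            sub = _TRANSVERSIONS[base][int(rng.integers(2))]
            if is_rna:
                sub = sub.replace("T", "U")
            mutated[p] = sub
        candidate = "".join(mutated)
        rescan = scan_seed_sites(candidate, mirna, site.utr_id)
        if not any(s.overlaps(site.start, site.end) for s in rescan):
            return candidate
    raise RuntimeError("could not disrupt the site; try more mutations")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def scan_fasta(
    path: str | Path, mirna: str
) -> list[SeedSite]:
    """Scan every UTR in a FASTA file; sites ordered by UTR id, then start."""
    sites: list[SeedSite] = []
    for utr_id, seq in read_fasta(path).items():
        sites.extend(scan_seed_sites(seq, mirna, utr_id=utr_id))
    return sorted(sites, key=lambda s: (s.utr_id, s.start, s.end))
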