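"""Bundled worked-example dataset.

Summary statistics from a published two-group miRNA deep-sequencing screen
(24 tumor vs 14 adjacent-normal samples): the 25-miRNA significance
signature with raw and adjusted p-values, group-mean/fold-change worked
examples, the seven polycistronic cluster summaries, and a reporter-assay
3'-UTR fragment with a seed-complementary miRNA sequence. These numbers
drive the worked-example tests and the acceptance report; they are inputs,
not values computed by this package.
"""

from __future__ import annotations

#: Holm family size under which the printed adjusted p-values are reproduced
#: (multiplier at ascending rank k is FAMILY_SIZE - k + 1).
SIGNATURE_FAMILY_SIZE = 145

#: (mirna_id, raw p, printed Holm-adjusted p), ordered by ascending raw p.
SIGNATURE_PVALUES: list[tuple[str, float, float]] = [
    ("hsa-miR-215", 3.21e-08, 4.66e-06),
    ("hsa-miR-497-5p", 2.43e-06, 3.49e-04),
    ("hsa-miR-204-5p", 4.69e-06, 6.71e-04),
    ("hsa-miR-425-5p", 5.98e-06, 8.49e-04),
    ("hsa-miR-96-5p", 1.34e-05, 1.89e-03),
    ("hsa-miR-1301", 1.72e-05, 2.40e-03),
    ("hsa-miR-335-3p", 2.89e-05, 4.02e-03),
    ("hsa-miR-183-5p", 5.13e-05, 7.08e-03),
    ("hsa-miR-24-2-3p", 6.04e-05, 8.27e-03),
    ("hsa-miR-130b-5p", 7.64e-05, 1.04e-02),
    ("hsa-miR-92a-3p", 9.93e-05, 1.34e-02),
    ("hsa-miR-320a-3p", 1.15e-04, 1.54e-02),
    ("hsa-miR-130b-3p", 1.23e-04, 1.64e-02),
    ("hsa-miR-145-5p", 1.47e-04, 1.94e-02),
    ("hsa-miR-126-3p", 1.55e-04, 2.03e-02),
    ("hsa-miR-139-5p", 1.57e-04, 2.04e-02),
    ("hsa-let-7a-3p", 1.59e-04, 2.05e-02),
    ("hsa-miR-489-5p", 1.59e-04, 2.05e-02),
    ("hsa-miR-362-5p", 1.69e-04, 2.15e-02),
    ("hsa-miR-429-5p", 1.91e-04, 2.40e-02),
    ("hsa-miR-19b-3p", 2.43e-04, 3.04e-02),
    ("hsa-miR-362-3p", 2.56e-04, 3.17e-02),
    ("hsa-miR-320a-5p", 2.72e-04, 3.34e-02),
    ("hsa-miR-337-5p", 3.44e-04, 4.19e-02),
    ("hsa-miR-143-5p", 3.91e-04, 4.73e-02),
]

#: mirna_id -> (mean tumor, mean normal, printed 1-d.p. fold or None for N/A)
FOLD_CHANGE_EXAMPLES: dict[str, tuple[float, float, float | None]] = {
    "hsa-miR-130b-5p": (3729.0, 1352.0, 2.8),
    "hsa-miR-497-5p": (1980.0, 6520.0, 3.3),
    "hsa-miR-301b-5p": (323.0, 89.0, 3.6),
    "hsa-miR-92a-3p": (182.0, 0.0, None),
}

#: Seven polycistronic clusters with per-member (id, raw p, direction,
#: printed fold or None). chrom/context are pass-through annotation labels.
CLUSTER_TABLE: dict[str, dict] = {
    "miR-143-145": {
        "chrom": "chr5",
        "context": "5q32 intergenic",
        "members": [
            ("hsa-miR-143-5p", 3.91e-04, "down", 2.4),
            ("hsa-miR-145-3p", 7.36e-03, "down", 3.2),
            ("hsa-miR-145-5p", 1.47e-04, "down", 3.4),
        ],
    },
    "miR-497-195": {
        "chrom": "chr17",
        "context": "17p13.1 MIR497HG intron 1",
        "members": [
            ("hsa-miR-497-5p", 2.43e-06, "down", 3.3),
            ("hsa-miR-195-5p", 3.18e-03, "down", 3.0),
        ],
    },
    "miR-17-92": {
        "chrom": "chr13",
        "context": "13q31.3 C13orf25 intron 3",
        "members": [
            ("hsa-miR-17-3p", 2.66e-02, "up", 1.9),
            ("hsa-miR-18a-3p", 1.43e-02, "up", 3.0),
            ("hsa-miR-19b-3p", 9.93e-05, "up", None),
            ("hsa-miR-92a-3p", 2.43e-04, "up", None),
        ],
    },
    "miR-183-182": {
        "chrom": "chr7",
        "context": "7q32.2 intergenic",
        "members": [
            ("hsa-miR-183-3p", 5.42e-03, "up", 2.5),
            ("hsa-miR-183-5p", 5.13e-05, "up", 3.2),
            ("hsa-miR-96-3p", 2.70e-03, "up", 2.5),
            ("hsa-miR-96-5p", 1.34e-05, "up", 3.0),
            ("hsa-miR-182-5p", 4.76e-03, "up", 3.8),
        ],
    },
    "miR-200b-429": {
        "chrom": "chr1",
        "context": "1p36.33 intergenic",
        "members": [
            ("hsa-miR-200b-3p", 2.65e-02, "up", 1.7),
            ("hsa-miR-200a-3p", 2.46e-02, "up", 1.9),
            ("hsa-miR-200a-5p", 1.25e-03, "up", 2.9),
            ("hsa-miR-429-5p", 1.91e-04, "up", 3.1),
        ],
    },
    "miR-301b-130b": {
        "chrom": "chr22",
        "context": "22q11.21 PPIL2 exon 2",
        "members": [
            ("hsa-miR-301b-5p", 1.41e-03, "up", 3.6),
            ("hsa-miR-130b-3p", 1.23e-04, "up", 2.2),
            ("hsa-miR-130b-5p", 7.64e-05, "up", 2.8),
        ],
    },
    "miR-532-502": {
        "chrom": "chrX",
        "context": "Xp11.23 CLCN5 intron 3",
        "members": [
            ("hsa-miR-532-5p", 1.58e-02, "up", 2.0),
            ("hsa-miR-188-3p", 2.72e-02, "up", 2.2),
            ("hsa-miR-362-3p", 2.56e-04, "up", 2.3),
            ("hsa-miR-362-5p", 1.69e-04, "up", 2.2),
            ("hsa-miR-501-3p", 2.13e-02, "up", 2.3),
            ("hsa-miR-660-3p", 3.00e-02, "up", 2.6),
            ("hsa-miR-502-3p", 1.01e-02, "up", 2.1),
            ("hsa-miR-502-5p", 2.55e-02, "up", 2.0),
        ],
    },
}

#: Reporter-assay 3'-UTR fragment carrying one seed-complementary site.
REPORTER_UTR = "CCTTGGAGATACTGAAAGAGA"

#: Locally supplied mature miRNA sequence whose positions 2-8 are the
#: Watson-Crick complement of the reporter site (used for scanning tests;
#: no external database entry is asserted).
REPORTER_MIRNA = "ACUCUUUCCCUGUUGCACUAC"
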