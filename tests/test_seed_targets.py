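import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirdeq.examples import REPORTER_MIRNA, REPORTER_UTR
from mirdeq.seed_targets import (
    AlphabetError,
    SeedSite,
    mutate_site,
    read_fasta,
    reverse_complement,
    scan_fasta,
    scan_seed_sites,
    write_fasta,
)


def _dna(seq):
    return seq.upper().replace("U", "T")


def oracle_sites(utr, mirna):
    """Brute-force substring enumeration, independent of the scanner."""
    u, m = _dna(utr), _dna(mirna)
    rc6 = reverse_complement(m[1:7])
    rc7 = reverse_complement(m[1:8])
    found = {}
    # key: core locus (start of the 6-nt core match)
    for s in range(len(u) - 5):
        if u[s:s + 6] != rc6:
            continue
        found[s] = ("6mer", s, s + 6)
    for s in range(len(u) - 5):
        if u[s:s + 6] == rc6 and s + 6 < len(u) and u[s + 6] == "A":
            found[s] = ("7mer-A1", s, s + 7)
    for s in range(len(u) - 6):
        if u[s:s + 7] == rc7:
            core = s + 1
            if core in found and found[core][0] == "7mer-A1":
                found[core] = ("8mer", s, s + 8)
            else:
                found[core] = ("7mer-m8", s, s + 7)
    return sorted(found.values(), key=lambda x: (x[1], x[2]))


class TestScan:
    def test_reporter_site_is_single_8mer(self):
        sites = scan_seed_sites(REPORTER_UTR, REPORTER_MIRNA)
        assert len(sites) == 1
        (site,) = sites
        assert site.site_class == "8mer"
        assert (site.start, site.end) == (13, 21)
        assert site.matched_seed == "GAAAGAGA"
        assert site.end == len(REPORTER_UTR)  # ends at the terminal A

    def test_empty_utr(self):
        assert scan_seed_sites("", REPORTER_MIRNA) == []

    def test_exact_6mer_at_zero(self):
        mirna = "AACGTACGTACGTACGTACGT"
        core = reverse_complement(mirna[1:7])
        utr = core  # nothing before or after: plain 6mer at position 0
        (site,) = scan_seed_sites(utr, mirna)
        assert (site.start, site.end, site.site_class) == (0, 6, "6mer")

    def test_class_discrimination(self):
        m = "ACTCTTTCCCTGTTGCACTAC"
        core6 = reverse_complement(m[1:7])   # AAAGAG
        core7 = reverse_complement(m[1:8])   # GAAAGAG
        cases = {
            "C" + core6 + "C": "6mer",
            "C" + core6 + "A": "7mer-A1",
            core7 + "C": "7mer-m8",
            core7 + "A": "8mer",
        }
        for utr, expected in cases.items():
            (site,) = scan_seed_sites(utr, m)
            assert site.site_class == expected, utr

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            scan_seed_sites("ACGTN", REPORTER_MIRNA)
        with pytest.raises(AlphabetError):
            scan_seed_sites("ACGT", "ACGTXCGTA")

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            scan_seed_sites("ACGTACGT", "ACGTACG")

    def test_rna_input_equivalent(self):
        rna_sites = scan_seed_sites(
            REPORTER_UTR.replace("T", "U"), REPORTER_MIRNA
        )
        dna_sites = scan_seed_sites(REPORTER_UTR, _dna(REPORTER_MIRNA))
        assert [(s.start, s.end, s.site_class) for s in rna_sites] == [
            (s.start, s.end, s.site_class) for s in dna_sites
        ]

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            utr = "".join(rng.choice(bases, size=rng.integers(10, 200)))
            mirna = "".join(rng.choice(bases, size=22))
            # seed the UTR with the core sometimes so matches are not rare
            core = reverse_complement(mirna[1:7])
            if rng.random() < 0.7:
                pos = rng.integers(0, max(len(utr) - 6, 1))
                utr = utr[:pos] + core + utr[pos + 6:]
            got = [
                (s.site_class, s.start, s.end)
                for s in scan_seed_sites(utr, mirna)
            ]
            assert got == oracle_sites(utr, mirna)

    def test_reported_sites_pair_with_seed(self):
        rng = np.random.default_rng(10)
        bases = np.array(list("ACGT"))
        checked = 0
        for _ in range(100):
            mirna = "".join(rng.choice(bases, size=21))
            utr = (
                "".join(rng.choice(bases, size=30))
                + reverse_complement(mirna[1:8]) + "A"
                + "".join(rng.choice(bases, size=30))
            )
            for site in scan_seed_sites(utr, mirna):
                checked += 1
                matched = _dna(site.matched_seed)
                if site.site_class in ("7mer-A1", "8mer"):
                    assert matched[-1] == "A"
                    matched = matched[:-1]
                n = len(matched)
                # matched core reverse-complement pairs seed 2..(n+1)
                assert reverse_complement(matched) == _dna(mirna)[1:1 + n]
        assert checked > 0


class TestMutate:
    def test_reporter_disruption(self):
        (site,) = scan_seed_sites(REPORTER_UTR, REPORTER_MIRNA)
        mutated = mutate_site(REPORTER_UTR, site, REPORTER_MIRNA, 3, seed=1)
        assert len(mutated) == len(REPORTER_UTR)
        rescan = scan_seed_sites(mutated, REPORTER_MIRNA)
        assert not any(s.overlaps(site.start, site.end) for s in rescan)
        # exactly 3 positions changed, all inside the site
        diffs = [
            i for i, (a, b) in enumerate(zip(REPORTER_UTR, mutated)) if a != b
        ]
        assert len(diffs) == 3
        assert all(site.start <= i < site.end for i in diffs)

    def test_full_seed_replacement(self):
        mirna = "AACGTACGTACGTACGTACGT"
        utr = "TT" + reverse_complement(mirna[1:7]) + "TT"
        (site,) = scan_seed_sites(utr, mirna)
        mutated = mutate_site(utr, site, mirna, 6, seed=0)
        assert scan_seed_sites(mutated, mirna) == []

    def test_deterministic(self):
        (site,) = scan_seed_sites(REPORTER_UTR, REPORTER_MIRNA)
        a = mutate_site(REPORTER_UTR, site, REPORTER_MIRNA, 3, seed=42)
        b = mutate_site(REPORTER_UTR, site, REPORTER_MIRNA, 3, seed=42)
        assert a == b

    def test_zero_mutations_error(self):
        (site,) = scan_seed_sites(REPORTER_UTR, REPORTER_MIRNA)
        with pytest.raises(ValueError, match="zero mutations"):
            mutate_site(REPORTER_UTR, site, REPORTER_MIRNA, 0)

    def test_too_many_mutations_error(self):
        (site,) = scan_seed_sites(REPORTER_UTR, REPORTER_MIRNA)
        with pytest.raises(ValueError, match="exceeds site length"):
            mutate_site(REPORTER_UTR, site, REPORTER_MIRNA, 9)

    def test_outside_site_untouched(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            (site,) = scan_seed_sites(REPORTER_UTR, REPORTER_MIRNA)
            mutated = mutate_site(
                REPORTER_UTR, site, REPORTER_MIRNA, 2, seed=seed
            )
            assert mutated[: site.start] == REPORTER_UTR[: site.start]
            assert mutated[site.end:] == REPORTER_UTR[site.end:]

    def test_rna_alphabet_preserved(self):
        utr = REPORTER_UTR.replace("T", "U")
        (site,) = scan_seed_sites(utr, REPORTER_MIRNA)
        mutated = mutate_site(utr, site, REPORTER_MIRNA, 3, seed=2)
        assert "T" not in mutated


class TestSiteType:
    def test_invalid_class(self):
        with pytest.raises(ValueError, match="site class"):
            SeedSite("u", 0, 6, "9mer", "ACGTAC")

    def test_invalid_length(self):
        with pytest.raises(ValueError, match="length"):
            SeedSite("u", 0, 5, "6mer", "ACGTA")


class TestFasta:
    def test_roundtrip_and_scan(self, tmp_path):
        path = tmp_path / "utrs.fasta"
        write_fasta({"frag": REPORTER_UTR, "empty": "ACGT" * 10}, path)
        back = read_fasta(path)
        assert back["frag"] == REPORTER_UTR
        sites = scan_fasta(path, REPORTER_MIRNA)
        assert [s.utr_id for s in sites] == ["frag"]


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=0, max_size=80), st.data())
def test_scan_oracle_property(utr, data):
    mirna = data.draw(st.text(alphabet="ACGT", min_size=8, max_size=25))
    got = [(s.site_class, s.start, s.end) for s in scan_seed_sites(utr, mirna)]
    assert got == oracle_sites(utr, mirna)
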