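"""Scanner correctness against brute-force oracles and stated edge cases."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cuttaggro as ctg
from cuttaggro.intervals import GenomicInterval
from cuttaggro.motifs import reverse_complement

from _oracles import (
    naive_intersect,
    naive_isolated,
    naive_iupac_scan,
    naive_microsatellites,
    naive_scan_ggaa,
    naive_tandem,
)
from conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


# ---------------------------------------------------------------- scan_ggaa
@pytest.mark.parametrize(
    "seq, expected",
    [
        ("GGAA", [(0, "+")]),
        ("TTCC", [(0, "-")]),
        ("GGAAGGAAGG", [(0, "+"), (4, "+")]),
        ("GGNA", []),  # N never matches
        ("ACGT", []),
    ],
)
def test_scan_ggaa_examples(seq, expected):
    sites = ctg.scan_ggaa(seq, "c")
    assert [(s.interval.start, s.interval.strand) for s in sites] == expected


def test_scan_ggaa_rejects_non_nucleotide():
    with pytest.raises(ValueError, match="non-IUPAC"):
        ctg.scan_ggaa("GGAAX", "c")


# ---------------------------------------------------- microsatellite finding
def test_microsatellite_examples():
    seq = "A" * 20 + "GGAA" * 4 + "A" * 20
    loci = ctg.find_microsatellites(seq, "c")
    assert len(loci) == 1
    assert (loci[0].interval.start, loci[0].interval.end, loci[0].unit_count) == (20, 36, 4)
    assert ctg.find_microsatellites("A" * 10 + "GGAA" * 3 + "A" * 10, "c") == []


def test_planted_microsatellite_in_random_background(rng):
    seq = random_seq(rng, 10_000)
    seq = seq[:1000] + "GGAA" * 6 + seq[1024:]
    loci = ctg.find_microsatellites(seq, "c", min_units=4)
    expected = naive_microsatellites(seq, 4)
    assert [(l.interval.start, l.interval.end, l.unit_count) for l in loci] == expected
    planted = [l for l in loci if l.interval.start == 1000]
    assert planted and planted[0].unit_count >= 6  # chance left-flank unit may extend it


def test_min_units_validation():
    with pytest.raises(ValueError):
        ctg.find_microsatellites("GGAA", "c", min_units=1)


# ------------------------------------------------------------ isolated GGAA
def test_isolated_examples():
    lone = ctg.scan_ggaa("A" * 48 + "GGAA" + "A" * 48, "c")
    assert len(ctg.find_isolated_ggaa(lone)) == 1

    close = ctg.scan_ggaa("GGAA" + "C" * 10 + "GGAA", "c")
    assert ctg.find_isolated_ggaa(close) == []

    boundary = ctg.scan_ggaa("GGAA" + "C" * 20 + "GGAA", "c")
    assert len(ctg.find_isolated_ggaa(boundary)) == 2  # gap == min_gap qualifies


def test_isolated_rejects_unsorted():
    sites = ctg.scan_ggaa("GGAA" + "C" * 30 + "GGAA", "c")
    with pytest.raises(ValueError, match="sorted"):
        ctg.find_isolated_ggaa(sites[::-1])


# ----------------------------------------------------------- cofactor scans
def test_cofactor_examples():
    sites = ctg.scan_cofactor_motifs("TGACTCA", "c", {"AP1": "TGASTCA"})
    assert [(s.interval.start, s.interval.strand) for s in sites] == [(0, "+")]
    # TGAGTCA matches the consensus on both strands -> one + site
    sites = ctg.scan_cofactor_motifs("TGAGTCA", "c", {"AP1": "TGASTCA"})
    assert [(s.interval.start, s.interval.strand) for s in sites] == [(0, "+")]
    assert ctg.scan_cofactor_motifs("TGACTCA", "c", {}) == []


def test_cofactor_invalid_pattern():
    with pytest.raises(ValueError, match="IUPAC"):
        ctg.scan_cofactor_motifs("ACGT", "c", {"bad": "AXG"})


# ----------------------------------------------------------- tandem pairing
def test_tandem_edge_distance_rule():
    # GGAA at [500,504), AP1 at [600,607): edge distance 96 <= 200
    seq = ["A"] * 1000
    seq[500:504] = "GGAA"
    seq[600:607] = "TGACTCA"
    seq = "".join(seq)
    ggaa = [s for s in ctg.scan_ggaa(seq, "c") if s.interval.start == 500]
    cof = ctg.scan_cofactor_motifs(seq, "c", {"AP1": "TGASTCA"})
    els = ctg.classify_tandem_sites(ggaa, cof, window=200)
    assert [e.element_class for e in els] == ["tandem_ggaa_ap1"]
    assert els[0].partner_site.interval.start == 600
    assert ctg.classify_tandem_sites(ggaa, cof, window=95) == []


def test_tandem_multilabel():
    seq = ["A"] * 1000
    seq[500:504] = "GGAA"
    seq[554:561] = "TGACTCA"  # AP1 at 50 bp
    seq[624:632] = "GCGCCAAA"  # E2F at 120 bp
    seq = "".join(seq)
    ggaa = [s for s in ctg.scan_ggaa(seq, "c") if s.interval.start == 500]
    cof = ctg.scan_cofactor_motifs(seq, "c", {"AP1": "TGASTCA", "E2F": "GCGSSAAA"})
    els = ctg.classify_tandem_sites(ggaa, cof, window=200)
    assert sorted(e.element_class for e in els) == ["tandem_ggaa_ap1", "tandem_ggaa_e2f"]


# ------------------------------------------------------ interval intersection
def test_intersect_half_open_semantics():
    a = [GenomicInterval("c", 10, 20)]
    assert ctg.intersect_intervals(a, [GenomicInterval("c", 19, 30)]) == a
    assert ctg.intersect_intervals(a, [GenomicInterval("c", 20, 30)]) == []


def test_intersect_random_vs_bruteforce(rng):
    def rand_ivs(n):
        out = []
        for _ in range(n):
            chrom = f"chr{rng.integers(1, 3)}"
            s = int(rng.integers(0, 1000))
            out.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 50))))
        return sorted(out, key=lambda iv: (iv.chrom, iv.start))

    a, b = rand_ivs(100), rand_ivs(100)
    got = ctg.intersect_intervals(a, b)
    want = [
        a[i]
        for i in naive_intersect(
            [(iv.chrom, iv.start, iv.end) for iv in a],
            [(iv.chrom, iv.start, iv.end) for iv in b],
        )
    ]
    assert got == want


# ------------------------------------------------- oracle equivalence sweep
def test_all_scanners_match_oracles_on_random_sequences(rng):
    """Vectorized scanners agree exactly with the quadratic reimplementation."""
    for _ in range(30):
        seq = random_seq(rng, 2_000)
        sites = ctg.scan_ggaa(seq, "c")
        assert [(s.interval.start, s.interval.strand) for s in sites] == sorted(
            naive_scan_ggaa(seq)
        )
        loci = ctg.find_microsatellites(seq, "c", min_units=2)
        assert [
            (l.interval.start, l.interval.end, l.unit_count) for l in loci
        ] == naive_microsatellites(seq, 2)
        iso = ctg.find_isolated_ggaa(sites, min_gap=20)
        pairs = [(s.interval.start, s.interval.end) for s in sites]
        assert [(s.interval.start, s.interval.end) for s in iso] == [
            pairs[i] for i in naive_isolated(pairs, 20)
        ]
        for name, pat in ctg.DEFAULT_COFACTOR_PATTERNS.items():
            got = [
                (s.interval.start, s.interval.strand)
                for s in ctg.scan_cofactor_motifs(seq, "c", {name: pat})
            ]
            assert got == naive_iupac_scan(seq, pat)
        cof = ctg.scan_cofactor_motifs(seq, "c")
        els = ctg.classify_tandem_sites(sites, cof, window=50)
        want = naive_tandem(
            [(s.interval.start, s.interval.end) for s in sites],
            [(c.motif_name, c.interval.start, c.interval.end) for c in cof],
            50,
        )
        got = [
            (
                sites.index(e.site),
                e.element_class.removeprefix("tandem_ggaa_").upper(),
                cof.index(e.partner_site),
            )
            for e in els
        ]
        assert sorted(got) == sorted(want)


# ------------------------------------------------------------ property tests
@given(dna, st.integers(min_value=0, max_value=40))
def test_isolation_monotone_in_min_gap(seq, gap):
    sites = ctg.scan_ggaa(seq, "c")
    wide = {s.interval for s in ctg.find_isolated_ggaa(sites, min_gap=gap + 5)}
    narrow = {s.interval for s in ctg.find_isolated_ggaa(sites, min_gap=gap)}
    assert wide <= narrow


@given(dna, st.integers(min_value=0, max_value=100))
def test_tandem_monotone_in_window(seq, window):
    sites = ctg.scan_ggaa(seq, "c")
    cof = ctg.scan_cofactor_motifs(seq, "c")
    small = {
        (e.site.interval, e.element_class)
        for e in ctg.classify_tandem_sites(sites, cof, window=window)
    }
    big = {
        (e.site.interval, e.element_class)
        for e in ctg.classify_tandem_sites(sites, cof, window=window + 50)
    }
    assert small <= big


@given(dna, st.integers(min_value=2, max_value=6))
def test_microsatellites_monotone_in_min_units(seq, units):
    strict = {l.interval for l in ctg.find_microsatellites(seq, "c", min_units=units + 1)}
    loose = {l.interval for l in ctg.find_microsatellites(seq, "c", min_units=units)}
    assert strict <= loose


def test_strand_symmetry_under_reverse_complement(rng):
    """Reverse-complementing the sequence mirrors all scanner coordinates."""
    seq = random_seq(rng, 3_000)
    n = len(seq)
    rc = reverse_complement(seq)
    fwd = ctg.scan_ggaa(seq, "c")
    rev = ctg.scan_ggaa(rc, "c")
    flip = {"+": "-", "-": "+"}
    mirrored = sorted(
        (n - s.interval.end, n - s.interval.start, flip[s.interval.strand]) for s in fwd
    )
    assert mirrored == sorted(
        (s.interval.start, s.interval.end, s.interval.strand) for s in rev
    )
    fwd_ms = ctg.find_microsatellites(seq, "c", min_units=2)
    rev_ms = ctg.find_microsatellites(rc, "c", min_units=2)
    assert sorted((n - l.interval.end, n - l.interval.start, l.unit_count) for l in fwd_ms) == sorted(
        (l.interval.start, l.interval.end, l.unit_count) for l in rev_ms
    )


# --------------------------------------------- planted-element recovery (sim)
def test_planted_elements_recovered_from_simulated_genome(tiny_bundle):
    """The scanners recover every planted element from the simulated genome."""
    cfg = tiny_bundle.config
    truth = tiny_bundle.truth.elements
    genome = tiny_bundle.genome
    ggaa, microsats, cof = [], [], []
    for chrom in sorted(genome):
        ggaa.extend(ctg.scan_ggaa(genome[chrom], chrom))
        microsats.extend(
            ctg.find_microsatellites(genome[chrom], chrom, cfg.microsat_units_range[0])
        )
        cof.extend(ctg.scan_cofactor_motifs(genome[chrom], chrom))
    iso = ctg.find_isolated_ggaa(ggaa, min_gap=cfg.min_gap)
    tandem = ctg.classify_tandem_sites(ggaa, cof, window=cfg.pairing_window)

    ms_found = {(l.interval.chrom, l.interval.start, l.interval.end) for l in microsats}
    for r in truth[truth.element_class == "microsatellite"].itertuples():
        assert (r.chrom, r.start, r.end) in ms_found

    iso_found = {(s.interval.chrom, s.interval.start) for s in iso}
    for r in truth[truth.element_class == "isolated_ggaa"].itertuples():
        assert (r.chrom, r.start) in iso_found

    tandem_found = {
        (e.site.interval.chrom, e.element_class, e.site.interval.start) for e in tandem
    }
    for r in truth[truth.element_class.str.startswith("tandem")].itertuples():
        hits = [
            t for t in tandem_found
            if t[0] == r.chrom and t[1] == r.element_class and r.start <= t[2] < r.end
        ]
        assert hits, f"planted {r.element_id} not recovered"
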