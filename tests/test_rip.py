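"""RIP calling: consensus, site detection, spectrum, indices, window scans."""

import numpy as np
import pytest

from defensescan import rip
from defensescan.simulate import apply_rip


def _brute_dinucleotide(seq: str, dinuc: str) -> int:
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == dinuc)


def _prealigned(rows, family_id="fam"):
    copies = [
        (f"c{i+1}", "chr1", 100 * i, 100 * i + len(r.replace("-", "")), "+", r)
        for i, r in enumerate(rows)
    ]
    return rip.family_from_prealigned(family_id, copies)


class TestConsensus:
    def test_majority_base(self):
        assert rip.build_consensus(["C", "C", "T"]) == "C"
        assert rip.build_consensus(["A", "A", "C"]) == "A"

    def test_ga_column_reconstructs_ancestral_g(self):
        # the A in a pure G/A column may be RIP-derived, so G is ancestral
        assert rip.build_consensus(["A", "A", "G"]) == "G"

    def test_ct_tie_resolves_to_ancestral_c(self):
        assert rip.build_consensus(["C", "T"]) == "C"
        assert rip.build_consensus(["G", "A"]) == "G"

    def test_ct_column_is_ancestrally_c_even_under_t_majority(self):
        # RIP only creates T from C, so any C in a pure C/T column is ancestral
        assert rip.build_consensus(["T", "T", "T", "C"]) == "C"

    def test_identical_copies_reproduce_themselves(self):
        assert rip.build_consensus(["ACGT", "ACGT"]) == "ACGT"

    def test_gap_only_on_gap_majority(self):
        assert rip.build_consensus(["A-", "A-", "AC"]) == "A-"
        assert rip.build_consensus(["AC", "AC", "A-"]) == "AC"

    def test_fewer_than_two_copies_rejected(self):
        with pytest.raises(ValueError):
            rip.build_consensus(["ACGT"])


class TestCallRipSites:
    def test_plus_strand_c_to_t(self):
        fam = _prealigned(["ACGA", "ATGA"])
        fam.consensus = "ACGA"
        sites = rip.call_rip_sites(fam)
        assert len(sites) == 1
        s = sites[0]
        assert (s.column, s.strand, s.context) == (1, "+", "CpG")
        assert s.position == 101  # copy c2 starts at 100

    def test_g_to_a_reported_on_minus_strand(self):
        fam = _prealigned(["TCGT", "TCAT"])
        fam.consensus = "TCGT"
        sites = rip.call_rip_sites(fam)
        assert len(sites) == 1
        s = sites[0]
        assert (s.column, s.strand, s.context) == (2, "-", "CpG")

    def test_identical_copies_yield_no_sites(self):
        fam = _prealigned(["ACGT", "ACGT", "ACGT"])
        assert rip.call_rip_sites(fam) == []

    def test_gap_neighbour_skipped(self):
        fam = _prealigned(["AC-A", "AT-A"])
        fam.consensus = "AC-A"
        assert rip.call_rip_sites(fam) == []

    def test_each_copy_counts_independently(self):
        fam = _prealigned(["ACGA", "ATGA", "ATGA", "ATGA"])
        sites = rip.call_rip_sites(fam)
        assert len(sites) == 3

    def test_minus_strand_copy_positions_map_back_to_plus(self):
        # copy on '-' strand: alignment in copy orientation, genome
        # coordinate counted from the interval's right edge
        copies = [
            ("a", "chr1", 0, 4, "+", "ACGA"),
            ("b", "chr1", 10, 14, "-", "ATGA"),
        ]
        fam = rip.family_from_prealigned("f", copies)
        fam.consensus = "ACGA"
        (site,) = rip.call_rip_sites(fam)
        assert site.position == 12  # end-1-offset = 14-1-1
        assert site.strand == "-"

    def test_highest_gc_model(self):
        fam = _prealigned(["ACGA", "ATGA"])
        sites = rip.call_rip_sites(fam, model="highest-gc")
        assert len(sites) == 1


class TestSpectrum:
    def test_fraction_cg_to_ta(self):
        fam = _prealigned(["ACGTACGT", "ATGTACGC"])
        # consensus = copy1 orientation: C->T at col 1, T->C at col 7
        fam.consensus = "ACGTACGT"
        spec = rip.mutation_spectrum([fam])
        assert spec.total == 2
        assert spec.counts["CG_TA"] == 1
        assert spec.counts["AT_GC"] == 1

    def test_planted_three_to_one_ratio(self):
        fam = _prealigned(["CACACATT", "TATATATT"])
        fam.consensus = "CACACATT"
        spec = rip.mutation_spectrum([fam])
        assert spec.total == 3
        assert spec.fraction_CG_to_TA == pytest.approx(1.0)

    def test_no_substitutions(self):
        fam = _prealigned(["ACGT", "ACGT"])
        spec = rip.mutation_spectrum([fam])
        assert spec.total == 0
        assert spec.fraction_CG_to_TA is None
        assert spec.fractions == {}


class TestPreference:
    def test_all_cpg(self):
        fam = _prealigned(["ACGA", "ATGA"])
        sites = rip.call_rip_sites(fam)
        assert rip.dinucleotide_preference(sites) == {"CpG": 1.0}

    def test_even_split(self):
        fam = _prealigned(["CACGAA", "TACGAA", "CATGAA"])
        sites = rip.call_rip_sites(fam)  # one CpA event, one CpG event
        pref = rip.dinucleotide_preference(sites)
        assert pref == {"CpA": 0.5, "CpG": 0.5}
        assert rip.dinucleotide_counts(sites) == {"CpA": 1, "CpG": 1}

    def test_empty(self):
        assert rip.dinucleotide_preference([]) == {}


class TestRipIndices:
    def test_hand_counted_example(self):
        ri = rip.rip_indices("TACATGAT")
        assert ri.product == pytest.approx(0.5)
        assert ri.substrate == pytest.approx(2.0)
        assert ri.cri == pytest.approx(-1.5)

    def test_undefined_when_denominators_vanish(self):
        ri = rip.rip_indices("CCCC")
        assert ri.product is None and ri.substrate is None and ri.cri is None

    def test_matches_brute_force_counter(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            ri = rip.rip_indices(seq)
            apt = _brute_dinucleotide(seq, "AT")
            denom = _brute_dinucleotide(seq, "AC") + _brute_dinucleotide(seq, "GT")
            if apt:
                assert ri.product == pytest.approx(
                    _brute_dinucleotide(seq, "TA") / apt
                )
            if denom:
                expected = (
                    _brute_dinucleotide(seq, "CA")
                    + _brute_dinucleotide(seq, "TG")
                ) / denom
                assert ri.substrate == pytest.approx(expected)


class TestWindowedTracks:
    def test_window_tiling(self):
        seq = "ACGT" * 250  # 1000 bp
        tracks = rip.windowed_tracks("chr1", seq, window=500, step=100)
        assert len(tracks) == 6
        assert [t.start for t in tracks] == [0, 100, 200, 300, 400, 500]

    def test_tail_window_flag(self):
        seq = "A" * 1050
        no_tail = rip.windowed_tracks("chr1", seq, window=500, step=100)
        with_tail = rip.windowed_tracks(
            "chr1", seq, window=500, step=100, include_tail=True
        )
        assert len(with_tail) == len(no_tail) + 1
        assert with_tail[-1].end == 1050

    def test_event_counts_per_window(self):
        seq = "ACGT" * 250
        tracks = rip.windowed_tracks(
            "chr1", seq, rip_positions=[50, 550], mc_positions=[99],
            window=500, step=100,
        )
        # events fall in every window whose [start, end) contains them
        assert [t.rip_site_count for t in tracks] == [1, 1, 1, 1, 1, 1]
        assert [t.mc_count for t in tracks] == [1, 0, 0, 0, 0, 0]

    def test_indices_match_direct_computation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        for t in rip.windowed_tracks("chr1", seq):
            direct = rip.rip_indices(seq[t.start : t.end])
            assert t.indices.cri == direct.cri

    def test_oversized_window_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert rip.windowed_tracks("chr1", "ACGT", window=500) == []


class TestFamilyAlignment:
    def test_indels_merge_into_shared_columns(self):
        copies = [
            ("a", "chr1", 0, 10, "+", "ACGTACGTAA"),
            ("b", "chr1", 20, 29, "+", "ACGACGTAA"),
            ("c", "chr1", 40, 51, "+", "ACGTTACGTAA"),
        ]
        fam = rip.align_family("f", copies)
        rows = [c.gapped_seq for c in fam.copies]
        assert len({len(r) for r in rows}) == 1
        assert rows[0].replace("-", "") == "ACGTACGTAA"
        assert rows[1].replace("-", "") == "ACGACGTAA"

    def test_inclusion_rule(self):
        long_seq = "ACGT" * 100  # 400 bp
        fam = rip.align_family("f", [
            ("a", "chr1", 0, 400, "+", long_seq),
            ("b", "chr1", 500, 900, "+", long_seq),
        ])
        assert fam.passes_inclusion()
        short = rip.align_family("f", [
            ("a", "chr1", 0, 40, "+", "ACGT" * 10),
            ("b", "chr1", 50, 90, "+", "ACGT" * 10),
        ])
        assert not short.passes_inclusion()

    def test_low_identity_family_excluded(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = "".join(rng.choice(list("ACGT"), size=400))
        fam = rip.family_from_prealigned("f", [
            ("a", "chr1", 0, 400, "+", a), ("b", "chr1", 500, 900, "+", b),
        ])
        assert fam.mean_pairwise_identity() < 0.5
        assert not fam.passes_inclusion()


def test_cri_increases_with_cpa_rip_dosage():
    """Mean CRI rises strictly with rip_rate for TpA-generating (CpA) RIP.

    The product index counts the TpA created when a CpA cytosine mutates,
    and the substrate index loses that CpA, so CRI responds directly to
    CpA-type dosage; CpG-type events instead feed TpG/CpA back into the
    substrate term and are tracked by RIP-site density, not CRI.
    """
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    master = "".join(bases[rng.integers(0, 4, size=5000)])
    weights = {"CpA": 1.0, "CpC": 0.0, "CpG": 0.0, "CpT": 0.0}
    means = []
    for rate in (0.1, 0.3, 0.6):
        mutated, _, _ = apply_rip(
            [(f"c{i}", master) for i in range(5)], rate, weights, seed=123,
        )
        cris = [rip.rip_indices(seq).cri for _, seq in mutated]
        means.append(np.mean([c for c in cris if c is not None]))
    assert means[0] < means[1] < means[2]
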