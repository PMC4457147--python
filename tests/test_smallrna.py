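"""Library summaries, locus scanning and milRNA/disiRNA classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defensescan import smallrna as sm
from defensescan.fold import BundledFolder
from defensescan.io import BedRecord
from defensescan.rip import revcomp


def _reads(chrom, specs):
    """specs: (start, end, strand, count) tuples -> sorted BedRecords."""
    recs = [
        BedRecord(chrom, s, e, f"u{i}", c, strand)
        for i, (s, e, strand, c) in enumerate(specs)
    ]
    return sorted(recs, key=lambda r: (r.chrom, r.start))


class TestLibrarySummaries:
    def test_collapse_unique(self):
        table = sm.collapse_unique(["AC", "AC", "GT"])
        assert table.counts == {"AC": 2, "GT": 1}
        assert table.total_reads == 3
        assert sm.collapse_unique([]).counts == {}

    def test_collapse_matches_brute_force(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=4)) for _ in range(300)]
        table = sm.collapse_unique(seqs)
        assert table.counts == {s: seqs.count(s) for s in set(seqs)}

    def test_partition_identity_and_percentages(self):
        a = sm.collapse_unique(["AA", "CC", "GG"])
        b = sm.collapse_unique(["CC", "TT"])
        out = sm.partition_libraries(a, b)
        assert out["shared"] == 1
        assert out["a_specific"] == 2
        assert out["b_specific"] == 1
        assert out["total_unique"] == 4
        assert out["shared_pct"] == 25.0

    def test_partition_extremes(self):
        a = sm.collapse_unique(["AA", "CC"])
        assert sm.partition_libraries(a, a)["shared_pct"] == 100.0
        b = sm.collapse_unique(["TT"])
        assert sm.partition_libraries(a, b)["shared"] == 0

    @given(
        st.sets(st.text(alphabet="ACGT", min_size=2, max_size=6)),
        st.sets(st.text(alphabet="ACGT", min_size=2, max_size=6)),
    )
    @settings(deadline=None, max_examples=50)
    def test_partition_counts_cover_the_union(self, seqs_a, seqs_b):
        a = sm.collapse_unique(sorted(seqs_a))
        b = sm.collapse_unique(sorted(seqs_b))
        out = sm.partition_libraries(a, b)
        assert (
            out["shared"] + out["a_specific"] + out["b_specific"]
            == len(seqs_a | seqs_b)
        )

    def test_length_filter_inclusive_bounds(self):
        reads = ["A" * n for n in (17, 18, 25, 30, 31)]
        kept = sm.length_filter(reads)
        assert sorted(len(r) for r in kept) == [18, 25, 30]
        assert sm.length_filter([]) == []

    def test_tpm(self):
        assert sm.tpm([5]) == [1e6]
        assert sm.tpm([1, 3]) == [250_000.0, 750_000.0]
        values = sm.tpm([3, 7, 11, 19])
        assert sum(values) == pytest.approx(1e6)
        with pytest.raises(ValueError):
            sm.tpm([])

    def test_five_prime_bias(self):
        reads = ["T" * 20] * 6 + ["A" * 20] * 3 + ["C" * 20]
        bias = sm.five_prime_bias(reads)
        assert bias == {"A": 0.3, "C": 0.1, "U": 0.6}
        assert sm.five_prime_bias([]) == {}


class TestScanLoci:
    def test_dense_cluster_retained(self):
        # 30 reads spread over a 100 bp span -> 300 reads/kb
        specs = [(1000 + 2 * i, 1000 + 2 * i + 21, "+", 1) for i in range(30)]
        specs[-1] = (1079, 1100, "+", 1)
        (locus,) = sm.scan_loci(_reads("chr1", specs), min_density=270)
        assert locus.density == pytest.approx(300.0)
        assert locus.length == 100

    def test_sparse_cluster_discarded(self):
        specs = [(1000 + 20 * i, 1000 + 20 * i + 20, "+", 1) for i in range(5)]
        assert sm.scan_loci(_reads("chr1", specs), min_density=60,
                            min_reads=1) == []

    def test_empty_input(self):
        assert sm.scan_loci([]) == []

    def test_unsorted_input_rejected(self):
        recs = [
            BedRecord("chr1", 500, 520, "a", 1, "+"),
            BedRecord("chr1", 100, 120, "b", 1, "+"),
        ]
        with pytest.raises(ValueError, match="sort"):
            sm.scan_loci(recs)

    def test_gap_splits_loci(self):
        specs = [(0, 20, "+", 20), (25, 45, "+", 20), (200, 220, "+", 20)]
        loci = sm.scan_loci(_reads("chr1", specs), min_density=60, max_gap=50)
        assert len(loci) == 2

    def test_multimap_weighting(self):
        recs = [
            BedRecord("chr1", 0, 20, "m", 2, "+"),
            BedRecord("chr1", 10, 30, "m", 2, "+"),   # same name: 2 hits
            BedRecord("chr1", 15, 35, "u", 10, "+"),
        ]
        (frac,) = sm.scan_loci(recs, min_density=1, min_reads=1,
                               multimap="fractional")
        assert frac.total_reads == pytest.approx(12.0)
        (uniq,) = sm.scan_loci(recs, min_density=1, min_reads=1,
                               multimap="unique")
        assert uniq.total_reads == pytest.approx(10.0)
        (every,) = sm.scan_loci(recs, min_density=1, min_reads=1,
                                multimap="all")
        assert every.total_reads == pytest.approx(14.0)


def _hairpin_genome(locus_len=100, flank=80, seed=0):
    """Genome with one planted hairpin spanning locus +/- flank."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    prefix = "".join(bases[rng.integers(0, 4, size=2000)])
    arm_len = (locus_len + 2 * flank - 20) // 2
    arm = "".join(bases[rng.integers(0, 4, size=arm_len)])
    loop = "".join(bases[rng.integers(0, 4, size=locus_len + 2 * flank - 2 * arm_len)])
    hairpin = arm + loop + revcomp(arm)
    suffix = "".join(bases[rng.integers(0, 4, size=2000)])
    start = len(prefix) + flank          # locus start
    return {"chr1": prefix + hairpin + suffix}, start


class TestCallMilrna:
    def _locus(self, genome, start, plus, minus, locus_len=100):
        mature = (start + 5, start + 26)
        specs = [(mature[0], mature[1], "+", plus - 5)]
        specs += [(start + 30 + i, start + 30 + i + 20, "+", 1) for i in range(5)]
        specs += [(start + 40, start + 60, "-", minus)] if minus else []
        reads = _reads("chr1", specs)
        (locus,) = sm.scan_loci(reads, min_density=60, min_reads=1)
        return locus

    def test_planted_hairpin_locus_accepted(self):
        genome, start = _hairpin_genome()
        locus = self._locus(genome, start, plus=60, minus=2)
        out = sm.call_milrna(locus, genome, folder=BundledFolder())
        assert out.classification == "milRNA"
        assert out.hairpin.mfe <= -20.0
        assert out.hairpin.mfei > 0.8
        assert out.hairpin.mature_on_stem

    def test_weak_strand_bias_rejected_before_folding(self):
        genome, start = _hairpin_genome()
        locus = self._locus(genome, start, plus=300, minus=40)
        assert locus.strand_ratio == pytest.approx(7.5)
        out = sm.call_milrna(locus, genome, folder=BundledFolder())
        assert out.classification == "none"
        assert out.hairpin is None  # criterion 1 fails first, no fold done

    def test_low_density_rejected(self):
        genome, start = _hairpin_genome()
        locus = self._locus(genome, start, plus=60, minus=2)
        out = sm.call_milrna(
            locus, genome, folder=BundledFolder(), min_density=1e6
        )
        assert out.classification == "none"

    def test_non_hairpin_sequence_rejected_by_energy(self, rng):
        genome = {"chr1": "".join(rng.choice(list("AC"), size=4000))}
        locus = self._locus(genome, 2000, plus=60, minus=2)
        out = sm.call_milrna(locus, genome, folder=BundledFolder())
        # A/C-only sequence cannot pair at all: MFE 0, criterion 4 fails
        assert out.classification == "none"
        assert out.hairpin.mfe == 0.0

    def test_mfei_gate(self):
        genome, start = _hairpin_genome()
        locus = self._locus(genome, start, plus=60, minus=2)
        out = sm.call_milrna(
            locus, genome, folder=BundledFolder(), mfei_min=1e9
        )
        assert out.classification == "none"


class TestCallDisirna:
    def _locus(self, plus, minus, length=500):
        return sm.SmallRnaLocus("chr1", 0, length, plus, minus)

    def test_balanced_dense_locus_accepted(self):
        locus = self._locus(30, 28)
        assert locus.strand_ratio == pytest.approx(30 / 28)
        assert locus.density == pytest.approx(116.0)
        assert sm.call_disirna(locus).classification == "disiRNA"

    def test_strand_biased_locus_rejected(self):
        locus = self._locus(30, 2)
        assert locus.strand_ratio == 15.0
        assert sm.call_disirna(locus).classification == "none"

    def test_sparse_locus_rejected(self):
        locus = self._locus(3, 3)
        assert locus.density == pytest.approx(12.0)
        assert sm.call_disirna(locus).classification == "none"

    def test_milrna_priority_preserved(self):
        locus = self._locus(30, 28)
        locus.classification = "milRNA"
        assert sm.call_disirna(locus).classification == "milRNA"

    def test_zero_minor_strand_is_infinite_ratio(self):
        locus = self._locus(30, 0)
        assert locus.strand_ratio == float("inf")


def test_threshold_monotonicity():
    """Raising any acceptance threshold never yields more accepted loci."""
    genome, start = _hairpin_genome()
    specs = [(start + 5, start + 26, "+", 55)]
    specs += [(start + 30 + i, start + 30 + i + 20, "+", 1) for i in range(5)]
    specs += [(start + 40, start + 60, "-", 2)]
    reads = _reads("chr1", specs)

    def n_accepted(**kw):
        loci = sm.classify_loci(reads, genome, folder=BundledFolder(), **kw)
        return sum(1 for l in loci if l.classification != "none")

    base = n_accepted()
    assert n_accepted(min_density_mil=1e9, min_density_disi=1e9) <= base
    assert n_accepted(strand_fold=1e9, balance_max=0.0) <= base
    assert n_accepted(mfei_min=1e9, balance_max=0.0) <= base
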