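"""TSS calling, merging, categorization, UTR assignment, promoters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribolens.genome import AnnotatedGenome, FivePrimeTrack, GeneRecord, reverse_complement
from ribolens.quantify import DataError
from ribolens.tss import (
    TSSRecord,
    assign_utr,
    call_tss,
    categorize_tss,
    consensus_scan,
    extract_promoters,
    merge_tss,
    normalize_tracks,
)


def _track(length, plus=(), minus=()):
    t = FivePrimeTrack.zeros(length)
    for pos, v in plus:
        t.plus[pos] = v
    for pos, v in minus:
        t.minus[pos] = v
    return t


class TestNormalize:
    def test_equal_depth_equal_factors(self):
        a = _track(100, plus=[(1, 50), (2, 50)])
        b = _track(100, plus=[(5, 100)])
        na, nb = normalize_tracks(a, b)
        assert na.total == pytest.approx(1e6)
        assert nb.total == pytest.approx(1e6)

    def test_double_depth_half_factor(self):
        a = _track(100, plus=[(1, 200)])
        b = _track(100, plus=[(1, 100)])
        na, nb = normalize_tracks(a, b)
        assert na.plus[1] == nb.plus[1] == pytest.approx(1e6)

    def test_empty_track_raises(self):
        with pytest.raises(DataError):
            normalize_tracks(_track(10), _track(10, plus=[(0, 1)]))


class TestCall:
    def test_ratio_above_threshold_is_candidate(self):
        p = _track(200, plus=[(50, 10)])
        m = _track(200, plus=[(50, 4)])
        recs = call_tss(p, m, min_density=1.0)
        assert [r.position for r in recs] == [50]
        assert recs[0].enrichment_ratio == pytest.approx(10.5 / 4.5)

    def test_ratio_one_rejected(self):
        p = _track(200, plus=[(50, 4)])
        m = _track(200, plus=[(50, 4)])
        assert call_tss(p, m, min_density=1.0) == []

    def test_below_density_floor_rejected(self):
        p = _track(200, plus=[(50, 5)])
        m = _track(200)
        assert call_tss(p, m, min_density=10.0) == []

    def test_non_local_maximum_suppressed(self):
        p = _track(200, plus=[(50, 100), (52, 30)])
        m = _track(200)
        assert [r.position for r in call_tss(p, m, min_density=1.0)] == [50]

    def test_min_ratio_must_exceed_one(self):
        with pytest.raises(DataError):
            call_tss(_track(10), _track(10), min_ratio=1.0)


class TestMerge:
    def test_within_window_collapse(self):
        recs = [
            TSSRecord(100, "+", 3.0, 10.0, supporting_libraries=("a",)),
            TSSRecord(103, "+", 4.0, 20.0, supporting_libraries=("b",)),
        ]
        merged = merge_tss(recs)
        assert len(merged) == 1
        assert merged[0].position == 103  # higher density wins
        assert merged[0].peak_density == pytest.approx(30.0)
        assert merged[0].supporting_libraries == ("a", "b")

    def test_beyond_window_stay_separate(self):
        recs = [TSSRecord(100, "+", 3.0, 10.0), TSSRecord(106, "+", 3.0, 10.0)]
        assert len(merge_tss(recs)) == 2

    def test_strands_never_merge(self):
        recs = [TSSRecord(100, "+", 3.0, 10.0), TSSRecord(100, "-", 3.0, 10.0)]
        assert len(merge_tss(recs)) == 2

    @given(st.lists(st.integers(0, 300), min_size=0, max_size=40),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_separated(self, positions, seed):
        rng = np.random.default_rng(seed)
        recs = [
            TSSRecord(p, rng.choice(["+", "-"]), 3.0, float(rng.integers(1, 50)))
            for p in positions
        ]
        once = merge_tss(recs)
        twice = merge_tss(once)
        assert [(r.position, r.strand, r.peak_density) for r in once] == [
            (r.position, r.strand, r.peak_density) for r in twice
        ]
        for strand in "+-":
            pos = sorted(r.position for r in once if r.strand == strand)
            assert all(b - a > 4 for a, b in zip(pos, pos[1:]))


def _layout_genome(genes, length=4000):
    return AnnotatedGenome("A" * length, genes)


class TestCategorize:
    def setup_method(self):
        self.genome = _layout_genome(
            [
                GeneRecord("gP", 1000, 1600, "+"),
                GeneRecord("gM", 2500, 3100, "-"),
            ]
        )

    def _one(self, pos, strand, density=10.0):
        return TSSRecord(pos, strand, 5.0, density)

    def test_sole_upstream_tss_is_primary(self):
        recs = categorize_tss([self._one(750, "+")], self.genome)
        assert recs[0].category == "P" and recs[0].associated_gene == "gP"

    def test_lower_density_second_tss_is_secondary(self):
        recs = categorize_tss(
            [self._one(750, "+", 10.0), self._one(950, "+", 5.0)], self.genome
        )
        cats = {r.position: r.category for r in recs}
        assert cats == {750: "P", 950: "S"}

    def test_antisense_and_intergenic(self):
        recs = categorize_tss(
            [self._one(1300, "-"), self._one(2, "+")], self.genome
        )
        assert recs[0].category == "A"
        assert recs[1].category == "N"

    def test_internal_beyond_downstream_window(self):
        recs = categorize_tss([self._one(1200, "+")], self.genome)
        assert recs[0].category == "I"  # 200 nt into the gene, past the window

    def test_minus_strand_upstream_is_larger_coordinate(self):
        recs = categorize_tss([self._one(3250, "-")], self.genome)
        assert recs[0].category == "P" and recs[0].associated_gene == "gM"

    def test_every_record_gets_exactly_one_category(self, rng):
        genome, records = _random_layout(rng)
        out = categorize_tss(records, genome)
        assert all(r.category in "PSIAN" for r in out)

    def test_matches_independent_rule_oracle(self, rng):
        for _ in range(60):
            genome, records = _random_layout(rng)
            out = categorize_tss(records, genome)
            expect = _oracle_categories(records, genome)
            assert [r.category for r in out] == expect


def _random_layout(rng, length=3000, n_genes=3, n_tss=8):
    genes = []
    cursor = 300
    for i in range(n_genes):
        glen = int(rng.integers(150, 400)) * 3
        if cursor + glen > length - 200:
            break
        genes.append(
            GeneRecord(f"g{i}", cursor, cursor + glen,
                       "+" if rng.random() < 0.5 else "-")
        )
        cursor += glen + int(rng.integers(50, 400))
    genome = _layout_genome(genes, length)
    records = [
        TSSRecord(int(rng.integers(0, length)), rng.choice(["+", "-"]),
                  5.0, float(rng.integers(1, 100)))
        for _ in range(n_tss)
    ]
    return genome, records


def _oracle_categories(records, genome, upstream=300, downstream=100):
    """Direct per-record reimplementation of the categorization rules."""
    prim = {}
    # role of each record for each gene, computed per gene independently
    gene_windows = {}
    for g in genome.genes:
        members = []
        for i, r in enumerate(records):
            if r.strand != g.strand:
                continue
            rel = (r.position - g.start) if g.strand == "+" else (g.end - 1 - r.position)
            if -upstream < rel <= downstream:  # rel > 0 is downstream of the start
                members.append(i)
        if not members:
            continue

        def rank(i):
            r = records[i]
            upstream_pref = -r.position if g.strand == "+" else r.position
            return (r.peak_density, upstream_pref)

        best = max(members, key=rank)
        gene_windows[g.gene_id] = (best, members)
    cats = []
    for i, r in enumerate(records):
        role = None  # (priority, distance, category, gene)
        for g in genome.genes:
            if g.gene_id in gene_windows:
                best, members = gene_windows[g.gene_id]
                if i in members:
                    cat = "P" if i == best else "S"
                    dist = abs(r.position - (g.start if g.strand == "+" else g.end - 1))
                    cand = ("PS".index(cat), dist, cat, g.gene_id)
                    if role is None or cand < role:
                        role = cand
        if role is not None:
            cats.append(role[2])
            continue
        cat = "N"
        for g in genome.genes:
            if g.start <= r.position < g.end:
                if g.strand == r.strand:
                    cat = "I"
                    break
                cat = "A"
        cats.append(cat)
    return cats


class TestUtrAssignment:
    def setup_method(self):
        seq = list("A" * 500)
        seq[150:200] = list("GC" * 25)
        self.genome = AnnotatedGenome(
            "".join(seq), [GeneRecord("g1", 200, 350, "+"),
                           GeneRecord("g2", 380, 470, "-")]
        )

    def test_plus_strand_length_and_sequence(self):
        recs = [TSSRecord(150, "+", 5.0, 9.0, "P", "g1")]
        utrs = assign_utr(recs, self.genome)
        assert utrs[0].length == 50
        assert utrs[0].sequence == "GC" * 25
        assert not utrs[0].leaderless

    def test_tss_at_start_codon_is_leaderless(self):
        recs = [TSSRecord(200, "+", 5.0, 9.0, "P", "g1")]
        utrs = assign_utr(recs, self.genome)
        assert utrs[0].length == 0 and utrs[0].leaderless

    def test_minus_strand_sequence_is_reverse_complement(self):
        recs = [TSSRecord(479, "-", 5.0, 9.0, "P", "g2")]
        utrs = assign_utr(recs, self.genome)
        assert utrs[0].length == 10
        plus_slice = self.genome.sequence[470:480]
        assert utrs[0].sequence == reverse_complement(plus_slice).replace("T", "U")

    def test_downstream_tss_skipped(self, caplog):
        recs = [TSSRecord(250, "+", 5.0, 9.0, "P", "g1")]
        with caplog.at_level("WARNING"):
            assert assign_utr(recs, self.genome) == []

    def test_non_primary_ignored(self):
        recs = [TSSRecord(150, "+", 5.0, 9.0, "S", "g1")]
        assert assign_utr(recs, self.genome) == []


class TestPromoters:
    def test_planted_minus10_box_found(self):
        seq = list("A" * 300)
        seq[188:194] = list("TATAAT")  # ends 6 nt before the TSS at 200
        genome = AnnotatedGenome("".join(seq), [])
        recs = [TSSRecord(200, "+", 5.0, 9.0)]
        df = extract_promoters(recs, genome, length=50)
        assert (38, 0) in df.iloc[0]["minus10_hits"]

    def test_minus_strand_sequence_reverse_complement(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = AnnotatedGenome(seq, [])
        df = extract_promoters([TSSRecord(100, "-", 5.0, 9.0)], genome, length=50)
        assert df.iloc[0]["sequence"] == reverse_complement(seq[101:151])

    def test_scan_matches_brute_force(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            hits = consensus_scan(seq, "TATAAT", max_mismatch=1)
            brute = []
            for i in range(45):
                mm = sum(1 for a, b in zip(seq[i : i + 6], "TATAAT") if a != b)
                if mm <= 1:
                    brute.append((i, mm))
            assert hits == brute

    def test_contig_edge_truncated_and_flagged(self):
        genome = AnnotatedGenome("ACGT" * 25, [])
        df = extract_promoters([TSSRecord(10, "+", 5.0, 9.0)], genome, length=50)
        assert df.iloc[0]["truncated"]
        assert len(df.iloc[0]["sequence"]) == 10


def test_noise_free_recovery_all_planted_no_extras(small_study):
    from ribolens.synthetic import simulate_drnaseq

    cfg, genome, truth = small_study
    tp, tm = simulate_drnaseq(truth, cfg, exact=True)[0]
    npair = normalize_tracks(tp, tm)
    called = merge_tss(call_tss(*npair, library="x"))
    got = {(r.position, r.strand) for r in called}
    want = {
        (int(p), s) for p, s in zip(truth.tss_positions()["position"],
                                    truth.tss_positions()["strand"])
    }
    assert got == want
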