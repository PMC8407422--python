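"""A-site shifting, metagene/periodicity, occupancy, folding, SD scoring."""

import numpy as np
import pandas as pd
import pytest

from ribolens.genome import AnnotatedGenome, FivePrimeTrack, GeneRecord
from ribolens.quantify import DataError
from ribolens.tss import UTRRecord
from ribolens.utr import (
    PAIRS,
    asite_track,
    fold_mfe,
    metagene,
    position_frequency_matrix,
    sd_score,
    sd_scores,
    te_by_mfe,
    utr_occupancy,
)


class TestAsiteShift:
    def test_plus_strand_shift(self):
        t = FivePrimeTrack.zeros(3000)
        t.plus[1000] = 7
        shifted = asite_track(t, 17)
        assert shifted.plus[1017] == 7 and shifted.plus[1000] == 0

    def test_minus_strand_shift(self):
        t = FivePrimeTrack.zeros(3000)
        t.minus[2000] = 3
        shifted = asite_track(t, 17)
        assert shifted.minus[1983] == 3

    def test_counts_conserved_away_from_edges(self, rng):
        t = FivePrimeTrack.zeros(500)
        t.plus[100:400] = rng.integers(0, 5, size=300)
        t.minus[100:400] = rng.integers(0, 5, size=300)
        assert asite_track(t, 17).total == t.total

    def test_shift_then_reverse_shift_restores(self, rng):
        t = FivePrimeTrack.zeros(500)
        t.plus[100:400] = rng.integers(0, 5, size=300)
        t.minus[100:400] = rng.integers(0, 5, size=300)
        fwd = asite_track(t, 17)
        # reverse: swap strand roles by shifting the other way
        back = FivePrimeTrack(
            np.concatenate([fwd.plus[17:], np.zeros(17)]),
            np.concatenate([np.zeros(17), fwd.minus[:-17]]),
        )
        assert back.allclose(t)


class TestMetagene:
    def test_pure_frame0_gives_unit_fraction(self):
        from ribolens.synthetic import SimulationConfig, generate_genome, simulate_riboseq

        cfg = SimulationConfig(
            genome_length=60_000, n_genes=25, frame0_fraction=1.0,
            library_depth=100_000, utr_ribo_occupancy=(0.0, 0.0), seed=4,
        )
        genome, truth = generate_genome(cfg)
        trk = simulate_riboseq(truth, cfg, exact=True)[(0, 0)]
        prof = metagene(asite_track(trk, cfg.asite_offset), genome)
        assert prof.frame_fractions[0] == pytest.approx(1.0)

    def test_planted_frame_fraction_recovered(self):
        from ribolens.synthetic import SimulationConfig, generate_genome, simulate_riboseq

        cfg = SimulationConfig(
            genome_length=80_000, n_genes=40, frame0_fraction=0.7,
            library_depth=500_000, seed=5,
        )
        genome, truth = generate_genome(cfg)
        trk = simulate_riboseq(truth, cfg)[(0, 0)]
        prof = metagene(asite_track(trk, cfg.asite_offset), genome)
        assert prof.frame_fractions[0] == pytest.approx(0.70, abs=0.05)

    def test_uniform_track_flat_profile(self):
        genes = [GeneRecord(f"g{i}", 500 + 1500 * i, 500 + 1500 * i + 900, "+")
                 for i in range(10)]
        genome = AnnotatedGenome("A" * 20_000, genes)
        t = FivePrimeTrack(np.full(20_000, 5.0), np.zeros(20_000))
        prof = metagene(t, genome)
        assert np.allclose(prof.density, 1.0)

    def test_empty_annotation_raises(self):
        genome = AnnotatedGenome("A" * 1000, [])
        with pytest.raises(DataError):
            metagene(FivePrimeTrack.zeros(1000), genome)


class TestOccupancy:
    def _setup(self):
        gene = GeneRecord("g1", 100, 400, "+")
        genome = AnnotatedGenome("A" * 600, [gene])
        utrs = [UTRRecord("g1", 60, 40, "A" * 40, False)]
        rpf = FivePrimeTrack.zeros(600)
        rna = FivePrimeTrack.zeros(600)
        return genome, utrs, rpf, rna

    def test_hand_computed_ratio(self):
        genome, utrs, rpf, rna = self._setup()
        rpf.plus[60:100] = 5.0   # UTR RPF density 5/nt
        rna.plus[60:100] = 10.0  # UTR RNA density 10/nt
        rpf.plus[115:385] = 4.0  # trimmed CDS window
        rna.plus[100:400] = 4.0
        df, summary = utr_occupancy(rpf, rna, utrs, genome)
        assert df.iloc[0]["utr_ratio"] == pytest.approx(0.5)
        assert df.iloc[0]["cds_ratio"] == pytest.approx(1.0)

    def test_identical_tracks_give_unit_ratios(self):
        genome, utrs, rpf, rna = self._setup()
        rpf.plus[:] = 3.0
        df, summary = utr_occupancy(rpf, rpf.copy(), utrs, genome)
        assert np.allclose(df["utr_ratio"], df["cds_ratio"])
        assert summary["wilcoxon_p"] == pytest.approx(1.0)

    def test_short_utrs_excluded(self):
        genome, utrs, rpf, rna = self._setup()
        utrs[0] = UTRRecord("g1", 95, 5, "A" * 5, True)
        rpf.plus[:] = rna.plus[:] = 1.0
        with pytest.raises(DataError):
            utr_occupancy(rpf, rna, utrs, genome)

    def test_condition_shift_recovered_from_simulator(self):
        """The planted UTR-occupancy contrast between conditions is seen in
        the per-gene median relative occupancy."""
        from ribolens.synthetic import SimulationConfig, generate_genome, simulate_riboseq, simulate_rnaseq
        from ribolens.tss import UTRRecord as U

        cfg = SimulationConfig(
            genome_length=120_000, n_genes=80, library_depth=1_000_000,
            internal_tss_prob=0.0, seed=8, utr_ribo_occupancy=(0.5, 1.4),
        )
        genome, truth = generate_genome(cfg)
        utrs = [
            U(r.gene_id, int(r.tss), int(r.utr_length), "", int(r.utr_length) < 5)
            for r in truth.genes.itertuples() if r.tss >= 0 and r.utr_length >= 10
        ]
        med = {}
        for ci in (0, 1):
            rpf = asite_track(simulate_riboseq(truth, cfg)[(ci, 0)], cfg.asite_offset)
            rna = simulate_rnaseq(truth, cfg)[(ci, 0)]
            _, summary = utr_occupancy(rpf, rna, utrs, genome)
            med[ci] = summary["median_relative_occupancy"]
        assert med[0] == pytest.approx(0.5, rel=0.25)
        assert med[1] == pytest.approx(1.4, rel=0.25)
        assert med[1] / med[0] == pytest.approx(2.8, rel=0.2)


# --- folding ----------------------------------------------------------------

def _enumerate_max_pairs(seq):
    """Exhaustive enumeration of nested structures (oracle for short RNA)."""
    n = len(seq)

    def best(i, j):
        if j - i <= 3:
            return 0
        # position j-1 unpaired, or paired with some k
        result = best(i, j - 1)
        for k in range(i, j - 4):
            if (seq[k], seq[j - 1]) in PAIRS:
                result = max(result, best(i, k) + best(k + 1, j - 1) + 1)
        return result

    return best(0, n)


class TestFold:
    def test_too_short_to_pair(self):
        assert fold_mfe("ACGU").energy == 0

    def test_simple_hairpin(self):
        res = fold_mfe("GGGAAAACCC")
        assert res.energy == -3
        assert len(res.pairs) == 3

    def test_invalid_characters_rejected(self):
        with pytest.raises(DataError):
            fold_mfe("ACGX")

    def test_pairs_are_nested_and_loop_respected(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 40))))
            res = fold_mfe(seq)
            for i, j in res.pairs:
                assert j - i > 3
                assert (seq[i], seq[j]) in PAIRS
            for (i, j) in res.pairs:
                for (k, l) in res.pairs:
                    assert not (i < k < j < l)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(4, 13))))
            assert -fold_mfe(seq).energy == _enumerate_max_pairs(seq)


class TestTeByMfe:
    def test_planted_structure_effect_detected(self, rng):
        n = 200
        energies = pd.Series(rng.uniform(-40, 0, size=n),
                             index=[f"g{i}" for i in range(n)])
        te = pd.Series(rng.normal(0, 0.5, size=n), index=energies.index)
        te[energies < energies.median()] -= 1.0  # structured UTRs reduce TE
        res = te_by_mfe(energies, te)
        assert res["p"] < 0.05
        assert res["median_difference"] == pytest.approx(-1.0, abs=0.4)

    def test_identical_distributions_no_shift(self, rng):
        energies = pd.Series(rng.uniform(-40, 0, 100),
                             index=[f"g{i}" for i in range(100)])
        te = pd.Series(np.zeros(100), index=energies.index)
        assert te_by_mfe(energies, te)["median_difference"] == 0

    def test_threshold_beyond_all_values_raises(self, rng):
        energies = pd.Series(rng.uniform(-40, 0, 20),
                             index=[f"g{i}" for i in range(20)])
        te = pd.Series(np.zeros(20), index=energies.index)
        with pytest.raises(DataError):
            te_by_mfe(energies, te, threshold=-1000.0)


class TestSdScore:
    def test_perfect_sd_scores_six(self):
        seq = "A" * 10 + "AGGAGG" + "A" * 9  # motif at -15..-10
        assert sd_score(seq)[0] == 6

    def test_poly_c_scores_zero(self):
        assert sd_score("C" * 25)[0] == 0

    def test_partial_complement(self):
        seq = "C" * 12 + "GGAGG" + "C" * 8
        assert sd_score(seq)[0] == 5

    def test_short_sequence_flagged(self):
        score, flagged = sd_score("AGGAGG")
        assert flagged

    def test_seeded_high_te_cohort_scores_higher(self, rng):
        high = []
        low = []
        for _ in range(60):
            bases = rng.choice(list("ACU"), size=30)  # G-free background
            s = "".join(bases)
            high.append(s[:12] + "AGGAGG" + s[18:])
            low.append("".join(rng.choice(list("ACU"), size=30)))
        dh = sd_scores({f"h{i}": s for i, s in enumerate(high)})
        dl = sd_scores({f"l{i}": s for i, s in enumerate(low)})
        assert dh["sd_score"].mean() - dl["sd_score"].mean() > 2
        _, info_h = position_frequency_matrix(high)
        _, info_l = position_frequency_matrix(low)
        # SD columns (-18..-13) are sharply conserved in the seeded cohort
        assert info_h.loc[-18:-13].mean() > info_l.loc[-18:-13].mean() + 1
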