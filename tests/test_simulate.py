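"""Forward simulator: break initiation, repair patterns, MMR, segregation,
replication, phenotype, cohort driver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hetdna as h
from hetdna.genome import ORIGIN_B, ORIGIN_R, parental_chromatids
from hetdna.simulate import (
    BreakDescription,
    Mechanism,
    MMRMode,
    MotherCellState,
    Timing,
    apply_repair,
)

from conftest import make_colony_from_state


@pytest.fixture()
def cfg():
    return h.SimConfig(seed=0, p_branch_migration=0.0, p_template_switch=0.0)


class TestInitiateBreak:
    def test_g1_breaks_both_sisters_at_same_position(self, full_map):
        cfg = h.SimConfig(seed=0, p_g1=1.0)
        rng = np.random.default_rng(0)
        brk = h.initiate_break(cfg, full_map, rng)
        assert brk.timing == Timing.G1
        assert len(brk.chromatid_indices) == 2
        assert brk.chromatid_indices in ((0, 1), (2, 3))

    def test_g2_breaks_one_chromatid(self, full_map):
        cfg = h.SimConfig(seed=0, p_g1=0.0)
        rng = np.random.default_rng(0)
        brk = h.initiate_break(cfg, full_map, rng)
        assert brk.timing == Timing.G2
        assert len(brk.chromatid_indices) == 1

    def test_recipient_homologs_equally_susceptible(self, full_map):
        """Both homologs recipients at 1:1 within the binomial 99% CI."""
        cfg = h.SimConfig(seed=0)
        rng = np.random.default_rng(123)
        n = 10_000
        n_r = sum(
            h.initiate_break(cfg, full_map, rng).recipient_origin == ORIGIN_R
            for _ in range(n)
        )
        half_width = 2.576 * np.sqrt(n * 0.25)
        assert abs(n_r - n / 2) < half_width


class TestRepairPatterns:
    """Mechanism -> strand-pattern contracts on the mother chromatids."""

    def _state(self, full_map, cfg, mech, lengths, d=100_000):
        brk = BreakDescription(Timing.G2, ORIGIN_B, d, (2,))
        return h.simulate_repair(
            brk, mech, cfg, full_map, rng=np.random.default_rng(7), lengths=lengths
        )

    def test_one_ended_sdsa_unidirectional_het(self, full_map, cfg):
        d = 100_000
        st_ = self._state(
            full_map, cfg, Mechanism.ONE_ENDED_SDSA, {"het": 5000, "side": "R"}
        )
        broken = st_.chromatids[2]
        in_tract = (full_map.positions > d) & (full_map.positions <= d + 5000)
        assert np.array_equal(broken.mismatches(), in_tract)
        for i in (0, 1, 3):
            assert st_.chromatids[i].mismatch_count() == 0

    def test_dhj_co_zero_lengths_pure_coupling_switch(self, full_map, cfg):
        st_ = self._state(
            full_map,
            cfg,
            Mechanism.DHJ_RESOLUTION_CO,
            {"het_proximal": 0, "het_distal": 0},
        )
        for c in st_.chromatids:
            assert c.mismatch_count() == 0
        # distal (telomere-ward) arms exchanged between the two products
        d = 100_000
        distal = full_map.positions < d  # DSB left of the centromere
        b_product = st_.chromatids[2]
        donor_product = st_.chromatids[0]
        assert (b_product.watson[distal] == ORIGIN_R).all()
        assert (b_product.watson[~distal] == ORIGIN_B).all()
        assert (donor_product.watson[distal] == ORIGIN_B).all()

    def test_gap_repair_full_conversion_no_mismatch(self, full_map, cfg):
        d = 100_000
        st_ = self._state(
            full_map,
            cfg,
            Mechanism.GAP_REPAIR,
            {"gap": 5000, "side": "R", "gap_het_side": None},
        )
        broken = st_.chromatids[2]
        in_gap = (full_map.positions > d) & (full_map.positions <= d + 5000)
        assert (broken.watson[in_gap] == ORIGIN_R).all()
        assert (broken.crick[in_gap] == ORIGIN_R).all()
        assert broken.mismatch_count() == 0

    def test_two_ended_sdsa_strand_switch_at_break(self, full_map, cfg):
        d = 100_000
        st_ = self._state(
            full_map,
            cfg,
            Mechanism.TWO_ENDED_SDSA,
            {"het_left": 4000, "het_right": 4000},
        )
        broken = st_.chromatids[2]
        left = (full_map.positions >= d - 4000) & (full_map.positions < d)
        right = (full_map.positions > d) & (full_map.positions <= d + 4000)
        # donor sequence on opposite strands on the two sides
        assert (broken.crick[left] == ORIGIN_R).all()
        assert (broken.watson[left] == ORIGIN_B).all()
        assert (broken.watson[right] == ORIGIN_R).all()
        assert (broken.crick[right] == ORIGIN_B).all()

    def test_bir_donor_homozygosity_to_telomere(self, full_map, cfg):
        d = 100_000
        st_ = self._state(full_map, cfg, Mechanism.BIR, {})
        broken = st_.chromatids[2]
        distal = full_map.positions < d
        assert (broken.watson[distal] == ORIGIN_R).all()
        assert (broken.crick[distal] == ORIGIN_R).all()
        assert broken.mismatch_count() == 0
        # donor untouched
        assert st_.chromatids[0].mismatch_count() == 0
        assert (st_.chromatids[0].watson == ORIGIN_R).all()

    def test_unknown_mechanism_rejected(self, full_map, cfg):
        with pytest.raises(ValueError):
            self._state(full_map, cfg, "NOT_A_MECHANISM", {})

    def test_dsb_outside_chromosome_rejected(self, full_map, cfg):
        brk = BreakDescription(Timing.G2, ORIGIN_B, 10**9, (2,))
        with pytest.raises(h.InvalidParameterError):
            h.simulate_repair(
                brk,
                Mechanism.ONE_ENDED_SDSA,
                cfg,
                full_map,
                rng=np.random.default_rng(0),
                lengths={"het": 1000, "side": "R"},
            )


class TestApplyMMR:
    def _het_chromatid(self, full_map, cfg):
        d = 100_000
        st_ = h.simulate_repair(
            BreakDescription(Timing.G2, ORIGIN_B, d, (2,)),
            Mechanism.ONE_ENDED_SDSA,
            cfg,
            full_map,
            rng=np.random.default_rng(1),
            lengths={"het": 5000, "side": "R"},
        )
        return st_.chromatids[2]

    def test_conversion_writes_donor_on_both_strands(self, full_map, cfg):
        chrom = self._het_chromatid(full_map, cfg)
        mm = chrom.mismatches()
        out = h.apply_mmr(chrom, MMRMode.CONVERSION, donor_origin=ORIGIN_R)
        assert out.mismatch_count() == 0
        assert (out.watson[mm] == ORIGIN_R).all()
        assert (out.crick[mm] == ORIGIN_R).all()

    def test_restoration_recreates_parental_chromatid(self, full_map, cfg):
        chrom = self._het_chromatid(full_map, cfg)
        out = h.apply_mmr(chrom, MMRMode.RESTORATION, donor_origin=ORIGIN_R)
        parental = parental_chromatids(full_map)[2]
        assert np.array_equal(out.watson, parental.watson)
        assert np.array_equal(out.crick, parental.crick)

    def test_patchy_mixes_conversion_and_restoration(self, full_map, cfg):
        chrom = self._het_chromatid(full_map, cfg)
        out = h.apply_mmr(
            chrom,
            MMRMode.PATCHY,
            donor_origin=ORIGIN_R,
            patch_median=1000.0,
            marker_map=full_map,
            rng=np.random.default_rng(3),
        )
        mm = chrom.mismatches()
        assert out.mismatch_count() == 0
        repaired = out.watson[mm]
        assert (repaired == ORIGIN_R).any() and (repaired == ORIGIN_B).any()

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_none_is_identity(self, seed):
        """With MMR off (mlh1), the mismatch count never changes."""
        rng = np.random.default_rng(seed)
        w = rng.integers(0, 2, 50).astype(np.int8)
        c = rng.integers(0, 2, 50).astype(np.int8)
        chrom = h.Chromatid(w, c, ORIGIN_R)
        out = h.apply_mmr(chrom, MMRMode.NONE)
        assert np.array_equal(out.watson, w) and np.array_equal(out.crick, c)


class TestSegregationReplication:
    def test_each_daughter_gets_one_chromatid_per_centromere(self, full_map):
        state = MotherCellState(full_map, parental_chromatids(full_map))
        d1, d2, _ = h.segregate_daughters(state, np.random.default_rng(0))
        for d in (d1, d2):
            origins = sorted(c.centromere_origin for c in d.chromatids)
            assert origins == [ORIGIN_R, ORIGIN_B]

    def test_no_event_mother_both_daughters_single_copy(self, full_map):
        state = MotherCellState(full_map, parental_chromatids(full_map))
        d1, d2, sectored = h.segregate_daughters(state, np.random.default_rng(0))
        assert not sectored
        assert d1.sup4_copies == d2.sup4_copies == 1.0

    def test_co_mother_sectored_segregation_two_and_zero(self, full_map, cfg):
        brk = BreakDescription(Timing.G2, ORIGIN_B, 100_000, (2,))
        state = h.simulate_repair(
            brk,
            Mechanism.DHJ_RESOLUTION_CO,
            cfg,
            full_map,
            rng=np.random.default_rng(2),
            lengths={"het_proximal": 2000, "het_distal": 2000},
        )
        d1, d2, sectored = h.segregate_daughters(state, np.random.default_rng(0))
        assert sectored
        assert d1.sup4_copies == 2.0 and d2.sup4_copies == 0.0
        assert d1.sup4_copies + d2.sup4_copies == 2.0  # conservation

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_conservation_through_replication(self, seed):
        """The 8 granddaughter homologs are exactly the 8 mother strands."""
        m = h.make_marker_map(200, 100_000, 1.0, seed=5, centromere_position=50_000)
        cfg = h.SimConfig(seed=0)
        rng = np.random.default_rng(seed)
        colony = h.simulate_colony(cfg, m, rng)
        mother_strands = sorted(
            s.tobytes()
            for c in colony.mother.chromatids
            for s in (c.watson, c.crick)
        )
        gd_homologs = sorted(
            homolog.tobytes()
            for name in ("W1", "W2", "R1", "R2")
            for homolog in colony.granddaughters[name].homologs
        )
        assert mother_strands == gd_homologs

    def test_homoduplex_chromosome_replicates_identically(self, full_map):
        state = MotherCellState(full_map, parental_chromatids(full_map))
        d1, _, _ = h.segregate_daughters(state, np.random.default_rng(0))
        a, b = h.replicate_to_granddaughters(d1, np.random.default_rng(1))
        assert np.array_equal(np.sort(a.homologs, 0), np.sort(b.homologs, 0))


class TestColonyColor:
    @pytest.mark.parametrize(
        "copies,color", [(0, "red"), (1, "pink"), (2, "white")]
    )
    def test_dosage_phenotype(self, copies, color):
        assert h.colony_color(copies) == color

    def test_invalid_copy_number(self):
        with pytest.raises(h.InvalidParameterError):
            h.colony_color(3)


class TestCohort:
    def test_deterministic_under_seed(self, panel_map):
        cfg = h.SimConfig(seed=9)
        a = h.simulate_cohort(cfg, panel_map, 5, seed=42)
        b = h.simulate_cohort(cfg, panel_map, 5, seed=42)
        for ca, cb in zip(a, b):
            for i in range(4):
                assert np.array_equal(
                    ca.mother.chromatids[i].watson, cb.mother.chromatids[i].watson
                )
            assert ca.mother.brk.position == cb.mother.brk.position

    def test_selection_mode_emits_sectored_colonies_only(self, panel_map):
        cfg = h.SimConfig(seed=2)
        cohort = h.simulate_cohort(cfg, panel_map, 10, seed=3, selection=True)
        for colony in cohort:
            assert colony.sectored
            assert colony.colors == ("white", "red")
            assert colony.daughters[0].sup4_copies == 2.0
            assert colony.daughters[1].sup4_copies == 0.0

    def test_single_mechanism_cohort_ground_truth(self, panel_map):
        """All-SDSA cohort: every repair is a one-ended SDSA NCO."""
        cfg = h.SimConfig(
            seed=4,
            mechanism_weights={Mechanism.ONE_ENDED_SDSA: 1.0},
            p_branch_migration=0.0,
            p_template_switch=0.0,
        )
        cohort = h.simulate_cohort(cfg, panel_map, 100, seed=5, selection=False)
        assert len(cohort) == 100
        for colony in cohort:
            for rep in colony.mother.repairs:
                assert rep.mechanism == Mechanism.ONE_ENDED_SDSA
                assert not rep.is_co
                assert all(t.kind in ("het", "restoration") for t in rep.tracts)
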