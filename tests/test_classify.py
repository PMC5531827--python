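"""Event classification: initiation, outcome, class templates, DSB
intervals, tract lengths, recipient identification."""

import numpy as np
import pytest

import hetdna as h
from hetdna.classify import COMPLEX, call_events, tract_length_from_bounds
from hetdna.genome import ORIGIN_B, ORIGIN_R
from hetdna.simulate import Mechanism

from conftest import dscb_colony, make_colony_from_state, single_repair_colony


def analyze(colony, marker_map, sigma=0.0, seed=0):
    return h.analyze_colony(
        colony, marker_map, np.random.default_rng(seed), noise_sigma=sigma
    )


class TestInitiation:
    def test_single_heteroduplex_chromatid_is_scb(self, full_map, simple_config):
        """One chromatid with a heteroduplex, the illustrated SCB pattern."""
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.ONE_ENDED_SDSA,
            {"het": 6000, "side": "R"},
        )
        call = analyze(colony, full_map).call
        assert call.initiation == "SCB"
        assert len(call.events) == 1

    def test_co_pair_plus_nco_chromatid_is_dscb(self, full_map, simple_config):
        """Two chromatids in the CO configuration plus one NCO chromatid,
        the illustrated DSCB pattern (three altered chromatids)."""
        colony = dscb_colony(
            full_map,
            simple_config,
            [
                (Mechanism.DHJ_RESOLUTION_CO, {"het_proximal": 4000, "het_distal": 4000}),
                (Mechanism.ONE_ENDED_SDSA, {"het": 6000, "side": "R"}),
            ],
        )
        call = analyze(colony, full_map).call
        assert call.initiation == "DSCB"
        outcomes = sorted(ev.outcome for ev in call.events)
        assert outcomes == ["CO", "NCO"]

    def test_no_event_is_none(self, full_map):
        state = h.MotherCellState(full_map, h.parental_chromatids(full_map))
        colony = make_colony_from_state(state)
        assert analyze(colony, full_map).call.initiation == "NONE"

    def test_double_gap_repair_gives_four_zero_and_dscb(
        self, full_map, simple_config
    ):
        """Both sisters converted over the same interval: the 4:0 pattern
        diagnostic of a DSCB."""
        colony = dscb_colony(
            full_map,
            simple_config,
            [
                (Mechanism.GAP_REPAIR, {"gap": 5000, "side": "R", "gap_het_side": None}),
                (Mechanism.GAP_REPAIR, {"gap": 5000, "side": "R", "gap_het_side": None}),
            ],
        )
        call = analyze(colony, full_map).call
        assert call.initiation == "DSCB"
        ratios = [t.ratio for ev in call.events for t in ev.tracts]
        assert ratios == ["4:0", "4:0"]


class TestOutcome:
    def test_coupling_switch_pair_is_co(self, full_map, simple_config):
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.DHJ_RESOLUTION_CO,
            {"het_proximal": 3000, "het_distal": 3000},
        )
        an = analyze(colony, full_map)
        (ev,) = an.call.events
        assert ev.outcome == "CO"
        origins = {
            an.rm.chromatids[k].centromere_origin for k in ev.chromatids
        }
        assert origins == {ORIGIN_R, ORIGIN_B}  # one from each sister pair

    def test_internal_heteroduplex_is_nco(self, full_map, simple_config):
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.ONE_ENDED_SDSA,
            {"het": 6000, "side": "L"},
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.outcome == "NCO"

    def test_terminal_donor_homozygosity_without_partner_is_bir(
        self, full_map, simple_config
    ):
        colony = single_repair_colony(full_map, simple_config, Mechanism.BIR, {})
        (ev,) = analyze(colony, full_map).call.events
        assert ev.outcome == "BIR"
        assert ev.event_class is None
        assert ev.recipient == "B"


MECHANISM_CLASS_CASES = [
    (Mechanism.ONE_ENDED_SDSA, {"het": 5000, "side": "R"}, 1),
    (Mechanism.ONE_ENDED_SDSA, {"het": 5000, "side": "L"}, 1),
    (Mechanism.GAP_REPAIR, {"gap": 5000, "side": "R", "gap_het_side": None}, 2),
    (Mechanism.GAP_REPAIR, {"gap": 5000, "side": "L", "gap_het_side": None}, 2),
    (
        Mechanism.GAP_REPAIR,
        {"gap": 5000, "side": "R", "gap_het_side": "same", "het": 4000},
        3,
    ),
    (Mechanism.DHJ_RESOLUTION_CO, {"het_proximal": 4000, "het_distal": 0}, 4),
    (Mechanism.DHJ_RESOLUTION_CO, {"het_proximal": 0, "het_distal": 4000}, 4),
    (Mechanism.DHJ_RESOLUTION_CO, {"het_proximal": 4000, "het_distal": 4000}, 6),
    (Mechanism.DHJ_RESOLUTION_CO, {"het_proximal": 0, "het_distal": 0}, 7),
    (Mechanism.DHJ_RESOLUTION_NCO, {"conv": 5000, "second_het": 0, "side": "R"}, 8),
    (Mechanism.TWO_ENDED_SDSA, {"het_left": 4000, "het_right": 4000}, COMPLEX),
    (Mechanism.DHJ_DISSOLUTION, {"het_left": 3000, "het_right": 5000}, COMPLEX),
]


class TestAssignClass:
    @pytest.mark.parametrize("mech,lengths,expected", MECHANISM_CLASS_CASES)
    def test_canonical_mechanism_patterns(
        self, full_map, simple_config, mech, lengths, expected
    ):
        colony = single_repair_colony(full_map, simple_config, mech, lengths)
        (ev,) = analyze(colony, full_map).call.events
        assert ev.event_class == expected

    def test_gap_with_opposite_side_het_in_dscb_is_class_5(
        self, full_map, simple_config
    ):
        """Heteroduplex and conversion flanking the break: identified as
        Class 5 when a sister crossover localizes the break at the
        junction (the hybrid pattern alone cannot orient the break)."""
        colony = dscb_colony(
            full_map,
            simple_config,
            [
                (
                    Mechanism.GAP_REPAIR,
                    {"gap": 5000, "side": "R", "gap_het_side": "opposite", "het": 4000},
                ),
                (Mechanism.DHJ_RESOLUTION_CO, {"het_proximal": 4000, "het_distal": 4000}),
            ],
        )
        call = analyze(colony, full_map).call
        classes = sorted(
            str(ev.event_class) for ev in call.events
        )
        assert classes == ["5", "6"]

    def test_isolated_hybrid_tract_reported_class_3(
        self, full_map, simple_config
    ):
        """Without an independent break localization, the hybrid
        conversion+heteroduplex pattern is reported as Class 3."""
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.GAP_REPAIR,
            {"gap": 5000, "side": "R", "gap_het_side": "opposite", "het": 4000},
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.event_class == 3

    def test_symmetric_heteroduplex_on_both_co_chromatids_is_complex(
        self, full_map
    ):
        """Branch migration leaves heteroduplex at the same positions on
        both crossover chromatids — outside the eight templates."""
        cfg = h.SimConfig(
            seed=1,
            p_branch_migration=1.0,
            branch_migration_length=h.LengthDist(kind="fixed", median=4000),
            p_template_switch=0.0,
        )
        colony = single_repair_colony(
            full_map,
            cfg,
            Mechanism.DHJ_RESOLUTION_CO,
            {"het_proximal": 3000, "het_distal": 3000},
        )
        call = analyze(colony, full_map).call
        assert any(ev.event_class == COMPLEX for ev in call.events)

    def test_template_switch_split_tract_is_complex(self, full_map):
        cfg = h.SimConfig(
            seed=1,
            p_branch_migration=0.0,
            p_template_switch=1.0,
            template_switch_length=h.LengthDist(kind="fixed", median=2000),
        )
        colony = single_repair_colony(
            full_map,
            cfg,
            Mechanism.ONE_ENDED_SDSA,
            {"het": 9000, "side": "R"},
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.event_class == COMPLEX


class TestDsbInterval:
    def test_strand_switch_brackets_the_break(self, full_map, simple_config):
        """A bidirectional heteroduplex with a strand switch pins the DSB
        between the two markers flanking the switch."""
        d = 100_000
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.TWO_ENDED_SDSA,
            {"het_left": 4000, "het_right": 4000},
            dsb=d,
        )
        (ev,) = analyze(colony, full_map).call.events
        lo, hi = ev.dsb_interval
        assert lo <= d <= hi
        assert ev.dsb_tight
        # bracket is the marker pair flanking the switch
        below = full_map.positions[full_map.positions < d]
        above = full_map.positions[full_map.positions > d]
        assert lo == below[-1] and hi == above[0]

    def test_unidirectional_tract_spans_edge_to_edge(
        self, full_map, simple_config
    ):
        d = 100_000
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.ONE_ENDED_SDSA,
            {"het": 8000, "side": "R"},
            dsb=d,
        )
        (ev,) = analyze(colony, full_map).call.events
        lo, hi = ev.dsb_interval
        assert not ev.dsb_tight
        t = ev.tracts[0]
        assert (lo, hi) == (t.first_bp, t.last_bp)
        assert d <= lo  # break at the tract's proximal edge is consistent

    def test_no_event_no_interval(self, full_map):
        state = h.MotherCellState(full_map, h.parental_chromatids(full_map))
        call = analyze(make_colony_from_state(state), full_map).call
        assert call.events == []


class TestTractLength:
    def test_direct_formula(self):
        # flanking markers at 1000/9000, outermost affected at 2000/8000
        assert tract_length_from_bounds(2000, 8000, 1000, 9000) == 7000.0

    def test_published_hom_tract_coordinates(self):
        # flanks 54198 & 60701; tract borders 56117 & 57170
        assert tract_length_from_bounds(56_117, 57_170, 54_198, 60_701) == 3778.0

    def test_single_marker_tract_half_flank_distance(self):
        assert tract_length_from_bounds(5000, 5000, 4000, 6000) == 1000.0

    def test_bounds_property_on_simulated_event(self, full_map, simple_config):
        """min tract <= reported <= max tract, against brute-force marker
        recounting."""
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.ONE_ENDED_SDSA,
            {"het": 7000, "side": "R"},
        )
        an = analyze(colony, full_map)
        (ev,) = an.call.events
        t = ev.tracts[0]
        pos = full_map.positions
        inner = t.last_bp - t.first_bp
        below = pos[pos < t.first_bp]
        above = pos[pos > t.last_bp]
        outer = above[0] - below[-1]
        assert inner <= ev.tract_length_bp <= outer
        assert ev.tract_length_bp == (inner + outer) / 2

    def test_co_tract_lengths_summed_over_chromatids(
        self, full_map, simple_config
    ):
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.DHJ_RESOLUTION_CO,
            {"het_proximal": 4000, "het_distal": 4000},
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.outcome == "CO"
        # two per-chromatid tracts, each a few kb: the sum is larger than
        # either side alone could be
        assert ev.tract_length_bp > 6000


class TestRecipient:
    def test_heteroduplex_on_blue_chromatid_names_blue_recipient(
        self, full_map, simple_config
    ):
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.ONE_ENDED_SDSA,
            {"het": 6000, "side": "R"},
            recipient=ORIGIN_B,
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.recipient == "B"

    def test_red_recipient_event(self, full_map, simple_config):
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.GAP_REPAIR,
            {"gap": 5000, "side": "R", "gap_het_side": None},
            recipient=ORIGIN_R,
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.recipient == "R"

    def test_class7_crossover_recipient_ambiguous(self, full_map, simple_config):
        colony = single_repair_colony(
            full_map,
            simple_config,
            Mechanism.DHJ_RESOLUTION_CO,
            {"het_proximal": 0, "het_distal": 0},
        )
        (ev,) = analyze(colony, full_map).call.events
        assert ev.event_class == 7
        assert ev.recipient == "AMBIGUOUS"
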