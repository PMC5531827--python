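"""Shared fixtures: marker maps, colony builders, and the published
worked-example configurations (microarray segment coordinates of the
YYy310-9-5WR sectored colony and the SCB/DSCB illustration patterns).

All fixture data are generated programmatically; the strand layouts of the
worked examples are synthetic reconstructions consistent with the published
segment coordinates and strand-numbering description.
"""

from __future__ import annotations

import numpy as np
import pytest

import hetdna as h
from hetdna.genome import ORIGIN_B, ORIGIN_R
from hetdna.simulate import (
    BreakDescription,
    Colony,
    MotherCellState,
    Timing,
    apply_repair,
    replicate_to_granddaughters,
    segregate_daughters,
)


@pytest.fixture(scope="session")
def full_map():
    """chrV-scale map with every marker assayed (noise-free round trips)."""
    return h.make_marker_map(
        2750,
        577_000,
        1.0,
        seed=3,
        centromere_position=152_000,
        sup4_position=30_000,
    )


@pytest.fixture(scope="session")
def panel_map():
    """chrV-scale map with the 13k/55k assayed fraction (~0.9 kb spacing)."""
    return h.chr5_like_map(11)


@pytest.fixture()
def simple_config():
    """Study-condition config with the complex-event channels off, for
    canonical mechanism -> class checks."""
    return h.SimConfig(seed=1, p_branch_migration=0.0, p_template_switch=0.0)


def off_marker(marker_map, d: int) -> int:
    """Shift a break coordinate off any exact marker position."""
    while marker_map.markers_in(d, d).size:
        d += 1
    return d


def make_colony_from_state(state: MotherCellState, seed: int = 1) -> Colony:
    """Segregate + replicate a prepared mother state into a Colony."""
    rng = np.random.default_rng(seed)
    d1, d2, sectored = segregate_daughters(state, rng, prefer_sectored=True)
    gd = {}
    for prefix, daughter in (("W", d1), ("R", d2)):
        a, b = replicate_to_granddaughters(daughter, rng)
        gd[f"{prefix}1"], gd[f"{prefix}2"] = a, b
    return Colony(state, (d1, d2), gd, sectored, ("n/a", "n/a"))


def single_repair_colony(
    marker_map,
    config,
    mechanism,
    lengths,
    *,
    recipient=ORIGIN_B,
    dsb=100_000,
    seed=1,
) -> Colony:
    """SCB colony with one fully specified repair event."""
    dsb = off_marker(marker_map, dsb)
    broken = (2,) if recipient == ORIGIN_B else (0,)
    brk = BreakDescription(Timing.G2, recipient, dsb, broken)
    state = h.simulate_repair(
        brk,
        mechanism,
        config,
        marker_map,
        rng=np.random.default_rng(seed),
        lengths=lengths,
    )
    return make_colony_from_state(state, seed=seed)


def dscb_colony(
    marker_map,
    config,
    repairs,
    *,
    recipient=ORIGIN_B,
    dsb=100_000,
    seed=1,
) -> Colony:
    """DSCB colony: ``repairs`` is [(mechanism, lengths), (mechanism,
    lengths)] applied to the two broken sisters."""
    dsb = off_marker(marker_map, dsb)
    sisters = (2, 3) if recipient == ORIGIN_B else (0, 1)
    donors = (0, 1) if recipient == ORIGIN_B else (2, 3)
    brk = BreakDescription(Timing.G1, recipient, dsb, sisters)
    state = MotherCellState(
        marker_map, h.parental_chromatids(marker_map), brk=brk
    )
    rng = np.random.default_rng(seed)
    for (mech, lengths), broken, donor in zip(repairs, sisters, donors):
        apply_repair(
            state, broken, donor, mech, config, dsb, rng, lengths=lengths
        )
    return make_colony_from_state(state, seed=seed)


# ---------------------------------------------------------------------------
# the YYy310-9-5WR worked example (microarray segment coordinates)

FIG5A_BOUNDS = (51_915, 53_612, 54_198, 56_117, 57_170, 60_701)
FIG5A_TRANSITIONS = [(51_915, 53_612), (54_198, 56_117), (57_170, 60_701)]


def _origin_steps(positions, steps):
    """Strand vector from [(threshold, origin_below), ..., (None, origin)]."""
    out = np.empty(positions.size, dtype=np.int8)
    remaining = np.ones(positions.size, dtype=bool)
    for threshold, origin in steps:
        if threshold is None:
            out[remaining] = origin
            break
        sel = remaining & (positions <= threshold)
        out[sel] = origin
        remaining &= ~sel
    return out


@pytest.fixture(scope="session")
def yyy310_fixture():
    """Synthetic strand-level reconstruction of the YYy310-9-5WR colony.

    The W1 granddaughter's zygosity pattern follows the published chrV
    segment coordinates (homozygous YJM789 to 51915; heterozygous
    53612-54198; homozygous W303-1A 56117-57170; heterozygous from 60701).
    The eight strands realize a crossover on the chromatids holding
    strands 1-2 and 7-8 and a non-crossover heteroduplex on strands 5-6;
    all strand switches fall inside the published transition gaps, so no
    marker placement can contradict the observed segments.
    """
    B, R = ORIGIN_B, ORIGIN_R
    grid = [p for p in range(1000, 166000, 1000)]
    gaps = [(51_915, 53_612), (54_198, 56_117), (57_170, 60_701)]
    grid = [
        p
        for p in grid
        if not any(lo < p < hi for lo, hi in gaps)
    ]
    positions = np.array(sorted(set(grid) | set(FIG5A_BOUNDS)), dtype=np.int64)
    m = h.MarkerMap(
        chromosome_id="chrV",
        positions=positions,
        assayed=np.ones(positions.size, dtype=bool),
        centromere_position=151_987,
        sup4_marker_index=int(np.searchsorted(positions, 30_000)),
    )
    p = positions
    strands = {
        1: _origin_steps(p, [(54_198, B), (None, R)]),
        2: _origin_steps(p, [(51_915, B), (None, R)]),
        3: np.full(p.size, R, dtype=np.int8),
        4: np.full(p.size, R, dtype=np.int8),
        5: _origin_steps(p, [(51_915, B), (57_170, R), (None, B)]),
        6: np.full(p.size, B, dtype=np.int8),
        7: _origin_steps(p, [(54_198, R), (None, B)]),
        8: _origin_steps(p, [(57_170, R), (None, B)]),
    }
    # granddaughter homolog composition per the strand-numbering scheme
    gds = {
        "W1": (strands[1], strands[5]),
        "W2": (strands[2], strands[6]),
        "R1": (strands[3], strands[7]),
        "R2": (strands[4], strands[8]),
    }
    return m, strands, gds
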