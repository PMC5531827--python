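"""End-to-end colony analysis: readout -> phasing -> reconstruction -> calls.

Ties the forward simulator to the inference stack the way the assay works:
each granddaughter genotype is read out through the microarray emulator,
phased with a spore haplotype, the mother cell is reconstructed from the
four phased granddaughters, and events are classified.

Spore haplotypes are taken as one true homolog of each granddaughter
restricted to the assayed panel (the spore hybridizations are separate
noise sources in the laboratory; here they serve only to fix coupling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .arrays import (
    DEFAULT_THRESHOLDS,
    MEANS_FIG5,
    call_zygosity,
    hybridization_profile,
)
from .classify import ColonyCall, call_events
from .genome import MarkerMap
from .inference import (
    PhasedGranddaughter,
    ReconstructedMother,
    phase_granddaughter,
    reconstruct_mother,
)
from .simulate import Colony, MotherCellState, SimConfig, simulate_cohort

GD_NAMES = ("W1", "W2", "R1", "R2")


@dataclass
class ColonyAnalysis:
    colony: Colony
    phased: dict
    rm: ReconstructedMother
    call: ColonyCall


def phase_colony(
    colony: Colony,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    *,
    noise_sigma: float = 0.1,
    means=MEANS_FIG5,
    thresholds=DEFAULT_THRESHOLDS,
) -> dict:
    """Array readout + spore phasing for the four granddaughters."""
    assayed = marker_map.assayed_indices
    positions = marker_map.assayed_positions
    phased = {}
    for name in GD_NAMES:
        gd = colony.granddaughters[name]
        profile = hybridization_profile(
            gd.zygosity(),
            marker_map,
            means=means,
            noise_sigma=noise_sigma,
            rng=rng,
        )
        calls = call_zygosity(profile, thresholds)
        spore = gd.homologs[int(rng.integers(2))][assayed]
        phased[name] = phase_granddaughter(
            calls, spore, positions, marker_map.centromere_position
        )
    return phased


def analyze_colony(
    colony: Colony,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    *,
    noise_sigma: float = 0.1,
    means=MEANS_FIG5,
    thresholds=DEFAULT_THRESHOLDS,
) -> ColonyAnalysis:
    phased = phase_colony(
        colony,
        marker_map,
        rng,
        noise_sigma=noise_sigma,
        means=means,
        thresholds=thresholds,
    )
    rm = reconstruct_mother(
        phased["W1"], phased["W2"], phased["R1"], phased["R2"], marker_map
    )
    return ColonyAnalysis(colony, phased, rm, call_events(rm))


def run_cohort(
    config: SimConfig,
    marker_map: MarkerMap,
    n_colonies: int,
    *,
    seed: int,
    noise_sigma: float = 0.1,
    selection: bool = True,
) -> list[ColonyAnalysis]:
    """Simulate, read out and analyze a cohort (one seeded RNG stream)."""
    colonies = simulate_cohort(
        config, marker_map, n_colonies, seed=seed, selection=selection
    )
    rng = np.random.default_rng(seed + 1_000_003)
    return [
        analyze_colony(c, marker_map, rng, noise_sigma=noise_sigma)
        for c in colonies
    ]


# ---------------------------------------------------------------------------
# ground-truth helpers (used by the validation suites)


def truth_strand_pairs(colony: Colony, marker_map: MarkerMap) -> dict:
    """Expected reconstructed strand content per (sector, centromere origin).

    Maps ("W"|"R", origin) to the unordered pair of the corresponding
    mother chromatid's strand vectors restricted to the assayed panel —
    what a perfect reconstruction must recover.
    """
    assayed = marker_map.assayed_indices
    out = {}
    for sector, daughter in zip(("W", "R"), colony.daughters):
        for chrom in daughter.chromatids:
            key = (sector, chrom.centromere_origin)
            out[key] = frozenset(
                (chrom.watson[assayed].tobytes(), chrom.crick[assayed].tobytes())
            )
    return out


def reconstructed_strand_pairs(rm: ReconstructedMother) -> dict:
    out = {}
    for chrom in rm.chromatids:
        key = (chrom.sector, chrom.centromere_origin)
        out[key] = frozenset(
            (
                chrom.strand_a.astype(np.int8).tobytes(),
                chrom.strand_b.astype(np.int8).tobytes(),
            )
        )
    return out


def centromere_coupling_readable(
    mother: MotherCellState, marker_map: MarkerMap
) -> bool:
    """Whether the centromere-proximal coupling readout is uncompromised.

    Reconstruction pairs granddaughter homologs by the origin read next to
    the centromere; when a repair tract covers the assayed markers flanking
    the centromere that readout is undefined and the strand assignment is
    genuinely ambiguous (a conversion tract spanning the centromere
    replaces the very sequence the pairing relies on).  Such colonies are
    rare (DSB within a tract length of the centromere) and are excluded
    from round-trip identity checks.
    """
    pos = marker_map.assayed_positions
    cen = marker_map.centromere_position
    left = pos[pos <= cen]
    right = pos[pos >= cen]
    flanks = [int(p) for p in (left[-1:], right[:1]) for p in p]
    for rep in mother.repairs:
        for t in rep.tracts:
            for f in flanks:
                if t.start <= f <= t.end:
                    return False
    return True


def truth_visible_tracts(
    mother: MotherCellState, marker_map: MarkerMap
) -> list[tuple]:
    """Ground-truth repair tracts that contain at least one assayed marker.

    Returns (chromatid_index, kind, first_assayed_bp, last_assayed_bp,
    true_start_bp, true_end_bp) per visible tract.
    """
    assayed_pos = marker_map.assayed_positions
    out = []
    for rep in mother.repairs:
        for t in rep.tracts:
            inside = assayed_pos[(assayed_pos >= t.start) & (assayed_pos <= t.end)]
            if inside.size == 0:
                continue
            out.append(
                (t.chromatid, t.kind, int(inside[0]), int(inside[-1]), t.start, t.end)
            )
    return out
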