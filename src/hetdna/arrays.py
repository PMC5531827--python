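"""SNP-microarray readout emulation and zygosity segmentation.

The study's arrays carry allele-specific oligonucleotides for ~13,000 of
the ~55,000 heterozygous SNPs.  Hybridization ratios are normalized against
a heterozygous control: a heterozygous marker reads ~1 on both allele
channels, the duplicated allele of an LOH region reads ~1.7 and the missing
allele ~0.3 (the running text also quotes 1.5 for the duplicated allele;
both presets are provided, 1.7 is the default).

Readout noise is multiplicative log-normal — the paper publishes no noise
model; sigma=0.1 keeps single-marker miscalls rare, which matches the
paper's ability to resolve single-SNP segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import InvalidParameterError, MarkerMap

HET, HOM_R, HOM_B, UNCALLED = 0, 1, 2, 3
CALL_LABELS = {HET: "HET", HOM_R: "HOM_R", HOM_B: "HOM_B", UNCALLED: "UNCALLED"}

#: hybridization ratio means (het, duplicated allele, absent allele)
MEANS_FIG5 = (1.0, 1.7, 0.3)
#: alternative preset from the running text (duplication ~1.5)
MEANS_TEXT = (1.0, 1.5, 0.3)

#: calling thresholds (hom_high, hom_low): midpoints between the stated means
DEFAULT_THRESHOLDS = (1.35, 0.65)


@dataclass
class HybProfile:
    """Normalized hybridization ratios at the assayed markers."""

    marker_indices: np.ndarray  # indices into the full marker map
    positions: np.ndarray
    ratio_r: np.ndarray
    ratio_b: np.ndarray


@dataclass
class Segment:
    state: int  # HET / HOM_R / HOM_B
    first_index: int  # index into the profile's marker list
    last_index: int
    first_bp: int
    last_bp: int

    @property
    def label(self) -> str:
        return CALL_LABELS[self.state]


@dataclass
class ZygositySegments:
    """Maximal runs of identical zygosity over the called markers.

    ``transitions`` are the uncertainty intervals between adjacent
    segments: (last marker bp of the previous run, first marker bp of the
    next run) — the true transition lies strictly inside.
    """

    segments: list[Segment] = field(default_factory=list)
    transitions: list[tuple[int, int]] = field(default_factory=list)


def hybridization_profile(
    zygosity: np.ndarray,
    marker_map: MarkerMap,
    *,
    means: tuple[float, float, float] = MEANS_FIG5,
    noise_sigma: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> HybProfile:
    """Emulate the two allele-channel ratios at every assayed marker.

    ``zygosity`` is a per-marker code vector over the *full* map (HET=0,
    HOM_R=1, HOM_B=2), e.g. from ``GranddaughterGenotype.zygosity``.
    """
    het, dup, absent = means
    if min(het, dup, absent) <= 0:
        raise InvalidParameterError("ratio means must be positive")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    idx = marker_map.assayed_indices
    z = np.asarray(zygosity)[idx]
    ratio_r = np.full(z.size, het, dtype=float)
    ratio_b = np.full(z.size, het, dtype=float)
    ratio_r[z == HOM_R] = dup
    ratio_b[z == HOM_R] = absent
    ratio_r[z == HOM_B] = absent
    ratio_b[z == HOM_B] = dup
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        ratio_r = ratio_r * np.exp(rng.normal(0.0, noise_sigma, z.size))
        ratio_b = ratio_b * np.exp(rng.normal(0.0, noise_sigma, z.size))
    return HybProfile(
        marker_indices=idx,
        positions=marker_map.positions[idx],
        ratio_r=ratio_r,
        ratio_b=ratio_b,
    )


def call_zygosity(
    profile: HybProfile,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Per-marker calls from the two ratios.

    HOM_X requires ratio_X >= hom_high *and* the other ratio <= hom_low;
    HET requires both ratios inside the het band [hom_low, hom_high];
    anything else (e.g. both ratios high) is UNCALLED.
    """
    hom_high, hom_low = thresholds
    if not hom_high > hom_low:
        raise InvalidParameterError("thresholds must satisfy hom_high > hom_low")
    r, b = profile.ratio_r, profile.ratio_b
    calls = np.full(r.size, UNCALLED, dtype=np.int8)
    in_band = (r >= hom_low) & (r <= hom_high) & (b >= hom_low) & (b <= hom_high)
    calls[in_band] = HET
    calls[(r >= hom_high) & (b <= hom_low)] = HOM_R
    calls[(b >= hom_high) & (r <= hom_low)] = HOM_B
    return calls


def segment_transitions(
    calls: np.ndarray,
    positions: np.ndarray,
    *,
    min_run: int = 1,
) -> ZygositySegments:
    """Maximal runs of identical zygosity; UNCALLED markers are skipped.

    ``min_run`` optionally suppresses runs shorter than that many markers
    (no smoothing by default — the study resolves single-SNP segments).
    Transition intervals are reported as (last bp of run i, first bp of
    run i+1).
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    keep = calls != UNCALLED
    c = calls[keep]
    p = positions[keep]
    orig_idx = np.flatnonzero(keep)
    result = ZygositySegments()
    if c.size == 0:
        return result
    boundaries = np.flatnonzero(np.diff(c) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries, [c.size - 1]))
    runs = [
        Segment(
            state=int(c[s]),
            first_index=int(orig_idx[s]),
            last_index=int(orig_idx[e]),
            first_bp=int(p[s]),
            last_bp=int(p[e]),
        )
        for s, e in zip(starts, ends)
        if (e - s + 1) >= min_run
    ]
    # after dropping short runs, merge adjacent same-state survivors
    merged: list[Segment] = []
    for seg in runs:
        if merged and merged[-1].state == seg.state:
            merged[-1].last_index = seg.last_index
            merged[-1].last_bp = seg.last_bp
        else:
            merged.append(seg)
    result.segments = merged
    result.transitions = [
        (merged[i].last_bp, merged[i + 1].first_bp)
        for i in range(len(merged) - 1)
    ]
    return result


def genotype_to_segments(
    zygosity: np.ndarray,
    marker_map: MarkerMap,
    *,
    means: tuple[float, float, float] = MEANS_FIG5,
    noise_sigma: float = 0.1,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, ZygositySegments]:
    """Convenience: genotype -> profile -> calls -> segments."""
    profile = hybridization_profile(
        zygosity, marker_map, means=means, noise_sigma=noise_sigma, rng=rng
    )
    calls = call_zygosity(profile, thresholds)
    return calls, segment_transitions(calls, profile.positions)
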