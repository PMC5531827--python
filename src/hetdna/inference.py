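"""Reconstruction of the mother cell's eight DNA strands.

Each sectored colony yields four granddaughter diploids (W1, W2 from the
white sector; R1, R2 from the red sector).  Because replication of an
unrepaired heteroduplex distributes its two strands to the two
granddaughters, there is a one-to-one correspondence between the eight
granddaughter homologs and the eight DNA strands of the mother cell's four
chromatids.  The procedure is:

1. Phase each granddaughter: zygosity segments plus a spore-derived
   haplotype give the two homolog allele vectors.
2. Within a sector, pair the homologs of the two granddaughters by
   centromere origin — the two homologs with, say, an R centromere are the
   two strands of the daughter chromosome carrying the R centromere, which
   itself is one of the mother's chromatids.
3. Assign daughter chromosomes to mother sister pairs by centromere origin.

Heteroduplex segments of a reconstructed chromatid are the maximal runs of
markers where its two strands disagree.

Strand numbering convention: the white-sector R-centromere chromatid holds
strands 1 (from W1) and 2 (from W2); red-sector R-centromere, strands 3-4;
white-sector B-centromere, strands 5-6; red-sector B-centromere, strands
7-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .arrays import HET, HOM_B, HOM_R, UNCALLED
from .genome import MarkerMap, ORIGIN_B, ORIGIN_R

MISSING = -1


class PhasingConflictError(ValueError):
    """The spore haplotype contradicts a homozygous call."""


class ReconstructionError(ValueError):
    """Centromere-origin pairing impossible (e.g. three homologs with the
    same centromere origin in one sector) — flagged for manual review; such
    patterns arise from aneuploidy or BIR."""


@dataclass
class PhasedGranddaughter:
    """Two homolog allele vectors over the assayed markers.

    Entries are parental origins (R=0, B=1) or -1 where no call was made.
    ``centromere_origin`` holds the origin of each homolog at the marker
    closest to the centromere.
    """

    homologs: np.ndarray  # (2, n_assayed) int8
    centromere_origins: tuple[int, int]

    def homolog_by_centromere(self, origin: int) -> Optional[int]:
        matches = [i for i, o in enumerate(self.centromere_origins) if o == origin]
        return matches[0] if len(matches) == 1 else None


def phase_granddaughter(
    calls: np.ndarray,
    spore: np.ndarray,
    positions: np.ndarray,
    centromere_position: int,
) -> PhasedGranddaughter:
    """Phase one granddaughter from zygosity calls and a spore haplotype.

    ``calls`` and ``spore`` are over the assayed markers; the spore vector
    is the allele series of one haploid derivative (it fixes which allele
    sits on which homolog in every heterozygous segment).  Homolog 1 is the
    spore's homolog; homolog 2 carries the complementary allele in HET
    segments and the same allele in HOM segments.

    Raises :class:`PhasingConflictError` when the spore carries the allele
    a homozygous call says is absent.
    """
    calls = np.asarray(calls)
    spore = np.asarray(spore)
    n = calls.size
    h1 = np.full(n, MISSING, dtype=np.int8)
    h2 = np.full(n, MISSING, dtype=np.int8)

    het = calls == HET
    h1[het] = spore[het]
    h2[het] = 1 - spore[het]
    for hom_call, origin in ((HOM_R, ORIGIN_R), (HOM_B, ORIGIN_B)):
        m = calls == hom_call
        conflict = m & (spore != origin) & (spore != MISSING)
        if conflict.any():
            idx = int(np.flatnonzero(conflict)[0])
            raise PhasingConflictError(
                f"spore carries the absent allele at marker {idx} "
                f"(pos {int(np.asarray(positions)[idx])})"
            )
        h1[m] = origin
        h2[m] = origin

    homologs = np.stack([h1, h2])
    cen = _centromere_origins(homologs, positions, centromere_position)
    return PhasedGranddaughter(homologs, cen)


def _centromere_origins(
    homologs: np.ndarray, positions, target: int
) -> tuple[int, int]:
    """Centromere origin of each homolog.

    Read at the closest marker where the two homologs *disagree*: markers
    where they agree carry no coupling information, and tract regions (a
    foreign or converted strand matching the other homolog) are exactly the
    agreeing ones, so the nearest disagreeing marker reads parental
    content.  A homolog pair that never disagrees (whole-chromosome LOH)
    falls back to the nearest called marker, giving both homologs the same
    origin — downstream pairing then raises the reconstruction error such
    aneuploidy-like patterns deserve.
    """
    h1, h2 = homologs
    pos = np.asarray(positions)
    diff = (h1 != MISSING) & (h2 != MISSING) & (h1 != h2)
    idx = np.flatnonzero(diff)
    if idx.size == 0:
        idx = np.flatnonzero((h1 != MISSING) & (h2 != MISSING))
        if idx.size == 0:
            return (MISSING, MISSING)
    j = idx[np.argmin(np.abs(pos[idx] - target))]
    return (int(h1[j]), int(h2[j]))


@dataclass
class ReconChromatid:
    """One reconstructed mother chromatid: two strand-origin vectors."""

    strand_a: np.ndarray
    strand_b: np.ndarray
    strand_ids: tuple[int, int]
    centromere_origin: int
    sector: str  # "W" or "R"

    def valid(self) -> np.ndarray:
        return (self.strand_a != MISSING) & (self.strand_b != MISSING)

    def mismatches(self) -> np.ndarray:
        return self.valid() & (self.strand_a != self.strand_b)


@dataclass
class SegmentCall:
    """A maximal heteroduplex run on a reconstructed chromatid."""

    chromatid: int
    first_index: int
    last_index: int
    first_bp: int
    last_bp: int


@dataclass
class ReconstructedMother:
    """Four chromatids (order: white-R, red-R, white-B, red-B), each strand
    tagged with its source granddaughter homolog (strands 1-8)."""

    positions: np.ndarray
    centromere_position: int
    chromatids: list[ReconChromatid]
    het_segments: list[SegmentCall] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def sister_indices(self, origin: int) -> list[int]:
        return [
            i
            for i, c in enumerate(self.chromatids)
            if c.centromere_origin == origin
        ]


def _pair_sector(
    gd1: PhasedGranddaughter, gd2: PhasedGranddaughter
) -> list[tuple[int, int, int]]:
    """Pair homologs of two granddaughters into daughter chromosomes.

    Returns [(homolog_of_gd1, homolog_of_gd2, centromere_origin), ...] with
    one entry per centromere origin.  Pairing is by centromere origin; when
    a granddaughter's two homologs share a centromere origin the pairing
    minimizing total strand disagreement is chosen (ties toward fewer
    heteroduplex runs), a parsimony rule for the pathological cases the
    centromere allele cannot resolve.
    """
    pairings = [((0, 0), (1, 1)), ((0, 1), (1, 0))]

    def consistent(p):
        out = []
        for i, j in p:
            o1, o2 = gd1.centromere_origins[i], gd2.centromere_origins[j]
            if o1 != o2 or o1 == MISSING:
                return None
            out.append((i, j, o1))
        if {o for _, _, o in out} != {ORIGIN_R, ORIGIN_B}:
            return None
        return out

    valid = [c for p in pairings if (c := consistent(p)) is not None]
    if not valid:
        raise ReconstructionError(
            "cannot pair granddaughter homologs by centromere origin"
        )
    if len(valid) == 1:
        return valid[0]

    def score(assignment):
        mismatch = 0
        runs = 0
        for i, j, _ in assignment:
            a, b = gd1.homologs[i], gd2.homologs[j]
            ok = (a != MISSING) & (b != MISSING)
            diff = ok & (a != b)
            mismatch += int(diff.sum())
            runs += int(np.count_nonzero(np.diff(diff.astype(int)) == 1)) + int(
                diff[:1].any()
            )
        return (mismatch, runs)

    return min(valid, key=score)


def reconstruct_mother(
    w1: PhasedGranddaughter,
    w2: PhasedGranddaughter,
    r1: PhasedGranddaughter,
    r2: PhasedGranddaughter,
    marker_map: MarkerMap,
) -> ReconstructedMother:
    """Rebuild the mother cell's four chromatids from the four phased
    granddaughters.

    When a sector shows a single genotype, pass the same
    :class:`PhasedGranddaughter` twice — the reconstruction then yields
    homoduplex chromatids for that side (repair left no persistent
    heteroduplex in that daughter).
    """
    positions = marker_map.assayed_positions
    cen = marker_map.centromere_position
    chromatids: list[ReconChromatid] = []
    # strand ids: (sector, centromere origin) -> (id of gd1 strand, gd2 strand)
    ids = {
        ("W", ORIGIN_R): (1, 2),
        ("R", ORIGIN_R): (3, 4),
        ("W", ORIGIN_B): (5, 6),
        ("R", ORIGIN_B): (7, 8),
    }
    for sector, gda, gdb in (("W", w1, w2), ("R", r1, r2)):
        for i, j, origin in _pair_sector(gda, gdb):
            chromatids.append(
                ReconChromatid(
                    strand_a=gda.homologs[i].copy(),
                    strand_b=gdb.homologs[j].copy(),
                    strand_ids=ids[(sector, origin)],
                    centromere_origin=origin,
                    sector=sector,
                )
            )
    # canonical order: white-R, red-R, white-B, red-B
    order = {(1, 2): 0, (3, 4): 1, (5, 6): 2, (7, 8): 3}
    chromatids.sort(key=lambda c: order[c.strand_ids])
    rm = ReconstructedMother(
        positions=positions, centromere_position=cen, chromatids=chromatids
    )
    for k, chrom in enumerate(chromatids):
        rm.het_segments.extend(_het_runs(k, chrom, positions))
    return rm


def _het_runs(
    chrom_idx: int, chrom: ReconChromatid, positions: np.ndarray
) -> list[SegmentCall]:
    valid_idx = np.flatnonzero(chrom.valid())
    if valid_idx.size == 0:
        return []
    diff = (chrom.strand_a != chrom.strand_b)[valid_idx]
    out = []
    start = None
    for k, flag in enumerate(diff):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            out.append((start, k - 1))
            start = None
    if start is not None:
        out.append((start, diff.size - 1))
    return [
        SegmentCall(
            chromatid=chrom_idx,
            first_index=int(valid_idx[s]),
            last_index=int(valid_idx[e]),
            first_bp=int(positions[valid_idx[s]]),
            last_bp=int(positions[valid_idx[e]]),
        )
        for s, e in out
    ]
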