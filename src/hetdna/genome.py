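"""Diploid marker map and strand-level chromatid representation.

The experimental system is a hybrid diploid (W303-1A x YJM789) heterozygous
for ~55,000 SNPs, ~13,000 of which are assayed by SNP-specific microarrays
(~1 kb mean spacing of assayed markers).  Everything downstream works at
marker resolution: a chromatid is a pair of strand-origin vectors (one per
DNA strand), each entry recording which parental haploid the sequence at
that marker derives from.  A heteroduplex is simply a run of markers where
the two strands disagree.

Origins are encoded as small integers: ``R`` (0) for the W303-1A-derived
("red") homolog and ``B`` (1) for the YJM789-derived ("blue") homolog.
Coordinates are 1-based base pairs; BED exports convert to 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

ORIGIN_R: int = 0
ORIGIN_B: int = 1

ORIGIN_LABELS = {ORIGIN_R: "R", ORIGIN_B: "B"}
ORIGIN_CODES = {"R": ORIGIN_R, "B": ORIGIN_B}


def other_origin(origin: int) -> int:
    """The opposite parental origin (donor of a given recipient and vice versa)."""
    return 1 - origin


class InvalidParameterError(ValueError):
    """Raised when a marker-map or simulation parameter is out of range."""


@dataclass
class MarkerMap:
    """Ordered heterozygous SNP positions on one chromosome.

    Parameters
    ----------
    chromosome_id : str
        Chromosome label used in exports.
    positions : ndarray of int
        1-based bp coordinates, strictly increasing.
    assayed : ndarray of bool
        Markers present on the microarray panel.
    centromere_position : int
        1-based bp coordinate of the centromere.
    sup4_marker_index : int, optional
        Index of the marker carrying the SUP4-o insertion on the B homolog;
        must lie on the arm distal to the centromere used for selection.
    heterology_blocks : sequence of (start, end)
        Marker-free intervals (models the HS4 inverted-Ty heterology, which
        is detected only through flanking markers).
    """

    chromosome_id: str
    positions: np.ndarray
    assayed: np.ndarray
    centromere_position: int
    sup4_marker_index: Optional[int] = None
    heterology_blocks: Sequence[tuple[int, int]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.assayed = np.asarray(self.assayed, dtype=bool)
        if self.positions.ndim != 1 or self.positions.size < 2:
            raise InvalidParameterError("need at least two markers")
        if self.assayed.shape != self.positions.shape:
            raise InvalidParameterError("assayed flag must match positions")
        if self.positions[0] < 1:
            raise InvalidParameterError("positions are 1-based (>= 1)")
        if not np.all(np.diff(self.positions) > 0):
            raise InvalidParameterError("positions must be strictly increasing")
        for lo, hi in self.heterology_blocks:
            inside = (self.positions >= lo) & (self.positions <= hi)
            if inside.any():
                raise InvalidParameterError(
                    "heterology blocks must contain no markers"
                )
        if self.sup4_marker_index is not None:
            idx = int(self.sup4_marker_index)
            if not 0 <= idx < self.n_markers:
                raise InvalidParameterError("sup4_marker_index out of range")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    @property
    def assayed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.assayed)

    @property
    def assayed_positions(self) -> np.ndarray:
        return self.positions[self.assayed]

    def markers_in(self, lo: float, hi: float) -> np.ndarray:
        """Indices of markers with lo <= position <= hi."""
        i0 = int(np.searchsorted(self.positions, lo, side="left"))
        i1 = int(np.searchsorted(self.positions, hi, side="right"))
        return np.arange(i0, i1)

    def subset_panel(self) -> "MarkerMap":
        """A map restricted to the assayed panel (all markers assayed)."""
        keep = self.assayed
        sup4 = None
        if self.sup4_marker_index is not None and keep[self.sup4_marker_index]:
            sup4 = int(keep[: self.sup4_marker_index].sum())
        return MarkerMap(
            chromosome_id=self.chromosome_id,
            positions=self.positions[keep],
            assayed=np.ones(int(keep.sum()), dtype=bool),
            centromere_position=self.centromere_position,
            sup4_marker_index=sup4,
            heterology_blocks=tuple(self.heterology_blocks),
        )


@dataclass
class Chromatid:
    """One chromatid: two strand-origin vectors plus a centromere origin.

    ``watson`` and ``crick`` hold the parental origin of each strand at every
    marker.  The mismatch set (markers inside heteroduplex DNA) is always
    recomputed from the strands, never stored.
    """

    watson: np.ndarray
    crick: np.ndarray
    centromere_origin: int

    def __post_init__(self) -> None:
        self.watson = np.asarray(self.watson, dtype=np.int8)
        self.crick = np.asarray(self.crick, dtype=np.int8)
        if self.watson.shape != self.crick.shape:
            raise InvalidParameterError("strand vectors must have equal length")

    @property
    def n_markers(self) -> int:
        return int(self.watson.size)

    def mismatches(self) -> np.ndarray:
        """Boolean mask of markers inside heteroduplex DNA."""
        return self.watson != self.crick

    def mismatch_count(self) -> int:
        return int(np.count_nonzero(self.mismatches()))

    def strand(self, name: str) -> np.ndarray:
        if name == "W":
            return self.watson
        if name == "C":
            return self.crick
        raise KeyError(name)

    def copy(self) -> "Chromatid":
        return Chromatid(
            self.watson.copy(), self.crick.copy(), self.centromere_origin
        )

    def sup4_copies(self, marker_map: MarkerMap) -> float:
        """SUP4-o copy number carried by this chromatid.

        The suppressor is inserted on the B homolog, so a chromatid carries a
        full copy when both strands at the insertion marker are B-derived.  A
        heteroduplex over the insertion contributes half a copy (one strand);
        such chromatids never satisfy the 2:0 sectored-segregation pattern.
        """
        idx = marker_map.sup4_marker_index
        if idx is None:
            return 0.0
        w = 1.0 if self.watson[idx] == ORIGIN_B else 0.0
        c = 1.0 if self.crick[idx] == ORIGIN_B else 0.0
        return (w + c) / 2.0


def make_marker_map(
    n_markers: int,
    chrom_length: int,
    assayed_fraction: float,
    seed: int,
    *,
    chromosome_id: str = "chr_sim",
    centromere_position: Optional[int] = None,
    sup4_position: Optional[int] = None,
    heterology_blocks: Sequence[tuple[int, int]] = (),
) -> MarkerMap:
    """Draw a random marker map with a uniformly sampled assayed panel.

    Positions are sampled uniformly without replacement over
    ``1..chrom_length`` (outside any heterology block) and sorted; the SNP
    spacing distribution of the real hybrid is not published, so uniform
    placement is the modeling assumption.  The assayed subset is sampled
    uniformly; with the genome-scale defaults (55,000 markers, 13,000
    assayed) the mean assayed spacing is ~1 kb.

    Parameters mirror the study counts; ``sup4_position`` places the SUP4-o
    insertion at the assayed marker nearest that coordinate.
    """
    n_markers = int(n_markers)
    chrom_length = int(chrom_length)
    if n_markers < 2:
        raise InvalidParameterError("n_markers must be >= 2")
    if not 0 < assayed_fraction <= 1:
        raise InvalidParameterError("assayed_fraction must be in (0, 1]")
    blocked = sum(hi - lo + 1 for lo, hi in heterology_blocks)
    if n_markers > chrom_length - blocked:
        raise InvalidParameterError(
            f"cannot place {n_markers} markers on {chrom_length} bp"
        )
    rng = np.random.default_rng(seed)
    candidates = np.arange(1, chrom_length + 1, dtype=np.int64)
    for lo, hi in heterology_blocks:
        candidates = candidates[(candidates < lo) | (candidates > hi)]
    positions = np.sort(rng.choice(candidates, size=n_markers, replace=False))
    n_assayed = max(2, int(round(assayed_fraction * n_markers)))
    n_assayed = min(n_assayed, n_markers)
    assayed = np.zeros(n_markers, dtype=bool)
    assayed[rng.choice(n_markers, size=n_assayed, replace=False)] = True

    if centromere_position is None:
        centromere_position = int(round(0.5 * chrom_length))
    sup4_idx = None
    if sup4_position is not None:
        assayed_idx = np.flatnonzero(assayed)
        sup4_idx = int(
            assayed_idx[
                np.argmin(np.abs(positions[assayed_idx] - sup4_position))
            ]
        )
    return MarkerMap(
        chromosome_id=chromosome_id,
        positions=positions,
        assayed=assayed,
        centromere_position=int(centromere_position),
        sup4_marker_index=sup4_idx,
        heterology_blocks=tuple(heterology_blocks),
    )


def chr5_like_map(
    seed: int,
    *,
    n_markers: int = 2750,
    chrom_length: int = 576_874,
    assayed_fraction: float = 13_000 / 55_000,
) -> MarkerMap:
    """A chromosome-V-scale map matching the study's marker density.

    Chromosome V carries the selection system of strain YYy310: SUP4-o near
    the left telomere (~30 kb) and CEN5 at ~152 kb, ~120 kb apart.  Marker
    count scales the genome-wide 55,000 SNPs to the chrV length; the assayed
    fraction reproduces the 13k/55k microarray panel (~0.9 kb assayed
    spacing).
    """
    return make_marker_map(
        n_markers,
        chrom_length,
        assayed_fraction,
        seed,
        chromosome_id="chrV_sim",
        centromere_position=151_987,
        sup4_position=30_000,
    )


def parental_chromatids(marker_map: MarkerMap) -> list[Chromatid]:
    """The four G2 chromatids of an unrecombined diploid.

    Returns two R sisters followed by two B sisters; all strand vectors are
    uniform and every mismatch set is empty.  SUP4-o copies live on the B
    sisters only (one per sister, i.e. the replicated insertion-bearing
    homolog).
    """
    n = marker_map.n_markers
    out = []
    for origin in (ORIGIN_R, ORIGIN_R, ORIGIN_B, ORIGIN_B):
        vec = np.full(n, origin, dtype=np.int8)
        out.append(Chromatid(vec.copy(), vec.copy(), origin))
    return out


# ---------------------------------------------------------------------------
# plain-text interfaces

_ALLELE_PAIRS = ("A/G", "C/T", "G/A", "T/C")


def write_marker_map_tsv(marker_map: MarkerMap, path) -> None:
    """Marker map TSV: chrom, pos (1-based), allele_R, allele_B, assayed."""
    import pandas as pd

    n = marker_map.n_markers
    pairs = [_ALLELE_PAIRS[i % 4].split("/") for i in range(n)]
    df = pd.DataFrame(
        {
            "chrom": marker_map.chromosome_id,
            "pos": marker_map.positions,
            "allele_R": [p[0] for p in pairs],
            "allele_B": [p[1] for p in pairs],
            "assayed": marker_map.assayed.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_map_tsv(
    path,
    *,
    centromere_position: int,
    sup4_marker_index: Optional[int] = None,
) -> MarkerMap:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "allele_R", "allele_B", "assayed"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"marker map TSV needs columns {sorted(required)}"
        )
    return MarkerMap(
        chromosome_id=str(df["chrom"].iloc[0]),
        positions=df["pos"].to_numpy(np.int64),
        assayed=df["assayed"].to_numpy(bool),
        centromere_position=centromere_position,
        sup4_marker_index=sup4_marker_index,
    )
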