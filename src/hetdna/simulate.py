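"""Forward simulation of mitotic DSB repair at strand resolution.

This is the synthetic-data generator of the package: it produces mother-cell
chromatid configurations (with ground-truth annotation), segregates them
into daughters, and replicates daughters into the four granddaughter
genotypes per sectored colony that the readout and inference modules
consume.

The repair mechanisms implemented are the double-strand-break repair
pathways relevant to an MMR-deficient (mlh1) diploid:

* one-ended SDSA        -> one chromatid, unidirectional heteroduplex
* two-ended SDSA        -> one chromatid, bidirectional heteroduplex with a
                           strand switch at the DSB
* dHJ dissolution       -> same product as two-ended SDSA
* dHJ resolution (CO)   -> reciprocal exchange; heteroduplexes on the two
                           crossover chromatids, flanking the DSB, pointing
                           in opposite directions (nick-directed pattern)
* dHJ resolution (NCO)  -> conversion tract on the recipient adjacent to the
                           DSB with a heteroduplex at the same position on
                           the donor, plus a (usually short) second-end
                           heteroduplex on the recipient's other side
* BIR                   -> donor sequence copied conservatively from the DSB
                           to the telomere, no heteroduplex
* gap repair            -> double-stranded gap filled from the donor: both
                           strands donor over the gap (3:1, or 4:0 when both
                           sisters convert), optionally flanked by a
                           heteroduplex on the same or the opposite side

A break in G1 is replicated into two sister chromatids broken at the same
position (DSCB); each broken sister then draws its own repair mechanism.  A
break in S/G2 affects a single chromatid (SCB).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaincinv

from .genome import (
    Chromatid,
    InvalidParameterError,
    MarkerMap,
    ORIGIN_B,
    ORIGIN_LABELS,
    ORIGIN_R,
    other_origin,
    parental_chromatids,
)


class Mechanism(str, enum.Enum):
    ONE_ENDED_SDSA = "ONE_ENDED_SDSA"
    TWO_ENDED_SDSA = "TWO_ENDED_SDSA"
    DHJ_RESOLUTION_CO = "DHJ_RESOLUTION_CO"
    DHJ_RESOLUTION_NCO = "DHJ_RESOLUTION_NCO"
    DHJ_DISSOLUTION = "DHJ_DISSOLUTION"
    BIR = "BIR"
    GAP_REPAIR = "GAP_REPAIR"


class MMRMode(str, enum.Enum):
    CONVERSION = "CONVERSION"
    RESTORATION = "RESTORATION"
    PATCHY = "PATCHY"
    NONE = "NONE"


class Timing(str, enum.Enum):
    G1 = "G1"
    G2 = "G2"


@dataclass
class LengthDist:
    """Tract-length distribution in bp, parameterized by its median.

    ``gamma`` with shape 2 is the default: resection proceeds in two steps
    (short MRX/Sae2 nicking followed by processive Exo1/Sgs1-Dna2
    resection), which makes near-zero heteroduplex tracts rare; the paper
    reports medians but no distribution shape.
    """

    kind: str = "gamma"
    median: float = 5400.0
    shape: float = 2.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.median <= 0:
            return 0.0
        if self.kind == "fixed":
            return float(self.median)
        if self.kind == "exponential":
            return float(rng.exponential(self.median / np.log(2.0)))
        if self.kind == "gamma":
            scale = self.median / float(gammaincinv(self.shape, 0.5))
            return float(rng.gamma(self.shape, scale))
        raise InvalidParameterError(f"unknown length distribution {self.kind!r}")


DEFAULT_MECHANISM_WEIGHTS = {
    Mechanism.ONE_ENDED_SDSA: 0.30,
    Mechanism.GAP_REPAIR: 0.25,
    Mechanism.DHJ_RESOLUTION_CO: 0.20,
    Mechanism.TWO_ENDED_SDSA: 0.08,
    Mechanism.DHJ_DISSOLUTION: 0.07,
    Mechanism.DHJ_RESOLUTION_NCO: 0.05,
    Mechanism.BIR: 0.05,
}


@dataclass
class SimConfig:
    """Study-condition parameters for the forward simulation.

    Defaults emulate the UV-treated mlh1 hybrid diploid: SCB and DSCB events
    about equally frequent (p_g1 = 0.5), both homologs equally likely to be
    the recipient, heteroduplex side lengths with a 5.4 kb median (the
    published NCO tract median), and no Mlh1-dependent mismatch repair.
    """

    p_g1: float = 0.5
    p_recipient_r: float = 0.5
    mechanism_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_MECHANISM_WEIGHTS)
    )
    het_length: LengthDist = field(default_factory=LengthDist)
    gap_length: LengthDist = field(default_factory=LengthDist)
    # second-end heteroduplex of a dHJ resolved as NCO; short by default, so
    # it frequently contains no assayed marker (the Class 8 presentation).
    second_het_length: LengthDist = field(
        default_factory=lambda: LengthDist(median=500.0)
    )
    p_gap_het: float = 0.5
    p_gap_het_same_side: float = 0.6
    mmr_probs: dict = field(default_factory=lambda: {MMRMode.NONE: 1.0})
    mmr_patch_median: float = 300.0
    p_branch_migration: float = 0.10
    branch_migration_length: LengthDist = field(
        default_factory=lambda: LengthDist(median=1000.0)
    )
    p_template_switch: float = 0.05
    template_switch_length: LengthDist = field(
        default_factory=lambda: LengthDist(median=800.0)
    )
    sister_repair_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mechanism_weights = {
            Mechanism(k): float(v) for k, v in self.mechanism_weights.items()
        }
        self.mmr_probs = {MMRMode(k): float(v) for k, v in self.mmr_probs.items()}
        for name, probs in (
            ("mechanism_weights", self.mechanism_weights),
            ("mmr_probs", self.mmr_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in probs.values()):
                raise InvalidParameterError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mechanism_weights"] = {
            k.value: v for k, v in self.mechanism_weights.items()
        }
        d["mmr_probs"] = {k.value: v for k, v in self.mmr_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in (
            "het_length",
            "gap_length",
            "second_het_length",
            "branch_migration_length",
            "template_switch_length",
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = LengthDist(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class TractTruth:
    """One true repair-tract interval on a chromatid (bp, inclusive)."""

    chromatid: int
    kind: str  # het | conversion | restoration | symmetric_het | bir_terminal
    start: int
    end: int
    strand: Optional[str] = None  # which strand carries donor sequence

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class BreakDescription:
    timing: Timing
    recipient_origin: int
    position: int
    chromatid_indices: tuple[int, ...]


@dataclass
class RepairTruth:
    mechanism: Mechanism
    chromatid: int
    donor_chromatid: int
    dsb_position: int
    is_co: bool
    tracts: list[TractTruth] = field(default_factory=list)
    mmr_mode: MMRMode = MMRMode.NONE


@dataclass
class MotherCellState:
    """Four chromatids (two sister pairs) after repair, before segregation."""

    marker_map: MarkerMap
    chromatids: list[Chromatid]
    brk: Optional[BreakDescription] = None
    repairs: list[RepairTruth] = field(default_factory=list)

    def sister_indices(self, origin: int) -> list[int]:
        return [
            i
            for i, c in enumerate(self.chromatids)
            if c.centromere_origin == origin
        ]


@dataclass
class GranddaughterGenotype:
    """Two homolog allele vectors of a granddaughter diploid.

    ``sources`` records, per homolog, the mother chromatid index and strand
    ('W'/'C') it was replicated from — this is the ground-truth side of the
    one-to-one strand correspondence the inference module reconstructs.
    """

    homologs: np.ndarray  # (2, n_markers) int8 parental origins
    sources: tuple[tuple[int, str], tuple[int, str]]

    def zygosity(self) -> np.ndarray:
        """Per-marker codes: 0=HET, 1=HOM_R, 2=HOM_B."""
        a, b = self.homologs
        out = np.zeros(a.size, dtype=np.int8)
        hom = a == b
        out[hom & (a == ORIGIN_R)] = 1
        out[hom & (a == ORIGIN_B)] = 2
        return out


@dataclass
class Daughter:
    chromatid_indices: tuple[int, int]
    chromatids: list[Chromatid]
    sup4_copies: float


@dataclass
class Colony:
    mother: MotherCellState
    daughters: tuple[Daughter, Daughter]  # (white-side, red-side) if sectored
    granddaughters: dict  # keys W1, W2, R1, R2 -> GranddaughterGenotype
    sectored: bool
    colors: tuple[str, str]


# ---------------------------------------------------------------------------
# break initiation


def initiate_break(
    config: SimConfig, marker_map: MarkerMap, rng: np.random.Generator
) -> BreakDescription:
    """Draw DSB timing, recipient homolog and position.

    A G1 break is replicated into two sister chromatids broken at the same
    position (DSCB); a G2 break affects one chromatid (SCB).  Chromatid
    indices refer to the ``parental_chromatids`` order (R sisters 0-1, B
    sisters 2-3).
    """
    timing = Timing.G1 if rng.random() < config.p_g1 else Timing.G2
    recipient = ORIGIN_R if rng.random() < config.p_recipient_r else ORIGIN_B
    lo = int(marker_map.positions[0])
    hi = int(marker_map.positions[-1])
    position = int(rng.integers(lo + 1, hi))
    # breaks sit between SNPs: a lesion at the exact marker coordinate is
    # below the assay's resolution and would leave an unphysical parental
    # island at the cut site
    while marker_map.markers_in(position, position).size:
        position = int(rng.integers(lo + 1, hi))
    sisters = (0, 1) if recipient == ORIGIN_R else (2, 3)
    if timing == Timing.G1:
        broken = sisters
    else:
        broken = (sisters[int(rng.integers(2))],)
    return BreakDescription(timing, recipient, position, broken)


# ---------------------------------------------------------------------------
# repair mechanics


def _side_intervals(d: int, left_len: float, right_len: float):
    """bp intervals (inclusive) immediately left/right of the DSB."""
    left = (int(d - left_len), d - 1) if left_len > 0 else None
    right = (d + 1, int(d + right_len)) if right_len > 0 else None
    return left, right


def _set_strand(
    chromatid: Chromatid,
    marker_map: MarkerMap,
    interval: Optional[tuple[int, int]],
    strand: str,
    origin: int,
) -> None:
    if interval is None:
        return
    idx = marker_map.markers_in(interval[0], interval[1])
    chromatid.strand(strand)[idx] = origin


def _set_both(
    chromatid: Chromatid,
    marker_map: MarkerMap,
    interval: Optional[tuple[int, int]],
    origin: int,
) -> None:
    if interval is None:
        return
    idx = marker_map.markers_in(interval[0], interval[1])
    chromatid.watson[idx] = origin
    chromatid.crick[idx] = origin


def _distal_is_right(marker_map: MarkerMap, d: int) -> bool:
    """True when the telomere-ward side of the DSB is the right side."""
    return d >= marker_map.centromere_position


def apply_repair(
    state: MotherCellState,
    broken_idx: int,
    donor_idx: int,
    mechanism: Mechanism,
    config: SimConfig,
    dsb_position: int,
    rng: np.random.Generator,
    *,
    lengths: Optional[dict] = None,
) -> RepairTruth:
    """Apply one repair event in place and return its ground truth.

    ``lengths`` overrides drawn tract lengths, e.g. ``{"het_left": 5000,
    "het_right": 0}``; used to realize specific class geometries exactly.
    Keys: het_left/het_right (SDSA, dHJ), conv ("gap"/dHJ-NCO conversion),
    second_het, side ("L"/"R"), gap_het_side ("same"/"opposite"/None).
    """
    mechanism = Mechanism(mechanism)
    m = state.marker_map
    d = int(dsb_position)
    if not (m.positions[0] <= d <= m.positions[-1]):
        raise InvalidParameterError("DSB outside the marker interval")
    chromatid = state.chromatids[broken_idx]
    donor_chr = state.chromatids[donor_idx]
    recipient = chromatid.centromere_origin
    donor = donor_chr.centromere_origin
    if recipient == donor:
        raise InvalidParameterError("donor must be the unbroken homolog")
    ov = lengths or {}
    truth = RepairTruth(
        mechanism=mechanism,
        chromatid=broken_idx,
        donor_chromatid=donor_idx,
        dsb_position=d,
        is_co=mechanism == Mechanism.DHJ_RESOLUTION_CO,
    )

    def het_len(key: str) -> float:
        return float(ov.get(key, config.het_length.draw(rng)))

    chrom_end_right = int(m.positions[-1])
    chrom_end_left = int(m.positions[0])

    if mechanism == Mechanism.ONE_ENDED_SDSA:
        side = ov.get("side") or ("L" if rng.random() < 0.5 else "R")
        L = het_len("het")
        if side == "R":
            iv = (d + 1, min(int(d + L), chrom_end_right))
            _set_strand(chromatid, m, iv, "W", donor)
            truth.tracts.append(TractTruth(broken_idx, "het", *iv, strand="W"))
        else:
            iv = (max(int(d - L), chrom_end_left), d - 1)
            _set_strand(chromatid, m, iv, "C", donor)
            truth.tracts.append(TractTruth(broken_idx, "het", *iv, strand="C"))

    elif mechanism in (Mechanism.TWO_ENDED_SDSA, Mechanism.DHJ_DISSOLUTION):
        # bidirectional heteroduplex with a strand switch at the DSB: the
        # donor-derived sequence is on opposite strands left and right
        Ll, Lr = het_len("het_left"), het_len("het_right")
        left, right = _side_intervals(d, Ll, Lr)
        _set_strand(chromatid, m, left, "C", donor)
        _set_strand(chromatid, m, right, "W", donor)
        if left:
            truth.tracts.append(TractTruth(broken_idx, "het", *left, strand="C"))
        if right:
            truth.tracts.append(TractTruth(broken_idx, "het", *right, strand="W"))

    elif mechanism == Mechanism.DHJ_RESOLUTION_CO:
        # reciprocal exchange of the telomere-ward arms, heteroduplexes
        # flanking the DSB on the two crossover products (nick-directed)
        distal_right = _distal_is_right(m, d)
        if distal_right:
            distal_idx = m.markers_in(d + 1, chrom_end_right)
        else:
            distal_idx = m.markers_in(chrom_end_left, d - 1)
        for arr_name in ("watson", "crick"):
            a = getattr(chromatid, arr_name)
            b = getattr(donor_chr, arr_name)
            a[distal_idx], b[distal_idx] = b[distal_idx].copy(), a[distal_idx].copy()
        Lp = float(ov.get("het_proximal", config.het_length.draw(rng)))
        Ld = float(ov.get("het_distal", config.het_length.draw(rng)))
        if distal_right:
            prox_iv, dist_iv = _side_intervals(d, Lp, Ld)
            prox_strand, dist_strand = "C", "W"
        else:
            dist_iv, prox_iv = _side_intervals(d, Ld, Lp)
            prox_strand, dist_strand = "W", "C"
        # recipient-centromere product keeps its proximal arm: het there
        _set_strand(chromatid, m, prox_iv, prox_strand, donor)
        # donor-centromere product received the recipient distal arm: het there
        _set_strand(donor_chr, m, dist_iv, dist_strand, donor)
        if prox_iv:
            truth.tracts.append(
                TractTruth(broken_idx, "het", *prox_iv, strand=prox_strand)
            )
        if dist_iv:
            truth.tracts.append(
                TractTruth(donor_idx, "het", *dist_iv, strand=dist_strand)
            )
        if config.p_branch_migration > 0 and rng.random() < config.p_branch_migration:
            _branch_migrate(state, truth, config, rng)

    elif mechanism == Mechanism.DHJ_RESOLUTION_NCO:
        # conversion tract on the recipient adjacent to the DSB; the donor
        # keeps the invading recipient strand over the same interval
        # (heteroduplex on the donor); second-end heteroduplex on the
        # recipient's other side, usually short.
        side = ov.get("side") or ("L" if rng.random() < 0.5 else "R")
        Lc = float(ov.get("conv", config.gap_length.draw(rng)))
        Ls = float(ov.get("second_het", config.second_het_length.draw(rng)))
        if side == "R":
            conv_iv = (d + 1, min(int(d + Lc), chrom_end_right)) if Lc > 0 else None
            sec_iv = (max(int(d - Ls), chrom_end_left), d - 1) if Ls > 0 else None
            sec_strand, donor_strand = "C", "W"
        else:
            conv_iv = (max(int(d - Lc), chrom_end_left), d - 1) if Lc > 0 else None
            sec_iv = (d + 1, min(int(d + Ls), chrom_end_right)) if Ls > 0 else None
            sec_strand, donor_strand = "W", "C"
        _set_both(chromatid, m, conv_iv, donor)
        _set_strand(donor_chr, m, conv_iv, donor_strand, recipient)
        _set_strand(chromatid, m, sec_iv, sec_strand, donor)
        if conv_iv:
            truth.tracts.append(TractTruth(broken_idx, "conversion", *conv_iv))
            truth.tracts.append(
                TractTruth(donor_idx, "het", *conv_iv, strand=donor_strand)
            )
        if sec_iv:
            truth.tracts.append(
                TractTruth(broken_idx, "het", *sec_iv, strand=sec_strand)
            )
        if config.p_branch_migration > 0 and rng.random() < config.p_branch_migration:
            _branch_migrate(state, truth, config, rng)

    elif mechanism == Mechanism.BIR:
        distal_right = _distal_is_right(m, d)
        if distal_right:
            iv = (d + 1, chrom_end_right)
        else:
            iv = (chrom_end_left, d - 1)
        _set_both(chromatid, m, iv, donor)
        truth.tracts.append(TractTruth(broken_idx, "bir_terminal", *iv))

    elif mechanism == Mechanism.GAP_REPAIR:
        side = ov.get("side") or ("L" if rng.random() < 0.5 else "R")
        G = float(ov.get("gap", config.gap_length.draw(rng)))
        if G <= 0:
            raise InvalidParameterError("gap repair needs a positive gap length")
        if side == "R":
            gap_iv = (d + 1, min(int(d + G), chrom_end_right))
        else:
            gap_iv = (max(int(d - G), chrom_end_left), d - 1)
        _set_both(chromatid, m, gap_iv, donor)
        truth.tracts.append(TractTruth(broken_idx, "conversion", *gap_iv))
        want_het = ov.get(
            "gap_het_side",
            (
                ("same" if rng.random() < config.p_gap_het_same_side else "opposite")
                if rng.random() < config.p_gap_het
                else None
            ),
        )
        if want_het:
            Lh = het_len("het")
            if (side == "R") == (want_het == "same"):
                # heteroduplex distal to the gap end on the right
                start = gap_iv[1] + 1 if want_het == "same" else d + 1
                iv = (start, min(int(start + Lh - 1), chrom_end_right))
                _set_strand(chromatid, m, iv, "W", donor)
                truth.tracts.append(TractTruth(broken_idx, "het", *iv, strand="W"))
            else:
                end = gap_iv[0] - 1 if want_het == "same" else d - 1
                iv = (max(int(end - Lh + 1), chrom_end_left), end)
                _set_strand(chromatid, m, iv, "C", donor)
                truth.tracts.append(TractTruth(broken_idx, "het", *iv, strand="C"))
    else:  # pragma: no cover - enum is exhaustive
        raise InvalidParameterError(f"unknown mechanism {mechanism!r}")

    if (
        mechanism
        in (Mechanism.ONE_ENDED_SDSA, Mechanism.TWO_ENDED_SDSA, Mechanism.DHJ_DISSOLUTION)
        and config.p_template_switch > 0
        and rng.random() < config.p_template_switch
    ):
        _template_switch(state, truth, config, rng)

    state.repairs.append(truth)
    return truth


def _branch_migrate(
    state: MotherCellState,
    truth: RepairTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Extend a junction-containing intermediate by branch migration.

    Migration of a Holliday junction past the heteroduplex boundary creates
    *symmetric* heteroduplex: both interacting chromatids acquire a foreign
    strand over the same interval.  Such events fall outside the eight
    simple classes.
    """
    het_tracts = [t for t in truth.tracts if t.kind == "het"]
    if not het_tracts:
        return
    m = state.marker_map
    t = het_tracts[int(rng.integers(len(het_tracts)))]
    L = config.branch_migration_length.draw(rng)
    if L <= 0:
        return
    d = truth.dsb_position
    if t.end < d:  # tract on the left: migrate further left
        iv = (max(int(t.start - L), int(m.positions[0])), t.start - 1)
    else:
        iv = (t.end + 1, min(int(t.end + L), int(m.positions[-1])))
    if iv[0] > iv[1]:
        return
    idx = m.markers_in(iv[0], iv[1])
    if idx.size == 0:
        return
    owner = t.chromatid
    partner = (
        truth.donor_chromatid if owner == truth.chromatid else truth.chromatid
    )
    own_strand = t.strand or "W"
    other_strand = "C" if own_strand == "W" else "W"
    # symmetric heteroduplex: on each interacting chromatid, one strand
    # flips against the local duplex content (works on either side of a
    # crossover exchange point)
    c_owner = state.chromatids[owner]
    c_partner = state.chromatids[partner]
    c_owner.strand(own_strand)[idx] = 1 - c_owner.strand(own_strand)[idx]
    c_partner.strand(other_strand)[idx] = 1 - c_partner.strand(other_strand)[idx]
    truth.tracts.append(TractTruth(owner, "symmetric_het", *iv, strand=own_strand))
    truth.tracts.append(TractTruth(partner, "symmetric_het", *iv))


def _template_switch(
    state: MotherCellState,
    truth: RepairTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Interrupt a heteroduplex tract with a restored (recipient) block."""
    het_tracts = [t for t in truth.tracts if t.kind == "het"]
    if not het_tracts:
        return
    m = state.marker_map
    t = het_tracts[int(rng.integers(len(het_tracts)))]
    span = t.end - t.start
    L = min(config.template_switch_length.draw(rng), span * 0.5)
    if L < 1 or span < 4:
        return
    start = int(t.start + rng.integers(1, max(2, int(span - L))))
    iv = (start, int(start + L))
    rec = state.chromatids[truth.chromatid]
    _set_strand(rec, m, iv, t.strand or "W", rec.centromere_origin)
    truth.tracts.append(TractTruth(truth.chromatid, "restoration", *iv))


def simulate_repair(
    brk: BreakDescription,
    mechanism,
    config: SimConfig,
    marker_map: MarkerMap,
    *,
    rng: Optional[np.random.Generator] = None,
    lengths: Optional[dict] = None,
) -> MotherCellState:
    """Build a mother-cell state realizing one mechanism for one break.

    For a DSCB ``brk`` the same mechanism (and explicit ``lengths``, if
    given) is applied to both broken sisters; ``simulate_colony`` is the
    driver that draws mechanisms independently per sister.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state = MotherCellState(marker_map, parental_chromatids(marker_map), brk=brk)
    donor_pool = state.sister_indices(other_origin(brk.recipient_origin))
    for k, broken_idx in enumerate(brk.chromatid_indices):
        apply_repair(
            state,
            broken_idx,
            donor_pool[k % len(donor_pool)],
            mechanism,
            config,
            brk.position,
            rng,
            lengths=lengths,
        )
    return state


# ---------------------------------------------------------------------------
# mismatch repair


def apply_mmr(
    chromatid: Chromatid,
    mode,
    *,
    donor_origin: Optional[int] = None,
    patch_median: float = 300.0,
    marker_map: Optional[MarkerMap] = None,
    rng: Optional[np.random.Generator] = None,
) -> Chromatid:
    """Repair (or not) the mismatches of a chromatid, returning a new one.

    CONVERSION writes the donor origin on both strands at every mismatch;
    RESTORATION writes the recipient origin (the chromatid becomes identical
    to an unbroken parental chromatid when all its mismatches derive from
    one tract); PATCHY alternates conversion- and restoration-type repair in
    contiguous patches (geometric patch lengths around ``patch_median`` bp);
    NONE is the identity (the mlh1 situation).

    ``donor_origin`` defaults to the opposite of the chromatid's centromere
    origin, which is correct for tracts laid on an unexchanged recipient.
    """
    mode = MMRMode(mode)
    out = chromatid.copy()
    if mode == MMRMode.NONE:
        return out
    mm = np.flatnonzero(out.mismatches())
    if mm.size == 0:
        return out
    donor = (
        donor_origin
        if donor_origin is not None
        else other_origin(chromatid.centromere_origin)
    )
    recipient = other_origin(donor)
    if mode == MMRMode.CONVERSION:
        out.watson[mm] = donor
        out.crick[mm] = donor
    elif mode == MMRMode.RESTORATION:
        out.watson[mm] = recipient
        out.crick[mm] = recipient
    else:  # PATCHY
        if rng is None:
            rng = np.random.default_rng(0)
        positions = (
            marker_map.positions[mm] if marker_map is not None else mm.astype(float)
        )
        scale = patch_median / np.log(2.0) if marker_map is not None else 3.0
        choice = rng.random() < 0.5
        edge = positions[0] + rng.exponential(scale)
        for j, pos in zip(mm, positions):
            while pos > edge:
                choice = not choice
                edge += rng.exponential(scale)
            target = donor if choice else recipient
            out.watson[j] = target
            out.crick[j] = target
    return out


# ---------------------------------------------------------------------------
# segregation, replication, phenotype


def segregate_daughters(
    mother: MotherCellState,
    rng: np.random.Generator,
    *,
    prefer_sectored: bool = True,
) -> tuple[Daughter, Daughter, bool]:
    """Segregate the four chromatids: one per centromere origin per daughter.

    When a crossover occurred, the segregation that co-segregates the
    recombined chromatids (SUP4-o copy numbers 2 and 0 -> a red/white
    sectored colony) is chosen when ``prefer_sectored``; otherwise, and for
    non-CO mothers, the pairing is random.  Returns (D1, D2, sectored) with
    D1 the white-side (SUP4-o = 2) daughter when sectored.
    """
    m = mother.marker_map
    r = mother.sister_indices(ORIGIN_R)
    b = mother.sister_indices(ORIGIN_B)
    pairings = [
        ((r[0], b[0]), (r[1], b[1])),
        ((r[0], b[1]), (r[1], b[0])),
    ]

    def build(pair):
        chroms = [mother.chromatids[i] for i in pair]
        copies = sum(c.sup4_copies(m) for c in chroms)
        return Daughter(pair, chroms, copies)

    options = [(build(p1), build(p2)) for p1, p2 in pairings]
    if prefer_sectored:
        for d1, d2 in options:
            if {d1.sup4_copies, d2.sup4_copies} == {2.0, 0.0}:
                if d1.sup4_copies == 2.0:
                    return d1, d2, True
                return d2, d1, True
    d1, d2 = options[int(rng.integers(2))]
    return d1, d2, False


def replicate_to_granddaughters(
    daughter: Daughter, rng: np.random.Generator
) -> tuple[GranddaughterGenotype, GranddaughterGenotype]:
    """Semiconservative replication at marker resolution.

    Each chromosome's Watson strand seeds one granddaughter homolog and its
    Crick strand the other; which granddaughter receives which strand is
    random per chromosome.  Every daughter strand appears, marker for
    marker, as exactly one granddaughter homolog.
    """
    homologs_a, homologs_b = [], []
    sources_a, sources_b = [], []
    for chrom_idx, chrom in zip(daughter.chromatid_indices, daughter.chromatids):
        first_w = bool(rng.integers(2))
        if first_w:
            homologs_a.append(chrom.watson.copy())
            homologs_b.append(chrom.crick.copy())
            sources_a.append((chrom_idx, "W"))
            sources_b.append((chrom_idx, "C"))
        else:
            homologs_a.append(chrom.crick.copy())
            homologs_b.append(chrom.watson.copy())
            sources_a.append((chrom_idx, "C"))
            sources_b.append((chrom_idx, "W"))
    gda = GranddaughterGenotype(np.stack(homologs_a), tuple(sources_a))
    gdb = GranddaughterGenotype(np.stack(homologs_b), tuple(sources_b))
    return gda, gdb


def colony_color(sup4_copies: int) -> str:
    """SUP4-o dosage phenotype: 0 -> red, 1 -> pink, 2 -> white."""
    colors = {0: "red", 1: "pink", 2: "white"}
    try:
        return colors[int(sup4_copies)]
    except (KeyError, ValueError, TypeError):
        raise InvalidParameterError(
            f"sup4_copies must be 0, 1 or 2 (got {sup4_copies!r})"
        ) from None


# ---------------------------------------------------------------------------
# colony / cohort drivers


def simulate_colony(
    config: SimConfig, marker_map: MarkerMap, rng: np.random.Generator
) -> Colony:
    """One UV-style event: break, per-sister repair, MMR, segregation,
    replication into the four granddaughter genotypes."""
    brk = initiate_break(config, marker_map, rng)
    state = MotherCellState(
        marker_map, parental_chromatids(marker_map), brk=brk
    )
    donor_pool = state.sister_indices(other_origin(brk.recipient_origin))
    mechs = list(config.mechanism_weights)
    weights = np.array([config.mechanism_weights[k] for k in mechs])
    for k, broken_idx in enumerate(brk.chromatid_indices):
        if (
            config.sister_repair_fraction > 0
            and rng.random() < config.sister_repair_fraction
        ):
            continue  # repaired off the sister: invisible to the assay
        mech = mechs[int(rng.choice(len(mechs), p=weights))]
        apply_repair(
            state, broken_idx, donor_pool[k % 2], mech, config, brk.position, rng
        )
    # Mlh1-dependent MMR (a no-op under the mlh1 default)
    modes = list(config.mmr_probs)
    probs = np.array([config.mmr_probs[k] for k in modes])
    for repair in state.repairs:
        mode = modes[int(rng.choice(len(modes), p=probs))]
        repair.mmr_mode = mode
        if mode != MMRMode.NONE:
            idx = repair.chromatid
            state.chromatids[idx] = apply_mmr(
                state.chromatids[idx],
                mode,
                donor_origin=state.chromatids[
                    repair.donor_chromatid
                ].centromere_origin,
                patch_median=config.mmr_patch_median,
                marker_map=marker_map,
                rng=rng,
            )
    d1, d2, sectored = segregate_daughters(mother=state, rng=rng)
    gd = {}
    for prefix, daughter in (("W", d1), ("R", d2)):
        a, b = replicate_to_granddaughters(daughter, rng)
        gd[f"{prefix}1"], gd[f"{prefix}2"] = a, b
    colors = tuple(
        colony_color(int(d.sup4_copies))
        if float(d.sup4_copies).is_integer() and 0 <= d.sup4_copies <= 2
        else "undetermined"
        for d in (d1, d2)
    )
    return Colony(state, (d1, d2), gd, sectored, colors)


def simulate_cohort(
    config: SimConfig,
    marker_map: MarkerMap,
    n_colonies: int,
    *,
    seed: Optional[int] = None,
    selection: bool = True,
    max_tries: int = 2_000_000,
) -> list[Colony]:
    """Simulate a cohort of colonies, reproducibly under a fixed seed.

    With ``selection`` on, only colonies whose selected chromosome produced
    a red/white sector (a crossover with the sectored segregation) are
    emitted, mirroring the SUP4-o assay; the rejection rate then reflects
    the CO mechanism weight and the SUP4-o--centromere interval length.
    """
    if n_colonies < 1:
        raise InvalidParameterError("n_colonies must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: list[Colony] = []
    tries = 0
    while len(out) < n_colonies:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("selection rejection exceeded max_tries")
        colony = simulate_colony(config, marker_map, rng)
        if selection and not colony.sectored:
            continue
        out.append(colony)
    return out
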