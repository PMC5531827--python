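"""Event calling from a reconstructed mother cell.

Given the four reconstructed chromatids (assayed-marker resolution), this
module calls:

* initiation — SCB (one repair event), DSCB (two or more), or NONE;
* outcome per repair — CO (reciprocal terminal exchange on two chromatids
  from different sister pairs), BIR (unpartnered terminal donor
  homozygosity), or NCO;
* event class — the eight "simple" templates, with COMPLEX as a strict
  fallback;
* the DSB interval — never a fabricated point: the two markers bracketing
  a strand switch or crossover exchange when one exists, otherwise the
  full tract span;
* tract lengths — the average of the maximum tract (distance between the
  closest unaffected flanking markers) and the minimum tract (distance
  between the outermost affected markers); for a CO the two chromatids'
  tracts are measured against the exchange boundary and summed.

Class templates (NCO: 1, 2, 3, 5, 8; CO: 4, 6, 7):

1. single unidirectional heteroduplex, no strand switch
2. single continuous conversion tract
3. hybrid conversion + heteroduplex, contiguous, one side of the DSB
4. CO with a heteroduplex on only one chromatid
5. heteroduplex one side of the DSB, conversion tract the other
6. CO, unidirectional heteroduplexes on both chromatids, opposite
   directions flanking the exchange
7. CO with no visible heteroduplex or conversion on either chromatid
8. NCO, conversion tract on one chromatid and a heteroduplex at the same
   position on the other

Classes 3 and 5 show the same single-chromatid pattern (a conversion run
adjacent to a heteroduplex run); they differ only in where the initiating
break sat.  When another repair of the same colony localizes the break
tightly (a crossover exchange point or a strand switch — the DSCB
situation), the junction is tested against it; otherwise the hybrid tract
is reported as Class 3, reading the tract as lying on one side of a break
at its edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome import ORIGIN_LABELS, other_origin
from .inference import MISSING, ReconChromatid, ReconstructedMother

PAR, HETD, CONV = 0, 1, 2

COMPLEX = "COMPLEX"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class Tract:
    """One maximal same-kind run of altered markers on a chromatid."""

    chromatid: int
    kind: str  # "het" | "conv"
    first_index: int  # assayed-marker index
    last_index: int
    first_bp: int
    last_bp: int
    v_first: int  # position within the chromatid's called-marker sequence
    v_last: int
    terminal: bool = False  # conversion run reaching a chromosome end
    ratio: str = ""  # "3:1" | "4:0" | "het"
    has_strand_switch: bool = False
    switch_bracket: Optional[tuple[int, int]] = None  # bp

    @property
    def n_markers(self) -> int:
        return self.v_last - self.v_first + 1


@dataclass
class EventCall:
    """One inferred repair event."""

    chromatids: tuple[int, ...]
    outcome: str  # "CO" | "NCO" | "BIR"
    event_class: object = None  # 1..8 | "COMPLEX" | None (BIR)
    recipient: Optional[str] = None  # "R" | "B" | "AMBIGUOUS" | None
    dsb_interval: Optional[tuple[int, int]] = None  # bp, endpoints inclusive
    dsb_tight: bool = False
    tracts: list[Tract] = field(default_factory=list)
    tract_length_bp: Optional[float] = None
    length_flagged: bool = False  # a flank fell off the chromosome end
    notes: list[str] = field(default_factory=list)


@dataclass
class ColonyCall:
    initiation: str  # "SCB" | "DSCB" | "NONE"
    events: list[EventCall]
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# low-level per-chromatid scan


@dataclass
class _ChromScan:
    valid_idx: np.ndarray  # assayed-marker indices with both strands called
    states: np.ndarray  # PAR/HETD/CONV over valid markers
    tracts: list[Tract]
    terminal: list[Tract]


def _scan_chromatid(
    k: int, chrom: ReconChromatid, positions: np.ndarray
) -> _ChromScan:
    valid_idx = np.flatnonzero(chrom.valid())
    a = chrom.strand_a[valid_idx]
    b = chrom.strand_b[valid_idx]
    o = chrom.centromere_origin
    states = np.full(valid_idx.size, PAR, dtype=np.int8)
    states[a != b] = HETD
    states[(a == b) & (a == other_origin(o))] = CONV

    tracts: list[Tract] = []
    n = states.size
    s = 0
    while s < n:
        if states[s] == PAR:
            s += 1
            continue
        e = s
        while e + 1 < n and states[e + 1] == states[s]:
            e += 1
        kind = "het" if states[s] == HETD else "conv"
        t = Tract(
            chromatid=k,
            kind=kind,
            first_index=int(valid_idx[s]),
            last_index=int(valid_idx[e]),
            first_bp=0,
            last_bp=0,
            v_first=s,
            v_last=e,
        )
        t.first_bp = int(positions[t.first_index])
        t.last_bp = int(positions[t.last_index])
        if kind == "conv" and (s == 0 or e == n - 1):
            t.terminal = True
        if kind == "het":
            run_a = a[s : e + 1]
            if run_a.min() != run_a.max():
                t.has_strand_switch = True
                flip = int(np.flatnonzero(np.diff(run_a) != 0)[0])
                t.switch_bracket = (
                    int(positions[valid_idx[s + flip]]),
                    int(positions[valid_idx[s + flip + 1]]),
                )
        tracts.append(t)
        s = e + 1
    terminal = [t for t in tracts if t.terminal]
    interior = [t for t in tracts if not t.terminal]
    return _ChromScan(valid_idx, states, interior, terminal)


def _flank_bp(
    scan: _ChromScan, positions: np.ndarray, v: int, direction: int, want=PAR
) -> Optional[int]:
    """bp of the nearest called marker with the wanted state beyond v."""
    j = v + direction
    while 0 <= j < scan.states.size:
        if scan.states[j] == want or want is None:
            return int(positions[scan.valid_idx[j]])
        j += direction
    return None


def tract_length_from_bounds(
    inner_lo: float, inner_hi: float, outer_lo: float, outer_hi: float
) -> float:
    """Average of the maximum and minimum tract length.

    ``inner`` are the outermost affected markers (minimum tract), ``outer``
    the closest unaffected markers flanking the tract (maximum tract).
    """
    return ((outer_hi - outer_lo) + (inner_hi - inner_lo)) / 2.0


# ---------------------------------------------------------------------------
# event assembly


def _intervals_overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] <= y[1] and y[0] <= x[1]


def call_events(rm: ReconstructedMother) -> ColonyCall:
    """Assemble repair events and classify them; see module docstring."""
    positions = rm.positions
    scans = [
        _scan_chromatid(k, c, positions) for k, c in enumerate(rm.chromatids)
    ]
    notes: list[str] = []

    # -- crossover / BIR detection from terminal conversion runs
    co_pairs: list[tuple[int, int, str]] = []  # (chromatid, chromatid, end)
    bir: list[tuple[int, str]] = []
    for end in ("L", "R"):
        cands = []
        for k, sc in enumerate(scans):
            for t in sc.terminal:
                at_left = t.v_first == 0
                if (end == "L") == at_left:
                    cands.append(k)
                    break
        while len(cands) >= 2:
            k0 = cands.pop(0)
            partner = next(
                (
                    k
                    for k in cands
                    if rm.chromatids[k].centromere_origin
                    != rm.chromatids[k0].centromere_origin
                ),
                None,
            )
            if partner is None:
                bir.append((k0, end))
                continue
            cands.remove(partner)
            co_pairs.append((k0, partner, end))
        for k in cands:
            bir.append((k, end))

    events: list[EventCall] = []
    used = set()

    for k0, k1, end in co_pairs:
        ev = EventCall(chromatids=(k0, k1), outcome="CO")
        ev.tracts = list(scans[k0].tracts) + list(scans[k1].tracts)
        _resolve_co(ev, rm, scans, end)
        events.append(ev)
        used.update((k0, k1))

    for k, end in bir:
        ev = EventCall(chromatids=(k,), outcome="BIR")
        ev.tracts = list(scans[k].tracts)
        term = next(
            t
            for t in scans[k].terminal
            if (t.v_first == 0) == (end == "L")
        )
        flank = _flank_bp(scans[k], positions, term.v_first, -1) if end == "R" else _flank_bp(
            scans[k], positions, term.v_last, +1
        )
        inner = term.first_bp if end == "R" else term.last_bp
        if flank is not None:
            ev.dsb_interval = tuple(sorted((flank, inner)))
        ev.recipient = ORIGIN_LABELS[rm.chromatids[k].centromere_origin]
        events.append(ev)
        used.add(k)

    # -- non-crossover events on the remaining chromatids
    remaining = [
        k for k, sc in enumerate(scans) if k not in used and sc.tracts
    ]
    # Class 8 merge: a conversion-bearing chromatid absorbs an overlapping
    # heteroduplex-only chromatid from the other homolog.
    merged_partner: dict[int, int] = {}
    for k in list(remaining):
        if any(t.kind == "conv" for t in scans[k].tracts):
            for j in list(remaining):
                if j == k or j in merged_partner or k in merged_partner.values():
                    continue
                if (
                    rm.chromatids[j].centromere_origin
                    == rm.chromatids[k].centromere_origin
                ):
                    continue
                if any(t.kind == "conv" for t in scans[j].tracts):
                    continue
                span_k = [
                    (t.first_bp, t.last_bp)
                    for t in scans[k].tracts
                    if t.kind == "conv"
                ]
                span_j = [(t.first_bp, t.last_bp) for t in scans[j].tracts]
                if any(
                    _intervals_overlap(x, y) for x in span_k for y in span_j
                ):
                    merged_partner[k] = j
    absorbed = set(merged_partner.values())
    for k in remaining:
        if k in absorbed:
            continue
        chroms = (k,) if k not in merged_partner else (k, merged_partner[k])
        ev = EventCall(chromatids=chroms, outcome="NCO")
        ev.tracts = [t for kk in chroms for t in scans[kk].tracts]
        ev.recipient = ORIGIN_LABELS[rm.chromatids[k].centromere_origin]
        events.append(ev)

    # -- per-event refinement
    _annotate_ratios(events, rm, scans)
    tight = [
        ev.dsb_interval
        for ev in events
        if ev.dsb_tight and ev.dsb_interval is not None
    ]
    for t in (
        t for ev in events for t in ev.tracts if t.switch_bracket is not None
    ):
        tight.append(t.switch_bracket)
    for ev in events:
        if ev.outcome == "NCO":
            _classify_nco(ev, rm, scans, tight)
        _measure_tract(ev, rm, scans)

    if not events:
        initiation = "NONE"
    elif len(events) == 1:
        initiation = "SCB"
    else:
        initiation = "DSCB"
        recips = {ev.recipient for ev in events if ev.recipient in ("R", "B")}
        if len(recips) > 1:
            notes.append("repair events on different homologs")
    return ColonyCall(initiation=initiation, events=events, notes=notes)


# ---------------------------------------------------------------------------
# crossover geometry


def _co_brackets(
    scan: _ChromScan, positions: np.ndarray, end: str
) -> tuple[Optional[tuple], Optional[tuple], Optional[Tract]]:
    """Candidate exchange brackets for one CO product.

    Returns (bracket_if_donor, bracket_if_recipient, adjacent_het).  The
    donor-centromere product carries its heteroduplex distal to the
    exchange (between the parental region and the exchanged arm), the
    recipient-centromere product proximal to it.
    """
    term = next(t for t in scan.terminal if (t.v_first == 0) == (end == "L"))
    inward = +1 if end == "L" else -1  # direction from terminal run to cen
    # marker adjacent to the terminal run on the centromere side
    edge_v = term.v_last if end == "L" else term.v_first
    j = edge_v + inward
    het = None
    if 0 <= j < scan.states.size and scan.states[j] == HETD:
        # find the het tract containing j
        for t in scan.tracts:
            if t.kind == "het" and t.v_first <= j <= t.v_last:
                het = t
                break
    term_edge_bp = int(positions[scan.valid_idx[edge_v]])
    if het is None:
        par_bp = _flank_bp(scan, positions, edge_v, inward)
        if par_bp is None:
            par_bp = term_edge_bp
        bracket = tuple(sorted((par_bp, term_edge_bp)))
        return bracket, bracket, None
    het_inner_v = het.v_last if end == "L" else het.v_first
    het_outer_v = het.v_first if end == "L" else het.v_last
    par_bp = _flank_bp(scan, positions, het_inner_v, inward)
    if par_bp is None:
        par_bp = int(positions[scan.valid_idx[het_inner_v]])
    # donor product: exchange between parental region and the heteroduplex
    b_donor = tuple(
        sorted((par_bp, int(positions[scan.valid_idx[het_inner_v]])))
    )
    # recipient product: exchange between the heteroduplex and the arm
    b_recip = tuple(
        sorted((int(positions[scan.valid_idx[het_outer_v]]), term_edge_bp))
    )
    return b_donor, b_recip, het


def _resolve_co(
    ev: EventCall,
    rm: ReconstructedMother,
    scans: list[_ChromScan],
    end: str,
) -> None:
    k0, k1 = ev.chromatids
    d0, r0, het0 = _co_brackets(scans[k0], rm.positions, end)
    d1, r1, het1 = _co_brackets(scans[k1], rm.positions, end)
    options = []
    if _intervals_overlap(r0, d1):  # k0 recipient
        lo = max(r0[0], d1[0])
        hi = min(r0[1], d1[1])
        options.append((k0, (lo, hi)))
    if _intervals_overlap(r1, d0):  # k1 recipient
        lo = max(r1[0], d0[0])
        hi = min(r1[1], d0[1])
        options.append((k1, (lo, hi)))
    n_het = sum(h is not None for h in (het0, het1))
    if len(options) == 1:
        rk, bracket = options[0]
        ev.recipient = ORIGIN_LABELS[rm.chromatids[rk].centromere_origin]
        ev.dsb_interval = bracket
        ev.dsb_tight = True
    elif len(options) == 2:
        ev.recipient = AMBIGUOUS if n_het == 0 else ORIGIN_LABELS[
            rm.chromatids[options[0][0]].centromere_origin
        ]
        if n_het == 0:
            ev.recipient = AMBIGUOUS
        ev.dsb_interval = options[0][1]
        ev.dsb_tight = True
    else:
        ev.recipient = AMBIGUOUS
        span = [x for b in (d0, r0, d1, r1) for x in b]
        ev.dsb_interval = (min(span), max(span))
        ev.notes.append("exchange geometry inconsistent")

    # class assignment for the CO
    interior = ev.tracts
    any_switch = any(t.has_strand_switch for t in interior)
    kinds = sorted(t.kind for t in interior)
    if any(t.kind == "conv" for t in interior) or any_switch:
        ev.event_class = COMPLEX
    elif len(interior) == 0:
        ev.event_class = 7
        ev.recipient = AMBIGUOUS
    elif len(interior) == 1 and (interior[0] is het0 or interior[0] is het1):
        ev.event_class = 4
    elif (
        len(interior) == 2
        and het0 is not None
        and het1 is not None
        and any(t is het0 for t in interior)
        and any(t is het1 for t in interior)
        and len(options) >= 1
        and not _intervals_overlap(
            (het0.first_bp, het0.last_bp), (het1.first_bp, het1.last_bp)
        )
    ):
        ev.event_class = 6
    else:
        ev.event_class = COMPLEX


# ---------------------------------------------------------------------------
# non-crossover classification


def _classify_nco(
    ev: EventCall,
    rm: ReconstructedMother,
    scans: list[_ChromScan],
    tight_brackets: list[tuple[int, int]],
) -> None:
    anchor = ev.chromatids[0]
    own = [t for t in ev.tracts if t.chromatid == anchor]
    partner = [t for t in ev.tracts if t.chromatid != anchor]
    hets = [t for t in own if t.kind == "het"]
    convs = [t for t in own if t.kind == "conv"]
    if any(t.has_strand_switch for t in hets):
        ev.event_class = COMPLEX
        sw = next(t.switch_bracket for t in hets if t.has_strand_switch)
        ev.dsb_interval = sw
        ev.dsb_tight = True
        ev.notes.append("heteroduplex spans the break (strand switch)")
        return
    if partner:
        # merged two-chromatid event: the Class 8 template or complex
        if (
            len(own) == 1
            and len(convs) == 1
            and len(partner) == 1
            and partner[0].kind == "het"
        ):
            ev.event_class = 8
            t = convs[0]
            ev.dsb_interval = (t.first_bp, t.last_bp)
        else:
            ev.event_class = COMPLEX
            lo = min(t.first_bp for t in ev.tracts)
            hi = max(t.last_bp for t in ev.tracts)
            ev.dsb_interval = (lo, hi)
        return
    if len(own) == 1:
        t = own[0]
        ev.event_class = 1 if t.kind == "het" else 2
        ev.dsb_interval = (t.first_bp, t.last_bp)
        return
    if len(own) == 2 and len(hets) == 1 and len(convs) == 1:
        left, right = sorted(own, key=lambda t: t.v_first)
        adjacent = right.v_first == left.v_last + 1
        if adjacent:
            junction = (left.last_bp, right.first_bp)
            at_break = any(
                _intervals_overlap(junction, b) for b in tight_brackets
            )
            if at_break:
                ev.event_class = 5
                ev.dsb_interval = junction
                ev.dsb_tight = True
            else:
                ev.event_class = 3
                ev.dsb_interval = (left.first_bp, right.last_bp)
            return
    ev.event_class = COMPLEX
    ev.dsb_interval = (
        min(t.first_bp for t in own),
        max(t.last_bp for t in own),
    )


# ---------------------------------------------------------------------------
# segregation-ratio annotation and tract lengths


def _annotate_ratios(
    events: list[EventCall],
    rm: ReconstructedMother,
    scans: list[_ChromScan],
) -> None:
    for ev in events:
        for t in ev.tracts:
            if t.kind == "het":
                t.ratio = "het"
                continue
            o = rm.chromatids[t.chromatid].centromere_origin
            sisters = [
                i for i in rm.sister_indices(o) if i != t.chromatid
            ]
            four_zero = False
            for s in sisters:
                sc = scans[s]
                for st in sc.tracts:
                    if st.kind == "conv" and _intervals_overlap(
                        (st.first_bp, st.last_bp), (t.first_bp, t.last_bp)
                    ):
                        four_zero = True
            t.ratio = "4:0" if four_zero else "3:1"


def _measure_tract(
    ev: EventCall, rm: ReconstructedMother, scans: list[_ChromScan]
) -> None:
    positions = rm.positions
    if ev.outcome == "BIR" or not ev.tracts:
        ev.tract_length_bp = None
        return
    if ev.outcome == "CO":
        total = 0.0
        measured = False
        for k in ev.chromatids:
            own = [t for t in ev.tracts if t.chromatid == k]
            if not own:
                continue
            sc = scans[k]
            v_lo = min(t.v_first for t in own)
            v_hi = max(t.v_last for t in own)
            inner_lo = float(positions[sc.valid_idx[v_lo]])
            inner_hi = float(positions[sc.valid_idx[v_hi]])
            lo_flank = _flank_bp(sc, positions, v_lo, -1, want=None)
            hi_flank = _flank_bp(sc, positions, v_hi, +1, want=None)
            if lo_flank is None:
                lo_flank, ev.length_flagged = float(positions[0]), True
            if hi_flank is None:
                hi_flank, ev.length_flagged = float(positions[-1]), True
            total += tract_length_from_bounds(
                inner_lo, inner_hi, lo_flank, hi_flank
            )
            measured = True
        ev.tract_length_bp = total if measured else None
        return
    anchor = ev.chromatids[0]
    sc = scans[anchor]
    own = [t for t in ev.tracts if t.chromatid == anchor]
    v_lo = min(t.v_first for t in own)
    v_hi = max(t.v_last for t in own)
    inner_lo = float(positions[sc.valid_idx[v_lo]])
    inner_hi = float(positions[sc.valid_idx[v_hi]])
    lo_flank = _flank_bp(sc, positions, v_lo, -1)
    hi_flank = _flank_bp(sc, positions, v_hi, +1)
    if lo_flank is None:
        lo_flank, ev.length_flagged = float(positions[0]), True
    if hi_flank is None:
        hi_flank, ev.length_flagged = float(positions[-1]), True
    ev.tract_length_bp = tract_length_from_bounds(
        inner_lo, inner_hi, lo_flank, hi_flank
    )


# ---------------------------------------------------------------------------
# spec-level convenience operations


def classify_initiation(rm: ReconstructedMother) -> str:
    """SCB, DSCB or NONE for a reconstructed mother cell."""
    return call_events(rm).initiation


def classify_outcomes(rm: ReconstructedMother) -> list[str]:
    """Outcome (CO/NCO/BIR) of each repair event."""
    return [ev.outcome for ev in call_events(rm).events]


def assign_classes(rm: ReconstructedMother) -> list[object]:
    """Event class (1-8, COMPLEX, or None for BIR) of each repair event."""
    return [ev.event_class for ev in call_events(rm).events]
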