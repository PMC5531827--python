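"""Plain-text interchange: TSV/BED/JSON writers and readers.

Internal coordinates are 1-based; BED exports are 0-based half-open.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd

from .arrays import CALL_LABELS, HybProfile, ZygositySegments
from .classify import ColonyCall
from .genome import MarkerMap, ORIGIN_LABELS
from .inference import ReconstructedMother
from .simulate import Colony, GranddaughterGenotype

ZYG_LABELS = {0: "HET", 1: "HOM_R", 2: "HOM_B"}


def write_genotypes_tsv(
    colony: Colony, marker_map: MarkerMap, path, *, assayed_only: bool = True
) -> None:
    """Marker x granddaughter zygosity matrix (HET / HOM_R / HOM_B)."""
    idx = (
        marker_map.assayed_indices
        if assayed_only
        else np.arange(marker_map.n_markers)
    )
    cols = {
        "chrom": marker_map.chromosome_id,
        "pos": marker_map.positions[idx],
    }
    for name in ("W1", "W2", "R1", "R2"):
        z = colony.granddaughters[name].zygosity()[idx]
        cols[name] = [ZYG_LABELS[int(v)] for v in z]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: HybProfile, chromosome_id: str, path) -> None:
    pd.DataFrame(
        {
            "chrom": chromosome_id,
            "pos": profile.positions,
            "ratio_R": np.round(profile.ratio_r, 4),
            "ratio_B": np.round(profile.ratio_b, 4),
        }
    ).to_csv(path, sep="\t", index=False)


def write_segments_bed(
    segments: ZygositySegments, chromosome_id: str, path
) -> None:
    """Zygosity segments as BED (0-based half-open, name = state)."""
    rows = [
        (chromosome_id, s.first_bp - 1, s.last_bp, s.label)
        for s in segments.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_transitions_tsv(
    segments: ZygositySegments, chromosome_id: str, path
) -> None:
    rows = [
        {
            "chrom": chromosome_id,
            "last_bp_prev": lo,
            "first_bp_next": hi,
        }
        for lo, hi in segments.transitions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def reconstruction_to_dict(rm: ReconstructedMother) -> dict:
    return {
        "centromere_position": int(rm.centromere_position),
        "chromatids": [
            {
                "strand_ids": list(c.strand_ids),
                "sector": c.sector,
                "centromere_origin": ORIGIN_LABELS[c.centromere_origin],
            }
            for c in rm.chromatids
        ],
        "het_segments": [
            {
                "chromatid": s.chromatid,
                "first_bp": s.first_bp,
                "last_bp": s.last_bp,
            }
            for s in rm.het_segments
        ],
    }


def colony_call_to_dict(call: ColonyCall) -> dict:
    return {
        "initiation": call.initiation,
        "notes": list(call.notes),
        "events": [
            {
                "chromatids": list(ev.chromatids),
                "outcome": ev.outcome,
                "class": ev.event_class,
                "recipient": ev.recipient,
                "dsb_interval": list(ev.dsb_interval)
                if ev.dsb_interval
                else None,
                "dsb_tight": ev.dsb_tight,
                "tract_length_bp": ev.tract_length_bp,
                "tracts": [
                    {
                        "chromatid": t.chromatid,
                        "kind": t.kind,
                        "ratio": t.ratio,
                        "first_bp": t.first_bp,
                        "last_bp": t.last_bp,
                    }
                    for t in ev.tracts
                ],
            }
            for ev in call.events
        ],
    }


def write_event_calls(calls: Iterable[ColonyCall], path) -> None:
    """Event-call table: one row per event, JSON-compatible columns."""
    rows = []
    for i, call in enumerate(calls):
        for j, ev in enumerate(call.events):
            rows.append(
                {
                    "colony": i,
                    "event": j,
                    "initiation": call.initiation,
                    "outcome": ev.outcome,
                    "class": str(ev.event_class),
                    "recipient": ev.recipient,
                    "dsb_lo": ev.dsb_interval[0] if ev.dsb_interval else None,
                    "dsb_hi": ev.dsb_interval[1] if ev.dsb_interval else None,
                    "tract_length_bp": ev.tract_length_bp,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_coerce)


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
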