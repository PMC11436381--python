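"""Copy-number typing, complex-event grouping and arm labelling.

Typing compares the call's mean LRR against the three expectations implied
by its fitted bdev ``d``: a gain at fraction ``f_g = 4d/(1-2d)`` predicts
``log2(1 + f_g/2)``, a loss at ``f_l = 4d/(1+2d)`` predicts
``log2(1 - f_l/2)``, and copy-neutral LOH predicts 0.  The winner is the
type with the smallest standardized distance; when the top two are closer
than a margin the type is left undetermined — a real, expected category on
arrays, not a failure mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .caller import MosaicCall, estimate_cell_fraction
from .genome import GenomeBuild, interval_overlap

__all__ = ["classify_type", "merge_complex", "arm_label", "CompositeEvent"]

_TYPE_TOKEN = {"gain": "dup", "loss": "del", "cnloh": "loh", "undetermined": "und"}

_SE_FLOOR = 1e-3


def classify_type(call: MosaicCall, margin: float = 1.5) -> str:
    """Assign gain / loss / cnloh / undetermined from (bdev, LRR)."""
    d = call.bdev
    if math.isnan(call.lrr_mean):
        return "undetermined"
    se = max(call.lrr_se if not math.isnan(call.lrr_se) else _SE_FLOOR, _SE_FLOOR)
    expected = {}
    for typ in ("gain", "loss", "cnloh"):
        f_t = estimate_cell_fraction(d, typ)
        if typ == "gain":
            e = math.log2(1.0 + f_t / 2.0)
        elif typ == "loss":
            e = math.log2(1.0 - f_t / 2.0)
        else:
            e = 0.0
        expected[typ] = abs(call.lrr_mean - e) / se
    ranked = sorted(expected, key=expected.get)
    if expected[ranked[1]] - expected[ranked[0]] < margin:
        return "undetermined"
    return ranked[0]


@dataclass
class CompositeEvent:
    """One or more adjacent calls reported as a single complex event."""

    calls: list[MosaicCall] = field(default_factory=list)
    group: str | None = None

    @property
    def chrom(self) -> str:
        return self.calls[0].chrom

    @property
    def start(self) -> int:
        return min(c.start for c in self.calls)

    @property
    def end(self) -> int:
        return max(c.end for c in self.calls)

    @property
    def pattern(self) -> str:
        return "-".join(_TYPE_TOKEN.get(c.type or "undetermined", "und") for c in self.calls)

    @property
    def is_composite(self) -> bool:
        return len(self.calls) > 1

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def merge_complex(
    calls: list[MosaicCall], max_gap: int = 1_000_000
) -> list[CompositeEvent]:
    """Group adjacent differently-typed calls into composite events.

    Calls on one sample-chromosome, sorted by start; consecutive calls of
    different types separated by less than ``max_gap`` bases are chained
    into one composite (e.g. a deletion flanked by copy-neutral LOH on both
    sides gives the pattern ``loh-del-loh``).  Single calls pass through as
    singleton composites.
    """
    if not calls:
        return []
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start))
    groups: list[CompositeEvent] = [CompositeEvent([ordered[0]])]
    for call in ordered[1:]:
        prev = groups[-1].calls[-1]
        gap = call.start - prev.end - 1
        if call.chrom == prev.chrom and gap < max_gap and call.type != prev.type:
            groups[-1].calls.append(call)
        else:
            groups.append(CompositeEvent([call]))
    for i, g in enumerate(groups):
        if g.is_composite:
            g.group = f"comp{i + 1}"
            for c in g.calls:
                c.group = g.group
    return groups


def arm_label(
    call: MosaicCall,
    genome: GenomeBuild,
    whole_frac: float = 0.95,
    other_max: float = 0.05,
) -> str:
    """'w' (whole chromosome), 'p'/'q' (one arm), or 'partial'.

    A call is whole-chromosome when it covers at least ``whole_frac`` of
    the chromosome, and a single-arm event when it covers at least that
    fraction of one arm and under ``other_max`` of the other.
    """
    geom = genome[call.chrom]
    iv = (call.chrom, call.start, call.end)
    chrom_frac = interval_overlap(iv, (call.chrom, 1, geom.length))[1]
    if chrom_frac >= whole_frac:
        return "w"
    p_frac = interval_overlap(iv, (call.chrom, *geom.p_arm))[1]
    q_frac = interval_overlap(iv, (call.chrom, *geom.q_arm))[1]
    if p_frac >= whole_frac and q_frac < other_max:
        return "p"
    if q_frac >= whole_frac and p_frac < other_max:
        return "q"
    return "partial"
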