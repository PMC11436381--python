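"""Cohort-level reporting: tissue concordance, origin summary, event tables.

Display conventions follow clinical reporting practice: event size in Mb is
``(end - start) / 1e6`` rounded half-up to 2 decimals, arm labels are
appended as "(p)"/"(q)"/"(w)", per-tissue cell fractions print as integer
percents and tissues not assayed print as "nd" (not done).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .caller import MosaicCall
from .genome import GenomeBuild, interval_overlap
from .filters import FilterTrace
from .origin import OriginCall

__all__ = [
    "size_mb",
    "TissueComparison",
    "TissueConcordance",
    "tissue_concordance",
    "origin_summary",
    "table1_format",
    "workflow_counts",
    "diagnostic_yield_pct",
]

_TYPE_TOKEN = {"gain": "dup", "loss": "del", "cnloh": "loh", "undetermined": "und"}


def size_mb(start: int, end: int) -> float:
    """Event size in Mb, (end - start)/1e6 rounded half-up to 2 decimals."""
    mb = Decimal(end - start) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class TissueComparison:
    """One event's cross-tissue detection status for one individual."""

    individual: str
    chrom: str
    start: int
    end: int
    type: str | None
    tissues_assayed: list[str]
    detected_in: list[str]
    cell_fraction: dict[str, float] = field(default_factory=dict)  # tissue -> f

    def __post_init__(self) -> None:
        if not set(self.detected_in) <= set(self.tissues_assayed):
            raise ValueError("detected_in must be a subset of tissues_assayed")

    def pct(self, tissue: str) -> str:
        """Integer-percent display; 'nd' when the tissue was not assayed."""
        if tissue not in self.tissues_assayed:
            return "nd"
        f = self.cell_fraction.get(tissue)
        return "0" if f is None else str(int(round(100 * f)))


@dataclass
class TissueConcordance:
    comparisons: list[TissueComparison]
    n_comparable: int            # saliva events with a blood sample assayed
    n_discordant: int            # of those, absent from blood
    n_blood_comparable: int      # blood events with a saliva sample assayed
    n_blood_also_in_saliva: int

    @property
    def discordance_pct(self) -> float:
        if self.n_comparable == 0:
            return float("nan")
        return round(100.0 * self.n_discordant / self.n_comparable, 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "individual": c.individual,
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "type": c.type,
                    "blood_pct": c.pct("blood"),
                    "saliva_pct": c.pct("saliva"),
                }
                for c in self.comparisons
            ]
        )


def _match(a: MosaicCall, b: MosaicCall, recip: float) -> bool:
    return (
        a.type == b.type
        and min(interval_overlap(a.interval, b.interval)) >= recip
    )


def tissue_concordance(
    calls: list[MosaicCall],
    manifest: dict[str, list[str]],
    reciprocal_overlap: float = 0.50,
) -> TissueConcordance:
    """Cross-tissue concordance of surviving calls.

    For every saliva call of an individual who also has a blood sample,
    look for a matching blood call (same locus at reciprocal overlap, same
    type); the headline number is the fraction of such comparable events
    *not* seen in blood.  The symmetric blood-to-saliva count is also
    reported, with per-tissue cell fractions.
    """
    by_ind: dict[str, dict[str, list[MosaicCall]]] = {}
    for c in calls:
        by_ind.setdefault(c.individual, {}).setdefault(c.tissue, []).append(c)

    comparisons: list[TissueComparison] = []
    n_comp = n_disc = n_blood_comp = n_blood_also = 0
    for ind, tissues in by_ind.items():
        assayed = manifest.get(ind, list(tissues))
        for sal in tissues.get("saliva", []):
            if "blood" not in assayed:
                continue
            n_comp += 1
            match = next(
                (b for b in tissues.get("blood", []) if _match(sal, b, reciprocal_overlap)),
                None,
            )
            detected = ["saliva"] + (["blood"] if match else [])
            cf = {"saliva": sal.cell_fraction}
            if match:
                cf["blood"] = match.cell_fraction
            else:
                n_disc += 1
                cf["blood"] = 0.0
            comparisons.append(
                TissueComparison(
                    ind, sal.chrom, sal.start, sal.end, sal.type,
                    assayed, detected, cf,
                )
            )
        for blo in tissues.get("blood", []):
            if "saliva" not in assayed:
                continue
            n_blood_comp += 1
            if any(_match(blo, s, reciprocal_overlap) for s in tissues.get("saliva", [])):
                n_blood_also += 1
    return TissueConcordance(comparisons, n_comp, n_disc, n_blood_comp, n_blood_also)


def origin_summary(origins: list[OriginCall | str]) -> dict:
    """Counts and percentages (1 decimal) per origin class.

    Undetermined calls are reported separately and excluded from the
    percentage denominator; the combined meiotic share is also given.
    """
    labels = [o.origin if isinstance(o, OriginCall) else o for o in origins]
    classes = ("mitotic", "meiosis_I", "meiosis_II")
    counts = {c: labels.count(c) for c in classes}
    n_undet = labels.count("undetermined")
    total = sum(counts.values())
    pct = {
        c: (round(100.0 * counts[c] / total, 1) if total else float("nan"))
        for c in classes
    }
    meiotic = counts["meiosis_I"] + counts["meiosis_II"]
    return {
        "counts": counts,
        "n_undetermined": n_undet,
        "n_classified": total,
        "pct": pct,
        "meiotic_pct": round(100.0 * meiotic / total, 1) if total else float("nan"),
    }


def table1_format(
    comparisons: list[TissueComparison],
    genome: GenomeBuild,
    arm_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Clinical-style event table: chromosome, type, coordinates with arm
    suffix, size in Mb, per-tissue percent columns."""
    from .interpret import arm_label as _arm_label

    rows = []
    for i, c in enumerate(comparisons):
        arm = (arm_labels or {}).get(i)
        if arm is None:
            probe = MosaicCall(
                individual=c.individual, tissue="saliva", chrom=c.chrom,
                start=c.start, end=c.end, n_snps=1, n_hets=1, bdev=0.0,
                lrr_mean=0.0, lrr_se=0.0, lod=0.0, phase_concordance=0.5,
            )
            arm = _arm_label(probe, genome)
        suffix = f" ({arm})" if arm in ("p", "q", "w") else ""
        rows.append(
            {
                "Chr.": c.chrom,
                "Event type": _TYPE_TOKEN.get(c.type or "undetermined", "und"),
                "Start-end": f"{c.start}-{c.end}{suffix}",
                "Size (Mb)": f"{size_mb(c.start, c.end):.2f}",
                "Blood %": c.pct("blood"),
                "Saliva %": c.pct("saliva"),
            }
        )
    return pd.DataFrame(
        rows, columns=["Chr.", "Event type", "Start-end", "Size (Mb)", "Blood %", "Saliva %"]
    )


def workflow_counts(traces: list[FilterTrace]) -> pd.DataFrame:
    """Stage-count table: candidates in, survivors after each stage, with a
    per-type breakdown after the first stage."""
    rows = []
    if traces:
        rows.append({"stage": "candidates", "n_events": traces[0].n_input, "by_type": ""})
    for t in traces:
        by_type: dict[str, int] = {}
        for c in t.survivors:
            tok = _TYPE_TOKEN.get(c.type or "undetermined", "und")
            by_type[tok] = by_type.get(tok, 0) + 1
        rows.append(
            {
                "stage": t.stage,
                "n_events": t.n_surviving,
                "by_type": ",".join(f"{k}={v}" for k, v in sorted(by_type.items())),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "n_events", "by_type"])


def diagnostic_yield_pct(n_with_finding: int, cohort_size: int) -> float:
    """Percent of the cohort carrying a finding, to 2 decimals."""
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    pct = Decimal(100 * n_with_finding) / Decimal(cohort_size)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
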