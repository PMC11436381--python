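"""Genome builds, chromosome arm geometry and interval utilities.

All coordinates in this package are 1-based and inclusive on both ends,
matching the way large chromosomal events are printed in clinical reports.
The single exception is BED export/import (0-based half-open), handled in
:mod:`mcalite.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import yaml

__all__ = [
    "ChromosomeGeometry",
    "GenomeBuild",
    "GeneIntervalSet",
    "toy_genome",
    "grch37",
    "interval_overlap",
]


@dataclass(frozen=True)
class ChromosomeGeometry:
    """One chromosome: total length and centromere placement.

    The p-arm runs from base 1 to the base before the centromere, the q-arm
    from the base after the centromere to the chromosome end.
    """

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not (1 < self.cen_start <= self.cen_end < self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere [{self.cen_start}, "
                f"{self.cen_end}] must lie strictly inside (1, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (1, self.cen_start - 1)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.cen_end + 1, self.length)

    def arm_of(self, pos: int) -> str:
        """'p', 'q' or 'cen' for a 1-based position."""
        if pos < self.cen_start:
            return "p"
        if pos > self.cen_end:
            return "q"
        return "cen"


class GenomeBuild:
    """A named set of chromosomes with centromere/arm annotations."""

    def __init__(self, label: str, chromosomes: Iterable[ChromosomeGeometry]):
        self.label = label
        self.chromosomes: dict[str, ChromosomeGeometry] = {c.name: c for c in chromosomes}
        if not self.chromosomes:
            raise ValueError("genome build needs at least one chromosome")

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> ChromosomeGeometry:
        try:
            return self.chromosomes[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in build {self.label!r}") from None

    def __iter__(self) -> Iterator[ChromosomeGeometry]:
        return iter(self.chromosomes.values())

    def names(self) -> list[str]:
        return list(self.chromosomes)

    # ------------------------------------------------------------------ yaml
    @classmethod
    def from_yaml(cls, path: str) -> "GenomeBuild":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        chroms = [
            ChromosomeGeometry(
                name=str(name),
                length=int(spec["length"]),
                cen_start=int(spec["centromere"][0]),
                cen_end=int(spec["centromere"][1]),
            )
            for name, spec in cfg["chromosomes"].items()
        ]
        return cls(label=cfg.get("label", "unnamed"), chromosomes=chroms)

    def to_yaml(self, path: str) -> None:
        cfg = {
            "label": self.label,
            "chromosomes": {
                c.name: {"length": c.length, "centromere": [c.cen_start, c.cen_end]}
                for c in self
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def toy_genome() -> GenomeBuild:
    """Small 3-autosome + X build used throughout the test-suite.

    Centromeres sit at roughly 40% of each chromosome, mimicking a
    submetacentric karyotype at desk scale.
    """
    return GenomeBuild(
        "toy37",
        [
            ChromosomeGeometry("1", 60_000_000, 24_000_000, 25_000_000),
            ChromosomeGeometry("2", 45_000_000, 18_000_000, 18_600_000),
            ChromosomeGeometry("3", 30_000_000, 12_000_000, 12_500_000),
            ChromosomeGeometry("X", 40_000_000, 16_000_000, 16_500_000),
        ],
    )


# GRCh37 chromosome lengths and UCSC centromere gap intervals (1-based).
_GRCH37: dict[str, tuple[int, int, int]] = {
    "1": (249250621, 121535435, 124535434),
    "2": (243199373, 92326172, 95326171),
    "3": (198022430, 90504855, 93504854),
    "4": (191154276, 49660118, 52660117),
    "5": (180915260, 46405642, 49405641),
    "6": (171115067, 58830167, 61830166),
    "7": (159138663, 58054332, 61054331),
    "8": (146364022, 43838888, 46838887),
    "9": (141213431, 47367680, 50367679),
    "10": (135534747, 39254936, 42254935),
    "11": (135006516, 51644206, 54644205),
    "12": (133851895, 34856695, 37856694),
    "13": (115169878, 16000001, 19000000),
    "14": (107349540, 16000001, 19000000),
    "15": (102531392, 17000001, 20000000),
    "16": (90354753, 35335802, 38335801),
    "17": (81195210, 22263007, 25263006),
    "18": (78077248, 15460899, 18460898),
    "19": (59128983, 24681783, 27681782),
    "20": (63025520, 26369570, 29369569),
    "21": (48129895, 11288130, 14288129),
    "22": (51304566, 13000001, 16000000),
    "X": (155270560, 58632013, 61632012),
    "Y": (59373566, 10104554, 13104553),
}


def grch37() -> GenomeBuild:
    """Human GRCh37 with UCSC centromere gaps as arm boundaries."""
    return GenomeBuild(
        "GRCh37",
        [ChromosomeGeometry(n, L, cs, ce) for n, (L, cs, ce) in _GRCH37.items()],
    )


def interval_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> tuple[float, float]:
    """Reciprocal overlap fractions of two 1-based inclusive intervals.

    Returns ``(overlap/len(a), overlap/len(b))``; ``(0.0, 0.0)`` when the
    intervals are disjoint or on different chromosomes.
    """
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if start_a > end_a or start_b > end_b:
        raise ValueError("invalid interval: start > end")
    if chrom_a != chrom_b:
        return (0.0, 0.0)
    shared = min(end_a, end_b) - max(start_a, start_b) + 1
    if shared <= 0:
        return (0.0, 0.0)
    return (shared / (end_a - start_a + 1), shared / (end_b - start_b + 1))


@dataclass
class GeneIntervalSet:
    """Named genomic intervals (1-based inclusive), e.g. a disease-gene list."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, name in self.intervals:
            if start > end or start < 1:
                raise ValueError(f"invalid interval for {name}: {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def validate_against(self, genome: GenomeBuild) -> None:
        for chrom, start, end, name in self.intervals:
            if chrom not in genome:
                raise ValueError(f"{name}: unknown chromosome {chrom!r}")
            if end > genome[chrom].length:
                raise ValueError(f"{name}: interval exceeds {chrom} length")

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Names of intervals sharing at least one base with the query."""
        return [
            name
            for c, s, e, name in self.intervals
            if c == chrom and min(end, e) >= max(start, s)
        ]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.overlapping(chrom, start, end))
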