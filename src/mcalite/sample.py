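"""In-memory containers for one genotyping-array sample.

A :class:`SampleArray` holds, per chromosome, columnar numpy arrays of probe
position, genotype, phase and the two intensity-derived signals:

* **BAF** (B-allele frequency): 0 / 0.5 / 1 for AA / AB / BB in a clean
  diploid; mosaic imbalance shifts heterozygous BAF off 0.5.
* **LRR** (log R ratio): log2 of observed over expected total intensity;
  0 at copy number 2.

Genotype codes: 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
For phased heterozygotes ``hap1``/``hap2`` give the allele (0 = ref,
1 = alt) on each haplotype in phase order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SnpRecord", "ChromosomeData", "SampleArray"]

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1


@dataclass(frozen=True)
class SnpRecord:
    """A single array probe (record-level view used by I/O and tests)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt: int
    phased: bool
    hap1: int
    hap2: int
    baf: float
    lrr: float

    def __post_init__(self) -> None:
        if not np.isnan(self.baf) and not (0.0 <= self.baf <= 1.0):
            raise ValueError(
                f"BAF {self.baf} outside [0, 1] at {self.chrom}:{self.pos}"
            )


@dataclass
class ChromosomeData:
    """Columnar probe data for one chromosome, sorted by position."""

    pos: np.ndarray          # int64, 1-based, strictly increasing
    gt: np.ndarray           # int8
    phased: np.ndarray       # bool
    hap1: np.ndarray         # int8
    hap2: np.ndarray         # int8
    baf: np.ndarray          # float64, nan = missing
    lrr: np.ndarray          # float64, nan = missing
    ref: str = "A"
    alt: str = "C"

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("gt", "phased", "hap1", "hap2", "baf", "lrr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("positions must be strictly increasing")
        ok = ~np.isnan(self.baf)
        if np.any((self.baf[ok] < 0) | (self.baf[ok] > 1)):
            bad = int(self.pos[ok][(self.baf[ok] < 0) | (self.baf[ok] > 1)][0])
            raise ValueError(f"BAF outside [0, 1] at position {bad}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_het(self) -> int:
        return int(np.sum(self.gt == GT_HET))

    def slice_interval(self, start: int, end: int) -> np.ndarray:
        """Boolean mask of probes inside [start, end] (1-based inclusive)."""
        return (self.pos >= start) & (self.pos <= end)


class SampleArray:
    """One tissue sample of one individual: per-chromosome probe data + QC."""

    def __init__(
        self,
        individual: str,
        tissue: str,
        chromosomes: dict[str, ChromosomeData] | None = None,
    ):
        self.individual = individual
        self.tissue = tissue
        self.chromosomes: dict[str, ChromosomeData] = chromosomes or {}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> ChromosomeData:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} absent from sample "
                f"{self.individual}/{self.tissue}"
            ) from None

    @property
    def label(self) -> str:
        return f"{self.individual}/{self.tissue}"

    def records(self, chrom: str):
        """Yield :class:`SnpRecord` views (slow path; I/O and tests)."""
        cd = self[chrom]
        for i in range(len(cd)):
            yield SnpRecord(
                chrom=chrom,
                pos=int(cd.pos[i]),
                ref=cd.ref,
                alt=cd.alt,
                gt=int(cd.gt[i]),
                phased=bool(cd.phased[i]),
                hap1=int(cd.hap1[i]),
                hap2=int(cd.hap2[i]),
                baf=float(cd.baf[i]),
                lrr=float(cd.lrr[i]),
            )

    # ------------------------------------------------------------------- QC
    def qc_stats(self) -> dict[str, float]:
        """Sample-level QC: robust het-BAF sd, LRR sd, call rate.

        The het-BAF spread uses the median absolute deviation scaled to a
        Gaussian sd so that genuine mosaic segments do not inflate it.
        """
        het_dev, lrr_all, n_called, n_total = [], [], 0, 0
        for cd in self.chromosomes.values():
            het = (cd.gt == GT_HET) & ~np.isnan(cd.baf)
            het_dev.append(np.abs(cd.baf[het] - 0.5))
            lrr_all.append(cd.lrr[~np.isnan(cd.lrr)])
            n_called += int(np.sum(cd.gt != GT_MISSING))
            n_total += len(cd)
        het_dev = np.concatenate(het_dev) if het_dev else np.array([])
        lrr_all = np.concatenate(lrr_all) if lrr_all else np.array([])
        return {
            "baf_sd_het": float(1.4826 * np.median(het_dev)) if len(het_dev) else float("nan"),
            "lrr_sd": float(np.std(lrr_all)) if len(lrr_all) else float("nan"),
            "call_rate": n_called / n_total if n_total else float("nan"),
        }

    def median_snp_spacing(self) -> float:
        """Median inter-probe distance across the sample (bp)."""
        gaps = [np.diff(cd.pos) for cd in self.chromosomes.values() if len(cd) > 1]
        return float(np.median(np.concatenate(gaps))) if gaps else float("nan")
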