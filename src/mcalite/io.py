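"""Readers and writers: per-sample VCF (GT/BAF/LRR), BED, call tables.

Internal coordinates are 1-based inclusive; BED files are the only 0-based
half-open surface (``start - 1`` on export, ``start + 1`` on import).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from cyvcf2 import VCF

from .genome import GeneIntervalSet, GenomeBuild
from .sample import GT_HET, GT_MISSING, ChromosomeData, SampleArray

__all__ = [
    "read_sample_vcf",
    "write_sample_vcf",
    "write_calls_bed",
    "read_bed",
    "VcfFormatError",
]


class VcfFormatError(ValueError):
    """The VCF lacks a FORMAT field this pipeline requires."""


def _fmt_float(x: float) -> str:
    return "." if math.isnan(x) else f"{x:.4f}"


def write_sample_vcf(sample: SampleArray, path: str, genome: GenomeBuild) -> None:
    """Write a single-sample VCF 4.2 with FORMAT GT, BAF and LRR."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mcalite\n##genome_build={genome.label}\n")
        for chrom in genome:
            if chrom.name in sample.chromosomes:
                fh.write(f"##contig=<ID={chrom.name},length={chrom.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=BAF,Number=1,Type=Float,Description="B allele frequency">\n')
        fh.write('##FORMAT=<ID=LRR,Number=1,Type=Float,Description="Log R ratio">\n')
        name = f"{sample.individual}_{sample.tissue}"
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{name}\n")
        for chrom in genome.names():
            if chrom not in sample.chromosomes:
                continue
            cd = sample[chrom]
            for i in range(len(cd)):
                gt = int(cd.gt[i])
                if gt == GT_MISSING:
                    gt_str = "./."
                elif gt == GT_HET:
                    sep = "|" if cd.phased[i] else "/"
                    gt_str = f"{cd.hap1[i]}{sep}{cd.hap2[i]}"
                else:
                    a = 0 if gt == 0 else 1
                    gt_str = f"{a}/{a}"
                fh.write(
                    f"{chrom}\t{cd.pos[i]}\t.\t{cd.ref}\t{cd.alt}\t.\t.\t.\t"
                    f"GT:BAF:LRR\t{gt_str}:{_fmt_float(cd.baf[i])}:{_fmt_float(cd.lrr[i])}\n"
                )


def read_sample_vcf(
    path: str, genome: GenomeBuild, sample_name: str | None = None
) -> SampleArray:
    """Read one sample's GT/BAF/LRR from a VCF into a :class:`SampleArray`.

    The individual id and tissue are recovered from the sample column name
    when it follows the ``<id>_<tissue>`` convention used by
    :func:`write_sample_vcf`; otherwise the whole name becomes the id.

    Raises
    ------
    VcfFormatError
        if the FORMAT definitions lack GT, BAF or LRR.
    ValueError
        if a BAF value falls outside [0, 1] (the offending record is named).
    """
    vcf = VCF(path)
    header_ids = {
        h.info().get("ID")
        for h in vcf.header_iter()
        if h.type == "FORMAT"
    }
    for needed in ("GT", "BAF", "LRR"):
        if needed not in header_ids:
            raise VcfFormatError(f"{path}: FORMAT field {needed} missing from header")
    samples = vcf.samples
    if sample_name is None:
        if len(samples) != 1:
            raise ValueError(
                f"{path}: {len(samples)} samples present; pass sample_name"
            )
        idx = 0
    else:
        idx = samples.index(sample_name)
    name = samples[idx]
    individual, _, tissue = name.rpartition("_")
    if not individual:
        individual, tissue = name, "unknown"

    per_chrom: dict[str, list[tuple]] = {}
    for v in vcf:
        chrom = v.CHROM
        baf_arr = v.format("BAF")
        lrr_arr = v.format("LRR")
        if baf_arr is None or lrr_arr is None:
            raise VcfFormatError(f"{path}: record {chrom}:{v.POS} lacks BAF/LRR")
        baf = float(baf_arr[idx][0])
        lrr = float(lrr_arr[idx][0])
        if not math.isfinite(baf) or baf < -1e30:
            baf = float("nan")
        if not math.isfinite(lrr) or lrr < -1e30:
            lrr = float("nan")
        if not math.isnan(baf) and not (0.0 <= baf <= 1.0):
            raise ValueError(f"{path}: BAF {baf:.4f} outside [0, 1] at {chrom}:{v.POS}")
        a0, a1, phased = v.genotypes[idx]
        if a0 < 0 or a1 < 0:
            gt, h1, h2 = GT_MISSING, 0, 0
        else:
            gt = a0 + a1
            h1, h2 = a0, a1
        per_chrom.setdefault(chrom, []).append(
            (v.POS, gt, bool(phased), h1, h2, baf, lrr, v.REF, v.ALT[0] if v.ALT else "C")
        )

    chromosomes: dict[str, ChromosomeData] = {}
    order = [c for c in genome.names() if c in per_chrom]
    order += [c for c in per_chrom if c not in order]
    for chrom in order:
        rows = sorted(per_chrom[chrom])
        chromosomes[chrom] = ChromosomeData(
            pos=np.array([r[0] for r in rows], dtype=np.int64),
            gt=np.array([r[1] for r in rows], dtype=np.int8),
            phased=np.array([r[2] for r in rows], dtype=bool),
            hap1=np.array([r[3] for r in rows], dtype=np.int8),
            hap2=np.array([r[4] for r in rows], dtype=np.int8),
            baf=np.array([r[5] for r in rows], dtype=np.float64),
            lrr=np.array([r[6] for r in rows], dtype=np.float64),
            ref=rows[0][7],
            alt=rows[0][8],
        )
    return SampleArray(individual=individual, tissue=tissue, chromosomes=chromosomes)


def write_calls_bed(calls: Sequence, path: str, genome: GenomeBuild) -> None:
    """Write calls as BED (0-based half-open), sorted by (chrom, start).

    The name column packs type, bdev, LOD and cell fraction; the score
    column is the LOD capped at 1000, as integer.
    """
    order = {name: i for i, name in enumerate(genome.names())}
    for c in calls:
        if c.chrom not in order:
            raise ValueError(f"unknown chromosome {c.chrom!r} in call")
    rows = sorted(calls, key=lambda c: (order[c.chrom], c.start, c.end))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for c in rows:
            cf = getattr(c, "cell_fraction", None)
            cf_s = "na" if cf is None or (isinstance(cf, float) and math.isnan(cf)) else f"{cf:.3f}"
            typ = getattr(c, "type", None) or "unknown"
            name = f"{typ};bdev={c.bdev:.4f};lod={c.lod:.2f};cf={cf_s}"
            score = int(min(c.lod, 1000))
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\t{score}\n")


def read_bed(path: str) -> GeneIntervalSet:
    """Read a BED file into 1-based inclusive intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            intervals.append((chrom, start + 1, end, name))
    return GeneIntervalSet(intervals)
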