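"""Reference cohort configurations for validation and demonstration.

These builders encode the study conditions the package is validated
against: a two-tissue cohort in which most mosaic events are confined to
saliva, a 20-polysomy cohort with known mitotic/meiotic origins, and an
engineered 20-call set with a designed fate at every filter stage.  They
are first-class library code (the acceptance pipeline and the test-suite
both run them), not throwaway test data.
"""

from __future__ import annotations

import numpy as np

from .caller import MosaicCall
from .genome import GeneIntervalSet
from .sample import ChromosomeData, SampleArray
from .simulate import CohortConfig, EventSpec, IndividualSpec, NoiseModel

__all__ = [
    "tissue_cohort_config",
    "origin_cohort_config",
    "filter_fate_fixture",
]


def tissue_cohort_config() -> CohortConfig:
    """26 individuals with saliva + blood arrays and one mosaic event each.

    Mirrors a cohort in which 23 of 26 events are present in saliva only
    and 3 are shared, with the blood cell fraction below the saliva one.
    Events are 10 Mb, at cell fractions 0.30-0.45, cycling through gains,
    losses and copy-neutral LOH at staggered positions on one chromosome.
    """
    individuals = []
    types = ("gain", "loss", "cnloh")
    for i in range(26):
        saliva_f = 0.30 + 0.01 * (i % 16)
        shared = i < 3          # first three events also detectable in blood
        blood_f = round(saliva_f - 0.12, 2) if shared else 0.0
        start = 2_000_000 + 600_000 * i
        individuals.append(
            IndividualSpec(
                id=f"P{i + 1:03d}",
                tissues=["saliva", "blood"],
                events=[
                    EventSpec(
                        chrom="3",
                        start=start,
                        end=start + 10_000_000,
                        type=types[i % 3],
                        fractions={"saliva": saliva_f, "blood": blood_f},
                        hap=1 + i % 2,
                    )
                ],
            )
        )
    return CohortConfig(individuals=individuals, chroms=["3"])


def origin_cohort_config(
    fractions: tuple[float, ...] = (0.3, 0.35, 0.4),
    noise: NoiseModel = NoiseModel(),
) -> CohortConfig:
    """20 whole-chromosome trisomies: 5 mitotic, 8 meiosis I, 7 meiosis II.

    Meiotic events carry one or two crossovers placed mid-arm so that the
    pericentromeric and distal third-haplotype windows are informative.
    """
    origins = ["mitotic"] * 5 + ["meiosis_I"] * 8 + ["meiosis_II"] * 7
    individuals = []
    for i, origin in enumerate(origins):
        if origin == "mitotic":
            xo: tuple[int, ...] = ()
        elif origin == "meiosis_I":
            xo = (20_000_000,) if i % 2 else (6_000_000, 21_000_000)
        else:
            xo = (19_000_000 + 500_000 * (i % 4),)
        individuals.append(
            IndividualSpec(
                id=f"T{i + 1:02d}",
                tissues=["saliva"],
                events=[
                    EventSpec(
                        chrom="3",
                        start=1,
                        end=30_000_000,
                        type="gain",
                        origin=origin,
                        fractions={"saliva": fractions[i % len(fractions)]},
                        hap=1 + i % 2,
                        crossovers=xo,
                    )
                ],
            )
        )
    # chromosome 2 stays event-free so per-sample noise levels (het sd,
    # hom displacement rate) are estimable outside the trisomy
    return CohortConfig(individuals=individuals, chroms=["2", "3"], noise=noise)


def _uniform_sample(individual: str, noisy: bool = False) -> SampleArray:
    """Synthetic minimal sample: 3 kb probe grid, used only for QC stages."""
    n = 2000
    pos = np.arange(1, n + 1, dtype=np.int64) * 3000
    gt = np.tile([0, 1, 2, 1], n // 4).astype(np.int8)
    het = gt == 1
    baf = np.where(het, 0.5, np.where(gt == 2, 1.0, 0.0)).astype(float)
    if noisy:
        # alternate het BAF at 0.4/0.6: robust sd 1.4826*0.1 >> QC ceiling
        baf[het] = np.tile([0.4, 0.6], int(het.sum()) // 2)
    cd = ChromosomeData(
        pos=pos,
        gt=gt,
        phased=het.copy(),
        hap1=(gt >= 1).astype(np.int8),
        hap2=(gt == 2).astype(np.int8),
        baf=baf,
        lrr=np.zeros(n),
    )
    return SampleArray(individual, "saliva", {"3": cd})


def _mk_call(ind: str, **kw) -> MosaicCall:
    base = dict(
        individual=ind,
        tissue="saliva",
        chrom="3",
        start=2_000_000,
        end=7_000_000,
        n_snps=1600,
        n_hets=600,
        bdev=0.08,
        lrr_mean=0.0,
        lrr_se=0.01,
        lod=200.0,
        phase_concordance=0.98,
        type="cnloh",
        cell_fraction=0.16,
    )
    base.update(kw)
    return MosaicCall(**base)


def filter_fate_fixture():
    """Engineered 20-call set with a designed fate at every cascade stage.

    Returns ``(calls, samples, cohort_calls, germline_cnvs, dd_genes,
    expected, n_individuals)`` where ``expected`` maps individual id to
    either ``"pass"`` or ``(stage, reason)``.
    """
    calls: list[MosaicCall] = []
    expected: dict[str, str | tuple[str, str]] = {}

    def add(ind, fate, **kw):
        calls.append(_mk_call(ind, **kw))
        expected[ind] = fate

    # --- stage 1 fates
    add("F01", ("stage1", "min_length"), start=2_000_000, end=2_099_998)  # 99,999 bp
    add("F02", ("stage1", "min_lod"), lod=9.99)
    add("F03", ("stage1", "germline_flag"), germline_flag=True,
        bdev=0.16, lrr_mean=0.58, type="gain", cell_fraction=0.94)
    add("F04", ("stage1", "max_cf"), bdev=0.255, cell_fraction=0.51)  # cnloh f = 2d
    # --- stage 2 fates (loci distinct from every other surviving call)
    add("F05", ("stage2", "cohort_freq"), start=10_000_000, end=15_000_000)
    add("F06", ("stage2", "germline_cnv"), start=20_000_000, end=21_000_000)
    add("F07", ("stage2", "min_size_no_gene"), start=23_000_000, end=23_900_000)
    add("F08", "pass", start=25_000_000, end=25_900_000)  # <1 Mb but hits a DD gene
    # --- stage 3 fates
    add("F09", ("stage3", "low_bdev"), start=16_000_000, end=18_000_000,
        bdev=0.005, cell_fraction=0.01, lod=15.0)
    add("F10", ("stage3", "sparse_snps"), start=26_500_000, end=29_500_000,
        n_snps=100, n_hets=40)
    add("F11", ("stage3", "noisy_sample"), start=8_000_000, end=9_500_000)
    # --- clean survivors, disjoint loci on another chromosome
    for i in range(12, 21):
        start = 1_000_000 + 1_500_000 * (i - 12)
        add(f"F{i:02d}", "pass", chrom="2", start=start, end=start + 1_200_000)

    # cohort context: the F05 locus recurs in 3 of 100 individuals (3% > 1%)
    cohort_calls = list(calls)
    for j in range(2):
        cohort_calls.append(
            _mk_call(f"R{j + 1:02d}", start=10_100_000, end=15_100_000)
        )
    germline_cnvs = GeneIntervalSet([("3", 20_100_000, 21_100_000, "known_cnv")])
    dd_genes = GeneIntervalSet([("3", 25_400_000, 25_500_000, "DDG2P_GENE")])
    samples = {
        ("F10", "saliva"): _uniform_sample("F10"),
        ("F11", "saliva"): _uniform_sample("F11", noisy=True),
    }
    return calls, samples, cohort_calls, germline_cnvs, dd_genes, expected, 100
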