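"""Synthetic genotyping-array cohorts with spiked mosaic events.

The generator models a mixture of a normal diploid cell population and a
fraction ``f`` of cells carrying a chromosomal alteration.  At a probe where
the affected cells carry ``b_a`` copies of the B allele out of ``n_a`` total
copies, and normal cells ``b_n`` of ``n_n``, the expected signals are

    BAF = (f * b_a + (1 - f) * b_n) / (f * n_a + (1 - f) * n_n)
    LRR = log2((f * n_a + (1 - f) * n_n) / 2)

Everything else — trisomy vs tetrasomy, mitotic vs meiotic extra haplotypes,
monosomy, copy-neutral LOH, third-haplotype sites at homozygous probes —
falls out of this one mixture rule applied to the simulated haplotypes.

Polysomy origins:

* *mitotic* — the extra copy is an exact duplicate of one of the child's own
  homologs, so no third haplotype exists anywhere in the event.
* *meiosis I* — the two copies transmitted by one parent are different
  homologs at the centromere (heterodisomy); a third haplotype is visible in
  the pericentromeric region.
* *meiosis II* — the transmitted copies are sister chromatids, identical at
  the centromere (isodisomy) and diverging distal to a crossover; third
  haplotypes appear only towards the telomeres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .genome import GenomeBuild, toy_genome
from .sample import ChromosomeData, SampleArray

__all__ = [
    "NoiseModel",
    "TruthEvent",
    "HaplotypeTruth",
    "CohortConfig",
    "IndividualSpec",
    "EventSpec",
    "CohortSim",
    "simulate_phased_sample",
    "expected_signal",
    "spike_event",
    "build_polysomy_haplotype",
    "simulate_cohort",
    "bdev_from_fraction",
]

MEIOTIC_ORIGINS = ("meiosis_I", "meiosis_II")
VALID_ORIGINS = ("mitotic", "meiosis_I", "meiosis_II", "rescue", "na")
VALID_TYPES = ("gain", "loss", "cnloh")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian array noise: het BAF sd, hom BAF half-normal sd, LRR sd."""

    baf_sd_het: float = 0.03
    baf_sd_hom: float = 0.015
    lrr_sd: float = 0.15

    def __post_init__(self) -> None:
        if min(self.baf_sd_het, self.baf_sd_hom, self.lrr_sd) < 0:
            raise ValueError("noise sds must be >= 0")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0)


@dataclass
class TruthEvent:
    """Ground truth for one simulated mosaic event."""

    individual: str
    chrom: str
    start: int
    end: int
    type: str                      # gain | loss | cnloh
    origin: str = "na"             # mitotic | meiosis_I | meiosis_II | rescue | na
    cell_fraction: dict[str, float] = field(default_factory=dict)  # tissue -> f
    hap: int = 1                   # which child homolog is duplicated/retained/kept
    crossovers: tuple[int, ...] = ()
    extra_copies: int = 1          # 1 = trisomy, 2 = tetrasomy-style
    group: str | None = None       # composite-event group id

    def __post_init__(self) -> None:
        if self.type not in VALID_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.start > self.end:
            raise ValueError("event start > end")
        for tissue, f in self.cell_fraction.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"cell fraction for {tissue} must be in (0, 1]")
        if self.crossovers and self.origin not in MEIOTIC_ORIGINS:
            raise ValueError("crossovers only apply to meiotic origins")
        if self.origin in MEIOTIC_ORIGINS and not self.crossovers:
            raise ValueError(f"{self.origin} requires at least one crossover")
        if self.origin == "rescue" and self.type == "gain":
            raise ValueError("rescue origin applies to monosomy/UPD simulation, not gains")
        if self.hap not in (1, 2):
            raise ValueError("hap selector must be 1 or 2")

    def present_in(self, tissue: str) -> bool:
        return self.cell_fraction.get(tissue, 0.0) > 0.0


@dataclass
class HaplotypeTruth:
    """Simulated parental haplotypes per chromosome.

    ``m1``/``m2`` are the transmitting ("maternal") homologs, ``f1``/``f2``
    the other parent's.  The child carries ``hap1 = m1`` and ``hap2 = f1``;
    ``m2``/``f2`` exist only to build meiotic extra haplotypes.
    """

    haps: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> dict[str, np.ndarray]:
        return self.haps[chrom]


# --------------------------------------------------------------------------
# closed-form expected signals
# --------------------------------------------------------------------------

def bdev_from_fraction(f: float, event_type: str) -> float:
    """Expected |BAF - 0.5| at phased hets for a mosaic event at fraction f."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"cell fraction {f} outside [0, 1]")
    if event_type == "gain":
        return f / (2.0 * (2.0 + f))
    if event_type == "loss":
        return f / (2.0 * (2.0 - f))
    if event_type == "cnloh":
        return f / 2.0
    raise ValueError(f"unknown event type {event_type!r}")


def expected_signal(
    event_type: str,
    f: float,
    genotype: str = "het",
    alt_on_affected: bool = True,
    third_haplotype: bool = False,
) -> tuple[float, float]:
    """Expected (BAF, LRR) at one probe under the cell-mixture model.

    ``alt_on_affected``: for hets, whether the ALT allele sits on the
    duplicated (gain), retained (loss) or kept (cnloh) haplotype.  For
    homozygous probes ``third_haplotype`` marks sites where a meiotic extra
    copy carries the allele absent from the individual's own two homologs;
    ``alt_on_affected`` then says whether the individual is hom-ALT.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"cell fraction {f} outside [0, 1]")
    if event_type not in VALID_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    if event_type == "gain":
        lrr = math.log2(1.0 + f / 2.0)
    elif event_type == "loss":
        lrr = math.log2(1.0 - f / 2.0) if f < 2.0 else float("-inf")
    else:
        lrr = 0.0
    if genotype == "het":
        d = bdev_from_fraction(f, event_type)
        baf = 0.5 + d if alt_on_affected else 0.5 - d
        return (baf, lrr)
    if genotype != "hom":
        raise ValueError("genotype must be 'het' or 'hom'")
    hom_baf = 1.0 if alt_on_affected else 0.0
    if event_type == "gain" and third_haplotype:
        shift = f / (2.0 + f)
        return (1.0 - shift if alt_on_affected else shift, lrr)
    return (hom_baf, lrr)


# --------------------------------------------------------------------------
# haplotype simulation
# --------------------------------------------------------------------------

def _simulate_chrom_haplotypes(
    geom, spacing: int, maf_range: tuple[float, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Probe grid + four parental haplotypes for one chromosome.

    Probes sit on a jittered ~uniform grid and skip the centromere gap
    (real arrays carry no probes there).
    """
    n = geom.length // spacing
    pos = (np.arange(1, n + 1) * spacing
           + rng.integers(-spacing // 4, spacing // 4 + 1, size=n))
    pos = np.unique(np.clip(pos, 1, geom.length))
    keep = (pos < geom.cen_start) | (pos > geom.cen_end)
    pos = pos[keep]
    maf = rng.uniform(maf_range[0], maf_range[1], size=len(pos))
    haps = {
        name: (rng.random(len(pos)) < maf).astype(np.int8)
        for name in ("m1", "m2", "f1", "f2")
    }
    haps["pos"] = pos.astype(np.int64)
    return haps


def _apply_noise(
    baf_mean: np.ndarray,
    lrr_mean: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Add array noise: Gaussian at interior BAF, half-normal at 0/1."""
    baf = baf_mean.copy()
    interior = (baf_mean > 0.0) & (baf_mean < 1.0)
    if noise.baf_sd_het > 0:
        baf[interior] += rng.normal(0.0, noise.baf_sd_het, size=int(interior.sum()))
    at_zero = baf_mean == 0.0
    at_one = baf_mean == 1.0
    if noise.baf_sd_hom > 0:
        baf[at_zero] += np.abs(rng.normal(0.0, noise.baf_sd_hom, size=int(at_zero.sum())))
        baf[at_one] -= np.abs(rng.normal(0.0, noise.baf_sd_hom, size=int(at_one.sum())))
    np.clip(baf, 0.0, 1.0, out=baf)
    lrr = lrr_mean.copy()
    if noise.lrr_sd > 0:
        lrr += rng.normal(0.0, noise.lrr_sd, size=len(lrr))
    return baf, lrr


def _base_chromosome(haps: dict[str, np.ndarray]) -> ChromosomeData:
    """Diploid ChromosomeData (means only, no noise) from haplotypes."""
    h1, h2 = haps["m1"], haps["f1"]
    gt = (h1 + h2).astype(np.int8)
    n = len(haps["pos"])
    return ChromosomeData(
        pos=haps["pos"].copy(),
        gt=gt,
        phased=np.ones(n, dtype=bool),
        hap1=h1.copy(),
        hap2=h2.copy(),
        baf=(h1 + h2) / 2.0,
        lrr=np.zeros(n),
    )


def simulate_phased_sample(
    genome: GenomeBuild | None = None,
    spacing: int = 3000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.SeedSequence = 0,
    chroms: list[str] | None = None,
    noise: NoiseModel = NoiseModel(),
    roh: list[tuple[str, int, int]] | None = None,
    individual: str = "sim",
    tissue: str = "saliva",
) -> tuple[SampleArray, HaplotypeTruth]:
    """Simulate one phased, event-free array sample.

    Returns the sample and the parental-haplotype truth needed later to
    spike events of known meiotic/mitotic origin.  Pure function of the
    configuration and seed.  An optional run of homozygosity copies one
    haplotype over the other within the given interval(s).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ValueError("MAF range must sit inside (0, 0.5]")
    genome = genome or toy_genome()
    chroms = chroms or genome.names()
    rng = np.random.default_rng(seed)
    truth = HaplotypeTruth()
    chromosomes: dict[str, ChromosomeData] = {}
    for chrom in chroms:
        haps = _simulate_chrom_haplotypes(genome[chrom], spacing, maf_range, rng)
        for r_chrom, r_start, r_end in roh or []:
            if r_chrom == chrom:
                mask = (haps["pos"] >= r_start) & (haps["pos"] <= r_end)
                haps["f1"] = haps["f1"].copy()
                haps["f1"][mask] = haps["m1"][mask]
        truth.haps[chrom] = haps
        cd = _base_chromosome(haps)
        cd.baf, cd.lrr = _apply_noise(cd.baf, cd.lrr, noise, rng)
        chromosomes[chrom] = cd
    return SampleArray(individual, tissue, chromosomes), truth


# --------------------------------------------------------------------------
# extra haplotypes and event spiking
# --------------------------------------------------------------------------

def build_polysomy_haplotype(
    transmitted: np.ndarray,
    untransmitted: np.ndarray,
    origin: str,
    crossovers: tuple[int, ...],
    positions: np.ndarray,
    centromere: tuple[int, int],
) -> np.ndarray:
    """Allele sequence of the extra chromosome copy in a polysomy.

    ``transmitted`` is the homolog the child already carries from the
    transmitting parent; ``untransmitted`` is that parent's other homolog.
    The extra copy is anchored at the centromere — heterodisomic
    (= untransmitted) for meiosis I, isodisomic (= transmitted) for
    meiosis II — and alternates homolog at each crossover moving away
    from the centromere.
    """
    if origin == "rescue":
        raise ValueError("rescue origin applies to monosomy/UPD simulation, not gains")
    if origin == "mitotic":
        if crossovers:
            raise ValueError("mitotic polysomy takes no crossovers")
        return transmitted.copy()
    if origin not in MEIOTIC_ORIGINS:
        raise ValueError(f"unknown polysomy origin {origin!r}")
    if not crossovers:
        raise ValueError(f"{origin} requires at least one crossover")
    cen_mid = (centromere[0] + centromere[1]) / 2.0
    xo = np.asarray(sorted(crossovers), dtype=float)
    # crossovers strictly between the centromere and each probe
    lo = np.minimum(positions, cen_mid)
    hi = np.maximum(positions, cen_mid)
    n_between = (xo[None, :] > lo[:, None]) & (xo[None, :] <= hi[:, None])
    parity = n_between.sum(axis=1) % 2
    anchor = untransmitted if origin == "meiosis_I" else transmitted
    other = transmitted if origin == "meiosis_I" else untransmitted
    return np.where(parity == 0, anchor, other).astype(np.int8)


def _event_copy_arrays(
    truth: TruthEvent, haps: dict[str, np.ndarray], mask: np.ndarray, genome: GenomeBuild
) -> tuple[np.ndarray, int]:
    """(B-allele count, total copy number) per probe in affected cells."""
    h1, h2 = haps["m1"][mask], haps["f1"][mask]
    if truth.type == "gain":
        if truth.hap == 1:
            transmitted, untransmitted = haps["m1"][mask], haps["m2"][mask]
        else:
            transmitted, untransmitted = haps["f1"][mask], haps["f2"][mask]
        geom = genome[truth.chrom]
        extra = build_polysomy_haplotype(
            transmitted,
            untransmitted,
            truth.origin if truth.origin in ("mitotic", *MEIOTIC_ORIGINS) else "mitotic",
            truth.crossovers,
            haps["pos"][mask],
            (geom.cen_start, geom.cen_end),
        )
        b = h1 + h2 + truth.extra_copies * extra
        n = 2 + truth.extra_copies
    elif truth.type == "loss":
        retained = h1 if truth.hap == 1 else h2
        b, n = retained.astype(np.int64), 1
    else:  # cnloh
        kept = h1 if truth.hap == 1 else h2
        b, n = 2 * kept.astype(np.int64), 2
    return b.astype(np.float64), n


def spike_event(
    sample: SampleArray,
    truth: TruthEvent,
    noise: NoiseModel,
    hap_truth: HaplotypeTruth,
    genome: GenomeBuild | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SampleArray:
    """Return a copy of ``sample`` with one mosaic event written in.

    Within the event interval every probe's BAF/LRR mean is replaced by the
    cell-mixture expectation given which haplotype is affected, then noise
    is re-drawn; probes outside the interval are untouched.
    """
    genome = genome or toy_genome()
    f = truth.cell_fraction.get(sample.tissue, 0.0)
    new_chroms = dict(sample.chromosomes)
    if f > 0.0:
        cd = sample[truth.chrom]
        haps = hap_truth[truth.chrom]
        mask = cd.slice_interval(truth.start, truth.end)
        b_aff, n_aff = _event_copy_arrays(truth, haps, mask, genome)
        b_norm = (haps["m1"][mask] + haps["f1"][mask]).astype(np.float64)
        denom = f * n_aff + (1.0 - f) * 2.0
        baf_mean = (f * b_aff + (1.0 - f) * b_norm) / denom
        lrr_mean = np.full(int(mask.sum()), math.log2(denom / 2.0) if denom > 0 else -8.0)
        rng = np.random.default_rng(seed)
        baf_new, lrr_new = _apply_noise(baf_mean, lrr_mean, noise, rng)
        baf, lrr = cd.baf.copy(), cd.lrr.copy()
        baf[mask], lrr[mask] = baf_new, lrr_new
        new_chroms[truth.chrom] = replace(cd, baf=baf, lrr=lrr)
    return SampleArray(sample.individual, sample.tissue, new_chroms)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass
class EventSpec:
    chrom: str
    start: int
    end: int
    type: str
    fractions: dict[str, float]        # tissue -> f (0 = absent in tissue)
    origin: str = "na"
    hap: int = 1
    crossovers: tuple[int, ...] = ()
    extra_copies: int = 1
    group: str | None = None


@dataclass
class IndividualSpec:
    id: str
    tissues: list[str]
    events: list[EventSpec] = field(default_factory=list)
    roh: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class CohortConfig:
    individuals: list[IndividualSpec]
    genome: GenomeBuild = field(default_factory=toy_genome)
    chroms: list[str] | None = None
    spacing: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    noise: NoiseModel = NoiseModel()

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        genome = toy_genome()
        if "genome" in cfg and cfg["genome"] not in (None, "toy37"):
            genome = GenomeBuild.from_yaml(cfg["genome"])
        noise = NoiseModel(**cfg.get("noise", {}))
        individuals = []
        for ind in cfg["individuals"]:
            events = [
                EventSpec(
                    chrom=str(e["chrom"]),
                    start=int(e["start"]),
                    end=int(e["end"]),
                    type=e["type"],
                    fractions={k: float(v) for k, v in e["fractions"].items()},
                    origin=e.get("origin", "na"),
                    hap=int(e.get("hap", 1)),
                    crossovers=tuple(e.get("crossovers", ())),
                    extra_copies=int(e.get("extra_copies", 1)),
                    group=e.get("group"),
                )
                for e in ind.get("events", [])
            ]
            individuals.append(
                IndividualSpec(
                    id=str(ind["id"]),
                    tissues=list(ind.get("tissues", ["saliva"])),
                    events=events,
                    roh=[tuple(r) for r in ind.get("roh", [])],
                )
            )
        return cls(
            individuals=individuals,
            genome=genome,
            chroms=cfg.get("chroms"),
            spacing=int(cfg.get("spacing", 3000)),
            maf_range=tuple(cfg.get("maf_range", (0.05, 0.5))),
            noise=noise,
        )


@dataclass
class CohortSim:
    """Simulated cohort: samples keyed by (individual, tissue) + truth."""

    samples: dict[tuple[str, str], SampleArray]
    truth: list[TruthEvent]
    manifest: dict[str, list[str]]     # individual -> tissues assayed
    hap_truth: dict[str, HaplotypeTruth]

    def truth_for(self, tissue: str) -> list[TruthEvent]:
        return [t for t in self.truth if t.present_in(tissue)]


def _check_event_overlaps(ind: IndividualSpec) -> None:
    evs = sorted(ind.events, key=lambda e: (e.chrom, e.start))
    for a, b in zip(evs, evs[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            if a.group is None or a.group != b.group:
                raise ValueError(
                    f"{ind.id}: overlapping events on {a.chrom} without a shared "
                    "composite group id"
                )


def simulate_cohort(config: CohortConfig, seed: int = 0) -> CohortSim:
    """Simulate every individual/tissue in the config; deterministic in seed.

    Tissues of one individual share haplotypes and genotypes; only the
    noise draw and each event's tissue-specific cell fraction differ —
    saliva and blood are the same person.
    """
    root = np.random.SeedSequence(seed)
    ind_seeds = root.spawn(len(config.individuals))
    samples: dict[tuple[str, str], SampleArray] = {}
    truth_events: list[TruthEvent] = []
    hap_truths: dict[str, HaplotypeTruth] = {}
    manifest: dict[str, list[str]] = {}
    for ind, ind_ss in zip(config.individuals, ind_seeds):
        _check_event_overlaps(ind)
        for e in ind.events:
            if e.chrom not in config.genome:
                raise ValueError(f"{ind.id}: unknown chromosome {e.chrom!r}")
        hap_ss, *tissue_ss = ind_ss.spawn(1 + len(ind.tissues))
        base, hap_truth = simulate_phased_sample(
            genome=config.genome,
            spacing=config.spacing,
            maf_range=config.maf_range,
            seed=hap_ss,
            chroms=config.chroms,
            noise=ZERO_NOISE,
            roh=ind.roh or None,
            individual=ind.id,
        )
        hap_truths[ind.id] = hap_truth
        events = [
            TruthEvent(
                individual=ind.id,
                chrom=e.chrom,
                start=e.start,
                end=e.end,
                type=e.type,
                origin=e.origin,
                cell_fraction={t: f for t, f in e.fractions.items() if f > 0.0},
                hap=e.hap,
                crossovers=e.crossovers,
                extra_copies=e.extra_copies,
                group=e.group,
            )
            for e in ind.events
        ]
        truth_events.extend(events)
        manifest[ind.id] = list(ind.tissues)
        for tissue, t_ss in zip(ind.tissues, tissue_ss):
            spike_ss, noise_ss = t_ss.spawn(2)
            sample = SampleArray(
                ind.id,
                tissue,
                {c: replace(cd, baf=cd.baf.copy(), lrr=cd.lrr.copy())
                 for c, cd in base.chromosomes.items()},
            )
            for ev, ev_ss in zip(events, spike_ss.spawn(max(len(events), 1))):
                sample = spike_event(
                    sample, ev, ZERO_NOISE, hap_truth, config.genome, seed=ev_ss
                )
            rng = np.random.default_rng(noise_ss)
            for cd in sample.chromosomes.values():
                cd.baf, cd.lrr = _apply_noise(cd.baf, cd.lrr, config.noise, rng)
            samples[(ind.id, tissue)] = sample
    return CohortSim(samples, truth_events, manifest, hap_truths)
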