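"""End-to-end validation pipelines run on simulated cohorts.

Each function regenerates its inputs from a seed, runs the full
detection/classification/filtering stack, and returns the measured
performance — nothing is cached or tabulated in advance.  The problem
sizes (one 30 Mb chromosome per event, ~10,000 probes at 3 kb spacing)
keep a full run to a couple of minutes on one core while leaving several
hundred heterozygous probes under every event.
"""

from __future__ import annotations

import numpy as np

from .caller import MosaicScan
from .cohorts import origin_cohort_config, tissue_cohort_config
from .genome import interval_overlap, toy_genome
from .origin import classify_polysomy_origin
from .report import TissueConcordance, origin_summary, tissue_concordance
from .filters import run_cascade
from .simulate import NoiseModel, TruthEvent, simulate_cohort, simulate_phased_sample, spike_event

__all__ = [
    "caller_performance",
    "origin_benchmark",
    "concordance_benchmark",
]


def caller_performance(
    seed: int,
    n_events: int = 100,
    n_null: int = 20,
    fractions: tuple[float, ...] = (0.2, 0.25, 0.3, 0.35, 0.4),
    min_lod: float = 10.0,
) -> dict:
    """Detection sensitivity, false positives and bdev accuracy.

    Spikes ``n_events`` single events (>= 5 Mb, fraction >= 0.2, default
    noise and probe density, types cycling gain/loss/cnloh) into fresh
    samples and scans ``n_null`` event-free genomes.  An event counts as
    detected when a call with LOD >= ``min_lod`` overlaps its interval at
    >= 50% reciprocally; bdev error is measured on detected events.
    """
    from .simulate import bdev_from_fraction

    rng = np.random.default_rng(seed)
    types = ("gain", "loss", "cnloh")
    detected = 0
    bdev_errors = []
    for i in range(n_events):
        ev_seed = int(rng.integers(0, 2**31 - 1))
        sample, hap = simulate_phased_sample(chroms=["3"], seed=ev_seed)
        f = fractions[i % len(fractions)]
        typ = types[i % 3]
        length = 5_000_000 + int(rng.integers(0, 3_000_000))
        start = 1_000_000 + int(rng.integers(0, 30_000_000 - length - 2_000_000))
        truth = TruthEvent(
            individual=f"E{i}", chrom="3", start=start, end=start + length,
            type=typ, cell_fraction={"saliva": f},
        )
        spiked = spike_event(sample, truth, NoiseModel(), hap,
                             seed=int(rng.integers(0, 2**31 - 1)))
        calls = MosaicScan(spiked).fit(["3"]).calls
        hits = [
            c for c in calls
            if c.lod >= min_lod
            and min(interval_overlap(c.interval, ("3", truth.start, truth.end))) >= 0.5
        ]
        if hits:
            detected += 1
            best = max(hits, key=lambda c: c.n_hets)
            bdev_errors.append(abs(best.bdev - bdev_from_fraction(f, typ)))
    n_fp = 0
    for j in range(n_null):
        null_seed = int(rng.integers(0, 2**31 - 1))
        sample, _ = simulate_phased_sample(chroms=["3"], seed=null_seed)
        n_fp += sum(1 for c in MosaicScan(sample).fit(["3"]).calls if c.lod >= min_lod)
    return {
        "n_events": n_events,
        "sensitivity": detected / n_events,
        "n_null_genomes": n_null,
        "n_false_positives": n_fp,
        "bdev_mean_abs_error": float(np.mean(bdev_errors)) if bdev_errors else float("nan"),
        "bdev_max_abs_error": float(np.max(bdev_errors)) if bdev_errors else float("nan"),
    }


def origin_benchmark(seed: int) -> dict:
    """Run the 20-polysomy cohort end-to-end and summarise origins.

    Simulates 5 mitotic / 8 meiosis-I / 7 meiosis-II whole-chromosome
    trisomies, calls and types each sample, classifies each gain's origin
    from its third-haplotype pattern, and returns the origin summary plus
    the per-event assignments.
    """
    genome = toy_genome()
    sim = simulate_cohort(origin_cohort_config(), seed=seed)
    truth_by_ind = {t.individual: t.origin for t in sim.truth}
    assigned: dict[str, str] = {}
    for (ind, _tissue), sample in sim.samples.items():
        res = MosaicScan(sample).fit(["3"]).interpret()
        gains = [c for c in res.calls if c.type == "gain"]
        if not gains:
            assigned[ind] = "undetermined"
            continue
        call = max(gains, key=lambda c: c.n_hets)
        assigned[ind] = classify_polysomy_origin(call, sample, genome).origin
    summary = origin_summary(list(assigned.values()))
    n_correct = sum(assigned[i] == truth_by_ind[i] for i in truth_by_ind)
    summary["accuracy"] = n_correct / len(truth_by_ind)
    summary["assigned"] = assigned
    return summary


def concordance_benchmark(seed: int) -> TissueConcordance:
    """Simulate the 26-individual two-tissue cohort, call every sample,
    run the filter cascade, and measure saliva/blood concordance.

    The cohort emulates a small slice of a much larger study; the rarity
    filter therefore takes a nominal cohort size of 2,000 individuals as
    its frequency denominator.
    """
    sim = simulate_cohort(tissue_cohort_config(), seed=seed)
    calls = []
    for sample in sim.samples.values():
        calls.extend(MosaicScan(sample).fit().interpret().calls)
    survivors, _traces = run_cascade(calls, sim.samples, n_individuals=2000)
    return tissue_concordance(survivors, sim.manifest)
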