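"""Three-stage filter cascade over candidate mosaic calls.

Stage 1 removes calls that are short (< 100 kbp), weakly supported
(LOD < 10), flagged as likely germline CNVs, at high cell fraction
(> 50%, where constitutive events live), or in samples whose background
phase concordance exceeds the contamination threshold (0.51).  Stage 2
keeps only rare events: recurrent loci (> 1% of cohort individuals at 50%
reciprocal overlap, same type), known germline CNV loci, and sub-1 Mb
calls not touching a developmental-disorder gene are removed.  Stage 3
replaces manual data-quality review with automated proxies: minimum BAF
deviation, minimum probe density, and a per-sample noise ceiling.

Every call carries a first-fail trace; stage counts are conserved
(removed + surviving = input) by construction and asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .caller import MosaicCall, estimate_cell_fraction, sample_background_concordance
from .genome import GeneIntervalSet, interval_overlap
from .sample import SampleArray

__all__ = [
    "FilterConfig",
    "FilterRecord",
    "FilterTrace",
    "stage1_call_filters",
    "stage2_rarity_filters",
    "stage3_qc_review",
    "run_cascade",
]


@dataclass
class FilterConfig:
    # stage 1
    min_length: int = 100_000
    min_lod: float = 10.0
    max_cell_fraction: float = 0.50
    phase_conc_threshold: float = 0.51
    # remove when the *sample background* concordance exceeds the threshold
    # (contamination-like); set to "call_below" to instead drop calls whose
    # own concordance is under the threshold.
    phase_conc_mode: str = "sample_above"
    # the excess over 0.5 must also be significant at this z level, so the
    # threshold keeps its genome-wide meaning on small het counts
    phase_conc_z: float = 5.0
    # stage 2
    max_cohort_freq: float = 0.01
    reciprocal_overlap: float = 0.50
    min_size_without_gene: int = 1_000_000
    # stage 3
    min_bdev: float = 0.01
    min_density_frac: float = 0.25
    max_het_baf_sd: float = 0.06


@dataclass
class FilterRecord:
    stage: str
    check: str
    passed: bool
    value: float


@dataclass
class FilterTrace:
    """Outcome of one filter stage over a set of calls."""

    stage: str
    n_input: int
    survivors: list[MosaicCall] = field(default_factory=list)
    removed: list[tuple[MosaicCall, str, float]] = field(default_factory=list)
    records: dict[int, list[FilterRecord]] = field(default_factory=dict)

    @property
    def n_surviving(self) -> int:
        return len(self.survivors)

    def reason_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason, _ in self.removed:
            out[reason] = out.get(reason, 0) + 1
        return out

    def check_conservation(self) -> None:
        if len(self.survivors) + len(self.removed) != self.n_input:
            raise AssertionError(
                f"{self.stage}: {len(self.survivors)} + {len(self.removed)} "
                f"!= {self.n_input}"
            )


def _apply_checks(stage: str, calls: list[MosaicCall], checks) -> FilterTrace:
    """Run ordered (name, fn) checks with first-fail semantics."""
    trace = FilterTrace(stage=stage, n_input=len(calls))
    for call in calls:
        recs: list[FilterRecord] = []
        failed = None
        for name, fn in checks:
            passed, value = fn(call)
            recs.append(FilterRecord(stage, name, passed, value))
            if not passed:
                failed = (name, value)
                break
        trace.records[id(call)] = recs
        if failed is None:
            trace.survivors.append(call)
        else:
            trace.removed.append((call, failed[0], failed[1]))
    trace.check_conservation()
    return trace


def _call_cell_fraction(call: MosaicCall) -> float:
    """Cell fraction for filtering; for untyped calls take the smallest of
    the three inversions so a call is only removed when every reading of
    its bdev puts it above the cap."""
    if call.type in ("gain", "loss", "cnloh") and not math.isnan(call.cell_fraction):
        return call.cell_fraction
    three = estimate_cell_fraction(call.bdev, "undetermined")
    return three["interval"][0]


def stage1_call_filters(
    calls: list[MosaicCall],
    samples: dict[tuple[str, str], SampleArray] | None,
    config: FilterConfig | None = None,
) -> FilterTrace:
    """Per-call evidence filters (length, LOD, germline flag, cell fraction,
    phase-concordance QC)."""
    config = config or FilterConfig()
    bg_conc: dict[tuple[str, str], tuple[float, int]] = {}
    if samples and config.phase_conc_mode == "sample_above":
        by_sample: dict[tuple[str, str], list] = {}
        for c in calls:
            by_sample.setdefault((c.individual, c.tissue), []).append(c.interval)
        for key, intervals in by_sample.items():
            if key in samples:
                bg_conc[key] = sample_background_concordance(
                    samples[key], intervals, with_pairs=True
                )

    def phase_conc(call):
        if config.phase_conc_mode == "call_below":
            return call.phase_concordance >= config.phase_conc_threshold, call.phase_concordance
        conc, n_pairs = bg_conc.get((call.individual, call.tissue), (0.5, 0))
        z = (conc - 0.5) / math.sqrt(0.25 / n_pairs) if n_pairs else 0.0
        flagged = conc > config.phase_conc_threshold and z > config.phase_conc_z
        return not flagged, conc

    checks = [
        ("phase_concordance", phase_conc),
        ("min_length", lambda c: (c.length >= config.min_length, float(c.length))),
        ("min_lod", lambda c: (c.lod >= config.min_lod, c.lod)),
        ("germline_flag", lambda c: (not c.germline_flag, float(c.germline_flag))),
        (
            "max_cf",
            lambda c: (
                _call_cell_fraction(c) <= config.max_cell_fraction,
                _call_cell_fraction(c),
            ),
        ),
    ]
    return _apply_checks("stage1", calls, checks)


def stage2_rarity_filters(
    calls: list[MosaicCall],
    cohort_calls: list[MosaicCall],
    germline_cnvs: GeneIntervalSet | None,
    dd_genes: GeneIntervalSet | None,
    config: FilterConfig | None = None,
    n_individuals: int | None = None,
) -> FilterTrace:
    """Rarity filters against the cohort and known germline CNV loci."""
    config = config or FilterConfig()
    if n_individuals is None:
        n_individuals = len({c.individual for c in cohort_calls}) or 1
    if dd_genes is None and any(
        c.length < config.min_size_without_gene for c in calls
    ):
        raise ValueError(
            "calls under the minimum size are present but no developmental-"
            "disorder gene list was given; pass dd_genes to apply the size "
            "exemption"
        )

    def cohort_freq(call):
        hits = {
            c.individual
            for c in cohort_calls
            if c.type == call.type
            and min(interval_overlap(c.interval, call.interval)) >= config.reciprocal_overlap
        }
        hits.add(call.individual)
        freq = len(hits) / n_individuals
        return freq <= config.max_cohort_freq, freq

    def germline_overlap(call):
        if germline_cnvs is None:
            return True, 0.0
        best = 0.0
        for chrom, start, end, _ in germline_cnvs:
            fr = min(interval_overlap(call.interval, (chrom, start, end)))
            best = max(best, fr)
        return best < config.reciprocal_overlap, best

    def size_or_gene(call):
        if call.length >= config.min_size_without_gene:
            return True, float(call.length)
        hit = dd_genes.any_overlap(*call.interval) if dd_genes else False
        return hit, float(call.length)

    checks = [
        ("cohort_freq", cohort_freq),
        ("germline_cnv", germline_overlap),
        ("min_size_no_gene", size_or_gene),
    ]
    return _apply_checks("stage2", calls, checks)


def stage3_qc_review(
    calls: list[MosaicCall],
    samples: dict[tuple[str, str], SampleArray],
    config: FilterConfig | None = None,
) -> FilterTrace:
    """Automated stand-ins for manual data-quality review."""
    config = config or FilterConfig()
    qc_cache: dict[tuple[str, str], dict] = {}
    spacing_cache: dict[tuple[str, str], float] = {}

    def _sample(call) -> SampleArray | None:
        return samples.get((call.individual, call.tissue))

    def low_bdev(call):
        return call.bdev >= config.min_bdev, call.bdev

    def sparse_snps(call):
        smp = _sample(call)
        if smp is None:
            return True, 0.0
        key = (call.individual, call.tissue)
        if key not in spacing_cache:
            spacing_cache[key] = smp.median_snp_spacing()
        median_density = 1.0 / spacing_cache[key]
        density = call.n_snps / call.length
        return density >= config.min_density_frac * median_density, density

    def noisy_sample(call):
        smp = _sample(call)
        if smp is None:
            return True, 0.0
        key = (call.individual, call.tissue)
        if key not in qc_cache:
            qc_cache[key] = smp.qc_stats()
        sd = qc_cache[key]["baf_sd_het"]
        return sd <= config.max_het_baf_sd, sd

    checks = [
        ("low_bdev", low_bdev),
        ("sparse_snps", sparse_snps),
        ("noisy_sample", noisy_sample),
    ]
    return _apply_checks("stage3", calls, checks)


def run_cascade(
    calls: list[MosaicCall],
    samples: dict[tuple[str, str], SampleArray],
    cohort_calls: list[MosaicCall] | None = None,
    germline_cnvs: GeneIntervalSet | None = None,
    dd_genes: GeneIntervalSet | None = None,
    config: FilterConfig | None = None,
    n_individuals: int | None = None,
) -> tuple[list[MosaicCall], list[FilterTrace]]:
    """Run all three stages; returns (survivors, ordered traces)."""
    config = config or FilterConfig()
    t1 = stage1_call_filters(calls, samples, config)
    t2 = stage2_rarity_filters(
        t1.survivors, cohort_calls if cohort_calls is not None else calls,
        germline_cnvs, dd_genes, config, n_individuals,
    )
    t3 = stage3_qc_review(t2.survivors, samples, config)
    return t3.survivors, [t1, t2, t3]
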