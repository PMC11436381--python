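"""Mosaic-event detection from phased BAF by hidden-state segmentation.

The detection signal is the *signed* BAF deviation at phased heterozygous
probes: ``s_i = (BAF_i - 0.5) * sigma_i`` with ``sigma_i = +1`` when the
first-phase allele is ALT.  Under no event the ``s_i`` scatter around 0;
inside a mosaic event they sit at ``+d`` or ``-d`` consistently along one
haplotype, where ``d`` (the "bdev") is a type-specific function of the
fraction of cells carrying the event.

Segmentation uses a 3-state HMM (neutral, event at +d, event at -d) with
Gaussian emissions, run over a grid of candidate ``d`` values; the Viterbi
path defines call intervals.  Orientation flips inside one interval are
allowed (meiotic crossovers, phasing switch errors) and counted.  Each call
is scored with a maximum-likelihood ``d``, a log10 likelihood ratio (LOD)
against the neutral model, and its phase concordance.

The public surface follows the model/results idiom: build a
:class:`MosaicScan` from a sample, call :meth:`~MosaicScan.fit`, and read
calls and diagnostics off the returned :class:`MosaicScanResult`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild, toy_genome
from .sample import GT_HET, SampleArray

__all__ = [
    "MosaicCall",
    "CallerParams",
    "MosaicScan",
    "MosaicScanResult",
    "phased_deviation_series",
    "segment_events",
    "lod_score",
    "estimate_cell_fraction",
    "sample_background_concordance",
]

LN10 = math.log(10.0)


@dataclass
class MosaicCall:
    """One detected mosaic event and its evidence scores."""

    individual: str
    tissue: str
    chrom: str
    start: int               # 1-based inclusive, first supporting het
    end: int                 # last supporting het
    n_snps: int
    n_hets: int
    bdev: float              # fitted |BAF - 0.5| at hets
    lrr_mean: float
    lrr_se: float
    lod: float
    phase_concordance: float
    orientation_switches: int = 0
    germline_flag: bool = False
    type: str | None = None          # assigned by event_interpretation
    cell_fraction: float = float("nan")
    arm: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("call end < start")
        if self.n_hets > self.n_snps:
            raise ValueError("n_hets > n_snps")
        if self.lod < 0:
            raise ValueError("LOD must be >= 0")
        if not (0.0 <= self.bdev <= 0.5):
            raise ValueError("bdev must lie in [0, 0.5]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _default_fine_grid() -> np.ndarray:
    # fine where mosaic fractions <= 50% live, coarser above
    return np.concatenate(
        [np.arange(0.0, 0.25, 0.0025), np.arange(0.25, 0.5 + 1e-12, 0.01)]
    )


def _default_coarse_grid() -> np.ndarray:
    return np.array(
        [0.01, 0.02, 0.03, 0.045, 0.065, 0.09, 0.12, 0.16, 0.21, 0.28, 0.36, 0.45]
    )


@dataclass
class CallerParams:
    """Tunables of the segmentation HMM; all log penalties in nats."""

    coarse_grid: np.ndarray = field(default_factory=_default_coarse_grid)
    fine_grid: np.ndarray = field(default_factory=_default_fine_grid)
    log_enter: float = math.log(1e-12)   # neutral -> event
    log_exit: float = math.log(1e-3)     # event -> neutral
    log_flip: float = math.log(0.15)     # +d <-> -d within an event; flips are
                                         # routine (meiotic haplotypes, phasing
                                         # switch errors) so the cost per flip
                                         # must stay below the per-site signal
    min_hets: int = 25                   # per chromosome, else no calls
    min_seg_hets: int = 10               # per segment
    merge_gap_hets: int = 10             # neutral gap below which segments merge
    arm_aware: bool = False              # forbid calls crossing the centromere
    sd_floor: float = 0.008              # floor on the robust noise estimate
    split_z: float = 8.0                 # z threshold for bdev change-points
                                         # inside one segment (splits adjacent
                                         # events of different magnitude)
    germline_dup_bdev: tuple[float, float] = (0.14, 0.20)   # around 1/6
    germline_dup_lrr: float = 0.40
    germline_del_bdev: float = 0.45
    germline_del_lrr: float = -0.70


# --------------------------------------------------------------------------
# signal extraction
# --------------------------------------------------------------------------

def phased_deviation_series(
    sample: SampleArray, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Signed BAF deviations at phased hets on one chromosome.

    Returns ``(positions, s, probe_indices, n_unphased_dropped)``.
    """
    cd = sample[chrom]
    het = (cd.gt == GT_HET) & ~np.isnan(cd.baf)
    usable = het & cd.phased
    n_dropped = int(het.sum() - usable.sum())
    idx = np.flatnonzero(usable)
    sigma = np.where(cd.hap1[idx] == 1, 1.0, -1.0)
    s = (cd.baf[idx] - 0.5) * sigma
    return cd.pos[idx], s, idx, n_dropped


def _robust_sd(sample: SampleArray, floor: float) -> float:
    """Genome-wide robust het-BAF noise sd for one sample.

    Uses the median |BAF - 0.5| over all phased hets (x1.4826, the Gaussian
    consistency factor for a half-normal median), so an event confined to a
    minority of the genome cannot inflate the estimate — unlike a
    per-chromosome MAD of the *signed* series, which a whole-chromosome
    meiotic event (random per-site orientation) would blow up to ~bdev.
    """
    devs = []
    for chrom in sample.chromosomes:
        _, s, _, _ = phased_deviation_series(sample, chrom)
        devs.append(np.abs(s))
    dev = np.concatenate(devs) if devs else np.array([])
    if len(dev) == 0:
        return floor
    return max(1.4826 * float(np.median(dev)), floor)


# --------------------------------------------------------------------------
# Viterbi over the bdev grid
# --------------------------------------------------------------------------

def _viterbi(s: np.ndarray, sd: float, params: CallerParams):
    """Best-scoring Viterbi path over states (neutral, +d, -d) x d-grid.

    Returns ``(states, d_star)`` where ``states`` is the decoded path
    (0 neutral, 1 = +d, 2 = -d) for the best grid value ``d_star``.
    """
    grid = np.asarray(params.coarse_grid, dtype=float)
    n, G = len(s), len(grid)
    inv2v = 1.0 / (2.0 * sd * sd)
    mu = np.stack([np.zeros(G), grid, -grid], axis=1)          # (G, 3)
    E = -((s[:, None, None] - mu[None, :, :]) ** 2) * inv2v    # (n, G, 3)
    T = np.array(
        [
            [0.0, params.log_enter, params.log_enter],
            [params.log_exit, 0.0, params.log_flip],
            [params.log_exit, params.log_flip, 0.0],
        ]
    )  # T[i, j]: from state i to state j
    V = E[0] + np.array([0.0, params.log_enter, params.log_enter])
    bp = np.zeros((n, G, 3), dtype=np.int8)
    for t in range(1, n):
        M = V[:, :, None] + T[None, :, :]      # (G, from, to)
        bp[t] = M.argmax(axis=1)
        V = M.max(axis=1) + E[t]
    g_star = int(V.max(axis=1).argmax())
    states = np.zeros(n, dtype=np.int8)
    states[-1] = int(V[g_star].argmax())
    for t in range(n - 1, 0, -1):
        states[t - 1] = bp[t, g_star, states[t]]
    return states, float(grid[g_star])


def _segments_from_path(states: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Index ranges [i, j] (inclusive) of non-neutral runs, gap-merged."""
    nz = np.flatnonzero(states != 0)
    if len(nz) == 0:
        return []
    breaks = np.flatnonzero(np.diff(nz) > 1)
    runs = []
    start = nz[0]
    for b in breaks:
        runs.append((start, nz[b]))
        start = nz[b + 1]
    runs.append((start, nz[-1]))
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def _changepoint_splits(
    x: np.ndarray, sd: float, min_size: int, z_thresh: float, offset: int = 0
) -> list[int]:
    """Recursive binary segmentation on mean shifts of the |deviation| series.

    The HMM fits one bdev per path, so two abutting events of different
    magnitude (e.g. a deletion flanked by copy-neutral LOH) land in one
    segment; this step splits them wherever the two-sample z statistic of
    the best mean shift exceeds ``z_thresh``.  Returns absolute split
    indices (start of the right part).
    """
    n = len(x)
    if n < 2 * min_size:
        return []
    cum = np.cumsum(x)
    k = np.arange(min_size, n - min_size + 1)
    m1 = cum[k - 1] / k
    m2 = (cum[-1] - cum[k - 1]) / (n - k)
    z = np.abs(m1 - m2) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    i = int(np.argmax(z))
    if z[i] < z_thresh:
        return []
    split = int(k[i])
    left = _changepoint_splits(x[:split], sd, min_size, z_thresh, offset)
    right = _changepoint_splits(x[split:], sd, min_size, z_thresh, offset + split)
    return left + [offset + split] + right


def _fit_bdev(s_seg: np.ndarray, o_seg: np.ndarray, grid: np.ndarray) -> float:
    """ML bdev on the grid given per-site orientations (Gaussian => mean)."""
    m = float(np.mean(o_seg * s_seg))
    m = min(max(m, 0.0), 0.5)
    return float(grid[np.argmin(np.abs(grid - m))])


def lod_score(s_seg: np.ndarray, o_seg: np.ndarray, d: float, sd: float) -> float:
    """log10 likelihood ratio of the oriented-event model vs the null.

    Gaussian emissions with common sd cancel everywhere except the means,
    so the LOD reduces to a sum of squared-residual differences.
    """
    resid_null = np.sum(s_seg**2)
    resid_alt = np.sum((s_seg - o_seg * d) ** 2)
    return max((resid_null - resid_alt) / (2.0 * sd * sd) / LN10, 0.0)


def sample_background_concordance(
    sample: SampleArray,
    exclude: list[tuple[str, int, int]] | None = None,
    with_pairs: bool = False,
):
    """Adjacent-pair sign concordance of phased-het deviations off-call.

    ~0.5 in a clean sample; values above ~0.51 indicate genome-wide phase-
    coherent imbalance (e.g. DNA contamination) and are used as a sample QC
    in the filter cascade.
    """
    exclude = exclude or []
    agree = total = 0
    for chrom in sample.chromosomes:
        pos, s, _, _ = phased_deviation_series(sample, chrom)
        keep = np.ones(len(pos), dtype=bool)
        for c, a, b in exclude:
            if c == chrom:
                keep &= ~((pos >= a) & (pos <= b))
        s = s[keep]
        nz = s[s != 0]
        if len(nz) > 1:
            agree += int(np.sum(np.sign(nz[1:]) == np.sign(nz[:-1])))
            total += len(nz) - 1
    conc = agree / total if total else 0.5
    return (conc, total) if with_pairs else conc


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def _scan_block(
    sample: SampleArray,
    chrom: str,
    block: np.ndarray,
    pos: np.ndarray,
    s: np.ndarray,
    sd: float,
    params: CallerParams,
) -> list[MosaicCall]:
    """Run the HMM on one contiguous het block (whole chrom or one arm)."""
    pos_b, s_b = pos[block], s[block]
    if len(s_b) < params.min_hets:
        return []
    states, _ = _viterbi(s_b, sd, params)
    cd = sample[chrom]
    calls = []
    pieces: list[tuple[int, int]] = []
    for i, j in _segments_from_path(states, params.merge_gap_hets):
        splits = _changepoint_splits(
            np.abs(s_b[i : j + 1]), sd, params.min_seg_hets, params.split_z
        )
        bounds = [i] + [i + sp for sp in splits] + [j + 1]
        pieces.extend((a, b - 1) for a, b in zip(bounds, bounds[1:]))
    for i, j in pieces:
        seg = slice(i, j + 1)
        o = np.where(states[seg] == 2, -1.0, 1.0)
        # merged neutral gaps inherit the preceding orientation
        neutral = states[seg] == 0
        if neutral.any():
            filled = np.where(neutral, np.nan, o)
            o = pd.Series(filled).ffill().bfill().to_numpy()
        s_seg = s_b[seg]
        if len(s_seg) < params.min_seg_hets:
            continue
        d_hat = _fit_bdev(s_seg, o, params.fine_grid)
        lod = lod_score(s_seg, o, d_hat, sd)
        start, end = int(pos_b[i]), int(pos_b[j])
        in_iv = cd.slice_interval(start, end)
        lrr_iv = cd.lrr[in_iv]
        lrr_iv = lrr_iv[~np.isnan(lrr_iv)]
        lrr_mean = float(np.mean(lrr_iv)) if len(lrr_iv) else float("nan")
        lrr_se = (
            float(np.std(lrr_iv) / math.sqrt(len(lrr_iv))) if len(lrr_iv) else float("nan")
        )
        conc = float(np.mean(np.sign(s_seg) == o)) if len(s_seg) else 0.5
        switches = int(np.sum(np.diff(o) != 0))
        lo, hi = params.germline_dup_bdev
        germline = (
            (lo <= d_hat <= hi and not math.isnan(lrr_mean) and lrr_mean >= params.germline_dup_lrr)
            or (d_hat >= params.germline_del_bdev and not math.isnan(lrr_mean)
                and lrr_mean <= params.germline_del_lrr)
        )
        calls.append(
            MosaicCall(
                individual=sample.individual,
                tissue=sample.tissue,
                chrom=chrom,
                start=start,
                end=end,
                n_snps=int(in_iv.sum()),
                n_hets=len(s_seg),
                bdev=d_hat,
                lrr_mean=lrr_mean,
                lrr_se=lrr_se,
                lod=lod,
                phase_concordance=max(conc, 0.5),
                orientation_switches=switches,
                germline_flag=bool(germline),
            )
        )
    return calls


def segment_events(
    sample: SampleArray,
    params: CallerParams | None = None,
    genome: GenomeBuild | None = None,
    chroms: list[str] | None = None,
) -> list[MosaicCall]:
    """Detect candidate mosaic events in one sample.

    With ``params.arm_aware`` the p- and q-arms are segmented separately and
    no call can cross the centromere.
    """
    params = params or CallerParams()
    genome = genome or toy_genome()
    sd = _robust_sd(sample, params.sd_floor)
    calls: list[MosaicCall] = []
    for chrom in chroms or list(sample.chromosomes):
        pos, s, _, _ = phased_deviation_series(sample, chrom)
        if len(s) < params.min_hets:
            warnings.warn(
                f"{sample.label} {chrom}: only {len(s)} phased hets "
                f"(< {params.min_hets}); no calls made"
            )
            continue
        if params.arm_aware and genome is not None and chrom in genome:
            geom = genome[chrom]
            blocks = [pos < geom.cen_start, pos > geom.cen_end]
        else:
            blocks = [np.ones(len(pos), dtype=bool)]
        for block in blocks:
            calls.extend(_scan_block(sample, chrom, block, pos, s, sd, params))
    return calls


# --------------------------------------------------------------------------
# cell-fraction inversion
# --------------------------------------------------------------------------

def estimate_cell_fraction(d: float, event_type: str):
    """Invert the bdev/cell-fraction mixture relations.

    gain: f = 4d / (1 - 2d); loss: f = 4d / (1 + 2d); cnloh: f = 2d;
    results clipped to [0, 1].  For ``event_type='undetermined'`` all three
    inversions are returned with their [min, max] envelope.
    """
    if not (0.0 <= d <= 0.5):
        raise ValueError(f"bdev {d} outside [0, 0.5]")
    if event_type == "gain":
        return min(4.0 * d / (1.0 - 2.0 * d), 1.0) if d < 0.5 else 1.0
    if event_type == "loss":
        return min(4.0 * d / (1.0 + 2.0 * d), 1.0)
    if event_type == "cnloh":
        return min(2.0 * d, 1.0)
    if event_type == "undetermined":
        three = {t: estimate_cell_fraction(d, t) for t in ("gain", "loss", "cnloh")}
        three["interval"] = (min(three.values()), max(three.values()))
        return three
    raise ValueError(f"unknown event type {event_type!r}")


# --------------------------------------------------------------------------
# model / results surface
# --------------------------------------------------------------------------

class MosaicScan:
    """Per-sample mosaic-alteration scan model.

    Parameters
    ----------
    sample : SampleArray
        One tissue sample with BAF/LRR.
    genome : GenomeBuild, optional
        Arm geometry; defaults to the packaged toy build.
    params : CallerParams, optional
        HMM and scoring tunables.
    """

    def __init__(
        self,
        sample: SampleArray,
        genome: GenomeBuild | None = None,
        params: CallerParams | None = None,
    ):
        self.sample = sample
        self.genome = genome or toy_genome()
        self.params = params or CallerParams()

    @classmethod
    def from_vcf(
        cls,
        path: str,
        genome: GenomeBuild | None = None,
        params: CallerParams | None = None,
        sample_name: str | None = None,
    ) -> "MosaicScan":
        from .io import read_sample_vcf

        genome = genome or toy_genome()
        return cls(read_sample_vcf(path, genome, sample_name), genome, params)

    def fit(self, chroms: list[str] | None = None) -> "MosaicScanResult":
        """Segment the sample and score every candidate call."""
        diagnostics: dict = {}
        for chrom in chroms or list(self.sample.chromosomes):
            pos, s, _, dropped = phased_deviation_series(self.sample, chrom)
            diagnostics[chrom] = {
                "n_phased_hets": len(s),
                "n_unphased_dropped": dropped,
            }
        diagnostics["sd_hat"] = _robust_sd(self.sample, self.params.sd_floor)
        calls = segment_events(self.sample, self.params, self.genome, chroms)
        return MosaicScanResult(self, calls, diagnostics)


class MosaicScanResult:
    """Fit result: the calls, per-chromosome diagnostics, and summaries."""

    def __init__(self, model: MosaicScan, calls: list[MosaicCall], diagnostics: dict):
        self.model = model
        self.calls = calls
        self.diagnostics = diagnostics

    def interpret(self, margin: float = 1.5) -> "MosaicScanResult":
        """Assign copy-number type, cell fraction and arm label to each call."""
        from .interpret import arm_label, classify_type

        for call in self.calls:
            call.type = classify_type(call, margin=margin)
            if call.type in ("gain", "loss", "cnloh"):
                call.cell_fraction = estimate_cell_fraction(call.bdev, call.type)
            call.arm = arm_label(call, self.model.genome)
        return self

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "individual", "tissue", "chrom", "start", "end", "n_snps", "n_hets",
            "bdev", "lrr_mean", "lrr_se", "lod", "phase_concordance",
            "orientation_switches", "germline_flag", "type", "cell_fraction",
            "arm", "group",
        ]
        return pd.DataFrame([{c: getattr(call, c) for c in cols} for call in self.calls],
                            columns=cols)

    def summary(self) -> str:
        lines = [
            f"MosaicScan of {self.model.sample.label} "
            f"({sum(isinstance(v, dict) for v in self.diagnostics.values())} chromosomes)",
            "-" * 72,
        ]
        for chrom, diag in self.diagnostics.items():
            if not isinstance(diag, dict):
                continue
            lines.append(
                f"  {chrom}: {diag['n_phased_hets']} phased hets, "
                f"{diag['n_unphased_dropped']} unphased dropped"
            )
        lines.append(f"noise sd estimate: {self.diagnostics.get('sd_hat', float('nan')):.4f}")
        lines.append(f"{len(self.calls)} candidate call(s)")
        for c in self.calls:
            typ = c.type or "untyped"
            cf = f", cf={c.cell_fraction:.2f}" if not math.isnan(c.cell_fraction) else ""
            lines.append(
                f"  {c.chrom}:{c.start}-{c.end} {typ} bdev={c.bdev:.4f} "
                f"lod={c.lod:.1f} conc={c.phase_concordance:.3f}{cf}"
            )
        return "\n".join(lines)

    def plot(self, chrom: str, ax=None):
        """BAF/LRR scatter with call intervals shaded (needs matplotlib)."""
        import matplotlib.pyplot as plt

        cd = self.model.sample[chrom]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ax.scatter(cd.pos / 1e6, cd.baf, s=2, c="steelblue", label="BAF")
        ax.scatter(cd.pos / 1e6, cd.lrr + 0.5, s=2, c="darkorange", alpha=0.4, label="LRR+0.5")
        for c in self.calls:
            if c.chrom == chrom:
                ax.axvspan(c.start / 1e6, c.end / 1e6, color="red", alpha=0.15)
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("BAF")
        ax.legend(loc="upper right", markerscale=4)
        return ax
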