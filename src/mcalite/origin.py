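"""Mitotic vs meiotic origin of mosaic polysomies and monosomies.

A trisomy's extra chromosome betrays its origin at *third-haplotype sites*:
probes where the individual is homozygous but the extra copy carries the
other allele, pulling BAF off 0 or 1 by ``f / (2 + f)``.  A mitotically
duplicated homolog can never create such sites; a meiosis-I error leaves
them near the centromere (centromeric heterodisomy); a meiosis-II error
leaves them only distal to a crossover (centromeric isodisomy).

Mosaic monosomies that arise by mitotic nondisjunction keep both parental
haplotypes in the mixture, so hets show split BAF bands at 0.5 +/- d.
Monosomy *rescue* produces isodisomy — a run of homozygosity — which a
phase-based caller cannot see at all; the classifier therefore never
returns a positive rescue call, it can only flag that limitation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .caller import MosaicCall
from .genome import GenomeBuild
from .sample import GT_HET, GT_HOM_ALT, GT_HOM_REF, SampleArray

__all__ = [
    "OriginCall",
    "third_haplotype_sites",
    "classify_polysomy_origin",
    "classify_monosomy_origin",
]


@dataclass
class OriginCall:
    """Origin assignment for one polysomy call."""

    call_id: str
    origin: str                 # mitotic | meiosis_I | meiosis_II | undetermined
    proximal_density: float
    distal_density: float
    n_sites: int                # supporting third-haplotype sites in the event
    density_floor: float

    def __post_init__(self) -> None:
        if self.proximal_density < 0 or self.distal_density < 0:
            raise ValueError("densities must be >= 0")


def _hom_noise_sd(sample: SampleArray, exclude: tuple[str, int, int] | None) -> float:
    """Half-normal sd of hom-site BAF displacement, off the event."""
    devs = []
    for chrom, cd in sample.chromosomes.items():
        hom = ((cd.gt == GT_HOM_REF) | (cd.gt == GT_HOM_ALT)) & ~np.isnan(cd.baf)
        if exclude is not None and chrom == exclude[0]:
            hom &= ~cd.slice_interval(exclude[1], exclude[2])
        dev = np.minimum(cd.baf[hom], 1.0 - cd.baf[hom])
        devs.append(dev)
    dev = np.concatenate(devs) if devs else np.array([])
    if len(dev) == 0:
        return 0.0
    # median of |N(0, sd)| is 0.6745 sd
    return float(np.median(dev) / 0.6745)


def _third_hap_window(f: float, tol: float) -> tuple[float, float]:
    shift = f / (2.0 + f)
    tol = min(tol, 0.45 * shift)   # window must stay clear of 0 and of 0.5
    return (shift - tol, shift + tol)


def third_haplotype_sites(
    sample: SampleArray,
    call: MosaicCall,
    f: float | None = None,
    tol: float | None = None,
) -> np.ndarray:
    """Positions of hom probes displaced by ~f/(2+f) inside a gain call.

    These are the sites where the extra copy carries the allele the
    individual's own two homologs lack.  ``tol`` defaults to three times
    the off-event hom-noise sd.
    """
    if call.type != "gain":
        raise ValueError(f"third-haplotype sites are defined for gains, not {call.type!r}")
    f = call.cell_fraction if f is None else f
    if f is None or math.isnan(f) or not (0.0 < f <= 1.0):
        raise ValueError("a cell-fraction estimate in (0, 1] is required")
    if tol is None:
        tol = max(3.0 * _hom_noise_sd(sample, call.interval), 0.015)
    lo, hi = _third_hap_window(f, tol)
    cd = sample[call.chrom]
    in_call = cd.slice_interval(call.start, call.end)
    hom = ((cd.gt == GT_HOM_REF) | (cd.gt == GT_HOM_ALT)) & ~np.isnan(cd.baf)
    dev = np.minimum(cd.baf, 1.0 - cd.baf)   # displacement toward the interior
    hit = in_call & hom & (dev >= lo) & (dev <= hi)
    return cd.pos[hit]


def _window_masks(
    pos: np.ndarray, call: MosaicCall, geom, window_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split event probes into centromere-proximal and distal windows.

    The proximal window is the ``window_frac`` share of the event length
    adjacent to the centromere (split across both sides when the event
    spans it)."""
    w = int(window_frac * (call.end - call.start + 1))
    spans = call.start < geom.cen_start and call.end > geom.cen_end
    if spans:
        w = w // 2
        prox = ((pos >= geom.cen_start - w) & (pos < geom.cen_start)) | (
            (pos > geom.cen_end) & (pos <= geom.cen_end + w)
        )
    elif call.end < geom.cen_start:          # p-arm event
        prox = pos >= call.end - w + 1
    else:                                    # q-arm event
        prox = pos <= call.start + w - 1
    in_event = (pos >= call.start) & (pos <= call.end)
    return in_event & prox, in_event & ~prox


def classify_polysomy_origin(
    call: MosaicCall,
    sample: SampleArray,
    genome: GenomeBuild,
    window_frac: float = 0.2,
    floor_mult: float = 3.0,
    min_floor: float = 0.02,
    min_window_homs: int = 10,
) -> OriginCall:
    """Mitotic / meiosis-I / meiosis-II classification of a gain call.

    Third-haplotype site *density* (qualifying homs / all homs) is measured
    in a centromere-proximal window and in the rest of the event.  The
    density floor is ``floor_mult`` times the rate at which off-event hom
    probes fall into the same BAF acceptance window by noise alone.
    """
    if call.chrom not in genome:
        raise ValueError(f"no centromere known for chromosome {call.chrom!r}")
    geom = genome[call.chrom]
    call_id = f"{call.individual}/{call.tissue}:{call.chrom}:{call.start}-{call.end}"
    f = call.cell_fraction
    tol = max(3.0 * _hom_noise_sd(sample, call.interval), 0.015)
    sites = third_haplotype_sites(sample, call, f=f, tol=tol)

    cd = sample[call.chrom]
    hom_mask = ((cd.gt == GT_HOM_REF) | (cd.gt == GT_HOM_ALT)) & ~np.isnan(cd.baf)
    prox, dist = _window_masks(cd.pos, call, geom, window_frac)
    n_prox_hom = int(np.sum(hom_mask & prox))
    n_dist_hom = int(np.sum(hom_mask & dist))
    site_set = set(sites.tolist())
    in_site = np.isin(cd.pos, sites)
    prox_density = float(np.sum(in_site & prox)) / n_prox_hom if n_prox_hom else 0.0
    dist_density = float(np.sum(in_site & dist)) / n_dist_hom if n_dist_hom else 0.0

    # noise rate: off-event homs landing in the acceptance window by chance
    lo, hi = _third_hap_window(f, tol)
    n_noise = n_off = 0
    for chrom, ocd in sample.chromosomes.items():
        hom = ((ocd.gt == GT_HOM_REF) | (ocd.gt == GT_HOM_ALT)) & ~np.isnan(ocd.baf)
        if chrom == call.chrom:
            hom &= ~ocd.slice_interval(call.start, call.end)
        dev = np.minimum(ocd.baf[hom], 1.0 - ocd.baf[hom])
        n_noise += int(np.sum((dev >= lo) & (dev <= hi)))
        n_off += int(hom.sum())
    noise_rate = n_noise / n_off if n_off else 0.0
    floor = max(floor_mult * noise_rate, min_floor)

    if n_prox_hom < min_window_homs or n_dist_hom < min_window_homs:
        origin = "undetermined"
    elif prox_density >= floor:
        origin = "meiosis_I"
    elif dist_density >= floor:
        origin = "meiosis_II"
    else:
        origin = "mitotic"
    return OriginCall(
        call_id=call_id,
        origin=origin,
        proximal_density=prox_density,
        distal_density=dist_density,
        n_sites=len(site_set),
        density_floor=floor,
    )


def classify_monosomy_origin(
    call: MosaicCall,
    sample: SampleArray,
    min_hets: int = 10,
    band_tol: float = 0.5,
) -> str:
    """'mitotic_nondisjunction' or 'undetermined' for a mosaic monosomy.

    Mitotic nondisjunction leaves both haplotypes in the cell mixture and
    splits het BAF into bands at 0.5 +/- d; we require the median het
    displacement to sit within ``band_tol`` (relative) of the fitted bdev.
    Monosomy rescue would present as homozygosity and is not callable by a
    phase-based method, so a positive rescue assignment is never returned.
    """
    if call.type != "loss":
        raise ValueError(f"monosomy origin is defined for losses, not {call.type!r}")
    cd = sample[call.chrom]
    in_call = cd.slice_interval(call.start, call.end)
    het = in_call & (cd.gt == GT_HET) & ~np.isnan(cd.baf)
    if int(het.sum()) < min_hets:
        warnings.warn(
            f"{call.chrom}:{call.start}-{call.end}: only {int(het.sum())} hets; "
            "monosomy origin undetermined"
        )
        return "undetermined"
    dev = np.abs(cd.baf[het] - 0.5)
    med = float(np.median(dev))
    if call.bdev > 0 and abs(med - call.bdev) <= band_tol * call.bdev:
        return "mitotic_nondisjunction"
    return "undetermined"
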