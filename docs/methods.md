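# Methods

## Signal model

All detection rests on a two-population mixture: a fraction *f* of cells
carry the alteration, the rest are normal diploid.  At a probe where
affected cells carry `b_a` copies of the B allele out of `n_a` total and
normal cells `b_n` of `n_n`:

    BAF = (f·b_a + (1−f)·b_n) / (f·n_a + (1−f)·n_n)
    LRR = log2( (f·n_a + (1−f)·n_n) / 2 )

Specialising to a heterozygote whose ALT allele sits on the affected
haplotype gives the familiar closed forms — gain: BAF = ½ + f/(2(2+f)),
LRR = log2(1+f/2); loss (ALT retained): BAF = ½ + f/(2(2−f)),
LRR = log2(1−f/2); copy-neutral LOH: BAF = ½ ± f/2, LRR = 0.  At a
homozygous probe where a meiotic extra copy carries the missing allele
("third-haplotype site") the BAF moves off 0/1 by f/(2+f).  The test-suite
checks every closed form against a brute-force pool of 10⁶ explicit cells.

Cell-fraction estimation inverts the het relations: f = 4d/(1−2d) for
gains, 4d/(1+2d) for losses, 2d for CN-LOH, clipped to [0,1].  The
inversion is exact (round trip to 1e−9 on a grid of f); for calls whose
type cannot be determined all three inversions and their envelope are
reported, and the cascade's cell-fraction cap uses the smallest, so an
untyped call is only removed when every reading puts it above the cap.

## Detection

The caller works on the *signed* phased-BAF series at heterozygous probes,
s_i = (BAF_i − ½)·σ_i with σ_i = +1 when the first-phase allele is ALT.
Unphased hets are dropped from the series (counted in diagnostics and in
`n_snps`).  Segmentation is a 3-state HMM — neutral, event at +d, event at
−d — with Gaussian emissions, evaluated by Viterbi decoding jointly over a
12-point coarse grid of candidate d; the best-likelihood grid value's path
defines intervals.  Per-interval d is then refitted by maximum likelihood
on a fine grid (0–0.25 in steps of 0.0025, 0.25–0.5 in steps of 0.01 —
fine where the ≤50% cell-fraction filters live) and scored with
LOD = log10 L(s | ±d̂, decoded orientations) / L(s | d = 0), which is
non-negative by construction because d = 0 lies on the grid.

Orientation flips inside an event are *cheap* (log-penalty ln 0.15 per
flip) and counted per call.  This is deliberate: a meiotic extra haplotype
is a mosaic of the transmitting parent's two homologs, so without linkage
disequilibrium its BAF deviation flips direction at essentially every
informative probe; a strong flip penalty fragments exactly the calls the
origin classifier needs.  The flip cost must simply stay below the
per-site signal (d²/2σ² ≈ 2.4 nats at d = 2.2σ) while keeping the null
path stable (entering an event costs ln 1e−12, leaving ln 1e−3).

The per-sample noise σ is estimated genome-wide as 1.4826 × median
|BAF − ½| over all phased hets (the Gaussian consistency factor for a
half-normal median), floored at 0.008.  A per-chromosome MAD of the signed
series would be inflated to ≈ d by a whole-chromosome meiotic event, whose
random per-site orientations destroy the sign cancellation; the
genome-wide unsigned median is robust as long as events cover a minority
of probes, which is why the validation cohorts always include an
event-free chromosome.

One HMM path carries a single d, so two abutting events of different
magnitude (a deletion flanked by CN-LOH, say) land in one segment.  A
recursive binary-segmentation pass on the unsigned deviation series splits
a segment wherever the best mean-shift z statistic exceeds 8 (conservative
against the thousands of implicit tests per genome), and each piece is
scored separately.  Adjacent differently-typed calls separated by under
1 Mb are then reported as one composite event with an ordered pattern
string (`loh-del-loh`).

Segments merge across neutral gaps shorter than 10 hets; chromosomes with
fewer than 25 phased hets yield no calls (with a warning).  An optional
arm-aware mode segments p and q arms separately so no call can cross the
centromere; it is off by default so that whole-chromosome events are
reported as single "w" calls.

## Typing and arm labels

Each call's mean LRR is compared with the three expectations implied by
its d̂ (gain, loss, CN-LOH above); the winner by standardized distance is
assigned unless the top two are within 1.5 standard-error units, in which
case the call is *undetermined* — a real category on arrays, not an error.
Arm labels: "w" when the call covers ≥ 95% of the chromosome, "p"/"q" when
it covers ≥ 95% of one arm and < 5% of the other, otherwise "partial".
The method cannot distinguish trisomy from tetrasomy or isochromosome
gains; the simulator can generate multi-copy gains (`extra_copies`) but
the caller reports them all as gains.

## Origin classification

For a gain call, third-haplotype sites are homozygous probes inside the
call whose interior displacement lies within a tolerance of f̂/(2+f̂); the
tolerance is 3× the off-event homozygote noise sd (floored at 0.015 and
capped at 45% of the expected displacement so the window stays clear of
0).  Site *density* (qualifying / all homs) is measured in a
centromere-proximal window — 20% of the event length abutting the
centromere, split across both sides when the event spans it — and in the
remaining distal region.  The decision floor is 3× the rate at which
off-event homozygotes land in the same BAF window by chance, with a
minimum of 0.02.  Proximal density above the floor ⇒ meiosis I; proximal
below but distal above ⇒ meiosis II; both below ⇒ mitotic; fewer than 10
informative homs in a window ⇒ undetermined.  The window fraction and
floors are config parameters: the underlying pattern is qualitative and
any reasonable pericentromeric window reproduces it.

Mosaic monosomies are classified `mitotic_nondisjunction` when hets inside
the call show the split BAF bands at ½ ± d that prove both parental
haplotypes persist in the mixture (median displacement within 50% of d̂,
at least 10 hets).  Monosomy *rescue* produces isodisomy — a run of
homozygosity — which a phase-based caller cannot see, so a positive rescue
call is never returned; the same limitation means only
heterodisomy-containing mosaic UPD is detectable at all, and CN-LOH
spiked wholly inside a run of homozygosity must (and does) produce no
call.

## Filter cascade

Stage 1 (evidence): drop calls < 100 kbp, LOD < 10, germline-flagged
(d̂ ≈ 1/6 with LRR ≈ +0.585, or d̂ ≥ 0.45 with LRR ≤ −0.7 — constitutive
duplication/deletion signatures), estimated cell fraction > 50%, or in
samples failing the phase-concordance QC.  That QC follows the
contamination reading of the 0.51 threshold: the *background* (off-call)
adjacent-pair sign concordance of the sample's phased deviations is ≈ 0.5
in clean DNA and rises genome-wide under contamination; a sample is
flagged when it exceeds 0.51 *and* the excess is significant at z > 5, so
the genome-wide threshold keeps its meaning at desk-scale het counts.  An
alternative mode (`call_below`) instead drops calls whose own concordance
falls below the threshold; the statistic to use is genuinely ambiguous
and both directions are config flags.

Stage 2 (rarity): drop calls whose locus recurs (≥ 50% reciprocal
overlap, same type) in > 1% of cohort individuals, calls matching a
listed germline CNV at ≥ 50% reciprocal overlap, and calls < 1 Mb with no
base overlap with a developmental-disorder gene interval.  Requesting the
size rule without a gene list is an error rather than a silent skip.

Stage 3 (quality proxies replacing manual review): drop calls with
d̂ < 0.01, calls whose probe density is below 25% of the sample median,
and calls in samples whose robust het-BAF sd exceeds 0.06.

Checks run in a fixed order with first-fail semantics; each stage
asserts conservation (removed + surviving = input) on every run.

## The simulator

`simulate_phased_sample` draws biallelic SNPs on a jittered ~3 kb grid
(none inside the centromere gap, as on real arrays), minor allele
frequencies uniform on [0.05, 0.5], four parental haplotypes per
chromosome, and perfect phasing; noise defaults are Gaussian sd 0.03 on
het BAF, half-normal sd 0.015 toward the interior at homozygotes, and
sd 0.15 on LRR — typical array-like values chosen once.  Tissues of one
individual share haplotypes and genotypes; only the noise draw and each
event's per-tissue cell fraction differ, with saliva fractions at or
above blood.  Events are written in through the mixture model above;
meiotic extra haplotypes are built from the transmitting parent's two
homologs, anchored at the centromere (untransmitted homolog for meiosis I,
transmitted for meiosis II) and alternating at each crossover moving
outward.  Everything is a pure function of (config, seed) via spawned
`SeedSequence` streams.

What the simulator does **not** model: linkage disequilibrium (real
haplotypes share long stretches, so real meiotic events flip orientation
at IBD-block scale rather than per SNP), chip-specific probe maps,
GC-wave LRR structure, phasing switch errors (phasing is perfect here;
statistical phasing would add switches at ~cM scale, which the caller's
cheap orientation flips are designed to absorb), and genotype-calling
error.  Passing tests therefore demonstrate correctness
of the algorithms under the stated mixture model, not performance on any
particular commercial array.

## Validation problem sizes

The validation cohorts run on a toy genome (three autosomes + X, 30–60 Mb,
centromeres at ~40%) at ~1 SNP / 3 kb: 100 spiked events of ≥ 5 Mb at
f ≥ 0.2 plus 20 null genomes for sensitivity/specificity, a 26-individual
two-tissue cohort (23 saliva-only events, 3 shared with blood below
saliva) for concordance, and 20 whole-chromosome trisomies
(5 mitotic / 8 meiosis I / 7 meiosis II) for origin percentages.  These
sizes leave several hundred informative hets under every event — the
regime the method needs — while a full validation run completes in about
a minute on one core.  GRCh37 arm geometry ships for formatting
real-coordinate event tables.

## Known limitations

* Phase-based blindness inside runs of homozygosity (isodisomy, rescue
  events) is inherent, not an implementation gap.
* The cohort-frequency filter needs an externally supplied cohort size
  when the analysed samples are a slice of a larger study.
* LOD values are model-relative; they are comparable within this
  implementation but not numerically to other callers.
* LRR participates in typing only, not in segmentation (a deliberate
  robustness choice; an LRR emission term would sharpen boundaries of
  large CNVs at the cost of sensitivity to LRR noise).
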