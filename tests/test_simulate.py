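"""Simulator: mixture math, haplotype construction, spiking, cohorts."""

import math

import numpy as np
import pytest

from mcalite import (
    CohortConfig,
    EventSpec,
    IndividualSpec,
    NoiseModel,
    TruthEvent,
    bdev_from_fraction,
    build_polysomy_haplotype,
    expected_signal,
    simulate_cohort,
    simulate_phased_sample,
    spike_event,
)
from mcalite.simulate import ZERO_NOISE
from conftest import brute_force_mixture_baf


class TestExpectedSignal:
    def test_gain_half_matches_explicit_cell_pool(self):
        # 50/50 mixture of a million disomic AB and trisomic AAB/ABB cells
        baf, lrr = expected_signal("gain", 0.5, "het", alt_on_affected=True)
        oracle = brute_force_mixture_baf(0.5, 1_000_000, b_aff=2, n_aff=3)
        assert baf == pytest.approx(oracle, abs=1e-12)
        assert baf - 0.5 == pytest.approx(0.1)
        assert lrr == pytest.approx(math.log2(1.25))

    @pytest.mark.parametrize("typ,b_aff,n_aff", [
        ("gain", 2, 3), ("loss", 1, 1), ("cnloh", 2, 2),
    ])
    @pytest.mark.parametrize("f", [0.05, 0.2, 0.35, 0.6, 0.9, 1.0])
    def test_closed_forms_match_million_cell_oracle(self, typ, b_aff, n_aff, f):
        baf, _ = expected_signal(typ, f, "het", alt_on_affected=True)
        oracle = brute_force_mixture_baf(f, 1_000_000, b_aff, n_aff)
        # agreement to 3 significant digits
        assert baf == pytest.approx(oracle, rel=5e-4)

    def test_third_haplotype_hom_site_oracle(self):
        # AA individual, extra copy carries B: AAB cells vs AA cells
        baf, _ = expected_signal("gain", 0.4, "hom", alt_on_affected=False,
                                 third_haplotype=True)
        oracle = brute_force_mixture_baf(0.4, 1_000_000, b_aff=1, n_aff=3,
                                         b_norm=0, n_norm=2)
        assert baf == pytest.approx(oracle, rel=5e-4)
        assert baf == pytest.approx(0.4 / 2.4)

    def test_complete_cnloh_and_absent_event_limits(self):
        assert expected_signal("cnloh", 1.0, "het")[0] in (0.0, 1.0)
        assert expected_signal("cnloh", 1.0, "het")[1] == 0.0
        for typ in ("gain", "loss", "cnloh"):
            assert expected_signal(typ, 0.0, "het") == (0.5, 0.0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            expected_signal("gain", 1.2, "het")
        with pytest.raises(ValueError):
            bdev_from_fraction(-0.1, "loss")

    def test_bdev_ordering_and_monotonicity(self):
        """gain < loss < cnloh deviation at any fixed fraction; all increasing."""
        grid = np.linspace(0.01, 0.99, 60)
        for typ in ("gain", "loss", "cnloh"):
            d = np.array([bdev_from_fraction(f, typ) for f in grid])
            assert np.all(np.diff(d) > 0)
        for f in grid:
            dg, dl, dc = (bdev_from_fraction(f, t) for t in ("gain", "loss", "cnloh"))
            assert dg < dl < dc


class TestSimulatePhasedSample:
    def test_snp_count_tracks_spacing(self, genome):
        sample, _ = simulate_phased_sample(chroms=["3"], spacing=3000, seed=0)
        n = len(sample["3"])
        assert 0.9 * 10_000 < n < 10_000  # minus the centromere gap

    def test_zero_noise_sample_is_exact(self):
        sample, _ = simulate_phased_sample(chroms=["3"], seed=1, noise=ZERO_NOISE)
        cd = sample["3"]
        het = cd.gt == 1
        assert np.all(cd.baf[het] == 0.5)
        assert np.all(cd.lrr == 0.0)
        assert np.all(np.isin(cd.baf[~het], [0.0, 1.0]))

    def test_same_seed_reproduces_sample(self):
        a, _ = simulate_phased_sample(chroms=["3"], seed=7)
        b, _ = simulate_phased_sample(chroms=["3"], seed=7)
        np.testing.assert_array_equal(a["3"].pos, b["3"].pos)
        np.testing.assert_array_equal(a["3"].baf, b["3"].baf)

    def test_roh_interval_has_no_hets(self):
        sample, _ = simulate_phased_sample(
            chroms=["3"], seed=2, roh=[("3", 20_000_000, 26_000_000)]
        )
        cd = sample["3"]
        inside = cd.slice_interval(20_000_000, 26_000_000)
        assert np.all(cd.gt[inside] != 1)
        assert np.any(cd.gt[~inside] == 1)

    def test_positions_avoid_centromere(self, genome):
        sample, _ = simulate_phased_sample(chroms=["3"], seed=3)
        geom = genome["3"]
        pos = sample["3"].pos
        assert not np.any((pos >= geom.cen_start) & (pos <= geom.cen_end))


class TestSpikeEvent:
    def test_zero_noise_gain_hits_closed_form_exactly(self):
        sample, hap = simulate_phased_sample(chroms=["3"], seed=5, noise=ZERO_NOISE)
        t = TruthEvent(individual="sim", chrom="3", start=5_000_000, end=10_000_000,
                       type="gain", origin="mitotic", cell_fraction={"saliva": 0.4})
        sp = spike_event(sample, t, ZERO_NOISE, hap, seed=6)
        cd = sp["3"]
        inside = cd.slice_interval(t.start, t.end)
        het = inside & (cd.gt == 1)
        d = 0.4 / (2 * 2.4)
        dev = np.abs(cd.baf[het] - 0.5)
        np.testing.assert_allclose(dev, d, atol=1e-12)
        np.testing.assert_allclose(cd.lrr[inside], math.log2(1.2), atol=1e-12)
        # untouched outside
        outside_het = ~inside & (cd.gt == 1)
        assert np.all(cd.baf[outside_het] == 0.5)

    def test_full_fraction_loss_is_hemizygous(self):
        sample, hap = simulate_phased_sample(chroms=["3"], seed=8, noise=ZERO_NOISE)
        t = TruthEvent(individual="sim", chrom="3", start=5_000_000, end=9_000_000,
                       type="loss", cell_fraction={"saliva": 1.0})
        sp = spike_event(sample, t, ZERO_NOISE, hap, seed=9)
        cd = sp["3"]
        inside = cd.slice_interval(t.start, t.end)
        assert np.all(np.isin(cd.baf[inside], [0.0, 1.0]))
        np.testing.assert_allclose(cd.lrr[inside], -1.0, atol=1e-12)

    def test_cnloh_inside_roh_is_invisible(self):
        roh = [("3", 18_000_000, 28_000_000)]
        base, hap = simulate_phased_sample(chroms=["3"], seed=10, noise=ZERO_NOISE, roh=roh)
        t = TruthEvent(individual="sim", chrom="3", start=20_000_000, end=26_000_000,
                       type="cnloh", cell_fraction={"saliva": 0.5})
        sp = spike_event(base, t, ZERO_NOISE, hap, seed=11)
        np.testing.assert_array_equal(base["3"].baf, sp["3"].baf)
        np.testing.assert_array_equal(base["3"].lrr, sp["3"].lrr)


class TestPolysomyHaplotype:
    @pytest.fixture()
    def haps(self):
        _, hap = simulate_phased_sample(chroms=["3"], seed=13, noise=ZERO_NOISE)
        return hap["3"]

    @staticmethod
    def _third_hap_mask(haps, extra):
        child_hom = haps["m1"] == haps["f1"]
        return child_hom & (extra != haps["m1"])

    def test_mitotic_copy_has_no_third_haplotype_sites(self, haps, genome):
        extra = build_polysomy_haplotype(
            haps["m1"], haps["m2"], "mitotic", (), haps["pos"],
            (genome["3"].cen_start, genome["3"].cen_end),
        )
        assert not self._third_hap_mask(haps, extra).any()

    def test_meiosis_I_third_haplotypes_pericentromeric(self, haps, genome):
        """Enumerating sites where the transmitted copies differ shows third
        haplotypes adjacent to the centromere for an MI error."""
        cen = (genome["3"].cen_start, genome["3"].cen_end)
        extra = build_polysomy_haplotype(
            haps["m1"], haps["m2"], "meiosis_I", (20_000_000,), haps["pos"], cen
        )
        mask = self._third_hap_mask(haps, extra)
        pos = haps["pos"]
        near_cen = (pos > cen[0] - 4_000_000) & (pos < cen[1] + 4_000_000)
        beyond_xo = pos > 20_000_000
        # heterodisomy at the centromere: brute-force enumeration finds sites
        expected_near = self._third_hap_mask(
            haps, np.asarray(haps["m2"])
        ) & near_cen
        assert mask[near_cen].sum() == expected_near.sum() > 0
        assert mask[beyond_xo].sum() == 0  # extra returns to transmitted homolog

    def test_meiosis_II_third_haplotypes_distal_only(self, haps, genome):
        cen = (genome["3"].cen_start, genome["3"].cen_end)
        xo = 20_000_000
        extra = build_polysomy_haplotype(
            haps["m1"], haps["m2"], "meiosis_II", (xo,), haps["pos"], cen
        )
        mask = self._third_hap_mask(haps, extra)
        pos = haps["pos"]
        assert mask[pos <= xo].sum() == 0      # isodisomic through the centromere
        assert mask[pos > xo].sum() > 0        # divergence distal to the crossover

    def test_invalid_origin_configs_rejected(self, haps, genome):
        cen = (genome["3"].cen_start, genome["3"].cen_end)
        with pytest.raises(ValueError):
            build_polysomy_haplotype(haps["m1"], haps["m2"], "meiosis_I", (),
                                     haps["pos"], cen)
        with pytest.raises(ValueError):
            build_polysomy_haplotype(haps["m1"], haps["m2"], "rescue", (),
                                     haps["pos"], cen)
        with pytest.raises(ValueError):
            TruthEvent(individual="x", chrom="3", start=1, end=2, type="gain",
                       origin="rescue", cell_fraction={"saliva": 0.3})


class TestSimulateCohort:
    def test_tissue_specific_fractions_shape_the_truth(self):
        cfg = CohortConfig(individuals=[IndividualSpec(
            id="i1", tissues=["blood", "saliva"],
            events=[EventSpec(chrom="3", start=2_000_000, end=8_000_000,
                              type="gain", fractions={"blood": 0.0, "saliva": 0.3})],
        )], chroms=["3"])
        sim = simulate_cohort(cfg, seed=1)
        (t,) = sim.truth
        assert not t.present_in("blood") and t.present_in("saliva")
        # blood sample carries no imbalance inside the interval
        blood = sim.samples[("i1", "blood")]["3"]
        inside = blood.slice_interval(2_000_000, 8_000_000) & (blood.gt == 1)
        assert np.median(np.abs(blood.baf[inside] - 0.5)) < 0.05

    def test_tissues_share_genotypes(self):
        cfg = CohortConfig(individuals=[IndividualSpec(
            id="i1", tissues=["blood", "saliva"])], chroms=["3"])
        sim = simulate_cohort(cfg, seed=2)
        np.testing.assert_array_equal(
            sim.samples[("i1", "blood")]["3"].gt,
            sim.samples[("i1", "saliva")]["3"].gt,
        )

    def test_deterministic_under_seed(self):
        cfg = CohortConfig(individuals=[IndividualSpec(id="i1", tissues=["saliva"])],
                           chroms=["3"])
        a = simulate_cohort(cfg, seed=3)
        b = simulate_cohort(cfg, seed=3)
        np.testing.assert_array_equal(
            a.samples[("i1", "saliva")]["3"].baf,
            b.samples[("i1", "saliva")]["3"].baf,
        )

    def test_composite_events_share_group_id(self):
        cfg = CohortConfig(individuals=[IndividualSpec(
            id="i1", tissues=["saliva"],
            events=[
                EventSpec(chrom="1", start=30_000_000, end=39_000_000, type="cnloh",
                          fractions={"saliva": 0.4}, group="g1"),
                EventSpec(chrom="1", start=39_000_100, end=48_000_000, type="loss",
                          fractions={"saliva": 0.4}, group="g1"),
                EventSpec(chrom="1", start=48_000_100, end=57_000_000, type="cnloh",
                          fractions={"saliva": 0.4}, group="g1"),
            ],
        )], chroms=["1"])
        sim = simulate_cohort(cfg, seed=4)
        assert [t.group for t in sim.truth] == ["g1", "g1", "g1"]

    def test_overlapping_events_without_group_rejected(self):
        cfg = CohortConfig(individuals=[IndividualSpec(
            id="i1", tissues=["saliva"],
            events=[
                EventSpec(chrom="3", start=1_000_000, end=9_000_000, type="gain",
                          fractions={"saliva": 0.3}),
                EventSpec(chrom="3", start=5_000_000, end=12_000_000, type="loss",
                          fractions={"saliva": 0.3}),
            ],
        )], chroms=["3"])
        with pytest.raises(ValueError, match="composite group"):
            simulate_cohort(cfg, seed=5)

    def test_unknown_chromosome_rejected(self):
        cfg = CohortConfig(individuals=[IndividualSpec(
            id="i1", tissues=["saliva"],
            events=[EventSpec(chrom="chr99", start=1, end=100, type="gain",
                              fractions={"saliva": 0.3})],
        )])
        with pytest.raises(ValueError, match="chr99"):
            simulate_cohort(cfg, seed=6)

    def test_zero_noise_spiked_cohort_matches_expected_signal(self):
        f = 0.35
        cfg = CohortConfig(
            individuals=[IndividualSpec(
                id="i1", tissues=["saliva"],
                events=[EventSpec(chrom="3", start=4_000_000, end=11_000_000,
                                  type="cnloh", fractions={"saliva": f})],
            )],
            chroms=["3"], noise=NoiseModel(0.0, 0.0, 0.0),
        )
        sim = simulate_cohort(cfg, seed=7)
        cd = sim.samples[("i1", "saliva")]["3"]
        het = cd.slice_interval(4_000_000, 11_000_000) & (cd.gt == 1)
        np.testing.assert_allclose(np.abs(cd.baf[het] - 0.5), f / 2, atol=1e-12)
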