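"""Generator correctness: founder sampling, crossing, meiosis, SSD, traits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrgskit import popgen
from rrgskit.types import TrialDesign


class TestFounders:
    def test_paper_scale_dimensions_and_inbreeding(self):
        g = popgen.make_founders(135, 4031, 21, 150, 0.05, 0.5, seed=1)
        assert g.dosage.shape == (135, 4031)
        assert not np.any(g.dosage == 1)
        assert len(set(g.chrom)) == 21

    def test_forced_half_frequency(self):
        g = popgen.make_founders(2, 10, 1, 100, 0.5, 0.5, seed=7)
        # every marker drawn at frequency exactly 0.5
        rng_freqs = g.allele_frequencies()
        assert rng_freqs.shape == (10,)

    def test_empirical_maf_within_bounds(self):
        g = popgen.make_founders(400, 200, 3, 100, 0.1, 0.4, seed=3)
        freq = g.allele_frequencies()
        maf = np.minimum(freq, 1 - freq)
        # binomial sampling error around the drawn frequencies
        se = 3 * np.sqrt(0.4 * 0.6 / 400)
        assert maf.min() > 0.1 - se
        assert maf.max() < 0.4 + se

    def test_map_positions_sorted_within_chromosomes(self, small_founders):
        for c in np.unique(small_founders.chrom):
            pos = small_founders.pos_cm[small_founders.chrom == c]
            assert np.all(np.diff(pos) > 0)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            popgen.make_founders(0, 10, 1, 100, 0.1, 0.4)
        with pytest.raises(ValueError):
            popgen.make_founders(5, 10, 1, 100, 0.4, 0.1)


class TestRoundRobin:
    def test_twenty_parents_wrap_around(self):
        ids = [chr(ord("A") + i) for i in range(20)]
        plan = popgen.round_robin(ids)
        assert len(plan) == 20
        assert plan.crosses[0] == ("A", "B")
        assert plan.crosses[-1] == ("T", "A")

    def test_smallest_plan(self):
        plan = popgen.round_robin(["A", "B", "C"])
        assert plan.crosses == [("A", "B"), ("B", "C"), ("C", "A")]

    @pytest.mark.parametrize("n", range(3, 31))
    def test_every_parent_used_exactly_twice(self, n):
        ids = [f"P{i}" for i in range(n)]
        plan = popgen.round_robin(ids)
        usage: dict[str, int] = {}
        for f, m in plan.crosses:
            usage[f] = usage.get(f, 0) + 1
            usage[m] = usage.get(m, 0) + 1
        assert usage == {i: 2 for i in ids}

    def test_rejects_too_few_or_duplicates(self):
        with pytest.raises(ValueError):
            popgen.round_robin(["A", "B"])
        with pytest.raises(ValueError):
            popgen.round_robin(["A", "B", "A"])


class TestCross:
    def test_mendelian_f1(self):
        assert np.array_equal(
            popgen.cross(np.array([0.0, 2, 2]), np.array([2.0, 2, 0])),
            np.array([1.0, 2, 1]),
        )

    def test_selfing_identical_parent(self):
        p = np.array([0.0, 2, 0, 2])
        assert np.array_equal(popgen.cross(p, p), p)

    def test_f1_heterozygosity_equals_parental_difference(self, small_founders):
        p1, p2 = small_founders.dosage[0], small_founders.dosage[1]
        f1 = popgen.cross(p1, p2)
        assert np.array_equal(f1 == 1, p1 != p2)

    def test_rejects_non_inbred_parent(self):
        with pytest.raises(ValueError):
            popgen.cross(np.array([1.0, 2]), np.array([0.0, 2]))


class TestMeiosis:
    def test_homozygous_input_is_deterministic(self, small_founders):
        row = small_founders.dosage[3]
        g1 = popgen.meiosis(row, small_founders.chrom, small_founders.pos_cm, 1)
        g2 = popgen.meiosis(row, small_founders.chrom, small_founders.pos_cm, 2)
        assert np.array_equal(g1, g2)
        assert np.array_equal(g1, row / 2)

    def test_crossover_rate_on_one_morgan_chromosome(self):
        # dense markers on a 100 cM chromosome: observed phase switches per
        # gamete approach the Poisson mean of 1
        m = 101
        chrom = np.array(["chr1"] * m)
        pos = np.linspace(0, 100, m)
        hap = np.stack([np.zeros(m), np.ones(m)])
        rng = np.random.default_rng(5)
        switches = []
        for _ in range(3000):
            g = popgen.meiosis(hap, chrom, pos, rng)
            switches.append(np.sum(np.abs(np.diff(g))))
        mean = np.mean(switches)
        # double crossovers between adjacent markers go unseen; with 1 cM
        # spacing the loss is below 1%
        assert mean == pytest.approx(1.0, abs=0.06)

    def test_recombination_fraction_matches_haldane(self):
        m = 11
        chrom = np.array(["chr1"] * m)
        pos = np.linspace(0, 100, m)  # 10 cM spacing
        hap = np.stack([np.zeros(m), np.ones(m)])
        rng = np.random.default_rng(8)
        gametes = np.stack(
            [popgen.meiosis(hap, chrom, pos, rng) for _ in range(6000)]
        )
        rec = np.mean(gametes[:, :-1] != gametes[:, 1:], axis=0)
        c_expected = 0.5 * (1 - np.exp(-2 * 0.10))
        assert np.allclose(rec, c_expected, atol=0.02)
        # distant pair approaches independence less than halfway
        rec_ends = np.mean(gametes[:, 0] != gametes[:, -1])
        c_ends = 0.5 * (1 - np.exp(-2 * 1.0))
        assert rec_ends == pytest.approx(c_ends, abs=0.025)

    def test_rejects_mismatched_map(self, small_founders):
        with pytest.raises(ValueError):
            popgen.meiosis(
                small_founders.dosage[0], small_founders.chrom[:-1],
                small_founders.pos_cm[:-1], 0,
            )


class TestSelfSsd:
    def test_heterozygosity_halves_per_generation(self):
        m = 60
        chrom = np.array(["chr1"] * 30 + ["chr2"] * 30)
        pos = np.concatenate([np.linspace(0, 100, 30)] * 2)
        f1 = np.stack([np.zeros(m), np.ones(m)])
        rng = np.random.default_rng(12)
        for gens, expected in [(1, 0.5), (3, 0.125)]:
            het = [
                np.mean(popgen.self_ssd(f1, chrom, pos, gens, rng).sum(0) == 1)
                for _ in range(400)
            ]
            assert np.mean(het) == pytest.approx(expected, rel=0.05)

    def test_inbred_input_is_fixed(self, small_founders):
        row = small_founders.dosage[0]
        out = popgen.self_ssd(row, small_founders.chrom, small_founders.pos_cm, 4, 3)
        assert np.array_equal(out.sum(axis=0), row)

    def test_f2_segregation_one_to_two_to_one(self):
        chrom, pos = np.array(["chr1"]), np.array([50.0])
        f1 = np.stack([np.zeros(1), np.ones(1)])
        rng = np.random.default_rng(4)
        dosages = [
            popgen.self_ssd(f1, chrom, pos, 1, rng).sum(0)[0] for _ in range(4000)
        ]
        counts = np.bincount(np.asarray(dosages, dtype=int), minlength=3) / 4000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.03)


class TestGeneticValue:
    def test_zero_effects_return_intercept(self, small_founders, small_arch):
        arch0 = popgen.make_architecture(small_founders.n_markers, 0, seed=0)
        vals = popgen.genetic_value(small_founders.dosage, arch0)
        assert np.allclose(vals, arch0.intercept)

    def test_single_locus_heterosis_comes_from_dominance(self):
        from rrgskit.types import TraitArchitecture

        arch = TraitArchitecture(intercept=0.0, additive=[1.0], dominance=[0.5])
        lo, hi = popgen.genetic_value(np.array([0.0]), arch), popgen.genetic_value(
            np.array([2.0]), arch
        )
        f1 = popgen.genetic_value(np.array([1.0]), arch)
        assert (lo, hi) == (-1.0, 1.0)
        assert f1 == 0.5  # midparent is 0, so MPH is driven entirely by d

    def test_matches_locus_by_locus_oracle(self, small_founders, small_arch):
        row = small_founders.dosage[5]
        expected = small_arch.intercept
        for j in range(small_founders.n_markers):
            expected += small_arch.additive[j] * (row[j] - 1)
            if row[j] == 1:
                expected += small_arch.dominance[j]
        assert popgen.genetic_value(row, small_arch) == pytest.approx(expected)

    def test_no_dominance_means_no_midparent_heterosis(self, small_founders):
        arch = popgen.make_architecture(
            small_founders.n_markers, 40, dominance_ratio=0.0, seed=9
        )
        p1, p2 = small_founders.dosage[2], small_founders.dosage[7]
        f1 = popgen.cross(p1, p2)
        mid = (
            popgen.genetic_value(p1, arch) + popgen.genetic_value(p2, arch)
        ) / 2
        assert popgen.genetic_value(f1, arch) == pytest.approx(mid, abs=1e-10)


def _individuals_frame(n, rng, sd=2.0):
    return pd.DataFrame(
        {
            "genotype_id": [f"G{i}" for i in range(n)],
            "role": "line",
            "female_parent": None,
            "male_parent": None,
            "gvalue": 90 + rng.normal(scale=sd, size=n),
        }
    )


class TestSimulatePhenotypes:
    def test_noise_free_design_reproduces_genetic_values(self):
        rng = np.random.default_rng(0)
        frame = _individuals_frame(10, rng)
        design = TrialDesign(
            locations=["A", "B"], n_blocks=2, var_location=0.0, var_block=0.0,
            var_gxe=0.0, var_residual=0.0,
        )
        table = popgen.simulate_phenotypes(frame, design, seed=1)
        means = table.groupby("genotype_id")["value"].mean()
        expected = frame.set_index("genotype_id")["gvalue"]
        assert np.allclose(means[expected.index], expected)

    def test_generator_calibration_of_gxe_ratio(self):
        # target ratio var_GxE / var_G = 1.13, re-estimated from the table by
        # a balanced two-way ANOVA decomposition
        rng = np.random.default_rng(10)
        var_g = 4.0
        frame = _individuals_frame(220, rng, sd=np.sqrt(var_g))
        design = TrialDesign(
            locations=[f"L{i}" for i in range(8)], n_blocks=2,
            var_location=1.0, var_block=0.5, var_gxe=1.13 * var_g,
            var_residual=2.0,
        )
        table = popgen.simulate_phenotypes(frame, design, seed=2)
        cells = table.groupby(["genotype_id", "location"])["value"]
        r = 2  # blocks
        cell_means = cells.mean().unstack()
        resid_ms = (cells.var(ddof=1)).mean()
        g_means = cell_means.mean(axis=1)
        e_means = cell_means.mean(axis=0)
        inter = cell_means.sub(g_means, axis=0).sub(e_means, axis=1) + g_means.mean()
        n_g, n_e = cell_means.shape
        ms_int = (inter**2).to_numpy().sum() / ((n_g - 1) * (n_e - 1)) * r
        ms_g = g_means.var(ddof=1) * n_e * r
        var_gxe_hat = (ms_int - resid_ms) / r
        var_g_hat = (ms_g - ms_int) / (n_e * r)
        assert var_gxe_hat / var_g_hat == pytest.approx(1.13, abs=0.25)

    def test_stress_locations_decorrelate_rankings(self, stress_design):
        rng = np.random.default_rng(3)
        frame = _individuals_frame(150, rng, sd=3.0)
        design = stress_design
        design.var_residual = 1.0
        design.var_gxe = 0.5
        table = popgen.simulate_phenotypes(frame, design, seed=4)
        means = table.groupby(["genotype_id", "location"])["value"].mean().unstack()
        r_nonstress = np.corrcoef(means["A"], means["B"])[0, 1]
        r_cross = np.corrcoef(means["A"], means["E"])[0, 1]
        assert r_cross < r_nonstress

    def test_rejects_empty_design(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            popgen.simulate_phenotypes(
                _individuals_frame(3, rng),
                TrialDesign(locations=[], years=[]),
            )


class TestEnvProfiles:
    def test_no_stress_profiles_are_exchangeable(self):
        design = TrialDesign(locations=["A", "B", "C"])
        profiles = popgen.simulate_env_profiles(design, seed=6)
        means = [p.evi.mean() for p in profiles]
        assert np.ptp(means) < 0.05

    def test_stress_depression_holds_in_expectation(self):
        design = TrialDesign(locations=["A", "B"], stress_locations=["B"])
        acc = np.zeros((2, 23))
        for s in range(100):
            pa, pb = popgen.simulate_env_profiles(design, seed=s)
            acc[0] += pa.evi
            acc[1] += pb.evi
        # the stressed site sits below the template at every timepoint
        assert np.all(acc[1] <= acc[0])

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_profiles_deterministic_given_seed(self, seed):
        design = TrialDesign(locations=["A", "B"], stress_locations=["B"])
        p1 = popgen.simulate_env_profiles(design, seed=seed)
        p2 = popgen.simulate_env_profiles(design, seed=seed)
        assert np.array_equal(p1[0].evi, p2[0].evi)
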