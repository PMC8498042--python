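"""Environment diagnostics: distances, clustering, PCA, Mantel, VCI."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from rrgskit import gxe, pheno, popgen
from rrgskit.types import EnvironmentProfile, TrialDesign


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"E{i}" for i in range(values.shape[0])]
    return gxe.DistanceMatrix(ids=ids, values=values)


class TestDistances:
    def test_identical_columns_have_zero_distance(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [0.0, 0, 0]})
        d = gxe.euclidean_distances(m)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_hand_example_three_four_five(self):
        m = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        assert gxe.euclidean_distances(m).values[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        d = gxe.euclidean_distances(m)
        for i, ci in enumerate(m.columns):
            for j, cj in enumerate(m.columns):
                expected = np.sqrt(((m[ci] - m[cj]) ** 2).sum())
                assert d.values[i, j] == pytest.approx(expected)

    def test_triangle_inequality_and_symmetry(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(6, 5)))
        d = gxe.euclidean_distances(m).values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_missing_cells_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            gxe.euclidean_distances(m)


class TestCompleteLinkage:
    def test_three_point_merge_order(self):
        # distances 1 (A,B), 2 (A,C), 3 (B,C): the pair at height 1 merges
        # first, the final merge is at the maximum 3
        d = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ids=["A", "B", "C"])
        Z, flat = gxe.complete_linkage(d, n_clusters=2)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(3.0)
        assert flat["A"] == flat["B"] != flat["C"]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(5, 7)))
        Z, _ = gxe.complete_linkage(gxe.euclidean_distances(m))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(5)
        left = rng.normal(size=(10, 4)) * 0.1
        right = rng.normal(size=(10, 3)) * 0.1 + 8.0
        m = pd.DataFrame(np.hstack([left, right]))
        d = gxe.euclidean_distances(m)
        _, flat = gxe.complete_linkage(d, n_clusters=2)
        labels = [flat[i] for i in d.ids]
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_newick_export_contains_all_leaves(self):
        d = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ids=["A", "B", "C"])
        Z, _ = gxe.complete_linkage(d)
        nwk = gxe.linkage_to_newick(Z, d.ids)
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self):
        u = np.array([1.0, 2, 3, 4])
        v = np.array([1.0, -1, 2])
        m = pd.DataFrame(np.outer(u, v))
        res = gxe.pca(m, center=True)
        assert res.explained[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(8, 5)))
        res = gxe.pca(m)
        assert res.explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(6, 3)))
        res = gxe.pca(m, center=True)
        cov = np.cov(m.to_numpy().T, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.explained, eig / eig.sum(), atol=1e-10)

    def test_projection_reproduces_reference_scores(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(7, 4)), columns=list("wxyz"))
        res = gxe.pca(m)
        proj = gxe.project_onto(res, m)
        assert np.allclose(proj.to_numpy(), res.scores.to_numpy(), atol=1e-10)

    def test_reference_mean_projects_to_origin(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(7, 4)), columns=list("wxyz"))
        res = gxe.pca(m)
        mean_row = pd.DataFrame([m.mean()], columns=m.columns)
        proj = gxe.project_onto(res, mean_row)
        assert np.allclose(proj.to_numpy(), 0.0, atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            gxe.pca(pd.DataFrame(np.ones((4, 3))))


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(5, 6)))
        d = gxe.euclidean_distances(m)
        r, p = gxe.mantel(d, d, n_permutations=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200, abs=0.02)

    def test_exhaustive_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(11)
        a = pd.DataFrame(rng.normal(size=(3, 4)))
        b = pd.DataFrame(rng.normal(size=(3, 4)))
        d1 = gxe.euclidean_distances(a)
        d2 = gxe.euclidean_distances(b)
        r, p = gxe.mantel(d1, d2, exhaustive=True)
        # independent brute force over all 24 orderings
        iu = np.triu_indices(4, k=1)
        robs = np.corrcoef(d1.values[iu], d2.values[iu])[0, 1]
        count = 0
        for perm in permutations(range(4)):
            pm = np.asarray(perm)
            rp = np.corrcoef(d1.values[iu], d2.values[np.ix_(pm, pm)][iu])[0, 1]
            count += rp >= robs - 1e-12
        assert r == pytest.approx(robs)
        assert p == pytest.approx(count / 24)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(12)
        pvals = []
        for rep in range(200):
            a = pd.DataFrame(rng.normal(size=(6, 5)))
            b = pd.DataFrame(rng.normal(size=(6, 5)))
            _, p = gxe.mantel(
                gxe.euclidean_distances(a), gxe.euclidean_distances(b),
                n_permutations=99, seed=rep,
            )
            pvals.append(p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_agrees_with_skbio_reference(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(13)
        a = pd.DataFrame(rng.normal(size=(6, 5)))
        b = pd.DataFrame(rng.normal(size=(6, 5)))
        d1 = gxe.euclidean_distances(a)
        d2 = gxe.euclidean_distances(b)
        r, _ = gxe.mantel(d1, d2, n_permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(d1.values, ids=d1.ids), SkbioDM(d2.values, ids=d2.ids),
            permutations=0,
        )
        assert r == pytest.approx(float(r_ref), abs=1e-10)

    def test_mismatched_ids_rejected(self):
        d1 = _dm(np.zeros((3, 3)), ids=["a", "b", "c"])
        d2 = _dm(np.zeros((3, 3)), ids=["a", "b", "z"])
        with pytest.raises(ValueError):
            gxe.mantel(d1, d2)


class TestVci:
    def test_endpoint_and_midpoint_values(self):
        prof = EnvironmentProfile(
            location_id="X", dates=np.arange(3.0),
            evi=np.array([0.2, 0.5, 0.8]), evi_min=0.2, evi_max=0.8,
        )
        assert np.allclose(gxe.vci(prof), [0.0, 0.5, 1.0])

    def test_clamped_outside_reference_range(self):
        prof = EnvironmentProfile(
            location_id="X", dates=np.arange(2.0),
            evi=np.array([0.1, 0.9]), evi_min=0.2, evi_max=0.8,
        )
        assert np.allclose(gxe.vci(prof), [0.0, 1.0])

    def test_degenerate_reference_range_rejected(self):
        prof = EnvironmentProfile(
            location_id="X", dates=np.arange(2.0),
            evi=np.array([0.5, 0.5]), evi_min=0.5, evi_max=0.5,
        )
        with pytest.raises(ValueError):
            gxe.vci(prof)


class TestProfileDistances:
    def test_identical_profiles_distance_zero(self):
        t = np.arange(10.0)
        evi = 0.3 + 0.02 * t
        mk = lambda loc: EnvironmentProfile(loc, t, evi.copy(), 0.1, 0.8)
        d = gxe.profile_distances([mk("A"), mk("B")])
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_stress_profiles_separate_from_controls(self):
        design = TrialDesign(
            locations=["A", "B", "C", "D"], stress_locations=["C", "D"]
        )
        profiles = popgen.simulate_env_profiles(design, seed=3)
        d = gxe.profile_distances(profiles, on="vci")
        within = [d.values[0, 1], d.values[2, 3]]
        between = [d.values[0, 2], d.values[0, 3], d.values[1, 2], d.values[1, 3]]
        assert min(between) > max(within)
        _, flat = gxe.complete_linkage(d, n_clusters=2)
        assert flat["A"] == flat["B"] != flat["C"]
        assert flat["C"] == flat["D"]


class TestInteractionEffects:
    def test_zero_interaction_variance_gives_near_zero_effects(self):
        rng = np.random.default_rng(14)
        rows = []
        for loc in ["L1", "L2", "L3"]:
            for b in (1, 2):
                for f in ["F1", "F2", "F3", "F4"]:
                    for m in ["M1", "M2"]:
                        rows.append(
                            dict(genotype_id=f"H{f}{m}", role="hybrid",
                                 female_parent=f, male_parent=m, location=loc,
                                 year=2019, block=b,
                                 value=90 + rng.normal(scale=0.5))
                        )
                for lid in ["P1", "P2", "P3"]:
                    rows.append(
                        dict(genotype_id=lid, role="line", female_parent=None,
                             male_parent=None, location=loc, year=2019,
                             block=b, value=88 + rng.normal(scale=0.5))
                    )
        table = pd.DataFrame(rows)
        _, fit = pheno.fit_variance_components(table)
        mat = gxe.interaction_effects(fit)
        assert mat.shape == (4, 3)
        assert np.abs(mat.to_numpy()).max() < 0.3

    def test_duplicate_environments_have_similar_columns(self, stress_design):
        rng = np.random.default_rng(15)
        females = [f"F{i}" for i in range(10)]
        males = ["M1", "M2"]
        gca = dict(zip(females, rng.normal(scale=2.0, size=10)))
        gxe_eff = {f: rng.normal(scale=1.5) for f in females}
        rows = []
        for loc in ["L1", "L2", "L3"]:
            for b in (1, 2):
                for f in females:
                    for m in males:
                        # L1 and L2 share the same interaction pattern; L3 flips it
                        ieff = gxe_eff[f] if loc in ("L1", "L2") else -gxe_eff[f]
                        rows.append(
                            dict(genotype_id=f"H{f}{m}", role="hybrid",
                                 female_parent=f, male_parent=m, location=loc,
                                 year=2019, block=b,
                                 value=90 + gca[f] + ieff
                                 + rng.normal(scale=0.5))
                        )
                for lid in ["P1", "P2"]:
                    rows.append(
                        dict(genotype_id=lid, role="line", female_parent=None,
                             male_parent=None, location=loc, year=2019,
                             block=b, value=88 + rng.normal(scale=0.5))
                    )
        table = pd.DataFrame(rows)
        _, fit = pheno.fit_variance_components(table)
        mat = gxe.interaction_effects(fit)
        d = gxe.euclidean_distances(mat)
        ids = d.ids
        i1, i2, i3 = (ids.index(f"L{k}_2019") for k in (1, 2, 3))
        assert d.values[i1, i2] < d.values[i1, i3]
        assert d.values[i1, i2] < d.values[i2, i3]

    def test_missing_term_rejected(self):
        from rrgskit.lmm import MixedModelFit

        fit = MixedModelFit(
            beta=np.zeros(1), fixed_names=["mu"], varcomp={"residual": 1.0},
            blups={}, level_names={}, fitted=np.zeros(2),
            residuals=np.zeros(2), converged=True, n_iter=1,
        )
        with pytest.raises(KeyError):
            gxe.interaction_effects(fit)
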