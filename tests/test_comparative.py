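from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.decomposition import PCA as SkPCA

from phytofp.comparative import (
    AbundanceMatrix,
    ProfileCompound,
    SpeciesProfile,
    build_abundance_matrix,
    dedupe_profile,
    distribution_table,
    hca,
    heatmap_matrix,
    normalize_compound_name,
    pca,
    venn_regions,
)
from phytofp.feature_io import FeatureRecord
from phytofp.np_classifier import ClassPrediction
from phytofp.synthetic import GeneratorSpec, generate_species_profiles


def record(name, mode="positive", area=1e6, rep="R1", species="S"):
    return FeatureRecord(
        compound_name=name, formula=None, ion_mode=mode,
        precursor_mz=301.0, calc_mw=300.0, rt=10.0, peak_area=area,
        db_hits=frozenset({"mzCloud"}), has_ms2=True, msi_level=2,
        species=species, replicate_id=rep,
    )


def profile(species, names, superclasses=None, areas=None):
    compounds = []
    for i, name in enumerate(names):
        pred = None
        if superclasses:
            pred = ClassPrediction(name, {"superclass": superclasses[i]},
                                   {"superclass": 1.0}, True)
        compounds.append(ProfileCompound(
            name=name, prediction=pred,
            areas=areas[i] if areas else {"R1": 1e6},
        ))
    return SpeciesProfile(species=species, compounds=compounds)


class TestDedupe:
    def test_both_modes_keeps_higher_area(self):
        recs = [record("Emodin", "positive", 5e6), record("Emodin", "negative", 8e6)]
        prof = dedupe_profile(recs, species="S")
        assert len(prof.compounds) == 1
        assert prof.compounds[0].areas == {"R1": 8e6}

    def test_unique_names_pass_through(self):
        recs = [record(f"c{i}") for i in range(7)]
        assert len(dedupe_profile(recs, "S").compounds) == 7

    def test_matches_brute_force_groupby(self, rng):
        names = [f"c{rng.integers(10)}" for _ in range(60)]
        reps = [f"R{rng.integers(1, 4)}" for _ in range(60)]
        areas = rng.uniform(1e5, 1e7, 60)
        recs = [record(n, area=a, rep=r) for n, a, r in zip(names, areas, reps)]
        prof = dedupe_profile(recs, "S")
        assert {c.name for c in prof.compounds} == set(names)
        for c in prof.compounds:
            for rep_id, area in c.areas.items():
                expected = max(a for n, a, r in zip(names, areas, reps)
                               if n == c.name and r == rep_id)
                assert area == expected

    def test_name_normalization_folds_case_and_punct(self):
        assert normalize_compound_name("Aloin-A") == normalize_compound_name("aloin a")


class TestVenn:
    def test_identical_sets_all_in_center(self):
        names = [f"c{i}" for i in range(9)]
        profiles = [profile(sp, names) for sp in "ABCD"]
        v = venn_regions(profiles)
        assert v.count("A", "B", "C", "D") == 9
        assert v.union_size == 9
        assert all(c == 0 for reg, c in v.region_counts.items() if len(reg) < 4)

    def test_disjoint_sets_only_singletons(self):
        profiles = [profile(sp, [f"{sp}{i}" for i in range(3)]) for sp in "ABCD"]
        v = venn_regions(profiles)
        for sp in "ABCD":
            assert v.count(sp) == 3
        assert v.union_size == 12

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError):
            venn_regions([profile("A", ["x"]), profile("A", ["y"])])

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_membership_pattern_enumeration(self, data):
        """Region counts equal brute-force 2^4 pattern enumeration."""
        universe = [f"m{i}" for i in range(50)]
        sets = {}
        for sp in "ABCD":
            sets[sp] = set(data.draw(st.lists(
                st.sampled_from(universe), max_size=50, unique=True)))
        profiles = [profile(sp, sorted(sets[sp])) for sp in "ABCD"]
        if not any(sets.values()):
            return
        v = venn_regions(profiles)
        union = set().union(*sets.values())
        for r in range(1, 5):
            for combo in combinations("ABCD", r):
                inside = set.intersection(*(sets[s] for s in combo)) if combo else set()
                outside = set.union(*(sets[s] for s in "ABCD" if s not in combo), set())
                expected = len(inside - outside)
                assert v.count(*combo) == expected
        assert v.union_size == len(union)

    def test_planted_design_recovered_exactly(self):
        profiles, ledger = generate_species_profiles(GeneratorSpec(seed=31))
        v = venn_regions(profiles)
        assert v.region_counts == ledger.expected_region_counts() | {
            reg: 0 for reg in v.region_counts if reg not in
            ledger.expected_region_counts()
        }
        assert v.count("Cascara", "Frangula", "Rhubarb", "Senna") == 4
        assert v.shared_by("Cascara", "Frangula") == 21
        assert v.count("Cascara", "Frangula") == 10
        assert v.shared_by("Rhubarb", "Senna") == 13
        assert v.count("Rhubarb", "Senna") == 5


class TestDistribution:
    def test_single_superclass_row_is_100_percent(self):
        prof = profile("A", ["x", "y"], superclasses=["Flavonoids"] * 2)
        table = distribution_table([prof])
        assert table.loc["Flavonoids", "A"] == 2
        assert table.loc["Flavonoids", "A %"] == 100.0

    def test_empty_profile_gives_zero_column(self):
        a = profile("A", ["x"], superclasses=["Flavonoids"])
        b = profile("B", [])
        table = distribution_table([a, b])
        assert table["B"].sum() == 0

    def test_column_sums_equal_profile_sizes(self, rng):
        scs = ["Flavonoids", "Stilbenoids", "Coumarins"]
        profiles = []
        for sp in "AB":
            names = [f"{sp}{i}" for i in range(int(rng.integers(3, 12)))]
            labels = [scs[rng.integers(3)] for _ in names]
            profiles.append(profile(sp, names, superclasses=labels))
        table = distribution_table(profiles)
        for p in profiles:
            assert table[p.species].sum() == len(p.compounds)


class TestAbundanceMatrix:
    def test_four_species_three_replicates_is_twelve_columns(self):
        profiles, _ = generate_species_profiles(GeneratorSpec(seed=33))
        m = build_abundance_matrix(profiles)
        assert len(m.samples) == 12
        assert m.values.shape[0] == 253

    def test_single_species_single_replicate_column_vector(self):
        prof = profile("A", ["x", "y"])
        m = build_abundance_matrix([prof])
        assert m.values.shape == (2, 1)

    def test_matches_planted_matrix(self):
        profiles, ledger = generate_species_profiles(GeneratorSpec(seed=34))
        m = build_abundance_matrix(profiles)
        planted = ledger.planted_abundance
        assert list(planted.columns) == m.samples
        assert np.allclose(m.values, planted.loc[m.compounds].values)


class TestPca:
    def test_rank_one_matrix_gives_pc1_100(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.outer(np.array([1.0, 2.0, 5.0]), base)
        m = AbundanceMatrix(values, ["a", "b", "c"], list("wxyz"), ["s"] * 4)
        result = pca(m, scaling="none")
        assert result.explained_variance_pct[0] == pytest.approx(100.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        """Explained variances equal covariance eigenvalue shares to 1e-8."""
        for _ in range(5):
            values = rng.uniform(1.0, 10.0, size=(6, 8))
            m = AbundanceMatrix(values, [f"c{i}" for i in range(6)],
                                [f"s{j}" for j in range(8)], ["sp"] * 8)
            result = pca(m, scaling="autoscale")
            scaled = (values - values.mean(1, keepdims=True)) / values.std(
                1, ddof=1, keepdims=True)
            x = scaled.T - scaled.T.mean(0)
            eig = np.linalg.eigvalsh(np.cov(x.T))[::-1]
            expected = 100.0 * eig / eig.sum()
            n = len(result.explained_variance_pct)
            assert np.allclose(result.explained_variance_pct, expected[:n],
                               atol=1e-8)

    def test_agrees_with_sklearn(self, rng):
        values = rng.uniform(0.0, 5.0, size=(10, 7))
        m = AbundanceMatrix(values, [f"c{i}" for i in range(10)],
                            [f"s{j}" for j in range(7)], ["sp"] * 7)
        result = pca(m, scaling="none")
        sk = SkPCA().fit(values.T)
        n = len(result.explained_variance_pct)
        assert np.allclose(result.explained_variance_pct,
                           100.0 * sk.explained_variance_ratio_[:n], atol=1e-8)

    def test_duplicated_samples_coincide_in_score_space(self, rng):
        values = rng.uniform(1.0, 5.0, size=(5, 3))
        dup = np.c_[values, values[:, 0]]
        m = AbundanceMatrix(dup, [f"c{i}" for i in range(5)],
                            list("wxyz"), ["sp"] * 4)
        result = pca(m, scaling="none")
        assert np.allclose(result.scores[0], result.scores[3], atol=1e-9)

    def test_fewer_than_two_samples_rejected(self):
        m = AbundanceMatrix(np.ones((3, 1)), list("abc"), ["s"], ["sp"])
        with pytest.raises(ValueError):
            pca(m)

    def test_constant_rows_dropped_and_reported(self):
        values = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        m = AbundanceMatrix(values, ["const", "a", "b"], list("xyz"), ["sp"] * 3)
        result = pca(m, scaling="autoscale")
        assert result.dropped_constant_rows == ["const"]


def brute_force_average_linkage(x):
    """Naive agglomeration: merge the closest pair under average linkage."""
    clusters = {i: [i] for i in range(len(x))}
    next_id = len(x)
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = np.mean([np.linalg.norm(x[i] - x[j])
                         for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHca:
    def test_identical_samples_merge_at_zero(self):
        values = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 6.0]])
        m = AbundanceMatrix(values, ["a", "b"], ["s1", "s2", "s3"], ["sp"] * 3)
        result = hca(m)
        assert result.merges[0][2] == pytest.approx(0.0)
        assert {result.merges[0][0], result.merges[0][1]} == {0, 1}

    def test_outlier_merges_last(self):
        values = np.array([[0.0, 0.1, 100.0], [0.0, 0.1, 100.0]])
        m = AbundanceMatrix(values, ["a", "b"], ["s1", "s2", "out"], ["sp"] * 3)
        result = hca(m)
        assert result.merges[-1][2] > result.merges[0][2]
        assert 2 in result.merges[-1][:2] or result.merges[-1][0] >= 3

    def test_matches_brute_force_agglomeration(self, rng):
        """Merge heights equal a naive average-linkage implementation."""
        for _ in range(5):
            values = rng.uniform(0.0, 10.0, size=(4, 6))
            m = AbundanceMatrix(values, [f"c{i}" for i in range(4)],
                                [f"s{j}" for j in range(6)], ["sp"] * 6)
            result = hca(m, linkage="average")
            expected = brute_force_average_linkage(values.T)
            got_heights = sorted(h for _, _, h in result.merges)
            exp_heights = sorted(h for _, _, h in expected)
            assert np.allclose(got_heights, exp_heights, atol=1e-9)

    def test_average_linkage_heights_nondecreasing(self, rng):
        values = rng.uniform(0.0, 10.0, size=(5, 8))
        m = AbundanceMatrix(values, [f"c{i}" for i in range(5)],
                            [f"s{j}" for j in range(8)], ["sp"] * 8)
        heights = [h for _, _, h in hca(m).merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_nan_cells_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            m = AbundanceMatrix(np.nan_to_num(values), ["a", "b"],
                                ["s1", "s2"], ["sp"] * 2)
            m.values[0, 1] = np.nan
            hca(m)


class TestHeatmap:
    def test_counts_bounded_by_profile_totals(self):
        profiles, ledger = generate_species_profiles(GeneratorSpec(seed=35))
        labels = ledger.molecule_labels
        for p in profiles:
            for c in p.compounds:
                c.prediction = ClassPrediction(
                    c.name, {"superclass": labels[c.name]["superclass"]},
                    {"superclass": 1.0}, True)
        heat, row_order, col_order = heatmap_matrix(profiles)
        for p in profiles:
            for rid in p.replicate_ids:
                assert heat[f"{p.species}:{rid}"].sum() <= len(p.compounds)
        assert sorted(row_order) == list(range(heat.shape[0]))
        assert sorted(col_order) == list(range(heat.shape[1]))

    def test_single_superclass_single_row(self):
        prof = profile("A", ["x", "y"], superclasses=["Flavonoids"] * 2)
        heat, _, _ = heatmap_matrix([prof])
        assert heat.shape[0] == 1
        assert heat.iloc[0, 0] == 2

    def test_counts_match_planted_membership(self):
        profiles, ledger = generate_species_profiles(GeneratorSpec(seed=36))
        labels = ledger.molecule_labels
        for p in profiles:
            for c in p.compounds:
                c.prediction = ClassPrediction(
                    c.name, {"superclass": labels[c.name]["superclass"]},
                    {"superclass": 1.0}, True)
        heat, _, _ = heatmap_matrix(profiles)
        membership = ledger.membership
        for p in profiles:
            present = membership.index[membership[p.species]]
            by_sc = {}
            for name in present:
                sc = labels[name]["superclass"]
                by_sc[sc] = by_sc.get(sc, 0) + 1
            for sc, count in by_sc.items():
                for rid in p.replicate_ids:
                    assert heat.loc[sc, f"{p.species}:{rid}"] == count
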