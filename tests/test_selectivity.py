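import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from culturocall import culturability as cb, selectivity as sel
from culturocall.io import AbundanceTable, ValidationError

from conftest import make_metadata, make_table

META = make_metadata(
    [
        ("I1", "inoculum", "1", "caecum", "inoculum"),
        ("S1", "culture", "1", "BHI", "non_supplemented"),
        ("S2", "culture", "1", "BHI+glucose", "carbohydrate"),
    ]
)

TAX = pd.DataFrame(
    {
        "phylum": ["Firmicutes", "Firmicutes", "Bacteroidetes"],
        "class": ["Clostridia", "Clostridia", None],
        "order": ["Clostridiales", "Clostridiales", None],
        "family": ["Lachnospiraceae", "Ruminococcaceae", None],
        "genus": [None, None, None],
    },
    index=["OTU1", "OTU2", "OTU3"],
)


def _ra(counts, samples=("I1", "S1", "S2"), otus=None):
    table = AbundanceTable(make_table(counts, otus=otus, samples=list(samples)))
    return cb.relative_abundance(table)


class TestFamilyAbundance:
    def test_single_family_owns_everything(self):
        ra = _ra([[30, 40, 50], [70, 60, 50]])
        tax = TAX.loc[["OTU1", "OTU2"]].copy()
        tax["family"] = "Lachnospiraceae"
        matrix = sel.family_abundance(ra, tax, META)
        assert np.allclose(matrix.loc["Lachnospiraceae"], 1.0)

    def test_split_by_counts(self):
        ra = _ra([[10, 30, 30], [10, 70, 70]])
        matrix = sel.family_abundance(ra, TAX.loc[["OTU1", "OTU2"]], META)
        assert matrix.loc["Lachnospiraceae", "BHI"] == pytest.approx(0.3)
        assert matrix.loc["Ruminococcaceae", "BHI"] == pytest.approx(0.7)

    def test_unassigned_binned_by_deepest_rank(self):
        ra = _ra([[1, 1, 1], [1, 1, 1], [1, 1, 1]], otus=["OTU1", "OTU2", "OTU3"])
        matrix = sel.family_abundance(ra, TAX, META)
        assert "unassigned_Bacteroidetes" in matrix.index

    def test_matches_brute_force_sum(self, small_dataset):
        ds = small_dataset
        ra = cb.relative_abundance(ds.table)
        matrix = sel.family_abundance(ra, ds.community.taxonomy, ds.metadata)
        cultures = [s for s in ds.metadata.index if ds.metadata.loc[s, "role"] == "culture"]
        rng = np.random.default_rng(1)
        for s in rng.choice(cultures, size=5, replace=False):
            cond = ds.metadata.loc[s, "condition"]
            for family in matrix.index:
                total = 0.0
                for otu in ra.index:
                    if sel.family_of(ds.community.taxonomy, otu) == family:
                        total += ra.loc[otu, s]
                assert matrix.loc[family, cond] == pytest.approx(total)

    def test_column_mass_bounded_by_one(self, small_dataset):
        ds = small_dataset
        ra = cb.relative_abundance(ds.table)
        matrix = sel.family_abundance(ra, ds.community.taxonomy, ds.metadata)
        assert ((matrix >= 0) & (matrix <= 1)).all().all()
        assert (matrix.sum(axis=0) <= 1 + 1e-9).all()


class TestRankConditions:
    def test_absent_family_all_zero_lexicographic(self):
        matrix = pd.DataFrame(
            [[0.0, 0.0, 0.0]], index=["Lachnospiraceae"], columns=["c", "a", "b"]
        )
        top = sel.rank_conditions(matrix, "Lachnospiraceae", 3)
        assert list(top["condition"]) == ["a", "b", "c"]
        assert (top["abundance"] == 0).all()

    def test_k_exceeding_conditions_returns_all(self):
        matrix = pd.DataFrame([[0.4, 0.6]], index=["F"], columns=["a", "b"])
        top = sel.rank_conditions(matrix, "F", 10)
        assert list(top["condition"]) == ["b", "a"]

    def test_unknown_family_error_lists_available(self):
        matrix = pd.DataFrame([[0.4]], index=["F"], columns=["a"])
        with pytest.raises(KeyError, match="F"):
            sel.rank_conditions(matrix, "Nope", 1)

    def test_planted_multiplier_dominates_top_conditions(self):
        """10x antibiotic multiplier for one family: antibiotic conditions
        occupy the majority of its top-5 in most replicates."""
        from culturocall.synthetic import SimulationConfig, generate_community, simulate_cultures

        hits = trials = 0
        for rep in range(20):
            cfg = SimulationConfig(
                n_species=40, n_inocula=2, n_conditions=60, depth=100_000,
                frac_unculturable=0.0, n_unculturable_clades=0, clade_sizes=(),
                selectivity_multipliers={"Bacteroidaceae": {"antibiotic": 10.0}},
                seed=500 + rep,
            )
            community = generate_community(cfg)
            table, metadata = simulate_cultures(community, cfg)
            n_anti = (metadata["category"] == "antibiotic").sum()
            if n_anti < 3:
                continue
            trials += 1
            ra = cb.relative_abundance(table)
            matrix = sel.family_abundance(ra, community.taxonomy, metadata)
            top = sel.rank_conditions(matrix, "Bacteroidaceae", 5)
            cat_of = metadata.set_index("condition")["category"]
            n_top_anti = sum(cat_of[c] == "antibiotic" for c in top["condition"])
            hits += n_top_anti >= min(3, n_anti)
        assert trials >= 10
        assert hits >= 0.8 * trials


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        ra = _ra([[10, 10, 10], [90, 90, 90]])
        d = sel.bray_curtis(ra)
        assert np.allclose(d, 0.0)

    def test_disjoint_supports_one(self):
        ra = _ra([[100, 0], [0, 100]], samples=("A", "B"))
        assert sel.bray_curtis(ra).loc["A", "B"] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        ra = pd.DataFrame({"i": [0.5, 0.5, 0.0], "j": [0.5, 0.0, 0.5]})
        assert sel.bray_curtis(ra).loc["i", "j"] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        n_otus=st.integers(2, 15),
        n_samples=st.integers(2, 8),
        seed=st.integers(0, 2**20),
    )
    def test_metric_properties_hold_for_any_profile(self, n_otus, n_samples, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(n_otus, n_samples)) + 1
        ra = pd.DataFrame(counts / counts.sum(axis=0))
        d = sel.bray_curtis(ra).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= -1e-12 and d.max() <= 1 + 1e-12

    def test_bounds_symmetry_identity_random_pairs(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 100, size=(25, 50)) + 1
        ra = pd.DataFrame(counts / counts.sum(axis=0))
        d = sel.bray_curtis(ra).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        # spot-check the min formula on every pair
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                expected = 1 - np.minimum(ra.iloc[:, i], ra.iloc[:, j]).sum()
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestPCoA:
    def test_two_samples_on_one_axis(self):
        d = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]], index=["a", "b"], columns=["a", "b"])
        result = sel.pcoa(d, n_axes=1)
        coords = np.sort(result.coordinates["PCo1"].to_numpy())
        assert coords == pytest.approx([-0.3, 0.3])

    def test_three_equidistant_points(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        result = sel.pcoa(d, n_axes=2)
        c = result.coordinates.to_numpy()
        dists = [np.linalg.norm(c[i] - c[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert np.allclose(dists, dists[0], atol=1e-9)

    def test_euclidean_distances_reconstructed_exactly(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(12, 2))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        result = sel.pcoa(pd.DataFrame(d), n_axes=2)
        c = result.coordinates.to_numpy()
        reconstructed = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        assert np.abs(reconstructed - d).max() < 1e-8

    def test_non_symmetric_rejected(self):
        d = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            sel.pcoa(d)

    def test_matches_scikit_bio(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 50, size=(15, 8)) + 1
        ra = pd.DataFrame(counts / counts.sum(axis=0))
        d = sel.bray_curtis(ra)
        ours = sel.pcoa(d, n_axes=3)
        theirs = skbio_ordination.pcoa(d.to_numpy())
        assert np.allclose(
            ours.eigenvalues[:3],
            np.clip(theirs.eigvals.to_numpy()[:3], 0, None),
            atol=1e-8,
        )
        for axis in range(3):
            a = ours.coordinates.iloc[:, axis].to_numpy()
            b = theirs.samples.iloc[:, axis].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)  # sign-free


class TestConditionDivergence:
    def test_identical_culture_zero(self):
        ra = _ra([[10, 10, 5], [90, 90, 95]])
        records = sel.condition_divergence(ra, META)
        bhi = records[records["condition"] == "BHI"].iloc[0]
        assert bhi["bray_curtis"] == pytest.approx(0.0)

    def test_takeover_by_rare_otu(self):
        # culture 100% one OTU that sat at 1% in the inoculum
        ra = _ra([[1, 100, 1], [99, 0, 99]])
        records = sel.condition_divergence(ra, META)
        bhi = records[records["condition"] == "BHI"].iloc[0]
        assert bhi["bray_curtis"] == pytest.approx(0.99)

    def test_missing_inoculum_errors(self):
        md = make_metadata(
            [
                ("I1", "inoculum", "1", "caecum", "inoculum"),
                ("S9", "culture", "2", "BHI", "non_supplemented"),
            ]
        )
        ra = _ra([[1, 1], [1, 1]], samples=("I1", "S9"))
        with pytest.raises(ValidationError, match="2"):
            sel.condition_divergence(ra, md)

    def test_extreme_fruit_multipliers_raise_divergence(self):
        """Strong fruit-category selection pushes fruit conditions above
        non-supplemented broths in median divergence (Monte Carlo)."""
        from culturocall.synthetic import SimulationConfig, generate_community, simulate_cultures

        hits = trials = 0
        for rep in range(20):
            cfg = SimulationConfig(
                n_species=40, n_inocula=2, n_conditions=24, depth=100_000,
                frac_unculturable=0.0, n_unculturable_clades=0, clade_sizes=(),
                selectivity_multipliers={
                    "Lachnospiraceae": {"fruit": 50.0},
                    "Bacteroidaceae": {"fruit": 0.02},
                    "Ruminococcaceae": {"fruit": 0.02},
                },
                seed=900 + rep,
            )
            community = generate_community(cfg)
            table, metadata = simulate_cultures(community, cfg)
            records = sel.condition_divergence(
                cb.relative_abundance(table), metadata
            )
            by_cat = records.groupby("category")["bray_curtis"].median()
            if "fruit" not in by_cat.index or "non_supplemented" not in by_cat.index:
                continue
            trials += 1
            hits += by_cat["fruit"] > by_cat["non_supplemented"]
        assert trials >= 10
        assert hits >= 0.8 * trials

    def test_deterministic_order(self, small_dataset):
        ds = small_dataset
        ra = cb.relative_abundance(ds.table)
        first = sel.condition_divergence(ra, ds.metadata)
        second = sel.condition_divergence(ra, ds.metadata)
        pd.testing.assert_frame_equal(first, second)
        assert (first["bray_curtis"].diff().dropna() <= 1e-12).all()
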