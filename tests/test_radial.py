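"""Annulus assignment, enrichment profiles, permutation nulls, scan/cumulative."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optopattern import (
    DEFAULT_BREAKPOINTS,
    GeneSet,
    SpotDataset,
    SyntheticConfig,
    assign_annuli,
    cumulative_profile,
    generate_spot_dataset,
    geneset_profile,
    permutation_test,
    scan_bins,
)
from conftest import random_spot_dataset


def uniform_dataset(n=25, value=4):
    """Spatially uniform counts: every gene identical at every spot."""
    side = int(np.sqrt(n))
    coords = np.array(
        [[i * 100.0, j * 100.0] for i in range(side) for j in range(side)]
    )
    n = len(coords)
    counts = np.full((4, n), value)
    return SpotDataset(
        [f"g{i}" for i in range(4)], [f"s{i}" for i in range(n)], counts, coords
    )


class TestAssignAnnuli:
    def test_six_breakpoints_make_seven_bins(self, tiny_spots):
        part = assign_annuli(tiny_spots, "s1", DEFAULT_BREAKPOINTS)
        assert part.n_bins == 7

    def test_half_open_boundaries(self):
        coords = np.array([[0.0, 0.0], [600.0, 0.0], [500.0, 0.0], [499.999, 0.0]])
        ds = SpotDataset(
            ["g"], ["c", "a", "b", "d"], np.ones((1, 4), int), coords
        )
        part = assign_annuli(ds, "c", DEFAULT_BREAKPOINTS)
        # 500 <= 600 < 775 -> second bin; exactly 500 also second bin
        assert part.assignment.tolist() == [0, 1, 1, 0]

    def test_beyond_last_breakpoint_is_outer_open_bin(self):
        coords = np.array([[0.0, 0.0], [5000.0, 0.0]])
        ds = SpotDataset(["g"], ["c", "far"], np.ones((1, 2), int), coords)
        part = assign_annuli(ds, "c", DEFAULT_BREAKPOINTS)
        assert part.assignment.tolist() == [0, 6]

    def test_unknown_center_spot_errors(self, tiny_spots):
        with pytest.raises(KeyError):
            assign_annuli(tiny_spots, "nope", DEFAULT_BREAKPOINTS)

    def test_bins_are_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        ds = random_spot_dataset(rng, n_spots=50)
        part = assign_annuli(ds, (0.0, 0.0), (100, 200, 400))
        assert part.assignment.min() >= 0 and part.assignment.max() <= 3
        assert len(part.assignment) == 50  # every spot in exactly one bin


class TestGenesetProfile:
    def test_two_bin_arithmetic(self):
        # set counts [8, 2] of totals [100, 100] -> fractions .08/.02, norm 1.6/0.4
        coords = np.array([[0.0, 0.0], [300.0, 0.0]])
        counts = np.array([[8, 2], [92, 98]])
        ds = SpotDataset(["SET", "OTHER"], ["s1", "s2"], counts, coords)
        part = assign_annuli(ds, "s1", (100.0,))
        prof = geneset_profile(ds, part, GeneSet("m", ("SET",)))
        assert prof.raw_fraction == pytest.approx([0.08, 0.02])
        assert prof.norm_score == pytest.approx([1.6, 0.4])

    def test_uniform_data_gives_flat_profile(self):
        ds = uniform_dataset()
        part = assign_annuli(ds, "s0", (150.0, 300.0))
        prof = geneset_profile(ds, part, GeneSet("m", ("g0",)))
        assert prof.norm_score == pytest.approx(np.ones(3))

    def test_empty_outer_bin_flagged_and_excluded(self, tiny_spots):
        part = assign_annuli(tiny_spots, "s1", (150.0, 5000.0))
        prof = geneset_profile(tiny_spots, part, GeneSet("m", ("GA",)))
        assert prof.empty_bins.tolist() == [False, False, True]
        assert np.isnan(prof.norm_score[2])
        included = prof.norm_score[~prof.empty_bins]
        assert included.mean() == pytest.approx(1.0)

    def test_missing_genes_warn_but_absent_set_errors(self, tiny_spots, caplog):
        part = assign_annuli(tiny_spots, "s1", (150.0,))
        with caplog.at_level("WARNING", logger="optopattern.radial"):
            geneset_profile(tiny_spots, part, GeneSet("m", ("GA", "NOPE")))
        assert any("missing from panel" in r.message for r in caplog.records)
        with pytest.raises(ValueError):
            geneset_profile(tiny_spots, part, GeneSet("m", ("NOPE",)))

    def test_normalization_mean_is_one_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ds = random_spot_dataset(rng, n_genes=8, n_spots=40)
            part = assign_annuli(ds, (0.0, 0.0), (200, 400, 600))
            prof = geneset_profile(ds, part, GeneSet("m", ("g0", "g3")))
            m = np.nanmean(prof.norm_score[~prof.empty_bins])
            assert m == pytest.approx(1.0, abs=1e-12)

    def test_profile_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(4)
        ds = random_spot_dataset(rng, n_spots=60)
        center = np.array([50.0, -20.0])
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shifted = SpotDataset(
            ds.gene_ids, ds.spot_ids, ds.counts,
            (ds.coords - center) @ rot.T + np.array([1000.0, 2000.0]),
        )
        gs = GeneSet("m", ("g1", "g4"))
        p1 = geneset_profile(ds, assign_annuli(ds, center, (150, 400)), gs)
        p2 = geneset_profile(
            shifted, assign_annuli(shifted, (1000.0, 2000.0), (150, 400)), gs
        )
        assert np.allclose(p1.norm_score, p2.norm_score, equal_nan=True)


class TestPermutationTest:
    def test_uniform_data_saturates_ties_to_p_one(self):
        ds = uniform_dataset(n=49)
        res = permutation_test(
            ds, GeneSet("m", ("g0",)), "s0", (150.0, 300.0),
            n_permutations=50, null_kind="center", seed=0,
        )
        assert np.all(res.p_values[~res.observed.empty_bins] == 1.0)

    def test_exhaustive_center_null_matches_bruteforce_oracle(self):
        """Enumerating every spot as center must reproduce an independently
        coded brute-force enumeration exactly (p and null scores)."""
        cfg = SyntheticConfig(
            grid_shape=(9, 9), n_genes=12,
            induced_set=GeneSet("m", ("SHH", "FOXA2")), rng_seed=2,
        )
        ds = generate_spot_dataset(cfg)
        bp = (250.0, 500.0)
        gs = cfg.induced_set
        res = permutation_test(
            ds, gs, "spot_004_004", bp, null_kind="center", exhaustive=True,
        )

        # oracle: plain python/numpy loop, written independently of the library path
        set_rows = [list(ds.gene_ids).index(g) for g in gs.genes]
        null = []
        for ci in range(ds.n_spots):
            c = ds.coords[ci]
            fracs, bins = [], [[], [], []]
            for si in range(ds.n_spots):
                dist = float(np.hypot(*(ds.coords[si] - c)))
                k = 0 if dist < bp[0] else (1 if dist < bp[1] else 2)
                bins[k].append(si)
            for members in bins:
                if not members:
                    fracs.append(np.nan)
                    continue
                s = sum(int(ds.counts[r, m]) for r in set_rows for m in members)
                t = sum(int(ds.counts[:, m].sum()) for m in members)
                fracs.append(s / t if t else np.nan)
            mean = np.nanmean([f for f in fracs if not np.isnan(f)])
            null.append([f / mean for f in fracs])
        null = np.asarray(null)
        obs = null[4 * 9 + 4]  # spot_004_004 row-major index
        n = ds.n_spots
        p_oracle = (1.0 + np.nansum(null >= obs[None, :], axis=0)) / (n + 1.0)

        assert np.allclose(res.null_scores, null, equal_nan=True)
        assert np.array_equal(res.p_values, p_oracle)

    def test_localized_induction_significant_in_innermost_bin(self):
        cfg = SyntheticConfig(rng_seed=12)
        ds = generate_spot_dataset(cfg)
        center = tuple(ds.coords.mean(axis=0))
        for kind, seed in (("center", 1), ("geneset", 2)):
            res = permutation_test(
                ds, cfg.induced_set, center, DEFAULT_BREAKPOINTS,
                n_permutations=1000, null_kind=kind, seed=seed,
            )
            assert res.p_values[0] <= 0.05

    def test_strict_tie_policy_matches_exceedance_fraction(self):
        cfg = SyntheticConfig(grid_shape=(10, 10), n_genes=20, rng_seed=5)
        ds = generate_spot_dataset(cfg)
        center = tuple(ds.coords.mean(axis=0))
        kw = dict(n_permutations=200, null_kind="geneset", seed=7)
        smooth = permutation_test(
            ds, cfg.induced_set, center, (300.0, 600.0), tie_policy="add_one", **kw
        )
        strict = permutation_test(
            ds, cfg.induced_set, center, (300.0, 600.0), tie_policy="strict", **kw
        )
        gt = np.nansum(
            strict.null_scores > strict.observed.norm_score[None, :], axis=0
        )
        assert np.allclose(strict.p_values, gt / 200)
        assert np.all(smooth.p_values > 0)  # add-one smoothing never returns 0

    def test_whole_panel_geneset_null_is_undefined(self, tiny_spots):
        with pytest.raises(ValueError):
            permutation_test(
                tiny_spots, GeneSet("m", ("GA", "GB", "GC")), "s1", (150.0,),
                null_kind="geneset", n_permutations=10, seed=0,
            )

    def test_abundance_matched_null_runs_and_is_reproducible(self):
        cfg = SyntheticConfig(grid_shape=(10, 10), n_genes=40, rng_seed=6)
        ds = generate_spot_dataset(cfg)
        kw = dict(
            n_permutations=50, null_kind="geneset", seed=3, abundance_matched=True
        )
        a = permutation_test(ds, cfg.induced_set, (450.0, 450.0), (300.0, 600.0), **kw)
        b = permutation_test(ds, cfg.induced_set, (450.0, 450.0), (300.0, 600.0), **kw)
        assert np.allclose(a.null_scores, b.null_scores, equal_nan=True)


class TestScanBins:
    def test_bin_counts_and_breakpoint_geometry(self, tiny_spots):
        profiles = scan_bins(tiny_spots, GeneSet("m", ("GA",)), "s1")
        assert sorted(profiles) == [6, 7, 8, 9]
        bp7 = profiles[7].breakpoints
        assert len(bp7) == 6 and bp7[-1] == pytest.approx(1825.0)
        assert np.allclose(np.diff(bp7), 1825.0 / 6)

    def test_uniform_data_flat_for_every_binning(self):
        ds = uniform_dataset(n=100)
        profiles = scan_bins(
            ds, GeneSet("m", ("g0",)), "s0", extent=400.0, n_bins_range=(6, 7, 8, 9)
        )
        for prof in profiles.values():
            ok = ~prof.empty_bins
            assert np.allclose(prof.norm_score[ok], 1.0)

    def test_induction_peak_stable_across_binnings(self):
        cfg = SyntheticConfig(rng_seed=21)
        ds = generate_spot_dataset(cfg)
        profiles = scan_bins(ds, cfg.induced_set, tuple(ds.coords.mean(axis=0)))
        for n, prof in profiles.items():
            assert np.nanargmax(prof.norm_score) == 0, f"peak not innermost at n={n}"


class TestCumulativeProfile:
    def test_uniform_data_is_flat_one(self):
        ds = uniform_dataset(n=49)
        cp = cumulative_profile(ds, GeneSet("m", ("g0",)), "s0")
        assert np.allclose(cp.values, 1.0)

    def test_concentrated_set_decays_toward_one(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0], [300.0, 0.0]])
        counts = np.array([[30, 0, 0, 0], [10, 40, 40, 40]])
        ds = SpotDataset(["SET", "O"], ["a", "b", "c", "d"], counts, coords)
        cp = cumulative_profile(ds, GeneSet("m", ("SET",)), "a")
        assert cp.values[0] == cp.values.max()
        assert np.all(np.diff(cp.values) <= 1e-12)
        assert cp.values[-1] == pytest.approx(1.0, abs=1e-12)

    def test_final_rank_is_exactly_one(self):
        rng = np.random.default_rng(9)
        ds = random_spot_dataset(rng, n_spots=30)
        cp = cumulative_profile(ds, GeneSet("m", ("g0", "g2")), (0.0, 0.0))
        assert cp.values[-1] == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_profile_normalization_property(seed):
    """Mean of the normalized score over non-empty bins is one for any data."""
    rng = np.random.default_rng(seed)
    ds = random_spot_dataset(rng, n_genes=5, n_spots=15)
    part = assign_annuli(ds, (0.0, 0.0), (150.0, 350.0, 700.0))
    prof = geneset_profile(ds, part, GeneSet("m", ("g0",)))
    included = prof.norm_score[~prof.empty_bins]
    if len(included):
        assert np.nanmean(included) == pytest.approx(1.0, abs=1e-12)
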