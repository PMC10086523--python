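"""TAD separation score, boundaries, rearrangements, connectivity, DoD."""

import numpy as np
import pytest

from chromarch import balance, simulate, tads
from chromarch.config import DoDConfig
from chromarch.model import BinGrid, Boundary, ContactMap, Domain, GenomeAssembly
from chromarch.tads import (
    assemble_domains,
    classify_rearrangements,
    degree_of_disorder,
    find_boundaries,
    intra_tad_connectivity,
    match_boundaries,
    tad_separation_score,
)

from conftest import dense_to_map

RES = 40_000


def grid_of(n):
    return BinGrid(GenomeAssembly(("chr1",), (n * RES,)), RES)


def two_block_map(n=40, k=20, inside=5.0, outside=0.5):
    dense = np.full((n, n), outside)
    dense[:k, :k] = inside
    dense[k:, k:] = inside
    cmap = dense_to_map(grid_of(n), "chr1", dense,
                        weights=np.ones(n))
    return cmap


class TestSeparationScore:
    def test_uniform_matrix_constant_score(self):
        n = 30
        cmap = dense_to_map(grid_of(n), "chr1", np.full((n, n), 3.0),
                            weights=np.ones(n))
        track = tad_separation_score(cmap, (4, 6))
        s = track.score.values["chr1"]
        interior = s[6:-6]
        assert np.nanstd(interior) == pytest.approx(0.0, abs=1e-10)

    def test_two_blocks_minimum_at_border(self):
        cmap = two_block_map()
        track = tad_separation_score(cmap, (4, 6))
        s = track.score.values["chr1"]
        assert np.nanargmin(s) == 20

    def test_window_larger_than_chromosome_rejected(self):
        n = 8
        cmap = dense_to_map(grid_of(n), "chr1", np.ones((n, n)),
                            weights=np.ones(n))
        with pytest.raises(ValueError, match="window"):
            tad_separation_score(cmap, (10,))


class TestBoundaries:
    def test_flat_track_no_boundaries(self):
        n = 30
        cmap = dense_to_map(grid_of(n), "chr1", np.full((n, n), 3.0),
                            weights=np.ones(n))
        track = tad_separation_score(cmap, (4, 6))
        assert find_boundaries(track, fdr=0.01) == []

    def test_two_blocks_one_boundary_two_domains(self):
        cmap = two_block_map()
        track = tad_separation_score(cmap, (4, 6))
        bounds = find_boundaries(track, fdr=0.05)
        assert len(bounds) == 1
        assert bounds[0].start // RES == 20
        doms = assemble_domains(bounds, grid_of(40))
        assert [(d.start // RES, d.end // RES) for d in doms] == [(0, 20), (20, 40)]

    def test_lowering_fdr_never_increases_boundary_count(self):
        params = simulate.default_hic_params(seed=4, depth=1e6, c_tad=3.0,
                                             c_comp=1.0)
        cmap, _ = simulate.simulate_contact_map(params)
        b = balance.kr_balance(cmap)
        track = tad_separation_score(b)
        counts = [len(find_boundaries(track, fdr)) for fdr in (0.1, 0.01, 0.001)]
        assert counts == sorted(counts, reverse=True)

    def test_simulated_boundary_recovery(self):
        params = simulate.default_hic_params(seed=0, depth=1e6, c_tad=3.0,
                                             c_comp=1.0)
        cmap, truth = simulate.simulate_contact_map(params)
        b = balance.kr_balance(cmap)
        track = tad_separation_score(b)
        bounds = find_boundaries(track, fdr=0.01)
        found = np.array(sorted(x.start // RES for x in bounds))
        planted = np.array(truth.boundaries)
        recall = np.mean([np.min(np.abs(found - p)) <= 1 for p in planted])
        precision = np.mean([np.min(np.abs(planted - f)) <= 1 for f in found])
        assert recall >= 0.9
        assert precision >= 0.9


class TestMatchBoundaries:
    def b(self, pos):
        return Boundary("chr1", pos * RES, (pos + 1) * RES)

    def test_identical_all_stable(self):
        bs = [self.b(5), self.b(10)]
        y, a = match_boundaries(bs, list(bs), tol_bins=1, resolution=RES)
        assert all(x.stability == "stable" for x in y + a)

    def test_disjoint_all_lost_gained(self):
        y, a = match_boundaries([self.b(5)], [self.b(20)], 1, RES)
        assert y[0].stability == "lost"
        assert a[0].stability == "gained"

    def test_equidistant_tie_leftmost_wins(self):
        # two young boundaries both 1 bin from one aged boundary
        y, a = match_boundaries([self.b(9), self.b(11)], [self.b(10)], 1, RES)
        assert y[0].stability == "stable"   # leftmost
        assert y[1].stability == "lost"
        assert a[0].stability == "stable"


class TestClassifyRearrangements:
    def d(self, s, e):
        return Domain("chr1", s * RES, e * RES)

    def test_identical_all_stable(self):
        ts = [self.d(0, 10), self.d(10, 20)]
        rep = classify_rearrangements(ts, list(ts), 1, RES)
        assert all(t.rearrangement == "stable" for t in rep.young + rep.aged)

    def test_split_and_merge(self):
        young = [self.d(0, 100)]
        aged = [self.d(0, 60), self.d(60, 100)]
        rep = classify_rearrangements(young, aged, 1, RES)
        assert rep.young[0].rearrangement == "split"
        rep2 = classify_rearrangements(aged, young, 1, RES)
        assert rep2.aged[0].rearrangement == "merge"

    def test_shift(self):
        rep = classify_rearrangements([self.d(0, 10)], [self.d(0, 14)], 1, RES)
        assert rep.young[0].rearrangement == "shift"

    def test_entangled_component_indeterminate(self):
        young = [self.d(0, 10), self.d(10, 20)]
        aged = [self.d(0, 12), self.d(12, 20)]
        rep = classify_rearrangements(young, aged, 1, RES)
        assert all(t.rearrangement == "indeterminate" for t in rep.young)

    def test_symmetry_splits_equal_merges_on_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cuts_y = np.unique(rng.choice(np.arange(1, 50), 6)) * 2
            cuts_a = np.unique(rng.choice(np.arange(1, 50), 6)) * 2
            young = [self.d(s, e) for s, e in
                     zip([0, *cuts_y], [*cuts_y, 100])]
            aged = [self.d(s, e) for s, e in
                    zip([0, *cuts_a], [*cuts_a, 100])]
            fwd = classify_rearrangements(young, aged, 1, RES)
            rev = classify_rearrangements(aged, young, 1, RES)
            n_split_fwd = sum(t.rearrangement == "split" for t in fwd.young)
            n_merge_rev = sum(t.rearrangement == "merge" for t in rev.aged)
            assert n_split_fwd == n_merge_rev

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            classify_rearrangements([self.d(0, 10), self.d(5, 15)],
                                    [self.d(0, 10)], 1, RES)


class TestConnectivity:
    def toy_map(self, intra=4.0, inter=1.0, scale=1.0):
        dense = np.full((6, 6), inter)
        dense[:3, :3] = intra
        dense[3:, 3:] = intra
        return dense_to_map(grid_of(6), "chr1", dense * scale)

    def toy_tads(self):
        return [Domain("chr1", 0, 3 * RES), Domain("chr1", 3 * RES, 6 * RES)]

    def test_hand_counted_value(self):
        # intra: 6 pixels of 4 -> mean 4; inter: 9 pixels of 1 -> sum 9
        recs = intra_tad_connectivity(self.toy_map(), self.toy_tads())
        assert recs[0].connectivity == pytest.approx(4 / 9)
        assert recs[1].connectivity == pytest.approx(4 / 9)

    def test_scale_invariance(self):
        r1 = intra_tad_connectivity(self.toy_map(), self.toy_tads())
        r10 = intra_tad_connectivity(self.toy_map(scale=10), self.toy_tads())
        assert r1[0].connectivity == pytest.approx(r10[0].connectivity)

    def test_intra_enrichment_increases_connectivity(self):
        base = intra_tad_connectivity(self.toy_map(), self.toy_tads())
        boosted = intra_tad_connectivity(self.toy_map(intra=8.0),
                                         self.toy_tads())
        assert boosted[0].connectivity > base[0].connectivity

    def test_zero_inter_counts_missing_not_infinite(self):
        recs = intra_tad_connectivity(self.toy_map(inter=0.0), self.toy_tads())
        assert np.isnan(recs[0].connectivity)

    def test_mean_denominator_variant(self):
        recs = intra_tad_connectivity(self.toy_map(), self.toy_tads(),
                                      denominator="mean")
        # inter mean per pixel = 1 -> connectivity = 4 / 1
        assert recs[0].connectivity == pytest.approx(4.0)


class TestDegreeOfDisorder:
    def _map_with_pixels(self, n, hot_pixels, hot=50.0, scale=1.0):
        """Flat decaying background with planted hot pixels."""
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        dense = 10.0 * (1 + d) ** -0.5
        for i, j in hot_pixels:
            dense[i, j] = dense[j, i] = hot
        return dense_to_map(grid_of(n), "chr1", dense * scale,
                            weights=np.ones(n))

    @staticmethod
    def brute_force_dod(pixels, k):
        pts = np.asarray(pixels, dtype=float)
        if len(pts) < k + 1:
            return float("nan")
        means = []
        for i in range(len(pts)):
            dists = sorted(np.hypot(*(pts[i] - pts[j]))
                           for j in range(len(pts)) if j != i)
            means.append(np.mean(dists[:k]))
        return float(np.mean(means))

    def test_single_cluster_matches_brute_force(self):
        n = 40
        cluster = [(5, 20), (5, 21), (6, 20), (6, 21)]
        cmap = self._map_with_pixels(n, cluster)
        tad = Domain("chr1", 0, n * RES)
        got = degree_of_disorder(cmap, tad, DoDConfig(k=3, top=0.995))
        assert got == pytest.approx(self.brute_force_dod(cluster, 3), rel=1e-9)

    def test_two_distant_clusters_strictly_larger(self):
        n = 40
        one = [(5, 20), (5, 21), (6, 20), (6, 21)]
        two = [(2, 10), (2, 11), (25, 33), (25, 34)]  # clusters ~30 bins apart
        tad = Domain("chr1", 0, n * RES)
        d_one = degree_of_disorder(self._map_with_pixels(n, one), tad,
                                   DoDConfig(k=3, top=0.995))
        d_two = degree_of_disorder(self._map_with_pixels(n, two), tad,
                                   DoDConfig(k=3, top=0.995))
        assert d_two > d_one
        assert d_two == pytest.approx(self.brute_force_dod(two, 3), rel=1e-9)

    def test_too_few_significant_pixels_missing(self):
        n = 20
        cmap = self._map_with_pixels(n, [(3, 10)])
        tad = Domain("chr1", 0, n * RES)
        assert np.isnan(degree_of_disorder(cmap, tad,
                                           DoDConfig(k=3, top=0.999)))

    def test_scale_invariance(self):
        n = 40
        cluster = [(5, 20), (5, 21), (6, 20), (6, 21)]
        tad = Domain("chr1", 0, n * RES)
        d1 = degree_of_disorder(self._map_with_pixels(n, cluster), tad,
                                DoDConfig(k=3, top=0.995))
        d2 = degree_of_disorder(self._map_with_pixels(n, cluster, scale=10.0),
                                tad, DoDConfig(k=3, top=0.995))
        assert d1 == pytest.approx(d2)


class TestDistanceToNearest:
    def test_nearest_feature_distance(self):
        bounds = [Boundary("chr1", 100_000, 140_000),
                  Boundary("chr2", 0, 40_000)]
        feats = [Domain("chr1", 0, 40_000), Domain("chr1", 200_000, 280_000)]
        d = tads.distance_to_nearest(bounds, feats)
        # chr1 boundary midpoint 120k; features at 20k and 240k -> 100k
        assert d[0] == 100_000
        assert np.isinf(d[1])  # no chr2 features
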