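"""Cell aggregation, co-accessibility scoring, peak-to-gene linkages."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from chromarch import simulate
from chromarch.config import AggregateConfig, LinkageConfig
from chromarch.linkages import (
    Aggregate,
    cluster_linkages,
    coaccessibility_scores,
    linkage_coaccess_fraction,
    make_aggregates,
    peak_to_gene,
)
from chromarch.model import CellMatrices, Interval, SitePair
from chromarch.simulate import MultiomeSimParams, PlantedLinkage


def sim_cells(seed=5, n_cells=500, rho=0.8, n_links=20, condition="shared"):
    links = tuple(PlantedLinkage(peak=p, gene=g, rho=rho, condition=condition)
                  for g, p in enumerate(range(n_links)))
    params = MultiomeSimParams(n_cells=n_cells, n_peaks=60, n_genes=20,
                               linkages=links, seed=seed)
    return simulate.simulate_multiome(params), links


class TestMakeAggregates:
    def test_k_one_aggregates_are_single_cells(self):
        (cells, _), _ = sim_cells(n_cells=50)
        cfg = AggregateConfig(k=1, n_aggregates=20)
        aggs = make_aggregates(cells, "young", cfg, seed=0)
        assert all(len(a.members) == 1 for a in aggs)
        shared = [len(set(a.members) & set(b.members))
                  for a, b in combinations(aggs, 2)]
        assert max(shared, default=0) == 0

    def test_condition_purity(self):
        (cells, _), _ = sim_cells()
        for cond in ("young", "aged"):
            idx = set(cells.cells_of(cond).tolist())
            for a in make_aggregates(cells, cond, AggregateConfig(), seed=1):
                assert set(a.members) <= idx
                assert a.condition == cond

    def test_overlap_constraints_hold_posthoc(self):
        (cells, _), _ = sim_cells(seed=2)
        cfg = AggregateConfig()
        aggs = make_aggregates(cells, "young", cfg, seed=3)
        shared = [len(set(a.members) & set(b.members))
                  for a, b in combinations(aggs, 2)]
        assert np.median(shared) == 0
        assert np.mean(shared) / cfg.k <= cfg.max_mean_overlap

    def test_duplicate_cells_collapse_to_one_candidate(self):
        n, p = 60, 8
        acc = sp.csr_matrix(np.tile(np.arange(p), (n, 1)))
        expr = sp.csr_matrix(np.ones((n, 3)))
        cells = CellMatrices(
            acc, expr,
            pd.DataFrame({"chrom": "chrS", "start": np.arange(p) * 1000,
                          "end": np.arange(p) * 1000 + 500,
                          "name": [f"p{k}" for k in range(p)]}),
            pd.DataFrame({"name": ["g0", "g1", "g2"], "chrom": "chrS",
                          "tss": [0, 1000, 2000], "strand": "+"}),
            [f"c{i}" for i in range(n)],
            ["young"] * 30 + ["aged"] * 30)
        cfg = AggregateConfig(k=10, n_aggregates=10)
        with pytest.raises(RuntimeError, match="aggregates"):
            # all kNN sets identical -> only 1 distinct candidate, under the
            # ceil(n/k) = 3 bound and below the minimum viable count
            make_aggregates(cells, "young", cfg, seed=0)

    def test_too_few_cells_rejected(self):
        (cells, _), _ = sim_cells(n_cells=500)
        with pytest.raises(ValueError, match="cells"):
            make_aggregates(cells, "young", AggregateConfig(k=501), seed=0)

    def test_deterministic(self):
        (cells, _), _ = sim_cells(seed=4)
        a1 = make_aggregates(cells, "young", AggregateConfig(), seed=9)
        a2 = make_aggregates(cells, "young", AggregateConfig(), seed=9)
        assert [a.members for a in a1] == [a.members for a in a2]


def toy_aggregates(n_agg, vectors_acc, vectors_expr=None, condition="young"):
    """Build aggregates from explicit per-peak/gene vectors (aggs x feats)."""
    vectors_expr = vectors_expr if vectors_expr is not None else vectors_acc
    return [Aggregate(i, condition, (i,), vectors_acc[i], vectors_expr[i])
            for i in range(n_agg)]


class TestCoaccessibilityScores:
    def _peaks(self, n, spacing=10_000):
        return pd.DataFrame({"chrom": "chrS",
                             "start": np.arange(n) * spacing,
                             "end": np.arange(n) * spacing + 500,
                             "name": [f"p{k}" for k in range(n)]})

    def test_duplicated_peak_scores_one(self):
        rng = np.random.default_rng(0)
        A = rng.poisson(5, (20, 3)).astype(float)
        A[:, 2] = A[:, 0]  # peak 2 duplicates peak 0... at another position
        aggs = toy_aggregates(20, A)
        pairs = coaccessibility_scores(aggs, self._peaks(3), max_dist=500_000)
        by_pos = {(p.site1.start, p.site2.start): p.score for p in pairs}
        assert by_pos[(0, 20_000)] == pytest.approx(1.0)

    def test_pairs_beyond_max_dist_absent(self):
        rng = np.random.default_rng(1)
        A = rng.poisson(5, (20, 2)).astype(float)
        aggs = toy_aggregates(20, A)
        peaks = self._peaks(2, spacing=600_000)
        pairs = coaccessibility_scores(aggs, peaks, max_dist=500_000)
        assert pairs == []

    def test_null_scores_small(self):
        rng = np.random.default_rng(2)
        A = rng.poisson(5, (100, 30)).astype(float)
        aggs = toy_aggregates(100, A)
        pairs = coaccessibility_scores(aggs, self._peaks(30), max_dist=10**7)
        # kept pairs all have positive score; among all tested pairs >=95%
        # are |r| < 0.3 under independence
        n_tested = 30 * 29 // 2
        big = sum(p.score >= 0.3 for p in pairs)
        assert big / n_tested < 0.05

    def test_minimum_aggregate_count_enforced(self):
        A = np.ones((5, 3))
        with pytest.raises(ValueError, match="10 aggregates"):
            coaccessibility_scores(toy_aggregates(5, A), self._peaks(3), 10**6)


class TestPeakToGene:
    def test_planted_links_recovered(self):
        (cells, _), links = sim_cells(seed=5, rho=0.8)
        ay = make_aggregates(cells, "young", AggregateConfig(), seed=11)
        aa = make_aggregates(cells, "aged", AggregateConfig(), seed=12)
        out = peak_to_gene(ay, aa, cells.peaks, cells.genes, LinkageConfig())
        planted = {(pl.peak, pl.gene) for pl in links}
        got = {(l.peak, l.gene) for l in out}
        assert len(got & planted) / len(planted) >= 0.9
        # a few extra links are legitimate: background peaks share latent
        # programs with linked genes, so their correlation is real
        assert len(got - planted) <= 5

    def test_all_null_respects_fdr(self):
        params = MultiomeSimParams(n_cells=400, n_peaks=40, n_genes=15,
                                   linkages=(), seed=6)
        cells, _ = simulate.simulate_multiome(params)
        ay = make_aggregates(cells, "young", AggregateConfig(), seed=21)
        aa = make_aggregates(cells, "aged", AggregateConfig(), seed=22)
        out = peak_to_gene(ay, aa, cells.peaks, cells.genes, LinkageConfig())
        assert len(out) == 0

    def test_distant_pairs_never_tested(self):
        rng = np.random.default_rng(3)
        A = rng.poisson(5, (20, 1)).astype(float)
        E = A.copy()  # perfectly correlated, but 501 kb away
        aggs_y = toy_aggregates(10, A[:10], E[:10], "young")
        aggs_a = toy_aggregates(10, A[10:], E[10:], "aged")
        peaks = pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [1000],
                              "name": ["p0"]})
        genes = pd.DataFrame({"name": ["g0"], "chrom": ["chrS"],
                              "tss": [501_500], "strand": ["+"]})
        cfg = LinkageConfig(max_distance=500_000)
        assert peak_to_gene(aggs_y, aggs_a, peaks, genes, cfg) == []

    def test_invariant_to_count_scaling(self):
        (cells, _), _ = sim_cells(seed=7)
        ay = make_aggregates(cells, "young", AggregateConfig(), seed=31)
        aa = make_aggregates(cells, "aged", AggregateConfig(), seed=32)
        out1 = peak_to_gene(ay, aa, cells.peaks, cells.genes, LinkageConfig())

        def scale(aggs, f):
            return [Aggregate(a.id, a.condition, a.members,
                              a.accessibility * f, a.expression * f)
                    for a in aggs]

        out2 = peak_to_gene(scale(ay, 5.0), scale(aa, 5.0), cells.peaks,
                            cells.genes, LinkageConfig())
        assert [(l.peak, l.gene) for l in out1] == [(l.peak, l.gene)
                                                    for l in out2]
        np.testing.assert_allclose([l.correlation for l in out1],
                                   [l.correlation for l in out2], atol=1e-12)

    def test_aggregate_correlation_tracks_latent_oracle(self):
        """Mean deviation of estimated aggregate-level correlations from the
        latent-factor oracle (correlation of aggregated conditional means,
        a deterministic transform of the latents) stays within +-0.1."""
        (cells, truth), links = sim_cells(seed=8, rho=0.8)
        ay = make_aggregates(cells, "young", AggregateConfig(), seed=41)
        aa = make_aggregates(cells, "aged", AggregateConfig(), seed=42)
        out = {(l.peak, l.gene): l.correlation
               for l in peak_to_gene(ay, aa, cells.peaks, cells.genes,
                                     LinkageConfig(fdr_threshold=1.0,
                                                   correlation_threshold=-1))}
        aggs = ay + aa
        P = truth.latent["peak_prob"]
        R = truth.latent["gene_rate"]
        gaps = []
        for pl in links:
            p_agg = np.array([P[list(a.members), pl.peak].sum() for a in aggs])
            r_agg = np.array([R[list(a.members), pl.gene].sum() for a in aggs])
            oracle = np.corrcoef(p_agg, r_agg)[0, 1]
            gaps.append(out[(pl.peak, pl.gene)] - oracle)
        assert abs(np.mean(gaps)) <= 0.1


class TestClusterLinkages:
    def _links_with_profiles(self, profiles, n_each=4):
        from chromarch.linkages import Linkage
        out = []
        rng = np.random.default_rng(0)
        for ci, prof in enumerate(profiles):
            for k in range(n_each):
                noisy = prof + rng.normal(0, 0.05, len(prof))
                out.append(Linkage(
                    peak=ci * n_each + k,
                    peak_interval=Interval("chrS", k * 1000, k * 1000 + 500),
                    gene=ci, tss=0, correlation=0.9, pvalue=0.0, fdr=0.0,
                    acc_profile=noisy, expr_profile=noisy.copy()))
        return out

    def test_orthogonal_patterns_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        profiles = [np.eye(5)[i].repeat(8) for i in range(5)]
        links = self._links_with_profiles(profiles)
        out = cluster_linkages(links, n_clusters=5, seed=0)
        truth = [l.gene for l in out]
        assert adjusted_rand_score(truth, [l.cluster for l in out]) >= 0.9

    def test_duplicate_rows_co_cluster(self):
        profiles = [np.eye(5)[i].repeat(8) for i in range(5)]
        links = self._links_with_profiles(profiles)
        links[0].acc_profile = links[1].acc_profile.copy()
        links[0].expr_profile = links[1].expr_profile.copy()
        out = cluster_linkages(links, n_clusters=5, seed=0)
        assert out[0].cluster == out[1].cluster

    def test_fixed_seed_identical_assignment(self):
        profiles = [np.eye(5)[i].repeat(8) for i in range(5)]
        links = self._links_with_profiles(profiles)
        c1 = [l.cluster for l in cluster_linkages(links, 5, seed=3)]
        c2 = [l.cluster for l in cluster_linkages(links, 5, seed=3)]
        assert c1 == c2

    def test_fewer_linkages_than_clusters_rejected(self):
        links = self._links_with_profiles([np.ones(10)], n_each=3)
        with pytest.raises(ValueError, match="clusters"):
            cluster_linkages(links, n_clusters=5, seed=0)


class TestLinkageCoaccessFraction:
    def _linkage(self, peak_pos, gene):
        from chromarch.linkages import Linkage
        return Linkage(peak=peak_pos, gene=gene, tss=0,
                       peak_interval=Interval("chrS", peak_pos, peak_pos + 500),
                       correlation=0.9, pvalue=0.0, fdr=0.0)

    def _pair(self, a, b):
        return SitePair(Interval("chrS", a, a + 500),
                        Interval("chrS", b, b + 500), 0.5)

    def test_all_pairs_coaccessible_gives_one(self):
        links = [self._linkage(p, 0) for p in (0, 1000, 2000)]
        pairs = [self._pair(0, 1000), self._pair(0, 2000), self._pair(1000, 2000)]
        assert linkage_coaccess_fraction(links, pairs) == 1.0

    def test_none_coaccessible_gives_zero(self):
        links = [self._linkage(p, 0) for p in (0, 1000, 2000)]
        assert linkage_coaccess_fraction(links, []) == 0.0

    def test_mean_over_genes(self):
        links = ([self._linkage(p, 0) for p in (0, 1000, 2000)]
                 + [self._linkage(p, 1) for p in (5000, 6000)])
        pairs = [self._pair(0, 1000), self._pair(0, 2000),
                 self._pair(1000, 2000)]  # gene 0 fully covered, gene 1 not
        assert linkage_coaccess_fraction(links, pairs) == pytest.approx(0.5)

    def test_no_multi_peak_gene_missing(self):
        links = [self._linkage(0, 0)]
        assert np.isnan(linkage_coaccess_fraction(links, []))
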