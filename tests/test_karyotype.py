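import numpy as np
import pytest

from haploscan import gl_engine, karyotype, ld_blocks


@pytest.fixture(scope="module")
def block_and_table(small_cohort):
    cfg, ds, truth = small_cohort
    table = gl_engine.call_snps(ds)
    block = ld_blocks.HaploblockRegion(cfg.chrom, *cfg.inversion_interval)
    return cfg, ds, truth, table, block


class TestClusterKaryotypes:
    def test_forced_three_cluster_geometry(self):
        rng = np.random.default_rng(0)
        pc1 = np.concatenate(
            [rng.normal(-1.0, 0.01, 5), rng.normal(0.0, 0.01, 5),
             rng.normal(1.0, 0.01, 5)]
        )
        assigns, diag = karyotype.cluster_karyotypes(pc1)
        assert diag["structure"]
        assert list(diag["sizes"]) == [5, 5, 5]
        mids = [a for a in assigns if a.cluster == "middle"]
        assert len(mids) == 5
        assert all(a.label == karyotype.LABEL_HET for a in mids)

    def test_no_structure_flags_unassigned(self):
        rng = np.random.default_rng(1)
        pc1 = rng.normal(0, 0.01, size=30)
        assigns, diag = karyotype.cluster_karyotypes(pc1)
        assert not diag["structure"]
        assert all(a.label == karyotype.LABEL_NONE for a in assigns)

    def test_sign_flip_swaps_sides_not_heterokaryotypes(self):
        rng = np.random.default_rng(2)
        pc1 = np.concatenate(
            [rng.normal(-1, 0.02, 10), rng.normal(0, 0.02, 6), rng.normal(1, 0.02, 3)]
        )
        a1, _ = karyotype.cluster_karyotypes(pc1)
        a2, _ = karyotype.cluster_karyotypes(-pc1)
        mid1 = {a.individual for a in a1 if a.cluster == "middle"}
        mid2 = {a.individual for a in a2 if a.cluster == "middle"}
        assert mid1 == mid2
        left1 = {a.individual for a in a1 if a.cluster == "left"}
        right2 = {a.individual for a in a2 if a.cluster == "right"}
        assert left1 == right2

    def test_unbalanced_clusters_still_exact(self):
        # the regime this analysis actually meets: one tiny homokaryotype group
        rng = np.random.default_rng(3)
        pc1 = np.concatenate(
            [rng.normal(-0.3, 0.01, 100), rng.normal(0.0, 0.01, 15),
             rng.normal(0.3, 0.01, 3)]
        )
        _a, diag = karyotype.cluster_karyotypes(pc1)
        assert diag["structure"]
        assert list(diag["sizes"]) == [100, 15, 3]

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            karyotype.cluster_karyotypes(np.zeros(5))


class TestBlockPca:
    def test_three_clumps_match_truth(self, block_and_table):
        cfg, ds, truth, table, block = block_and_table
        res = karyotype.block_pca(ds, table, block)
        assigns, diag = karyotype.cluster_karyotypes(res.pc(1), ds.individuals)
        assert diag["structure"]
        cluster_of = {a.individual: a.cluster for a in assigns}
        # middle cluster should be exactly the true heterokaryotypes
        mids = {i for i, c in cluster_of.items() if c == "middle"}
        hets = {
            ind for ind, k in zip(ds.individuals, truth.karyotype) if k == "STD/INV"
        }
        assert mids == hets

    def test_no_inversion_no_structure(self, small_cohort):
        cfg, ds, truth = small_cohort
        table = gl_engine.call_snps(ds)
        # negative control: same-size region outside the inversion
        ctrl = ld_blocks.HaploblockRegion(cfg.chrom, 4_500_000, 6_000_000)
        res = karyotype.block_pca(ds, table, ctrl)
        _a, diag = karyotype.cluster_karyotypes(res.pc(1), ds.individuals)
        assert not diag["structure"]

    def test_block_too_small(self, block_and_table):
        cfg, ds, _truth, table, _block = block_and_table
        tiny = ld_blocks.HaploblockRegion(cfg.chrom, 0, 5_000)
        with pytest.raises(ValueError, match="too small"):
            karyotype.block_pca(ds, table, tiny)


class TestHobsProfiles:
    def test_all_het_group_is_one(self):
        import pandas as pd

        from haploscan.gtio import GLDataset
        from conftest import hard_gl

        S, N = 40, 6
        gl = np.broadcast_to(hard_gl([1] * N)[None], (S, N, 3)).copy()
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, S + 1) * 1000, "major": "A",
             "minor": "C"}
        )
        ds = GLDataset(sites=sites, individuals=[f"i{k}" for k in range(N)], gl=gl)
        assigns = [
            karyotype.KaryotypeAssignment(f"i{k}", 0.0, "middle",
                                          karyotype.LABEL_HET)
            for k in range(N)
        ]
        with pytest.warns(UserWarning):
            profiles = karyotype.hobs_profiles(ds, assigns, "chr1")
        assert np.allclose(profiles["middle"].mean_hobs, 1.0, atol=1e-6)

    def test_ordering_inside_interval(self, block_and_table):
        cfg, ds, truth, table, block = block_and_table
        # truth-group profiles: het > STD/STD > INV/INV in windowed H_obs
        label_to_cluster = {"STD/STD": "left", "STD/INV": "middle",
                            "INV/INV": "right"}
        assigns = [
            karyotype.KaryotypeAssignment(ind, 0.0, label_to_cluster[k], k)
            for ind, k in zip(ds.individuals, truth.karyotype)
        ]
        profiles = karyotype.hobs_profiles(ds, assigns, cfg.chrom,
                                           site_table=table)
        start, end = truth.inversion_interval
        common = set(profiles["left"].window_start) & set(
            profiles["middle"].window_start
        ) & set(profiles["right"].window_start)
        wins = {}
        for g in ("left", "middle", "right"):
            p = profiles[g]
            sel = {
                ws: (m, n)
                for ws, m, n in zip(p.window_start, p.mean_hobs, p.n_snps)
            }
            wins[g] = sel
        inside = [
            w for w in common
            if start <= w < end and all(wins[g][w][1] >= 5 for g in wins)
        ]
        ok = [
            w for w in inside
            if wins["middle"][w][0] > wins["left"][w][0] > wins["right"][w][0]
        ]
        assert len(ok) / len(inside) >= 0.95

    def test_outside_interval_groups_agree(self, block_and_table):
        cfg, ds, truth, table, block = block_and_table
        label_to_cluster = {"STD/STD": "left", "STD/INV": "middle",
                            "INV/INV": "right"}
        assigns = [
            karyotype.KaryotypeAssignment(ind, 0.0, label_to_cluster[k], k)
            for ind, k in zip(ds.individuals, truth.karyotype)
        ]
        profiles = karyotype.hobs_profiles(ds, assigns, cfg.chrom,
                                           site_table=table)
        means = {
            g: np.mean(
                profiles[g].snp_hobs[
                    (profiles[g].snp_pos <= truth.inversion_interval[0])
                    | (profiles[g].snp_pos > truth.inversion_interval[1])
                ]
            )
            for g in profiles
        }
        vals = list(means.values())
        assert max(vals) - min(vals) <= 0.05


class TestOrientAndRefine:
    def _profiles_from_truth(self, cfg, ds, truth, table):
        label_to_cluster = {"STD/STD": "left", "STD/INV": "middle",
                            "INV/INV": "right"}
        assigns = [
            karyotype.KaryotypeAssignment(ind, 0.0, label_to_cluster[k], k)
            for ind, k in zip(ds.individuals, truth.karyotype)
        ]
        profiles = karyotype.hobs_profiles(ds, assigns, cfg.chrom,
                                           site_table=table)
        return assigns, profiles

    def test_lower_hobs_side_is_inverted(self, block_and_table):
        cfg, ds, truth, table, block = block_and_table
        assigns, profiles = self._profiles_from_truth(cfg, ds, truth, table)
        refined, new_assigns, means = karyotype.orient_and_refine(
            block, profiles, assigns
        )
        assert refined.oriented
        assert refined.orientation == "right"  # truth INV/INV mapped to right
        label_of = {a.individual: a.label for a in new_assigns}
        truth_of = dict(zip(ds.individuals, truth.karyotype))
        acc = np.mean([label_of[i] == truth_of[i] for i in ds.individuals])
        assert acc == 1.0

    def test_refined_interval_matches_truth(self, block_and_table):
        cfg, ds, truth, table, _block = block_and_table
        assigns, profiles = self._profiles_from_truth(cfg, ds, truth, table)
        # seed from a deliberately sloppy LD interval
        sloppy = ld_blocks.HaploblockRegion(
            cfg.chrom, truth.inversion_interval[0] - 500_000,
            truth.inversion_interval[1] + 500_000,
        )
        refined, _a, _m = karyotype.orient_and_refine(sloppy, profiles, assigns)
        assert refined.refined
        from haploscan.gtio import RegionRecord

        tr = RegionRecord(cfg.chrom, *truth.inversion_interval)
        assert refined.region.jaccard(tr) >= 0.8

    def test_equal_means_ambiguous(self):
        rng = np.random.default_rng(4)
        window_start = np.arange(0, 200_000, 10_000)
        prof = {}
        for g in ("left", "middle", "right"):
            prof[g] = karyotype.HobsProfile(
                group=g, window=10_000, window_start=window_start,
                mean_hobs=np.full(window_start.size, 0.3),
                n_snps=np.full(window_start.size, 10),
                snp_pos=np.arange(1, 201) * 1000,
                snp_hobs=np.full(200, 0.3),
            )
        block = ld_blocks.HaploblockRegion("chr1", 50_000, 150_000)
        out, _a, _m = karyotype.orient_and_refine(block, prof, None)
        assert out.orientation == "ambiguous" and not out.refined

    def test_orientation_stable_across_window_sizes(self, block_and_table):
        cfg, ds, truth, table, block = block_and_table
        label_to_cluster = {"STD/STD": "left", "STD/INV": "middle",
                            "INV/INV": "right"}
        assigns = [
            karyotype.KaryotypeAssignment(ind, 0.0, label_to_cluster[k], k)
            for ind, k in zip(ds.individuals, truth.karyotype)
        ]
        orientations = []
        for w in (5_000, 10_000, 20_000):
            profiles = karyotype.hobs_profiles(
                ds, assigns, cfg.chrom, site_table=table, window=w
            )
            out, _a, _m = karyotype.orient_and_refine(block, profiles, assigns)
            orientations.append(out.orientation)
        assert orientations == ["right"] * 3
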