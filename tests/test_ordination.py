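import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from milletmyco.io import CountTable, SampleMetadata
from milletmyco.ordination import (
    DistanceMatrix,
    betadisper,
    bh_fdr,
    bray_curtis,
    envfit,
    kruskal_stress,
    nmds,
    permanova,
)

RSCRIPT = shutil.which("Rscript")


def _dist(points):
    return DistanceMatrix(
        [f"s{i}" for i in range(len(points))], squareform(pdist(np.asarray(points, float)))
    )


def _table(counts):
    arr = np.asarray(counts)
    return CountTable(
        pd.DataFrame(arr, index=[f"O{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])])
    )


def _meta(table, **cols):
    base = {"site": "S1", "plant_type": "wild", "plot": "P1"}
    base.update(cols)
    return SampleMetadata(pd.DataFrame(base, index=table.sample_ids))


class TestBrayCurtis:
    def test_identity_zero(self):
        t = _table([[3, 3], [7, 7]])
        assert bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = _table([[5, 0], [0, 9]])
        assert bray_curtis(t).values[0, 1] == 1.0

    def test_closed_form_half(self):
        t = _table(np.array([[1, 0], [1, 1], [0, 1]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)

    def test_all_zero_sample_errors(self):
        t = _table([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(t)

    def test_symmetry_and_range_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = _table(rng.integers(0, 50, size=(8, 6)) + (rng.random((8, 6)) < 0.1))
            d = bray_curtis(t).values
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= 0).all() and (d <= 1).all()


class TestNMDS:
    def test_planar_points_near_zero_stress(self):
        rng = np.random.default_rng(1)
        d = _dist(rng.random((5, 2)))
        out = nmds(d, n_restarts=10, seed=0)
        assert out.stress < 0.01

    def test_duplicate_samples_coincident_scores(self):
        pts = np.array([[0, 0], [0, 0], [1, 0], [0.2, 0.9], [0.8, 0.7]])
        out = nmds(_dist(pts), n_restarts=10, seed=0)
        s = out.scores.to_numpy()
        span = np.abs(s).max()
        assert np.linalg.norm(s[0] - s[1]) < 0.05 * span

    def test_stress_decreases_with_embedding_dimension(self):
        rng = np.random.default_rng(2)
        d = _dist(rng.random((8, 5)))
        s2 = nmds(d, k=2, n_restarts=8, seed=0).stress
        s7 = nmds(d, k=7, n_restarts=8, seed=0).stress
        assert s7 < s2

    @pytest.mark.skipif(RSCRIPT is None, reason="Rscript not available")
    def test_stress_matches_vegan_metamds(self, tmp_path):
        """Independent oracle: vegan's metaMDS on the same distances
        reaches a comparable Kruskal stress-1 (within 0.02)."""
        rng = np.random.default_rng(7)
        pts = rng.random((10, 4))
        d = _dist(pts)
        out = nmds(d, n_restarts=20, seed=0)
        np.savetxt(tmp_path / "d.csv", d.values, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- as.dist(as.matrix(read.csv('{tmp_path}/d.csv', header=FALSE)))
            fit <- metaMDS(d, k=2, trymax=20, trace=0)
            cat(fit$stress)
        """)
        r = subprocess.run([RSCRIPT, "-e", script], capture_output=True, text=True, check=True)
        vegan_stress = float(r.stdout.strip())
        assert abs(out.stress - vegan_stress) < 0.02


class TestPermanova:
    def _design60(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 60, size=(40, 60)))
        sites = np.repeat(["S1", "S2", "S3"], 20)
        pts = np.tile(np.repeat(["cultivated", "wild"], 10), 3)
        meta = SampleMetadata(
            pd.DataFrame({"site": sites, "plant_type": pts, "plot": "P1"}, index=t.sample_ids)
        )
        return t, meta

    def test_degrees_of_freedom_3x2_design(self):
        t, meta = self._design60()
        res = permanova(bray_curtis(t), meta, n_perm=9, seed=0)
        assert res.table["df"].to_dict() == {
            "site": 2, "plant_type": 1, "site:plant_type": 2,
            "Residuals": 54, "Total": 59,
        }

    def test_r2_sums_to_one_and_reorder_invariant(self):
        t, meta = self._design60()
        d = bray_curtis(t)
        res = permanova(d, meta, n_perm=9, seed=0)
        terms = ["site", "plant_type", "site:plant_type", "Residuals"]
        assert res.table.loc[terms, "R2"].sum() == pytest.approx(1.0)
        # shuffle sample order
        order = np.random.default_rng(1).permutation(60)
        ids = [d.sample_ids[i] for i in order]
        d2 = DistanceMatrix(ids, d.values[np.ix_(order, order)])
        res2 = permanova(d2, meta, n_perm=9, seed=0)
        assert np.allclose(res.table["SS"], res2.table["SS"])

    def test_p_within_theoretical_bounds(self):
        t, meta = self._design60()
        res = permanova(bray_curtis(t), meta, n_perm=99, seed=0)
        p = res.table["p"].dropna()
        assert ((p >= 1 / 100) & (p <= 1)).all()

    def test_single_level_term_errors(self):
        t, meta = self._design60()
        with pytest.raises(ValueError, match="single level"):
            permanova(bray_curtis(t), meta, terms=("plot",), n_perm=9)

    def test_exact_p_matches_enumeration_oracle(self):
        """On a 6-sample, 2-group toy the permutation p over the full
        enumeration equals an independently computed exact p (one-way
        pseudo-F from within/between distance sums)."""
        rng = np.random.default_rng(5)
        t = _table(rng.integers(1, 40, size=(12, 6)))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        meta = SampleMetadata(
            pd.DataFrame({"site": "S", "plant_type": "wild", "plot": "P", "grp": groups},
                         index=t.sample_ids)
        )
        d = bray_curtis(t)

        # independent oracle: classic distance-based one-way F
        def oracle_F(dm, lab):
            n = len(lab)
            tot = (dm ** 2)[np.triu_indices(n, 1)].sum() / n
            within = 0.0
            for g in np.unique(lab):
                idx = np.where(lab == g)[0]
                sub = dm[np.ix_(idx, idx)]
                within += (sub ** 2)[np.triu_indices(len(idx), 1)].sum() / len(idx)
            between = tot - within
            return (between / 1) / (within / (n - 2))

        perms = [np.array(p) for p in itertools.permutations(range(6))]
        F_obs = oracle_F(d.values, groups)
        count = sum(
            oracle_F(d.values[np.ix_(p, p)], groups) >= F_obs - 1e-12 for p in perms
        )
        p_oracle = count / len(perms)

        res = permanova(d, meta, terms=("grp",), permutations=perms)
        assert res.table.loc["grp", "p"] == pytest.approx(p_oracle, abs=1e-12)

    @pytest.mark.skipif(RSCRIPT is None, reason="Rscript not available")
    def test_partition_matches_vegan_adonis2(self, tmp_path):
        """SS, F and R2 of the sequential partition equal vegan adonis2."""
        rng = np.random.default_rng(42)
        t = _table(rng.poisson(20, (25, 18)))
        sites = np.repeat(["A", "B", "C"], 6)
        pts = np.tile(["cultivated", "wild"], 9)
        meta = SampleMetadata(
            pd.DataFrame({"site": sites, "plant_type": pts, "plot": "P"}, index=t.sample_ids)
        )
        res = permanova(bray_curtis(t), meta, n_perm=9, seed=0)
        t.counts.T.to_csv(tmp_path / "x.csv")
        pd.DataFrame({"site": sites, "pt": pts}).to_csv(tmp_path / "m.csv", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv('{tmp_path}/x.csv', row.names=1))
            m <- read.csv('{tmp_path}/m.csv')
            a <- adonis2(vegdist(x,'bray') ~ site * pt, data=m, permutations=2, by='terms')
            write.csv(data.frame(SS=a$SumOfSqs, R2=a$R2, F=a$F), '{tmp_path}/out.csv')
        """)
        subprocess.run([RSCRIPT, "-e", script], capture_output=True, text=True, check=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        assert np.allclose(res.table["SS"].iloc[:4], ref["SS"].iloc[:4], atol=1e-8)
        assert np.allclose(res.table["R2"].iloc[:4], ref["R2"].iloc[:4], atol=1e-8)
        assert np.allclose(res.table["F"].iloc[:3], ref["F"].iloc[:3], atol=1e-8)


class TestBetadisper:
    def test_mirror_image_groups_equal_dispersion(self):
        pts = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
        mirror = -pts + 10
        d = _dist(np.vstack([pts, mirror]))
        res = betadisper(d, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"], abs=1e-9)
        assert res.p > 0.5

    def test_all_identical_samples_zero_distances(self):
        d = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        res = betadisper(d, ["g1", "g1", "g2", "g2"], n_perm=19, seed=0)
        assert np.allclose(res.distances, 0)

    def test_size_one_group_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        d = _dist(rng.random((7, 3)))
        with caplog.at_level("WARNING"):
            res = betadisper(d, ["a", "a", "a", "b", "b", "b", "c"], n_perm=19, seed=0)
        assert "c" in caplog.text

    def test_power_against_doubled_dispersion(self):
        """A group with doubled within-group spread is flagged at
        alpha=0.05 in >= 90% of simulated datasets."""
        rej = 0
        for rep in range(100):
            rng = np.random.default_rng(700 + rep)
            a = rng.normal(0, 1, (10, 3))
            b = rng.normal(0, 3, (10, 3))
            d = _dist(np.vstack([a, b]))
            res = betadisper(d, ["a"] * 10 + ["b"] * 10, n_perm=99, seed=rng)
            rej += res.p <= 0.05
        assert rej >= 90


class TestEnvfit:
    def _ordination(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(
            rng.normal(size=(n, 2)), columns=["NMDS1", "NMDS2"],
            index=[f"s{i}" for i in range(n)],
        )
        from milletmyco.ordination import Ordination

        return Ordination(scores=scores, stress=0.1, converged=True, n_restarts_used=1)

    def _meta(self, ord_, **soil):
        df = pd.DataFrame(
            {"site": "S", "plant_type": "wild", "plot": "P", **soil},
            index=ord_.scores.index,
        )
        return SampleMetadata(df)

    def test_variable_equal_to_axis1(self):
        ord_ = self._ordination()
        meta = self._meta(ord_, total_P=ord_.scores["NMDS1"].to_numpy())
        res = envfit(ord_, meta, n_perm=99, seed=0)
        assert res.loc["total_P", "r2"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc["total_P", "NMDS1"] == pytest.approx(1.0, abs=1e-9)
        assert abs(res.loc["total_P", "NMDS2"]) < 1e-9

    def test_negated_axis2_direction(self):
        ord_ = self._ordination(seed=1)
        meta = self._meta(ord_, pH_H2O=-ord_.scores["NMDS2"].to_numpy())
        res = envfit(ord_, meta, n_perm=99, seed=0)
        assert res.loc["pH_H2O", "r2"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc["pH_H2O", "NMDS2"] == pytest.approx(-1.0, abs=1e-9)

    def test_constant_variable_r2_zero(self, caplog):
        ord_ = self._ordination(seed=2)
        meta = self._meta(ord_, NO3=np.full(20, 5.0))
        with caplog.at_level("WARNING"):
            res = envfit(ord_, meta, n_perm=99, seed=0)
        assert res.loc["NO3", "r2"] == 0.0
        assert res.loc["NO3", "p"] == 1.0

    def test_null_p_values_uniform(self):
        """Independent variable: permutation p-values are uniform (KS test
        not rejected at alpha=0.01 over simulated nulls)."""
        ps = []
        for rep in range(300):
            rng = np.random.default_rng(900 + rep)
            ord_ = self._ordination(seed=900 + rep)
            meta = self._meta(ord_, NH4=rng.normal(size=20))
            ps.append(envfit(ord_, meta, variables=["NH4"], n_perm=199, seed=rng).loc["NH4", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_step_up_hand_computation(self):
        # step-up: p*(m/rank) then cumulative min from the largest
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
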