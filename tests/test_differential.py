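"""Beta-binomial Wald DML testing, BH adjustment and DMR merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rremtools import differential as diff

from conftest import betabin_replicates


def _records(pos, is_dml, direction, contig="c"):
    n = len(pos)
    return pd.DataFrame({
        "contig": contig, "pos": pos, "is_dml": is_dml,
        "direction": direction,
        "diff": [0.3 if d == "hyper" else -0.3 for d in direction],
        "wald_stat": [4.0 if d == "hyper" else -4.0 for d in direction],
    })


class TestWald:
    def test_identical_groups_null(self):
        m = np.array([[5.0, 6.0, 7.0]])
        d = np.array([[20.0, 20.0, 20.0]])
        res = diff.wald_test(m, d, m, d, np.array([0.0]))
        assert res["diff"].iloc[0] == 0
        assert res["wald_stat"].iloc[0] == 0
        assert res["p_value"].iloc[0] == 1

    def test_matches_two_proportion_z(self):
        # phi = 0, one large replicate per group -> classical unpooled z
        m1, d1 = np.array([[300.0]]), np.array([[1000.0]])
        m2, d2 = np.array([[260.0]]), np.array([[1000.0]])
        res = diff.wald_test(m1, d1, m2, d2, np.array([0.0]))
        p1, p2 = 0.3, 0.26
        z = (p1 - p2) / np.sqrt(p1 * (1 - p1) / 1000 + p2 * (1 - p2) / 1000)
        assert res["wald_stat"].iloc[0] == pytest.approx(z, abs=1e-6)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        m1 = rng.binomial(30, 0.5, (50, 3)).astype(float)
        m2 = rng.binomial(30, 0.3, (50, 3)).astype(float)
        d = np.full((50, 3), 30.0)
        phi = np.full(50, 0.01)
        a = diff.wald_test(m1, d, m2, d, phi)
        b = diff.wald_test(m2, d, m1, d, phi)
        np.testing.assert_allclose(a["diff"], -b["diff"])
        np.testing.assert_allclose(a["wald_stat"], -b["wald_stat"])
        np.testing.assert_allclose(a["p_value"], b["p_value"])

    def test_boundary_proportions_have_positive_variance(self):
        m1 = np.array([[0.0, 0.0]])
        m2 = np.array([[20.0, 20.0]])
        d = np.array([[20.0, 20.0]])
        res = diff.wald_test(m1, d, m2, d, np.array([0.0]))
        assert np.isfinite(res["wald_stat"].iloc[0])
        assert res["se"].iloc[0] > 0


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(diff.bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_and_ties(self):
        assert diff.bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(diff.bh_adjust([0.3, 0.3, 0.3]),
                                   [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_order_invariance_and_cap(self, ps):
        adj = diff.bh_adjust(ps)
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = diff.bh_adjust(np.asarray(ps)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])


class TestDispersion:
    def test_zero_variance_shrinks_to_prior(self):
        # identical replicate proportions -> site estimate 0
        m = np.tile(np.array([[10.0, 10.0, 10.0]]), (20, 1))
        d = np.full((20, 3), 20.0)
        phi = diff.estimate_dispersion(m, d, m, d, k=10.0)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_k_zero_pure_site_estimate(self):
        rng = np.random.default_rng(4)
        reps = betabin_replicates(rng, np.full(500, 0.5), 50, 3, phi=0.05)
        reps2 = betabin_replicates(rng, np.full(500, 0.5), 50, 3, phi=0.05)
        def mats(rs):
            return (np.stack([r["n_modified"].to_numpy(float) for r in rs], 1),
                    np.stack([r["depth"].to_numpy(float) for r in rs], 1))
        m1, d1 = mats(reps)
        m2, d2 = mats(reps2)
        phi0 = diff.estimate_dispersion(m1, d1, m2, d2, k=0.0)
        phi10 = diff.estimate_dispersion(m1, d1, m2, d2, k=10.0)
        assert phi0.std() > phi10.std()  # shrinkage stabilizes

    def test_recovers_simulated_dispersion(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 2000)
        def mats(rs):
            return (np.stack([r["n_modified"].to_numpy(float) for r in rs], 1),
                    np.stack([r["depth"].to_numpy(float) for r in rs], 1))
        m1, d1 = mats(betabin_replicates(rng, p, 50, 3, phi=0.02))
        m2, d2 = mats(betabin_replicates(rng, p, 50, 3, phi=0.02))
        phi = diff.estimate_dispersion(m1, d1, m2, d2, k=10.0)
        assert abs(np.median(phi) - 0.02) <= 0.3 * 0.02


class TestCallDML:
    def test_boundary_inclusive(self):
        rec = pd.DataFrame({"p_value": [0.05, 0.051], "diff": [0.10, 0.3],
                            "mu1": 0.5, "mu2": 0.4, "se": 0.01,
                            "wald_stat": 3.0})
        # feed pre-adjusted values through a 2-test BH (identical ps stay put)
        rec1 = rec.iloc[[0]].copy()
        out, counts = diff.call_dml(rec1)
        assert bool(out["is_dml"].iloc[0])  # fdr == 0.05, diff == 0.10
        assert counts == {"hyper": 1, "hypo": 0}
        rec2 = rec.iloc[[1]].copy()
        out, _ = diff.call_dml(rec2)
        assert not bool(out["is_dml"].iloc[0])  # fdr 0.051 > 0.05

    def test_direction_counts(self):
        rec = pd.DataFrame({"p_value": [1e-8, 1e-8, 0.9],
                            "diff": [0.2, -0.2, 0.0],
                            "mu1": 0, "mu2": 0, "se": 1, "wald_stat": 0})
        _, counts = diff.call_dml(rec)
        assert counts == {"hyper": 1, "hypo": 1}


def brute_force_dmr(records: pd.DataFrame, config: diff.TestConfig) -> list[tuple]:
    """Exhaustive interval enumerator over significant loci.

    Emits every maximal run of same-direction significant loci with
    consecutive gaps <= merge_gap that passes the size, count and
    significant-fraction thresholds.  Independent of the greedy scan.
    """
    out = []
    for contig, sub in records.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy()
        sig = sub[sub["is_dml"]].reset_index(drop=True)
        n = len(sig)

        def valid(i, j):
            d = sig["direction"].iloc[i:j + 1]
            if d.nunique() > 1:
                return False
            p = sig["pos"].iloc[i:j + 1].to_numpy()
            return (np.diff(p) <= config.dmr_merge_gap).all()

        for i in range(n):
            for j in range(i, n):
                if not valid(i, j):
                    continue
                if i > 0 and valid(i - 1, j):
                    continue  # extendable left
                if j < n - 1 and valid(i, j + 1):
                    continue  # extendable right
                start = int(sig["pos"].iloc[i])
                end = int(sig["pos"].iloc[j]) + 1
                members = j - i + 1
                tested = int(((pos >= start) & (pos < end)).sum())
                if (end - start >= config.dmr_min_length
                        and members >= config.dmr_min_cpgs
                        and members / tested >= config.dmr_min_sig_fraction):
                    out.append((contig, start, end, members))
    return sorted(out)


class TestCallDMR:
    def test_no_significant_loci(self):
        rec = _records([0, 50, 100], [False] * 3, ["hyper"] * 3)
        assert diff.call_dmr(rec).empty

    def test_hand_merge(self):
        rec = _records([0, 40, 80], [True] * 3, ["hyper"] * 3)
        out = diff.call_dmr(rec)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["n_cpgs"]) == (0, 81, 3)
        assert row["direction"] == "hyper"
        assert row["area_stat"] == pytest.approx(12.0)

    def test_distant_loci_do_not_merge(self):
        rec = _records([0, 500], [True, True], ["hyper", "hyper"])
        assert diff.call_dmr(rec).empty

    def test_direction_change_breaks_run(self):
        rec = _records([0, 40, 80, 120, 160, 200], [True] * 6,
                       ["hyper"] * 3 + ["hypo"] * 3)
        out = diff.call_dmr(rec)
        assert len(out) == 2
        assert out["direction"].tolist() == ["hyper", "hypo"]

    def test_sig_fraction_threshold(self):
        # 3 significant of 7 tested inside the span -> fraction < 0.5
        pos = [0, 20, 40, 60, 80, 100, 120]
        is_dml = [True, False, False, True, False, False, True]
        rec = _records(pos, is_dml, ["hyper"] * 7)
        assert diff.call_dmr(rec).empty

    def test_unsorted_rejected(self):
        rec = _records([100, 0], [True, True], ["hyper", "hyper"])
        with pytest.raises(ValueError, match="sorted"):
            diff.call_dmr(rec)

    def test_matches_brute_force_enumeration(self):
        config = diff.TestConfig()
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 31))
            pos = np.sort(rng.choice(2000, size=n, replace=False))
            rec = pd.DataFrame({
                "contig": "c", "pos": pos,
                "is_dml": rng.random(n) < 0.6,
                "direction": np.where(rng.random(n) < 0.7, "hyper", "hypo"),
                "diff": rng.uniform(-0.5, 0.5, n),
                "wald_stat": rng.normal(0, 3, n),
            })
            got = sorted((r.contig, r.start, r.end, r.n_cpgs)
                         for r in diff.call_dmr(rec, config).itertuples())
            assert got == brute_force_dmr(rec, config), f"seed {seed}"


class TestEndToEnd:
    def test_null_has_few_calls(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.2, 0.8, 2000)
        g1 = betabin_replicates(rng, p, 30, 3, phi=0.01)
        g2 = betabin_replicates(rng, p, 30, 3, phi=0.01)
        res, counts = diff.dml_test(g1, g2)
        assert len(res) == 2000
        assert counts["hyper"] + counts["hypo"] <= 3

    def test_effect_recovery_direction(self):
        rng = np.random.default_rng(11)
        p1 = np.full(300, 0.5)
        p2 = np.full(300, 0.2)
        g1 = betabin_replicates(rng, p1, 40, 3, phi=0.005)
        g2 = betabin_replicates(rng, p2, 40, 3, phi=0.005)
        res, counts = diff.dml_test(g1, g2)
        assert counts["hyper"] >= 0.7 * 300
        assert counts["hypo"] == 0
        assert res["diff"].mean() == pytest.approx(0.3, abs=0.05)

    def test_sites_missing_in_one_group_dropped(self):
        g1 = [pd.DataFrame({"contig": "c", "pos": [0, 50],
                            "n_modified": [5, 5], "n_unmodified": [5, 5],
                            "depth": [10, 10]})]
        g2 = [pd.DataFrame({"contig": "c", "pos": [50],
                            "n_modified": [5], "n_unmodified": [5],
                            "depth": [10]})]
        res, _ = diff.dml_test(g1, g2)
        assert res["pos"].tolist() == [50]
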