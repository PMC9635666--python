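"""Two-locus Monte-Carlo lookup tables: folding, conditioning, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhoflow.twolocus import (
    LookupTable,
    TableSparsityError,
    build_lookup_table,
    config_r2,
    default_rho_grid,
    enumerate_folded_configs,
    fold_config,
    simulate_two_locus,
)


@st.composite
def configs(draw, n=12):
    c11 = draw(st.integers(0, n))
    c10 = draw(st.integers(0, n - c11))
    c01 = draw(st.integers(0, n - c11 - c10))
    return (c11, c10, c01, n - c11 - c10 - c01)


class TestFolding:
    @given(configs())
    @settings(max_examples=200, deadline=None)
    def test_fold_is_invariant_over_symmetry_orbit(self, cfg):
        c11, c10, c01, c00 = cfg
        images = [
            (c11, c10, c01, c00),
            (c01, c00, c11, c10),
            (c10, c11, c00, c01),
            (c00, c01, c10, c11),
            (c11, c01, c10, c00),
        ]
        folded = {fold_config(i) for i in images}
        assert len(folded) == 1

    @given(configs())
    @settings(max_examples=100, deadline=None)
    def test_r2_invariant_under_folding(self, cfg):
        n = sum(cfg)
        pa = (cfg[0] + cfg[1]) / n
        pb = (cfg[0] + cfg[2]) / n
        if min(pa, 1 - pa) == 0 or min(pb, 1 - pb) == 0:
            return
        assert config_r2(cfg, n) == pytest.approx(config_r2(fold_config(cfg), n))

    def test_enumeration_covers_folded_space(self):
        cfgs = enumerate_folded_configs(6)
        assert all(sum(c) == 6 for c in cfgs)
        assert all(1 <= c[0] + c[1] <= 5 and 1 <= c[0] + c[2] <= 5 for c in cfgs)
        assert all(fold_config(c) == c for c in cfgs)
        assert len(set(cfgs)) == len(cfgs)


class TestTableBuild:
    def test_columns_normalized_and_grid_validated(self, tiny_table):
        assert np.allclose(tiny_table.P.sum(axis=0), 1.0)
        with pytest.raises(ValueError):
            build_lookup_table(10, 0.04, [0.1, 1.0], [(0.0, 1.0)], 100, 1)
        with pytest.raises(ValueError):
            build_lookup_table(9, 0.04, [0.0, 1.0], [(0.0, 1.0)], 100, 1)

    def test_expected_r2_decreases_in_rho(self, tiny_table):
        er2 = tiny_table.expected_r2()
        # allow small MC wiggle but demand a clear overall decay
        assert er2[0] > er2[-1] * 2
        assert np.all(np.diff(er2) < 0.03)

    def test_deterministic_given_seed(self):
        kw = dict(rho_grid=[0.0, 1.0, 10.0], size_history=[(0.0, 1.0)])
        a = build_lookup_table(8, 0.04, mc_replicates=500, seed=5, **kw)
        b = build_lookup_table(8, 0.04, mc_replicates=500, seed=5, **kw)
        assert np.array_equal(a.P, b.P)

    def test_save_load_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "table.tsv"
        tiny_table.save(path)
        back = LookupTable.load(path)
        assert np.allclose(back.P, tiny_table.P)
        assert np.allclose(back.var_P, tiny_table.var_P)
        assert back.configs == tiny_table.configs
        assert np.allclose(back.rho_grid, tiny_table.rho_grid)
        assert back.size_history == tiny_table.size_history

    def test_sparsity_error_in_rejection_mode(self):
        with pytest.raises(TableSparsityError):
            build_lookup_table(
                10, 0.04, [0.0, 1.0], [(0.0, 1.0)], 400, 3,
                mode="rejection", theta_locus=1e-6,
            )

    def test_rejection_mode_agrees_with_conditional(self):
        """Finite-theta rejection sampling converges to the small-theta
        conditional scheme (theta_locus = 0.2 is small enough)."""
        kw = dict(rho_grid=[0.0, 5.0], size_history=[(0.0, 1.0)])
        cond = build_lookup_table(6, 0.04, mc_replicates=4000, seed=11, **kw)
        rej = build_lookup_table(
            6, 0.04, mc_replicates=120_000, seed=12, mode="rejection",
            theta_locus=0.2, **kw
        )
        for g in range(2):
            tv = 0.5 * np.abs(cond.P[:, g] - rej.P[:, g]).sum()
            assert tv < 0.08


class TestAgainstOracles:
    def test_marginal_spectrum_is_neutral_sfs(self):
        """Weighting one locus by its own branch length recovers the 1/i
        neutral site-frequency spectrum."""
        n = 8
        rng = np.random.default_rng(21)
        w = np.zeros(n)
        for _ in range(6000):
            da, db, ta, tb = simulate_two_locus(n, 0.5, [(0.0, 1.0)], rng)
            w[da.bit_count() - 1] += ta
        obs = w[: n - 1] / w.sum()
        exp = (1 / np.arange(1, n)) / (1 / np.arange(1, n)).sum()
        assert np.max(np.abs(obs - exp) / exp) < 0.12

    def test_fully_linked_matches_shared_tree_oracle(self):
        """rho = 0: both loci share one genealogy.  An independent plain
        Kingman simulation with two branch-weighted mutations must give the
        same expected r^2."""
        n = 10
        rng = np.random.default_rng(31)

        def kingman_two_mutations():
            # simple coalescent: merge random pairs at exponential times
            lineages = [(1 << i) for i in range(n)]
            birth = [0.0] * n
            t = 0.0
            seg_masks: list[int] = []
            seg_lens: list[float] = []
            while len(lineages) > 1:
                k = len(lineages)
                t += rng.exponential(2.0 / (k * (k - 1)))
                i, j = rng.choice(k, 2, replace=False)
                for x in (i, j):
                    seg_masks.append(lineages[x])
                    seg_lens.append(t - birth[x])
                merged = lineages[i] | lineages[j]
                lineages = [lineages[x] for x in range(k) if x not in (i, j)] + [merged]
                birth = [birth[x] for x in range(k) if x not in (i, j)] + [t]
            masks = np.array(seg_masks)
            lens = np.array(seg_lens)
            probs = lens / lens.sum()
            ia, ib = rng.choice(len(masks), 2, p=probs, replace=True)
            w = lens.sum() ** 2
            return int(masks[ia]), int(masks[ib]), w

        tot_w = 0.0
        acc = 0.0
        for _ in range(8000):
            da, db, w = kingman_two_mutations()
            c11 = (da & db).bit_count()
            ca, cb = da.bit_count(), db.bit_count()
            cfg = (c11, ca - c11, cb - c11, n - ca - cb + c11)
            acc += w * config_r2(cfg, n)
            tot_w += w
        oracle_r2 = acc / tot_w

        tab = build_lookup_table(
            n, 0.04, [0.0, 0.5], [(0.0, 1.0)], 4000, 55
        )
        assert tab.expected_r2()[0] == pytest.approx(oracle_r2, rel=0.08)

    def test_config_distribution_matches_msprime(self):
        """Cross-validation against msprime genealogies with exact edge-pair
        enumeration, at rho = 0 and a moderate rho."""
        import msprime

        n = 8
        grid = np.array([0.0, 5.0])
        tab = build_lookup_table(n, 0.04, grid, [(0.0, 1.0)], 4000, 66)
        cfgs = enumerate_folded_configs(n)
        index = {c: i for i, c in enumerate(cfgs)}

        def masks_lens(tree):
            masks, mk, lens = {}, [], []
            for u in tree.nodes(order="postorder"):
                if tree.is_leaf(u):
                    masks[u] = 1 << u
                else:
                    mm = 0
                    for ch in tree.children(u):
                        mm |= masks[ch]
                    masks[u] = mm
                if tree.parent(u) != -1 and masks[u] != (1 << n) - 1:
                    mk.append(masks[u])
                    lens.append(tree.branch_length(u))
            return np.array(mk, dtype=np.uint64), np.array(lens)

        for gi, rho in enumerate(grid):
            N = 1000
            rm = msprime.RateMap(position=[0, 1, 2], rate=[0.0, rho / (4 * N)])
            reps = msprime.sim_ancestry(
                samples=n // 2, population_size=N, sequence_length=2,
                recombination_rate=rm, random_seed=500 + gi,
                num_replicates=4000, discrete_genome=True, ploidy=2,
            )
            P = np.zeros(len(cfgs))
            for ts in reps:
                ma, la = masks_lens(ts.first())
                mb, lb = masks_lens(ts.last())
                c11 = np.bitwise_count(ma[:, None] & mb[None, :]).astype(int)
                ca = np.bitwise_count(ma).astype(int)[:, None] + 0 * c11
                cb = np.bitwise_count(mb).astype(int)[None, :] + 0 * c11
                w = la[:, None] * lb[None, :]
                for cc, aa, bb, ww in zip(
                    c11.ravel(), ca.ravel(), cb.ravel(), w.ravel()
                ):
                    P[index[fold_config((cc, aa - cc, bb - cc, n - aa - bb + cc))]] += ww
            P /= P.sum()
            tv = 0.5 * np.abs(tab.P[:, gi] - P).sum()
            assert tv < 0.06, f"rho={rho}: TV={tv:.3f}"

    def test_two_epoch_history_changes_table(self):
        const = build_lookup_table(8, 0.04, [0.0, 2.0], [(0.0, 1.0)], 3000, 9)
        grown = build_lookup_table(
            8, 0.04, [0.0, 2.0], [(0.0, 1.0), (0.5, 4.0)], 3000, 9
        )
        tv = 0.5 * np.abs(const.P[:, 1] - grown.P[:, 1]).sum()
        assert tv > 0.05
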