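"""Transfer entropy estimator and its local E/I decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from localte.calcium import BinaryRaster
from localte.te import (
    TEConfig,
    embed_states,
    local_te_split,
    select_roi,
    te_matrix,
    te_matrix_sweep,
    transfer_entropy,
)


def naive_te(x, y, k_x=1, k_y=1, d=1):
    """Independent oracle: plug-in TE from explicit probability tables."""
    n_min = max(k_x, d + k_y - 1)
    tuples = []
    for n in range(n_min, len(x)):
        xp = tuple(x[n - m] for m in range(1, k_x + 1))
        yp = tuple(y[n - d - m] for m in range(k_y))
        tuples.append((x[n], xp, yp))
    total = len(tuples)
    from collections import Counter

    joint = Counter(tuples)
    c_xpyp = Counter((xp, yp) for _, xp, yp in tuples)
    c_xpxn = Counter((xn, xp) for xn, xp, _ in tuples)
    c_xp = Counter(xp for _, xp, _ in tuples)
    te = 0.0
    for (xn, xp, yp), c in joint.items():
        p = c / total
        p_cond_full = c / c_xpyp[(xp, yp)]
        p_cond_x = c_xpxn[(xn, xp)] / c_xp[xp]
        te += p * np.log2(p_cond_full / p_cond_x)
    return te


class TestEmbedding:
    def test_index_arithmetic_same_bin(self):
        x = np.arange(10) % 2
        y = (np.arange(10) + 1) % 2
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=0)
        n_idx, x_n, x_past, y_past = embed_states(x, y, cfg)
        i = np.where(n_idx == 5)[0][0]
        assert x_n[i] == x[5]
        assert x_past[i].tolist() == [x[4]]
        assert y_past[i].tolist() == [y[5], y[4]]  # d=0 includes same-bin value

    def test_index_arithmetic_delayed(self):
        rng = np.random.default_rng(0)
        x, y = rng.integers(0, 2, 12), rng.integers(0, 2, 12)
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=2)
        n_idx, x_n, x_past, y_past = embed_states(x, y, cfg)
        i = np.where(n_idx == 5)[0][0]
        assert y_past[i].tolist() == [y[3], y[2]]

    def test_valid_tuple_count(self):
        x = np.zeros(10, dtype=int)
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=2)
        n_idx, *_ = embed_states(x, x, cfg)
        assert len(n_idx) == 7  # n = 3..9

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            embed_states(np.zeros(3, int), np.zeros(3, int), TEConfig(k_x=1, k_y=2, delay_bins=2))


class TestTransferEntropy:
    def test_factorized_counts_give_zero(self):
        # y's past carries no information: identical x_n distribution in
        # every (x_past, y_past) block
        x = np.array([0, 1] * 50)
        y = np.zeros(100, dtype=int)
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        assert transfer_entropy(x, y, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_copier_equals_conditional_entropy(self):
        # x copies y with lag 1; x's own past is uninformative by design
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 4000)
        x = np.roll(y, 1)
        x[0] = 0
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        te = transfer_entropy(x, y, cfg)
        # oracle: H(x_n | x_past) from the same empirical counts
        n_idx, x_n, x_past, _ = embed_states(x, y, cfg)
        h = 0.0
        for xp in (0, 1):
            sel = x_past[:, 0] == xp
            p_xp = sel.mean()
            for xn in (0, 1):
                p = (x_n[sel] == xn).mean()
                if p > 0:
                    h -= p_xp * p * np.log2(p)
        assert te == pytest.approx(h, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(25, 200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nonnegative_and_partition_identity(self, seed, t_len):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, t_len)
        y = rng.integers(0, 2, t_len)
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=rng.integers(0, 3))
        total = transfer_entropy(x, y, cfg)
        te_e, te_i = local_te_split(x, y, cfg)
        assert total >= -1e-12
        assert te_e + te_i == pytest.approx(total, abs=1e-12)

    def test_matches_bruteforce_oracle_exhaustively(self):
        # every toy series pair at T=6, k=1, d=1 against the table oracle
        t_len = 6
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        for xi in range(2**t_len):
            x = np.array([(xi >> b) & 1 for b in range(t_len)])
            for yi in range(2**t_len):
                y = np.array([(yi >> b) & 1 for b in range(t_len)])
                assert transfer_entropy(x, y, cfg) == pytest.approx(
                    naive_te(x, y), abs=1e-12
                )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle_random_length20(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.integers(0, 2, 20), rng.integers(0, 2, 20)
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        assert transfer_entropy(x, y, cfg) == pytest.approx(naive_te(x, y), abs=1e-12)

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(3)
        x, y = rng.integers(0, 2, 500), rng.integers(0, 2, 500)
        cfg = TEConfig()
        assert transfer_entropy(1 - x, 1 - y, cfg) == pytest.approx(
            transfer_entropy(x, y, cfg), abs=1e-12
        )

    def test_shuffled_source_below_coupled_value(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 3000)
        x = np.roll(y, 1)
        x[0] = 0
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        coupled = transfer_entropy(x, y, cfg)
        shuffled = np.median(
            [
                transfer_entropy(x, rng.permutation(y), cfg)
                for _ in range(11)
            ]
        )
        assert shuffled < coupled


class TestLocalSplit:
    def test_copier_is_purely_excitatory(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 2000)
        x = np.roll(y, 1)
        x[0] = 0
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        te_e, te_i = local_te_split(x, y, cfg)
        assert te_i == pytest.approx(0.0, abs=1e-12)
        assert te_e == pytest.approx(transfer_entropy(x, y, cfg), abs=1e-12)

    def test_inverter_is_purely_inhibitory(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 2000)
        x = 1 - np.roll(y, 1)
        x[0] = 0
        cfg = TEConfig(k_x=1, k_y=1, delay_bins=1)
        te_e, te_i = local_te_split(x, y, cfg)
        assert te_e == pytest.approx(0.0, abs=1e-12)
        assert te_i == pytest.approx(transfer_entropy(x, y, cfg), abs=1e-12)

    def test_source_activity_uses_any_entry_rule(self):
        # k_y=2: y_past [0,1] counts as active; build a series where x copies
        # "y active in last two bins" and check it routes to E
        rng = np.random.default_rng(9)
        y = (rng.random(3000) < 0.3).astype(int)
        active = np.maximum(y, np.roll(y, 1))
        x = np.roll(active, 1)
        x[:2] = 0
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=1)
        te_e, te_i = local_te_split(x, y, cfg)
        assert te_e > 10 * max(te_i, 1e-6)


class TestROI:
    def test_threshold_above_max_selects_all(self):
        avg = np.array([0.1, 0.9, 0.2, 0.8])
        assert select_roi(avg, 0.9 + 1e-9).sum() == 4
        assert select_roi(avg, "all").all()

    def test_threshold_at_min_selects_none(self):
        avg = np.array([0.1, 0.9, 0.2, 0.8])
        assert select_roi(avg, 0.1).sum() == 0

    def test_mask_by_direct_comparison(self):
        avg = np.array([0.1, 0.9, 0.2, 0.8])
        assert select_roi(avg, 0.5).tolist() == [True, False, True, False]

    def test_roi_gates_tuples_by_current_index_only(self):
        # embedding may reach outside the mask; only n must be selected
        rng = np.random.default_rng(2)
        x, y = rng.integers(0, 2, 400), rng.integers(0, 2, 400)
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=1)
        mask = np.zeros(400, dtype=bool)
        mask[200:] = True  # indices below 200 excluded, but usable as pasts
        te = transfer_entropy(x, y, cfg, roi_mask=mask)
        te_manual = transfer_entropy(x[198:], y[198:], cfg)
        assert te == pytest.approx(te_manual, abs=1e-12)

    def test_empty_selection_raises(self):
        x = np.zeros(50, dtype=int)
        with pytest.raises(ValueError):
            transfer_entropy(x, x, TEConfig(), roi_mask=np.zeros(50, dtype=bool))


class TestTEMatrix:
    def test_copier_pair_asymmetry(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, 3000)
        b = np.roll(a, 1)
        b[0] = 0
        raster = BinaryRaster(np.stack([a, b]).astype(np.int8), 10.0)
        res = te_matrix(raster, TEConfig(k_x=1, k_y=2, delay_bins=1))
        assert res.te_total[1, 0] > 5 * res.te_total[0, 1]

    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(10)
        states = rng.integers(0, 2, (4, 500)).astype(np.int8)
        raster = BinaryRaster(states, 10.0)
        cfg = TEConfig(k_x=1, k_y=2, delay_bins=1)
        res = te_matrix(raster, cfg)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert np.isnan(res.te_total[i, j])
                else:
                    assert res.te_total[i, j] == pytest.approx(
                        transfer_entropy(states[i], states[j], cfg), abs=1e-12
                    )

    def test_independent_te_shrinks_with_length(self):
        rng = np.random.default_rng(12)
        vals = []
        for t_len in (200, 20_000):
            states = rng.integers(0, 2, (2, t_len)).astype(np.int8)
            res = te_matrix(BinaryRaster(states, 10.0), TEConfig())
            vals.append(np.nanmean(res.te_total))
        assert vals[1] < vals[0]

    def test_sweep_levels_match_single_threshold_runs(self):
        rng = np.random.default_rng(13)
        states = (rng.random((3, 800)) < 0.2).astype(np.int8)
        raster = BinaryRaster(states, 10.0)
        avg = rng.random(800)
        thresholds = np.array([0.3, 0.6, 0.9])
        sweep = te_matrix_sweep(raster, 1, 2, 1, avg, thresholds)
        for th, res in zip(thresholds, sweep):
            single = te_matrix(
                raster, TEConfig(k_x=1, k_y=2, delay_bins=1, roi_threshold=th), avg
            )
            assert np.allclose(
                res.te_total, single.te_total, atol=1e-12, equal_nan=True
            )
            assert res.n_samples_used == single.n_samples_used

    def test_partition_identity_at_scale(self, short_simulation):
        from localte.calcium import bin_spikes

        raster = bin_spikes(short_simulation, 10.0)
        res = te_matrix(raster, TEConfig(k_x=1, k_y=2, delay_bins=0))
        off = ~np.eye(raster.n_neurons, dtype=bool)
        assert np.all(res.te_total[off] >= -1e-12)
        assert np.allclose(
            res.te_e[off] + res.te_i[off], res.te_total[off], atol=1e-12
        )
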