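"""Pearson and shrinkage partial-correlation network estimation."""

import numpy as np
import pandas as pd
import pytest

from glyconet.netinfer import (
    build_ggm,
    consensus,
    partial_correlation,
    pcor_significance,
    pearson_network,
)
from glyconet.synth import SimulationConfig, simulate_cohort

COLS10 = [f"IgG1_G{i % 3}" for i in range(3)]


def frame(arr, prefix="v"):
    cols = [f"{prefix}{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def bh_oracle(pvals, alpha):
    """Hand step-up rule: largest k with p_(k) <= k/m * alpha."""
    order = np.argsort(pvals)
    m = len(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank / m * alpha:
            k_max = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


class TestPearson:
    def test_identical_columns_fully_correlated(self, rng):
        x = rng.normal(size=100)
        values = frame(np.column_stack([x, x + 0.0, rng.normal(size=100)]))
        net = pearson_network(values, alpha=0.01)
        assert net.coef[0, 1] == pytest.approx(1.0)
        assert net.mask[0, 1]

    def test_null_data_yields_no_edges(self, rng):
        values = frame(rng.normal(size=(1000, 10)))
        net = pearson_network(values, alpha=0.01)
        assert net.mask.sum() // 2 <= 1

    def test_bh_mask_matches_hand_oracle(self, rng):
        z = rng.normal(size=(60, 4))
        z[:, 1] += 0.8 * z[:, 0]
        z[:, 3] += 0.2 * z[:, 2]
        net = pearson_network(frame(z), alpha=0.05)
        iu, ju = net.triu()
        np.testing.assert_array_equal(
            net.mask[iu, ju], bh_oracle(net.pvalues[iu, ju], 0.05)
        )

    def test_zero_variance_column_rejected(self, rng):
        arr = rng.normal(size=(50, 3))
        arr[:, 2] = 4.2
        with pytest.raises(ValueError, match="v2"):
            pearson_network(frame(arr))

    def test_symmetry_and_bounds(self, rng):
        net = pearson_network(frame(rng.normal(size=(80, 6))))
        assert np.allclose(net.coef, net.coef.T)
        assert np.allclose(np.diag(net.coef), 1.0)
        assert (np.abs(net.coef) <= 1.0 + 1e-12).all()


class TestPartialCorrelation:
    def test_chain_dependence_vanishes_given_middle(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n) * 0.6
        z = 0.8 * y + rng.normal(size=n) * 0.6
        net = partial_correlation(frame(np.column_stack([x, y, z])))
        assert abs(net.coef[0, 2]) < 0.05
        assert net.coef[0, 1] > 0.3

    def test_lambda_zero_equals_plain_inversion(self, rng):
        arr = rng.normal(size=(500, 5))
        arr[:, 1] += arr[:, 0]
        net = partial_correlation(frame(arr), shrinkage=0.0)
        # oracle: invert the sample correlation matrix directly
        r = np.corrcoef(arr, rowvar=False)
        omega = np.linalg.inv(r)
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(net.coef, expected, atol=1e-10)

    def test_two_variables_shrink_pearson(self, rng):
        arr = rng.normal(size=(200, 2))
        arr[:, 1] += 0.7 * arr[:, 0]
        net = partial_correlation(frame(arr))
        r = np.corrcoef(arr, rowvar=False)[0, 1]
        assert net.coef[0, 1] == pytest.approx((1 - net.shrinkage) * r, rel=1e-9)

    def test_confounders_conditioned_but_hidden(self, rng):
        n = 1500
        conf = rng.normal(size=n)
        a = conf + rng.normal(size=n) * 0.4
        b = conf + rng.normal(size=n) * 0.4
        values = frame(np.column_stack([a, b]))
        confounders = pd.DataFrame({"age": conf})
        with_conf = partial_correlation(values, confounders)
        without = partial_correlation(values)
        assert with_conf.labels == ("v0", "v1")
        assert abs(with_conf.coef[0, 1]) < 0.1
        assert without.coef[0, 1] > 0.5

    def test_sign_recovery_against_truth(self, rng):
        cfg = SimulationConfig(n_samples=1000, dilution_sd=0.0, missing_rate=0.0,
                               seed=11)
        matrix, truth = simulate_cohort(cfg)
        net = partial_correlation(np.log(matrix.values))
        omega = truth["precision"]
        d = np.sqrt(np.diag(omega))
        true_pcor = -omega / np.outer(d, d)
        iu, ju = net.triu()
        strong = np.abs(true_pcor[iu, ju]) >= 0.2
        assert (
            np.sign(net.coef[iu, ju][strong])
            == np.sign(true_pcor[iu, ju][strong])
        ).all()


class TestSignificance:
    def test_zero_pcor_gives_unit_pvalue(self):
        from glyconet.netinfer import CorrelationNetwork

        net = CorrelationNetwork(
            labels=("a", "b"), coef=np.eye(2), kind="partial", n_samples=100
        )
        out = pcor_significance(net, alpha=0.01)
        assert out.pvalues[0, 1] == pytest.approx(1.0)

    def test_planted_edges_recovered(self):
        """Planted partial correlations of 0.3 at n=700 are detected with
        high sensitivity."""
        cfg = SimulationConfig(
            n_samples=700, rho=0.3, rho_x=0.3, dilution_sd=0.0, seed=5
        )
        matrix, truth = simulate_cohort(cfg)
        net = pcor_significance(
            partial_correlation(np.log(matrix.values)), alpha=0.01
        )
        found = net.significant_pairs()
        sens = len(found & truth["edges"]) / len(truth["edges"])
        assert sens >= 0.9

    def test_permutation_null_edge_rate(self, rng):
        n, p, n_perm = 150, 8, 100
        base = rng.normal(size=(n, p))
        edge_count = 0
        for _ in range(n_perm):
            perm = np.column_stack(
                [base[rng.permutation(n), j] for j in range(p)]
            )
            net = pcor_significance(partial_correlation(frame(perm)), alpha=0.01)
            edge_count += net.mask.sum() // 2
        n_pairs = p * (p - 1) // 2
        assert edge_count / (n_perm * n_pairs) <= 2 * 0.01

    def test_empirical_null_mode_controls_null_data(self, rng):
        net = partial_correlation(frame(rng.normal(size=(400, 10))))
        out = pcor_significance(net, alpha=0.01, method="empirical_null")
        assert out.mask.sum() // 2 <= 1

    def test_empirical_null_detects_planted_edge(self, rng):
        arr = rng.normal(size=(500, 8))
        arr[:, 1] += 0.8 * arr[:, 0]
        out = pcor_significance(
            partial_correlation(frame(arr)), alpha=0.01, method="empirical_null"
        )
        assert out.mask[0, 1]

    def test_unknown_method_rejected(self, rng):
        net = partial_correlation(frame(rng.normal(size=(50, 4))))
        with pytest.raises(ValueError, match="method"):
            pcor_significance(net, method="bogus")


class TestGGMAndConsensus:
    def _net(self, coef, mask, kind, labels=("a", "b", "c")):
        from glyconet.netinfer import CorrelationNetwork

        return CorrelationNetwork(
            labels=labels, coef=coef, kind=kind, n_samples=10, mask=mask
        )

    def test_pearson_masking_rule(self):
        coef = np.eye(3)
        coef[0, 1] = coef[1, 0] = 0.5
        coef[1, 2] = coef[2, 1] = 0.4
        partial_mask = np.zeros((3, 3), bool)
        partial_mask[0, 1] = partial_mask[1, 0] = True
        partial_mask[1, 2] = partial_mask[2, 1] = True
        pearson_mask = np.zeros((3, 3), bool)
        pearson_mask[1, 2] = pearson_mask[2, 1] = True
        g = build_ggm(
            self._net(np.eye(3) + 0.0, pearson_mask, "pearson"),
            self._net(coef, partial_mask, "partial"),
        )
        assert not g.mask[0, 1]  # partial-significant but Pearson-masked
        assert g.mask[1, 2]  # both significant
        assert g.coef[1, 2] == pytest.approx(0.4)  # partial coefficient kept

    def test_empty_partial_mask_empty_ggm(self):
        empty = np.zeros((3, 3), bool)
        full = ~np.eye(3, dtype=bool)
        g = build_ggm(
            self._net(np.eye(3), full, "pearson"),
            self._net(np.eye(3), empty, "partial"),
        )
        assert not g.mask.any()

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label"):
            build_ggm(
                self._net(np.eye(3), np.zeros((3, 3), bool), "pearson"),
                self._net(
                    np.eye(3), np.zeros((3, 3), bool), "partial", labels=("x", "y", "z")
                ),
            )

    def test_consensus_counts_match_set_algebra(self, rng):
        from glyconet.netinfer import CorrelationNetwork

        p = 6
        labels = tuple(f"n{i}" for i in range(p))
        nets, masks = [], []
        for _ in range(4):
            m = np.zeros((p, p), bool)
            iu, ju = np.triu_indices(p, 1)
            sel = rng.random(len(iu)) < 0.4
            m[iu[sel], ju[sel]] = m[ju[sel], iu[sel]] = True
            masks.append(m)
            nets.append(
                CorrelationNetwork(
                    labels=labels, coef=np.eye(p), kind="partial",
                    n_samples=10, mask=m,
                )
            )
        cons = consensus(nets)
        iu, ju = np.triu_indices(p, 1)
        for i, j in zip(iu, ju):
            count = sum(m[i, j] for m in masks)
            assert cons.counts[i, j] == count
            assert cons.mask[i, j] == (count == 4)

    def test_identical_networks_fully_replicated(self, rng):
        from glyconet.netinfer import CorrelationNetwork

        m = np.zeros((3, 3), bool)
        m[0, 1] = m[1, 0] = True
        net = CorrelationNetwork(
            labels=("a", "b", "c"), coef=np.eye(3), kind="partial",
            n_samples=10, mask=m,
        )
        cons = consensus([net, net, net, net])
        assert cons.mask[0, 1] and cons.counts[0, 1] == 4
        assert not cons.mask[0, 2]
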