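"""Genotype-phenotype maps: phi, one-hot features, and gauge fixing."""

import itertools

import numpy as np
import pytest

from cregrammar.gpmap import (
    FeatureMap,
    GPMapParams,
    allowed_pairs,
    gauge_fix_consensus,
    gauge_fix_uniform,
    one_hot_encode,
    phi,
    phi_many,
    position_averaged_params,
)
from cregrammar.synthetic_data import encoding_position_alphabets

SMALL = (("A", "B"), ("A", "B"), ("A", "B", "C"))


def random_params(alphas, architecture, seed=0, theta0=0.3):
    rng = np.random.default_rng(seed)
    th_add = {(i, ch): float(rng.normal()) for i, a in enumerate(alphas) for ch in a}
    th_pair = {
        (i, j, a, b): float(rng.normal())
        for (i, j) in allowed_pairs(len(alphas), architecture)
        for a in alphas[i]
        for b in alphas[j]
    }
    return GPMapParams(alphas, architecture, theta0, th_add, th_pair)


def all_sequences(alphas):
    return ["".join(s) for s in itertools.product(*alphas)]


class TestPhi:
    def test_constant_map(self):
        p = GPMapParams(SMALL, "pairwise", theta0=2.5)
        assert all(phi(s, p) == 2.5 for s in all_sequences(SMALL))

    def test_matches_one_hot_contraction(self):
        p = random_params(SMALL, "pairwise", seed=1)
        fm = FeatureMap(SMALL, "pairwise")
        w = fm.weights_from_params(p)
        for s in all_sequences(SMALL):
            assert phi(s, p) == pytest.approx(fm.encode(s) @ w + p.theta0)

    def test_zero_pairs_reduce_to_additive(self):
        p = random_params(SMALL, "pairwise", seed=2)
        p_zero = GPMapParams(SMALL, "pairwise", p.theta0, p.theta_add, {})
        p_add = GPMapParams(SMALL, "additive", p.theta0, p.theta_add, {})
        for s in all_sequences(SMALL):
            assert phi(s, p_zero) == pytest.approx(phi(s, p_add))

    def test_architecture_nesting(self):
        """Zero-filling the extra pair blocks leaves phi unchanged."""
        p_n = random_params(SMALL, "neighbor", seed=3)
        pair_full = dict(p_n.theta_pair)
        for (i, j) in allowed_pairs(3, "pairwise"):
            for a in SMALL[i]:
                for b in SMALL[j]:
                    pair_full.setdefault((i, j, a, b), 0.0)
        p_p = GPMapParams(SMALL, "pairwise", p_n.theta0, p_n.theta_add, pair_full)
        for s in all_sequences(SMALL):
            assert phi(s, p_p) == pytest.approx(phi(s, p_n))

    def test_unknown_character_errors(self):
        p = random_params(SMALL, "additive")
        with pytest.raises(KeyError):
            phi("ABZ", p)
        with pytest.raises(ValueError):
            phi("AB", p)


class TestOneHot:
    def test_block_structure(self):
        x = one_hot_encode("ABC", SMALL, "pairwise")
        fm = FeatureMap(SMALL, "pairwise")
        assert x[: fm.n_additive].sum() == 3  # L ones in the additive block
        assert x[fm.n_additive :].sum() == 3  # C(3,2) ones in the pair block

    def test_crx_nrl_dimensions(self, crx_nrl_alphabet):
        alphas = encoding_position_alphabets(crx_nrl_alphabet, 4)
        fm = FeatureMap(alphas, "pairwise")
        assert fm.n_additive == 4 * 9 + 2
        x = fm.encode("OOCNR")
        assert x[fm.n_additive :].sum() == 10  # C(5,2) position pairs

    def test_decode_round_trip(self):
        fm = FeatureMap(SMALL, "pairwise")
        for s in all_sequences(SMALL):
            assert fm.decode(fm.encode(s)) == s


@pytest.mark.parametrize("architecture", ["additive", "neighbor", "pairwise"])
class TestUniformGauge:
    def test_phi_preserved_exhaustively(self, architecture):
        p = random_params(SMALL, architecture, seed=4)
        fixed = gauge_fix_uniform(p)
        seqs = all_sequences(SMALL)
        assert np.max(np.abs(phi_many(seqs, fixed) - phi_many(seqs, p))) < 1e-9

    def test_zero_means(self, architecture):
        fixed = gauge_fix_uniform(random_params(SMALL, architecture, seed=5))
        for i, alpha in enumerate(SMALL):
            assert np.mean([fixed.theta_add[(i, c)] for c in alpha]) == pytest.approx(0, abs=1e-12)
        for (i, j) in fixed.pairs:
            A = np.array(
                [[fixed.theta_pair[(i, j, a, b)] for b in SMALL[j]] for a in SMALL[i]]
            )
            assert np.allclose(A.mean(axis=0), 0, atol=1e-12)
            assert np.allclose(A.mean(axis=1), 0, atol=1e-12)

    def test_idempotent(self, architecture):
        fixed = gauge_fix_uniform(random_params(SMALL, architecture, seed=6))
        twice = gauge_fix_uniform(fixed)
        assert twice.theta0 == pytest.approx(fixed.theta0)
        for k in fixed.theta_add:
            assert twice.theta_add[k] == pytest.approx(fixed.theta_add[k])


class TestConsensusGauge:
    def test_phi_preserved_and_consensus_zeroed(self):
        p = random_params(SMALL, "pairwise", seed=7)
        cons = "ABC"
        fixed = gauge_fix_consensus(p, cons)
        seqs = all_sequences(SMALL)
        assert np.max(np.abs(phi_many(seqs, fixed) - phi_many(seqs, p))) < 1e-9
        assert fixed.theta0 == pytest.approx(phi(cons, p))
        for i, ch in enumerate(cons):
            assert fixed.theta_add[(i, ch)] == pytest.approx(0, abs=1e-12)

    def test_constant_shift_absorbed_by_theta0(self):
        p = random_params(SMALL, "pairwise", seed=8)
        shifted_add = dict(p.theta_add)
        for ch in SMALL[0]:
            shifted_add[(0, ch)] += 1.7
        p2 = GPMapParams(SMALL, "pairwise", p.theta0, shifted_add, p.theta_pair)
        f1 = gauge_fix_uniform(p)
        f2 = gauge_fix_uniform(p2)
        assert f2.theta0 == pytest.approx(f1.theta0 + 1.7)
        for k in f1.theta_add:
            assert f2.theta_add[k] == pytest.approx(f1.theta_add[k])

    def test_basal_consensus_on_crx_nrl_encoding(self, crx_nrl_alphabet):
        """Consensus gauge on the all-pad + Hsp68 sequence gives phi(basal) =
        theta0 and no parameters touching the basal characters."""
        alphas = encoding_position_alphabets(crx_nrl_alphabet, 4)
        p = random_params(alphas, "pairwise", seed=9)
        fixed = gauge_fix_consensus(p, "OOOOH")
        assert fixed.theta0 == pytest.approx(phi("OOOOH", p))
        for i in range(4):
            assert fixed.theta_add[(i, "O")] == pytest.approx(0, abs=1e-9)
        assert fixed.theta_add[(4, "H")] == pytest.approx(0, abs=1e-9)
        for (i, j) in fixed.pairs:
            ci = "O" if i < 4 else "H"
            cj = "O" if j < 4 else "H"
            for a in alphas[i]:
                assert fixed.theta_pair[(i, j, a, cj)] == pytest.approx(0, abs=1e-9)
            for b in alphas[j]:
                assert fixed.theta_pair[(i, j, ci, b)] == pytest.approx(0, abs=1e-9)

    def test_unknown_consensus_errors(self):
        with pytest.raises(KeyError):
            gauge_fix_consensus(random_params(SMALL, "pairwise"), "ZZZ")


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        p = random_params(SMALL, "pairwise", seed=10)
        path = tmp_path / "model.json"
        p.to_json(path)
        q = GPMapParams.from_json(path)
        assert q.theta0 == p.theta0
        assert q.theta_add == p.theta_add
        assert q.theta_pair == p.theta_pair
        assert q.architecture == p.architecture


class TestParamSummary:
    def test_hand_computed_means(self):
        alphas = (("A", "B"), ("A", "B"), ("A", "B"))
        th_add = {(0, "A"): 1.0, (1, "A"): 3.0, (2, "A"): 2.0,
                  (0, "B"): 0.0, (1, "B"): 0.0, (2, "B"): 0.0}
        th_pair = {
            (i, j, a, b): (2.0 if (a, b) == ("A", "B") else 0.0)
            for (i, j) in allowed_pairs(3, "pairwise")
            for a in ("A", "B")
            for b in ("A", "B")
        }
        p = GPMapParams(alphas, "pairwise", 0.0, th_add, th_pair)
        summ = position_averaged_params(p)
        assert summ.additive_mean["A"] == pytest.approx(2.0)
        assert summ.pair_mean.loc["A", "B"] == pytest.approx(2.0)
        assert summ.pair_mean.loc["B", "A"] == pytest.approx(0.0)

    def test_pad_character_excluded(self, crx_nrl_alphabet):
        alphas = encoding_position_alphabets(crx_nrl_alphabet, 4)
        p = GPMapParams(alphas, "additive",
                        theta_add={(i, ch): 1.0 for i, a in enumerate(alphas) for ch in a})
        summ = position_averaged_params(p)
        assert "O" not in summ.additive_mean.index
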