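"""Change-point model: marginal likelihood, sampler correctness against
the exhaustive enumeration oracle, determinism and state invariants."""

import numpy as np
import pytest
from scipy import integrate

from alnseg import SegmentationModel, brute_force_posterior, segment_log_marginal
from alnseg.encoding import CONS2, PAIR8, EncodedSequence
from alnseg.model import log_likelihood, mc_standard_error


class TestSegmentLogMarginal:
    def test_empty_counts(self):
        assert segment_log_marginal([0, 0], [1.0, 1.0]) == 0.0

    def test_beta_binomial_case(self):
        """counts (2,1) under a uniform prior: the ordered marginal is
        the integral of theta^2 (1-theta) over [0, 1] = 1/12."""
        got = segment_log_marginal([2, 1], [1.0, 1.0])
        assert got == pytest.approx(np.log(1 / 12))
        oracle, _ = integrate.quad(lambda t: t**2 * (1 - t), 0, 1)
        assert got == pytest.approx(np.log(oracle))

    @pytest.mark.parametrize("A", [2, 8, 32])
    def test_single_symbol_symmetric(self, A):
        counts = np.zeros(A, dtype=int)
        counts[0] = 1
        assert segment_log_marginal(counts, np.ones(A)) == pytest.approx(np.log(1 / A))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            segment_log_marginal([1, 2], [1.0, 0.0])

    def test_direct_gamma_evaluation(self):
        """Brute-force Gamma-function evaluation of the marginal."""
        from math import gamma

        counts = np.array([3, 1, 2])
        alpha = np.array([0.5, 1.5, 2.0])
        S, N = alpha.sum(), counts.sum()
        expected = gamma(S) / gamma(S + N)
        for a, n in zip(alpha, counts):
            expected *= gamma(a + n) / gamma(a)
        assert segment_log_marginal(counts, alpha) == pytest.approx(np.log(expected))


class TestLogLikelihood:
    def _seq(self, text):
        idx = {s: i for i, s in enumerate(PAIR8.alphabet)}
        return EncodedSequence(
            np.array([idx[c] for c in text], dtype=np.uint8), PAIR8
        )

    def test_single_segment(self):
        seq = self._seq("aafafa")
        alpha = np.ones((1, 8))
        got = log_likelihood(seq, [], [0], alpha)
        assert got == pytest.approx(segment_log_marginal(seq.symbol_counts(), alpha[0]))

    def test_additivity_across_boundary(self):
        seq = self._seq("aaaaffff")
        alpha = np.ones((2, 8)) * 0.7
        whole = log_likelihood(seq, [4], [0, 1], alpha)
        left = segment_log_marginal(
            np.bincount(seq.symbols[:4], minlength=8), alpha[0]
        )
        right = segment_log_marginal(
            np.bincount(seq.symbols[4:], minlength=8), alpha[1]
        )
        assert whole == pytest.approx(left + right)

    def test_label_out_of_range(self):
        seq = self._seq("aaaa")
        with pytest.raises(ValueError, match="label"):
            log_likelihood(seq, [], [3], np.ones((2, 8)))


class TestBruteForce:
    def test_symmetric_sequence_symmetric_probs(self):
        seq = EncodedSequence(np.array([0, 0, 1, 1, 0, 0], dtype=np.uint8), CONS2)
        out = brute_force_posterior(seq, np.array([[1.0, 1.0]]), changepoint_prior=0.1)
        bp = out["boundary_prob"]
        assert bp == pytest.approx(bp[::-1])

    def test_uniform_likelihood_recovers_prior(self):
        """With enormous symmetric alpha every segmentation is equally
        likely, so inclusion probability reverts to the prior rho."""
        seq = EncodedSequence(np.array([0, 1, 0, 1, 1], dtype=np.uint8), CONS2)
        out = brute_force_posterior(seq, np.array([[1e7, 1e7]]), changepoint_prior=0.03)
        assert out["boundary_prob"] == pytest.approx(0.03, abs=1e-4)

    def test_enumeration_cap(self):
        seq = EncodedSequence(np.zeros(40, dtype=np.uint8), CONS2)
        with pytest.raises(ValueError, match="cap"):
            brute_force_posterior(seq, np.array([[1.0, 1.0]]))


def _mcmc_marginals(res):
    """Boundary inclusion probabilities and per-position class
    probabilities from the stored post-burn-in states."""
    n = len(res.seq)
    keep = np.flatnonzero(res.state_iters >= res.burn_in_index)
    incl = np.zeros(n - 1)
    incl_series = np.zeros((len(keep), n - 1))
    for row, st in enumerate(keep):
        nb = res.state_nb[st]
        for b in res.state_bnd[st, :nb]:
            incl_series[row, b - 1] = 1.0
    incl = incl_series.mean(axis=0)
    K = res.n_classes
    cp = np.zeros((n, K))
    pos = np.arange(n)
    for st in keep:
        cp[pos, res.state_labels[st]] += 1
    cp /= len(keep)
    return incl, incl_series, cp


class TestSamplerVsOracle:
    def test_fixed_boundaries_always_present(self, tiny_binary_seq):
        res = SegmentationModel(tiny_binary_seq, n_classes=2).fit(
            iterations=500, seed=3, thin=1
        )
        for st in range(len(res.state_iters)):
            nb = res.state_nb[st]
            assert 6 in res.state_bnd[st, :nb]

    def test_same_seed_identical_traces(self, tiny_binary_seq):
        m = SegmentationModel(tiny_binary_seq, n_classes=2)
        a = m.fit(iterations=800, seed=9)
        b = m.fit(iterations=800, seed=9)
        assert np.array_equal(a.loglik, b.loglik)
        assert np.array_equal(a.alpha_trace, b.alpha_trace)
        assert np.array_equal(a.state_labels, b.state_labels)

    def test_counts_conserved_in_every_state(self, tiny_binary_seq):
        res = SegmentationModel(tiny_binary_seq, n_classes=2).fit(
            iterations=300, seed=5, thin=3
        )
        total = tiny_binary_seq.symbol_counts()
        for st in range(len(res.state_iters)):
            nb = res.state_nb[st]
            cuts = [0, *res.state_bnd[st, :nb].tolist(), len(tiny_binary_seq)]
            per_seg = [
                np.bincount(tiny_binary_seq.symbols[i:j], minlength=2)
                for i, j in zip(cuts[:-1], cuts[1:])
            ]
            assert np.array_equal(np.sum(per_seg, axis=0), total)

    def test_marginals_match_enumeration(self, tiny_binary_seq):
        """Central correctness property: with alpha and pi held fixed the
        sampler's boundary and class marginals match exhaustive
        enumeration within Monte-Carlo error."""
        alpha = np.array([[1.0, 1.0], [0.3, 3.0]])
        pi = np.array([0.5, 0.5])
        oracle = brute_force_posterior(tiny_binary_seq, alpha, pi, changepoint_prior=0.1)
        res = SegmentationModel(tiny_binary_seq, n_classes=2, changepoint_prior=0.1).fit(
            iterations=30_000,
            seed=1,
            thin=1,
            burn_in=0.2,
            sample_alpha=False,
            sample_pi=False,
            alpha_init=alpha,
            pi_init=pi,
            proposals_per_sweep=12,
        )
        incl, incl_series, cp = _mcmc_marginals(res)
        for b in range(len(incl)):
            se = mc_standard_error(incl_series[:, b])
            assert abs(incl[b] - oracle["boundary_prob"][b]) <= max(3 * se, 1e-12)
        assert np.abs(cp - oracle["class_prob"]).max() < 0.02


def test_posterior_k_and_L_arithmetic():
    """A constant trace gives k and L by direct arithmetic."""
    idx = np.zeros(100, dtype=np.uint8)
    seq = EncodedSequence(idx, CONS2, fixed_boundaries=[50])
    res = SegmentationModel(seq, n_classes=1, changepoint_prior=1e-6).fit(
        iterations=200, seed=2, proposals_per_sweep=1
    )
    k, L = res.posterior_k_and_L()
    assert k == 0.0
    assert L == 50.0


def test_empty_sequence_rejected():
    seq = EncodedSequence(np.empty(0, dtype=np.uint8), CONS2)
    with pytest.raises(ValueError, match="non-empty"):
        SegmentationModel(seq)


def test_summary_renders(planted3_fit):
    text = planted3_fit.summary()
    assert "DICV" in text
    assert "classes (K): 3" in text
    assert "conservation" in text


def test_save_load_roundtrip(tmp_path, tiny_binary_seq):
    res = SegmentationModel(tiny_binary_seq, n_classes=2).fit(iterations=400, seed=4)
    res.save(tmp_path / "trace")
    from alnseg import SegmentationResults

    back = SegmentationResults.load(tmp_path / "trace", tiny_binary_seq)
    assert np.allclose(back.loglik, res.loglik)
    assert np.array_equal(back.state_labels, res.state_labels)
    assert back.seed == res.seed
    assert back.dicv() == pytest.approx(res.dicv())
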