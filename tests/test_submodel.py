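"""Rate matrices, transition probabilities, discrete gamma, pruning
likelihood against exhaustive enumeration, fitting and model selection."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, linalg, stats

from quartetphylo.core import PAIRINGS, QuartetTree, Topology
from quartetphylo.submodel import (
    ModelParams,
    ModelSpec,
    build_rate_matrix,
    compress_alignment,
    default_params,
    discretize_gamma,
    fit_model,
    log_likelihood,
    model_catalog,
    select_model,
    transition_probabilities,
)
from quartetphylo.synthetic_data import (
    SimModel,
    SimulationConfig,
    evolve_alignment,
    sample_root_codons,
    simulate_gene_set,
)
from quartetphylo.core import CodonAlignment, ROLES

from conftest import make_alignment

def _uniform_law():
    from quartetphylo.synthetic_data import SENSE_CODONS
    return {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}


# ---------------------------------------------------------------------------
# independent oracle: likelihood by enumeration of internal states
# ---------------------------------------------------------------------------

def brute_force_lnL(aln, topology, exch, freqs, branches, p_inv=0.0, alpha=None, k=4):
    """Sum over the 16 internal-state combinations per site, mixture over
    rate categories; transition matrices via scipy.linalg.expm."""
    pi = np.asarray(freqs, dtype=float)
    # generator assembled by definition, independently of the implementation
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(exch, pairs):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()
    rates = discretize_gamma(alpha, k) if alpha is not None else np.array([1.0])
    code = {b: i for i, b in enumerate("ACGT")}
    (i1, i2), (j1, j2) = PAIRINGS[topology]
    lnl = 0.0
    for site in range(len(aln.rows[0])):
        obs = [aln.rows[t][site] for t in range(4)]
        leaf = [
            np.ones(4) if b not in code else np.eye(4)[code[b]]
            for b in obs
        ]
        site_L = 0.0
        for r in rates:
            P = [linalg.expm(Q * t * r) for t in branches]
            total = 0.0
            for u, v in itertools.product(range(4), repeat=2):
                total += (
                    pi[u]
                    * (P[i1][u] @ leaf[i1]) * (P[i2][u] @ leaf[i2])
                    * P[4][u, v]
                    * (P[j1][v] @ leaf[j1]) * (P[j2][v] @ leaf[j2])
                )
            site_L += total / len(rates)
        if p_inv > 0:
            inv = sum(pi[x] * leaf[0][x] * leaf[1][x] * leaf[2][x] * leaf[3][x]
                      for x in range(4))
            site_L = p_inv * inv + (1 - p_inv) * site_L
        lnl += math.log(site_L)
    return lnl


def _random_alignment(rng, n_sites=50, missing=False):
    alphabet = list("ACGT" + ("-N" if missing else ""))
    rows = tuple("".join(rng.choice(alphabet, n_sites)) for _ in range(4))
    return CodonAlignment(ROLES, rows)


def _random_gtr(rng):
    exch = np.concatenate([rng.uniform(0.3, 3.0, 5), [1.0]])
    freqs = rng.dirichlet((5.0,) * 4)
    return exch, freqs


class TestRateMatrix:
    def test_jc_symmetric_unit_rate(self):
        Q = build_rate_matrix(np.ones(6), np.full(4, 0.25))
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(np.diag(Q), -1.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_detailed_balance_random_gtr(self, rng):
        for _ in range(5):
            exch, freqs = _random_gtr(rng)
            Q = build_rate_matrix(exch, freqs)
            assert np.allclose(freqs[:, None] * Q, (freqs[:, None] * Q).T)

    def test_k80_transition_transversion_ratio(self):
        kappa = 2.0
        exch = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        Q = build_rate_matrix(exch, np.full(4, 0.25))
        assert Q[0, 2] / Q[0, 1] == pytest.approx(kappa)  # A->G vs A->C

    def test_zero_frequency_with_rate_rejected(self):
        with pytest.raises(ValueError, match="zero frequency"):
            build_rate_matrix(np.ones(6), np.array([0.5, 0.5, 0.0, 0.0]))


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self, rng):
        exch, freqs = _random_gtr(rng)
        Q = build_rate_matrix(exch, freqs)
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(4), atol=1e-14)

    def test_jc_closed_form(self):
        Q = build_rate_matrix(np.ones(6), np.full(4, 0.25))
        for t in (0.01, 0.3, 1.7):
            P = transition_probabilities(Q, t)
            same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
            assert np.allclose(np.diag(P), same, atol=1e-12)
            assert P[0, 1] == pytest.approx(diff, abs=1e-12)

    def test_long_branch_reaches_stationarity(self, rng):
        exch, freqs = _random_gtr(rng)
        Q = build_rate_matrix(exch, freqs)
        P = transition_probabilities(Q, 100.0)
        assert np.allclose(P, np.tile(freqs, (4, 1)), atol=1e-6)

    def test_rows_are_stochastic(self, rng):
        exch, freqs = _random_gtr(rng)
        Q = build_rate_matrix(exch, freqs)
        P = transition_probabilities(Q, 0.42, rate_multiplier=1.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(np.ones(6), np.full(4, 0.25))
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


class TestDiscreteGamma:
    def test_huge_alpha_no_heterogeneity(self):
        assert np.allclose(discretize_gamma(1e6, 4), 1.0, atol=1e-2)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 2.0])
    def test_mean_is_one(self, alpha):
        assert discretize_gamma(alpha, 4).mean() == pytest.approx(1.0, abs=1e-10)

    def test_matches_quadrature_oracle(self):
        """Bin means by direct numerical integration of the gamma density."""
        alpha, k = 0.5, 4
        edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), alpha, scale=1 / alpha)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            num, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, alpha, scale=1 / alpha),
                lo, min(hi, 1e3), limit=200,
            )
            expected.append(num * k)
        assert np.allclose(discretize_gamma(alpha, k), expected, atol=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0)


class TestPruningLikelihood:
    def test_single_constant_site_stationary(self):
        aln = make_alignment("A", "A", "A", "A")
        tree = QuartetTree(Topology.T1, (0.0,) * 5)
        params = default_params(ModelSpec("JC"))
        lnl = log_likelihood(aln, tree, ModelSpec("JC"), params)
        assert lnl == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("topology", list(Topology))
    def test_matches_enumeration_oracle(self, topology, rng):
        """Pruning == brute-force internal-state enumeration (GTR+G)."""
        for trial in range(5):
            exch, freqs = _random_gtr(rng)
            alpha = rng.uniform(0.3, 3.0)
            branches = rng.uniform(0.01, 0.8, 5)
            aln = _random_alignment(rng, 40, missing=(trial == 4))
            spec = ModelSpec("GTR", plus_g=True)
            params = ModelParams(exch=exch, freqs=freqs, alpha=alpha)
            mine = log_likelihood(aln, QuartetTree(topology, tuple(branches)),
                                  spec, params)
            oracle = brute_force_lnL(aln, topology, exch, freqs, branches,
                                     alpha=alpha)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_invariant_class_matches_oracle(self, rng):
        exch, freqs = _random_gtr(rng)
        branches = rng.uniform(0.05, 0.5, 5)
        aln = _random_alignment(rng, 30)
        spec = ModelSpec("GTR", plus_i=True)
        params = ModelParams(exch=exch, freqs=freqs, p_inv=0.3)
        mine = log_likelihood(aln, QuartetTree(Topology.T2, tuple(branches)),
                              spec, params)
        oracle = brute_force_lnL(aln, Topology.T2, exch, freqs, branches,
                                 p_inv=0.3)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_site_order_invariance_and_duplication(self, rng):
        aln = _random_alignment(rng, 60)
        tree = QuartetTree(Topology.T1, (0.1, 0.2, 0.1, 0.3, 0.05))
        spec = ModelSpec("HKY85")
        params = ModelParams(
            exch=np.array([1, 4, 1, 1, 4, 1.0]),
            freqs=np.array([0.3, 0.2, 0.2, 0.3]),
        )
        base = log_likelihood(aln, tree, spec, params)
        perm = rng.permutation(60)
        shuffled = CodonAlignment(
            aln.names, tuple("".join(r[i] for i in perm) for r in aln.rows)
        )
        doubled = CodonAlignment(aln.names, tuple(r + r for r in aln.rows))
        assert log_likelihood(shuffled, tree, spec, params) == pytest.approx(base, abs=1e-9)
        assert log_likelihood(doubled, tree, spec, params) == pytest.approx(2 * base, rel=1e-12)


class TestFitting:
    def test_nested_model_never_beats_superset(self, small_gene_set):
        genes, _ = small_gene_set
        part = compress_alignment(genes[0].alignment)
        hky = fit_model(part, Topology.T1, ModelSpec("HKY85"))
        gtr = fit_model(part, Topology.T1, ModelSpec("GTR"))
        assert gtr.lnL >= hky.lnL - 1e-4

    def test_criteria_are_definitional(self, small_gene_set):
        genes, _ = small_gene_set
        fit = fit_model(compress_alignment(genes[1].alignment),
                        Topology.T2, ModelSpec("K80"))
        assert fit.aic == -2 * fit.lnL + 2 * fit.k
        assert fit.bic == -2 * fit.lnL + fit.k * math.log(fit.n_sites)
        assert fit.k == 1 + 5  # kappa + branch lengths

    def test_jc_data_recovers_flat_exchangeabilities(self, rng):
        root = sample_root_codons(_uniform_law(), 3334, rng)  # ~10 kb
        aln = evolve_alignment(
            root, Topology.T1, (0.1, 0.1, 0.1, 0.1, 0.05),
            SimModel(exch=(1.0,) * 6, freqs=(0.25,) * 4), (1, 1, 1), rng,
        )
        fit = fit_model(compress_alignment(aln), Topology.T1, ModelSpec("GTR"))
        assert np.all(np.abs(fit.params.exch - 1.0) < 0.10 * 3)  # within 30 %

    def test_alpha_recovery_under_gamma(self):
        """Simulated alpha=0.5 is recovered inside [0.35, 0.7] mostly."""
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            rates = stats.gamma.rvs(0.5, scale=2.0, size=1667,
                                    random_state=rng)
            root = sample_root_codons(_uniform_law(), 1667, rng)
            # site-specific rates: emulate +G by drawing each codon's rate
            aln_rows = None
            from quartetphylo.synthetic_data import _evolve_branch, _seq_to_codes, _codes_to_seq
            model = SimModel(exch=(1.0,) * 6, freqs=(0.25,) * 4)
            eng = model.engine()
            codes = _seq_to_codes(root)
            site_rates = np.repeat(rates, 3)
            b = (0.15, 0.15, 0.15, 0.15, 0.05)
            v = _evolve_branch(codes, b[4], eng, site_rates, rng)
            rows = [
                _evolve_branch(codes, b[0], eng, site_rates, rng),
                _evolve_branch(codes, b[1], eng, site_rates, rng),
                _evolve_branch(v, b[2], eng, site_rates, rng),
                _evolve_branch(v, b[3], eng, site_rates, rng),
            ]
            aln = CodonAlignment(ROLES, tuple(_codes_to_seq(r) for r in rows))
            fit = fit_model(compress_alignment(aln), Topology.T1,
                            ModelSpec("JC", plus_g=True))
            hits += 0.35 <= fit.params.alpha <= 0.7
        assert hits >= int(0.75 * n_rep)


class TestSelection:
    def test_singleton_catalog_returned(self, small_gene_set):
        genes, _ = small_gene_set
        fit = select_model(genes[0].alignment, Topology.T1, catalog=["K80+G"])
        assert fit.spec.label == "K80+G"

    def test_catalog_sizes(self):
        assert len(model_catalog("jmt88")) == 88
        assert len(model_catalog("small")) == 3

    def test_more_data_concentrates_selection(self):
        """BIC picks the generating family more often with longer genes."""
        def hit_rate(n_codons, seeds):
            hits = 0
            for s in seeds:
                rng = np.random.default_rng(s)
                root = sample_root_codons(_uniform_law(), n_codons, rng)
                aln = evolve_alignment(
                    root, Topology.T1, (0.1, 0.1, 0.1, 0.1, 0.05),
                    SimModel(exch=(1.0,) * 6, freqs=(0.25,) * 4), (1, 1, 1), rng,
                )
                fit = select_model(compress_alignment(aln), Topology.T1,
                                   catalog=["JC", "GTR"], criterion="BIC")
                hits += fit.spec.name == "JC"
            return hits / len(seeds)

        seeds = range(300, 306)
        assert hit_rate(1667, seeds) >= hit_rate(167, seeds)
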