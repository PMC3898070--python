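"""Time-reversible nucleotide substitution models and the quartet likelihood.

Implements the jModelTest-style catalog of named time-reversible models
(JC through GTR, each optionally with a proportion of invariant sites
``+I`` and discrete-gamma rate heterogeneity ``+G``), transition
probabilities via symmetrized eigendecomposition, the Felsenstein pruning
likelihood on the three quartet topologies with site-pattern compression,
maximum-likelihood fitting by coordinate ascent, and AIC/BIC model
selection.

Conventions
-----------
* Bases are ordered A, C, G, T; exchangeabilities are ordered
  (AC, AG, AT, CG, CT, GT) with the GT rate class fixed to 1.
* Rate matrices are scaled to one expected substitution per unit branch
  length at stationarity (before any per-category rate multiplier).
* Branch lengths are bounded in [1e-8, 10] during optimization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .core import PAIRINGS, CodonAlignment, QuartetTree, Topology, role_ordered_rows

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PAIR_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
#: (row, col) base indices for the six unordered pairs, in PAIR_NAMES order.
_PAIR_IDX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_GT_PAIR = 5

BRANCH_MIN, BRANCH_MAX = 1e-8, 10.0

# name -> (rate-class code over AC,AG,AT,CG,CT,GT; equal base frequencies?)
# The 11 substitution schemes of the jModelTest catalog, equal-frequency
# and unequal-frequency variants.
_SCHEMES: dict[str, tuple[str, bool]] = {
    "JC": ("000000", True), "F81": ("000000", False),
    "K80": ("010010", True), "HKY85": ("010010", False),
    "TrNef": ("010020", True), "TrN": ("010020", False),
    "TPM1": ("012210", True), "TPM1uf": ("012210", False),
    "TPM2": ("010212", True), "TPM2uf": ("010212", False),
    "TPM3": ("012012", True), "TPM3uf": ("012012", False),
    "TIM1ef": ("012230", True), "TIM1": ("012230", False),
    "TIM2ef": ("010232", True), "TIM2": ("010232", False),
    "TIM3ef": ("012032", True), "TIM3": ("012032", False),
    "TVMef": ("012314", True), "TVM": ("012314", False),
    "SYM": ("012345", True), "GTR": ("012345", False),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named time-reversible model family, optionally +I and/or +G."""

    name: str
    plus_i: bool = False
    plus_g: bool = False
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.name not in _SCHEMES:
            raise ValueError(f"unknown model scheme {self.name!r}")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @classmethod
    def from_label(cls, label: str, n_categories: int = 4) -> "ModelSpec":
        """Parse labels like ``"HKY85+I+G"`` or ``"GTR+G"``."""
        parts = label.split("+")
        return cls(
            parts[0],
            plus_i="I" in parts[1:],
            plus_g="G" in parts[1:],
            n_categories=n_categories,
        )

    @property
    def label(self) -> str:
        return self.name + ("+I" if self.plus_i else "") + ("+G" if self.plus_g else "")

    @property
    def code(self) -> str:
        return _SCHEMES[self.name][0]

    @property
    def equal_freqs(self) -> bool:
        return _SCHEMES[self.name][1]

    @property
    def rate_classes(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.code)

    @property
    def n_rate_classes(self) -> int:
        return max(self.rate_classes) + 1

    @property
    def gt_class(self) -> int:
        """The rate class containing GT, fixed to 1 in the parameterization."""
        return self.rate_classes[_GT_PAIR]

    @property
    def n_free_exchangeabilities(self) -> int:
        return self.n_rate_classes - 1

    def free_parameter_count(self, n_branches: int = 5) -> int:
        """jModelTest-style K: substitution + frequency + I/G + branches."""
        k = self.n_free_exchangeabilities
        if not self.equal_freqs:
            k += 3
        k += int(self.plus_i) + int(self.plus_g)
        return k + n_branches


@dataclass
class ModelParams:
    """Continuous parameter values for a ModelSpec."""

    exch: np.ndarray  # 6 exchangeabilities (AC..GT), GT class == 1
    freqs: np.ndarray  # 4 base frequencies, sum 1
    p_inv: float = 0.0
    alpha: float | None = None  # gamma shape, if +G

    def copy(self) -> "ModelParams":
        return ModelParams(self.exch.copy(), self.freqs.copy(), self.p_inv, self.alpha)


def default_params(spec: ModelSpec, freqs: np.ndarray | None = None) -> ModelParams:
    """Documented starting values: exchangeabilities 1, p_inv 0.01, alpha 1."""
    if spec.equal_freqs or freqs is None:
        f = np.full(4, 0.25)
    else:
        f = np.asarray(freqs, dtype=float)
        f = f / f.sum()
    return ModelParams(
        exch=np.ones(6),
        freqs=f,
        p_inv=0.01 if spec.plus_i else 0.0,
        alpha=1.0 if spec.plus_g else None,
    )


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(exch: Sequence[float], freqs: Sequence[float]) -> np.ndarray:
    """GTR generator: q_ij = r_ij * pi_j, scaled to unit expected rate.

    Raises if a base has zero frequency but a nonzero exchangeability
    touches it (the model would be irreducible-degenerate).
    """
    r = np.asarray(exch, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if r.shape != (6,):
        raise ValueError("need 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
    if pi.shape != (4,):
        raise ValueError("need 4 base frequencies")
    if np.any(r < 0):
        raise ValueError("negative exchangeability")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1")
    for k, (i, j) in enumerate(_PAIR_IDX):
        if r[k] > 0 and (pi[i] == 0 or pi[j] == 0):
            raise ValueError(
                f"zero frequency with nonzero exchangeability for pair {PAIR_NAMES[k]}"
            )
    R = np.zeros((4, 4))
    for k, (i, j) in enumerate(_PAIR_IDX):
        R[i, j] = R[j, i] = r[k]
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / mu


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (left null vector)."""
    w, vl = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


class _Eigen:
    """Symmetrized eigendecomposition of a reversible generator."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = (d[:, None] * Q) / d[None, :]
        S = 0.5 * (S + S.T)  # symmetric up to round-off by reversibility
        w, V = np.linalg.eigh(S)
        self.w = w
        self.left = V / d[:, None]   # diag(1/d) @ V
        self.right = V.T * d[None, :]  # V.T @ diag(d)

    def P(self, t: float) -> np.ndarray:
        E = np.exp(self.w * t)
        P = (self.left * E[None, :]) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


def transition_probabilities(
    Q: np.ndarray, t: float, rate_multiplier: float = 1.0
) -> np.ndarray:
    """P(t) = exp(Q * t * r) for a reversible generator.

    The stationary distribution is recovered from Q, the generator is
    symmetrized with it, and the matrix exponential is taken through the
    eigendecomposition.  Rows sum to 1 to machine precision.
    """
    if t < 0:
        raise ValueError("negative branch length")
    pi = stationary_distribution(Q)
    return _Eigen(Q, pi).P(t * rate_multiplier)


def discretize_gamma(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-of-quantile-bin discrete gamma rates (Yang's approach).

    Returns ``k`` rates with equal probability 1/k and mean exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    # X ~ Gamma(alpha, rate=alpha) so E[X]=1; bin means via the shape+1 trick.
    # scipy.special is used directly (the rv_continuous wrappers are slow
    # enough to dominate model fitting).
    edges = special.gammaincinv(alpha, np.arange(1, k) / k) / alpha
    upper = np.concatenate(
        ([0.0], special.gammainc(alpha + 1.0, alpha * edges), [1.0])
    )
    rates = k * np.diff(upper)
    return rates / rates.mean()  # exact renormalization against round-off


# ---------------------------------------------------------------------------
# Pattern compression
# ---------------------------------------------------------------------------

_MISSING = 4  # leaf code for gap / N / any ambiguity: partial likelihood 1


def _encode_rows(rows: Sequence[str]) -> np.ndarray:
    """(4, L) int8 codes; anything outside ACGT becomes the missing code."""
    lut = np.full(256, _MISSING, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return np.vstack([lut[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows])


@dataclass
class PartitionData:
    """Pattern-compressed data for one partition (one gene), role order."""

    codes: np.ndarray     # (4, npat) int8, 4 = missing
    counts: np.ndarray    # (npat,) float
    n_sites: int
    freqs_emp: np.ndarray  # empirical ACGT frequencies (missing excluded)

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    @property
    def partials(self) -> np.ndarray:
        """(4, npat, 4) leaf partial likelihoods (one-hot; missing -> ones)."""
        eye = np.vstack([np.eye(4), np.ones(4)])
        return eye[self.codes]


def compress_alignment(
    aln: CodonAlignment, role_map: Mapping[str, str] | None = None
) -> PartitionData:
    """Site-pattern compression of a quartet alignment in role order."""
    rows = role_ordered_rows(aln, role_map)
    codes = _encode_rows(rows)
    key = ((codes[0].astype(np.int32) * 5 + codes[1]) * 5 + codes[2]) * 5 + codes[3]
    pats, counts = np.unique(key, return_counts=True)
    # decode pattern keys back to per-taxon codes
    dec = np.empty((4, pats.size), dtype=np.int8)
    rem = pats.copy()
    for i in (3, 2, 1, 0):
        dec[i] = rem % 5
        rem //= 5
    obs = codes[codes != _MISSING]
    if obs.size == 0:
        freqs = np.full(4, 0.25)
    else:
        freqs = np.bincount(obs, minlength=4).astype(float)
        freqs /= freqs.sum()
    return PartitionData(dec, counts.astype(float), codes.shape[1], freqs)


# ---------------------------------------------------------------------------
# Vectorized quartet likelihood over partitions
# ---------------------------------------------------------------------------

class QuartetLikelihood:
    """Pruning likelihood on quartet topologies, vectorized over partitions.

    A single gene is the one-partition case.  All partitions must share
    the same model *family* (they may differ in parameter values), which
    keeps the gamma-category axis rectangular.  Branch lengths are shared
    across partitions; model parameters are per-partition.
    """

    def __init__(self, partitions: Sequence[PartitionData]):
        if not partitions:
            raise ValueError("no partitions")
        self.partitions = list(partitions)
        self.part_index = np.concatenate(
            [np.full(p.n_patterns, i, dtype=np.int64) for i, p in enumerate(partitions)]
        )
        self._partials = [
            np.concatenate([p.partials[r] for p in partitions], axis=0)
            for r in range(4)
        ]  # per role: (Npat, 4)
        codes = np.concatenate([p.codes for p in partitions], axis=1)  # (4, Npat)
        self._codes = np.minimum(codes, 3).astype(np.int64)
        self._missing = [codes[r] == 4 for r in range(4)]
        self._any_missing = [m.any() for m in self._missing]
        self.counts = np.concatenate([p.counts for p in partitions])
        self.n_sites = sum(p.n_sites for p in partitions)
        self._models_set = False

    # -- model parameters ---------------------------------------------------

    def set_models(self, spec: ModelSpec, params: Sequence[ModelParams]) -> None:
        """Install one parameter set per partition (shared family ``spec``)."""
        if len(params) != len(self.partitions):
            raise ValueError("one ModelParams per partition required")
        npart = len(params)
        k = spec.n_categories if spec.plus_g else 1
        self.spec = spec
        self.freqs = np.vstack([p.freqs for p in params])  # (npart, 4)
        self.p_inv = np.array([p.p_inv for p in params])
        self.rates = np.ones((npart, k))
        left = np.empty((npart, 4, 4))
        right = np.empty((npart, 4, 4))
        w = np.empty((npart, 4))
        for i, p in enumerate(params):
            Q = build_rate_matrix(p.exch, p.freqs)
            eig = _Eigen(Q, p.freqs)
            left[i], right[i], w[i] = eig.left, eig.right, eig.w
            if spec.plus_g:
                if p.alpha is None:
                    raise ValueError("+G model without alpha")
                self.rates[i] = discretize_gamma(p.alpha, k)
        self._left, self._right, self._w = left, right, w
        # Variable-category rates keep mean 1; the invariant class enters the
        # mixture at rate 0 without rescaling the others (branch lengths are
        # then substitutions per *variable* site under +I).
        self.rates_eff = self.rates
        self._pi_pat = self.freqs[self.part_index]  # (Npat, 4)
        self._models_set = True

    def set_counts(self, counts: np.ndarray) -> None:
        """Replace pattern counts (bootstrap resampling)."""
        if counts.shape != self.counts.shape:
            raise ValueError("counts shape mismatch")
        self.counts = np.asarray(counts, dtype=float)

    def resample_counts(self, rng: np.random.Generator) -> np.ndarray:
        """Multinomial column resample within each partition."""
        out = np.empty_like(self.counts)
        start = 0
        for p in self.partitions:
            n = p.n_patterns
            c = p.counts
            out[start:start + n] = rng.multinomial(int(c.sum()), c / c.sum())
            start += n
        return out

    # -- likelihood ---------------------------------------------------------

    def branch_P(self, t: float) -> np.ndarray:
        """(npart, k, 4, 4) transition matrices for one branch length."""
        # exp(w * t * r) per partition/category
        E = np.exp(self._w[:, None, :] * (t * self.rates_eff)[:, :, None])
        # (left * E) @ right, batched over partition and category
        return np.matmul(self._left[:, None, :, :] * E[:, :, None, :],
                         self._right[:, None, :, :])

    def _site_L(self, topology: Topology, P: Sequence[np.ndarray]) -> np.ndarray:
        """Per-pattern mixture site likelihoods from precomputed P matrices."""
        if not self._models_set:
            raise RuntimeError("set_models first")
        (i1, i2), (j1, j2) = PAIRINGS[topology]
        L = self._partials
        if len(self.partitions) == 1:
            # fast path in (k, n, 4) layout: matmuls over tiny matrices beat
            # einsum's per-call overhead in the optimizer inner loop
            pint = P[4][0]  # (k, 4, 4)
            A = np.matmul(L[i1], P[i1][0].transpose(0, 2, 1)) * np.matmul(
                L[i2], P[i2][0].transpose(0, 2, 1)
            )  # (k, n, 4)
            Bv = np.matmul(L[j1], P[j1][0].transpose(0, 2, 1)) * np.matmul(
                L[j2], P[j2][0].transpose(0, 2, 1)
            )
            inner = np.matmul(Bv, pint.transpose(0, 2, 1))
            Lvar = ((A * inner) @ self.freqs[0]).mean(axis=0)  # (n,)
            pinv = float(self.p_inv[0])
            if pinv > 0:
                allL = L[0] * L[1] * L[2] * L[3]
                Linv = allL @ self.freqs[0]
                return pinv * Linv + (1.0 - pinv) * Lvar
            return Lvar
        idx = self.part_index

        def leaf_cond(Pb: np.ndarray, role: int) -> np.ndarray:
            # one-hot leaf: conditional at the parent is a column gather of P;
            # a missing leaf sums P's rows to 1, i.e. the conditional is 1.
            A = Pb[idx, :, :, self._codes[role]]  # (Npat, k, 4)
            if self._any_missing[role]:
                A[self._missing[role]] = 1.0
            return A

        A = leaf_cond(P[i1], i1) * leaf_cond(P[i2], i2)
        Bv = leaf_cond(P[j1], j1) * leaf_cond(P[j2], j2)
        inner = np.einsum("nkab,nkb->nka", P[4][idx], Bv)
        Lvar = np.einsum("na,nka,nka->nk", self._pi_pat, A, inner).mean(axis=1)
        if np.any(self.p_inv > 0):
            pinv = self.p_inv[idx]
            allL = L[0] * L[1] * L[2] * L[3]  # (Npat, 4) indicator product
            Linv = (self._pi_pat * allL).sum(axis=1)
            return pinv * Linv + (1.0 - pinv) * Lvar
        return Lvar

    def site_likelihoods(self, topology: Topology, branches: Sequence[float]) -> np.ndarray:
        """Per-pattern site likelihoods under the mixture model. (Npat,)"""
        b = np.asarray(branches, dtype=float)
        if b.shape != (5,) or np.any(b < 0):
            raise ValueError("need 5 non-negative branch lengths")
        return self._site_L(topology, [self.branch_P(t) for t in b])

    def lnL_P(self, topology: Topology, P: Sequence[np.ndarray]) -> float:
        site = self._site_L(topology, P)
        return float(self.counts @ np.log(np.maximum(site, 1e-300)))

    def lnL(self, topology: Topology, branches: Sequence[float]) -> float:
        site = self.site_likelihoods(topology, branches)
        return float(self.counts @ np.log(np.maximum(site, 1e-300)))

    def per_partition_lnL(self, topology: Topology, branches: Sequence[float]) -> np.ndarray:
        site = self.site_likelihoods(topology, branches)
        vals = self.counts * np.log(np.maximum(site, 1e-300))
        return np.bincount(self.part_index, weights=vals, minlength=len(self.partitions))


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def optimize_branches(
    ql: QuartetLikelihood,
    topology: Topology,
    branches0: Sequence[float],
    *,
    max_rounds: int = 5,
    tol: float = 1e-6,
    xtol: float = 1e-5,
    maxiter: int = 40,
) -> tuple[np.ndarray, float]:
    """Coordinate ascent: Brent line search per branch length.

    Transition matrices for the four branches not being searched are
    cached, so each line-search evaluation recomputes only one of them.
    """
    b = np.clip(np.asarray(branches0, dtype=float), BRANCH_MIN, BRANCH_MAX)
    P = [ql.branch_P(t) for t in b]
    best = ql.lnL_P(topology, P)
    for _ in range(max_rounds):
        prev = best
        for i in range(5):
            def neg(t: float, i=i) -> float:
                P[i] = ql.branch_P(t)
                return -ql.lnL_P(topology, P)

            res = optimize.minimize_scalar(
                neg,
                bounds=(BRANCH_MIN, BRANCH_MAX),
                method="bounded",
                options={"xatol": xtol, "maxiter": maxiter},
            )
            if -res.fun >= best:
                b[i] = res.x
                best = -res.fun
            P[i] = ql.branch_P(b[i])
        if best - prev < tol:
            break
    return b, best


@dataclass
class ModelFit:
    """A fitted model on one topology: parameters, lnL, and criteria."""

    spec: ModelSpec
    params: ModelParams
    topology: Topology
    branches: np.ndarray
    lnL: float
    k: int
    n_sites: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.lnL + self.k * math.log(self.n_sites)

    @property
    def tree(self) -> QuartetTree:
        return QuartetTree(self.topology, tuple(self.branches))


def _pack(spec: ModelSpec, params: ModelParams) -> np.ndarray:
    theta = []
    for c in range(spec.n_rate_classes):
        if c == spec.gt_class:
            continue
        # representative pair for the class
        k = spec.rate_classes.index(c)
        theta.append(math.log(max(params.exch[k], 1e-8)))
    if spec.plus_i:
        p = min(max(params.p_inv, 1e-6), 0.9999)
        theta.append(math.log(p / (1 - p)))
    if spec.plus_g:
        theta.append(math.log(params.alpha if params.alpha else 1.0))
    return np.array(theta)


def _unpack(spec: ModelSpec, theta: np.ndarray, freqs: np.ndarray) -> ModelParams:
    vals = np.ones(spec.n_rate_classes)
    t = 0
    for c in range(spec.n_rate_classes):
        if c == spec.gt_class:
            continue
        vals[c] = math.exp(min(max(theta[t], -12.0), 12.0))
        t += 1
    exch = vals[np.array(spec.rate_classes)]
    p_inv = 0.0
    if spec.plus_i:
        x = min(max(theta[t], -30.0), 30.0)
        p_inv = 1.0 / (1.0 + math.exp(-x))
        p_inv = min(p_inv, 0.999)
        t += 1
    alpha = None
    if spec.plus_g:
        alpha = math.exp(min(max(theta[t], -5.0), 7.0))
        t += 1
    f = np.full(4, 0.25) if spec.equal_freqs else freqs
    return ModelParams(exch=exch, freqs=f, p_inv=p_inv, alpha=alpha)


def fit_model(
    data: CodonAlignment | PartitionData,
    topology: Topology,
    spec: ModelSpec | str,
    *,
    role_map: Mapping[str, str] | None = None,
    params0: ModelParams | None = None,
    branches0: Sequence[float] | None = None,
    max_rounds: int = 50,
    tol: float = 1e-6,
    branch_xtol: float = 1e-5,
) -> ModelFit:
    """ML fit of one model family on one topology by coordinate ascent.

    Alternates Brent line searches over the five branch lengths with
    Nelder-Mead over the family's free continuous parameters until the
    log-likelihood improves by less than ``tol`` across a full round.
    Starting values: branches 0.1, exchangeabilities 1, p_inv 0.01,
    alpha 1; empirical base frequencies for unequal-frequency families.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_label(spec)
    part = data if isinstance(data, PartitionData) else compress_alignment(data, role_map)
    if part.n_patterns < 1:
        raise ValueError("empty alignment")
    ql = QuartetLikelihood([part])
    params = params0.copy() if params0 is not None else default_params(spec, part.freqs_emp)
    if spec.equal_freqs:
        params.freqs = np.full(4, 0.25)
    b = np.full(5, 0.1) if branches0 is None else np.asarray(branches0, dtype=float)
    ql.set_models(spec, [params])
    best = ql.lnL(topology, b)
    theta = _pack(spec, params)
    converged = False
    for _ in range(max_rounds):
        prev = best
        b, best = optimize_branches(
            ql, topology, b, max_rounds=2, tol=tol, xtol=branch_xtol
        )
        if theta.size:
            def neg(th: np.ndarray) -> float:
                p = _unpack(spec, th, params.freqs)
                ql.set_models(spec, [p])
                return -ql.lnL(topology, b)

            res = optimize.minimize(
                neg, theta, method="Nelder-Mead",
                options={"maxiter": 50 * max(theta.size, 1), "xatol": 1e-3,
                         "fatol": max(tol, 1e-7)},
            )
            if -res.fun >= best:
                theta = res.x
                best = -res.fun
            params = _unpack(spec, theta, params.freqs)
            ql.set_models(spec, [params])
        if best - prev < tol:
            converged = True
            break
    return ModelFit(
        spec=spec,
        params=params,
        topology=topology,
        branches=b,
        lnL=best,
        k=spec.free_parameter_count(),
        n_sites=part.n_sites,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

#: Reduced catalog for pipeline-scale runs (library default is jmt88).
SMALL_CATALOG = ("JC+G", "HKY85+G", "GTR+G")


def model_catalog(which: str | Iterable[str] = "jmt88") -> list[ModelSpec]:
    """Named catalogs: ``"jmt88"`` (11 schemes x 2 freqs x 4 variants),
    ``"small"`` ({JC, HKY85, GTR} x +G), or an iterable of labels."""
    if isinstance(which, str):
        if which == "small":
            return [ModelSpec.from_label(s) for s in SMALL_CATALOG]
        if which == "jmt88":
            out = []
            for name in _SCHEMES:
                for pi_, pg in ((False, False), (True, False), (False, True), (True, True)):
                    out.append(ModelSpec(name, plus_i=pi_, plus_g=pg))
            return out
        raise ValueError(f"unknown catalog {which!r}")
    return [s if isinstance(s, ModelSpec) else ModelSpec.from_label(s) for s in which]


def select_model(
    data: CodonAlignment | PartitionData,
    topology: Topology,
    catalog: str | Iterable[ModelSpec | str] = "jmt88",
    criterion: str = "BIC",
    *,
    role_map: Mapping[str, str] | None = None,
    **fit_kwargs,
) -> ModelFit:
    """Fit every catalog model on one topology; return the criterion argmin.

    Ties are broken by fewer free parameters, then catalog order.
    """
    specs = model_catalog(catalog)
    if not specs:
        raise ValueError("empty catalog")
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError("criterion must be AIC or BIC")
    part = data if isinstance(data, PartitionData) else compress_alignment(data, role_map)
    best: ModelFit | None = None
    best_key: tuple | None = None
    for order, spec in enumerate(specs):
        fit = fit_model(part, topology, spec, **fit_kwargs)
        value = fit.aic if crit == "AIC" else fit.bic
        key = (round(value, 9), fit.k, order)
        if best_key is None or key < best_key:
            best, best_key = fit, key
    assert best is not None
    return best


def log_likelihood(
    data: CodonAlignment | PartitionData,
    tree: QuartetTree,
    spec: ModelSpec | str,
    params: ModelParams,
    *,
    role_map: Mapping[str, str] | None = None,
) -> float:
    """Pruning log-likelihood of a quartet tree under fixed parameters."""
    if isinstance(spec, str):
        spec = ModelSpec.from_label(spec)
    part = data if isinstance(data, PartitionData) else compress_alignment(data, role_map)
    ql = QuartetLikelihood([part])
    ql.set_models(spec, [params])
    return ql.lnL(tree.topology, np.asarray(tree.branches))
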