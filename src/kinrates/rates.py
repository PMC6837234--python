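"""Bayesian estimation of the instantaneous global rate of lexical replacement.

Model
-----
Each meaning's cognate classes form a k-state character evolving on a dated
phylogeny under a continuous-time Markov chain with a single base rate and
frequency-scaled transitions (an F81-style generalization of the Mk model):

    q_ij = mu * pi_j   (i != j),      q_ii = -mu * (1 - pi_i),

with pi fixed at the empirical tip-state frequencies by default. The
reported quantity is the normalized global rate of replacement, the
stationary expected flux

    R = -sum_i pi_i q_ii = mu * (1 - sum_i pi_i^2),

scaled to events per 10,000 years. Phylogenetic uncertainty is integrated
over by letting the MCMC chain move across a posterior sample of trees.

Branch lengths arrive in years; internally they are rescaled to 10-kyr units
so mu is O(1) under the default exponential(mean 1) prior.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from . import _pruning
from .io import prune_to_taxa
from .types import MultistateCharacter, TreeSample, ValidationError

log = logging.getLogger(__name__)

YEARS_PER_UNIT = 10_000.0  # internal time unit: 10 kyr


# ---------------------------------------------------------------------------
# schedules and priors


@dataclasses.dataclass(frozen=True)
class ChainSchedule:
    """MCMC iteration bookkeeping: total, burn-in, thinning interval.

    The retained sample has (total - burn_in)/thin draws, taken at
    iterations burn_in + thin, burn_in + 2*thin, ..., total.
    """

    total: int = 10_010_000
    burn_in: int = 10_000
    thin: int = 1_000

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.total):
            raise ValidationError("burn_in must satisfy 0 <= burn_in < total")
        if self.thin < 1:
            raise ValidationError("thinning interval must be >= 1")
        if (self.total - self.burn_in) % self.thin != 0:
            raise ValidationError("(total - burn_in) must be divisible by thin")

    @property
    def n_draws(self) -> int:
        return (self.total - self.burn_in) // self.thin


#: The published analysis schedule: 10,010,000 iterations, 10,000 burn-in,
#: sampling every 1,000 -> 10,000 retained draws per chain.
PAPER_SCHEDULE = ChainSchedule(10_010_000, 10_000, 1_000)

#: Desk-scale schedule for tests and examples: same bookkeeping invariants,
#: 1,000 retained draws.
TEST_SCHEDULE = ChainSchedule(110_000, 10_000, 100)


@dataclasses.dataclass(frozen=True)
class ExponentialPrior:
    """Exponential prior on the base rate mu (per 10 kyr)."""

    mean: float = 1.0

    @property
    def _kernel_args(self):
        return 0, 1.0 / self.mean, 0.0

    def logpdf(self, mu: float) -> float:
        if mu < 0:
            return -np.inf
        return float(-np.log(self.mean) - mu / self.mean)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(self.mean, size=n)


@dataclasses.dataclass(frozen=True)
class UniformPrior:
    """Uniform prior on mu over (low, high), per 10 kyr."""

    low: float = 0.0
    high: float = 100.0

    @property
    def _kernel_args(self):
        return 1, max(self.low, 1e-300), self.high

    def logpdf(self, mu: float) -> float:
        if self.low <= mu <= self.high:
            return float(-np.log(self.high - self.low))
        return -np.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(max(self.low, 1e-12), self.high, size=n)


Prior = Union[ExponentialPrior, UniformPrior]


# ---------------------------------------------------------------------------
# model pieces


def empirical_frequencies(character: MultistateCharacter) -> np.ndarray:
    """Empirical state frequencies among non-missing tips (no pseudocounts)."""
    states = [s for s in character.states.values() if s is not None]
    if not states:
        raise ValidationError(f"character {character.meaning!r} has no observed tips")
    counts = np.bincount(states, minlength=character.k).astype(float)
    return counts / counts.sum()


def build_q(pi: np.ndarray, mu: float) -> np.ndarray:
    """Rate matrix of the frequency-scaled single-rate model.

    q_ij = mu*pi_j off-diagonal, q_ii = -mu*(1 - pi_i). For k = 1 the matrix
    is the degenerate 1x1 zero (no observable change is possible)."""
    pi = np.asarray(pi, dtype=float)
    _check_pi(pi)
    if mu < 0:
        raise ValidationError("mu must be non-negative")
    k = len(pi)
    if k == 1:
        log.warning("k=1 character: degenerate zero rate matrix")
        return np.zeros((1, 1))
    q = mu * np.tile(pi, (k, 1))
    np.fill_diagonal(q, -mu * (1.0 - pi))
    return q


def global_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Normalized global rate R = -sum_i pi_i q_ii (expected flux at
    stationarity), in the units of q (per year or per 10 kyr)."""
    return float(-np.sum(np.asarray(pi) * np.diag(q)))


def scale_rate(r_per_year: float) -> float:
    """Convert a per-year rate to per-10,000-years. Exact."""
    return r_per_year * YEARS_PER_UNIT


def transition_matrix(pi: np.ndarray, mu: float, t: float) -> np.ndarray:
    """Closed-form transition probabilities p_ij(t) = pi_j + (d_ij - pi_j) e^(-mu t)."""
    if t < 0:
        raise ValidationError("time must be non-negative")
    pi = np.asarray(pi, dtype=float)
    _check_pi(pi)
    k = len(pi)
    e = np.exp(-mu * t)
    return e * np.eye(k) + (1.0 - e) * np.tile(pi, (k, 1))


def _check_pi(pi: np.ndarray) -> None:
    if np.any(pi <= 0):
        raise ValidationError("state frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValidationError(f"state frequencies must sum to 1 (got {pi.sum()!r})")


def validate_q(q: np.ndarray) -> None:
    """Q-matrix invariants: zero row sums, non-negative off-diagonals."""
    q = np.asarray(q, dtype=float)
    if np.max(np.abs(q.sum(axis=1))) > 1e-10:
        raise ValidationError("Q rows must sum to 0")
    off = q[~np.eye(len(q), dtype=bool)]
    if off.size and off.min() < 0:
        raise ValidationError("Q off-diagonals must be non-negative")


def pruning_loglik(
    tree: dendropy.Tree,
    character: MultistateCharacter,
    pi: np.ndarray,
    mu: float,
) -> float:
    """Felsenstein pruning log-likelihood of one character on one tree.

    ``mu`` must be in per-unit-of-branch-length terms (per year for trees in
    years). Missing tips contribute a partial-likelihood vector of ones; the
    root is combined with the ``pi`` weights. Impossible data yield -inf.
    """
    pi = np.asarray(pi, dtype=float)
    _check_pi(pi)
    taxa = sorted({leaf.taxon.label for leaf in tree.leaf_node_iter()})
    extra = set(character.observed_taxa) - set(taxa)
    if extra:
        raise ValidationError(f"character has taxa not on the tree: {sorted(extra)}")
    tindex = {t: i for i, t in enumerate(taxa)}
    tipstate = np.full(len(taxa), -1, dtype=np.int64)
    for t, s in character.states.items():
        if t in tindex and s is not None:
            if s >= len(pi):
                raise ValidationError(f"tip state {s} >= k={len(pi)}")
            tipstate[tindex[t]] = s
    cp, ci, el, lt = _pruning.pack_tree(tree, tindex)
    ll = _pruning.tree_loglik(
        float(mu), pi, 0, len(el), cp, ci, el, lt, tipstate
    )
    if ll == -np.inf:
        log.warning("zero likelihood for character %r", character.meaning)
    return float(ll)


# ---------------------------------------------------------------------------
# MCMC


@dataclasses.dataclass
class RatePosterior:
    """Posterior draws of the normalized replacement rate for one meaning.

    ``rates`` are R draws per 10,000 years; ``mu`` the matching base-rate
    draws (per 10 kyr); ``tree_index``/``loglik`` record, per draw, which
    tree of the sample the chain sat on and the (unpowered) data
    log-likelihood.
    """

    meaning: str
    rates: np.ndarray
    mu: np.ndarray
    tree_index: np.ndarray
    loglik: np.ndarray
    seed: int
    schedule: ChainSchedule
    acceptance: float
    step: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rates) != self.schedule.n_draws:
            raise ValidationError(
                f"draw count {len(self.rates)} != schedule draws {self.schedule.n_draws}"
            )
        if np.any(self.rates < 0):
            raise ValidationError("rates must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.rates.mean())

    def interval(self, prob: float = 0.95) -> tuple[float, float]:
        lo = (1 - prob) / 2
        return tuple(np.quantile(self.rates, [lo, 1 - lo]))


def _prepare(character, trees, pi_mode, prune):
    """Shared setup: resolve pi, prune trees, pack the sample."""
    if isinstance(trees, dendropy.Tree):
        trees = TreeSample([trees])
    elif not isinstance(trees, TreeSample):
        trees = TreeSample(list(trees))
    observed = character.observed_taxa
    if not observed:
        raise ValidationError(f"character {character.meaning!r} is all-missing")
    k = character.k
    if pi_mode == "empirical":
        pi = empirical_frequencies(character)
    elif pi_mode == "uniform":
        pi = np.full(k, 1.0 / k)
    else:
        pi = np.asarray(pi_mode, dtype=float)
    _check_pi(pi)
    use_trees = []
    for t in trees:
        leaf_labels = {l.taxon.label for l in t.leaf_node_iter()}
        if not set(observed) <= leaf_labels:
            raise ValidationError(
                f"tree lacks taxa {sorted(set(observed) - leaf_labels)}"
            )
        if prune and len(observed) >= 2 and set(observed) != leaf_labels:
            use_trees.append(prune_to_taxa(t, observed))
        else:
            use_trees.append(t)
    taxa = sorted({l.taxon.label for t in use_trees for l in t.leaf_node_iter()})
    tindex = {t: i for i, t in enumerate(taxa)}
    tipstate = np.full(len(taxa), -1, dtype=np.int64)
    for t, s in character.states.items():
        if t in tindex and s is not None:
            tipstate[tindex[t]] = s
    packed = _pruning.pack_sample(use_trees, tindex, scale=1.0 / YEARS_PER_UNIT)
    return pi, packed, tipstate, len(use_trees)


def mcmc_rate(
    character: MultistateCharacter,
    trees: Union[TreeSample, dendropy.Tree, Sequence[dendropy.Tree]],
    prior: Prior = ExponentialPrior(),
    schedule: ChainSchedule = PAPER_SCHEDULE,
    seed: int = 0,
    pi_mode: Union[str, np.ndarray] = "empirical",
    prune: bool = True,
    tree_scheme: str = "random",
    power: float = 1.0,
    step0: float = 0.5,
) -> RatePosterior:
    """Sample the posterior of the replacement rate for one meaning.

    Metropolis-Hastings on log mu (Gaussian proposal, adaptive step toward
    0.2-0.4 acceptance during burn-in, frozen afterwards). With the default
    ``tree_scheme='random'`` each iteration proposes, with probability 0.5,
    replacing the current tree by one drawn uniformly from the sample
    (MH-accepted); ``'sequential'`` cycles through the trees in equal chunks
    instead. ``power`` exponentiates the likelihood (0 = prior-only mode).

    Retained mu draws are converted to the normalized global rate
    R = mu (1 - sum pi^2) per 10,000 years. Identical (data, seed, schedule)
    give bit-identical draws.
    """
    if tree_scheme not in ("random", "sequential"):
        raise ValidationError(f"unknown tree_scheme {tree_scheme!r}")
    pi, packed, tipstate, n_trees = _prepare(character, trees, pi_mode, prune)
    node_offset, child_ptr, child_idx, edge_len, leaf_taxon = packed
    rng = np.random.default_rng(seed)
    total = schedule.total
    z = rng.standard_normal(total)
    u_acc = rng.uniform(1e-300, 1.0, total)
    u_move = rng.uniform(0.0, 1.0, total)
    tree_prop = rng.integers(0, n_trees, total)
    mu0 = float(np.median(prior.sample(rng, 11)))
    prior_kind, p1, p2 = prior._kernel_args
    out_logmu, out_tree, out_ll, acc_rate, step = _pruning.run_chain(
        np.log(mu0), 0,
        pi, np.array([0, len(pi)], dtype=np.int64), np.ones(1),
        node_offset, child_ptr, child_idx, edge_len, leaf_taxon,
        tipstate[None, :],
        z, u_acc, u_move, tree_prop,
        total, schedule.burn_in, schedule.thin,
        step0, prior_kind, p1, p2, float(power),
        0 if tree_scheme == "random" else 1, 50,
    )
    mu_draws = np.exp(out_logmu)
    norm = 1.0 - float(np.sum(pi**2))
    rates = mu_draws * norm
    return RatePosterior(
        meaning=character.meaning,
        rates=rates,
        mu=mu_draws,
        tree_index=out_tree,
        loglik=out_ll,
        seed=seed,
        schedule=schedule,
        acceptance=acc_rate,
        step=step,
        pi=pi,
    )


def mcmc_rate_joint(
    characters: Sequence[MultistateCharacter],
    trees: Union[TreeSample, dendropy.Tree, Sequence[dendropy.Tree]],
    prior: Prior = ExponentialPrior(),
    schedule: ChainSchedule = PAPER_SCHEDULE,
    seed: int = 0,
    pi_mode: str = "empirical",
    tree_scheme: str = "random",
    step0: float = 0.5,
) -> RatePosterior:
    """Joint posterior of one shared replacement rate across many characters.

    All characters are assumed to replace at the same normalized rate R (per
    10 kyr); character c contributes its pruning likelihood at base rate
    mu_c = R / (1 - sum pi_c^2). Constant (k=1) characters carry no signal
    under the model and are skipped with a log message. The sampler walks
    log R with the prior placed on R itself.
    """
    characters = list(characters)
    usable = [c for c in characters if c.k >= 2]
    skipped = len(characters) - len(usable)
    if skipped:
        log.info("skipping %d constant characters (no signal under the model)", skipped)
    if not usable:
        raise ValidationError("no characters with >= 2 states")
    if isinstance(trees, dendropy.Tree):
        trees = TreeSample([trees])
    elif not isinstance(trees, TreeSample):
        trees = TreeSample(list(trees))
    taxa = sorted({l.taxon.label for t in trees for l in t.leaf_node_iter()})
    tindex = {t: i for i, t in enumerate(taxa)}
    pis, facs = [], []
    tipstates = np.full((len(usable), len(taxa)), -1, dtype=np.int64)
    for ci, c in enumerate(usable):
        extra = set(c.observed_taxa) - set(taxa)
        if extra:
            raise ValidationError(f"character taxa not on trees: {sorted(extra)}")
        if pi_mode == "empirical":
            pi = empirical_frequencies(c)
        elif pi_mode == "uniform":
            pi = np.full(c.k, 1.0 / c.k)
        else:
            raise ValidationError("pi_mode must be 'empirical' or 'uniform'")
        norm = 1.0 - float(np.sum(pi**2))
        pis.append(pi)
        facs.append(1.0 / norm)
        for t, s in c.states.items():
            if s is not None:
                tipstates[ci, tindex[t]] = s
    pi_flat = np.concatenate(pis)
    pi_off = np.zeros(len(pis) + 1, dtype=np.int64)
    pi_off[1:] = np.cumsum([len(p) for p in pis])
    fac = np.asarray(facs)
    node_offset, child_ptr, child_idx, edge_len, leaf_taxon = _pruning.pack_sample(
        list(trees), tindex, scale=1.0 / YEARS_PER_UNIT
    )
    n_trees = len(trees)
    rng = np.random.default_rng(seed)
    total = schedule.total
    z = rng.standard_normal(total)
    u_acc = rng.uniform(1e-300, 1.0, total)
    u_move = rng.uniform(0.0, 1.0, total)
    tree_prop = rng.integers(0, n_trees, total)
    r0 = float(np.median(prior.sample(rng, 11)))
    prior_kind, p1, p2 = prior._kernel_args
    out_logr, out_tree, out_ll, acc_rate, step = _pruning.run_chain(
        np.log(r0), 0, pi_flat, pi_off, fac,
        node_offset, child_ptr, child_idx, edge_len, leaf_taxon, tipstates,
        z, u_acc, u_move, tree_prop,
        total, schedule.burn_in, schedule.thin,
        step0, prior_kind, p1, p2, 1.0,
        0 if tree_scheme == "random" else 1, 50,
    )
    r_draws = np.exp(out_logr)
    return RatePosterior(
        meaning=usable[0].meaning,
        rates=r_draws,
        mu=r_draws,
        tree_index=out_tree,
        loglik=out_ll,
        seed=seed,
        schedule=schedule,
        acceptance=acc_rate,
        step=step,
        pi=np.asarray([]),
    )


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


@dataclasses.dataclass
class SteppingStoneResult:
    """Stepping-stone marginal-likelihood estimate.

    ``betas`` are the K+1 power-posterior exponents 0 = b_0 < ... < b_K = 1
    (Beta(0.3, 1) quantile spacing); ``log_ml`` is the summed log mean
    likelihood ratio between adjacent rungs."""

    n_stones: int
    betas: np.ndarray
    iters_per_stone: int
    log_ml: float
    per_stone: np.ndarray

    def __post_init__(self) -> None:
        b = self.betas
        if not (b[0] >= 0 and np.all(np.diff(b) > 0) and abs(b[-1] - 1.0) < 1e-12):
            raise ValidationError("betas must be strictly increasing from 0 to 1")


def stepping_stone_betas(n_stones: int, alpha: float = 0.3) -> np.ndarray:
    """Power ladder: quantiles of Beta(alpha, 1), i.e. (k/K)^(1/alpha)."""
    k = np.arange(n_stones + 1)
    return (k / n_stones) ** (1.0 / alpha)


def stepping_stone(
    character: MultistateCharacter,
    trees: Union[TreeSample, dendropy.Tree, Sequence[dendropy.Tree]],
    prior: Prior = ExponentialPrior(),
    n_stones: int = 100,
    iters_per_stone: int = 1_000,
    seed: int = 0,
    pi_mode: Union[str, np.ndarray] = "empirical",
    prune: bool = True,
    alpha: float = 0.3,
    step0: float = 0.5,
) -> SteppingStoneResult:
    """Estimate the log marginal likelihood by stepping-stone sampling.

    For each rung b_k the chain samples the power posterior L^(b_k) * prior
    (warm-started from the previous rung) and the estimator accumulates
    log mean L^(b_{k+1} - b_k). With likelihood identically 1 the estimate
    is exactly 0.
    """
    pi, packed, tipstate, n_trees = _prepare(character, trees, pi_mode, prune)
    node_offset, child_ptr, child_idx, edge_len, leaf_taxon = packed
    betas = stepping_stone_betas(n_stones, alpha)
    rng = np.random.default_rng(seed)
    prior_kind, p1, p2 = prior._kernel_args
    logmu = float(np.log(np.median(prior.sample(rng, 11))))
    tree0 = 0
    warm = max(50, iters_per_stone // 10)
    per_stone = np.zeros(n_stones)
    step = step0
    for k in range(n_stones):
        total = warm + iters_per_stone
        z = rng.standard_normal(total)
        u_acc = rng.uniform(1e-300, 1.0, total)
        u_move = rng.uniform(0.0, 1.0, total)
        tree_prop = rng.integers(0, n_trees, total)
        out_logmu, out_tree, out_ll, _, step = _pruning.run_chain(
            logmu, tree0,
            pi, np.array([0, len(pi)], dtype=np.int64), np.ones(1),
            node_offset, child_ptr, child_idx, edge_len, leaf_taxon,
            tipstate[None, :],
            z, u_acc, u_move, tree_prop,
            total, warm, 1,
            step, prior_kind, p1, p2, float(betas[k]),
            0, 25,
        )
        logmu = float(out_logmu[-1])
        tree0 = int(out_tree[-1])
        d = betas[k + 1] - betas[k]
        w = d * out_ll
        m = w.max()
        if not np.isfinite(m):
            log.warning("degenerate likelihood at stone %d", k)
            per_stone[k] = -np.inf
        else:
            per_stone[k] = m + np.log(np.mean(np.exp(w - m)))
    return SteppingStoneResult(
        n_stones=n_stones,
        betas=betas,
        iters_per_stone=iters_per_stone,
        log_ml=float(per_stone.sum()),
        per_stone=per_stone,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries


@dataclasses.dataclass
class ConvergenceReport:
    """Gelman-Rubin diagnostic for one meaning's chains."""

    psrf: float
    n_chains: int
    passed: bool
    threshold: float = 1.1


def gelman_rubin(
    chains: Sequence[np.ndarray], threshold: float = 1.1
) -> ConvergenceReport:
    """Split-chain potential scale reduction factor (PSRF).

    Each chain is split in half; PSRF compares between- and within-half
    variances. Values near 1 indicate the chains have mixed over the same
    distribution; the default pass threshold is 1.1.
    """
    arrs = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(arrs) < 2:
        raise ValidationError("gelman_rubin needs at least 2 chains")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValidationError("chains must have equal length")
    half = n // 2
    splits = []
    for a in arrs:
        splits.append(a[:half])
        splits.append(a[half: 2 * half])
    x = np.asarray(splits)
    m, n2 = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0:
        psrf = 1.0 if b == 0 else np.inf
    else:
        var_hat = (n2 - 1) / n2 * w + b / n2
        psrf = float(np.sqrt(var_hat / w))
    return ConvergenceReport(
        psrf=psrf, n_chains=len(arrs), passed=bool(psrf < threshold), threshold=threshold
    )


@dataclasses.dataclass
class RateSummary:
    """Pooled posterior summary for one meaning (rates per 10 kyr)."""

    meaning: str
    mean: float
    ci_low: float
    ci_high: float
    psrf: float
    n_chains: int
    n_draws: int


def summarize(
    posteriors: Sequence[RatePosterior], ci: float = 0.95
) -> RateSummary:
    """Pool the post-burn-in draws of several chains for one meaning.

    Chains are concatenated (order-invariant for the reported statistics);
    the mean and an equal-tail credible interval are reported together with
    the split-chain PSRF. A failed diagnostic warns but does not block."""
    if not posteriors:
        raise ValidationError("no posteriors to summarize")
    meanings = {p.meaning for p in posteriors}
    if len(meanings) > 1:
        raise ValidationError(f"posteriors mix meanings: {sorted(meanings)}")
    draws = np.concatenate([p.rates for p in posteriors])
    if len(posteriors) >= 2:
        report = gelman_rubin([p.rates for p in posteriors])
        if not report.passed:
            warnings.warn(
                f"{posteriors[0].meaning}: PSRF {report.psrf:.3f} exceeds "
                f"{report.threshold}; chains may not have converged"
            )
        psrf = report.psrf
    else:
        psrf = float("nan")
    lo = (1 - ci) / 2
    qlo, qhi = np.quantile(draws, [lo, 1 - lo])
    return RateSummary(
        meaning=posteriors[0].meaning,
        mean=float(draws.mean()),
        ci_low=float(qlo),
        ci_high=float(qhi),
        psrf=psrf,
        n_chains=len(posteriors),
        n_draws=len(draws),
    )
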