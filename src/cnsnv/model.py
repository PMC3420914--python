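"""Copy-number-aware Binomial mixture model for SNV calling.

The model stratifies genomic positions by a discrete somatic copy-number
state and, within each stratum of ploidy ``c``, explains the observed
reference-matching read count ``a`` out of depth ``N`` with a mixture of
``c + 1`` Binomial components — one per genotype ``a..a``, ``a..ab``, ...,
``b..b``.  Amplified strata therefore admit genotypes such as ``aaaab``
whose expected reference-read fraction (~0.8 at five copies) is far from
the diploid heterozygous 0.5, which is what lets the model recover
variants with heavily skewed allelic ratios that a diploid caller scores
as noise.

Parameters are estimated per stratum by MAP expectation-maximization
under conjugate priors: a Dirichlet prior over the genotype weights
``pi_c`` (heavily favouring the all-reference genotype) and a Beta prior
on each Binomial success probability ``mu_{c,k}`` (near-pure at the
homozygous-reference end, decreasing toward homozygous variant).  The
per-position evidence for a variant is ``p(SNV) = 1 - P(all-reference
genotype | a, N, c)``.
"""
from __future__ import annotations

import enum
import functools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import binom as _binom

logger = logging.getLogger(__name__)

#: positions with p(SNV) at or above this value are flagged as SNVs
DEFAULT_THRESHOLD = 0.77

#: Binomial success probabilities are kept inside this open interval
MU_FLOOR = 1e-6

_PI_FLOOR = 1e-12


class CNAState(enum.IntEnum):
    """Discrete copy-number state of a segment.

    The integer encoding doubles as the ploidy used to build the genotype
    space.  Deletions are analysed with the neutral (diploid) state space,
    hence the single NEUT_LOSS state at code 2.
    """

    NEUT_LOSS = 2
    GAIN = 3
    AMP = 4
    HLAMP = 5

    @property
    def ploidy(self) -> int:
        return int(self)

    @classmethod
    def from_code(cls, code) -> "CNAState":
        try:
            return cls(int(code))
        except (ValueError, TypeError):
            raise ValueError(
                f"unknown copy-number state code {code!r}: expected one of "
                "2 (NEUT/LOSS), 3 (GAIN), 4 (AMP), 5 (HLAMP)"
            ) from None


@dataclass(frozen=True)
class GenotypeSpace:
    """Ordered genotypes allowed in one copy-number state.

    Genotypes run from all-reference to all-variant in strictly decreasing
    reference-allele count; index 0 is the unique non-variant genotype.
    """

    state: CNAState
    genotypes: Tuple[str, ...]
    ref_counts: Tuple[int, ...]

    def __len__(self) -> int:
        return len(self.genotypes)


@functools.lru_cache(maxsize=None)
def genotype_space(state: CNAState) -> GenotypeSpace:
    """Enumerate the ploidy+1 genotypes induced by a copy-number state.

    >>> genotype_space(CNAState.NEUT_LOSS).genotypes
    ('aa', 'ab', 'bb')
    """
    state = CNAState.from_code(state)
    c = state.ploidy
    genotypes = tuple("a" * r + "b" * (c - r) for r in range(c, -1, -1))
    ref_counts = tuple(range(c, -1, -1))
    return GenotypeSpace(state=state, genotypes=genotypes, ref_counts=ref_counts)


@dataclass(frozen=True)
class AllelicCount:
    """Observed allelic counts at one genomic position.

    ``ref_count`` is the number of aligned reads matching the reference
    base; ``depth`` the total number of aligned reads.
    """

    chrom: str
    pos: int
    ref_count: int
    depth: int
    state: CNAState = CNAState.NEUT_LOSS

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not (0 <= self.ref_count <= self.depth):
            raise ValueError(
                f"need 0 <= ref_count <= depth, got ref_count={self.ref_count} "
                f"depth={self.depth} at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class Hyperparams:
    """Conjugate prior settings, one block per copy-number state.

    ``delta[c]`` are Dirichlet pseudocounts over the K_c genotypes;
    ``alpha[c]``/``beta[c]`` the Beta parameters of each ``mu_{c,k}``.
    """

    delta: Mapping[CNAState, np.ndarray]
    alpha: Mapping[CNAState, np.ndarray]
    beta: Mapping[CNAState, np.ndarray]

    def __post_init__(self):
        for state in CNAState:
            k = len(genotype_space(state))
            for name in ("delta", "alpha", "beta"):
                vec = np.asarray(getattr(self, name)[state], dtype=float)
                if vec.shape != (k,):
                    raise ValueError(
                        f"{name}[{state.name}] must have length {k}, got {vec.shape}"
                    )
                if not np.all(vec > 0):
                    raise ValueError(f"{name}[{state.name}] must be strictly positive")

    def mu_means(self, state: CNAState) -> np.ndarray:
        """Prior (Beta) mean of each Binomial success probability."""
        a, b = np.asarray(self.alpha[state], float), np.asarray(self.beta[state], float)
        return a / (a + b)

    def pi_means(self, state: CNAState) -> np.ndarray:
        """Prior (Dirichlet) mean of the genotype weights."""
        d = np.asarray(self.delta[state], float)
        return d / d.sum()


def default_hyperparams(
    epsilon: float = 0.01,
    concentration: float = 100.0,
    delta_ref: float = 1000.0,
    delta_var: float = 2.0,
) -> Hyperparams:
    """Repository-default priors.

    For a genotype with ``r`` reference alleles at ploidy ``c`` the Beta
    mean is ``(1-epsilon)*(r/c) + epsilon*(1-r/c)``: homozygous-reference
    positions are nearly pure (mean 0.99 at the default sequencing-error
    rate ``epsilon``) and the mean decreases linearly toward homozygous
    variant.  The Dirichlet puts ``delta_ref`` pseudocounts on the
    all-reference genotype and ``delta_var`` on each variant genotype, so
    the prior genotype weights favour wild type (~99% at the defaults).
    """
    if not (0 < epsilon < 0.5):
        raise ValueError("epsilon must be in (0, 0.5)")
    delta, alpha, beta = {}, {}, {}
    for state in CNAState:
        space = genotype_space(state)
        c = state.ploidy
        frac = np.array(space.ref_counts, float) / c
        means = (1.0 - epsilon) * frac + epsilon * (1.0 - frac)
        alpha[state] = means * concentration
        beta[state] = (1.0 - means) * concentration
        d = np.full(len(space), delta_var, float)
        d[0] = delta_ref
        delta[state] = d
    return Hyperparams(delta=delta, alpha=alpha, beta=beta)


@dataclass
class ModelParams:
    """Fitted mixture parameters per copy-number state."""

    mu: Dict[CNAState, np.ndarray]
    pi: Dict[CNAState, np.ndarray]

    @classmethod
    def from_prior(cls, hyper: Hyperparams) -> "ModelParams":
        mu = {s: hyper.mu_means(s).copy() for s in CNAState}
        pi = {s: hyper.pi_means(s).copy() for s in CNAState}
        return cls(mu=mu, pi=pi)

    def validate(self) -> None:
        for state in CNAState:
            mu, pi = self.mu[state], self.pi[state]
            k = len(genotype_space(state))
            if mu.shape != (k,) or pi.shape != (k,):
                raise ValueError(f"parameter length mismatch for {state.name}")
            if not (np.all(mu > 0) and np.all(mu < 1)):
                raise ValueError(f"mu out of (0,1) for {state.name}")
            if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8) or np.any(pi < 0):
                raise ValueError(f"pi not a probability simplex for {state.name}")

    def to_file(self, path) -> None:
        """Serialize as a flat text table: state, genotype, mu, pi per line."""
        with open(path, "w") as fh:
            fh.write("# cnsnv model parameters v1\n")
            fh.write("state_code\tgenotype\tmu\tpi\n")
            for state in CNAState:
                space = genotype_space(state)
                for g, m, p in zip(space.genotypes, self.mu[state], self.pi[state]):
                    fh.write(f"{int(state)}\t{g}\t{m:.17g}\t{p:.17g}\n")

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        mu = {s: {} for s in CNAState}
        pi = {s: {} for s in CNAState}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("state_code"):
                    continue
                code, g, m, p = line.split("\t")
                state = CNAState.from_code(code)
                mu[state][g] = float(m)
                pi[state][g] = float(p)
        out_mu, out_pi = {}, {}
        for state in CNAState:
            space = genotype_space(state)
            missing = [g for g in space.genotypes if g not in mu[state]]
            if missing:
                raise ValueError(f"parameter file {path} missing genotypes {missing}")
            out_mu[state] = np.array([mu[state][g] for g in space.genotypes])
            out_pi[state] = np.array([pi[state][g] for g in space.genotypes])
        params = cls(mu=out_mu, pi=out_pi)
        params.validate()
        return params


@dataclass
class StateFit:
    """Per-state EM diagnostics."""

    n_positions: int
    iterations: int
    converged: bool
    fitted: bool
    log_posterior_trace: list = field(default_factory=list)


@dataclass
class FitReport:
    states: Dict[CNAState, StateFit] = field(default_factory=dict)


@dataclass
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-6  # relative change in complete-data log posterior
    min_depth: int = 1


@dataclass
class SNVCall:
    """Classification result at one position."""

    chrom: str
    pos: int
    state: CNAState
    posterior: np.ndarray
    map_genotype: str
    p_snv: float
    passed: bool
    nocall: bool = False


def log_likelihood(ref_count, depth, mu_ck):
    """log Binomial(ref_count | depth, mu_ck), elementwise.

    Computed in the log domain; finite for every valid (a, N) pair
    including the empty observation N = 0 (log 1 = 0).
    """
    mu = np.asarray(mu_ck, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError(f"mu must lie strictly inside (0, 1), got {mu_ck!r}")
    a = np.asarray(ref_count)
    n = np.asarray(depth)
    if np.any(a < 0) or np.any(a > n):
        raise ValueError("need 0 <= ref_count <= depth")
    return _binom.logpmf(a, n, mu)


def posterior_matrix(ref_count, depth, mu: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Genotype posteriors for many positions at once.

    Returns an (n_positions, K) row-normalized matrix computed via
    log-sum-exp: row_i ~ pi_k * Binom(a_i | N_i, mu_k).
    """
    a = np.atleast_1d(np.asarray(ref_count))
    n = np.atleast_1d(np.asarray(depth))
    logw = log_likelihood(a[:, None], n[:, None], mu[None, :]) + np.log(pi)[None, :]
    norm = logsumexp(logw, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise RuntimeError("all genotype components carry zero mass at some position")
    return np.exp(logw - norm)


def genotype_posterior(count: AllelicCount, params: ModelParams) -> np.ndarray:
    """Posterior probability that each genotype gave rise to one observation."""
    if count.state not in params.mu:
        raise KeyError(f"no parameters for state {count.state!r}")
    return posterior_matrix(
        count.ref_count, count.depth, params.mu[count.state], params.pi[count.state]
    )[0]


def p_snv(posterior: np.ndarray, space: GenotypeSpace) -> float:
    """Probability that the position carries any variant-containing genotype.

    Equals one minus the posterior mass on the all-reference genotype.
    """
    posterior = np.asarray(posterior, float)
    if posterior.shape[-1] != len(space):
        raise ValueError(
            f"posterior length {posterior.shape[-1]} does not match "
            f"{len(space)} genotypes of {space.state.name}"
        )
    return float(1.0 - posterior[..., 0])


def snv_scores(ref_count, depth, mu: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Vectorized p(SNV) for arrays of counts under one state's parameters."""
    return 1.0 - posterior_matrix(ref_count, depth, mu, pi)[:, 0]


def _dirichlet_logpdf(pi: np.ndarray, delta: np.ndarray) -> float:
    return float(
        np.sum((delta - 1.0) * np.log(pi)) + gammaln(delta.sum()) - gammaln(delta).sum()
    )


def _beta_logpdf(mu: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> float:
    return float(
        np.sum((alpha - 1.0) * np.log(mu) + (beta - 1.0) * np.log1p(-mu))
        - betaln(alpha, beta).sum()
    )


def _log_posterior(a, n, mu, pi, delta, alpha, beta):
    logw = _binom.logpmf(a[:, None], n[:, None], mu[None, :]) + np.log(pi)[None, :]
    per_pos = logsumexp(logw, axis=1)
    obj = per_pos.sum() + _dirichlet_logpdf(pi, delta) + _beta_logpdf(mu, alpha, beta)
    return obj, logw, per_pos


def fit_em(
    counts: pd.DataFrame,
    hyper: Optional[Hyperparams] = None,
    config: Optional[EMConfig] = None,
) -> Tuple[ModelParams, FitReport]:
    """MAP-EM, run independently for each copy-number stratum.

    ``counts`` needs columns ``ref_count``, ``depth``, ``state_code``.
    Parameters start at the prior means; each E-step computes genotype
    responsibilities, each M-step applies the conjugate MAP updates
    (Dirichlet pseudocounts added to responsibility sums for pi, Beta
    pseudocounts added to responsibility-weighted reference counts and
    depths for mu).  Iteration stops when the complete-data log posterior
    increases by less than ``tol`` (relative) or after ``max_iter`` steps.
    States with no usable positions keep their prior means and are
    flagged unfitted in the report.
    """
    hyper = hyper if hyper is not None else default_hyperparams()
    config = config if config is not None else EMConfig()
    params = ModelParams.from_prior(hyper)
    report = FitReport()

    for state in CNAState:
        sub = counts[
            (counts["state_code"] == int(state)) & (counts["depth"] >= config.min_depth)
        ]
        if len(sub) == 0:
            report.states[state] = StateFit(0, 0, False, fitted=False)
            continue
        a = sub["ref_count"].to_numpy(dtype=float)
        n = sub["depth"].to_numpy(dtype=float)
        delta = np.asarray(hyper.delta[state], float)
        alpha = np.asarray(hyper.alpha[state], float)
        beta = np.asarray(hyper.beta[state], float)
        mu = params.mu[state].copy()
        pi = params.pi[state].copy()

        trace: list = []
        converged = False
        prev = -np.inf
        for _ in range(config.max_iter + 1):
            obj, logw, per_pos = _log_posterior(a, n, mu, pi, delta, alpha, beta)
            if not np.isfinite(obj):
                raise RuntimeError(
                    f"non-finite log posterior in state {state.name} "
                    f"(iteration {len(trace)})"
                )
            trace.append(obj)
            if trace and len(trace) > 1 and abs(obj - prev) < config.tol * abs(prev):
                converged = True
                break
            prev = obj
            if len(trace) > config.max_iter:
                break
            # E-step responsibilities
            resp = np.exp(logw - per_pos[:, None])
            # M-step: conjugate MAP updates
            pi = resp.sum(axis=0) + delta - 1.0
            pi = np.maximum(pi, _PI_FLOOR)
            pi = pi / pi.sum()
            num = resp.T @ a + alpha - 1.0
            den = resp.T @ n + alpha + beta - 2.0
            mu = np.clip(num / den, MU_FLOOR, 1.0 - MU_FLOOR)
            if np.any(np.diff(mu) >= 0):
                logger.warning(
                    "mu no longer strictly decreasing over the genotype order in "
                    "state %s (possible label switching): %s",
                    state.name,
                    mu,
                )
        params.mu[state] = mu
        params.pi[state] = pi
        report.states[state] = StateFit(
            n_positions=len(sub),
            iterations=len(trace) - 1,
            converged=converged,
            fitted=True,
            log_posterior_trace=trace,
        )
    return params, report


def classify(
    count: AllelicCount,
    params: ModelParams,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = 1,
) -> SNVCall:
    """Score a single position.

    Below ``min_depth`` the position is a no-call: the posterior falls
    back to the prior genotype weights and the pass flag is False.  Ties
    in the MAP genotype break toward the more reference-rich genotype
    (argmax returns the first maximum, and genotypes are ordered from
    all-reference down).
    """
    space = genotype_space(count.state)
    if count.depth < min_depth:
        post = params.pi[count.state].copy()
        post = post / post.sum()
        return SNVCall(
            chrom=count.chrom,
            pos=count.pos,
            state=count.state,
            posterior=post,
            map_genotype=space.genotypes[int(np.argmax(post))],
            p_snv=p_snv(post, space),
            passed=False,
            nocall=True,
        )
    post = genotype_posterior(count, params)
    prob = p_snv(post, space)
    return SNVCall(
        chrom=count.chrom,
        pos=count.pos,
        state=count.state,
        posterior=post,
        map_genotype=space.genotypes[int(np.argmax(post))],
        p_snv=prob,
        passed=prob >= threshold,
        nocall=False,
    )


def classify_positions(
    counts: pd.DataFrame,
    params: ModelParams,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Score every position in a counts table.

    Returns the call table: one row per classified position with the
    per-genotype posterior (as an array-valued column), MAP genotype,
    p(SNV), and the threshold pass flag.  Positions below ``min_depth``
    are no-calls and are excluded (logged).
    """
    usable = counts[counts["depth"] >= min_depth]
    n_dropped = len(counts) - len(usable)
    if n_dropped:
        logger.info("dropping %d position(s) below min_depth=%d", n_dropped, min_depth)
    frames = []
    for code, sub in usable.groupby("state_code", sort=True):
        state = CNAState.from_code(code)
        space = genotype_space(state)
        post = posterior_matrix(
            sub["ref_count"].to_numpy(), sub["depth"].to_numpy(),
            params.mu[state], params.pi[state],
        )
        scores = 1.0 - post[:, 0]
        map_idx = np.argmax(post, axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "ref_count": sub["ref_count"].to_numpy(),
                    "depth": sub["depth"].to_numpy(),
                    "state_code": int(state),
                    "map_genotype": [space.genotypes[i] for i in map_idx],
                    "p_snv": scores,
                    "passed": scores >= threshold,
                    "posterior": list(post),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "ref_count", "depth", "state_code",
                "map_genotype", "p_snv", "passed", "posterior",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def force_state(counts: pd.DataFrame, state: CNAState = CNAState.NEUT_LOSS) -> pd.DataFrame:
    """Copy of a counts table with every position assigned one state."""
    out = counts.copy()
    out["state_code"] = int(state)
    return out


def diploid_baseline(
    counts: pd.DataFrame,
    hyper: Optional[Hyperparams] = None,
    config: Optional[EMConfig] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> Tuple[pd.DataFrame, ModelParams, FitReport]:
    """Diploid comparator: the identical pipeline with every position
    forced to the neutral three-genotype state space (the copy-number-blind
    caller the full model is benchmarked against)."""
    forced = force_state(counts, CNAState.NEUT_LOSS)
    cfg = config if config is not None else EMConfig()
    params, report = fit_em(forced, hyper, cfg)
    calls = classify_positions(forced, params, threshold=threshold, min_depth=cfg.min_depth)
    return calls, params, report
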