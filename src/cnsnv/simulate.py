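"""Synthetic allelic-count generator for the in-silico study design.

Each copy-number stratum gets ``n_per_state`` positions.  A position's
genotype is drawn from the stratum's prior genotype weights, its depth
from a zero-truncated Poisson, and its reference-read count from a
Binomial whose success probability is the genotype's prior-mean
reference fraction.  This mirrors how the model itself explains data, so
parameter recovery and the ROC comparison measure the method rather than
model mismatch; real tumour data additionally carry alignment artefacts,
normal-cell admixture and depth autocorrelation that the generator does
not emulate.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .model import CNAState, Hyperparams, default_hyperparams, genotype_space

#: gap between per-state position blocks on the synthetic chromosome
_BLOCK = 10_000_000


@dataclass
class SimConfig:
    """Study-design knobs.

    Defaults are the simulation-study conditions: 1000 positions per
    copy-number state, 100 independent test sets, Poisson mean depth 30
    (zero depths resampled), priors as in :func:`default_hyperparams`.
    """

    n_per_state: int = 1000
    n_test_sets: int = 100
    depth_lambda: float = 30.0
    seed: int = 0
    hyper: Optional[Hyperparams] = None
    sample_params: bool = False  # draw mu/pi from the priors instead of their means

    def __post_init__(self):
        if self.n_per_state < 1:
            raise ValueError("n_per_state must be >= 1")
        if self.depth_lambda <= 0:
            raise ValueError("depth_lambda must be > 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def state_block(state: CNAState) -> Tuple[int, int]:
    """1-based inclusive coordinate block reserved for a state's positions."""
    start = (int(state) - 2) * _BLOCK + 1
    return start, start + _BLOCK - 1


def default_segments(n_per_state: Optional[int] = None) -> pd.DataFrame:
    """Segment table matching the generator's position layout."""
    rows = []
    for state in CNAState:
        start, end = state_block(state)
        if n_per_state is not None:
            end = start + n_per_state - 1
        rows.append(("1", start, end, int(state)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state_code"])


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    depth = rng.poisson(lam, size)
    while True:
        zero = depth == 0
        if not zero.any():
            return depth
        depth[zero] = rng.poisson(lam, int(zero.sum()))


def simulate_dataset(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one dataset: (counts table, per-position truth table).

    Truth rows carry the generating genotype and a binary variant label
    (genotype is not the all-reference one).  Fully deterministic given
    the configuration seed (or a supplied generator).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    hyper = config.hyper if config.hyper is not None else default_hyperparams()
    count_rows, truth_rows = [], []
    for state in CNAState:
        space = genotype_space(state)
        if config.sample_params:
            pi = rng.dirichlet(np.asarray(hyper.delta[state], float))
            mu = rng.beta(
                np.asarray(hyper.alpha[state], float),
                np.asarray(hyper.beta[state], float),
            )
        else:
            pi = hyper.pi_means(state)
            mu = hyper.mu_means(state)
        n = config.n_per_state
        geno_idx = rng.choice(len(space), size=n, p=pi)
        depth = _truncated_poisson(rng, config.depth_lambda, n)
        ref = rng.binomial(depth, mu[geno_idx])
        start = state_block(state)[0]
        pos = np.arange(start, start + n)
        count_rows.append(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": pos,
                    "ref_count": ref,
                    "depth": depth,
                    "state_code": int(state),
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": pos,
                    "genotype": [space.genotypes[i] for i in geno_idx],
                    "is_variant": (geno_idx != 0).astype(np.int64),
                    "state_code": int(state),
                }
            )
        )
    counts = pd.concat(count_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return counts, truth


def make_fixture(
    out_dir, tiny: bool = True, seed: int = 0, depth_lambda: float = 30.0
) -> dict:
    """Write a small counts/segments/truth fixture for tests and demos.

    With ``tiny`` the fixture holds 100 positions per copy-number state
    (400 count rows); otherwise the full 1000 per state.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 100 if tiny else 1000
    config = SimConfig(n_per_state=n, depth_lambda=depth_lambda, seed=seed)
    counts, truth = simulate_dataset(config)
    paths = {
        "counts": out / "counts.tsv",
        "segments": out / "segments.tsv",
        "truth": out / "truth.tsv",
    }
    counts[["chrom", "pos", "ref_count", "depth"]].to_csv(
        paths["counts"], sep="\t", index=False
    )
    default_segments(n).to_csv(paths["segments"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
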