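"""ROC machinery and the copy-number-aware vs. diploid simulation study.

The study trains both callers on one simulated training set, scores 100
independent test sets, and reports per-stratum mean AUC and mean
sensitivity at false positive rates 0.01, 0.05 and 0.1 with percentile
95% confidence intervals over the replicates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import sklearn.metrics as _skm

from .model import (
    CNAState,
    EMConfig,
    default_hyperparams,
    fit_em,
    force_state,
    snv_scores,
)
from .simulate import SimConfig, simulate_dataset

FPR_TARGETS = (0.01, 0.05, 0.1)


@dataclass
class RocResult:
    """One ROC sweep: descending thresholds, paired FPR/TPR, trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocResult:
    """Threshold sweep over the unique score values (ties grouped).

    Requires at least one positive and one negative label; the curve
    always contains the (0,0) and (1,1) endpoints.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError(
            "ROC needs at least one positive and one negative label "
            f"(got {n_pos} positives out of {len(labels)})"
        )
    fpr, tpr, thresholds = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr))
    )


def sensitivity_at_fpr(roc: RocResult, fpr_target: float) -> float:
    """TPR at the largest achieved FPR <= target (step function, no
    interpolation).  Below the smallest achievable nonzero FPR this is
    the TPR at FPR 0."""
    idx = int(np.searchsorted(roc.fpr, fpr_target, side="right")) - 1
    idx = max(idx, 0)
    # among ties in fpr, take the highest tpr (the achieved operating point)
    while idx + 1 < len(roc.fpr) and roc.fpr[idx + 1] == roc.fpr[idx]:
        idx += 1
    return float(roc.tpr[idx])


@dataclass
class StudyResult:
    """Replicate-level metrics and their aggregate summary table."""

    replicates: pd.DataFrame  # one row per (test set, state, model)
    table: pd.DataFrame  # mean and 95% CI per (state, model, metric)
    params: Dict[str, object]


def _metric_columns(fpr_targets: Sequence[float]):
    return ["auc"] + [f"sens@{t:g}" for t in fpr_targets]


def run_simulation_study(
    config: Optional[SimConfig] = None,
    fpr_targets: Sequence[float] = FPR_TARGETS,
    em_config: Optional[EMConfig] = None,
) -> StudyResult:
    """Train and benchmark the copy-number-aware model against the diploid
    comparator on simulated data.

    One training set (``config.n_per_state`` positions per stratum) is
    drawn and both callers are fitted on it; the diploid comparator is
    fitted per stratum on the same training rows but with the neutral
    three-genotype space, so in the NEUT stratum the two callers are the
    same fit and their metrics coincide exactly.  Each of the
    ``config.n_test_sets`` test sets is then scored and per-stratum AUC
    and sensitivity at the FPR targets recorded; positions whose true
    genotype is all-reference form the negative class.
    """
    config = config if config is not None else SimConfig()
    hyper = config.hyper if config.hyper is not None else default_hyperparams()
    em_config = em_config if em_config is not None else EMConfig()

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_test_sets + 1)
    train_rng = np.random.default_rng(children[0])
    train_counts, _ = simulate_dataset(config, rng=train_rng)

    cn_params, _ = fit_em(train_counts, hyper, em_config)
    dip_mu, dip_pi = {}, {}
    for state in CNAState:
        sub = train_counts[train_counts["state_code"] == int(state)]
        p, _ = fit_em(force_state(sub), hyper, em_config)
        dip_mu[state] = p.mu[CNAState.NEUT_LOSS]
        dip_pi[state] = p.pi[CNAState.NEUT_LOSS]

    metric_cols = _metric_columns(fpr_targets)
    records = []
    for rep in range(config.n_test_sets):
        rng = np.random.default_rng(children[rep + 1])
        counts, truth = simulate_dataset(config, rng=rng)
        for state in CNAState:
            mask = counts["state_code"] == int(state)
            a = counts.loc[mask, "ref_count"].to_numpy()
            n = counts.loc[mask, "depth"].to_numpy()
            labels = truth.loc[mask.to_numpy(), "is_variant"].to_numpy()
            scored = {
                "cn_aware": snv_scores(a, n, cn_params.mu[state], cn_params.pi[state]),
                "diploid": snv_scores(a, n, dip_mu[state], dip_pi[state]),
            }
            degenerate = labels.sum() in (0, len(labels))
            for model, scores in scored.items():
                row = {"replicate": rep, "state": state.name, "model": model}
                if degenerate:
                    # a test set with no positive (or no negative) positions
                    # has no ROC; the cell is excluded from the averages
                    row["auc"] = np.nan
                    for t in fpr_targets:
                        row[f"sens@{t:g}"] = np.nan
                else:
                    roc = roc_curve(scores, labels)
                    row["auc"] = roc.auc
                    for t in fpr_targets:
                        row[f"sens@{t:g}"] = sensitivity_at_fpr(roc, t)
                records.append(row)
    replicates = pd.DataFrame.from_records(records)

    rows = []
    for (state, model), sub in replicates.groupby(["state", "model"], sort=False):
        for metric in metric_cols:
            vals = sub[metric].to_numpy()
            valid = vals[~np.isnan(vals)]
            if valid.size == 0:
                rows.append(
                    {
                        "state": state,
                        "model": model,
                        "metric": metric,
                        "mean": np.nan,
                        "ci_lower": np.nan,
                        "ci_upper": np.nan,
                        "n_replicates": 0,
                    }
                )
                continue
            lo, hi = np.percentile(valid, [2.5, 97.5])
            rows.append(
                {
                    "state": state,
                    "model": model,
                    "metric": metric,
                    "mean": float(valid.mean()),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "n_replicates": int(valid.size),
                }
            )
    table = pd.DataFrame(rows)
    return StudyResult(
        replicates=replicates,
        table=table,
        params={"cn_aware": cn_params, "diploid_mu": dip_mu, "diploid_pi": dip_pi},
    )


def study_sensitivities(
    result: StudyResult, state: CNAState = CNAState.HLAMP, model: str = "cn_aware"
) -> Dict[float, float]:
    """Mean sensitivity per FPR target for one (state, model) cell."""
    sub = result.table[
        (result.table["state"] == state.name)
        & (result.table["model"] == model)
        & result.table["metric"].str.startswith("sens@")
    ]
    return {
        float(m.split("@")[1]): v for m, v in zip(sub["metric"], sub["mean"])
    }


def write_study(result: StudyResult, prefix) -> None:
    """Write the aggregate table and per-replicate metrics as TSV."""
    result.table.to_csv(f"{prefix}.study.tsv", sep="\t", index=False)
    result.replicates.to_csv(f"{prefix}.replicates.tsv", sep="\t", index=False)


def plot_study(result: StudyResult, path) -> None:
    """Bar chart of mean sensitivities (with CI whiskers) per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sens = result.table[result.table["metric"].str.startswith("sens@")]
    targets = sorted(sens["metric"].unique())
    states = [s.name for s in CNAState]
    fig, axes = plt.subplots(1, len(targets), figsize=(4 * len(targets), 3.2), sharey=True)
    for ax, metric in zip(np.atleast_1d(axes), targets):
        sub = sens[sens["metric"] == metric]
        width = 0.38
        x = np.arange(len(states))
        for off, model in ((-width / 2, "cn_aware"), (width / 2, "diploid")):
            rows = sub[sub["model"] == model].set_index("state").reindex(states)
            err = np.vstack(
                [rows["mean"] - rows["ci_lower"], rows["ci_upper"] - rows["mean"]]
            )
            ax.bar(x + off, rows["mean"], width, yerr=err, capsize=2, label=model)
        ax.set_xticks(x, states, rotation=45)
        ax.set_title(metric)
        ax.set_ylim(0, 1.05)
    np.atleast_1d(axes)[0].set_ylabel("sensitivity")
    np.atleast_1d(axes)[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
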