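"""Downstream statistics for deep-amplicon revalidation of SNV calls.

Two procedures operate on ultra-deep targeted resequencing counts:

* a one-tailed Binomial exact presence test of each target position
  against a background error rate estimated from the ten positions
  flanking it (five on each side), with Benjamini-Hochberg correction
  and a somatic/germline/absent decision table across the normal,
  primary and metastatic samples;
* a 2x2 chi-squared allelic-skew test comparing non-reference
  frequencies between normal and tumour at validated germline sites,
  flagged only when the corrected p-value is significant and the two
  frequencies differ by at least 10%.

The disparity rule is relative by default: |f_normal - f_tumour| divided
by the larger of the two frequencies must reach ``min_disparity``.  An
absolute-difference mode is available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom
from scipy.stats import chi2_contingency, fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_NULL_RATE = 1e-6
DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_MIN_DISPARITY = 0.10
DEFAULT_DEPTH_DISPARITY_FACTOR = 10.0

SAMPLES = ("normal", "primary", "metastatic")


@dataclass(frozen=True)
class AmpliconObservation:
    """Deep-amplicon counts at one target in one sample.

    ``flank_*`` pool the ten positions immediately flanking the target
    (five on each side); they estimate the local background error rate.
    """

    sample: str
    chrom: str
    pos: int
    nonref: int
    depth: int
    flank_nonref: int
    flank_depth: int

    def __post_init__(self):
        for name in ("nonref", "depth", "flank_nonref", "flank_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nonref > self.depth:
            raise ValueError("nonref exceeds depth")
        if self.flank_nonref > self.flank_depth:
            raise ValueError("flank_nonref exceeds flank_depth")


def presence_test(
    obs: AmpliconObservation, min_null_rate: float = MIN_NULL_RATE
) -> float:
    """One-tailed Binomial exact test for the presence of the variant.

    The null rate is the pooled flanking non-reference fraction (floored
    at ``min_null_rate``); the p-value is the exact upper tail
    P(X >= nonref | depth, p0).  Zero target depth is undefined and
    returns NaN with a warning.
    """
    if obs.flank_depth <= 0:
        raise ValueError("flank depth must be positive to estimate the null rate")
    if obs.depth == 0:
        logger.warning(
            "zero target depth at %s:%d (%s); presence undefined",
            obs.chrom, obs.pos, obs.sample,
        )
        return float("nan")
    p0 = max(obs.flank_nonref / obs.flank_depth, min_null_rate)
    return float(_binom.sf(obs.nonref - 1, obs.depth, p0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    NaN entries pass through as NaN and do not count toward the family
    size.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class ValidationVerdict:
    """Per-target presence flags and somatic/germline status."""

    chrom: str
    pos: int
    present: Dict[str, Optional[bool]] = field(default_factory=dict)
    q_values: Dict[str, float] = field(default_factory=dict)
    status: str = "inconclusive"  # somatic | germline | absent | inconclusive


def call_status(
    normal: Optional[AmpliconObservation],
    primary: Optional[AmpliconObservation],
    metastatic: Optional[AmpliconObservation],
    q_values: Dict[str, float],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    depth_disparity_factor: float = DEFAULT_DEPTH_DISPARITY_FACTOR,
) -> ValidationVerdict:
    """Apply the somatic/germline decision table to one target.

    A variant is *somatic* when absent in the normal but present in a
    tumour sample, *germline* when present in both the normal and the
    metastatic sample, *absent* when present nowhere.  A normal-vs-
    metastatic depth imbalance beyond ``depth_disparity_factor`` makes
    the target *inconclusive* regardless of the tests; missing samples
    yield a partial verdict.
    """
    obs = {"normal": normal, "primary": primary, "metastatic": metastatic}
    anchor = next((o for o in obs.values() if o is not None), None)
    if anchor is None:
        raise ValueError("at least one sample observation is required")
    present: Dict[str, Optional[bool]] = {}
    for name, o in obs.items():
        if o is None:
            present[name] = None
        else:
            q = q_values.get(name, float("nan"))
            present[name] = bool(q < q_threshold) if np.isfinite(q) else None
    verdict = ValidationVerdict(
        chrom=anchor.chrom, pos=anchor.pos, present=present, q_values=dict(q_values)
    )

    if normal is not None and metastatic is not None:
        depths = sorted([normal.depth, metastatic.depth])
        if depths[0] == 0 or depths[1] / max(depths[0], 1) > depth_disparity_factor:
            verdict.status = "inconclusive"
            return verdict

    in_normal = present["normal"]
    in_tumour = [present[s] for s in ("primary", "metastatic")]
    if in_normal is False and any(x is True for x in in_tumour):
        verdict.status = "somatic"
    elif in_normal is True and present["metastatic"] is True:
        verdict.status = "germline"
    elif in_normal is False and all(x is False for x in in_tumour if x is not None) and any(
        x is not None for x in in_tumour
    ):
        verdict.status = "absent"
    else:
        verdict.status = "inconclusive"
    return verdict


@dataclass
class SkewResult:
    statistic: float
    p_value: float
    disparity: float  # |f_normal - f_tumour|
    rel_disparity: float  # disparity / max(f_normal, f_tumour)
    method: str = "chi2"


def skew_test(
    normal: Tuple[int, int], tumor: Tuple[int, int]
) -> SkewResult:
    """Allelic-skew test between two samples at one site.

    Inputs are (nonref_count, depth) pairs.  A 2x2 chi-squared test
    without continuity correction compares (nonref, ref) across samples;
    when any expected cell drops below 1 the p-value falls back to
    Fisher's exact test (warned).  Symmetric under swapping the samples.
    """
    (x1, n1), (x2, n2) = normal, tumor
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both depths must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("need 0 <= nonref <= depth in both samples")
    f1, f2 = x1 / n1, x2 / n2
    disparity = abs(f1 - f2)
    rel = disparity / max(f1, f2) if max(f1, f2) > 0 else 0.0
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if f1 == f2:
        return SkewResult(0.0, 1.0, disparity, rel, "chi2")
    if np.any(table.sum(axis=0) == 0):
        # one allele absent in both samples: no 2x2 test possible
        return SkewResult(0.0, 1.0, disparity, rel, "degenerate")
    stat, p, _, expected = chi2_contingency(table, correction=False)
    if np.any(expected < 1.0):
        logger.warning(
            "expected cell below 1 (min %.3g); falling back to Fisher's exact test",
            expected.min(),
        )
        _, p = fisher_exact(table.astype(int))
        return SkewResult(float(stat), float(p), disparity, rel, "fisher")
    return SkewResult(float(stat), float(p), disparity, rel, "chi2")


def skew_flags(
    rows: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_disparity: float = DEFAULT_MIN_DISPARITY,
    disparity_mode: str = "relative",
) -> pd.DataFrame:
    """Run the skew test across a table of sites and flag skewed ones.

    ``rows`` needs columns normal_nonref, normal_depth, tumor_nonref,
    tumor_depth (plus any identifier columns, which are passed through).
    The flag requires the BH-corrected p-value below ``q_threshold`` and
    the frequency disparity (relative by default) at least
    ``min_disparity``.
    """
    if disparity_mode not in ("relative", "absolute"):
        raise ValueError("disparity_mode must be 'relative' or 'absolute'")
    out = rows.copy().reset_index(drop=True)
    results = [
        skew_test(
            (int(r.normal_nonref), int(r.normal_depth)),
            (int(r.tumor_nonref), int(r.tumor_depth)),
        )
        for r in out.itertuples(index=False)
    ]
    out["chi2_stat"] = [r.statistic for r in results]
    out["p_value"] = [r.p_value for r in results]
    out["disparity"] = [r.disparity for r in results]
    out["rel_disparity"] = [r.rel_disparity for r in results]
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    disp = out["rel_disparity"] if disparity_mode == "relative" else out["disparity"]
    out["skewed"] = (out["q_value"] < q_threshold) & (disp >= min_disparity)
    return out


def presence_table(
    rows: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    depth_disparity_factor: float = DEFAULT_DEPTH_DISPARITY_FACTOR,
) -> pd.DataFrame:
    """Presence tests plus verdicts for a long-format amplicon table.

    ``rows`` needs columns sample, chrom, pos, nonref, depth,
    flank_nonref, flank_depth; one row per (target, sample).  BH
    correction is applied within each sample's family of targets.
    """
    obs: Dict[Tuple[str, int], Dict[str, AmpliconObservation]] = {}
    for r in rows.itertuples(index=False):
        o = AmpliconObservation(
            sample=str(r.sample), chrom=str(r.chrom), pos=int(r.pos),
            nonref=int(r.nonref), depth=int(r.depth),
            flank_nonref=int(r.flank_nonref), flank_depth=int(r.flank_depth),
        )
        if o.sample not in SAMPLES:
            raise ValueError(f"unknown sample label {o.sample!r}; expected {SAMPLES}")
        obs.setdefault((o.chrom, o.pos), {})[o.sample] = o

    pvals: Dict[str, Dict[Tuple[str, int], float]] = {s: {} for s in SAMPLES}
    for key, per_sample in obs.items():
        for sample, o in per_sample.items():
            pvals[sample][key] = presence_test(o)
    qvals: Dict[str, Dict[Tuple[str, int], float]] = {s: {} for s in SAMPLES}
    for sample in SAMPLES:
        keys = list(pvals[sample])
        if keys:
            q = bh_adjust([pvals[sample][k] for k in keys])
            qvals[sample] = dict(zip(keys, q))

    records = []
    for key, per_sample in obs.items():
        qv = {s: qvals[s].get(key, float("nan")) for s in SAMPLES if key in qvals.get(s, {})}
        verdict = call_status(
            per_sample.get("normal"),
            per_sample.get("primary"),
            per_sample.get("metastatic"),
            qv,
            q_threshold=q_threshold,
            depth_disparity_factor=depth_disparity_factor,
        )
        rec = {"chrom": key[0], "pos": key[1], "status": verdict.status}
        for s in SAMPLES:
            rec[f"p_{s}"] = pvals[s].get(key, float("nan"))
            rec[f"q_{s}"] = qv.get(s, float("nan"))
            rec[f"present_{s}"] = verdict.present.get(s)
        records.append(rec)
    return pd.DataFrame.from_records(records).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
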