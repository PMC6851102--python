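"""SAINT-style scoring of proximity-labeling spectral counts.

The bait was tagged at both termini (``bait_N`` and ``bait_C``); two isogenic
pools (A, B) per condition are biological replicates. Scoring uses a
two-component Poisson model per prey: a background component whose mean is
estimated from the control runs and a "true interaction" component whose mean
is the bait-run mean, floored at ``min_true_fold`` times background. The
posterior probability of the true component is computed per bait run by Bayes'
rule and averaged per terminus.

The high-confidence filter keeps preys with max posterior above a score
threshold, enough unique spectra in both analyses, and spectral counts
sufficiently enriched over control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import poisson

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.1

CONDITIONS = ("bait_N", "bait_C", "control")
BAIT_CONDITIONS = ("bait_N", "bait_C")


class InputError(ValueError):
    """Invalid spectral-count input."""


@dataclass
class SpectralCountTable:
    """Prey x run spectral counts with per-run metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by prey id, one column per run id, integer cells.
    runs
        DataFrame indexed by run id with columns ``condition`` (one of
        ``bait_N``/``bait_C``/``control``) and ``pool`` (``A``/``B``).
    unique_peptides
        Optional DataFrame shaped like ``counts`` holding unique-peptide
        counts per prey per run.
    """

    counts: pd.DataFrame
    runs: pd.DataFrame
    unique_peptides: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.runs.index):
            missing = set(self.counts.columns) - set(self.runs.index)
            raise InputError(f"runs missing metadata: {sorted(missing)}")
        bad = set(self.runs["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(f"unknown conditions: {sorted(bad)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise InputError("spectral counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise InputError("spectral counts must be non-negative")
        if not self.run_ids("control"):
            raise InputError("at least one control run is required")

    def run_ids(self, condition: str, pool: str | None = None) -> list[str]:
        mask = self.runs["condition"] == condition
        if pool is not None:
            mask &= self.runs["pool"] == pool
        return list(self.runs.index[mask])

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "SpectralCountTable":
        """Build from long format ``prey, run, condition, pool,
        spectral_count[, unique_peptides]``."""
        required = {"prey", "run", "condition", "pool", "spectral_count"}
        if not required <= set(frame.columns):
            raise InputError(f"long table needs columns {sorted(required)}")
        counts = frame.pivot_table(
            index="prey", columns="run", values="spectral_count", fill_value=0
        ).astype(np.int64)
        runs = (
            frame[["run", "condition", "pool"]]
            .drop_duplicates("run")
            .set_index("run")
        )
        unique = None
        if "unique_peptides" in frame.columns and frame["unique_peptides"].notna().any():
            unique = frame.pivot_table(
                index="prey", columns="run", values="unique_peptides", fill_value=0
            ).astype(np.int64)
        return cls(counts=counts, runs=runs, unique_peptides=unique)


@dataclass(frozen=True)
class InteractorFilterSpec:
    """Thresholds of the high-confidence interactor filter.

    ``min_unique_spectra`` is the minimum acceptable count, i.e. the default
    3 enforces "more than 2". ``both_analyses_rule`` selects whether the
    unique-spectra condition must hold for both bait termini or both pools.
    """

    min_max_score: float = 0.8
    min_unique_spectra: int = 3
    min_fold: float = 2.5
    both_analyses_rule: Literal["both_baits", "both_pools"] = "both_baits"

    def __post_init__(self) -> None:
        if self.min_max_score <= 0 or self.min_fold <= 0 or self.min_unique_spectra <= 0:
            raise InputError("filter thresholds must be positive")
        if self.both_analyses_rule not in ("both_baits", "both_pools"):
            raise InputError(f"unknown both_analyses_rule {self.both_analyses_rule!r}")


def _posterior(
    x: np.ndarray, lam_true: np.ndarray, lam_false: np.ndarray, prior: float
) -> np.ndarray:
    """P(true | count) under the two-component Poisson model."""
    # log-space to stay stable for large counts
    log_t = poisson.logpmf(x, lam_true) + np.log(prior)
    log_f = poisson.logpmf(x, lam_false) + np.log1p(-prior)
    m = np.maximum(log_t, log_f)
    return np.exp(log_t - m) / (np.exp(log_t - m) + np.exp(log_f - m))


def saint_score(
    table: SpectralCountTable,
    prior: float = 0.5,
    min_true_fold: float = 2.0,
    filter_spec: InteractorFilterSpec | None = None,
) -> pd.DataFrame:
    """Score every prey against the control-derived background.

    Returns one row per prey with columns ``score_N``, ``score_C``,
    ``max_score``, ``total_N``, ``total_C``, ``fold_vs_control`` and
    ``unique_ok``. Scores are posterior probabilities in [0, 1], monotone
    non-decreasing in the prey's bait counts for fixed background.
    """
    if not 0 < prior < 1:
        raise InputError("prior must be in (0, 1)")
    if min_true_fold <= 1:
        raise InputError("min_true_fold must exceed 1")
    spec = filter_spec or InteractorFilterSpec()

    control_runs = table.run_ids("control")
    control_mean = table.counts[control_runs].mean(axis=1).to_numpy(dtype=float)
    lam_false = control_mean + PSEUDOCOUNT

    result = pd.DataFrame(index=table.counts.index)
    bait_runs_all: list[str] = []
    for terminus, suffix in (("bait_N", "N"), ("bait_C", "C")):
        runs = table.run_ids(terminus)
        if not runs:
            raise InputError(f"no runs for condition {terminus!r}")
        bait_runs_all.extend(runs)
        bait = table.counts[runs].to_numpy(dtype=float)
        lam_true = np.maximum(bait.mean(axis=1), min_true_fold * lam_false)
        post = np.column_stack(
            [_posterior(bait[:, j], lam_true, lam_false, prior) for j in range(bait.shape[1])]
        )
        result[f"score_{suffix}"] = post.mean(axis=1)
        result[f"total_{suffix}"] = table.counts[runs].sum(axis=1)

    result["max_score"] = result[["score_N", "score_C"]].max(axis=1)
    bait_mean = table.counts[bait_runs_all].mean(axis=1).to_numpy(dtype=float)
    result["fold_vs_control"] = (bait_mean + PSEUDOCOUNT) / (control_mean + PSEUDOCOUNT)
    result["unique_ok"] = _unique_ok(table, spec)
    return result


def _unique_ok(table: SpectralCountTable, spec: InteractorFilterSpec) -> pd.Series:
    """Unique-spectra condition per prey under the chosen "both analyses" rule.

    Falls back to total spectral counts per analysis when unique-peptide
    counts were not supplied (the published table prints totals only).
    """
    source = table.unique_peptides
    if source is None:
        logger.warning(
            "unique-peptide counts absent; substituting total spectral counts"
        )
        source = table.counts
    source = source.reindex(index=table.counts.index, fill_value=0)

    if spec.both_analyses_rule == "both_baits":
        groups = [table.run_ids(cond) for cond in BAIT_CONDITIONS]
    else:
        pools = sorted(set(table.runs.loc[table.runs["condition"] != "control", "pool"]))
        groups = [
            [r for cond in BAIT_CONDITIONS for r in table.run_ids(cond, pool)]
            for pool in pools
        ]
    ok = pd.Series(True, index=table.counts.index)
    for runs in groups:
        ok &= source[runs].sum(axis=1) >= spec.min_unique_spectra
    return ok


def filter_interactors(
    scores: pd.DataFrame, spec: InteractorFilterSpec | None = None
) -> pd.DataFrame:
    """Apply the high-confidence filter to a :func:`saint_score` table.

    Keeps preys with ``max_score`` strictly above the threshold, the
    unique-spectra condition satisfied, and ``fold_vs_control`` at least
    ``min_fold``. Output is sorted by total spectral count (both termini)
    descending, ties broken lexicographically by prey id.
    """
    spec = spec or InteractorFilterSpec()
    if scores.empty:
        return scores.copy()
    keep = (
        (scores["max_score"] > spec.min_max_score)
        & scores["unique_ok"]
        & (scores["fold_vs_control"] >= spec.min_fold)
    )
    retained = scores.loc[keep].copy()
    total = (retained["total_N"] + retained["total_C"]).to_numpy()
    order = np.lexsort((retained.index.to_numpy(), -total))
    return retained.iloc[order]
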