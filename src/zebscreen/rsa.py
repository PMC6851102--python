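"""Redundant shRNA activity (RSA) gene statistics and differential ranking.

A gene's RSA p-value asks whether its hairpins cluster unexpectedly near the
top of the depletion ranking: with the gene's k barcode ranks r_1 <= ... <= r_k
among N targeting barcodes, the statistic is

    P = min over i in 1..k of  P(X >= i),  X ~ Hypergeometric(N, k, r_i)

reported as logP = log10(P). Differential essentiality between two screen
arms is the difference of logP values, ranked ascending (most arm-A-specific
first).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .screen import BarcodeLibrary

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Invalid RSA input."""


def hypergeom_upper_tail(i: int, k: int, r: int, N: int) -> float:
    """P(X >= i) for X ~ Hypergeometric(population N, successes k, draws r).

    Exact upper tail, in [0, 1].
    """
    if not (1 <= i <= k <= N):
        raise InputError(f"need 1 <= i <= k <= N, got i={i}, k={k}, N={N}")
    if not (1 <= r <= N):
        raise InputError(f"need 1 <= r <= N, got r={r}, N={N}")
    return float(hypergeom.sf(i - 1, N, k, r))


def rsa_logp(gene_ranks: Sequence[int], N: int) -> float:
    """log10 of the minimum hypergeometric upper tail over rank prefixes.

    ``gene_ranks`` are the gene's barcode ranks (1 = most depleted) among N
    targeting barcodes, sorted non-decreasing. Tied ranks produced by the
    worst-rank tie rule are accepted; decreasing or out-of-range ranks are
    errors. Lower (more negative) logP = stronger coordinated depletion.
    """
    ranks = list(gene_ranks)
    if not ranks:
        raise InputError("empty rank list")
    if any(r < 1 or r > N for r in ranks):
        raise InputError(f"ranks must lie in 1..{N}")
    if any(b < a for a, b in zip(ranks, ranks[1:])):
        raise InputError("ranks must be sorted non-decreasing")
    k = len(ranks)
    p = min(hypergeom_upper_tail(i, k, r_i, N) for i, r_i in enumerate(ranks, start=1))
    return math.log10(p) if p > 0 else -math.inf


def screen_rsa(
    collapsed: pd.DataFrame,
    library: BarcodeLibrary,
    arm: str,
) -> pd.DataFrame:
    """Gene-level RSA scores for one screen arm.

    Parameters
    ----------
    collapsed
        Output of :func:`zebscreen.screen.collapse_replicates`: one
        percentile column per group, indexed by shrna_id.
    arm
        Column of ``collapsed`` to score.

    Targeting barcodes are ranked ascending by collapsed percentile; tied
    percentiles all receive the worst (largest) rank of their tied block, so
    tie order cannot manufacture significance. Genes with no detected
    barcode get logP 0 and are flagged.

    Returns a frame with columns ``gene, logp, rank, n_shrnas, arm,
    no_barcodes`` sorted ascending by logp (rank 1 = most depleted).
    """
    if arm not in collapsed.columns:
        raise InputError(f"arm {arm!r} not in collapsed table")
    gene_of = library.gene_of()
    targeting = library.entries.loc[library.entries["class"] == "targeting", "shrna_id"]
    pct = collapsed.loc[collapsed.index.intersection(targeting), arm].dropna()
    N = len(pct)
    if N == 0:
        raise InputError("no targeting barcodes with percentiles")
    # worst rank of the tied block ("max" method)
    ranks = pct.rank(method="max").astype(int)

    rows = []
    for gene, shrnas in gene_of.loc[targeting].groupby(gene_of.loc[targeting]).groups.items():
        gene_ranks = sorted(ranks.reindex(shrnas).dropna().astype(int))
        if not gene_ranks:
            logger.warning("gene %s has zero detected barcodes; logP set to 0", gene)
            rows.append(
                {"gene": gene, "logp": 0.0, "n_shrnas": 0, "no_barcodes": True}
            )
            continue
        rows.append(
            {
                "gene": gene,
                "logp": rsa_logp(gene_ranks, N),
                "n_shrnas": len(gene_ranks),
                "no_barcodes": False,
            }
        )
    out = pd.DataFrame(rows).sort_values(["logp", "gene"], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["arm"] = arm
    return out.reset_index(drop=True)


def differential_rank(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Differential essentiality between two arms: delta = logP_a - logP_b.

    Genes missing from one arm are excluded with a warning. Output is sorted
    ascending by delta (most arm-A-essential first) with a percentile column
    (100 * average rank / n) and the integer rank change for inspection.
    """
    a_idx = a.set_index("gene")
    b_idx = b.set_index("gene")
    common = a_idx.index.intersection(b_idx.index)
    dropped = a_idx.index.symmetric_difference(b_idx.index)
    if len(dropped):
        logger.warning("genes missing from one arm excluded: %s", sorted(dropped))
    delta = a_idx.loc[common, "logp"] - b_idx.loc[common, "logp"]
    out = pd.DataFrame(
        {
            "gene": common,
            "delta": delta.to_numpy(),
            "logp_a": a_idx.loc[common, "logp"].to_numpy(),
            "logp_b": b_idx.loc[common, "logp"].to_numpy(),
            "rank_change": (
                a_idx.loc[common, "rank"] - b_idx.loc[common, "rank"]
            ).to_numpy(),
        }
    )
    ranks = out["delta"].rank(method="average")
    out["percentile"] = 100.0 * ranks / len(out)
    out = out.sort_values(["delta", "gene"], kind="mergesort").reset_index(drop=True)
    return out


def intersect_top(
    diff: pd.DataFrame,
    interactors: Sequence[str],
    top_fraction: float = 0.15,
    symbol_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Genes in the top ``ceil(top_fraction * n)`` of the differential list
    whose symbol maps (case-insensitively) to a filtered interactor.

    ``symbol_map`` translates screen symbols to interactome symbols (e.g.
    mouse to human); identity mapping if omitted. Output preserves
    differential order.
    """
    if not 0 < top_fraction <= 1:
        raise InputError("top_fraction must be in (0, 1]")
    if symbol_map is not None and len(symbol_map) == 0:
        raise InputError("empty symbol mapping")
    mapping = {k.upper(): v.upper() for k, v in (symbol_map or {}).items()}
    interactor_set = {p.upper() for p in interactors}
    n_top = math.ceil(top_fraction * len(diff))
    top = diff.iloc[:n_top]
    hits = []
    for gene in top["gene"]:
        symbol = mapping.get(gene.upper(), gene.upper())
        if symbol in interactor_set:
            hits.append(gene)
    return hits
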