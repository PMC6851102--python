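"""Target-prioritization funnel: co-occupancy -> expression -> TSS distance.

Stages, applied in order per gene:

1. co-occupancy: intervals covered by at least one peak from each of two
   ChIP peak sets (intersection, 0-based half-open, >= 1 shared base);
2. inverse-expression filter: repressed by at least 50% (fold <= 0.5) with
   p <= 0.05 in the primary overexpression dataset and significantly changed
   (p <= 0.05) in at least one other dataset;
3. TSS proximity: a co-bound interval within +/-250 bp of the gene's TSS;
4. E-box annotation: exact CACCTG occurrences (both strands) in the promoter
   sequence — recorded per gene, a hard filter only on request;
5. optional validation stratification when a validation fold table is
   supplied (fold_oe <= 0.5 or fold_rescue >= 2).

Every input gene appears exactly once in the audit table with the stage it
reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import importlib.resources

import numpy as np
import pandas as pd

from .io import BedInterval

EBOX_MOTIF = "CACCTG"
EXPRESSION_DATASETS = ("OE_393P", "miR200_344SQ", "ZEB1_3T3L1", "shZEB1_MDA231")
PRIMARY_DATASET = "OE_393P"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STAGES = ("input", "cobound", "expression", "tss", "validated")


class FunnelError(ValueError):
    """Invalid funnel input."""


@dataclass(frozen=True)
class FunnelConfig:
    tss_window: int = 250
    max_fold: float = 0.5
    alpha: float = 0.05
    primary_dataset: str = PRIMARY_DATASET
    require_primary_significance: bool = True
    require_ebox: bool = False
    ebox_motif: str = EBOX_MOTIF

    def __post_init__(self) -> None:
        if self.tss_window <= 0:
            raise FunnelError("tss_window must be positive")
        if not set(self.ebox_motif) <= set("ACGT"):
            raise FunnelError("ebox motif must be ACGT-only")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(peaks: Sequence[BedInterval]) -> list[BedInterval]:
    """Union coverage of a peak set, per chromosome."""
    merged: list[BedInterval] = []
    for iv in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = BedInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(BedInterval(iv.chrom, iv.start, iv.end))
    return merged


def overlap_peaks(
    a: Sequence[BedInterval], b: Sequence[BedInterval]
) -> list[BedInterval]:
    """Intersection intervals: regions covered by >= 1 peak from each set.

    Coordinates are 0-based half-open; abutting intervals ([100,200) and
    [200,300)) do not overlap. Output is sorted and disjoint.
    """
    out: list[BedInterval] = []
    merged_b: dict[str, list[BedInterval]] = {}
    for iv in merge_intervals(b):
        merged_b.setdefault(iv.chrom, []).append(iv)
    for iv in merge_intervals(a):
        others = merged_b.get(iv.chrom, [])
        # peaks are few per chrom after merging; linear scan is fine
        for other in others:
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if lo < hi:
                out.append(BedInterval(iv.chrom, lo, hi))
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def tss_distance(tss: int, interval: BedInterval) -> int:
    """Unsigned distance from a TSS coordinate to the nearest covered base.

    Zero when the interval covers the TSS.
    """
    if interval.start <= tss < interval.end:
        return 0
    if tss < interval.start:
        return interval.start - tss
    return tss - (interval.end - 1)


def assign_to_tss(
    cobound: Sequence[BedInterval],
    annotation: pd.DataFrame,
    window: int = 250,
) -> pd.DataFrame:
    """Minimal unsigned peak distance from each gene's TSS.

    ``annotation`` needs columns ``gene, chrom, tss`` (``strand`` optional;
    the window is symmetric and strand-agnostic). Genes on chromosomes with
    no co-bound peak get infinite distance and fail. Returns columns
    ``gene, tss_distance, tss_pass``.
    """
    required = {"gene", "chrom", "tss"}
    if not required <= set(annotation.columns):
        raise FunnelError(f"annotation needs columns {sorted(required)}")
    by_chrom: dict[str, list[BedInterval]] = {}
    for iv in cobound:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    rows = []
    for rec in annotation.itertuples(index=False):
        peaks = by_chrom.get(rec.chrom, [])
        dist = min((tss_distance(int(rec.tss), iv) for iv in peaks), default=math.inf)
        rows.append(
            {"gene": rec.gene, "tss_distance": dist, "tss_pass": dist <= window}
        )
    return pd.DataFrame(rows)


def expression_filter(
    expr: pd.DataFrame,
    primary: str = PRIMARY_DATASET,
    max_fold: float = 0.5,
    alpha: float = 0.05,
    require_primary_significance: bool = True,
) -> pd.DataFrame:
    """Inverse-expression filter over the four perturbation datasets.

    ``expr`` is indexed by gene with columns ``{dataset}_fold`` and
    ``{dataset}_p``. A gene passes iff fold(primary) <= max_fold, the
    primary p-value is <= alpha (when required), and at least one other
    dataset has p <= alpha. Missing cells are treated as non-significant.

    Returns per-gene flags: one ``{dataset}_sig`` column per dataset plus
    ``primary_fold_ok`` and ``expr_pass``.
    """
    fold_col = f"{primary}_fold"
    p_col = f"{primary}_p"
    if fold_col not in expr.columns or p_col not in expr.columns:
        raise FunnelError(f"primary dataset {primary!r} absent from expression table")
    datasets = sorted(
        {c.rsplit("_", 1)[0] for c in expr.columns if c.endswith(("_fold", "_p"))}
    )
    out = pd.DataFrame(index=expr.index)
    for ds in datasets:
        p = expr.get(f"{ds}_p")
        out[f"{ds}_sig"] = (p.notna() & (p <= alpha)) if p is not None else False
    fold = expr[fold_col]
    out["primary_fold_ok"] = fold.notna() & (fold <= max_fold)
    primary_ok = out["primary_fold_ok"]
    if require_primary_significance:
        primary_ok = primary_ok & out[f"{primary}_sig"]
    others = [f"{ds}_sig" for ds in datasets if ds != primary]
    other_ok = out[others].any(axis=1) if others else False
    out["expr_pass"] = primary_ok & other_ok
    return out


def scan_ebox(
    seq: str, motif: str = EBOX_MOTIF, both_strands: bool = True
) -> tuple[int, list[int]]:
    """Count exact motif occurrences on the forward strand and, optionally,
    reverse-strand occurrences (reverse complement matched on the forward
    strand). Overlapping matches count; N never matches.

    Returns ``(count, positions)`` with 0-based forward-strand offsets.
    """
    seq = seq.upper()
    if not set(seq) <= set("ACGTN"):
        raise FunnelError("sequence must be ACGTN-only")
    if not set(motif.upper()) <= set("ACGT"):
        raise FunnelError("motif must be ACGT-only")
    patterns = {motif.upper()}
    if both_strands:
        patterns.add(reverse_complement(motif.upper()))
    positions = [
        i
        for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] in patterns
    ]
    return len(positions), positions


def run_funnel(
    peaks_a: Sequence[BedInterval],
    peaks_b: Sequence[BedInterval],
    annotation: pd.DataFrame,
    expression: pd.DataFrame,
    promoters: Mapping[str, str] | None = None,
    config: FunnelConfig | None = None,
    validation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run every funnel stage and emit the per-gene audit table.

    ``validation``, when given, is indexed by gene with columns ``fold_oe``
    and/or ``fold_rescue``; a candidate is ``validated`` iff
    fold_oe <= 0.5 or fold_rescue >= 2.

    The returned frame has one row per annotated gene with ``cobound``,
    ``expr_pass`` (plus per-dataset flags), ``tss_distance``, ``tss_pass``,
    ``ebox_count``, ``candidate``, ``validated`` and ``stage_reached``;
    stage pass-sets are nested by construction.
    """
    config = config or FunnelConfig()
    cobound = overlap_peaks(peaks_a, peaks_b)
    tss = assign_to_tss(cobound, annotation, window=config.tss_window).set_index("gene")
    expr_flags = expression_filter(
        expression,
        primary=config.primary_dataset,
        max_fold=config.max_fold,
        alpha=config.alpha,
        require_primary_significance=config.require_primary_significance,
    )

    out = pd.DataFrame(index=pd.Index(annotation["gene"], name="gene"))
    out["cobound"] = np.isfinite(tss["tss_distance"].reindex(out.index))
    expr_flags = expr_flags.reindex(out.index, fill_value=False)
    out = out.join(expr_flags)
    out["expr_pass"] = out["cobound"] & out["expr_pass"]
    out["tss_distance"] = tss["tss_distance"].reindex(out.index)
    out["tss_pass"] = out["expr_pass"] & (out["tss_distance"] <= config.tss_window)

    ebox = {}
    for gene in out.index:
        seq = (promoters or {}).get(gene)
        ebox[gene] = scan_ebox(seq, config.ebox_motif)[0] if seq else 0
    out["ebox_count"] = pd.Series(ebox)

    candidate = out["tss_pass"]
    if config.require_ebox:
        candidate = candidate & (out["ebox_count"] >= 1)
    out["candidate"] = candidate

    if validation is not None:
        fold_oe = validation.get("fold_oe")
        fold_rescue = validation.get("fold_rescue")
        ok = pd.Series(False, index=out.index)
        if fold_oe is not None:
            ok |= fold_oe.reindex(out.index) <= 0.5
        if fold_rescue is not None:
            ok |= fold_rescue.reindex(out.index) >= 2.0
        out["validated"] = out["candidate"] & ok.fillna(False)
    else:
        out["validated"] = False

    # without a validation table "tss" is the deepest reachable stage
    out["stage_reached"] = np.select(
        [out["validated"], out["tss_pass"], out["expr_pass"], out["cobound"]],
        ["validated", "tss", "expression", "cobound"],
        default="input",
    )
    return out.reset_index()


def stage_counts(audit: pd.DataFrame) -> dict[str, int]:
    """Number of genes surviving each funnel stage (nested counts)."""
    return {
        "input": int(len(audit)),
        "cobound": int(audit["cobound"].sum()),
        "expression": int(audit["expr_pass"].sum()),
        "tss": int(audit["tss_pass"].sum()),
        "candidate": int(audit["candidate"].sum()),
        "validated": int(audit["validated"].sum()),
    }


def load_candidate_expression() -> pd.DataFrame:
    """Bundled expression responses of the 37 candidate ZEB1/NuRD target
    genes across the four perturbation datasets (fold and t-test p per
    dataset; NA where not measured). Indexed by gene symbol.
    """
    ref = importlib.resources.files("zebscreen.data").joinpath(
        "zeb1_candidate_targets.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    return frame.set_index("gene")
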