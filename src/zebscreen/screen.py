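"""Barcode read processing for the pooled shRNA dropout screen.

Reads are filtered for a fixed 4-bp spacer (default ``CGAA`` starting at the
18th base, 1-based) allowing one mismatch, then the class-appropriate window
is extracted (positions 23-40 for targeting barcodes, 1-18 for the
non-targeting library) and matched against the barcode library. Counts are
library-size normalized to counts-per-million, converted to log2 fold changes
against a reference sample, ranked into percentiles, and biological
replicates are collapsed by averaging percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import iter_fastq_sequences

logger = logging.getLogger(__name__)

NORM_TOTAL = 1e6
DNA = set("ACGT")


class LibraryError(ValueError):
    """Invalid barcode library."""


class SampleError(ValueError):
    """Invalid sample data or metadata."""


@dataclass(frozen=True)
class ReadLayout:
    """Fixed positions within a read, 1-based inclusive.

    ``spacer_start`` is the 1-based position of the first spacer base. The
    single base between spacer end (21) and the targeting window start (23)
    is ignored.
    """

    spacer: str = "CGAA"
    spacer_start: int = 18
    max_spacer_mismatch: int = 1
    targeting_window: tuple[int, int] = (23, 40)
    non_targeting_window: tuple[int, int] = (1, 18)

    def __post_init__(self) -> None:
        if len(self.spacer) != 4:
            raise SampleError("spacer must be exactly 4 bases")
        if self.spacer_start < 1:
            raise SampleError("spacer_start is 1-based and must be >= 1")
        for lo, hi in (self.targeting_window, self.non_targeting_window):
            if lo < 1 or hi < lo:
                raise SampleError(f"invalid window ({lo}, {hi})")

    def window(self, barcode_class: str) -> tuple[int, int]:
        return (
            self.targeting_window
            if barcode_class == "targeting"
            else self.non_targeting_window
        )


@dataclass
class BarcodeLibrary:
    """Barcode library: (shrna_id, gene, barcode, class) entries.

    Barcodes must be unique within a class and share one length.
    """

    entries: pd.DataFrame  # columns: shrna_id, gene, barcode, class

    def __post_init__(self) -> None:
        required = {"shrna_id", "gene", "barcode", "class"}
        if not required <= set(self.entries.columns):
            raise LibraryError(f"library needs columns {sorted(required)}")
        bad_class = set(self.entries["class"]) - {"targeting", "non_targeting"}
        if bad_class:
            raise LibraryError(f"unknown barcode classes: {sorted(bad_class)}")
        for cls, group in self.entries.groupby("class"):
            if group["barcode"].duplicated().any():
                dup = group.loc[group["barcode"].duplicated(), "barcode"].iloc[0]
                raise LibraryError(f"duplicate barcode {dup!r} in class {cls!r}")
        if self.entries["barcode"].str.len().nunique() > 1:
            raise LibraryError("barcodes must all have the same length")
        self.entries = self.entries.reset_index(drop=True)

    @property
    def barcode_length(self) -> int:
        return len(self.entries["barcode"].iloc[0])

    def barcodes(self, barcode_class: str) -> pd.Series:
        mask = self.entries["class"] == barcode_class
        return self.entries.loc[mask, "barcode"]

    def lookup(self, barcode_class: str) -> dict[str, str]:
        """barcode -> shrna_id for one class."""
        mask = self.entries["class"] == barcode_class
        sub = self.entries.loc[mask]
        return dict(zip(sub["barcode"], sub["shrna_id"]))

    def gene_of(self) -> pd.Series:
        return self.entries.set_index("shrna_id")["gene"]


@dataclass
class SampleSheet:
    """Per-sample metadata: cell line arm, environment, replicate id."""

    samples: pd.DataFrame  # columns: sample, arm, environment, replicate

    def __post_init__(self) -> None:
        required = {"sample", "arm", "environment", "replicate"}
        if not required <= set(self.samples.columns):
            raise SampleError(f"sample sheet needs columns {sorted(required)}")
        if self.samples["sample"].duplicated().any():
            raise SampleError("duplicate sample ids in sample sheet")


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def spacer_match(read: str, layout: ReadLayout | None = None) -> bool:
    """True iff the spacer window matches within the mismatch tolerance.

    Characters outside ACGT always count as mismatches. Reads too short to
    contain the spacer fail (logged, not fatal).
    """
    layout = layout or ReadLayout()
    start = layout.spacer_start - 1
    end = start + len(layout.spacer)
    if len(read) < end:
        logger.debug("read shorter than spacer window: %r", read)
        return False
    window = read[start:end]
    mism = sum(
        1 for got, want in zip(window, layout.spacer) if got != want or got not in DNA
    )
    return mism <= layout.max_spacer_mismatch


def _nearest_unique(barcode: str, candidates: Mapping[str, str]) -> str | None:
    """Unique nearest neighbour at Hamming distance 1, else None."""
    hits = []
    for pos in range(len(barcode)):
        for base in "ACGT":
            if base == barcode[pos]:
                continue
            trial = barcode[:pos] + base + barcode[pos + 1 :]
            if trial in candidates:
                hits.append(trial)
                if len(hits) > 1:
                    return None
    return hits[0] if len(hits) == 1 else None


def demultiplex(
    sample_reads: Mapping[str, Iterable[str] | str],
    library: BarcodeLibrary,
    layout: ReadLayout | None = None,
    barcode_class: str = "targeting",
    barcode_mm: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count barcode occurrences per sample.

    Parameters
    ----------
    sample_reads
        Mapping of sample id to either a FASTQ path or an iterable of read
        sequences.
    barcode_mm
        0 for exact matching (default); 1 rescues reads whose extracted
        window has a unique library barcode at Hamming distance 1
        (ambiguous reads stay unassigned).

    Returns
    -------
    counts, qc
        ``counts``: shrna_id x sample integer matrix. ``qc``: per-sample
        totals satisfying ``assigned + unassigned + spacer_fail == total``.
    """
    layout = layout or ReadLayout()
    if barcode_mm not in (0, 1):
        raise SampleError("barcode_mm must be 0 or 1")
    lookup = library.lookup(barcode_class)
    if not lookup:
        raise LibraryError(f"library has no {barcode_class!r} barcodes")
    lo, hi = layout.window(barcode_class)
    start, end = lo - 1, hi

    shrna_ids = library.entries.loc[
        library.entries["class"] == barcode_class, "shrna_id"
    ].tolist()
    counts = pd.DataFrame(0, index=pd.Index(shrna_ids, name="shrna_id"), columns=[])
    qc_rows = []
    spacer_start = layout.spacer_start - 1
    spacer = layout.spacer
    spacer_end = spacer_start + len(spacer)
    max_mm = layout.max_spacer_mismatch

    for sample, source in sample_reads.items():
        reads = iter_fastq_sequences(source) if isinstance(source, str) else source
        tally: dict[str, int] = {}
        total = spacer_fail = unassigned = 0
        for read in reads:
            total += 1
            window = read[spacer_start:spacer_end]
            if len(window) < len(spacer) or (
                sum(
                    1
                    for got, want in zip(window, spacer)
                    if got != want or got not in DNA
                )
                > max_mm
            ):
                spacer_fail += 1
                continue
            barcode = read[start:end]
            hit = lookup.get(barcode)
            if hit is None and barcode_mm == 1 and len(barcode) == end - start:
                rescued = _nearest_unique(barcode, lookup)
                hit = lookup[rescued] if rescued is not None else None
            if hit is None:
                unassigned += 1
            else:
                tally[hit] = tally.get(hit, 0) + 1
        if total == 0:
            logger.warning("sample %s has no reads; zero column emitted", sample)
        counts[sample] = pd.Series(tally, dtype=np.int64).reindex(
            counts.index, fill_value=0
        )
        assigned = total - spacer_fail - unassigned
        qc_rows.append(
            {
                "sample": sample,
                "total_reads": total,
                "spacer_fail": spacer_fail,
                "assigned": assigned,
                "unassigned": unassigned,
            }
        )
    return counts.astype(np.int64), pd.DataFrame(qc_rows)


def normalize_library_size(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column to sum to 1e6 (counts-per-million)."""
    sums = raw.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise SampleError(f"zero-sum sample(s): {list(zero.index)}")
    return raw / sums * NORM_TOTAL


def fold_change_percentile(
    norm: pd.DataFrame,
    reference_sample: str,
    pseudocount: float = 1.0,
    targeting_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """log2 fold change vs the reference plus within-sample percentiles.

    Percentile = 100 * average rank / n, ranks ascending over the targeting
    barcodes of the sample, so depleted barcodes get low percentiles.
    Non-targeting barcodes (ids not in ``targeting_ids``) receive NaN
    percentiles and are excluded from the ranking.

    Returns a frame with a two-level column index ``(sample, {fold, pct})``
    for every non-reference sample.
    """
    if reference_sample not in norm.columns:
        raise SampleError(f"reference sample {reference_sample!r} absent")
    if targeting_ids is None:
        targeting = pd.Series(True, index=norm.index)
    else:
        targeting = norm.index.isin(targeting_ids)
        targeting = pd.Series(targeting, index=norm.index)
    ref = norm[reference_sample] + pseudocount
    pieces = {}
    for sample in norm.columns:
        if sample == reference_sample:
            continue
        fold = np.log2((norm[sample] + pseudocount) / ref)
        ranks = fold[targeting].rank(method="average")
        pct = 100.0 * ranks / targeting.sum()
        pieces[(sample, "fold")] = fold
        pieces[(sample, "pct")] = pct.reindex(norm.index)
    out = pd.DataFrame(pieces, index=norm.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "metric"])
    return out


def collapse_replicates(
    folds: pd.DataFrame, grouping: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Average replicate percentile columns per group.

    ``grouping`` maps a group label (e.g. ``arm_A:in_vitro``) to the sample
    ids of its biological replicates. Returns one percentile column per
    group.
    """
    out = {}
    for group, samples in grouping.items():
        if not samples:
            raise SampleError(f"group {group!r} has zero replicates")
        missing = [s for s in samples if (s, "pct") not in folds.columns]
        if missing:
            raise SampleError(f"group {group!r}: samples missing from folds: {missing}")
        out[group] = pd.concat([folds[(s, "pct")] for s in samples], axis=1).mean(axis=1)
    return pd.DataFrame(out, index=folds.index)
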