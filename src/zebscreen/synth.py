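"""Synthetic inputs with the statistical structure each analysis stage assumes.

Three generators:

* :func:`gen_bioid_counts` — bait/control spectral-count tables with planted
  true interactors (Poisson counts, bait-run mean inflated by a configurable
  fold);
* :func:`gen_screen_reads` — barcoded shRNA screen reads with the fixed
  spacer/barcode layout, negative-binomial per-barcode coverage, planted
  per-arm gene depletion, and a controlled fraction of spacer errors;
* :func:`gen_funnel_fixture` — two peak sets, a TSS annotation, promoter
  sequences and a four-dataset expression table with planted co-bound,
  repressed, TSS-proximal target genes carrying E-box motifs.

All generators are deterministic given (config, seed) and assert that every
planted positive satisfies its stage's passing condition by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .funnel import scan_ebox
from .interactome import SpectralCountTable
from .io import BedInterval, FastqRecord, write_bed, write_fasta, write_fastq, write_tsv
from .screen import BarcodeLibrary, ReadLayout


class ConfigError(ValueError):
    """A simulation config field is invalid; the message names the field."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


# ---------------------------------------------------------------------------
# BioID


@dataclass(frozen=True)
class BioidSimConfig:
    n_preys: int = 500
    n_true_interactors: int = 50
    runs_per_condition: int = 2  # two isogenic pools per bait, A and B
    control_mean: float = 2.0
    enrichment_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_preys > 0, "n_preys must be positive")
        _require(
            0 <= self.n_true_interactors <= self.n_preys,
            "n_true_interactors must be in [0, n_preys]",
        )
        _require(self.runs_per_condition > 0, "runs_per_condition must be positive")
        _require(self.control_mean > 0, "control_mean must be positive")
        _require(self.enrichment_fold >= 1, "enrichment_fold must be >= 1")


@dataclass
class BioidSim:
    table: SpectralCountTable
    truth: pd.Series  # bool per prey: planted true interactor


def gen_bioid_counts(cfg: BioidSimConfig) -> BioidSim:
    """Simulate a prey x run spectral-count table with planted interactors.

    True interactors draw Poisson counts with mean
    ``control_mean * enrichment_fold`` in bait runs and ``control_mean`` in
    control runs; background preys have mean ``control_mean`` everywhere.
    """
    rng = np.random.default_rng(cfg.seed)
    preys = [f"prey{i:04d}" for i in range(cfg.n_preys)]
    true_idx = rng.choice(cfg.n_preys, size=cfg.n_true_interactors, replace=False)
    truth = pd.Series(False, index=pd.Index(preys, name="prey"))
    truth.iloc[np.sort(true_idx)] = True

    run_rows = []
    columns = {}
    for condition in ("bait_N", "bait_C", "control"):
        for r in range(cfg.runs_per_condition):
            pool = "AB"[r % 2]
            run_id = f"{condition}_{pool}{r // 2 + 1}"
            run_rows.append({"run": run_id, "condition": condition, "pool": pool})
            mean = np.full(cfg.n_preys, cfg.control_mean)
            if condition != "control":
                mean = np.where(
                    truth.to_numpy(), cfg.control_mean * cfg.enrichment_fold, mean
                )
            columns[run_id] = rng.poisson(mean)
    counts = pd.DataFrame(columns, index=truth.index)
    runs = pd.DataFrame(run_rows).set_index("run")
    # unique peptides track spectral counts at roughly 0.4x, as in real MS
    # output where repeated spectra map to fewer distinct peptides
    unique = np.ceil(0.4 * counts).astype(np.int64)
    return BioidSim(
        table=SpectralCountTable(counts=counts, runs=runs, unique_peptides=unique),
        truth=truth,
    )


def write_bioid(sim: BioidSim, outdir: str | os.PathLike) -> None:
    """Write the long-format count TSV and the truth table."""
    os.makedirs(outdir, exist_ok=True)
    long = (
        sim.table.counts.reset_index()
        .melt(id_vars="prey", var_name="run", value_name="spectral_count")
        .merge(sim.table.runs.reset_index(), on="run")
    )
    write_tsv(os.path.join(outdir, "bioid_counts.tsv"), long)
    write_tsv(
        os.path.join(outdir, "bioid_truth.tsv"),
        sim.truth.rename("true_interactor").reset_index(),
    )


# ---------------------------------------------------------------------------
# shRNA screen reads


@dataclass(frozen=True)
class ScreenSimConfig:
    n_genes: int = 235
    shrnas_per_gene: int = 10
    barcode_length: int = 18
    reads_per_barcode: int = 500
    frac_essential_a: float = 0.1
    frac_essential_b: float = 0.0
    depletion_strength: float = 0.2
    spacer: str = "CGAA"
    dispersion: float = 0.1  # NB overdispersion: var = m + dispersion * m^2
    frac_spacer_err1: float = 0.05
    frac_spacer_err2: float = 0.01
    replicates: int = 1
    n_non_targeting: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0, "n_genes must be positive")
        _require(self.shrnas_per_gene > 0, "shrnas_per_gene must be positive")
        _require(self.barcode_length > 0, "barcode_length must be positive")
        _require(self.reads_per_barcode > 0, "reads_per_barcode must be positive")
        _require(len(self.spacer) == 4, "spacer must be exactly 4 bases")
        _require(set(self.spacer) <= set("ACGT"), "spacer must be ACGT-only")
        for name in ("frac_essential_a", "frac_essential_b"):
            _require(0 <= getattr(self, name) <= 1, f"{name} must be a fraction")
        _require(
            0 < self.depletion_strength <= 1, "depletion_strength must be in (0, 1]"
        )
        _require(self.dispersion >= 0, "dispersion must be non-negative")
        _require(
            self.frac_spacer_err1 + self.frac_spacer_err2 <= 1,
            "spacer error fractions must sum to <= 1",
        )
        _require(self.replicates >= 1, "replicates must be >= 1")


@dataclass
class ScreenSim:
    library: BarcodeLibrary
    layout: ReadLayout
    reads: dict[str, list[str]]  # sample id -> read sequences
    truth: pd.DataFrame  # gene, essential_a, essential_b
    planted_counts: pd.DataFrame  # shrna_id x sample, all planted reads
    spacer2_counts: pd.DataFrame  # reads planted with 2-base spacer errors
    samples: pd.DataFrame  # sample, arm, environment, replicate

    def grouping(self) -> dict[str, list[str]]:
        """Replicate grouping for collapse: arm:environment -> samples."""
        groups: dict[str, list[str]] = {}
        for rec in self.samples.itertuples(index=False):
            if rec.environment == "reference":
                continue
            groups.setdefault(f"{rec.arm}:{rec.environment}", []).append(rec.sample)
        return groups

    def reference_of(self, arm: str) -> str:
        mask = (self.samples["arm"] == arm) & (
            self.samples["environment"] == "reference"
        )
        return self.samples.loc[mask, "sample"].iloc[0]


def _random_unique_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            kmer = "".join("ACGT"[b] for b in row)
            if kmer not in seen:
                seen.add(kmer)
                out.append(kmer)
    return out


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion * m^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _mutate_spacer(rng: np.random.Generator, spacer: str, n_errors: int) -> str:
    positions = rng.choice(len(spacer), size=n_errors, replace=False)
    bases = list(spacer)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = alternatives[rng.integers(0, 3)]
    return "".join(bases)


def gen_screen_reads(cfg: ScreenSimConfig) -> ScreenSim:
    """Simulate barcode reads for a two-arm dropout screen.

    Samples per arm: one ``reference`` plus ``replicates`` ``in_vitro``
    endpoint samples. Barcodes of genes planted essential in an arm are
    depleted multiplicatively by ``depletion_strength`` in that arm's
    endpoint samples. A configurable fraction of reads carries one
    (passing) or two (failing) spacer mismatches.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = ReadLayout(spacer=cfg.spacer)
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    n_barcodes = cfg.n_genes * cfg.shrnas_per_gene
    barcodes = _random_unique_kmers(rng, n_barcodes + cfg.n_non_targeting, cfg.barcode_length)

    entries = pd.DataFrame(
        {
            "shrna_id": [f"sh{i:05d}" for i in range(n_barcodes)],
            "gene": np.repeat(genes, cfg.shrnas_per_gene),
            "barcode": barcodes[:n_barcodes],
            "class": "targeting",
        }
    )
    if cfg.n_non_targeting:
        entries = pd.concat(
            [
                entries,
                pd.DataFrame(
                    {
                        "shrna_id": [f"nt{i:05d}" for i in range(cfg.n_non_targeting)],
                        "gene": "non_targeting",
                        "barcode": barcodes[n_barcodes:],
                        "class": "non_targeting",
                    }
                ),
            ],
            ignore_index=True,
        )
    library = BarcodeLibrary(entries=entries)

    essential_a = rng.random(cfg.n_genes) < cfg.frac_essential_a
    essential_b = rng.random(cfg.n_genes) < cfg.frac_essential_b
    truth = pd.DataFrame(
        {"gene": genes, "essential_a": essential_a, "essential_b": essential_b}
    )

    sample_rows = []
    for arm, ess in (("arm_A", essential_a), ("arm_B", essential_b)):
        sample_rows.append(
            {"sample": f"{arm}_ref", "arm": arm, "environment": "reference", "replicate": 0}
        )
        for rep in range(1, cfg.replicates + 1):
            sample_rows.append(
                {
                    "sample": f"{arm}_vitro_r{rep}",
                    "arm": arm,
                    "environment": "in_vitro",
                    "replicate": rep,
                }
            )
    samples = pd.DataFrame(sample_rows)

    # fixed 17-nt prefix and 1-nt gap between spacer end and barcode window
    prefix = ("ACGT" * 5)[: layout.spacer_start - 1]
    gap = "T" * (layout.targeting_window[0] - 1 - (layout.spacer_start - 1 + 4))

    targeting = library.entries["class"] == "targeting"
    shrna_ids = library.entries.loc[targeting, "shrna_id"].to_numpy()
    bc_seqs = library.entries.loc[targeting, "barcode"].to_numpy()
    gene_ess = {
        "arm_A": np.repeat(essential_a, cfg.shrnas_per_gene),
        "arm_B": np.repeat(essential_b, cfg.shrnas_per_gene),
    }

    reads: dict[str, list[str]] = {}
    planted = {}
    spacer2 = {}
    p_clean = 1.0 - cfg.frac_spacer_err1 - cfg.frac_spacer_err2
    for rec in samples.itertuples(index=False):
        mean = np.full(len(bc_seqs), float(cfg.reads_per_barcode))
        if rec.environment != "reference":
            mean = np.where(
                gene_ess[rec.arm], mean * cfg.depletion_strength, mean
            )
        counts = _nb_counts(rng, mean, cfg.dispersion)
        split = rng.multinomial(
            counts, [p_clean, cfg.frac_spacer_err1, cfg.frac_spacer_err2]
        )
        sample_reads: list[str] = []
        for j, barcode in enumerate(bc_seqs):
            clean = prefix + cfg.spacer + gap + barcode
            n0, n1, n2 = split[j]
            sample_reads.extend([clean] * n0)
            for _ in range(n1):
                sample_reads.append(
                    prefix + _mutate_spacer(rng, cfg.spacer, 1) + gap + barcode
                )
            for _ in range(n2):
                sample_reads.append(
                    prefix + _mutate_spacer(rng, cfg.spacer, 2) + gap + barcode
                )
        reads[rec.sample] = sample_reads
        planted[rec.sample] = counts
        spacer2[rec.sample] = split[:, 2]

    index = pd.Index(shrna_ids, name="shrna_id")
    return ScreenSim(
        library=library,
        layout=layout,
        reads=reads,
        truth=truth,
        planted_counts=pd.DataFrame(planted, index=index),
        spacer2_counts=pd.DataFrame(spacer2, index=index),
        samples=samples,
    )


def write_screen(sim: ScreenSim, outdir: str | os.PathLike) -> dict[str, str]:
    """Write per-sample FASTQ files, the library TSV and the truth table.

    Returns the sample -> FASTQ path mapping. Qualities are constant 'I';
    the pipeline never uses them.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for sample, seqs in sim.reads.items():
        path = os.path.join(outdir, f"{sample}.fastq")
        write_fastq(
            path,
            (
                FastqRecord(f"{sample}:{i}", seq, "I" * len(seq))
                for i, seq in enumerate(seqs)
            ),
        )
        paths[sample] = path
    write_tsv(os.path.join(outdir, "library.tsv"), sim.library.entries)
    write_tsv(os.path.join(outdir, "screen_truth.tsv"), sim.truth)
    write_tsv(os.path.join(outdir, "samples.tsv"), sim.samples)
    return paths


# ---------------------------------------------------------------------------
# Funnel fixture


@dataclass(frozen=True)
class FunnelSimConfig:
    n_genes: int = 100
    frac_cobound: float = 0.5
    frac_repressed: float = 0.2
    promoter_length: int = 500
    tss_window: int = 250
    ebox_motif: str = "CACCTG"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0, "n_genes must be positive")
        _require(0 <= self.frac_cobound <= 1, "frac_cobound must be a fraction")
        _require(0 <= self.frac_repressed <= 1, "frac_repressed must be a fraction")
        _require(self.promoter_length >= 10, "promoter_length must be >= 10")
        _require(self.tss_window > 0, "tss_window must be positive")
        _require(
            len(self.ebox_motif) > 0 and set(self.ebox_motif) <= set("ACGT"),
            "ebox_motif must be non-empty and ACGT-only",
        )


@dataclass
class FunnelSim:
    peaks_a: list[BedInterval]
    peaks_b: list[BedInterval]
    annotation: pd.DataFrame  # gene, chrom, tss, strand
    expression: pd.DataFrame  # indexed by gene, {dataset}_{fold,p} columns
    promoters: dict[str, str]
    truth: pd.Series  # bool per gene: planted target


_DATASETS = ("OE_393P", "miR200_344SQ", "ZEB1_3T3L1", "shZEB1_MDA231")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def gen_funnel_fixture(cfg: FunnelSimConfig) -> FunnelSim:
    """Build a co-occupancy/expression/promoter fixture with planted targets.

    ``round(n_genes * frac_cobound * frac_repressed)`` genes are planted as
    targets satisfying every funnel criterion; each remaining gene violates
    at least one criterion (missing co-occupancy, failing expression, or a
    co-bound site outside the TSS window).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    spacing = max(10_000, 4 * cfg.tss_window + 2 * cfg.promoter_length)
    tss = 5_000 + spacing * np.arange(cfg.n_genes)
    annotation = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chr1",
            "tss": tss,
            "strand": np.where(rng.random(cfg.n_genes) < 0.5, "+", "-"),
        }
    )

    n_targets = round(cfg.n_genes * cfg.frac_cobound * cfg.frac_repressed)
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    target_idx = rng.choice(cfg.n_genes, size=n_targets, replace=False)
    is_target[target_idx] = True
    violations = ("not_cobound", "expr_fail", "tss_far")
    violation = np.where(
        is_target, "none", rng.choice(violations, size=cfg.n_genes)
    )

    peaks_a: list[BedInterval] = []
    peaks_b: list[BedInterval] = []
    expr_rows = []
    promoters: dict[str, str] = {}
    for i, gene in enumerate(genes):
        mode = violation[i]
        t = int(tss[i])
        if mode in ("none", "expr_fail"):
            # overlapping peaks from both factors covering the TSS
            peaks_a.append(BedInterval("chr1", t - 100, t + 60, f"{gene}_a"))
            peaks_b.append(BedInterval("chr1", t - 40, t + 120, f"{gene}_b"))
        elif mode == "tss_far":
            far = t + cfg.tss_window + 1 + int(rng.integers(0, cfg.tss_window))
            peaks_a.append(BedInterval("chr1", far, far + 160, f"{gene}_a"))
            peaks_b.append(BedInterval("chr1", far + 40, far + 200, f"{gene}_b"))
        elif rng.random() < 0.5:
            # one factor only: never co-bound
            peaks_a.append(BedInterval("chr1", t - 100, t + 60, f"{gene}_a"))

        passing = mode in ("none", "tss_far")
        row = {"gene": gene}
        if passing:
            row["OE_393P_fold"] = float(rng.uniform(0.05, 0.45))
            row["OE_393P_p"] = float(rng.uniform(0.0, 0.04))
            row["miR200_344SQ_fold"] = float(rng.uniform(1.5, 3.0))
            row["miR200_344SQ_p"] = float(rng.uniform(0.0, 0.04))
            for ds in _DATASETS[2:]:
                row[f"{ds}_fold"] = float(rng.uniform(0.6, 1.4))
                row[f"{ds}_p"] = float(rng.uniform(0.2, 1.0))
        else:
            row["OE_393P_fold"] = float(rng.uniform(0.6, 1.4))
            row["OE_393P_p"] = float(rng.uniform(0.2, 1.0))
            for ds in _DATASETS[1:]:
                row[f"{ds}_fold"] = float(rng.uniform(0.6, 1.4))
                row[f"{ds}_p"] = float(rng.uniform(0.2, 1.0))
        expr_rows.append(row)

        seq = _random_seq(rng, cfg.promoter_length)
        if mode == "none":
            pos = int(rng.integers(0, cfg.promoter_length - len(cfg.ebox_motif)))
            seq = seq[:pos] + cfg.ebox_motif + seq[pos + len(cfg.ebox_motif) :]
        promoters[gene] = seq

    expression = pd.DataFrame(expr_rows).set_index("gene")
    truth = pd.Series(is_target, index=pd.Index(genes, name="gene"))
    sim = FunnelSim(
        peaks_a=sorted(peaks_a, key=lambda p: (p.chrom, p.start)),
        peaks_b=sorted(peaks_b, key=lambda p: (p.chrom, p.start)),
        annotation=annotation,
        expression=expression,
        promoters=promoters,
        truth=truth,
    )
    _check_funnel_labels(sim, cfg)
    return sim


def _check_funnel_labels(sim: FunnelSim, cfg: FunnelSimConfig) -> None:
    """Planted positives must satisfy every stage's passing condition."""
    tss_of = sim.annotation.set_index("gene")["tss"]
    for gene in sim.truth.index[sim.truth]:
        t = int(tss_of[gene])
        near_a = any(
            p.start - cfg.tss_window <= t < p.end + cfg.tss_window for p in sim.peaks_a
        )
        near_b = any(
            p.start - cfg.tss_window <= t < p.end + cfg.tss_window for p in sim.peaks_b
        )
        assert near_a and near_b, f"planted target {gene} lacks co-bound peaks"
        row = sim.expression.loc[gene]
        assert row["OE_393P_fold"] <= 0.5 and row["OE_393P_p"] <= 0.05
        assert any(row[f"{ds}_p"] <= 0.05 for ds in _DATASETS[1:])
        count, _ = scan_ebox(sim.promoters[gene], cfg.ebox_motif)
        assert count >= 1, f"planted target {gene} lacks an E-box"


def write_funnel(sim: FunnelSim, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_bed(os.path.join(outdir, "peaks_a.bed"), sim.peaks_a)
    write_bed(os.path.join(outdir, "peaks_b.bed"), sim.peaks_b)
    write_tsv(os.path.join(outdir, "annotation.tsv"), sim.annotation)
    write_tsv(os.path.join(outdir, "expression.tsv"), sim.expression.reset_index())
    write_fasta(os.path.join(outdir, "promoters.fa"), sim.promoters)
    write_tsv(
        os.path.join(outdir, "funnel_truth.tsv"),
        sim.truth.rename("target").reset_index(),
    )
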