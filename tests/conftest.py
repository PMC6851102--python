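import logging

import pandas as pd
import pytest

from zebscreen import screen, synth

logging.getLogger("zebscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bioid_sim():
    return synth.gen_bioid_counts(
        synth.BioidSimConfig(
            n_preys=200, n_true_interactors=20, control_mean=2.0,
            enrichment_fold=8.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def screen_sim():
    """Small two-arm screen: 40 genes x 5 shRNAs, 2 replicates."""
    return synth.gen_screen_reads(
        synth.ScreenSimConfig(
            n_genes=40, shrnas_per_gene=5, reads_per_barcode=150,
            frac_essential_a=0.2, frac_essential_b=0.0,
            depletion_strength=0.15, replicates=2, seed=7,
        )
    )


@pytest.fixture(scope="session")
def funnel_sim():
    return synth.gen_funnel_fixture(
        synth.FunnelSimConfig(
            n_genes=100, frac_cobound=0.5, frac_repressed=0.2, seed=5
        )
    )


def collapse_screen(sim: synth.ScreenSim) -> pd.DataFrame:
    """Demux -> normalize -> fold -> collapse, returning percentile columns."""
    raw, _ = screen.demultiplex(sim.reads, sim.library, sim.layout)
    norm = screen.normalize_library_size(raw)
    targeting = sim.library.entries.loc[
        sim.library.entries["class"] == "targeting", "shrna_id"
    ]
    parts = []
    for arm in ("arm_A", "arm_B"):
        arm_samples = sim.samples.loc[sim.samples["arm"] == arm, "sample"]
        folds = screen.fold_change_percentile(
            norm[list(arm_samples)],
            reference_sample=sim.reference_of(arm),
            targeting_ids=targeting,
        )
        grouping = {g: s for g, s in sim.grouping().items() if g.startswith(arm)}
        parts.append(screen.collapse_replicates(folds, grouping))
    return pd.concat(parts, axis=1)


@pytest.fixture(scope="session")
def screen_collapsed(screen_sim):
    return collapse_screen(screen_sim)
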