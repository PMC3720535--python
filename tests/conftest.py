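import numpy as np
import pandas as pd
import pytest

from exsirna.pipeline import analyze_panel
from exsirna.simdata import SimConfig, simulate


def small_config(**overrides) -> SimConfig:
    """A desk-corner panel: few loci on a small genome, cheap to simulate."""
    defaults = dict(
        seed=0,
        n_scaffolds=2,
        scaffold_length=20_000,
        loci_per_class={"I": 3, "II": 3, "III": 3, "IV": 2},
        base_abundance=(6.5, 0.5),
        min_locus_separation=1200,
        ip_carryover_loci=10,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_panel():
    """One full-size synthetic panel analysed end to end (shared, read-only)."""
    cfg = SimConfig(seed=11)
    sim = simulate(cfg)
    result = analyze_panel(sim.libraries, sim.genome, sim.annotation)
    return sim, result


def alignment_frame(rows):
    """Alignment table from (scaffold, start, end, strand, weight) tuples."""
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "strand",
                                     "weight"])
    df["read"] = ["A" * (e - s) for s, e in zip(df["start"], df["end"])]
    df["n_hits"] = 1
    df["count"] = 1
    df["library"] = "wt"
    return df
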