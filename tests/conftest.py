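import numpy as np
import pandas as pd
import pytest

from thermotrace.synthetic_community import CommunitySimConfig, generate_study
from thermotrace.types import OtuCountTable, Pretreatment, SampleRecord


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast, reduced-size synthetic study configuration."""
    return CommunitySimConfig(
        n_background_otus=80,
        n_thermospore_otus=8,
        library_size=8000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    return generate_study(small_sim_config)


@pytest.fixture(scope="session")
def default_study():
    """One study at the generator's default settings."""
    return generate_study(CommunitySimConfig(seed=5))


def make_paired_metadata():
    """Minimal valid design: one microcosm pair per pretreatment."""
    meta = []
    for pre in Pretreatment:
        for day in (0, 7):
            sid = SampleRecord.make_id(pre, "R1", day)
            meta.append(SampleRecord(sid, pre, "R1", day))
    return meta


@pytest.fixture
def toy_pair_table():
    """Two-sample (one pair) count table with a clear enrichment signal.

    OTU_A: 2 -> 900 reads out of 45,000 (the canonical germination case);
    OTU_B: dominant background that shrinks in relative terms;
    OTU_C: modest absolute counts, below every criterion.
    """
    day0 = {"OTU_A": 2, "OTU_B": 44600, "OTU_C": 398}
    day7 = {"OTU_A": 900, "OTU_B": 43700, "OTU_C": 400}
    df = pd.DataFrame({"PLUS4_R1_d0": day0, "PLUS4_R1_d7": day7})
    table = OtuCountTable(df)
    meta = [
        SampleRecord("PLUS4_R1_d0", Pretreatment.PLUS4, "R1", 0),
        SampleRecord("PLUS4_R1_d7", Pretreatment.PLUS4, "R1", 7),
    ]
    return table, meta
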