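import numpy as np
import pandas as pd
import pytest

from svscape.io_formats import VariantTable
from svscape.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One in-memory synthetic cohort shared across tests (read-only)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_cfg_kwargs():
    """Reduced generator settings for tests that re-simulate repeatedly."""
    return dict(n_snps=600, n_indels=500, n_svs=150, n_qtl=60, n_re=40,
                n_genes=10, n_background_repeats=30)


def make_table(rows, samples=None, dosages=None, infos=None) -> VariantTable:
    """Build a VariantTable from (id, chrom, pos, start, end, vtype, length,
    qual) tuples; REF/ALT are placeholders."""
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "start", "end",
                                     "vtype", "length", "qual"])
    df["ref"] = "A"
    df["alt"] = "T"
    samples = samples or []
    if dosages is None:
        dosages = np.zeros((len(df), len(samples)), dtype=np.int16)
    return VariantTable(df, np.asarray(dosages, dtype=np.int16), samples,
                        infos or [])
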