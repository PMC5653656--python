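import numpy as np
import pandas as pd
import pytest

from cistrans.io import SiteTable
from cistrans.simdata import SimConfig, simulate_dataset


def make_site(f0_a, f0_b, f1_a, f1_b, site_id="s1"):
    """Per-site mapping in the form the fitting stages consume."""
    return {"site_id": site_id,
            "f0_a": np.asarray(f0_a, dtype=float),
            "f0_b": np.asarray(f0_b, dtype=float),
            "f1_a": np.asarray(f1_a, dtype=float),
            "f1_b": np.asarray(f1_b, dtype=float)}


def make_table(rows):
    """SiteTable from a list of (site_id, chrom, pos, f0_a, f0_b, f1_a, f1_b)."""
    recs = []
    for sid, chrom, pos, f0a, f0b, f1a, f1b in rows:
        rec = {"site_id": sid, "chrom": chrom, "pos": pos, "assay": "TF1"}
        rec.update({f"F0_A_rep{i+1}": v for i, v in enumerate(f0a)})
        rec.update({f"F0_B_rep{i+1}": v for i, v in enumerate(f0b)})
        rec.update({f"F1_A_rep{i+1}": v for i, v in enumerate(f1a)})
        rec.update({f"F1_B_rep{i+1}": v for i, v in enumerate(f1b)})
        recs.append(rec)
    return SiteTable(pd.DataFrame(recs))


@pytest.fixture(scope="session")
def small_dataset():
    """A 4 x 40 site synthetic dataset with truth, shared across tests."""
    cfg = SimConfig(n_sites_per_class=40, seed=101)
    table, truth = simulate_dataset(cfg)
    return cfg, table, truth
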