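import numpy as np
import pandas as pd
import pytest

from stftwas.data_io import GenotypePanel, _variant_stats
from stftwas.synthetic_data import FixtureSpec, generate_study_bundle


def make_panel(dosages, chrom="1", spacing=1000, start=1001,
               ids=None, ref="A", alt="G"):
    """GenotypePanel from a raw dosage matrix with computed QC stats."""
    dosages = np.asarray(dosages, dtype=float)
    n_samples, n_variants = dosages.shape
    maf, miss, hwe = _variant_stats(dosages)
    variants = pd.DataFrame({
        "id": ids if ids is not None
        else [f"v{i:04d}" for i in range(n_variants)],
        "chrom": chrom,
        "pos": start + np.arange(n_variants) * spacing,
        "ref": ref, "alt": alt,
        "maf": maf, "missing_rate": miss, "hwe_p": hwe,
    })
    return GenotypePanel([f"S{i}" for i in range(n_samples)], variants,
                         dosages)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One small synthetic study bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(n_ref_samples=200, n_cohort_samples=600,
                       n_variants=600, n_blocks=15, n_genes=6,
                       h2_expr=0.4, h2_trait=0.3, seed=11)
    truth = generate_study_bundle(spec, out)
    return out, spec, truth
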