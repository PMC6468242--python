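import numpy as np
import pytest

from adacomplex.pipeline import demo_config, run_all
from adacomplex.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    """One full pipeline run on the bundled synthetic demo (seed 0)."""
    out = tmp_path_factory.mktemp("demo")
    report = run_all(demo_config(out_dir=str(out), seed=0))
    return report, out


@pytest.fixture
def small_config():
    """A fast miniature of the default synthetic study."""
    return SyntheticConfig(
        seed=7,
        chrom_sizes={"chrA": 60_000, "chrB": 60_000},
        n_genes=40,
        n_canonical_loci=10,
        n_ada2b_only_loci=4,
        n_unbound_controls=4,
        spectra_per_run=1000,
        n_contaminants=20,
        n_shared_pairs=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
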