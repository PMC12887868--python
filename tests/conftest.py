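import numpy as np
import pandas as pd
import pytest

from cistwas.decompose import decompose_chromosome, merge_components
from cistwas.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two-chromosome synthetic population with one trait-driving gene."""
    config = SimulationConfig(
        n_individuals=150, n_chromosomes=2, genes_per_chromosome=8,
        variants_per_gene_window=10, cis_h2=0.4,
        phenotype_effects=[("G1_001", "both", 1.0)], seed=42)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def decomposed(small_dataset):
    """Merged vc/cis/trans/pred tables for the small dataset."""
    d = small_dataset
    per_chrom = []
    for c in d.annotation["chr"].unique():
        genes = d.annotation[d.annotation["chr"] == c].reset_index(drop=True)
        vcs, comps = decompose_chromosome(genes, d.panel, d.expression,
                                          extend=d.config.extend)
        per_chrom.append((genes, vcs, comps))
    return merge_components(per_chrom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_panel(dosage, positions=None, chrom="1", ids=None):
    """Tiny GenotypePanel from a dosage array, for hand-built cases."""
    from cistwas.io import GenotypePanel
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = list(range(1000, 1000 + 100 * m, 100))
    if ids is None:
        ids = [f"I{i}" for i in range(n)]
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chromosome": chrom, "position": positions,
        "allele_ref": "A", "allele_alt": "T"})
    return GenotypePanel(ids, variants, dosage)
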