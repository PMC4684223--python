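import numpy as np
import pytest

from napusgwas import popgen, sim


@pytest.fixture(scope="session")
def small_panel():
    """Structured two-subpopulation panel: 150 samples, 2 x 250 markers."""
    cfg = sim.SimConfig(
        n_samples=150,
        chromosomes=(("A01", 250, 4_000_000), ("A02", 250, 4_000_000)),
        n_subpops=2,
        fst=0.08,
        ld_rho=0.7,
        missing_rate=0.02,
        seed=42,
    )
    return sim.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def qc_panel(small_panel):
    G, mm = popgen.filter_markers(small_panel.genotypes, small_panel.marker_map)
    return G, mm


@pytest.fixture(scope="session")
def panel_phenotype(qc_panel):
    """Replicate-averaged phenotype with one strong planted QTL (marker 100)."""
    G, mm = qc_panel
    qtl_id = mm["id"].iloc[100]
    table = sim.simulate_phenotypes(
        G, mm, [sim.QTLSpec(qtl_id, 1.0)],
        sim.TraitSimParams(mu=5.0, var_g_poly=0.3, var_e=0.2, var_ge=0.2, var_resid=0.3),
        seed=11,
    )
    y = table.groupby("accession", observed=True)["value"].mean().reindex(G.samples).to_numpy()
    return y, qtl_id, table


def rng_of(*parts) -> np.random.Generator:
    return np.random.default_rng(parts)
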