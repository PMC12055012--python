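import numpy as np
import pytest

from fatelink import simulate as sim


@pytest.fixture(scope="session")
def small_multiome():
    """Two cell types, fragments on, a few planted QC failures and lineage cells."""
    design = sim.SimDesign(
        celltypes=("ILC2", "T"),
        cells_per_condition=25,  # 200 cells
        qc_fail_counts={m: 2 for m in sim.QC_FAIL_MODES},
        lineage_pos_fraction=0.3,
        seed=11,
    )
    genome, peaks = sim.make_genome(design, seed=11)
    paired, cells = sim.simulate_counts(genome, peaks, design, seed=11)
    return design, genome, peaks, paired, cells


@pytest.fixture(scope="session")
def linked_multiome():
    """One cell type, no fragments, links planted in every group."""
    design = sim.SimDesign(
        celltypes=("ILC2",),
        cells_per_condition=200,  # 800 cells
        n_genes=120,
        emit_fragments=False,
        seed=21,
    )
    genome, peaks = sim.make_genome(design, seed=21)
    links = sim.plant_links(genome, peaks, 12, groups=sim.GROUPS, target_r=0.45,
                            rng=np.random.default_rng(21))
    design.planted_links = links
    paired, cells = sim.simulate_counts(genome, peaks, design, seed=21)
    return design, genome, peaks, paired, cells
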