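import math

import pandas as pd
import pytest

import mammosig as m


@pytest.fixture(scope="session")
def sc3():
    """Small 3-type simulation with clustering run end to end."""
    cfg = m.ScSimConfig(
        n_cells=300,
        n_genes=400,
        k_types=3,
        type_props=(0.4, 0.35, 0.25),
        markers_per_type=30,
        marker_logfc=math.log(8),
        frac_mito_genes=0.05,
        n_aggregate_cells=0,
        seed=11,
    )
    umi, truth = m.simulate_sc(cfg)
    norm = m.normalize(umi)
    emb = m.pca_embed(norm, n_pcs=10, n_hvg=200)
    assign = m.snn_cluster(emb, k_neighbors=15, resolution=0.5, seed=0)
    assign.labels.index = pd.Index(norm.barcodes, name="barcode")
    assign = m.ClusterAssignment(assign.labels)
    return {"cfg": cfg, "umi": umi, "truth": truth, "norm": norm,
            "embedding": emb, "clusters": assign}
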