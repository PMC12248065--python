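import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from apamap import endseq_clustering, synthetic_data
from apamap.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def scenario():
    """Default study conditions: 200 two-PAS exons, 10% internal-priming
    decoys, depth 500 reads/exon/sample, 3 replicate pairs, jitter +/-5."""
    cfg = SimConfig(n_genes=200, rng_seed=11)
    genome, genes, truth = synthetic_data.simulate_genome(cfg)
    reads = synthetic_data.simulate_endseq(cfg, truth)
    clusters = endseq_clustering.call_clusters(reads)
    surviving = endseq_clustering.apply_filters(
        clusters, genome, synthetic_data.reference_pas_records(truth))
    return {
        "config": cfg, "genome": genome, "genes": genes, "truth": truth,
        "reads": reads, "clusters": clusters, "surviving": surviving,
        "manifest": synthetic_data.make_manifest(
            synthetic_data.default_samples(cfg)),
    }


def reads_from_coverage(coverage, chrom="chrT", strand="+", origin=100,
                        sample="s1"):
    """Single-sample read table realising an exact per-base coverage vector."""
    cov = np.asarray(coverage, dtype=int)
    pos = np.repeat(origin + np.arange(cov.size), cov)
    return {sample: pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": strand})}
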