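from __future__ import annotations

import numpy as np
import pytest

from scisokit import SimulationConfig, simulate
from scisokit.pipeline import run_all


def run_pipeline(exp, outdir, params=None):
    return run_all(
        exp.annotation_gtf, exp.genome_fasta, exp.reads_fastq, exp.alignments_sam,
        exp.whitelist_tsv, exp.clusters_tsv, exp.junction_counts_tsv,
        exp.cage_bed, exp.polya_bed, exp.peptides_txt, outdir, params=params,
    )


@pytest.fixture(scope="session")
def noisefree_world(tmp_path_factory):
    """Default-scale noise-free experiment (20 genes, 4 clusters, 200 cells,
    ~20k reads) plus the full pipeline run on it."""
    cfg = SimulationConfig(seed=1234, truncation_prob=0.0, barcode_error_rate=0.0)
    base = tmp_path_factory.mktemp("noisefree")
    exp = simulate(cfg, base / "sim")
    res = run_pipeline(exp, base / "out")
    return exp, res


@pytest.fixture(scope="session")
def noisy_world(tmp_path_factory):
    """Small experiment with 5' truncation and barcode errors switched on."""
    cfg = SimulationConfig(
        seed=77, n_genes=8, cells_per_cluster=10, reads_per_cell_mean=40,
        truncation_prob=0.08, barcode_error_rate=0.10,
    )
    base = tmp_path_factory.mktemp("noisy")
    exp = simulate(cfg, base / "sim")
    res = run_pipeline(exp, base / "out")
    return exp, res


@pytest.fixture(scope="session")
def synthetic_annotation():
    """A 50-gene reference + novel isoforms, no reads (for classifier/event tests)."""
    from scisokit.simulate import simulate_novel_isoforms, simulate_reference

    cfg = SimulationConfig(seed=9, n_genes=50, transcripts_per_gene=(2, 4),
                           novel_isoform_fraction=0.6)
    rng = np.random.default_rng(cfg.seed)
    genome, annotation = simulate_reference(cfg, rng)
    novels, truth = simulate_novel_isoforms(genome, annotation, cfg, rng)
    return genome.freeze(), annotation, novels, truth
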