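import numpy as np
import pytest

from ipactools.genome_model import ExtendedAnnotation, GeneModel
from ipactools.pipeline import PipelineConfig, run_pipeline
from ipactools.synthetic_data import SimulationConfig, simulate


def make_gene(gene_id, chrom, strand, start, end, cds=None, exons=None, biotype="protein_coding"):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=exons or [(start, end)],
        cds=cds if cds is not None else [],
        biotype=biotype,
    )


@pytest.fixture
def toy_ann():
    """Two coding genes on a 20 kb chromosome, one per strand.

    + gene A: [1000, 3000), CDS [1100, 2850)  -> stop cut 2850, ext end 3050
    - gene B: [6000, 8000), CDS [6150, 7900)  -> stop cut 6150, ext start 5950
    """
    a = make_gene("A", "c", "+", 1000, 3000, cds=[(1100, 2850)])
    b = make_gene("B", "c", "-", 6000, 8000, cds=[(6150, 7900)])
    return ExtendedAnnotation([a, b], {"c": 20000}, extension_nt=50)


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory):
    cfg = SimulationConfig(n_genes=80, n_sites=150, ip_artifact_rate=0.1, seed=11)
    outdir = tmp_path_factory.mktemp("sim")
    paths = simulate(cfg, str(outdir))
    paths["cfg"] = cfg
    return paths


@pytest.fixture(scope="session")
def pipeline_run(sim_paths, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        gff3=sim_paths["gff3"],
        tags_bed=sim_paths["tags"],
        fasta=sim_paths["fasta"],
        chrom_sizes=sim_paths["chrom_sizes"],
        outdir=str(outdir),
        seed=17,
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(42)
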