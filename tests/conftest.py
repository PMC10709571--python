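import numpy as np
import pytest

from ambigene import SimConfig, simulate


@pytest.fixture
def small_tables():
    """Two mappers x 3 samples x 4 genes with hand-set counts."""
    from ambigene import CountTable, DesignTable
    genes = ["g1", "g2", "g3", "g4"]
    samples = ["s1", "s2", "s3", "s4"]
    a = CountTable(genes, samples, np.array([[10, 12, 50, 60],
                                             [5, 6, 7, 8],
                                             [100, 90, 80, 70],
                                             [0, 1, 2, 3]]))
    b = CountTable(genes, samples, np.array([[11, 13, 48, 55],
                                             [5, 5, 9, 7],
                                             [95, 92, 85, 75],
                                             [1, 0, 3, 2]]))
    design = DesignTable(samples, ["ctrl", "ctrl", "case", "case"])
    return {"hisat2": a, "star": b}, design


@pytest.fixture(scope="session")
def null_sim():
    """No group effect, no mapper effect: the exchangeable null."""
    cfg = SimConfig(n_genes=2000, n_per_group=5, n_groups=2, k_mappers=3,
                    dispersion=0.1, seed=101)
    return simulate(cfg)


@pytest.fixture(scope="session")
def planted_sim():
    """5% joint-effect genes at |log2FC| = 2: the planted difficult genes."""
    cfg = SimConfig(n_genes=2000, n_per_group=5, n_groups=2, k_mappers=3,
                    dispersion=0.1, frac_joint=0.05, log2fc_group=2.0,
                    log2fc_mapper=2.0, seed=202)
    return simulate(cfg)


@pytest.fixture
def tiny_gtf(tmp_path):
    lines = [
        'chr1\tens\tgene\t100\t250\t.\t+\t.\tgene_id "G1"; gene_biotype "processed_pseudogene";',
        'chr1\tens\ttranscript\t100\t250\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
        'chr1\tens\texon\t100\t250\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "processed_pseudogene";',
        'chr1\tens\tgene\t1000\t2000\t.\t-\t.\tgene_id "G2"; gene_biotype "protein_coding";',
        'chr1\tens\ttranscript\t1000\t1500\t.\t-\t.\tgene_id "G2"; transcript_id "T2";',
        'chr1\tens\texon\t1000\t1100\t.\t-\t.\tgene_id "G2"; transcript_id "T2"; gene_biotype "protein_coding";',
        'chr1\tens\texon\t1400\t1500\t.\t-\t.\tgene_id "G2"; transcript_id "T2"; gene_biotype "protein_coding";',
        'chr1\tens\ttranscript\t1000\t2000\t.\t-\t.\tgene_id "G2"; transcript_id "T3";',
        'chr1\tens\texon\t1000\t1100\t.\t-\t.\tgene_id "G2"; transcript_id "T3"; gene_biotype "protein_coding";',
        'chr1\tens\texon\t1300\t1350\t.\t-\t.\tgene_id "G2"; transcript_id "T3"; gene_biotype "protein_coding";',
        'chr1\tens\texon\t1600\t1700\t.\t-\t.\tgene_id "G2"; transcript_id "T3"; gene_biotype "protein_coding";',
        'chr1\tens\texon\t1900\t2000\t.\t-\t.\tgene_id "G2"; transcript_id "T3"; gene_biotype "protein_coding";',
    ]
    path = tmp_path / "tiny.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
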