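import numpy as np
import pytest
from pyfaidx import Fasta

from chipcompendium.intervals import GenomicInterval
from chipcompendium.io import write_fasta
from chipcompendium.model import Gene, GenomeAnnotation
from chipcompendium.simulate import (
    build_genome,
    default_config,
    simulate_compendium,
    write_bundle,
)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                     max_len=120):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


@pytest.fixture(scope="session")
def default_bundle_dir(tmp_path_factory):
    """The default synthetic compendium bundle, written once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    write_bundle(default_config(seed=1), outdir)
    return outdir


@pytest.fixture(scope="session")
def default_study():
    """In-memory default synthetic study: (config, compendium, truth, annotation,
    sequences).  Deterministic: regenerating with seed 1 matches the bundle."""
    cfg = default_config(seed=1)
    rng = np.random.default_rng(cfg.seed)
    sequences, annotation = build_genome(cfg, rng)
    compendium, truth, annotation = simulate_compendium(
        cfg, annotation, sequences, rng
    )
    return cfg, compendium, truth, annotation, sequences


@pytest.fixture(scope="session")
def default_fasta(default_bundle_dir):
    return Fasta(str(default_bundle_dir / "genome.fa"))


@pytest.fixture(scope="session")
def uniform_genome(tmp_path_factory):
    """A 200 kb single-chromosome i.i.d. uniform genome for motif nulls."""
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200_000)])
    path = tmp_path_factory.mktemp("genome") / "uniform.fa"
    write_fasta({"chr1": seq}, path)
    return Fasta(str(path)), {"chr1": 200_000}, seq


def toy_annotation(genes=None, chrom_len=100_000, **kwargs):
    genes = genes if genes is not None else [
        Gene("gA", "chr1", "+", 5_000, 9_000),
        Gene("gB", "chr1", "-", 20_000, 26_000),
        Gene("gC", "chr2", "+", 10_000, 14_000),
    ]
    return GenomeAnnotation(
        chrom_sizes={"chr1": chrom_len, "chr2": chrom_len}, genes=genes, **kwargs
    )
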