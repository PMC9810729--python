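import os
import textwrap

import pytest

from apashift import SimParams, simulate_dataset
from apashift.pipeline import parse_config


SMALL_PARAMS = SimParams(
    n_genes=60, seed=11, replicates=2, n_shortened=6, n_lengthened=2
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic dataset shared across tests (generated once)."""
    root = tmp_path_factory.mktemp("smallds")
    data = root / "data"
    truth = simulate_dataset(SMALL_PARAMS, str(data))
    return {"dir": str(data), "truth": truth, "params": SMALL_PARAMS,
            "root": str(root)}


def make_config(data_dir: str, out_dir: str, replicates: int = 2,
                seed: int = 11, extra: str = "") -> str:
    reps_a = ",".join(
        os.path.join(data_dir, f"cov_d14_r{i}.bedGraph")
        for i in range(1, replicates + 1)
    )
    reps_b = ",".join(
        os.path.join(data_dir, f"cov_d21_r{i}.bedGraph")
        for i in range(1, replicates + 1)
    )
    text = textwrap.dedent(f"""\
        gtf={os.path.join(data_dir, 'genome.gtf')}
        pa_bed={os.path.join(data_dir, 'pa_sites.bed')}
        coverage_a={reps_a}
        coverage_b={reps_b}
        de_table={os.path.join(data_dir, 'de_truth.tsv')}
        mirna_counts={os.path.join(data_dir, 'mirna_counts.tsv')}
        out_dir={out_dir}
        seed={seed}
        {extra}
    """)
    path = os.path.join(out_dir, "run.cfg")
    os.makedirs(out_dir, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(text)
    return path


@pytest.fixture(scope="session")
def small_config(small_dataset):
    out = os.path.join(small_dataset["root"], "out")
    path = make_config(small_dataset["dir"], out,
                       replicates=SMALL_PARAMS.replicates)
    return parse_config(path)


@pytest.fixture(scope="session")
def small_loaded(small_dataset):
    """Gene models, segmentations and per-replicate coverage."""
    from apashift import (load_coverage, load_gene_models, load_pa_sites,
                          segment_utr)
    d = small_dataset["dir"]
    genes = load_gene_models(os.path.join(d, "genome.gtf"), min_utr_len=150)
    pa = load_pa_sites(os.path.join(d, "pa_sites.bed"), genes)
    segs = {g.gene_id: segment_utr(g, pa[g.gene_id]) for g in genes}
    covs = {}
    for cond in ("d14", "d21"):
        covs[cond] = [
            load_coverage(os.path.join(d, f"cov_{cond}_r{i}.bedGraph"),
                          genes, cond, f"r{i}")
            for i in range(1, SMALL_PARAMS.replicates + 1)
        ]
    return {"genes": genes, "pa": pa, "segs": segs, "covs": covs}
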