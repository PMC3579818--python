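import pytest

from krabkit import ncounter, simulate


@pytest.fixture(scope="session")
def proteome():
    """50 synthetic KRAB genes with planted fingers; seed fixed."""
    records, annotations, truth = simulate.gen_proteome(
        50, zf_count_range=(1, 15), krab_o_fraction=0.1, seed=11
    )
    return records, annotations, truth


@pytest.fixture(scope="session")
def planted_loci():
    loci, truth = simulate.gen_loci(
        cluster_sizes=(2, 5, 41), n_singletons=10, seed=11
    )
    return loci, truth


@pytest.fixture(scope="session")
def counts_run():
    """Synthetic nCounter run with 10 planted 4-fold pluripotency effects."""
    counts, info, design, truth = simulate.gen_counts(
        n_targets=100, n_effect_genes=10, effect_fold=4.0, cv=0.10, seed=11
    )
    return (
        ncounter.CountMatrix(counts, info),
        ncounter.AssayDesign(design),
        truth,
    )


@pytest.fixture(scope="session")
def normalized_run(counts_run):
    m, design, truth = counts_run
    corrected = ncounter.background_correct(m)
    g = ncounter.genorm_stability(corrected)
    return ncounter.normalize_counts(corrected, g), design, truth
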