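import numpy as np
import pytest

from aisnp import genotype_io as gio
from aisnp import synthetic_data as sd


@pytest.fixture
def toy_loci():
    return [
        gio.Locus("rsA", "1", 100, "A", "G"),
        gio.Locus("rsB", "2", 200, "C", "T"),
        gio.Locus("rsC", "3", 300, "G", "A"),
    ]


@pytest.fixture
def toy_matrix(toy_loci):
    codes = np.array(
        [
            [0, 1, 2],
            [1, 1, gio.MISSING],
            [2, 0, 0],
            [0, 2, 1],
        ],
        dtype=np.int16,
    )
    return gio.GenotypeMatrix(["s1", "s2", "s3", "s4"], toy_loci, codes)


@pytest.fixture
def toy_manifest():
    return gio.PopulationManifest(
        {"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"},
        {"P1": "X", "P2": "Y"},
    )


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic 4-source + admixed-cohort dataset used across modules."""
    cfg = sd.default_study_config(seed=7, n_loci=30, n_per_population=60)
    freqs = sd.simulate_frequencies(cfg)
    gm, manifest = sd.simulate_genotypes(freqs, cfg)
    cohort_spec = cfg.admixed_cohorts[0]
    cohort, q_true = sd.simulate_admixed_cohort(
        freqs, cohort_spec.alpha, cohort_spec.n_individuals, cfg,
        label=cohort_spec.label,
    )
    for s in cohort.samples:
        manifest.sample_to_population[s] = cohort_spec.label
    manifest.population_to_super[cohort_spec.label] = "AMR"
    full = gio.concat_matrices([gm, cohort])
    return {
        "cfg": cfg,
        "freqs": freqs,
        "sources": gm,
        "cohort": cohort,
        "q_true": q_true,
        "manifest": manifest,
        "full": full,
    }
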