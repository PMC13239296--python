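import numpy as np
import pandas as pd
import pytest

from kelppopgen import GenotypeMatrix, scenario_full_study


def make_gm(calls, populations=None, cohorts=None, ages=None,
            read_depth=7.0, reproducibility=0.99, clone_ids=None):
    """Build a GenotypeMatrix from a plain call matrix with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loc = calls.shape
    individuals = pd.DataFrame(
        {
            "individual_id": [f"ind{i:03d}" for i in range(n_ind)],
            "population": populations if populations is not None else ["cool"] * n_ind,
            "cohort": cohorts if cohorts is not None else ["wild"] * n_ind,
            "age_months": pd.array(
                ages if ages is not None else [pd.NA] * n_ind, dtype="Int64"
            ),
        }
    )
    locus_ids = [f"L{j:04d}" for j in range(n_loc)]
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "clone_id": clone_ids if clone_ids is not None else locus_ids,
            "read_depth": read_depth,
            "reproducibility": reproducibility,
        }
    )
    return GenotypeMatrix(calls, individuals, loci)


@pytest.fixture(scope="session")
def bundle():
    """Synthetic full-study dataset shared across tests (fixed seed)."""
    return scenario_full_study(seed=11)


@pytest.fixture(scope="session")
def bundle_neutral_index(bundle):
    gm = bundle.genotypes
    planted = set(bundle.manifest["provenance_loci"]) | set(
        bundle.manifest["hatchery_loci"]
    )
    return gm.loci_index([l for l in gm.locus_ids if l not in planted])
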