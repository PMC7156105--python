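import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ggam.pedigree import Pedigree

settings.register_profile("suite", derandomize=True, max_examples=20, deadline=None)
settings.load_profile("suite")


def make_pedigree(rows):
    """rows: (id, dam, sire, sex, cohort, immigrant) tuples; None = unknown."""
    return Pedigree(
        pd.DataFrame(
            rows, columns=["id", "dam", "sire", "sex", "cohort", "immigrant"]
        )
    )


@pytest.fixture
def trio():
    """Unrelated founder pair plus one offspring."""
    return make_pedigree(
        [
            ("d", None, None, "F", 1, False),
            ("s", None, None, "M", 1, False),
            ("o", "d", "s", "F", 2, False),
        ]
    )


@pytest.fixture
def fullsib_mating():
    """Founder pair, two full sibs, and their inbred offspring (F = 0.25)."""
    return make_pedigree(
        [
            ("d", None, None, "F", 1, False),
            ("s", None, None, "M", 1, False),
            ("b1", "d", "s", "F", 2, False),
            ("b2", "d", "s", "M", 2, False),
            ("x", "b1", "b2", "F", 3, False),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One forward-simulated dataset at reduced scale, shared read-only."""
    from ggam.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=20, n_years=10, n_founder_pairs=8))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short reference fit on the shared dataset (diagnostics warnings ok)."""
    import warnings

    from ggam.model import ChainConfig, FitDiagnosticsWarning, PriorSpec, build_design, fit_mcmc
    from ggam.pedigree import assign_genetic_groups, compute_q, prune_pedigree

    ds = small_dataset
    phen = set(ds.broods["female_id"]) | set(ds.broods["male_id"])
    ped = prune_pedigree(ds.pedigree, phen)
    q = compute_q(ped, assign_genetic_groups(ped), phenotyped=phen)
    design = build_design(ped, q, ds.broods)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitDiagnosticsWarning)
        samples = fit_mcmc(
            design,
            PriorSpec(),
            ChainConfig(n_iter=1200, burn_in=400, thin=2, seed=77),
            store_animal=True,
        )
    return dict(samples=samples, design=design, q=q, ped=ped, dataset=ds)
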