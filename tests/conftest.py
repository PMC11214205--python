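import numpy as np
import pandas as pd
import pytest

from holosel import AbundanceTable, GeneratorConfig, generate_genus_table


@pytest.fixture(scope="session")
def small_genus_table():
    """80-sample two-enterotype rarefied table with true labels."""
    from holosel import rarefy

    cfg = GeneratorConfig(n_pm=40, n_rt=40, seed=42)
    table, truth = generate_genus_table(cfg)
    rare = rarefy(table, depth=7000, seed=1)
    return rare, truth.loc[rare.data.index]


@pytest.fixture(scope="session")
def study_population():
    """One random-mating population on the study design (pedigree + phenotypes)."""
    from holosel import generate_study_phenotypes

    return generate_study_phenotypes(seed=77)


@pytest.fixture
def toy_counts():
    df = pd.DataFrame(
        {"A": [4, 10, 0], "B": [0, 10, 5], "C": [0, 0, 5]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return AbundanceTable(df, kind="counts")
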