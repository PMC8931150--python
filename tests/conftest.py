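import pandas as pd
import pytest
from hypothesis import settings

from cnvsex.datasets import collection_a

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_df() -> pd.DataFrame:
    """Bundled 20-adult validation cohort (80 CNV values)."""
    return collection_a()


def _replicate_vectors(df: pd.DataFrame, method: str):
    sub = df[df["method"] == method]
    wide = sub.pivot(index="specimen_id", columns="biological_replicate",
                     values="cnv")
    order = [f"F{i}" for i in range(1, 11)] + [f"M{i}" for i in range(1, 11)]
    wide = wide.loc[order]
    return wide[1].to_list(), wide[2].to_list()


@pytest.fixture(scope="session")
def ddpcr_replicates(cohort_df):
    """(replicate I, replicate II) ddPCR CNVs for the 20 specimens."""
    return _replicate_vectors(cohort_df, "ddPCR")


@pytest.fixture(scope="session")
def qpcr_replicates(cohort_df):
    """(replicate I, replicate II) qPCR CNVs for the 20 specimens."""
    return _replicate_vectors(cohort_df, "qPCR")


@pytest.fixture(scope="session")
def qpcr_specimen_means(cohort_df):
    """Per-specimen qPCR mean CNVs split by true sex: (female, male)."""
    sub = cohort_df[cohort_df["method"] == "qPCR"]
    means = sub.groupby(["specimen_id", "true_sex"])["cnv"].mean().reset_index()
    f = means[means["true_sex"] == "F"]["cnv"].to_list()
    m = means[means["true_sex"] == "M"]["cnv"].to_list()
    return f, m
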