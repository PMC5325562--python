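import pandas as pd
import pytest

from adragree import load_flowchart, reference


@pytest.fixture(scope="session")
def chart():
    return load_flowchart()


@pytest.fixture(scope="session")
def whoumc_tab():
    return reference.crosstab("WHO-UMC")


@pytest.fixture(scope="session")
def lcat_tab():
    return reference.crosstab("LCAT")


@pytest.fixture(scope="session")
def study_assessments() -> pd.DataFrame:
    return reference.reconstructed_assessments()


@pytest.fixture(scope="session")
def question_table_printed():
    """The printed per-question response counts as a QuestionResponseTable."""
    from adragree.diagnostics import QuestionResponseTable
    from adragree.flowchart import NEGATIVE, POSITIVE, QUESTION_IDS

    raw = reference.question_responses()
    raters = ["1", "2", "3", "4"]
    cols = pd.MultiIndex.from_product([[NEGATIVE, POSITIVE], raters],
                                      names=["response", "rater"])
    counts = pd.DataFrame(0, index=list(QUESTION_IDS), columns=cols)
    for q in QUESTION_IDS:
        for r in raters:
            counts.loc[q, (NEGATIVE, r)] = int(raw.loc[q, f"neg_{r}"])
            counts.loc[q, (POSITIVE, r)] = int(raw.loc[q, f"pos_{r}"])
    return QuestionResponseTable(counts)
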