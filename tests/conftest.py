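import pytest

from efl_ratchet import conservation, datasets, factors


@pytest.fixture(scope="session")
def survey_table() -> factors.FactorTable:
    return datasets.load_survey_table()


@pytest.fixture
def write_tsv(tmp_path):
    """Write TSV text to a temp file and return its path."""

    def _write(text: str, name: str = "table.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


def make_alignment(rows_a, rows_b):
    """Small labelled alignment straight from literal strings."""
    ids = [f"A{i}" for i in range(len(rows_a))] + [f"B{i}" for i in range(len(rows_b))]
    return conservation.LabelledAlignment(
        ids=ids,
        sequences=list(rows_a) + list(rows_b),
        families=["A"] * len(rows_a) + ["B"] * len(rows_b),
    )


@pytest.fixture
def tiny_alignment():
    return make_alignment(["ACDE", "ACDE", "ACDE"], ["ACDE", "ACDF"])
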