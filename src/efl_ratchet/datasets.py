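"""Bundled example data."""

from importlib import resources

from .factors import FactorTable, parse_factor_table


def survey_table_path():
    """Path to the bundled synthetic survey table.

    A synthetic reconstruction of the published eukaryote-wide
    eEF1A/eEF1Balpha/EFL survey: all prose-documented exceptional taxa
    (co-maintainers, divergent sequences) encoded explicitly, the bulk
    mutually-exclusive pattern filled with placeholder taxa at realistic
    proportions.  It is NOT the original supplementary table.
    """
    return resources.files("efl_ratchet.data") / "survey_table_synthetic.tsv"


def load_survey_table() -> FactorTable:
    with survey_table_path().open(encoding="utf-8") as fh:
        return parse_factor_table(fh, source="survey_table_synthetic.tsv")
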