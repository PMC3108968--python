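"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .survey import ExpertSurveyData, read_survey_long

#: Policy scales of the bundled Germany excerpt (ideology is separate).
GERMANY_POLICIES = [
    "Decentralization",
    "Environment",
    "EU Accountability",
    "EU Authority",
    "EU Peacekeeping",
    "Immigration",
    "Social",
    "Taxes vs Spending",
]

GERMANY_IDEOLOGY_COLUMN = "Ideological Scaling"


def load_germany_example() -> ExpertSurveyData:
    """Germany excerpt of the Benoit-Laver expert survey on party positions.

    The first three respondents' 1-20 ratings of 10 German parties on 8
    policy scales plus the left-right ideological scale (2002-2004 survey
    round).  Small enough to run the full analysis in seconds.
    """
    with resources.as_file(
        resources.files("minkmds").joinpath("data/germany_table2.csv")
    ) as path:
        return read_survey_long(
            path,
            policy_columns=GERMANY_POLICIES,
            ideology_column=GERMANY_IDEOLOGY_COLUMN,
            country_label="Germany",
        )
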