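"""Bundled reference tables from the long-term clinical follow-up study of
menstrual-cycle breast thermometry that this package reimplements.

Two small tables are shipped so the headline analyses run with no download:

* the luteal-window (cycle days −11…−1) cross-subject daily mean
  vascularity (breast − oral, °C) for the three study groups — 18 breast
  cancer non-survivors, 65 healthy controls, 18 survivors;
* per-patient tumour pathology (size, grade, involved nodes, in-situ
  status) and post-operative follow-up durations for the 36 cancer cases,
  including the prognostic index printed in the study report
  (``npi_printed``) for cross-checking the score computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

GROUP_COLUMNS = ("non-survivor", "control", "survivor")


def _read(name: str) -> pd.DataFrame:
    with resources.files("mammotherm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_luteal_daily_means() -> pd.DataFrame:
    """Luteal-phase daily mean vascularity per group, days −11…−1.

    Returns a frame indexed by ``cycle_day`` with one column per group.
    """
    df = _read("luteal_daily_means.csv").set_index("cycle_day")
    return df[list(GROUP_COLUMNS)]


def load_reference_pathology() -> pd.DataFrame:
    """Pathology and follow-up for the 36 breast cancer cases.

    Columns: subject_id, group (survivor / non-survivor), age_at_surgery_y,
    survival_y, size_mm (NaN where unavailable), grade (NaN for two in-situ
    rows), nodes, in_situ (bool), npi_printed (NaN for in-situ rows).
    """
    df = _read("pathology_followup.csv")
    df["in_situ"] = df["in_situ"].astype(bool)
    return df
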