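"""Bundled reference data: printed labeled-protein reports from two soil
SIP experiments.

The package ships the published per-identification atom% values and MAG
quality estimates from a :sup:`13`\\ CO2 rhizosphere experiment (three plant
hosts, two labeling timepoints) and a :sup:`13`\\ C-methanol soil-microcosm
experiment (two incubation triplicates).  They serve as worked examples for
the labeled-protein support rules, MAG acceptance verdicts, and summary
statistics, exactly as reported.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .binning import MAGRecord

_REPLICATE_COLS = ["d3_r1", "d3_r2", "d3_r3", "d8_r1", "d8_r2", "d8_r3"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("prosip.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t", na_values=["-"])


def co2_reference() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-identification table, MAG quality table) for the CO2 study."""
    return (
        _load("co2_labeled_identifications.tsv"),
        _load("co2_mag_quality.tsv"),
    )


def methanol_reference() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-protein replicate presence table, MAG quality table) for the
    methanol study."""
    return (
        _load("methanol_labeled_identifications.tsv"),
        _load("methanol_mag_quality.tsv"),
    )


def co2_mag_records() -> list[MAGRecord]:
    """MAG candidates from the CO2 study with labeled-identification
    support counted from the per-identification table."""
    idents, quality = co2_reference()
    support = idents.groupby("mag_id").size()
    records = []
    for row in quality.itertuples():
        records.append(
            MAGRecord(
                mag_id=row.mag_id,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                mode="targeted_co2",
                n_labeled_identifications=int(support.get(row.mag_id, 0)),
                taxonomy=row.taxonomy,
            )
        )
    return records


def methanol_mag_records() -> list[MAGRecord]:
    """MAG candidates from the methanol study; replicate support per
    incubation triplicate comes from the non-missing atom% cells."""
    idents, quality = methanol_reference()
    support: dict[str, dict[str, set]] = {}
    for row in idents.itertuples():
        per_mag = support.setdefault(row.mag_id, {"day3": set(), "day8": set()})
        for col in _REPLICATE_COLS:
            value = getattr(row, col)
            if not (isinstance(value, float) and np.isnan(value)):
                day, rep = col.split("_")
                per_mag["day3" if day == "d3" else "day8"].add(rep)
    records = []
    for row in quality.itertuples():
        reps = support.get(row.mag_id, {"day3": set(), "day8": set()})
        records.append(
            MAGRecord(
                mag_id=row.mag_id,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                mode="targeted_methanol",
                replicate_support={
                    k: frozenset(v) for k, v in reps.items()
                },
                taxonomy=row.taxonomy,
            )
        )
    return records
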