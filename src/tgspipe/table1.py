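"""Packaged reference table of 30 tag variants and its summary statistics.

The shipped TSV transcribes a published table of thirty tag variants
associated with sprint/power athlete status (rsID, localization, alleles,
nearest gene, odds ratio, p-value, source trait).  It is the one fully
printed dataset available to this pipeline, so it doubles as a regression
fixture: the summary computed here (per-trait counts, SNP/INDEL
classification, minimum p) must reproduce the printed figures exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["Table1Fixture", "load_table1", "table1_summary", "EXPECTED_ROWS"]

EXPECTED_ROWS = 30


class FixtureError(ValueError):
    """The packaged table fails validation (corruption or bad transcription)."""


@dataclass
class Table1Fixture:
    """The 30-row tag-variant table as a validated DataFrame."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"rsid", "localization", "alleles", "nearest_gene", "OR", "p_value", "trait"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FixtureError(f"fixture missing columns {sorted(missing)}")
        if len(self.frame) != EXPECTED_ROWS:
            raise FixtureError(
                f"fixture has {len(self.frame)} rows, expected {EXPECTED_ROWS}"
            )
        if not (self.frame["OR"] > 0).all():
            raise FixtureError("all odds ratios must be positive")
        if not ((self.frame["p_value"] > 0) & (self.frame["p_value"] <= 0.01)).all():
            raise FixtureError("all p-values must lie in (0, 0.01]")


def load_table1(path: str | Path | None = None) -> Table1Fixture:
    """Load and validate the packaged table (or a caller-supplied copy)."""
    if path is None:
        source = resources.files("tgspipe").joinpath("data/table1.tsv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t", dtype={"rsid": str})
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    frame["OR"] = frame["OR"].astype(float)
    frame["p_value"] = frame["p_value"].astype(float)
    return Table1Fixture(frame=frame)


def _classify_alleles(alleles: str) -> str:
    parts = alleles.split("/")
    if len(parts) != 2 or not all(parts):
        raise FixtureError(f"malformed alleles field {alleles!r}")
    return "SNP" if all(len(a) == 1 for a in parts) else "INDEL"


def table1_summary(fixture: Table1Fixture) -> dict:
    """Per-trait counts, SNP/INDEL tally, minimum p, and OR range."""
    df = fixture.frame
    classes = df["alleles"].map(_classify_alleles)
    trait_counts = df["trait"].value_counts().to_dict()
    i_min = df["p_value"].idxmin()
    return {
        "n_rows": int(len(df)),
        "trait_counts": {t: int(c) for t, c in sorted(trait_counts.items())},
        "n_snp": int((classes == "SNP").sum()),
        "n_indel": int((classes == "INDEL").sum()),
        "min_p": float(df.loc[i_min, "p_value"]),
        "min_p_rsid": str(df.loc[i_min, "rsid"]),
        "or_range": [float(df["OR"].min()), float(df["OR"].max())],
    }
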