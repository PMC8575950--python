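"""Packaged transcription of the comparative transfer tables.

The package ships three CSVs transcribing the published comparative tables
cell-for-cell: raw inputs (literature TE/donor frequencies or this-work
titres, accessory/total ORF counts) alongside the printed derived cells and
a ``flags`` column marking the cells that are internally inconsistent as
printed (they are stored verbatim, never silently corrected).  Loading the
fixture and rebuilding the ledger reproduces every unflagged derived cell at
printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .annotations import read_mobility_records
from .metrics import DonorCalibration, MobilityRecord
from .geometry import ProphageModel
from .render import as_fraction


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ltmob") / "data" / name))


def load_table(name: str) -> pd.DataFrame:
    """Raw fixture frame ("table1", "table2" or "table3"), cells as strings."""
    return pd.read_csv(_data_path(f"{name}.csv"), dtype=str, keep_default_na=False)


def load_calibrations() -> dict[str, DonorCalibration]:
    frame = pd.read_csv(_data_path("calibrations.csv"))
    return {
        row.organism: DonorCalibration(
            row.organism, float(row.od_landmark), as_fraction(str(row.donor_cfu_per_ml))
        )
        for row in frame.itertuples()
    }


def load_prophage_models() -> dict[str, ProphageModel]:
    frame = pd.read_csv(_data_path("prophage_models.csv"))
    return {
        row.phage_id: ProphageModel(
            row.phage_id, int(row.headful_size_bp), int(row.max_headfuls)
        )
        for row in frame.itertuples()
    }


@dataclass
class PaperFixture:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    records_table1: list[MobilityRecord]
    records_table3: list[MobilityRecord]
    calibrations: dict[str, DonorCalibration]
    prophage_models: dict[str, ProphageModel]


def paper_fixture() -> PaperFixture:
    """Load the packaged tables as validated records plus calibrations/models."""
    return PaperFixture(
        table1=load_table("table1"),
        table2=load_table("table2"),
        table3=load_table("table3"),
        records_table1=read_mobility_records(_data_path("table1.csv")),
        records_table3=read_mobility_records(_data_path("table3.csv")),
        calibrations=load_calibrations(),
        prophage_models=load_prophage_models(),
    )


def export_fixture(outdir: str | Path) -> list[Path]:
    """Copy the packaged fixture CSVs into ``outdir``; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("table1", "table2", "table3", "calibrations", "prophage_models"):
        src = _data_path(f"{name}.csv")
        dst = outdir / f"{name}.csv"
        dst.write_text(src.read_text())
        written.append(dst)
    return written
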