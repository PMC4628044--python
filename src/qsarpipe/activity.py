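"""Activity conversion, classification and modeling-table assembly.

IC50 values are micromolar throughout; pIC50 = -log10(IC50 in uM).
Inactivity is an input annotation (the assays flag it against a mass
concentration threshold, which is compound-dependent in molar units), so
it is carried from the activity table rather than derived from the uM
value.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import QsarPipeError

log = logging.getLogger(__name__)

CELL_LINES = ("HuCCA-1", "HepG2", "A549", "MOLT-3")

HIGHLY = "highly active"
MODERATELY = "moderately active"
WEAKLY = "weakly active"
INACTIVE = "inactive"
WEAKLY_TO_INACTIVE = "weakly to inactive"


def check_cell_line(name: str) -> str:
    if name not in CELL_LINES:
        raise QsarPipeError(
            f"unknown cell line {name!r}; expected one of {list(CELL_LINES)}")
    return name


def ic50_to_pic50(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 / uM); strictly decreasing in IC50."""
    if not ic50_um > 0:
        raise QsarPipeError(f"IC50 must be positive, got {ic50_um}")
    return -math.log10(ic50_um)


def classify_experimental(ic50_um: float | None, inactive: bool = False) -> str:
    """Four-class label from a measured IC50 (uM) or the inactive flag.

    Boundaries (exactly 1 or 10 uM) resolve to the more active class.
    """
    if inactive:
        return INACTIVE
    if ic50_um is None:
        raise QsarPipeError("need an IC50 value unless the record is flagged inactive")
    if not ic50_um > 0:
        raise QsarPipeError(f"IC50 must be positive, got {ic50_um}")
    if ic50_um <= 1.0:
        return HIGHLY
    if ic50_um <= 10.0:
        return MODERATELY
    return WEAKLY


def classify_predicted(pic50: float) -> str:
    """Three-class label for a model-predicted pIC50.

    Boundaries (exactly 0 or -1) resolve to the more active class.
    """
    if not math.isfinite(pic50):
        raise QsarPipeError(f"predicted pIC50 must be finite, got {pic50}")
    if pic50 >= 0.0:
        return HIGHLY
    if pic50 >= -1.0:
        return MODERATELY
    return WEAKLY_TO_INACTIVE


@dataclass(frozen=True)
class ActivityRecord:
    """One (compound, cell line) measurement."""

    compound_id: str
    cell_line: str
    ic50_um: float | None
    inactive: bool = False

    def __post_init__(self):
        check_cell_line(self.cell_line)
        if self.inactive and self.ic50_um is not None:
            raise QsarPipeError(
                f"{self.compound_id}/{self.cell_line}: record is both "
                "inactive and carries an IC50 value")
        if not self.inactive and self.ic50_um is None:
            raise QsarPipeError(
                f"{self.compound_id}/{self.cell_line}: active record "
                "without an IC50 value")

    @property
    def pic50(self) -> float | None:
        return None if self.inactive else ic50_to_pic50(self.ic50_um)

    @property
    def experimental_class(self) -> str:
        return classify_experimental(self.ic50_um, self.inactive)


def read_activity_table(path: str) -> list[ActivityRecord]:
    """Load a delimited activity table.

    Expected columns: compound_id, cell_line, ic50_uM (may be empty),
    inactive (true/false).  Extra columns are ignored.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "cell_line", "ic50_uM", "inactive"}
    missing = required - set(df.columns)
    if missing:
        raise QsarPipeError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        inactive = str(row["inactive"]).strip().lower() in ("true", "1", "yes")
        ic50 = None if inactive or pd.isna(row["ic50_uM"]) else float(row["ic50_uM"])
        records.append(ActivityRecord(str(row["compound_id"]), row["cell_line"],
                                      ic50, inactive))
    return records


@dataclass
class ModelingTable:
    """Per-cell-line join of descriptors and pIC50 for model building."""

    cell_line: str
    data: pd.DataFrame  # index: compound_id; columns: descriptors + 'pic50'

    @property
    def n(self) -> int:
        return len(self.data)

    def features(self) -> pd.DataFrame:
        return self.data.drop(columns=["pic50"])

    def response(self) -> pd.Series:
        return self.data["pic50"]


def assemble_modeling_table(
    activities: list[ActivityRecord],
    descriptors: pd.DataFrame,
    cell_line: str,
) -> ModelingTable:
    """Join active records for one cell line with their descriptor rows.

    ``descriptors`` is indexed (or indexable) by compound_id.  Inactive
    records are excluded; active compounds without descriptors are an
    error listing the missing ids.  Output rows are sorted by compound id
    for deterministic downstream behaviour.
    """
    check_cell_line(cell_line)
    if "compound_id" in descriptors.columns:
        descriptors = descriptors.set_index(descriptors["compound_id"].astype(str))
        descriptors = descriptors.drop(columns=["compound_id"])
    active = [r for r in activities if r.cell_line == cell_line and not r.inactive]
    if not active:
        log.warning("no active records for cell line %s; empty table", cell_line)
        return ModelingTable(cell_line, pd.DataFrame(columns=["pic50"]))
    missing = [r.compound_id for r in active if r.compound_id not in descriptors.index]
    if missing:
        raise QsarPipeError(
            f"{cell_line}: active compounds missing descriptors: {missing}")

    def sort_key(cid: str):
        return (0, int(cid)) if cid.isdigit() else (1, cid)

    ids = sorted((r.compound_id for r in active), key=sort_key)
    pic50 = {r.compound_id: r.pic50 for r in active}
    table = descriptors.loc[ids].copy()
    table["pic50"] = [pic50[c] for c in ids]
    return ModelingTable(cell_line, table)
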