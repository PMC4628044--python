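"""Machine-readable transcription of the published study tables.

Every value in the bundled data files carries a citation string naming
the table or section it was transcribed from; the test suite enforces
that no fixture value exists without one.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .activity import ActivityRecord, CELL_LINES
from .modeling import QsarModel, published_models


def _read_csv(name: str) -> pd.DataFrame:
    text = (resources.files("qsarpipe") / f"data/{name}").read_text()
    return pd.read_csv(io.StringIO(text), dtype={"compound_id": str})


def _read_json(name: str) -> dict:
    text = (resources.files("qsarpipe") / f"data/{name}").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class PublishedFixture:
    """Immutable accessor over the transcribed activity / model tables."""

    activities: pd.DataFrame          # compound_id, cell_line, ic50_uM, inactive, citation
    pic50_pairs: pd.DataFrame         # compound_id, cell_line, exp_pic50, loo_pred_pic50, citation
    models_raw: dict                  # published equations + statistics
    printed_descriptors: pd.DataFrame  # compound_id, descriptor, value, citation
    printed_predictions: pd.DataFrame  # compound_id, cell_line, pic50, citation

    def activity_records(self) -> list[ActivityRecord]:
        records = []
        for _, row in self.activities.iterrows():
            inactive = str(row["inactive"]).lower() == "true"
            ic50 = None if inactive else float(row["ic50_uM"])
            records.append(ActivityRecord(str(row["compound_id"]),
                                          row["cell_line"], ic50, inactive))
        return records

    def pairs_for(self, cell_line: str) -> pd.DataFrame:
        out = self.pic50_pairs[self.pic50_pairs["cell_line"] == cell_line]
        return out.reset_index(drop=True)

    def models(self) -> dict[str, QsarModel]:
        return published_models()

    def model_statistics(self, cell_line: str) -> dict:
        d = self.models_raw[cell_line]
        return {"N": d["n"], "R_Tr": d["r_tr"], "RMSE_Tr": d["rmse_tr"],
                "R_CV": d["r_cv"], "RMSE_CV": d["rmse_cv"]}

    def printed_descriptor(self, compound_id: str, descriptor: str) -> float:
        df = self.printed_descriptors
        hit = df[(df["compound_id"] == compound_id) & (df["descriptor"] == descriptor)]
        if hit.empty:
            raise KeyError(f"no printed value for {descriptor} of {compound_id}")
        return float(hit["value"].iloc[0])

    def printed_prediction(self, compound_id: str, cell_line: str) -> float:
        df = self.printed_predictions
        hit = df[(df["compound_id"] == compound_id) & (df["cell_line"] == cell_line)]
        if hit.empty:
            raise KeyError(f"no printed prediction for {compound_id}/{cell_line}")
        return float(hit["pic50"].iloc[0])

    def training_sizes(self) -> dict[str, int]:
        active = self.activities[self.activities["inactive"].astype(str)
                                 .str.lower() != "true"]
        return {c: int((active["cell_line"] == c).sum()) for c in CELL_LINES}


@lru_cache(maxsize=1)
def published_fixture() -> PublishedFixture:
    """Load (once) the bundled transcription of the study's data tables."""
    return PublishedFixture(
        activities=_read_csv("activities.csv"),
        pic50_pairs=_read_csv("pic50_pairs.csv"),
        models_raw=_read_json("published_models.json"),
        printed_descriptors=_read_csv("printed_descriptors.csv"),
        printed_predictions=_read_csv("printed_predictions.csv"),
    )
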