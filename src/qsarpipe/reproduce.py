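"""Recompute the headline published numbers from the bundled fixtures.

Each target re-runs the relevant pipeline stage (equation application,
unit conversion, exclusion rule, or pooled LOO metrics) and reports the
freshly computed value next to the printed one with a tolerance verdict.
"""
from __future__ import annotations

from dataclasses import dataclass

from .activity import ic50_to_pic50
from .fixtures import published_fixture
from .modeling import regression_metrics


@dataclass(frozen=True)
class TargetResult:
    target_id: str
    description: str
    computed: float
    expected: float
    tolerance: float
    n: int

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance

    def as_dict(self) -> dict:
        return {
            "id": self.target_id,
            "description": self.description,
            "computed": self.computed,
            "expected": self.expected,
            "tolerance": self.tolerance,
            "n": self.n,
            "pass": self.passed,
        }


def _equation_target(tid, cell, inputs, expected, description) -> TargetResult:
    fx = published_fixture()
    model = fx.models()[cell]
    value = round(model.predict_one(inputs), 3)
    return TargetResult(tid, description, value, expected, 0.0005, len(inputs))


def _metric_target(tid, cell, which, expected, description) -> TargetResult:
    fx = published_fixture()
    pairs = fx.pairs_for(cell)
    r, rmse_cv = regression_metrics(pairs["exp_pic50"], pairs["loo_pred_pic50"])
    value = r if which == "R" else rmse_cv
    return TargetResult(tid, description, round(value, 4), expected, 0.001, len(pairs))


def compute_target(target_id: str) -> TargetResult:
    fx = published_fixture()
    if target_id == "t1":
        return _equation_target(
            "t1", "HuCCA-1",
            {"R5e+": fx.printed_descriptor("7D", "R5e+"), "nArCOOR": 0},
            fx.printed_prediction("7D", "HuCCA-1"),
            "HuCCA-1 equation on compound 7D (printed R5e+, no aromatic ester)")
    if target_id == "t2":
        return _equation_target(
            "t2", "HuCCA-1",
            {"R5e+": fx.printed_descriptor("8N", "R5e+"), "nArCOOR": 1},
            fx.printed_prediction("8N", "HuCCA-1"),
            "HuCCA-1 equation on compound 8N (printed R5e+, one aromatic ester)")
    if target_id == "t3":
        return _equation_target(
            "t3", "MOLT-3",
            {"Lop": fx.printed_descriptor("8Q", "Lop"),
             "R7m": fx.printed_descriptor("8Q", "R7m")},
            fx.printed_prediction("8Q", "MOLT-3"),
            "MOLT-3 equation on compound 8Q (printed Lop and R7m)")
    if target_id == "t4":
        acts = fx.activities
        row = acts[(acts["compound_id"] == "21") & (acts["cell_line"] == "HuCCA-1")]
        value = round(ic50_to_pic50(float(row["ic50_uM"].iloc[0])), 3)
        pairs = fx.pairs_for("HuCCA-1")
        expected = float(pairs[pairs["compound_id"] == "21"]["exp_pic50"].iloc[0])
        return TargetResult("t4", "pIC50 conversion of compound 21 vs HuCCA-1",
                            value, expected, 0.0005, 1)
    if target_id == "t5":
        sizes = fx.training_sizes()
        return TargetResult("t5", "HuCCA-1 training size after the exclusion rule",
                            float(sizes["HuCCA-1"]),
                            float(fx.model_statistics("HuCCA-1")["N"]), 0.0,
                            sizes["HuCCA-1"])
    metric_specs = {
        "t7": ("HuCCA-1", "RMSE", "HuCCA-1 RMSE_CV over pooled LOO pairs"),
        "t8": ("HuCCA-1", "R", "HuCCA-1 R_CV over pooled LOO pairs"),
        "t9": ("MOLT-3", "RMSE", "MOLT-3 RMSE_CV over pooled LOO pairs"),
        "t10": ("MOLT-3", "R", "MOLT-3 R_CV over pooled LOO pairs"),
        "t11": ("A549", "RMSE", "A549 RMSE_CV over pooled LOO pairs"),
        "t12": ("HepG2", "RMSE", "HepG2 RMSE_CV over pooled LOO pairs"),
    }
    if target_id in metric_specs:
        cell, which, desc = metric_specs[target_id]
        stats = published_fixture().model_statistics(cell)
        expected = stats["R_CV"] if which == "R" else stats["RMSE_CV"]
        return _metric_target(target_id, cell, which, expected, desc)
    raise KeyError(f"unknown target id {target_id!r}")


ALL_TARGETS = ("t1", "t2", "t3", "t4", "t5",
               "t7", "t8", "t9", "t10", "t11", "t12")


def compute_all_targets() -> dict[str, TargetResult]:
    return {tid: compute_target(tid) for tid in ALL_TARGETS}
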