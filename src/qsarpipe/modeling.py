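"""Feature selection, MLR fitting, LOO cross-validation and prediction.

The model form is Y = B0 + sum_n Bn * Xn fit by ordinary least squares.
Performance is summarised by the Pearson correlation R between observed
and predicted values and the root mean square error with denominator N.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .activity import CELL_LINES, ModelingTable, check_cell_line, classify_predicted
from .errors import ModelingError

log = logging.getLogger(__name__)


# -- metrics -----------------------------------------------------------------

def regression_metrics(observed, predicted) -> tuple[float, float]:
    """Pearson R and RMSE (denominator N) over paired values.

    Raises :class:`ModelingError` for fewer than 2 pairs or a constant
    observed vector (R undefined); use :func:`rmse` alone in that case.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ModelingError("observed and predicted must be equal-length vectors")
    if obs.size < 2:
        raise ModelingError("need at least 2 pairs")
    if np.ptp(obs) == 0:
        raise ModelingError("observed values are constant; R undefined")
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r, rmse(obs, pred)


def rmse(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


# -- model objects -----------------------------------------------------------

@dataclass(frozen=True)
class QsarModel:
    """Intercept plus named coefficients for one cell line."""

    cell_line: str
    intercept: float
    coefficients: dict[str, float]
    source: str = "fitted"  # fitted | published
    notes: str = ""

    def predict_one(self, vector) -> float:
        """B0 + sum Bn * Xn for a mapping / DescriptorVector of values."""
        total = self.intercept
        for name, coef in self.coefficients.items():
            try:
                total += coef * float(vector[name])
            except KeyError:
                raise ModelingError(
                    f"{self.cell_line} model needs descriptor {name!r}, "
                    "absent from the supplied vector") from None
        return total

    def predict(self, table: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.coefficients if c not in table.columns]
        if missing:
            raise ModelingError(
                f"{self.cell_line} model: missing descriptor columns {missing}")
        out = pd.Series(self.intercept, index=table.index, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * table[name].astype(float)
        return out

    def to_dict(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "source": self.source,
            "notes": self.notes,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "QsarModel":
        return cls(d["cell_line"], float(d["intercept"]),
                   {k: float(v) for k, v in d["coefficients"].items()},
                   d.get("source", "fitted"), d.get("notes", ""))

    @classmethod
    def from_json(cls, path: str) -> "QsarModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


predict = QsarModel.predict_one  # functional alias: predict(model, vector)


@dataclass
class ValidationReport:
    """Training fit plus LOO statistics for one model."""

    n: int
    fitted: pd.Series
    loo_predictions: pd.Series | None
    r_tr: float
    rmse_tr: float
    r_cv: float | None = None
    rmse_cv: float | None = None

    def summary(self) -> dict:
        out = {"N": self.n, "R_Tr": self.r_tr, "RMSE_Tr": self.rmse_tr}
        if self.r_cv is not None:
            out.update({"R_CV": self.r_cv, "RMSE_CV": self.rmse_cv})
        return out


@dataclass
class SelectionTrace:
    """Audit log of the correlation filter and stepwise stages."""

    survivors: dict[str, float] = field(default_factory=dict)  # name -> |r| or r
    dropped_constant: list[str] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def log_step(self, action: str, name: str, p_value: float) -> None:
        self.steps.append({"action": action, "descriptor": name,
                           "p_value": float(p_value)})

    def to_text(self) -> str:
        lines = ["# selection trace"]
        for name, r in self.survivors.items():
            lines.append(f"filter keep\t{name}\tr={r:+.4f}")
        for name in self.dropped_constant:
            lines.append(f"filter drop-constant\t{name}")
        for s in self.steps:
            lines.append(f"stepwise {s['action']}\t{s['descriptor']}\t"
                         f"p={s['p_value']:.6g}")
        lines.append("selected\t" + ",".join(self.selected))
        return "\n".join(lines) + "\n"


# -- feature selection -------------------------------------------------------

def correlation_filter(
    features: pd.DataFrame,
    response: pd.Series,
    threshold: float = 0.6,
) -> SelectionTrace:
    """Keep descriptors with |Pearson r| vs the response >= ``threshold``.

    Constant columns are dropped with a warning (their correlation is
    undefined).  Requires at least 3 rows.
    """
    if len(features) < 3:
        raise ModelingError(f"correlation filter needs >= 3 rows, got {len(features)}")
    trace = SelectionTrace()
    y = response.to_numpy(dtype=float)
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            log.warning("descriptor %s is constant; dropped from selection", name)
            trace.dropped_constant.append(name)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= threshold:
            trace.survivors[name] = r
    trace.selected = list(trace.survivors)
    return trace


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ModelingError(
            f"rank-deficient design over columns {list(X.columns)}")
    return sm.OLS(y, design).fit()


def stepwise_mlr_select(
    features: pd.DataFrame,
    response: pd.Series,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    candidates: list[str] | None = None,
) -> SelectionTrace:
    """Forward-entry / backward-removal selection by partial-F p-values.

    Each iteration enters the candidate with the smallest partial p-value
    if it is <= ``p_enter`` (ties break by column order), then removes any
    included descriptor whose p-value has risen to >= ``p_remove``.  A
    candidate whose entry would leave fewer rows than parameters + 1 is
    refused and logged.  Perfectly collinear candidates are skipped, so
    exactly one of a duplicated pair can enter.
    """
    trace = SelectionTrace()
    pool = list(candidates if candidates is not None else features.columns)
    y = response.to_numpy(dtype=float)
    n = len(features)
    selected: list[str] = []

    changed = True
    while changed:
        changed = False
        # forward step
        best_name, best_p = None, None
        for name in pool:
            if name in selected:
                continue
            if n < len(selected) + 3:  # rows must exceed parameters (B0 + slopes)
                trace.log_step("refuse", name, float("nan"))
                log.warning("refusing to enter %s: %d rows cannot support "
                            "%d parameters", name, n, len(selected) + 2)
                continue
            trial = features[selected + [name]]
            design = sm.add_constant(trial.to_numpy(dtype=float), has_constant="add")
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue  # collinear with what is already in
            res = sm.OLS(y, design).fit()
            p = float(res.pvalues[-1])
            if p <= p_enter and (best_p is None or p < best_p):
                best_name, best_p = name, p
        if best_name is not None:
            selected.append(best_name)
            trace.log_step("enter", best_name, best_p)
            changed = True
        # backward step
        while len(selected) > 0:
            res = _ols(y, features[selected])
            pvals = dict(zip(selected, res.pvalues[1:]))
            worst = max(selected, key=lambda s: pvals[s])
            if pvals[worst] >= p_remove:
                selected.remove(worst)
                trace.log_step("remove", worst, pvals[worst])
                changed = True
            else:
                break

    trace.selected = selected
    trace.survivors = {s: float("nan") for s in selected}
    return trace


def select_features(
    table: ModelingTable,
    corr_threshold: float = 0.6,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> SelectionTrace:
    """The full two-stage selection: correlation filter then stepwise MLR."""
    filt = correlation_filter(table.features(), table.response(), corr_threshold)
    step = stepwise_mlr_select(table.features(), table.response(),
                               p_enter, p_remove, candidates=filt.selected)
    step.survivors = filt.survivors
    step.dropped_constant = filt.dropped_constant
    return step


# -- fitting and validation --------------------------------------------------

def fit_mlr(table: ModelingTable, descriptors: list[str]) -> tuple[QsarModel, ValidationReport]:
    """Ordinary least squares of pIC50 on the named descriptors."""
    if table.n < len(descriptors) + 2:
        raise ModelingError(
            f"{table.cell_line}: {table.n} rows cannot support "
            f"{len(descriptors)} descriptors + intercept")
    X = table.data[list(descriptors)]
    y = table.response().to_numpy(dtype=float)
    res = _ols(y, X)
    coefs = dict(zip(descriptors, res.params[1:]))
    model = QsarModel(table.cell_line, float(res.params[0]),
                      {k: float(v) for k, v in coefs.items()}, source="fitted")
    fitted = pd.Series(res.fittedvalues, index=table.data.index)
    if np.ptp(y) == 0:
        raise ModelingError(f"{table.cell_line}: response is constant")
    r_tr, rmse_tr = regression_metrics(y, fitted.to_numpy())
    report = ValidationReport(table.n, fitted, None, r_tr, rmse_tr)
    return model, report


def loo_cross_validate(table: ModelingTable, descriptors: list[str]) -> ValidationReport:
    """Leave-one-out: refit on N-1 rows, predict the held-out row, pool.

    Deterministic; R_CV / RMSE_CV are computed over the pooled held-out
    predictions.
    """
    if table.n < len(descriptors) + 3:
        raise ModelingError(
            f"{table.cell_line}: {table.n} rows are too few for LOO with "
            f"{len(descriptors)} descriptors")
    model, report = fit_mlr(table, descriptors)
    y = table.response()
    preds = {}
    for held_out in table.data.index:
        rest = ModelingTable(table.cell_line, table.data.drop(index=held_out))
        try:
            fold_model, _ = fit_mlr(rest, descriptors)
        except ModelingError as exc:
            raise ModelingError(f"LOO fold {held_out!r}: {exc}") from exc
        preds[held_out] = fold_model.predict_one(table.data.loc[held_out])
    loo = pd.Series(preds).loc[table.data.index]
    r_cv, rmse_cv = regression_metrics(y.to_numpy(), loo.to_numpy())
    report.loo_predictions = loo
    report.r_cv = r_cv
    report.rmse_cv = rmse_cv
    return report


# -- published equations -----------------------------------------------------

def published_models() -> dict[str, QsarModel]:
    """The four published per-cell-line equations, keyed by cell line."""
    text = (resources.files("qsarpipe") / "data/published_models.json").read_text()
    raw = json.loads(text)
    out = {}
    for cell, d in raw.items():
        check_cell_line(cell)
        out[cell] = QsarModel(cell, float(d["intercept"]),
                              {k: float(v) for k, v in d["coefficients"].items()},
                              source="published", notes=d.get("note", ""))
    assert set(out) == set(CELL_LINES)
    return out


def rank_candidates(predictions: dict[str, float]) -> pd.DataFrame:
    """Rank compounds by predicted pIC50 (descending; ties by compound id).

    Returns a DataFrame with columns compound_id, pic50, predicted_class,
    rank (1-based).
    """
    if not predictions:
        raise ModelingError("no predictions to rank")
    rows = sorted(predictions.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["compound_id", "pic50"])
    df["predicted_class"] = df["pic50"].map(classify_predicted)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
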