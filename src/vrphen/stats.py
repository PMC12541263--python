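"""Inference layer: correlation screen, backward stepwise OLS, VIF.

The analysis proceeds in three stages, mirroring common practice in
small-sample digital-phenotyping studies:

1. descriptive statistics of the outcome measures;
2. a Pearson correlation screen of every kinematic feature against
   every outcome measure (no multiple-testing correction; the number of
   tests performed is reported alongside);
3. per outcome, backward stepwise multiple linear regression over the
   seven features (removal when p > p_remove, re-entry of excluded
   predictors when p < p_enter), with variance inflation factors
   computed on the retained set after selection.

Selection is fully deterministic: ties on p are broken by predictor
column order, and every removal/entry is recorded in a step trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .features import FEATURE_NAMES
from .scales import MEASURES, descriptives as scale_descriptives, ScoreSet

__all__ = [
    "StatsError",
    "CorrelationRecord",
    "StepwiseConfig",
    "StepwiseResult",
    "OLSFit",
    "pearson_with_p",
    "correlation_screen",
    "correlations_to_frame",
    "ols_fit",
    "backward_stepwise",
    "vif",
    "run_inference",
    "InferenceResult",
    "models_to_frame",
    "write_reports",
]

EMPTY_MARK = "—"  # em dash rendered for empty models


class StatsError(ValueError):
    """Raised for inference-stage contract violations."""


# ---------------------------------------------------------------- correlations


@dataclass(frozen=True)
class CorrelationRecord:
    feature: str
    measure: str
    r: float
    p: float
    n: int
    significant: bool
    computable: bool = True


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("length mismatch between vectors")
    n = len(x)
    if n < 3:
        raise StatsError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def correlation_screen(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """All feature x measure Pearson correlations, listwise per pair.

    Pairs with fewer than 3 complete cases or a constant vector are
    reported as not computable rather than silently dropped. Records
    are ordered by feature, then by descending \\|r\\| within feature.
    """
    common = features.index.intersection(scores.index)
    feature_cols = [c for c in FEATURE_NAMES if c in features.columns]
    measure_cols = [c for c in MEASURES if c in scores.columns]
    records: list[CorrelationRecord] = []
    for feat in feature_cols:
        block: list[CorrelationRecord] = []
        for meas in measure_cols:
            pair = pd.concat(
                [features.loc[common, feat], scores.loc[common, meas]], axis=1
            ).dropna()
            try:
                r, p, n = pearson_with_p(pair.iloc[:, 0], pair.iloc[:, 1])
                block.append(
                    CorrelationRecord(feat, meas, r, p, n, bool(p < alpha))
                )
            except StatsError:
                block.append(
                    CorrelationRecord(
                        feat, meas, float("nan"), float("nan"), len(pair), False, False
                    )
                )
        block.sort(key=lambda rec: (-abs(rec.r) if rec.computable else 1.0))
        records.extend(block)
    return records


def correlations_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


# ------------------------------------------------------------------------ OLS


@dataclass(frozen=True)
class OLSFit:
    intercept: float
    coef: dict[str, float]
    pvalues: dict[str, float]
    intercept_p: float
    r2: float
    n: int


def _find_dependent_columns(X: pd.DataFrame) -> list[str]:
    dependent = []
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    for j, name in enumerate(X.columns, start=1):
        others = np.delete(A, j, axis=1)
        resid = A[:, j] - others @ np.linalg.lstsq(others, A[:, j], rcond=None)[0]
        denom = np.sum((A[:, j] - A[:, j].mean()) ** 2)
        if denom == 0 or np.sum(resid**2) / denom < 1e-10:
            dependent.append(name)
    return dependent


def ols_fit(X: pd.DataFrame, y) -> OLSFit:
    """Ordinary least squares with intercept; two-sided t-test p-values."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise StatsError("length mismatch between design and outcome")
    if n <= k + 1:
        raise StatsError(f"need n > k+1 observations (n={n}, k={k})")
    design = sm.add_constant(X.to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(design) < k + 1:
        bad = _find_dependent_columns(X)
        raise StatsError(f"rank-deficient design; dependent columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return OLSFit(
        intercept=float(fit.params[0]),
        coef={c: float(v) for c, v in zip(X.columns, fit.params[1:])},
        pvalues={c: float(v) for c, v in zip(X.columns, fit.pvalues[1:])},
        intercept_p=float(fit.pvalues[0]),
        r2=float(fit.rsquared),
        n=n,
    )


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: 1/(1-R²_j), column j on the others.

    A single predictor has VIF 1 by convention; perfectly collinear
    columns report infinity.
    """
    X = pd.DataFrame(X)
    if X.shape[1] == 0:
        return {}
    for c in X.columns:
        if np.std(X[c].to_numpy(float)) == 0:
            raise StatsError(f"constant column {c!r}")
    if X.shape[1] == 1:
        return {X.columns[0]: 1.0}
    out = {}
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    for j, name in enumerate(X.columns, start=1):
        others = np.delete(A, j, axis=1)
        target = A[:, j]
        resid = target - others @ np.linalg.lstsq(others, target, rcond=None)[0]
        sse = float(np.sum(resid**2))
        sst = float(np.sum((target - target.mean()) ** 2))
        r2_j = 1.0 - sse / sst
        out[name] = float("inf") if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return out


# ------------------------------------------------------------------- stepwise


@dataclass(frozen=True)
class StepwiseConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_flag: float = 5.0
    max_steps: int = 100

    def __post_init__(self) -> None:
        for name in ("p_enter", "p_remove"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_enter > self.p_remove:
            raise ValueError("p_enter must not exceed p_remove (prevents cycling)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")


@dataclass
class StepwiseResult:
    outcome: str
    predictors: list[str]
    coef: dict[str, float]
    pvalues: dict[str, float]
    intercept: float
    r2: float
    vif: dict[str, float]
    empty_model: bool
    trace: list[dict] = field(default_factory=list)
    full_model_vif: dict[str, float] = field(default_factory=dict)
    vif_flagged: list[str] = field(default_factory=list)


def backward_stepwise(
    X: pd.DataFrame, y, cfg: StepwiseConfig | None = None, outcome: str = "y"
) -> StepwiseResult:
    """Backward elimination with re-entry, SPSS-style.

    Starting from the full model (or, when n is too small for it, the
    largest fittable model by marginal \\|r\\| ranking, noted in the
    trace), repeatedly: remove the predictor with the largest p above
    ``p_remove``; when none qualifies, re-enter the excluded predictor
    with the smallest add-one p below ``p_enter``; stop when stable.
    Ties on p break by column order. An empty final model is valid and
    flagged.
    """
    cfg = cfg or StepwiseConfig()
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    columns = list(X.columns)
    n = len(X)
    if n < 3:
        raise StatsError(f"too few observations for selection (n={n})")

    trace: list[dict] = []
    # perfectly collinear predictors make the full model unfittable; drop the
    # later-ordered member of each redundant set before selection starts
    keep: list[str] = []
    A = np.empty((n, 0))
    for c in columns:
        col = X[c].to_numpy(float)
        sd = col.std()
        if sd == 0:
            trace.append({"step": 0, "action": "drop_collinear", "predictor": c})
            continue
        trial = np.hstack([A, ((col - col.mean()) / sd)[:, None]])
        if np.linalg.matrix_rank(trial) > A.shape[1]:
            A = trial
            keep.append(c)
        else:
            trace.append({"step": 0, "action": "drop_collinear", "predictor": c})
    columns = keep

    if n > len(columns) + 1:
        current = list(columns)
    else:
        # not enough df for the full model: seed with the strongest marginals
        m = max(1, n - 2)
        ranked = sorted(
            columns,
            key=lambda c: (
                -abs(np.corrcoef(X[c].to_numpy(float), y)[0, 1])
                if np.std(X[c].to_numpy(float)) > 0
                else 0.0
            ),
        )
        current = [c for c in columns if c in set(ranked[:m])]
        trace.append(
            {"step": 0, "action": "reduced_start", "predictors": list(current)}
        )

    try:
        trace.append(
            {"step": 0, "action": "full_model_vif", "vif": vif(X[current])}
        )
    except StatsError:
        pass
    full_vif = next(
        (t["vif"] for t in trace if t["action"] == "full_model_vif"), {}
    )

    step = 0
    while True:
        step += 1
        if step > cfg.max_steps:
            raise StatsError(
                f"selection did not converge within {cfg.max_steps} steps; "
                f"trace: {trace}"
            )
        changed = False
        if current:
            fit = ols_fit(X[current], y)
            worst, worst_p = None, -1.0
            for c in current:  # column order breaks ties
                p = fit.pvalues[c]
                if p > cfg.p_remove and p > worst_p:
                    worst, worst_p = c, p
            if worst is not None:
                current.remove(worst)
                trace.append(
                    {"step": step, "action": "remove", "predictor": worst, "p": worst_p}
                )
                changed = True
        if not changed and cfg.p_enter > 0:
            best, best_p = None, np.inf
            for c in columns:
                if c in current:
                    continue
                trial = current + [c]
                if n <= len(trial) + 1:
                    continue
                try:
                    p = ols_fit(X[trial], y).pvalues[c]
                except StatsError:
                    continue
                if p < cfg.p_enter and p < best_p:
                    best, best_p = c, p
            if best is not None:
                current.append(best)
                current = [c for c in columns if c in current]  # keep column order
                trace.append(
                    {"step": step, "action": "enter", "predictor": best, "p": best_p}
                )
                changed = True
        if not changed:
            break

    if current:
        fit = ols_fit(X[current], y)
        result = StepwiseResult(
            outcome=outcome,
            predictors=list(current),
            coef={c: fit.coef[c] for c in current},
            pvalues={c: fit.pvalues[c] for c in current},
            intercept=fit.intercept,
            r2=fit.r2,
            vif=vif(X[current]),
            empty_model=False,
            trace=trace,
            full_model_vif=full_vif,
        )
    else:
        result = StepwiseResult(
            outcome=outcome,
            predictors=[],
            coef={},
            pvalues={},
            intercept=float(np.mean(y)),
            r2=0.0,
            vif={},
            empty_model=True,
            trace=trace,
            full_model_vif=full_vif,
        )
    result.vif_flagged = [c for c, v in result.vif.items() if v >= cfg.vif_flag]
    return result


# -------------------------------------------------------------- orchestration


@dataclass
class InferenceResult:
    descriptives: pd.DataFrame
    correlations: list[CorrelationRecord]
    models: dict[str, StepwiseResult | None]
    refusals: dict[str, str]
    n_correlation_tests: int
    alpha: float
    stepwise_cfg: StepwiseConfig


def run_inference(
    features: pd.DataFrame,
    scores: pd.DataFrame | list[ScoreSet],
    stepwise_cfg: StepwiseConfig | None = None,
    alpha: float = 0.05,
) -> InferenceResult:
    """Descriptives, correlation screen, then stepwise per outcome measure.

    Per-outcome stepwise failures on degenerate inputs (too few
    subjects, constant outcome) are recorded as refusals rather than
    aborting the other stages.
    """
    stepwise_cfg = stepwise_cfg or StepwiseConfig()
    if isinstance(scores, list):
        desc = scale_descriptives(scores)
        from .scales import scores_to_frame

        scores = scores_to_frame(scores)
    else:
        desc = pd.DataFrame(
            {
                "measure": list(scores.columns),
                "mean": [float(scores[c].mean()) for c in scores.columns],
                "sd": [float(scores[c].std(ddof=1)) for c in scores.columns],
            }
        )
    for frame, label in ((features, "features"), (scores, "scores")):
        if frame.index.has_duplicates:
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise StatsError(f"duplicate subject ids in {label}: {dupes}")

    records = correlation_screen(features, scores, alpha=alpha)

    common = features.index.intersection(scores.index)
    feature_cols = [c for c in FEATURE_NAMES if c in features.columns]
    measure_cols = [c for c in MEASURES if c in scores.columns]
    models: dict[str, StepwiseResult | None] = {}
    refusals: dict[str, str] = {}
    for meas in measure_cols:
        joined = pd.concat(
            [features.loc[common, feature_cols], scores.loc[common, meas]], axis=1
        ).dropna()
        try:
            if np.std(joined[meas].to_numpy(float)) == 0:
                raise StatsError("constant outcome")
            models[meas] = backward_stepwise(
                joined[feature_cols], joined[meas], stepwise_cfg, outcome=meas
            )
        except StatsError as exc:
            models[meas] = None
            refusals[meas] = str(exc)

    return InferenceResult(
        descriptives=desc,
        correlations=records,
        models=models,
        refusals=refusals,
        n_correlation_tests=len(records),
        alpha=alpha,
        stepwise_cfg=stepwise_cfg,
    )


def models_to_frame(models: dict[str, StepwiseResult | None]) -> pd.DataFrame:
    """Long-form model report; empty or refused models render as dashes."""
    rows = []
    for outcome, res in models.items():
        if res is None or res.empty_model:
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": EMPTY_MARK,
                    "beta": EMPTY_MARK,
                    "p": EMPTY_MARK,
                    "r2": EMPTY_MARK,
                    "vif": EMPTY_MARK,
                }
            )
            continue
        for c in res.predictors:
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": c,
                    "beta": f"{res.coef[c]:.6g}",
                    "p": f"{res.pvalues[c]:.6g}",
                    "r2": f"{res.r2:.6g}",
                    "vif": f"{res.vif[c]:.6g}",
                }
            )
    return pd.DataFrame(rows, columns=["outcome", "predictor", "beta", "p", "r2", "vif"])


def write_reports(outdir: str | Path, result: InferenceResult) -> dict[str, Path]:
    """Write descriptives.csv, correlations.csv, models.csv/json, trace.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "descriptives": outdir / "descriptives.csv",
        "correlations": outdir / "correlations.csv",
        "models_csv": outdir / "models.csv",
        "models_json": outdir / "models.json",
        "trace": outdir / "trace.log",
    }
    result.descriptives.to_csv(paths["descriptives"], index=False, float_format="%.10g")
    correlations_to_frame(result.correlations).to_csv(
        paths["correlations"], index=False, float_format="%.10g"
    )
    models_to_frame(result.models).to_csv(paths["models_csv"], index=False)

    payload = {
        "alpha": result.alpha,
        "n_correlation_tests": result.n_correlation_tests,
        "selection": {
            "p_enter": result.stepwise_cfg.p_enter,
            "p_remove": result.stepwise_cfg.p_remove,
            "vif_flag": result.stepwise_cfg.vif_flag,
        },
        "models": {
            outcome: (
                None
                if res is None
                else {
                    "predictors": res.predictors,
                    "coef": res.coef,
                    "pvalues": res.pvalues,
                    "intercept": res.intercept,
                    "r2": res.r2,
                    "vif": res.vif,
                    "empty_model": res.empty_model,
                    "vif_flagged": res.vif_flagged,
                }
            )
            for outcome, res in result.models.items()
        },
        "refusals": result.refusals,
    }
    with open(paths["models_json"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(paths["trace"], "w", encoding="utf-8") as fh:
        for outcome, res in result.models.items():
            if res is None:
                fh.write(f"{outcome}: refused ({result.refusals.get(outcome)})\n")
                continue
            for entry in res.trace:
                fh.write(f"{outcome}: {json.dumps(entry, sort_keys=True, default=str)}\n")
            final = EMPTY_MARK if res.empty_model else ",".join(res.predictors)
            fh.write(f"{outcome}: final [{final}] r2={res.r2:.6g}\n")
    return paths
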