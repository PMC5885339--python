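"""Experiment orchestration and reporting.

Runs the sampler × objective grid (sample → GA search → evaluate on the
untouched imbalanced test half), assembles rows with training-phase
(pooled cross-validation) and testing-phase metrics, and provides the
cohort group-comparison statistics (Pearson chi-square for categorical
variables, unpaired equal-variance Student's t for continuous ones).

Formatting conventions: AC/SE/SP as percentages to 2 decimals, G-mean and
AUC as fractions to 4 decimals; percentages inside count cells to 1
decimal, e.g. ``614 (54.1%)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BINARY_FEATURES, CohortTable
from .metrics import MetricSet, auc_score, confusion_metrics
from .sampling import undersample
from .wrapper import GAParams, TrainedModel, ga_search, predict_scores

SIGNIFICANCE_LEVEL = 0.05


# ---------------------------------------------------------------------------
# formatting helpers
# ---------------------------------------------------------------------------

def fmt_pct(fraction: float) -> str:
    """Fraction -> percentage with 2 decimals, e.g. 0.77 -> '77.00'."""
    return f"{100.0 * fraction:.2f}"


def fmt_frac(value: float) -> str:
    """G-mean / AUC style: 4 decimals."""
    return f"{value:.4f}"


def fmt_count_pct(count: int, total: int) -> str:
    """'614 (54.1%)' — count with its percentage of the class total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{count} ({100.0 * count / total:.1f}%)"


def prevalence_percent(positives: int, total: int) -> float:
    """Class prevalence on the percent scale, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * positives / total, 1)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def evaluate_model(model: TrainedModel, test: CohortTable) -> MetricSet:
    """Metrics of a trained model on a held-out table; never refits."""
    pred, dec = predict_scores(model, test)
    return confusion_metrics(test.labels, pred, scores=dec)


@dataclass
class ExperimentRow:
    sampler: str
    objective: str
    train_metrics: MetricSet   # pooled cross-validation, training phase
    test_metrics: MetricSet    # untouched test half
    model: TrainedModel | None = None


@dataclass
class ExperimentReport:
    rows: list[ExperimentRow]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append({
                "sampler": r.sampler, "objective": r.objective,
                "train_AC": r.train_metrics.ac, "train_SE": r.train_metrics.se,
                "train_SP": r.train_metrics.sp,
                "test_AC": r.test_metrics.ac, "test_SE": r.test_metrics.se,
                "test_SP": r.test_metrics.sp,
                "test_Gmean": r.test_metrics.gmean,
                "test_AUC": r.test_metrics.auc,
            })
        return pd.DataFrame.from_records(records)

    def to_text(self) -> str:
        header = (f"{'Group':<28}{'AC%':>8}{'SE%':>8}{'SP%':>8}"
                  f"{'AC%':>8}{'SE%':>8}{'SP%':>8}{'G-mean':>9}{'AUC':>9}")
        lines = [f"{'':<28}{'Training phase':^24}{'Testing phase':^42}", header]
        for r in self.rows:
            t, e = r.train_metrics, r.test_metrics
            lines.append(
                f"{r.sampler + ' + ' + r.objective:<28}"
                f"{fmt_pct(t.ac):>8}{fmt_pct(t.se):>8}{fmt_pct(t.sp):>8}"
                f"{fmt_pct(e.ac):>8}{fmt_pct(e.se):>8}{fmt_pct(e.sp):>8}"
                f"{fmt_frac(e.gmean):>9}{fmt_frac(e.auc):>9}")
        return "\n".join(lines)

    def write(self, out_dir: str | Path, stem: str = "experiment") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / f"{stem}.csv", index=False,
                               float_format="%.6f")
        (out / f"{stem}.txt").write_text(self.to_text() + "\n")


def run_experiment(train: CohortTable, test: CohortTable,
                   samplers: Sequence[str], objectives: Sequence[str],
                   ga_params: GAParams, n_folds: int = 10,
                   keep_models: bool = False) -> ExperimentReport:
    """Run every (sampler, objective) configuration and assemble the report
    in configuration order: sample -> GA search -> evaluate on ``test``."""
    rows: list[ExperimentRow] = []
    for sampler in samplers:
        sampled = undersample(train, sampler, seed=ga_params.seed)
        for objective in objectives:
            model = ga_search(sampled.sampled, objective, ga_params,
                              n_folds=n_folds)
            model.provenance["sampler"] = sampled.method
            rows.append(ExperimentRow(
                sampler=sampled.method, objective=objective.upper(),
                train_metrics=model.validation_metrics,
                test_metrics=evaluate_model(model, test),
                model=model if keep_models else None))
    return ExperimentReport(rows=rows, metadata={
        "samplers": list(samplers), "objectives": [o.upper() for o in objectives],
        "seed": ga_params.seed, "ga_params": ga_params,
        "train_n": train.n, "test_n": test.n})


# ---------------------------------------------------------------------------
# repeated random-undersampling experiment
# ---------------------------------------------------------------------------

def average_metrics(metric_sets: Sequence[MetricSet]) -> dict[str, float]:
    """Arithmetic column-wise mean of AC/SE/SP/G-mean/AUC."""
    if not metric_sets:
        raise ValueError("no metric rows to average")
    cols = {}
    for name in ("ac", "se", "sp", "gmean", "auc"):
        vals = [getattr(m, name) for m in metric_sets]
        cols[name] = float(np.mean(vals)) if None not in vals else None
    return cols


def repeated_subset_experiment(train: CohortTable, test: CohortTable,
                               k: int, objective: str, ga_params: GAParams,
                               n_folds: int = 10
                               ) -> tuple[list[MetricSet], dict[str, float]]:
    """Train and test on ``k`` random-undersampled subsets (seeds
    ``ga_params.seed + i``) and append the column-wise average row."""
    if k < 1:
        raise ValueError("k must be >= 1")
    per_subset: list[MetricSet] = []
    for i in range(k):
        seed = ga_params.seed + i
        sampled = undersample(train, "random", seed=seed)
        params_i = GAParams(
            population_n=ga_params.population_n,
            max_not_improved=ga_params.max_not_improved,
            max_iteration=ga_params.max_iteration,
            mutation_bit_rate=ga_params.mutation_bit_rate,
            mutation_sigma=ga_params.mutation_sigma, seed=seed)
        model = ga_search(sampled.sampled, objective, params_i, n_folds=n_folds)
        per_subset.append(evaluate_model(model, test))
    return per_subset, average_metrics(per_subset)


# ---------------------------------------------------------------------------
# cohort group comparisons (case vs control descriptive statistics)
# ---------------------------------------------------------------------------

def compare_groups(cohort: CohortTable,
                   variables: Sequence[str] | None = None,
                   types: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-variable comparison of the fracture and non-fracture groups.

    Categorical (binary) variables get per-class counts with percentages of
    the class total and a Pearson chi-square p-value (no continuity
    correction); continuous variables get per-class mean, SD and median with
    an unpaired equal-variance Student's t-test p-value.  A variable with a
    single observed level is flagged (``note`` column) rather than dropped.
    """
    if cohort.labels.min() == cohort.labels.max():
        raise ValueError("both classes must be present")
    if variables is None:
        variables = cohort.feature_names
    types = dict(types or {})
    for v in variables:
        if v not in cohort.features.columns:
            raise ValueError(f"unknown variable {v!r}")
        types.setdefault(v, "categorical" if v in BINARY_FEATURES else "continuous")

    y = cohort.labels
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    rows = []
    for v in variables:
        x = cohort.features[v].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        row: dict = {"variable": v, "type": types[v], "note": ""}
        if types[v] == "categorical":
            c0, c1 = int(x0.sum()), int(x1.sum())
            row.update(group0=fmt_count_pct(c0, n0), group1=fmt_count_pct(c1, n1))
            contingency = np.array([[c0, n0 - c0], [c1, n1 - c1]])
            if np.any(contingency.sum(axis=0) == 0):
                row.update(statistic=np.nan, p_value=np.nan,
                           note="single observed level; chi-square undefined")
            else:
                chi2, p, _, _ = stats.chi2_contingency(contingency,
                                                       correction=False)
                row.update(statistic=float(chi2), p_value=float(p))
        elif types[v] == "continuous":
            row.update(
                group0=f"{x0.mean():.2f} ± {x0.std(ddof=1):.2f}",
                group1=f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
                median0=float(np.median(x0)), median1=float(np.median(x1)))
            t, p = stats.ttest_ind(x1, x0, equal_var=True)
            row.update(statistic=float(t), p_value=float(p))
        else:
            raise ValueError(f"unknown variable type {types[v]!r} for {v!r}")
        p = row.get("p_value", np.nan)
        row["significant"] = bool(p < SIGNIFICANCE_LEVEL) if np.isfinite(p) else False
        rows.append(row)
    return pd.DataFrame(rows)
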