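"""Monte-Carlo study engine.

For each replicate a fresh sample is drawn, every requested strategy is
fitted, and the dose-response difference and its robust standard error are
evaluated on a dose grid. Across replicates the engine aggregates, per
strategy and grid dose:

* the mean estimate and bias against the true dose-response difference,
* the empirical SE (standard deviation of estimates across replicates),
* the average model-based SE (mean of the per-replicate delta-method SEs),
* the coverage of nominal 95% (or chosen-level) confidence intervals.

Aggregation is streaming (Welford one-pass mean/variance) so full-scale runs
need no per-replicate storage. Replicates use independent RNG substreams
spawned from the master seed, so each is reproducible on its own and results
do not depend on execution order.

For the zero-dose-excluding strategy the estimand is referenced to the
minimum observed positive dose, which varies by replicate; coverage for it
is judged against the per-replicate truth Delta(x) - Delta(x_ref).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import delta_curve
from .exceptions import SlabsplineError
from .modelzoo import ModelSpec, catalog_models, fit_model
from .simgen import ScenarioConfig, draw_sample, true_delta

__all__ = ["ReplicateResult", "ScenarioResult", "default_grid", "run_replicate", "run_scenario"]

Z95 = 1.959963984540054  # normal 97.5% quantile


def default_grid(config: ScenarioConfig) -> np.ndarray:
    """Evaluation doses: a few fixed low doses plus 19 points spanning the support.

    {0.01, 0.025, 0.05} union 19 evenly spaced points from 0.05*gamma_X to
    0.95*gamma_X. The low fixed points probe the region where the safe-dose
    assumption bites; the even points cover the bulk of the dose support.
    """
    low = np.array([0.01, 0.025, 0.05])
    spread = np.linspace(0.05 * config.gamma_X, 0.95 * config.gamma_X, 19)
    return np.unique(np.concatenate([low, spread]))


@dataclass
class ReplicateResult:
    """Per-model curve evaluations and coefficient summaries for one replicate."""

    estimates: dict[int, np.ndarray]
    ses: dict[int, np.ndarray]
    truths: dict[int, np.ndarray]
    coefficients: dict[int, dict[str, float]]
    sigma_hat: dict[int, float]
    failures: dict[int, str] = field(default_factory=dict)


def run_replicate(
    config: ScenarioConfig,
    specs: list[ModelSpec],
    grid,
    rng: np.random.Generator,
    hc: str = "HC1",
    level: float = 0.95,
) -> ReplicateResult:
    """Draw one sample, fit every strategy, evaluate Delta-hat on the grid.

    A strategy that fails on a given sample (collinearity, empty category)
    is recorded with a reason code and NaN results; it never aborts the run.
    """
    grid = np.asarray(grid, dtype=float)
    sample = draw_sample(config, rng)
    base_truth = true_delta(grid, config)
    out = ReplicateResult({}, {}, {}, {}, {})
    for spec in specs:
        sid = spec.strategy_id
        try:
            fit = fit_model(spec, sample.doses, sample.outcomes, kind=hc)
            curve = delta_curve(fit, spec, grid, level=level)
        except SlabsplineError as err:
            out.estimates[sid] = np.full(len(grid), np.nan)
            out.ses[sid] = np.full(len(grid), np.nan)
            out.truths[sid] = base_truth
            out.coefficients[sid] = {}
            out.sigma_hat[sid] = np.nan
            out.failures[sid] = f"{type(err).__name__}: {err}"
            continue
        out.estimates[sid] = curve.estimate
        out.ses[sid] = curve.se
        if spec.reference_rule == "minimum_observed_positive":
            ref_truth = float(true_delta(np.array([curve.reference_dose]), config)[0])
            out.truths[sid] = np.asarray(base_truth - ref_truth)
        else:
            out.truths[sid] = base_truth
        out.coefficients[sid] = dict(zip(fit.design_labels, fit.coefficients))
        out.sigma_hat[sid] = fit.sigma_hat
    return out


class _Welford:
    """Streaming mean/SD accumulator (one cell per model x grid point)."""

    def __init__(self, shape):
        self.n = np.zeros(shape, dtype=int)
        self.mean = np.zeros(shape)
        self.m2 = np.zeros(shape)

    def add(self, values):
        ok = np.isfinite(values)
        self.n[ok] += 1
        delta = np.where(ok, values - self.mean, 0.0)
        self.mean[ok] += delta[ok] / self.n[ok]
        self.m2[ok] += delta[ok] * (values[ok] - self.mean[ok])

    def sd(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 1, np.sqrt(self.m2 / np.maximum(self.n - 1, 1)), np.nan)


@dataclass
class ScenarioResult:
    """Aggregated operating characteristics and coefficient summaries."""

    metrics: pd.DataFrame
    coefficient_summary: pd.DataFrame
    failure_counts: dict[int, int]


def run_scenario(
    config: ScenarioConfig,
    specs: list[ModelSpec] | None = None,
    grid=None,
    hc: str = "HC1",
    level: float = 0.95,
) -> ScenarioResult:
    """Run the full Monte-Carlo experiment for one scenario.

    Coverage compares estimate +/- z * SE against the (per-replicate) truth;
    denominators exclude replicates where a model failed or a grid point was
    unrepresentable, and the contributing count is reported per cell.
    """
    if specs is None:
        specs = catalog_models()
    grid = default_grid(config) if grid is None else np.asarray(grid, dtype=float)
    sids = [s.strategy_id for s in specs]
    n_g = len(grid)
    shape = (len(specs), n_g)
    est_acc = _Welford(shape)
    se_acc = _Welford(shape)
    truth_acc = _Welford(shape)
    cover = np.zeros(shape, dtype=int)
    cover_n = np.zeros(shape, dtype=int)
    coef_acc: dict[int, dict[str, _Welford]] = {sid: {} for sid in sids}
    sigma_acc: dict[int, _Welford] = {sid: _Welford((1,)) for sid in sids}
    failures = {sid: 0 for sid in sids}

    z = Z95 if level == 0.95 else float(_norm_ppf(0.5 + level / 2.0))
    streams = np.random.SeedSequence(config.seed).spawn(config.M)
    for m in range(config.M):
        rng = np.random.default_rng(streams[m])
        rep = run_replicate(config, specs, grid, rng, hc=hc, level=level)
        est = np.vstack([rep.estimates[sid] for sid in sids])
        se = np.vstack([rep.ses[sid] for sid in sids])
        truth = np.vstack([rep.truths[sid] for sid in sids])
        est_acc.add(est)
        se_acc.add(se)
        truth_acc.add(np.where(np.isfinite(est), truth, np.nan))
        ok = np.isfinite(est) & np.isfinite(se)
        hit = ok & (np.abs(est - truth) <= z * se)
        cover += hit
        cover_n += ok
        for i, sid in enumerate(sids):
            if sid in rep.failures:
                failures[sid] += 1
            for lab, val in rep.coefficients[sid].items():
                coef_acc[sid].setdefault(lab, _Welford((1,))).add(np.array([val]))
            sigma_acc[sid].add(np.array([rep.sigma_hat[sid]]))

    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        coverage = np.where(cover_n > 0, cover / np.maximum(cover_n, 1), np.nan)
    for i, spec in enumerate(specs):
        for j, gx in enumerate(grid):
            rows.append(
                {
                    "scenario": config.name or "custom",
                    "strategy_id": spec.strategy_id,
                    "model_label": spec.label,
                    "dose": gx,
                    "true_delta": truth_acc.mean[i, j] if truth_acc.n[i, j] else np.nan,
                    "mean_estimate": est_acc.mean[i, j] if est_acc.n[i, j] else np.nan,
                    "bias": (est_acc.mean[i, j] - truth_acc.mean[i, j]) if est_acc.n[i, j] else np.nan,
                    "empirical_se": est_acc.sd()[i, j],
                    "average_se": se_acc.mean[i, j] if se_acc.n[i, j] else np.nan,
                    "coverage": coverage[i, j],
                    "n_replicates": int(cover_n[i, j]),
                }
            )
    metrics = pd.DataFrame(rows)

    coef_rows = []
    for spec in specs:
        sid = spec.strategy_id
        for lab, acc in coef_acc[sid].items():
            coef_rows.append(
                {
                    "scenario": config.name or "custom",
                    "strategy_id": sid,
                    "model_label": spec.label,
                    "coefficient": lab,
                    "mean": acc.mean[0],
                    "sd": acc.sd()[0],
                    "n_replicates": int(acc.n[0]),
                }
            )
        acc = sigma_acc[sid]
        if acc.n[0]:
            coef_rows.append(
                {
                    "scenario": config.name or "custom",
                    "strategy_id": sid,
                    "model_label": spec.label,
                    "coefficient": "sigma_hat",
                    "mean": acc.mean[0],
                    "sd": acc.sd()[0],
                    "n_replicates": int(acc.n[0]),
                }
            )
    coef_summary = pd.DataFrame(coef_rows)
    return ScenarioResult(metrics, coef_summary, failures)


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return norm.ppf(q)
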