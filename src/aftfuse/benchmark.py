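"""Monte-Carlo experiment driver: fits methods over replicates and scores them.

One replicate = one dataset from the generator (replicate seeds are
base_seed + replicate index), one shared cross-fitted nuisance fit, and one
fit per requested method. Scores follow the simulation conventions: RMSE of
the covariate part of alpha, FDR of its selection, and TIR of the confounding
call. Parallelism is by replicate with per-replicate seeding, so reports are
invariant to the worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .bootstrap import bootstrap_632, coverage
from .comparators import ComparatorSpec, fit_comparator
from .estimator import FitOptions, fit_integrative, fit_naive, fit_oracle, fit_rct_only
from .metrics import fdr, rmse, tir
from .nuisance import cross_fit
from .simulate import SimulationConfig, calibrate_censoring, generate

__all__ = ["MetricsReport", "run_benchmark", "run_inference_study", "scenario_label"]

_COMPARATORS = ("oa", "gm0", "gm1", "meta", "gm01")


def scenario_label(config: SimulationConfig) -> str:
    conf = "uc" if config.confounded else "nuc"
    return f"{conf}_p{config.p}_cr{int(round(config.censor_rate * 100))}"


def _parse_method(method: str) -> tuple[str, str]:
    base, _, rule = method.partition(".")
    return base, (rule or "cv")


def _fit_one_method(method: str, dataset, truth, nuisance, options: FitOptions):
    base, rule = _parse_method(method)
    opts = replace(options, tuning=rule if rule in ("cv", "bic") else options.tuning)
    if base == "rl":
        if rule in ("cv", "bic"):
            est = fit_integrative(dataset, opts, nuisance)
        elif rule == "rct":
            est = fit_rct_only(dataset, replace(options, tuning="cv"))
        elif rule == "nai":
            est = fit_naive(dataset, replace(options, tuning="cv"), nuisance)
        elif rule == "or":
            sa = np.flatnonzero(truth.alpha_star != 0)
            sb = np.flatnonzero(truth.beta_star != 0)
            est = fit_oracle(dataset, sa, sb, options, nuisance)
        else:
            raise ValueError(f"unknown rl variant '{method}'")
    elif base in _COMPARATORS:
        est = fit_comparator(dataset, nuisance, ComparatorSpec(base, opts))
    else:
        raise ValueError(f"unknown method '{method}'")
    return est.alpha[1:].copy(), bool(est.confounding_detected)


def _replicate(config: SimulationConfig, methods, options: FitOptions, need_arm_means: bool,
               seed: int):
    cfg = replace(config, seed=seed)
    dataset, truth = generate(cfg)
    opts = replace(options, seed=seed)
    nuisance = cross_fit(dataset, opts.learner, K=opts.cross_fit_folds, seed=seed,
                         arm_means=need_arm_means)
    out = {}
    for method in methods:
        out[method] = _fit_one_method(method, dataset, truth, nuisance, opts)
    return out


@dataclass
class MetricsReport:
    """Aggregated metrics plus the raw per-replicate estimates."""

    table: pd.DataFrame
    estimates: dict = field(default_factory=dict)   # (scenario, method) -> (B, p) alpha estimates
    flags: dict = field(default_factory=dict)       # (scenario, method) -> (B,) confounding calls
    B: int = 0
    base_seed: int = 0
    n_failed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "B": self.B,
            "base_seed": self.base_seed,
            "n_failed": self.n_failed,
        }


def run_benchmark(scenarios, methods, B: int, base_seed: int = 0,
                  options: FitOptions | None = None, workers: int = 1) -> MetricsReport:
    """Run ``B`` replicates of every scenario and score every method.

    The censoring window is calibrated once per scenario and shared by its
    replicates. Replicate failures are recorded; the report flags if more
    than 1% fail.
    """
    options = options or FitOptions()
    if isinstance(scenarios, SimulationConfig):
        scenarios = [scenarios]
    methods = list(methods)
    need_arm_means = any(_parse_method(m)[0] in _COMPARATORS for m in methods)
    rows = []
    estimates: dict = {}
    flags: dict = {}
    n_failed = 0
    for config in scenarios:
        label = scenario_label(config)
        if config.censor_rate > 0 and config.t0 is None:
            t0, t1 = calibrate_censoring(replace(config, seed=base_seed))
            config = replace(config, t0=t0, t1=t1)
        _, truth = generate(replace(config, seed=base_seed))
        seeds = [base_seed + r for r in range(B)]

        def one(seed):
            try:
                return _replicate(config, methods, options, need_arm_means, seed)
            except Exception as err:  # noqa: BLE001 - replicate-level fault isolation
                return ("failed", seed, repr(err))

        results = Parallel(n_jobs=workers)(delayed(one)(s) for s in seeds)
        ok = [r for r in results if not (isinstance(r, tuple) and r and r[0] == "failed")]
        n_failed += len(results) - len(ok)
        for method in methods:
            est = np.array([r[method][0] for r in ok])
            flg = np.array([r[method][1] for r in ok])
            estimates[(label, method)] = est
            flags[(label, method)] = flg
            rows.append(
                {
                    "scenario": label,
                    "method": method,
                    "B": len(ok),
                    "rmse_x100": 100 * rmse(est, truth.alpha_star),
                    "fdr_pct": 100 * fdr(est, truth.alpha_star),
                    "tir_pct": 100 * tir(flg, truth.confounded),
                }
            )
    report = MetricsReport(
        table=pd.DataFrame(rows), estimates=estimates, flags=flags,
        B=B, base_seed=base_seed, n_failed=n_failed,
    )
    if n_failed > 0.01 * B * len(scenarios):
        report.table.attrs["warning"] = f"{n_failed} replicate failures (>1%)"
    return report


def run_inference_study(config: SimulationConfig, B: int, n_boot: int = 500,
                        base_seed: int = 0, level: float = 0.95,
                        options: FitOptions | None = None, workers: int = 1) -> dict:
    """Bias / SD / mean bootstrap SE / coverage for the integrative and
    RCT-only estimators, per covariate coefficient of alpha.

    Returns ``{"both": summary, "rct": summary, "truth": alpha*}`` where each
    summary holds the (B, p) estimate and SE arrays and the per-coefficient
    aggregates.
    """
    options = options or FitOptions()
    if config.censor_rate > 0 and config.t0 is None:
        t0, t1 = calibrate_censoring(replace(config, seed=base_seed))
        config = replace(config, t0=t0, t1=t1)
    _, truth = generate(replace(config, seed=base_seed))
    p = config.p

    def one(seed):
        cfg = replace(config, seed=seed)
        dataset, _ = generate(cfg)
        opts = replace(options, seed=seed)
        nuisance = cross_fit(dataset, opts.learner, K=opts.cross_fit_folds, seed=seed,
                             arm_means=False)
        out = {}
        est_both = fit_integrative(dataset, opts, nuisance)
        boot_both = bootstrap_632(dataset, nuisance, est_both, n_boot=n_boot, level=level,
                                  seed=seed, options=opts)
        out["both"] = (est_both.alpha[1:], boot_both.se[1 : p + 1])
        rct_idx = np.flatnonzero(dataset.source == 1)
        ds_rct = dataset.subset(rct_idx)
        nu_rct = cross_fit(ds_rct, opts.learner, K=opts.cross_fit_folds, seed=seed,
                           arm_means=False)
        est_rct = fit_rct_only(ds_rct, opts, nu_rct)
        boot_rct = bootstrap_632(ds_rct, nu_rct, est_rct, n_boot=n_boot, level=level,
                                 seed=seed, options=opts)
        out["rct"] = (est_rct.alpha[1:], boot_rct.se[1 : p + 1])
        return out

    results = Parallel(n_jobs=workers)(delayed(one)(base_seed + r) for r in range(B))
    z = {"both": {}, "rct": {}}
    from scipy import stats as _st

    zq = _st.norm.ppf(0.5 + level / 2)
    for key in ("both", "rct"):
        est = np.array([r[key][0] for r in results])
        se = np.array([r[key][1] for r in results])
        lo, hi = est - zq * se, est + zq * se
        z[key] = {
            "estimates": est,
            "se": se,
            "bias": est.mean(axis=0) - truth.alpha_star,
            "sd": est.std(axis=0, ddof=1),
            "mean_se": se.mean(axis=0),
            "cp": coverage(lo, hi, truth.alpha_star),
        }
    z["truth"] = truth.alpha_star
    return z
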