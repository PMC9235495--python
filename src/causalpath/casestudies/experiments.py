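"""Sampling-distribution experiments over the case-study systems.

``run_sampling_experiment`` reproduces the benchmark protocol: for each
training-set size n and each repeat, generate fresh observational data from
the true process, fit the LVM variant, estimate the causal query, and compare
against a simulation ground truth computed once from the true parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._util import derive_seed
from ..query import NonIdentifiableQueryError, estimate_query, ground_truth_query
from ..identify import identify
from ..scm import Dataset
from .builders import CaseStudySpec
from .gillespie import cs3_input_sampler, cs3_reaction_network, simulate_replicates

__all__ = ["EvaluationResult", "run_sampling_experiment", "generate_case_data", "case_truth",
           "load_expression_data"]


def load_expression_data(path, spec: CaseStudySpec) -> Dataset:
    """Load a user-supplied expression table (samples x genes CSV with a header
    row) as the observational dataset for a case study.

    The expression-compendium case studies ship with synthetic stand-ins; this
    loader is the path for running them on real normalized expression profiles
    with columns matching the case's observed genes.
    """
    frame = pd.read_csv(path)
    needed = sorted(spec.correct.observed)
    missing = set(needed) - set(frame.columns)
    if missing:
        raise ValueError(
            f"expression table lacks columns for observed genes: {sorted(missing)}"
        )
    return Dataset(frame[needed].astype(float),
                   {"kind": "observational", "source": str(path)})


@dataclass
class EvaluationResult:
    """Per-(variant, n, repeat) query estimates plus the simulation truth."""

    case: str
    table: pd.DataFrame  # columns: variant, n, repeat, estimate
    truth: float
    truth_se: float = float("nan")
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Bias and RMSE of the estimates per (variant, n)."""
        rows = []
        for (variant, n), grp in self.table.groupby(["variant", "n"]):
            est = grp["estimate"].to_numpy()
            bias = float(est.mean() - self.truth)
            rmse = float(np.sqrt(np.mean((est - self.truth) ** 2)))
            rows.append(
                {"variant": variant, "n": int(n), "repeats": len(est),
                 "bias": bias, "rmse": rmse, "sd": float(est.std(ddof=1)) if len(est) > 1 else 0.0}
            )
        return pd.DataFrame(rows).sort_values(["variant", "n"]).reset_index(drop=True)

    def save(self, prefix) -> None:
        import json

        self.table.to_csv(f"{prefix}_estimates.csv", index=False)
        self.summary().to_csv(f"{prefix}_summary.csv", index=False)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"case": self.case, "truth": self.truth, "truth_se": self.truth_se,
                       "meta": self.meta}, fh, indent=2, default=float)


def generate_case_data(spec: CaseStudySpec, theta: dict, n: int, seed: int,
                       do_map: dict | None = None) -> Dataset:
    """Observational (or interventional) data from the case's true process."""
    if spec.data_mode == "gillespie":
        net = cs3_reaction_network()
        return simulate_replicates(
            net, n, t_max=10.0, seed=seed, init_sampler=cs3_input_sampler,
            observed=sorted(spec.correct.observed), fixed=do_map,
        )
    if do_map:
        return spec.correct.sample_interventional(theta, do_map, n, seed)
    return spec.correct.sample_observational(theta, n, seed)


def case_truth(spec: CaseStudySpec, theta: dict, seed: int, n_truth: int = 10000):
    """Ground-truth query value: the mean over interventional samples drawn
    from the true process with the intervention applied."""
    do = {k: float(v) for k, v in spec.query.targets.items()}
    if spec.data_mode == "gillespie":
        n_truth = min(n_truth, 2000)  # jump-process sampling is the costly path
        data = generate_case_data(spec, theta, n_truth, seed, do_map=do)
        col = data.column(spec.query.outcomes[0])
        return float(col.mean()), float(col.std(ddof=1) / np.sqrt(len(col)))
    est = ground_truth_query(spec.correct, theta, spec.query, n=n_truth, seed=seed)
    (o,) = spec.query.outcomes if len(spec.query.outcomes) == 1 else (spec.query.outcomes[0],)
    col = est.draws[o].to_numpy()
    return float(col.mean()), float(col.std(ddof=1) / np.sqrt(len(col)))


def run_sampling_experiment(
    spec: CaseStudySpec,
    n_grid,
    repeats: int = 20,
    seed: int = 0,
    variants=("correct", "misspecified"),
    fit_kwargs: dict | None = None,
    s_draws: int = 300,
    l_draws: int = 20,
    n_truth: int = 10000,
    progress: bool = False,
) -> EvaluationResult:
    """Sampling distribution of the query estimate across data regenerations.

    Refuses to run non-identifiable queries (the estimator itself would).
    Bit-identical under a fixed seed.
    """
    res = identify(spec.correct.admg(), spec.query)
    if not res.identifiable:
        raise NonIdentifiableQueryError(res)
    fit_kwargs = {"chains": 2, "warmup": 250, "draws": 200, "max_depth": 5} | (fit_kwargs or {})
    theta = spec.true_theta()
    truth, truth_se = case_truth(spec, theta, derive_seed(seed, spec.name, "truth"), n_truth)
    (outcome,) = spec.query.outcomes
    rows = []
    for variant in variants:
        model = spec.model(variant)
        for n in n_grid:
            for rep in range(repeats):
                data_seed = derive_seed(seed, spec.name, "data", n, rep)
                data = generate_case_data(spec, theta, int(n), data_seed)
                try:
                    trained = model.fit(
                        data, seed=derive_seed(seed, spec.name, variant, "fit", n, rep),
                        **fit_kwargs,
                    )
                    est = estimate_query(
                        trained, spec.query, s_draws=s_draws, l_draws=l_draws,
                        seed=derive_seed(seed, spec.name, variant, "query", n, rep),
                    )
                except NonIdentifiableQueryError:
                    raise
                except Exception as err:  # annotate failures with their context
                    raise RuntimeError(
                        f"{spec.name}/{variant}: fit or estimation failed at n={n}, "
                        f"repeat={rep}: {err}"
                    ) from err
                rows.append(
                    {"variant": variant, "n": int(n), "repeat": rep,
                     "estimate": est.expectation[outcome]}
                )
                if progress:
                    print(f"[{spec.name}] {variant} n={n} rep={rep} "
                          f"est={rows[-1]['estimate']:.4f}", flush=True)
    table = pd.DataFrame(rows)
    meta = {"seed": seed, "repeats": repeats, "n_grid": list(map(int, n_grid)),
            "s_draws": s_draws, "l_draws": l_draws, "fit_kwargs": fit_kwargs,
            "theta_seed": spec.theta_seed}
    return EvaluationResult(spec.name, table, truth, truth_se, meta)
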