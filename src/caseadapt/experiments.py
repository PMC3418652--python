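"""Experiment runner: retrieval-count sweeps, regularization sweeps, and
arm comparisons on synthetic case libraries.

The classifier arms follow the study design:

* ``LR``          — baseline logistic classifier, training split only.
* ``LR_all``      — logistic classifier trained on training split plus the
                    whole retrieval library pooled.
* ``Ada_LR``      — per-query full retrain on training cases plus
                    emphasized retrieved cases (no regularization prior).
* ``Ada_Reg_Non`` — per-query refit on retrieved cases only, no prior
                    (the overfitting-prone ablation).
* ``Ada_Reg_Uni`` — retrieved cases plus isotropic Gaussian prior centered
                    at the baseline discriminant.
* ``Ada_Reg_Var`` — same, with the prior mean interpolated per query from
                    pretrained per-training-case vectors.

Each runner scores every test case, evaluates the empirical AUC with a
percentile bootstrap, and returns a tidy table with full provenance
(config echo and seed); rows are bit-reproducible from (config, seed).
Wall-clock time per row is recorded for information only.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .adaptive import fit_adaptive
from .baseline import BaselineLogistic
from .data import CaseLibrary, augment
from .evaluation import (
    DEFAULT_PARAM_GRID,
    ScoredTestSet,
    bootstrap_auc,
    compute_auc,
    paired_bootstrap_compare,
    select_by_cv,
)
from .full_retrain import fit_ada_lr
from .logistic import sigmoid
from .retrieval import retrieve
from .synthetic import SyntheticSpec, generate, oracle_scores
from .varying import fit_adaptive_varying, train_varying_prior

__all__ = [
    "ARMS",
    "ExperimentConfig",
    "SweepResult",
    "run_nr_sweep",
    "run_c_sweep",
    "run_arm_comparison",
]

ARMS = ("LR", "LR_all", "Ada_LR", "Ada_Reg_Non", "Ada_Reg_Uni", "Ada_Reg_Var")
DEFAULT_NR_GRID = (6, 10, 20, 50, 100, 200, 300)


@dataclass
class ExperimentConfig:
    arms: tuple = ARMS
    nr_grid: tuple = DEFAULT_NR_GRID
    c_grid: tuple = DEFAULT_PARAM_GRID
    n_r: int = 50                     # fixed N_r for c-sweep / comparison
    C: float | str = "cv"             # regularization strength or "cv"
    C_prime: float | str = 0.2        # coupling strength or "cv"
    kappa: float = 1.0                # Ada_LR emphasis magnitude
    data: SyntheticSpec = field(default_factory=SyntheticSpec)
    seed: int = 0
    n_boot: int = 2000
    cv_folds: int = 10

    def __post_init__(self):
        if not self.arms:
            raise ValueError("arms must be nonempty")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arm(s): {sorted(unknown)}")
        if any(nr < 1 for nr in self.nr_grid):
            raise ValueError("nr_grid values must be >= 1")


@dataclass
class SweepResult:
    table: pd.DataFrame
    provenance: dict

    def save(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "results.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1, default=str)


class _Bench:
    """Fitted shared state for one experiment: data, baseline, prior model."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.train, self.test, self.library, self.meta = generate(config.data)
        self.baseline = BaselineLogistic().fit(
            self.train.features, self.train.labels
        )
        pooled_X = np.vstack([self.train.features, self.library.features])
        pooled_y = np.concatenate([self.train.labels, self.library.labels])
        self.baseline_all = BaselineLogistic().fit(pooled_X, pooled_y)
        self.test_X = self.test.features
        self.test_y = self.test.labels
        self._varying = None

    def resolve_C(self, n_r: int) -> float:
        cfg = self.config
        if cfg.C != "cv":
            return float(cfg.C)
        from .adaptive import AdaptiveUniformClassifier

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, _ = select_by_cv(
                self.train.features, self.train.labels,
                lambda c: AdaptiveUniformClassifier(n_r=n_r, C=c),
                grid=cfg.c_grid, k=cfg.cv_folds, seed=cfg.seed + 1,
            )
        return best

    def resolve_C_prime(self) -> float:
        cfg = self.config
        if cfg.C_prime != "cv":
            return float(cfg.C_prime)
        from .varying import AdaptiveVaryingClassifier

        C_for_refit = float(cfg.C) if cfg.C != "cv" else 0.2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, _ = select_by_cv(
                self.train.features, self.train.labels,
                lambda cp: AdaptiveVaryingClassifier(
                    n_r=self.config.n_r, C=C_for_refit, C_prime=cp
                ),
                grid=cfg.c_grid, k=cfg.cv_folds, seed=cfg.seed + 2,
            )
        return best

    @property
    def varying_model(self):
        if self._varying is None:
            cp = self.resolve_C_prime()
            self._varying = train_varying_prior(
                self.train, C_prime=cp, sigma=self.baseline.sigma_,
                baseline=self.baseline,
            )
        return self._varying

    # -- per-arm scoring ---------------------------------------------------

    def scores(self, arm: str, n_r: int, C: float | None = None) -> np.ndarray:
        if arm == "LR":
            return self.baseline.predict_proba(self.test_X)[:, 1]
        if arm == "LR_all":
            return self.baseline_all.predict_proba(self.test_X)[:, 1]
        if arm == "oracle":
            return oracle_scores(self.test_X, self.meta)
        bl = self.baseline
        out = np.empty(self.test_X.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, x in enumerate(self.test_X):
                retrieved = retrieve(
                    x, self.library, n_r, std=bl.standardizer_, sigma=bl.sigma_
                )
                if arm == "Ada_LR":
                    fit = fit_ada_lr(
                        x, retrieved, self.train, bl, kappa=self.config.kappa
                    )
                elif arm == "Ada_Reg_Non":
                    fit = fit_adaptive(x, retrieved, bl, method="none")
                elif arm == "Ada_Reg_Uni":
                    fit = fit_adaptive(x, retrieved, bl, C=C, method="uniform")
                elif arm == "Ada_Reg_Var":
                    fit = fit_adaptive_varying(
                        x, retrieved, self.varying_model, bl, C=C
                    )
                else:
                    raise ValueError(f"unknown arm {arm!r}")
                xa = augment(x, bl.standardizer_)
                out[i] = sigmoid(xa @ fit.w)
        return out


def _row(bench: _Bench, arm: str, n_r: int, C, n_boot: int, seed: int,
         precomputed=None) -> dict:
    t0 = time.perf_counter()
    try:
        s = bench.scores(arm, n_r, C) if precomputed is None else precomputed
        scored = ScoredTestSet(s, bench.test_y, tag=arm)
        rep = bootstrap_auc(scored, n_boot=n_boot, seed=seed)
        return {
            "arm": arm, "n_r": n_r, "C": C, "auc": rep.auc,
            "ci_lo": rep.bootstrap_ci[0], "ci_hi": rep.bootstrap_ci[1],
            "runtime_s": time.perf_counter() - t0, "error": "",
        }
    except Exception as exc:  # record, keep the run going
        return {
            "arm": arm, "n_r": n_r, "C": C, "auc": np.nan,
            "ci_lo": np.nan, "ci_hi": np.nan,
            "runtime_s": time.perf_counter() - t0, "error": str(exc),
        }


def _provenance(config: ExperimentConfig, kind: str) -> dict:
    d = asdict(config)
    d["data"] = asdict(config.data)
    return {"kind": kind, "config": d, "seed": config.seed}


def run_nr_sweep(config: ExperimentConfig, bench: _Bench | None = None) -> SweepResult:
    """AUC of each arm as the number of retrieved cases varies."""
    bench = bench or _Bench(config)
    rows = []
    for nr in config.nr_grid:
        C = None
        if any(a in config.arms for a in ("Ada_Reg_Uni", "Ada_Reg_Var")):
            C = bench.resolve_C(nr)
        for arm in config.arms:
            rows.append(_row(bench, arm, nr, C, config.n_boot, config.seed + 10))
    return SweepResult(pd.DataFrame(rows), _provenance(config, "nr_sweep"))


def run_c_sweep(config: ExperimentConfig, bench: _Bench | None = None) -> SweepResult:
    """AUC of the uniform-prior classifier over the C grid at fixed N_r.

    Reference rows for the baseline (no retrieval) and the retrieved-only
    refit (no prior) are appended: the sweep approaches the former as
    C grows and the latter as C -> 0.
    """
    bench = bench or _Bench(config)
    rows = []
    for C in config.c_grid:
        rows.append(
            _row(bench, "Ada_Reg_Uni", config.n_r, float(C), config.n_boot,
                 config.seed + 10)
        )
    rows.append(_row(bench, "LR", config.n_r, None, config.n_boot, config.seed + 10))
    rows.append(
        _row(bench, "Ada_Reg_Non", config.n_r, 0.0, config.n_boot, config.seed + 10)
    )
    return SweepResult(pd.DataFrame(rows), _provenance(config, "c_sweep"))


def run_arm_comparison(
    config: ExperimentConfig,
    bench: _Bench | None = None,
    include_oracle: bool = False,
) -> SweepResult:
    """All requested arms on identical test cases, with paired p-values.

    Each adaptive arm is compared against LR and LR_all by the paired
    bootstrap on the shared test scores.
    """
    bench = bench or _Bench(config)
    n_r = config.n_r
    C = None
    if any(a in config.arms for a in ("Ada_Reg_Uni", "Ada_Reg_Var")):
        C = bench.resolve_C(n_r)
    arm_list = list(config.arms) + (["oracle"] if include_oracle else [])
    scored = {}
    rows = []
    for arm in arm_list:
        try:
            s = bench.scores(arm, n_r, C)
        except Exception:
            s = None
        row = _row(bench, arm, n_r, C, config.n_boot, config.seed + 10,
                   precomputed=s)
        if s is not None and not row["error"]:
            scored[arm] = ScoredTestSet(s, bench.test_y, tag=arm)
        rows.append(row)
    df = pd.DataFrame(rows)
    for ref in ("LR", "LR_all"):
        col = []
        for arm in df["arm"]:
            if ref in scored and arm in scored and arm not in ("LR", "LR_all"):
                cmp = paired_bootstrap_compare(
                    scored[arm], scored[ref], n_boot=config.n_boot,
                    seed=config.seed + 20,
                )
                col.append(cmp["p_value"])
            else:
                col.append(np.nan)
        df[f"p_vs_{ref}"] = col
    return SweepResult(df, _provenance(config, "arm_comparison"))
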