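"""Monte-Carlo studies: empirical type-I-error levels and power.

A study repeatedly simulates case-control datasets under a penetrance
model, runs a configured battery of tests per replicate, and reports the
rejection proportion at each significance level together with its binomial
Monte-Carlo standard error sqrt(p(1-p)/reps).

Seeding: the master seed spawns one child ``SeedSequence`` per replicate,
so any single replicate can be reproduced in isolation and results do not
depend on how the replicate loop is scheduled.  Per-replicate p-values are
kept on the result so further significance levels can be evaluated without
resimulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import comparators
from .simulate import LplmModel, sample_case_control
from .smt import adjusted_smt, smt_test

__all__ = [
    "StudyConfig",
    "StudyResult",
    "replicate_pvalues",
    "run_level_study",
    "run_power_study",
    "run_subset_curve",
]

#: battery entries: name -> (runner kind, kwargs)
KNOWN_TESTS = (
    "smt",
    "adjusted_smt",
    "single_marker_best",
    "pairwise_1df_best",
    "pairwise_4df_best",
    "threeway_1df",
    "threeway_8df",
)


@dataclass(frozen=True)
class StudyConfig:
    """Specification of one simulation study.

    ``model`` is either a fixed penetrance model or a callable
    ``rng -> model`` for families whose parameters are redrawn each
    replicate (the multiplicative null and the semi-null models).
    ``correction`` applies to the best-of-set comparators: "none" uses the
    most-significant-member policy, "bonferroni" divides alpha by the
    number of enumerated tests.
    """

    model: object
    n_replicates: int = 1000
    n_cases: int = 3000
    n_controls: int = 3000
    alphas: tuple[float, ...] = (0.05,)
    tests: tuple[str, ...] = ("smt",)
    correction: str = "none"
    subset_sizes: tuple[int, ...] | None = None
    adjust: Mapping | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if not self.tests:
            raise ValueError("no tests configured")
        unknown = [t for t in self.tests if t not in KNOWN_TESTS]
        if unknown:
            raise ValueError(f"unknown tests: {unknown}; choose from {KNOWN_TESTS}")
        if not all(0.0 < a <= 1.0 for a in self.alphas):
            raise ValueError("significance levels must lie in (0, 1]")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError("correction must be 'none' or 'bonferroni'")


@dataclass(frozen=True)
class StudyResult:
    """Rejection proportions with Monte-Carlo error, plus raw p-values."""

    summary: pd.DataFrame  # columns: test, alpha, subset_k, power, se, reps
    pvalues: pd.DataFrame  # one row per replicate, one column per test

    def proportion(self, test: str, alpha: float, subset_k=None) -> float:
        sel = self.summary[
            (self.summary["test"] == test)
            & (np.isclose(self.summary["alpha"], alpha))
        ]
        if subset_k is not None:
            sel = sel[sel["subset_k"] == subset_k]
        if len(sel) != 1:
            raise KeyError(f"no unique study cell for ({test}, {alpha}, {subset_k})")
        return float(sel["power"].iloc[0])

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False, float_format="%.6g")


def replicate_pvalues(config: StudyConfig) -> pd.DataFrame:
    """Run the configured battery once per replicate; p-values per test."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    records = []
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        model = config.model(rng) if callable(config.model) else config.model
        rep = sample_case_control(model, config.n_cases, config.n_controls, rng)
        row: dict = {"replicate": i}
        for test in config.tests:
            row[test] = _apply_test(test, rep, config)
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("replicate")


def _apply_test(test: str, rep, config: StudyConfig) -> float:
    G, y, spec = rep.genotypes, rep.phenotype, rep.spec
    if test == "smt":
        return smt_test(G, y, spec).p_final
    if test == "adjusted_smt":
        return adjusted_smt(G, y, spec, **dict(config.adjust or {})).p_final
    order, mode = {
        "single_marker_best": (1, "allelic"),
        "pairwise_1df_best": (2, "allelic"),
        "pairwise_4df_best": (2, "genotypic"),
        "threeway_1df": (3, "allelic"),
        "threeway_8df": (3, "genotypic"),
    }[test]
    res = comparators.best_of_set(
        G, y, order=order, mode=mode, correction=config.correction
    )
    return res.corrected_p


def _summarize(pvalues: pd.DataFrame, alphas, subset_k=None) -> pd.DataFrame:
    reps = len(pvalues)
    rows = []
    for test in pvalues.columns:
        p = pvalues[test].to_numpy()
        for alpha in alphas:
            prop = float(np.mean(p <= alpha))
            rows.append(
                {
                    "test": test,
                    "alpha": alpha,
                    "subset_k": subset_k,
                    "power": prop,
                    "se": float(np.sqrt(prop * (1 - prop) / reps)),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def _run(config: StudyConfig) -> StudyResult:
    pvalues = replicate_pvalues(config)
    return StudyResult(summary=_summarize(pvalues, config.alphas), pvalues=pvalues)


def _probe_model(config: StudyConfig):
    if callable(config.model):
        return config.model(np.random.default_rng(np.random.SeedSequence(config.seed)))
    return config.model


def run_level_study(config: StudyConfig) -> StudyResult:
    """Empirical type-I-error study under a null or semi-null model."""
    variant = getattr(_probe_model(config), "variant", None)
    if variant not in (
        "multiplicative",
        "dominance_semi_null",
        "pairwise_semi_null",
    ):
        raise ValueError(
            "level studies require a null or semi-null model; got "
            f"variant {variant!r}"
        )
    return _run(config)


def run_power_study(config: StudyConfig) -> StudyResult:
    """Power study: rejection proportion of the configured battery."""
    return _run(config)


def run_subset_curve(config: StudyConfig) -> StudyResult:
    """SMT power against the number k of available model SNPs.

    Data are generated under the *full* model each replicate; the SMT is
    then applied to the first k SNPs (set order) for every configured k,
    mimicking partial knowledge of a liability pathway.
    """
    model = _probe_model(config)
    if not isinstance(model, LplmModel):
        raise ValueError("subset curves are defined for LPLM-family models")
    if not config.subset_sizes:
        raise ValueError("subset_sizes must be configured")
    n = model.n_snps
    for k in config.subset_sizes:
        if not 2 <= k <= n:
            raise ValueError(f"subset size {k} outside [2, {n}]")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    records = []
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        m = config.model(rng) if callable(config.model) else config.model
        rep = sample_case_control(m, config.n_cases, config.n_controls, rng)
        row: dict = {"replicate": i}
        for k in config.subset_sizes:
            Gk = rep.genotypes.subset(k)
            row[f"smt_k{k}"] = smt_test(Gk, rep.phenotype, rep.spec).p_final
        records.append(row)
    pvalues = pd.DataFrame.from_records(records).set_index("replicate")
    parts = []
    for k in config.subset_sizes:
        part = _summarize(pvalues[[f"smt_k{k}"]], config.alphas, subset_k=k)
        part["test"] = "smt"
        parts.append(part)
    return StudyResult(summary=pd.concat(parts, ignore_index=True), pvalues=pvalues)
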