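"""Standard single-marker, dominance and interaction tests.

These are the benchmarks the SMT is compared against: the 1-d.f. additive
single-marker test, the 1-d.f. dominance-deviation test, and 2-/3-SNP
interaction tests in two flavours.  "Allelic" interaction uses products of
additive genotype terms only (one term per order); "genotypic" interaction
uses products spanning additive and heterozygote-dominance terms (4 terms
for a pair, 8 for a triple).  All p-values come from likelihood-ratio tests
of the interaction block over the model with all lower-order terms.

Sparse genotype tables routinely empty cells (think of the triple-homozygote
cell in a 27-cell table at n = 6,000): rather than aborting, linearly
dependent terms are dropped, the degrees of freedom reduced, and the result
flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regression import (
    DesignMatrix,
    TestResult,
    fit_logistic,
    likelihood_ratio_test,
    _validate_phenotype,
)
from .smt import GenotypeMatrix

__all__ = [
    "BestOfSetResult",
    "MonomorphicSNPError",
    "best_of_set",
    "dominance_test",
    "interaction_term_labels",
    "pairwise_interaction_test",
    "single_marker_test",
    "threeway_interaction_test",
]


class MonomorphicSNPError(ValueError):
    """SNP shows no genotype variation in the sample."""


def _as_array(g) -> np.ndarray:
    g = np.asarray(g, dtype=np.float64).ravel()
    if not np.isfinite(g).all() or g.min() < -1e-9 or g.max() > 2 + 1e-9:
        raise ValueError("genotype counts must be finite and in [0, 2]")
    return g


def _het(g: np.ndarray) -> np.ndarray:
    return (np.abs(g - 1.0) < 1e-9).astype(np.float64)


def interaction_term_labels(order: int, mode: str) -> tuple[str, ...]:
    """Labels of the interaction block for a pair/triple in each mode."""
    if mode == "allelic":
        return ("a" * order,)
    if mode != "genotypic":
        raise ValueError("mode must be 'allelic' or 'genotypic'")
    return tuple(
        "".join(kind) for kind in itertools.product("ad", repeat=order)
    )


def _independent_columns(
    ordered: list[tuple[str, np.ndarray]], rtol: float = 1e-8
) -> list[tuple[str, np.ndarray]]:
    """Greedy Gram-Schmidt column selection preserving the given priority order."""
    kept: list[tuple[str, np.ndarray]] = []
    basis: list[np.ndarray] = []
    for label, col in ordered:
        norm0 = np.linalg.norm(col)
        if norm0 == 0.0:
            continue
        resid = col.astype(np.float64).copy()
        for q in basis:
            resid -= (q @ resid) * q
        if np.linalg.norm(resid) > rtol * norm0:
            basis.append(resid / np.linalg.norm(resid))
            kept.append((label, col))
    return kept


def _block_lrt(
    y: np.ndarray,
    null_cols: list[tuple[str, np.ndarray]],
    block_cols: list[tuple[str, np.ndarray]],
) -> TestResult:
    """LRT of the block over the null columns, with rank-deficiency collapse."""
    n = y.shape[0]
    ones = [("intercept", np.ones(n))]
    kept_all = _independent_columns(ones + null_cols + block_cols)
    kept_labels = {lab for lab, _ in kept_all}
    null_kept = [(lab, c) for lab, c in null_cols if lab in kept_labels]
    block_kept = [(lab, c) for lab, c in block_cols if lab in kept_labels]
    flags = []
    if len(null_kept) < len(null_cols):
        flags.append("rank_deficient_main_effects")
    if len(block_kept) < len(block_cols):
        flags.append("df_reduced")
    df = len(block_kept)
    if df == 0:
        # complete collapse (e.g. identical SNPs): nothing testable remains;
        # report the conservative no-evidence result rather than aborting
        return TestResult(
            0.0, 1, 1.0,
            flags=tuple(flags) + ("no_testable_interaction",),
        )
    X0 = DesignMatrix.from_columns(n, dict(null_kept))
    X1 = DesignMatrix.from_columns(n, dict(null_kept + block_kept))
    fit0 = fit_logistic(X0, y)
    fit1 = fit_logistic(X1, y)
    res = likelihood_ratio_test(fit0, fit1, df)
    if df == 1:
        label = block_kept[0][0]
        eff = fit1.coefficient(label)
        se = fit1.standard_error(label)
        res = TestResult(
            res.statistic, res.df, res.p_value, eff, se, tuple(flags)
        )
    elif flags:
        res = TestResult(res.statistic, res.df, res.p_value, flags=tuple(flags))
    return res


def single_marker_test(g, y) -> TestResult:
    """1-d.f. additive logistic test of one SNP; effect is the log odds ratio."""
    g = _as_array(g)
    y = _validate_phenotype(y, g.shape[0])
    if np.unique(g).size < 2:
        raise MonomorphicSNPError("monomorphic SNP")
    res = _block_lrt(y, [], [("additive", g)])
    odds = None if res.effect_estimate is None else float(np.exp(res.effect_estimate))
    return TestResult(
        res.statistic, res.df, res.p_value, res.effect_estimate,
        res.effect_se, odds, res.flags,
    )


def dominance_test(g, y) -> TestResult:
    """1-d.f. test of the heterozygote indicator on top of the additive term."""
    g = _as_array(g)
    y = _validate_phenotype(y, g.shape[0])
    d = _het(g)
    if d.sum() == 0:
        raise ValueError("no heterozygotes: dominance deviation undefined")
    if np.unique(g).size < 2:
        raise MonomorphicSNPError("monomorphic SNP")
    return _block_lrt(y, [("additive", g)], [("dominance", d)])


def _main_effect_cols(gs: Sequence[np.ndarray], mode: str):
    cols = []
    for i, g in enumerate(gs, start=1):
        cols.append((f"a{i}", g))
        if mode == "genotypic":
            cols.append((f"d{i}", _het(g)))
    return cols


def _product(gs: Sequence[np.ndarray], kinds: str) -> np.ndarray:
    out = np.ones_like(gs[0])
    for g, kind in zip(gs, kinds):
        out = out * (g if kind == "a" else _het(g))
    return out


def pairwise_interaction_test(g1, g2, y, mode: str = "allelic") -> TestResult:
    """2-SNP interaction LRT: 1 d.f. (allelic) or 4 d.f. (genotypic)."""
    gs = [_as_array(g1), _as_array(g2)]
    y = _validate_phenotype(y, gs[0].shape[0])
    for g in gs:
        if np.unique(g).size < 2:
            raise MonomorphicSNPError("monomorphic SNP")
    labels = interaction_term_labels(2, mode)
    null_cols = _main_effect_cols(gs, mode)
    block = [(f"int_{lab}", _product(gs, lab)) for lab in labels]
    return _block_lrt(y, null_cols, block)


def threeway_interaction_test(g1, g2, g3, y, mode: str = "allelic") -> TestResult:
    """3-SNP interaction LRT over all lower-order terms: 1 or 8 d.f.

    The null model carries all main effects and all two-way products of the
    chosen mode; the tested block is the single allelic triple product or
    the eight {additive, dominance}^3 triple products.
    """
    gs = [_as_array(g1), _as_array(g2), _as_array(g3)]
    y = _validate_phenotype(y, gs[0].shape[0])
    for g in gs:
        if np.unique(g).size < 2:
            raise MonomorphicSNPError("monomorphic SNP")
    null_cols = _main_effect_cols(gs, mode)
    for (i, j) in itertools.combinations(range(3), 2):
        pair = [gs[i], gs[j]]
        for lab in interaction_term_labels(2, mode):
            null_cols.append((f"int{i+1}{j+1}_{lab}", _product(pair, lab)))
    block = [
        (f"int123_{lab}", _product(gs, lab))
        for lab in interaction_term_labels(3, mode)
    ]
    return _block_lrt(y, null_cols, block)


@dataclass(frozen=True)
class BestOfSetResult:
    """Minimum p over all singles/pairs/triples of a SNP set."""

    order: int
    mode: str
    n_tests: int
    min_p: float
    best_members: tuple[str, ...]
    p_values: tuple[float, ...]
    corrected_p: float  # min(1, m * min_p) under the Bonferroni policy, else min_p

    def significant(self, alpha: float) -> bool:
        return self.corrected_p <= alpha


def best_of_set(
    G: GenotypeMatrix,
    y,
    order: int,
    mode: str = "allelic",
    correction: str = "none",
) -> BestOfSetResult:
    """Enumerate all subsets of the given order and take the most significant.

    ``correction="none"`` reports the raw minimum p (most-significant-pair
    policy); ``correction="bonferroni"`` scales it by the number m of
    enumerated tests, so comparing ``corrected_p`` against a base alpha
    implements the alpha/m decision rule.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if correction not in ("none", "bonferroni"):
        raise ValueError("correction must be 'none' or 'bonferroni'")
    if G.n_snps < order:
        raise ValueError("set size below the order of the test")
    yv = _validate_phenotype(y, G.n_individuals)
    members = list(itertools.combinations(range(G.n_snps), order))
    pvals = []
    for combo in members:
        gs = [G.values[:, j] for j in combo]
        if order == 1:
            res = single_marker_test(gs[0], yv)
        elif order == 2:
            res = pairwise_interaction_test(gs[0], gs[1], yv, mode=mode)
        else:
            res = threeway_interaction_test(gs[0], gs[1], gs[2], yv, mode=mode)
        pvals.append(res.p_value)
    pvals_arr = np.asarray(pvals)
    k = int(np.argmin(pvals_arr))
    min_p = float(pvals_arr[k])
    m = len(members)
    corrected = min(1.0, m * min_p) if correction == "bonferroni" else min_p
    return BestOfSetResult(
        order=order,
        mode=mode,
        n_tests=m,
        min_p=min_p,
        best_members=tuple(G.snp_ids[j] for j in members[k]),
        p_values=tuple(float(p) for p in pvals_arr),
        corrected_p=corrected,
    )
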