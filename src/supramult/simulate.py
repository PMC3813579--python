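"""Case-control genotype simulation under penetrance models.

This module is the package's only data source: it generates SNP-set
genotypes under Hardy-Weinberg equilibrium and draws case-control samples
by rejection against a penetrance model.  The model catalogue covers

* ``multiplicative`` -- per-allele relative risks combined multiplicatively
  (the no-interaction null for the SMT level study),
* ``dominance_semi_null`` / ``pairwise_semi_null`` -- multiplicative base
  with purely recessive SNPs, resp. double-recessive SNP pairs, layered on
  top (deviation from multiplicativity attributable to dominance or
  two-way interaction only),
* ``lplm`` / ``weighted_lplm`` -- limiting-pathway liability models: a
  baseline penetrance f0 below, and an elevated penetrance p1 at or above,
  a critical (optionally weighted) risk-allele load threshold,
* ``recessive`` -- 3-SNP completely recessive models (elevated penetrance
  only for the triple homozygous-risk genotype; REZ-A..D presets).

Exact load distributions (for threshold calibration and prevalence) are
computed by dynamic-programming convolution of the per-SNP count
distributions, and LD-tagged proxy markers can be layered on any genotype
matrix via a two-locus haplotype model with a requested r-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .smt import GenotypeMatrix, RiskAlleleSpec

__all__ = [
    "CalibrationResult",
    "DominanceSemiNullModel",
    "LplmModel",
    "MarginalEffect",
    "ModelConfigurationError",
    "MultiplicativeModel",
    "PairwiseSemiNullModel",
    "RecessiveModel",
    "SimReplicate",
    "TaggingConfig",
    "assign_modified_weights",
    "calibrate_lplm_threshold",
    "draw_population_genotypes",
    "load_distribution",
    "make_tagged_proxies",
    "marginal_allelic_effect",
    "model_from_config",
    "penetrance",
    "sample_case_control",
]

BASELINE_PENETRANCE = 0.03
#: population tail mass at/above the liability threshold ("about 1.5%")
LPLM_TARGET_TAIL = 0.015
#: fraction of the population with capped (>1) multiplicative penetrance
#: beyond which the model configuration is rejected
MAX_CAP_FRACTION = 1e-3
MIN_PREVALENCE = 1e-4


class ModelConfigurationError(ValueError):
    """Penetrance-model parameters outside the supported regime."""


def _snp_ids(n: int) -> tuple[str, ...]:
    return tuple(f"snp{i+1:03d}" for i in range(n))


def _validate_freqs(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64).ravel()
    if q.size == 0 or not ((q > 0) & (q < 1)).all():
        raise ModelConfigurationError("allele frequencies must lie in (0, 1)")
    return q


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_hwe(rng: np.random.Generator, q: np.ndarray, n: int) -> np.ndarray:
    """HWE genotype counts Binomial(2, q) as the sum of two allele draws."""
    u = rng.random((2, int(n), q.size))
    return (u < q).sum(axis=0).astype(np.float64)


# ---------------------------------------------------------------------------
# load distributions


def load_distribution(
    q: Sequence[float], weights: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the weighted risk-allele load under HWE.

    Convolves the per-SNP count distributions {(1-q)^2, 2q(1-q), q^2} on
    supports {0, w, 2w}; returns (support, probabilities) sorted ascending.
    """
    q = _validate_freqs(np.asarray(q))
    if weights is None:
        w = np.ones_like(q)
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
        if w.shape != q.shape or (w <= 0).any():
            raise ValueError("weights must be positive, one per SNP")
    support = np.array([0.0])
    probs = np.array([1.0])
    for qi, wi in zip(q, w):
        geno_p = np.array([(1 - qi) ** 2, 2 * qi * (1 - qi), qi**2])
        vals = (support[:, None] + wi * np.array([0.0, 1.0, 2.0])[None, :]).ravel()
        ps = (probs[:, None] * geno_p[None, :]).ravel()
        keys = np.round(vals, 9)
        support, inv = np.unique(keys, return_inverse=True)
        probs = np.bincount(inv, weights=ps, minlength=support.size)
    return support, probs


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    tail: float  # achieved P(L >= threshold)


def calibrate_lplm_threshold(
    q: Sequence[float],
    weights: Sequence[float] | None = None,
    target_tail: float = LPLM_TARGET_TAIL,
) -> CalibrationResult:
    """Liability threshold with population tail mass closest to the target.

    The threshold is chosen among the support values of the exact load
    distribution so that P(L >= T) is nearest ``target_tail`` (about 1.5%
    of the general population at or above the threshold); the achieved tail
    is reported because small sets cannot hit the target exactly.
    """
    support, probs = load_distribution(q, weights)
    if support.size < 2:
        raise ModelConfigurationError("degenerate load distribution")
    tails = probs[::-1].cumsum()[::-1]  # tails[k] = P(L >= support[k])
    # exclude T = min(support): everyone is above, not a real split
    cand = np.arange(1, support.size)
    k = cand[np.argmin(np.abs(tails[cand] - target_tail))]
    return CalibrationResult(threshold=float(support[k]), tail=float(tails[k]))


def assign_modified_weights(n_snps: int) -> np.ndarray:
    """Risk-allele weights in thirds of the set order: 0.5, then 1, then 2."""
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    k = math.ceil(n_snps / 3)
    w = np.empty(n_snps, dtype=np.float64)
    w[:k] = 0.5
    w[k : 2 * k] = 1.0
    w[2 * k :] = 2.0
    return w


# ---------------------------------------------------------------------------
# penetrance models


@dataclass(frozen=True)
class _ModelBase:
    q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _validate_freqs(self.q))

    @property
    def n_snps(self) -> int:
        return self.q.size

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return _snp_ids(self.n_snps)

    def risk_spec(self) -> RiskAlleleSpec:
        """Unit-weight spec declaring allele "A" the risk allele everywhere."""
        n = self.n_snps
        return RiskAlleleSpec.from_lists(self.snp_ids, ("A",) * n)

    # subclasses implement:
    def raw_penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        return np.minimum(self.raw_penetrance(genotypes), 1.0)

    def prevalence(self) -> float:
        raise NotImplementedError

    def _p_disease_given_allele(self, snp_index: int, risk: bool) -> float:
        raise NotImplementedError


def _check_pen(value: float, name: str) -> float:
    if not 0.0 < value < 1.0:
        raise ModelConfigurationError(f"{name} must lie in (0, 1)")
    return float(value)


def _geno_probs(qi: float) -> np.ndarray:
    return np.array([(1 - qi) ** 2, 2 * qi * (1 - qi), qi**2])


#: fixed seed and size of the deterministic Monte-Carlo used to evaluate
#: prevalence and marginal effects of odds-scale models
_MC_SEED = 20130
_MC_DRAWS = 100_000


def _calibrate_intercept(scores: np.ndarray, target: float) -> float:
    """Intercept b with mean(expit(b + scores)) == target (monotone in b)."""
    lo = float(logit(target) - max(scores.max(), 0.0) - 1.0)
    hi = float(logit(target) - min(scores.min(), 0.0) + 1.0)
    return float(
        brentq(lambda b: float(np.mean(expit(b + scores))) - target, lo, hi)
    )


class _MultiplicativeFamily(_ModelBase):
    """Shared machinery of the multiplicative-base models.

    Each model contributes a genotype score S(x) (a sum of per-SNP and,
    for the semi-null variants, special log relative-risk terms) and
    combines it with the baseline on one of two scales:

    * ``scale="odds"`` (default): logit p(x) = logit(baseline) + S(x) --
      no interaction on the logarithmic scale of the logistic regression,
      i.e. the exact null of the tests in this package;
    * ``scale="risk"``: p(x) = baseline * exp(S(x)), capped at 1 --
      multiplicative relative risks.  Equivalent to the odds scale only in
      the rare-disease limit: for common outcomes the cap and the odds
      transformation make the risk scale mildly supra-multiplicative on
      the logit scale.
    """

    def _check_scale(self) -> None:
        if self.scale not in ("odds", "risk"):
            raise ModelConfigurationError("scale must be 'odds' or 'risk'")

    def _score(self, genotypes: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def raw_penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        genotypes = np.atleast_2d(np.asarray(genotypes, dtype=np.float64))
        s = self._score(genotypes)
        if self.scale == "odds":
            return expit(logit(self.baseline) + s)
        return self.baseline * np.exp(s)

    def _risk_scale_prevalence(self) -> float:
        raise NotImplementedError

    def prevalence(self) -> float:
        if self.prevalence_hint is not None:
            return float(self.prevalence_hint)
        if self.scale == "risk":
            return self._risk_scale_prevalence()
        rng = np.random.default_rng(_MC_SEED)
        g = _draw_hwe(rng, self.q, _MC_DRAWS)
        return float(self.penetrance(g).mean())

    def _p_disease_given_allele(self, i: int, risk: bool) -> float:
        if self.scale == "risk":
            return self._risk_scale_marginal(i, risk)
        rng = np.random.default_rng(_MC_SEED + 1)
        g = _draw_hwe(rng, self.q, _MC_DRAWS)
        qi = self.q[i]
        g[:, i] = (1.0 if risk else 0.0) + rng.binomial(1, qi, size=_MC_DRAWS)
        return float(self.penetrance(g).mean())

    def _risk_scale_marginal(self, i: int, risk: bool) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class MultiplicativeModel(_MultiplicativeFamily):
    """Per-allele relative risks combined multiplicatively (no interaction)."""

    allele_rr: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline: float = BASELINE_PENETRANCE
    scale: str = "odds"
    prevalence_hint: float | None = None

    variant = "multiplicative"

    def __post_init__(self) -> None:
        super().__post_init__()
        rr = np.asarray(self.allele_rr, dtype=np.float64).ravel()
        if rr.shape != self.q.shape or (rr <= 0).any():
            raise ModelConfigurationError("one positive relative risk per SNP")
        object.__setattr__(self, "allele_rr", rr)
        _check_pen(self.baseline, "baseline penetrance")
        self._check_scale()

    @classmethod
    def draw_null(
        cls,
        n_snps: int,
        rng,
        rr_range: tuple[float, float] = (1.2, 1.5),
        freq_range: tuple[float, float] = (0.1, 0.9),
        prevalence: float = 0.05,
        scale: str = "odds",
        n_calib: int = 50_000,
    ) -> "MultiplicativeModel":
        """Random null-model replicate: q ~ U(freq_range), rr ~ U(rr_range).

        The baseline is calibrated so the population prevalence hits the
        requested value (closed form on the risk scale, Monte-Carlo root
        finding on the odds scale).
        """
        rng = _rng(rng)
        q = rng.uniform(*freq_range, size=n_snps)
        rr = rng.uniform(*rr_range, size=n_snps)
        if scale == "risk":
            mean_factor = np.prod((1 - q + q * rr) ** 2)
            return cls(q=q, allele_rr=rr, baseline=prevalence / mean_factor,
                       scale=scale)
        g = _draw_hwe(rng, q, int(n_calib))
        b = _calibrate_intercept(g @ np.log(rr), prevalence)
        return cls(q=q, allele_rr=rr, baseline=float(expit(b)), scale=scale,
                   prevalence_hint=prevalence)

    def _score(self, genotypes: np.ndarray) -> np.ndarray:
        return genotypes @ np.log(self.allele_rr)

    def _risk_scale_prevalence(self) -> float:
        return float(
            self.baseline * np.prod((1 - self.q + self.q * self.allele_rr) ** 2)
        )

    def _risk_scale_marginal(self, i: int, risk: bool) -> float:
        qi, rr = self.q[i], self.allele_rr[i]
        others = np.prod(
            np.delete((1 - self.q + self.q * self.allele_rr) ** 2, i)
        )
        own = rr * (1 - qi + qi * rr) if risk else (1 - qi + qi * rr)
        return float(self.baseline * own * others)


@dataclass(frozen=True)
class DominanceSemiNullModel(_MultiplicativeFamily):
    """Multiplicative base with a purely recessive SNP subset (model B1 type).

    SNPs in ``recessive_snps`` contribute the relative risk ``hom_rr`` only
    when homozygous for the risk allele; the remaining SNPs act per-allele.
    """

    allele_rr: np.ndarray = field(default=None)  # type: ignore[assignment]
    recessive_snps: tuple[int, ...] = ()
    hom_rr: float = None  # type: ignore[assignment]
    baseline: float = BASELINE_PENETRANCE
    scale: str = "odds"
    prevalence_hint: float | None = None

    variant = "dominance_semi_null"

    def __post_init__(self) -> None:
        super().__post_init__()
        rr = np.asarray(self.allele_rr, dtype=np.float64).ravel()
        if rr.shape != self.q.shape or (rr <= 0).any():
            raise ModelConfigurationError("one positive relative risk per SNP")
        object.__setattr__(self, "allele_rr", rr)
        rec = tuple(sorted(int(i) for i in self.recessive_snps))
        if len(set(rec)) != len(rec) or any(
            not 0 <= i < self.n_snps for i in rec
        ):
            raise ModelConfigurationError("invalid recessive SNP indices")
        object.__setattr__(self, "recessive_snps", rec)
        if self.hom_rr is None or self.hom_rr <= 0:
            raise ModelConfigurationError(
                "hom_rr (homozygote relative risk) is required and positive"
            )
        _check_pen(self.baseline, "baseline penetrance")
        self._check_scale()

    @classmethod
    def draw(
        cls,
        rng,
        n_snps: int = 30,
        n_recessive: int = 15,
        hom_rr: float = None,  # type: ignore[assignment]
        rr_range: tuple[float, float] = (1.2, 1.5),
        freq_range: tuple[float, float] = (0.1, 0.9),
        prevalence: float = 0.05,
        scale: str = "odds",
        n_calib: int = 50_000,
    ) -> "DominanceSemiNullModel":
        if hom_rr is None:
            raise ModelConfigurationError("hom_rr is required for model B1")
        if not 0 < n_recessive <= n_snps:
            raise ModelConfigurationError("n_recessive must lie in [1, n_snps]")
        rng = _rng(rng)
        q = rng.uniform(*freq_range, size=n_snps)
        rr = rng.uniform(*rr_range, size=n_snps)
        rec = tuple(range(n_recessive))
        rr[list(rec)] = 1.0  # recessive SNPs carry no per-allele effect
        model = cls(q=q, allele_rr=rr, recessive_snps=rec, hom_rr=hom_rr,
                    baseline=0.5, scale=scale)
        if scale == "risk":
            mean = model._risk_scale_prevalence() / 0.5
            return replace(model, baseline=prevalence / mean)
        g = _draw_hwe(rng, q, int(n_calib))
        b = _calibrate_intercept(model._score(g), prevalence)
        return replace(model, baseline=float(expit(b)), prevalence_hint=prevalence)

    def _factors(self) -> list[np.ndarray]:
        """Per-SNP genotype relative-risk tables over counts (0, 1, 2)."""
        tables = []
        for i in range(self.n_snps):
            t = self.allele_rr[i] ** np.array([0.0, 1.0, 2.0])
            if i in self.recessive_snps:
                t = t * np.array([1.0, 1.0, self.hom_rr])
            tables.append(t)
        return tables

    def _score(self, genotypes: np.ndarray) -> np.ndarray:
        counts = np.rint(genotypes).astype(np.intp)
        out = np.zeros(genotypes.shape[0])
        for i, table in enumerate(self._factors()):
            out += np.log(table)[counts[:, i]]
        return out

    def _risk_scale_prevalence(self) -> float:
        prev = self.baseline
        for i, table in enumerate(self._factors()):
            prev *= float(_geno_probs(self.q[i]) @ table)
        return float(prev)

    def _risk_scale_marginal(self, i: int, risk: bool) -> float:
        tables = self._factors()
        others = self.baseline
        for j, table in enumerate(tables):
            if j != i:
                others *= float(_geno_probs(self.q[j]) @ table)
        qi = self.q[i]
        t = tables[i]
        own = (1 - qi) * t[1] + qi * t[2] if risk else (1 - qi) * t[0] + qi * t[1]
        return float(others * own)


@dataclass(frozen=True)
class PairwiseSemiNullModel(_MultiplicativeFamily):
    """Multiplicative base with double-recessive SNP pairs (model B2 type).

    Each listed pair contributes the relative risk ``pair_rr`` only for the
    two-locus genotype carrying 4 risk alleles (both SNPs homozygous).
    """

    allele_rr: np.ndarray = field(default=None)  # type: ignore[assignment]
    pairs: tuple[tuple[int, int], ...] = ()
    pair_rr: float = None  # type: ignore[assignment]
    baseline: float = BASELINE_PENETRANCE
    scale: str = "odds"
    prevalence_hint: float | None = None

    variant = "pairwise_semi_null"

    def __post_init__(self) -> None:
        super().__post_init__()
        rr = np.asarray(self.allele_rr, dtype=np.float64).ravel()
        if rr.shape != self.q.shape or (rr <= 0).any():
            raise ModelConfigurationError("one positive relative risk per SNP")
        object.__setattr__(self, "allele_rr", rr)
        pairs = tuple(tuple(sorted((int(a), int(b)))) for a, b in self.pairs)
        flat = [i for p in pairs for i in p]
        if len(set(flat)) != len(flat) or any(
            not 0 <= i < self.n_snps for i in flat
        ):
            raise ModelConfigurationError("pairs must be disjoint valid indices")
        object.__setattr__(self, "pairs", pairs)
        if self.pair_rr is None or self.pair_rr <= 0:
            raise ModelConfigurationError(
                "pair_rr (double-recessive relative risk) is required and positive"
            )
        _check_pen(self.baseline, "baseline penetrance")
        self._check_scale()

    @classmethod
    def draw(
        cls,
        rng,
        n_snps: int = 30,
        n_pairs: int = 7,
        pair_rr: float = None,  # type: ignore[assignment]
        rr_range: tuple[float, float] = (1.2, 1.5),
        freq_range: tuple[float, float] = (0.1, 0.9),
        prevalence: float = 0.05,
        scale: str = "odds",
        n_calib: int = 50_000,
    ) -> "PairwiseSemiNullModel":
        if pair_rr is None:
            raise ModelConfigurationError("pair_rr is required for model B2")
        if not 0 < 2 * n_pairs <= n_snps:
            raise ModelConfigurationError("2 * n_pairs must lie in [2, n_snps]")
        rng = _rng(rng)
        q = rng.uniform(*freq_range, size=n_snps)
        rr = rng.uniform(*rr_range, size=n_snps)
        pairs = tuple((2 * k, 2 * k + 1) for k in range(n_pairs))
        flat = [i for p in pairs for i in p]
        rr[flat] = 1.0  # pair SNPs act only through the double-recessive term
        model = cls(q=q, allele_rr=rr, pairs=pairs, pair_rr=pair_rr,
                    baseline=0.5, scale=scale)
        if scale == "risk":
            mean = model._risk_scale_prevalence() / 0.5
            return replace(model, baseline=prevalence / mean)
        g = _draw_hwe(rng, q, int(n_calib))
        b = _calibrate_intercept(model._score(g), prevalence)
        return replace(model, baseline=float(expit(b)), prevalence_hint=prevalence)

    def _score(self, genotypes: np.ndarray) -> np.ndarray:
        out = genotypes @ np.log(self.allele_rr)
        for i, j in self.pairs:
            both = (genotypes[:, i] > 1.5) & (genotypes[:, j] > 1.5)
            out = out + both * math.log(self.pair_rr)
        return out

    def _risk_scale_prevalence(self) -> float:
        paired = {i for p in self.pairs for i in p}
        prev = self.baseline
        for i in range(self.n_snps):
            if i not in paired:
                prev *= float((1 - self.q[i] + self.q[i] * self.allele_rr[i]) ** 2)
        for i, j in self.pairs:
            e_i = (1 - self.q[i] + self.q[i] * self.allele_rr[i]) ** 2
            e_j = (1 - self.q[j] + self.q[j] * self.allele_rr[j]) ** 2
            p_hom = (self.q[i] ** 2) * (self.q[j] ** 2)
            hom_factor = (self.allele_rr[i] ** 2) * (self.allele_rr[j] ** 2)
            prev *= float(e_i * e_j + p_hom * hom_factor * (self.pair_rr - 1.0))
        return float(prev)

    def _risk_scale_marginal(self, i: int, risk: bool) -> float:
        # expectation of the penetrance factor of SNP i's unit (pair or single),
        # conditional on one allele at SNP i, times the other units' means
        partner = None
        for a, b in self.pairs:
            if i == a:
                partner = b
            elif i == b:
                partner = a
        qi, rri = self.q[i], self.allele_rr[i]
        own_counts = (
            [(1.0, 1 - qi), (2.0, qi)] if risk else [(0.0, 1 - qi), (1.0, qi)]
        )
        if partner is None:
            own = sum(p * rri**c for c, p in own_counts)
        else:
            qj, rrj = self.q[partner], self.allele_rr[partner]
            own = 0.0
            for c, pc in own_counts:
                for gj, pj in zip((0.0, 1.0, 2.0), _geno_probs(qj)):
                    f = (rri**c) * (rrj**gj)
                    if c == 2.0 and gj == 2.0:
                        f *= self.pair_rr
                    own += pc * pj * f
        total = self._risk_scale_prevalence() / self.baseline
        # divide out this unit's unconditional mean factor
        if partner is None:
            unit_mean = (1 - qi + qi * rri) ** 2
        else:
            qj, rrj = self.q[partner], self.allele_rr[partner]
            unit_mean = (1 - qi + qi * rri) ** 2 * (1 - qj + qj * rrj) ** 2 + (
                qi**2
            ) * (qj**2) * (rri**2) * (rrj**2) * (self.pair_rr - 1.0)
        others = total / unit_mean
        return float(self.baseline * own * others)


@dataclass(frozen=True)
class LplmModel(_ModelBase):
    """Limiting-pathway liability model: f0 below, p1 at/above the threshold."""

    threshold: float = None  # type: ignore[assignment]
    p1: float = None  # type: ignore[assignment]
    f0: float = BASELINE_PENETRANCE
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.threshold is None or self.p1 is None:
            raise ModelConfigurationError("threshold and p1 are required")
        _check_pen(self.p1, "elevated penetrance p1")
        _check_pen(self.f0, "baseline penetrance f0")
        if self.p1 <= self.f0:
            raise ModelConfigurationError("p1 must exceed f0")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64).ravel()
            if w.shape != self.q.shape or (w <= 0).any():
                raise ModelConfigurationError("weights must be positive per SNP")
            object.__setattr__(self, "weights", w)

    @property
    def variant(self) -> str:
        return "lplm" if self.weights is None else "weighted_lplm"

    @classmethod
    def calibrated(
        cls,
        n_snps: int,
        p1: float,
        q: float | Sequence[float] = 0.5,
        f0: float = BASELINE_PENETRANCE,
        target_tail: float = LPLM_TARGET_TAIL,
        weights: Sequence[float] | None = None,
    ) -> "LplmModel":
        """LPLM with the threshold calibrated to the population tail target."""
        qv = np.full(n_snps, q, dtype=np.float64) if np.isscalar(q) else np.asarray(q)
        cal = calibrate_lplm_threshold(qv, weights, target_tail)
        return cls(q=qv, threshold=cal.threshold, p1=p1, f0=f0, weights=weights)

    def _w(self) -> np.ndarray:
        return self.weights if self.weights is not None else np.ones(self.n_snps)

    def raw_penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        genotypes = np.atleast_2d(np.asarray(genotypes, dtype=np.float64))
        load = genotypes @ self._w()
        return np.where(load >= self.threshold - 1e-9, self.p1, self.f0)

    def population_tail(self) -> float:
        support, probs = load_distribution(self.q, self._w())
        return float(probs[support >= self.threshold - 1e-9].sum())

    def prevalence(self) -> float:
        tail = self.population_tail()
        return float(self.f0 + (self.p1 - self.f0) * tail)

    def _p_disease_given_allele(self, i: int, risk: bool) -> float:
        w = self._w()
        support, probs = load_distribution(
            np.delete(self.q, i), np.delete(w, i)
        )
        qi, wi = self.q[i], w[i]
        own = [(1.0, 1 - qi), (2.0, qi)] if risk else [(0.0, 1 - qi), (1.0, qi)]
        tail = 0.0
        for c, pc in own:
            tail += pc * probs[support >= self.threshold - wi * c - 1e-9].sum()
        return float(self.f0 + (self.p1 - self.f0) * tail)


@dataclass(frozen=True)
class RecessiveModel(_ModelBase):
    """3-SNP completely recessive model: elevated penetrance only when all
    three SNPs are homozygous for the risk allele."""

    high_penetrance: float = None  # type: ignore[assignment]
    f0: float = BASELINE_PENETRANCE

    variant = "recessive"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_snps != 3:
            raise ModelConfigurationError("recessive model is defined by 3 SNPs")
        _check_pen(self.high_penetrance, "high-risk genotype penetrance")
        _check_pen(self.f0, "baseline penetrance f0")
        if self.high_penetrance <= self.f0:
            raise ModelConfigurationError("high penetrance must exceed f0")

    # Published presets: frequencies / triple-homozygote penetrance
    @classmethod
    def rez_a(cls) -> "RecessiveModel":
        return cls(q=np.array([0.2, 0.5, 0.8]), high_penetrance=0.20)

    @classmethod
    def rez_b(cls) -> "RecessiveModel":
        return cls(q=np.array([0.2, 0.3, 0.4]), high_penetrance=0.70)

    @classmethod
    def rez_c(cls) -> "RecessiveModel":
        return cls(q=np.array([0.4, 0.5, 0.6]), high_penetrance=0.10)

    @classmethod
    def rez_d(cls) -> "RecessiveModel":
        return cls(q=np.array([0.6, 0.7, 0.8]), high_penetrance=0.05)

    def raw_penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        genotypes = np.atleast_2d(np.asarray(genotypes, dtype=np.float64))
        all_hom = (genotypes > 1.5).all(axis=1)
        return np.where(all_hom, self.high_penetrance, self.f0)

    def prevalence(self) -> float:
        p_hom = float(np.prod(self.q**2))
        return float(self.f0 + p_hom * (self.high_penetrance - self.f0))

    def _p_disease_given_allele(self, i: int, risk: bool) -> float:
        if not risk:
            return float(self.f0)
        others = float(np.prod(np.delete(self.q, i) ** 2))
        return float(
            self.f0 + self.q[i] * others * (self.high_penetrance - self.f0)
        )


PenetranceModel = (
    MultiplicativeModel
    | DominanceSemiNullModel
    | PairwiseSemiNullModel
    | LplmModel
    | RecessiveModel
)


def penetrance(model, genotype_row: np.ndarray) -> np.ndarray | float:
    """Disease probability for one genotype row (or a stack of rows)."""
    arr = np.asarray(genotype_row, dtype=np.float64)
    if arr.ndim == 1:
        if arr.size != model.n_snps:
            raise ValueError("genotype length does not match model")
        return float(model.penetrance(arr[None, :])[0])
    if arr.shape[1] != model.n_snps:
        raise ValueError("genotype width does not match model")
    return model.penetrance(arr)


@dataclass(frozen=True)
class MarginalEffect:
    relative_risk: float
    odds_ratio: float


def marginal_allelic_effect(model, snp_index: int) -> MarginalEffect:
    """Exact marginal effect of one risk allele under HWE enumeration.

    Conditions a randomly drawn allele at the SNP on being the risk or the
    non-risk allele (the other allele and all other SNPs follow HWE) and
    compares disease probabilities.  Both the allele-exposure relative risk
    and the allelic odds ratio are returned; published ranges sit between
    the two definitions.
    """
    if not 0 <= snp_index < model.n_snps:
        raise ValueError("snp_index out of range")
    p_risk = model._p_disease_given_allele(snp_index, True)
    p_non = model._p_disease_given_allele(snp_index, False)
    rr = p_risk / p_non
    odds = (p_risk / (1 - p_risk)) / (p_non / (1 - p_non))
    return MarginalEffect(relative_risk=float(rr), odds_ratio=float(odds))


# ---------------------------------------------------------------------------
# sampling


def draw_population_genotypes(
    q: Sequence[float],
    n_individuals: int,
    seed,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: counts ~ Binomial(2, q_i), independent across SNPs."""
    q = _validate_freqs(np.asarray(q))
    rng = _rng(seed)
    vals = _draw_hwe(rng, q, int(n_individuals))
    ids = tuple(snp_ids) if snp_ids is not None else _snp_ids(q.size)
    return GenotypeMatrix(values=vals, snp_ids=ids, oriented=True)


@dataclass(frozen=True)
class SimReplicate:
    """One simulated case-control dataset with its generating model."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    spec: RiskAlleleSpec
    model: object
    seed: object
    proxies: GenotypeMatrix | None = None
    prevalence: float = float("nan")
    capped_fraction: float = 0.0
    n_drawn: int = 0

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())


def sample_case_control(
    model, n_cases: int, n_controls: int, seed
) -> SimReplicate:
    """Rejection-sample a case-control dataset under the penetrance model.

    Genotypes are drawn from the HWE population, disease status is
    Bernoulli(penetrance), and drawing continues until both quotas are
    filled exactly.  Models whose multiplicative penetrance exceeds 1 for
    more than 0.1% of the drawn population are rejected as misconfigured.
    """
    rng = _rng(seed)
    prev = model.prevalence()
    if not 0.0 < prev < 1.0:
        raise ModelConfigurationError("population prevalence outside (0, 1)")
    if prev < MIN_PREVALENCE:
        raise ModelConfigurationError(
            f"prevalence {prev:.2e} below {MIN_PREVALENCE}; rejection sampling "
            "would be impractical -- use an enriched sampling scheme"
        )
    q = model.q
    need_cases, need_controls = int(n_cases), int(n_controls)
    cases, controls = [], []
    n_drawn = 0
    n_capped = 0
    while need_cases > 0 or need_controls > 0:
        expect = max(
            need_cases / prev if need_cases > 0 else 0.0,
            need_controls / (1.0 - prev) if need_controls > 0 else 0.0,
        )
        chunk = int(min(max(2000, 1.1 * expect), 400_000))
        g = _draw_hwe(rng, q, chunk)
        raw = model.raw_penetrance(g)
        n_capped += int((raw > 1.0).sum())
        pen = np.minimum(raw, 1.0)
        n_drawn += chunk
        sick = rng.random(chunk) < pen
        if need_cases > 0:
            take = g[sick][:need_cases]
            cases.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = g[~sick][:need_controls]
            controls.append(take)
            need_controls -= take.shape[0]
    capped_fraction = n_capped / n_drawn
    if capped_fraction > MAX_CAP_FRACTION:
        raise ModelConfigurationError(
            f"penetrance capped at 1 for {capped_fraction:.2%} of the "
            "population; model configuration rejected"
        )
    vals = np.vstack(cases + controls)
    y = np.concatenate(
        [np.ones(int(n_cases)), np.zeros(int(n_controls))]
    )
    ids = model.snp_ids
    sample_ids = tuple(
        [f"case{i+1:05d}" for i in range(int(n_cases))]
        + [f"ctrl{i+1:05d}" for i in range(int(n_controls))]
    )
    G = GenotypeMatrix(values=vals, snp_ids=ids, sample_ids=sample_ids)
    return SimReplicate(
        genotypes=G,
        phenotype=y,
        spec=model.risk_spec(),
        model=model,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        prevalence=prev,
        capped_fraction=capped_fraction,
        n_drawn=n_drawn,
    )


# ---------------------------------------------------------------------------
# LD tagging


@dataclass(frozen=True)
class TaggingConfig:
    """Proxy-marker specification: target r-squared and proxy frequencies."""

    r2: float
    proxy_freqs: np.ndarray | None = None  # default: equal to causal

    def __post_init__(self) -> None:
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError("r2 must lie in (0, 1]")
        if self.proxy_freqs is not None:
            object.__setattr__(
                self, "proxy_freqs", _validate_freqs(self.proxy_freqs)
            )


def make_tagged_proxies(
    G_causal: GenotypeMatrix,
    q: Sequence[float],
    config: TaggingConfig | float,
    seed,
) -> GenotypeMatrix:
    """Proxy genotypes in LD with the causal SNPs at the requested r-squared.

    Per SNP a two-locus haplotype distribution with correlation sqrt(r2) is
    built and proxy alleles are sampled conditional on each causal allele.
    The empirical genotype-count r-squared converges to the target as the
    sample grows.
    """
    if not isinstance(config, TaggingConfig):
        config = TaggingConfig(r2=float(config))
    q = _validate_freqs(np.asarray(q))
    if q.size != G_causal.n_snps:
        raise ValueError("frequency vector does not match genotype matrix")
    qp = config.proxy_freqs if config.proxy_freqs is not None else q
    if qp.size != q.size:
        raise ValueError("proxy frequency vector has wrong length")
    rng = _rng(seed)
    r = math.sqrt(config.r2)
    counts = np.rint(G_causal.values).astype(np.intp)
    out = np.empty_like(G_causal.values)
    for j in range(q.size):
        qc, qpj = q[j], qp[j]
        d_max = min(qc * (1 - qpj), qpj * (1 - qc))
        r_max = d_max / math.sqrt(qc * (1 - qc) * qpj * (1 - qpj))
        if r > r_max + 1e-12:
            raise ValueError(
                f"requested r2 {config.r2:.3f} infeasible for frequencies "
                f"({qc:.3f}, {qpj:.3f}); maximum achievable r2 is {r_max**2:.3f}"
            )
        d = r * math.sqrt(qc * (1 - qc) * qpj * (1 - qpj))
        p_given_risk = (qc * qpj + d) / qc
        p_given_non = ((1 - qc) * qpj - d) / (1 - qc)
        g = counts[:, j]
        out[:, j] = rng.binomial(g, p_given_risk) + rng.binomial(
            2 - g, p_given_non
        )
    return GenotypeMatrix(
        values=out,
        snp_ids=tuple(f"{s}_proxy" for s in G_causal.snp_ids),
        sample_ids=G_causal.sample_ids,
        oriented=True,
    )


# ---------------------------------------------------------------------------
# config-driven construction (CLI / study configs)


def model_from_config(cfg: dict) -> "PenetranceModel | Callable":
    """Build a model (or per-replicate model factory) from a plain dict.

    ``variant`` selects the model family.  Families whose parameters are
    redrawn per replicate (null and semi-null models) return a callable
    ``rng -> model``; fully specified families return an instance.
    """
    cfg = dict(cfg)
    variant = cfg.pop("variant")
    if variant in ("rez-a", "rez_a"):
        return RecessiveModel.rez_a()
    if variant in ("rez-b", "rez_b"):
        return RecessiveModel.rez_b()
    if variant in ("rez-c", "rez_c"):
        return RecessiveModel.rez_c()
    if variant in ("rez-d", "rez_d"):
        return RecessiveModel.rez_d()
    if variant == "recessive":
        return RecessiveModel(
            q=np.asarray(cfg["q"]),
            high_penetrance=cfg["high_penetrance"],
            f0=cfg.get("f0", BASELINE_PENETRANCE),
        )
    if variant in ("null", "multiplicative"):
        n = int(cfg["n_snps"])
        kwargs = {
            k: cfg[k]
            for k in ("rr_range", "freq_range", "prevalence", "scale")
            if k in cfg
        }
        return lambda rng: MultiplicativeModel.draw_null(n, rng, **kwargs)
    if variant in ("b1", "dominance_semi_null"):
        kwargs = {
            k: cfg[k]
            for k in ("n_snps", "n_recessive", "hom_rr", "prevalence", "scale")
            if k in cfg
        }
        return lambda rng: DominanceSemiNullModel.draw(rng, **kwargs)
    if variant in ("b2", "pairwise_semi_null"):
        kwargs = {
            k: cfg[k]
            for k in ("n_snps", "n_pairs", "pair_rr", "prevalence", "scale")
            if k in cfg
        }
        return lambda rng: PairwiseSemiNullModel.draw(rng, **kwargs)
    if variant in ("lplm", "wlplm", "weighted_lplm"):
        n = int(cfg["n_snps"])
        weights = cfg.get("weights")
        if variant != "lplm" and weights is None:
            weights = assign_modified_weights(n)
        return LplmModel.calibrated(
            n_snps=n,
            p1=float(cfg["p1"]),
            q=cfg.get("q", 0.5),
            f0=cfg.get("f0", BASELINE_PENETRANCE),
            target_tail=cfg.get("target_tail", LPLM_TARGET_TAIL),
            weights=weights,
        )
    raise ValueError(f"unknown model variant {variant!r}")
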