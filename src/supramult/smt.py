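"""The supra-multiplicativity test (SMT) and its threshold-profile diagnostics.

The SMT asks whether the joint disease risk of a pre-specified set of n risk
alleles exceeds what their marginal (multiplicative) effects predict.  For an
individual j let L_j be the (optionally weighted) count of externally
designated risk alleles across the set.  For every load cut-off T with
individuals on both sides, a logistic model

    logit P(case) = mu + sum_i beta_i x_ij                    (null)
    logit P(case) = mu + sum_i beta_i x_ij + pi * I(L_j >= T) (alternative)

is fitted and the indicator coefficient pi is tested with one degree of
freedom.  Because the best cut-off is unknown a priori, all v valid cut-offs
are scanned and the final p-value is Bonferroni corrected:
p_final = min(1, v * min_T p_T).  The scan of pi-hat against T (the
"threshold profile") is itself diagnostic: under a limiting-pathway
liability model it peaks sharply at the generating threshold.

Risk-allele orientation is always external: the caller supplies a
:class:`RiskAlleleSpec` naming each SNP's risk allele (and optional weight),
and genotype counts are flipped to count that allele before the load is
formed.  Deriving orientation from the analysed data itself would bias the
load and is deliberately not done here (a drafting utility in
:mod:`supramult.io` marks its output as data-derived).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.stats import chi2

from .regression import (
    CollinearityError,
    DesignMatrix,
    _collinear_columns,
    _irls,
    _is_separated,
    _validate_phenotype,
    fit_logistic,
)

__all__ = [
    "GenotypeMatrix",
    "RiskAlleleSpec",
    "SMTResult",
    "ThresholdProfile",
    "adjusted_smt",
    "compute_allele_load",
    "orient_to_risk_alleles",
    "smt_test",
    "threshold_profile",
    "valid_thresholds",
]

MAX_SET_SIZE = 500

#: columns of the threshold-profile table, mirroring the published layout
PROFILE_COLUMNS = (
    "threshold",
    "p_value",
    "pi",
    "se_pi",
    "odds_ratio",
    "se_log_or",
    "freq_cases",
    "freq_controls",
    "flags",
)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Genotypes of a SNP set, one row per individual, one column per SNP.

    ``values`` are allele counts in [0, 2] (hard calls) or expected counts
    (dosage mode).  When ``oriented`` is True the counts already count each
    SNP's designated risk allele; otherwise ``counted_alleles`` records, per
    SNP, the (counted, other) allele pair so that orientation against a
    :class:`RiskAlleleSpec` is decidable.
    """

    values: np.ndarray
    snp_ids: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None
    counted_alleles: tuple[tuple[str, str], ...] | None = None
    oriented: bool = True
    dosage: bool = False

    def __post_init__(self) -> None:
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        if vals.ndim != 2:
            raise ValueError("genotype values must be a 2-d array")
        if vals.shape[1] != len(self.snp_ids):
            raise ValueError("number of SNP ids does not match matrix width")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP ids must be unique")
        if vals.shape[1] < 2:
            raise ValueError("a SNP set needs at least 2 SNPs")
        if not np.isfinite(vals).all():
            raise ValueError("genotype matrix contains missing/non-finite values")
        if vals.min() < -1e-9 or vals.max() > 2.0 + 1e-9:
            raise ValueError("genotype counts must lie in [0, 2]")
        if self.sample_ids is not None:
            sids = tuple(str(s) for s in self.sample_ids)
            object.__setattr__(self, "sample_ids", sids)
            if len(sids) != vals.shape[0]:
                raise ValueError("number of sample ids does not match rows")
            if len(set(sids)) != len(sids):
                raise ValueError("duplicate sample ids")
        if self.counted_alleles is not None and len(self.counted_alleles) != len(
            self.snp_ids
        ):
            raise ValueError("counted_alleles must cover every SNP")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset(self, k: int) -> "GenotypeMatrix":
        """First-k-SNPs view (set order defines 'first')."""
        if not 2 <= k <= self.n_snps:
            raise ValueError(f"subset size {k} outside [2, {self.n_snps}]")
        return replace(
            self,
            values=self.values[:, :k],
            snp_ids=self.snp_ids[:k],
            counted_alleles=None
            if self.counted_alleles is None
            else self.counted_alleles[:k],
        )


@dataclass(frozen=True)
class RiskAlleleSpec:
    """External designation of each SNP's risk allele and load weight."""

    snp_ids: tuple[str, ...]
    risk_alleles: tuple[str, ...]
    weights: tuple[float, ...]
    data_derived: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        object.__setattr__(
            self, "risk_alleles", tuple(str(a) for a in self.risk_alleles)
        )
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP in risk-allele spec")
        if not (len(self.snp_ids) == len(self.risk_alleles) == len(self.weights)):
            raise ValueError("spec fields must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("risk-allele weights must be positive")

    @classmethod
    def from_lists(
        cls,
        snp_ids: Sequence[str],
        risk_alleles: Sequence[str],
        weights: Sequence[float] | None = None,
    ) -> "RiskAlleleSpec":
        if weights is None:
            weights = [1.0] * len(snp_ids)
        return cls(tuple(snp_ids), tuple(risk_alleles), tuple(weights))

    def _index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}

    def risk_allele_of(self, snp: str) -> str:
        return self.risk_alleles[self._index()[snp]]

    def weight_of(self, snp: str) -> float:
        return self.weights[self._index()[snp]]

    def weights_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        idx = self._index()
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(
                "SNPs missing from risk-allele spec: " + ", ".join(missing)
            )
        return np.array([self.weights[idx[s]] for s in snp_ids], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "risk_allele": self.risk_alleles,
                "weight": self.weights,
            }
        )


def orient_to_risk_alleles(G: GenotypeMatrix, spec: RiskAlleleSpec) -> GenotypeMatrix:
    """Flip genotype counts so that every column counts the spec's risk allele.

    Idempotent: an already-oriented matrix is returned unchanged.
    """
    if G.oriented:
        return G
    if G.counted_alleles is None:
        raise ValueError(
            "cannot orient: genotype matrix carries no allele labels"
        )
    vals = G.values.copy()
    for j, snp in enumerate(G.snp_ids):
        counted, other = G.counted_alleles[j]
        try:
            risk = spec.risk_allele_of(snp)
        except KeyError:
            raise KeyError(f"SNP {snp} absent from risk-allele spec") from None
        if risk == counted:
            continue
        if risk == other:
            vals[:, j] = 2.0 - vals[:, j]
        else:
            raise ValueError(
                f"risk allele {risk} of SNP {snp} is not among its alleles "
                f"({counted}, {other})"
            )
    return replace(G, values=vals, oriented=True)


def compute_allele_load(G: GenotypeMatrix, spec: RiskAlleleSpec) -> np.ndarray:
    """Per-individual weighted risk-allele load L_j = sum_i w_i * x_ij.

    Counts are oriented to the spec's risk alleles first (flipping
    2 - count where the file-encoded counted allele is the non-risk one).
    With unit weights the load is an integer in [0, 2n].
    """
    G = orient_to_risk_alleles(G, spec)
    w = spec.weights_for(G.snp_ids)
    return G.values @ w


def valid_thresholds(L: np.ndarray) -> np.ndarray:
    """Load cut-offs T with individuals on both sides (L >= T and L < T).

    These are the distinct observed load values excluding the minimum, so
    each distinct above/below split is tested exactly once; for integer
    loads with a densely observed range this is {min(L)+1, ..., max(L)}.
    An all-equal load vector yields an empty list (degenerate scan).
    """
    L = np.asarray(L, dtype=np.float64).ravel()
    if L.size == 0:
        raise ValueError("empty load vector")
    uniq = np.unique(L)
    return uniq[1:]


@dataclass(frozen=True)
class ThresholdProfile:
    """Per-threshold scan results: pi-hat, se, p, 2x2 odds ratio, frequencies."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in PROFILE_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"profile missing column {col}")
        t = self.data["threshold"].to_numpy()
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("profile thresholds must be strictly increasing")

    @property
    def thresholds(self) -> np.ndarray:
        return self.data["threshold"].to_numpy()

    def peak_threshold(self) -> float:
        """Threshold with the largest estimable indicator estimate pi-hat.

        Thresholds whose indicator separated (coefficient unbounded, standard
        error infinite) carry no usable effect estimate and are skipped.
        """
        usable = self.data[np.isfinite(self.data["se_pi"])]
        if usable.empty:
            raise ValueError("no estimable thresholds in profile")
        return float(usable.loc[usable["pi"].idxmax(), "threshold"])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class SMTResult:
    """Outcome of the Bonferroni-corrected threshold scan."""

    profile: ThresholdProfile
    v: int
    best_threshold: float | None
    p_final: float
    flags: tuple[str, ...] = ()

    @property
    def min_p(self) -> float:
        if self.profile.data.empty:
            return 1.0
        return float(self.profile.data["p_value"].min())

    def summary_dict(self) -> dict:
        return {
            "v": self.v,
            "best_threshold": self.best_threshold,
            "min_p": self.min_p,
            "p_final": self.p_final,
            "flags": list(self.flags),
        }


def _two_by_two(above: np.ndarray, case_mask: np.ndarray):
    """Odds ratio (cases-above * controls-below) / (cases-below * controls-above).

    Zero cells get the Haldane-Anscombe 0.5 continuity correction, flagged.
    """
    a = float(np.sum(above & case_mask))        # cases above
    b = float(np.sum(~above & case_mask))       # cases below
    c = float(np.sum(above & ~case_mask))       # controls above
    d = float(np.sum(~above & ~case_mask))      # controls below
    flag = ""
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flag = "haldane"
    or_ = (a * d) / (b * c)
    se_log_or = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return or_, se_log_or, flag


def smt_test(
    G: GenotypeMatrix,
    y: np.ndarray,
    spec: RiskAlleleSpec,
    extra_covariates: Mapping[str, np.ndarray] | None = None,
    inference: str = "lrt",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SMTResult:
    """Run the supra-multiplicativity test on a SNP set.

    For each valid load cut-off T the model with the marginal SNP effects
    (plus any extra covariates) is compared against the same model augmented
    with the indicator I(L >= T); the minimum 1-d.f. p-value over the scan
    is Bonferroni corrected by the number of valid cut-offs v.

    Parameters
    ----------
    G, y, spec : genotype set, 0/1 phenotype, external risk-allele spec
    extra_covariates : optional mapping label -> column added to *both*
        the null and the alternative model
    inference : "lrt" (default) for the likelihood-ratio p per threshold,
        or "wald" for the Wald p of the indicator coefficient
    """
    if inference not in ("lrt", "wald"):
        raise ValueError("inference must be 'lrt' or 'wald'")
    if G.n_snps > MAX_SET_SIZE:
        raise ValueError(f"SNP set larger than supported maximum {MAX_SET_SIZE}")
    G = orient_to_risk_alleles(G, spec)
    yv = _validate_phenotype(y, G.n_individuals)
    L = compute_allele_load(G, spec)

    thresholds = valid_thresholds(L)
    if thresholds.size == 0:
        warnings.warn(
            "all individuals have identical allele load; no valid thresholds",
            stacklevel=2,
        )
        empty = pd.DataFrame({c: [] for c in PROFILE_COLUMNS})
        return SMTResult(
            profile=ThresholdProfile(empty),
            v=0,
            best_threshold=None,
            p_final=1.0,
            flags=("no_valid_thresholds",),
        )

    cols: dict[str, np.ndarray] = {s: G.values[:, j] for j, s in enumerate(G.snp_ids)}
    if extra_covariates:
        for label, col in extra_covariates.items():
            if label in cols:
                raise ValueError(f"duplicate covariate label {label}")
            cols[label] = np.asarray(col, dtype=np.float64)
    X_null = DesignMatrix.from_columns(G.n_individuals, cols)
    null_fit = fit_logistic(X_null, yv, max_iter=max_iter, tol=tol)

    n, p_null = X_null.values.shape
    X_alt = np.empty((n, p_null + 1), dtype=np.float64)
    X_alt[:, :p_null] = X_null.values
    beta0 = np.append(null_fit.coefficients, 0.0)
    case_mask = yv == 1.0
    ll_null = null_fit.log_likelihood

    rows = []
    for T in thresholds:
        above = L >= T
        X_alt[:, -1] = above
        beta, ll, chol, converged, singular = _irls(X_alt, yv, beta0, max_iter, tol)
        flags_t: list[str] = []
        if singular:
            labels = X_null.columns + (f"I(L>={T:g})",)
            bad = _collinear_columns(X_alt, labels)
            if bad:
                raise CollinearityError(bad, prefix=f"threshold {T:g}: ")
            separated = True  # singular weights without rank loss: saturation
        else:
            separated = _is_separated(X_alt, beta)
        pi_hat = float(beta[-1])
        if chol is not None:
            e = np.zeros(p_null + 1)
            e[-1] = 1.0
            var = float(cho_solve(chol, e, check_finite=False)[-1])
            se_pi = float(np.sqrt(var)) if var > 0 else np.inf
        else:
            se_pi = np.inf
        if separated:
            # the indicator MLE is unbounded but the likelihood supremum is
            # finite, so the LRT stays well-defined; the estimate/se do not
            flags_t.append("separated")
            se_pi = np.inf
        elif not converged:
            flags_t.append("not_converged")
        if inference == "lrt":
            stat = max(0.0, 2.0 * (ll - ll_null))
            p_unc = float(chi2.sf(stat, 1))
        elif separated or not (np.isfinite(se_pi) and se_pi > 0):
            p_unc = 1.0  # no trustworthy Wald statistic at this threshold
            if not separated:
                flags_t.append("unreliable_wald")
        else:
            p_unc = float(chi2.sf((pi_hat / se_pi) ** 2, 1))
        or_, se_log_or, haldane = _two_by_two(above, case_mask)
        if haldane:
            flags_t.append(haldane)
        rows.append(
            {
                "threshold": float(T),
                "p_value": p_unc,
                "pi": pi_hat,
                "se_pi": se_pi,
                "odds_ratio": or_,
                "se_log_or": se_log_or,
                "freq_cases": float(np.mean(above[case_mask])),
                "freq_controls": float(np.mean(above[~case_mask])),
                "flags": ";".join(flags_t),
            }
        )

    profile = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    v = int(thresholds.size)
    min_p = float(profile["p_value"].min())
    best = float(profile.loc[profile["p_value"].idxmin(), "threshold"])
    # idxmin returns the first minimum; thresholds ascend, so ties break small
    p_final = min(1.0, v * min_p)
    return SMTResult(
        profile=ThresholdProfile(profile),
        v=v,
        best_threshold=best,
        p_final=p_final,
    )


def threshold_profile(
    G: GenotypeMatrix,
    y: np.ndarray,
    spec: RiskAlleleSpec,
    extra_covariates: Mapping[str, np.ndarray] | None = None,
    **kwargs,
) -> ThresholdProfile:
    """Per-threshold diagnostics (pi-hat curve, 2x2 odds ratios) of the scan."""
    return smt_test(G, y, spec, extra_covariates=extra_covariates, **kwargs).profile


def _heterozygote(col: np.ndarray) -> np.ndarray:
    return (np.abs(col - 1.0) < 1e-9).astype(np.float64)


def adjusted_smt(
    G: GenotypeMatrix,
    y: np.ndarray,
    spec: RiskAlleleSpec,
    dominance_snps: Sequence[str] = (),
    interaction_pairs: Sequence[tuple[str, str]] = (),
    interaction_triples: Sequence[tuple[str, str, str]] = (),
    pair_mode: str = "genotypic",
    extra_covariates: Mapping[str, np.ndarray] | None = None,
    **kwargs,
) -> SMTResult:
    """SMT adjusted for known dominance / low-order interaction terms.

    Confirmed dominance deviations or k-way interactions inflate the plain
    SMT level; adding them as covariates to both the null and alternative
    model restores it, so that a significant result can be attributed to
    interaction beyond the adjusted-for terms.

    ``pair_mode`` controls the pair covariates: "allelic" adds the single
    additive-product term per pair; "genotypic" (default) additionally adds
    the pair members' dominance terms and all four {additive, dominance}
    cross products, spanning the full 3x3 genotype table of the pair.
    Triples contribute their allelic three-way product.
    """
    if pair_mode not in ("allelic", "genotypic"):
        raise ValueError("pair_mode must be 'allelic' or 'genotypic'")
    G = orient_to_risk_alleles(G, spec)
    idx = {s: j for j, s in enumerate(G.snp_ids)}

    def column(snp: str) -> np.ndarray:
        if snp not in idx:
            raise KeyError(f"SNP {snp} not in the analysed set")
        return G.values[:, idx[snp]]

    if len(set(dominance_snps)) != len(tuple(dominance_snps)):
        raise ValueError("duplicate SNP in dominance adjustment list")
    pairs = [tuple(sorted(p)) for p in interaction_pairs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate pair in interaction adjustment list")
    triples = [tuple(sorted(t)) for t in interaction_triples]
    if len(set(triples)) != len(triples):
        raise ValueError("duplicate triple in interaction adjustment list")

    cov: dict[str, np.ndarray] = {}

    def add_dominance(snp: str) -> None:
        label = f"dom:{snp}"
        if label not in cov:
            cov[label] = _heterozygote(column(snp))

    for snp in dominance_snps:
        add_dominance(snp)
    for s1, s2 in pairs:
        a1, a2 = column(s1), column(s2)
        cov[f"int:{s1}*{s2}"] = a1 * a2
        if pair_mode == "genotypic":
            add_dominance(s1)
            add_dominance(s2)
            d1, d2 = _heterozygote(a1), _heterozygote(a2)
            cov[f"int:{s1}*dom:{s2}"] = a1 * d2
            cov[f"int:dom:{s1}*{s2}"] = d1 * a2
            cov[f"int:dom:{s1}*dom:{s2}"] = d1 * d2
    for s1, s2, s3 in triples:
        cov[f"int:{s1}*{s2}*{s3}"] = column(s1) * column(s2) * column(s3)

    if extra_covariates:
        for label, colv in extra_covariates.items():
            if label in cov:
                raise ValueError(f"duplicate covariate label {label}")
            cov[label] = np.asarray(colv, dtype=np.float64)

    # empty genotype cells can make a saturated pair adjustment collinear
    # with the main effects; drop the dependent adjustment columns (the
    # corresponding cells carry no individuals, so nothing is adjusted away)
    base = [("intercept", np.ones(G.n_individuals))]
    base += [(s, G.values[:, j]) for j, s in enumerate(G.snp_ids)]
    kept: dict[str, np.ndarray] = {}
    basis: list[np.ndarray] = []
    for _lab, col in base:
        r = col.astype(np.float64).copy()
        for qvec in basis:
            r -= (qvec @ r) * qvec
        if np.linalg.norm(r) > 1e-9:
            basis.append(r / np.linalg.norm(r))
    for lab, col in cov.items():
        r = col.astype(np.float64).copy()
        norm0 = np.linalg.norm(r)
        for qvec in basis:
            r -= (qvec @ r) * qvec
        if norm0 > 0 and np.linalg.norm(r) > 1e-8 * norm0:
            basis.append(r / np.linalg.norm(r))
            kept[lab] = col

    return smt_test(G, y, spec, extra_covariates=kept, **kwargs)
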