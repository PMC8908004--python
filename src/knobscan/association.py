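"""Single-locus mixed linear model scan over the knob panel.

Fits y = S a + P b + g + e per marker, where S holds the marker code
(additive minor-allele dose or heterozygote indicator), P the population
structure covariates (principal components and, by default in mixed panels,
the line/hybrid contrast), and g ~ N(0, K sigma_g^2) the polygenic effect
with a marker-derived genomic relationship matrix K. Variance components are
estimated by REML (exactly per marker by default, or once on the null model),
and each marker is tested with a Wald t statistic on n - p residual degrees
of freedom — appropriate for panels of a few dozen entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import RotatedDesign, _reml_loglik, gls_last_coef, optimize_delta
from .genotypes import (
    EncodedMatrix,
    KnobMatrix,
    encode_additive,
    encode_dominance,
    heterozygote_frequency,
    minor_allele_frequency,
)
from .phenotypes import EntryMeans, VarianceComponents
from .simulate import PanelEntry

__all__ = [
    "AssociationModelSpec", "KinshipMatrix", "AssociationResult",
    "compute_kinship", "compute_pcs", "fit_null_mlm", "test_marker",
    "run_scan",
]

_TINY_P = 5e-324  # smallest positive subnormal; p-values stay in (0, 1]


@dataclass(frozen=True)
class AssociationModelSpec:
    """Configuration of one scan.

    ``group_covariate`` adds the line/hybrid indicator as a fixed structure
    covariate whenever the panel mixes both entry types; without it the
    heterozygote indicator of the dominance model is confounded with
    heterosis (only hybrids can be heterozygous).
    """

    encoding: str = "additive"  # or "dominance"
    n_pcs: int = 0
    kinship_mode: str = "vanraden"  # or "identity"
    vc_mode: str = "per_marker_exact"  # or "null_once"
    group_covariate: bool = True

    def __post_init__(self) -> None:
        if self.encoding not in ("additive", "dominance"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.kinship_mode not in ("vanraden", "identity"):
            raise ValueError(f"unknown kinship_mode {self.kinship_mode!r}")
        if self.vc_mode not in ("per_marker_exact", "null_once"):
            raise ValueError(f"unknown vc_mode {self.vc_mode!r}")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")


@dataclass(frozen=True)
class KinshipMatrix:
    entries: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.entries),) * 2:
            raise ValueError("kinship must be square over the entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


@dataclass(frozen=True)
class AssociationResult:
    locus_id: str
    chromosome: int
    arm: str
    encoding: str
    trait: str
    maf: float
    effect: float
    se: float
    p_value: float
    marker_h2: float
    significant: bool | None = None


def compute_kinship(m: KnobMatrix, ridge_scale: float = 1e-6) -> KinshipMatrix:
    """VanRaden genomic relationship from the knob count matrix.

    G = Z Z' / (2 sum p_k (1 - p_k)) with Z the column-centred counts and p_k
    the presence-allele frequency. A ridge of ``ridge_scale`` times the mean
    diagonal guarantees positive semi-definiteness in degenerate panels.
    """
    counts = m.counts.astype(float)
    p = counts.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic; kinship undefined")
    Z = counts - 2.0 * p
    denom = 2.0 * float((p * (1.0 - p)).sum())
    G = Z @ Z.T / denom
    G = G + ridge_scale * float(np.diag(G).mean()) * np.eye(G.shape[0])
    return KinshipMatrix(list(m.entries), G)


def compute_pcs(m: KnobMatrix, n_pcs: int) -> np.ndarray:
    """Principal-component scores of the centred count matrix.

    Deterministic up to sign; signs are fixed by making the largest-magnitude
    locus loading of each component positive.
    """
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    Z = m.counts.astype(float)
    Z = Z - Z.mean(axis=0)
    if n_pcs == 0:
        return np.empty((Z.shape[0], 0))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds genotype matrix rank {rank}")
    scores = U[:, :n_pcs] * s[:n_pcs]
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    return scores


def _eigen_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-8 * max(1.0, abs(d.max())):
        raise ValueError(
            f"kinship is not positive semi-definite (min eigenvalue {d.min():.3e})"
        )
    if np.ptp(d) < 1e-8 * max(1.0, abs(d.max())):
        warnings.warn(
            "kinship is (a multiple of) the identity: the REML likelihood is "
            "flat in the variance ratio; only the total variance is "
            "identifiable", stacklevel=3,
        )
    return np.clip(d, 0.0, None), U


def _check_design(n: int, X: np.ndarray) -> None:
    p = X.shape[1]
    if n <= p + 2:
        raise ValueError(f"{n} entries cannot support {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")


def fit_null_mlm(
    y: np.ndarray, covariates: np.ndarray | None, K: np.ndarray
) -> tuple[VarianceComponents, float]:
    """REML variance components of the no-marker model.

    Returns the components and the profiled REML log-likelihood at the
    optimum of the variance ratio sigma_g^2 / sigma_e^2.
    """
    y = np.asarray(y, float)
    X = _with_intercept(len(y), covariates)
    _check_design(len(y), X)
    d, U = _eigen_kinship(np.asarray(K, float))
    rot = RotatedDesign(eigvals=d, U=U, X=U.T @ X)
    yr = U.T @ y
    delta = optimize_delta(yr[:, None], rot)
    ll = float(_reml_loglik(yr[:, None], rot.X, rot.eigvals, delta)[0])
    _, _, s2e, s2g, _ = gls_last_coef(yr[:, None], rot, delta)
    return VarianceComponents(float(s2g[0]), float(s2e[0]), float("nan")), ll


def _with_intercept(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X = np.column_stack([X, np.asarray(covariates, float)])
    return X


def _marker_stats(
    Y: np.ndarray, X_base: np.ndarray, code: np.ndarray,
    d: np.ndarray, U: np.ndarray,
    delta_fixed: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Effect, SE and two-sided p for one marker, vectorised over columns of Y.

    ``delta_fixed`` pins the variance ratio (null-once / external components);
    None re-estimates it per response column with the marker in the model.
    """
    X = np.column_stack([X_base, code.astype(float)])
    rot = RotatedDesign(eigvals=d, U=U, X=U.T @ X)
    Yr = U.T @ Y
    if delta_fixed is None:
        delta = optimize_delta(Yr, rot)
    else:
        delta = np.broadcast_to(np.atleast_1d(delta_fixed), (Y.shape[1],))
    beta, se, _, _, nu = gls_last_coef(Yr, rot, delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), int(nu[0])), _TINY_P)
    return beta, se, p, int(nu[0])


def test_marker(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    marker_codes: np.ndarray,
    vc: VarianceComponents | None = None,
    counted_allele: str = "presence",
) -> tuple[float, float, float, float]:
    """GLS marker test; returns (effect, se, p_value, marker_h2).

    The effect is sign-normalised to be per copy of the knob-presence allele:
    when the additive code counts the absence allele the coefficient is
    negated. ``vc`` pins the variance components (P3D-style / OLS limit when
    sigma_g^2 = 0); None re-estimates them exactly with the marker in the
    model. marker_h2 is the fraction of phenotypic variance explained,
    effect^2 Var(code) / Var(y).
    """
    y = np.asarray(y, float)
    code = np.asarray(marker_codes, float)
    if code.std() == 0:
        raise ValueError("marker code has zero variance; cannot be tested")
    X_base = _with_intercept(len(y), covariates)
    _check_design(len(y), np.column_stack([X_base, code]))
    d, U = _eigen_kinship(np.asarray(K, float))
    delta_fixed = None
    if vc is not None:
        delta_fixed = np.array(
            [vc.sigma2_g / vc.sigma2_e if vc.sigma2_e > 0 else 0.0])
    beta, se, p, _ = _marker_stats(
        y[:, None], X_base, code, d, U, delta_fixed)
    effect = float(beta[0])
    if counted_allele == "absence":
        effect = -effect
    h2 = effect**2 * float(code.var()) / float(y.var()) if y.var() > 0 else 0.0
    return effect, float(se[0]), float(p[0]), h2


def _align_blues(
    entries: list[str], blues
) -> np.ndarray:
    """Accept EntryMeans lists, Series or DataFrames and align to entries."""
    if isinstance(blues, pd.Series):
        series = blues
    elif isinstance(blues, pd.DataFrame):
        raise TypeError("pass a single-trait Series or list of EntryMeans")
    else:
        series = pd.Series({b.entry_id: b.blue for b in blues})
    missing = [e for e in entries if e not in series.index]
    extra = [e for e in series.index if e not in entries]
    if missing or extra:
        raise ValueError(
            f"genotype/BLUE entry mismatch; missing BLUEs for {missing}, "
            f"unmatched BLUEs {extra}"
        )
    return series.loc[entries].to_numpy(float)


def _structure_covariates(
    panel: list[PanelEntry], m: KnobMatrix, spec: AssociationModelSpec
) -> np.ndarray:
    cov = compute_pcs(m, spec.n_pcs)
    if spec.group_covariate:
        types = {e.entry_type for e in panel}
        if len(types) > 1:
            grp = np.array(
                [1.0 if e.entry_type == "hybrid" else 0.0 for e in panel])
            cov = np.column_stack([cov, grp]) if cov.size else grp[:, None]
    return cov


def _encode(m: KnobMatrix, encoding: str) -> EncodedMatrix:
    return encode_additive(m) if encoding == "additive" else encode_dominance(m)


def run_scan(
    panel: list[PanelEntry],
    blues,
    spec: AssociationModelSpec,
    trait: str = "",
) -> pd.DataFrame:
    """Scan every polymorphic knob locus under one encoding.

    Returns a chromosome-ordered table with one row per testable locus:
    locus_id, chromosome, arm, encoding, trait, maf (heterozygote frequency
    under the dominance encoding), effect, se, p_value, marker_h2 and a
    ``significant`` column left empty until a threshold is applied.
    """
    m = KnobMatrix.from_panel(panel)
    if spec.n_pcs >= len(m.entries) - 2:
        raise ValueError("n_pcs must be smaller than n_entries - 2")
    y = _align_blues(m.entries, blues)
    enc = _encode(m, spec.encoding)
    K = _kinship_values(m, spec)
    cov = _structure_covariates(panel, m, spec)
    X_base = _with_intercept(len(y), cov)
    _check_design(len(y), X_base)
    d, U = _eigen_kinship(K)
    delta_fixed = None
    if spec.vc_mode == "null_once":
        vc, _ = fit_null_mlm(y, cov, K)
        delta_fixed = np.array(
            [vc.sigma2_g / vc.sigma2_e if vc.sigma2_e > 0 else 0.0])
    rows = []
    for j, locus in enumerate(enc.loci):
        code = enc.values[:, j].astype(float)
        if code.std() == 0:  # defensive; encoders already exclude these
            warnings.warn(f"zero-variance code at {locus.locus_id}; skipped")
            continue
        beta, se, p, _ = _marker_stats(
            y[:, None], X_base, code, d, U, delta_fixed)
        effect = float(beta[0])
        if enc.model == "additive" and enc.counted_allele[j] == "absence":
            effect = -effect
        maf = (
            minor_allele_frequency(m, locus.locus_id)
            if enc.model == "additive"
            else heterozygote_frequency(m, locus.locus_id)
        )
        h2 = (
            effect**2 * float(code.var()) / float(y.var())
            if y.var() > 0 else 0.0
        )
        rows.append(
            {"locus_id": locus.locus_id, "chromosome": locus.chromosome,
             "arm": locus.arm, "encoding": enc.model, "trait": trait,
             "maf": maf, "effect": effect, "se": float(se[0]),
             "p_value": float(p[0]), "marker_h2": h2, "significant": pd.NA}
        )
    out = pd.DataFrame(
        rows, columns=["locus_id", "chromosome", "arm", "encoding", "trait",
                       "maf", "effect", "se", "p_value", "marker_h2",
                       "significant"],
    )
    return out.sort_values("chromosome", kind="stable").reset_index(drop=True)


def _kinship_values(m: KnobMatrix, spec: AssociationModelSpec) -> np.ndarray:
    if spec.kinship_mode == "identity":
        return np.eye(len(m.entries))
    return compute_kinship(m).values


def scan_min_pvalues(
    panel: list[PanelEntry],
    Y: np.ndarray,
    spec: AssociationModelSpec,
) -> np.ndarray:
    """Minimum p-value across testable markers for each column of Y.

    Shared engine for the permutation threshold: the genotype, kinship and
    covariate structure is fixed while many (possibly permuted) response
    vectors are scanned at once. Uses the same numerical path as
    :func:`run_scan`, so the identity permutation reproduces the scan.
    """
    m = KnobMatrix.from_panel(panel)
    enc = _encode(m, spec.encoding)
    if not enc.loci:
        raise ValueError("no polymorphic markers to scan")
    K = _kinship_values(m, spec)
    cov = _structure_covariates(panel, m, spec)
    X_base = _with_intercept(Y.shape[0], cov)
    d, U = _eigen_kinship(K)
    delta_fixed = None
    if spec.vc_mode == "null_once":
        rot0 = RotatedDesign(eigvals=d, U=U, X=U.T @ X_base)
        delta_fixed = optimize_delta(U.T @ Y, rot0)
    minp = np.full(Y.shape[1], np.inf)
    for j in range(len(enc.loci)):
        code = enc.values[:, j].astype(float)
        _, _, p, _ = _marker_stats(Y, X_base, code, d, U, delta_fixed)
        minp = np.minimum(minp, p)
    return minp
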