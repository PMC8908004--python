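"""Resampling-based significance threshold for the knob scan.

The phenotype vector is shuffled against the fixed genotype, kinship and
covariate structure; each shuffle is rescanned and the best (minimum) marker
p-value recorded. The empirical 5% quantile of those minima — equivalently
the 95% quantile of the best -log10 p scores — is the family-wise threshold:
a real marker is declared significant when its p-value does not exceed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationModelSpec, scan_min_pvalues
from .simulate import PanelEntry

__all__ = ["PermutationReport", "permutation_threshold", "apply_threshold"]


@dataclass(frozen=True)
class PermutationReport:
    trait: str
    encoding: str
    n_perm: int
    best_scores: np.ndarray  # per-permutation minimum p-values
    threshold_p: float
    level: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.best_scores) != self.n_perm:
            raise ValueError("best_scores length must equal n_perm")
        if not 0.0 < self.threshold_p < 1.0:
            raise ValueError("threshold_p must lie in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"permutation": np.arange(1, self.n_perm + 1),
             "min_p": self.best_scores}
        )


def permutation_threshold(
    panel: list[PanelEntry],
    blues,
    spec: AssociationModelSpec,
    n_perm: int = 50,
    level: float = 0.95,
    seed: int = 0,
    trait: str = "",
) -> PermutationReport:
    """Empirical family-wise p-value threshold from phenotype permutations.

    Only the response vector is shuffled; structure covariates stay attached
    to their genotype rows. Variance components are re-estimated for every
    permutation (per marker, or once per permutation under ``null_once``).
    The threshold is the type-7 (linear-interpolation) ``1 - level`` quantile
    of the per-permutation minimum p-values. The mirror of the published
    procedure uses n_perm = 50, which makes a noisy 5% quantile; prefer a few
    hundred permutations when runtime allows.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a noisy {100 * (1 - level):g}% quantile; "
            f"consider several hundred permutations", stacklevel=2,
        )
    from .association import _align_blues  # shared alignment/validation

    entries = [e.entry_id for e in panel]
    y = _align_blues(entries, blues)
    rng = np.random.default_rng(seed)
    n = len(y)
    Y = np.empty((n, n_perm))
    for i in range(n_perm):
        Y[:, i] = y[rng.permutation(n)]
    best = scan_min_pvalues(panel, Y, spec)
    threshold_p = float(np.quantile(best, 1.0 - level))  # type-7 linear
    return PermutationReport(
        trait=trait, encoding=spec.encoding, n_perm=n_perm,
        best_scores=best, threshold_p=threshold_p, level=level, seed=seed,
    )


def apply_threshold(
    results: pd.DataFrame, report: PermutationReport
) -> pd.DataFrame:
    """Mark scan rows significant when p_value <= threshold_p (ties count).

    The results table must come from a scan with the same trait and encoding
    as the permutation report.
    """
    out = results.copy()
    if out.empty:
        return out
    traits = set(out["trait"].unique())
    encodings = set(out["encoding"].unique())
    if traits - {report.trait} or encodings - {report.encoding}:
        raise ValueError(
            f"scan results ({traits}, {encodings}) do not match permutation "
            f"report ({report.trait!r}, {report.encoding!r})"
        )
    out["significant"] = out["p_value"] <= report.threshold_p
    return out
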