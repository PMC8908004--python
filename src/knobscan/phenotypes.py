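"""Entry means (BLUEs), heritability, genome size and descriptive summaries.

Under a completely randomised design with homoscedastic errors the best
linear unbiased estimate of an entry's mean is its arithmetic replicate
mean, and entry-mean heritability is sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)
with r the (harmonic-mean) replicate number. Variance components come from a
one-way random-effects model fitted by restricted maximum likelihood; when
the panel mixes inbred lines and hybrids the line/hybrid contrast enters as
a fixed effect so that heterosis is treated as population structure rather
than genetic variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import RotatedDesign, _reml_loglik, gls_last_coef, optimize_delta
from .simulate import PlantRecord

__all__ = [
    "EntryMeans", "VarianceComponents", "TRAIT_FIELDS",
    "compute_blues", "estimate_heritability", "genome_size_from_peaks",
    "pg_to_mbp", "trait_correlations", "group_summaries",
]

TRAIT_FIELDS = {"mf": "mf_days", "ff": "ff_days", "gs": "gs_pg"}

#: DNA mass-to-length conversion, megabase pairs per picogram.
MBP_PER_PG = 978.0


@dataclass(frozen=True)
class EntryMeans:
    entry_id: str
    trait: str
    blue: float
    n_reps: int


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    r_eff: float


def _trait_series(records: list[PlantRecord], trait: str) -> pd.DataFrame:
    if trait not in TRAIT_FIELDS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {list(TRAIT_FIELDS)}")
    field = TRAIT_FIELDS[trait]
    return pd.DataFrame(
        {"entry_id": [r.entry_id for r in records],
         "y": [getattr(r, field) for r in records]}
    )


def compute_blues(
    records: list[PlantRecord], trait: str,
    entry_order: list[str] | None = None,
) -> list[EntryMeans]:
    """Replicate means per entry, ordered to match the genotype panel.

    Raises if an entry requested in ``entry_order`` has no phenotype records.
    """
    df = _trait_series(records, trait)
    grouped = df.groupby("entry_id", sort=False)["y"].agg(["mean", "count"])
    if entry_order is not None:
        missing = [e for e in entry_order if e not in grouped.index]
        if missing:
            raise ValueError(f"entries with no phenotype records: {missing}")
        grouped = grouped.loc[entry_order]
    return [
        EntryMeans(entry_id=str(eid), trait=trait,
                   blue=float(row["mean"]), n_reps=int(row["count"]))
        for eid, row in grouped.iterrows()
    ]


def blues_frame(records: list[PlantRecord],
                entry_order: list[str] | None = None) -> pd.DataFrame:
    """All three traits' BLUEs in one entry-indexed table."""
    cols = {}
    for trait in TRAIT_FIELDS:
        ems = compute_blues(records, trait, entry_order)
        cols[trait] = pd.Series({e.entry_id: e.blue for e in ems})
        cols["n_reps"] = pd.Series({e.entry_id: e.n_reps for e in ems})
    out = pd.DataFrame(cols)
    out.index.name = "entry_id"
    if entry_order is not None:
        out = out.loc[entry_order]
    return out


def _one_way_rotation(y: np.ndarray, entry_idx: np.ndarray,
                      X_entry: np.ndarray) -> tuple[RotatedDesign, np.ndarray]:
    """Exact eigen-rotation of the one-way model V = sg2*ZZ' + se2*I.

    ZZ' is block diagonal in all-ones blocks: each entry contributes one
    eigenvalue r_i along its mean and r_i - 1 zero eigenvalues along within-
    entry contrasts. Fixed effects are constant within entry, so their
    rotated rows are sqrt(r_i) * x_i on the mean components and zero on the
    contrasts; the contrasts only enter through the within-entry sum of
    squares, which is preserved by spreading it over r_i - 1 pseudo-rows.
    """
    n_entries = X_entry.shape[0]
    r = np.bincount(entry_idx, minlength=n_entries).astype(float)
    sums = np.bincount(entry_idx, weights=y, minlength=n_entries)
    means = sums / r
    ss_within = np.bincount(
        entry_idx, weights=(y - means[entry_idx]) ** 2, minlength=n_entries)
    rows_y = [np.sqrt(r) * means]
    rows_d = [r]
    rows_X = [np.sqrt(r)[:, None] * X_entry]
    for i in range(n_entries):
        k = int(r[i]) - 1
        if k > 0:
            rows_y.append(np.full(k, np.sqrt(max(ss_within[i], 0.0) / k)))
            rows_d.append(np.zeros(k))
            rows_X.append(np.zeros((k, X_entry.shape[1])))
    yrot = np.concatenate(rows_y)
    drot = np.concatenate(rows_d)
    Xrot = np.vstack(rows_X)
    rot = RotatedDesign(eigvals=drot, U=np.eye(0), X=Xrot)
    return rot, yrot


def estimate_heritability(
    records: list[PlantRecord], trait: str,
    entry_types: dict[str, str] | None = None,
) -> tuple[float, VarianceComponents]:
    """Entry-mean heritability from plant-level records via REML.

    Fits entry as a random effect; when ``entry_types`` distinguishes lines
    from hybrids their contrast is a fixed effect, so the heterotic group
    shift does not inflate the genetic variance. Returns
    ``h2 = sg2 / (sg2 + se2 / r_eff)`` with r_eff the harmonic mean of
    per-entry replicate counts.
    """
    df = _trait_series(records, trait)
    entries = df["entry_id"].unique().tolist()
    if len(entries) < 2:
        raise ValueError("need at least 2 entries to separate variance components")
    eidx = df["entry_id"].map({e: i for i, e in enumerate(entries)}).to_numpy()
    counts = np.bincount(eidx)
    if (counts <= 1).all():
        raise ValueError(
            "every entry has a single replicate; residual variance is "
            "unidentifiable"
        )
    X_entry = np.ones((len(entries), 1))
    if entry_types is not None:
        types = pd.Series([entry_types[e] for e in entries])
        dummies = pd.get_dummies(types, drop_first=True, dtype=float)
        if dummies.shape[1]:
            X_entry = np.column_stack([X_entry, dummies.to_numpy()])
    y = df["y"].to_numpy(float)
    rot, yrot = _one_way_rotation(y, eidx, X_entry)
    delta = optimize_delta(yrot[:, None], rot)
    _, _, s2e, s2g, _ = gls_last_coef(yrot[:, None], rot, delta)
    sigma2_e = float(s2e[0])
    sigma2_g = float(s2g[0])
    if sigma2_g < 1e-10 * sigma2_e:  # boundary: floor at zero
        sigma2_g = 0.0
    r_eff = len(entries) / float((1.0 / counts).sum())
    h2 = sigma2_g / (sigma2_g + sigma2_e / r_eff)
    return h2, VarianceComponents(sigma2_g, sigma2_e, r_eff)


def reml_loglik_one_way(
    records: list[PlantRecord], trait: str, delta: float,
    entry_types: dict[str, str] | None = None,
) -> float:
    """Profiled REML log-likelihood at a given variance ratio (for audits)."""
    df = _trait_series(records, trait)
    entries = df["entry_id"].unique().tolist()
    eidx = df["entry_id"].map({e: i for i, e in enumerate(entries)}).to_numpy()
    X_entry = np.ones((len(entries), 1))
    if entry_types is not None:
        types = pd.Series([entry_types[e] for e in entries])
        dummies = pd.get_dummies(types, drop_first=True, dtype=float)
        if dummies.shape[1]:
            X_entry = np.column_stack([X_entry, dummies.to_numpy()])
    rot, yrot = _one_way_rotation(df["y"].to_numpy(float), eidx, X_entry)
    return float(
        _reml_loglik(yrot[:, None], rot.X, rot.eigvals, np.array([delta]))[0]
    )


def genome_size_from_peaks(
    sample_peak_mean: float, standard_peak_mean: float, standard_2c_pg: float
) -> float:
    """2C genome size from G0/G1 fluorescence peak means against an internal
    standard: sample_pg = (sample peak / standard peak) * standard_pg."""
    for name, v in (("sample_peak_mean", sample_peak_mean),
                    ("standard_peak_mean", standard_peak_mean),
                    ("standard_2c_pg", standard_2c_pg)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return sample_peak_mean / standard_peak_mean * standard_2c_pg


def pg_to_mbp(pg: float) -> int:
    """Convert 2C picograms to megabase pairs (978 Mbp/pg, round half up)."""
    if pg < 0:
        raise ValueError(f"genome size cannot be negative, got {pg}")
    return int(math.floor(pg * MBP_PER_PG + 0.5))


_TABLE_LABELS = {
    "ff": "Female flowering", "mf": "Male flowering",
    "gs": "Genome size", "dosage": "Knob dosage classes",
}


def trait_correlations(blues: pd.DataFrame,
                       dosage: pd.Series) -> pd.DataFrame:
    """Pairwise Pearson correlations among FF, MF, GS and knob dosage class.

    ``blues`` must carry columns mf/ff/gs indexed by entry_id; ``dosage`` the
    per-entry dosage class. Zero-variance vectors yield NaN (undefined), not
    zero. Layout mirrors a traits-by-traits upper triangle.
    """
    data = blues[["ff", "mf", "gs"]].copy()
    data["dosage"] = dosage.reindex(blues.index)
    if data.isna().any().any():
        raise ValueError("missing trait or dosage values for some entries")
    if len(data) < 3:
        raise ValueError("need at least 3 entries for correlations")
    order = ["ff", "mf", "gs", "dosage"]
    corr = np.full((4, 4), np.nan)
    arr = data[order].to_numpy(float)
    sd = arr.std(axis=0)
    for i in range(4):
        for j in range(4):
            if sd[i] == 0 or sd[j] == 0:
                if i != j:
                    warnings.warn(
                        f"zero variance in {order[i]}/{order[j]}; correlation "
                        f"undefined", stacklevel=2)
                continue
            corr[i, j] = np.corrcoef(arr[:, i], arr[:, j])[0, 1]
    full = pd.DataFrame(
        corr, index=[_TABLE_LABELS[k] for k in order],
        columns=[_TABLE_LABELS[k] for k in order],
    )
    # upper-triangle presentation: rows FF, MF, GS x columns MF, GS, dosage
    out = full.iloc[:3, 1:].copy()
    for i in range(3):
        for j in range(3):
            if j < i:
                out.iloc[i, j] = np.nan
    return out


def group_summaries(
    records: list[PlantRecord], entry_types: dict[str, str]
) -> pd.DataFrame:
    """Per-group descriptive statistics of the plant-level phenotypes.

    Quartiles use linear interpolation (the inclusive-median convention, R
    type 7). The standard deviation is the sample SD, reported as 0 for a
    single observation.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    for trait, field in TRAIT_FIELDS.items():
        df = pd.DataFrame(
            {"group": [entry_types[r.entry_id] for r in records],
             "y": [getattr(r, field) for r in records]}
        )
        for group, sub in df.groupby("group", sort=True):
            v = sub["y"].to_numpy(float)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            rows.append(
                {"group": group, "trait": trait, "n": len(v),
                 "mean": v.mean(), "q1": q1, "median": med, "q3": q3,
                 "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
            )
    return pd.DataFrame(rows)
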