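"""Knob marker matrix and model-specific encodings.

The panel is stored biology-facing (knob-presence allele counts 0/1/2); the
statistics-facing codes — minor-allele dose for the allele-substitution model
and a heterozygote indicator for the heterozygous-(dis)advantage model — are
derived in memory per scan, because which allele is minor depends on the
panel composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DEFAULT_LOCI, KnobGenotype, KnobLocus, PanelEntry

__all__ = [
    "KnobMatrix", "EncodedMatrix", "encode_additive", "encode_dominance",
    "minor_allele_frequency", "dosage_class",
]


@dataclass(frozen=True)
class KnobMatrix:
    """Entries x loci table of knob-presence allele counts."""

    entries: list[str]
    loci: list[KnobLocus]
    counts: np.ndarray  # (n_entries, n_loci) ints in {0,1,2}

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.entries), len(self.loci)):
            raise ValueError(
                f"counts shape {c.shape} does not match "
                f"{len(self.entries)} entries x {len(self.loci)} loci"
            )
        if not np.isin(c, (0, 1, 2)).all():
            raise ValueError("all counts must be 0, 1 or 2 (no missing calls)")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate entry_ids")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")

    @classmethod
    def from_panel(cls, panel: list[PanelEntry]) -> "KnobMatrix":
        loci = list(DEFAULT_LOCI)
        counts = np.array(
            [[e.genotype.counts[l.locus_id] for l in loci] for e in panel],
            dtype=int,
        )
        return cls([e.entry_id for e in panel], loci, counts)

    def locus_index(self, locus_id: str) -> int:
        for i, l in enumerate(self.loci):
            if l.locus_id == locus_id:
                return i
        raise KeyError(f"unknown locus {locus_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.entries, name="entry_id"),
            columns=[l.locus_id for l in self.loci],
        )


@dataclass(frozen=True)
class EncodedMatrix:
    """Numeric design codes for one model, with bookkeeping for sign recovery.

    ``counted_allele`` records, per retained locus, which allele the additive
    code counts ("presence" or "absence"); it is None for the dominance model.
    ``excluded`` lists (locus_id, reason) pairs dropped from the scan.
    """

    model: str  # "additive" or "dominance"
    entries: list[str]
    loci: list[KnobLocus]
    values: np.ndarray
    counted_allele: list[str] | None
    excluded: list[tuple[str, str]]


def presence_frequency(m: KnobMatrix, locus_id: str) -> float:
    """Empirical frequency of the knob-presence allele at one locus."""
    j = m.locus_index(locus_id)
    return float(m.counts[:, j].sum()) / (2.0 * len(m.entries))


def minor_allele_frequency(m: KnobMatrix, locus_id: str) -> float:
    """min(f, 1-f) for the knob-presence allele frequency f; in [0, 0.5]."""
    f = presence_frequency(m, locus_id)
    return min(f, 1.0 - f)


def encode_additive(m: KnobMatrix) -> EncodedMatrix:
    """Code each locus as copies of its minor allele (0/1/2).

    The minor allele is the one at empirical frequency < 0.5; at an exact tie
    the absence allele is counted, matching the convention that treats the
    minor allele as knob absence. Monomorphic loci are excluded with a
    warning. Heterozygotes code 1 under either orientation.
    """
    if len(m.entries) < 2:
        raise ValueError("additive encoding needs at least 2 entries")
    kept, codes, counted, excluded = [], [], [], []
    for j, locus in enumerate(m.loci):
        col = m.counts[:, j]
        if col.min() == col.max():
            excluded.append((locus.locus_id, "monomorphic"))
            continue
        f_presence = col.sum() / (2.0 * len(m.entries))
        if f_presence < 0.5:
            codes.append(col.copy())
            counted.append("presence")
        else:  # tie counts absence
            codes.append(2 - col)
            counted.append("absence")
        kept.append(locus)
    for locus_id, reason in excluded:
        warnings.warn(
            f"locus {locus_id} is {reason}; excluded from additive scan",
            stacklevel=2,
        )
    values = (
        np.column_stack(codes) if codes else np.empty((len(m.entries), 0), int)
    )
    return EncodedMatrix("additive", list(m.entries), kept, values,
                         counted, excluded)


def encode_dominance(m: KnobMatrix) -> EncodedMatrix:
    """Code 1 for heterozygotes, 0 for either homozygote.

    Loci with no heterozygotes (e.g. an all-inbred panel) carry no contrast
    and are excluded with a warning.
    """
    if len(m.entries) < 2:
        raise ValueError("dominance encoding needs at least 2 entries")
    kept, codes, excluded = [], [], []
    for j, locus in enumerate(m.loci):
        col = (m.counts[:, j] == 1).astype(int)
        if col.min() == col.max():
            excluded.append((locus.locus_id, "no heterozygotes"))
            continue
        codes.append(col)
        kept.append(locus)
    for locus_id, reason in excluded:
        warnings.warn(
            f"locus {locus_id} has {reason}; excluded from dominance scan",
            stacklevel=2,
        )
    values = (
        np.column_stack(codes) if codes else np.empty((len(m.entries), 0), int)
    )
    return EncodedMatrix("dominance", list(m.entries), kept, values,
                         None, excluded)


def heterozygote_frequency(m: KnobMatrix, locus_id: str) -> float:
    """Fraction of entries heterozygous at a locus (the dominance-model
    analogue of a minor-allele frequency)."""
    j = m.locus_index(locus_id)
    return float((m.counts[:, j] == 1).mean())


_VARIABLE_LOCI = tuple(l.locus_id for l in DEFAULT_LOCI)


def dosage_class(g: KnobGenotype) -> int:
    """Total knob dosage: sum of presence-allele counts over the four
    variable loci (0-8)."""
    missing = [l for l in _VARIABLE_LOCI if l not in g.counts]
    if missing:
        raise ValueError(f"genotype missing loci: {missing}")
    return int(sum(g.counts[l] for l in _VARIABLE_LOCI))
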