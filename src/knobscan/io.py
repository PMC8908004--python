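"""Readers, writers and run configuration binding the pipeline stages.

Genotypes and phenotypes travel as CSV, results as TSV; every table written
here is stamped with a header comment carrying the tool version, the config
hash and the seed, so an artifact can always be traced to the run that
produced it. All files are UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    DEFAULT_LOCI,
    GeneratorParams,
    KnobGenotype,
    PanelEntry,
    PlantRecord,
    ReplicateDesign,
    assay1_design,
    assay2_design,
)
from .genotypes import KnobMatrix

__all__ = [
    "RunConfig", "read_genotypes", "read_panel", "write_panel",
    "read_phenotypes", "write_phenotypes", "write_table", "read_table",
    "load_config", "config_hash",
]

_LOCI_COLS = [l.locus_id for l in DEFAULT_LOCI]
_GENO_COLS = ["entry_id", "entry_type", "parent1", "parent2", *_LOCI_COLS]
_PHENO_COLS = ["plant_id", "entry_id", "replicate", "mf_days", "ff_days", "gs_pg"]


class ParseError(ValueError):
    """A malformed input table; the message names the offending cell."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_panel(path: str | Path) -> list[PanelEntry]:
    """Load a genotype CSV into panel entries, validating every cell."""
    df = _read_csv(path, _GENO_COLS)
    if df["entry_id"].duplicated().any():
        dupes = df.loc[df["entry_id"].duplicated(), "entry_id"].tolist()
        raise ParseError(f"{path}: duplicate entry_id(s) {dupes}")
    panel: list[PanelEntry] = []
    for i, row in df.iterrows():
        counts = {}
        for locus in _LOCI_COLS:
            raw = row[locus]
            try:
                code = int(raw)
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer code {raw!r} at row {i + 1}, "
                    f"locus {locus}"
                ) from None
            if code not in (0, 1, 2):
                raise ParseError(
                    f"{path}: code {code} outside 0/1/2 at row {i + 1}, "
                    f"locus {locus}"
                )
            counts[locus] = code
        parents = (row["parent1"], row["parent2"])
        panel.append(
            PanelEntry(
                entry_id=row["entry_id"],
                entry_type=row["entry_type"],
                genotype=KnobGenotype(counts),
                parents=parents if parents[0] and parents[1] else None,
            )
        )
    return panel


def read_genotypes(path: str | Path) -> KnobMatrix:
    """Load a genotype CSV as the entries x loci knob count matrix."""
    return KnobMatrix.from_panel(read_panel(path))


def write_panel(panel: list[PanelEntry], path: str | Path,
                stamp: str = "") -> None:
    rows = []
    for e in panel:
        p1, p2 = e.parents if e.parents else ("", "")
        rows.append(
            {"entry_id": e.entry_id, "entry_type": e.entry_type,
             "parent1": p1, "parent2": p2,
             **{l: e.genotype.counts[l] for l in _LOCI_COLS}}
        )
    _write_frame(pd.DataFrame(rows, columns=_GENO_COLS), path, stamp, sep=",")


def read_phenotypes(path: str | Path) -> list[PlantRecord]:
    df = _read_csv(path, _PHENO_COLS)
    records = []
    for i, row in df.iterrows():
        try:
            rec = PlantRecord(
                plant_id=row["plant_id"], entry_id=row["entry_id"],
                replicate=int(row["replicate"]),
                mf_days=float(row["mf_days"]), ff_days=float(row["ff_days"]),
                gs_pg=float(row["gs_pg"]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from None
        for name in ("mf_days", "ff_days", "gs_pg"):
            v = getattr(rec, name)
            if not np.isfinite(v) or v <= 0:
                raise ParseError(
                    f"{path}: non-positive or non-finite {name} at row {i + 1}"
                )
        records.append(rec)
    return records


def write_phenotypes(records: list[PlantRecord], path: str | Path,
                     stamp: str = "") -> None:
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in _PHENO_COLS} for r in records],
        columns=_PHENO_COLS,
    )
    _write_frame(df, path, stamp, sep=",")


def _write_frame(df: pd.DataFrame, path: str | Path, stamp: str,
                 sep: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# knobscan v{__version__}{' ' + stamp if stamp else ''}\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


def write_table(df: pd.DataFrame, path: str | Path, stamp: str = "") -> None:
    """Write a results table as stamped TSV."""
    _write_frame(df, path, stamp, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


_DESIGNS = {"assay1": assay1_design, "assay2": assay2_design}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, loadable from a flat YAML file."""

    generator: GeneratorParams = field(default_factory=GeneratorParams)
    encodings: tuple[str, ...] = ("additive", "dominance")
    traits: tuple[str, ...] = ("mf", "ff")
    n_pcs: int = 0
    kinship_mode: str = "vanraden"
    vc_mode: str = "per_marker_exact"
    group_covariate: bool = True
    n_perm: int = 50
    level: float = 0.95
    seed: int = 0
    out_dir: str = "knobscan_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        for t in self.traits:
            if t not in ("mf", "ff", "gs"):
                raise ValueError(f"unknown trait {t!r}")


def _design_from(value) -> ReplicateDesign:
    if isinstance(value, str):
        try:
            return _DESIGNS[value]()
        except KeyError:
            raise ValueError(
                f"unknown design preset {value!r}; use one of {list(_DESIGNS)}"
            ) from None
    return ReplicateDesign(**value)


def load_config(path: str | Path | None = None, seed: int | None = None,
                out_dir: str | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus command-line overrides."""
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    gen_block = dict(raw.pop("generator", {}))
    if "design" in gen_block:
        gen_block["design"] = _design_from(gen_block["design"])
    cfg_seed = seed if seed is not None else int(raw.pop("seed", 0))
    raw.pop("seed", None)
    gen_block.setdefault("seed", cfg_seed)
    params = GeneratorParams(**gen_block)
    if out_dir is not None:
        raw["out_dir"] = out_dir
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("encodings", "traits"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(generator=params, seed=cfg_seed, **raw)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the analysis configuration.

    Output location and log level are presentation details and do not enter
    the hash, so reruns into different directories stamp identically.
    """
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
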