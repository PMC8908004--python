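"""End-to-end run: simulate -> BLUEs/heritability -> scans -> thresholds."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .association import AssociationModelSpec, run_scan
from .genotypes import dosage_class
from .io import (
    RunConfig,
    config_hash,
    write_panel,
    write_phenotypes,
    write_table,
)
from .phenotypes import (
    blues_frame,
    estimate_heritability,
    group_summaries,
    trait_correlations,
)
from .simulate import generate_panel, simulate_phenotypes
from .threshold import apply_threshold, permutation_threshold

log = logging.getLogger("knobscan")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the artifact files; returns their paths.

    Stages: panel simulation, phenotype simulation, entry means and
    heritability, association scans for each trait x encoding, permutation
    thresholds, and the descriptive correlation/summary tables. Any stage
    failure propagates with the stage named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config_hash(config)} seed={config.seed}"
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    t0 = stage("simulate")
    panel = generate_panel(config.generator)
    records = simulate_phenotypes(panel, config.generator)
    entry_types = {e.entry_id: e.entry_type for e in panel}
    artifacts["genotypes"] = out / "genotypes.csv"
    write_panel(panel, artifacts["genotypes"], stamp)
    artifacts["phenotypes"] = out / "phenotypes.csv"
    write_phenotypes(records, artifacts["phenotypes"], stamp)
    log.info("stage simulate done in %.2fs (%d entries, %d plants)",
             time.perf_counter() - t0, len(panel), len(records))

    t0 = stage("blues")
    entry_order = [e.entry_id for e in panel]
    blues = blues_frame(records, entry_order)
    artifacts["blues"] = out / "blues.tsv"
    write_table(blues.reset_index(), artifacts["blues"], stamp)
    herit_rows = []
    for trait in ("mf", "ff", "gs"):
        h2, vc = estimate_heritability(records, trait, entry_types)
        herit_rows.append(
            {"trait": trait, "h2": h2, "sigma2_g": vc.sigma2_g,
             "sigma2_e": vc.sigma2_e, "r_eff": vc.r_eff}
        )
    artifacts["heritability"] = out / "heritability.tsv"
    write_table(pd.DataFrame(herit_rows), artifacts["heritability"], stamp)
    log.info("stage blues done in %.2fs", time.perf_counter() - t0)

    t0 = stage("scan")
    all_results, all_thresholds = [], []
    for trait in config.traits:
        for encoding in config.encodings:
            spec = AssociationModelSpec(
                encoding=encoding, n_pcs=config.n_pcs,
                kinship_mode=config.kinship_mode, vc_mode=config.vc_mode,
                group_covariate=config.group_covariate,
            )
            results = run_scan(panel, blues[trait], spec, trait=trait)
            report = permutation_threshold(
                panel, blues[trait], spec, n_perm=config.n_perm,
                level=config.level, seed=config.seed, trait=trait,
            )
            results = apply_threshold(results, report)
            all_results.append(results)
            all_thresholds.append(
                {"trait": trait, "encoding": encoding,
                 "n_perm": report.n_perm, "level": report.level,
                 "threshold_p": report.threshold_p}
            )
            log.info("scan %s/%s: threshold_p=%.4g, %d significant",
                     trait, encoding, report.threshold_p,
                     int(results["significant"].sum()))
    artifacts["results"] = out / "scan_results.tsv"
    write_table(pd.concat(all_results, ignore_index=True),
                artifacts["results"], stamp)
    artifacts["thresholds"] = out / "thresholds.tsv"
    write_table(pd.DataFrame(all_thresholds), artifacts["thresholds"], stamp)
    log.info("stage scan done in %.2fs", time.perf_counter() - t0)

    t0 = stage("report")
    dosage = pd.Series(
        {e.entry_id: dosage_class(e.genotype) for e in panel})
    artifacts["correlations"] = out / "correlations.tsv"
    write_table(
        trait_correlations(blues, dosage).reset_index(names="trait"),
        artifacts["correlations"], stamp,
    )
    artifacts["summaries"] = out / "group_summaries.tsv"
    write_table(group_summaries(records, entry_types),
                artifacts["summaries"], stamp)
    log.info("stage report done in %.2fs", time.perf_counter() - t0)
    return artifacts
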