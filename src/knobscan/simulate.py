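"""Synthetic knob panels and phenotypes.

Emulates a maize association panel segregating at four heterochromatic knob
loci (K3L, K5L, K7S, K9S): inbred lines derived by repeated self-fertilisation
from a single segregating seed, F1 hybrids crossed between those lines, and
replicate-level phenotypes (male/female flowering time in days, 2C genome
size in picograms) laid out as a completely randomised design.

The default parameters define the study conditions the rest of the package is
calibrated against: a single causal knob locus (K9S) with negative additive
and heterozygous-advantage effects on flowering, heterosis expressed as a
line/hybrid intercept shift, genetically correlated male and female flowering,
and a genome size trait with no knob effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KnobLocus", "KnobGenotype", "PanelEntry", "PlantRecord",
    "ReplicateDesign", "GeneratorParams", "DEFAULT_LOCI",
    "simulate_selfing_pedigree", "make_hybrid", "generate_panel",
    "simulate_phenotypes", "records_to_frame", "panel_to_frame",
    "assay1_design", "assay2_design",
]


@dataclass(frozen=True)
class KnobLocus:
    """A knob position named K<chromosome><arm>, e.g. K9S = chr 9 short arm."""

    locus_id: str
    chromosome: int
    arm: str  # "short" or "long"

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 10:
            raise ValueError(f"chromosome must be in 1..10, got {self.chromosome}")
        if self.arm not in ("short", "long"):
            raise ValueError(f"arm must be 'short' or 'long', got {self.arm!r}")
        expected = f"K{self.chromosome}{'S' if self.arm == 'short' else 'L'}"
        if not self.locus_id.startswith(expected):
            raise ValueError(
                f"locus_id {self.locus_id!r} inconsistent with chromosome "
                f"{self.chromosome} / {self.arm} arm (expected prefix {expected})"
            )

    @classmethod
    def from_label(cls, label: str) -> "KnobLocus":
        """Parse a K<chr><S|L> label such as 'K9S'."""
        body = label[1:]
        arm = {"S": "short", "L": "long"}[body[-1]]
        return cls(label, int(body[:-1]), arm)


DEFAULT_LOCI: tuple[KnobLocus, ...] = tuple(
    KnobLocus.from_label(lbl) for lbl in ("K3L", "K5L", "K7S", "K9S")
)


@dataclass(frozen=True)
class KnobGenotype:
    """Knob-presence allele counts per locus (0, 1 or 2)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for locus, c in self.counts.items():
            if c not in (0, 1, 2):
                raise ValueError(
                    f"invalid allele count {c!r} at {locus}: must be 0, 1 or 2"
                )

    def is_fixed(self) -> bool:
        """True when no locus is heterozygous."""
        return all(c != 1 for c in self.counts.values())

    def __getitem__(self, locus: str) -> int:
        return self.counts[locus]


@dataclass(frozen=True)
class PanelEntry:
    entry_id: str
    entry_type: str  # "line" or "hybrid"
    genotype: KnobGenotype
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.entry_type not in ("line", "hybrid"):
            raise ValueError(f"entry_type must be line/hybrid, got {self.entry_type!r}")
        if self.entry_type == "hybrid" and (
            self.parents is None or len(self.parents) != 2
        ):
            raise ValueError("hybrids require exactly two parents")
        if self.entry_type == "line" and self.parents is not None:
            raise ValueError("line entries carry no parents")


@dataclass(frozen=True)
class PlantRecord:
    """One plant's replicate-level phenotypes."""

    plant_id: str
    entry_id: str
    replicate: int
    mf_days: float
    ff_days: float
    gs_pg: float


@dataclass(frozen=True)
class ReplicateDesign:
    """Completely randomised design: entry counts and replicates per type."""

    n_lines: int
    reps_line: int
    n_hybrids: int = 0
    reps_hybrid: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.reps_line < 1:
            raise ValueError("need at least one line with one replicate")
        if self.n_hybrids > 0 and self.reps_hybrid < 1:
            raise ValueError("hybrid replicate count must be >= 1")

    @property
    def n_entries(self) -> int:
        return self.n_lines + self.n_hybrids

    @property
    def n_plants(self) -> int:
        return self.n_lines * self.reps_line + self.n_hybrids * self.reps_hybrid

    @property
    def r_eff(self) -> float:
        """Harmonic-mean replicate number over entries."""
        inv = self.n_lines / self.reps_line
        if self.n_hybrids:
            inv += self.n_hybrids / self.reps_hybrid
        return self.n_entries / inv


def assay1_design() -> ReplicateDesign:
    """8 parent lines x 3 replicates plus 35 hybrids x 5 replicates."""
    return ReplicateDesign(n_lines=8, reps_line=3, n_hybrids=35, reps_hybrid=5)


def assay2_design() -> ReplicateDesign:
    """20 inbred lines x 5 replicates, no hybrids."""
    return ReplicateDesign(n_lines=20, reps_line=5)


@dataclass(frozen=True)
class GeneratorParams:
    """All simulation knobs; the defaults define the study conditions.

    Flowering-time means are line/hybrid group means in days; ``a_*`` is the
    additive effect per knob-presence allele at the causal locus, ``d_*`` the
    extra effect of heterozygosity there. Heritabilities are entry-mean
    (repeatability) targets given the design's replicate structure. ``rho_g``
    correlates the polygenic male/female flowering effects; ``rho_e``
    correlates their plant-level residuals (both traits are scored on the
    same plant). Genome size is in 2C picograms.
    """

    n_self_generations: int = 9
    design: ReplicateDesign = field(default_factory=assay1_design)
    mu_mf_line: float = 70.0
    mu_ff_line: float = 72.0
    mu_mf_hybrid: float = 63.0
    mu_ff_hybrid: float = 64.0
    a_mf: float = -0.45
    a_ff: float = -0.51
    d_mf: float = -1.40
    d_ff: float = -1.53
    h2_mf: float = 0.51
    h2_ff: float = 0.41
    h2_gs: float = 0.26
    rho_g: float = 0.95
    rho_e: float = 0.65
    mu_gs_line: float = 5.4
    mu_gs_hybrid: float = 5.6
    gs_knob_effect: float = 0.0
    sigma_e_ft: float = 2.5
    sigma_e_gs: float = 0.35
    causal_locus: str = "K9S"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h2_mf", "h2_ff", "h2_gs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rho_g", "rho_e"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        if self.n_self_generations < 1:
            raise ValueError("n_self_generations must be >= 1")
        if self.sigma_e_ft <= 0 or self.sigma_e_gs <= 0:
            raise ValueError("residual standard deviations must be positive")


class GenerationError(RuntimeError):
    """Raised when a panel cannot be assembled from the pedigree."""


def _validate_counts(counts: dict[str, int]) -> None:
    bad = {k: v for k, v in counts.items() if v not in (0, 1, 2)}
    if bad:
        raise ValueError(f"allele counts must be 0/1/2; offending loci: {bad}")


def simulate_selfing_pedigree(
    founder: KnobGenotype,
    n_generations: int,
    n_lineages: int,
    seed: int,
) -> list[KnobGenotype]:
    """Self-fertilise a founder for ``n_generations``, one descendant per line.

    Each heterozygous locus segregates independently each generation
    (offspring counts 0/1/2 with probability 1/4, 1/2, 1/4); homozygous loci
    are transmitted unchanged, so fixation is absorbing. Residual
    heterozygosity per initially heterozygous locus is 0.5**n_generations.
    """
    _validate_counts(founder.counts)
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    loci = list(founder.counts)
    G = _self_lineages(
        np.tile([founder.counts[l] for l in loci], (n_lineages, 1)),
        n_generations, rng,
    )
    return [
        KnobGenotype(dict(zip(loci, row))) for row in G.tolist()
    ]


def _self_lineages(G: np.ndarray, n_generations: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorised Mendelian selfing of an (n_lineages, n_loci) count array."""
    for _ in range(n_generations):
        het = G == 1
        n_het = int(het.sum())
        if n_het == 0:
            break
        # offspring of a selfed heterozygote: 0,1,2 w.p. 1/4, 1/2, 1/4
        G = G.copy()
        G[het] = rng.choice([0, 1, 2], size=n_het, p=[0.25, 0.5, 0.25])
    return G


def make_hybrid(parent1: KnobGenotype, parent2: KnobGenotype) -> KnobGenotype:
    """Cross two fixed lines; each locus receives one allele from each parent."""
    for i, p in enumerate((parent1, parent2), start=1):
        _validate_counts(p.counts)
        if not p.is_fixed():
            raise ValueError(
                f"parent {i} is heterozygous; only crosses between fixed "
                f"inbred lines are supported"
            )
    if set(parent1.counts) != set(parent2.counts):
        raise ValueError("parents genotyped at different loci")
    return KnobGenotype(
        {l: parent1.counts[l] // 2 + parent2.counts[l] // 2
         for l in parent1.counts}
    )


def generate_panel(params: GeneratorParams) -> list[PanelEntry]:
    """Assemble the line + hybrid panel for the configured design.

    Line genotypes are descendants of a fully heterozygous founder selfed for
    ``n_self_generations``; only fixed descendants enter the panel (sampled
    without replacement). Hybrids are crosses between ordered pairs of
    distinct panel lines, sampled without replacement, so reciprocal crosses
    count as different hybrids.
    """
    rng = np.random.default_rng(_substream(params.seed, "panel"))
    design = params.design
    loci = [l.locus_id for l in DEFAULT_LOCI]
    # pool sized so a fixation shortfall is a pathology, not bad luck
    p_fix = (1.0 - 0.5**params.n_self_generations) ** len(loci)
    pool = max(int(np.ceil(4 * design.n_lines / max(p_fix, 1e-9))), 256)
    founder = np.ones((pool, len(loci)), dtype=int)
    G = _self_lineages(founder, params.n_self_generations, rng)
    fixed = G[(G != 1).all(axis=1)]
    if fixed.shape[0] < design.n_lines:
        raise GenerationError(
            f"only {fixed.shape[0]} of {founder.shape[0]} lineages fixed after "
            f"{params.n_self_generations} selfing generations; cannot draw "
            f"{design.n_lines} lines — increase n_self_generations"
        )
    pick = rng.choice(fixed.shape[0], size=design.n_lines, replace=False)
    width = max(2, len(str(design.n_entries)))
    lines = [
        PanelEntry(
            entry_id=f"L{i + 1:0{width}d}",
            entry_type="line",
            genotype=KnobGenotype(dict(zip(loci, fixed[j].tolist()))),
        )
        for i, j in enumerate(pick)
    ]
    entries = list(lines)
    if design.n_hybrids:
        ordered_pairs = [
            (i, j)
            for i in range(design.n_lines)
            for j in range(design.n_lines)
            if i != j
        ]
        if design.n_hybrids > len(ordered_pairs):
            raise GenerationError(
                f"{design.n_hybrids} hybrids requested but only "
                f"{len(ordered_pairs)} ordered crosses exist between "
                f"{design.n_lines} lines"
            )
        chosen = rng.choice(len(ordered_pairs), size=design.n_hybrids,
                            replace=False)
        for h, k in enumerate(chosen):
            i, j = ordered_pairs[k]
            entries.append(
                PanelEntry(
                    entry_id=f"H{h + 1:0{width}d}",
                    entry_type="hybrid",
                    genotype=make_hybrid(lines[i].genotype, lines[j].genotype),
                    parents=(lines[i].entry_id, lines[j].entry_id),
                )
            )
    return entries


def _substream(seed: int, name: str) -> int:
    """Derive a named per-stage seed (< 2**31) from the top-level seed."""
    import hashlib

    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def expected_marker_variance(params: GeneratorParams, trait: str) -> float:
    """Entry-count-weighted genetic variance contributed by the causal locus.

    Under the segregating-seed pedigree each line is 0 or 2 at the causal
    locus with probability 1/2 (additive variance a^2 per line), and a hybrid
    of two independent such lines is 0/1/2 with probability 1/4, 1/2, 1/4
    (Var(count)=0.5, Var(het)=0.25, Cov=0). Genome size uses the dosage over
    all four loci instead.
    """
    design = params.design
    nl, nh = design.n_lines, design.n_hybrids
    if trait == "gs":
        e2 = params.gs_knob_effect**2
        v_line, v_hyb = e2 * 4.0, e2 * 2.0
    else:
        a = params.a_mf if trait == "mf" else params.a_ff
        d = params.d_mf if trait == "mf" else params.d_ff
        v_line = a**2
        v_hyb = a**2 * 0.5 + d**2 * 0.25
    return (nl * v_line + nh * v_hyb) / (nl + nh)


def polygenic_variances(params: GeneratorParams) -> dict[str, float]:
    """Polygenic entry variances calibrated so total genetic variance hits h2.

    The entry-mean heritability target h2 = sg2 / (sg2 + se2/r_eff) fixes the
    TOTAL genetic variance sg2; the causal-locus contribution is subtracted so
    the polygenic remainder var(u) = max(0, sg2_target - V_marker). When the
    marker alone exceeds the target the polygenic term collapses to zero and a
    warning is issued.
    """
    r_eff = params.design.r_eff
    out: dict[str, float] = {}
    for trait, h2, se2 in (
        ("mf", params.h2_mf, params.sigma_e_ft**2),
        ("ff", params.h2_ff, params.sigma_e_ft**2),
        ("gs", params.h2_gs, params.sigma_e_gs**2),
    ):
        if h2 >= 1.0:
            raise ValueError("heritability of exactly 1 is not simulable")
        target = h2 / (1.0 - h2) * se2 / r_eff
        vm = expected_marker_variance(params, trait)
        if vm > target and h2 > 0:
            warnings.warn(
                f"causal-locus variance {vm:.3g} exceeds the h2-implied "
                f"genetic variance {target:.3g} for {trait}; polygenic "
                f"variance floored at 0", stacklevel=2,
            )
        out[trait] = max(0.0, target - vm)
    return out


def simulate_phenotypes(
    panel: list[PanelEntry], params: GeneratorParams
) -> list[PlantRecord]:
    """Draw replicate-level phenotypes for every entry of the panel.

    Entry genetic value = group mean + causal-locus effects + correlated
    polygenic deviation; plant value = entry value + residual. Male and
    female flowering share both a genetic correlation (rho_g) and a
    within-plant residual correlation (rho_e); genome size is independent.
    """
    if not panel:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(_substream(params.seed, "phenotypes"))
    vu = polygenic_variances(params)
    s_mf, s_ff, s_gs = np.sqrt([vu["mf"], vu["ff"], vu["gs"]])
    rg, re = params.rho_g, params.rho_e
    design = params.design
    records: list[PlantRecord] = []
    for entry in panel:
        g = entry.genotype
        x9 = g[params.causal_locus] if params.causal_locus in g.counts else 0
        het9 = 1.0 if x9 == 1 else 0.0
        dosage = sum(g.counts.values())
        z1, z2, z3 = rng.standard_normal(3)
        u_mf = s_mf * z1
        u_ff = s_ff * (rg * z1 + np.sqrt(1.0 - rg**2) * z2)
        u_gs = s_gs * z3
        if entry.entry_type == "line":
            mu_mf, mu_ff, mu_gs = (
                params.mu_mf_line, params.mu_ff_line, params.mu_gs_line)
            reps = design.reps_line
        else:
            mu_mf, mu_ff, mu_gs = (
                params.mu_mf_hybrid, params.mu_ff_hybrid, params.mu_gs_hybrid)
            reps = design.reps_hybrid
        g_mf = mu_mf + params.a_mf * x9 + params.d_mf * het9 + u_mf
        g_ff = mu_ff + params.a_ff * x9 + params.d_ff * het9 + u_ff
        g_gs = mu_gs + params.gs_knob_effect * dosage + u_gs
        for rep in range(1, reps + 1):
            w1, w2, w3 = rng.standard_normal(3)
            e_mf = params.sigma_e_ft * w1
            e_ff = params.sigma_e_ft * (re * w1 + np.sqrt(1.0 - re**2) * w2)
            e_gs = params.sigma_e_gs * w3
            records.append(
                PlantRecord(
                    plant_id=f"{entry.entry_id}_r{rep}",
                    entry_id=entry.entry_id,
                    replicate=rep,
                    mf_days=float(g_mf + e_mf),
                    ff_days=float(g_ff + e_ff),
                    gs_pg=float(g_gs + e_gs),
                )
            )
    return records


def panel_to_frame(panel: list[PanelEntry]) -> pd.DataFrame:
    """Genotype table: entry_id, entry_type, parent1, parent2, one column per locus."""
    loci = [l.locus_id for l in DEFAULT_LOCI]
    rows = []
    for e in panel:
        p1, p2 = e.parents if e.parents else ("", "")
        rows.append(
            {"entry_id": e.entry_id, "entry_type": e.entry_type,
             "parent1": p1, "parent2": p2,
             **{l: e.genotype.counts.get(l, 0) for l in loci}}
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[PlantRecord]) -> pd.DataFrame:
    """Phenotype table: plant_id, entry_id, replicate, mf_days, ff_days, gs_pg."""
    return pd.DataFrame(
        [
            {"plant_id": r.plant_id, "entry_id": r.entry_id,
             "replicate": r.replicate, "mf_days": r.mf_days,
             "ff_days": r.ff_days, "gs_pg": r.gs_pg}
            for r in records
        ]
    )


def null_params(seed: int = 0, **overrides) -> GeneratorParams:
    """Parameters with every knob effect switched off (for calibration runs)."""
    base = GeneratorParams(
        a_mf=0.0, a_ff=0.0, d_mf=0.0, d_ff=0.0, gs_knob_effect=0.0, seed=seed)
    return replace(base, **overrides) if overrides else base
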