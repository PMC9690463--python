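"""Synthetic multi-study QTL catalogs with planted truth.

The generator emulates the structure of a literature meta-QTL corpus:
a master genetic map of 7 barley chromosomes; a handful of true QTL
positions ("planted MQTLs") per chromosome with a stress-class profile;
and a set of mapping studies, each with its own marker panel (a jittered
subsample of the master map) and population (F2/BC/RIL/DH with 72-317
lines, the range spanned by published barley abiotic-stress studies).
Each planted QTL is assigned to one study and reported at a peak scattered
normally around its true position with the standard deviation its own
reported precision implies (capped at a configurable bound), with R² drawn
from 0.03-0.55 and LOD from 2.5-15 — the ranges of the published corpus.

Everything derives deterministically from one integer seed, so pipeline
runs on synthetic data are exactly reproducible and recovered MQTLs can be
compared against the planted truth.

What the generator does not emulate: genotype-level noise (QTL mapping is
not re-run; mapped QTLs are planted directly), inter-study marker naming
discrepancies, and systematically biased maps — so recovery results
characterise the meta-analysis machinery, not literature curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from metaqtl.catalog import (
    PopulationDescriptor,
    QTLCatalog,
    QTLRecord,
    STRESS_CLASSES,
)
from metaqtl.linkage import LinkageMap, MarkerLocus
from metaqtl.projection import confidence_interval
from metaqtl.reporting import GeneFeature

import pandas as pd

#: Stress-class mix of the emitted QTLs, matching the proportions of the
#: published 585-QTL corpus (drought 210, salinity 206, mineral 106,
#: waterlogging 47, low temperature 16).
DEFAULT_STRESS_WEIGHTS = {
    "drought": 210 / 585,
    "salinity": 206 / 585,
    "mineral": 106 / 585,
    "waterlogging": 47 / 585,
    "low_temperature": 16 / 585,
}

#: Population-type mix; doubled haploids dominate the published corpus.
DEFAULT_POP_WEIGHTS = {"DH": 0.6, "RIL": 0.2, "F2": 0.1, "BC": 0.1}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults are the package's standard study
    conditions for recovery experiments."""

    n_chromosomes: int = 7
    chromosome_length_cm: float = 150.0
    markers_per_chromosome: int = 120
    n_studies: int = 26
    mqtls_per_chromosome: int = 3
    min_separation_cm: float = 20.0
    qtls_per_mqtl: int = 10
    qtl_scatter_sd_cm: float = 5.0
    map_jitter_sd_cm: float = 0.5
    marker_subsample_fraction: float = 0.7
    r2_range: tuple[float, float] = (0.03, 0.55)
    lod_range: tuple[float, float] = (2.5, 15.0)
    n_lines_range: tuple[int, int] = (72, 317)
    seed: int = 17

    def chromosome_names(self) -> list[str]:
        return [f"{i}H" for i in range(1, self.n_chromosomes + 1)]


@dataclass(frozen=True)
class PlantedMQTL:
    """One true locus: position and how many member QTLs per stress."""

    chromosome: str
    pos_cm: float
    stress_counts: dict[str, int]

    @property
    def n_qtls(self) -> int:
        return sum(self.stress_counts.values())


@dataclass
class SyntheticTruth:
    """Planted MQTLs, the master map, and the per-QTL study assignment."""

    master_map: LinkageMap
    mqtls: list[PlantedMQTL]
    config: SimulationConfig
    # one blueprint per planted QTL: (mqtl index, stress, study index)
    blueprints: list[tuple[int, str, int]] = field(default_factory=list)

    def mqtls_on(self, chromosome: str) -> list[PlantedMQTL]:
        return [m for m in self.mqtls if m.chromosome == chromosome]

    def positions_on(self, chromosome: str) -> np.ndarray:
        return np.array(sorted(m.pos_cm for m in self.mqtls_on(chromosome)))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *key]))


def simulate_master_map(
    n_chromosomes: int = 7,
    length_cm: float = 150.0,
    n_markers: int = 120,
    seed: int = 17,
    chrom_names: Sequence[str] | None = None,
) -> LinkageMap:
    """A master map with uniform-ordered marker positions per chromosome.

    Marker names are deterministic in the seed; the first and last markers
    are pinned to 0 and ``length_cm`` so every chromosome spans its full
    length.
    """
    if n_markers < 2:
        raise ValueError("need at least 2 markers per chromosome")
    names = list(chrom_names) if chrom_names else [f"{i}H" for i in range(1, n_chromosomes + 1)]
    rng = _rng(seed, 0)
    loci = []
    for ci, chrom in enumerate(names):
        pos = np.sort(rng.uniform(0.0, length_cm, n_markers))
        pos[0], pos[-1] = 0.0, length_cm
        for j, p in enumerate(pos):
            loci.append(MarkerLocus(f"m{chrom}_{j:03d}", chrom, float(p)))
    return LinkageMap("master", loci)


def _plant_positions(rng: np.random.Generator, n: int, length: float,
                     min_sep: float, margin: float = 10.0) -> np.ndarray:
    """n positions in [margin, length-margin] with pairwise separation >= min_sep."""
    for _ in range(1000):
        pos = np.sort(rng.uniform(margin, length - margin, n))
        if n == 1 or np.diff(pos).min() >= min_sep:
            return pos
    # dense fallback: evenly spaced
    return np.linspace(margin, length - margin, n)


def generate_truth(config: SimulationConfig | None = None) -> SyntheticTruth:
    """Plant MQTL positions, stress profiles and study assignments."""
    cfg = config or SimulationConfig()
    master = simulate_master_map(
        cfg.n_chromosomes, cfg.chromosome_length_cm, cfg.markers_per_chromosome,
        seed=cfg.seed,
    )
    rng = _rng(cfg.seed, 1)
    stresses = list(DEFAULT_STRESS_WEIGHTS)
    weights = np.array([DEFAULT_STRESS_WEIGHTS[s] for s in stresses])
    mqtls: list[PlantedMQTL] = []
    for chrom in cfg.chromosome_names():
        positions = _plant_positions(
            rng, cfg.mqtls_per_chromosome, cfg.chromosome_length_cm, cfg.min_separation_cm
        )
        for pos in positions:
            counts = rng.multinomial(cfg.qtls_per_mqtl, weights)
            mqtls.append(
                PlantedMQTL(chrom, float(pos), dict(zip(stresses, counts.tolist())))
            )
    blueprints: list[tuple[int, str, int]] = []
    for mi, mq in enumerate(mqtls):
        for stress in STRESS_CLASSES:
            for _ in range(mq.stress_counts.get(stress, 0)):
                blueprints.append((mi, stress, int(rng.integers(cfg.n_studies))))
    return SyntheticTruth(master, mqtls, cfg, blueprints)


def study_population(truth: SyntheticTruth, study_index: int) -> PopulationDescriptor:
    """The (deterministic) mapping population of one study."""
    cfg = truth.config
    rng = _rng(cfg.seed, 2, study_index)
    types = list(DEFAULT_POP_WEIGHTS)
    pop_type = rng.choice(types, p=[DEFAULT_POP_WEIGHTS[t] for t in types])
    lo, hi = cfg.n_lines_range
    n_lines = int(rng.integers(lo, hi + 1))
    return PopulationDescriptor(str(pop_type), n_lines, f"study{study_index:02d}",
                                parents=f"P{study_index}a x P{study_index}b")


def simulate_study(
    truth: SyntheticTruth, study_index: int
) -> tuple[LinkageMap, list[QTLRecord]]:
    """Materialise one study: its marker panel and its reported QTLs.

    The study map subsamples the master markers at the configured fraction
    and jitters positions with Normal(0, map_jitter_sd²); chromosomes left
    with fewer than two markers are dropped (exercising the consensus
    builder's exclusion rule).  QTL peaks scatter normally around the
    planted positions with the standard deviation implied by the QTL's own
    reported precision — CI95(pop, N, R²)/3.92, the same quantity the
    meta-analysis later attributes to it — capped at ``qtl_scatter_sd_cm``
    and truncated to the chromosome.  Tying the scatter to the reported
    precision keeps the generated data coherent with the known-variance
    mixture model, which is what a parameter-recovery experiment needs;
    the cap keeps low-precision QTLs (tiny N·R²) from scattering across
    half a chromosome.
    """
    cfg = truth.config
    rng = _rng(cfg.seed, 3, study_index)
    pop = study_population(truth, study_index)

    loci: list[MarkerLocus] = []
    for chrom in truth.master_map.chromosomes:
        master_loci = truth.master_map.loci(chrom)
        n_keep = int(round(cfg.marker_subsample_fraction * len(master_loci)))
        idx = np.sort(rng.choice(len(master_loci), size=n_keep, replace=False))
        if len(idx) < 2:
            continue  # chromosome dropped from this study
        for i in idx:
            m = master_loci[i]
            jitter = rng.normal(0.0, cfg.map_jitter_sd_cm) if cfg.map_jitter_sd_cm > 0 else 0.0
            loci.append(MarkerLocus(m.name, chrom, max(0.0, m.pos_cm + jitter)))
    study_map = LinkageMap(pop.study_id, loci, weight=pop.n_lines)

    records: list[QTLRecord] = []
    for qi, (mi, stress, si) in enumerate(truth.blueprints):
        if si != study_index:
            continue
        planted = truth.mqtls[mi]
        if planted.chromosome not in study_map:
            continue
        r2 = float(rng.uniform(*cfg.r2_range))
        lod = float(rng.uniform(*cfg.lod_range))
        ci = confidence_interval(pop.pop_type, pop.n_lines, r2)
        scatter_sd = min(ci / 3.92, cfg.qtl_scatter_sd_cm)
        peak = planted.pos_cm + (
            rng.normal(0.0, scatter_sd) if scatter_sd > 0 else 0.0
        )
        peak = float(np.clip(peak, 0.0, cfg.chromosome_length_cm))
        chrom_loci = study_map.loci(planted.chromosome)
        below = [m for m in chrom_loci if m.pos_cm <= peak]
        above = [m for m in chrom_loci if m.pos_cm > peak]
        flank_left = (below[-1] if below else chrom_loci[0]).name
        flank_right = (above[0] if above else chrom_loci[-1]).name
        records.append(
            QTLRecord(
                qtl_id=f"{pop.study_id}_q{qi:04d}",
                trait=f"{stress}_trait",
                stress=stress,
                chromosome=planted.chromosome,
                peak_cm=peak,
                r2=r2,
                lod=lod,
                flank_left=flank_left,
                flank_right=flank_right,
                population=pop,
            )
        )
    return study_map, records


@dataclass
class SyntheticDataset:
    """A complete generated dataset ready for the pipeline."""

    truth: SyntheticTruth
    study_maps: dict[str, LinkageMap]
    catalog: QTLCatalog

    @property
    def config(self) -> SimulationConfig:
        return self.truth.config


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate truth, all study maps and the pooled QTL catalog."""
    truth = generate_truth(config)
    cfg = truth.config
    maps: dict[str, LinkageMap] = {}
    records: list[QTLRecord] = []
    studies: dict[str, PopulationDescriptor] = {}
    for si in range(cfg.n_studies):
        study_map, recs = simulate_study(truth, si)
        maps[study_map.map_id] = study_map
        records.extend(recs)
        studies[study_map.map_id] = study_population(truth, si)
    return SyntheticDataset(truth, maps, QTLCatalog(records, studies))


def simulate_annotation(
    truth: SyntheticTruth,
    genes_per_chromosome: int = 50,
    cm_to_bp_rate: float = 1e6,
    gene_length_bp: int = 5000,
) -> tuple[list[GeneFeature], pd.DataFrame]:
    """Anchors at every master marker (bp = cM * rate) and uniform genes.

    Supports candidate-gene overlap tests without a real genome: the cM->bp
    relation is exactly linear, so expected overlaps are computable by hand.
    """
    if cm_to_bp_rate <= 0:
        raise ValueError("cm_to_bp_rate must be positive")
    cfg = truth.config
    rng = _rng(cfg.seed, 4)
    anchor_rows = []
    genes: list[GeneFeature] = []
    for chrom in truth.master_map.chromosomes:
        for m in truth.master_map.loci(chrom):
            anchor_rows.append(
                {"marker": m.name, "chromosome": chrom, "cm": m.pos_cm,
                 "bp": m.pos_cm * cm_to_bp_rate}
            )
        span = cfg.chromosome_length_cm * cm_to_bp_rate
        starts = np.sort(rng.uniform(1, max(span - gene_length_bp, 2), genes_per_chromosome))
        for gi, start in enumerate(starts):
            genes.append(
                GeneFeature(f"g{chrom}_{gi:03d}", chrom, int(start),
                            int(start) + gene_length_bp - 1, "+")
            )
    return genes, pd.DataFrame(anchor_rows, columns=["marker", "chromosome", "cm", "bp"])
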