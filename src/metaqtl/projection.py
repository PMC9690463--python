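"""Confidence-interval recalculation and QTL transfer onto the consensus map.

Before meta-analysis, every QTL's 95% confidence interval is recomputed
from its mapping population with the empirical population-type constants of
the QTL-precision literature:

    CI95 (cM) = k(pop) / (N * R^2)

with k = 530 for F2 and backcross populations, k = 163 for recombinant
inbred lines and k = 287.30 for doubled haploids, N the number of lines and
R² the fraction of phenotypic variance explained.  The doubled-haploid
constant is configurable (:data:`CI_CONSTANTS` is a plain dict) since
different compendia print slightly different values.

QTL midpoints and their recalculated CI endpoints are then transferred onto
the consensus map by piecewise-linear interpolation between markers the
source map shares with the consensus; positions outside the shared span are
extrapolated with the nearest interval's scale and clamped to the
chromosome bounds, with a warning flag on the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from metaqtl.catalog import QTLRecord
from metaqtl.errors import ProjectionError
from metaqtl.linkage import LinkageMap, common_markers

#: Population-type constants k in CI95 = k / (N * R^2).
CI_CONSTANTS: dict[str, float] = {"F2": 530.0, "BC": 530.0, "RIL": 163.0, "DH": 287.30}


def confidence_interval(
    pop_type: str,
    n_lines: int,
    r2: float,
    constants: dict[str, float] | None = None,
) -> float:
    """95% CI width (cM) of a QTL position from population type, N and R².

    Strictly decreasing in both ``n_lines`` and ``r2``: doubling either
    halves the interval.
    """
    constants = constants or CI_CONSTANTS
    if pop_type not in constants:
        raise ProjectionError(f"unknown population type {pop_type!r}")
    if n_lines < 2:
        raise ProjectionError("population must have at least 2 lines")
    if not (0.0 < r2 <= 1.0):
        raise ProjectionError("CI undefined: r2 must be in (0, 1]")
    return constants[pop_type] / (n_lines * r2)


@dataclass(frozen=True)
class ProjectedQTL:
    """A QTL after CI recalculation and transfer onto the consensus map."""

    source: QTLRecord
    ci_cm: float
    consensus_chromosome: str
    consensus_peak_cm: float
    consensus_ci_lo_cm: float
    consensus_ci_hi_cm: float
    projection_scale: float
    extrapolated: bool = False
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.ci_cm <= 0:
            raise ValueError("recalculated CI width must be positive")
        if not (self.consensus_ci_lo_cm <= self.consensus_peak_cm <= self.consensus_ci_hi_cm):
            raise ValueError(f"{self.qtl_id}: projected peak outside its CI")

    # convenience passthroughs so grouping/reporting code can treat source
    # and projected records uniformly
    @property
    def qtl_id(self) -> str:
        return self.source.qtl_id

    @property
    def stress(self) -> str:
        return self.source.stress

    @property
    def chromosome(self) -> str:
        return self.consensus_chromosome

    @property
    def r2(self) -> float | None:
        return self.source.r2

    @property
    def position_sd_cm(self) -> float:
        """Standard deviation implied by the 95% CI (normal interval: CI/3.92)."""
        return self.ci_cm / 3.92


class MapProjector:
    """Piecewise-linear coordinate transfer for one chromosome.

    Built from the markers a source map shares with the consensus.  To
    guarantee a monotone (order-preserving) transfer even when residual
    order conflicts survive, the anchor set is reduced to the longest
    subsequence of shared markers whose consensus positions are
    nondecreasing in source order.
    """

    def __init__(self, source_map: LinkageMap, consensus: LinkageMap, chromosome: str):
        shared = common_markers(source_map, consensus, chromosome)
        if len(shared) < 2:
            raise ProjectionError(
                f"chromosome {chromosome}: fewer than 2 markers common to "
                f"{source_map.map_id!r} and the consensus"
            )
        src = np.array([s[1] for s in shared])
        dst = np.array([s[2] for s in shared])
        keep = _longest_nondecreasing(dst)
        src, dst = src[keep], dst[keep]
        # collapse source-position ties to keep interpolation well defined
        uniq, inv = np.unique(np.round(src, 9), return_index=True)
        src, dst = src[inv], dst[inv]
        if len(src) < 2:
            raise ProjectionError(
                f"chromosome {chromosome}: no order-consistent marker pair for projection"
            )
        self.chromosome = chromosome
        self.src = src
        self.dst = dst
        cons_loci = consensus.loci(chromosome)
        self.chrom_lo = 0.0
        self.chrom_hi = max(m.pos_cm for m in cons_loci)

    def local_scale(self, pos_cm: float) -> float:
        """cM-per-cM stretch of the interval containing ``pos_cm``."""
        i = int(np.clip(np.searchsorted(self.src, pos_cm, side="right") - 1, 0, len(self.src) - 2))
        return float((self.dst[i + 1] - self.dst[i]) / (self.src[i + 1] - self.src[i]))

    def transform(self, pos_cm: float) -> tuple[float, bool, bool]:
        """Transfer one source position; returns (pos, extrapolated, clamped)."""
        extrapolated = clamped = False
        if pos_cm < self.src[0]:
            scale = (self.dst[1] - self.dst[0]) / (self.src[1] - self.src[0])
            out = self.dst[0] - scale * (self.src[0] - pos_cm)
            extrapolated = True
        elif pos_cm > self.src[-1]:
            scale = (self.dst[-1] - self.dst[-2]) / (self.src[-1] - self.src[-2])
            out = self.dst[-1] + scale * (pos_cm - self.src[-1])
            extrapolated = True
        else:
            out = float(np.interp(pos_cm, self.src, self.dst))
        if out < self.chrom_lo:
            out, clamped = self.chrom_lo, True
        elif out > self.chrom_hi:
            out, clamped = self.chrom_hi, True
        return float(out), extrapolated, clamped


def _longest_nondecreasing(values: np.ndarray) -> np.ndarray:
    """Indices of the longest nondecreasing subsequence (patience sorting)."""
    import bisect

    n = len(values)
    tails: list[float] = []
    tail_idx: list[int] = []
    prev = np.full(n, -1)
    for i, v in enumerate(values):
        j = bisect.bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        if j > 0:
            prev[i] = tail_idx[j - 1]
    out = []
    k = tail_idx[-1]
    while k >= 0:
        out.append(k)
        k = prev[k]
    return np.array(out[::-1])


def project_position(
    pos_cm: float, source_map: LinkageMap, consensus: LinkageMap, chromosome: str
) -> float:
    """Transfer a single source-map position onto the consensus (cM).

    Convenience wrapper around :class:`MapProjector`; monotone in
    ``pos_cm`` and an exact fixed point at every shared marker.
    """
    return MapProjector(source_map, consensus, chromosome).transform(pos_cm)[0]


def project_qtl(
    record: QTLRecord,
    source_map: LinkageMap,
    consensus: LinkageMap,
    constants: dict[str, float] | None = None,
    projector: MapProjector | None = None,
) -> ProjectedQTL:
    """Recalculate a record's 95% CI and project peak and CI endpoints.

    The CI endpoints (peak ± CI/2 on the source scale) are each transferred
    through the same piecewise-linear map as the peak, so a locally
    stretched consensus stretches the interval with it.
    """
    if record.r2 is None:
        raise ProjectionError(f"{record.qtl_id}: r2 required to recalculate the CI")
    ci = confidence_interval(
        record.population.pop_type, record.population.n_lines, record.r2, constants
    )
    proj = projector or MapProjector(source_map, consensus, record.chromosome)
    peak, pe, pc = proj.transform(record.peak_cm)
    lo, le, lc = proj.transform(record.peak_cm - ci / 2.0)
    hi, he, hc = proj.transform(record.peak_cm + ci / 2.0)
    lo, hi = min(lo, peak), max(hi, peak)
    return ProjectedQTL(
        source=record,
        ci_cm=ci,
        consensus_chromosome=record.chromosome,
        consensus_peak_cm=peak,
        consensus_ci_lo_cm=lo,
        consensus_ci_hi_cm=hi,
        projection_scale=proj.local_scale(record.peak_cm),
        extrapolated=pe or le or he,
        clamped=pc or lc or hc,
    )


def project_catalog(
    records: Sequence[QTLRecord],
    source_maps: dict[str, LinkageMap],
    consensus: LinkageMap,
    constants: dict[str, float] | None = None,
) -> tuple[list[ProjectedQTL], list[tuple[str, str]]]:
    """Project every record; returns (projected, [(qtl_id, failure reason)])."""
    projectors: dict[tuple[str, str], MapProjector] = {}
    projected: list[ProjectedQTL] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        sid = rec.population.study_id
        key = (sid, rec.chromosome)
        try:
            if key not in projectors:
                projectors[key] = MapProjector(source_maps[sid], consensus, rec.chromosome)
            projected.append(
                project_qtl(rec, source_maps[sid], consensus, constants, projectors[key])
            )
        except (ProjectionError, KeyError) as exc:
            failures.append((rec.qtl_id, str(exc)))
    return projected, failures
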