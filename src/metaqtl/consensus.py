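"""Consensus (composite) genetic-map construction by weighted least squares.

Individual linkage maps disagree on marker spacing and, occasionally, on
local marker order.  The builder merges them onto a reference frame in two
stages that mirror common composite-map practice: maps are integrated one
at a time in descending weight; a chromosome of an incoming map is only
accepted if it shares at least two markers with the growing consensus, and
order conflicts are removed first with the inversion filter
(:func:`metaqtl.linkage.filter_inversions`).  Consensus coordinates of the
shared markers then minimise

    sum over maps m, adjacent shared pairs (a, b):
        w_m * ((x_b - x_a) - d_ab^m)^2

i.e. a weighted least-squares fit to the inter-marker distances, anchored
per chromosome at the smallest-position reference marker.  Markers private
to a single map carry no distance constraints linking maps and are placed
afterwards by linear interpolation between their nearest flanking shared
markers on their own map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from metaqtl.errors import MetaQTLError
from metaqtl.linkage import (
    LinkageMap,
    MarkerLocus,
    common_markers,
    detect_inversions,
    filter_inversions,
)

REASON_TOO_FEW_COMMON = "fewer than 2 common markers"
REASON_INCONSISTENT = "all maps inconsistent"


@dataclass
class ChromosomeBuildInfo:
    """Per-chromosome merge diagnostics."""

    n_maps_merged: int = 0
    n_common_markers: int = 0
    rss: float = 0.0
    #: marker-placement noise implied by the fit's unweighted residuals,
    #: sqrt(mean(residual^2)/2): each inter-marker distance observation has
    #: two noisy endpoints.  Used downstream as the projection-noise term.
    marker_noise_sd_cm: float = 0.0
    shifted_by_cm: float = 0.0
    dropped_disconnected: list[str] = field(default_factory=list)


@dataclass
class ConsensusBuildReport:
    """Diagnostics of a consensus build.

    ``excluded_chromosomes`` holds ``(map_id, chromosome, reason)`` with
    reason one of :data:`REASON_TOO_FEW_COMMON` / :data:`REASON_INCONSISTENT`;
    ``discarded_markers`` holds ``(map_id, chromosome, marker, reason)``.
    """

    per_chromosome: dict[str, ChromosomeBuildInfo] = field(default_factory=dict)
    excluded_chromosomes: list[tuple[str, str, str]] = field(default_factory=list)
    discarded_markers: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def total_rss(self) -> float:
        return sum(c.rss for c in self.per_chromosome.values())

    def to_dict(self) -> dict:
        return {
            "per_chromosome": {
                chrom: {
                    "n_maps_merged": info.n_maps_merged,
                    "n_common_markers": info.n_common_markers,
                    "rss": info.rss,
                    "shifted_by_cm": info.shifted_by_cm,
                    "dropped_disconnected": info.dropped_disconnected,
                }
                for chrom, info in self.per_chromosome.items()
            },
            "excluded_chromosomes": [list(t) for t in self.excluded_chromosomes],
            "discarded_markers": [list(t) for t in self.discarded_markers],
            "total_rss": self.total_rss,
        }


def _pava(values: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: nearest nondecreasing sequence (uniform weights)."""
    vals = values.astype(float).copy()
    n = len(vals)
    weights = np.ones(n)
    # blocks as (value, weight) merged left-to-right
    out_v: list[float] = []
    out_w: list[float] = []
    for v, w in zip(vals, weights):
        out_v.append(v)
        out_w.append(w)
        while len(out_v) > 1 and out_v[-2] > out_v[-1]:
            v2, w2 = out_v.pop(), out_w.pop()
            v1, w1 = out_v.pop(), out_w.pop()
            out_v.append((v1 * w1 + v2 * w2) / (w1 + w2))
            out_w.append(w1 + w2)
    result = np.empty(n)
    i = 0
    for v, w in zip(out_v, out_w):
        k = int(round(w))
        result[i : i + k] = v
        i += k
    return result


def _interp_transfer(pos: float, src: np.ndarray, dst: np.ndarray) -> float:
    """Piecewise-linear transfer src->dst; outside the span the nearest
    interval's scale is extended."""
    if len(src) == 1:
        return float(dst[0] + (pos - src[0]))
    if pos <= src[0]:
        scale = (dst[1] - dst[0]) / (src[1] - src[0])
        return float(dst[0] + scale * (pos - src[0]))
    if pos >= src[-1]:
        scale = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
        return float(dst[-1] + scale * (pos - src[-1]))
    return float(np.interp(pos, src, dst))


class _ChromosomeAssembly:
    """Accumulates accepted sources for one chromosome and refits positions."""

    def __init__(self, chromosome: str, reference_loci: list[MarkerLocus], ref_weight: float):
        self.chromosome = chromosome
        self.ref_names = [m.name for m in reference_loci]
        self.ref_pos = {m.name: m.pos_cm for m in reference_loci}
        # sources: (map_id, weight, [(name, pos) sorted by pos])
        self.sources: list[tuple[str, float, list[tuple[str, float]]]] = [
            ("__reference__", ref_weight, [(m.name, m.pos_cm) for m in reference_loci])
        ]
        self.estimate: dict[str, float] = dict(self.ref_pos)
        self.info = ChromosomeBuildInfo()

    def marker_names(self) -> set[str]:
        return set(self.estimate)

    def add_source(self, map_id: str, weight: float, loci: list[tuple[str, float]]) -> None:
        self.sources.append((map_id, weight, sorted(loci, key=lambda t: t[1])))
        self.info.n_maps_merged += 1

    def refit(self) -> None:
        membership: dict[str, int] = {}
        for _, _, loci in self.sources:
            for name, _ in loci:
                membership[name] = membership.get(name, 0) + 1
        shared = {n for n, c in membership.items() if c >= 2}
        if not shared:
            # nothing merged yet: consensus is the reference as-is
            self.estimate = dict(self.ref_pos)
            return

        names = sorted(shared)
        index = {n: i for i, n in enumerate(names)}
        anchor_candidates = [n for n in self.ref_names if n in shared]
        if not anchor_candidates:
            raise MetaQTLError(
                f"chromosome {self.chromosome}: no reference marker among shared markers"
            )
        anchor = min(anchor_candidates, key=lambda n: (self.ref_pos[n], n))

        ia, ib, dist, wts = [], [], [], []
        for _, weight, loci in self.sources:
            chain = [(n, p) for n, p in loci if n in shared]
            for (na, pa), (nb, pb) in zip(chain, chain[1:]):
                ia.append(index[na])
                ib.append(index[nb])
                dist.append(pb - pa)
                wts.append(weight)
        ia = np.asarray(ia)
        ib = np.asarray(ib)
        dist = np.asarray(dist, dtype=float)
        wts = np.asarray(wts, dtype=float)

        n = len(names)
        adj = coo_matrix((np.ones(len(ia)), (ia, ib)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        keep_label = labels[index[anchor]]
        dropped = [names[i] for i in range(n) if labels[i] != keep_label]
        if dropped:
            self.info.dropped_disconnected = sorted(
                set(self.info.dropped_disconnected) | set(dropped)
            )
        keep = labels == keep_label
        mask = keep[ia] & keep[ib]
        ia, ib, dist, wts = ia[mask], ib[mask], dist[mask], wts[mask]

        # weighted normal equations for minimize sum w ((x_b - x_a) - d)^2,
        # with the anchor pinned to its reference coordinate
        ata = np.zeros((n, n))
        atb = np.zeros(n)
        np.add.at(ata, (ia, ia), wts)
        np.add.at(ata, (ib, ib), wts)
        np.add.at(ata, (ia, ib), -wts)
        np.add.at(ata, (ib, ia), -wts)
        np.add.at(atb, ib, wts * dist)
        np.add.at(atb, ia, -wts * dist)

        a_i = index[anchor]
        free_idx = np.array([i for i in range(n) if keep[i] and i != a_i], dtype=int)
        x = np.full(n, np.nan)
        x[a_i] = self.ref_pos[anchor]
        if len(free_idx):
            rhs = atb[free_idx] - ata[np.ix_(free_idx, [a_i])].ravel() * x[a_i]
            sub = ata[np.ix_(free_idx, free_idx)]
            try:
                x[free_idx] = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                x[free_idx], *_ = np.linalg.lstsq(sub, rhs, rcond=None)
        resid = x[ib] - x[ia] - dist
        self.info.rss = float((wts * resid**2).sum())
        self.info.marker_noise_sd_cm = (
            float(np.sqrt(np.mean(resid**2) / 2.0)) if len(resid) else 0.0
        )

        fitted = {names[i]: float(x[i]) for i in range(n) if keep[i]}

        # keep reference-marker order consistent with the reference
        ref_in_fit = [nm for nm in self.ref_names if nm in fitted]
        ref_in_fit.sort(key=lambda nmm: (self.ref_pos[nmm], nmm))
        if len(ref_in_fit) > 1:
            adjusted = _pava(np.array([fitted[nm] for nm in ref_in_fit]))
            for nm, v in zip(ref_in_fit, adjusted):
                fitted[nm] = float(v)

        # private markers: interpolate on their own source between flanking
        # shared markers
        estimate = dict(fitted)
        for _, _, loci in self.sources:
            src_shared = [(n2, p2) for n2, p2 in loci if n2 in fitted]
            if len(src_shared) < 1:
                continue
            src = np.array([p for _, p in src_shared])
            dst = np.array([fitted[n2] for n2, _ in src_shared])
            order = np.argsort(src, kind="stable")
            src, dst = src[order], dst[order]
            for n2, p2 in loci:
                if n2 in fitted or n2 in dropped:
                    continue
                if membership[n2] == 1:
                    estimate[n2] = _interp_transfer(p2, src, dst)

        self.info.n_common_markers = len(fitted)

        # origin convention: chromosome starts at 0 if the fit went negative
        low = min(estimate.values())
        if low < 0:
            estimate = {n2: p2 - low for n2, p2 in estimate.items()}
            self.info.shifted_by_cm = -low
        self.estimate = estimate

    def estimate_map(self) -> LinkageMap:
        loci = [MarkerLocus(n, self.chromosome, p) for n, p in self.estimate.items()]
        return LinkageMap("__consensus__", loci)


def build_consensus(
    reference: LinkageMap,
    maps: Sequence[LinkageMap],
    weights: Sequence[float] | None = None,
    inversion_threshold_cm: float = 1.0,
    map_id: str = "consensus",
) -> tuple[LinkageMap, ConsensusBuildReport]:
    """Merge individual maps onto a reference into a consensus map.

    ``weights`` overrides the maps' own ``weight`` attributes (same order).
    Maps are merged in descending weight.  Returns the consensus map and a
    :class:`ConsensusBuildReport`; merging a map with itself returns the map
    unchanged with zero residual.
    """
    if not reference.chromosomes:
        raise MetaQTLError("reference map is empty")
    if weights is not None:
        if len(weights) != len(maps):
            raise ValueError("weights length must match maps")
        maps = [
            LinkageMap(m.map_id, m.all_loci(), weight=w) for m, w in zip(maps, weights)
        ]

    report = ConsensusBuildReport()
    assemblies: dict[str, _ChromosomeAssembly] = {
        chrom: _ChromosomeAssembly(chrom, reference.loci(chrom), reference.weight)
        for chrom in reference.chromosomes
    }

    for m in sorted(maps, key=lambda mm: -mm.weight):
        for chrom in m.chromosomes:
            asm = assemblies.get(chrom)
            if asm is None:
                report.excluded_chromosomes.append((m.map_id, chrom, REASON_TOO_FEW_COMMON))
                continue
            current = asm.estimate_map()
            shared = common_markers(current, m, chrom)
            if len(shared) < 2:
                report.excluded_chromosomes.append((m.map_id, chrom, REASON_TOO_FEW_COMMON))
                continue
            inversions = detect_inversions(m, current, chrom)
            loci = [(loc.name, loc.pos_cm) for loc in m.loci(chrom)]
            if inversions:
                discard, _ = filter_inversions(inversions, threshold=inversion_threshold_cm)
                for name in discard:
                    report.discarded_markers.append(
                        (m.map_id, chrom, name, "order conflict with consensus")
                    )
                discard_set = set(discard)
                loci = [t for t in loci if t[0] not in discard_set]
                still_shared = [s for s in shared if s[0] not in discard_set]
                if len(still_shared) < 2:
                    report.excluded_chromosomes.append((m.map_id, chrom, REASON_INCONSISTENT))
                    continue
            asm.add_source(m.map_id, m.weight, loci)
            asm.refit()

    all_loci: list[MarkerLocus] = []
    for chrom, asm in assemblies.items():
        for name, pos in sorted(asm.estimate.items(), key=lambda t: (t[1], t[0])):
            all_loci.append(MarkerLocus(name, chrom, pos))
        report.per_chromosome[chrom] = asm.info

    return LinkageMap(map_id, all_loci, weight=1.0), report


def map_length_stats(lm: LinkageMap) -> dict:
    """Per-chromosome and total length (cM), marker count, mean spacing.

    Total length is the sum over chromosomes of (max - min) position; the
    mean adjacent spacing divides by (markers - 1) summed over chromosomes
    with at least two markers (a single-marker chromosome contributes zero
    length and no spacing interval).
    """
    per_chrom = {}
    total_len = 0.0
    n_markers = 0
    n_intervals = 0
    for chrom in lm.chromosomes:
        loci = lm.loci(chrom)
        length = lm.chromosome_length(chrom)
        per_chrom[chrom] = {
            "length_cm": length,
            "n_markers": len(loci),
            "mean_spacing_cm": (length / (len(loci) - 1)) if len(loci) > 1 else float("nan"),
        }
        total_len += length
        n_markers += len(loci)
        if len(loci) > 1:
            n_intervals += len(loci) - 1
    return {
        "per_chromosome": per_chrom,
        "total_length_cm": total_len,
        "n_markers": n_markers,
        "mean_spacing_cm": (total_len / n_intervals) if n_intervals else float("nan"),
    }
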