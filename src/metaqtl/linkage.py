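"""Genetic linkage-map model, map-file I/O and order-consistency diagnostics.

A :class:`LinkageMap` stores, per chromosome, an ordered list of markers
with centimorgan positions.  Individual maps from different studies share
only a subset of markers; before they can be merged into a consensus map,
marker-order conflicts (inversions) between a map and a reference must be
detected and filtered.  The filtering rule follows standard consensus-map
practice: inconsistently ordered loci are discarded, except that for a pair
of inverted markers closer than a configurable threshold (default 1 cM,
i.e. markers so tightly linked that their true order is effectively
unresolved) only one of the two is dropped, to retain a maximum number of
common markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from metaqtl.errors import ChromosomeExclusionError, MapFormatError

#: Tolerance (cM) below which two positions are considered tied; avoids
#: spurious order flips from text round-trips of double-precision values.
POSITION_TOL = 1e-9


@dataclass(frozen=True)
class MarkerLocus:
    """A single mapped marker: name, chromosome and position in cM."""

    name: str
    chromosome: str
    pos_cm: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be nonempty")
        if not np.isfinite(self.pos_cm):
            raise ValueError(f"marker {self.name}: position must be finite")


class LinkageMap:
    """Ordered markers with cM positions per chromosome.

    Parameters
    ----------
    map_id:
        Identifier for the map (study id, "consensus", ...).
    loci:
        Iterable of :class:`MarkerLocus`.  Stored sorted by position within
        each chromosome; the input order is irrelevant.
    weight:
        Positive merging weight used by the consensus builder.  Defaults to
        1; for study maps the study's population size is the conventional
        choice.
    """

    def __init__(self, map_id: str, loci: Iterable[MarkerLocus], weight: float = 1.0):
        if weight <= 0:
            raise ValueError("map weight must be positive")
        self.map_id = map_id
        self.weight = float(weight)
        by_chrom: dict[str, list[MarkerLocus]] = {}
        for locus in loci:
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        self._loci: dict[str, list[MarkerLocus]] = {}
        for chrom in sorted(by_chrom):
            markers = sorted(by_chrom[chrom], key=lambda m: (m.pos_cm, m.name))
            names = [m.name for m in markers]
            if len(set(names)) != len(names):
                dup = sorted({n for n in names if names.count(n) > 1})
                raise MapFormatError(
                    f"map {map_id!r}: duplicate marker(s) on {chrom}: {', '.join(dup)}"
                )
            self._loci[chrom] = markers

    # -- accessors ---------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self._loci)

    def loci(self, chromosome: str) -> list[MarkerLocus]:
        """Markers on one chromosome, sorted by position."""
        return list(self._loci.get(chromosome, []))

    def positions(self, chromosome: str) -> dict[str, float]:
        """Mapping marker name -> cM position for one chromosome."""
        return {m.name: m.pos_cm for m in self._loci.get(chromosome, [])}

    def all_loci(self) -> list[MarkerLocus]:
        return [m for chrom in self._loci.values() for m in chrom]

    def n_markers(self, chromosome: str | None = None) -> int:
        if chromosome is not None:
            return len(self._loci.get(chromosome, []))
        return sum(len(v) for v in self._loci.values())

    def chromosome_length(self, chromosome: str) -> float:
        loci = self._loci.get(chromosome, [])
        if not loci:
            return 0.0
        return loci[-1].pos_cm - loci[0].pos_cm

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self._loci

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkageMap):
            return NotImplemented
        return self.map_id == other.map_id and self.to_frame().equals(other.to_frame())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LinkageMap({self.map_id!r}, {self.n_markers()} markers on "
            f"{len(self._loci)} chromosomes, weight={self.weight:g})"
        )

    # -- conversion --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Three-column DataFrame (marker, chromosome, pos_cm)."""
        rows = [(m.name, m.chromosome, m.pos_cm) for m in self.all_loci()]
        return pd.DataFrame(rows, columns=["marker", "chromosome", "pos_cm"])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, map_id: str, weight: float = 1.0
    ) -> "LinkageMap":
        loci = [
            MarkerLocus(str(r.marker), str(r.chromosome), float(r.pos_cm))
            for r in frame.itertuples()
        ]
        return cls(map_id, loci, weight=weight)


# ---------------------------------------------------------------------------
# I/O: 3-column delimited text (marker, chromosome, position-cM)
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["marker", "chromosome", "pos_cm"]


def read_map(
    path: str | Path,
    map_id: str | None = None,
    weight: float = 1.0,
    sep: str | None = None,
    on_error: str = "raise",
) -> LinkageMap | tuple[LinkageMap, list[str]]:
    """Read a linkage map from 3-column delimited text.

    The header row is optional (detected by whether the third field of the
    first line parses as a number).  ``on_error="raise"`` aborts on any
    invalid row; ``on_error="report"`` skips invalid rows and returns
    ``(map, row_error_report)``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, header=None, engine="python", dtype=str,
                      comment="#", skip_blank_lines=True)
    if raw.shape[1] < 3:
        raise MapFormatError(f"{path}: expected 3 columns (marker, chromosome, cM)")
    raw = raw.iloc[:, :3]
    raw.columns = _MAP_COLUMNS
    first = str(raw.iloc[0, 2])
    try:
        float(first)
    except ValueError:
        raw = raw.iloc[1:].reset_index(drop=True)

    errors: list[str] = []
    loci: list[MarkerLocus] = []
    for i, row in raw.iterrows():
        try:
            pos = float(row.pos_cm)
        except (TypeError, ValueError):
            errors.append(f"row {i}: unparsable cM value {row.pos_cm!r}")
            continue
        if not np.isfinite(pos) or pos < 0:
            errors.append(f"row {i}: negative or non-finite cM {row.pos_cm!r}")
            continue
        loci.append(MarkerLocus(str(row.marker), str(row.chromosome), pos))
    if errors and on_error == "raise":
        raise MapFormatError(f"{path}: " + "; ".join(errors))
    lm = LinkageMap(map_id or path.stem, loci, weight=weight)
    if on_error == "report":
        return lm, errors
    return lm


def write_map(lm: LinkageMap, path: str | Path, sep: str = "\t") -> None:
    """Write a map in the same 3-column format ``read_map`` consumes."""
    lm.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Common markers and inversion diagnostics
# ---------------------------------------------------------------------------


def common_markers(
    map_a: LinkageMap, map_b: LinkageMap, chromosome: str
) -> list[tuple[str, float, float]]:
    """Markers shared by both maps on one chromosome.

    Returns ``(name, pos_in_a, pos_in_b)`` tuples ordered by position in
    ``map_a``.  Empty if the chromosome is missing from either map.
    """
    pos_a = map_a.positions(chromosome)
    pos_b = map_b.positions(chromosome)
    shared = sorted(set(pos_a) & set(pos_b), key=lambda n: (pos_a[n], n))
    return [(n, pos_a[n], pos_b[n]) for n in shared]


@dataclass(frozen=True)
class InversionPair:
    """A pair of common markers ordered oppositely in two maps.

    ``marker_a``/``marker_b`` are in reference order (``marker_a`` first on
    the reference); ``ref_sep_cm`` is their reference-map separation, the
    distance the 1 cM close-linkage rule is measured on.  ``disp_a`` and
    ``disp_b`` are each marker's rank displacement between the two maps,
    used as the "farther from its reference position" tie-break.
    """

    marker_a: str
    marker_b: str
    ref_sep_cm: float
    disp_a: int = 0
    disp_b: int = 0

    @property
    def markers(self) -> tuple[str, str]:
        return (self.marker_a, self.marker_b)


def detect_inversions(
    map_x: LinkageMap, reference: LinkageMap, chromosome: str
) -> list[InversionPair]:
    """All common-marker pairs whose relative order differs between maps.

    Exhaustive over the C(n, 2) pairs of the n common markers; ties in
    position (within ``POSITION_TOL``) are not counted as order conflicts.
    Raises :class:`ChromosomeExclusionError` with fewer than two common
    markers, signalling the chromosome-exclusion rule of the consensus
    builder.
    """
    shared = common_markers(reference, map_x, chromosome)
    if len(shared) < 2:
        raise ChromosomeExclusionError(
            f"chromosome {chromosome}: fewer than 2 common markers between "
            f"{map_x.map_id!r} and {reference.map_id!r}"
        )
    names = [s[0] for s in shared]  # ordered by reference position
    ref_pos = np.array([s[1] for s in shared])
    x_pos = np.array([s[2] for s in shared])
    rank_ref = np.arange(len(names))
    rank_x = np.empty(len(names), dtype=int)
    rank_x[np.lexsort((names, x_pos))] = np.arange(len(names))
    disp = np.abs(rank_x - rank_ref)

    d_ref = ref_pos[None, :] - ref_pos[:, None]  # [i, j] = pos_j - pos_i
    d_x = x_pos[None, :] - x_pos[:, None]
    flipped = np.triu((d_ref > POSITION_TOL) & (d_x < -POSITION_TOL), k=1)
    pairs = [
        InversionPair(names[i], names[j], float(d_ref[i, j]), int(disp[i]), int(disp[j]))
        for i, j in zip(*np.nonzero(flipped))
    ]
    return pairs


def filter_inversions(
    pairs: Sequence[InversionPair], threshold: float = 1.0
) -> tuple[list[str], list[str]]:
    """Decide which markers to discard to remove all order conflicts.

    Rules: an inverted pair separated by at least ``threshold`` cM on the
    reference loses both markers (truly inconsistent loci); a pair closer
    than the threshold loses exactly one (very closely linked markers whose
    order is unresolved).  Which member of a close pair is dropped follows
    a greedy rule aimed at keeping the maximum number of markers: the one
    involved in more conflicts, then the one with the larger rank
    displacement, then the lexicographically later name.

    Returns ``(markers_to_discard, markers_retained)`` over the markers
    appearing in ``pairs``.
    """
    all_markers = sorted({m for p in pairs for m in p.markers})
    discard: set[str] = set()

    for p in pairs:
        if p.ref_sep_cm >= threshold:
            discard.update(p.markers)

    open_pairs = [p for p in pairs if p.ref_sep_cm < threshold
                  and not (set(p.markers) & discard)]
    disp: dict[str, int] = {}
    for p in pairs:
        disp[p.marker_a] = max(disp.get(p.marker_a, 0), p.disp_a)
        disp[p.marker_b] = max(disp.get(p.marker_b, 0), p.disp_b)
    while open_pairs:
        counts: dict[str, int] = {}
        for p in open_pairs:
            for m in p.markers:
                counts[m] = counts.get(m, 0) + 1
        victim = max(counts, key=lambda m: (counts[m], disp.get(m, 0), m))
        discard.add(victim)
        open_pairs = [p for p in open_pairs if victim not in p.markers]

    retained = [m for m in all_markers if m not in discard]
    return sorted(discard), retained


def drop_markers(lm: LinkageMap, names: Iterable[str]) -> LinkageMap:
    """A copy of the map with the named markers removed (all chromosomes)."""
    drop = set(names)
    kept = [m for m in lm.all_loci() if m.name not in drop]
    return LinkageMap(lm.map_id, kept, weight=lm.weight)
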