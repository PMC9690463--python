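"""Data model, validation and I/O for multi-study QTL tables.

A catalog row describes one QTL as reported by a mapping study: trait,
stress class, chromosome, peak position on the study's own map, optional
95% CI bounds and LOD, explained variance R², flanking markers and the
mapping-population descriptor (type and number of lines).  The five stress
classes are fixed — drought, salinity, waterlogging, mineral (toxicity and
deficiency) and low temperature — because the downstream reports are
organised around them; trait names are free text.

The canonical column vocabulary is ``qtl_id, trait, stress, chr, peak_cm,
ci_lo_cm, ci_hi_cm, lod, r2, flank_left, flank_right, pop_type, n_lines,
study_id``; a header mapping adapts foreign layouts.  Invalid rows are not
silently dropped: they are collected into a rejection report with reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from metaqtl.errors import CatalogFormatError
from metaqtl.linkage import LinkageMap

STRESS_CLASSES = ("drought", "salinity", "waterlogging", "mineral", "low_temperature")
POP_TYPES = ("F2", "BC", "RIL", "DH")
CHROMOSOMES = tuple(f"{i}H" for i in range(1, 8))

CANONICAL_COLUMNS = (
    "qtl_id", "trait", "stress", "chr", "peak_cm", "ci_lo_cm", "ci_hi_cm",
    "lod", "r2", "flank_left", "flank_right", "pop_type", "n_lines", "study_id",
)
REQUIRED_COLUMNS = ("qtl_id", "trait", "stress", "chr", "peak_cm", "pop_type",
                    "n_lines", "study_id")


@dataclass(frozen=True)
class PopulationDescriptor:
    """A mapping population: type, size, parents and owning study."""

    pop_type: str
    n_lines: int
    study_id: str
    parents: str = ""

    def __post_init__(self) -> None:
        if self.pop_type not in POP_TYPES:
            raise ValueError(f"unknown population type {self.pop_type!r}")
        if self.n_lines < 2:
            raise ValueError("population must have at least 2 lines")


@dataclass(frozen=True)
class QTLRecord:
    """One literature or simulated QTL on its source map."""

    qtl_id: str
    trait: str
    stress: str
    chromosome: str
    peak_cm: float
    r2: float | None
    population: PopulationDescriptor
    ci_lo_cm: float | None = None
    ci_hi_cm: float | None = None
    lod: float | None = None
    flank_left: str | None = None
    flank_right: str | None = None

    def __post_init__(self) -> None:
        if self.stress not in STRESS_CLASSES:
            raise ValueError(f"{self.qtl_id}: unknown stress class {self.stress!r}")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"{self.qtl_id}: r2 out of [0,1]")
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"{self.qtl_id}: negative LOD")
        if self.ci_lo_cm is not None and self.ci_hi_cm is not None:
            if not (self.ci_lo_cm <= self.peak_cm <= self.ci_hi_cm):
                raise ValueError(f"{self.qtl_id}: peak outside its CI")


@dataclass
class QTLCatalog:
    """A collection of QTL records plus the studies they come from."""

    records: list[QTLRecord] = field(default_factory=list)
    studies: dict[str, PopulationDescriptor] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.qtl_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate qtl_id(s): {', '.join(dup)}")
        for r in self.records:
            sid = r.population.study_id
            if sid not in self.studies:
                self.studies[sid] = r.population
        missing = {r.population.study_id for r in self.records} - set(self.studies)
        if missing:
            raise ValueError(f"records reference unknown studies: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, records: Iterable[QTLRecord]) -> "QTLCatalog":
        recs = list(records)
        sids = {r.population.study_id for r in recs}
        return QTLCatalog(recs, {s: d for s, d in self.studies.items() if s in sids})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "qtl_id": r.qtl_id, "trait": r.trait, "stress": r.stress,
                "chr": r.chromosome, "peak_cm": r.peak_cm,
                "ci_lo_cm": r.ci_lo_cm, "ci_hi_cm": r.ci_hi_cm, "lod": r.lod,
                "r2": r.r2, "flank_left": r.flank_left, "flank_right": r.flank_right,
                "pop_type": r.population.pop_type, "n_lines": r.population.n_lines,
                "study_id": r.population.study_id,
            })
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_float(value, allow_missing=True):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise ValueError("missing numeric value")
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none", "."):
        if allow_missing:
            return None
        raise ValueError("missing numeric value")
    return float(s)


def load_qtl_table(
    path: str | Path,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> tuple[QTLCatalog, pd.DataFrame]:
    """Load a delimited QTL table into a validated catalog.

    ``column_map`` maps foreign header names to the canonical vocabulary
    (``{"Chromosome": "chr", ...}``).  Missing required columns are a hard
    error; rows violating record invariants (unparsable numbers, r2 outside
    [0,1], unknown stress, ...) are rejected with a reason, preserving row
    order.  Returns ``(catalog, rejection_report)`` where the report is a
    DataFrame with the original row index, qtl_id and a ``reason`` column.
    """
    frame = pd.read_csv(Path(path), sep=sep, engine="python", dtype=str)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return catalog_from_frame(frame)


def catalog_from_frame(frame: pd.DataFrame) -> tuple[QTLCatalog, pd.DataFrame]:
    """Validate a canonical-layout DataFrame into (catalog, rejection report)."""
    records: list[QTLRecord] = []
    rejects: list[dict] = []
    for i, row in frame.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValueError, TypeError) as exc:
            rejects.append({"row": i, "qtl_id": row.get("qtl_id", ""), "reason": str(exc)})
    report = pd.DataFrame(rejects, columns=["row", "qtl_id", "reason"])
    return QTLCatalog(records), report


def _record_from_row(row: pd.Series) -> QTLRecord:
    r2 = _parse_float(row.get("r2"))
    if r2 is not None and not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 out of [0,1]")
    n_lines_val = _parse_float(row.get("n_lines"))
    if n_lines_val is None:
        raise ValueError("missing n_lines")
    pop = PopulationDescriptor(
        pop_type=str(row["pop_type"]).strip(),
        n_lines=int(n_lines_val),
        study_id=str(row["study_id"]).strip(),
        parents=str(row.get("parents", "") or ""),
    )
    flank_left = row.get("flank_left")
    flank_right = row.get("flank_right")
    return QTLRecord(
        qtl_id=str(row["qtl_id"]).strip(),
        trait=str(row["trait"]).strip(),
        stress=str(row["stress"]).strip(),
        chromosome=str(row["chr"]).strip(),
        peak_cm=_parse_float(row["peak_cm"], allow_missing=False),
        ci_lo_cm=_parse_float(row.get("ci_lo_cm")),
        ci_hi_cm=_parse_float(row.get("ci_hi_cm")),
        lod=_parse_float(row.get("lod")),
        r2=r2,
        flank_left=None if pd.isna(flank_left) or flank_left in (None, "") else str(flank_left),
        flank_right=None if pd.isna(flank_right) or flank_right in (None, "") else str(flank_right),
        population=pop,
    )


def write_qtl_table(catalog: QTLCatalog, path: str | Path, sep: str = "\t") -> None:
    """Write a catalog in the canonical column layout (round-trip safe)."""
    catalog.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Projectability partition and counting
# ---------------------------------------------------------------------------


def filter_projectable(
    catalog: QTLCatalog,
    consensus: LinkageMap,
    source_maps: Mapping[str, LinkageMap] | None = None,
) -> tuple[QTLCatalog, QTLCatalog, pd.DataFrame]:
    """Partition a catalog into (projectable, unprojectable) against a consensus.

    A record is projectable iff its chromosome survives in the consensus,
    CI recalculation is possible (R² and population size present), and at
    least two markers of its source map's chromosome — or, when source maps
    are not supplied, both of its flanking markers — exist on the consensus
    chromosome.  Returns the two sub-catalogs plus a reason report for the
    unprojectable side; ``|projectable| + |unprojectable| == |input|``.
    """
    keep: list[QTLRecord] = []
    drop: list[QTLRecord] = []
    reasons: list[dict] = []

    def _reject(rec: QTLRecord, why: str) -> None:
        drop.append(rec)
        reasons.append({"qtl_id": rec.qtl_id, "reason": why})

    for rec in catalog.records:
        if rec.chromosome not in consensus:
            _reject(rec, "chromosome absent from consensus")
            continue
        if rec.r2 is None or rec.r2 <= 0:
            _reject(rec, "missing r2 (CI cannot be recalculated)")
            continue
        cons_names = set(consensus.positions(rec.chromosome))
        if source_maps is not None:
            smap = source_maps.get(rec.population.study_id)
            if smap is None:
                _reject(rec, "no source map for study")
                continue
            shared = set(smap.positions(rec.chromosome)) & cons_names
            if len(shared) < 2:
                _reject(rec, "fewer than 2 source markers on consensus chromosome")
                continue
        else:
            flanks = {rec.flank_left, rec.flank_right} - {None}
            if len(flanks) < 2 or not flanks <= cons_names:
                _reject(rec, "flanking markers absent from consensus")
                continue
        keep.append(rec)

    report = pd.DataFrame(reasons, columns=["qtl_id", "reason"])
    return catalog.subset(keep), catalog.subset(drop), report


_GROUP_KEY_GETTERS = {
    "chromosome": lambda r: getattr(r, "chromosome", None) or r.source.chromosome,
    "stress": lambda r: getattr(r, "stress", None) or r.source.stress,
    "mqtl": lambda r: getattr(r, "mqtl_id"),
}


def summarize_counts(records: Iterable, group_keys: Sequence[str]) -> pd.DataFrame:
    """Contingency table of record counts over a subset of {chromosome, stress}.

    Accepts :class:`QTLRecord` or projected records (anything exposing the
    requested keys directly or through a ``source`` attribute).  All
    observed key levels appear explicitly, including zero cells; the total
    over all cells equals the number of input records.
    """
    group_keys = list(group_keys)
    for key in group_keys:
        if key not in _GROUP_KEY_GETTERS:
            raise ValueError(f"unknown group key {key!r}")
    rows = []
    for rec in records:
        rows.append({key: _GROUP_KEY_GETTERS[key](rec) for key in group_keys})
    frame = pd.DataFrame(rows, columns=group_keys)
    if len(group_keys) == 1:
        counts = frame.groupby(group_keys[0]).size().sort_index()
        return counts.to_frame("count")
    table = pd.crosstab(frame[group_keys[0]], frame[group_keys[1]], dropna=False)
    return table.sort_index().sort_index(axis=1)
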