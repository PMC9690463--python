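"""Summary surfaces: distribution tables, stress overlap, classification,
candidate-gene interval overlap.

Mirrors the tables conventionally reported by meta-QTL studies: a
chromosome-by-stress table of projected QTL counts with detected MQTL
counts in brackets, a per-MQTL breakdown of member QTLs by stress class,
an effect-size classification (an MQTL is "mega" when its R² exceeds 30%
of phenotypic variance, "major" when above 20% but not mega), and a
generic candidate-gene lookup that maps an MQTL confidence interval from
genetic (cM) to physical (bp) coordinates through marker anchors and
returns the annotated genes overlapping the interval.

Machine-readable transcriptions of the published barley abiotic-stress
summary tables ship with the package (``metaqtl/data``) and load into the
same structures the pipeline produces, so published margins can be checked
with the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from metaqtl.catalog import STRESS_CLASSES
from metaqtl.errors import MetaQTLError
from metaqtl.meta import MQTL
from metaqtl.projection import ProjectedQTL

MAJOR_R2_THRESHOLD = 0.20
MEGA_R2_THRESHOLD = 0.30


def _data_path(name: str):
    return resources.files("metaqtl.data").joinpath(name)


# ---------------------------------------------------------------------------
# Distribution table (QTL counts with MQTL counts in brackets)
# ---------------------------------------------------------------------------


@dataclass
class DistributionTable:
    """Chromosome-by-stress counts of projected QTLs and detected MQTLs."""

    qtls: pd.DataFrame   # rows: chromosomes, columns: stress classes
    mqtls: pd.DataFrame  # same shape

    def qtl_total(self) -> int:
        return int(self.qtls.to_numpy().sum())

    def mqtl_total(self) -> int:
        return int(self.mqtls.to_numpy().sum())

    def qtl_by_stress(self) -> pd.Series:
        return self.qtls.sum(axis=0)

    def qtl_by_chromosome(self) -> pd.Series:
        return self.qtls.sum(axis=1)

    def mqtl_by_stress(self) -> pd.Series:
        return self.mqtls.sum(axis=0)

    def mqtl_by_chromosome(self) -> pd.Series:
        return self.mqtls.sum(axis=1)

    def formatted(self) -> pd.DataFrame:
        """String cells ``"q(m)"`` with Total row and column."""
        q = self.qtls.copy()
        m = self.mqtls.copy()
        q.loc["Total"] = q.sum(axis=0)
        m.loc["Total"] = m.sum(axis=0)
        q["Total"] = q.sum(axis=1)
        m["Total"] = m.sum(axis=1)
        return q.astype(int).astype(str) + "(" + m.astype(int).astype(str) + ")"


def distribution_table(
    projected: Sequence[ProjectedQTL], mqtls: Sequence[MQTL]
) -> DistributionTable:
    """Count projected QTLs and MQTLs per chromosome and stress class.

    Every member id must belong to a projected record.  Each MQTL is
    counted once, under its modal member stress (ties broken by the
    canonical stress order), so the bracket grand total equals the number
    of MQTLs, matching the published layout.  The QTL grand total equals
    the number of projected records.
    """
    by_id = {p.qtl_id: p for p in projected}
    for mq in mqtls:
        unknown = [m for m in mq.members if m not in by_id]
        if unknown:
            raise MetaQTLError(f"{mq.mqtl_id}: member(s) not in projected set: {unknown}")

    chroms = sorted({p.consensus_chromosome for p in projected})
    qtab = pd.DataFrame(0, index=chroms, columns=list(STRESS_CLASSES))
    mtab = pd.DataFrame(0, index=chroms, columns=list(STRESS_CLASSES))
    for p in projected:
        qtab.loc[p.consensus_chromosome, p.stress] += 1
    for mq in mqtls:
        modal = max(STRESS_CLASSES, key=lambda st: (mq.stress_counts.get(st, 0),
                                                    -STRESS_CLASSES.index(st)))
        mtab.loc[mq.chromosome, modal] += 1
    return DistributionTable(qtab, mtab)


def load_published_distribution() -> DistributionTable:
    """The published chromosome-by-stress distribution table as shipped."""
    frame = pd.read_csv(_data_path("published_distribution.tsv"), sep="\t")
    qtab = frame.pivot(index="chr", columns="stress", values="n_qtls")
    mtab = frame.pivot(index="chr", columns="stress", values="n_mqtls")
    cols = list(STRESS_CLASSES)
    return DistributionTable(qtab[cols].sort_index(), mtab[cols].sort_index())


# ---------------------------------------------------------------------------
# Per-MQTL stress overlap
# ---------------------------------------------------------------------------


def overlap_table(mqtls: Sequence[MQTL]) -> pd.DataFrame:
    """Per-MQTL member counts by stress class.

    Rows are MQTL ids; the five stress columns sum to the membership
    (``total``), and ``n_stresses`` counts the stress classes represented.
    """
    rows = {}
    for mq in mqtls:
        rows[mq.mqtl_id] = {st: mq.stress_counts.get(st, 0) for st in STRESS_CLASSES}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(STRESS_CLASSES))
    table = table.fillna(0).astype(int)
    table["total"] = table[list(STRESS_CLASSES)].sum(axis=1)
    table["n_stresses"] = (table[list(STRESS_CLASSES)] > 0).sum(axis=1)
    return table


def load_published_overlap() -> pd.DataFrame:
    """The published per-MQTL stress-overlap table, same layout as
    :func:`overlap_table`."""
    frame = pd.read_csv(_data_path("published_overlap.tsv"), sep="\t", index_col="mqtl_id")
    frame = frame[list(STRESS_CLASSES)]
    frame["total"] = frame[list(STRESS_CLASSES)].sum(axis=1)
    frame["n_stresses"] = (frame[list(STRESS_CLASSES)] > 0).sum(axis=1)
    return frame


def load_published_mqtl_summary() -> pd.DataFrame:
    """Published per-MQTL summary (chromosome, meta R², physical peak/CI)."""
    return pd.read_csv(_data_path("published_mqtl_summary.tsv"), sep="\t",
                       index_col="mqtl_id")


# ---------------------------------------------------------------------------
# Effect-size classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MQTLClassification:
    """Effect-size tier of one MQTL: ordinary, major (R² > 20%) or mega (> 30%)."""

    mqtl_id: str
    tier: str
    r2_used: float | None
    warning: str | None = None


def classify_mqtls(
    mqtls: Sequence[MQTL] | Mapping[str, float],
    major_threshold: float = MAJOR_R2_THRESHOLD,
    mega_threshold: float = MEGA_R2_THRESHOLD,
) -> list[MQTLClassification]:
    """Assign each MQTL to exactly one tier from its R².

    "Major" is read exclusively of "mega": mega iff R² > ``mega_threshold``,
    major iff ``major_threshold`` < R² <= ``mega_threshold``, ordinary
    otherwise.  A missing R² classifies as ordinary with a warning.
    Accepts either MQTL objects (using ``meta_r2``) or a mapping
    ``mqtl_id -> r2``.
    """
    if isinstance(mqtls, Mapping):
        items = list(mqtls.items())
    else:
        items = [(m.mqtl_id, m.meta_r2) for m in mqtls]
    out = []
    for mqtl_id, r2 in items:
        if r2 is None or (isinstance(r2, float) and np.isnan(r2)):
            out.append(MQTLClassification(mqtl_id, "ordinary", None, "missing r2"))
        elif r2 > mega_threshold:
            out.append(MQTLClassification(mqtl_id, "mega", float(r2)))
        elif r2 > major_threshold:
            out.append(MQTLClassification(mqtl_id, "major", float(r2)))
        else:
            out.append(MQTLClassification(mqtl_id, "ordinary", float(r2)))
    return out


def tier_counts(classifications: Iterable[MQTLClassification]) -> dict[str, int]:
    counts = {"ordinary": 0, "major": 0, "mega": 0}
    for c in classifications:
        counts[c.tier] += 1
    return counts


# ---------------------------------------------------------------------------
# Candidate-gene interval overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """A gene from an annotation: 1-based inclusive bp interval."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")


def read_anchors(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Marker anchor table: columns marker, cm, bp (optional chromosome)."""
    frame = pd.read_csv(Path(path), sep=sep)
    required = {"marker", "cm", "bp"}
    if not required <= set(frame.columns):
        raise MetaQTLError(f"{path}: anchor table needs columns {sorted(required)}")
    return frame


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GeneFeature]:
    """Read gene features from a GFF3 annotation via :mod:`gffutils`."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneFeature] = []
    for feat in db.features_of_type(feature_type):
        genes.append(
            GeneFeature(feat.id, feat.seqid, feat.start, feat.end, feat.strand or ".")
        )
    return genes


def cm_to_bp(pos_cm: float, anchors: pd.DataFrame, chromosome: str | None = None
             ) -> tuple[float, bool]:
    """Map a genetic position to bp via piecewise-linear anchor interpolation.

    Returns ``(bp, extrapolated)``; outside the anchored span the nearest
    interval's rate extends the mapping.  Needs at least two anchors.
    """
    if chromosome is not None and "chromosome" in anchors.columns:
        anchors = anchors[anchors["chromosome"] == chromosome]
    anchors = anchors.sort_values("cm")
    cm = anchors["cm"].to_numpy(dtype=float)
    bp = anchors["bp"].to_numpy(dtype=float)
    if len(cm) < 2:
        raise MetaQTLError("need at least 2 anchors to interpolate cM -> bp")
    if pos_cm < cm[0]:
        rate = (bp[1] - bp[0]) / (cm[1] - cm[0])
        return float(bp[0] - rate * (cm[0] - pos_cm)), True
    if pos_cm > cm[-1]:
        rate = (bp[-1] - bp[-2]) / (cm[-1] - cm[-2])
        return float(bp[-1] + rate * (pos_cm - cm[-1])), True
    return float(np.interp(pos_cm, cm, bp)), False


def genes_in_mqtl(
    mqtl: MQTL,
    anchors: pd.DataFrame,
    genes: Sequence[GeneFeature],
) -> tuple[list[GeneFeature], bool]:
    """Genes whose bp interval overlaps the MQTL's 95% CI (closed intervals).

    The CI endpoints are mapped cM -> bp through the anchors; any overlap,
    on either strand, qualifies — a gene abutting the boundary bp exactly is
    included.  Returns ``(genes sorted by start, extrapolated_flag)``.
    """
    lo_bp, ex1 = cm_to_bp(mqtl.ci95_lo_cm, anchors, mqtl.chromosome)
    hi_bp, ex2 = cm_to_bp(mqtl.ci95_hi_cm, anchors, mqtl.chromosome)
    lo_bp, hi_bp = min(lo_bp, hi_bp), max(lo_bp, hi_bp)
    hits = [
        g for g in genes
        if g.chromosome == mqtl.chromosome and g.end_bp >= lo_bp and g.start_bp <= hi_bp
    ]
    return sorted(hits, key=lambda g: (g.start_bp, g.gene_id)), (ex1 or ex2)
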