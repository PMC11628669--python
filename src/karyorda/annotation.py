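"""Gene-window annotation of outlier loci against a GFF3 reference.

Each outlier SNP position is matched to annotated genes on the same
contig whose span lies strictly closer than a window (default 50 kbp).
Distance is measured to the nearest edge of the gene span; a locus
inside the span has distance 0.  Relation (upstream/downstream) follows
gene strand: upstream is the 5' side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationHit:
    """One gene within the window of one locus (distance in bp)."""

    locus_id: str
    gene_id: str
    contig: str
    distance: int
    relation: str  # within | upstream | downstream


def read_annotation(path: str | Path) -> dict[str, pd.DataFrame]:
    """Parse gene features from a GFF3 into per-contig sorted tables.

    Returns ``{contig: DataFrame(gene_id, start, end, strand)}`` with
    1-based inclusive coordinates, sorted by start.
    """
    import gffutils

    try:
        db = gffutils.create_db(str(path), dbfn=":memory:",
                                force=True, keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"gene_id": gid, "contig": feat.seqid,
                     "start": feat.start, "end": feat.end,
                     "strand": feat.strand})
    if not rows:
        raise ValueError(f"{path}: no gene features found")
    table = pd.DataFrame(rows)
    return {
        contig: grp.drop(columns="contig").sort_values(
            ["start", "gene_id"]).reset_index(drop=True)
        for contig, grp in table.groupby("contig")
    }


def _distance_and_relation(pos: int, start: int, end: int,
                           strand: str) -> tuple[int, str]:
    if start <= pos <= end:
        return 0, "within"
    if pos < start:
        d = start - pos
        side_5prime = strand != "-"
    else:
        d = pos - end
        side_5prime = strand == "-"
    return d, "upstream" if side_5prime else "downstream"


def genes_near(contig: str, position: int,
               genes: dict[str, pd.DataFrame],
               window: int = 50_000,
               locus_id: str = "") -> list[AnnotationHit]:
    """Genes on ``contig`` with edge distance to ``position`` < ``window``.

    Strict inequality: a gene exactly ``window`` bp away is not
    reported.  Hits are sorted by distance, ties by gene_id.  An unknown
    contig yields an empty list with a warning.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if contig not in genes:
        warnings.warn(f"contig {contig!r} absent from annotation")
        return []
    table = genes[contig]
    hits = []
    for row in table.itertuples():
        d, rel = _distance_and_relation(position, row.start, row.end,
                                        row.strand)
        if d < window:
            hits.append(AnnotationHit(locus_id, row.gene_id, contig,
                                      int(d), rel))
    hits.sort(key=lambda h: (h.distance, h.gene_id))
    return hits


def annotate_outliers(report: pd.DataFrame, locus_map: pd.DataFrame,
                      genes: dict[str, pd.DataFrame],
                      window: int = 50_000) -> pd.DataFrame:
    """Join the outlier report with gene hits inside the window.

    Returns one row per (outlier, gene) pair; outliers without hits (or
    without genomic coordinates, like the karyotype pseudo-locus) keep a
    single row with empty annotation columns.
    """
    pos_of = locus_map.set_index("locus_id")[["contig", "position"]]
    rows = []
    for _, row in report.iterrows():
        lid = row["locus_id"]
        base = row.to_dict()
        if row.get("is_karyotype", False) or lid not in pos_of.index:
            rows.append({**base, "gene_id": pd.NA, "distance": pd.NA,
                         "relation": pd.NA})
            continue
        contig, pos = pos_of.loc[lid]
        hits = genes_near(str(contig), int(pos), genes, window, locus_id=lid)
        if not hits:
            rows.append({**base, "gene_id": pd.NA, "distance": pd.NA,
                         "relation": pd.NA})
        for h in hits:
            rows.append({**base, "gene_id": h.gene_id,
                         "distance": h.distance, "relation": h.relation})
    return pd.DataFrame(rows)
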