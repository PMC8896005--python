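"""Coverage and fold-enrichment statistics.

Two headline computations: (i) per-feature-class TE coverage percentages
with TE-vs-non-TE fold enrichment or depletion, and (ii) per-(motif, TE
type) fold enrichment of motif occurrences with a one-sided binomial null
and the coverage/fold/significance filter cascade, plus the
motif-percentage-in-TE summary and promoter gene counting.

Fold enrichment of a motif in a TE type is the proportion of the motif's
genomic instances fully inside that TE type divided by the TE type's share
of the genome; the binomial null treats each instance as an independent
Bernoulli trial with success probability equal to that genome share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from temotif.intervals import GenomicInterval, IntervalSet, contained_hits
from temotif.motifs import MotifHit
from temotif.stats import binomial_tail

logger = logging.getLogger(__name__)


def percent(part: float, whole: float) -> float:
    """Percentage helper used by all report tables."""
    if whole <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * part / whole


@dataclass
class CoverageRow:
    """TE coverage of one feature class, with TE-vs-non-TE fold change."""

    feature_class: str
    class_bp: int
    te_bp: int
    percent_te: float  # TE bp / class bp
    te_share: float  # % of all TE bases that lie in this class
    non_te_share: float  # % of all non-TE bases that lie in this class
    fold: Optional[float]  # te_share / non_te_share
    direction: str  # "enriched" / "depleted" / "none" / "undefined"
    fold_display: Optional[float]  # reciprocal for depletions, as reported

    @property
    def is_depleted(self) -> bool:
        return self.direction == "depleted"


def _fold_fields(te_share: float, non_te_share: float):
    if non_te_share == 0 and te_share == 0:
        return None, "undefined", None
    if non_te_share == 0:
        return float("inf"), "enriched", float("inf")
    if te_share == 0:
        return 0.0, "depleted", float("inf")
    fold = te_share / non_te_share
    if fold >= 1:
        return fold, "enriched", fold
    return fold, "depleted", 1.0 / fold


def coverage_table(partition: pd.DataFrame) -> List[CoverageRow]:
    """Coverage report from a feature partition table.

    Requires the ``whole_genome`` row to define total genome and TE bp.
    Fold changes below 1 are also reported as the reciprocal depletion,
    matching the usual phrasing ("x-fold depletion").
    """
    whole = partition[partition["feature_class"] == "whole_genome"]
    if len(whole) != 1:
        raise ValueError("partition table must contain a whole_genome row")
    genome_bp = int(whole["class_bp"].iloc[0])
    te_total = int(whole["te_bp"].iloc[0])
    non_te_total = genome_bp - te_total
    rows = []
    for r in partition.itertuples(index=False):
        if r.class_bp == 0:
            rows.append(
                CoverageRow(r.feature_class, 0, 0, 0.0, 0.0, 0.0, None, "undefined", None)
            )
            continue
        pct = percent(r.te_bp, r.class_bp)
        te_share = percent(r.te_bp, te_total) if te_total else 0.0
        non_te_share = (
            percent(r.class_bp - r.te_bp, non_te_total) if non_te_total else 0.0
        )
        fold, direction, disp = _fold_fields(te_share, non_te_share)
        rows.append(
            CoverageRow(
                r.feature_class, int(r.class_bp), int(r.te_bp), pct,
                te_share, non_te_share, fold, direction, disp,
            )
        )
    return rows


def coverage_frame(rows: Sequence[CoverageRow]) -> pd.DataFrame:
    """Report table with the printed 1-decimal rounding convention."""
    return pd.DataFrame(
        {
            "feature_class": [r.feature_class for r in rows],
            "class_bp": [r.class_bp for r in rows],
            "te_bp": [r.te_bp for r in rows],
            "percent_te": [round(r.percent_te, 1) for r in rows],
            "te_share_pct": [round(r.te_share, 1) for r in rows],
            "non_te_share_pct": [round(r.non_te_share, 1) for r in rows],
            "direction": [r.direction for r in rows],
            "fold": [
                round(r.fold_display, 1) if r.fold_display not in (None, float("inf")) else r.fold_display
                for r in rows
            ],
        }
    )


# ---------------------------------------------------------------------------
# Per-(motif, TE type) enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRecord:
    """Fold enrichment of one motif in one TE type against the binomial null."""

    motif_id: str
    tf_name: str
    te_type: str
    te_family: str
    n_total: int
    n_in: int
    te_bp: int
    genome_bp: int
    fold: float
    pvalue: float
    passes_filters: bool = False


def te_type_bp(tes: pd.DataFrame) -> Dict[str, int]:
    """Merged bp per TE type (overlapping fragments counted once)."""
    out: Dict[str, int] = {}
    for te_type, grp in tes.groupby("te_type", sort=True):
        ivs = IntervalSet(
            [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in grp.itertuples(index=False)]
        )
        out[str(te_type)] = ivs.merge().total_bp
    return out


def motif_te_enrichment(
    hits: Sequence[MotifHit],
    tes: pd.DataFrame,
    genome_bp: int,
) -> List[EnrichmentRecord]:
    """Per-(motif, TE type) fold enrichment with one-sided binomial p.

    ``hits`` is the full genome-wide scan output (all motifs pooled);
    containment annotation is (re)computed here against the un-merged TE
    table. Every (motif, TE type) pair with at least one genomic instance
    of the motif yields a record, including pairs with ``n_in = 0``.
    Motifs with zero genomic instances are omitted with a log notice.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    type_bp = te_type_bp(tes)
    families = (
        tes.drop_duplicates("te_type").set_index("te_type")["te_family"].to_dict()
    )
    contained_hits(list(hits), tes)  # annotates in place
    by_motif: Dict[str, List[MotifHit]] = {}
    tf_names: Dict[str, str] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)
        tf_names[h.motif_id] = h.tf_name
    records: List[EnrichmentRecord] = []
    for motif_id in sorted(by_motif):
        mh = by_motif[motif_id]
        n_total = len(mh)
        if n_total == 0:  # pragma: no cover - grouping implies >= 1
            logger.info("motif %s has no genomic instances; omitted", motif_id)
            continue
        in_counts: Dict[str, int] = {}
        for h in mh:
            if h.te_type is not None:
                in_counts[h.te_type] = in_counts.get(h.te_type, 0) + 1
        for te_type in sorted(type_bp):
            bp = type_bp[te_type]
            p0 = bp / genome_bp
            n_in = in_counts.get(te_type, 0)
            fold = (n_in / n_total) / p0 if p0 > 0 else float("nan")
            records.append(
                EnrichmentRecord(
                    motif_id=motif_id,
                    tf_name=tf_names[motif_id],
                    te_type=te_type,
                    te_family=str(families.get(te_type, "")),
                    n_total=n_total,
                    n_in=n_in,
                    te_bp=bp,
                    genome_bp=int(genome_bp),
                    fold=fold,
                    pvalue=binomial_tail(n_in, n_total, p0),
                )
            )
    return records


def filter_enriched(
    records: Sequence[EnrichmentRecord],
    min_te_bp: int = 20000,
    min_fold: float = 20.0,
    max_p: float = 1e-12,
) -> List[EnrichmentRecord]:
    """Apply the filter cascade: TE types covering more than ``min_te_bp``
    of the genome, fold strictly above ``min_fold``, binomial p strictly
    below ``max_p``. Flags every record and returns the passing subset."""
    kept = []
    for r in records:
        r.passes_filters = (
            r.te_bp > min_te_bp and r.fold > min_fold and r.pvalue < max_p
        )
        if r.passes_filters:
            kept.append(r)
    return kept


def motif_percent_in_te(
    records: Sequence[EnrichmentRecord],
    te_types: Optional[Set[str]] = None,
) -> float:
    """Percentage of a motif's genomic instances inside the chosen TE types."""
    if not records:
        raise ValueError("no enrichment records for motif")
    motif_ids = {r.motif_id for r in records}
    if len(motif_ids) != 1:
        raise ValueError("records must belong to a single motif")
    n_total = records[0].n_total
    if n_total == 0:
        raise ValueError("motif has no genomic instances")
    sel = records if te_types is None else [r for r in records if r.te_type in te_types]
    return percent(sum(r.n_in for r in sel), n_total)


def motif_census(records: Sequence[EnrichmentRecord]) -> Tuple[int, int, float]:
    """(motifs with >= 1 TE-contained instance, motifs total, percentage)."""
    per_motif: Dict[str, int] = {}
    for r in records:
        per_motif[r.motif_id] = per_motif.get(r.motif_id, 0) + r.n_in
    total = len(per_motif)
    with_te = sum(1 for v in per_motif.values() if v > 0)
    return with_te, total, percent(with_te, total) if total else float("nan")


def genes_with_te_motifs(
    promoter_windows: Mapping[str, GenomicInterval],
    te_hits: Sequence[MotifHit],
) -> Tuple[Dict[str, Set[str]], Set[str]]:
    """Genes whose promoter window fully contains a TE-contained motif hit.

    A gene counts for a motif when at least one TE-contained hit lies fully
    within its promoter window; a hit inside two overlapping windows counts
    for both genes (genes are counted, not hits). Returns the per-motif
    gene sets and their deduplicated union.
    """
    per_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for gid, win in promoter_windows.items():
        per_chrom.setdefault(win.chrom, []).append((win.start, win.end, gid))
    arrays = {}
    for chrom, wins in per_chrom.items():
        wins.sort()
        starts = np.array([w[0] for w in wins], dtype=np.int64)
        ends = np.array([w[1] for w in wins], dtype=np.int64)
        gids = [w[2] for w in wins]
        max_len = int((ends - starts).max())
        arrays[chrom] = (starts, ends, gids, max_len)
    per_motif: Dict[str, Set[str]] = {}
    for h in te_hits:
        iv = h.interval
        if iv.chrom not in arrays:
            continue
        starts, ends, gids, max_len = arrays[iv.chrom]
        hi = int(np.searchsorted(starts, iv.start, side="right"))
        lo = int(np.searchsorted(starts, iv.start - max_len, side="left"))
        for j in range(lo, hi):
            if starts[j] <= iv.start and ends[j] >= iv.end:
                per_motif.setdefault(h.motif_id, set()).add(gids[j])
    union: Set[str] = set()
    for genes in per_motif.values():
        union |= genes
    return per_motif, union


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in records],
            "tf_name": [r.tf_name for r in records],
            "te_type": [r.te_type for r in records],
            "te_family": [r.te_family for r in records],
            "n_total": [r.n_total for r in records],
            "n_in": [r.n_in for r in records],
            "te_bp": [r.te_bp for r in records],
            "genome_bp": [r.genome_bp for r in records],
            "fold": [r.fold for r in records],
            "pvalue": [r.pvalue for r in records],
            "passes_filters": [r.passes_filters for r in records],
        }
    )
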