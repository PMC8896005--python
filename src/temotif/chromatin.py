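"""Chromatin accessibility and TF-binding association for TE-resident motifs.

Peak summits (ATAC or ChIP) are extended 50 bp each side into 101-bp summit
regions and merged across developmental stages before any fraction is
computed. A motif instance is "accessible" when its interval lies fully
within a merged accessible region; a TF's bound region is "TE-derived"
when it fully contains at least one TE-contained cognate motif hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from temotif.intervals import GenomicInterval, IntervalSet
from temotif.motifs import MotifHit
from temotif.stats import fisher_exact_two_sided

logger = logging.getLogger(__name__)


@dataclass
class SummitRegionSet:
    """Fixed-width summit regions for one assay/TF, pre- and post-merge."""

    label: str
    raw: IntervalSet
    merged: IntervalSet


def build_summit_regions(
    summits: Mapping[str, Sequence[Tuple[str, int]]],
    chrom_sizes: Mapping[str, int],
    flank: int = 50,
    label: str = "",
) -> SummitRegionSet:
    """Extend single-base summits into (2*flank+1)-bp regions and merge.

    ``summits`` maps a stage name to its (chrom, position) summit list; all
    stages are pooled before merging. Regions are clipped at chromosome
    bounds; off-chromosome summits are rejected.
    """
    raw: List[GenomicInterval] = []
    for stage in sorted(summits):
        for chrom, pos in summits[stage]:
            if chrom not in chrom_sizes:
                raise ValueError(f"summit on unknown chromosome {chrom}")
            size = chrom_sizes[chrom]
            if not (0 <= pos < size):
                raise ValueError(f"summit {chrom}:{pos} is off-chromosome")
            raw.append(
                GenomicInterval(chrom, max(0, pos - flank), min(size, pos + flank + 1))
            )
    rs = IntervalSet(raw, label=label)
    return SummitRegionSet(label=label, raw=rs, merged=rs.merge())


@dataclass
class FractionResult:
    """Fraction of a motif's accessible (or bound) instances that are in TEs."""

    motif_id: str
    tf_name: str
    denominator: int
    numerator: int
    percent: float
    passes_denominator: bool
    passes_percent: bool

    @property
    def passes_gates(self) -> bool:
        return self.passes_denominator and self.passes_percent


def _containment_index(merged: IntervalSet):
    by = merged.by_chrom()

    def contains(iv: GenomicInterval) -> bool:
        if iv.chrom not in by:
            return False
        starts, ends = by[iv.chrom]
        idx = int(np.searchsorted(starts, iv.start, side="right")) - 1
        return idx >= 0 and ends[idx] >= iv.end

    return contains


def accessible_motif_fractions(
    hits: Sequence[MotifHit],
    atac: SummitRegionSet,
    min_sites: int = 3000,
    min_pct: float = 10.0,
) -> List[FractionResult]:
    """Per motif: accessible instances and the share of those inside TEs.

    ``hits`` must already carry TE-containment annotation (``te_type`` set
    for TE-contained hits). The denominator is the motif's hits fully
    within merged accessible regions; the numerator those additionally
    TE-contained. Gates are strict: denominator > ``min_sites`` and percent
    > ``min_pct``. All motifs are returned with their gate flags so census
    claims remain checkable.
    """
    contains = _containment_index(atac.merged)
    denom: Dict[str, int] = {}
    numer: Dict[str, int] = {}
    tf: Dict[str, str] = {}
    for h in hits:
        tf.setdefault(h.motif_id, h.tf_name)
        denom.setdefault(h.motif_id, 0)
        numer.setdefault(h.motif_id, 0)
        if contains(h.interval):
            denom[h.motif_id] += 1
            if h.te_type is not None:
                numer[h.motif_id] += 1
    out = []
    for motif_id in sorted(denom):
        d, n = denom[motif_id], numer[motif_id]
        pct = 100.0 * n / d if d else 0.0
        out.append(
            FractionResult(
                motif_id=motif_id,
                tf_name=tf[motif_id],
                denominator=d,
                numerator=n,
                percent=pct,
                passes_denominator=d > min_sites,
                passes_percent=pct > min_pct,
            )
        )
    return out


def bound_motif_fractions(
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
    chip: Mapping[str, SummitRegionSet],
    motif_to_tf: Mapping[str, str],
    min_regions: int = 500,
    min_pct: float = 5.0,
) -> List[FractionResult]:
    """Per cognate (motif, TF) pair: bound regions with the motif, and the
    share of those whose contained motif is TE-provided.

    A TF's merged bound region counts once toward the denominator when it
    fully contains at least one cognate motif hit, and toward the numerator
    when at least one contained hit is TE-contained. The region-count gate
    applies to the TF's total merged bound regions (strict), the percent
    gate to the TE-derived share (strict). Motifs whose TF has no ChIP data
    are skipped with a notice.
    """
    out = []
    for motif_id in sorted(hits_by_motif):
        tf_name = motif_to_tf.get(motif_id, motif_id)
        if tf_name not in chip:
            logger.info("no ChIP summit set for TF %s (motif %s); skipped", tf_name, motif_id)
            continue
        regions = list(chip[tf_name].merged)
        n_regions = len(regions)
        mhits = hits_by_motif[motif_id]
        starts_by_chrom: Dict[str, List[Tuple[int, int, bool]]] = {}
        for h in mhits:
            starts_by_chrom.setdefault(h.interval.chrom, []).append(
                (h.interval.start, h.interval.end, h.te_type is not None)
            )
        for lst in starts_by_chrom.values():
            lst.sort()
        denom = numer = 0
        for reg in regions:
            lst = starts_by_chrom.get(reg.chrom, [])
            has_hit = has_te_hit = False
            starts = [x[0] for x in lst]
            lo = int(np.searchsorted(starts, reg.start, side="left"))
            for j in range(lo, len(lst)):
                s, e, in_te = lst[j]
                if s >= reg.end:
                    break
                if e <= reg.end:  # fully contained
                    has_hit = True
                    has_te_hit = has_te_hit or in_te
            if has_hit:
                denom += 1
                if has_te_hit:
                    numer += 1
        pct = 100.0 * numer / denom if denom else 0.0
        out.append(
            FractionResult(
                motif_id=motif_id,
                tf_name=tf_name,
                denominator=denom,
                numerator=numer,
                percent=pct,
                passes_denominator=n_regions > min_regions,
                passes_percent=pct > min_pct,
            )
        )
    return out


def top_te_contributors(
    counts: Mapping[str, int],
    k: int = 5,
) -> List[Tuple[str, int]]:
    """Top-k TE types by count, ties broken lexicographically by type name."""
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


@dataclass
class FisherResult:
    tf_name: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    pvalue: float
    degenerate: bool


def accessibility_fisher(
    chip: SummitRegionSet,
    atac: SummitRegionSet,
    cognate_hits: Sequence[MotifHit],
    tf_name: str = "",
) -> FisherResult:
    """Association between TE-provided motifs and accessibility, per TF.

    Each merged bound region is classified by (fully contains a
    TE-contained cognate motif hit?) x (overlaps a merged accessible
    region?); the two-sided Fisher exact p on the 2x2 table is returned
    alongside the table. Degenerate margins give p = 1 with a flag.
    """
    atac_by = atac.merged.by_chrom()

    def overlaps(iv: GenomicInterval) -> bool:
        if iv.chrom not in atac_by:
            return False
        starts, ends = atac_by[iv.chrom]
        idx = int(np.searchsorted(starts, iv.end, side="left"))
        return idx > 0 and ends[idx - 1] > iv.start

    te_hits_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for h in cognate_hits:
        if h.te_type is not None:
            te_hits_by_chrom.setdefault(h.interval.chrom, []).append(
                (h.interval.start, h.interval.end)
            )
    for lst in te_hits_by_chrom.values():
        lst.sort()

    def has_te_motif(reg: GenomicInterval) -> bool:
        lst = te_hits_by_chrom.get(reg.chrom, [])
        starts = [x[0] for x in lst]
        lo = int(np.searchsorted(starts, reg.start, side="left"))
        for j in range(lo, len(lst)):
            s, e = lst[j]
            if s >= reg.end:
                return False
            if e <= reg.end:
                return True
        return False

    a = b = c = d = 0
    for reg in chip.merged:
        te = has_te_motif(reg)
        acc = overlaps(reg)
        if te and acc:
            a += 1
        elif te:
            b += 1
        elif acc:
            c += 1
        else:
            d += 1
    table = ((a, b), (c, d))
    p, degenerate = fisher_exact_two_sided(table)
    return FisherResult(tf_name=tf_name, table=table, pvalue=p, degenerate=degenerate)


def fraction_frame(results: Sequence[FractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "tf_name": [r.tf_name for r in results],
            "denominator": [r.denominator for r in results],
            "numerator": [r.numerator for r in results],
            "percent": [round(r.percent, 1) for r in results],
            "passes_denominator": [r.passes_denominator for r in results],
            "passes_percent": [r.passes_percent for r in results],
            "passes_gates": [r.passes_gates for r in results],
        }
    )
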