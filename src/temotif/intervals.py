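"""Interval algebra on genomic coordinates.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases. Readers for 1-based formats
convert on ingest. The merge operation unions overlapping *and* book-ended
intervals, matching ``bedtools merge`` defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Subset containment; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A collection of intervals, optionally tagged with a label.

    The set itself is unordered and may contain overlapping members;
    :meth:`merge` returns the minimal non-overlapping, non-abutting cover.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: Optional[str] = None,
    ) -> None:
        self.intervals: List[GenomicInterval] = list(intervals)
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:  # pragma: no cover
        tag = f" label={self.label!r}" if self.label else ""
        return f"<IntervalSet n={len(self.intervals)}{tag}>"

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start then end."""
        out: Dict[str, Tuple[List[int], List[int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, ([], []))
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        res = {}
        for chrom, (starts, ends) in out.items():
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            order = np.lexsort((e, s))
            res[chrom] = (s[order], e[order])
        return res

    def merge(self) -> "IntervalSet":
        """Minimal set covering the same bases (book-ended intervals union)."""
        merged: List[GenomicInterval] = []
        for chrom, (starts, ends) in sorted(self.by_chrom().items()):
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:  # overlap or book-ended
                    cur_e = max(cur_e, int(e))
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(merged, label=self.label)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-wise intersection of the two covers (both merged first)."""
        a = self.merge().by_chrom()
        b = other.merge().by_chrom()
        out: List[GenomicInterval] = []
        for chrom in sorted(set(a) & set(b)):
            sa, ea = a[chrom]
            sb, eb = b[chrom]
            i = j = 0
            while i < len(sa) and j < len(sb):
                lo = max(sa[i], sb[j])
                hi = min(ea[i], eb[j])
                if lo < hi:
                    out.append(GenomicInterval(chrom, int(lo), int(hi)))
                if ea[i] <= eb[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of self not covered by other (both merged first)."""
        a = self.merge().by_chrom()
        b = other.merge().by_chrom()
        out: List[GenomicInterval] = []
        for chrom in sorted(a):
            sa, ea = a[chrom]
            if chrom not in b:
                out.extend(
                    GenomicInterval(chrom, int(s), int(e)) for s, e in zip(sa, ea)
                )
                continue
            sb, eb = b[chrom]
            j = 0
            for s, e in zip(sa, ea):
                cur = int(s)
                while j < len(sb) and eb[j] <= cur:
                    j += 1
                k = j
                while k < len(sb) and sb[k] < e:
                    if sb[k] > cur:
                        out.append(GenomicInterval(chrom, cur, int(sb[k])))
                    cur = max(cur, int(eb[k]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out.append(GenomicInterval(chrom, cur, int(e)))
        return IntervalSet(out)

    def intersect_bp(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_bp

    def contains_interval(self, iv: GenomicInterval) -> bool:
        """True if ``iv`` is fully covered by a single merged member."""
        merged = self.merge().by_chrom()
        if iv.chrom not in merged:
            return False
        starts, ends = merged[iv.chrom]
        idx = int(np.searchsorted(starts, iv.start, side="right")) - 1
        return idx >= 0 and ends[idx] >= iv.end


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Functional alias for :meth:`IntervalSet.merge`."""
    return s.merge()


# ---------------------------------------------------------------------------
# Containment with TE annotation
# ---------------------------------------------------------------------------

TE_COLUMNS = ["chrom", "start", "end", "te_type", "te_family", "repeat_class"]


def contained_hits(
    hits: Sequence,
    tes: pd.DataFrame,
) -> list:
    """Return hits fully contained in a TE record, annotated with its labels.

    Containment is tested against the un-merged TE table so the covering
    record's type/family is unambiguous. A hit contained in several
    (overlapping or abutting) TE records is attributed to the longest
    covering record, ties broken by lexicographic type name; such hits get
    ``ambiguous_te=True``. Strand is ignored. Each ``hit`` must expose an
    ``interval`` attribute and accept ``te_type``/``te_family``/
    ``ambiguous_te`` attribute assignment.
    """
    if len(tes) == 0 or len(hits) == 0:
        return []
    per_chrom: Dict[str, pd.DataFrame] = {}
    max_len: Dict[str, int] = {}
    for chrom, grp in tes.groupby("chrom", sort=False):
        g = grp.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
        per_chrom[chrom] = g
        max_len[chrom] = int((g["end"] - g["start"]).max())
    kept = []
    for hit in hits:
        iv = hit.interval
        g = per_chrom.get(iv.chrom)
        if g is None:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        hi = int(np.searchsorted(starts, iv.start, side="right"))
        lo = int(np.searchsorted(starts, iv.start - max_len[iv.chrom], side="left"))
        covering = [
            j for j in range(lo, hi) if starts[j] <= iv.start and ends[j] >= iv.end
        ]
        if not covering:
            continue
        best = min(
            covering,
            key=lambda j: (-(ends[j] - starts[j]), str(g["te_type"].iat[j])),
        )
        hit.te_type = g["te_type"].iat[best]
        hit.te_family = g["te_family"].iat[best]
        hit.ambiguous_te = len(covering) > 1
        kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Gene models and promoters
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A protein-coding gene: span plus sub-feature interval sets."""

    gene_id: str
    span: GenomicInterval
    coding_exons: IntervalSet = field(default_factory=IntervalSet)
    utr5: IntervalSet = field(default_factory=IntervalSet)
    utr3: IntervalSet = field(default_factory=IntervalSet)
    operon_id: Optional[str] = None

    @property
    def introns(self) -> IntervalSet:
        """Span minus exons and UTRs."""
        covered = IntervalSet(
            list(self.coding_exons) + list(self.utr5) + list(self.utr3)
        )
        if len(covered) == 0:
            return IntervalSet([self.span])
        return IntervalSet([self.span]).subtract(covered)


def promoter_window(
    span: GenomicInterval,
    upstream_bp: int = 2500,
    chrom_len: Optional[int] = None,
) -> Optional[GenomicInterval]:
    """The upstream window of a stranded span, clipped at chromosome ends.

    Returns None when the window is empty after clipping (gene starting at
    base 0 on the + strand, or ending at the chromosome end on −).
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    if span.strand == "+":
        lo = max(0, span.start - upstream_bp)
        hi = span.start
    elif span.strand == "-":
        lo = span.end
        hi = span.end + upstream_bp
        if chrom_len is not None:
            hi = min(hi, chrom_len)
    else:
        raise ValueError(f"unstranded span {span.chrom}:{span.start}-{span.end}")
    if lo >= hi:
        return None
    return GenomicInterval(span.chrom, lo, hi, span.strand)


def promoter_windows(
    genes: Sequence[GeneModel],
    operons: Optional[Mapping[str, GenomicInterval]] = None,
    upstream_bp: int = 2500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    collapse_operons: bool = False,
) -> Dict[str, GenomicInterval]:
    """Per-gene (or per-operon) raw promoter windows keyed by id.

    With ``collapse_operons``, genes carrying an operon id contribute no
    individual window; the operon's own upstream window stands in. Without
    it, every gene gets its own window (the convention used for gene-count
    analyses).
    """
    sizes = chrom_sizes or {}
    out: Dict[str, GenomicInterval] = {}
    for gene in genes:
        if collapse_operons and gene.operon_id is not None:
            continue
        w = promoter_window(gene.span, upstream_bp, sizes.get(gene.span.chrom))
        if w is not None:
            out[gene.gene_id] = w
    if collapse_operons and operons:
        for op_id, span in sorted(operons.items()):
            w = promoter_window(span, upstream_bp, sizes.get(span.chrom))
            if w is not None:
                out[op_id] = w
    return out


def promoters(
    genes: Sequence[GeneModel],
    operons: Optional[Mapping[str, GenomicInterval]] = None,
    upstream_bp: int = 2500,
    exclusive: bool = False,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    collapse_operons: Optional[bool] = None,
) -> IntervalSet:
    """Promoter track: windows ``upstream_bp`` upstream of gene/operon starts.

    ``exclusive=True`` subtracts coding exons, UTRs, and introns of *any*
    gene from the windows (the coverage-partition variant) and, by default,
    collapses operon members onto one operon promoter. ``exclusive=False``
    keeps the raw windows including overlapping features (the gene-count
    variant).
    """
    if collapse_operons is None:
        collapse_operons = exclusive
    wins = promoter_windows(
        genes, operons, upstream_bp, chrom_sizes, collapse_operons=collapse_operons
    )
    prom = IntervalSet(list(wins.values()), label="promoters")
    if not exclusive:
        return prom
    feats: List[GenomicInterval] = []
    for g in genes:
        feats.extend(g.coding_exons)
        feats.extend(g.utr5)
        feats.extend(g.utr3)
        feats.extend(g.introns)
    return prom.subtract(IntervalSet(feats))


def feature_partition(
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneModel],
    operons: Optional[Mapping[str, GenomicInterval]],
    tes: IntervalSet,
    upstream_bp: int = 2500,
) -> pd.DataFrame:
    """Per-feature-class totals and TE overlap.

    Emits one row per class (coding exons, 5'UTR, 3'UTR, introns, exclusive
    promoters, operon promoters, distal intergenic, whole genome) with the
    class's total bp and the bp of that class covered by TEs. Classes other
    than distal intergenic may overlap one another, so column sums can
    exceed the genome size. Distal intergenic is the genome minus every
    other class.
    """
    for g in genes:
        if g.span.chrom not in chrom_sizes:
            raise ValueError(f"missing chromosome length for {g.span.chrom}")
        if g.span.end > chrom_sizes[g.span.chrom]:
            raise ValueError(f"gene {g.gene_id} extends past {g.span.chrom}")
    genome = IntervalSet(
        [GenomicInterval(c, 0, int(n)) for c, n in sorted(chrom_sizes.items())]
    )
    exons = IntervalSet([iv for g in genes for iv in g.coding_exons])
    utr5 = IntervalSet([iv for g in genes for iv in g.utr5])
    utr3 = IntervalSet([iv for g in genes for iv in g.utr3])
    introns = IntervalSet([iv for g in genes for iv in g.introns])

    gene_wins = promoter_windows(
        genes, None, upstream_bp, chrom_sizes, collapse_operons=True
    )
    op_wins = (
        promoter_windows([], operons, upstream_bp, chrom_sizes, collapse_operons=True)
        if operons
        else {}
    )
    feats = IntervalSet(
        list(exons) + list(utr5) + list(utr3) + list(introns)
    )
    prom = IntervalSet(list(gene_wins.values())).subtract(feats)
    op_prom = IntervalSet(list(op_wins.values())).subtract(feats)

    classes = {
        "coding_exons": exons,
        "utr5": utr5,
        "utr3": utr3,
        "introns": introns,
        "promoters": prom,
        "operon_promoters": op_prom,
    }
    everything = IntervalSet(
        [iv for cls in classes.values() for iv in cls]
    )
    classes["distal_intergenic"] = genome.subtract(everything)
    classes["whole_genome"] = genome

    te_merged = tes.merge()
    rows = []
    for name, cls in classes.items():
        merged = cls.merge()
        rows.append(
            {
                "feature_class": name,
                "class_bp": merged.total_bp,
                "te_bp": merged.intersect_bp(te_merged),
            }
        )
    return pd.DataFrame(rows, columns=["feature_class", "class_bp", "te_bp"])
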