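"""Cross-species comparison of promoter TE-provided motifs.

For each motif, the genes whose promoters carry a TE-contained motif hit
are collected in both species, restricted to a one-to-one ortholog map,
and the number of shared orthologs is tested against an upper-tail
hypergeometric null: drawing the species-B positives from the N mapped
orthologs, how often would at least k of the K species-A positives be hit
by chance. Shared pairs are further classified by whether the promoter TEs
on the two sides belong to the same (normalized) TE family, and by whether
the species-A hit is bound by the cognate TF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from temotif.chromatin import SummitRegionSet, _containment_index
from temotif.intervals import GenomicInterval
from temotif.motifs import MotifHit
from temotif.stats import hypergeom_tail

logger = logging.getLogger(__name__)

# Normalization of repeat-family labels across species annotations:
# superfamily synonyms collapse onto one key so "similar family" is
# comparable between differently curated repeat libraries. Editable /
# overridable by the caller.
DEFAULT_FAMILY_MAP: Dict[str, str] = {
    "Tc1/mariner": "Tc1/mariner",
    "TcMar-Tc1": "Tc1/mariner",
    "TcMar-Mariner": "Tc1/mariner",
    "TcMar-Tc2": "Tc1/mariner",
    "TcMar-Tc4": "Tc1/mariner",
    "Mariner/Tc1": "Tc1/mariner",
    "DNA/TcMar": "Tc1/mariner",
    "Helitron": "Helitron",
    "RC/Helitron": "Helitron",
    "hAT": "hAT",
    "DNA/hAT": "hAT",
    "MULE-MuDR": "MULE-MuDR",
    "DNA/MULE-MuDR": "MULE-MuDR",
    "CELE14B": "CELE14B",
    "LINE/CR1": "CR1",
    "CR1": "CR1",
    "LINE/RTE": "RTE",
    "RTE": "RTE",
    "LTR/Gypsy": "Gypsy",
    "Gypsy": "Gypsy",
    "LTR/Pao": "Pao",
    "Pao": "Pao",
}


def normalize_family(label: str, family_map: Optional[Mapping[str, str]] = None) -> str:
    fmap = DEFAULT_FAMILY_MAP if family_map is None else family_map
    if label in fmap:
        return fmap[label]
    logger.warning("unknown TE family label %r; using raw string equality", label)
    return label


def promoter_te_motif_genes(
    promoter_windows: Mapping[str, "GenomicInterval"],
    te_hits: Sequence[MotifHit],
) -> Tuple[Dict[str, Set[str]], Dict[str, Dict[str, List[MotifHit]]]]:
    """Genes with a TE-contained motif hit fully inside their promoter window.

    Returns per-motif gene sets plus, for downstream family/binding
    classification, the hits themselves keyed by (motif, gene). The same
    containment convention as the single-species gene counting applies; a
    hit inside two overlapping windows counts for both genes.
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
        arrays[chrom] = (starts, ends, gids, int((ends - starts).max()))
    gene_sets: Dict[str, Set[str]] = {}
    hits_by: Dict[str, Dict[str, List[MotifHit]]] = {}
    for h in te_hits:
        iv = h.interval
        if iv.chrom not in arrays:
            continue
        starts, ends, gids, max_len = arrays[iv.chrom]
        hi = int(np.searchsorted(starts, iv.start, side="right"))
        lo = int(np.searchsorted(starts, iv.start - max_len, side="left"))
        for j in range(lo, hi):
            if starts[j] <= iv.start and ends[j] >= iv.end:
                gene_sets.setdefault(h.motif_id, set()).add(gids[j])
                hits_by.setdefault(h.motif_id, {}).setdefault(gids[j], []).append(h)
    return gene_sets, hits_by


class OrthologMap:
    """Strictly one-to-one gene pairs between species A and species B."""

    def __init__(self, pairs: Sequence[Tuple[str, str]]) -> None:
        a_ids = [a for a, _ in pairs]
        b_ids = [b for _, b in pairs]
        if len(set(a_ids)) != len(pairs) or len(set(b_ids)) != len(pairs):
            raise ValueError("ortholog map is not one-to-one")
        self.pairs: List[Tuple[str, str]] = sorted(pairs)
        self.a_to_b = dict(self.pairs)
        self.b_to_a = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class OrthologSharingResult:
    """Shared-ortholog statistics for one motif."""

    motif_id: str
    N: int  # one-to-one orthologs in the map
    K: int  # orthologs with a promoter TE-motif in species A
    n: int  # same in species B
    k: int  # shared
    pvalue: float
    shared_pairs: List[Tuple[str, str]] = field(default_factory=list)
    family_similar: int = 0
    family_different: int = 0
    bound_shared: Optional[int] = None

    @property
    def stars(self) -> str:
        """Significance stars at 0.05 / 0.01 / 1e-05."""
        if self.pvalue < 1e-5:
            return "***"
        if self.pvalue < 0.01:
            return "**"
        if self.pvalue < 0.05:
            return "*"
        return ""


def shared_ortholog_test(
    genes_a: Set[str],
    genes_b: Set[str],
    omap: OrthologMap,
    motif_id: str = "",
) -> OrthologSharingResult:
    """Upper-tail hypergeometric test on shared promoter-TE-motif orthologs.

    The population is every mapped one-to-one ortholog; gene ids absent
    from the map are dropped with a notice. Symmetric in the two species.
    """
    N = len(omap)
    if N == 0:
        raise ValueError("empty ortholog map")
    dropped_a = genes_a - set(omap.a_to_b)
    dropped_b = genes_b - set(omap.b_to_a)
    if dropped_a or dropped_b:
        logger.info(
            "%s: dropped %d/%d unmapped gene ids (A/B)",
            motif_id, len(dropped_a), len(dropped_b),
        )
    set_a = genes_a & set(omap.a_to_b)
    set_b = genes_b & set(omap.b_to_a)
    shared = sorted(
        (a, omap.a_to_b[a]) for a in set_a if omap.a_to_b[a] in set_b
    )
    K, n, k = len(set_a), len(set_b), len(shared)
    return OrthologSharingResult(
        motif_id=motif_id,
        N=N,
        K=K,
        n=n,
        k=k,
        pvalue=hypergeom_tail(k, N, K, n),
        shared_pairs=shared,
    )


def family_similarity(
    result: OrthologSharingResult,
    families_a: Mapping[str, Set[str]],
    families_b: Mapping[str, Set[str]],
    family_map: Optional[Mapping[str, str]] = None,
) -> OrthologSharingResult:
    """Classify shared pairs by promoter-TE family agreement.

    ``families_a[gene]`` holds the family labels of the motif-containing
    promoter TEs of that gene. A pair is "similar" when any normalized
    A-side label equals any normalized B-side label.
    """
    similar = different = 0
    for a, b in result.shared_pairs:
        fa = {normalize_family(f, family_map) for f in families_a.get(a, set())}
        fb = {normalize_family(f, family_map) for f in families_b.get(b, set())}
        if fa & fb:
            similar += 1
        else:
            different += 1
    result.family_similar = similar
    result.family_different = different
    return result


def bound_shared(
    result: OrthologSharingResult,
    hits_by_gene_a: Mapping[str, Sequence[MotifHit]],
    chip_a: Optional[SummitRegionSet],
) -> OrthologSharingResult:
    """Count shared pairs whose species-A promoter TE-motif hit is bound.

    A pair counts when any of the A-side gene's promoter TE-motif hits lies
    fully within a cognate merged bound region. With no ChIP set the count
    is left undefined (None).
    """
    if chip_a is None:
        logger.info("%s: no ChIP summit set; bound_shared undefined", result.motif_id)
        result.bound_shared = None
        return result
    contains = _containment_index(chip_a.merged)
    count = 0
    for a, _b in result.shared_pairs:
        if any(contains(h.interval) for h in hits_by_gene_a.get(a, ())):
            count += 1
    result.bound_shared = count
    return result
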