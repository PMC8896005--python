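"""Seeded synthetic-genome generator with ground truth for every stage.

The generator emulates the statistical structure the pipeline analyses: a
multi-chromosome AT-rich genome carrying non-overlapping TE intervals of
named types and families, motif occurrences planted at controlled rates
inside and outside TEs (words rejection-sampled from each PWM's
high-scoring tail so the scanner recovers them), multi-stage ATAC/ChIP
summit sets covering chosen sites, and a second species sharing one-to-one
orthologs whose promoters carry TEs of similar or different families.

One global integer seed drives named substreams (genome, TEs, genes,
planting, summits, orthologs, species B), so changing one plan section
does not perturb the draws of the others. Output is byte-identical for
identical seeds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from temotif import io as tio
from temotif.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    promoter_window,
    promoter_windows,
)
from temotif.motifs import (
    BASES,
    BackgroundModel,
    PWM,
    ScoreMatrix,
    revcomp,
    sample_high_scoring_word,
)

_STREAMS = {
    "genome": 0, "te": 1, "genes": 2, "motifs": 3, "plant": 4,
    "summits": 5, "ortho": 6,
    "b_genome": 16, "b_te": 17, "b_genes": 18, "b_plant": 20, "b_summits": 21,
}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[name]])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TETypePlan:
    name: str
    family: str
    repeat_class: str = "DNA"
    copies: int = 10
    length_range: Tuple[int, int] = (500, 1500)


@dataclass
class MotifPlan:
    """Planting plan for one motif.

    Exactly one planting style is typically used per motif: explicit
    ``n_inside`` (per TE type) plus ``n_outside``; ``target_fold``
    (te_type, fold, n_total) which derives the split from the realized TE
    coverage; or ``n_uniform`` placements irrespective of TEs (null mode).
    """

    motif_id: str
    tf_name: str
    width: int = 10
    dominant_prob: float = 0.92
    n_outside: int = 0
    n_inside: Dict[str, int] = field(default_factory=dict)
    target_fold: Optional[Tuple[str, float, int]] = None
    n_uniform: int = 0


@dataclass
class GenePlan:
    n_genes: int = 400
    span_range: Tuple[int, int] = (500, 900)
    gap_range: Tuple[int, int] = (100, 500)
    operon_fraction: float = 0.15


@dataclass
class SummitPlan:
    # stage names must not contain underscores (they appear in file names)
    stages: Tuple[str, ...] = ("embryo", "l3", "adult")
    accessible_fraction: float = 0.8
    noise_summits: int = 150
    bound_fraction: float = 0.6
    bound_noise: int = 80


@dataclass
class OrthologPlan:
    """Cross-species sharing plan.

    ``per_motif`` maps a motif id to (K, n, k, similar_fraction): orthologs
    with a promoter TE-motif in species A, in species B, shared, and the
    fraction of shared pairs whose promoter TEs carry the same family.
    """

    n_orthologs: int = 150
    per_motif: Dict[str, Tuple[int, int, int, float]] = field(default_factory=dict)
    b_chrom_lengths: Dict[str, int] = field(default_factory=dict)
    promoter_te_length: Tuple[int, int] = (250, 450)


@dataclass
class SynthConfig:
    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrI": 250_000, "chrII": 250_000}
    )
    base_comp: Tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32)
    te_types: List[TETypePlan] = field(default_factory=list)
    motifs: List[MotifPlan] = field(default_factory=list)
    genes: GenePlan = field(default_factory=GenePlan)
    summits: Optional[SummitPlan] = field(default_factory=SummitPlan)
    orthologs: Optional[OrthologPlan] = None
    plant_pvalue: float = 1e-6
    scan_pvalue: float = 1e-4  # threshold the bundle is meant to be scanned at
    site_spacing: int = 1
    promoter_bp: int = 2500

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def expected_te_fraction(self) -> float:
        bp = sum(t.copies * (t.length_range[0] + t.length_range[1]) / 2 for t in self.te_types)
        return bp / self.genome_bp


def default_te_library() -> List[TETypePlan]:
    """A small worm-flavoured repeat library totalling ~9% of an 800 kb
    genome; the two most abundant types each cover more than 20 kb so the
    filter cascade's coverage gate is exercisable."""
    return [
        TETypePlan("CELE1", "Tc1/mariner", "DNA", copies=24, length_range=(900, 1100)),
        TETypePlan("Tc1", "Tc1/mariner", "DNA", copies=6, length_range=(1500, 1700)),
        TETypePlan("Helitron2_CE", "Helitron", "RC", copies=22, length_range=(900, 1100)),
        TETypePlan("HelitronY2_CE", "Helitron", "RC", copies=8, length_range=(400, 900)),
        TETypePlan("CELE14B", "hAT", "DNA", copies=6, length_range=(700, 1000)),
        TETypePlan("LINE2C", "CR1", "LINE", copies=5, length_range=(600, 800)),
    ]


def default_config(seed: int = 0) -> SynthConfig:
    """The standard toy bundle: 2 x 400 kb, ~9% TE, 10 motifs, 400 genes."""
    motifs = []
    for i in range(10):
        motifs.append(
            MotifPlan(
                motif_id=f"M{i:03d}_2.00",
                tf_name=f"tf-{i}",
                width=8 + (i % 5),
                dominant_prob=0.95,
                n_outside=60,
                n_inside={},
            )
        )
    # two wide motifs strongly enriched in the two large TE types, one modest
    motifs[3].target_fold = ("CELE1", 22.0, 500)
    motifs[3].n_outside = 0
    motifs[4].target_fold = ("Helitron2_CE", 22.0, 500)
    motifs[4].n_outside = 0
    motifs[2].n_inside = {"Tc1": 15}
    cfg = SynthConfig(
        seed=seed,
        chrom_lengths={"chrI": 400_000, "chrII": 400_000},
        te_types=default_te_library(),
        motifs=motifs,
    )
    cfg.orthologs = OrthologPlan(
        n_orthologs=150,
        per_motif={
            motifs[3].motif_id: (25, 20, 12, 0.5),
            motifs[4].motif_id: (20, 18, 10, 0.3),
        },
        b_chrom_lengths={"chrI_b": 200_000, "chrII_b": 200_000},
    )
    return cfg


def fold_recovery_config(seed: int, target_fold: float = 22.0) -> SynthConfig:
    """Bundle for fold-recovery runs: one wide high-IC motif planted at a
    controlled in-TE excess in a TE type covering > 20 kb of a 1.2 Mb genome."""
    te_types = [
        TETypePlan("CELE1", "Tc1/mariner", "DNA", copies=24, length_range=(900, 1100)),
        TETypePlan("Helitron2_CE", "Helitron", "RC", copies=20, length_range=(800, 1200)),
        TETypePlan("CELE14B", "hAT", "DNA", copies=15, length_range=(700, 1100)),
    ]
    motif = MotifPlan(
        motif_id="M000_2.00",
        tf_name="tf-0",
        width=14,
        dominant_prob=0.95,
        target_fold=("CELE1", target_fold, 600),
    )
    return SynthConfig(
        seed=seed,
        chrom_lengths={"chrI": 600_000, "chrII": 600_000},
        te_types=te_types,
        motifs=[motif],
        genes=GenePlan(n_genes=200),
        summits=None,
        orthologs=None,
    )


def ortholog_config(seed: int) -> SynthConfig:
    """Bundle for cross-species sharing runs: sparse, well-separated genes
    and motifs planted only through the ortholog plan, so promoter TE-motif
    gene sets match the plan up to rare background matches."""
    te_types = [
        TETypePlan("CELE1", "Tc1/mariner", "DNA", copies=8, length_range=(800, 1200)),
        TETypePlan("Helitron2_CE", "Helitron", "RC", copies=8, length_range=(700, 1100)),
        TETypePlan("CELE14B", "hAT", "DNA", copies=6, length_range=(700, 1000)),
    ]
    motifs = [
        MotifPlan(
            motif_id=f"M{i:03d}_2.00",
            tf_name=f"tf-{i}",
            width=12,
            dominant_prob=0.95,
        )
        for i in range(2)
    ]
    cfg = SynthConfig(
        seed=seed,
        chrom_lengths={"chrI": 350_000, "chrII": 350_000},
        te_types=te_types,
        motifs=motifs,
        # genes spaced beyond twice the promoter length so neighbouring
        # promoter windows never overlap and planted sharing stays clean
        genes=GenePlan(n_genes=100, span_range=(800, 1200), gap_range=(5200, 6500)),
        summits=SummitPlan(bound_fraction=0.7, noise_summits=60, bound_noise=40),
    )
    cfg.orthologs = OrthologPlan(
        n_orthologs=90,
        per_motif={
            "M000_2.00": (30, 24, 15, 0.4),
            "M001_2.00": (24, 20, 10, 0.5),
        },
        b_chrom_lengths={"chrI_b": 350_000, "chrII_b": 350_000},
    )
    return cfg


def null_config(seed: int, n_motifs: int = 10, n_per_motif: int = 1000) -> SynthConfig:
    """Calibration bundle: motif placements uniform, irrespective of TEs.

    TE copies are long relative to the motifs (small containment edge
    effect), per-type expected in-TE counts are ~30 (mild discreteness of
    the binomial null), and placements may collide (``site_spacing=0``) so
    counts are not underdispersed by space exclusion.
    """
    te_types = [
        TETypePlan(f"NULLTE{i}", fam, "DNA", copies=7, length_range=(2000, 2500))
        for i, fam in enumerate(["Tc1/mariner", "Helitron", "hAT", "CR1"])
    ]
    motifs = [
        MotifPlan(
            motif_id=f"M{i:03d}_2.00",
            tf_name=f"tf-{i}",
            width=10,
            dominant_prob=0.95,
            n_uniform=n_per_motif,
        )
        for i in range(n_motifs)
    ]
    return SynthConfig(
        seed=seed,
        te_types=te_types,
        motifs=motifs,
        genes=GenePlan(n_genes=100),
        summits=None,
        orthologs=None,
        site_spacing=0,
    )


def null_bundle(config: SynthConfig) -> "Bundle":
    """Generate with every planting plan converted to uniform placement."""
    import copy

    cfg = copy.deepcopy(config)
    for m in cfg.motifs:
        total = m.n_outside + sum(m.n_inside.values()) + m.n_uniform
        if m.target_fold is not None:
            total += m.target_fold[2]
        m.n_outside = 0
        m.n_inside = {}
        m.target_fold = None
        m.n_uniform = total
    return generate(cfg)


# ---------------------------------------------------------------------------
# Bundle containers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesData:
    """Everything generated for one species."""

    genome: Dict[str, str]
    chrom_sizes: Dict[str, int]
    tes: pd.DataFrame
    genes: List[GeneModel]
    operons: Dict[str, GenomicInterval]
    sites: pd.DataFrame  # ground-truth planted sites


@dataclass
class GroundTruth:
    sites_a: pd.DataFrame
    sites_b: Optional[pd.DataFrame]
    expected_fold: Dict[Tuple[str, str], float]
    expected_genes: Dict[str, Set[str]]  # per motif, species A, inclusive promoters
    ortholog_truth: Dict[str, Tuple[int, int, int, int, int]]  # K, n, k, similar, different


@dataclass
class Bundle:
    config: SynthConfig
    a: SpeciesData
    b: Optional[SpeciesData]
    pwms: List[PWM]
    background: BackgroundModel
    atac_summits: Dict[str, List[Tuple[str, int]]]
    chip_summits: Dict[str, Dict[str, List[Tuple[str, int]]]]
    ortholog_pairs: List[Tuple[str, str]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Internal builders
# ---------------------------------------------------------------------------


def _random_pwm(plan: MotifPlan, rng: np.random.Generator) -> PWM:
    dom = rng.integers(0, 4, size=plan.width)
    mat = np.full((plan.width, 4), (1.0 - plan.dominant_prob) / 3.0)
    mat[np.arange(plan.width), dom] = plan.dominant_prob
    return PWM(plan.motif_id, plan.tf_name, mat)


def _draw_genome(
    chrom_lengths: Mapping[str, int],
    base_comp: Sequence[float],
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    comp = np.asarray(base_comp, dtype=float)
    comp = comp / comp.sum()
    return {
        chrom: rng.choice(4, size=chrom_lengths[chrom], p=comp).astype(np.int8)
        for chrom in sorted(chrom_lengths)
    }


def _place_interval(
    occ: Dict[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    length: int,
    rng: np.random.Generator,
    max_tries: int = 2000,
    gap: int = 1,
) -> Tuple[str, int]:
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        hi = chrom_lengths[chrom] - length - gap
        if hi <= gap:
            continue
        start = int(rng.integers(gap, hi))
        if not occ[chrom][start - gap : start + length + gap].any():
            occ[chrom][start : start + length] = True
            return chrom, start
    raise RuntimeError(
        f"could not place an interval of length {length}; plan infeasible "
        "(more planted bp than available space)"
    )


def _place_tes(
    config: SynthConfig, rng: np.random.Generator, chrom_lengths: Mapping[str, int]
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray]]:
    occ = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    rows = []
    for plan in config.te_types:
        for _ in range(plan.copies):
            length = int(rng.integers(plan.length_range[0], plan.length_range[1] + 1))
            chrom, start = _place_interval(occ, chrom_lengths, length, rng)
            rows.append(
                (chrom, start, start + length, plan.name, plan.family, plan.repeat_class)
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "te_type", "te_family", "repeat_class"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True), occ


def _place_genes(
    plan: GenePlan,
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    prefix: str,
    promoter_bp: int,
) -> Tuple[List[GeneModel], Dict[str, GenomicInterval]]:
    genes: List[GeneModel] = []
    gid = 0
    for chrom in sorted(chrom_lengths):
        pos = promoter_bp  # leave room for the first promoter
        size = chrom_lengths[chrom]
        while gid < plan.n_genes and pos + plan.span_range[1] + promoter_bp < size:
            span_len = int(rng.integers(plan.span_range[0], plan.span_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, pos, pos + span_len, strand)
            u5 = int(rng.integers(60, 150))
            u3 = int(rng.integers(80, 200))
            body_lo, body_hi = pos + u5, pos + span_len - u3
            n_exons = int(rng.integers(2, 4))
            cuts = np.sort(rng.integers(body_lo + 30, body_hi - 30, size=2 * (n_exons - 1)))
            bounds = [body_lo, *map(int, cuts), body_hi]
            exons = [
                GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1], strand)
                for i in range(n_exons)
                if bounds[2 * i] < bounds[2 * i + 1]
            ]
            if strand == "+":
                utr5 = [GenomicInterval(chrom, pos, pos + u5, strand)]
                utr3 = [GenomicInterval(chrom, pos + span_len - u3, pos + span_len, strand)]
            else:
                utr3 = [GenomicInterval(chrom, pos, pos + u3, strand)]
                utr5 = [GenomicInterval(chrom, pos + span_len - u5, pos + span_len, strand)]
            genes.append(
                GeneModel(
                    gene_id=f"{prefix}g{gid:04d}",
                    span=span,
                    coding_exons=IntervalSet(exons),
                    utr5=IntervalSet(utr5),
                    utr3=IntervalSet(utr3),
                )
            )
            gid += 1
            pos += span_len + int(rng.integers(plan.gap_range[0], plan.gap_range[1] + 1))
        if gid >= plan.n_genes:
            break
    # group a fraction of adjacent gene pairs into operons
    operons: Dict[str, GenomicInterval] = {}
    i = 0
    op = 0
    while i + 1 < len(genes):
        if rng.random() < plan.operon_fraction and genes[i].span.chrom == genes[i + 1].span.chrom:
            op_id = f"{prefix}op{op:03d}"
            a, b = genes[i], genes[i + 1]
            strand = a.span.strand
            operons[op_id] = GenomicInterval(
                a.span.chrom, a.span.start, b.span.end, strand
            )
            a.operon_id = op_id
            b.operon_id = op_id
            op += 1
            i += 2
        else:
            i += 1
    return genes, operons


def _stamp_word(seq: np.ndarray, start: int, word: str, strand: str) -> None:
    w = word if strand == "+" else revcomp(word)
    seq[start : start + len(w)] = [BASES.index(ch) for ch in w]


class _SitePlanter:
    """Places non-overlapping motif sites and stamps their words."""

    def __init__(
        self,
        genome: Dict[str, np.ndarray],
        chrom_lengths: Mapping[str, int],
        te_occ: Dict[str, np.ndarray],
        rng: np.random.Generator,
        spacing: int,
        plant_p: float,
    ) -> None:
        self.genome = genome
        self.chrom_lengths = dict(chrom_lengths)
        self.te_occ = te_occ
        self.site_occ = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        self.rng = rng
        self.spacing = max(0, spacing)
        self.plant_p = plant_p
        self.rows: List[dict] = []

    def _free(self, chrom: str, start: int, w: int) -> bool:
        if self.spacing == 0:  # calibration mode: placements may collide
            return True
        lo = max(0, start - self.spacing)
        return not self.site_occ[chrom][lo : start + w + self.spacing].any()

    def _record(self, pwm, sm, chrom, start, te_type, te_family, gene_id=None):
        w = pwm.width
        word = sample_high_scoring_word(pwm, sm, self.rng, max_p=self.plant_p)
        strand = "+" if self.rng.random() < 0.5 else "-"
        _stamp_word(self.genome[chrom], start, word, strand)
        self.site_occ[chrom][start : start + w] = True
        self.rows.append(
            dict(
                motif_id=pwm.motif_id, chrom=chrom, start=start, end=start + w,
                strand=strand, te_type=te_type, te_family=te_family,
                gene_id=gene_id,
            )
        )

    def plant_outside(self, pwm: PWM, sm: ScoreMatrix, count: int, max_tries: int = 4000) -> None:
        w = pwm.width
        for _ in range(count):
            for _try in range(max_tries):
                chrom, start = self._sample_pos(w)
                if not self.te_occ[chrom][start : start + w].any() and self._free(chrom, start, w):
                    break
            else:
                raise RuntimeError("could not place outside-TE site; plan infeasible")
            self._record(pwm, sm, chrom, start, None, None)

    def plant_uniform(self, pwm: PWM, sm: ScoreMatrix, count: int, tes: pd.DataFrame, max_tries: int = 4000) -> None:
        w = pwm.width
        for _ in range(count):
            for _try in range(max_tries):
                chrom, start = self._sample_pos(w)
                if self._free(chrom, start, w):
                    break
            else:
                raise RuntimeError("could not place uniform site; plan infeasible")
            te_type, te_family = _covering_te(tes, chrom, start, start + w)
            self._record(pwm, sm, chrom, start, te_type, te_family)

    def plant_inside(
        self, pwm: PWM, sm: ScoreMatrix, tes: pd.DataFrame, te_type: str, count: int,
        max_tries: int = 4000,
    ) -> None:
        w = pwm.width
        copies = tes[(tes["te_type"] == te_type) & (tes["end"] - tes["start"] >= w + 2)]
        if len(copies) == 0:
            raise RuntimeError(f"no {te_type} copy can hold a width-{w} site")
        copies = copies.reset_index(drop=True)
        for _ in range(count):
            for _try in range(max_tries):
                row = copies.iloc[int(self.rng.integers(0, len(copies)))]
                start = int(self.rng.integers(row.start + 1, row.end - w))
                if self._free(row.chrom, start, w):
                    break
            else:
                raise RuntimeError(f"could not place site inside {te_type}; plan infeasible")
            fam = str(row.te_family)
            self._record(pwm, sm, row.chrom, start, te_type, fam)

    def plant_in_promoter_te(
        self, pwm: PWM, sm: ScoreMatrix, te: pd.Series, gene_id: str
    ) -> None:
        w = pwm.width
        for _try in range(2000):
            start = int(self.rng.integers(te.start + 1, te.end - w))
            if self._free(te.chrom, start, w):
                break
        else:
            raise RuntimeError("could not place promoter-TE site; plan infeasible")
        self._record(pwm, sm, te.chrom, start, str(te.te_type), str(te.te_family), gene_id)

    def _sample_pos(self, w: int) -> Tuple[str, int]:
        chroms = sorted(self.chrom_lengths)
        weights = np.array([self.chrom_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        chrom = chroms[int(self.rng.choice(len(chroms), p=weights))]
        return chrom, int(self.rng.integers(1, self.chrom_lengths[chrom] - w - 1))

    def frame(self) -> pd.DataFrame:
        cols = ["motif_id", "chrom", "start", "end", "strand", "te_type", "te_family", "gene_id"]
        if not self.rows:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.rows)[cols]


def _covering_te(tes: pd.DataFrame, chrom: str, start: int, end: int):
    sub = tes[(tes["chrom"] == chrom) & (tes["start"] <= start) & (tes["end"] >= end)]
    if len(sub) == 0:
        return None, None
    return str(sub.iloc[0]["te_type"]), str(sub.iloc[0]["te_family"])


def _feasibility_check(config: SynthConfig) -> None:
    genome_bp = config.genome_bp
    te_bp = sum(t.copies * t.length_range[1] for t in config.te_types)
    site_bp = 0
    for m in config.motifs:
        n = m.n_outside + sum(m.n_inside.values()) + m.n_uniform
        if m.target_fold is not None:
            n += m.target_fold[2]
        site_bp += n * (m.width + 2 * config.site_spacing)
    if te_bp > 0.6 * genome_bp or site_bp > 0.5 * genome_bp:
        raise ValueError(
            f"infeasible plan: TEs {te_bp} bp + sites {site_bp} bp on a "
            f"{genome_bp} bp genome"
        )
    for m in config.motifs:
        for te_type, count in m.n_inside.items():
            plans = [t for t in config.te_types if t.name == te_type]
            if not plans:
                raise ValueError(f"planting into unknown TE type {te_type}")
            cap = plans[0].copies * plans[0].length_range[0]
            if count * (m.width + 2 * config.site_spacing) > 0.8 * cap:
                raise ValueError(f"infeasible plan: {count} sites in {te_type}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: SynthConfig) -> Bundle:
    """Produce the full synthetic bundle plus ground truth, in memory.

    Use :func:`write_bundle` to serialize to the on-disk layout.
    """
    _feasibility_check(config)
    seed = config.seed

    bg = BackgroundModel(np.asarray(config.base_comp, dtype=float))
    m_rng = _rng(seed, "motifs")
    pwms = [_random_pwm(p, m_rng) for p in config.motifs]
    sms = {p.motif_id: ScoreMatrix(p, bg) for p in pwms}

    ortho_a: Dict[str, List[Tuple[str, str]]] = {}
    ortho_b: Dict[str, List[Tuple[str, str]]] = {}
    pairs: List[Tuple[str, str]] = []
    planned_ortho: Dict[str, Tuple[int, int, int, int, int]] = {}
    if config.orthologs is not None:
        o_rng = _rng(seed, "ortho")
        n_orth = config.orthologs.n_orthologs
        pairs = [(f"a_g{i:04d}", f"b_g{i:04d}") for i in range(n_orth)]
        fams = sorted({t.family for t in config.te_types})
        if len(fams) < 2:
            raise ValueError("ortholog plan needs at least two TE families")
        for motif_id in sorted(config.orthologs.per_motif):
            K, n, k, simfrac = config.orthologs.per_motif[motif_id]
            if not (k <= min(K, n) and K <= n_orth and n <= n_orth):
                raise ValueError(f"inconsistent ortholog plan for {motif_id}")
            idx = o_rng.permutation(n_orth)
            a_idx = sorted(int(i) for i in idx[:K])
            rest = [int(i) for i in idx[K:]]
            shared = sorted(int(i) for i in o_rng.permutation(a_idx)[:k])
            b_only = sorted(rest[: n - k])
            b_idx = sorted(shared + b_only)
            n_similar = int(round(simfrac * k))
            similar_set = set(sorted(shared)[:n_similar])
            a_list, b_list = [], []
            for i in a_idx:
                fam = fams[int(o_rng.integers(0, len(fams)))]
                a_list.append((pairs[i][0], fam))
                if i in shared:
                    if i in similar_set:
                        b_fam = fam
                    else:
                        others = [f for f in fams if f != fam]
                        b_fam = others[int(o_rng.integers(0, len(others)))]
                    b_list.append((pairs[i][1], b_fam))
            for i in b_only:
                fam = fams[int(o_rng.integers(0, len(fams)))]
                b_list.append((pairs[i][1], fam))
            ortho_a[motif_id] = a_list
            ortho_b[motif_id] = sorted(b_list)
            planned_ortho[motif_id] = (K, n, k, n_similar, k - n_similar)

    species_a = _build_species(
        config, "a", config.chrom_lengths, pwms, sms, bg, ortho_a
    )

    species_b = None
    if config.orthologs is not None:
        b_lengths = config.orthologs.b_chrom_lengths or {
            c + "_b": n for c, n in config.chrom_lengths.items()
        }
        species_b = _build_species(
            config, "b", b_lengths, pwms, sms, bg, ortho_b
        )

    atac, chip = _plan_summits(config, species_a)

    truth = _assemble_truth(config, species_a, species_b, planned_ortho)
    return Bundle(
        config=config,
        a=species_a,
        b=species_b,
        pwms=pwms,
        background=bg,
        atac_summits=atac,
        chip_summits=chip,
        ortholog_pairs=pairs,
        truth=truth,
    )


def _build_species(
    config: SynthConfig,
    which: str,
    chrom_lengths: Mapping[str, int],
    pwms: List[PWM],
    sms: Mapping[str, ScoreMatrix],
    bg: BackgroundModel,
    ortho_assign: Mapping[str, List[Tuple[str, str]]],
) -> SpeciesData:
    prefix = "" if which == "a" else "b_"
    name = lambda s: s if which == "a" else f"b_{s}"
    g_rng = _rng(config.seed, name("genome"))
    te_rng = _rng(config.seed, name("te"))
    gene_rng = _rng(config.seed, "genes" if which == "a" else "b_genes")
    plant_rng = _rng(config.seed, name("plant"))

    genome = _draw_genome(chrom_lengths, config.base_comp, g_rng)
    tes, te_occ = _place_tes(config, te_rng, chrom_lengths)
    gene_prefix = "a_" if which == "a" else "b_"
    genes, operons = _place_genes(
        config.genes, chrom_lengths, gene_rng, gene_prefix, config.promoter_bp
    )
    gene_by_id = {g.gene_id: g for g in genes}

    # promoter TEs for the ortholog plan
    prom_te_rows = []
    by_motif_pwm = {p.motif_id: p for p in pwms}
    planter = _SitePlanter(
        genome, chrom_lengths, te_occ, plant_rng, config.site_spacing, config.plant_pvalue
    )
    lo_len, hi_len = (
        config.orthologs.promoter_te_length if config.orthologs else (250, 450)
    )
    class_by_family = {t.family: t.repeat_class for t in config.te_types}
    for motif_id in sorted(ortho_assign):
        pwm = by_motif_pwm[motif_id]
        for gene_id, family in ortho_assign[motif_id]:
            gene = gene_by_id.get(gene_id)
            if gene is None:
                raise ValueError(f"ortholog plan names unknown gene {gene_id}")
            win = promoter_window(
                gene.span, config.promoter_bp, chrom_lengths[gene.span.chrom]
            )
            if win is None:
                raise RuntimeError(f"gene {gene_id} has no promoter window")
            # place into a free run of the (possibly crowded) promoter window
            seg = te_occ[win.chrom][win.start : win.end]
            edges = np.flatnonzero(
                np.diff(np.concatenate(([1], seg.astype(np.int8), [1])))
            )
            runs = [
                (int(edges[j]), int(edges[j + 1]))
                for j in range(0, len(edges), 2)
            ]
            min_len = pwm.width + 6
            runs = [r for r in runs if r[1] - r[0] >= min_len + 2]
            if not runs:
                raise RuntimeError(f"no room for promoter TE near {gene_id}")
            r0, r1 = runs[int(plant_rng.integers(0, len(runs)))]
            r0, r1 = r0 + 1, r1 - 1  # keep a 1 bp gap to neighbouring TEs
            te_len = int(
                min(r1 - r0, max(min_len, plant_rng.integers(lo_len, hi_len + 1)))
            )
            start = win.start + r0 + int(plant_rng.integers(0, r1 - r0 - te_len + 1))
            te_occ[win.chrom][start : start + te_len] = True
            te_row = pd.Series(
                dict(
                    chrom=win.chrom, start=start, end=start + te_len,
                    te_type=f"SYNPROM_{family.replace('/', '')}",
                    te_family=family,
                    repeat_class=class_by_family.get(family, "DNA"),
                )
            )
            prom_te_rows.append(te_row)
            planter.plant_in_promoter_te(pwm, sms[motif_id], te_row, gene_id)
    if prom_te_rows:
        tes = pd.concat([tes, pd.DataFrame(prom_te_rows)], ignore_index=True)
        tes = tes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # regular planting plans
    genome_bp = sum(chrom_lengths.values())
    for plan in config.motifs:
        pwm = by_motif_pwm[plan.motif_id]
        sm = sms[plan.motif_id]
        inside = dict(plan.n_inside)
        outside = plan.n_outside
        if plan.target_fold is not None:
            te_type, fold, n_total = plan.target_fold
            sub = tes[tes["te_type"] == te_type]
            type_bp = int((sub["end"] - sub["start"]).sum())
            q = type_bp / genome_bp
            # The scan also recovers chance matches at the p-value threshold;
            # their expected count is exact from the score-distribution table
            # (attained tail x number of windows, both strands). Plant so the
            # *expected estimated* fold, planted + chance matches, equals the
            # target.
            _cut, attained = sm.cutoff_for_pvalue(config.scan_pvalue)
            trials = 2 * sum(
                max(0, length - plan.width + 1) for length in chrom_lengths.values()
            )
            b_hat = attained * trials
            n_in = int(round(q * (fold * (n_total + b_hat) - b_hat)))
            n_in = max(0, n_in)
            if n_in > n_total:
                if which == "a":
                    raise ValueError(
                        f"target fold {fold} for {plan.motif_id} in {te_type} "
                        f"needs more in-TE sites than n_total (type share {q:.3f})"
                    )
                # species B only mirrors the motif content; cap at all-inside
                n_in = n_total
            inside[te_type] = inside.get(te_type, 0) + n_in
            outside += n_total - n_in
        for te_type in sorted(inside):
            planter.plant_inside(pwm, sm, tes, te_type, inside[te_type])
        if outside:
            planter.plant_outside(pwm, sm, outside)
        if plan.n_uniform:
            planter.plant_uniform(pwm, sm, plan.n_uniform, tes)

    genome_str = {c: "".join(BASES[i] for i in genome[c]) for c in sorted(genome)}
    sites = planter.frame().sort_values(
        ["chrom", "start", "motif_id"], kind="mergesort"
    ).reset_index(drop=True)
    return SpeciesData(
        genome=genome_str,
        chrom_sizes=dict(chrom_lengths),
        tes=tes,
        genes=genes,
        operons=operons,
        sites=sites,
    )


def _plan_summits(config: SynthConfig, species: SpeciesData):
    """Accessible and per-TF bound summit sets over species-A planted sites."""
    atac: Dict[str, List[Tuple[str, int]]] = {}
    chip: Dict[str, Dict[str, List[Tuple[str, int]]]] = {}
    plan = config.summits
    if plan is None:
        return atac, chip
    rng = _rng(config.seed, "summits")
    stages = list(plan.stages)
    atac = {s: [] for s in stages}
    accessible_flags = []
    site_positions: Dict[str, List[int]] = {}
    for r in species.sites.itertuples(index=False):
        site_positions.setdefault(r.chrom, []).append(int(r.start))
    tf_of = {p.motif_id: p.tf_name for p in config.motifs}
    for tf in sorted(set(tf_of.values())):
        chip[tf] = {s: [] for s in stages}
    bound_flags = []
    for r in species.sites.itertuples(index=False):
        mid = (int(r.start) + int(r.end)) // 2
        acc = bool(rng.random() < plan.accessible_fraction)
        accessible_flags.append(acc)
        if acc:
            atac[stages[int(rng.integers(0, len(stages)))]].append((r.chrom, mid))
        bnd = bool(rng.random() < plan.bound_fraction)
        bound_flags.append(bnd)
        if bnd:
            chip[tf_of[r.motif_id]][stages[int(rng.integers(0, len(stages)))]].append(
                (r.chrom, mid)
            )
    species.sites = species.sites.assign(
        accessible=accessible_flags, bound=bound_flags
    )

    def noise_positions(count: int) -> List[Tuple[str, int]]:
        out = []
        chroms = sorted(species.chrom_sizes)
        weights = np.array([species.chrom_sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        while len(out) < count:
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            pos = int(rng.integers(60, species.chrom_sizes[chrom] - 60))
            near = site_positions.get(chrom, [])
            lo = int(np.searchsorted(near, pos - 120))
            hi = int(np.searchsorted(near, pos + 120))
            if lo == hi:  # no planted site within 120 bp
                out.append((chrom, pos))
        return out

    for stage in stages:
        atac[stage].extend(noise_positions(plan.noise_summits))
        atac[stage].sort()
    for tf in sorted(chip):
        for stage in stages:
            chip[tf][stage].extend(noise_positions(plan.bound_noise))
            chip[tf][stage].sort()
    return atac, chip


def _assemble_truth(
    config: SynthConfig,
    a: SpeciesData,
    b: Optional[SpeciesData],
    planned_ortho: Dict[str, Tuple[int, int, int, int, int]],
) -> GroundTruth:
    expected_fold: Dict[Tuple[str, str], float] = {}
    for plan in config.motifs:
        if plan.target_fold is not None:
            te_type, fold, _n = plan.target_fold
            expected_fold[(plan.motif_id, te_type)] = fold
    wins = promoter_windows(
        a.genes, None, config.promoter_bp, a.chrom_sizes, collapse_operons=False
    )
    per_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for gid, w in wins.items():
        per_chrom.setdefault(w.chrom, []).append((w.start, w.end, gid))
    for lst in per_chrom.values():
        lst.sort()
    expected_genes: Dict[str, Set[str]] = {}
    for r in a.sites.itertuples(index=False):
        if r.te_type is None or (isinstance(r.te_type, float) and np.isnan(r.te_type)):
            continue
        for ws, we, gid in per_chrom.get(r.chrom, ()):  # windows are few per locus
            if ws <= r.start and r.end <= we:
                expected_genes.setdefault(r.motif_id, set()).add(gid)
    return GroundTruth(
        sites_a=a.sites,
        sites_b=b.sites if b is not None else None,
        expected_fold=expected_fold,
        expected_genes=expected_genes,
        ortholog_truth=planned_ortho,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "genome": "genome.fa",
    "tes": "tes.bed",
    "genes": "genes.gff",
    "motifs_chen": "motifs.chen",
    "motifs_meme": "motifs.meme",
    "orthologs": "orthologs.tsv",
}


def write_bundle(bundle: Bundle, outdir: str) -> None:
    """Write the bundle to its fixed on-disk layout (species B under
    ``species_b/``, ground truth under ``ground_truth/``)."""
    os.makedirs(outdir, exist_ok=True)

    def write_species(sp: SpeciesData, d: str) -> None:
        os.makedirs(d, exist_ok=True)
        tio.write_fasta(sp.genome, os.path.join(d, BUNDLE_FILES["genome"]))
        tio.write_te_table(sp.tes, os.path.join(d, BUNDLE_FILES["tes"]))
        tio.write_gff_genes(sp.genes, sp.operons, os.path.join(d, BUNDLE_FILES["genes"]))

    write_species(bundle.a, outdir)
    tio.write_cisbp_chen(bundle.pwms, os.path.join(outdir, BUNDLE_FILES["motifs_chen"]))
    tio.write_meme_minimal(
        bundle.pwms, os.path.join(outdir, BUNDLE_FILES["motifs_meme"]),
        background=bundle.background.freqs,
    )
    for stage in sorted(bundle.atac_summits):
        rows = pd.DataFrame(
            [
                (c, p, p + 1, f"atac_{stage}", 0, ".")
                for c, p in bundle.atac_summits[stage]
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        tio.write_bed(rows, os.path.join(outdir, f"atac_{stage}_summits.bed"))
    for tf in sorted(bundle.chip_summits):
        for stage in sorted(bundle.chip_summits[tf]):
            rows = pd.DataFrame(
                [
                    (c, p, p + 1, f"{tf}_{stage}", 0, ".")
                    for c, p in bundle.chip_summits[tf][stage]
                ],
                columns=["chrom", "start", "end", "name", "score", "strand"],
            )
            tio.write_bed(rows, os.path.join(outdir, f"chip_{tf}_{stage}_summits.bed"))
    if bundle.b is not None:
        write_species(bundle.b, os.path.join(outdir, "species_b"))
        tio.write_ortholog_map(
            bundle.ortholog_pairs, os.path.join(outdir, BUNDLE_FILES["orthologs"])
        )
    gt_dir = os.path.join(outdir, "ground_truth")
    os.makedirs(gt_dir, exist_ok=True)
    bundle.truth.sites_a.to_csv(os.path.join(gt_dir, "sites_a.tsv"), sep="\t", index=False)
    if bundle.truth.sites_b is not None:
        bundle.truth.sites_b.to_csv(os.path.join(gt_dir, "sites_b.tsv"), sep="\t", index=False)
    with open(os.path.join(gt_dir, "expected_fold.tsv"), "w") as fh:
        fh.write("motif_id\tte_type\tfold\n")
        for (m, t), f in sorted(bundle.truth.expected_fold.items()):
            fh.write(f"{m}\t{t}\t{f}\n")
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config_to_dict(bundle.config), fh, sort_keys=True)


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    return d


def config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    d["te_types"] = [TETypePlan(**t) for t in d.get("te_types", [])]
    motifs = []
    for m in d.get("motifs", []):
        m = dict(m)
        if m.get("target_fold") is not None:
            m["target_fold"] = tuple(m["target_fold"])
        motifs.append(MotifPlan(**m))
    d["motifs"] = motifs
    if d.get("genes") is not None:
        g = dict(d["genes"])
        g["span_range"] = tuple(g["span_range"])
        g["gap_range"] = tuple(g["gap_range"])
        d["genes"] = GenePlan(**g)
    if d.get("summits") is not None:
        s = dict(d["summits"])
        s["stages"] = tuple(s["stages"])
        d["summits"] = SummitPlan(**s)
    if d.get("orthologs") is not None:
        o = dict(d["orthologs"])
        o["per_motif"] = {k: tuple(v) for k, v in o.get("per_motif", {}).items()}
        o["promoter_te_length"] = tuple(o["promoter_te_length"])
        d["orthologs"] = OrthologPlan(**o)
    d["base_comp"] = tuple(d["base_comp"])
    return SynthConfig(**d)


def load_config(path: str) -> SynthConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
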