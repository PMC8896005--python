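"""Shared fixtures and per-base oracle helpers."""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pytest

from temotif.intervals import GeneModel, GenomicInterval, IntervalSet


def cover_bitmap(intervals: Sequence[GenomicInterval], sizes: Dict[str, int]):
    """Per-base boolean arrays marking covered bases (the merge oracle)."""
    maps = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    for iv in intervals:
        maps[iv.chrom][iv.start : iv.end] = True
    return maps


def bitmap_total(maps) -> int:
    return int(sum(m.sum() for m in maps.values()))


def random_intervals(rng, sizes, n, max_len=2000) -> List[GenomicInterval]:
    chroms = sorted(sizes)
    out = []
    for _ in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, max(1, sizes[c] - length)))
        out.append(GenomicInterval(c, start, start + length))
    return out


def random_gene(rng, chrom, size, gid) -> GeneModel:
    span_len = int(rng.integers(600, 1500))
    start = int(rng.integers(0, size - span_len))
    strand = "+" if rng.random() < 0.5 else "-"
    span = GenomicInterval(chrom, start, start + span_len, strand)
    u5, u3 = int(rng.integers(50, 120)), int(rng.integers(50, 120))
    lo, hi = start + u5, start + span_len - u3
    cut = int(rng.integers(lo + 20, hi - 20))
    cut2 = int(rng.integers(cut, hi - 10))
    exons = [GenomicInterval(chrom, lo, cut, strand)]
    if cut2 > cut + 1:
        exons.append(GenomicInterval(chrom, cut2, hi, strand))
    if strand == "+":
        utr5 = [GenomicInterval(chrom, start, lo, strand)]
        utr3 = [GenomicInterval(chrom, hi, start + span_len, strand)]
    else:
        utr3 = [GenomicInterval(chrom, start, lo, strand)]
        utr5 = [GenomicInterval(chrom, hi, start + span_len, strand)]
    return GeneModel(
        gene_id=gid,
        span=span,
        coding_exons=IntervalSet(exons),
        utr5=IntervalSet(utr5),
        utr3=IntervalSet(utr3),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One shared standard synthetic bundle (seed 101)."""
    from temotif.synth import default_config, generate

    return generate(default_config(seed=101))


@pytest.fixture(scope="session")
def default_bundle_dir(default_bundle, tmp_path_factory):
    from temotif.synth import write_bundle

    d = tmp_path_factory.mktemp("bundle") / "b101"
    write_bundle(default_bundle, str(d))
    return str(d)


@pytest.fixture(scope="session")
def default_run(default_bundle_dir, tmp_path_factory):
    """Full pipeline output on the shared bundle."""
    from temotif.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("run") / "out101"
    cfg = RunConfig(bundle_dir=default_bundle_dir, out_dir=str(out))
    manifest = run_pipeline(cfg)
    return str(out), manifest
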