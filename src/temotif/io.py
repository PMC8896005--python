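"""Readers and writers for the plain-text formats the pipeline consumes.

Coordinate conventions: BED-like files are 0-based half-open and pass
through unchanged; the GFF-lite gene format is 1-based inclusive and is
converted to 0-based half-open on ingest. All writers emit deterministic,
sorted output.
"""

from __future__ import annotations

import io as _io
from typing import Dict, List, Mapping, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from temotif.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    TE_COLUMNS,
)
from temotif.motifs import PWM

PathOrHandle = Union[str, TextIO]


def _open(path: PathOrHandle, mode: str = "r"):
    if isinstance(path, str):
        return open(path, mode), True
    return path, False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathOrHandle) -> Dict[str, str]:
    """Read a (multi-line, possibly soft-masked) FASTA into uppercase strings."""
    handle, close = _open(path)
    try:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: PathOrHandle, width: int = 60) -> None:
    handle, close = _open(path, "w")
    try:
        for chrom in sorted(genome):
            handle.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: PathOrHandle) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with at least chrom/start/end columns."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    handle, close = _open(path)
    try:
        rows = []
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            rows.append(parts[:6] + [""] * (6 - len(parts[:6])))
    finally:
        if close:
            handle.close()
    df = pd.DataFrame(rows, columns=names)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: PathOrHandle) -> None:
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    handle, close = _open(path, "w")
    try:
        for row in out.itertuples(index=False):
            handle.write("\t".join(str(v) for v in row) + "\n")
    finally:
        if close:
            handle.close()


def interval_set_from_bed(df: pd.DataFrame, label: Optional[str] = None) -> IntervalSet:
    ivs = [
        GenomicInterval(
            r.chrom,
            int(r.start),
            int(r.end),
            r.strand if getattr(r, "strand", ".") in ("+", "-") else ".",
        )
        for r in df.itertuples(index=False)
    ]
    return IntervalSet(ivs, label=label)


def read_summits(path: PathOrHandle) -> List[Tuple[str, int]]:
    """Read peak summits as (chrom, position) pairs.

    Accepts single-base BED intervals; wider records (MACS2-style peaks
    whose name carries a summit suffix) are reduced to their midpoint.
    """
    df = read_bed(path)
    out = []
    for r in df.itertuples(index=False):
        if r.end - r.start == 1:
            out.append((r.chrom, int(r.start)))
        else:
            out.append((r.chrom, int((r.start + r.end) // 2)))
    return out


# ---------------------------------------------------------------------------
# TE annotation table (RepeatMasker-flavoured BED)
# ---------------------------------------------------------------------------


def read_te_table(path: PathOrHandle) -> pd.DataFrame:
    """Read a TE annotation: chrom, start, end, te_type, te_family, repeat_class."""
    handle, close = _open(path)
    try:
        rows = []
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: TE table needs 6 columns")
            rows.append(parts[:6])
    finally:
        if close:
            handle.close()
    df = pd.DataFrame(rows, columns=TE_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"malformed TE interval {bad.chrom}:[{bad.start},{bad.end})"
        )
    return df


def write_te_table(df: pd.DataFrame, path: PathOrHandle) -> None:
    write_bed(df[TE_COLUMNS], path)


def te_interval_set(df: pd.DataFrame, te_type: Optional[str] = None) -> IntervalSet:
    sub = df if te_type is None else df[df["te_type"] == te_type]
    return IntervalSet(
        [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sub.itertuples(index=False)
        ],
        label=te_type,
    )


# ---------------------------------------------------------------------------
# GFF-lite gene models (1-based inclusive on disk)
# ---------------------------------------------------------------------------

_FEATURE_KEYS = {"CDS": "coding_exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}


def _parse_attrs(text: str) -> Dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff_genes(
    path: PathOrHandle,
) -> Tuple[List[GeneModel], Dict[str, GenomicInterval]]:
    """Read gene/operon models from tab-separated GFF-lite.

    Expected feature types: ``gene`` (attribute ``gene_id``, optional
    ``operon_id``), ``CDS``, ``five_prime_UTR``, ``three_prime_UTR`` (each
    with ``gene_id``), and ``operon`` (attribute ``operon_id``). Starts are
    converted from 1-based inclusive to 0-based half-open.
    """
    genes: Dict[str, GeneModel] = {}
    subfeats: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    operons: Dict[str, GenomicInterval] = {}
    handle, close = _open(path)
    try:
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF line has fewer than 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts[:9]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand if strand in "+-" else ".")
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a["gene_id"]
                genes[gid] = GeneModel(
                    gene_id=gid, span=iv, operon_id=a.get("operon_id") or None
                )
            elif ftype in _FEATURE_KEYS:
                gid = a["gene_id"]
                subfeats.setdefault(gid, {}).setdefault(_FEATURE_KEYS[ftype], []).append(iv)
            elif ftype == "operon":
                operons[a["operon_id"]] = iv
    finally:
        if close:
            handle.close()
    for gid, feats in subfeats.items():
        if gid not in genes:
            raise ValueError(f"sub-feature for unknown gene {gid}")
        g = genes[gid]
        for key, ivs in feats.items():
            setattr(g, key, IntervalSet(ivs))
    return [genes[g] for g in sorted(genes)], operons


def write_gff_genes(
    genes: Sequence[GeneModel],
    operons: Mapping[str, GenomicInterval],
    path: PathOrHandle,
) -> None:
    handle, close = _open(path, "w")

    def line(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return (
            f"{iv.chrom}\ttemotif\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}\n"
        )

    try:
        for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            attrs = f"gene_id={g.gene_id}"
            if g.operon_id:
                attrs += f";operon_id={g.operon_id}"
            handle.write(line(g.span, "gene", attrs))
            for ftype, key in (("CDS", "coding_exons"), ("five_prime_UTR", "utr5"), ("three_prime_UTR", "utr3")):
                for iv in sorted(getattr(g, key), key=lambda i: i.start):
                    handle.write(line(iv, ftype, f"gene_id={g.gene_id}"))
        for op_id in sorted(operons):
            handle.write(line(operons[op_id], "operon", f"operon_id={op_id}"))
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Motif formats
# ---------------------------------------------------------------------------

BASES = "ACGT"


def read_cisbp_chen(path: PathOrHandle) -> List[PWM]:
    """Read PWMs from the Cis-BP "chen" tab dialect.

    A file holds one or more blocks. Each block opens with a header line
    ``>motif_id[<TAB>tf_name]``, optionally followed by a column-header line
    (``Pos A C G T``), then one row per position: position index and four
    tab-separated probabilities. Rows whose probabilities deviate from sum 1
    by less than 1e-3 are renormalized; larger deviations are rejected with
    the offending line number.
    """
    handle, close = _open(path)
    pwms: List[PWM] = []
    cur_id: Optional[str] = None
    cur_tf = ""
    rows: List[List[float]] = []

    def flush() -> None:
        nonlocal rows
        if cur_id is None:
            return
        if not rows:
            raise ValueError(f"motif block {cur_id} has no matrix rows")
        pwms.append(PWM(cur_id, cur_tf or cur_id, np.asarray(rows, dtype=float)))
        rows = []

    try:
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                cur_id = fields[0].strip()
                cur_tf = fields[1].strip() if len(fields) > 1 else ""
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() in ("pos", "position"):
                continue
            if cur_id is None:
                raise ValueError(f"{path}:{ln}: matrix row before any motif header")
            try:
                vals = [float(x) for x in parts[1:5]]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric cell ({exc})") from None
            if len(vals) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 probability columns")
            dev = abs(sum(vals) - 1.0)
            if dev >= 1e-3:
                raise ValueError(
                    f"{path}:{ln}: row probabilities sum to {sum(vals):.6f}"
                )
            total = sum(vals)
            if abs(total - 1.0) > 1e-12:
                vals = [v / total for v in vals]
            rows.append(vals)
        flush()
    finally:
        if close:
            handle.close()
    return pwms


def write_cisbp_chen(pwms: Sequence[PWM], path: PathOrHandle) -> None:
    handle, close = _open(path, "w")
    try:
        for pwm in pwms:
            handle.write(f">{pwm.motif_id}\t{pwm.tf_name}\n")
            handle.write("Pos\tA\tC\tG\tT\n")
            for i, row in enumerate(pwm.matrix, 1):
                handle.write(
                    f"{i}\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )
    finally:
        if close:
            handle.close()


def read_meme_minimal(path: PathOrHandle) -> List[PWM]:
    """Read PWMs from MEME minimal motif format (via Bio.motifs)."""
    handle, close = _open(path)
    try:
        records = bio_motifs.parse(handle, "minimal")
        pwms = []
        for m in records:
            mat = np.array(
                [[m.counts[b][i] for b in BASES] for i in range(m.length)], dtype=float
            )
            mat /= mat.sum(axis=1, keepdims=True)
            pwms.append(PWM(m.name, m.name, mat))
    finally:
        if close:
            handle.close()
    return pwms


def write_meme_minimal(
    pwms: Sequence[PWM],
    path: PathOrHandle,
    background: Optional[Sequence[float]] = None,
) -> None:
    bg = list(background) if background is not None else [0.25] * 4
    handle, close = _open(path, "w")
    try:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        handle.write("strands: + -\n\n")
        handle.write("Background letter frequencies\n")
        handle.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)) + "\n\n"
        )
        for pwm in pwms:
            handle.write(f"MOTIF {pwm.motif_id} {pwm.tf_name}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                "nsites= 1000000 E= 0\n"
            )
            for row in pwm.matrix:
                handle.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            handle.write("\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Motif hits (BED6+2) and ortholog map
# ---------------------------------------------------------------------------


def write_hits_bed(hits: Sequence, path: PathOrHandle) -> None:
    """Write motif hits as BED6+2: name=motif id, score=log-odds, then
    p-value and TF name."""
    rows = sorted(
        hits, key=lambda h: (h.interval.chrom, h.interval.start, h.motif_id, h.interval.strand)
    )
    handle, close = _open(path, "w")
    try:
        for h in rows:
            iv = h.interval
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.motif_id}\t"
                f"{h.score:.4f}\t{iv.strand}\t{h.pvalue:.4g}\t{h.tf_name}\n"
            )
    finally:
        if close:
            handle.close()


def read_hits_bed(path: PathOrHandle) -> List:
    """Read motif hits back from the BED6+2 layout of :func:`write_hits_bed`."""
    from temotif.motifs import MotifHit

    handle, close = _open(path)
    hits = []
    try:
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{ln}: expected 8 columns of hit BED")
            chrom, start, end, motif_id, score, strand, pval, tf = parts[:8]
            hits.append(
                MotifHit(
                    motif_id=motif_id,
                    tf_name=tf,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    score=float(score),
                    pvalue=float(pval),
                )
            )
    finally:
        if close:
            handle.close()
    return hits


def read_ortholog_map(path: PathOrHandle) -> List[Tuple[str, str]]:
    """Two-column TSV of one-to-one ortholog gene ids (species A, species B)."""
    handle, close = _open(path)
    try:
        pairs = []
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            pairs.append((parts[0], parts[1]))
    finally:
        if close:
            handle.close()
    seen_a = {a for a, _ in pairs}
    seen_b = {b for _, b in pairs}
    if len(seen_a) != len(pairs) or len(seen_b) != len(pairs):
        raise ValueError("ortholog map is not one-to-one")
    return pairs


def write_ortholog_map(pairs: Sequence[Tuple[str, str]], path: PathOrHandle) -> None:
    handle, close = _open(path, "w")
    try:
        for a, b in sorted(pairs):
            handle.write(f"{a}\t{b}\n")
    finally:
        if close:
            handle.close()
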