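"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention). Sequences are
upper-cased on load. Motif libraries are returned as :class:`~enhmotif.scan.PWM`
objects with a +0.25 pseudocount applied per cell before normalization when the
source provides raw counts (JASPAR PFM); probability matrices (MEME minimal)
are taken as-is so that a write/read round-trip is the identity.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .scan import BASES, PWM

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene_id", "fpkm_a", "fpkm_b", "fold", "q_value"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-style interval: 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise FormatError(f"interval {self.name!r}: start {self.start} < 0")
        if self.end <= self.start:
            raise FormatError(
                f"interval {self.name!r}: end {self.end} <= start {self.start}"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"interval {self.name!r}: bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 intervals.

    Intervals missing a name column are auto-named ``region_<i>`` (1-based).
    Names must be unique within the file.
    """
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else f"region_{len(intervals) + 1}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate interval name {name!r}")
            seen.add(name)
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - set(BASES + "N")
        if bad:
            raise FormatError(f"{path}: {rec.id!r} contains non-ACGTN characters {sorted(bad)}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Motif libraries

PSEUDOCOUNT = 0.25  # per cell, added to raw counts before normalization


def _pwm_from_counts(motif_id: str, counts: np.ndarray, path) -> PWM:
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] != 4:
        raise FormatError(f"{path}: motif {motif_id!r}: columns must have 4 base counts")
    colsums = counts.sum(axis=1)
    if np.any(colsums <= 0):
        j = int(np.argmin(colsums))
        raise FormatError(f"{path}: motif {motif_id!r}: zero-total column {j}")
    probs = (counts + PSEUDOCOUNT) / (colsums + 4 * PSEUDOCOUNT)[:, None]
    raw_probs = counts / colsums[:, None]
    return PWM(motif_id=motif_id, probs=probs, raw_probs=raw_probs, counts=counts)


def read_motif_library(path, fmt: str = "jaspar-pfm", background=None) -> list[PWM]:
    """Read a motif library in JASPAR PFM or minimal MEME format.

    JASPAR count matrices get a +0.25 per-cell pseudocount before normalization
    (information content is still computed on the raw counts); MEME minimal
    probability matrices are used verbatim.
    """
    if fmt not in {"jaspar-pfm", "meme-minimal"}:
        raise ValueError(f"unknown motif format {fmt!r}")
    text = Path(path).read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty motif file, returning empty library")
        return []
    pwms: list[PWM] = []
    if fmt == "jaspar-pfm":
        try:
            parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: failed to parse JASPAR PFM: {exc}") from exc
        for m in parsed:
            counts = np.array([[m.counts[b][j] for b in BASES] for j in range(m.length)])
            name = m.matrix_id or m.name
            pwms.append(_pwm_from_counts(name, counts, path))
    else:
        # parsed directly: installed MEME readers rescale probabilities
        # through integer counts, which breaks the exact round-trip contract
        bg = None if background is None else np.asarray(background, dtype=float)
        for name, probs in _parse_meme_minimal(text, path):
            sums = probs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                j = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"{path}: motif {name!r}: probability column {j} sums to {sums[j]:.6f}, not 1"
                )
            off = np.abs(sums - 1.0) > 1e-9
            probs[off] = probs[off] / sums[off, None]  # repair text rounding
            pwms.append(PWM(motif_id=name, probs=probs, background=bg))
    ids = [p.motif_id for p in pwms]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FormatError(f"{path}: duplicate motif id {dup!r}")
    return pwms


def _parse_meme_minimal(text: str, path) -> list[tuple[str, np.ndarray]]:
    """Parse the letter-probability blocks of a minimal MEME file."""
    lines = text.splitlines()
    if not any(l.startswith("MEME version") for l in lines[:5]):
        raise FormatError(f"{path}: missing 'MEME version' header")
    out: list[tuple[str, np.ndarray]] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without a name (line {i + 1})")
            name = parts[1]
            i += 1
            while i < len(lines) and not lines[i].lstrip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {name!r} has no probability matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name!r} has no probability matrix")
            header = dict(
                token.split("=") for token in lines[i].replace("= ", "=").split()
                if "=" in token
            )
            try:
                width = int(header["w"])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: motif {name!r}: bad matrix header") from exc
            rows = []
            for j in range(width):
                i += 1
                if i >= len(lines):
                    raise FormatError(f"{path}: motif {name!r}: truncated matrix")
                vals = lines[i].split()
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {name!r}: matrix row {j} has {len(vals)} columns, not 4"
                    )
                rows.append([float(v) for v in vals])
            out.append((name, np.array(rows)))
        i += 1
    return out


def write_meme_minimal(pwms: Iterable[PWM], path, background=None) -> None:
    """Write motifs in the minimal MEME text format."""
    pwms = list(pwms)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.length} nsites= 20 E= 0\n")
            # 12 decimals keep read-back column sums within 1e-12 of 1, so a
            # write/read round trip is the identity
            for row in p.probs:
                fh.write(" " + " ".join(f"{v:.12f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Expression / DE tables


def read_expression_table(path) -> pd.DataFrame:
    """Read a two-condition expression summary.

    Expected TSV columns: ``gene_id, fpkm_a, fpkm_b, fold, q_value``. If the
    ``fold`` column is absent it is recomputed as ``fpkm_b / fpkm_a`` (+inf when
    ``fpkm_a`` is zero and ``fpkm_b`` positive); when present the supplied fold
    is trusted, since upstream differential-expression tools normalize fold
    estimates beyond the raw FPKM ratio.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fpkm_a", "fpkm_b", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required columns {sorted(missing)}; found {list(df.columns)}"
        )
    if "fold" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = df["fpkm_b"] / df["fpkm_a"]
        fold = fold.where(df["fpkm_a"] > 0, np.where(df["fpkm_b"] > 0, np.inf, 1.0))
        df["fold"] = fold
    df = df[EXPRESSION_COLUMNS]
    for col in ("fpkm_a", "fpkm_b"):
        if (df[col] < 0).any():
            gene = df.loc[df[col] < 0, "gene_id"].iloc[0]
            raise FormatError(f"{path}: negative FPKM for gene {gene!r}")
    q = df["q_value"].dropna()
    if ((q < 0) | (q > 1)).any():
        raise FormatError(f"{path}: q_value outside [0, 1]")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    return df


def read_de_table(path) -> pd.DataFrame:
    """Read a knockdown differential-expression table (gene, log2fc, padj)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required columns {sorted(missing)}; found {list(df.columns)}"
        )
    dup = df["gene"][df["gene"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene {dup.iloc[0]!r}")
    return df


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into term -> gene-set (symbols upper-cased)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            term = fields[0]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = {g.upper() for g in fields[2:] if g}
    return terms


def write_gmt(terms: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in terms:
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# TSS tables and ortholog maps


def read_tss_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, chrom, tss, strand (one canonical TSS/gene)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required columns {sorted(missing)}; found {list(df.columns)}"
        )
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: negative TSS coordinate")
    return df


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV mapping enhancer name -> orthologous sequence id."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if fields[0] in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate enhancer {fields[0]!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def write_ortholog_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for enh, orth in mapping.items():
            fh.write(f"{enh}\t{orth}\n")


# ---------------------------------------------------------------------------
# Result tables


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a result table as TSV with 6 significant digits for floats.

    Row order is preserved (each module ranks its own results); writing the
    same table twice yields byte-identical files.
    """
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
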