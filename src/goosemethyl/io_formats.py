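"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 input (1-based,
closed) is converted on read; BED output needs no conversion.  Strands are
kept separate in per-cytosine call tables: merging the two cytosines of a
CpG dyad is always an explicit downstream operation, never implicit.

The methylation-call table dialect is defined here: a tab-separated file
with header ``chrom  pos  strand  context  depth  meth_count`` where
``pos`` is 0-based, ``strand`` is ``+``/``-``, ``context`` is one of
``CG``/``CHG``/``CHH``, and ``0 <= meth_count <= depth``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "depth", "meth_count"]
CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent input files."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene with its span, strand and exon structure.

    ``start``/``end`` are the genomic half-open span.  The transcription
    start site is the first transcribed base in genomic coordinates:
    ``start`` for ``+`` genes and ``end - 1`` for ``-`` genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise FormatError(f"gene {self.gene_id}: invalid span [{self.start},{self.end})")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e <= s:
                raise FormatError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint and non-empty"
                )
            prev_end = e
        if self.exons:
            if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
                raise FormatError(f"gene {self.gene_id}: exon outside gene span")
        if self.cds is not None:
            cs, ce = self.cds
            if not self.start <= cs < ce <= self.end:
                raise FormatError(f"gene {self.gene_id}: CDS outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        return tuple(out)

    @property
    def utr5(self) -> tuple[tuple[int, int], ...]:
        """Exonic intervals upstream of the CDS in transcription orientation."""
        return self._utr(five_prime=True)

    @property
    def utr3(self) -> tuple[tuple[int, int], ...]:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> tuple[tuple[int, int], ...]:
        if self.cds is None:
            return ()
        cs, ce = self.cds
        left = five_prime if self.strand == "+" else not five_prime
        out = []
        for s, e in self.exons:
            if left:
                s2, e2 = s, min(e, cs)
            else:
                s2, e2 = max(s, ce), e
            if s2 < e2:
                out.append((s2, e2))
        return tuple(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> dict[str, str]:
    """Load a genome FASTA into an ordered ``{chrom: sequence}`` dict (uppercased)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    return genome


def write_fasta(genome: Mapping[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# methylation call tables
# ---------------------------------------------------------------------------


def derive_context(seq: str, pos: int, strand: str) -> str:
    """Sequence context (CG/CHG/CHH) of the cytosine at ``pos`` on ``strand``.

    On the minus strand the cytosine sits opposite a genomic G and its
    context reads leftward on the reverse complement.  Contexts truncated
    by a contig edge fall back to CHH (no G/C can complete them).
    """
    if strand == "+":
        b1 = seq[pos + 1] if pos + 1 < len(seq) else ""
        b2 = seq[pos + 2] if pos + 2 < len(seq) else ""
        if b1 == "G":
            return "CG"
        if b2 == "G":
            return "CHG"
        return "CHH"
    b1 = seq[pos - 1] if pos >= 1 else ""
    b2 = seq[pos - 2] if pos >= 2 else ""
    if b1 == "C":
        return "CG"
    if b2 == "C":
        return "CHG"
    return "CHH"


def read_methylation_table(
    path: PathLike, genome: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Read a per-cytosine methylation call table.

    Returns a DataFrame with columns ``chrom, pos, strand, context, depth,
    meth_count``.  If ``genome`` is given, each row's context (and the
    presence of a C/G at the stated position) is re-derived from the
    sequence and mismatches are rejected.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(raw.columns) != CALL_COLUMNS:
        raise FormatError(
            f"{path}: expected header {CALL_COLUMNS}, found {list(raw.columns)}"
        )
    df = raw.copy()
    for col in ("pos", "depth", "meth_count"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values % 1 != 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}:{line}: malformed integer in column {col!r}")
        df[col] = values.astype(np.int64)
    _validate_calls(df, label=str(path))
    if genome is not None:
        _check_contexts(df, genome, label=str(path))
    return df.reset_index(drop=True)


def _validate_calls(df: pd.DataFrame, label: str = "calls") -> None:
    def _fail(mask: pd.Series, msg: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 2
            raise FormatError(f"{label}:{line}: {msg}")

    _fail(~df["strand"].isin(STRANDS), "strand must be + or -")
    _fail(~df["context"].isin(CONTEXTS), "context must be CG, CHG or CHH")
    _fail(df["pos"] < 0, "pos must be non-negative")
    _fail(df["depth"] < 0, "depth must be non-negative")
    _fail((df["meth_count"] < 0) | (df["meth_count"] > df["depth"]),
          "meth_count must satisfy 0 <= meth_count <= depth")
    dup = df.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    _fail(dup, "(chrom, pos, strand) must be unique per sample")


def _check_contexts(df: pd.DataFrame, genome: Mapping[str, str], label: str) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise FormatError(f"{label}: chromosome {chrom!r} absent from genome")
        seq = genome[chrom]
        for idx, row in sub.iterrows():
            pos, strand = int(row["pos"]), row["strand"]
            if pos >= len(seq):
                raise FormatError(f"{label}: position {pos} beyond {chrom} length")
            base = seq[pos]
            want = "C" if strand == "+" else "G"
            if base != want:
                raise FormatError(
                    f"{label}: no cytosine at {chrom}:{pos}({strand}) — genome has {base}"
                )
            ctx = derive_context(seq, pos, strand)
            if ctx != row["context"]:
                raise FormatError(
                    f"{label}: context mismatch at {chrom}:{pos}({strand}): "
                    f"table says {row['context']}, genome says {ctx}"
                )


def write_methylation_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# gene model files (GFF3 / BED12)
# ---------------------------------------------------------------------------


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene models from GFF3 or 12-column BED, sniffed by content.

    GFF3 coordinates (1-based closed) are shifted to the internal 0-based
    half-open convention.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    fields = first.rstrip("\n").split("\t")
    if len(fields) == 12 and fields[1].isdigit() and fields[2].isdigit():
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises ValueError on duplicate IDs
        raise FormatError(f"{path}: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = g.id
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(g, featuretype="exon")
        )
        cds_parts = [(f.start - 1, f.end) for f in db.children(g, featuretype="CDS")]
        cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts)) if cds_parts else None
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=tuple(exons),
                cds=cds,
            )
        )
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand,
                    start=start, end=end, exons=exons, cds=cds,
                )
            )
    return genes


def write_gene_models_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS), converting to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                "\t".join(
                    [g.chrom, "goosemethyl", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            rna_id = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(
                    [g.chrom, "goosemethyl", "mRNA", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", f"ID={rna_id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    "\t".join(
                        [g.chrom, "goosemethyl", "exon", str(s + 1), str(e),
                         ".", g.strand, ".", f"ID={rna_id}.e{i};Parent={rna_id}"]
                    )
                    + "\n"
                )
            if g.cds is not None:
                cs, ce = g.cds
                for i, (s, e) in enumerate(g.exons, start=1):
                    s2, e2 = max(s, cs), min(e, ce)
                    if s2 < e2:
                        fh.write(
                            "\t".join(
                                [g.chrom, "goosemethyl", "CDS", str(s2 + 1), str(e2),
                                 ".", g.strand, "0", f"ID={rna_id}.c{i};Parent={rna_id}"]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def write_bed(intervals: Union[pd.DataFrame, Iterable[Mapping]], path: PathLike) -> None:
    """Write named, scored intervals as 5-column BED.

    ``score`` is expected in [0, 1] and is scaled to the BED 0-1000 integer
    range.  Rows are sorted by (chrom, start).  Overlapping intervals are
    written as-is — BED permits overlap.
    """
    df = pd.DataFrame(intervals)
    if df.empty:
        Path(path).write_text("")
        return
    required = ["chrom", "start", "end", "name", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"write_bed: missing columns {missing}")
    if (df["start"] >= df["end"]).any():
        raise FormatError("write_bed: start must be < end")
    out = df[required].copy()
    out["score"] = (
        np.clip(np.round(out["score"].astype(float) * 1000), 0, 1000).astype(int)
    )
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read a 5-column BED back into a DataFrame (score as 0-1000 integer)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "name": str, "score": np.int64},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score"])
    return df


# ---------------------------------------------------------------------------
# sample sheet and expression matrix
# ---------------------------------------------------------------------------


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read the sample sheet (sample_id, breed, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "breed": str, "stage": str})
    required = ["sample_id", "breed", "stage", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any():
        raise FormatError(f"{path}: replicate must be a positive integer")
    df["replicate"] = rep.astype(int)
    return df


def require_replicates(sheet: pd.DataFrame, breed: str, stage: str, n: int = 2) -> list[str]:
    """Sample ids of a (breed, stage) group, requiring at least ``n`` replicates."""
    ids = sheet.loc[(sheet["breed"] == breed) & (sheet["stage"] == stage), "sample_id"]
    if len(ids) < n:
        raise FormatError(
            f"group ({breed}, {stage}) has {len(ids)} replicates; at least {n} required"
        )
    return list(ids)


def read_fpkm(path: PathLike) -> pd.DataFrame:
    """Read a genes x samples FPKM matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    df = df.set_index("gene_id")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric FPKM value")
    if (values < 0).any():
        raise FormatError(f"{path}: negative FPKM value")
    return df


def write_fpkm(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id", float_format="%.6g")
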