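"""Coverage readers and +1-anchored window extraction.

Profiles are extracted in a fixed 1200-bp window per gene: 200 bp upstream to
1000 bp downstream of the +1 nucleosome dyad, so the anchor sits at index 200
and the window spans 6-7 nucleosomes of an average yeast gene. Genes on the
Crick strand are reversed so the index always increases into the gene body.

All genomic coordinates are 0-based half-open internally (BED/bigWig
convention); 1-based annotation inputs must be declared explicitly.

Upstream contract: coverage tracks are expected to be RPM-normalized
mononucleosome signal (fragments in the 130-200 bp range); read processing is
out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UPSTREAM = 200
DOWNSTREAM = 1000
WINDOW_LENGTH = UPSTREAM + DOWNSTREAM
ANCHOR_INDEX = UPSTREAM

SMALL_GENE_MAX = 1000      # small iff length <= 1000 bp
VERY_LARGE_GENE_MIN = 3000  # very large iff length >= 3000 bp


class CoverageParseError(ValueError):
    """Malformed coverage file; message names the offending line."""


@dataclass(frozen=True)
class PlusOneAnnotation:
    """+1 nucleosome annotation for one gene."""

    gene_id: str
    chromosome: str
    plus_one_dyad: int
    strand: str  # "+" (Watson) or "-" (Crick)
    gene_length: int

    def __post_init__(self) -> None:
        if self.plus_one_dyad < 0:
            raise ValueError(f"{self.gene_id}: plus_one_dyad must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_length < 300:
            logger.warning(
                "%s: gene_length %d bp is below the expected 300 bp minimum",
                self.gene_id,
                self.gene_length,
            )


def classify_gene_size(gene_lengths: np.ndarray | list[int]) -> pd.DataFrame:
    """Size classes: small (<= 1000 bp) vs large (> 1000 bp), with genes
    >= 3000 bp additionally flagged very large (they remain 'large')."""
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(~np.isfinite(lengths)):
        raise ValueError("gene lengths must be finite; drop missing genes first")
    size_class = np.where(lengths <= SMALL_GENE_MAX, "small", "large")
    very_large = lengths >= VERY_LARGE_GENE_MIN
    return pd.DataFrame({"size_class": size_class, "very_large": very_large})


@dataclass
class ProfileSet:
    """Matrix of +1-anchored profiles: genes x 1200 positions, anchor at 200."""

    values: np.ndarray
    gene_ids: list[str]
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != WINDOW_LENGTH:
            raise ValueError(f"values must be n_genes x {WINDOW_LENGTH}")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count must equal number of gene ids")
        if not np.isfinite(self.values).all():
            raise ValueError("profile values must be finite")
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths)
            if self.gene_lengths.size != len(self.gene_ids):
                raise ValueError("gene_lengths must match gene ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def size_classes(self) -> pd.DataFrame:
        if self.gene_lengths is None:
            raise ValueError("gene lengths are not available for this profile set")
        df = classify_gene_size(self.gene_lengths)
        df.index = pd.Index(self.gene_ids, name="gene_id")
        return df

    def subset(self, mask: np.ndarray) -> "ProfileSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ProfileSet(
            values=self.values[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths[idx],
        )


class _DenseCoverage:
    """Coverage accessor over per-chromosome dense arrays (bedGraph/wiggle)."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self._arrays = arrays

    def chromosomes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._arrays.items()}

    def chrom_length(self, chromosome: str) -> int:
        if chromosome not in self._arrays:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return len(self._arrays[chromosome])

    def values(self, chromosome: str, start: int, end: int) -> np.ndarray:
        if chromosome not in self._arrays:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        if end < start:
            raise ValueError("end must be >= start")
        arr = self._arrays[chromosome]
        out = np.zeros(end - start)
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


class _BigWigCoverage:
    """Coverage accessor backed by a bigWig file (uncovered positions -> 0)."""

    def __init__(self, path: str):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))

    def chromosomes(self) -> dict[str, int]:
        return dict(self._bw.chroms())

    def chrom_length(self, chromosome: str) -> int:
        length = self._bw.chroms(chromosome)
        if not length:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return int(length)

    def values(self, chromosome: str, start: int, end: int) -> np.ndarray:
        length = self.chrom_length(chromosome)
        out = np.zeros(end - start)
        lo, hi = max(start, 0), min(end, length)
        if hi > lo:
            vals = np.asarray(self._bw.values(chromosome, lo, hi), dtype=float)
            out[lo - start : hi - start] = np.nan_to_num(vals)
        return out


def _parse_bedgraph(path: str) -> _DenseCoverage:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise CoverageParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise CoverageParseError(f"{path}:{lineno}: malformed bedGraph line")
            if start < 0 or end < start:
                raise CoverageParseError(f"{path}:{lineno}: invalid interval")
            intervals.setdefault(chrom, []).append((start, end, value))
    arrays = {}
    for chrom, ivals in intervals.items():
        arr = np.zeros(max(end for _, end, _ in ivals))
        for start, end, value in ivals:
            arr[start:end] = value
        arrays[chrom] = arr
    return _DenseCoverage(arrays)


def _parse_wiggle(path: str) -> _DenseCoverage:
    """fixedStep/variableStep wiggle; wig coordinates are 1-based."""
    chunks: dict[str, list[tuple[int, float, int]]] = {}  # (0-based start, value, span)
    mode = None
    chrom = ""
    pos = step = span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                try:
                    chrom = fields["chrom"]
                    span = int(fields.get("span", 1))
                    if line.startswith("fixedStep"):
                        mode = "fixed"
                        pos = int(fields["start"])
                        step = int(fields.get("step", 1))
                    else:
                        mode = "variable"
                except (KeyError, ValueError):
                    raise CoverageParseError(f"{path}:{lineno}: malformed wiggle header")
                chunks.setdefault(chrom, [])
                continue
            if mode is None:
                raise CoverageParseError(f"{path}:{lineno}: data before wiggle header")
            parts = line.split()
            try:
                if mode == "fixed":
                    value = float(parts[0])
                    start = pos - 1
                    pos += step
                else:
                    start = int(parts[0]) - 1
                    value = float(parts[1])
            except (ValueError, IndexError):
                raise CoverageParseError(f"{path}:{lineno}: malformed wiggle line")
            chunks[chrom].append((start, value, span))
    arrays = {}
    for chrom, entries in chunks.items():
        arr = np.zeros(max(start + span for start, _, span in entries))
        for start, value, span in entries:
            arr[start : start + span] = value
        arrays[chrom] = arr
    return _DenseCoverage(arrays)


def read_coverage(path: str, format: str | None = None):
    """Open a coverage track (bigWig, bedGraph or wiggle).

    Returns an accessor with ``values(chromosome, start, end)`` (0-based
    half-open; a query of length L returns exactly L values, zeros where
    uncovered) and ``chrom_length(chromosome)``.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        if lower.endswith((".bw", ".bigwig")):
            format = "bigWig"
        elif lower.endswith((".wig", ".wiggle")):
            format = "wig"
        else:
            format = "bedGraph"
    if format == "bigWig":
        return _BigWigCoverage(path)
    if format == "bedGraph":
        return _parse_bedgraph(path)
    if format == "wig":
        return _parse_wiggle(path)
    raise ValueError(f"unknown coverage format {format!r}")


def extract_windows(
    coverage,
    annotations: list[PlusOneAnnotation],
    one_based: bool = False,
) -> ProfileSet:
    """Build the +1-anchored window matrix.

    Watson gene with dyad P covers [P-200, P+1000); Crick covers
    [P-999, P+201) reversed, so index 200 is the dyad and the index increases
    into the gene body in both cases. Windows that exceed chromosome bounds
    are skipped with a logged warning.
    """
    rows, ids, lengths = [], [], []
    n_skipped = 0
    for ann in annotations:
        dyad = ann.plus_one_dyad - 1 if one_based else ann.plus_one_dyad
        if ann.strand == "+":
            start, end = dyad - UPSTREAM, dyad + DOWNSTREAM
        else:
            start, end = dyad - DOWNSTREAM + 1, dyad + UPSTREAM + 1
        try:
            chrom_len = coverage.chrom_length(ann.chromosome)
        except KeyError:
            logger.warning("%s: unknown chromosome %s, skipped", ann.gene_id, ann.chromosome)
            n_skipped += 1
            continue
        if start < 0 or end > chrom_len:
            logger.warning(
                "%s: window [%d, %d) exceeds %s bounds, skipped",
                ann.gene_id, start, end, ann.chromosome,
            )
            n_skipped += 1
            continue
        window = coverage.values(ann.chromosome, start, end)
        if ann.strand == "-":
            window = window[::-1]
        rows.append(window)
        ids.append(ann.gene_id)
        lengths.append(ann.gene_length)
    if n_skipped:
        logger.warning("extract_windows: skipped %d genes with out-of-bounds windows", n_skipped)
    if not rows:
        raise ValueError("no gene window could be extracted")
    return ProfileSet(values=np.vstack(rows), gene_ids=ids, gene_lengths=np.array(lengths))


def read_plus_one_annotations(path: str) -> list[PlusOneAnnotation]:
    """BED-like TSV with columns gene_id, chrom, dyad, strand, length."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "dyad", "strand", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [
        PlusOneAnnotation(
            gene_id=str(row.gene_id),
            chromosome=str(row.chrom),
            plus_one_dyad=int(row.dyad),
            strand=str(row.strand),
            gene_length=int(row.length),
        )
        for row in df.itertuples(index=False)
    ]


def read_factor_table(path: str) -> pd.DataFrame:
    """Per-gene scalar/categorical factor table (TSV, first column gene_id).

    Numeric columns are parsed as reals; columns with no numeric content are
    kept categorical; a stray non-numeric cell inside a numeric column raises
    with the offending gene named. Duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError("factor table must have a gene_id column")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gene_id entries: {sorted(set(dupes))}")
    df = df.set_index("gene_id")
    out = {}
    for col in df.columns:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        present = raw.notna()
        convertible = numeric.notna()
        if convertible[present].all():
            out[col] = numeric
        elif not convertible[present].any():
            out[col] = raw
        else:
            bad = raw.index[present & ~convertible][0]
            raise ValueError(
                f"column {col!r}: non-numeric value {raw.loc[bad]!r} for gene {bad!r}"
            )
    return pd.DataFrame(out, index=df.index)


def rpm_normalize(values: np.ndarray, total_mapped_reads: float) -> np.ndarray:
    """Optional reads-per-million scaling for raw coverage.

    Off by default in the pipeline: input tracks are expected to be
    RPM-normalized already (upstream contract); use this only for raw
    counts.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return np.asarray(values, dtype=float) * (1e6 / total_mapped_reads)


def write_profile_set_bedgraph(
    profiles: ProfileSet, bedgraph_path: str, annotation_path: str
) -> None:
    """Write a profile set as bedGraph (one synthetic chromosome per gene,
    window = whole chromosome) plus the matching +1 annotation TSV, so the
    real-data readers can round-trip synthetic data."""
    with open(bedgraph_path, "w") as fh:
        for gene_id, row in zip(profiles.gene_ids, profiles.values):
            # run-length compress equal consecutive values
            change = np.flatnonzero(np.diff(row)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(row)]))
            for s, e in zip(starts, ends):
                fh.write(f"{gene_id}\t{s}\t{e}\t{row[s]:.10g}\n")
    lengths = (
        profiles.gene_lengths
        if profiles.gene_lengths is not None
        else np.full(profiles.n_genes, DOWNSTREAM)
    )
    ann = pd.DataFrame(
        {
            "gene_id": profiles.gene_ids,
            "chrom": profiles.gene_ids,
            "dyad": ANCHOR_INDEX,
            "strand": "+",
            "length": np.asarray(lengths, dtype=int),
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)
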