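"""Readers and writers for every external representation the pipeline touches.

Pool-seq analyses live on a small set of text formats: FASTQ for raw reads,
samtools mpileup for per-site read stacks, the "sync" format (one
``A:T:C:G:N:del`` count field per population per site) for exchanging pooled
allele counts, TSV for sampling metadata, and GFF3/BED plus a gene→GO TSV for
annotation.  All genomic coordinates are 1-based inclusive internally; BED
half-open intervals are converted on read.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: fixed allele order of sync count fields
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: index into a count 6-vector by nucleotide
ALLELE_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4, "*": 5}


class ParseError(ValueError):
    """Malformed line in an external file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class PopulationMeta:
    """One pooled sampling site: location, environment, and pool size."""

    code: str
    latitude: float
    longitude: float
    salinity: float
    temperature: float
    pool_individuals: int

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.code}: latitude {self.latitude} out of range")
        if self.salinity < 0:
            raise ValueError(f"{self.code}: negative salinity")
        if self.pool_individuals <= 0:
            raise ValueError(f"{self.code}: pool_individuals must be positive")

    @property
    def n_chromosomes(self) -> int:
        """Number of haploid genomes in the pool (2 per diploid fish)."""
        return 2 * self.pool_individuals


@dataclass
class SiteCounts:
    """Per-population base counts at one genomic site.

    ``counts`` has shape (n_populations, 6) in SYNC_ALLELES order; coverage
    is the sum of the four nucleotide counts (N and deletions excluded).
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_populations, 6)")
        if (self.counts < 0).any():
            raise ValueError(f"{self.chrom}:{self.pos}: negative count")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts[:, :4].sum(axis=1)


@dataclass(frozen=True)
class GeneInterval:
    """A gene span (1-based inclusive) with its GO annotations."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# FASTQ quality filtering
# ---------------------------------------------------------------------------

def qc_filter_read(
    bases: str,
    quals: Sequence[int],
    trim_len: int = 90,
    min_q: int = 10,
    frac_threshold: float = 0.05,
    frac_q: int = 20,
) -> tuple[bool, str | None, str]:
    """End-trim a read and decide whether it survives quality filtering.

    The read is truncated to its first ``trim_len`` bases and discarded when
    any trimmed base falls below ``min_q`` or when more than
    ``frac_threshold`` of trimmed positions fall below ``frac_q`` (strict
    inequality on the fraction).  Ambiguous (N) bases fail both thresholds.
    Reads shorter than ``trim_len`` are discarded with reason ``too_short``.

    Returns ``(keep, reason, trimmed_bases)``.
    """
    if len(bases) != len(quals):
        raise ValueError("bases and quality strings differ in length")
    if len(bases) < trim_len:
        return False, "too_short", bases
    trimmed = bases[:trim_len]
    q = np.asarray(quals[:trim_len], dtype=np.int64)
    # N bases are treated as failing any quality threshold
    is_n = np.frombuffer(trimmed.encode(), dtype=np.uint8) == ord("N")
    if bool((q < min_q).any() or is_n.any()):
        return False, "low_quality_base", trimmed
    n_below = int(((q < frac_q) | is_n).sum())
    if n_below / trim_len > frac_threshold:
        return False, "low_quality_fraction", trimmed
    return True, None, trimmed


def filter_fastq(
    in_path: str | Path,
    out_path: str | Path,
    trim_len: int = 90,
    min_q: int = 10,
    frac_threshold: float = 0.05,
    frac_q: int = 20,
) -> dict[str, int]:
    """Quality-filter a FASTQ file; returns counts per decision reason."""
    from Bio import SeqIO

    tally = {"kept": 0, "too_short": 0, "low_quality_base": 0,
             "low_quality_fraction": 0}
    with open(in_path) as handle, open(out_path, "w") as out:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            keep, reason, trimmed = qc_filter_read(
                str(rec.seq), quals, trim_len, min_q, frac_threshold, frac_q
            )
            if keep:
                tally["kept"] += 1
                qstr = "".join(chr(q + 33) for q in quals[:trim_len])
                out.write(f"@{rec.id}\n{trimmed}\n+\n{qstr}\n")
            else:
                tally[reason] += 1
    return tally


# ---------------------------------------------------------------------------
# mpileup parsing
# ---------------------------------------------------------------------------

def _decode_pileup_column(
    bases: str, quals: str, ref: str, min_base_q: int, max_reads: int,
    line_number: int | None = None,
) -> np.ndarray:
    """Decode one mpileup bases/quals pair into a 6-vector of counts.

    Read-start (``^`` + mapping quality), read-end (``$``) and indel
    (``+n``/``-n`` + n bases) markup is consumed without contributing counts;
    ``*`` records a deletion; ``>``/``<`` (reference skips) consume a quality
    character but count nothing.
    """
    counts = np.zeros(6, dtype=np.int64)
    ref = ref.upper()
    i = 0  # position in bases string
    qi = 0  # position in quals string
    used = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError("indel marker without length", line_number)
            length = int(bases[i + 1:j])
            i = j + length
            continue
        # a read base: consumes one quality character
        if qi >= len(quals):
            raise ParseError("more bases than quality characters", line_number)
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if used >= max_reads:
            continue
        used += 1
        if c in "><":
            continue
        if c in ".,":
            base = ref
        else:
            base = c.upper()
        if q < min_base_q:
            continue
        if base == "*":
            counts[5] += 1
        elif base in ALLELE_INDEX:
            counts[ALLELE_INDEX[base]] += 1
        elif base != "N":
            raise ParseError(f"unexpected pileup character {c!r}", line_number)
    if qi != len(quals):
        raise ParseError("bases and quality strings inconsistent", line_number)
    return counts


def pileup_to_site_counts(
    lines: Iterable[str],
    min_base_q: int = 20,
    max_reads: int = 1000,
) -> Iterator[SiteCounts]:
    """Parse samtools mpileup text into per-population SiteCounts.

    Each line carries (chrom, pos, ref) then one depth/bases/quals triplet
    per population.  Bases below ``min_base_q`` are excluded from counts and
    at most ``max_reads`` reads per population per site are considered.
    """
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6 or (len(fields) - 3) % 3 != 0:
            raise ParseError(f"expected 3 + 3k columns, got {len(fields)}", ln)
        chrom, pos_s, ref = fields[:3]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"non-integer position {pos_s!r}", ln) from None
        n_pops = (len(fields) - 3) // 3
        counts = np.zeros((n_pops, 6), dtype=np.int64)
        for p in range(n_pops):
            depth_s, bases, quals = fields[3 + 3 * p: 6 + 3 * p]
            try:
                depth = int(depth_s)
            except ValueError:
                raise ParseError(f"non-integer depth {depth_s!r}", ln) from None
            if depth == 0 and bases == "*" and quals == "*":
                continue  # samtools placeholder for an empty column
            col = _decode_pileup_column(bases, quals, ref, min_base_q,
                                        max_reads, ln)
            if col.sum() > depth and depth > 0:
                raise ParseError(
                    f"decoded {col.sum()} reads but depth column says {depth}", ln
                )
            counts[p] = col
        yield SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)


# ---------------------------------------------------------------------------
# sync format
# ---------------------------------------------------------------------------

def read_sync(path: str | Path) -> Iterator[SiteCounts]:
    """Stream SiteCounts from a sync file (chrom, pos, ref, count fields)."""
    with open(path) as handle:
        yield from read_sync_lines(handle)


def read_sync_lines(lines: Iterable[str]) -> Iterator[SiteCounts]:
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError("expected at least 4 tab-separated fields", ln)
        chrom, pos_s, ref = fields[:3]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"non-integer position {pos_s!r}", ln) from None
        counts = np.zeros((len(fields) - 3, 6), dtype=np.int64)
        for p, tok in enumerate(fields[3:]):
            parts = tok.split(":")
            if len(parts) != 6:
                raise ParseError(f"count field {tok!r} is not A:T:C:G:N:del", ln)
            try:
                vec = [int(x) for x in parts]
            except ValueError:
                raise ParseError(f"non-integer count in {tok!r}", ln) from None
            if any(v < 0 for v in vec):
                raise ParseError(f"negative count in {tok!r}", ln)
            counts[p] = vec
        yield SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)


def write_sync(sites: Iterable[SiteCounts], path: str | Path) -> None:
    """Write SiteCounts to sync text; round-trips bit-exactly via read_sync."""
    n_pops: int | None = None
    with open(path, "w") as out:
        for site in sites:
            if n_pops is None:
                n_pops = site.n_populations
            elif site.n_populations != n_pops:
                raise ValueError(
                    f"{site.chrom}:{site.pos}: {site.n_populations} populations, "
                    f"expected {n_pops}"
                )
            fields = [site.chrom, str(site.pos), site.ref]
            fields += [":".join(str(int(v)) for v in row) for row in site.counts]
            out.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# metadata and annotation
# ---------------------------------------------------------------------------

_META_COLUMNS = ["code", "latitude", "longitude", "salinity", "temperature",
                 "pool_individuals"]


def load_metadata(path: str | Path) -> list[PopulationMeta]:
    """Load the population metadata TSV, preserving row order."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["code"].duplicated().any():
        dupes = df.loc[df["code"].duplicated(), "code"].tolist()
        raise ValueError(f"duplicate population codes: {dupes}")
    return [
        PopulationMeta(
            code=str(r.code), latitude=float(r.latitude),
            longitude=float(r.longitude), salinity=float(r.salinity),
            temperature=float(r.temperature),
            pool_individuals=int(r.pool_individuals),
        )
        for r in df.itertuples()
    ]


def baltic_metadata() -> list[PopulationMeta]:
    """The ten-population Baltic Sea survey bundled with the package."""
    ref = importlib.resources.files("poolscan.data") / "baltic_metadata.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_metadata(path)


def baltic_mean_fst() -> pd.DataFrame:
    """Published 10×10 mean pairwise FST matrix for the Baltic survey."""
    ref = importlib.resources.files("poolscan.data") / "baltic_mean_fst.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_intervals_gff3(
    path: str | Path,
    feature_types: Sequence[str] = ("gene",),
    go_map: dict[str, set[str]] | None = None,
) -> list[GeneInterval]:
    """Extract gene spans from a GFF3 file (1-based inclusive, as stored)."""
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as handle:
        for ln, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError("GFF3 line does not have 9 columns", ln)
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in feature_types:
                continue
            a = _parse_gff3_attributes(attrs)
            gene_id = a.get("ID") or a.get("gene_id") or a.get("Name")
            if gene_id is None:
                raise ParseError("gene feature without ID attribute", ln)
            if gene_id in seen:
                raise ParseError(f"duplicate gene id {gene_id!r}", ln)
            seen.add(gene_id)
            terms = frozenset((go_map or {}).get(gene_id, set()))
            genes.append(GeneInterval(gene_id, chrom, int(start), int(end),
                                      strand, terms))
    return genes


def read_gene_intervals_bed(
    path: str | Path, go_map: dict[str, set[str]] | None = None
) -> list[GeneInterval]:
    """Read gene spans from BED (0-based half-open → 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED gene file needs at least 4 columns (name in col 4)")
    genes = []
    seen: set[str] = set()
    for r in df.itertuples(index=False):
        chrom, start0, end0, name = r[0], int(r[1]), int(r[2]), str(r[3])
        strand = str(r[5]) if df.shape[1] >= 6 else "+"
        if name in seen:
            raise ValueError(f"duplicate gene id {name!r}")
        seen.add(name)
        terms = frozenset((go_map or {}).get(name, set()))
        genes.append(GeneInterval(name, str(chrom), start0 + 1, end0, strand, terms))
    return genes


def load_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene_id, GO:ID) TSV into gene → GO-term sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go"],
                     comment="#", dtype=str)
    out: dict[str, set[str]] = {}
    for gene, go in zip(df["gene_id"], df["go"]):
        out.setdefault(gene, set()).add(go)
    return out


def sites_to_frame(sites: Iterable[SiteCounts]) -> pd.DataFrame:
    """Tabulate a SiteCounts stream: one row per site with stacked counts."""
    rows = []
    for s in sites:
        rows.append((s.chrom, s.pos, s.ref, s.counts.copy()))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "counts"])
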