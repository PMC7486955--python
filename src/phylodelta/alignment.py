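"""Alignment data model, FASTA/partition I/O, filtering, masking, trimming
and information-content statistics for UCE-style multi-locus data.

Characters are upper-case over the alphabet ``{A, C, G, T, N, -, ?}``.  The
three symbols ``N``, ``-`` and ``?`` are treated identically as *missing*
everywhere (missing-fraction filters, parsimony-informative-site calls,
completeness trimming, and likelihoods): pipelines of this kind interconvert
them freely, so distinguishing them would manufacture spurious structure.
IUPAC ambiguity codes other than ``N`` are rejected at parse time.

Coordinates are 0-based half-open internally; RAxML-style partition files
(``DNA, uce1 = 1-500``) use 1-based inclusive ranges on disk.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from scipy import stats as sps

__all__ = [
    "ALPHABET", "MISSING_CHARS", "UNAMBIGUOUS",
    "AlignmentError", "CharacterError", "PartitionError", "EmptyResultError",
    "SequenceRecord", "LocusAlignment", "PartitionMap", "ConcatenatedAlignment",
    "SampleMetadata", "LocusStats", "FilterConfig",
    "read_locus_set", "write_locus_fasta", "write_concatenated",
    "read_metadata", "write_metadata",
    "drop_high_missing_sequences", "RemovalReport", "concatenate",
    "pis_mask", "classify_columns", "locus_stats", "alignment_stats",
    "completeness_trim", "TrimResult", "mask_columns",
    "convert_pis_to_missing", "sample_missing_report", "MissingReport",
    "encode",
]

UNAMBIGUOUS = "ACGT"
MISSING_CHARS = "N-?"
ALPHABET = UNAMBIGUOUS + MISSING_CHARS

# byte-code mapping used across the package: A=0 C=1 G=2 T=3, missing=4
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(UNAMBIGUOUS):
    _CODE[ord(_c)] = _i
for _c in MISSING_CHARS:
    _CODE[ord(_c)] = 4

_MISSING_BYTES = frozenset(MISSING_CHARS.encode())


class AlignmentError(ValueError):
    pass


class CharacterError(AlignmentError):
    pass


class PartitionError(AlignmentError):
    pass


class EmptyResultError(AlignmentError):
    pass


def encode(matrix: np.ndarray) -> np.ndarray:
    """Map an ``S1`` character matrix to uint8 codes (A=0..T=3, missing=4)."""
    codes = _CODE[matrix.view(np.uint8)]
    if np.any(codes == 255):
        bad = np.argwhere(codes == 255)[0]
        raise CharacterError(f"character outside alphabet at row {bad[0]}, "
                             f"column {bad[1]}")
    return codes


def _validate_chars(chars: str, where: str) -> str:
    chars = chars.upper()
    bad = set(chars) - set(ALPHABET)
    if bad:
        pos = next(i for i, c in enumerate(chars) if c in bad)
        raise CharacterError(
            f"{where}: character {chars[pos]!r} at position {pos} is outside "
            f"the alphabet {ALPHABET!r} (IUPAC ambiguity codes other than N "
            f"are not supported)")
    return chars


@dataclass
class SequenceRecord:
    taxon: str
    chars: str

    def __post_init__(self):
        if not self.taxon:
            raise AlignmentError("empty taxon id")
        if not self.chars:
            raise AlignmentError(f"empty sequence for taxon {self.taxon!r}")
        self.chars = _validate_chars(self.chars, f"taxon {self.taxon!r}")

    def missing_fraction(self) -> float:
        return sum(self.chars.count(c) for c in MISSING_CHARS) / len(self.chars)


@dataclass
class LocusAlignment:
    locus_id: str
    records: list[SequenceRecord]

    def __post_init__(self):
        if not self.records:
            raise AlignmentError(f"locus {self.locus_id!r} has no records")
        lengths = {len(r.chars) for r in self.records}
        if len(lengths) != 1:
            offender = max(self.records, key=lambda r: len(r.chars))
            raise AlignmentError(
                f"ragged alignment in locus {self.locus_id!r}: taxon "
                f"{offender.taxon!r} has length {len(offender.chars)}, "
                f"others {sorted(lengths - {len(offender.chars)})}")
        taxa = [r.taxon for r in self.records]
        if len(set(taxa)) != len(taxa):
            raise AlignmentError(f"duplicate taxa in locus {self.locus_id!r}")

    @property
    def length(self) -> int:
        return len(self.records[0].chars)

    @property
    def taxa(self) -> list[str]:
        return [r.taxon for r in self.records]

    def to_matrix(self) -> np.ndarray:
        return np.array([list(r.chars) for r in self.records], dtype="S1")


@dataclass
class PartitionMap:
    entries: list[tuple[str, int, int]]

    def __post_init__(self):
        if not self.entries:
            raise PartitionError("empty partition map")
        pos = 0
        seen = set()
        for locus_id, start, end in self.entries:
            if locus_id in seen:
                raise PartitionError(f"duplicate locus id {locus_id!r}")
            seen.add(locus_id)
            if start != pos:
                raise PartitionError(
                    f"partition {locus_id!r} starts at {start}, expected {pos} "
                    f"(intervals must be contiguous and non-overlapping)")
            if end <= start:
                raise PartitionError(f"partition {locus_id!r} is empty or inverted")
            pos = end

    @property
    def total_length(self) -> int:
        return self.entries[-1][2]

    @property
    def locus_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def lengths(self) -> dict[str, int]:
        return {lid: end - start for lid, start, end in self.entries}

    def span(self, locus_id: str) -> tuple[int, int]:
        for lid, start, end in self.entries:
            if lid == locus_id:
                return start, end
        raise PartitionError(f"unknown locus {locus_id!r}")

    def locus_of_site(self) -> np.ndarray:
        """Integer partition index per column."""
        idx = np.empty(self.total_length, dtype=np.int64)
        for i, (_, start, end) in enumerate(self.entries):
            idx[start:end] = i
        return idx


@dataclass
class ConcatenatedAlignment:
    taxa: list[str]
    matrix: np.ndarray                      # (n_taxa, n_cols) dtype S1
    partitions: PartitionMap

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxa in concatenated alignment")
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.shape != (len(self.taxa), self.partitions.total_length):
            raise AlignmentError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.taxa)} taxa x {self.partitions.total_length} columns")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def codes(self) -> np.ndarray:
        return encode(self.matrix)

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.matrix[self.taxa.index(taxon)]
        except ValueError:
            raise AlignmentError(f"taxon {taxon!r} not in alignment") from None

    def get_locus(self, locus_id: str) -> LocusAlignment:
        start, end = self.partitions.span(locus_id)
        records = [SequenceRecord(t, self.matrix[i, start:end].tobytes().decode())
                   for i, t in enumerate(self.taxa)]
        return LocusAlignment(locus_id, records)

    def subset_taxa(self, taxa: Sequence[str]) -> "ConcatenatedAlignment":
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        rows = [self.taxa.index(t) for t in taxa]
        return ConcatenatedAlignment(list(taxa), self.matrix[rows].copy(),
                                     PartitionMap(list(self.partitions.entries)))

    def copy(self) -> "ConcatenatedAlignment":
        return ConcatenatedAlignment(list(self.taxa), self.matrix.copy(),
                                     PartitionMap(list(self.partitions.entries)))


@dataclass
class SampleMetadata:
    sample_id: str
    sample_type: str                        # "modern" | "historical"
    collection_year: Optional[int] = None
    batch: Optional[str] = None

    def __post_init__(self):
        if self.sample_type not in ("modern", "historical"):
            raise AlignmentError(
                f"sample {self.sample_id!r}: sample_type must be 'modern' or "
                f"'historical', got {self.sample_type!r}")
        if self.collection_year is not None and not (1800 <= self.collection_year <= 2100):
            raise AlignmentError(
                f"sample {self.sample_id!r}: implausible collection year "
                f"{self.collection_year}")


@dataclass
class LocusStats:
    locus_id: str
    alignment_length: int
    n_taxa: int
    undetermined: int
    variable_sites: int
    pis: int
    gc_content: float
    degenerate: bool = False


@dataclass
class FilterConfig:
    """Occupancy and coverage filters.

    ``max_individual_missing``: a sequence is dropped from a locus when its
    missing fraction strictly exceeds this (default 0.30).
    ``min_occupancy``: a locus is kept when at least this fraction of the
    sample universe is present (default 0.75).
    ``depth_threshold``: read depth below which a base call is masked in the
    filtered observation regime (default 6).
    """
    max_individual_missing: float = 0.30
    min_occupancy: float = 0.75
    depth_threshold: int = 6

    def __post_init__(self):
        if not (0.0 <= self.max_individual_missing <= 1.0):
            raise AlignmentError("max_individual_missing must be in [0, 1]")
        if not (0.0 <= self.min_occupancy <= 1.0):
            raise AlignmentError("min_occupancy must be in [0, 1]")
        if self.depth_threshold < 1:
            raise AlignmentError("depth_threshold must be >= 1")


# ----------------------------------------------------------------------- I/O

_PARTITION_RE = re.compile(r"^\s*DNA\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$",
                           re.IGNORECASE)


def _read_partition_file(path) -> PartitionMap:
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise PartitionError(f"cannot parse partition line {line!r}")
        name, a, b = m.group(1), int(m.group(2)), int(m.group(3))
        entries.append((name, a - 1, b))    # 1-based inclusive -> half-open
    return PartitionMap(entries)


def read_locus_set(fasta_paths, partition_path=None):
    """Read per-locus FASTAs, or one concatenated FASTA plus a partition file.

    Returns ``(loci, partition_map)``; the map is ``None`` when reading
    per-locus files (each file is one locus named after its stem).
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    fasta_paths = [Path(p) for p in fasta_paths]
    for p in fasta_paths:
        if not p.exists():
            raise FileNotFoundError(p)

    if partition_path is not None:
        if len(fasta_paths) != 1:
            raise AlignmentError("a partition file applies to exactly one FASTA")
        pmap = _read_partition_file(partition_path)
        records = [(r.id, _validate_chars(str(r.seq), f"taxon {r.id!r}"))
                   for r in SeqIO.parse(str(fasta_paths[0]), "fasta")]
        loci = []
        for locus_id, start, end in pmap.entries:
            loci.append(LocusAlignment(locus_id, [
                SequenceRecord(t, s[start:end]) for t, s in records]))
        return loci, pmap

    loci = []
    for p in fasta_paths:
        recs = [SequenceRecord(r.id, str(r.seq))
                for r in SeqIO.parse(str(p), "fasta")]
        loci.append(LocusAlignment(p.stem, recs))
    return loci, None


def write_locus_fasta(locus: LocusAlignment, path) -> None:
    SeqIO.write([BioSeqRecord(Seq(r.chars), id=r.taxon, description="")
                 for r in locus.records], str(path), "fasta")


def write_concatenated(aln: ConcatenatedAlignment, fasta_path,
                       partition_path=None) -> None:
    recs = [BioSeqRecord(Seq(aln.matrix[i].tobytes().decode()), id=t,
                         description="")
            for i, t in enumerate(aln.taxa)]
    SeqIO.write(recs, str(fasta_path), "fasta")
    if partition_path is not None:
        with open(partition_path, "w") as fh:
            for lid, start, end in aln.partitions.entries:
                fh.write(f"DNA, {lid} = {start + 1}-{end}\n")


def read_metadata(path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    out = {}
    for _, row in df.iterrows():
        year = row.get("collection_year")
        year = None if pd.isna(year) else int(year)
        batch = row.get("batch")
        batch = None if pd.isna(batch) else str(batch)
        md = SampleMetadata(str(row["sample_id"]), str(row["sample_type"]),
                            year, batch)
        out[md.sample_id] = md
    return out


def write_metadata(metadata: dict[str, SampleMetadata], path) -> None:
    rows = [{"sample_id": m.sample_id, "sample_type": m.sample_type,
             "collection_year": m.collection_year, "batch": m.batch}
            for m in metadata.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- filtering

@dataclass
class RemovalReport:
    removed: pd.DataFrame                   # sample_id, locus_id, missing_fraction
    degenerate_loci: list[str] = field(default_factory=list)


def drop_high_missing_sequences(loci: Iterable[LocusAlignment],
                                config: FilterConfig = FilterConfig()
                                ) -> tuple[list[LocusAlignment], RemovalReport]:
    """Remove sequences whose missing fraction strictly exceeds the threshold.

    Loci left with fewer than two sequences are retained but flagged as
    degenerate in the report.
    """
    kept_loci: list[LocusAlignment] = []
    rows = []
    degenerate = []
    for locus in loci:
        kept, dropped = [], []
        for rec in locus.records:
            frac = rec.missing_fraction()
            if frac > config.max_individual_missing:
                dropped.append((rec.taxon, frac))
            else:
                kept.append(rec)
        for taxon, frac in dropped:
            rows.append({"sample_id": taxon, "locus_id": locus.locus_id,
                         "missing_fraction": frac})
        if len(kept) < 2:
            degenerate.append(locus.locus_id)
            kept = kept or locus.records    # keep something rather than nothing
        kept_loci.append(LocusAlignment(locus.locus_id, kept))
    report = RemovalReport(
        pd.DataFrame(rows, columns=["sample_id", "locus_id", "missing_fraction"]),
        degenerate)
    return kept_loci, report


def concatenate(loci: Sequence[LocusAlignment], taxa_universe: Sequence[str],
                config: FilterConfig = FilterConfig()) -> ConcatenatedAlignment:
    """Concatenate loci meeting the occupancy threshold, padding absentees
    with N."""
    taxa_universe = list(taxa_universe)
    n = len(taxa_universe)
    kept = [loc for loc in loci
            if len(set(loc.taxa) & set(taxa_universe)) / n >= config.min_occupancy]
    if not kept:
        raise EmptyResultError(
            f"no locus reaches occupancy {config.min_occupancy:.0%} over "
            f"{n} samples")
    total = sum(loc.length for loc in kept)
    matrix = np.full((n, total), b"N", dtype="S1")
    entries = []
    pos = 0
    for loc in kept:
        row_of = {r.taxon: r for r in loc.records}
        for i, taxon in enumerate(taxa_universe):
            if taxon in row_of:
                matrix[i, pos:pos + loc.length] = np.frombuffer(
                    row_of[taxon].chars.encode(), dtype="S1")
        entries.append((loc.locus_id, pos, pos + loc.length))
        pos += loc.length
    return ConcatenatedAlignment(taxa_universe, matrix, PartitionMap(entries))


# ---------------------------------------------------------------- statistics

def _as_matrix(aln) -> np.ndarray:
    if isinstance(aln, ConcatenatedAlignment):
        return aln.matrix
    if isinstance(aln, LocusAlignment):
        return aln.to_matrix()
    return np.asarray(aln, dtype="S1")


def classify_columns(aln) -> np.ndarray:
    """Per-column classification: 0 constant, 1 variable (non-PIS), 2 PIS.

    A column is parsimony-informative when at least two distinct unambiguous
    states each occur in at least two sequences; missing symbols never count
    as states.
    """
    codes = encode(_as_matrix(aln))
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_deep = (counts >= 2).sum(axis=0)
    out = np.zeros(codes.shape[1], dtype=np.int8)
    out[n_states >= 2] = 1
    out[(n_states >= 2) & (n_deep >= 2)] = 2
    return out


def pis_mask(aln) -> np.ndarray:
    """Boolean vector marking parsimony-informative columns."""
    return classify_columns(aln) == 2


def locus_stats(locus) -> LocusStats:
    matrix = _as_matrix(locus)
    locus_id = locus.locus_id if isinstance(locus, LocusAlignment) else "alignment"
    codes = encode(matrix)
    cls = classify_columns(matrix)
    undetermined = int((codes == 4).sum())
    gc = int(((codes == 1) | (codes == 2)).sum())
    at = int(((codes == 0) | (codes == 3)).sum())
    degenerate = (gc + at) == 0
    return LocusStats(
        locus_id=locus_id,
        alignment_length=matrix.shape[1],
        n_taxa=matrix.shape[0],
        undetermined=undetermined,
        variable_sites=int((cls >= 1).sum()),
        pis=int((cls == 2).sum()),
        gc_content=0.0 if degenerate else gc / (gc + at),
        degenerate=degenerate,
    )


def alignment_stats(aln: ConcatenatedAlignment) -> pd.DataFrame:
    """Per-locus statistics table for a partitioned concatenation."""
    rows = []
    for lid, start, end in aln.partitions.entries:
        st = locus_stats(aln.matrix[:, start:end])
        st.locus_id = lid
        # count only taxa actually present (not fully missing) in the locus
        codes = encode(aln.matrix[:, start:end])
        st.n_taxa = int(((codes != 4).any(axis=1)).sum())
        rows.append(st.__dict__.copy())
    return pd.DataFrame(rows)


# ------------------------------------------------------- trimming & masking

@dataclass
class TrimResult:
    alignment: ConcatenatedAlignment
    kept_columns: np.ndarray
    dropped_loci: list[str]


def completeness_trim(aln: ConcatenatedAlignment, threshold_percent: float
                      ) -> TrimResult:
    """Keep columns where at least ``threshold_percent``% of sequences carry
    an unambiguous character; partitions are remapped and empty ones dropped."""
    if not (0 <= threshold_percent <= 100):
        raise AlignmentError("threshold must be in [0, 100]")
    codes = aln.codes()
    frac = (codes != 4).sum(axis=0) / aln.n_taxa
    keep = frac >= threshold_percent / 100.0
    kept_idx = np.nonzero(keep)[0]
    if kept_idx.size == 0:
        raise EmptyResultError(
            f"completeness threshold {threshold_percent}% removes every column")
    entries = []
    dropped = []
    pos = 0
    for lid, start, end in aln.partitions.entries:
        n_kept = int(keep[start:end].sum())
        if n_kept == 0:
            dropped.append(lid)
            continue
        entries.append((lid, pos, pos + n_kept))
        pos += n_kept
    trimmed = ConcatenatedAlignment(list(aln.taxa), aln.matrix[:, kept_idx],
                                    PartitionMap(entries))
    return TrimResult(trimmed, kept_idx, dropped)


def mask_columns(aln: ConcatenatedAlignment, column_indices
                 ) -> ConcatenatedAlignment:
    """Set the named columns to N in every row (idempotent)."""
    idx = np.asarray(sorted(set(int(i) for i in column_indices)), dtype=np.int64)
    out = aln.copy()
    if idx.size == 0:
        return out
    if idx.min() < 0 or idx.max() >= aln.n_columns:
        raise AlignmentError(
            f"column index out of range (0..{aln.n_columns - 1})")
    out.matrix[:, idx] = b"N"
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def convert_pis_to_missing(aln: ConcatenatedAlignment, sample_ids,
                           fraction: float, seed: int) -> ConcatenatedAlignment:
    """Convert a fraction of each named sample's parsimony-informative sites
    to N (the museum-degradation mimicry experiment).

    ``round(fraction * nPIS)`` PIS columns (half away from zero) are chosen
    uniformly without replacement, independently per sample, and set to N in
    that sample only.
    """
    if not (0.0 <= fraction <= 1.0):
        raise AlignmentError("fraction must be in [0, 1]")
    if isinstance(sample_ids, str):
        sample_ids = [sample_ids]
    unknown = [s for s in sample_ids if s not in aln.taxa]
    if unknown:
        raise AlignmentError(f"unknown samples: {unknown}")
    pis_cols = np.nonzero(pis_mask(aln))[0]
    k = _round_half_away(fraction * pis_cols.size)
    out = aln.copy()
    rng = np.random.default_rng(seed)
    for sample in sample_ids:
        chosen = rng.choice(pis_cols, size=k, replace=False)
        out.matrix[aln.taxa.index(sample), chosen] = b"N"
    return out


# ------------------------------------------------------------ missing report

@dataclass
class MissingReport:
    per_sample: pd.DataFrame
    mean_missing: dict[str, float]          # per sample type
    historical_modern_ratio: float          # NaN when undefined
    regression: dict                        # slope, intercept, adj_r2, p_value, n


def sample_missing_report(aln: ConcatenatedAlignment,
                          metadata: dict[str, SampleMetadata],
                          column_subset=None) -> MissingReport:
    """Per-sample missing-data summary, type means/ratio and the
    missing-vs-collection-year ordinary least squares regression."""
    untyped = [t for t in aln.taxa if t not in metadata]
    if untyped:
        raise AlignmentError(f"no metadata for taxa: {untyped}")
    codes = aln.codes()
    if column_subset is not None:
        idx = np.asarray(list(column_subset), dtype=np.int64)
        codes = codes[:, idx]
    n_cols = codes.shape[1]
    rows = []
    for i, taxon in enumerate(aln.taxa):
        md = metadata[taxon]
        miss = int((codes[i] == 4).sum())
        rows.append({"sample_id": taxon, "sample_type": md.sample_type,
                     "collection_year": md.collection_year,
                     "missing_count": miss,
                     "missing_percent": 100.0 * miss / n_cols if n_cols else np.nan})
    df = pd.DataFrame(rows)
    means = df.groupby("sample_type")["missing_count"].mean().to_dict()
    hist, mod = means.get("historical"), means.get("modern")
    if hist is None or mod is None:
        ratio = float("nan")
    elif mod == 0:
        ratio = float("inf") if hist > 0 else float("nan")
    else:
        ratio = float(hist / mod)

    reg = {"slope": np.nan, "intercept": np.nan, "adj_r2": np.nan,
           "p_value": np.nan, "n": 0}
    sub = df.dropna(subset=["collection_year"])
    if len(sub) >= 3 and sub["collection_year"].nunique() > 1:
        res = sps.linregress(sub["collection_year"].astype(float),
                             sub["missing_percent"].astype(float))
        n = len(sub)
        r2 = res.rvalue ** 2
        reg = {"slope": float(res.slope), "intercept": float(res.intercept),
               "adj_r2": float(1.0 - (1.0 - r2) * (n - 1) / (n - 2)),
               "p_value": float(res.pvalue), "n": n}
    return MissingReport(df, {k: float(v) for k, v in means.items()}, ratio, reg)
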