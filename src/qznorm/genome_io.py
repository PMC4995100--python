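"""Readers and writers for genomes, fragment files, annotations, and tracks.

All coordinates are 0-based, half-open (BED convention) internally. Every
other module consumes the container types defined here and never touches
files directly, so there is exactly one place where coordinate conventions
are enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GenomeTable",
    "FragmentSet",
    "IntervalSet",
    "DyadAnnotation",
    "Track",
    "ParseError",
    "ValidationError",
    "read_genome_table",
    "read_fragments",
    "read_intervals",
    "read_dyads",
    "write_fragments",
    "write_intervals",
    "write_dyads",
    "write_track",
    "read_bedgraph",
]


class ParseError(ValueError):
    """A file record could not be parsed; the message names the line."""


class ValidationError(ValueError):
    """An in-memory container violated one of its invariants."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome names and lengths defining the coordinate space.

    Parameters
    ----------
    lengths
        Mapping from chromosome name to length in basepairs. Order is
        preserved and used as the canonical chromosome order everywhere.
    """

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValidationError("genome table is empty")
        for chrom, length in self.lengths.items():
            if int(length) < 1:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))


@dataclass
class FragmentSet:
    """Paired-end fragment intervals for one sequencing fraction.

    Backed by a DataFrame with columns ``chrom``, ``start``, ``end``,
    ``count`` (multiplicity, integer >= 1). Duplicate intervals are kept:
    MNase-seq depth is signal.
    """

    frame: pd.DataFrame

    REQUIRED = ("chrom", "start", "end")

    def __post_init__(self) -> None:
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"FragmentSet frame lacks column {col!r}")
        if "count" not in df.columns:
            df = df.assign(count=np.ones(len(df), dtype=np.int64))
            self.frame = df
        if len(df) and not (df["start"].to_numpy() < df["end"].to_numpy()).all():
            raise ValidationError("fragment with start >= end")
        if len(df) and (df["count"].to_numpy() < 1).any():
            raise ValidationError("fragment multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_count(self) -> int:
        """Total number of fragments, multiplicities included."""
        return int(self.frame["count"].sum())

    def validate_bounds(self, genome: GenomeTable) -> None:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValidationError(f"fragment on unknown chromosome {chrom!r}")
            if (sub["start"].to_numpy() < 0).any() or (
                sub["end"].to_numpy() > genome[chrom]
            ).any():
                raise ValidationError(f"fragment out of bounds on {chrom}")

    def midpoints(self) -> np.ndarray:
        """Fragment midpoints, floor((start+end)/2) for even lengths."""
        s = self.frame["start"].to_numpy(dtype=np.int64)
        e = self.frame["end"].to_numpy(dtype=np.int64)
        return (s + e) // 2


@dataclass
class IntervalSet:
    """Labelled genomic intervals (reference zones, NDRs, ...)."""

    frame: pd.DataFrame  # chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"IntervalSet frame lacks column {col!r}")
        if "label" not in df.columns:
            df = df.assign(label="")
        if len(df) and not (df["start"].to_numpy() < df["end"].to_numpy()).all():
            raise ValidationError("interval with start >= end")
        # canonical sort
        self.frame = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_span(self) -> int:
        """Total basepairs covered, counting overlapping intervals once."""
        span = 0
        for _, sub in self.frame.groupby("chrom", sort=False):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        span += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                span += cur_e - cur_s
        return int(span)

    def merged(self) -> "IntervalSet":
        """Union of intervals: overlapping/adjacent intervals collapsed."""
        rows = []
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        rows.append((chrom, cur_s, cur_e, ""))
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                rows.append((chrom, cur_s, cur_e, ""))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


VALID_ROLES = {"plus_one", "minus_one", "generic", "fragile"}


@dataclass
class DyadAnnotation:
    """Oriented nucleosome dyad positions.

    Backed by a DataFrame with columns ``chrom``, ``dyad``, ``strand``
    (``+``/``-``/``.``) and ``role`` (plus_one, minus_one, generic, fragile).
    Entries with role ``plus_one`` must carry a defined strand.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("chrom", "dyad"):
            if col not in df.columns:
                raise ValidationError(f"DyadAnnotation frame lacks column {col!r}")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        if "role" not in df.columns:
            df = df.assign(role="generic")
        bad_roles = set(df["role"]) - VALID_ROLES
        if bad_roles:
            raise ValidationError(f"unknown dyad roles: {sorted(bad_roles)}")
        plus = df[df["role"] == "plus_one"]
        if len(plus) and (~plus["strand"].isin(["+", "-"])).any():
            raise ValidationError("plus_one dyads must have a defined strand")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def validate_bounds(self, genome: GenomeTable) -> None:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValidationError(f"dyad on unknown chromosome {chrom!r}")
            d = sub["dyad"].to_numpy()
            if (d < 0).any() or (d >= genome[chrom]).any():
                raise ValidationError(f"dyad out of bounds on {chrom}")

    def subset(self, mask) -> "DyadAnnotation":
        return DyadAnnotation(self.frame[mask].reset_index(drop=True))


@dataclass
class Track:
    """Per-basepair dense signal over a genome.

    ``data`` maps chromosome name to a float vector whose length equals the
    chromosome length. ``fraction`` tags the sequencing fraction (``T``
    input, ``A`` flow-through/H2A, ``Z`` IP/H2A.Z); ``normalized`` and
    ``scale`` record the normalization state. Fragment-derived tracks are
    non-negative; derived ratio/difference tracks may not be.
    """

    data: dict[str, np.ndarray]
    fraction: str | None = None
    normalized: bool = False
    scale: float = 1.0

    @classmethod
    def zeros(cls, genome: GenomeTable, fraction: str | None = None) -> "Track":
        return cls(
            {c: np.zeros(n, dtype=np.float64) for c, n in genome.lengths.items()},
            fraction=fraction,
        )

    def validate(self, genome: GenomeTable | None = None, nonnegative: bool = False) -> None:
        for chrom, arr in self.data.items():
            if genome is not None:
                if chrom not in genome:
                    raise ValidationError(f"track chromosome {chrom!r} not in genome")
                if len(arr) != genome[chrom]:
                    raise ValidationError(
                        f"track length {len(arr)} != chromosome length {genome[chrom]} on {chrom}"
                    )
            if not np.isfinite(arr).all():
                raise ValidationError(f"non-finite track values on {chrom}")
            if nonnegative and (arr < 0).any():
                raise ValidationError(f"negative track values on {chrom}")

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def scaled(self, factor: float) -> "Track":
        return Track(
            {c: arr * factor for c, arr in self.data.items()},
            fraction=self.fraction,
            normalized=True,
            scale=self.scale * factor,
        )

    def copy(self) -> "Track":
        return Track(
            {c: arr.copy() for c, arr in self.data.items()},
            fraction=self.fraction,
            normalized=self.normalized,
            scale=self.scale,
        )


# ---------------------------------------------------------------------------
# readers


def _lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a two-column (chrom, length) tab-separated genome table."""
    lengths: dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        chrom = fields[0]
        if chrom in lengths:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        try:
            lengths[chrom] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return GenomeTable(lengths)


def read_fragments(
    path: str | Path,
    dialect: str = "bed3",
    genome: GenomeTable | None = None,
) -> FragmentSet:
    """Read paired-end fragments from a BED3 or BEDPE file.

    BED3 records are taken as fragment extents directly. BEDPE records
    (chrom1 start1 end1 chrom2 start2 end2 ...) are collapsed to the outer
    span of the two mates, which must lie on the same chromosome.
    """
    if dialect not in ("bed3", "bedpe"):
        raise ValueError(f"unknown dialect {dialect!r}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        try:
            if dialect == "bed3":
                if len(fields) < 3:
                    raise ValueError("expected >= 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            else:
                if len(fields) < 6:
                    raise ValueError("expected >= 6 columns")
                c1, s1, e1, c2, s2, e2 = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]),
                    int(fields[5]),
                )
                if c1 != c2:
                    raise ValueError(f"mates on different chromosomes {c1!r}/{c2!r}")
                chrom, start, end = c1, min(s1, s2), max(e1, e2)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
    frags = FragmentSet(
        pd.DataFrame(
            {
                "chrom": np.asarray(chroms, dtype=object),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
                "count": np.ones(len(starts), dtype=np.int64),
            }
        )
    )
    if genome is not None:
        frags.validate_bounds(genome)
    return frags


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED-like file of labelled intervals (e.g. no-Z-zones, NDRs).

    A header row is sniffed: a first line whose second column is not an
    integer is skipped.
    """
    rows = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            if lineno == 1 or not rows:
                continue  # header row
            raise ParseError(f"{path}:{lineno}: non-integer coordinates")
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        label = fields[3] if len(fields) > 3 else ""
        rows.append((fields[0], start, end, label))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def read_dyads(path: str | Path, role: str = "generic") -> DyadAnnotation:
    """Read nucleosome dyads from a BED6-like file.

    The dyad is the midpoint of each interval (the position itself for
    1-bp records). Strand is taken from column 6 when present; a
    ``plus_one`` role requires it.
    """
    rows = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            if not rows:
                continue  # header row
            raise ParseError(f"{path}:{lineno}: non-integer coordinates")
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        if role == "plus_one" and strand == ".":
            raise ParseError(f"{path}:{lineno}: plus_one dyad lacks strand")
        rows.append((fields[0], (start + end) // 2, strand, role))
    return DyadAnnotation(pd.DataFrame(rows, columns=["chrom", "dyad", "strand", "role"]))


# ---------------------------------------------------------------------------
# writers


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    """Write fragments as BED3, repeating records per multiplicity."""
    df = frags.frame
    with open(path, "w") as fh:
        for chrom, start, end, count in zip(df["chrom"], df["start"], df["end"], df["count"]):
            rec = f"{chrom}\t{start}\t{end}\n" * int(count)
            fh.write(rec)


def write_intervals(ivals: IntervalSet, path: str | Path) -> None:
    ivals.frame.to_csv(path, sep="\t", header=False, index=False)


def write_dyads(dyads: DyadAnnotation, path: str | Path) -> None:
    """Write dyads as BED6 1-bp intervals (name = role, score = 0)."""
    df = dyads.frame
    with open(path, "w") as fh:
        for chrom, dyad, strand, role in zip(df["chrom"], df["dyad"], df["strand"], df["role"]):
            fh.write(f"{chrom}\t{dyad}\t{dyad + 1}\t{role}\t0\t{strand}\n")


def write_track(track: Track, path: str | Path, format: str = "bedgraph") -> None:
    """Write a track as bedGraph (zero runs omitted) or fixed-step wiggle.

    A read-back of the emitted bedGraph reproduces the vector bit-exactly;
    runs of equal value are compressed into single records.
    """
    if format not in ("bedgraph", "wig"):
        raise ValueError(f"unknown track format {format!r}")
    with open(path, "w") as fh:
        if format == "bedgraph":
            fh.write('track type=bedGraph name="qznorm"\n')
            for chrom, arr in track.data.items():
                if len(arr) == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = float(arr[s])
                    if v != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")
        else:
            for chrom, arr in track.data.items():
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.write("\n".join(repr(float(v)) for v in arr))
                fh.write("\n")


def read_bedgraph(path: str | Path, genome: GenomeTable) -> Track:
    """Read a bedGraph file into a dense track over the given genome."""
    track = Track.zeros(genome)
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in genome:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start >= end or end > genome[chrom]:
            raise ParseError(f"{path}:{lineno}: bad interval [{start},{end})")
        track.data[chrom][start:end] = value
    return track
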