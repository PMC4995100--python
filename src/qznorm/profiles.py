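"""Coverage/midpoint tracks and dyad-centered profile aggregation.

Two track flavours mirror the two ways MNase fragment data are plotted:
*tag coverage* counts every basepair covered by a fragment's extent, while
*tag counts* places a single count at each fragment midpoint. Meta-profiles
compile a track around a set of nucleosome dyads, orienting minus-strand
dyads so that positive offsets always point into the gene body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import DyadAnnotation, FragmentSet, GenomeTable, Track, ValidationError

__all__ = [
    "MetaProfile",
    "ProfileMatrix",
    "coverage_track",
    "midpoint_track",
    "compile_meta",
    "window_signal",
    "profile_matrix",
]


@dataclass
class MetaProfile:
    """Signal compiled around dyads: summed counts per offset.

    ``values`` holds the sum over dyads; ``mean`` divides by the number of
    usable dyads. ``n_dropped`` counts dyads discarded because their flank
    ran off a chromosome end (they are excluded entirely, never zero-padded).
    """

    offsets: np.ndarray  # -flank .. +flank inclusive
    values: np.ndarray
    n_dyads: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValidationError("offset/value length mismatch")
        if self.offsets[0] != -self.offsets[-1]:
            raise ValidationError("offset axis must be symmetric about 0")

    @property
    def mean(self) -> np.ndarray:
        return self.values / max(self.n_dyads, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "sum": self.values, "mean": self.mean})


@dataclass
class ProfileMatrix:
    """Per-dyad signal rows over a common offset axis."""

    offsets: np.ndarray
    matrix: np.ndarray  # (n_dyads, n_offsets)
    dyads: pd.DataFrame  # row metadata: chrom, dyad, strand, role, [sort_key]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.dyads), len(self.offsets)):
            raise ValidationError("matrix shape does not match metadata")

    def __len__(self) -> int:
        return len(self.dyads)

    def column_mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[str(o) for o in self.offsets])
        return pd.concat([self.dyads.reset_index(drop=True), df], axis=1)


def coverage_track(frags: FragmentSet, genome: GenomeTable) -> Track:
    """Tag coverage: per-basepair count of overlapping fragment extents."""
    frags.validate_bounds(genome)
    track = Track.zeros(genome, fraction=None)
    df = frags.frame
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = track.data[chrom]
        delta = np.zeros(len(arr) + 1, dtype=np.float64)
        counts = sub["count"].to_numpy(dtype=np.float64)
        np.add.at(delta, sub["start"].to_numpy(), counts)
        np.add.at(delta, sub["end"].to_numpy(), -counts)
        arr += np.cumsum(delta[:-1])
    return track


def midpoint_track(frags: FragmentSet, genome: GenomeTable) -> Track:
    """Tag counts: one count per fragment at its (floor) midpoint."""
    frags.validate_bounds(genome)
    track = Track.zeros(genome, fraction=None)
    df = frags.frame.assign(mid=frags.midpoints())
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = track.data[chrom]
        np.add.at(arr, sub["mid"].to_numpy(), sub["count"].to_numpy(dtype=np.float64))
    return track


def _dyad_rows(
    track: Track, dyads: DyadAnnotation, flank: int, orient_by_strand: bool
) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Extract per-dyad signal rows; edge-clipped dyads are dropped."""
    offsets = np.arange(-flank, flank + 1)
    rows: list[np.ndarray] = []
    kept: list[pd.DataFrame] = []
    dropped = 0
    for chrom, sub in dyads.frame.groupby("chrom", sort=False):
        if chrom not in track.data:
            dropped += len(sub)
            continue
        arr = track.data[chrom]
        pos = sub["dyad"].to_numpy(dtype=np.int64)
        ok = (pos - flank >= 0) & (pos + flank < len(arr))
        dropped += int((~ok).sum())
        if not ok.any():
            continue
        sub = sub[ok]
        pos = pos[ok]
        block = arr[pos[:, None] + offsets[None, :]]
        if orient_by_strand:
            minus = (sub["strand"] == "-").to_numpy()
            block[minus] = block[minus, ::-1]
        rows.append(block)
        kept.append(sub)
    if rows:
        matrix = np.vstack(rows)
        meta = pd.concat(kept, ignore_index=True)
    else:
        matrix = np.empty((0, len(offsets)))
        meta = dyads.frame.iloc[0:0].copy()
    return matrix, meta.reset_index(drop=True), dropped


def compile_meta(
    track: Track,
    dyads: DyadAnnotation,
    flank: int = 500,
    orient_by_strand: bool = True,
) -> MetaProfile:
    """Compile track signal around dyads into a summed meta-profile.

    Minus-strand dyads contribute their mirror image when orienting, so the
    offset axis reads upstream -> downstream for every dyad.
    """
    if len(dyads) == 0:
        raise ValidationError("empty dyad set")
    if flank < 1:
        raise ValidationError("flank must be >= 1")
    matrix, _, dropped = _dyad_rows(track, dyads, flank, orient_by_strand)
    if matrix.shape[0] == 0:
        raise ValidationError("no dyad survived edge clipping")
    return MetaProfile(
        offsets=np.arange(-flank, flank + 1),
        values=matrix.sum(axis=0),
        n_dyads=matrix.shape[0],
        n_dropped=dropped,
    )


def window_signal(
    track: Track, dyads: DyadAnnotation, halfwidth: int = 60
) -> np.ndarray:
    """Per-dyad sum of track signal over [dyad - halfwidth, dyad + halfwidth).

    The default 120-bp window is the per-nucleosome quantification window.
    Dyads whose window leaves the chromosome get NaN (flagged missing, not
    silently truncated). Returned in the dyad annotation's row order.
    """
    out = np.full(len(dyads), np.nan)
    for chrom, sub in dyads.frame.groupby("chrom", sort=False):
        if chrom not in track.data:
            continue
        arr = track.data[chrom]
        csum = np.concatenate(([0.0], np.cumsum(arr)))
        pos = sub["dyad"].to_numpy(dtype=np.int64)
        lo = pos - halfwidth
        hi = pos + halfwidth
        ok = (lo >= 0) & (hi <= len(arr))
        vals = np.full(len(sub), np.nan)
        vals[ok] = csum[hi[ok]] - csum[lo[ok]]
        out[sub.index.to_numpy()] = vals
    return out


def profile_matrix(
    track: Track,
    dyads: DyadAnnotation,
    flank: int = 500,
    sort_key: np.ndarray | None = None,
    orient_by_strand: bool = True,
) -> ProfileMatrix:
    """Per-dyad signal matrix, rows sorted by descending sort key.

    ``sort_key`` is aligned with the dyad annotation rows; dyads with a
    missing (NaN) key are dropped and counted. Ties break by (chrom, dyad).
    Without a key, rows stay in genomic order.
    """
    frame = dyads.frame.copy()
    dropped_key = 0
    if sort_key is not None:
        sort_key = np.asarray(sort_key, dtype=np.float64)
        if len(sort_key) != len(frame):
            raise ValidationError("sort_key length does not match dyads")
        frame = frame.assign(sort_key=sort_key)
        ok = ~frame["sort_key"].isna()
        dropped_key = int((~ok).sum())
        frame = frame[ok]
    ann = DyadAnnotation(frame.reset_index(drop=True))
    matrix, meta, dropped_edge = _dyad_rows(track, ann, flank, orient_by_strand)
    if sort_key is not None and len(meta):
        order = meta.sort_values(
            ["sort_key", "chrom", "dyad"], ascending=[False, True, True], kind="mergesort"
        ).index.to_numpy()
        matrix = matrix[order]
        meta = meta.iloc[order].reset_index(drop=True)
    return ProfileMatrix(
        offsets=np.arange(-flank, flank + 1),
        matrix=matrix,
        dyads=meta.reset_index(drop=True),
        n_dropped=dropped_edge + dropped_key,
    )
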