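"""TAZ normalization: joint scaling of input (T), H2A (A) and H2A.Z (Z) tracks.

One anti-H2A.Z immunoprecipitation yields three sequenced fractions: the
input (T, total soluble mononucleosomes), the IP eluate (Z, H2A.Z-enriched)
and the flow-through (A, H2A-enriched). Sequencing depths of the three
libraries are arbitrary, so their amplitudes must be put on a common scale
before occupancies can be compared:

* ``m`` rescales A to T using reference regions ("no-Z-zones") that carry
  H2A but essentially no H2A.Z — there the flow-through must reconstitute
  the input, so m = (input tag count in zones) / (flow-through tag count
  in zones).
* ``n`` rescales Z so that m*A + n*Z reproduces T around +1 nucleosome
  dyads, where both species are abundant. The fit is ordinary least
  squares on the compiled midpoint meta-profiles, which has a closed form
  and a convex objective.
* ``c`` converts the input to counts per million (CPM); the final
  per-fraction factors are c (input), c*m (flow-through) and c*n (IP).

Replicate averaging, when wanted, happens on the normalized tracks — never
by pooling raw reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import DyadAnnotation, IntervalSet, Track, ValidationError
from .profiles import MetaProfile, compile_meta

__all__ = [
    "NormalizationFactors",
    "NormalizedReaction",
    "count_in_zones",
    "fit_m",
    "fit_n",
    "cpm_factor",
    "normalize_reaction",
    "average_reactions",
]


@dataclass
class NormalizationFactors:
    """The (m, n, c) triple for one IP reaction plus fit diagnostics.

    ``residual`` is the root-mean-square misfit of m*A + n*Z against T over
    the fit window; ``n_clamped`` flags a negative unconstrained optimum
    clamped to zero (physically meaningless negative IP amplitude).
    """

    m: float
    n: float
    c: float
    residual: float
    fit_window: tuple[int, int]
    n_clamped: bool = False

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.c > 0 and self.n >= 0):
            raise ValidationError(f"non-positive normalization factor: m={self.m} n={self.n} c={self.c}")
        if not np.isfinite(self.residual):
            raise ValidationError("non-finite fit residual")

    @property
    def ft_factor(self) -> float:
        """Final scale for the flow-through (H2A) fraction: c*m."""
        return self.c * self.m

    @property
    def ip_factor(self) -> float:
        """Final scale for the IP (H2A.Z) fraction: c*n."""
        return self.c * self.n

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "n": self.n,
            "c": self.c,
            "residual": self.residual,
            "fit_window": list(self.fit_window),
            "n_clamped": self.n_clamped,
            "ft_factor": self.ft_factor,
            "ip_factor": self.ip_factor,
        }


@dataclass
class NormalizedReaction:
    """Normalized track triple (c*T, c*m*A, c*n*Z) with its factors."""

    T: Track
    A: Track
    Z: Track
    factors: NormalizationFactors


def count_in_zones(track: Track, zones: IntervalSet) -> float:
    """Total track signal over the union of zone intervals.

    Overlapping zones are merged first so shared basepairs count once.
    """
    if len(zones) == 0:
        raise ValidationError("empty zone set")
    total = 0.0
    merged = zones.merged()
    for chrom, sub in merged.frame.groupby("chrom", sort=False):
        if chrom not in track.data:
            raise ValidationError(f"zone chromosome {chrom!r} not in track")
        arr = track.data[chrom]
        for s, e in zip(sub["start"], sub["end"]):
            if s < 0 or e > len(arr):
                raise ValidationError(f"zone [{s},{e}) out of bounds on {chrom}")
            total += float(arr[s:e].sum())
    return total


def fit_m(input_track: Track, ft_track: Track, zones: IntervalSet) -> float:
    """Input-over-flow-through tag-count ratio in the no-Z-zones."""
    t = count_in_zones(input_track, zones)
    a = count_in_zones(ft_track, zones)
    if a <= 0:
        raise ValidationError("flow-through has zero signal in the reference zones")
    return t / a


def fit_n(
    meta_A: MetaProfile,
    meta_Z: MetaProfile,
    meta_T: MetaProfile,
    m: float,
    fit_window: tuple[int, int] | None = None,
) -> tuple[float, float, bool]:
    """Least-squares amplitude n such that m*A + n*Z best matches T.

    All three meta-profiles must share the same offset axis (compiled
    around the same +1 dyads). Minimizing sum_o (m*A + n*Z - T)^2 over
    n >= 0 gives the closed form n = sum Z*(T - m*A) / sum Z^2 when the
    non-negativity constraint is inactive; a negative optimum is clamped
    to 0 and flagged.

    Returns
    -------
    (n, residual, clamped)
        The fitted amplitude, the RMS misfit over the window, and whether
        the clamp was applied.
    """
    if not (
        np.array_equal(meta_A.offsets, meta_Z.offsets)
        and np.array_equal(meta_A.offsets, meta_T.offsets)
    ):
        raise ValidationError("meta-profiles are not on a common offset axis")
    offsets = meta_A.offsets
    if fit_window is None:
        window = np.ones(len(offsets), dtype=bool)
        fit_window = (int(offsets[0]), int(offsets[-1]))
    else:
        lo, hi = fit_window
        window = (offsets >= lo) & (offsets <= hi)
        if not window.any():
            raise ValidationError("fit window contains no offsets")
    A = meta_A.values[window]
    Z = meta_Z.values[window]
    T = meta_T.values[window]
    zz = float(np.dot(Z, Z))
    if zz == 0.0:
        raise ValidationError("H2A.Z meta-profile is all-zero in the fit window")
    n = float(np.dot(Z, T - m * A) / zz)
    clamped = n < 0.0
    if clamped:
        n = 0.0
    residual = float(np.sqrt(np.mean((m * A + n * Z - T) ** 2)))
    return n, residual, clamped


def cpm_factor(input_track: Track) -> float:
    """CPM conversion c = 1e6 / total input fragment count.

    Expects the input *midpoint* (tag-count) track, whose total equals the
    fragment count; applying c makes the input sum to exactly 1e6.
    """
    total = input_track.total()
    if total <= 0:
        raise ValidationError("input track is empty")
    return 1e6 / total


def normalize_reaction(
    T: Track,
    A: Track,
    Z: Track,
    zones: IntervalSet,
    plus_one: DyadAnnotation,
    flank: int = 500,
    fit_window: tuple[int, int] | None = None,
) -> NormalizedReaction:
    """Run the full TAZ normalization for one IP reaction.

    Parameters
    ----------
    T, A, Z
        Midpoint-count tracks of the input, flow-through and IP fractions
        of a single IP reaction (one technical replicate).
    zones
        H2A.Z-free reference regions anchoring the A-to-T scale.
    plus_one
        +1 nucleosome dyads around which the n fit compiles profiles.
    flank
        Half-width of the compiled meta-profile, in bp.
    fit_window
        Optional offset sub-range for the n fit; defaults to the full flank.

    Returns
    -------
    NormalizedReaction
        Tracks scaled to (c*T, c*m*A, c*n*Z) plus the factor triple.
    """
    m = fit_m(T, A, zones)
    meta_A = compile_meta(A, plus_one, flank=flank)
    meta_Z = compile_meta(Z, plus_one, flank=flank)
    meta_T = compile_meta(T, plus_one, flank=flank)
    n, residual, clamped = fit_n(meta_A, meta_Z, meta_T, m, fit_window=fit_window)
    c = cpm_factor(T)
    factors = NormalizationFactors(
        m=m,
        n=n,
        c=c,
        residual=residual,
        fit_window=fit_window if fit_window is not None else (-flank, flank),
        n_clamped=clamped,
    )
    T_norm = T.scaled(c)
    A_norm = A.scaled(c * m)
    Z_norm = Z.scaled(c * n)
    for tr, tag in ((T_norm, "T"), (A_norm, "A"), (Z_norm, "Z")):
        tr.fraction = tag
        tr.normalized = True
    return NormalizedReaction(T=T_norm, A=A_norm, Z=Z_norm, factors=factors)


def average_reactions(reactions: list[NormalizedReaction]) -> dict[str, Track]:
    """Average replicate reactions after normalization.

    Raw reads are never pooled: each reaction is TAZ-normalized on its own
    and the normalized tracks are averaged per fraction, which is how
    technical and biological replicates are combined. Returns the averaged
    {"T", "A", "Z"} track triple.
    """
    if not reactions:
        raise ValidationError("no reactions to average")
    out: dict[str, Track] = {}
    for tag in ("T", "A", "Z"):
        tracks = [getattr(rxn, tag) for rxn in reactions]
        data = {
            chrom: np.mean([t.data[chrom] for t in tracks], axis=0)
            for chrom in tracks[0].data
        }
        out[tag] = Track(data, fraction=tag, normalized=True)
    return out
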