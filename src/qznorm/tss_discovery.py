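"""Discovery of +1 nucleosomes / cryptic TSSs from delta(Z/A) profiles.

Blocking preinitiation-complex assembly makes H2A.Z accumulate specifically
at +1 nucleosomes, so a nucleosome whose delta(Z/A) profile is strong and
*centered on its own dyad* is a +1 candidate — a neighbor (+2 or -1) sees
the same signal but off-center. The procedure: build the per-nucleosome
delta(Z/A) profile matrix over a genome-wide dyad catalog, k-means cluster
it, admit clusters whose mean profile is strong and symmetric about the
dyad (small center-of-mass offset), then repeat once on the remainder to
pick up weaker +1 nucleosomes. Candidates are finally partitioned into
known +1 vs novel, and transcript direction is inferred as pointing away
from the nearest flanking NDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome_io import DyadAnnotation, IntervalSet, Track, ValidationError
from .profiles import ProfileMatrix, profile_matrix

__all__ = [
    "ClusterResult",
    "build_dza_matrix",
    "cluster_dza",
    "center_of_mass_offset",
    "select_symmetric",
    "discover_candidates",
    "annotate_candidates",
]

#: Maximum |center-of-mass offset| (bp) for a cluster mean profile to count
#: as dyad-centered. Well within half a nucleosome footprint.
DEFAULT_COM_TOL = 20.0
#: Half-width (bp) of the central window over which mean signal must clear
#: the floor — roughly the footprint under one nucleosome.
DEFAULT_CENTRAL_HALFWIDTH = 60
#: Positive floor on the mean central delta(Z/A) of an admitted cluster.
DEFAULT_SIGNAL_FLOOR = 0.1


@dataclass
class ClusterResult:
    """k-means labels over profile rows plus per-cluster mean profiles."""

    labels: np.ndarray
    means: np.ndarray  # (k, n_offsets)
    degenerate: bool = False


def build_dza_matrix(
    dza: Track,
    dyad_catalog: DyadAnnotation,
    flank: int = 200,
) -> ProfileMatrix:
    """delta(Z/A) profile rows around every catalog nucleosome dyad.

    Edge-clipped dyads are dropped and counted on the returned matrix.
    Catalog dyads are unoriented, so no strand flipping is applied.
    """
    if len(dyad_catalog) == 0:
        raise ValidationError("empty dyad catalog")
    return profile_matrix(dza, dyad_catalog, flank=flank, orient_by_strand=False)


def cluster_dza(matrix: ProfileMatrix, k: int = 4, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """Cluster delta(Z/A) profile rows with k-means (fixed seed).

    An all-zero matrix is flagged degenerate: one trivial cluster, and no
    downstream selection will admit it.
    """
    X = matrix.matrix
    if len(X) < k:
        raise ValidationError(f"need at least k={k} rows, got {len(X)}")
    if not np.any(X):
        return ClusterResult(
            labels=np.zeros(len(X), dtype=int),
            means=np.zeros((1, X.shape[1])),
            degenerate=True,
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    means = np.vstack([X[labels == i].mean(axis=0) for i in range(k)])
    return ClusterResult(labels=labels, means=means)


def center_of_mass_offset(offsets: np.ndarray, profile: np.ndarray) -> float:
    """Center of mass (bp) of the non-negative part of a profile.

    delta(Z/A) can be negative; only positive mass localizes the signal.
    Returns +inf when the profile carries no positive mass.
    """
    w = np.clip(np.asarray(profile, dtype=np.float64), 0.0, None)
    total = w.sum()
    if total <= 0:
        return float("inf")
    return float(np.dot(offsets, w) / total)


def select_symmetric(
    matrix: ProfileMatrix,
    clusters: ClusterResult,
    com_tol: float = DEFAULT_COM_TOL,
    central_halfwidth: int = DEFAULT_CENTRAL_HALFWIDTH,
    signal_floor: float = DEFAULT_SIGNAL_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Admit rows of clusters with strong, dyad-centered mean profiles.

    A cluster is admitted when its mean profile has (i) a center-of-mass
    offset within ``com_tol`` bp of the dyad and (ii) mean delta(Z/A) above
    ``signal_floor``, both evaluated within the central window
    (|offset| <= ``central_halfwidth``). The central restriction matters:
    delta(Z/A) of a true +1 nucleosome is skewed toward the adjacent NDR,
    where H2A depletion inflates the ratio, so a full-window center of
    mass would penalize exactly the nucleosomes being sought, while a +2
    or -1 neighbor has next to no *central* signal at all. Per-row central
    COM offsets are returned so candidates can be re-filtered individually.

    Returns
    -------
    (selected, row_com)
        Boolean row mask of admitted rows and per-row central COM offsets
        (bp; +inf for rows without positive central mass).
    """
    if clusters.degenerate:
        return np.zeros(len(matrix), dtype=bool), np.full(len(matrix), np.inf)
    offsets = matrix.offsets.astype(np.float64)
    central = np.abs(offsets) <= central_halfwidth
    admitted = []
    for i, mean_profile in enumerate(clusters.means):
        com = center_of_mass_offset(offsets[central], mean_profile[central])
        strong = mean_profile[central].mean() > signal_floor
        if abs(com) <= com_tol and strong:
            admitted.append(i)
    selected = np.isin(clusters.labels, admitted)
    row_com = np.array(
        [center_of_mass_offset(offsets[central], row[central]) for row in matrix.matrix]
    )
    return selected, row_com


def discover_candidates(
    matrix: ProfileMatrix,
    k: int = 4,
    seed: int = 0,
    n_iterations: int = 2,
    com_tol: float = DEFAULT_COM_TOL,
    central_halfwidth: int = DEFAULT_CENTRAL_HALFWIDTH,
    signal_floor: float = DEFAULT_SIGNAL_FLOOR,
    enforce_row_com: bool = True,
) -> pd.DataFrame:
    """Reiterated cluster-and-select: find +1 candidates in two passes.

    Pass 1 clusters all rows and admits symmetric, strong clusters; pass 2
    re-runs clustering on the remainder to recover +1 nucleosomes with
    weaker signal. Exactly two passes by default. With ``enforce_row_com``
    rows whose own central center of mass exceeds ``com_tol`` — or whose
    central signal is below the floor — are dropped from admitted
    clusters, so no reported candidate is off-center or empty.

    Returns a DataFrame with the candidate dyads, their pass (``iteration``),
    cluster id within that pass, and per-row ``com`` symmetry score.
    """
    remaining = np.arange(len(matrix))
    frames: list[pd.DataFrame] = []
    for it in range(1, n_iterations + 1):
        if len(remaining) == 0:
            break
        sub = ProfileMatrix(
            offsets=matrix.offsets,
            matrix=matrix.matrix[remaining],
            dyads=matrix.dyads.iloc[remaining].reset_index(drop=True),
        )
        if len(sub) < k:
            break
        clusters = cluster_dza(sub, k=k, seed=seed + it - 1)
        selected, row_com = select_symmetric(
            sub, clusters, com_tol, central_halfwidth, signal_floor
        )
        if enforce_row_com:
            central = np.abs(matrix.offsets) <= central_halfwidth
            row_strong = sub.matrix[:, central].mean(axis=1) > signal_floor
            selected &= (np.abs(row_com) <= com_tol) & row_strong
        idx = remaining[selected]
        if len(idx):
            out = matrix.dyads.iloc[idx][["chrom", "dyad"]].copy()
            out["iteration"] = it
            out["cluster"] = clusters.labels[selected]
            out["com"] = row_com[selected]
            out["row"] = idx
            frames.append(out)
        remaining = remaining[~selected]
    if not frames:
        return pd.DataFrame(columns=["chrom", "dyad", "iteration", "cluster", "com", "row"])
    return pd.concat(frames, ignore_index=True)


def annotate_candidates(
    candidates: pd.DataFrame,
    known_plus_one: DyadAnnotation,
    ndrs: IntervalSet,
    match_tol: int = 40,
    ndr_search: int = 300,
) -> pd.DataFrame:
    """Partition candidates into known vs novel and infer transcript direction.

    A candidate within ``match_tol`` bp of a known +1 dyad is
    ``known_plus_one``; the rest are ``novel``. Direction points away from
    the nearest NDR center within ``ndr_search`` bp: an NDR to the left
    implies rightward transcription ('+') and vice versa; with no NDR in
    range the direction is ``ambiguous``.
    """
    out = candidates.copy()
    status = np.full(len(out), "novel", dtype=object)
    direction = np.full(len(out), "ambiguous", dtype=object)

    known_by_chrom = {
        chrom: np.sort(sub["dyad"].to_numpy(dtype=np.int64))
        for chrom, sub in known_plus_one.frame.groupby("chrom", sort=False)
    }
    ndr_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy(dtype=np.int64))
        for chrom, sub in ndrs.frame.groupby("chrom", sort=False)
    }

    for i, (chrom, dyad) in enumerate(zip(out["chrom"], out["dyad"])):
        dyad = int(dyad)
        known = known_by_chrom.get(chrom)
        if known is not None and len(known):
            j = np.searchsorted(known, dyad)
            nearest = min(
                (abs(dyad - known[jj]) for jj in (j - 1, j) if 0 <= jj < len(known)),
                default=None,
            )
            if nearest is not None and nearest <= match_tol:
                status[i] = "known_plus_one"
        centers = ndr_by_chrom.get(chrom)
        if centers is not None and len(centers):
            j = np.searchsorted(centers, dyad)
            best = None
            for jj in (j - 1, j):
                if 0 <= jj < len(centers):
                    d = centers[jj] - dyad
                    if best is None or abs(d) < abs(best):
                        best = d
            if best is not None and abs(best) <= ndr_search and best != 0:
                direction[i] = "+" if best < 0 else "-"
    out["status"] = status
    out["direction"] = direction
    return out
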