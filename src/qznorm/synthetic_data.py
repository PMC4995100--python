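"""Synthetic qChIP-seq experiments with known ground truth.

The generator lays out a genome of regularly spaced nucleosome arrays, each
gene unit carrying a -1 nucleosome, a nucleosome-depleted region (NDR) and
a +1..+N array at 165-bp spacing. Every nucleosome gets a planted H2A.Z
*dimer fraction* — the probability that a fragment from it carries H2A.Z.
This summarizes the homotypic/heterotypic (AA/AZ/ZZ) mixture at the level
the immunoprecipitation actually observes (dimer pull-down that does not
distinguish the forms). Fractions follow the promoter-proximal enrichment
of real chromatin: high at +1, lower at -1, near zero in gene bodies, and
exactly zero inside designated no-Z-zone blocks used to anchor
normalization.

Fragment sampling mimics the experiment: mononucleosome fragments of
~147 bp (Gaussian length and positional jitter) are drawn from the
nucleosome grid. The IP reaction routes each H2A.Z fragment to the IP
with probability = IP efficiency (e) and everything else — including
escaped H2A.Z — to the flow-through, which fixes the *composition* of the
three libraries: input reads fall uniformly over nucleosomes, IP (Z)
reads with probability proportional to f*e, and flow-through (A) reads
proportional to 1 - f*e. Each library is then sequenced to its own
configured depth, as real libraries are. The scale factors this implies
are exact and recorded in the ground truth:

    m_true = (depth_T / depth_A) * mean(1 - f*e)
    n_true = (depth_T / depth_Z) * mean(f*e)

(means over nucleosomes). The normalized Z track reports
IP-efficiency-weighted occupancy (f * e), just as the real assay reports
IP efficiency relative to input.

Perturbations model conditional depletion experiments as rate switches:
``block_deposition`` (variant-deposition machinery removed; PIC-dependent
eviction continues, fractions decay with a configurable half-life),
``block_eviction`` (PIC removed; deposition continues, fractions relax
toward 1), and ``plant_shift`` (nucleosome array repositioning).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    DyadAnnotation,
    FragmentSet,
    GenomeTable,
    IntervalSet,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedGenome",
    "make_genome",
    "simulate_fractions",
    "apply_perturbation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Depth and geometry defaults describe a compact genome dense enough to
    recover normalization factors and per-nucleosome occupancies from a
    single simulated reaction.
    """

    n_chromosomes: int = 2
    chrom_length: int = 120_000
    spacing: int = 165  # nucleosome repeat length, bp
    ndr_width: int = 150
    n_nucs_per_gene: int = 8
    # planted H2A.Z dimer fractions per nucleosome class
    z_plus_one: float = 0.4
    z_minus_one: float = 0.15
    z_body: float = 0.02
    z_nozzone: float = 0.0
    n_nozzones: int = 16  # zone units (runs of H2A.Z-free nucleosomes)
    n_cryptic: int = 0  # planted cryptic divergent promoters
    depth: int = 100_000  # sequencing depth (fragments) of each fraction
    ip_efficiency: float = 0.85  # consistently above 0.8, as in practice
    frag_len_mean: float = 147.0
    frag_len_sd: float = 10.0
    jitter_sd: float = 20.0  # MNase trimming variability of midpoints
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("z_plus_one", "z_minus_one", "z_body", "z_nozzone", "ip_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")

    @property
    def unit_length(self) -> int:
        # -1 nucleosome region + NDR + array + trailing pad
        return self.spacing + self.ndr_width + self.n_nucs_per_gene * self.spacing + 35

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every simulated dataset.

    ``nucs`` has one row per nucleosome: chrom, dyad, role, strand,
    nominal ``position`` (+k, -1, or 0 for zone nucleosomes), planted
    ``z_frac``, whether PIC-dependent deposition/eviction acts there
    (``dynamic``), and cryptic-promoter membership. ``m_true``/``n_true``
    are the scale factors implied by the sampling depths, filled in by
    :func:`simulate_fractions`.
    """

    nucs: pd.DataFrame
    cryptic: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "ndr_center", "left_dyad", "right_dyad"]
        )
    )
    m_true: float | None = None
    n_true: float | None = None
    perturbation: str | None = None
    shifts: dict[int, int] | None = None

    def dyad_annotation(self) -> DyadAnnotation:
        return DyadAnnotation(
            self.nucs[["chrom", "dyad", "strand", "role"]].reset_index(drop=True)
        )


@dataclass
class SimulatedGenome:
    """A synthetic genome with its annotations and planted truth."""

    genome: GenomeTable
    dyads: DyadAnnotation  # full nucleosome catalog
    plus_one: DyadAnnotation  # canonical +1 dyads only (the "known" set)
    ndrs: IntervalSet
    nozzones: IntervalSet
    truth: GroundTruth
    config: SimulationConfig


def make_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the genome, nucleosome grid, annotations and planted truth.

    The layout is fully deterministic given the config: gene units tile
    each chromosome; ``n_nozzones`` evenly spaced units are replaced by
    H2A.Z-free zone blocks, and ``n_cryptic`` of the remaining gene units
    receive a cryptic divergent promoter (an internal NDR replacing one
    mid-array nucleosome, flanked by two oppositely oriented +1-like
    nucleosomes that are absent from the known +1 annotation).
    """
    unit_len = config.unit_length
    units_per_chrom = config.chrom_length // unit_len
    n_units = config.n_chromosomes * units_per_chrom
    if n_units < 1:
        raise ValidationError("chromosome too short for a single gene unit")
    if config.n_nozzones + config.n_cryptic > n_units:
        raise ValidationError("more zone/cryptic units requested than units available")

    zone_units = set(
        np.linspace(0, n_units - 1, config.n_nozzones, dtype=int).tolist()
        if config.n_nozzones
        else []
    )
    gene_units = [u for u in range(n_units) if u not in zone_units]
    cryptic_units = set(
        np.asarray(gene_units)[
            np.linspace(0, len(gene_units) - 1, config.n_cryptic, dtype=int)
        ].tolist()
        if config.n_cryptic
        else []
    )

    genome = GenomeTable(
        {f"chrS{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    )
    chroms = genome.chroms

    nuc_rows = []
    ndr_rows = []
    zone_rows = []
    cryptic_rows = []
    # index of the array nucleosome replaced by a cryptic promoter NDR
    cryptic_slot = max(3, config.n_nucs_per_gene // 2)

    for u in range(n_units):
        chrom = chroms[u // units_per_chrom]
        start = (u % units_per_chrom) * unit_len
        if u in zone_units:
            # zone block: plain nucleosome run, H2A.Z-free, no NDR
            n_zone_nucs = unit_len // config.spacing
            for k in range(n_zone_nucs):
                dyad = start + config.spacing // 2 + k * config.spacing
                nuc_rows.append(
                    (chrom, dyad, "generic", ".", 0, config.z_nozzone, False, False, ".")
                )
            zone_rows.append((chrom, start, start + unit_len, f"zone_{u}"))
            continue
        # gene unit: -1 nucleosome, NDR, +1..+N array
        minus1 = start + config.spacing // 2
        nuc_rows.append(
            (chrom, minus1, "minus_one", ".", -1, config.z_minus_one, False, False, ".")
        )
        ndr_start = start + config.spacing
        ndr_rows.append((chrom, ndr_start, ndr_start + config.ndr_width, f"ndr_{u}"))
        array_origin = ndr_start + config.ndr_width + 73
        is_cryptic_unit = u in cryptic_units
        for k in range(1, config.n_nucs_per_gene + 1):
            dyad = array_origin + (k - 1) * config.spacing
            if is_cryptic_unit and k == cryptic_slot:
                # internal NDR of the cryptic divergent promoter
                ndr_rows.append((chrom, dyad - 75, dyad + 75, f"cryptic_ndr_{u}"))
                cryptic_rows.append((chrom, dyad, dyad - config.spacing, dyad + config.spacing))
                continue
            if is_cryptic_unit and k in (cryptic_slot - 1, cryptic_slot + 1):
                # cryptic +1 pair flanking the internal NDR, divergent
                strand = "-" if k == cryptic_slot - 1 else "+"
                nuc_rows.append(
                    (chrom, dyad, "generic", strand, k, config.z_plus_one, True, True, strand)
                )
                continue
            if k == 1:
                nuc_rows.append(
                    (chrom, dyad, "plus_one", "+", 1, config.z_plus_one, True, False, ".")
                )
            else:
                nuc_rows.append(
                    (chrom, dyad, "generic", ".", k, config.z_body, False, False, ".")
                )

    nucs = pd.DataFrame(
        nuc_rows,
        columns=[
            "chrom",
            "dyad",
            "role",
            "strand",
            "position",
            "z_frac",
            "dynamic",
            "is_cryptic",
            "cryptic_strand",
        ],
    )
    truth = GroundTruth(
        nucs=nucs,
        cryptic=pd.DataFrame(
            cryptic_rows, columns=["chrom", "ndr_center", "left_dyad", "right_dyad"]
        ),
    )
    dyads = truth.dyad_annotation()
    plus_one = DyadAnnotation(
        nucs.loc[nucs["role"] == "plus_one", ["chrom", "dyad", "strand", "role"]].reset_index(
            drop=True
        )
    )
    ndrs = IntervalSet(pd.DataFrame(ndr_rows, columns=["chrom", "start", "end", "label"]))
    nozzones = IntervalSet(pd.DataFrame(zone_rows, columns=["chrom", "start", "end", "label"]))
    return SimulatedGenome(
        genome=genome,
        dyads=dyads,
        plus_one=plus_one,
        ndrs=ndrs,
        nozzones=nozzones,
        truth=truth,
        config=config,
    )


def _sample_fragments(
    nucs: pd.DataFrame,
    genome: GenomeTable,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    p: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw n mononucleosome fragments over nucleosomes (probabilities p)."""
    if p is None:
        idx = rng.integers(0, len(nucs), size=n)
    else:
        idx = rng.choice(len(nucs), size=n, p=p)
    dyads = nucs["dyad"].to_numpy()[idx]
    chrom_codes, chrom_names = pd.factorize(nucs["chrom"])
    codes = chrom_codes[idx]
    mids = dyads + np.rint(rng.normal(0.0, config.jitter_sd, size=n)).astype(np.int64)
    lengths = np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=n)).astype(
        np.int64
    )
    lengths = np.clip(lengths, 50, 300)
    starts = mids - lengths // 2
    chrom_lens = np.array([genome[c] for c in chrom_names])[codes]
    starts = np.clip(starts, 0, chrom_lens - lengths)
    ends = starts + lengths
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom_names, dtype=object)[codes],
            "start": starts,
            "end": ends,
            "count": np.ones(n, dtype=np.int64),
            "nuc_index": idx,
        }
    )


def simulate_fractions(
    sim: SimulatedGenome,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> dict[str, FragmentSet]:
    """Sample the input (T), flow-through (A) and IP (Z) fragment sets.

    Per-fragment IP routing — an H2A.Z fragment (probability = the
    nucleosome's planted dimer fraction f) is captured with probability
    ``ip_efficiency`` (e), everything else flows through — fixes each
    library's composition: input reads land uniformly over nucleosomes,
    IP reads proportional to f*e, flow-through reads proportional to
    1 - f*e. Each library is sequenced to ``depth`` fragments
    independently. The implied true scale factors recorded on the ground
    truth are m_true = mean(1 - f*e) and n_true = mean(f*e) (equal
    per-fraction depths cancel).
    """
    config = sim.config
    if truth is None:
        truth = sim.truth
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nucs = truth.nucs

    fe = nucs["z_frac"].to_numpy() * config.ip_efficiency
    w_a = 1.0 - fe
    sum_fe = fe.sum()
    sum_a = w_a.sum()
    if sum_a <= 0:
        raise ValidationError("degenerate truth: flow-through captures nothing")

    t_frame = _sample_fragments(nucs, sim.genome, config.depth, config, rng)
    a_frame = _sample_fragments(nucs, sim.genome, config.depth, config, rng, p=w_a / sum_a)
    if sum_fe > 0:
        z_frame = _sample_fragments(
            nucs, sim.genome, config.depth, config, rng, p=fe / sum_fe
        )
    else:
        z_frame = t_frame.iloc[0:0].copy()  # H2A.Z-free genome: empty IP

    truth.m_true = float(w_a.mean())
    truth.n_true = float(fe.mean())

    cols = ["chrom", "start", "end", "count"]
    out = {
        "T": FragmentSet(t_frame[cols].copy()),
        "A": FragmentSet(a_frame[cols].copy()),
        "Z": FragmentSet(z_frame[cols].copy()),
    }
    for tag, fs in out.items():
        fs.frame.attrs["fraction"] = tag
        fs.frame.attrs["seed"] = config.seed if seed is None else seed
    return out


def apply_perturbation(
    truth: GroundTruth,
    mode: str,
    elapsed: float = 60.0,
    half_life: float = 15.0,
    deposition_rate: float = 0.1,
    shifts: dict[int, int] | None = None,
) -> GroundTruth:
    """Derive the condition-2 ground truth from a perturbation model.

    Modes
    -----
    ``block_deposition``
        Variant deposition is off; PIC-dependent eviction continues at
        dynamic nucleosomes, so their fractions decay exponentially:
        f2 = f1 * 2^(-elapsed / half_life). At elapsed = one half-life the
        fraction is exactly halved.
    ``block_eviction``
        PIC-dependent eviction is off; deposition (rate per minute)
        continues at dynamic nucleosomes, relaxing fractions toward 1:
        f2 = 1 - (1 - f1) * exp(-deposition_rate * elapsed). A zero rate
        leaves the truth unchanged.
    ``plant_shift``
        Repositioning only: ``shifts`` maps nominal array position
        (+1, +2, ..., or -1) to a signed shift in bp applied along the
        gene direction (minus-strand nucleosomes shift mirror-image).
    """
    nucs = truth.nucs.copy()
    if mode == "block_deposition":
        decay = 0.5 ** (elapsed / half_life)
        mask = nucs["dynamic"].to_numpy()
        nucs.loc[mask, "z_frac"] = nucs.loc[mask, "z_frac"] * decay
    elif mode == "block_eviction":
        relax = np.exp(-deposition_rate * elapsed)
        mask = nucs["dynamic"].to_numpy()
        nucs.loc[mask, "z_frac"] = 1.0 - (1.0 - nucs.loc[mask, "z_frac"]) * relax
    elif mode == "plant_shift":
        if not shifts:
            raise ValidationError("plant_shift requires a shift table")
        sign = np.where(nucs["strand"] == "-", -1, 1)
        offset = nucs["position"].map(lambda p: shifts.get(int(p), 0)).to_numpy()
        nucs["dyad"] = nucs["dyad"] + sign * offset
    else:
        raise ValidationError(f"unknown perturbation mode {mode!r}")
    return GroundTruth(
        nucs=nucs,
        cryptic=truth.cryptic.copy(),
        perturbation=mode,
        shifts=dict(shifts) if shifts else None,
    )
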