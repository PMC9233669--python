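"""Ground-truth activity landscapes and simulated k-Seq datasets.

The simulator emulates the structure of a kinetic-sequencing experiment on
self-aminoacylating ribozyme mutant pools: five families of 21-nt variants
(wild type plus all single and double substitution mutants, 1954 sequences
each), six activated amino-acid substrates (BWO, BFO, BLO, BIO, BVO, BMO),
triplicate reactions at five substrate concentrations, and qPCR-based
quantitation of total reacted RNA.  Per-sequence activities follow a bimodal
distribution: an inactive background peak centred on the uncatalysed rate
k0*A0 plus a log-normal active tail whose substrate profile sharpens with
total activity (the activity-specificity coupling).

Counts are drawn multinomially at a configurable read depth, so every
downstream stage (fraction reacted, kinetic fitting, background estimation,
enhancement, specificity and landscape metrics) can be exercised against a
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_space import DNA_ALPHABET, enumerate_mutants, hamming_distance

DEFAULT_SUBSTRATES = ("BWO", "BFO", "BLO", "BIO", "BVO", "BMO")
AROMATIC_SUBSTRATES = ("BWO", "BFO")

#: Uncatalysed (background) reaction rate k0*A0 in 1/M/min, measured for the
#: randomized library by gel shift; used as the simulator's default for every
#: substrate.
DEFAULT_BACKGROUND_RATE = 0.55


@dataclass(frozen=True)
class ExperimentDesign:
    """Assay layout and kinetic constants of one k-Seq experiment.

    Concentrations are stored in micromolar, as configured at the bench; the
    kinetic law converts to molar internally because rate constants carry
    1/M/min units.  ``alpha`` is the substrate-hydrolysis coefficient applied
    uniformly to all substrates.  ``read_depth=None`` requests the noiseless
    limit (expected read fractions instead of multinomial draws).
    """

    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES
    concentrations_uM: tuple[float, ...] = (1250.0, 250.0, 50.0, 10.0, 2.0)
    replicates: int = 3
    reaction_time_min: float = 90.0
    alpha: float = 0.479
    rna_input_uM: float = 0.43
    input_pool_replicates: int = 6
    read_depth: int | None = 1_000_000
    qpcr_cv: float = 0.05
    qpcr_replicates: int = 3
    total_input_ng: float = 10.0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValueError("concentrations must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.reaction_time_min <= 0:
            raise ValueError("reaction time must be positive")
        if self.read_depth is not None and self.read_depth <= 0:
            raise ValueError("read_depth must be positive (or None for noiseless)")

    @property
    def noiseless(self) -> bool:
        return self.read_depth is None and self.qpcr_cv == 0.0


@dataclass(frozen=True)
class FamilySpec:
    """Generative parameters for one ribozyme family's activity landscape.

    ``preference_multipliers`` set the family's substrate-preference profile
    (relative kA factors per substrate).  ``cross_substrate_correlation`` is
    the correlation of the per-substrate log-activity noise across substrates.
    ``specificity_coupling`` > 0 sharpens an active sequence's substrate
    profile as its overall activity grows, producing the negative
    activity-promiscuity association seen in these pools.
    """

    name: str
    center: str
    inactive_fraction: float = 0.7
    active_log10kA_mean: float = 1.3
    active_log10kA_sd: float = 0.8
    preference_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in DEFAULT_SUBSTRATES}
    )
    cross_substrate_correlation: float = 0.8
    specificity_coupling: float = 0.5
    substrate_noise_sd: float = 0.3
    background_log10_sd: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.inactive_fraction <= 1.0):
            raise ValueError("inactive_fraction must lie in [0, 1]")
        if any(m <= 0 for m in self.preference_multipliers.values()):
            raise ValueError("preference multipliers must be positive")
        if not (0.0 <= self.cross_substrate_correlation <= 1.0):
            raise ValueError("cross-substrate correlation must lie in [0, 1]")


def default_family_specs(seed: int = 0, center_length: int = 21) -> list[FamilySpec]:
    """Five family specifications emulating the study's pools.

    Families 1A.1 and 1B.1 (motif 1) favour aromatic side chains (F, W >
    M, L, I, V) and contain mostly inactive mutants; families 2.1 and 2.2
    (motif 2) are broadly active with highly correlated substrate profiles
    (F > M, W, L > I, V); family 3.1 (motif 3) prefers F > W > the
    aliphatics and is the least mutationally tolerant.  Centers are seeded
    random 21-mers: the study's wild-type variable regions live in its data
    deposit, and none of the landscape statistics depend on the identity of
    the center sequence.
    """
    rng = np.random.default_rng(seed)
    centers = ["".join(rng.choice(list(DNA_ALPHABET), center_length)) for _ in range(5)]
    motif1 = {"BWO": 6.0, "BFO": 8.0, "BLO": 1.0, "BIO": 1.0, "BVO": 1.0, "BMO": 1.2}
    motif2 = {"BWO": 3.0, "BFO": 6.0, "BLO": 3.0, "BIO": 1.0, "BVO": 1.0, "BMO": 3.5}
    motif3 = {"BWO": 4.0, "BFO": 10.0, "BLO": 1.0, "BIO": 1.0, "BVO": 1.0, "BMO": 1.2}
    return [
        FamilySpec("1A.1", centers[0], inactive_fraction=0.75, preference_multipliers=motif1,
                   cross_substrate_correlation=0.6),
        FamilySpec("1B.1", centers[1], inactive_fraction=0.75, preference_multipliers=motif1,
                   cross_substrate_correlation=0.6),
        FamilySpec("2.1", centers[2], inactive_fraction=0.25, preference_multipliers=motif2,
                   cross_substrate_correlation=0.9),
        FamilySpec("2.2", centers[3], inactive_fraction=0.30, preference_multipliers=motif2,
                   cross_substrate_correlation=0.85),
        FamilySpec("3.1", centers[4], inactive_fraction=0.85, preference_multipliers=motif3,
                   cross_substrate_correlation=0.5),
    ]


@dataclass
class GroundTruthLandscape:
    """True per-sequence, per-substrate kinetics plus pool composition.

    ``k`` and ``A`` are sequence-by-substrate DataFrames (1/M/min and
    fraction); ``kA`` is their elementwise product.  ``abundance`` is each
    sequence's relative input fraction over the whole pooled library (sums to
    one); ``family`` maps sequence to family name; ``background`` holds the
    per-substrate k0*A0.
    """

    k: pd.DataFrame
    A: pd.DataFrame
    abundance: pd.Series
    family: pd.Series
    background: pd.Series
    centers: dict[str, str]

    @property
    def kA(self) -> pd.DataFrame:
        return self.k * self.A

    @property
    def enhancement(self) -> pd.DataFrame:
        """True catalytic enhancement r = kA / k0A0 per substrate."""
        return self.kA.div(self.background, axis=1)

    @property
    def sequences(self) -> pd.Index:
        return self.k.index

    @property
    def substrates(self) -> list[str]:
        return list(self.k.columns)


@dataclass
class SimulatedDataset:
    """Read-count table plus sample metadata and the truth that generated it."""

    counts: pd.DataFrame  # sequences x samples
    metadata: pd.DataFrame  # sample_id, role, substrate, concentration_uM, replicate, total_ng
    qpcr: pd.DataFrame  # sample_id, measurement, total_ng
    landscape: GroundTruthLandscape
    design: ExperimentDesign
    seed: int


def sample_doped_library(
    center: str,
    per_position_wt_rate: float,
    n_molecules: int,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Draw molecules from a doped synthesis of ``center``.

    Each position independently carries the wild-type base with probability
    ``per_position_wt_rate`` and each of the three substitutions with equal
    shares of the remainder (91% / 3% each in the study's library design).
    Returns sequence -> molecule count.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if not (0 < per_position_wt_rate <= 1):
        raise ValueError("per_position_wt_rate must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(center)
    base_idx = {b: i for i, b in enumerate(DNA_ALPHABET)}
    center_idx = np.array([base_idx[b] for b in center], dtype=np.int8)
    mutate = rng.random((n_molecules, L)) > per_position_wt_rate
    offsets = rng.integers(1, 4, size=(n_molecules, L), dtype=np.int8)
    idx = np.where(mutate, (center_idx[None, :] + offsets) % 4, center_idx[None, :])
    alphabet = np.frombuffer(DNA_ALPHABET.encode(), dtype="S1")
    seqs = alphabet[idx].view(f"S{L}").ravel()
    uniq, counts = np.unique(seqs, return_counts=True)
    return pd.Series(counts, index=[s.decode() for s in uniq]).sort_values(ascending=False)


def doped_abundance(center: str, sequences: Sequence[str], wt_rate: float = 0.91) -> pd.Series:
    """Expected relative abundance of each variant under doped synthesis.

    A variant at Hamming distance d from the center has synthesis probability
    proportional to wt_rate^(L-d) * ((1-wt_rate)/3)^d; abundances are
    renormalised over the supplied set.
    """
    sub_rate = (1.0 - wt_rate) / 3.0
    w = np.array(
        [wt_rate ** (len(center) - hamming_distance(center, s)) * sub_rate ** hamming_distance(center, s)
         for s in sequences]
    )
    return pd.Series(w / w.sum(), index=list(sequences))


def _correlated_normals(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m standard normals with pairwise correlation rho across columns."""
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, m))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def build_landscape(
    family_specs: Sequence[FamilySpec],
    design: ExperimentDesign,
    seed: int = 0,
    background: Mapping[str, float] | float = DEFAULT_BACKGROUND_RATE,
    wt_rate: float = 0.91,
) -> GroundTruthLandscape:
    """Draw a ground-truth (k, A) landscape for the configured families.

    Each sequence is inactive with probability ``inactive_fraction`` (its kA
    scatters log-normally around the background rate); otherwise its
    log10(kA) per substrate is the family's active distribution shifted by
    the preference multipliers, with the multiplier profile raised to a
    power that grows with the sequence's activity z-score when
    ``specificity_coupling`` > 0, plus correlated log-normal noise.  Wild
    types are always active.  Amplitudes A are drawn uniformly and k = kA/A.
    """
    if not family_specs:
        raise ValueError("at least one family spec is required")
    substrates = list(design.substrates)
    for spec in family_specs:
        missing = [s for s in substrates if s not in spec.preference_multipliers]
        if missing:
            raise ValueError(
                f"family {spec.name!r} lacks preference multipliers for {missing}"
            )
    rng = np.random.default_rng(seed)

    frames_k, frames_A = [], []
    abund_parts, fam_parts = [], []
    bg = (
        pd.Series({s: float(background) for s in substrates})
        if np.isscalar(background)
        else pd.Series({s: float(background[s]) for s in substrates})
    )
    # Overlapping neighborhoods (possible for short or similar centers) are
    # resolved by assigning each sequence to its nearest center, ties going
    # to the family listed first.
    from .sequence_space import assign_to_centers

    centers: dict[str, str] = {spec.name: spec.center for spec in family_specs}
    union = sorted(set().union(*(enumerate_mutants(s.center, 2) for s in family_specs)))
    owner = assign_to_centers(union, [s.center for s in family_specs])

    for spec in family_specs:
        seqs = sorted(s for s in union if owner[s] == spec.center)
        n = len(seqs)
        m = len(substrates)

        active = rng.random(n) >= spec.inactive_fraction
        active[seqs.index(spec.center)] = True

        z = rng.standard_normal(n)
        log_mult = np.log10([spec.preference_multipliers[s] for s in substrates])
        log_mult = log_mult - log_mult.mean()  # centre the profile
        sharpen = np.maximum(0.2, 1.0 + spec.specificity_coupling * z)
        eps = spec.substrate_noise_sd * _correlated_normals(
            rng, n, m, spec.cross_substrate_correlation
        )
        log_kA_active = (
            (spec.active_log10kA_mean + spec.active_log10kA_sd * z)[:, None]
            + sharpen[:, None] * log_mult[None, :]
            + eps
        )
        log_bg = np.log10(bg[substrates].to_numpy())[None, :]
        log_kA_inactive = log_bg + spec.background_log10_sd * rng.standard_normal((n, m))
        log_kA = np.where(active[:, None], log_kA_active, log_kA_inactive)
        kA = 10.0 ** log_kA

        A = np.where(
            active[:, None],
            rng.uniform(0.5, 1.0, (n, m)),
            rng.uniform(0.2, 1.0, (n, m)),
        )
        k = kA / A

        frames_k.append(pd.DataFrame(k, index=seqs, columns=substrates))
        frames_A.append(pd.DataFrame(A, index=seqs, columns=substrates))
        abund_parts.append(doped_abundance(spec.center, seqs, wt_rate) / len(family_specs))
        fam_parts.append(pd.Series(spec.name, index=seqs))

    return GroundTruthLandscape(
        k=pd.concat(frames_k),
        A=pd.concat(frames_A),
        abundance=pd.concat(abund_parts),
        family=pd.concat(fam_parts),
        background=bg,
        centers=centers,
    )


def kinetic_fraction_reacted(
    k: np.ndarray | float,
    A: np.ndarray | float,
    concentration_uM: float,
    alpha: float,
    t_min: float,
) -> np.ndarray | float:
    """Pseudo-first-order survival fraction F = A(1 - exp(-k alpha [S] t)).

    ``concentration_uM`` is converted to molar; k is in 1/M/min, t in min.
    """
    conc_M = concentration_uM * 1e-6
    return A * (1.0 - np.exp(-np.asarray(k) * alpha * conc_M * t_min))


def _draw_counts(
    rng: np.random.Generator, probs: np.ndarray, depth: int | None
) -> np.ndarray:
    if depth is None:  # noiseless limit: expected fractions at unit "depth"
        return probs * 1e12
    return rng.multinomial(depth, probs)


def simulate_kseq(
    landscape: GroundTruthLandscape,
    design: ExperimentDesign,
    seed: int = 0,
) -> SimulatedDataset:
    """Forward-simulate read counts and qPCR quantities for one experiment.

    For every (substrate, concentration, replicate) sample, each sequence's
    survival fraction F follows the pseudo-first-order law; reacted reads are
    multinomial with probabilities proportional to abundance x F, input-pool
    reads proportional to abundance alone.  Total reacted RNA (ng) is the
    true reacted mass perturbed by multiplicative log-normal qPCR noise, one
    draw per qPCR replicate.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    seqs = landscape.sequences
    p_in = landscape.abundance.loc[seqs].to_numpy()
    p_in = p_in / p_in.sum()

    samples, qpcr_rows, count_cols = [], [], {}

    def qpcr_draws(true_ng: float) -> list[float]:
        if design.qpcr_cv == 0.0:
            return [true_ng] * design.qpcr_replicates
        sigma = np.sqrt(np.log1p(design.qpcr_cv**2))
        return list(
            true_ng * np.exp(rng.normal(-0.5 * sigma**2, sigma, design.qpcr_replicates))
        )

    for rep in range(1, design.input_pool_replicates + 1):
        sid = f"input_r{rep}"
        count_cols[sid] = _draw_counts(rng, p_in, design.read_depth)
        ng = qpcr_draws(design.total_input_ng)
        samples.append((sid, "input", "", np.nan, rep, float(np.mean(ng))))
        qpcr_rows += [(sid, i + 1, v) for i, v in enumerate(ng)]

    for substrate in design.substrates:
        k = landscape.k[substrate].to_numpy()
        A = landscape.A[substrate].to_numpy()
        for conc in design.concentrations_uM:
            F = kinetic_fraction_reacted(
                k, A, conc, design.alpha, design.reaction_time_min
            )
            mass = p_in * F
            reacted_frac = mass.sum()
            probs = mass / reacted_frac
            for rep in range(1, design.replicates + 1):
                sid = f"{substrate}_{conc:g}uM_r{rep}"
                count_cols[sid] = _draw_counts(rng, probs, design.read_depth)
                ng = qpcr_draws(design.total_input_ng * reacted_frac)
                samples.append((sid, "reacted", substrate, conc, rep, float(np.mean(ng))))
                qpcr_rows += [(sid, i + 1, v) for i, v in enumerate(ng)]

    counts = pd.DataFrame(count_cols, index=seqs)
    if design.read_depth is not None:
        counts = counts.astype(np.int64)
    metadata = pd.DataFrame(
        samples,
        columns=["sample_id", "role", "substrate", "concentration_uM", "replicate", "total_ng"],
    )
    qpcr = pd.DataFrame(qpcr_rows, columns=["sample_id", "measurement", "total_ng"])
    return SimulatedDataset(
        counts=counts, metadata=metadata, qpcr=qpcr,
        landscape=landscape, design=design, seed=seed,
    )


def noiseless_design(design: ExperimentDesign) -> ExperimentDesign:
    """Copy of ``design`` with infinite depth and zero quantitation noise."""
    return replace(design, read_depth=None, qpcr_cv=0.0)
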