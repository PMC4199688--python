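"""Synthetic autotetraploid populations.

Generators for the data structures the analysis modules consume:
tetrasomic dosage genotypes, two-locus haplotype disequilibrium,
additive marker effects calibrated to a target variance fraction,
ordinal 1-9 chip scores, noisy two-allele peak-height signals, and
clone tables with amplification-batch structure and sequencing errors.

Tetrasomic inheritance is modeled as random chromosomal segregation
without double reduction, so the minor-allele dosage of an individual
is Binomial(4, p) at allele frequency p.  Defaults mirror the study
design the package targets: a discovery population of 208 tetraploid
genotypes scored for five tuber traits (CQA, CQS, TSC, TY, TSY) and a
validation panel of 40 genotypes with reducing-sugar measurements at
cold-storage time points T0, T1, T2, T4, T12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import PLOIDY, DosageMatrix, PeakSignal, SnpMarker
from .haplotypes import CloneTable, HaplotypeMatrix

__all__ = [
    "SimulationConfig",
    "MarkerSpec",
    "LdPairSpec",
    "TraitSpec",
    "CloneSpec",
    "SimulatedDataset",
    "simulate_dosages",
    "simulate_linked_pair",
    "simulate_trait",
    "simulate_peaks",
    "simulate_clone_table",
    "simulate_dataset",
    "default_discovery_config",
    "default_validation_config",
]

#: Discovery-population and validation-panel sizes of the target study design.
N_DISCOVERY = 208
N_VALIDATION = 40

DISCOVERY_TRAITS = ("CQA", "CQS", "TSC", "TY", "TSY")
VALIDATION_TRAITS = ("T0", "T1", "T2", "T4", "T12")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MarkerSpec:
    id: str
    minor_allele_freq: float
    scoring_mode: str = "dosage"

    def __post_init__(self) -> None:
        if not 0.0 <= self.minor_allele_freq <= 1.0:
            raise ValueError(f"allele frequency out of [0,1]: {self.minor_allele_freq}")


@dataclass(frozen=True)
class LdPairSpec:
    """Two-locus disequilibrium: haplotype-level coefficient D."""

    marker_i: str
    marker_j: str
    D: float


@dataclass(frozen=True)
class TraitSpec:
    name: str
    causal_marker: str | None = None
    target_r2: float = 0.0
    residual_sd: float = 1.0
    scale: str = "continuous"  # or "ordinal_1_9"
    mean: float = 0.0
    #: additive model on the log10 scale, values exponentiated (sugar traits)
    log_normal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.scale not in {"continuous", "ordinal_1_9"}:
            raise ValueError(f"unknown trait scale {self.scale!r}")


@dataclass(frozen=True)
class CloneSpec:
    n_clones: int = 161
    n_batches: int = 19
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    ``ld_pairs`` entries must satisfy the admissibility bound
    ``-min(p1*p2, q1*q2) <= D <= min(p1*q2, q1*p2)`` for the allele
    frequencies of the two markers involved.
    """

    n_individuals: int
    markers: Sequence[MarkerSpec]
    trait_specs: Sequence[TraitSpec] = ()
    ld_pairs: Sequence[LdPairSpec] = ()
    peak_noise_cv: float = 0.05
    clone_spec: CloneSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.peak_noise_cv < 0:
            raise ValueError("peak_noise_cv must be nonnegative")
        freqs = {m.id: m.minor_allele_freq for m in self.markers}
        ids = set(freqs)
        for pair in self.ld_pairs:
            if pair.marker_i not in ids or pair.marker_j not in ids:
                raise ValueError(f"ld pair references unknown marker: {pair}")
            _check_admissible_d(freqs[pair.marker_i], freqs[pair.marker_j], pair.D)
        for ts in self.trait_specs:
            if ts.causal_marker is not None and ts.causal_marker not in ids:
                raise ValueError(f"trait {ts.name!r} references unknown marker")


@dataclass
class SimulatedDataset:
    """Generated data plus the ground truth needed for recovery tests."""

    dosage_matrix: DosageMatrix
    trait_table: "pd.DataFrame"
    peak_signals: pd.DataFrame
    clone_table: CloneTable | None
    truth: dict = field(default_factory=dict)


def _check_admissible_d(p1: float, p2: float, D: float) -> None:
    q1, q2 = 1.0 - p1, 1.0 - p2
    lo, hi = -min(p1 * p2, q1 * q2), min(p1 * q2, q1 * p2)
    if not lo - 1e-12 <= D <= hi + 1e-12:
        raise ValueError(f"D={D} outside admissible range [{lo:.4g}, {hi:.4g}] for p1={p1}, p2={p2}")


def simulate_dosages(n: int, p: float, seed: int | np.random.Generator) -> np.ndarray:
    """Draw tetrasomic minor-allele dosages: Binomial(4, p) per individual."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency out of [0,1]: {p}")
    return _rng(seed).binomial(PLOIDY, p, size=n)


def simulate_linked_pair(
    n: int, p1: float, p2: float, D: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw dosages at two loci in gametic disequilibrium D.

    Each individual receives four independent two-locus haplotypes
    from the frequencies (p1*p2 + D, p1*q2 - D, q1*p2 - D, q1*q2 + D)
    for (minor,minor), (minor,major), (major,minor), (major,major);
    the per-locus dosages are the haplotype sums.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency out of [0,1]: {p}")
    _check_admissible_d(p1, p2, D)
    q1, q2 = 1.0 - p1, 1.0 - p2
    freqs = np.array([p1 * p2 + D, p1 * q2 - D, q1 * p2 - D, q1 * q2 + D])
    freqs = np.clip(freqs, 0.0, None)
    freqs = freqs / freqs.sum()
    hap = _rng(seed).multinomial(PLOIDY, freqs, size=n)
    d1 = hap[:, 0] + hap[:, 1]  # haplotypes carrying the minor allele at locus 1
    d2 = hap[:, 0] + hap[:, 2]
    return d1, d2


def simulate_trait(
    dosages: np.ndarray,
    target_r2: float,
    residual_sd: float,
    seed: int | np.random.Generator,
    scale: str = "continuous",
    mean: float = 0.0,
) -> np.ndarray:
    """Simulate an additive single-marker trait.

    ``y = mean + beta * d + eps`` with Gaussian residuals and
    ``beta = residual_sd * sqrt(r2 / ((1 - r2) * Var(d)))``, so the
    fraction of trait variance attributable to the dosage term equals
    ``target_r2`` (``Var(d)`` is the variance of the supplied dosage
    vector).  For ``scale="ordinal_1_9"`` the continuous values are
    binned into nine equal-probability categories labelled 1-9, the
    chip-color scoring convention (1 = very dark, 9 = very light).
    """
    if not 0.0 <= target_r2 < 1.0:
        raise ValueError("target_r2 must lie in [0, 1)")
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    d = np.asarray(dosages, dtype=float)
    var_d = d.var()
    if target_r2 > 0 and var_d == 0:
        raise ValueError("cannot target r2 > 0 with constant dosages")
    beta = 0.0 if target_r2 == 0 else residual_sd * np.sqrt(target_r2 / ((1 - target_r2) * var_d))
    y = mean + beta * d + _rng(seed).normal(0.0, residual_sd, size=d.shape)
    if scale == "ordinal_1_9":
        # equal-probability binning of the latent continuous value
        edges = np.quantile(y, np.arange(1, 9) / 9.0)
        y = np.digitize(y, edges) + 1
        return y.astype(int)
    if scale != "continuous":
        raise ValueError(f"unknown trait scale {scale!r}")
    return y


def simulate_peaks(dosage: int, noise_cv: float, seed: int | np.random.Generator) -> PeakSignal:
    """Two-allele peak heights whose noise-free ratio is dosage:(4-dosage).

    Heights are (4-d)/4 for the reference and d/4 for the alternate
    allele, each multiplied by independent log-normal noise with
    coefficient of variation ``noise_cv``.
    """
    if dosage not in range(PLOIDY + 1):
        raise ValueError(f"dosage must be in 0..{PLOIDY}, got {dosage}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    h = np.array([(PLOIDY - dosage) / PLOIDY, dosage / PLOIDY])
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = _rng(seed).lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=2)
        h = h * noise
    return PeakSignal(heights=tuple(h))


_BASES = np.array(list("ACGT"))


def simulate_clone_table(
    true_variants: HaplotypeMatrix,
    n_clones: int,
    n_batches: int,
    error_rate: float,
    seed: int | np.random.Generator,
) -> tuple[CloneTable, np.ndarray]:
    """Simulate sequenced cDNA clones from a set of true variants.

    Each clone copies one true variant column (uniformly at random),
    then every base is independently miscalled to a random other base
    with probability ``error_rate``.  Clones carry an amplification
    batch id drawn uniformly from ``n_batches`` batches; the consensus
    rule (>=3 clones from >=2 batches) needs at least two batches to
    be exercisable.  Returns the clone table and the true variant
    assignment of each clone.
    """
    if n_batches < 2:
        raise ValueError("need n_batches >= 2 to exercise the consensus rule")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = _rng(seed)
    variant_ids = list(true_variants.variant_ids)
    assignment = rng.integers(len(variant_ids), size=n_clones)
    batches = rng.integers(1, n_batches + 1, size=n_clones)
    calls = true_variants.values.to_numpy()[:, assignment].T.copy()  # clones x positions
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        for i, j in zip(*np.nonzero(flip)):
            others = [b for b in _BASES if b != calls[i, j]]
            calls[i, j] = others[rng.integers(3)]
    df = pd.DataFrame(calls, columns=list(true_variants.positions))
    df.insert(0, "batch", batches)
    df.insert(0, "tissue", "synthetic")
    df.insert(0, "cultivar", "synthetic")
    df.index = pd.Index([f"clone{i + 1}" for i in range(n_clones)], name="clone")
    return CloneTable(df), np.asarray([variant_ids[a] for a in assignment])


def default_discovery_config(seed: int = 0) -> SimulationConfig:
    """A CHIPS-ALL-like discovery study: n=208, five tuber traits.

    The causal marker mirrors the strongest starch-content association
    of the study design (MFA 8.5%, 19.9% of TSC variance); the other
    markers span the frequency range of the reported SNPs.
    """
    markers = [
        MarkerSpec("AGPaseS-T_1259_C", 0.085),
        MarkerSpec("GWD-A_3259_G", 0.066),
        MarkerSpec("PWD-T_10547_C", 0.49),
        MarkerSpec("BMY1-G_2533_A", 0.301),
        MarkerSpec("PHO1b-T_4404_C", 0.118),
        MarkerSpec("SssI-A_5858_G", 0.261),
    ]
    traits = [
        TraitSpec("CQA", None, 0.0, 1.0, "ordinal_1_9"),
        TraitSpec("CQS", None, 0.0, 1.0, "ordinal_1_9"),
        TraitSpec("TSC", "AGPaseS-T_1259_C", 0.199, 1.0, "continuous", mean=16.0),
        TraitSpec("TY", None, 0.0, 1.0, "continuous", mean=400.0),
        TraitSpec("TSY", "AGPaseS-T_1259_C", 0.103, 1.0, "continuous", mean=65.0),
    ]
    ld = [LdPairSpec("PWD-T_10547_C", "BMY1-G_2533_A", 0.0)]
    return SimulationConfig(
        n_individuals=N_DISCOVERY,
        markers=markers,
        trait_specs=traits,
        ld_pairs=ld,
        peak_noise_cv=0.05,
        clone_spec=CloneSpec(n_clones=161, n_batches=19, error_rate=0.001),
        seed=seed,
    )


def default_validation_config(seed: int = 0) -> SimulationConfig:
    """A SUGAR40-like validation panel: n=40, sugar time series."""
    markers = [
        MarkerSpec("AGPaseS-T_1259_C", 0.094),
        MarkerSpec("PWD-G_11140_A", 0.075),
        MarkerSpec("BMY1-G_2751_A", 0.064),
    ]
    traits = [
        TraitSpec(name, "AGPaseS-T_1259_C", 0.17, 0.25, "continuous", mean=0.0, log_normal=True)
        for name in VALIDATION_TRAITS
    ]
    return SimulationConfig(
        n_individuals=N_VALIDATION,
        markers=markers,
        trait_specs=traits,
        peak_noise_cv=0.05,
        seed=seed,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset (genotypes, traits, peaks, clones).

    All randomness flows from ``config.seed``; reruns with the same
    config are bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    individuals = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]

    # genotypes: LD pairs drawn jointly, remaining markers independently
    dosages: dict[str, np.ndarray] = {}
    in_pair = set()
    freqs = {m.id: m.minor_allele_freq for m in config.markers}
    modes = {m.id: m.scoring_mode for m in config.markers}
    for pair in config.ld_pairs:
        d1, d2 = simulate_linked_pair(
            config.n_individuals, freqs[pair.marker_i], freqs[pair.marker_j], pair.D, rng
        )
        dosages[pair.marker_i] = d1
        dosages[pair.marker_j] = d2
        in_pair.update({pair.marker_i, pair.marker_j})
    for spec in config.markers:
        if spec.id not in in_pair:
            dosages[spec.id] = simulate_dosages(config.n_individuals, spec.minor_allele_freq, rng)

    values = pd.DataFrame(dosages, index=pd.Index(individuals, name="individual"))
    markers = {}
    for spec in config.markers:
        try:
            markers[spec.id] = SnpMarker.from_id(spec.id, scoring_mode=spec.scoring_mode)
        except ValueError:
            pass  # free-form marker ids are allowed in simulations
        if spec.scoring_mode == "presence_absence":
            values[spec.id] = (values[spec.id] >= 1).astype(float)
    matrix = DosageMatrix(values, markers=markers, modes=modes)

    # traits
    trait_cols = {}
    truth_traits = {}
    for ts in config.trait_specs:
        d = dosages[ts.causal_marker] if ts.causal_marker else np.zeros(config.n_individuals)
        if ts.causal_marker is None:
            y = ts.mean + rng.normal(0.0, ts.residual_sd, size=config.n_individuals)
            if ts.scale == "ordinal_1_9":
                edges = np.quantile(y, np.arange(1, 9) / 9.0)
                y = (np.digitize(y, edges) + 1).astype(int)
            beta = 0.0
        else:
            var_d = d.var()
            beta = (
                0.0
                if ts.target_r2 == 0
                else ts.residual_sd * np.sqrt(ts.target_r2 / ((1 - ts.target_r2) * var_d))
            )
            y = simulate_trait(d, ts.target_r2, ts.residual_sd, rng, scale=ts.scale, mean=ts.mean)
        if ts.log_normal:
            y = np.power(10.0, y)
        trait_cols[ts.name] = y
        truth_traits[ts.name] = {
            "causal_marker": ts.causal_marker,
            "beta": beta,
            "target_r2": ts.target_r2,
            "scale": ts.scale,
        }
    trait_table = pd.DataFrame(trait_cols, index=values.index)

    # peak signals for dosage-scored biallelic markers
    rows = []
    for mid in values.columns:
        if modes[mid] != "dosage":
            continue
        for ind, d in zip(individuals, dosages[mid]):
            sig = simulate_peaks(int(d), config.peak_noise_cv, rng)
            rows.append((ind, mid, sig.heights[0], sig.heights[1]))
    peak_signals = pd.DataFrame(rows, columns=["individual", "marker", "height_allele1", "height_allele2"])

    clone_table = None
    truth_clones = None
    if config.clone_spec is not None:
        from .haplotypes import load_pho1a_haplotypes

        true_variants = load_pho1a_haplotypes()
        clone_table, truth_clones = simulate_clone_table(
            true_variants,
            config.clone_spec.n_clones,
            config.clone_spec.n_batches,
            config.clone_spec.error_rate,
            rng,
        )

    truth = {
        "traits": truth_traits,
        "allele_freqs": freqs,
        "ld_pairs": [(p.marker_i, p.marker_j, p.D) for p in config.ld_pairs],
        "clone_assignment": truth_clones,
    }
    return SimulatedDataset(
        dosage_matrix=matrix,
        trait_table=trait_table,
        peak_signals=peak_signals,
        clone_table=clone_table,
        truth=truth,
    )
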