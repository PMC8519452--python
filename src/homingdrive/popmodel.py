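"""Deterministic two-sex, two-stage population dynamics of the drive.

A single, randomly mating population with discrete non-overlapping
generations and two life stages.  Adults of generation t mate at random;
the drive homes in the germline of W/T parents; female drive carriers lay
fewer viable eggs (fecundity cost); juveniles lacking a functional copy of
the target gene die before eclosion (recessive lethality) and surviving
drive-carrier heterozygotes suffer an additional sex-specific somatic cost.
Only frequencies are tracked — the deterministic model is density free.

Census convention: the juvenile census is taken post-hatch (after the
female fecundity cost has acted) and before viability/somatic mortality;
the adult census after both.  Reported trajectories follow the experimental
scoring: generation 0 is the composition of the released adults, every
later generation is scored at the juvenile census.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics import (
    ALLELES,
    GENOTYPES,
    GENOTYPE_INDEX,
    Allele,
    DriveRates,
    Genotype,
    Sex,
    WT,
    WW,
    derive_rates,
    gamete_distribution,
    mendelian_rates,
)

N_GENO = len(GENOTYPES)
_EXTINCTION_EPS = 1e-12

#: genotype -> allele dosage matrix (10 x 4), rows sum to 1
_DOSAGE = np.zeros((N_GENO, len(ALLELES)))
for _g, _i in GENOTYPE_INDEX.items():
    for _a in _g.alleles:
        _DOSAGE[_i, ALLELES.index(_a)] += 0.5

_VIABLE = np.array([1.0 if g.is_viable else 0.0 for g in GENOTYPES])
_CARRIER = np.array([1.0 if g.is_carrier else 0.0 for g in GENOTYPES])
_HET_CARRIER = np.array([1.0 if g.is_het_carrier else 0.0 for g in GENOTYPES])

#: collapse map from ordered allele pairs (4 x 4) to unordered genotypes
_PAIR_TO_GENO = np.zeros((len(ALLELES), len(ALLELES)), dtype=int)
for _ia, _a in enumerate(ALLELES):
    for _ib, _b in enumerate(ALLELES):
        _PAIR_TO_GENO[_ia, _ib] = GENOTYPE_INDEX[Genotype.of(_a, _b)]


@dataclass(frozen=True)
class FitnessScheme:
    """Multiplicative fitness costs borne by viable drive-carrier heterozygotes.

    fecundity_cost_f : reduction in viable eggs laid by carrier females
                       (1 - relative hatching rate)
    somatic_cost_m/f : reduction in juvenile-to-adult survival of carrier
                       heterozygotes (1 - relative eclosion rate), per sex

    W/R, W/r, r/r and W/W individuals are fully fit in every component.
    """

    fecundity_cost_f: float = 0.0
    somatic_cost_m: float = 0.0
    somatic_cost_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fecundity_cost_f", "somatic_cost_m", "somatic_cost_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")

    @staticmethod
    def none() -> "FitnessScheme":
        return FitnessScheme(0.0, 0.0, 0.0)

    @staticmethod
    def observed() -> "FitnessScheme":
        """Costs measured in the phenotypic assays."""
        return FitnessScheme(0.216, 0.378, 0.462)

    @staticmethod
    def high() -> "FitnessScheme":
        """Measured fecundity cost plus somatic costs of 0.9 in both sexes."""
        return FitnessScheme(0.216, 0.9, 0.9)

    def somatic_survival(self, sex: Sex) -> np.ndarray:
        cost = self.somatic_cost_f if sex is Sex.FEMALE else self.somatic_cost_m
        return 1.0 - cost * _HET_CARRIER

    def fecundity_multiplier(self) -> np.ndarray:
        return 1.0 - self.fecundity_cost_f * _HET_CARRIER


@dataclass
class PopulationState:
    """Sex-specific genotype frequencies at one census."""

    generation: int
    stage: str  # "adult" | "juvenile"
    freq_f: np.ndarray
    freq_m: np.ndarray
    extinct: bool = False

    def __post_init__(self) -> None:
        self.freq_f = np.asarray(self.freq_f, dtype=float)
        self.freq_m = np.asarray(self.freq_m, dtype=float)
        if self.freq_f.shape != (N_GENO,) or self.freq_m.shape != (N_GENO,):
            raise ValueError(f"frequency vectors must have length {N_GENO}")
        if not self.extinct:
            for name, v in (("freq_f", self.freq_f), ("freq_m", self.freq_m)):
                if abs(v.sum() - 1.0) > 1e-10:
                    raise ValueError(f"{name} sums to {v.sum()!r}, not 1")
                if (v < -1e-15).any():
                    raise ValueError(f"{name} has negative entries")
            if self.stage == "adult" and (self.freq_f * (1 - _VIABLE)).any():
                raise ValueError("inviable genotypes present at the adult census")

    @staticmethod
    def adults_from_dict(
        comp: Mapping[Genotype, float], generation: int = 0
    ) -> "PopulationState":
        v = np.zeros(N_GENO)
        for g, f in comp.items():
            v[GENOTYPE_INDEX[g]] = f
        return PopulationState(generation, "adult", v.copy(), v.copy())

    def carrier(self, sex: Optional[Sex] = None) -> float:
        if sex is Sex.FEMALE:
            return float(self.freq_f @ _CARRIER)
        if sex is Sex.MALE:
            return float(self.freq_m @ _CARRIER)
        return float(0.5 * (self.freq_f + self.freq_m) @ _CARRIER)

    def allele_frequencies(self, sex: Sex) -> Dict[Allele, float]:
        v = self.freq_f if sex is Sex.FEMALE else self.freq_m
        return dict(zip(ALLELES, (v @ _DOSAGE).tolist()))


def gamete_matrix(sex: Sex, rates: DriveRates) -> np.ndarray:
    """Per-genotype gamete distributions, (10 genotypes x 4 alleles).

    Rows for inviable genotypes are zero: they never reach the adult stage.
    """
    M = np.zeros((N_GENO, len(ALLELES)))
    for g, i in GENOTYPE_INDEX.items():
        if g.is_viable:
            M[i] = gamete_distribution(g, sex, rates).probs
    return M


def _collapse_zygotes(female_pool: np.ndarray, male_pool: np.ndarray) -> np.ndarray:
    Z = np.outer(female_pool, male_pool)
    juv = np.zeros(N_GENO)
    np.add.at(juv, _PAIR_TO_GENO.ravel(), Z.ravel())
    return juv


def relative_reproductive_output(
    state: PopulationState, rates: DriveRates, fitness: FitnessScheme
) -> float:
    """Expected viable eggs per female, relative to an all-wild-type population.

    Product of the mean fecundity multiplier among adult females and the
    probability that a zygote carries a viable genotype.  Both factors are 1
    for wild type, so the value is 1 - genetic load at the egg-to-larva
    transition; somatic mortality is not included.
    """
    if state.extinct:
        return 0.0
    fec = fitness.fecundity_multiplier()
    mean_fec = float(state.freq_f @ fec)
    Mf = gamete_matrix(Sex.FEMALE, rates)
    Mm = gamete_matrix(Sex.MALE, rates)
    fpool = (state.freq_f * fec) @ Mf
    mpool = state.freq_m @ Mm
    fw, mw = fpool.sum(), mpool.sum()
    if fw <= _EXTINCTION_EPS or mw <= _EXTINCTION_EPS:
        return 0.0
    juv = _collapse_zygotes(fpool / fw, mpool / mw)
    return mean_fec * float(juv @ _VIABLE)


def step_generation(
    state: PopulationState, rates: DriveRates, fitness: FitnessScheme
) -> Tuple[PopulationState, PopulationState]:
    """Advance one generation; returns (juvenile census, adult census).

    Females contribute gametes weighted by frequency and fecundity; males by
    frequency alone (equal mating success).  Zygotes form by random union of
    the two renormalised pools, with the same distribution in both sexes
    (1:1 primary sex ratio) — this is the juvenile census.  Viability
    selection (recessive lethality) and the sex-specific somatic cost then
    act, and the renormalised survivors form the adult census.
    """
    if state.stage != "adult":
        raise ValueError("step_generation expects an adult-stage state")
    gen = state.generation + 1
    if state.extinct:
        juv = PopulationState(gen, "juvenile", state.freq_f, state.freq_m, extinct=True)
        adu = PopulationState(gen, "adult", state.freq_f, state.freq_m, extinct=True)
        return juv, adu

    fpool = (state.freq_f * fitness.fecundity_multiplier()) @ gamete_matrix(Sex.FEMALE, rates)
    mpool = state.freq_m @ gamete_matrix(Sex.MALE, rates)
    fw, mw = fpool.sum(), mpool.sum()
    if fw <= _EXTINCTION_EPS or mw <= _EXTINCTION_EPS:
        z = np.zeros(N_GENO)
        return (
            PopulationState(gen, "juvenile", z, z.copy(), extinct=True),
            PopulationState(gen, "adult", z.copy(), z.copy(), extinct=True),
        )
    juv_vec = _collapse_zygotes(fpool / fw, mpool / mw)
    juvenile = PopulationState(gen, "juvenile", juv_vec.copy(), juv_vec.copy())

    adult_vecs = []
    extinct = False
    for sex in (Sex.FEMALE, Sex.MALE):
        surv = juv_vec * _VIABLE * fitness.somatic_survival(sex)
        total = surv.sum()
        if total <= _EXTINCTION_EPS:
            extinct = True
            adult_vecs.append(np.zeros(N_GENO))
        else:
            adult_vecs.append(surv / total)
    adult = PopulationState(gen, "adult", adult_vecs[0], adult_vecs[1], extinct=extinct)
    return juvenile, adult


@dataclass(frozen=True)
class TrajectoryRecord:
    generation: int
    juvenile_carrier: float  # NaN at generation 0 (no juvenile census yet)
    adult_carrier_f: float
    adult_carrier_m: float
    allele_freq_f: Dict[Allele, float]
    allele_freq_m: Dict[Allele, float]
    relative_output: float
    extinct: bool

    @property
    def adult_carrier(self) -> float:
        return 0.5 * (self.adult_carrier_f + self.adult_carrier_m)

    def allele_frequency(self, allele: Allele) -> float:
        return 0.5 * (self.allele_freq_f[allele] + self.allele_freq_m[allele])


@dataclass
class Trajectory:
    """Per-generation summaries of one deterministic run."""

    records: List[TrajectoryRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> TrajectoryRecord:
        return self.records[i]

    def carrier_series(self) -> List[float]:
        """The experimentally scored drive-carrier frequency.

        Generation 0 reflects the starting adult population; later entries
        are the juvenile census.
        """
        out = []
        for rec in self.records:
            out.append(rec.adult_carrier if rec.generation == 0 else rec.juvenile_carrier)
        return out

    def allele_series(self, allele: Allele) -> List[float]:
        return [rec.allele_frequency(allele) for rec in self.records]

    def output_series(self) -> List[float]:
        return [rec.relative_output for rec in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: generation, stage, metric, sex, value."""
        rows = []
        for rec in self.records:
            rows.append((rec.generation, "juvenile", "carrier_freq", "both", rec.juvenile_carrier))
            rows.append((rec.generation, "adult", "carrier_freq", "female", rec.adult_carrier_f))
            rows.append((rec.generation, "adult", "carrier_freq", "male", rec.adult_carrier_m))
            for sex, freqs in (("female", rec.allele_freq_f), ("male", rec.allele_freq_m)):
                for allele, f in freqs.items():
                    rows.append((rec.generation, "adult", f"allele_{allele.symbol}", sex, f))
            rows.append((rec.generation, "adult", "relative_output", "both", rec.relative_output))
            rows.append((rec.generation, "adult", "extinct", "both", float(rec.extinct)))
        return pd.DataFrame(rows, columns=["generation", "stage", "metric", "sex", "value"])


SCENARIO_LABELS = ("no_cost", "observed_cost", "high_cost", "custom")

#: Measured transmission rates and end-joining fraction of the drive strain.
DEFAULT_D_F = 0.927
DEFAULT_D_M = 0.913
DEFAULT_U = 0.266


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: rates, costs, starting adults, horizon."""

    label: str
    rates: DriveRates
    fitness: FitnessScheme
    initial: Mapping[Genotype, float] = None  # type: ignore[assignment]
    generations: int = 12

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.initial is None:
            object.__setattr__(self, "initial", {WT: 0.2, WW: 0.8})
        total = sum(self.initial.values())
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"initial adult composition sums to {total!r}, not 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    def initial_state(self) -> PopulationState:
        return PopulationState.adults_from_dict(self.initial)


def release_scenario(
    label: str = "observed_cost",
    p: float = 0.0,
    release_frequency: float = 0.2,
    generations: int = 12,
    rates: Optional[DriveRates] = None,
    fitness: Optional[FitnessScheme] = None,
) -> ScenarioConfig:
    """Standard cage-release scenario: W/T adults released into wild type.

    The three named scenarios share the measured transmission rates and
    differ only in fitness costs: ``no_cost`` (none), ``observed_cost``
    (assay-measured) and ``high_cost`` (somatic costs of 0.9 in both sexes).
    """
    if rates is None:
        rates = derive_rates(DEFAULT_D_F, DEFAULT_D_M, DEFAULT_U, p)
    if fitness is None:
        presets = {
            "no_cost": FitnessScheme.none,
            "observed_cost": FitnessScheme.observed,
            "high_cost": FitnessScheme.high,
        }
        if label not in presets:
            raise ValueError(f"scenario {label!r} needs an explicit FitnessScheme")
        fitness = presets[label]()
    initial = {WT: release_frequency, WW: 1.0 - release_frequency}
    return ScenarioConfig(label, rates, fitness, initial, generations)


def control_scenario(release_frequency: float = 0.2, generations: int = 12) -> ScenarioConfig:
    """Non-driving null-allele control: Mendelian inheritance, no het costs.

    The control transgene is still a null allele of the essential gene, so
    homozygotes remain inviable; only homing and heterozygote costs are gone.
    """
    return ScenarioConfig(
        "custom",
        mendelian_rates(),
        FitnessScheme.none(),
        {WT: release_frequency, WW: 1.0 - release_frequency},
        generations,
    )


def _record(state: PopulationState, juvenile_carrier: float,
            rates: DriveRates, fitness: FitnessScheme) -> TrajectoryRecord:
    return TrajectoryRecord(
        generation=state.generation,
        juvenile_carrier=juvenile_carrier,
        adult_carrier_f=state.carrier(Sex.FEMALE),
        adult_carrier_m=state.carrier(Sex.MALE),
        allele_freq_f=state.allele_frequencies(Sex.FEMALE),
        allele_freq_m=state.allele_frequencies(Sex.MALE),
        relative_output=relative_reproductive_output(state, rates, fitness),
        extinct=state.extinct,
    )


def simulate_release(config: ScenarioConfig) -> Trajectory:
    """Iterate the recursion from the configured starting adults."""
    state = config.initial_state()
    traj = Trajectory(label=config.label)
    traj.records.append(_record(state, float("nan"), config.rates, config.fitness))
    for _ in range(config.generations):
        juvenile, state = step_generation(state, config.rates, config.fitness)
        traj.records.append(
            _record(state, juvenile.carrier(), config.rates, config.fitness)
        )
        if state.extinct:
            break
    return traj


def simulate_fixation_mimic(
    rates: DriveRates, fitness: FitnessScheme, generations: int
) -> Trajectory:
    """Breeding scheme in which every founding adult is a drive heterozygote.

    Mimics a population at genotype fixation of the drive — the regime of
    strongest selection for functional resistance.  Starts from 100% W/T
    adults of both sexes and tracks reproductive output and allele
    frequencies.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    config = ScenarioConfig("custom", rates, fitness, {WT: 1.0}, generations)
    traj = simulate_release(config)
    traj.label = "fixation_mimic"
    return traj


def sweep_functional_resistance(
    base: ScenarioConfig, p_values: Sequence[float]
) -> Dict[float, Trajectory]:
    """Re-run one scenario across functional-repair probabilities ``p``."""
    if len(p_values) == 0:
        raise ValueError("p_values must be non-empty")
    out: Dict[float, Trajectory] = {}
    for p in p_values:
        config = replace(base, rates=base.rates.with_p(p))
        out[p] = simulate_release(config)
    return out


def sweep_table(sweep: Mapping[float, Trajectory]) -> pd.DataFrame:
    """Tidy long table of a resistance sweep: generation, p, carrier_freq."""
    rows = []
    for p, traj in sweep.items():
        for gen, carrier in enumerate(traj.carrier_series()):
            rows.append((gen, p, carrier))
    return pd.DataFrame(rows, columns=["generation", "p", "carrier_freq"])


@dataclass(frozen=True)
class CostFit:
    best_cost: float
    sse_table: pd.DataFrame  # columns: cost, sse


def fit_somatic_cost(
    observed: Sequence[float], base: ScenarioConfig, grid: Sequence[float]
) -> CostFit:
    """Grid-search least-squares fit of a shared somatic cost.

    ``observed`` is a carrier-frequency series starting at generation 0
    (the released adults).  Each candidate replaces both sex-specific
    somatic costs while keeping the base fecundity cost, and the model is
    run over the observed horizon.  Ties break toward the smaller cost.
    """
    if len(observed) < 2:
        raise ValueError("observed series must cover at least 2 generations")
    if len(grid) == 0:
        raise ValueError("cost grid must be non-empty")
    rows = []
    for cost in grid:
        fitness = FitnessScheme(
            fecundity_cost_f=base.fitness.fecundity_cost_f,
            somatic_cost_m=cost,
            somatic_cost_f=cost,
        )
        config = replace(base, label="custom", fitness=fitness,
                         generations=len(observed) - 1)
        model = simulate_release(config).carrier_series()
        model = model + [0.0] * (len(observed) - len(model))  # extinct: flat zero
        sse = float(np.sum((np.asarray(model) - np.asarray(observed)) ** 2))
        rows.append((cost, sse))
    table = pd.DataFrame(rows, columns=["cost", "sse"])
    best = table.sort_values(["sse", "cost"], kind="stable").iloc[0]
    return CostFit(best_cost=float(best["cost"]), sse_table=table)


def plot_carrier_curves(trajectories: Mapping[str, Trajectory], path: str) -> None:
    """Write a carrier-frequency-vs-generation figure for labelled runs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, traj in trajectories.items():
        series = traj.carrier_series()
        ax.plot(range(len(series)), series, marker="o", label=label)
    ax.set_xlabel("generation")
    ax.set_ylabel("drive carrier frequency")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
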