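"""Synthetic data generators emulating the cage and sequencing experiments.

Three generators cover every pipeline input:

* finite-population cage trials — a two-sex Markov chain whose transition
  law is the deterministic recursion, sampled multinomially at the cage
  census sizes (400 adults seeded from a release mix, 450 scored eggs);
* individual-female progeny screens for estimating the transmission rate;
* amplicon read sets (FASTQ, Phred+33) drawn from a configured target-site
  allele spectrum, with optional uniform per-base error.

Everything is reproducible from an explicit seed, and each generator can
emit its configuration alongside its output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconReference
from .genetics import GENOTYPES, Sex
from .popmodel import (
    N_GENO,
    PopulationState,
    ScenarioConfig,
    _CARRIER,
    _VIABLE,
    step_generation,
)

DEFAULT_N_ADULTS = 400
DEFAULT_N_EGGS = 450


@dataclass(frozen=True)
class CageObservation:
    """One generation's census of one replicate cage."""

    replicate: int
    generation: int
    n_adults: int
    n_eggs_scored: int
    carrier_juveniles: int
    noncarrier_juveniles: int
    genotype_counts: Optional[Dict[str, int]] = None  # true juvenile genotypes
    extinct: bool = False

    @property
    def carrier_fraction(self) -> float:
        total = self.carrier_juveniles + self.noncarrier_juveniles
        return self.carrier_juveniles / total if total else float("nan")


def observations_frame(observations: Sequence[CageObservation]) -> pd.DataFrame:
    rows = [
        (o.replicate, o.generation, o.n_adults, o.n_eggs_scored,
         o.carrier_juveniles, o.noncarrier_juveniles, o.carrier_fraction,
         o.extinct)
        for o in observations
    ]
    return pd.DataFrame(rows, columns=[
        "replicate", "generation", "n_adults", "n_eggs_scored",
        "carrier_juveniles", "noncarrier_juveniles", "carrier_fraction",
        "extinct",
    ])


def _counts_to_state(counts_f: np.ndarray, counts_m: np.ndarray,
                     generation: int) -> Optional[PopulationState]:
    tf, tm = counts_f.sum(), counts_m.sum()
    if tf == 0 or tm == 0:
        return None
    return PopulationState(generation, "adult", counts_f / tf, counts_m / tm)


def simulate_cage_stochastic(
    config: ScenarioConfig,
    n_adults: int = DEFAULT_N_ADULTS,
    n_eggs_scored: int = DEFAULT_N_EGGS,
    replicates: int = 1,
    seed: int = 0,
    keep_genotypes: bool = False,
) -> List[CageObservation]:
    """Finite-population cage trials under the configured scenario.

    Each replicate is an independent Markov chain: adults of one generation
    are a multinomial draw (size n_adults/2 per sex) from the deterministic
    adult distribution conditional on the *realised* previous adults, and
    the scored juveniles are a multinomial draw of size ``n_eggs_scored``
    from the conditional juvenile distribution.  Marker phenotype equals
    drive-carrier status.
    """
    if n_adults < 2 or n_adults % 2:
        raise ValueError("n_adults must be an even count >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_per_sex = n_adults // 2
    init = config.initial_state()
    out: List[CageObservation] = []
    for rep in range(replicates):
        counts_f = rng.multinomial(n_per_sex, init.freq_f)
        counts_m = rng.multinomial(n_per_sex, init.freq_m)
        for gen in range(1, config.generations + 1):
            state = _counts_to_state(counts_f, counts_m, gen - 1)
            if state is None:
                out.append(CageObservation(rep, gen, n_adults, n_eggs_scored,
                                           0, 0, extinct=True))
                break
            juvenile, adult = step_generation(state, config.rates, config.fitness)
            if adult.extinct:
                out.append(CageObservation(rep, gen, n_adults, n_eggs_scored,
                                           0, 0, extinct=True))
                break
            egg_counts = rng.multinomial(n_eggs_scored, juvenile.freq_f)
            carriers = int(egg_counts @ _CARRIER.astype(int))
            geno = None
            if keep_genotypes:
                geno = {g.label: int(c) for g, c in zip(GENOTYPES, egg_counts) if c}
            out.append(CageObservation(
                rep, gen, n_adults, n_eggs_scored,
                carriers, int(n_eggs_scored - carriers), geno,
            ))
            counts_f = rng.multinomial(n_per_sex, adult.freq_f)
            counts_m = rng.multinomial(n_per_sex, adult.freq_m)
    return out


@dataclass(frozen=True)
class ProgenyScreen:
    """Individual-female marker screen and the pooled transmission estimate."""

    per_female: pd.DataFrame  # columns: female, brood, marker_positive
    d_hat: float
    se: float


def simulate_progeny_screen(
    d: float,
    n_females: int = 15,
    brood_size_mean: float = 100.0,
    seed: int = 0,
    dispersion: float = 5.0,
) -> ProgenyScreen:
    """Score the progeny of individual W/T females for the drive marker.

    Brood sizes are negative-binomial (mean ``brood_size_mean``, shape
    ``dispersion``; smaller shape = more overdispersion); each offspring is
    marker-positive with the transmission probability ``d``.  The pooled
    estimate is total positives over total progeny, with a binomial
    standard error.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    if n_females < 1:
        raise ValueError("need at least one female")
    rng = np.random.default_rng(seed)
    p_nb = dispersion / (dispersion + brood_size_mean)
    broods = rng.negative_binomial(dispersion, p_nb, size=n_females)
    broods = np.maximum(broods, 1)  # every scored female left progeny
    positives = rng.binomial(broods, d)
    total = int(broods.sum())
    d_hat = float(positives.sum() / total)
    se = float(np.sqrt(d_hat * (1.0 - d_hat) / total))
    table = pd.DataFrame({
        "female": np.arange(n_females),
        "brood": broods.astype(int),
        "marker_positive": positives.astype(int),
    })
    return ProgenyScreen(table, d_hat, se)


# ---------------------------------------------------------------------------
# amplicon reads

@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration of a synthetic amplicon read set.

    ``spectrum`` maps full allele sequences (edited copies of the
    reference) to frequencies summing to 1.  ``rounding`` chooses how
    frequencies become counts: "multinomial" sampling or deterministic
    "largest_remainder" apportionment (for exact round-trip checks).
    """

    spectrum: Mapping[str, float]
    n_reads: int = 1000
    error_rate: float = 0.0
    quality: int = 37
    low_quality: Optional[int] = None   # two-level quality mixture
    low_quality_fraction: float = 0.0
    seed: int = 0
    rounding: str = "multinomial"

    def __post_init__(self) -> None:
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum frequencies sum to {total!r}, not 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.rounding not in ("multinomial", "largest_remainder"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["spectrum"] = dict(d["spectrum"])
        return json.dumps(d, indent=2, sort_keys=True)


def largest_remainder_counts(freqs: Sequence[float], total: int) -> List[int]:
    """Apportion ``total`` into integer counts proportional to ``freqs``."""
    quotas = np.asarray(freqs, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def simulate_reads(
    reference: AmpliconReference, config: ReadSimConfig
) -> List[SeqRecord]:
    """Draw reads from the allele spectrum and apply uniform base errors.

    Reads are full-length allele sequences (pre-trimmed, single-end).  With
    error_rate 0 and largest-remainder rounding the emitted counts match
    the configured spectrum exactly.
    """
    for allele in config.spectrum:
        bad = set(allele.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"allele contains non-nucleotide characters {bad}")
    rng = np.random.default_rng(config.seed)
    items = list(config.spectrum.items())
    freqs = [f for _, f in items]
    if config.rounding == "largest_remainder":
        counts = largest_remainder_counts(freqs, config.n_reads)
    else:
        counts = rng.multinomial(config.n_reads, freqs).tolist()

    bases = np.array(list("ACGT"))
    records: List[SeqRecord] = []
    idx = 0
    for (allele, _), count in zip(items, counts):
        allele = allele.upper()
        for _ in range(count):
            seq = allele
            if config.error_rate > 0.0:
                arr = np.array(list(seq))
                hit = rng.random(len(arr)) < config.error_rate
                for pos in np.nonzero(hit)[0]:
                    choices = bases[bases != arr[pos]]
                    arr[pos] = rng.choice(choices)
                seq = "".join(arr)
            if config.low_quality is not None and config.low_quality_fraction > 0:
                low = rng.random(len(seq)) < config.low_quality_fraction
                quals = np.where(low, config.low_quality, config.quality)
            else:
                quals = np.full(len(seq), config.quality)
            record = SeqRecord(Seq(seq), id=f"sim_{idx:06d}", description="")
            record.letter_annotations["phred_quality"] = quals.astype(int).tolist()
            records.append(record)
            idx += 1
    return records


def write_fastq(records: Sequence[SeqRecord], path: str) -> None:
    with open(path, "w") as fh:
        seqio_write(records, fh, "fastq")


def write_provenance(path: str, payload: Mapping[str, object]) -> None:
    """Machine-readable record of the generator configuration and seed."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
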