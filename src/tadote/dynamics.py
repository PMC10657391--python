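"""Forward population dynamics of single-locus toxin-antidote haplotypes.

Haplotypes at one TA locus fall into four classes: ``FA`` (toxin and antidote
functional — the intact selfish element), ``fA`` (toxin dead, antidote
expressed), ``Fa`` (toxin functional, antidote silenced — never observed in
surveys, and self-destructive here) and ``fa`` (double null).  The recursion
tracks haplotype frequencies in an effectively infinite population (or a
finite Wright-Fisher population), forming parental genotypes by
Hardy-Weinberg proportions for the outcrossed fraction, selecting pollen
through the gamete-killing model, and mixing a selfed fraction ``s`` (rice is
predominantly selfing).

The evolutionary ordering claim embodied here: an antidote-silencing
mutation (``fa`` arising on an ``fA`` background) is neutral only where the
toxin is already dead; in the presence of ``FA`` it is purged, so promoter
silencing of the antidote can establish only after toxin loss.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    DiploidGenotype,
    Haplotype,
    HaplotypeAllele,
    SterileMaleError,
    male_gamete_distribution,
)
from .panel import STATE_TOKENS, single_locus_panel

__all__ = [
    "HAPLOTYPE_CLASSES",
    "DriveParams",
    "deterministic_step",
    "run_deterministic",
    "wright_fisher_run",
    "mutation_order_experiment",
    "MutationFateReport",
]

HAPLOTYPE_CLASSES: tuple[str, ...] = ("FA", "fA", "Fa", "fa")
_NCLASS = 4
_PAIRS = [(i, j) for i in range(_NCLASS) for j in range(i, _NCLASS)]


@dataclass(frozen=True)
class DriveParams:
    """Parameters of the single-locus recursion.

    ``killing_efficiency``: k of the toxin (default 1).
    ``selfing_rate``: fraction ``s`` of each plant's ovules self-pollinated
    (default 0.95, a typical rate for predominantly selfing rice; use 0 for
    clean outcrossing drive properties).
    """

    killing_efficiency: float = 1.0
    selfing_rate: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ConfigurationError("selfing rate must lie in [0, 1]")


@lru_cache(maxsize=32)
def _genotype_tables(k: float):
    """Per-genotype viable fraction, pollen pool and ovule pool vectors."""
    panel = single_locus_panel("qHMS1", k=k)
    alleles = {c: HaplotypeAllele(*STATE_TOKENS[c]) for c in HAPLOTYPE_CLASSES}
    haps = {c: Haplotype((alleles[c],),) for c in HAPLOTYPE_CLASSES}
    V = np.zeros(len(_PAIRS))
    pollen = np.zeros((len(_PAIRS), _NCLASS))
    ovule = np.zeros((len(_PAIRS), _NCLASS))
    for idx, (i, j) in enumerate(_PAIRS):
        g = DiploidGenotype(haps[HAPLOTYPE_CLASSES[i]], haps[HAPLOTYPE_CLASSES[j]])
        dist = male_gamete_distribution(g, panel)
        V[idx] = dist.viable_fraction
        for gc in dist.classes:
            ci = HAPLOTYPE_CLASSES.index(
                next(
                    c
                    for c in HAPLOTYPE_CLASSES
                    if STATE_TOKENS[c] == gc.haplotype.alleles[0].state
                )
            )
            pollen[idx, ci] += gc.post_freq
            ovule[idx, ci] += gc.prior_freq
    return V, pollen, ovule


def _as_freqs(freqs: Union[dict, np.ndarray, list]) -> np.ndarray:
    if isinstance(freqs, dict):
        unknown = set(freqs) - set(HAPLOTYPE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown haplotype classes {sorted(unknown)}")
        x = np.array([float(freqs.get(c, 0.0)) for c in HAPLOTYPE_CLASSES])
    else:
        x = np.asarray(freqs, dtype=float)
        if x.shape != (_NCLASS,):
            raise ConfigurationError(f"expected {_NCLASS} haplotype frequencies")
    if x.min() < -1e-12 or not np.isclose(x.sum(), 1.0, atol=1e-9):
        raise ConfigurationError("haplotype frequencies must be nonnegative and sum to 1")
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


def _genotype_freqs(x: np.ndarray) -> np.ndarray:
    f = np.empty(len(_PAIRS))
    for idx, (i, j) in enumerate(_PAIRS):
        f[idx] = x[i] * x[j] if i == j else 2.0 * x[i] * x[j]
    return f


def _offspring_genotype_probs(x: np.ndarray, params: DriveParams) -> np.ndarray:
    """Offspring (female-haplotype x male-haplotype) probability matrix."""
    V, pollen, ovule = _genotype_tables(params.killing_efficiency)
    f = _genotype_freqs(x)
    pollen_mass = float(f @ V)
    if pollen_mass <= 0.0:
        raise SterileMaleError("population male-extinct: no genotype produces viable pollen")
    y = (f * V) @ pollen / pollen_mass  # population pollen pool
    s = params.selfing_rate
    out = np.zeros((_NCLASS, _NCLASS))
    # outcrossed ovules: population ovule pool (= x) times population pollen pool
    out += (1.0 - s) * np.outer(x, y)
    # selfed ovules: each male-fertile plant fertilizes its own ovules with
    # its own pollen pool; a male-sterile plant sets no selfed seed
    if s > 0.0:
        for idx in range(len(_PAIRS)):
            if V[idx] > 0.0 and f[idx] > 0.0:
                out += s * f[idx] * np.outer(ovule[idx], pollen[idx])
    total = out.sum()
    if total <= 0.0:
        raise SterileMaleError("population male-extinct: no offspring produced")
    return out / total


def deterministic_step(freqs, params: DriveParams = DriveParams()) -> np.ndarray:
    """One generation of the infinite-population recursion."""
    x = _as_freqs(freqs)
    G = _offspring_genotype_probs(x, params)
    return (G.sum(axis=1) + G.sum(axis=0)) / 2.0


def mean_pollen_fertility(freqs, params: DriveParams = DriveParams()) -> float:
    """Population mean viable-pollen fraction under Hardy-Weinberg genotypes."""
    x = _as_freqs(freqs)
    V, _, _ = _genotype_tables(params.killing_efficiency)
    return float(_genotype_freqs(x) @ V)


def _trajectory_frame(rows: list, params: DriveParams, extra: dict) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["generation", *HAPLOTYPE_CLASSES, "mean_fertility"])
    df.attrs["params"] = {
        "killing_efficiency": params.killing_efficiency,
        "selfing_rate": params.selfing_rate,
        **extra,
    }
    return df


def run_deterministic(
    initial_freqs, generations: int, params: DriveParams = DriveParams()
) -> pd.DataFrame:
    """Deterministic trajectory; rows are generations 0..``generations``."""
    x = _as_freqs(initial_freqs)
    rows = [[0, *x, mean_pollen_fertility(x, params)]]
    for g in range(1, generations + 1):
        x = deterministic_step(x, params)
        rows.append([g, *x, mean_pollen_fertility(x, params)])
    return _trajectory_frame(rows, params, {"N": None, "seed": None})


def wright_fisher_run(
    initial_freqs,
    N: int,
    generations: int,
    seed: int,
    params: DriveParams = DriveParams(),
) -> pd.DataFrame:
    """Finite-population counterpart: each generation samples ``N`` diploid
    offspring multinomially from the deterministic offspring genotype
    distribution.  Bit-reproducible for a fixed seed."""
    if N < 2:
        raise ConfigurationError("population size N must be at least 2")
    rng = np.random.default_rng(seed)
    x = _as_freqs(initial_freqs)
    rows = [[0, *x, mean_pollen_fertility(x, params)]]
    for g in range(1, generations + 1):
        G = _offspring_genotype_probs(x, params)
        # collapse to unordered genotype classes for the multinomial draw
        probs = np.array(
            [G[i, j] + G[j, i] if i != j else G[i, i] for (i, j) in _PAIRS]
        )
        probs = probs / probs.sum()
        counts = rng.multinomial(N, probs)
        x = np.zeros(_NCLASS)
        for idx, (i, j) in enumerate(_PAIRS):
            x[i] += counts[idx]
            x[j] += counts[idx]
        x = x / (2.0 * N)
        rows.append([g, *x, mean_pollen_fertility(x, params)])
    return _trajectory_frame(rows, params, {"N": N, "seed": seed})


# ---------------------------------------------------------------------------
# mutation-order experiment

_SCENARIOS = {
    "fa_into_FA_background": ("fa", {"FA": 1.0}),
    "fa_into_fA_background": ("fa", {"fA": 1.0}),
    "Fa_into_any": ("Fa", {"FA": 0.5, "fA": 0.5}),
    "FA_into_fa_background": ("FA", {"fa": 1.0}),
}


@dataclass
class MutationFateReport:
    scenario: str
    mutant: str
    mode: str
    initial_freq: float
    final_freq: float
    outcome: str
    generations: int
    trajectory: Optional[pd.DataFrame] = None
    replicates: Optional[int] = None
    lost_fraction: Optional[float] = None
    established_fraction: Optional[float] = None


def mutation_order_experiment(
    scenario: str,
    params: DriveParams = DriveParams(),
    mode: str = "deterministic",
    generations: int = 200,
    resident: Optional[dict] = None,
    intro_freq: Optional[float] = None,
    N: int = 1000,
    replicates: int = 50,
    seed: Optional[int] = None,
    establish_threshold: float = 0.05,
) -> MutationFateReport:
    """Introduce a mutant haplotype into a resident population and report its fate.

    Deterministic mode introduces the mutant at frequency 0.005 (override
    with ``intro_freq``) and classifies the trajectory endpoint; Wright-Fisher
    mode introduces one copy (frequency 1/2N) and reports loss/establishment
    frequencies over seeded replicates.
    """
    if scenario not in _SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIOS)}"
        )
    mutant, default_resident = _SCENARIOS[scenario]
    resident = resident if resident is not None else default_resident
    mi = HAPLOTYPE_CLASSES.index(mutant)

    def _init(freq: float) -> np.ndarray:
        base = _as_freqs(resident)
        x = base * (1.0 - freq)
        x[mi] += freq
        return x

    if mode == "deterministic":
        f0 = intro_freq if intro_freq is not None else 0.005
        traj = run_deterministic(_init(f0), generations, params)
        final = float(traj[mutant].iloc[-1])
        if abs(final - f0) < 1e-9:
            outcome = "neutral"
        elif final > f0:
            outcome = "spreading"
        else:
            outcome = "declining"
        return MutationFateReport(
            scenario=scenario,
            mutant=mutant,
            mode=mode,
            initial_freq=f0,
            final_freq=final,
            outcome=outcome,
            generations=generations,
            trajectory=traj,
        )

    if mode != "wf":
        raise ConfigurationError(f"unknown mode {mode!r}; expected 'deterministic' or 'wf'")
    if seed is None:
        raise ConfigurationError("Wright-Fisher mode requires a seed")
    f0 = intro_freq if intro_freq is not None else 1.0 / (2.0 * N)
    rng = np.random.default_rng(seed)
    finals = []
    for _r in range(replicates):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traj = wright_fisher_run(_init(f0), N, generations, sub_seed, params)
        finals.append(float(traj[mutant].iloc[-1]))
    finals_arr = np.array(finals)
    return MutationFateReport(
        scenario=scenario,
        mutant=mutant,
        mode=mode,
        initial_freq=f0,
        final_freq=float(finals_arr.mean()),
        outcome="stochastic",
        generations=generations,
        replicates=replicates,
        lost_fraction=float((finals_arr == 0.0).mean()),
        established_fraction=float((finals_arr >= establish_threshold).mean()),
    )
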