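"""Stochastic serial-transfer simulator for persistence evolution.

Models the daily cycle: stationary-phase culture -> bactericidal treatment
(persisters survive) -> dilution bottleneck -> regrowth with mutation.
Also simulates selection of barcoded knockout libraries under the same
regime, producing read-count tables for downstream analysis.

All randomness flows through :class:`numpy.random.Generator` objects.  A
single top-level seed is expanded into independent child streams per
population by :meth:`numpy.random.Generator.spawn`, so runs are bit
reproducible for a given (config, seed) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ExtinctionError, InvalidParameterError

__all__ = [
    "GenotypeSpec",
    "DFEParams",
    "RegimeConfig",
    "LibraryConfig",
    "PopulationState",
    "CycleRecord",
    "ANCESTOR",
    "survival_fraction",
    "bottleneck_sample",
    "antibiotic_kill",
    "regrow_and_mutate",
    "run_evolution",
    "cumulative_generations",
    "doublings_to_stationary",
    "scaled_transfer",
    "sample_effect_table",
    "simulate_library_selection",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """A heritable type: persistence and growth phenotype plus label.

    Parameters
    ----------
    id : str
        Unique label (barcode or lineage name).
    pi : float
        Persister fraction in [0, 1]: probability that a cell is in the
        tolerant state when treatment starts.
    w : float
        Relative growth fitness (> 0; ancestor = 1).
    k_n : float
        Kill rate of normal cells during treatment, per hour.
    k_p : float
        Kill rate of persister cells, per hour (k_p <= k_n).
    is_control : bool
        Inert design flag (no phenotypic effect; used for normalization).
    """

    id: str
    pi: float
    w: float = 1.0
    k_n: float = 2.0
    k_p: float = 0.02
    is_control: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise InvalidParameterError(f"pi must be in [0, 1], got {self.pi}")
        if not self.w > 0.0:
            raise InvalidParameterError(f"w must be > 0, got {self.w}")
        if self.k_n < 0.0 or self.k_p < 0.0:
            raise InvalidParameterError("kill rates must be >= 0")
        if self.k_p > self.k_n:
            raise InvalidParameterError(
                f"persisters must die no faster than normal cells (k_p={self.k_p} > k_n={self.k_n})"
            )


#: Ancestral phenotype: endpoint survival of a 5-h treatment ~ pi.
ANCESTOR = GenotypeSpec(id="ancestor", pi=1.5e-4, w=1.0, k_n=2.0, k_p=0.02)


@dataclass(frozen=True)
class DFEParams:
    """Distribution of fitness effects of beneficial persistence mutations.

    Each mutation multiplies the parental persister fraction by
    ``phi ~ log-uniform[phi_min, phi_max]`` (capped at 1) and applies a
    pleiotropic growth cost ``w -> w * (1 - gamma * log10(phi))``.
    """

    phi_min: float = 2.0
    phi_max: float = 1000.0
    gamma: float = 0.03

    def __post_init__(self) -> None:
        if not 1.0 <= self.phi_min <= self.phi_max:
            raise InvalidParameterError("need 1 <= phi_min <= phi_max")
        if self.gamma < 0:
            raise InvalidParameterError("gamma must be >= 0")


@dataclass(frozen=True)
class RegimeConfig:
    """Selection-regime parameters for one serial-transfer experiment."""

    D: float
    n_cycles: int = 18
    N_stat: int = 500_000_000
    treat_hours: float = 5.0
    kill_model: str = "endpoint"
    mu: float = 1e-4
    dfe: DFEParams = field(default_factory=DFEParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.D < 1.0:
            raise InvalidParameterError(f"D must be in (0, 1), got {self.D}")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")
        if self.N_stat < 1:
            raise InvalidParameterError("N_stat must be >= 1")
        if self.treat_hours < 0:
            raise InvalidParameterError("treat_hours must be >= 0")
        if self.kill_model not in ("endpoint", "biphasic"):
            raise InvalidParameterError(f"unknown kill_model {self.kill_model!r}")
        if self.mu < 0:
            raise InvalidParameterError("mu must be >= 0")


@dataclass(frozen=True)
class LibraryConfig:
    """Pooled barcoded knockout-library parameters.

    ``effect_table`` maps design id -> (persister-fraction multiplier,
    growth-fitness multiplier); designs absent from the table are neutral.
    Only ``edit_fraction`` of each design's cells carry the edit; the rest
    are ancestral-phenotype barcode carriers.
    """

    n_designs: int = 4128
    edit_fraction: float = 0.17
    n_controls: int = 15
    effect_table: Mapping[str, tuple[float, float]] | None = None
    n_replicates: int = 8
    depth: int = 1_000_000
    rounds: int = 2
    with_treatment: bool = True

    def __post_init__(self) -> None:
        if self.n_designs < 1:
            raise InvalidParameterError("n_designs must be >= 1")
        if not 0.0 <= self.edit_fraction <= 1.0:
            raise InvalidParameterError("edit_fraction must be in [0, 1]")
        if self.n_controls >= self.n_designs:
            raise InvalidParameterError("n_controls must be < n_designs")
        if self.depth < 1:
            raise InvalidParameterError("depth must be >= 1")
        if self.rounds < 1:
            raise InvalidParameterError("rounds must be >= 1")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")

    def design_ids(self) -> list[str]:
        """Design labels; the last ``n_controls`` are inert controls."""
        width = len(str(self.n_designs - 1))
        ids = [f"d{i:0{width}d}" for i in range(self.n_designs - self.n_controls)]
        ids += [f"ctrl{i:02d}" for i in range(self.n_controls)]
        return ids


@dataclass
class PopulationState:
    """Genotype composition of one population at one point in a cycle."""

    counts: dict[str, int]
    genotypes: dict[str, GenotypeSpec]
    cycle: int = 0
    phase: str = "stationary"

    def __post_init__(self) -> None:
        for gid, n in self.counts.items():
            if n < 0:
                raise InvalidParameterError(f"negative count for genotype {gid!r}")
            if gid not in self.genotypes:
                raise InvalidParameterError(f"genotype {gid!r} has a count but no spec")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def extinct(self) -> bool:
        return self.total == 0

    def frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {}
        return {g: n / tot for g, n in self.counts.items() if n > 0}

    def pruned(self) -> "PopulationState":
        """Drop zero-count genotypes (specs retained only for live ones)."""
        live = {g: n for g, n in self.counts.items() if n > 0}
        return PopulationState(
            counts=live,
            genotypes={g: self.genotypes[g] for g in live},
            cycle=self.cycle,
            phase=self.phase,
        )


@dataclass(frozen=True)
class CycleRecord:
    """Bookkeeping for one treatment-dilution-regrowth cycle."""

    cycle: int
    n_before_treatment: int
    n_after_treatment: int
    n_transferred: int
    persister_fraction: float
    generations_this_cycle: float
    composition: Mapping[str, float]


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def survival_fraction(g: GenotypeSpec, t: float) -> float:
    """Biphasic survival S(t) = (1 - pi) e^(-k_n t) + pi e^(-k_p t).

    Monotone nonincreasing in ``t`` with S(0) = 1; the fast phase is the
    killing of normal cells, the slow tail the killing of persisters.
    """
    if t < 0:
        raise InvalidParameterError(f"treatment duration must be >= 0, got {t}")
    return (1.0 - g.pi) * math.exp(-g.k_n * t) + g.pi * math.exp(-g.k_p * t)


def bottleneck_sample(
    pop: PopulationState, D: float, rng: np.random.Generator
) -> PopulationState:
    """Serial-transfer dilution: each genotype count -> Binomial(n, D).

    ``D`` is the transferred fraction (1:500 dilution -> D = 0.002).
    ``D == 1`` is the identity transfer.
    """
    if not 0.0 < D <= 1.0:
        raise InvalidParameterError(f"dilution ratio must be in (0, 1], got {D}")
    if pop.extinct:
        raise ExtinctionError("cannot dilute an extinct population")
    if D == 1.0:
        new_counts = dict(pop.counts)
    else:
        gids = list(pop.counts)
        n = np.array([pop.counts[g] for g in gids], dtype=np.int64)
        drawn = rng.binomial(n, D)
        new_counts = {g: int(k) for g, k in zip(gids, drawn)}
    return PopulationState(
        counts=new_counts,
        genotypes=dict(pop.genotypes),
        cycle=pop.cycle,
        phase="post-bottleneck",
    ).pruned()


def _survival_probability(g: GenotypeSpec, cfg: RegimeConfig) -> float:
    if cfg.kill_model == "biphasic":
        return survival_fraction(g, cfg.treat_hours)
    return g.pi  # endpoint model: persisters survive, normal cells die


def antibiotic_kill(
    pop: PopulationState, cfg: RegimeConfig, rng: np.random.Generator
) -> PopulationState:
    """High-dose treatment: per-genotype survivors ~ Binomial(n, s_g)."""
    if cfg.treat_hours < 0:
        raise InvalidParameterError("negative treatment duration")
    gids = list(pop.counts)
    n = np.array([pop.counts[g] for g in gids], dtype=np.int64)
    s = np.array([_survival_probability(pop.genotypes[g], cfg) for g in gids])
    drawn = rng.binomial(n, s) if len(gids) else np.array([], dtype=np.int64)
    return PopulationState(
        counts={g: int(k) for g, k in zip(gids, drawn)},
        genotypes=dict(pop.genotypes),
        cycle=pop.cycle,
        phase="post-treatment",
    ).pruned()


def doublings_to_stationary(n_stat: float, n_seed: float) -> float:
    """Reference generations to regrow from ``n_seed`` to ``n_stat`` cells."""
    if n_seed <= 0:
        raise InvalidParameterError("n_seed must be > 0")
    return max(0.0, math.log2(n_stat / n_seed))


def scaled_transfer(n_transferred: float, d_from: float, d_to: float) -> float:
    """Transferred-cell count rescaled to a different dilution of the same pool."""
    for d in (d_from, d_to):
        if not 0.0 < d <= 1.0:
            raise InvalidParameterError(f"dilution ratio must be in (0, 1], got {d}")
    return n_transferred * (d_to / d_from)


def regrow_and_mutate(
    pop: PopulationState, cfg: RegimeConfig, rng: np.random.Generator
) -> tuple[PopulationState, float]:
    """Overnight regrowth to ``N_stat`` with selection on ``w`` and mutation.

    Genotype odds are updated by ``w_g**G`` (G = log2(N_stat / N_seed))
    relative to w = 1, then realized by a single multinomial draw of
    ``N_stat`` cells — a desk-scale shortcut with correct expectations.
    New beneficial mutants arise as Poisson(mu * (N_stat - N_seed)), each
    drawn from the DFE applied to a parent chosen by final abundance.
    """
    n_seed = pop.total
    if n_seed == 0:
        raise ExtinctionError("cannot regrow an extinct population")
    G = doublings_to_stationary(cfg.N_stat, n_seed)

    gids = list(pop.counts)
    counts = np.array([pop.counts[g] for g in gids], dtype=np.float64)
    w = np.array([pop.genotypes[g].w for g in gids])
    weights = counts * np.power(w, G)
    probs = weights / weights.sum()
    final = rng.multinomial(cfg.N_stat, probs)
    new_counts = {g: int(k) for g, k in zip(gids, final)}
    new_genotypes = dict(pop.genotypes)

    n_divisions = max(0, cfg.N_stat - n_seed)
    n_mutants = int(rng.poisson(cfg.mu * n_divisions)) if cfg.mu > 0 else 0
    if n_mutants > 0:
        tot = sum(new_counts.values())
        if tot > 0:
            parent_p = np.array([new_counts[g] for g in gids], dtype=np.float64) / tot
            parents = rng.choice(len(gids), size=n_mutants, p=parent_p)
            log_phi = rng.uniform(
                math.log(cfg.dfe.phi_min), math.log(cfg.dfe.phi_max), size=n_mutants
            )
            for j, pidx in enumerate(parents):
                parent = new_genotypes[gids[pidx]]
                if new_counts[gids[pidx]] == 0:
                    continue  # parent lineage already exhausted by earlier mutants
                phi = math.exp(log_phi[j])
                child = GenotypeSpec(
                    id=f"mut{pop.cycle}_{j}",
                    pi=min(1.0, parent.pi * phi),
                    w=max(1e-6, parent.w * (1.0 - cfg.dfe.gamma * math.log10(phi))),
                    k_n=parent.k_n,
                    k_p=parent.k_p,
                )
                new_counts[gids[pidx]] -= 1
                new_counts[child.id] = 1
                new_genotypes[child.id] = child

    out = PopulationState(
        counts=new_counts, genotypes=new_genotypes, cycle=pop.cycle, phase="stationary"
    ).pruned()
    return out, G


def run_evolution(
    cfg: RegimeConfig,
    rng: np.random.Generator | None = None,
    ancestor: GenotypeSpec = ANCESTOR,
) -> list[CycleRecord]:
    """Run one population through ``cfg.n_cycles`` of kill -> dilute -> regrow.

    Extinction (zero cells after treatment or transfer) terminates the run;
    it is recorded, not raised.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = PopulationState(
        counts={ancestor.id: cfg.N_stat},
        genotypes={ancestor.id: ancestor},
        phase="stationary",
    )
    records: list[CycleRecord] = []
    for cycle in range(cfg.n_cycles):
        pop.cycle = cycle
        n_before = pop.total
        killed = antibiotic_kill(pop, cfg, rng)
        n_after = killed.total
        pf = n_after / n_before
        if n_after == 0:
            records.append(
                CycleRecord(cycle, n_before, 0, 0, pf, 0.0, {})
            )
            break
        transferred = bottleneck_sample(killed, cfg.D, rng)
        n_tr = transferred.total
        if n_tr == 0:
            records.append(
                CycleRecord(cycle, n_before, n_after, 0, pf, 0.0, {})
            )
            break
        pop, G = regrow_and_mutate(transferred, cfg, rng)
        records.append(
            CycleRecord(cycle, n_before, n_after, n_tr, pf, G, pop.frequencies())
        )
    return records


def cumulative_generations(records: Sequence[CycleRecord]) -> float:
    """Total doublings over a run: sum of log2(N_stat / N_transferred).

    Cycles with zero transferred cells (extinction) contribute nothing.
    """
    if not records:
        raise InvalidParameterError("records must be nonempty")
    return sum(
        r.generations_this_cycle for r in records if r.n_transferred > 0
    )


# ---------------------------------------------------------------------------
# Barcoded-library selection
# ---------------------------------------------------------------------------

def sample_effect_table(
    lib: LibraryConfig,
    rng: np.random.Generator,
    fraction_beneficial: float = 0.05,
    phi_min: float = 2.0,
    phi_max: float = 100.0,
    gamma: float = 0.03,
) -> dict[str, tuple[float, float]]:
    """Draw a random effect table: most designs neutral, a few persistence-up.

    Control designs are always neutral. Beneficial designs get a persister
    multiplier phi ~ log-uniform[phi_min, phi_max] and the pleiotropic
    growth cost ``1 - gamma * log10(phi)``.
    """
    table: dict[str, tuple[float, float]] = {}
    for gid in lib.design_ids():
        if gid.startswith("ctrl"):
            table[gid] = (1.0, 1.0)
        elif rng.random() < fraction_beneficial:
            phi = math.exp(rng.uniform(math.log(phi_min), math.log(phi_max)))
            table[gid] = (phi, max(1e-6, 1.0 - gamma * math.log10(phi)))
        else:
            table[gid] = (1.0, 1.0)
    return table


def _library_replicate(
    lib: LibraryConfig,
    cfg: RegimeConfig,
    ancestor: GenotypeSpec,
    pi_mult: np.ndarray,
    w_mult: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate population; returns (before, after) read-count vectors.

    Internally each design is two bins: edited cells (effect applied) and
    unedited barcode carriers with the ancestral phenotype.
    """
    k = lib.n_designs
    init = rng.multinomial(cfg.N_stat, np.full(k, 1.0 / k))
    edited = rng.binomial(init, lib.edit_fraction)
    counts = np.stack([edited, init - edited])  # (2, k): edited, unedited

    pi_e = np.minimum(1.0, ancestor.pi * pi_mult)
    w_e = np.maximum(1e-6, ancestor.w * w_mult)
    if cfg.kill_model == "biphasic":
        s_edited = np.array(
            [
                survival_fraction(
                    replace(ancestor, id="tmp", pi=p), cfg.treat_hours
                )
                for p in pi_e
            ]
        )
        s_unedited = survival_fraction(ancestor, cfg.treat_hours)
    else:
        s_edited = pi_e
        s_unedited = ancestor.pi
    surv = np.stack([s_edited, np.full(k, s_unedited)])
    growth_w = np.stack([w_e, np.full(k, ancestor.w)])

    def design_freq(c: np.ndarray) -> np.ndarray:
        tot = c.sum()
        if tot == 0:
            return np.zeros(k)
        return c.sum(axis=0) / tot

    before_freq = design_freq(counts)
    for _ in range(lib.rounds):
        if counts.sum() == 0:
            break
        if lib.with_treatment:
            counts = rng.binomial(counts, surv)
        counts = rng.binomial(counts, cfg.D)
        tot = counts.sum()
        if tot == 0:
            break
        G = doublings_to_stationary(cfg.N_stat, tot)
        weights = counts * np.power(growth_w, G)
        probs = (weights / weights.sum()).ravel()
        counts = rng.multinomial(cfg.N_stat, probs).reshape(2, k)
    after_freq = design_freq(counts)

    before_reads = rng.multinomial(lib.depth, before_freq)
    if after_freq.sum() > 0:
        after_reads = rng.multinomial(lib.depth, after_freq)
    else:
        after_reads = np.zeros(k, dtype=np.int64)
    return before_reads, after_reads


def simulate_library_selection(
    lib: LibraryConfig,
    cfg: RegimeConfig,
    rng: np.random.Generator | None = None,
    ancestor: GenotypeSpec = ANCESTOR,
):
    """Simulate barcoded-library selection and return a BarcodeCountTable.

    Each replicate starts from an even pool of ``n_designs`` barcodes, runs
    ``lib.rounds`` cycles (treatment skipped when ``with_treatment`` is
    False — the growth-only control arm), and is sequenced before and after
    at ``lib.depth`` reads (multinomial sampling).
    """
    from .barcode_analysis import BarcodeCountTable  # deferred: avoid cycle
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = lib.design_ids()
    effect = lib.effect_table or {}
    pi_mult = np.array([effect.get(g, (1.0, 1.0))[0] for g in ids])
    w_mult = np.array([effect.get(g, (1.0, 1.0))[1] for g in ids])

    streams = rng.spawn(lib.n_replicates)
    data: dict[str, np.ndarray] = {}
    meta_rows = []
    arm = "selection" if lib.with_treatment else "growth-control"
    for r, child in enumerate(streams):
        before, after = _library_replicate(lib, cfg, ancestor, pi_mult, w_mult, child)
        for timepoint, reads in (("before", before), ("after", after)):
            sid = f"rep{r}_{timepoint}"
            data[sid] = reads.astype(np.int64)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "replicate": r,
                    "bottleneck": cfg.D,
                    "timepoint": timepoint,
                    "arm": arm,
                }
            )
    counts = pd.DataFrame(data, index=pd.Index(ids, name="design_id"))
    design_meta = pd.DataFrame(
        {
            "is_control": [g.startswith("ctrl") for g in ids],
            "group": ["control" if g.startswith("ctrl") else "ko" for g in ids],
        },
        index=counts.index,
    )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return BarcodeCountTable(counts=counts, design_meta=design_meta, sample_meta=sample_meta)
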