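"""Cross-link evidence, distance restraints, and the ensemble sampling plan.

Interpeptide cross-links are converted to Cα–Cα upper-bound restraints (mean
15 Å, SD 5 Å) applied symmetrically to every chain of the multimer.  Three
restraint-sampling strategies are supported:

* ``all``      — every experimental restraint on every chain;
* ``reduced``  — a random subset (default 6 of 12) drawn independently per
  chain, giving an asymmetric selection;
* ``random``   — restraints between uniformly drawn residue pairs in the
  modelled region, as a null control.

The :class:`EnsembleManifest` enumerates every (strategy, restraint set,
seed) triple so that any single model of the ensemble can be regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Linker",
    "CrossLink",
    "DistanceRestraint",
    "EnsembleManifest",
    "ManifestEntry",
    "PlanConfig",
    "restraints_from_crosslinks",
    "sample_reduced_restraints",
    "sample_random_restraints",
    "build_ensemble_plan",
    "derive_entry_seed",
]

DEFAULT_RESTRAINT_MEAN = 15.0  # Å
DEFAULT_RESTRAINT_SD = 5.0     # Å


class Linker(str, Enum):
    BS2G = "BS2G"
    DSBU = "DSBU"


@dataclass(frozen=True)
class CrossLink:
    protein: str
    res_a: int
    res_b: int
    linker: Linker
    replicate_ids: tuple[str, ...] = ()
    link_class: str = "interpeptide"  # or "dead_end"

    def __post_init__(self):
        if self.link_class == "interpeptide" and self.res_a == self.res_b:
            raise ValueError("interpeptide cross-link cannot be self-to-self")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.res_a, self.res_b), max(self.res_a, self.res_b))


@dataclass(frozen=True)
class DistanceRestraint:
    res_a: int
    res_b: int
    mean: float = DEFAULT_RESTRAINT_MEAN
    sd: float = DEFAULT_RESTRAINT_SD
    form: str = "upper_bound"

    def __post_init__(self):
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("restraint mean and sd must be positive")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.res_a, self.res_b), max(self.res_a, self.res_b))


def restraints_from_crosslinks(
    xls: list[CrossLink],
    mean: float = DEFAULT_RESTRAINT_MEAN,
    sd: float = DEFAULT_RESTRAINT_SD,
) -> list[DistanceRestraint]:
    """One upper-bound restraint per unique unordered residue pair."""
    seen: set[tuple[int, int]] = set()
    out: list[DistanceRestraint] = []
    for xl in xls:
        if xl.link_class != "interpeptide":
            raise ValueError(
                f"dead-end link at residue {xl.res_a} carries no distance "
                "information; only interpeptide links define restraints"
            )
        if xl.pair in seen:
            continue
        seen.add(xl.pair)
        out.append(DistanceRestraint(res_a=xl.pair[0], res_b=xl.pair[1],
                                     mean=mean, sd=sd))
    return out


def sample_reduced_restraints(xls: list[CrossLink], k: int = 6,
                              seed: int = 0) -> list[CrossLink]:
    """Uniform subset of exactly ``k`` cross-links, without replacement."""
    if not 0 <= k <= len(xls):
        raise ValueError(f"k={k} outside [0, {len(xls)}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(xls), size=k, replace=False)
    return [xls[i] for i in sorted(idx)]


def sample_random_restraints(
    region: tuple[int, int] = (301, 393),
    n: int = 12,
    seed: int = 0,
    mean: float = DEFAULT_RESTRAINT_MEAN,
    sd: float = DEFAULT_RESTRAINT_SD,
    distinct_pairs: bool = False,
) -> list[DistanceRestraint]:
    """``n`` restraints between uniformly drawn distinct residues in the region.

    Duplicate pairs across the set are allowed by default (a pair is drawn
    independently for each restraint); ``distinct_pairs`` enforces uniqueness.
    """
    start, end = region
    if end - start < 1:
        raise ValueError("region must span at least two residues")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    out: list[DistanceRestraint] = []
    seen: set[tuple[int, int]] = set()
    while len(out) < n:
        a, b = rng.choice(np.arange(start, end + 1), size=2, replace=False)
        pair = (int(min(a, b)), int(max(a, b)))
        if distinct_pairs and pair in seen:
            continue
        seen.add(pair)
        out.append(DistanceRestraint(res_a=pair[0], res_b=pair[1],
                                     mean=mean, sd=sd))
    return out


@dataclass(frozen=True)
class ManifestEntry:
    strategy: str              # all | reduced | random
    restraint_set_id: str
    seed: int
    n_models: int
    done: bool = False


@dataclass
class PlanConfig:
    """Ensemble design: counts per strategy (defaults reproduce the published
    12,000 + 100x20 + 100x20 = 16,000 plan)."""
    n_all_models: int = 12000
    n_reduced_sets: int = 100
    n_models_per_reduced_set: int = 20
    n_random_sets: int = 100
    n_models_per_random_set: int = 20
    master_seed: int = 0
    scale_down: int = 1  # uniformly divides total model counts

    def __post_init__(self):
        for v in (self.n_all_models, self.n_reduced_sets,
                  self.n_models_per_reduced_set, self.n_random_sets,
                  self.n_models_per_random_set):
            if v < 0:
                raise ValueError("plan counts must be nonnegative")
        if self.scale_down < 1:
            raise ValueError("scale_down must be >= 1")


@dataclass
class EnsembleManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    config: PlanConfig | None = None

    @property
    def totals(self) -> dict[str, int]:
        t: dict[str, int] = {}
        for e in self.entries:
            t[e.strategy] = t.get(e.strategy, 0) + e.n_models
        return t

    @property
    def grand_total(self) -> int:
        return sum(e.n_models for e in self.entries)


STRATEGY_INDEX = {"all": 0, "reduced": 1, "random": 2}


def derive_entry_seed(master_seed: int, strategy: str, set_index: int) -> int:
    """Deterministic per-entry seed from (master, strategy, set index)."""
    h = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(STRATEGY_INDEX[strategy], set_index),
    )
    return int(h.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _scaled(n_sets: int, per_set: int, factor: int) -> tuple[int, int]:
    """Scale a (sets x models-per-set) block so the total divides by factor."""
    total = n_sets * per_set
    if factor == 1 or total == 0:
        return n_sets, per_set
    new_total = max(total // factor, 1)
    if per_set >= factor:
        return n_sets, per_set // factor
    # fewer sets, one model each
    return min(n_sets, new_total), max(new_total // min(n_sets, new_total), 1)


def build_ensemble_plan(config: PlanConfig | None = None) -> EnsembleManifest:
    """Enumerate manifest entries for the three strategies.

    With the default config: one 'all' block of 12,000 models, 100 reduced
    restraint sets x 20 models, 100 random sets x 20 models.  ``scale_down``
    divides the totals uniformly (factor 100 gives 120 + 20 + 20 = 160).
    """
    cfg = config or PlanConfig()
    entries: list[ManifestEntry] = []

    n_all = cfg.n_all_models // cfg.scale_down if cfg.scale_down > 1 else cfg.n_all_models
    if n_all > 0:
        entries.append(ManifestEntry(
            strategy="all", restraint_set_id="all_000",
            seed=derive_entry_seed(cfg.master_seed, "all", 0),
            n_models=n_all))

    for strategy, n_sets, per_set in (
        ("reduced", cfg.n_reduced_sets, cfg.n_models_per_reduced_set),
        ("random", cfg.n_random_sets, cfg.n_models_per_random_set),
    ):
        s_sets, s_per = _scaled(n_sets, per_set, cfg.scale_down)
        for i in range(s_sets):
            entries.append(ManifestEntry(
                strategy=strategy, restraint_set_id=f"{strategy}_{i:03d}",
                seed=derive_entry_seed(cfg.master_seed, strategy, i),
                n_models=s_per))

    return EnsembleManifest(entries=entries, config=cfg)
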