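"""Clamped fuzzy-cognitive-map iteration engine.

The state of the system is a vector a with one component per concept,
a_i in [-1, 1], 0 the arbitrary baseline.  One update is a sparse
vector-matrix multiplication followed by an odd squashing function:

    a_i' = f(lambda * a_i + sum_j w_ji a_j)        (unlocked concepts)
    a_i' = clamp value                             (locked concepts)

Locked concepts are reasserted after every iteration; that is how protocols
(media/transcription factors ON), gene deletions (locked -1) and drug doses
enter the simulation.  Iteration continues until a fixed point (max-norm
change < epsilon), a detected limit cycle (state recurrence within a
window), or the iteration cap.

Indeterminate ("I") weights are resolved before iteration by a seeded draw
from Uniform[-r, r]; together with optional initial-state jitter this is the
source of replicate-to-replicate variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np

from .errors import (
    EnginePreconditionError,
    FcmError,
    NumericalFailureError,
    UnknownConceptError,
)
from .network import INDETERMINATE, ConceptNetwork, Influence

__all__ = [
    "ClampEntry", "ClampSchedule", "EngineConfig", "Trajectory",
    "ReplicateSet", "resolve_indeterminates", "update_state", "simulate",
    "run_replicates", "derive_seed", "SQUASH_FUNCTIONS", "load_protocol",
]


SQUASH_FUNCTIONS = {
    # odd, range (-1, 1), f(0) = 0, max slope 1
    "tanh": np.tanh,
    # logistic rescaled to (-1, 1); max slope 1/2
    "logistic": lambda x: 2.0 / (1.0 + np.exp(-x)) - 1.0,
}


def derive_seed(*parts: int) -> int:
    """Stable child seed from a master seed and indices (< 2**31)."""
    ss = np.random.SeedSequence(entropy=list(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ClampEntry:
    value: float
    locked: bool = True

    def __post_init__(self):
        if not (-1.0 <= self.value <= 1.0):
            raise FcmError(f"clamp value {self.value} outside [-1, 1]")


class ClampSchedule:
    """Concepts held at fixed values during iteration.

    Locked entries are reasserted after every iteration; unlocked entries
    only set the initial state.
    """

    def __init__(self, entries: Mapping[str, ClampEntry] | None = None):
        self.entries: dict[str, ClampEntry] = dict(entries or {})

    def set(self, cid: str, value: float, locked: bool = True) -> None:
        self.entries[cid] = ClampEntry(float(value), locked)

    def overlay(self, other: "ClampSchedule") -> "ClampSchedule":
        """New schedule where ``other`` wins on conflict (e.g. a knockout or
        drug overlay on top of a base protocol)."""
        merged = dict(self.entries)
        merged.update(other.entries)
        return ClampSchedule(merged)

    def validate(self, net: ConceptNetwork) -> None:
        unknown = [cid for cid in self.entries if cid not in net]
        if unknown:
            raise UnknownConceptError(
                f"clamped concepts not in network: {unknown}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClampSchedule):
            return NotImplemented
        return self.entries == other.entries

    def to_dict(self) -> dict:
        return {cid: {"value": e.value, "locked": e.locked}
                for cid, e in self.entries.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClampSchedule":
        sched = cls()
        for cid, spec in d.items():
            if isinstance(spec, Mapping):
                sched.set(cid, spec["value"], bool(spec.get("locked", True)))
            else:  # bare number means locked
                sched.set(cid, float(spec), True)
        return sched


@dataclass(frozen=True)
class EngineConfig:
    """Engine parameters.

    squash: transfer-function name ('tanh' default, or 'logistic').
    memory: self-contribution lambda in [0, 1] (0 = plain matrix iteration).
    tolerance: epsilon for max-norm convergence / cycle matching.
    max_iterations: iteration cap.
    cycle_window: how far back to look for a recurring state.
    indeterminacy_half_range: r; 'I' weights resolve to Uniform[-r, r].
    initial_jitter: sigma of seeded Gaussian jitter on unlocked initial state.
    seed: master seed for indeterminate resolution and jitter.
    """

    squash: str = "tanh"
    memory: float = 0.0
    tolerance: float = 1e-4
    max_iterations: int = 1000
    cycle_window: int = 50
    indeterminacy_half_range: float = 0.25
    initial_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.squash not in SQUASH_FUNCTIONS:
            raise FcmError(f"unknown squash {self.squash!r}")
        if not (0.0 <= self.memory <= 1.0):
            raise FcmError("memory lambda must lie in [0, 1]")
        if self.tolerance <= 0:
            raise FcmError("tolerance must be > 0")
        if self.max_iterations < 1 or self.cycle_window < 1:
            raise FcmError("max_iterations and cycle_window must be >= 1")
        if not (0.0 <= self.indeterminacy_half_range <= 1.0):
            raise FcmError("indeterminacy half-range must lie in [0, 1]")
        if self.initial_jitter < 0:
            raise FcmError("initial jitter must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EngineConfig":
        return cls(**dict(d))


@dataclass
class Trajectory:
    """Iterated states and their convergence classification.

    ``final_state`` is the fixed point, the element-wise mean over one
    detected cycle, or the last state at the iteration cap.
    """

    concept_ids: list[str]
    states: np.ndarray          # (iterations+1, n) including the initial state
    outcome: str                # fixed_point | limit_cycle | max_iterations
    iterations_to_convergence: int
    final_state: np.ndarray
    cycle_length: int = 0

    def value(self, cid: str) -> float:
        return float(self.final_state[self.concept_ids.index(cid)])

    def final_as_dict(self) -> dict[str, float]:
        return {cid: float(v)
                for cid, v in zip(self.concept_ids, self.final_state)}


@dataclass
class ReplicateSet:
    """Trajectories from distinct seeds under identical network/clamps/config."""

    concept_ids: list[str]
    trajectories: list[Trajectory]

    def __post_init__(self):
        for t in self.trajectories:
            if t.concept_ids != self.concept_ids:
                raise FcmError("replicates must share concept ordering")

    @property
    def k(self) -> int:
        return len(self.trajectories)

    @property
    def final_states(self) -> np.ndarray:
        return np.vstack([t.final_state for t in self.trajectories])

    def mean_final(self) -> np.ndarray:
        return self.final_states.mean(axis=0)

    def dispersion_final(self) -> np.ndarray:
        """Per-concept sample standard deviation (0 when k == 1)."""
        if self.k == 1:
            return np.zeros(len(self.concept_ids))
        return self.final_states.std(axis=0, ddof=1)

    def values(self, cid: str) -> np.ndarray:
        i = self.concept_ids.index(cid)
        return self.final_states[:, i]


# -- operations -------------------------------------------------------------

def resolve_indeterminates(net: ConceptNetwork, seed: int,
                           r: float = 0.25) -> ConceptNetwork:
    """Replace each 'I' weight by a seeded draw from Uniform[-r, r].

    r = 0 maps every indeterminate edge to weight 0, i.e. the edge is
    dropped (zero weights are not storable).  Determinate weights are
    untouched; the same (net, seed, r) always yields the same result.
    """
    if not (0.0 <= r <= 1.0):
        raise FcmError("indeterminacy half-range r must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = ConceptNetwork(net.concepts)
    # iterate in sorted edge order so resolution is independent of insertion
    for e in sorted(net.influences, key=lambda e: (e.source, e.target)):
        if e.is_indeterminate:
            w = float(rng.uniform(-r, r))
            if w == 0.0:
                continue  # degenerate draw: edge vanishes
            out.add_influence(Influence(e.source, e.target, w))
        else:
            out.add_influence(e)
    if r == 0.0:
        # all 'I' edges vanish; rebuild without consuming rng draws
        out = ConceptNetwork(
            net.concepts,
            [e for e in net.influences if not e.is_indeterminate],
        )
    return out


def _initial_state(net: ConceptNetwork, clamps: ClampSchedule,
                   config: EngineConfig) -> np.ndarray:
    n = net.n_concepts
    state = np.zeros(n)
    ids = net.concept_ids
    jitter_mask = np.ones(n, dtype=bool)
    for cid, entry in clamps.entries.items():
        i = ids.index(cid)
        state[i] = entry.value
        jitter_mask[i] = False
    if config.initial_jitter > 0:
        rng = np.random.default_rng(derive_seed(config.seed, 0x6A17))
        state[jitter_mask] += rng.normal(
            0.0, config.initial_jitter, jitter_mask.sum()
        )
        np.clip(state, -1.0, 1.0, out=state)
    return state


def update_state(state: np.ndarray, net: ConceptNetwork,
                 clamps: ClampSchedule | None = None,
                 config: EngineConfig | None = None) -> np.ndarray:
    """One synchronous update of the full state vector."""
    config = config or EngineConfig()
    clamps = clamps or ClampSchedule()
    if net.has_indeterminate():
        raise EnginePreconditionError(
            "network contains unresolved indeterminate weights"
        )
    w_t = net.adjacency().T.tocsr()
    f = SQUASH_FUNCTIONS[config.squash]
    state = np.asarray(state, dtype=float)
    new = f(config.memory * state + w_t @ state)
    for cid, entry in clamps.entries.items():
        if entry.locked:
            new[net.index_of(cid)] = entry.value
    return new


def simulate(net: ConceptNetwork, clamps: ClampSchedule | None = None,
             config: EngineConfig | None = None) -> Trajectory:
    """Iterate to a fixed point, limit cycle, or the iteration cap.

    The initial state is the clamp values where given (locked or not) and 0
    elsewhere, plus optional seeded jitter on unclamped concepts.
    Indeterminate weights are resolved internally with the config seed.
    """
    config = config or EngineConfig()
    clamps = clamps or ClampSchedule()
    clamps.validate(net)
    if net.has_indeterminate():
        net = resolve_indeterminates(
            net, config.seed, config.indeterminacy_half_range
        )

    ids = net.concept_ids
    w_t = net.adjacency().T.tocsr()
    f = SQUASH_FUNCTIONS[config.squash]
    locked_idx = np.array(
        [ids.index(cid) for cid, e in clamps.entries.items() if e.locked],
        dtype=int,
    )
    locked_vals = np.array(
        [e.value for e in clamps.entries.values() if e.locked]
    )

    state = _initial_state(net, clamps, config)
    history = [state.copy()]
    outcome = "max_iterations"
    iterations = config.max_iterations
    final = None
    cycle_len = 0

    for t in range(1, config.max_iterations + 1):
        new = f(config.memory * state + w_t @ state)
        if locked_idx.size:
            new[locked_idx] = locked_vals
        if not np.all(np.isfinite(new)):
            raise NumericalFailureError(t)
        if new.size == 0 or np.max(np.abs(new - state)) < config.tolerance:
            outcome = "fixed_point"
            iterations = t
            final = new
            history.append(new)
            break
        # limit-cycle check: does the new state recur within the window?
        lo = max(0, len(history) - config.cycle_window)
        for back in range(len(history) - 2, lo - 1, -1):
            if np.max(np.abs(new - history[back])) < config.tolerance:
                cycle_len = len(history) - back
                outcome = "limit_cycle"
                iterations = t
                history.append(new)
                final = np.mean(history[-cycle_len - 1:-1], axis=0)
                break
        if outcome == "limit_cycle":
            break
        history.append(new)
        state = new

    if final is None:
        final = history[-1]
    return Trajectory(
        concept_ids=ids,
        states=np.vstack(history),
        outcome=outcome,
        iterations_to_convergence=iterations,
        final_state=np.asarray(final, dtype=float),
        cycle_length=cycle_len,
    )


def run_replicates(net: ConceptNetwork, clamps: ClampSchedule | None = None,
                   config: EngineConfig | None = None, k: int = 3,
                   seed: int | None = None) -> ReplicateSet:
    """k seeded replicate simulations (triplicate by default).

    Per-replicate seeds derive deterministically from (seed, replicate
    index), so the same master seed always reproduces the same set and
    adding replicates never perturbs earlier ones.
    """
    if k < 1:
        raise FcmError("replicate count k must be >= 1")
    config = config or EngineConfig()
    master = config.seed if seed is None else int(seed)
    trajectories = []
    for i in range(k):
        cfg = replace(config, seed=derive_seed(master, i))
        trajectories.append(simulate(net, clamps, cfg))
    return ReplicateSet(net.concept_ids, trajectories)


# -- protocol files ---------------------------------------------------------

def load_protocol(path) -> tuple[ClampSchedule, EngineConfig]:
    """Read a protocol/config file (JSON or YAML).

    Layout::

        {"protocol": {"OCT4": 1.0, ...},             # locked-ON concepts
         "perturbations": {"ARSA": {"value": -1}},   # overlays, win on conflict
         "engine": {"tolerance": 1e-4, ...}}
    """
    text = open(path, encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise FcmError(f"{path}: protocol file must be a mapping")
    sched = ClampSchedule.from_dict(doc.get("protocol", {}))
    sched = sched.overlay(ClampSchedule.from_dict(doc.get("perturbations", {})))
    config = EngineConfig.from_dict(doc.get("engine", {}))
    return sched, config
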