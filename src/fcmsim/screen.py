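"""Drug and drug-combination screening ranked by angular cosine distance.

A drug is a named list of (target concept, action sign) pairs.  A treatment
is one drug or an unordered pair, applied at a dose d (fraction of maximum,
default range 65-85%): each target is clamped locked at action * d on top of
the disease background.  Every treatment is simulated in replicates, its
steady-state values over the disease-profile factors averaged into a profile
vector, and compared to the placebo (empty overlay, "all 0s" treatment
vector) via cosine similarity CS and the angular cosine distance
ACD = arccos(CS)/pi.  Ranking is by ACD descending: the best candidates are
the ones whose profile is as far from the untreated disease profile as
possible (i.e. a mirrored, normalised phenotype).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import ClampSchedule, EngineConfig, derive_seed, run_replicates
from .errors import FcmError, NumericalFailureError, UnknownConceptError
from .network import ConceptNetwork
from .stats import (
    DegenerateTestError,
    ExpectedProfile,
    angular_cosine_distance,
    cosine_similarity,
    paired_t_two_sided,
)

log = logging.getLogger(__name__)

__all__ = [
    "DrugSpec", "Treatment", "ScreenRecord", "load_drug_library",
    "enumerate_treatments", "treatment_to_clamps", "run_screen", "select_top",
    "records_to_frame", "DEFAULT_DOSE_RANGE", "DEFAULT_FIXED_DOSE",
]

DEFAULT_DOSE_RANGE = (0.65, 0.85)
DEFAULT_FIXED_DOSE = 0.75  # the mean of the sampled range
PLACEBO_NAME = "Placebo"


@dataclass(frozen=True)
class DrugSpec:
    """A drug as the set of concepts it activates (+1) or inhibits (-1)."""

    name: str
    targets: tuple[tuple[str, int], ...]
    drug_class: str = ""

    def __post_init__(self):
        if not self.targets:
            raise FcmError(f"drug {self.name!r} has no targets")
        for cid, action in self.targets:
            if action not in (+1, -1):
                raise FcmError(
                    f"drug {self.name!r}: action for {cid!r} must be +1/-1"
                )


@dataclass(frozen=True)
class Treatment:
    """One or two drugs at a common dose (fraction of maximum)."""

    drugs: tuple[DrugSpec, ...]
    dose: float | None = None

    def __post_init__(self):
        if not (1 <= len(self.drugs) <= 2):
            raise FcmError("a treatment holds 1 or 2 drugs")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise FcmError("a treatment cannot repeat a drug")

    @property
    def name(self) -> str:
        return " + ".join(d.name for d in self.drugs)


@dataclass
class ScreenRecord:
    """One treatment's steady-state profile and its distance from placebo."""

    name: str
    treatment: Treatment | None          # None for the placebo record
    profile_vector: np.ndarray
    cs: float
    acd: float
    p_paired: float
    rank: int = 0
    flagged: bool = False


def load_drug_library(path) -> list[DrugSpec]:
    """Read a drug library from JSON (list of objects with name, class,
    targets) or CSV (name, class, targets as 'concept:sign;concept:sign')."""
    path = str(path)
    drugs: list[DrugSpec] = []
    if path.endswith(".json"):
        doc = json.loads(open(path, encoding="utf-8").read())
        for item in doc:
            targets = tuple(
                (str(c), int(a)) for c, a in
                (t if isinstance(t, (list, tuple)) else t.split(":")
                 for t in item["targets"])
            )
            drugs.append(DrugSpec(item["name"], targets,
                                  item.get("class", "")))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0].lower() == "name":
                    continue
                name, drug_class, tfield = row[0], row[1], row[2]
                targets = tuple(
                    (tok.split(":")[0].strip(), int(tok.split(":")[1]))
                    for tok in tfield.split(";") if tok.strip()
                )
                drugs.append(DrugSpec(name.strip(), targets, drug_class.strip()))
    names = [d.name for d in drugs]
    if len(set(names)) != len(names):
        raise FcmError("drug library contains duplicate names")
    return drugs


def enumerate_treatments(library: Sequence[DrugSpec],
                         max_size: int = 2) -> list[Treatment]:
    """All singles plus all unordered pairs: n + n(n-1)/2 treatments for
    max_size 2 (a 41-drug library yields 861)."""
    if max_size not in (1, 2):
        raise FcmError("max_size must be 1 or 2")
    names = [d.name for d in library]
    if len(set(names)) != len(names):
        raise FcmError("drug library contains duplicate names")
    treatments = [Treatment((d,)) for d in library]
    if max_size == 2:
        treatments.extend(Treatment(pair) for pair in combinations(library, 2))
    return treatments


def treatment_to_clamps(treatment: Treatment,
                        dose: float | None = None) -> ClampSchedule:
    """Translate a dosed treatment into a locked clamp overlay.

    Each target is clamped at action * dose.  When two drugs hit the same
    concept with the same sign the larger magnitude wins; with opposite
    signs the contributions are summed (and bounded), and the conflict is
    logged.
    """
    d = treatment.dose if dose is None else dose
    if d is None:
        d = DEFAULT_FIXED_DOSE
    if not (0.0 < d <= 1.0):
        raise FcmError(f"dose {d} outside (0, 1]")
    values: dict[str, float] = {}
    for drug in treatment.drugs:
        for cid, action in drug.targets:
            v = action * d
            if cid in values:
                prev = values[cid]
                if (prev > 0) == (v > 0):
                    values[cid] = max(prev, v, key=abs)
                else:
                    log.warning(
                        "treatment %s: opposing actions on %s; summing",
                        treatment.name, cid,
                    )
                    values[cid] = float(np.clip(prev + v, -1.0, 1.0))
            else:
                values[cid] = v
    sched = ClampSchedule()
    for cid, v in values.items():
        sched.set(cid, v, locked=True)
    return sched


def _profile_vector(net: ConceptNetwork, clamps: ClampSchedule,
                    config: EngineConfig, profile: ExpectedProfile,
                    k_reps: int, seed: int) -> np.ndarray:
    reps = run_replicates(net, clamps, config, k=k_reps, seed=seed)
    mean = reps.mean_final()
    idx = [reps.concept_ids.index(cid) for cid in profile.concept_ids]
    return mean[idx]


def run_screen(net: ConceptNetwork, disease_clamps: ClampSchedule,
               treatments: Sequence[Treatment], profile: ExpectedProfile,
               config: EngineConfig | None = None, k_reps: int = 3,
               dose_mode: str = "sampled",
               dose_range: tuple[float, float] = DEFAULT_DOSE_RANGE,
               fixed_dose: float = DEFAULT_FIXED_DOSE,
               seed: int | None = None) -> list[ScreenRecord]:
    """Simulate every treatment on the disease background and rank by ACD.

    dose_mode 'sampled' draws a dose per treatment and replicate uniformly
    from dose_range with the screen seed; 'fixed' applies fixed_dose
    everywhere (deterministic).  Returns records sorted by ACD descending
    (ties broken by name), ranks 1..n assigned; a placebo record (CS 1,
    ACD 0) is always included.  Treatments whose simulation fails
    numerically are flagged and ranked last.
    """
    config = config or EngineConfig()
    if dose_mode not in ("sampled", "fixed"):
        raise FcmError("dose_mode must be 'sampled' or 'fixed'")
    lo, hi = dose_range
    if not (0.0 < lo <= hi <= 1.0):
        raise FcmError("dose range must satisfy 0 < lo <= hi <= 1")
    master = config.seed if seed is None else int(seed)
    missing = [cid for cid in profile.concept_ids if cid not in net]
    if missing:
        raise UnknownConceptError(f"profile concepts not in network: {missing}")
    for t in treatments:
        for drug in t.drugs:
            unknown = [cid for cid, _ in drug.targets if cid not in net]
            if unknown:
                raise UnknownConceptError(
                    f"drug {drug.name!r} targets unknown concepts: {unknown}"
                )

    placebo_vec = _profile_vector(
        net, disease_clamps, config, profile, k_reps, derive_seed(master, 0)
    )

    records: list[ScreenRecord] = []
    n_tests = 0
    for ti, t in enumerate(treatments, start=1):
        rng = np.random.default_rng(derive_seed(master, ti))
        vecs = []
        flagged = False
        try:
            for rep in range(k_reps):
                if dose_mode == "sampled":
                    dose = float(rng.uniform(lo, hi))
                else:
                    dose = fixed_dose
                overlay = disease_clamps.overlay(treatment_to_clamps(t, dose))
                vecs.append(
                    _profile_vector(net, overlay, config, profile, 1,
                                    derive_seed(master, ti, rep))
                )
            vec = np.mean(vecs, axis=0)
        except NumericalFailureError:
            vec = np.full(profile.n, np.nan)
            flagged = True
        if flagged or not np.any(vec):
            cs, acd, p = float("nan"), float("nan"), float("nan")
            flagged = True
        else:
            cs = cosine_similarity(vec, placebo_vec)
            acd = angular_cosine_distance(cs)
            try:
                p = paired_t_two_sided(vec, placebo_vec)
            except DegenerateTestError:
                p = 1.0
            n_tests += 1
        records.append(ScreenRecord(t.name, t, vec, cs, acd, p,
                                    flagged=flagged))

    records.append(
        ScreenRecord(PLACEBO_NAME, None, placebo_vec, cs=1.0, acd=0.0,
                     p_paired=1.0)
    )
    log.info("screen performed %d paired t-tests (no multiplicity correction)",
             n_tests)

    records.sort(key=lambda r: (r.flagged, -(r.acd if not r.flagged else 0.0),
                                r.name))
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records


def select_top(records: Sequence[ScreenRecord], k: int = 12,
               acd_min: float = 0.972, alpha: float = 1e-5
               ) -> list[ScreenRecord]:
    """First k ranked records with ACD > acd_min and paired p < alpha
    (may return fewer than k)."""
    out = [r for r in records
           if not r.flagged and r.acd > acd_min and r.p_paired < alpha]
    return out[:k]


def records_to_frame(records: Sequence[ScreenRecord],
                     profile: ExpectedProfile) -> pd.DataFrame:
    """Tabular screen output: one row per treatment, per-factor steady-state
    columns, then CS, ACD, paired p and rank."""
    rows = []
    for r in records:
        row = {"rank": r.rank, "treatment": r.name}
        for cid, v in zip(profile.concept_ids, r.profile_vector):
            row[cid] = float(v)
        row.update(cs=r.cs, acd=r.acd, p_value=r.p_paired, flagged=r.flagged)
        rows.append(row)
    return pd.DataFrame(rows)
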