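"""Disease models as clamp overlays and wild-type vs disease comparison.

A gene knockout is expressed as locking the gene concept at -1 (complete
loss of function, the worst case).  Hypomorphic alleles can be expressed by
locking at intermediate negative values, but the default disease operator is
the full knockout.  Conditions are compared per concept across replicate
steady states with the exact Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .engine import ClampSchedule, ReplicateSet
from .errors import FcmError, UnknownConceptError
from .network import ConceptNetwork
from .stats import DEFAULT_DEAD_ZONE, mann_whitney_exact

log = logging.getLogger(__name__)

__all__ = ["gene_knockout", "ConceptComparison", "ConditionComparison",
           "compare_conditions"]


def gene_knockout(net: ConceptNetwork, concept_id: str,
                  value: float = -1.0) -> ClampSchedule:
    """Clamp schedule locking ``concept_id`` OFF (value -1 by default).

    Compose onto a base protocol with ``protocol.overlay(knockout)``; the
    knockout wins on conflict (an override of a protocol-locked concept is
    logged).
    """
    if concept_id not in net:
        raise UnknownConceptError(f"unknown concept {concept_id!r}")
    sched = ClampSchedule()
    sched.set(concept_id, value, locked=True)
    return sched


def apply_knockouts(net: ConceptNetwork, protocol: ClampSchedule,
                    genes: Sequence[str]) -> ClampSchedule:
    """Overlay one or more knockouts onto a base protocol (knockout wins)."""
    merged = protocol
    for gid in genes:
        ko = gene_knockout(net, gid)
        if gid in merged.entries:
            log.info("knockout of %s overrides protocol clamp %s",
                     gid, merged.entries[gid])
        merged = merged.overlay(ko)
    return merged


@dataclass(frozen=True)
class ConceptComparison:
    concept_id: str
    wt_mean: float
    disease_mean: float
    delta: float
    direction: str  # up | down | unchanged
    p_value: float


@dataclass(frozen=True)
class ConditionComparison:
    records: tuple[ConceptComparison, ...]
    dead_zone: float

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, cid: str) -> ConceptComparison:
        for r in self.records:
            if r.concept_id == cid:
                return r
        raise KeyError(cid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "concept": r.concept_id,
                    "wt_mean": r.wt_mean,
                    "disease_mean": r.disease_mean,
                    "delta": r.delta,
                    "direction": r.direction,
                    "p_value": r.p_value,
                }
                for r in self.records
            ]
        )


def compare_conditions(wt: ReplicateSet, disease: ReplicateSet,
                       concepts: Sequence[str] | None = None,
                       dead_zone: float = DEFAULT_DEAD_ZONE,
                       ) -> ConditionComparison:
    """Per-concept wild-type vs disease comparison across replicates.

    Direction is up/down by the sign of (disease mean - wt mean) when |delta|
    exceeds the dead zone, else unchanged.  p comes from the exact two-sided
    Mann-Whitney U on the replicate final values (unpaired, even when seeds
    coincide).
    """
    if wt.concept_ids != disease.concept_ids:
        raise FcmError("condition comparison requires identical concept ordering")
    if concepts is None:
        concepts = wt.concept_ids
    unknown = [c for c in concepts if c not in wt.concept_ids]
    if unknown:
        raise UnknownConceptError(f"concepts not in replicate sets: {unknown}")

    records = []
    for cid in concepts:
        wv = wt.values(cid)
        dv = disease.values(cid)
        delta = float(dv.mean() - wv.mean())
        if abs(delta) <= dead_zone:
            direction = "unchanged"
        else:
            direction = "up" if delta > 0 else "down"
        _, p = mann_whitney_exact(wv, dv)
        records.append(
            ConceptComparison(
                concept_id=cid,
                wt_mean=float(wv.mean()),
                disease_mean=float(dv.mean()),
                delta=delta,
                direction=direction,
                p_value=p,
            )
        )
    return ConditionComparison(tuple(records), dead_zone)
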