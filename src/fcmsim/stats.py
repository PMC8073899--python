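"""Profile scoring and the statistical toolkit for simulation validation.

Covers: the bias-corrected binomial chance probability (how likely a set of
directional predictions succeeds by chance given the system's positive-
prediction bias), the exact two-sided Mann-Whitney U for small replicate
groups, the two-tailed paired t-test, cosine similarity, the angular cosine
distance ACD = arccos(CS)/pi used to rank treatments, and the
at-least-one-success probability for a shortlist of k recommendations.

No multiple-testing correction is applied anywhere; callers performing many
tests should count them (a note is logged by the screen module).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError, FcmError, UndefinedSimilarityError, UnknownConceptError

__all__ = [
    "DEFAULT_POSITIVE_BIAS", "DEFAULT_DEAD_ZONE", "ExpectedProfile",
    "ProfileScore", "chance_probability", "score_profile",
    "mann_whitney_exact", "cosine_similarity", "angular_cosine_distance",
    "paired_t_two_sided", "at_least_one_success",
]

#: Positive-prediction bias of the reference network; overridable wherever
#: it is consumed. Computable from any concrete network via
#: :func:`fcmsim.network.positive_fraction`.
DEFAULT_POSITIVE_BIAS = 0.658

#: Half-width of the "unchanged" band around baseline: activity with
#: |value| <= delta is treated as not expressed either way.
DEFAULT_DEAD_ZONE = 0.05


@dataclass(frozen=True)
class ExpectedProfile:
    """Ordered per-concept expected directions (+1 promoted, -1 inhibited)."""

    entries: tuple[tuple[str, int], ...]
    name: str = ""

    def __post_init__(self):
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise FcmError(f"profile {self.name!r}: duplicate concept ids")
        for cid, d in self.entries:
            if d not in (+1, -1):
                raise FcmError(
                    f"profile {self.name!r}: direction for {cid!r} must be +1/-1"
                )

    @property
    def concept_ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    @property
    def n(self) -> int:
        return len(self.entries)

    def drop(self, ids: Iterable[str]) -> "ExpectedProfile":
        drop = set(ids)
        return ExpectedProfile(
            tuple((c, d) for c, d in self.entries if c not in drop),
            name=self.name,
        )

    # -- serialization (CSV: concept,direction; JSON: list of pairs) -------

    @classmethod
    def from_json(cls, path, name: str | None = None) -> "ExpectedProfile":
        doc = json.loads(open(path, encoding="utf-8").read())
        if isinstance(doc, dict):
            entries = doc["entries"]
            name = name or doc.get("name", "")
        else:
            entries = doc
        return cls(tuple((str(c), int(d)) for c, d in entries), name=name or "")

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ExpectedProfile":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                if row[0].lower() in {"concept", "id"}:
                    continue
                entries.append((row[0].strip(), int(row[1])))
        return cls(tuple(entries), name=name or "")

    def to_json(self, path) -> None:
        doc = {"name": self.name, "entries": [list(e) for e in self.entries]}
        open(path, "w", encoding="utf-8").write(json.dumps(doc, indent=1))


@dataclass(frozen=True)
class ProfileScore:
    """Direction calls of a final state against an expected profile."""

    calls: tuple[tuple[str, int, float, bool], ...]  # (id, expected, value, ok)

    @property
    def n_total(self) -> int:
        return len(self.calls)

    @property
    def n_correct(self) -> int:
        return sum(1 for *_, ok in self.calls if ok)

    @property
    def all_correct(self) -> bool:
        return self.n_correct == self.n_total


def chance_probability(n_pos: int, n_neg: int,
                       p_pos: float = DEFAULT_POSITIVE_BIAS) -> float:
    """Probability that n_pos positive and n_neg negative directional
    predictions all succeed by chance under positive-prediction bias p_pos.

    Returns p_pos**n_pos * (1 - p_pos)**n_neg.  With an all-positive profile
    this is the plain biased binomial p_pos**N.
    """
    if not (0.0 < p_pos < 1.0):
        raise FcmError("p_pos must lie strictly between 0 and 1")
    if n_pos < 0 or n_neg < 0:
        raise FcmError("prediction counts must be >= 0")
    return p_pos ** n_pos * (1.0 - p_pos) ** n_neg


def score_profile(final_state, profile: ExpectedProfile,
                  dead_zone: float = DEFAULT_DEAD_ZONE) -> ProfileScore:
    """Call each profile entry correct iff sign(value) matches the expected
    direction and |value| > dead_zone.  Values inside the dead zone are never
    correct (they are indistinguishable from baseline).

    ``final_state`` is a mapping concept id -> value, or an object with a
    ``final_as_dict`` method (a Trajectory).
    """
    if dead_zone < 0:
        raise FcmError("dead zone must be >= 0")
    if hasattr(final_state, "final_as_dict"):
        final_state = final_state.final_as_dict()
    missing = [cid for cid in profile.concept_ids if cid not in final_state]
    if missing:
        raise UnknownConceptError(f"profile concepts missing from state: {missing}")
    calls = []
    for cid, expected in profile.entries:
        v = float(final_state[cid])
        ok = abs(v) > dead_zone and (v > 0) == (expected > 0)
        calls.append((cid, expected, v, ok))
    return ProfileScore(tuple(calls))


# -- Mann-Whitney -----------------------------------------------------------

_EXACT_PRODUCT_LIMIT = 400
_EXACT_ENUMERATION_LIMIT = 200_000


def _u_from_ranks(rank_sum: float, n_a: int) -> float:
    return rank_sum - n_a * (n_a + 1) / 2.0


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]
                       ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with an exact small-sample null.

    Returns (U of the first sample, two-sided p).  Ties get midranks.  The
    exact p enumerates every assignment of pooled ranks to the first group
    when that is feasible (n_a*n_b <= 400 and C(n_a+n_b, n_a) <= 2e5 — the
    triplicate comparisons this package makes are 3 vs 3); otherwise the
    normal approximation with tie correction and continuity correction is
    used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise FcmError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    u_obs = _u_from_ranks(float(ranks[:n_a].sum()), n_a)

    n = n_a + n_b
    if (n_a * n_b <= _EXACT_PRODUCT_LIMIT
            and math.comb(n, n_a) <= _EXACT_ENUMERATION_LIMIT):
        le = ge = total = 0
        eps = 1e-9
        for idx in combinations(range(n), n_a):
            u = _u_from_ranks(sum(ranks[i] for i in idx), n_a)
            total += 1
            if u <= u_obs + eps:
                le += 1
            if u >= u_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
    else:
        mean = n_a * n_b / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts ** 3) - counts).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            # continuity correction toward the mean
            z = (u_obs - mean - 0.5 * np.sign(u_obs - mean)) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u_obs, float(p)


# -- vector geometry --------------------------------------------------------

def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """dot(u, v) / (|u| |v|), clipped to [-1, 1] against rounding overshoot."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise FcmError("cosine similarity requires equal-length vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError(
            "cosine similarity undefined against a zero vector"
        )
    # (anti-)identical vectors are exact, not 1 - epsilon: a self-comparison
    # must yield a distance of exactly 0
    if np.array_equal(u, v):
        return 1.0
    if np.array_equal(u, -v):
        return -1.0
    return float(np.clip(float(u @ v) / (nu * nv), -1.0, 1.0))


def angular_cosine_distance(cs: float) -> float:
    """ACD = arccos(CS)/pi: 0 at identical direction, 1 at opposition."""
    if not (-1.0 <= cs <= 1.0):
        raise FcmError(f"cosine similarity {cs} outside [-1, 1]")
    return float(math.acos(cs) / math.pi)


def paired_t_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed paired t-test p on n-1 degrees of freedom.

    Raises :class:`DegenerateTestError` when the paired differences have
    zero variance (including x == y), where t is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise FcmError("paired t-test requires equal-length samples, n >= 2")
    d = x - y
    if np.ptp(d) == 0.0:
        raise DegenerateTestError(
            "paired differences are constant; t statistic undefined"
        )
    res = sps.ttest_rel(x, y)
    return float(res.pvalue)


def at_least_one_success(p: float, k: int) -> float:
    """1 - (1-p)**k: probability that at least one of k independent
    recommendations, each correct with probability p, is correct."""
    if not (0.0 <= p <= 1.0):
        raise FcmError("p must lie in [0, 1]")
    if k < 0:
        raise FcmError("k must be >= 0")
    return 1.0 - (1.0 - p) ** k
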