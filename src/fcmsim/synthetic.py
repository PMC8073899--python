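"""Synthetic networks: calibrated random generators and the MLD toy fixture.

The reference gene/protein network behind the published whole-brain-organoid
simulations is proprietary; only its summary statistics are public (4,660
concepts, 43,498 influences, hence mean degree 9.334; positive-edge share
0.658).  :func:`random_network` draws networks matching those statistics so
every pipeline stage is testable.  :func:`mld_fixture` loads a hand-curated
~20-concept metachromatic-leukodystrophy cascade (ARSA deficiency ->
sulfatide accumulation and lysosomal stress -> glial activation ->
demyelination -> neurodegeneration) shipped as plain-text data files; it is
a test harness with qualitatively correct signs, not a disease model of
record.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np

from .engine import ClampSchedule, EngineConfig, load_protocol
from .errors import FcmError
from .network import INDETERMINATE, Concept, ConceptNetwork, Influence, read_network
from .screen import DrugSpec, load_drug_library
from .stats import ExpectedProfile

__all__ = ["GeneratorSpec", "random_network", "MldFixture", "mld_fixture",
           "fixture_dir"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-network generator.

    Defaults reproduce the printed summary statistics of the reference
    network: mean degree > 9.3 and positive-edge fraction 0.658.
    """

    n_concepts: int = 500
    mean_degree: float = 9.334
    pos_fraction: float = 0.658
    ind_fraction: float = 0.0
    weight_range: tuple[float, float] = (0.1, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_concepts < 2:
            raise FcmError("need at least 2 concepts")
        if not (0.0 < self.pos_fraction < 1.0):
            raise FcmError("pos_fraction must lie in (0, 1)")
        if not (0.0 <= self.ind_fraction < 1.0):
            raise FcmError("ind_fraction must lie in [0, 1)")
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi <= 1.0):
            raise FcmError("weight range must be a sub-interval of (0, 1]")
        if self.n_edges > self.n_concepts * (self.n_concepts - 1):
            raise FcmError(
                f"infeasible density: {self.n_edges} edges over "
                f"{self.n_concepts} concepts"
            )

    @property
    def n_edges(self) -> int:
        return int(round(self.n_concepts * self.mean_degree))


def random_network(spec: GeneratorSpec) -> ConceptNetwork:
    """Draw a random signed network.

    Edges are uniform over ordered pairs without self-loops; each edge is
    indeterminate with probability ind_fraction, otherwise positive with
    probability pos_fraction; magnitudes are uniform over the weight range.
    Reproducible by seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_concepts, spec.n_edges
    width = len(str(n - 1))
    concepts = [Concept(f"C{i:0{width}d}", category="gene") for i in range(n)]
    net = ConceptNetwork(concepts)
    ids = [c.id for c in concepts]

    # ordered pairs without self-loops, indexed 0 .. n(n-1)-1
    ks = rng.choice(n * (n - 1), size=m, replace=False)
    indet = rng.random(m) < spec.ind_fraction
    pos = rng.random(m) < spec.pos_fraction
    mags = rng.uniform(spec.weight_range[0], spec.weight_range[1], size=m)
    for k, is_ind, is_pos, mag in zip(ks, indet, pos, mags):
        i, r = divmod(int(k), n - 1)
        j = r if r < i else r + 1
        if is_ind:
            w: float | str = INDETERMINATE
        else:
            w = mag if is_pos else -mag
        net.add_influence(Influence(ids[i], ids[j], w))
    return net


@dataclass(frozen=True)
class MldFixture:
    """Curated MLD toy model: network, reprogramming protocol, expected
    profiles for the healthy (WT) and diseased states, and a toy drug
    library containing a restorative sulfatide-clearance agonist."""

    network: ConceptNetwork
    protocol: ClampSchedule
    engine: EngineConfig
    wt_profile: ExpectedProfile
    mld_profile: ExpectedProfile
    drugs: list[DrugSpec]

    @property
    def screen_profile(self) -> ExpectedProfile:
        """The 9-factor treatment-screen profile (disease profile minus the
        clamped ARSA deletion itself)."""
        return self.mld_profile.drop(["ARSA"])


def fixture_dir():
    """Traversable directory holding the fixture's plain-text data files."""
    return resources.files("fcmsim") / "data" / "mld"


def mld_fixture() -> MldFixture:
    """Load the curated MLD fixture shipped with the package."""
    d = fixture_dir()
    with resources.as_file(d) as p:
        net = read_network(p / "network.tsv", concepts_path=p / "concepts.tsv")
        protocol, engine = load_protocol(p / "protocol.json")
        wt = ExpectedProfile.from_json(p / "profile_wt.json")
        mld = ExpectedProfile.from_json(p / "profile_mld.json")
        drugs = load_drug_library(p / "drugs.json")
    return MldFixture(net, protocol, engine, wt, mld, drugs)


def example_drug_library() -> list[DrugSpec]:
    """The shipped 41-entry drug library (names and classes mirroring the
    published repurposing set; target assignments are illustrative)."""
    with resources.as_file(resources.files("fcmsim") / "data"
                           / "drug_library.json") as p:
        return load_drug_library(p)
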