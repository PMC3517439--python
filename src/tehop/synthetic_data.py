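"""Simulated TE family histories with known ground truth.

The generator emulates the situation the pipeline is built to analyse:
a TE family amplifies in a burst — many copies spawned from one master
element over a short interval — and each copy then decays neutrally and
independently. Under a strict molecular clock at rate ``r``
(substitutions/site/MY) a burst of age ``a`` MYA leaves copies whose
expected K2P distance to the ancestor is ``r * a``, which is exactly the
model under which mean-divergence dating of the burst is unbiased.

Substitutions follow the K80 (Kimura two-parameter) process with
transition/transversion rate ratio ``kappa``: sites evolve independently
and are resampled with the exact finite-time transition probabilities,
so the downstream K2P estimator is the matching inverse of this
generator. A horizontal-transfer scenario plants the same focal family
in a donor and one or more recipient genomes, with the recipient copies
accumulating divergence only since the transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import Sequence, SpeciesTree, write_fasta

__all__ = [
    "BurstScenario",
    "HTScenario",
    "BurstResult",
    "SimulatedDataset",
    "k80_probabilities",
    "mutate_sequence",
    "simulate_burst",
    "simulate_ht_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# transition partner of A,C,G,T; transversions are the two remaining bases
_TRANSITION = {b"A": b"G", b"G": b"A", b"C": b"T", b"T": b"C"}
_TRANSVERSIONS = {
    b"A": (b"C", b"T"),
    b"G": (b"C", b"T"),
    b"C": (b"A", b"G"),
    b"T": (b"A", b"G"),
}


@dataclass
class BurstScenario:
    """One amplification burst: ``copy_count`` copies of a random ancestor.

    ``rate`` is in substitutions/site/MY, ``burst_age`` in MYA, so each
    copy sits at expected distance ``rate * burst_age`` from the
    ancestor. ``kappa`` is the transition/transversion *rate* ratio
    (alpha/beta). ``indel_rate`` is insertion-plus-deletion events per
    site (0 keeps copies alignment-free against the ancestor).
    """

    ancestral_length: int
    burst_age: float
    copy_count: int
    rate: float
    kappa: float = 2.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestral_length <= 0 or self.copy_count < 1:
            raise ValueError("ancestral_length and copy_count must be positive")
        if self.burst_age < 0 or self.rate < 0 or self.indel_rate < 0:
            raise ValueError("ages and rates must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class HTScenario:
    """A horizontal-transfer experiment on a species tree.

    Each genome in ``calibration_bursts`` receives its own independent
    old calibration family. The focal family descends from one ancestral
    element: the native lineage has carried it since ``focal_burst.burst_age``,
    recipients only since ``transfer_age``.
    """

    species_tree: SpeciesTree
    native_lineage: str
    recipient_lineages: list[str]
    transfer_age: float
    calibration_bursts: dict[str, BurstScenario]
    focal_burst: BurstScenario
    focal_family: str = "focal"
    calibration_family: str = "calib"

    def __post_init__(self) -> None:
        leaves = set(self.species_tree.leaf_labels())
        for lab in [self.native_lineage, *self.recipient_lineages]:
            if lab not in leaves:
                raise ValueError(f"lineage not in species tree: {lab}")
        if self.transfer_age > self.focal_burst.burst_age:
            raise ValueError("transfer cannot predate the focal family's origin")


@dataclass
class BurstResult:
    ancestor: Sequence
    copies: list[Sequence]
    scenario: BurstScenario


@dataclass
class SimulatedDataset:
    """Copies per (genome, family) plus the ground-truth table."""

    copies: dict[tuple[str, str], list[Sequence]]
    ancestors: dict[tuple[str, str], Sequence]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (genome, family), seqs in sorted(self.copies.items()):
            write_fasta(seqs, outdir / f"{genome}.{family}.copies.fasta")
        self.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def k80_probabilities(distance: float, kappa: float) -> tuple[float, float]:
    """Exact K80 substitution probabilities at total divergence ``distance``.

    With beta = 1/(kappa+2) and alpha = kappa/(kappa+2) (so the total
    rate alpha + 2 beta = 1 and time equals distance), the probability
    that a site shows a transition is
    ``P = 1/4 + 1/4 exp(-4 beta d) - 1/2 exp(-2 (alpha+beta) d)`` and the
    total transversion probability is ``Q = 1/2 - 1/2 exp(-4 beta d)``.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa / (kappa + 2.0)
    e1 = math.exp(-4.0 * beta * distance)
    e2 = math.exp(-2.0 * (alpha + beta) * distance)
    P = 0.25 + 0.25 * e1 - 0.5 * e2
    Q = 0.5 - 0.5 * e1
    return P, Q


def mutate_sequence(
    seq: Sequence,
    distance: float,
    kappa: float,
    rng: np.random.Generator,
) -> Sequence:
    """Resample every site of a gap-free sequence under the K80 model.

    Each site independently becomes a transition with probability
    ``P(distance)``, one of the two transversion bases (equiprobable)
    with probability ``Q(distance)``, and stays unchanged otherwise.
    The K2P estimator applied to (input, output) converges to
    ``distance`` as the length grows.
    """
    if "-" in seq.residues:
        raise ValueError("mutate_sequence requires a gap-free sequence")
    P, Q = k80_probabilities(distance, kappa)
    arr = seq.as_array().copy()
    u = rng.random(arr.shape[0])
    is_ts = u < P
    is_tv = (u >= P) & (u < P + Q)
    tv_pick = rng.integers(0, 2, size=arr.shape[0])
    out = arr.copy()
    for base in (b"A", b"C", b"G", b"T"):
        here = arr == base
        out[here & is_ts] = _TRANSITION[base]
        tvs = _TRANSVERSIONS[base]
        out[here & is_tv & (tv_pick == 0)] = tvs[0]
        out[here & is_tv & (tv_pick == 1)] = tvs[1]
    return Sequence(seq.id, out.tobytes().decode("ascii"))


def _apply_indels(residues: str, indel_rate: float, rng: np.random.Generator) -> str:
    """Geometric-length (mean 3) insertions/deletions applied uniformly."""
    if indel_rate <= 0:
        return residues
    n_events = rng.poisson(indel_rate * len(residues))
    s = residues
    for _ in range(n_events):
        length = int(rng.geometric(1.0 / 3.0))
        pos = int(rng.integers(0, max(len(s), 1)))
        if rng.random() < 0.5:  # deletion
            s = s[:pos] + s[pos + length :]
        else:  # insertion of random bases
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            s = s[:pos] + ins + s[pos:]
        if not s:
            s = "A"  # degenerate guard; practically unreachable at sane rates
    return s


def random_ancestor(length: int, rng: np.random.Generator, seq_id: str = "ancestor") -> Sequence:
    """Uniform-composition random ancestor sequence."""
    return Sequence(seq_id, _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii"))


def simulate_burst(
    scenario: BurstScenario,
    rng: Optional[np.random.Generator] = None,
    ancestor: Optional[Sequence] = None,
    copy_age: Optional[float] = None,
    prefix: str = "copy",
) -> BurstResult:
    """Simulate one amplification burst (star phylogeny of copies).

    Copies are independent K80 draws from the ancestor at distance
    ``rate * burst_age`` (or ``rate * copy_age`` when the copies have
    evolved for a different time than the family has existed, as for a
    horizontally transferred family). Indels, if enabled, are applied
    after substitution.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if ancestor is None:
        ancestor = random_ancestor(scenario.ancestral_length, rng)
    age = scenario.burst_age if copy_age is None else copy_age
    d = scenario.rate * age
    copies = []
    for i in range(scenario.copy_count):
        c = mutate_sequence(ancestor, d, scenario.kappa, rng)
        residues = _apply_indels(c.residues, scenario.indel_rate, rng)
        copies.append(Sequence(f"{prefix}{i+1}", residues))
    return BurstResult(ancestor=ancestor, copies=copies, scenario=scenario)


def simulate_ht_scenario(
    scenario: HTScenario,
    outdir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> SimulatedDataset:
    """Simulate calibration and focal families across genomes.

    Every genome named in ``calibration_bursts`` gets an independent
    calibration burst at that burst's own age. The focal family shares a
    single ancestral element: the native lineage's copies sit at
    ``rate * burst_age`` from it, recipients at ``rate * transfer_age``.
    The ground-truth table records the true age of every (genome,
    family) observation and the HT edge. Deterministic for a fixed seed;
    files are written only when ``outdir`` is given.
    """
    master = np.random.default_rng(scenario.focal_burst.seed if seed is None else seed)
    copies: dict[tuple[str, str], list[Sequence]] = {}
    ancestors: dict[tuple[str, str], Sequence] = {}
    rows = []

    for genome in sorted(scenario.calibration_bursts):
        burst = scenario.calibration_bursts[genome]
        res = simulate_burst(burst, rng=master, prefix=f"{genome}_{scenario.calibration_family}_")
        copies[(genome, scenario.calibration_family)] = res.copies
        ancestors[(genome, scenario.calibration_family)] = res.ancestor
        rows.append(
            dict(genome=genome, family=scenario.calibration_family, true_age=burst.burst_age,
                 rate=burst.rate, n_copies=len(res.copies), ht_from="")
        )

    focal_ancestor = random_ancestor(scenario.focal_burst.ancestral_length, master, seq_id="focal_ancestor")
    for genome in [scenario.native_lineage, *scenario.recipient_lineages]:
        native = genome == scenario.native_lineage
        age = scenario.focal_burst.burst_age if native else scenario.transfer_age
        res = simulate_burst(
            scenario.focal_burst,
            rng=master,
            ancestor=focal_ancestor,
            copy_age=age,
            prefix=f"{genome}_{scenario.focal_family}_",
        )
        copies[(genome, scenario.focal_family)] = res.copies
        ancestors[(genome, scenario.focal_family)] = focal_ancestor
        rows.append(
            dict(genome=genome, family=scenario.focal_family, true_age=age,
                 rate=scenario.focal_burst.rate, n_copies=len(res.copies),
                 ht_from="" if native else scenario.native_lineage)
        )

    truth = pd.DataFrame(rows)
    ds = SimulatedDataset(copies=copies, ancestors=ancestors, truth=truth)
    if outdir is not None:
        ds.write(outdir)
    return ds
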