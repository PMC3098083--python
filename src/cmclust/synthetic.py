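"""Seeded generators with known ground truth for every pipeline stage.

Three families of fixtures, each mirroring one of the toolkit's real
inputs:

* planted-partition distance matrices — items fall into groups, with
  intra-group distances drawn uniformly around a small mean and
  inter-group distances around a much larger one (the regime in which
  a family of related protein structures separates into classes);
* point-charge potential-grid families — each group shares a base
  charge system, members perturb the charges with Gaussian noise, and
  potentials come from the naive Coulomb generator, so within-group
  Hodgkin similarity approaches 1 as the noise vanishes;
* mutated sequence families — group ancestors differ from a common base
  sequence by many substitutions, members differ from their ancestor by
  few, so within-group alignment identity exceeds between-group
  identity.

All generators are bit-reproducible under a fixed seed.  Cluster sizes
default to at least six members: the coupled-map dynamics synchronizes
robustly inside groups of four or more maps, while pairs and triples
exchange orbits instead of synchronizing (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrostatics import (
    ChargeSystem,
    GridGeometry,
    PotentialGrid,
    coulomb_potential,
    default_geometry,
)
from .matrices import LabeledSquareMatrix

__all__ = [
    "PlantedPartitionSpec",
    "planted_distances",
    "charge_family_grids",
    "mutated_sequence_family",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Planted-partition distances: uniform noise around two means.

    Intra-group distances are drawn from [intra_mean - intra_spread,
    intra_mean + intra_spread], inter-group likewise; uniform noise
    keeps every draw trivially non-negative provided spread < mean.
    """

    sizes: tuple[int, ...] = (10, 10)
    intra_mean: float = 0.1
    intra_spread: float = 0.02
    inter_mean: float = 2.0
    inter_spread: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) == 0 or any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")
        if sum(self.sizes) < 2:
            raise ValueError("need at least two items in total")
        if self.inter_mean <= self.intra_mean:
            raise ValueError("inter-cluster mean must exceed intra-cluster mean")
        if self.intra_spread >= self.intra_mean or self.inter_spread >= self.inter_mean:
            raise ValueError("spread must be smaller than its mean (distances must stay positive)")
        if self.intra_spread < 0 or self.inter_spread < 0:
            raise ValueError("spreads must be non-negative")


def planted_distances(
    spec: PlantedPartitionSpec,
) -> tuple[LabeledSquareMatrix, np.ndarray]:
    """Distance matrix with a planted group structure plus true labels."""
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.sizes)
    truth = np.repeat(np.arange(len(spec.sizes)), spec.sizes)
    same = truth[:, None] == truth[None, :]
    intra = rng.uniform(
        spec.intra_mean - spec.intra_spread, spec.intra_mean + spec.intra_spread, (n, n)
    )
    inter = rng.uniform(
        spec.inter_mean - spec.inter_spread, spec.inter_mean + spec.inter_spread, (n, n)
    )
    d = np.where(same, intra, inter)
    d = np.triu(d, k=1)
    d = d + d.T
    labels = tuple(f"item{i:03d}" for i in range(n))
    return LabeledSquareMatrix(labels, d, "distance"), truth


def _random_charge_system(
    rng: np.random.Generator, n_charges: int, extent: float
) -> ChargeSystem:
    positions = rng.uniform(-extent / 2.0, extent / 2.0, size=(n_charges, 3))
    charges = rng.normal(0.0, 1.0, size=n_charges)
    radii = np.full(n_charges, 1.5)
    return ChargeSystem(positions, charges, radii)


def charge_family_grids(
    n_groups: int = 2,
    members_per_group: int = 6,
    charges_per_item: int = 20,
    perturbation_sigma: float = 0.05,
    geometry: GridGeometry | None = None,
    seed: int = 0,
    extent: float = 15.0,
) -> tuple[list[PotentialGrid], list[str], np.ndarray]:
    """Families of Coulomb potential grids with planted group structure.

    Each group has its own base charge system (random positions in a
    central box, standard-normal charges); members copy the base and add
    N(0, sigma) noise to every charge, so grids within a group are
    nearly parallel scalar fields and their Hodgkin similarity tends to
    1 as sigma tends to 0.  Returns (grids, labels, true group ids).
    """
    if perturbation_sigma < 0:
        raise ValueError("perturbation sigma must be >= 0")
    if geometry is None:
        geometry = default_geometry()
    rng = np.random.default_rng(seed)
    grids: list[PotentialGrid] = []
    labels: list[str] = []
    truth: list[int] = []
    for g in range(n_groups):
        base = _random_charge_system(rng, charges_per_item, extent)
        for m in range(members_per_group):
            q = base.charges + rng.normal(0.0, perturbation_sigma, size=len(base))
            member = ChargeSystem(base.positions, q, base.radii)
            grids.append(coulomb_potential(member, geometry))
            labels.append(f"g{g}m{m:02d}")
            truth.append(g)
    return grids, labels, np.asarray(truth)


def mutated_sequence_family(
    base_length: int = 167,
    n_groups: int = 2,
    members_per_group: int = 6,
    within_subs: int = 1,
    between_subs: int = 30,
    seed: int = 0,
) -> tuple[dict[str, str], np.ndarray]:
    """Sequence families derived from one ancestor by point substitutions.

    A single random base sequence is drawn per run; each group ancestor
    differs from it at ``between_subs`` seeded positions, and each
    member differs from its group ancestor at ``within_subs`` positions.
    Substitutions are uniform over the 19 non-identical residues.
    Returns ({label: sequence}, true group ids).
    """
    if between_subs <= within_subs:
        raise ValueError("between_subs must exceed within_subs")
    if between_subs > base_length or within_subs > base_length:
        raise ValueError("substitution counts cannot exceed the sequence length")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    base = rng.choice(alphabet, size=base_length)

    def mutate(seq: np.ndarray, n_subs: int) -> np.ndarray:
        out = seq.copy()
        positions = rng.choice(base_length, size=n_subs, replace=False)
        for pos in positions:
            options = [a for a in AMINO_ACIDS if a != out[pos]]
            out[pos] = options[rng.integers(len(options))]
        return out

    sequences: dict[str, str] = {}
    truth: list[int] = []
    for g in range(n_groups):
        ancestor = mutate(base, between_subs)
        for m in range(members_per_group):
            member = mutate(ancestor, within_subs) if within_subs else ancestor.copy()
            sequences[f"g{g}m{m:02d}"] = "".join(member)
            truth.append(g)
    return sequences, np.asarray(truth)
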