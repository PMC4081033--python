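"""Domain types for the generalized 1D lattice model of competitive DNA binding.

The DNA is a lattice of ``N`` base-pair units.  Each of ``f`` protein species
``g`` is characterized by the number of lattice units it covers when bound
(its footprint ``m(g)``), a dimensionless activity ``a(g) = K(g) * c0(g)``
(binding constant times free concentration) and, optionally, a per-position
relative affinity track ``K(n, g)`` indexed by the leftmost unit of the
fully-wrapped binding frame.

A *placement* is a bound particle ``(g, n, h1, h2)``: species ``g`` whose
nominal frame starts at ``n`` and which is unwrapped by ``h1`` bp from its
left end and ``h2`` bp from its right end (``h1 + h2 <= h_max``).  The
covered interval is ``[n + h1, n + m - h2)``; the unwrapped stretches of the
frame remain accessible to other particles.  A configuration is any set of
placements with pairwise-disjoint covered intervals; its statistical weight
is the product of per-particle weights ``a * K(n) * eps_u**(h1+h2)`` and of
pairwise interaction factors ``w(L, g1, g2)`` between neighboring particles,
where ``L`` is the uncovered distance between their covered edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

HARD_WALL = "hard_wall"
CYCLIC = "cyclic"


class LatticeModelError(ValueError):
    """Invalid model specification."""


@dataclass(frozen=True)
class UnwrapSpec:
    """Reversible peeling of DNA from a particle's ends.

    Parameters
    ----------
    h_max:
        Maximum total unwrapping ``h1 + h2`` in bp; must be smaller than the
        footprint.
    per_bp_penalty:
        Multiplicative Boltzmann factor per unwrapped bp (``eps_u``).  The
        default 1.0 treats unwrapping as a pure entropy of accessible states;
        values < 1 penalize breaking histone-DNA contacts.
    """

    h_max: int
    per_bp_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.h_max < 0:
            raise LatticeModelError(f"h_max must be >= 0, got {self.h_max}")
        if not (self.per_bp_penalty > 0):
            raise LatticeModelError("per_bp_penalty must be > 0")

    def states(self) -> list[tuple[int, int]]:
        """All allowed (h1, h2) unwrapping states."""
        return [
            (h1, h2)
            for t in range(self.h_max + 1)
            for h1 in range(t + 1)
            for h2 in [t - h1]
        ]


@dataclass(frozen=True)
class SpeciesSpec:
    """One DNA-binding species.

    ``activity`` is the dimensionless product ``K * c0``.  Alternatively give
    ``binding_constant`` (per molar) and ``concentration`` (molar), which are
    multiplied on load.
    """

    id: str
    footprint: int
    activity: float | None = None
    binding_constant: float | None = None
    concentration: float | None = None
    unwrap: UnwrapSpec | None = None
    is_nucleosome: bool = False

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise LatticeModelError(f"footprint must be >= 1, got {self.footprint}")
        if self.activity is None:
            if self.binding_constant is None or self.concentration is None:
                raise LatticeModelError(
                    f"species {self.id!r}: give either activity or both "
                    "binding_constant and concentration"
                )
        elif self.binding_constant is not None or self.concentration is not None:
            raise LatticeModelError(
                f"species {self.id!r}: activity and K/c0 are mutually exclusive"
            )
        if self.a < 0:
            raise LatticeModelError(f"species {self.id!r}: activity must be >= 0")
        if self.unwrap is not None and self.unwrap.h_max >= self.footprint:
            raise LatticeModelError(
                f"species {self.id!r}: h_max must be < footprint"
            )

    @property
    def a(self) -> float:
        """Dimensionless activity K*c0."""
        if self.activity is not None:
            return float(self.activity)
        return float(self.binding_constant) * float(self.concentration)

    @property
    def h_max(self) -> int:
        return 0 if self.unwrap is None else self.unwrap.h_max

    @property
    def eps_u(self) -> float:
        return 1.0 if self.unwrap is None else self.unwrap.per_bp_penalty

    def covered_lengths(self) -> list[int]:
        """Possible covered lengths, longest (fully wrapped) first."""
        return [self.footprint - t for t in range(self.h_max + 1)]


@dataclass(frozen=True)
class InteractionRule:
    """Distance-dependent statistical weight between a pair of species.

    ``w_values`` maps the uncovered gap ``L`` (bp between the covered edges of
    the two particles, ``L >= 0``) to a multiplicative weight; any gap not in
    the map has weight 1.  The rule is symmetric in the two species.
    """

    pair: tuple[str, str]
    w_values: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(self.pair))
        if len(self.pair) != 2:
            raise LatticeModelError("pair must name exactly two species")
        for gap, w in self.w_values.items():
            if gap < 0:
                raise LatticeModelError(f"interaction gap must be >= 0, got {gap}")
            if w < 0 or not np.isfinite(w):
                raise LatticeModelError(f"interaction weight w({gap}) must be >= 0")

    @property
    def range(self) -> int:
        """Largest gap with weight != 1 (0 for a trivial rule)."""
        nontrivial = [gap for gap, w in self.w_values.items() if w != 1.0]
        return max(nontrivial, default=0)

    def involves(self, g1: str, g2: str) -> bool:
        return {g1, g2} == set(self.pair) or (
            g1 == g2 and self.pair[0] == self.pair[1] == g1
        )

    @classmethod
    def contact(cls, g1: str, g2: str, omega: float) -> "InteractionRule":
        """McGhee-von Hippel contact cooperativity: w(0) = omega, else 1."""
        return cls((g1, g2), {0: float(omega)})

    @classmethod
    def exclusion(cls, g1: str, g2: str, v: int) -> "InteractionRule":
        """Long-range anticooperativity: binding prohibited at gaps < V."""
        return cls((g1, g2), {gap: 0.0 for gap in range(int(v))})


@dataclass(frozen=True)
class LinkerCapRule:
    """Limit on linker-protein (H1-like) binding around nucleosomes.

    Every linker particle must be assignable to a nucleosome adjacent to it
    in the left-to-right particle order (only other linkers in between), with
    at most ``cap`` linkers per nucleosome.  When ``allow_free_binding`` is
    False the linker must additionally lie *entirely* within ``vicinity`` bp
    of the covered edge of its assigned nucleosome (its far edge at most
    ``vicinity`` bp away), i.e. linker binding away from nucleosomes is
    prohibited and the vicinity is a zone the whole molecule occupies.
    """

    linker: str
    nucleosome: str
    cap: int = 1
    vicinity: int = 0
    allow_free_binding: bool = False

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise LatticeModelError("cap must be >= 1")
        if self.vicinity < 0:
            raise LatticeModelError("vicinity must be >= 0")


@dataclass
class LatticeModel:
    """A DNA segment plus species, affinity tracks and interaction rules."""

    N: int
    species: Sequence[SpeciesSpec]
    affinity: Mapping[str, np.ndarray] = field(default_factory=dict)
    interactions: Sequence[InteractionRule] = ()
    linker_cap: LinkerCapRule | None = None
    boundary: str = HARD_WALL

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.affinity = {k: np.asarray(v, dtype=float) for k, v in self.affinity.items()}
        self.interactions = list(self.interactions)
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if self.boundary not in (HARD_WALL, CYCLIC):
            raise LatticeModelError(f"unknown boundary {self.boundary!r}")
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise LatticeModelError("species ids must be unique")
        if self.species and self.N < max(s.footprint for s in self.species):
            raise LatticeModelError("lattice shorter than the largest footprint")
        for key, track in self.affinity.items():
            if key not in ids:
                raise LatticeModelError(f"affinity track for unknown species {key!r}")
            if track.shape != (self.N,):
                raise LatticeModelError(
                    f"affinity track for {key!r} has length {track.shape}, "
                    f"expected ({self.N},)"
                )
            if not np.all(np.isfinite(track)) or np.any(track < 0):
                raise LatticeModelError(
                    f"affinity track for {key!r} must be finite and >= 0"
                )
        for rule in self.interactions:
            for g in rule.pair:
                if g not in ids:
                    raise LatticeModelError(f"interaction names unknown species {g!r}")
        if self.boundary == CYCLIC and self.max_interaction_range() >= self.N:
            raise LatticeModelError(
                "interaction range must be < N under cyclic boundary "
                "(wrap-around pairing would be ambiguous)"
            )
        if self.linker_cap is not None:
            for g in (self.linker_cap.linker, self.linker_cap.nucleosome):
                if g not in ids:
                    raise LatticeModelError(f"linker cap names unknown species {g!r}")
            if self.linker_cap.linker == self.linker_cap.nucleosome:
                raise LatticeModelError("linker and nucleosome species must differ")
            if self.boundary == CYCLIC:
                raise LatticeModelError(
                    "linker cap rules are not supported under cyclic boundary"
                )

    # -- helpers -------------------------------------------------------

    def get_species(self, gid: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == gid:
                return s
        raise KeyError(gid)

    def affinity_track(self, gid: str) -> np.ndarray:
        """K(n, g) indexed by frame start; homogeneous tracks default to 1."""
        track = self.affinity.get(gid)
        if track is None:
            return np.ones(self.N)
        return track

    def max_interaction_range(self) -> int:
        return max((r.range for r in self.interactions), default=0)

    def pair_weights(self, g1: str, g2: str, max_gap: int) -> np.ndarray:
        """w(L, g1, g2) for L = 0..max_gap as a dense vector (default 1)."""
        w = np.ones(max_gap + 1)
        for rule in self.interactions:
            if rule.involves(g1, g2):
                for gap, val in rule.w_values.items():
                    if gap <= max_gap:
                        w[gap] = val
        return w


@dataclass
class LatticeSolution:
    """Exact equilibrium marginals of a :class:`LatticeModel`.

    Attributes
    ----------
    start_prob:
        Per species, ``start_prob[g][n]`` is the probability that a particle
        of species ``g`` (any unwrapping state) has its nominal frame start
        at ``n``.
    coverage:
        ``coverage[g][n]`` is the probability that lattice unit ``n`` is
        covered by species ``g``.
    free_prob:
        Probability that unit ``n`` is uncovered by every species.
    log_partition:
        Natural log of the grand partition function (empty lattice = 0).
    """

    species_ids: list[str]
    start_prob: dict[str, np.ndarray]
    coverage: dict[str, np.ndarray]
    free_prob: np.ndarray
    log_partition: float

    @property
    def total_coverage(self) -> np.ndarray:
        return sum(self.coverage.values())

    def occupancy(self, gid: str) -> np.ndarray:
        return self.coverage[gid]

    def nucleosome_occupancy(self, model: LatticeModel) -> np.ndarray:
        """Coverage of the species flagged is_nucleosome (or the first one)."""
        for s in model.species:
            if s.is_nucleosome:
                return self.coverage[s.id]
        return self.coverage[model.species[0].id]
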