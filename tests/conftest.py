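import numpy as np
import pytest

from nuclattice.model import (
    InteractionRule,
    LatticeModel,
    LinkerCapRule,
    SpeciesSpec,
    UnwrapSpec,
)


def random_small_model(rng: np.random.Generator) -> LatticeModel | None:
    """A random lattice instance small enough for brute-force enumeration.

    Covers 1-2 species, optional unwrapping, affinity tracks, contact /
    exclusion / tabulated interactions, linker-cap rules and both
    boundaries.  Returns None when the draw is internally inconsistent.
    """
    N = int(rng.integers(6, 13))
    ns = int(rng.integers(1, 3))
    species = []
    for i in range(ns):
        m = int(rng.integers(3, 6))
        m = min(m, N)
        hm = int(rng.integers(0, min(3, m)))
        uw = UnwrapSpec(hm, float(rng.uniform(0.5, 1.5))) if hm else None
        species.append(
            SpeciesSpec(
                f"S{i}", m, activity=float(rng.uniform(0.0, 2.0)),
                unwrap=uw, is_nucleosome=(i == 0),
            )
        )
    affinity = {}
    if rng.random() < 0.6:
        affinity["S0"] = rng.uniform(0.0, 2.0, N)
    interactions = []
    if rng.random() < 0.7:
        i, j = rng.integers(0, ns, 2)
        kind = rng.random()
        if kind < 0.4:
            interactions.append(
                InteractionRule.contact(f"S{i}", f"S{j}", float(rng.uniform(0.0, 6.0)))
            )
        elif kind < 0.7:
            interactions.append(
                InteractionRule.exclusion(f"S{i}", f"S{j}", int(rng.integers(1, 4)))
            )
        else:
            interactions.append(
                InteractionRule(
                    (f"S{i}", f"S{j}"),
                    {int(g): float(rng.uniform(0.0, 3.0)) for g in rng.integers(0, 4, 2)},
                )
            )
    boundary = "cyclic" if rng.random() < 0.25 else "hard_wall"
    cap = None
    if ns == 2 and boundary == "hard_wall" and rng.random() < 0.5:
        cap = LinkerCapRule(
            linker="S1", nucleosome="S0",
            cap=int(rng.integers(1, 3)),
            vicinity=int(rng.integers(0, 4)),
            allow_free_binding=bool(rng.random() < 0.4),
        )
    try:
        return LatticeModel(
            N=N, species=species, affinity=affinity,
            interactions=interactions, linker_cap=cap, boundary=boundary,
        )
    except Exception:
        return None


@pytest.fixture
def rng():
    return np.random.default_rng(20140703)
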