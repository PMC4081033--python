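"""Brute-force enumeration oracle for small lattice models.

Enumerates every configuration explicitly — each placement resolved to its
individual unwrapping state ``(g, n, h1, h2)`` — and accumulates exact
marginals.  Linker-cap legality is decided by exhaustive search over
non-crossing linker-to-nucleosome assignments, independently of the greedy
canonicalization used by the dynamic-programming solver, so the two
implementations cross-validate each other.

Only instances whose configuration count stays below a cap are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CYCLIC, LatticeModel, LatticeModelError, LatticeSolution

DEFAULT_MAX_CONFIGS = 10_000_000


class BruteForceTooLarge(RuntimeError):
    """Enumeration would exceed the configuration cap."""


@dataclass(frozen=True)
class _Placement:
    gi: int
    n: int          # frame start (absolute; may imply wrap under cyclic)
    h1: int
    h2: int
    s: int          # covered start (mod N under cyclic)
    ell: int
    weight: float
    mask: int       # bitmask of covered lattice units


def _enumerate_placements(model: LatticeModel) -> list[_Placement]:
    N = model.N
    cyclic = model.boundary == CYCLIC
    out = []
    for gi, sp in enumerate(model.species):
        if sp.a == 0.0:
            continue
        K = model.affinity_track(sp.id)
        m = sp.footprint
        starts = range(N) if cyclic else range(N - m + 1)
        for n in starts:
            k = K[n % N]
            if k == 0.0:
                continue
            for h1, h2 in (sp.unwrap.states() if sp.unwrap else [(0, 0)]):
                ell = m - h1 - h2
                s = (n + h1) % N if cyclic else n + h1
                mask = 0
                for pos in range(s, s + ell):
                    mask |= 1 << (pos % N if cyclic else pos)
                w = sp.a * k * sp.eps_u ** (h1 + h2)
                out.append(_Placement(gi, n, h1, h2, s, ell, w, mask))
    return out


def _pair_weight_tables(model: LatticeModel):
    ng = len(model.species)
    ids = [s.id for s in model.species]
    R = model.max_interaction_range()
    W = np.ones((ng, ng, R + 1))
    for i in range(ng):
        for j in range(ng):
            W[i, j] = model.pair_weights(ids[i], ids[j], R)
    return W, R


def _interaction_factor(config, model, W, R) -> float:
    """Product of w(gap) over neighboring pairs (circular under cyclic)."""
    if len(config) < 2:
        return 1.0
    N = model.N
    cyclic = model.boundary == CYCLIC
    ordered = sorted(config, key=lambda p: p.s)
    factor = 1.0
    pairs = len(ordered) if cyclic else len(ordered) - 1
    for i in range(pairs):
        a = ordered[i]
        b = ordered[(i + 1) % len(ordered)]
        gap = b.s - (a.s + a.ell)
        if cyclic and i == len(ordered) - 1:
            gap = b.s + N - (a.s + a.ell)
        if 0 <= gap <= R:
            factor *= W[a.gi, b.gi, gap]
        if factor == 0.0:
            return 0.0
    return factor


def _cap_legal(config, model) -> bool:
    """Exhaustive search for a valid non-crossing linker assignment."""
    rule = model.linker_cap
    if rule is None:
        return True
    ids = [s.id for s in model.species]
    nuc_gi = ids.index(rule.nucleosome)
    link_gi = ids.index(rule.linker)
    ordered = sorted(config, key=lambda p: p.s)
    # split into runs of linkers separated by nucleosomes; neutral species
    # contribute only geometry (they break nothing but stretch distances)
    events = []  # (kind, placement); kind: 'nuc' | 'link'
    for p in ordered:
        if p.gi == nuc_gi:
            events.append(("nuc", p))
        elif p.gi == link_gi:
            events.append(("link", p))
    nucs = [p for k, p in events if k == "nuc"]
    if not any(k == "link" for k, _ in events):
        return True
    if not nucs:
        return False

    def dist_ok(linker, nuc) -> bool:
        # the whole linker must lie within `vicinity` bp of the nucleosome
        # covered edge (far-edge distance)
        if rule.allow_free_binding:
            return True
        if nuc.s >= linker.s + linker.ell:   # nucleosome to the right
            span = nuc.s - linker.s
        else:                                 # nucleosome to the left
            span = (linker.s + linker.ell) - (nuc.s + nuc.ell)
        return span <= rule.vicinity

    # runs[i] = linkers between nucleosome i-1 and nucleosome i
    runs: list[list] = [[] for _ in range(len(nucs) + 1)]
    ri = 0
    for kind, p in events:
        if kind == "nuc":
            ri += 1
        else:
            runs[ri].append(p)

    def feasible(run_idx: int, credit: int) -> bool:
        """credit: remaining capacity of nucleosome run_idx-1 (left side)."""
        if run_idx == len(runs):
            return True
        run = runs[run_idx]
        left_nuc = nucs[run_idx - 1] if run_idx > 0 else None
        right_nuc = nucs[run_idx] if run_idx < len(nucs) else None
        for k1 in range(len(run) + 1):  # first k1 linkers to the left nucleosome
            k2 = len(run) - k1
            if k1 > 0 and (left_nuc is None or k1 > credit):
                continue
            if k2 > 0 and (right_nuc is None or k2 > rule.cap):
                continue
            if k1 > 0 and not all(dist_ok(l, left_nuc) for l in run[:k1]):
                continue
            if k2 > 0 and not all(dist_ok(l, right_nuc) for l in run[k1:]):
                continue
            if feasible(run_idx + 1, rule.cap - k2):
                return True
        return False

    return feasible(0, 0)


def enumerate_configurations(
    model: LatticeModel, max_configs: int = DEFAULT_MAX_CONFIGS
):
    """Yield every configuration as ``(placements, weight)``.

    ``placements`` is a tuple of ``(species_id, frame_start, h1, h2)``;
    ``weight`` is the full unnormalized Boltzmann weight including pair
    interactions, and 0.0 for configurations prohibited by a zero
    interaction weight or an unsatisfiable linker-cap assignment.
    """
    model.validate()
    if model.boundary == CYCLIC and model.linker_cap is not None:
        raise LatticeModelError("linker cap rules unsupported under cyclic boundary")
    placements = _enumerate_placements(model)
    placements.sort(key=lambda p: p.s)
    W, R = _pair_weight_tables(model)
    ids = [s.id for s in model.species]
    count = 0

    def weight_of(config: list[_Placement]) -> float:
        w = 1.0
        for p in config:
            w *= p.weight
        w *= _interaction_factor(config, model, W, R)
        if w != 0.0 and not _cap_legal(config, model):
            return 0.0
        return w

    def recurse(idx: int, mask: int, config: list[_Placement]):
        nonlocal count
        count += 1
        if count > max_configs:
            raise BruteForceTooLarge(
                f"more than {max_configs} configurations (cap exceeded)"
            )
        yield tuple((ids[p.gi], p.n, p.h1, p.h2) for p in config), weight_of(config), list(config)
        for j in range(idx, len(placements)):
            p = placements[j]
            if mask & p.mask:
                continue
            config.append(p)
            yield from recurse(j + 1, mask | p.mask, config)
            config.pop()

    for named, w, _ in recurse(0, 0, []):
        yield named, w


def brute_force_solve(
    model: LatticeModel, max_configs: int = DEFAULT_MAX_CONFIGS
) -> LatticeSolution:
    """Exact marginals by explicit enumeration of every configuration.

    Same contract as :func:`nuclattice.solver.solve`; raises
    :class:`BruteForceTooLarge` when the configuration count exceeds
    ``max_configs``.
    """
    model.validate()
    if model.boundary == CYCLIC and model.linker_cap is not None:
        raise LatticeModelError("linker cap rules unsupported under cyclic boundary")
    N = model.N
    placements = _enumerate_placements(model)
    placements.sort(key=lambda p: p.s)
    W, R = _pair_weight_tables(model)

    Z = 0.0
    start = {s.id: np.zeros(N) for s in model.species}
    coverage = {s.id: np.zeros(N) for s in model.species}
    ids = [s.id for s in model.species]
    count = 0

    def visit(config: list[_Placement]) -> None:
        nonlocal Z, count
        count += 1
        if count > max_configs:
            raise BruteForceTooLarge(
                f"more than {max_configs} configurations (cap exceeded)"
            )
        w = 1.0
        for p in config:
            w *= p.weight
        w *= _interaction_factor(config, model, W, R)
        if w == 0.0:
            return
        if not _cap_legal(config, model):
            return
        Z += w
        for p in config:
            start[ids[p.gi]][p.n % N] += w
            for pos in range(p.s, p.s + p.ell):
                coverage[ids[p.gi]][pos % N] += w

    def recurse(idx: int, mask: int, config: list[_Placement]) -> None:
        visit(config)
        for j in range(idx, len(placements)):
            p = placements[j]
            if mask & p.mask:
                continue
            config.append(p)
            recurse(j + 1, mask | p.mask, config)
            config.pop()

    recurse(0, 0, [])

    for g in ids:
        start[g] /= Z
        coverage[g] /= Z
    free = 1.0 - sum(coverage.values()) if ids else np.ones(N)
    return LatticeSolution(
        species_ids=ids,
        start_prob=start,
        coverage=coverage,
        free_prob=free,
        log_partition=float(np.log(Z)),
    )
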