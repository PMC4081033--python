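"""Finite-state bookkeeping for linker-cap rules in the transfer DP.

A configuration's linkers are legal iff there is a *non-crossing* assignment
of every linker to an adjacent nucleosome (only linkers between the two) with
at most ``cap`` linkers per nucleosome, and — when free binding is off — each
linker lying entirely within ``vicinity`` bp of its assigned nucleosome's
covered edge (i.e. the linker's far edge is at most ``vicinity`` bp from the
nucleosome, so the vicinity is a zone the whole molecule must occupy).

The DP canonicalizes assignments greedily left-to-right: a linker is
assigned to the last nucleosome whenever that nucleosome has capacity, no
linker is still pending and (if distances are enforced) it lies within
``vicinity``; otherwise it becomes *pending* and must be absorbed by the
next nucleosome.  Greedy assignment is complete: it succeeds whenever any
non-crossing assignment exists (left assignment only consumes capacity the
following particles could never reach, and minimizes the load carried to the
next nucleosome).  Each configuration is therefore counted exactly once.

State tuple ``(credit, ld, pending, pn)``:

* ``credit`` — remaining capacity of the last nucleosome (-1: none seen yet);
* ``ld`` — distance from the last nucleosome's right covered edge to the
  current right edge, saturated at ``vicinity + 1`` ("too far");
* ``pending`` — number of trailing linkers awaiting the next nucleosome;
* ``pn`` — distance from the first pending linker's *left* edge to the
  current right edge (saturated as above), so ``pn + gap`` is the span the
  arriving nucleosome must find within its vicinity.

Distances are only tracked when free binding is off; a state with pending
linkers at the end of the lattice is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LatticeModel

TOK_OTHER = 0
TOK_NUC = 1
TOK_LINK = 2

DEAD = -1


@dataclass
class CapMachine:
    """Dense transition tables over (gap, state, species, covered-length)."""

    n_states: int
    init_state: int
    accept: np.ndarray            # bool[n_states]
    d_near: int                   # gaps 0..d_near resolved; beyond -> t_far
    t_near: np.ndarray            # int[d_near+1, n_states, n_species, n_lengths]
    t_far: np.ndarray             # int[n_states, n_species, n_lengths]

    @property
    def trivial(self) -> bool:
        return self.n_states == 1


def _token_classes(model: LatticeModel) -> list[int]:
    rule = model.linker_cap
    toks = []
    for s in model.species:
        if rule is not None and s.id == rule.nucleosome:
            toks.append(TOK_NUC)
        elif rule is not None and s.id == rule.linker:
            toks.append(TOK_LINK)
        else:
            toks.append(TOK_OTHER)
    return toks


def build_cap_machine(model: LatticeModel, lengths: list[list[int]]) -> CapMachine:
    """Build the transition tables for ``model`` (trivial if no cap rule).

    ``lengths[gi]`` lists the possible covered lengths of species ``gi``.
    """
    n_species = len(model.species)
    n_lengths = max((len(ls) for ls in lengths), default=1)
    rule = model.linker_cap
    if rule is None:
        t_near = np.zeros((1, 1, n_species, n_lengths), dtype=np.int64)
        t_far = np.zeros((1, n_species, n_lengths), dtype=np.int64)
        return CapMachine(1, 0, np.array([True]), 0, t_near, t_far)

    toks = _token_classes(model)
    track_dist = not rule.allow_free_binding
    big = rule.vicinity + 1  # saturation value for distances
    d_near = rule.vicinity if track_dist else 0

    def canon(credit: int, ld: int, pending: int, pn: int):
        if not track_dist:
            ld, pn = 0, 0
        else:
            ld = min(ld, big)
            pn = min(pn, big)
            if pending > 0 or credit <= 0:
                ld = big  # left assignment impossible anyway
            if pending == 0:
                pn = 0
        if credit < 0:
            credit, ld = -1, big if track_dist else 0
        return (credit, ld, pending, pn)

    def step(state, d: int, tok: int, length: int):
        credit, ld, pending, pn = state
        if tok == TOK_NUC:
            if pending > 0 and track_dist and pn + d > rule.vicinity:
                return None
            return canon(rule.cap - pending, 0, 0, 0)  # fresh nucleosome: ld = 0
        if tok == TOK_LINK:
            can_left = (
                pending == 0
                and credit > 0
                and (not track_dist or ld + d + length <= rule.vicinity)
            )
            if can_left:
                return canon(credit - 1, ld + d + length, 0, 0)
            if pending + 1 > rule.cap:
                return None
            pn_new = length if pending == 0 else pn + d + length
            if track_dist and pn_new > rule.vicinity:
                return None  # can never fit in a right nucleosome's vicinity
            return canon(credit, ld + d + length, pending + 1, pn_new)
        # neutral species: passes through, stretching both distances
        if pending > 0:
            if track_dist and pn + d + length > rule.vicinity:
                return None
            return canon(credit, ld + d + length, pending, pn + d + length)
        return canon(credit, ld + d + length, pending, pn)

    init = canon(-1, big, 0, 0)

    # breadth-first enumeration of reachable states
    states = {init: 0}
    order = [init]
    frontier = [init]
    far_gap = d_near + 1  # representative "far" gap (saturates all distances)
    while frontier:
        new_frontier = []
        for st in frontier:
            for gi in range(n_species):
                for length in lengths[gi]:
                    for d in list(range(d_near + 1)) + [far_gap]:
                        nxt = step(st, d, toks[gi], length)
                        if nxt is not None and nxt not in states:
                            states[nxt] = len(order)
                            order.append(nxt)
                            new_frontier.append(nxt)
        frontier = new_frontier

    nq = len(order)
    t_near = np.full((d_near + 1, nq, n_species, n_lengths), DEAD, dtype=np.int64)
    t_far = np.full((nq, n_species, n_lengths), DEAD, dtype=np.int64)
    for qi, st in enumerate(order):
        for gi in range(n_species):
            for li, length in enumerate(lengths[gi]):
                for d in range(d_near + 1):
                    nxt = step(st, d, toks[gi], length)
                    if nxt is not None:
                        t_near[d, qi, gi, li] = states[nxt]
                nxt = step(st, far_gap, toks[gi], length)
                if nxt is not None:
                    t_far[qi, gi, li] = states[nxt]

    accept = np.array([st[2] == 0 for st in order])
    return CapMachine(nq, states[init], accept, d_near, t_near, t_far)
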