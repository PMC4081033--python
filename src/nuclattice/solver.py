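"""Exact equilibrium solver for the generalized 1D lattice binding model.

The solver computes exact Boltzmann-ensemble marginals (no sampling) by
dynamic programming over particle covered-end positions.  Unwrapping states
that share a covered interval are aggregated exactly (interaction gaps are
measured between covered edges, so only the covered interval and the summed
frame-anchored weights matter); linker-cap rules enter through a small
finite-state machine (:mod:`.capstate`); interactions of finite range ``R``
are handled by splitting neighbor sums into an exact near window (gap <= R)
and a cumulative far part where ``w = 1``.

Partition sums are accumulated with per-position multiplicative rescaling
(log offsets), so arbitrarily large activities and lattice lengths stay in
floating-point range; ``log_partition`` is exact to double precision.

Cyclic lattices are solved by conditioning on the anchor particle — the one
covering position 0 or, failing that, the first one clockwise of it — which
reduces each case to a linear solve on the remaining arc with the anchor as
a boundary "ghost" at both ends.  The cost is O(anchors x N); cyclic
boundaries are intended for repeat-unit tori, not chromosome-scale lattices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capstate import DEAD, CapMachine, build_cap_machine
from .model import (
    CYCLIC,
    LatticeModel,
    LatticeModelError,
    LatticeSolution,
)

_RESCALE_ABOVE = 1e120
_ZCHECK_ATOL = 1e-8


class NumericalError(RuntimeError):
    """Internal consistency failure of the partition-sum recursion."""


# ---------------------------------------------------------------------------
# placement weight tables
# ---------------------------------------------------------------------------


@dataclass
class _Tables:
    """Aggregated placement weights and interaction/transition tables."""

    N: int
    ng: int
    lengths: list[list[int]]       # covered lengths per species
    U: list[np.ndarray]            # per species: (n_lengths, N+1) by covered start
    conv: list[np.ndarray]         # same shape: sum of K over frame anchors
    W: np.ndarray                  # (ng, ng, D+1) pair weights by gap
    D: int                         # near-window size
    mach: CapMachine
    t_ext: np.ndarray              # (D+1, nq, ng, nl) transitions for gaps 0..D
    t_far: np.ndarray              # (nq, ng, nl)
    nl: int


def _placement_weights(model: LatticeModel, cyclic: bool):
    """U[g][li, s]: total weight of species-g placements with covered
    interval [s, s + lengths[g][li]), summed over unwrapping states."""
    N = model.N
    lengths: list[list[int]] = []
    U: list[np.ndarray] = []
    conv_all: list[np.ndarray] = []
    for sp in model.species:
        m = sp.footprint
        K = model.affinity_track(sp.id)
        ls = sp.covered_lengths()
        lengths.append(ls)
        u = np.zeros((len(ls), N + 1))
        cv = np.zeros((len(ls), N + 1))
        for li, ell in enumerate(ls):
            t = m - ell
            if cyclic:
                # frames wrap; K is looked up modulo N
                conv = np.zeros(N)
                for h1 in range(t + 1):
                    conv += np.roll(K, h1)  # K[(s - h1) mod N]
                cv[li, :N] = conv
                u[li, :N] = sp.a * sp.eps_u**t * conv
            else:
                Kvalid = K[: N - m + 1]  # frame starts 0..N-m
                conv = np.convolve(Kvalid, np.ones(t + 1))  # covered starts 0..N-ell
                cv[li, : N - ell + 1] = conv
                u[li, : N - ell + 1] = sp.a * sp.eps_u**t * conv
        U.append(u)
        conv_all.append(cv)
    return lengths, U, conv_all


def _build_tables(model: LatticeModel, cyclic: bool) -> _Tables:
    lengths, U, conv = _placement_weights(model, cyclic)
    ng = len(model.species)
    mach = build_cap_machine(model, lengths)
    D = max(model.max_interaction_range(), mach.d_near)
    ids = [s.id for s in model.species]
    W = np.ones((ng, ng, D + 1))
    for i, gi in enumerate(ids):
        for j, gj in enumerate(ids):
            W[i, j] = model.pair_weights(gi, gj, D)
    if np.any(W < 0):
        raise LatticeModelError("negative interaction weights")
    nl = max((len(ls) for ls in lengths), default=1)
    t_ext = np.empty((D + 1, mach.n_states, ng, nl), dtype=np.int64)
    for d in range(D + 1):
        t_ext[d] = mach.t_near[d] if d <= mach.d_near else mach.t_far
    return _Tables(model.N, ng, lengths, U, conv, W, D, mach, t_ext, mach.t_far, nl)


# ---------------------------------------------------------------------------
# linear engine (forward/backward over covered-end positions)
# ---------------------------------------------------------------------------


def _forward(tb: _Tables, L: int, ghost: int | None):
    """Prefix sums F[q, g, li, e] over configurations on [0, L).

    ``ghost`` is the species index of a virtual boundary particle whose right
    covered edge sits at position 0 (used for cyclic arcs); the empty prefix
    then carries the pair weight ``w(gap to ghost)`` for the first particle.
    Columns are stored with per-position log offsets ``lam``.
    """
    nq, ng, D = tb.mach.n_states, tb.ng, tb.D
    F = np.zeros((nq, ng, tb.nl, L + 1))
    Fsp = np.zeros((nq, ng, L + 1))
    Ccum = np.zeros((nq, ng, L + 1))
    lam = np.zeros(L + 1)
    q0 = tb.mach.init_state
    darange = np.arange(D + 1)
    for e in range(1, L + 1):
        prev_mag = max(Ccum[:, :, e - 1].max(), 1.0)
        delta = np.log(prev_mag) if prev_mag > _RESCALE_ABOVE else 0.0
        lam[e] = lam[e - 1] + delta
        for gi in range(ng):
            for li, ell in enumerate(tb.lengths[gi]):
                s = e - ell
                if s < 0:
                    continue
                u = tb.U[gi][li, s]
                if u == 0.0:
                    continue
                bracket = np.zeros(nq)
                # empty prefix
                init_w = 1.0
                if ghost is not None and s <= D:
                    init_w = tb.W[ghost, gi, s]
                tq0 = tb.t_far[q0, gi, li]
                if tq0 != DEAD and init_w != 0.0:
                    bracket[tq0] += init_w * np.exp(-lam[e])
                # far neighbors (gap > D, weight 1)
                x = s - D - 1
                if x >= 0:
                    farvec = Ccum[:, :, x].sum(axis=1) * np.exp(lam[x] - lam[e])
                    tq = tb.t_far[:, gi, li]
                    ok = tq != DEAD
                    np.add.at(bracket, tq[ok], farvec[ok])
                # near neighbors (gap d = 0..D)
                cols = s - darange
                valid = cols >= 0
                cc = np.where(valid, cols, 0)
                fac = np.where(valid, np.exp(lam[cc] - lam[e]), 0.0)
                Fsl = Fsp[:, :, cc] * fac[None, None, :]
                Cg = np.einsum("qgd,gd->qd", Fsl, tb.W[:, gi, :])
                tq = tb.t_ext[:, :, gi, li].T  # (nq, D+1)
                ok = tq != DEAD
                np.add.at(bracket, tq[ok], Cg[ok])
                F[:, gi, li, e] = u * bracket
        Fsp[:, :, e] = F[:, :, :, e].sum(axis=2)
        Ccum[:, :, e] = Ccum[:, :, e - 1] * np.exp(lam[e - 1] - lam[e]) + Fsp[:, :, e]
    return F, lam


def _backward(tb: _Tables, L: int, ghost: int | None):
    """Suffix sums B[q, g_prev, e]: completions to the right of a particle of
    species ``g_prev`` ending at ``e``, given cap state ``q`` after it.  Also
    returns SufG[qt, g, li, x] = sum over placements with covered start >= x
    of U * B[qt after them], used for the far part of the recursion."""
    nq, ng, D = tb.mach.n_states, tb.ng, tb.D
    B = np.zeros((nq, ng, L + 1))
    SufG = np.zeros((nq, ng, tb.nl, L + 2))
    mu = np.zeros(L + 2)
    accept = tb.mach.accept.astype(float)

    def close_w(e: int) -> np.ndarray:
        if ghost is None:
            return np.ones(ng)
        gap = L - e
        return tb.W[:, ghost, gap] if gap <= D else np.ones(ng)

    def update_sufg(x: int) -> None:
        out = SufG[:, :, :, x + 1] * np.exp(mu[x + 1] - mu[x])
        for gi in range(ng):
            for li, ell in enumerate(tb.lengths[gi]):
                if x > L:
                    continue
                u = tb.U[gi][li, x]
                if u == 0.0 or x + ell > L:
                    continue
                out[:, gi, li] += u * B[:, gi, x + ell] * np.exp(mu[x + ell] - mu[x])
        SufG[:, :, :, x] = out

    B[:, :, L] = accept[:, None] * close_w(L)[None, :]
    for e in range(L - 1, -1, -1):
        update_sufg(e + 1)
        prev_mag = max(B[:, :, e + 1].max(), SufG[:, :, :, e + 1].max(), 1.0)
        delta = np.log(prev_mag) if prev_mag > _RESCALE_ABOVE else 0.0
        mu[e] = mu[e + 1] + delta
        col = accept[:, None] * close_w(e)[None, :] * np.exp(-mu[e])
        for gi2 in range(ng):  # species of the appended particle
            for li2, ell2 in enumerate(tb.lengths[gi2]):
                # far: appended particle at covered start > e + D
                x = e + D + 1
                if x <= L:
                    tq = tb.t_far[:, gi2, li2]
                    ok = tq != DEAD
                    fv = np.zeros(nq)
                    fv[ok] = SufG[tq[ok], gi2, li2, x] * np.exp(mu[x] - mu[e])
                    col += fv[:, None]
                # near: covered start s2 = e + d, d = 0..D
                s2 = e + np.arange(D + 1)
                uvals = np.zeros(D + 1)
                inside = s2 <= L
                uvals[inside] = tb.U[gi2][li2, s2[inside]]
                uvals[s2 + ell2 > L] = 0.0
                if not uvals.any():
                    continue
                ends = np.where(s2 + ell2 <= L, s2 + ell2, L)
                fac = np.exp(mu[ends] - mu[e])
                tq = tb.t_ext[:, :, gi2, li2]  # (D+1, nq)
                Bg = B[:, gi2, :]
                bv = np.where(tq != DEAD, Bg[np.where(tq != DEAD, tq, 0), ends[:, None]], 0.0)
                Gq = uvals[:, None] * fac[:, None] * bv  # (D+1, nq)
                col += np.einsum("dq,yd->qy", Gq, tb.W[:, gi2, :])
        B[:, :, e] = col
    update_sufg(0)
    return B, SufG, mu


def _log_partition_forward(tb: _Tables, F, lam, L: int, ghost: int | None) -> float:
    accept = tb.mach.accept
    close = np.ones((tb.ng, L + 1))
    if ghost is not None:
        for e in range(max(0, L - tb.D), L + 1):
            close[:, e] = tb.W[:, ghost, L - e]
    Facc = F[accept].sum(axis=(0, 2))  # (ng, L+1)
    terms = (Facc * close).sum(axis=0)  # per end position
    lam_max = float(lam.max())
    total = float(np.sum(terms * np.exp(lam - lam_max)))
    if accept[tb.mach.init_state]:
        total += np.exp(-lam_max)  # empty configuration
    if total <= 0:
        raise NumericalError("non-positive partition sum")
    return lam_max + float(np.log(total))


def _log_partition_backward(tb: _Tables, B, SufG, mu, L: int, ghost: int | None) -> float:
    q0 = tb.mach.init_state
    acc = 0.0  # in the scale of mu[0]
    for gi in range(tb.ng):
        for li, ell in enumerate(tb.lengths[gi]):
            tq0 = tb.t_far[q0, gi, li]
            if tq0 == DEAD:
                continue
            x = tb.D + 1
            if x <= L:
                acc += SufG[tq0, gi, li, x] * np.exp(mu[x] - mu[0])
            for s in range(0, min(tb.D, L) + 1):
                u = tb.U[gi][li, s]
                if u == 0.0 or s + ell > L:
                    continue
                iw = tb.W[ghost, gi, s] if ghost is not None else 1.0
                acc += iw * u * B[tq0, gi, s + ell] * np.exp(mu[s + ell] - mu[0])
    if tb.mach.accept[q0]:
        acc += np.exp(-mu[0])
    if acc <= 0:
        raise NumericalError("non-positive partition sum")
    return float(mu[0]) + float(np.log(acc))


def _linear_marginals(tb: _Tables, L: int, ghost: int | None):
    """Aggregated placement marginals P[g][li, e] plus log Z on [0, L)."""
    F, lam = _forward(tb, L, ghost)
    B, SufG, mu = _backward(tb, L, ghost)
    logZ_f = _log_partition_forward(tb, F, lam, L, ghost)
    logZ_b = _log_partition_backward(tb, B, SufG, mu, L, ghost)
    if abs(logZ_f - logZ_b) > _ZCHECK_ATOL * max(1.0, abs(logZ_f)):
        raise NumericalError(
            f"forward/backward partition mismatch: {logZ_f} vs {logZ_b}"
        )
    scale = np.exp(lam + mu[: L + 1] - logZ_f)
    P = [
        np.einsum("qle,qe->le", F[:, gi, :, :], B[:, gi, :]) * scale[None, :]
        for gi in range(tb.ng)
    ]
    return P, logZ_f


# ---------------------------------------------------------------------------
# assembling LatticeSolution
# ---------------------------------------------------------------------------


def _empty_accumulators(model: LatticeModel):
    start = {s.id: np.zeros(model.N) for s in model.species}
    cover_diff = {s.id: np.zeros(model.N + 1) for s in model.species}
    return start, cover_diff


def _accumulate_linear(model, tb: _Tables, P, start, cover_diff):
    """Distribute aggregated placement marginals (hard-wall lattice)."""
    N = model.N
    for gi, sp in enumerate(model.species):
        m = sp.footprint
        K = model.affinity_track(sp.id)
        n_max = N - m  # last valid frame start
        for li, ell in enumerate(tb.lengths[gi]):
            t = m - ell
            pe = P[gi][li, :]
            idx = np.nonzero(pe)[0]
            if idx.size == 0:
                continue
            p = pe[idx]
            s = idx - ell  # covered starts
            np.add.at(cover_diff[sp.id], s, p)
            np.add.at(cover_diff[sp.id], s + ell, -p)
            # frame-start decomposition: each unwrap state h1 gets a share
            # proportional to K at its frame anchor
            r = np.zeros(N - ell + 1)
            r[s] = p / tb.conv[gi][li, s]
            csum = np.convolve(r, np.ones(t + 1))  # csum[n+t] = sum_h1 r[n+h1]
            start[sp.id][: n_max + 1] += K[: n_max + 1] * csum[t : t + n_max + 1]


def _accumulate_arc(model, tb: _Tables, P, start, cover_diff, weight, offset):
    """Distribute arc marginals (cyclic lattice; frames may wrap)."""
    N = model.N
    for gi, sp in enumerate(model.species):
        m = sp.footprint
        K = model.affinity_track(sp.id)
        for li, ell in enumerate(tb.lengths[gi]):
            t = m - ell
            pe = P[gi][li, :]
            idx = np.nonzero(pe)[0]
            if idx.size == 0:
                continue
            for e in idx:
                p = pe[e] * weight
                s_abs = offset + (e - ell)  # arc particles never wrap
                cover_diff[sp.id][s_abs] += p
                cover_diff[sp.id][s_abs + ell] -= p
                h1s = np.arange(t + 1)
                ns = (s_abs - h1s) % N
                kv = K[ns]
                tot = kv.sum()
                if tot > 0:
                    np.add.at(start[sp.id], ns, p * kv / tot)


def _finish_solution(model: LatticeModel, start, cover_diff, logZ) -> LatticeSolution:
    coverage = {g: np.cumsum(d)[: model.N] for g, d in cover_diff.items()}
    free = 1.0 - sum(coverage.values()) if coverage else np.ones(model.N)
    return LatticeSolution(
        species_ids=[s.id for s in model.species],
        start_prob=start,
        coverage=coverage,
        free_prob=free,
        log_partition=float(logZ),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def solve(model: LatticeModel) -> LatticeSolution:
    """Exact marginal binding probabilities for ``model``.

    Returns frame-start probabilities, per-species coverage ``c(g, n)``,
    free-DNA probability and the log grand-partition function.  Deterministic
    and exact (dynamic programming; no sampling).
    """
    model.validate()
    if model.boundary == CYCLIC:
        return _solve_cyclic(model)
    tb = _build_tables(model, cyclic=False)
    P, logZ = _linear_marginals(tb, model.N, ghost=None)
    start, cover_diff = _empty_accumulators(model)
    _accumulate_linear(model, tb, P, start, cover_diff)
    return _finish_solution(model, start, cover_diff, logZ)


def _solve_cyclic(model: LatticeModel) -> LatticeSolution:
    """Ring solve by conditioning on the anchor particle (see module doc)."""
    N = model.N
    tb = _build_tables(model, cyclic=True)
    start, cover_diff = _empty_accumulators(model)

    cases = []
    log_terms = [0.0]  # empty ring
    for gi in range(tb.ng):
        for li, ell in enumerate(tb.lengths[gi]):
            for s_a in range(N):
                u = tb.U[gi][li, s_a]
                if u == 0.0:
                    continue
                L_arc = N - ell
                if s_a + ell <= N:
                    # anchor does not wrap: arc = [s_a + ell, N + s_a)
                    arc0, limit = s_a + ell, N
                else:
                    # anchor covers the origin: arc = [s_a + ell - N, s_a)
                    arc0, limit = s_a + ell - N, s_a
                sub = _arc_tables(tb, arc0, limit, L_arc)
                P_arc, logZ_arc = _linear_marginals(sub, L_arc, ghost=gi)
                lw = np.log(u) + logZ_arc
                cases.append((gi, li, s_a, lw, P_arc, arc0))
                log_terms.append(lw)

    shift = max(log_terms)
    logZ = shift + np.log(np.sum(np.exp(np.array(log_terms) - shift)))

    for gi, li, s_a, lw, P_arc, arc0 in cases:
        w_case = float(np.exp(lw - logZ))
        _accumulate_anchor(model, tb, gi, li, s_a, w_case, start, cover_diff)
        _accumulate_arc(model, tb, P_arc, start, cover_diff, w_case, arc0)
    return _finish_solution(model, start, cover_diff, logZ)


def _arc_tables(tb: _Tables, arc0: int, limit: int, L_arc: int) -> _Tables:
    """Restriction of U to an arc: arc coord x -> absolute arc0 + x, with
    covered intervals required to end by ``limit`` (absolute coordinates)."""
    U_arc, conv_arc = [], []
    for gi in range(tb.ng):
        u = np.zeros((tb.U[gi].shape[0], L_arc + 1))
        cv = np.zeros_like(u)
        for li, ell in enumerate(tb.lengths[gi]):
            xs = np.arange(L_arc + 1)
            s_abs = arc0 + xs
            ok = s_abs + ell <= limit
            src = np.where(ok, s_abs, 0)
            u[li] = tb.U[gi][li, src] * ok
            cv[li] = tb.conv[gi][li, src] * ok
        U_arc.append(u)
        conv_arc.append(cv)
    return _Tables(
        L_arc, tb.ng, tb.lengths, U_arc, conv_arc, tb.W, tb.D, tb.mach,
        tb.t_ext, tb.t_far, tb.nl,
    )


def _accumulate_anchor(model, tb, gi, li, s_a, w_case, start, cover_diff):
    N = model.N
    sp = model.species[gi]
    ell = tb.lengths[gi][li]
    t = sp.footprint - ell
    K = model.affinity_track(sp.id)
    if s_a + ell <= N:
        cover_diff[sp.id][s_a] += w_case
        cover_diff[sp.id][s_a + ell] -= w_case
    else:  # wraps around the origin
        cover_diff[sp.id][s_a] += w_case
        cover_diff[sp.id][N] -= w_case
        cover_diff[sp.id][0] += w_case
        cover_diff[sp.id][(s_a + ell) % N] -= w_case
    h1s = np.arange(t + 1)
    ns = (s_a - h1s) % N
    kv = K[ns]
    tot = kv.sum()
    if tot > 0:
        np.add.at(start[sp.id], ns, w_case * kv / tot)
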