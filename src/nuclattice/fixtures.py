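"""Seeded generators and packaged constants for self-contained analyses.

Everything here is a pure function of its arguments (and an explicit seed
for the stochastic generators), so tests and pipelines are reproducible
without external downloads.  The module also provides canonical model
builders for the standard study conditions: homogeneous boundary models at
a target density, two-species nucleosome + linker-protein models, and the
refined capped-H1 (chromatosome stoichiometry) model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .isotherm import mcghee_von_hippel_activity
from .model import (
    InteractionRule,
    LatticeModel,
    LinkerCapRule,
    SpeciesSpec,
    UnwrapSpec,
)
from .repeats import SATELLITE_PAD, SATELLITE_UNIT_LENGTH, FragmentSet

#: conserved 234-bp consensus unit of the mouse pericentric major satellite
_SATELLITE_UNIT = (
    "GGACCTGGAATATGGCGAGAAAACTGAAAATCACGGAAAATGAGAAATACACACTTTAGGACGTGAAATAT"
    "GGCGAGGAAAACTGAAAAAGGTGGAAAATTTAGAAATGTCCACTGTAGGACGTGGAATATGGCAAGAAAAC"
    "TGAAAATCATGGAAAATGAGAAACATCCACTTGACGACTTGAAAAATGACGAAATCACTAAAAAACGTGAA"
    "AAATGAGAAATGCACACTGAA"
)

#: nominal nucleosome core particle footprint, bp
NCP_FOOTPRINT = 147

#: default linker-protein (H1) footprint, bp
LINKER_FOOTPRINT = 15


def satellite_unit() -> str:
    """The 234-nt major satellite repeat unit (mouse pericentric
    heterochromatin consensus)."""
    assert len(_SATELLITE_UNIT) == SATELLITE_UNIT_LENGTH
    return _SATELLITE_UNIT


def gen_boundary_model(
    density_target: float,
    N: int = 4000,
    footprint: int = NCP_FOOTPRINT,
    h_max: int = 0,
    unwrap_penalty: float = 1.0,
    contact: float | None = None,
    exclusion: int | None = None,
    boundary: str = "hard_wall",
) -> LatticeModel:
    """Homogeneous hard-wall nucleosome model at a target interior density.

    ``density_target`` is the covered fraction of saturation (interior
    coverage); the activity is obtained by inverting the McGhee-von Hippel
    isotherm, so for the plain hard-rod case the solved interior density
    matches the target up to finite-size effects (well under 1%).  Optional
    unwrapping and nucleosome-nucleosome interactions reuse the same base
    activity (the target then refers to the non-interacting reference).
    """
    if not 0 < density_target < 1:
        raise ValueError("density_target must be in (0, 1)")
    nu = density_target / footprint
    a = mcghee_von_hippel_activity(nu, footprint)
    spec = SpeciesSpec(
        "NCP",
        footprint,
        activity=a,
        unwrap=UnwrapSpec(h_max, unwrap_penalty) if h_max else None,
        is_nucleosome=True,
    )
    rules = []
    if contact is not None:
        rules.append(InteractionRule.contact("NCP", "NCP", contact))
    if exclusion is not None:
        rules.append(InteractionRule.exclusion("NCP", "NCP", int(exclusion)))
    return LatticeModel(N=N, species=[spec], interactions=rules, boundary=boundary)


#: default linker-to-nucleosome vicinity (bp of uncovered DNA within which
#: a linker protein must find a nucleosome edge)
LINKER_VICINITY = 30


def gen_linker_model(
    linker_activity: float,
    N: int = 6000,
    ncp_activity: float = 0.7,
    linker_footprint: int = LINKER_FOOTPRINT,
    vicinity: int = LINKER_VICINITY,
    cap: int | None = None,
) -> LatticeModel:
    """Nucleosome + linker-protein model for linker-concentration scans.

    The linker (H1-like) covers ``linker_footprint`` bp of linker DNA and
    binds only within ``vicinity`` bp of a nucleosome's covered edge.  By
    default the per-nucleosome count cap is set just above what the
    vicinity geometrically admits, so stoichiometry is limited by geometry
    alone; pass ``cap`` explicitly for a stoichiometric limit.  Gaps
    hosting linkers acquire both the linkers' excluded volume and their
    positional entropy, so the nucleosome repeat grows with linker activity
    and saturates when the vicinity fills up.
    """
    if cap is None:
        cap = 2 * max(1, vicinity // linker_footprint)
    ncp = SpeciesSpec("NCP", NCP_FOOTPRINT, activity=ncp_activity, is_nucleosome=True)
    linker = SpeciesSpec("H1", linker_footprint, activity=linker_activity)
    capr = LinkerCapRule(
        linker="H1", nucleosome="NCP", cap=cap, vicinity=vicinity,
        allow_free_binding=False,
    )
    return LatticeModel(N=N, species=[ncp, linker], linker_cap=capr)


def gen_capped_linker_model(
    linker_activity: float,
    N: int = 4000,
    ncp_activity: float = 0.7,
    linker_footprint: int = LINKER_FOOTPRINT,
    ncp_contact: float = 11.0,
    vicinity: int = 30,
    cap: int = 1,
) -> LatticeModel:
    """Refined chromatosome model: at most ``cap`` linkers per nucleosome.

    Linker binding is prohibited away from nucleosomes (within ``vicinity``
    bp of a nucleosome's covered edge only), nucleosome-H1 and
    nucleosome-H1-nucleosome distances stay flexible, and nucleosomes carry
    a contact cooperativity ``w(0, NCP, NCP)`` among themselves.
    """
    ncp = SpeciesSpec("NCP", NCP_FOOTPRINT, activity=ncp_activity, is_nucleosome=True)
    linker = SpeciesSpec("H1", linker_footprint, activity=linker_activity)
    rules = []
    if ncp_contact is not None and ncp_contact != 1.0:
        rules.append(InteractionRule.contact("NCP", "NCP", ncp_contact))
    capr = LinkerCapRule(
        linker="H1", nucleosome="NCP", cap=cap, vicinity=vicinity,
        allow_free_binding=False,
    )
    return LatticeModel(N=N, species=[ncp, linker], interactions=rules, linker_cap=capr)


#: canonical linker-activity titration grid for linker-concentration scans:
#: bound H1 per nucleosome rises from sub-stoichiometric to vicinity-
#: saturated across this range
LINKER_TITRATION_GRID = tuple(0.005 * 2**k for k in range(7))

#: canonical conditions for linker-size comparisons: equal linker activity
#: (K = 2e9 per molar at about 1 nM free linker), footprints at half /
#: nominal / double the 15-bp linker, and saturating nucleosome activity so
#: the repeat length is limited by the linkers rather than by nucleosome
#: scarcity
LINKER_SIZE_COMPARISON_ACTIVITY = 2.0
LINKER_SIZE_FOOTPRINTS = (5, 15, 30)
LINKER_SIZE_NCP_ACTIVITY = 20.0


def gen_unwrap_model(
    h_max: int,
    activity: float = 0.7,
    N: int = 3000,
    footprint: int = NCP_FOOTPRINT,
    unwrap_penalty: float = 1.0,
) -> LatticeModel:
    """Single-species hard-wall model at fixed activity with unwrapping.

    Used for scans over the maximum unwrapping length at constant
    ``K * c0`` (the bound density then rises with ``h_max`` as partially
    unwrapped states open up).
    """
    spec = SpeciesSpec(
        "NCP", footprint, activity=activity,
        unwrap=UnwrapSpec(h_max, unwrap_penalty) if h_max else None,
        is_nucleosome=True,
    )
    return LatticeModel(N=N, species=[spec])


def gen_fragment_set(
    n: int,
    modes: list[tuple[float, float, float]],
    length_dist: tuple[float, float, int, int] = (147.5, 10.0, 100, 200),
    seed: int = 0,
    unit_length: int = SATELLITE_UNIT_LENGTH,
    pad: int = SATELLITE_PAD,
) -> FragmentSet:
    """Seeded paired-end fragment sampler on the padded repeat reference.

    ``modes`` is a list of ``(position, sd, weight)`` for the left-end
    mixture (weights must sum to 1); ``length_dist`` is
    ``(mean, sd, min, max)`` with lengths redrawn until inside the bounds.
    Deterministic per seed.
    """
    weights = np.array([w for _, _, w in modes], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mode weights must sum to 1")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(len(modes), size=n, p=weights)
    pos = np.array([modes[i][0] for i in which])
    sd = np.array([modes[i][1] for i in which])
    left = np.rint(rng.normal(pos, sd)).astype(int) % unit_length
    mean, lsd, lmin, lmax = length_dist
    lens = np.rint(rng.normal(mean, lsd, size=n)).astype(int)
    bad = (lens < lmin) | (lens > lmax)
    while bad.any():
        lens[bad] = np.rint(rng.normal(mean, lsd, size=int(bad.sum()))).astype(int)
        bad = (lens < lmin) | (lens > lmax)
    table = pd.DataFrame({"left": left, "right": left + lens})
    return FragmentSet(table, unit_length=unit_length, pad=pad)


def gen_periodic_anchor_track(
    n_anchors: int,
    period: float = 200.0,
    amplitude: float = 0.3,
    jitter: float = 5.0,
    chrom_length: int = 200_000,
    window: int = 1500,
    seed: int = 0,
):
    """Synthetic occupancy track with anchor-phased oscillations.

    Around each anchor ``a`` the track is ``1 + amplitude *
    cos(2 pi (x - a') / period)`` with a seeded +-``jitter`` bp shift of the
    phase center; anchors are spaced so their windows do not overlap.
    Returns ``(track_dict, anchor_table)`` ready for
    :func:`nuclattice.aggregate.extract_and_average`.
    """
    rng = np.random.default_rng(seed)
    spacing = 2 * window + 200
    need = n_anchors * spacing + 2 * window
    if need > chrom_length:
        chrom_length = need + spacing
    arr = np.ones(chrom_length)
    positions = window + spacing * np.arange(n_anchors) + window // 2
    x = np.arange(-window, window + 1)
    for a in positions:
        shift = rng.integers(-int(jitter), int(jitter) + 1)
        arr[a - window : a + window + 1] = 1 + amplitude * np.cos(
            2 * np.pi * (x - shift) / period
        )
    anchors = pd.DataFrame({"chrom": "chrSim", "pos": positions, "strand": "+"})
    return {"chrSim": arr}, anchors
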