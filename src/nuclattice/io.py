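"""Readers and writers for the standard formats around the lattice models.

Plain-text genomics formats only: FASTA (via Biopython), BED, bedGraph,
2-column TSV tracks, JASPAR-style PWMs, fragment tables and YAML model
configurations.  bigWig tracks are read through pyBigWig when it is
installed.  All writers prepend a provenance header (version, config hash,
seed) as ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .aggregate import AnchorSet
from .model import (
    InteractionRule,
    LatticeModel,
    LatticeModelError,
    LatticeSolution,
    LinkerCapRule,
    SpeciesSpec,
    UnwrapSpec,
)
from .repeats import FragmentSet
from .seqaff import PWM


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def provenance_header(config: Mapping | None = None, seed: int | None = None) -> str:
    parts = [f"# nuclattice v{__version__}"]
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"# config sha256:{digest}")
    if seed is not None:
        parts.append(f"# seed {seed}")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """All records of a FASTA file as {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def read_track_tsv(path: str | Path, length: int | None = None) -> np.ndarray:
    """2-column TSV (position, value) to a dense per-bp array."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["pos", "value"])
    n = int(df["pos"].max()) + 1 if length is None else int(length)
    arr = np.zeros(n)
    arr[df["pos"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
    return arr


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """bedGraph to dense per-bp arrays keyed by chromosome."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = np.zeros(int(sub["end"].max()))
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[int(s) : int(e)] = v
        out[chrom] = arr
    return out


def read_bigwig(path: str | Path) -> dict[str, np.ndarray]:
    """bigWig to dense per-bp arrays (requires pyBigWig)."""
    import pyBigWig  # deferred: optional dependency

    bw = pyBigWig.open(str(path))
    out = {}
    for chrom, length in bw.chroms().items():
        out[chrom] = np.nan_to_num(np.asarray(bw.values(chrom, 0, length)))
    bw.close()
    return out


def read_any_track(path: str | Path) -> dict[str, np.ndarray]:
    p = Path(path)
    if p.suffix in (".bw", ".bigwig", ".bigWig"):
        return read_bigwig(p)
    return read_bedgraph(p)


def write_bedgraph(
    path: str | Path,
    values: np.ndarray,
    chrom: str = "lattice",
    header: str = "",
) -> None:
    """Dense per-bp array as run-length-compressed bedGraph."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        if values.size == 0:
            return
        change = np.nonzero(np.diff(values))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [values.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.10g}\n")


# ---------------------------------------------------------------------------
# anchors / fragments
# ---------------------------------------------------------------------------


def read_anchors_bed(path: str | Path) -> AnchorSet:
    """BED intervals to anchor points (interval midpoints; strand kept)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    pos = (df["start"] + df["end"]) // 2
    strand = df[5] if 5 in df.columns else "+"
    return AnchorSet(pd.DataFrame({"chrom": df["chrom"].astype(str), "pos": pos,
                                   "strand": strand}))


def read_fragments(
    path: str | Path, unit_length: int, pad: int
) -> FragmentSet:
    """BED or 3-column TSV (left, right[, count]) to a FragmentSet.

    BED input (first column non-numeric) uses columns 2 and 3; a count
    column replicates rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    first = df.iloc[0, 0]
    if isinstance(first, str) and not str(first).lstrip("-").isdigit():
        left, right = df[1].astype(int), df[2].astype(int)
        count = df[3].astype(int) if 3 in df.columns and df[3].dtype.kind in "iu" else None
    else:
        left, right = df[0].astype(int), df[1].astype(int)
        count = df[2].astype(int) if 2 in df.columns else None
    table = pd.DataFrame({"left": left, "right": right})
    if count is not None:
        table = table.loc[table.index.repeat(count)].reset_index(drop=True)
    return FragmentSet(table, unit_length=unit_length, pad=pad)


def write_fragments_bed(path: str | Path, fragments: FragmentSet,
                        chrom: str = "repeat", header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for rec in fragments.table.itertuples(index=False):
            fh.write(f"{chrom}\t{rec.left}\t{rec.right}\n")


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------


def read_pwm(path: str | Path) -> PWM:
    """JASPAR-style PWM: four whitespace-separated rows A, C, G, T of equal
    length (counts or probabilities; an optional leading 'A [ ... ]' layout
    is accepted)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            line = line.replace("[", " ").replace("]", " ")
            fields = line.split()
            if fields and fields[0].upper() in "ACGT":
                fields = fields[1:]
            rows.append([float(x) for x in fields])
    if len(rows) != 4:
        raise ValueError(f"expected 4 PWM rows (A,C,G,T), got {len(rows)}")
    mat = np.asarray(rows, dtype=float).T  # (length, 4)
    mat = mat / mat.sum(axis=1, keepdims=True)
    return PWM(mat)


# ---------------------------------------------------------------------------
# model configuration (YAML)
# ---------------------------------------------------------------------------


def load_model_config(path: str | Path) -> tuple[LatticeModel, dict]:
    """Build a LatticeModel from a YAML configuration file.

    Layout::

        lattice: {length: 4000, boundary: hard_wall}
        species:
          - id: NCP
            footprint: 147
            activity: 0.7            # or binding_constant + concentration
            unwrap: {h_max: 40, per_bp_penalty: 1.0}
            is_nucleosome: true
            affinity_track: path.tsv  # 2-column TSV or bedGraph (optional)
        interactions:
          - {pair: [NCP, NCP], contact: 11}
          - {pair: [NCP, NCP], exclude_below: 30}
          - {pair: [NCP, H1], weights: {0: 5.0, 1: 2.0}}
        linker_cap:
          {linker: H1, nucleosome: NCP, cap: 1, vicinity: 30,
           allow_free_binding: false}

    Returns the model and the raw config dict (for provenance hashing).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        lat = cfg["lattice"]
        N = int(lat["length"])
        boundary = lat.get("boundary", "hard_wall")
        species, affinity = [], {}
        for sc in cfg["species"]:
            unwrap = None
            if sc.get("unwrap"):
                unwrap = UnwrapSpec(
                    int(sc["unwrap"]["h_max"]),
                    float(sc["unwrap"].get("per_bp_penalty", 1.0)),
                )
            species.append(
                SpeciesSpec(
                    id=str(sc["id"]),
                    footprint=int(sc["footprint"]),
                    activity=sc.get("activity"),
                    binding_constant=sc.get("binding_constant"),
                    concentration=sc.get("concentration"),
                    unwrap=unwrap,
                    is_nucleosome=bool(sc.get("is_nucleosome", False)),
                )
            )
            if sc.get("affinity_track"):
                tp = path.parent / sc["affinity_track"]
                affinity[str(sc["id"])] = read_track_tsv(tp, length=N)
        rules = []
        for rc in cfg.get("interactions") or []:
            g1, g2 = rc["pair"]
            if "contact" in rc:
                rules.append(InteractionRule.contact(g1, g2, float(rc["contact"])))
            elif "exclude_below" in rc:
                rules.append(InteractionRule.exclusion(g1, g2, int(rc["exclude_below"])))
            elif "weights" in rc:
                rules.append(
                    InteractionRule((g1, g2), {int(k): float(v) for k, v in rc["weights"].items()})
                )
            else:
                raise LatticeModelError(
                    f"interaction for pair {g1},{g2} needs one of: contact, "
                    "exclude_below, weights"
                )
        cap = None
        if cfg.get("linker_cap"):
            lc = cfg["linker_cap"]
            cap = LinkerCapRule(
                linker=str(lc["linker"]),
                nucleosome=str(lc["nucleosome"]),
                cap=int(lc.get("cap", 1)),
                vicinity=int(lc.get("vicinity", 0)),
                allow_free_binding=bool(lc.get("allow_free_binding", False)),
            )
    except KeyError as exc:
        raise LatticeModelError(f"model config missing key: {exc}") from exc
    model = LatticeModel(
        N=N, species=species, affinity=affinity, interactions=rules,
        linker_cap=cap, boundary=boundary,
    )
    return model, cfg


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------


def write_solution(
    outdir: str | Path,
    solution: LatticeSolution,
    header: str = "",
    chrom: str = "lattice",
) -> list[Path]:
    """Coverage bedGraphs, start-probability TSV and JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for g in solution.species_ids:
        p = outdir / f"coverage_{g}.bedgraph"
        write_bedgraph(p, solution.coverage[g], chrom=chrom, header=header)
        written.append(p)
    sp = outdir / "start_prob.tsv"
    df = pd.DataFrame({"position": np.arange(len(solution.free_prob))})
    for g in solution.species_ids:
        df[f"start_{g}"] = solution.start_prob[g]
    with open(sp, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
    written.append(sp)
    js = outdir / "summary.json"
    summary = {
        "log_partition": solution.log_partition,
        "mean_coverage": {g: float(solution.coverage[g].mean()) for g in solution.species_ids},
        "mean_free": float(solution.free_prob.mean()),
    }
    js.write_text(json.dumps(summary, indent=2) + "\n")
    written.append(js)
    return written
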