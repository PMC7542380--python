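"""Circular-coordinate arithmetic on bacterial chromosomes.

Positions live on a circle of length ``L``.  Every gene is reduced to a
single representative position (midpoint by default), from which we derive:

* ``dist_to_ori_bp`` — shortest arc distance to the replication origin,
  in ``[0, L/2]``;
* ``rel_dist`` — the same distance scaled to ``[0, 1]`` (0 at *ori*, 1 at
  the antipode/terminus), i.e. ``2 * dist / L``;
* ``recentred_bp`` — signed offset from *ori* in ``(-L/2, L/2]``, clockwise
  (increasing coordinate) positive;
* ``half`` — ``upper`` (ori-proximal) or ``lower`` (ter-proximal).

Without an explicit terminus the halves are the equal arcs within ``L/4``
of *ori* (tie at exactly ``L/4`` goes to ``lower``).  With an explicit
*ter* the two replichore arcs may be unequal; a position is then ``upper``
iff it lies in the half of its own arc nearer *ori*.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ChromosomeDef

__all__ = [
    "gene_midpoint",
    "circular_distance",
    "recentre",
    "assign_half",
    "locate_genes",
]


def gene_midpoint(start_bp, end_bp, length_bp):
    """Midpoint of a (possibly origin-wrapping) gene on a circle of length L.

    Wrap is encoded as ``end_bp <= start_bp`` and resolved by unwrapping the
    end past L: ``floor((start + end + L) / 2) mod L``.
    """
    if np.any(np.asarray(length_bp) <= 0):
        raise ValueError("chromosome length must be positive")
    start = np.asarray(start_bp, dtype=np.int64)
    end = np.asarray(end_bp, dtype=np.int64)
    L = np.asarray(length_bp, dtype=np.int64)
    unwrapped_end = np.where(end <= start, end + L, end)
    mid = ((start + unwrapped_end) // 2) % L
    return mid if mid.ndim else int(mid)


def circular_distance(pos, ori, length_bp):
    """Shortest arc distance between two positions; symmetric, <= L/2."""
    pos = np.asarray(pos, dtype=np.int64)
    ori = np.asarray(ori, dtype=np.int64)
    L = np.asarray(length_bp, dtype=np.int64)
    d = np.abs(pos - ori)
    out = np.minimum(d, L - d)
    return out if out.ndim else int(out)


def recentre(pos, ori, length_bp):
    """Signed offset from *ori*, clockwise positive, in ``(-L/2, L/2]``."""
    pos = np.asarray(pos, dtype=np.int64)
    ori = np.asarray(ori, dtype=np.int64)
    L = np.asarray(length_bp, dtype=np.int64)
    r = (pos - ori) % L
    out = np.where(r * 2 > L, r - L, r)
    return out if out.ndim else int(out)


def assign_half(dist_to_ori_bp, length_bp, pos=None, ori=None, ter_bp=None):
    """Assign ``upper`` (ori-proximal) or ``lower`` (ter-proximal).

    Equal-arc default: upper iff ``dist < L/4`` (tie -> lower).  When
    ``ter_bp`` is given the replichore arcs split at *ori* and *ter*; a
    position is upper iff its distance along its own arc from *ori* is less
    than half that arc's length (per-arc midpoint rule; requires ``pos`` and
    ``ori``).
    """
    L = np.asarray(length_bp, dtype=np.int64)
    if ter_bp is None:
        dist = np.asarray(dist_to_ori_bp, dtype=np.int64)
        upper = dist * 4 < L
    else:
        if pos is None or ori is None:
            raise ValueError("explicit ter requires pos and ori")
        pos = np.asarray(pos, dtype=np.int64)
        ori = np.asarray(ori, dtype=np.int64)
        ter = np.asarray(ter_bp, dtype=np.int64)
        arc_cw = (ter - ori) % L          # ori -> ter clockwise
        arc_ccw = L - arc_cw              # ori -> ter the other way
        d_cw = (pos - ori) % L
        on_cw = d_cw < arc_cw
        d_along = np.where(on_cw, d_cw, (ori - pos) % L)
        arc_len = np.where(on_cw, arc_cw, arc_ccw)
        upper = 2 * d_along < arc_len
    out = np.where(upper, "upper", "lower")
    return out if out.ndim else str(out)


def locate_genes(
    genes: pd.DataFrame,
    chroms: Sequence[ChromosomeDef] | Mapping[str, ChromosomeDef],
    position_rule: str = "midpoint",
) -> pd.DataFrame:
    """Annotate a gene table with circular geometry relative to *ori*.

    Adds midpoint_bp, dist_to_ori_bp, rel_dist, recentred_bp and half.  The
    representative position is the gene midpoint by default; ``start`` uses
    the annotated start coordinate instead.
    """
    if position_rule not in ("midpoint", "start"):
        raise ValueError("position_rule must be 'midpoint' or 'start'")
    if isinstance(chroms, Mapping):
        by_id = dict(chroms)
    else:
        by_id = {c.chrom_id: c for c in chroms}
    missing = set(genes["chrom_id"].unique()) - set(by_id)
    if missing:
        raise ValueError(f"no ChromosomeDef for chromosome(s): {sorted(missing)}")

    out = genes.copy()
    L = out["chrom_id"].map(lambda c: by_id[c].length_bp).to_numpy(dtype=np.int64)
    ori = out["chrom_id"].map(lambda c: by_id[c].ori_bp).to_numpy(dtype=np.int64)
    ter = out["chrom_id"].map(lambda c: by_id[c].ter_bp)
    has_ter = ter.notna().to_numpy()

    mid = gene_midpoint(out["start_bp"].to_numpy(), out["end_bp"].to_numpy(), L)
    pos = mid if position_rule == "midpoint" else out["start_bp"].to_numpy(dtype=np.int64)
    dist = circular_distance(pos, ori, L)
    out["chrom_length_bp"] = L
    out["midpoint_bp"] = mid
    out["dist_to_ori_bp"] = dist
    out["rel_dist"] = 2.0 * dist / L
    out["recentred_bp"] = recentre(pos, ori, L)

    half = np.asarray(assign_half(dist, L), dtype=object)
    if has_ter.any():
        idx = np.flatnonzero(has_ter)
        half[idx] = assign_half(
            dist[idx], L[idx], pos=pos[idx], ori=ori[idx],
            ter_bp=ter.to_numpy()[idx].astype(np.int64),
        )
    out["half"] = half
    return out


def loci_table(loci: pd.DataFrame) -> pd.DataFrame:
    """Canonical column order for the per-gene loci TSV."""
    cols = [
        "gene_id", "genome_id", "chrom_id", "cluster_id", "category",
        "start_bp", "end_bp", "strand", "midpoint_bp",
        "dist_to_ori_bp", "rel_dist", "recentred_bp", "half",
    ]
    return loci[[c for c in cols if c in loci.columns]]
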