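"""Genome-wide diversity-reduction maps (classic B and B').

A reduction map stores, on a fixed step grid of evaluation positions,
the log reduction factor

    log B(x; m_i, s_j, k) = -1/2 * sum_{g in class k} V_A,g(m_i, s_j)
                                    * q_flank(kappa=s_j, r_{x,g})^2

per (mutation rate, selection coefficient) grid cell and feature class.
For the B' map, ``V_A,g`` is the solved segment equilibrium variance
``(U - 2R)s``; for the classic map it is the mutation-selection-balance
variance ``U*s`` (the ``R = 0`` special case), which makes
``B_classic <= B'`` pointwise by construction.

The recombination fraction ``r_{x,g}`` between an evaluation position and
a segment is the Haldane-transformed map distance to the segment
midpoint.  Segments on other chromosomes contribute through ``r = 0.5``
exactly (an unlinked fitness-variance effect, not dropped).  Per-class
tensors are stored separately so inference can mix classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bgskit.genome import RecombMap, SegmentSet, FeatureTrack, haldane
from bgskit.theory import (
    GridAxes,
    PopulationContext,
    solve_equilibrium_grid,
)

__all__ = [
    "ReductionMap",
    "compute_bprime",
    "compute_classic_b",
    "window_mean_B",
    "local_rescale",
    "solve_segment_equilibria",
]

_UNLINKED_R = 0.5


@dataclass
class ReductionMap:
    """Log-reduction tensors over positions x m-grid x s-grid x class.

    ``positions[chrom]`` are left edges of the evaluation step grid;
    ``logB[chrom]`` has shape (n_pos, n_m, n_s, n_class), float32,
    non-positive and finite.  ``kind`` is "bprime" or "classic".
    """

    positions: dict
    logB: dict
    grid: GridAxes
    classes: list
    step: int
    kind: str
    N: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def chroms(self):
        return sorted(self.positions)

    def total_logB(self, chrom) -> np.ndarray:
        """Sum over classes: log B(x; m_i, s_j) with all classes present."""
        return self.logB[chrom].sum(axis=3)

    def B_at(self, chrom, i: int, j: int) -> np.ndarray:
        return np.exp(self.total_logB(chrom)[:, i, j])

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind,
            "step": self.step,
            "N": self.N,
            "classes": list(self.classes),
            "s_values": self.grid.s_values.tolist(),
            "m_values": self.grid.m_values.tolist(),
            "chroms": self.chroms,
            "metadata": self.metadata,
        }
        (outdir / "map.json").write_text(json.dumps(meta, indent=2))
        for chrom in self.chroms:
            np.save(outdir / f"{chrom}.positions.npy", self.positions[chrom])
            np.save(outdir / f"{chrom}.logB.npy", self.logB[chrom])

    @classmethod
    def load(cls, outdir) -> "ReductionMap":
        outdir = Path(outdir)
        meta = json.loads((outdir / "map.json").read_text())
        grid = GridAxes(np.array(meta["s_values"]), np.array(meta["m_values"]))
        positions, logB = {}, {}
        for chrom in meta["chroms"]:
            positions[chrom] = np.load(outdir / f"{chrom}.positions.npy")
            logB[chrom] = np.load(outdir / f"{chrom}.logB.npy")
        return cls(
            positions=positions,
            logB=logB,
            grid=grid,
            classes=meta["classes"],
            step=meta["step"],
            kind=meta["kind"],
            N=meta["N"],
            metadata=meta.get("metadata", {}),
        )

    def to_bedgraph(self, path, i: int, j: int):
        """Export total B for one grid cell as BedGraph."""
        with open(path, "w") as fh:
            for chrom in self.chroms:
                pos = self.positions[chrom]
                b = self.B_at(chrom, i, j)
                for p, v in zip(pos, b):
                    fh.write(f"{chrom}\t{int(p)}\t{int(p) + self.step}\t{v:.6g}\n")


def solve_segment_equilibria(
    segments: SegmentSet,
    pop: PopulationContext,
    grid: GridAxes,
    rescale: np.ndarray | None = None,
) -> np.ndarray:
    """Equilibrium V_A for every segment over the grid.

    Returns ``VA[n_seg, n_m, n_s]``.  ``rescale`` optionally gives a
    per-segment factor in (0, 1] applied to N (local rescaling).  Results
    are cached per unique (L, M, rescale) triple.
    """
    df = segments.df
    if "M" not in df.columns:
        raise ValueError("segments must be map-annotated (run annotate_map)")
    nm, ns = grid.shape
    VA = np.empty((len(df), nm, ns))
    cache = {}
    resc = np.ones(len(df)) if rescale is None else np.asarray(rescale, float)
    if np.any(resc <= 0):
        raise ValueError("rescale factors must be positive")
    for g, row in enumerate(df.itertuples(index=False)):
        key = (row.L, row.M, resc[g])
        if key not in cache:
            p = PopulationContext(N=pop.N, rescale=min(1.0, pop.rescale * resc[g]))
            _, _, va = solve_equilibrium_grid(int(row.L), float(row.M), p, grid)
            cache[key] = va
        VA[g] = cache[key]
    return VA


def _classic_va(segments: SegmentSet, grid: GridAxes) -> np.ndarray:
    """Mutation-selection-balance V_A = U*s per segment and grid cell."""
    L = segments.df["L"].values.astype(float)
    m = grid.m_values
    s = grid.s_values
    return 2.0 * L[:, None, None] * m[None, :, None] * s[None, None, :]


def _eval_positions(chrom_lengths: dict, step: int) -> dict:
    return {
        chrom: np.arange(0, int(length), step, dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }


def _chrom_lengths_from_map(recmap: RecombMap) -> dict:
    return {chrom: int(pos[-1]) for chrom, (pos, _) in recmap.maps.items()}


def _assemble_map(
    segments: SegmentSet,
    recmap: RecombMap,
    grid: GridAxes,
    VA: np.ndarray,
    step: int,
    chrom_lengths: dict | None,
    floor: float,
    kind: str,
    N: float | None,
    chunk: int = 4096,
) -> ReductionMap:
    if chrom_lengths is None:
        chrom_lengths = _chrom_lengths_from_map(recmap)
    classes = segments.class_labels
    class_idx = {c: k for k, c in enumerate(classes)}
    df = segments.df
    seg_chrom = df["chrom"].values
    seg_mid = df["map_midpoint"].values
    seg_k = np.array([class_idx[c] for c in df["class_label"].values])
    nm, ns = grid.shape
    nk = len(classes)
    s_vals = grid.s_values

    # unlinked (other-chromosome) V_A totals per class
    va_class = np.zeros((nk, nm, ns))
    for k in range(nk):
        va_class[k] = VA[seg_k == k].sum(axis=0)
    va_by_chrom = {}
    for chrom in chrom_lengths:
        on = seg_chrom == chrom
        va_on = np.zeros((nk, nm, ns))
        for k in range(nk):
            va_on[k] = VA[on & (seg_k == k)].sum(axis=0)
        va_by_chrom[chrom] = va_on

    q_unlinked = 1.0 / (s_vals + _UNLINKED_R * (1.0 - s_vals)) ** 2  # (ns,)

    positions = _eval_positions(chrom_lengths, step)
    logB = {}
    for chrom, pos in positions.items():
        tensor = np.zeros((len(pos), nm, ns, nk), dtype=np.float64)
        # unlinked contribution from segments on other chromosomes
        va_other = va_class - va_by_chrom.get(chrom, 0.0)
        tensor -= 0.5 * np.einsum(
            "kij,j->ijk", va_other, q_unlinked
        )[None, :, :, :]
        on = np.flatnonzero(seg_chrom == chrom)
        if len(on):
            mids = seg_mid[on]
            ks = seg_k[on]
            va_on = VA[on]  # (n_on, nm, ns)
            map_pos = recmap.map_at(chrom, pos.astype(float))
            for a in range(0, len(pos), chunk):
                mp = map_pos[a : a + chunk]
                d = np.abs(mp[:, None] - mids[None, :])
                r = haldane(d)
                for j, s in enumerate(s_vals):
                    q2 = 1.0 / (s + r * (1.0 - s)) ** 2  # (chunk, n_on)
                    for k in range(nk):
                        sel = ks == k
                        if not np.any(sel):
                            continue
                        vam = va_on[sel, :, j]  # (ng, nm)
                        if floor > 0:
                            # truncate segments whose contribution is below
                            # the floor at every position of this chunk
                            q2max = q2[:, sel].max(axis=0)
                            vam = np.where(
                                0.5 * vam * q2max[:, None] >= floor, vam, 0.0
                            )
                        tensor[a : a + chunk, :, j, k] -= 0.5 * q2[:, sel] @ vam
        logB[chrom] = np.minimum(tensor, 0.0).astype(np.float32)
    return ReductionMap(
        positions=positions,
        logB=logB,
        grid=grid,
        classes=classes,
        step=step,
        kind=kind,
        N=N,
        metadata={"n_segments": len(df)},
    )


def compute_bprime(
    segments: SegmentSet,
    recmap: RecombMap,
    pop: PopulationContext,
    grid: GridAxes,
    step: int = 10_000,
    chrom_lengths: dict | None = None,
    floor: float = 1e-10,
    rescale: np.ndarray | None = None,
) -> ReductionMap:
    """B' reduction map from solved segment equilibria over the grid."""
    VA = solve_segment_equilibria(segments, pop, grid, rescale=rescale)
    return _assemble_map(
        segments, recmap, grid, VA, step, chrom_lengths, floor, "bprime", pop.N
    )


def compute_classic_b(
    segments: SegmentSet,
    recmap: RecombMap,
    grid: GridAxes,
    step: int = 10_000,
    chrom_lengths: dict | None = None,
    floor: float = 1e-10,
) -> ReductionMap:
    """Classic-BGS reduction map (independent of N)."""
    if np.any(grid.s_values <= 0):
        warnings.warn("classic model undefined at s = 0; such cells excluded")
    VA = _classic_va(segments, grid)
    return _assemble_map(
        segments, recmap, grid, VA, step, chrom_lengths, floor, "classic", None
    )


def position_weights(rmap: ReductionMap, mask: FeatureTrack | None) -> dict:
    """Accessibility weight of each evaluation position: the fraction of
    its [x, x+step) bin covered by the mask (1 everywhere if no mask)."""
    out = {}
    for chrom in rmap.chroms:
        pos = rmap.positions[chrom]
        if mask is None:
            out[chrom] = np.ones(len(pos))
            continue
        w = np.zeros(len(pos))
        sub = mask.intervals[mask.intervals["chrom"] == chrom]
        for s, e in zip(sub["start"].values, sub["end"].values):
            lo = np.searchsorted(pos + rmap.step, s, side="right")
            hi = np.searchsorted(pos, e, side="left")
            for idx in range(lo, hi):
                ov = min(e, pos[idx] + rmap.step) - max(s, pos[idx])
                w[idx] += max(0, ov)
        out[chrom] = w / rmap.step
    return out


def window_mean_B(
    rmap: ReductionMap,
    width: int,
    mask: FeatureTrack | None = None,
) -> pd.DataFrame:
    """Mask-weighted arithmetic window means of B per grid cell.

    Returns a tidy frame (chrom, start, end, accessible_weight) plus a
    ``Bbar`` object column holding the (n_m, n_s) mean-B matrix (classes
    summed in log space); windows with no accessible positions are
    flagged ``excluded``.
    """
    weights = position_weights(rmap, mask)
    rows = []
    for chrom in rmap.chroms:
        pos = rmap.positions[chrom]
        total = rmap.total_logB(chrom)  # (n_pos, nm, ns)
        B = np.exp(total)
        w = weights[chrom]
        widx = (pos // width).astype(int)
        for b in range(widx.max() + 1):
            in_b = widx == b
            wsum = w[in_b].sum()
            if wsum > 0:
                bbar = np.tensordot(w[in_b], B[in_b], axes=(0, 0)) / wsum
                excluded = False
            else:
                bbar = np.full(rmap.grid.shape, np.nan)
                excluded = True
            rows.append(
                {
                    "chrom": chrom,
                    "start": b * width,
                    "end": (b + 1) * width,
                    "accessible_weight": wsum,
                    "Bbar": bbar,
                    "excluded": excluded,
                }
            )
    return pd.DataFrame(rows)


def local_rescale(
    segments: SegmentSet,
    recmap: RecombMap,
    pop: PopulationContext,
    grid: GridAxes,
    bhat: dict,
    step: int = 10_000,
    chrom_lengths: dict | None = None,
    avg_scale: int = 1_000,
    floor: float = 1e-10,
) -> ReductionMap:
    """Re-solve segment equilibria with N replaced by B_hat(x_g) * N.

    ``bhat`` maps chromosome -> (positions_bp, B_hat values); the factor
    for each segment is B_hat averaged over ``avg_scale`` bp around the
    segment midpoint.  Identical to :func:`compute_bprime` when
    ``B_hat = 1`` everywhere, and for strongly selected cells.
    """
    df = segments.df
    resc = np.empty(len(df))
    for g, row in enumerate(df.itertuples(index=False)):
        if row.chrom not in bhat:
            raise ValueError(f"B_hat undefined for chromosome {row.chrom!r}")
        bpos, bval = bhat[row.chrom]
        bval = np.asarray(bval, dtype=float)
        if np.any(bval <= 0):
            raise ValueError("B_hat must be positive everywhere")
        mid = 0.5 * (row.start + row.end)
        in_win = (bpos >= mid - avg_scale / 2) & (bpos <= mid + avg_scale / 2)
        resc[g] = bval[in_win].mean() if np.any(in_win) else np.interp(
            mid, bpos, bval
        )
    out = compute_bprime(
        segments,
        recmap,
        pop,
        grid,
        step=step,
        chrom_lengths=chrom_lengths,
        floor=floor,
        rescale=resc,
    )
    out.kind = "bprime-rescaled"
    out.metadata["avg_scale"] = avg_scale
    return out
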