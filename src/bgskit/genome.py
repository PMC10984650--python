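"""Genomic input handling: feature tracks, recombination maps, masks,
allele counts, and the segment / window containers the theory operates on.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Strand is ignored throughout: the selection model is strand-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTrack",
    "RecombMap",
    "SegmentSet",
    "WindowedDiversity",
    "read_features",
    "assign_priority",
    "annotate_map",
    "windowed_diversity",
    "haldane",
    "inverse_haldane",
]


def haldane(d):
    """Map distance (Morgans) -> recombination fraction, capped at 0.5."""
    return 0.5 * -np.expm1(-2.0 * np.asarray(d, dtype=float))


def inverse_haldane(r):
    """Recombination fraction -> map distance in Morgans."""
    return -0.5 * np.log1p(-2.0 * np.asarray(r, dtype=float))


def _merge_intervals(starts, ends):
    """Merge sorted, possibly overlapping intervals (arrays)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def _subtract_intervals(starts, ends, sub_s, sub_e):
    """Set-subtract merged intervals (sub) from merged intervals."""
    out_s, out_e = [], []
    j = 0
    for s, e in zip(starts, ends):
        cur = s
        while j < len(sub_s) and sub_e[j] <= cur:
            j += 1
        k = j
        while k < len(sub_s) and sub_s[k] < e:
            if sub_s[k] > cur:
                out_s.append(cur)
                out_e.append(sub_s[k])
            cur = max(cur, sub_e[k])
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=int), np.array(out_e, dtype=int)


@dataclass
class FeatureTrack:
    """A set of intervals sharing one feature class label.

    ``intervals`` is a DataFrame with columns (chrom, start, end), sorted
    and non-overlapping after normalization.
    """

    intervals: pd.DataFrame
    class_label: str

    def __post_init__(self):
        df = self.intervals
        if len(df) and np.any(df["start"].values >= df["end"].values):
            raise ValueError("intervals require start < end")

    @classmethod
    def from_arrays(cls, chroms, starts, ends, class_label):
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        return cls(normalize_intervals(df), class_label)

    def __len__(self):
        return len(self.intervals)

    def total_bp(self) -> int:
        if not len(self.intervals):
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def by_chrom(self):
        for chrom, sub in self.intervals.groupby("chrom", sort=True):
            yield chrom, sub["start"].values, sub["end"].values

    def to_bed(self, path):
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


def normalize_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping intervals per chromosome."""
    parts = []
    for chrom, sub in df.groupby("chrom", sort=True):
        s, e = _merge_intervals(
            sub["start"].values.astype(int), sub["end"].values.astype(int)
        )
        parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(parts, ignore_index=True)


def read_features(path, class_label: str) -> FeatureTrack:
    """Read a BED file (3+ columns, 0-based half-open) as one feature class.

    Overlapping records are merged (with a warning); records with
    ``end <= start`` are rejected with an error log entry.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    bad = df["start"] >= df["end"] if len(df) else pd.Series(dtype=bool)
    if len(df) and bad.any():
        for _, row in df[bad].iterrows():
            logger.error(
                "rejecting BED record with end <= start: %s:%s-%s",
                row["chrom"], row["start"], row["end"],
            )
        df = df[~bad]
    merged = normalize_intervals(df)
    if len(merged) < len(df):
        warnings.warn(
            f"{path}: merged {len(df) - len(merged)} overlapping record(s) "
            f"in class {class_label!r}",
            stacklevel=2,
        )
    return FeatureTrack(merged, class_label)


@dataclass
class SegmentSet:
    """Disjoint, classified conserved segments.

    ``df`` columns: chrom, start, end, class_label, L and (after
    :func:`annotate_map`) M (internal map length, Morgans) and
    map_midpoint (cumulative map position of the segment midpoint).
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        if "L" not in df.columns:
            df = df.assign(L=df["end"] - df["start"])
            self.df = df
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("start")
            if np.any(sub["start"].values[1:] < sub["end"].values[:-1]):
                raise ValueError(f"segments overlap on {chrom}")

    def __len__(self):
        return len(self.df)

    @property
    def class_labels(self):
        return sorted(self.df["class_label"].unique())

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def split_long(self, max_map_length: float = 1e-3) -> "SegmentSet":
        """Split segments whose internal map length exceeds ``max_map_length``.

        Keeps the single-recombination-fraction approximation of the
        reduction map accurate; requires :func:`annotate_map` first.
        """
        if "M" not in self.df.columns:
            raise ValueError("annotate_map must be run before split_long")
        rows = []
        for row in self.df.itertuples(index=False):
            n = max(1, int(np.ceil(row.M / max_map_length)))
            if n == 1:
                rows.append(row._asdict())
                continue
            cuts = np.linspace(row.start, row.end, n + 1).astype(int)
            for a, b in zip(cuts[:-1], cuts[1:]):
                if b > a:
                    d = dict(row._asdict())
                    d.update(start=int(a), end=int(b), L=int(b - a))
                    d.pop("M", None)
                    d.pop("map_midpoint", None)
                    rows.append(d)
        out = pd.DataFrame(rows)
        return SegmentSet(out[["chrom", "start", "end", "class_label", "L"]])


def assign_priority(
    tracks: list[FeatureTrack],
    priority: list[str],
    fill_other: dict | None = None,
) -> SegmentSet:
    """Assign every basepair to exactly one feature class by priority.

    Overlapping basepairs go to the highest-priority (earliest in
    ``priority``) class; contiguous same-class runs become segments.  With
    ``fill_other`` (a ``{chrom: length}`` dict), the remainder of each
    chromosome becomes an ``"other"`` class, yielding a full-track model.
    """
    by_label = {t.class_label: t for t in tracks}
    unknown = set(by_label) - set(priority)
    if unknown:
        raise ValueError(f"classes missing from priority list: {sorted(unknown)}")
    chroms = sorted({c for t in tracks for c in t.intervals["chrom"].unique()})
    if fill_other:
        chroms = sorted(set(chroms) | set(fill_other))
    rows = []
    for chrom in chroms:
        taken_s = np.array([], dtype=int)
        taken_e = np.array([], dtype=int)
        for label in priority:
            track = by_label.get(label)
            if track is None:
                continue
            sub = track.intervals[track.intervals["chrom"] == chrom]
            s, e = sub["start"].values.astype(int), sub["end"].values.astype(int)
            keep_s, keep_e = _subtract_intervals(s, e, taken_s, taken_e)
            for a, b in zip(keep_s, keep_e):
                rows.append((chrom, int(a), int(b), label))
            taken_s, taken_e = _merge_intervals(
                np.concatenate([taken_s, keep_s]),
                np.concatenate([taken_e, keep_e]),
            )
        if fill_other:
            rest_s, rest_e = _subtract_intervals(
                np.array([0]), np.array([int(fill_other[chrom])]), taken_s, taken_e
            )
            for a, b in zip(rest_s, rest_e):
                rows.append((chrom, int(a), int(b), "other"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "class_label"])
    df = df.sort_values(["chrom", "start"], ignore_index=True)
    # merge adjacent same-class runs
    merged = []
    for row in df.itertuples(index=False):
        if (
            merged
            and merged[-1][0] == row.chrom
            and merged[-1][2] == row.start
            and merged[-1][3] == row.class_label
        ):
            merged[-1][2] = row.end
        else:
            merged.append([row.chrom, row.start, row.end, row.class_label])
    out = pd.DataFrame(merged, columns=["chrom", "start", "end", "class_label"])
    return SegmentSet(out)


@dataclass
class RecombMap:
    """Piecewise-linear cumulative genetic map per chromosome.

    ``maps`` maps chromosome name to ``(positions_bp, cumulative_morgans)``
    with strictly increasing positions and non-decreasing cumulative map.
    """

    maps: dict

    def __post_init__(self):
        for chrom, (pos, cum) in self.maps.items():
            pos = np.asarray(pos, dtype=float)
            cum = np.asarray(cum, dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if np.any(np.diff(cum) < 0):
                raise ValueError(f"{chrom}: cumulative map must be non-decreasing")
            self.maps[chrom] = (pos, cum)

    @classmethod
    def uniform(cls, chrom_lengths: dict, rate_cm_per_mb: float = 1.0) -> "RecombMap":
        """Constant-rate map (rate in cM/Mb) over given chromosome lengths."""
        rate = rate_cm_per_mb * 1e-8  # Morgans per bp
        return cls(
            {
                c: (np.array([0.0, float(ln)]), np.array([0.0, rate * ln]))
                for c, ln in chrom_lengths.items()
            }
        )

    @classmethod
    def read_tsv(cls, path) -> "RecombMap":
        """Read a HapMap-dialect map: (chrom, pos, rate cM/Mb, cum cM),
        or the two-column dialect (chrom, pos, cum cM).  A header line is
        detected and skipped."""
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
        # drop a header row if the position column is not numeric
        if not str(df.iloc[0, 1]).replace(".", "", 1).lstrip("-").isdigit():
            df = df.iloc[1:]
        ncol = df.shape[1]
        if ncol >= 4:
            df = df.iloc[:, [0, 1, 3]]
        elif ncol == 3:
            df = df.iloc[:, [0, 1, 2]]
        else:
            raise ValueError("recombination map needs >= 3 columns")
        df.columns = ["chrom", "pos", "cum_cM"]
        maps = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            pos = sub["pos"].astype(float).values
            cum = sub["cum_cM"].astype(float).values / 100.0  # cM -> Morgans
            order = np.argsort(pos)
            maps[str(chrom)] = (pos[order], cum[order])
        return cls(maps)

    def to_tsv(self, path):
        rows = []
        for chrom, (pos, cum) in sorted(self.maps.items()):
            rate = np.append(np.diff(cum) / np.diff(pos) * 1e8, 0.0)  # cM/Mb
            for p, r, c in zip(pos, rate, cum):
                rows.append((chrom, int(p), r, c * 100.0))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def map_at(self, chrom: str, pos_bp) -> np.ndarray:
        """Cumulative map value (Morgans) at position(s), clamped to extent."""
        if chrom not in self.maps:
            raise KeyError(f"chromosome {chrom!r} missing from recombination map")
        knots, cum = self.maps[chrom]
        pos_bp = np.asarray(pos_bp, dtype=float)
        if np.any(pos_bp < knots[0]) or np.any(pos_bp > knots[-1]):
            warnings.warn(
                f"{chrom}: positions outside map extent clamped to nearest knot",
                stacklevel=2,
            )
        out = np.interp(pos_bp, knots, cum)
        return float(out) if out.ndim == 0 else out


def annotate_map(segments: SegmentSet, recmap: RecombMap) -> SegmentSet:
    """Attach M (internal map length) and map_midpoint to each segment.

    Linear interpolation between map knots; a segment spanning knots picks
    up the sum of the piecewise contributions automatically through the
    cumulative map.
    """
    df = segments.df.copy()
    M = np.empty(len(df))
    mid = np.empty(len(df))
    for chrom, idx in df.groupby("chrom").groups.items():
        sub = df.loc[idx]
        a = recmap.map_at(chrom, sub["start"].values)
        b = recmap.map_at(chrom, sub["end"].values)
        M[df.index.get_indexer(idx)] = b - a
        mid[df.index.get_indexer(idx)] = recmap.map_at(
            chrom, (sub["start"].values + sub["end"].values) / 2.0
        )
    df["M"] = M
    df["map_midpoint"] = mid
    return SegmentSet(df)


@dataclass
class WindowedDiversity:
    """Per-window pairwise difference counts.

    ``df`` columns: chrom, start, end, Y (differing pairwise comparisons),
    n (total pairwise comparisons), accessible_bp.  Windows tile each
    chromosome at a fixed width; windows with n = 0 are flagged via the
    ``excluded`` column.
    """

    df: pd.DataFrame
    width: int | None = None

    def __post_init__(self):
        if np.any(self.df["Y"].values > self.df["n"].values):
            raise ValueError("Y must be <= n in every window")
        if "excluded" not in self.df.columns:
            self.df = self.df.assign(excluded=self.df["n"].values == 0)

    def __len__(self):
        return len(self.df)

    @property
    def pi(self) -> np.ndarray:
        """Observed diversity Y/n per window (NaN where excluded)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.df["n"].values > 0,
                self.df["Y"].values / self.df["n"].values,
                np.nan,
            )

    def to_tsv(self, path):
        cols = ["chrom", "start", "end", "Y", "n", "accessible_bp"]
        self.df[cols].to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path, width=None):
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        names = ["chrom", "start", "end", "Y", "n", "accessible_bp"][: df.shape[1]]
        df.columns = names
        if "accessible_bp" not in df.columns:
            df["accessible_bp"] = df["end"] - df["start"]
        return cls(df, width=width)


def _site_in_mask(chrom, pos, mask: FeatureTrack | None):
    if mask is None:
        return np.ones(len(pos), dtype=bool)
    sub = mask.intervals[mask.intervals["chrom"] == chrom]
    starts = sub["start"].values
    ends = sub["end"].values
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < ends[idx[ok]]
    return ok


def windowed_diversity(
    counts: pd.DataFrame,
    mask: FeatureTrack | None,
    width: int,
    chrom_lengths: dict | None = None,
) -> WindowedDiversity:
    """Summarize a per-site biallelic allele-count table into windows.

    Each accessible site with ``n = n_ref + n_alt`` observed chromosomes
    adds ``n_ref * n_alt`` differing and ``n*(n-1)/2`` total pairwise
    comparisons to its window; monomorphic sites contribute only to the
    total.  Sites with ``n < 2`` are skipped (counted); masked-out sites
    contribute nothing.  ``n`` is the per-site observed allele count, so
    diversity stays unbiased under missing genotypes.
    """
    required = {"chrom", "pos", "n_ref", "n_alt"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(np.ceil((sub["pos"].max() + 1) / width) * width)
            for c, sub in counts.groupby("chrom")
        }
    rows = []
    n_skipped = 0
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        nwin = int(np.ceil(length / width))
        Y = np.zeros(nwin)
        n = np.zeros(nwin)
        acc = np.zeros(nwin, dtype=int)
        sub = counts[counts["chrom"] == chrom]
        if len(sub):
            pos = sub["pos"].values.astype(int)
            nref = sub["n_ref"].values.astype(np.int64)
            nalt = sub["n_alt"].values.astype(np.int64)
            tot = nref + nalt
            keep = _site_in_mask(chrom, pos, mask)
            n_skipped += int(np.sum(keep & (tot < 2)))
            keep &= tot >= 2
            pos, nref, nalt, tot = pos[keep], nref[keep], nalt[keep], tot[keep]
            widx = pos // width
            np.add.at(Y, widx, nref * nalt)
            np.add.at(n, widx, tot * (tot - 1) // 2)
            np.add.at(acc, widx, 1)
        starts = np.arange(nwin) * width
        ends = np.minimum(starts + width, length)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "Y": Y,
                    "n": n,
                    "accessible_bp": acc,
                }
            )
        )
    if n_skipped:
        logger.info("skipped %d site(s) with n < 2", n_skipped)
    df = pd.concat(rows, ignore_index=True)
    return WindowedDiversity(df, width=width)
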