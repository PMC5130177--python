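"""Interval algebra over peak sets, promoters and TSS metaprofiles.

All coordinates are 0-based half-open (BED convention).  Interval sets are
plain pandas frames with columns chrom/start/end (+ optional name, score,
strand), kept sorted by (chrom, start, end).  Merge unions overlapping or
bookended intervals (gap <= max_gap, default 0 so touching intervals merge);
intersection is a sweep over start-sorted intervals with an active heap, so
pairs come out in O(n + m + k) time and match the brute-force base-set
definition exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class BedParseError(ValueError):
    """Malformed BED/bedGraph line (message carries the line number)."""


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"interval frame missing column {col!r}")
    if ((df["end"] <= df["start"]) | (df["start"] < 0)).any():
        bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)].index[:3].tolist()
        raise ValueError(f"invalid intervals (need 0 <= start < end) at rows {bad}")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Union overlapping/near intervals; gap <= max_gap merges (0 = bookended).

    Output is disjoint, sorted, and preserves total covered bases.
    """
    validate_intervals(df)
    if len(df) == 0:
        return df[["chrom", "start", "end"]].copy()
    s = sort_intervals(df)
    rows = []
    cur_chrom, cur_start, cur_end = None, None, None
    for chrom, start, end in zip(s["chrom"], s["start"], s["end"]):
        if chrom != cur_chrom or start > cur_end + max_gap:
            if cur_chrom is not None:
                rows.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
        else:
            cur_end = max(cur_end, end)
    rows.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _sweep_pairs_chrom(
    a_start: np.ndarray,
    a_end: np.ndarray,
    b_start: np.ndarray,
    b_end: np.ndarray,
    min_overlap: int,
) -> list[tuple[int, int]]:
    """Overlapping (i, j) pairs within one chromosome, both start-sorted."""
    pairs: list[tuple[int, int]] = []
    active: list[tuple[int, int]] = []  # (b_end, b_idx), min-heap on end
    j = 0
    nb = len(b_start)
    for i in range(len(a_start)):
        s, e = a_start[i], a_end[i]
        while j < nb and b_start[j] < e:
            heapq.heappush(active, (b_end[j], j))
            j += 1
        while active and active[0][0] <= s:
            heapq.heappop(active)
        for be, bj in active:
            ov = min(e, be) - max(s, b_start[bj])
            if ov >= min_overlap:
                pairs.append((i, bj))
    return pairs


def intersect_intervals(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> tuple[np.ndarray, pd.DataFrame]:
    """For each interval of ``a``: does it overlap any of ``b`` by >= min_overlap.

    Returns (flags aligned to the sorted ``a``, frame of overlapping index
    pairs).  Unsorted inputs are sorted internally.
    """
    validate_intervals(a)
    validate_intervals(b)
    a_s = sort_intervals(a)
    b_s = sort_intervals(b)
    flags = np.zeros(len(a_s), dtype=bool)
    all_pairs = []
    for chrom in a_s["chrom"].unique():
        am = a_s["chrom"] == chrom
        bm = b_s["chrom"] == chrom
        if not bm.any():
            continue
        a_idx = np.flatnonzero(am.to_numpy())
        b_idx = np.flatnonzero(bm.to_numpy())
        pairs = _sweep_pairs_chrom(
            a_s.loc[am, "start"].to_numpy(),
            a_s.loc[am, "end"].to_numpy(),
            b_s.loc[bm, "start"].to_numpy(),
            b_s.loc[bm, "end"].to_numpy(),
            min_overlap,
        )
        for i, jj in pairs:
            flags[a_idx[i]] = True
            all_pairs.append((a_idx[i], b_idx[jj]))
    pairs_df = pd.DataFrame(all_pairs, columns=["a_index", "b_index"])
    return flags, pairs_df


def condition_overlap_partition(
    sets: dict[str, pd.DataFrame],
) -> tuple[dict[str, int], pd.DataFrame]:
    """Venn partition of 2-3 named peak sets on the merged union space.

    Each interval of the merged union is labeled by the '+'-joined names of
    the sets overlapping it (name order as given).  Returns (counts per
    label, union frame with a ``label`` column).
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("condition_overlap_partition supports 2-3 sets")
    union = merge_intervals(pd.concat([sets[n] for n in names], ignore_index=True))
    member = {}
    for n in names:
        flags, _ = intersect_intervals(union, sets[n])
        member[n] = flags
    labels = [
        "+".join(n for n in names if member[n][i]) for i in range(len(union))
    ]
    out = union.copy()
    out["label"] = labels
    counts: dict[str, int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            counts["+".join(combo)] = 0
    for lab in labels:
        counts[lab] += 1
    return counts, out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int


def genes_frame(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "tss": g.tss, "start": g.start, "end": g.end}
            for g in genes
        ]
    ).set_index("gene_id")


def define_promoters(
    genes: pd.DataFrame, upstream: int = 1000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS, clipped at 0.

    '+' genes get [tss - upstream, tss + downstream); '-' genes the mirror
    [tss - downstream, tss + upstream).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - upstream, genes["tss"] - downstream)
    end = np.where(plus, genes["tss"] + downstream, genes["tss"] + upstream)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(start, 0).astype(int),
            "end": end.astype(int),
            "name": genes.index.to_numpy(),
            "score": 0,
            "strand": genes["strand"].to_numpy(),
        }
    )
    return sort_intervals(out)


@dataclass
class MetaProfile:
    """Mean signal per TSS-relative bin over a gene set."""

    offsets: np.ndarray   # bin start offsets relative to the TSS
    mean: np.ndarray
    n_sites: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "n_sites": self.n_sites})


def _coverage_lookup(track: pd.DataFrame):
    """Per-chrom arrays for vectorized point queries into a bedGraph track."""
    by = {}
    for chrom, sub in track.groupby("chrom"):
        s = sub.sort_values("start")
        by[chrom] = (
            s["start"].to_numpy(int), s["end"].to_numpy(int),
            s["value"].to_numpy(float),
        )
    return by


def tss_metaprofile(
    coverage: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 2000,
    binsize: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> MetaProfile:
    """Average per-base coverage in TSS-centered bins, strand aware.

    '+'-strand sites contribute bases [tss - window, tss + window) left to
    right; '-'-strand sites contribute the same bases reversed.  Sites whose
    window leaves the contig (start < 0, or beyond a provided chrom size, or
    on a chrom absent from the track) are excluded and counted.
    """
    if window % binsize != 0:
        raise ValueError("window must be divisible by binsize")
    if len(genes) == 0:
        raise ValueError("empty gene list")
    lookup = _coverage_lookup(coverage)
    n_bins = 2 * window // binsize
    total = np.zeros(n_bins)
    n_sites = 0
    n_excluded = 0
    for gene_id, row in genes.iterrows():
        chrom, tss, strand = row["chrom"], int(row["tss"]), row["strand"]
        lo, hi = tss - window, tss + window
        if chrom not in lookup or lo < 0 or (
            chrom_sizes is not None and hi > chrom_sizes.get(chrom, np.inf)
        ):
            n_excluded += 1
            continue
        starts, ends, values = lookup[chrom]
        pos = np.arange(lo, hi)
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        base = np.where(valid, values[np.clip(idx, 0, len(values) - 1)], 0.0)
        if strand == "-":
            base = base[::-1]
        total += base.reshape(n_bins, binsize).mean(axis=1)
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no usable TSS sites (all excluded)")
    offsets = np.arange(-window, window, binsize)
    return MetaProfile(offsets=offsets, mean=total / n_sites,
                       n_sites=n_sites, n_excluded=n_excluded)


# --- BED / bedGraph I/O -----------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3-BED6 into an interval frame (errors carry line numbers)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            if not 0 <= start < end:
                raise BedParseError(f"line {lineno}: need 0 <= start < end")
            row = {"chrom": parts[0], "start": start, "end": end}
            for key, val in zip(("name", "score", "strand"), parts[3:6]):
                row[key] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0)
    return sort_intervals(df) if len(df) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    out = df[cols].copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 fields")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: bad coordinate/value") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )
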