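"""Trans-eQTL hotspots: sliding-window counts, a chromosome-reassignment
permutation null, hotspot calling, and a co-localization permutation
test against previously mapped sterility QTL.

Windows are half-open [start, start + w) anchored at every grid
position; windows truncated at a chromosome end keep (and are judged
against) their true, shorter size. The null reassigns each trans eQTL
to a uniformly chosen grid position on a chromosome other than its
probe's chromosome, preserving both the per-probe eQTL count and the
trans definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import GeneticMap, SterilityQtlInterval, cm_to_mb
from .catalog import EqtlRecord
from .genoprob import build_grid

_SIZE_DECIMALS = 6


@dataclass
class WindowCount:
    chrom: str
    lo_cm: float
    hi_cm: float  # true (possibly truncated) end
    size_cm: float
    count: int


@dataclass
class Hotspot:
    chrom: str
    lo_cm: float
    hi_cm: float
    count: int
    threshold: int
    lo_mb: float = float("nan")
    hi_mb: float = float("nan")
    sterile_allele: str = "undetermined"
    members: list = field(default_factory=list)

    @property
    def size_cm(self) -> float:
        return self.hi_cm - self.lo_cm


def genome_grid(gmap: GeneticMap, step_cm: float = 2.0) -> dict[str, np.ndarray]:
    """Marker + pseudomarker anchor positions per chromosome."""
    return {c.name: build_grid(c, step_cm)[0] for c in gmap.chromosomes}


def _chrom_windows(grid: np.ndarray, window_cm: float) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) arrays of windows anchored at every grid position,
    truncated at the chromosome end."""
    end = grid[-1]
    lo = grid.copy()
    hi = np.minimum(lo + window_cm, end)
    return lo, hi


def _count_in_windows(
    peaks: np.ndarray, lo: np.ndarray, hi: np.ndarray, chrom_end: float
) -> np.ndarray:
    """Count peaks in [lo, hi); windows reaching the chromosome end are
    closed there so the terminal position is never lost."""
    peaks = np.sort(peaks)
    left = np.searchsorted(peaks, lo, side="left")
    right = np.where(
        hi >= chrom_end,
        np.searchsorted(peaks, hi, side="right"),
        np.searchsorted(peaks, hi, side="left"),
    )
    return right - left


def window_counts(
    records: list[EqtlRecord],
    gmap: GeneticMap,
    window_cm: float = 4.0,
    step_cm: float = 2.0,
) -> list[WindowCount]:
    grids = genome_grid(gmap, step_cm)
    by_chrom: dict[str, list[float]] = {c: [] for c in grids}
    for r in records:
        by_chrom[r.chrom].append(r.pos_cm)
    out: list[WindowCount] = []
    for chrom, grid in grids.items():
        lo, hi = _chrom_windows(grid, window_cm)
        counts = _count_in_windows(np.array(by_chrom[chrom]), lo, hi, grid[-1])
        for l, h, c in zip(lo, hi, counts):
            out.append(
                WindowCount(chrom, float(l), float(h), round(float(h - l), _SIZE_DECIMALS), int(c))
            )
    return out


class _WindowIndex:
    """Static geometry of the sliding windows over the genome grid.

    Windows are contiguous runs of global grid indices, so counts for
    every window come from one cumulative sum of a position bincount.
    """

    def __init__(self, gmap: GeneticMap, window_cm: float, step_cm: float):
        grids = genome_grid(gmap, step_cm)
        self.chrom_names = list(grids)
        self.grids = grids
        starts: list[int] = []
        ends: list[int] = []
        sizes: list[float] = []
        offsets: dict[str, int] = {}
        off = 0
        pos_parts = []
        chrom_parts = []
        for ci, c in enumerate(self.chrom_names):
            g = grids[c]
            offsets[c] = off
            lo, hi = _chrom_windows(g, window_cm)
            left = np.searchsorted(g, lo, side="left")
            right = np.where(
                hi >= g[-1],
                np.searchsorted(g, hi, side="right"),
                np.searchsorted(g, hi, side="left"),
            )
            starts.extend((left + off).tolist())
            ends.extend((right + off).tolist())
            sizes.extend(np.round(hi - lo, _SIZE_DECIMALS).tolist())
            pos_parts.append(g)
            chrom_parts.append(np.full(g.size, ci))
            off += g.size
        self.win_start = np.array(starts)
        self.win_end = np.array(ends)
        self.win_size = np.array(sizes)
        self.n_grid = off
        self.offsets = offsets
        self.all_pos = np.concatenate(pos_parts)
        self.all_chrom = np.concatenate(chrom_parts)
        self.distinct_sizes = sorted({float(s) for s in self.win_size})
        self.size_masks = {
            s: self.win_size == s for s in self.distinct_sizes
        }

    def counts(self, grid_idx: np.ndarray) -> np.ndarray:
        cs = np.concatenate(
            ([0], np.cumsum(np.bincount(grid_idx, minlength=self.n_grid)))
        )
        return cs[self.win_end] - cs[self.win_start]

    def grid_index(self, chrom: str, pos_cm: float) -> int:
        g = self.grids[chrom]
        return self.offsets[chrom] + int(np.argmin(np.abs(g - pos_cm)))


def uniform_null_positions(
    origin: np.ndarray, widx: _WindowIndex, rng: np.random.Generator
) -> np.ndarray:
    """Global grid indices for each record, uniform over grid positions on
    chromosomes other than the record's origin chromosome index."""
    n_chrom = len(widx.chrom_names)
    allowed = [np.flatnonzero(widx.all_chrom != i) for i in range(n_chrom)]
    out = np.empty(origin.size, dtype=int)
    for i in range(n_chrom):
        sel = origin == i
        k = int(sel.sum())
        if k:
            out[sel] = allowed[i][rng.integers(allowed[i].size, size=k)]
    return out


def hotspot_null_thresholds(
    records: list[EqtlRecord],
    gmap: GeneticMap,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    window_cm: float = 4.0,
    step_cm: float = 2.0,
    probes: pd.DataFrame | None = None,
    exclude: str = "probe",
) -> dict[float, int]:
    """Per-window-size count thresholds from position-reassignment
    permutations.

    Each trans eQTL is independently reassigned to a uniform grid
    position on a chromosome other than its probe's chromosome
    (``exclude='probe'``, default) or other than its observed eQTL
    chromosome (``exclude='eqtl'``). The threshold for each window size
    is the (1 - alpha) quantile of the per-permutation maxima among
    windows of that size.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    widx = _WindowIndex(gmap, window_cm, step_cm)
    if len(widx.chrom_names) < 2:
        raise ValueError("cannot reassign positions with a single chromosome")
    chrom_idx = {c: i for i, c in enumerate(widx.chrom_names)}
    if exclude == "probe":
        if probes is None:
            raise ValueError("probe annotation required for exclude='probe'")
        origin = np.array([chrom_idx[str(probes.loc[r.probe, "chr"])] for r in records])
    elif exclude == "eqtl":
        origin = np.array([chrom_idx[r.chrom] for r in records])
    else:
        raise ValueError(f"unknown exclude rule {exclude!r}")

    rng = np.random.default_rng(seed)
    maxima = {s: np.zeros(n_perm, dtype=int) for s in widx.distinct_sizes}
    for p in range(n_perm):
        idx = uniform_null_positions(origin, widx, rng)
        counts = widx.counts(idx)
        for s, mask in widx.size_masks.items():
            maxima[s][p] = counts[mask].max(initial=0)
    return {
        s: int(np.quantile(vals, 1.0 - alpha, method="higher"))
        for s, vals in maxima.items()
    }


def call_hotspots(
    counts: list[WindowCount],
    thresholds: dict[float, int],
    records: list[EqtlRecord] | None = None,
    gmap: GeneticMap | None = None,
) -> list[Hotspot]:
    """Windows whose count strictly exceeds their size-matched threshold,
    merged per chromosome when overlapping or adjacent."""
    flagged: dict[str, list[WindowCount]] = {}
    for w in counts:
        thr = thresholds.get(w.size_cm, 0)
        if w.count > thr:
            flagged.setdefault(w.chrom, []).append(w)
    hotspots: list[Hotspot] = []
    for chrom, ws in flagged.items():
        ws.sort(key=lambda w: w.lo_cm)
        merged: list[list[WindowCount]] = [[ws[0]]]
        for w in ws[1:]:
            if w.lo_cm <= merged[-1][-1].hi_cm:
                merged[-1].append(w)
            else:
                merged.append([w])
        for group in merged:
            lo = group[0].lo_cm
            hi = max(w.hi_cm for w in group)
            members = []
            if records is not None:
                chrom_end = max(w.hi_cm for w in counts if w.chrom == chrom)
                for r in records:
                    if r.chrom != chrom:
                        continue
                    if lo <= r.pos_cm < hi or (hi >= chrom_end and r.pos_cm == hi):
                        members.append(r)
            hs = Hotspot(
                chrom=chrom,
                lo_cm=lo,
                hi_cm=hi,
                count=len(members) if records is not None else max(w.count for w in group),
                threshold=min(thresholds.get(w.size_cm, 0) for w in group),
                members=members,
            )
            if gmap is not None:
                try:
                    hs.lo_mb = cm_to_mb(gmap, chrom, lo)
                    hs.hi_mb = cm_to_mb(gmap, chrom, hi)
                except ValueError:
                    pass
            hotspots.append(hs)
    hotspots.sort(key=lambda h: (h.chrom, h.lo_cm))
    return hotspots


def hotspots_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chr": h.chrom,
                "lo_cM": h.lo_cm,
                "hi_cM": h.hi_cm,
                "lo_Mb": h.lo_mb,
                "hi_Mb": h.hi_mb,
                "count": h.count,
                "threshold": h.threshold,
                "sterile_allele": h.sterile_allele,
            }
            for h in hotspots
        ]
    )


def write_hotspots_bed(hotspots: list[Hotspot], path) -> None:
    """0-based half-open BED in Mb-derived basepair coordinates."""
    lines = []
    for h in hotspots:
        if np.isnan(h.lo_mb) or np.isnan(h.hi_mb):
            continue
        lines.append(
            f"{h.chrom}\t{int(h.lo_mb * 1e6)}\t{int(h.hi_mb * 1e6)}\t"
            f"hotspot_n{h.count}\t{h.count}\t."
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Co-localization with sterility QTL
# ---------------------------------------------------------------------------


@dataclass
class ColocalizationResult:
    n_hotspots_overlapping: int
    n_grid_positions_overlapping: int
    cm_overlap: float
    p_hotspots: float
    p_positions: float
    p_cm: float
    n_perm: int
    seed: int


def _interval_overlap(lo1, hi1, lo2, hi2) -> float:
    return max(0.0, min(hi1, hi2) - max(lo1, lo2))


def _coloc_stats(
    intervals: list[tuple[str, float, float]],
    sterility: list[SterilityQtlInterval],
    grids: dict[str, np.ndarray],
) -> tuple[int, int, float]:
    n_hot = 0
    n_pos = 0
    cm = 0.0
    for chrom, lo, hi in intervals:
        qtls = [q for q in sterility if q.chrom == chrom]
        if any(_interval_overlap(lo, hi, q.lo_cm, q.hi_cm) > 0 for q in qtls):
            n_hot += 1
        # union of sterility intervals restricted to this hotspot
        segs = sorted(
            (max(lo, q.lo_cm), min(hi, q.hi_cm))
            for q in qtls
            if q.hi_cm > lo and q.lo_cm < hi
        )
        merged: list[list[float]] = []
        for s, e in segs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cm += sum(e - s for s, e in merged)
        grid = grids[chrom]
        in_hot = (grid >= lo) & (grid <= hi)
        in_qtl = np.zeros(grid.size, dtype=bool)
        for q in qtls:
            in_qtl |= (grid >= q.lo_cm) & (grid <= q.hi_cm)
        n_pos += int((in_hot & in_qtl).sum())
    return n_hot, n_pos, cm


def colocalization_test(
    hotspots: list[Hotspot],
    sterility: list[SterilityQtlInterval],
    gmap: GeneticMap,
    n_perm: int = 1000,
    seed: int = 0,
    step_cm: float = 2.0,
    max_attempts: int = 10_000,
) -> ColocalizationResult:
    """Permutation test of hotspot / sterility-QTL co-localization.

    Sterility intervals stay fixed; per permutation, intervals of the
    observed hotspot sizes are placed without overlap, uniformly at grid
    anchor positions where they fit within a chromosome, and three
    statistics are recorded: hotspots overlapping any sterility QTL,
    grid positions in both, and total cM of overlap.
    """
    if not hotspots:
        raise ValueError("need at least one hotspot")
    grids = genome_grid(gmap, step_cm)
    chrom_ends = {c: float(g[-1]) for c, g in grids.items()}
    observed = [(h.chrom, h.lo_cm, h.hi_cm) for h in hotspots]
    obs = _coloc_stats(observed, sterility, grids)
    if not sterility:
        return ColocalizationResult(0, 0, 0.0, 1.0, 1.0, 1.0, n_perm, seed)

    sizes = sorted((h.size_cm for h in hotspots), reverse=True)
    # anchors where an interval of each size fits on each chromosome
    rng = np.random.default_rng(seed)
    anchor_chrom: list[str] = []
    anchor_pos: list[float] = []
    for c, g in grids.items():
        anchor_chrom.extend([c] * g.size)
        anchor_pos.extend(g.tolist())
    anchor_chrom_arr = np.array(anchor_chrom)
    anchor_pos_arr = np.array(anchor_pos)

    exceed = np.zeros(3, dtype=int)
    for _ in range(n_perm):
        placed: list[tuple[str, float, float]] = []
        for size in sizes:
            fits = anchor_pos_arr + size <= np.array(
                [chrom_ends[c] for c in anchor_chrom_arr]
            )
            ok_idx = np.flatnonzero(fits)
            for attempt in range(max_attempts):
                j = ok_idx[rng.integers(ok_idx.size)]
                c, lo = anchor_chrom_arr[j], float(anchor_pos_arr[j])
                hi = lo + size
                clash = any(
                    pc == c and _interval_overlap(lo, hi, pl, ph) > 0
                    for pc, pl, ph in placed
                )
                if not clash:
                    placed.append((c, lo, hi))
                    break
            else:
                raise RuntimeError(
                    "could not place non-overlapping hotspot intervals; genome too small"
                )
        stats = _coloc_stats(placed, sterility, grids)
        for k in range(3):
            if stats[k] >= obs[k]:
                exceed[k] += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return ColocalizationResult(
        obs[0], obs[1], obs[2], float(p[0]), float(p[1]), float(p[2]), n_perm, seed
    )
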