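"""Map-function arithmetic and hidden-Markov genotype probabilities.

An F2 autosome is modelled as the tensor product of two independent
gamete Markov chains, giving the standard intercross transition matrix
over {AA, AB, BB}; the hemizygous male X has a single gamete chain over
{A, B}. Probabilities are smoothed by forward-backward over a grid that
contains every typed marker plus pseudomarkers at a fixed cM step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cross import CrossData, Chromosome

AUTOSOME_CLASSES = ("AA", "AB", "BB")
X_CLASSES = ("A", "B")

MAP_FUNCTIONS = ("haldane", "kosambi", "carter_falconer")


def recfrac_to_cm(r: float, fn: str = "carter_falconer") -> float:
    """Map distance (cM) corresponding to a recombination fraction."""
    r = float(r)
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    if fn == "haldane":
        return -50.0 * np.log1p(-2.0 * r)
    if fn == "kosambi":
        return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    if fn == "carter_falconer":
        # quarter-sum of inverse hyperbolic and circular tangents (in Morgans)
        return 25.0 * (np.arctanh(2 * r) + np.arctan(2 * r))
    raise ValueError(f"unknown map function {fn!r}")


def map_to_recfrac(d_cm: float, fn: str = "carter_falconer") -> float:
    """Recombination fraction for a map distance in cM.

    Haldane and Kosambi invert in closed form; Carter-Falconer is
    inverted by bracketed root-finding on the forward map function.
    """
    d = float(d_cm)
    if d < 0:
        raise ValueError(f"map distance must be non-negative, got {d}")
    if d == 0:
        return 0.0
    if fn == "haldane":
        return 0.5 * (1.0 - np.exp(-d / 50.0))
    if fn == "kosambi":
        return 0.5 * np.tanh(d / 50.0)
    if fn == "carter_falconer":
        hi = 0.5 - 1e-14
        if recfrac_to_cm(hi, fn) <= d:
            return hi
        return float(
            brentq(lambda r: recfrac_to_cm(r, fn) - d, 0.0, hi, xtol=1e-12)
        )
    raise ValueError(f"unknown map function {fn!r}")


def f2_transition(r: float) -> np.ndarray:
    """Autosomal F2 transition matrix over {AA, AB, BB} for one interval."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def x_transition(r: float) -> np.ndarray:
    """Male-X (single gamete) transition matrix over {A, B}."""
    return np.array([[1 - r, r], [r, 1 - r]])


F2_INIT = np.array([0.25, 0.5, 0.25])
X_INIT = np.array([0.5, 0.5])


@dataclass
class ChromProbs:
    """Grid positions and per-individual genotype probabilities on one
    chromosome; ``probs`` has shape (n_individuals, n_positions, n_classes)."""

    name: str
    is_x: bool
    positions: np.ndarray  # cM, includes every marker exactly once
    is_marker: np.ndarray  # bool per position
    marker_names: list[str | None]
    probs: np.ndarray

    @property
    def classes(self) -> tuple[str, ...]:
        return X_CLASSES if self.is_x else AUTOSOME_CLASSES

    def nearest_marker(self, pos_cm: float) -> str:
        idx = np.flatnonzero(self.is_marker)
        best = idx[np.argmin(np.abs(self.positions[idx] - pos_cm))]
        return self.marker_names[best]  # type: ignore[return-value]


@dataclass
class GenotypeProbabilities:
    chroms: dict[str, ChromProbs]
    individual_ids: list[str]
    step_cm: float
    error_rate: float
    map_function: str

    def n_positions(self) -> int:
        return sum(c.positions.size for c in self.chroms.values())

    def autosome_names(self) -> list[str]:
        return [n for n, c in self.chroms.items() if not c.is_x]

    def x_names(self) -> list[str]:
        return [n for n, c in self.chroms.items() if c.is_x]


def build_grid(chrom: Chromosome, step_cm: float) -> tuple[np.ndarray, np.ndarray, list[str | None]]:
    """Marker + pseudomarker grid: first-marker + k*step, truncated at the
    last marker, with all marker positions inserted exactly once."""
    cm = chrom.cm_positions
    lo, hi = cm[0], cm[-1]
    pseudo = lo + step_cm * np.arange(int(np.floor((hi - lo) / step_cm)) + 1)
    grid = np.unique(np.concatenate([cm, pseudo]))
    # merge pseudomarkers landing within numerical noise of a marker
    keep = np.ones(grid.size, dtype=bool)
    for i in range(1, grid.size):
        if grid[i] - grid[i - 1] < 1e-9:
            keep[i] = False
    grid = grid[keep]
    is_marker = np.zeros(grid.size, dtype=bool)
    names: list[str | None] = [None] * grid.size
    for m in chrom.markers:
        j = int(np.argmin(np.abs(grid - m.cm)))
        is_marker[j] = True
        names[j] = m.name
    return grid, is_marker, names


def _encode(block, classes) -> np.ndarray:
    """String codes -> integer codes (missing = -1), markers x individuals."""
    lut = {c: i for i, c in enumerate(classes)}
    arr = block.to_numpy()
    out = np.full(arr.shape, -1, dtype=np.int8)
    for code, i in lut.items():
        out[arr == code] = i
    return out


def _forward_backward(
    obs: np.ndarray,  # (n_ind, n_pos) int codes, -1 missing
    transitions: list[np.ndarray],  # per interval, (k, k)
    init: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    n_ind, n_pos = obs.shape
    k = init.size
    emit = np.empty((n_ind, n_pos, k))
    emit[:] = 1.0  # missing observations are uninformative
    for c in range(k):
        match = obs == c
        emit[match] = error_rate / (k - 1) if k > 1 else 1.0
        emit[match, c] = 1.0 - error_rate

    alpha = np.empty((n_ind, n_pos, k))
    scale = np.empty((n_ind, n_pos))
    a = init[None, :] * emit[:, 0]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0, None]
    for t in range(1, n_pos):
        a = (alpha[:, t - 1] @ transitions[t - 1]) * emit[:, t]
        scale[:, t] = a.sum(axis=1)
        alpha[:, t] = a / scale[:, t, None]

    beta = np.empty((n_ind, n_pos, k))
    beta[:, -1] = 1.0
    for t in range(n_pos - 2, -1, -1):
        b = (beta[:, t + 1] * emit[:, t + 1]) @ transitions[t].T
        beta[:, t] = b / b.sum(axis=1, keepdims=True)

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def calc_genoprob(
    cross: CrossData,
    step_cm: float = 2.0,
    error_rate: float = 0.001,
    map_function: str = "carter_falconer",
) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities on the marker+pseudomarker
    grid, allowing a symmetric genotyping-error emission model."""
    chroms: dict[str, ChromProbs] = {}
    ids = list(cross.individuals["id"])
    for chrom in cross.map.chromosomes:
        grid, is_marker, names = build_grid(chrom, step_cm)
        classes = X_CLASSES if chrom.is_x else AUTOSOME_CLASSES
        k = len(classes)
        codes = _encode(cross.chromosome_genotypes(chrom.name), classes)
        # spread marker observations onto the grid
        obs = np.full((len(ids), grid.size), -1, dtype=np.int8)
        marker_cols = {name: j for j, name in enumerate(names) if name is not None}
        for mi, m in enumerate(chrom.markers):
            obs[:, marker_cols[m.name]] = codes[mi]
        rs = [map_to_recfrac(d, map_function) for d in np.diff(grid)]
        trans_fn = x_transition if chrom.is_x else f2_transition
        transitions = [trans_fn(r) for r in rs]
        init = X_INIT if chrom.is_x else F2_INIT
        post = _forward_backward(obs, transitions, init, error_rate)
        chroms[chrom.name] = ChromProbs(
            chrom.name, chrom.is_x, grid, is_marker, names, post
        )
    return GenotypeProbabilities(chroms, ids, step_cm, error_rate, map_function)


def genotype_at_marker(
    probs: GenotypeProbabilities, chrom: str, marker: str
) -> np.ndarray:
    """Most-probable genotype class per individual at a typed marker.

    Returns integer codes; exact probability ties are returned as -1
    (treated as missing downstream).
    """
    cp = probs.chroms[chrom]
    try:
        j = cp.marker_names.index(marker)
    except ValueError:
        raise KeyError(f"marker {marker!r} not on chromosome {chrom}") from None
    p = cp.probs[:, j, :]
    best = np.argmax(p, axis=1).astype(np.int8)
    sorted_p = np.sort(p, axis=1)
    ties = (sorted_p[:, -1] - sorted_p[:, -2]) < 1e-12
    best[ties] = -1
    return best
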