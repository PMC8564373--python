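"""Color calling: from multichannel intensities to binary Bitbow codes.

Pipeline stages, in the order they run on real data:

1. :func:`unmix` — per-pixel nonnegative least squares against a reference
   mixing matrix turns C detection channels into 5 fluorophore abundances;
2. :func:`smooth` — a 3x3x3 median kernel (volumetric) followed by a
   10-sample centered rolling mean along the trace suppresses shot noise;
3. :func:`normalize_channels` — each pixel's 5-vector is divided by its
   channel sum so bright and dim pixels land on the same color scale;
4. :func:`call_bits` — per-cell median aggregation and per-channel
   thresholding yield the binary code;
5. :func:`consistency_stats` — soma-vs-neurite agreement diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import nnls
from skimage.filters import threshold_otsu

from .codes import DEFAULT_FLUOROPHORES, BitbowCode

__all__ = [
    "MixingMatrix",
    "TraceIntensitySeries",
    "CellColor",
    "unmix",
    "unmix_volume",
    "median_filter_volume",
    "sample_volume",
    "smooth",
    "normalize_channels",
    "call_bits",
    "auto_thresholds",
    "call_cells",
    "consistency_stats",
    "assignment_accuracy",
    "background_floor",
]

DEFAULT_THRESHOLD = 0.1


class IllConditionedMatrixError(ValueError):
    def __init__(self, message: str, cond: float):
        super().__init__(f"{message} (condition number {cond:.3g})")
        self.cond = cond


class UnlabeledCellError(ValueError):
    """Every pixel of the cell fell below the background floor."""


@dataclass(frozen=True)
class MixingMatrix:
    """Detection-channel x fluorophore reference spectra.

    Rows are detection channels (C >= number of fluorophores), columns are
    fluorophores; columns are normalized to unit sum on construction.
    """

    matrix: np.ndarray
    fluorophores: tuple[str, ...] = DEFAULT_FLUOROPHORES

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("mixing matrix must be 2-D")
        if m.shape[1] != len(self.fluorophores):
            raise ValueError(
                f"{m.shape[1]} columns but {len(self.fluorophores)} fluorophores"
            )
        if m.shape[0] < m.shape[1]:
            raise ValueError("need at least as many channels as fluorophores")
        if np.any(m < 0):
            raise ValueError("reference spectra must be nonnegative")
        sums = m.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("mixing matrix has an all-zero column")
        m = m / sums
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise IllConditionedMatrixError(
                "mixing matrix is rank deficient", float(np.linalg.cond(m))
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_fluorophores(self) -> int:
        return self.matrix.shape[1]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=list(self.fluorophores)).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(df.to_numpy(float), fluorophores=tuple(df.columns))


@dataclass(frozen=True)
class TraceIntensitySeries:
    """Per-node multichannel intensities along one neuron trace.

    ``coords`` are (x, y, z) voxel positions per node in trace order;
    ``intensities`` is (n_nodes, n_channels); ``label`` records provenance
    (``soma`` or ``neurite``).
    """

    node_ids: np.ndarray
    coords: np.ndarray
    intensities: np.ndarray
    label: str = "neurite"
    cell_id: str | int | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.node_ids)
        xyz = np.asarray(self.coords, dtype=float)
        val = np.asarray(self.intensities, dtype=float)
        if xyz.shape != (ids.size, 3):
            raise ValueError("coords must be (n_nodes, 3)")
        if val.ndim != 2 or val.shape[0] != ids.size:
            raise ValueError("intensities must be (n_nodes, n_channels)")
        if np.any(val < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "intensities", val)

    def __len__(self) -> int:
        return self.node_ids.size


def _nnls_rows(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise NNLS solve of M a = y, fast-pathing interior solutions.

    When the unconstrained least-squares solution is already nonnegative it
    coincides with the NNLS solution (active set empty); only rows with a
    negative component need the iterative solver.
    """
    pinv = np.linalg.pinv(M)
    A = Y @ pinv.T
    tol = 1e-10 * max(1.0, float(np.abs(A).max(initial=0.0)))
    bad = np.flatnonzero((A < -tol).any(axis=1))
    for i in bad:
        A[i], _ = nnls(M, Y[i])
    np.maximum(A, 0.0, out=A)
    return A


def unmix(raw: np.ndarray, M: MixingMatrix) -> np.ndarray:
    """Linear spectral unmixing: channels-last intensities -> abundances.

    Solves ``M @ a ~= y`` per pixel with nonnegativity (abundances are
    physical quantities); noiseless mixtures are recovered exactly when the
    matrix has full column rank.  Input shape ``(..., C)``, output
    ``(..., F)``.
    """
    y = np.asarray(raw, dtype=float)
    if y.shape[-1] != M.n_channels:
        raise ValueError(
            f"last axis has {y.shape[-1]} channels, matrix expects {M.n_channels}"
        )
    flat = y.reshape(-1, M.n_channels)
    out = _nnls_rows(M.matrix, flat)
    return out.reshape(y.shape[:-1] + (M.n_fluorophores,))


def unmix_volume(volume: np.ndarray, M: MixingMatrix) -> np.ndarray:
    """Unmix a channel-first image volume ``(C, Z, Y, X)`` -> ``(F, Z, Y, X)``."""
    if volume.ndim != 4 or volume.shape[0] != M.n_channels:
        raise ValueError("volume must be (C, Z, Y, X) with C matching the matrix")
    moved = np.moveaxis(volume, 0, -1)
    return np.moveaxis(unmix(moved, M), -1, 0)


def median_filter_volume(volume: np.ndarray) -> np.ndarray:
    """3x3x3 median per channel of a channel-first (F, Z, Y, X) volume."""
    return np.stack([ndimage.median_filter(c, size=3) for c in volume])


def sample_volume(volume: np.ndarray, coords: np.ndarray,
                  node_ids: np.ndarray | None = None) -> np.ndarray:
    """Sample a channel-first volume at (x, y, z) voxel coordinates.

    Returns an (n_nodes, n_channels) intensity matrix; out-of-bounds nodes
    raise with the offending node named.
    """
    shape = volume.shape[1:]  # (Z, Y, X)
    out = np.empty((len(coords), volume.shape[0]), dtype=float)
    for j, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
        if not (0 <= zi < shape[0] and 0 <= yi < shape[1] and 0 <= xi < shape[2]):
            node = node_ids[j] if node_ids is not None else j
            raise ValueError(
                f"node {node} at voxel (x={xi}, y={yi}, z={zi}) lies outside "
                "the volume"
            )
        out[j] = volume[:, zi, yi, xi]
    return out


def smooth(
    series: TraceIntensitySeries,
    volume: np.ndarray | None = None,
    window: int = 10,
    prefiltered: bool = False,
) -> TraceIntensitySeries:
    """Denoise a trace series: 3x3x3 median, then centered rolling mean.

    When ``volume`` (channel-first, already unmixed) is given, the median
    step replaces each node's value by the median over its 3x3x3 voxel
    neighborhood; otherwise a size-3 median filter runs along the node
    series itself.  Pass ``prefiltered=True`` when the volume has already
    been through :func:`median_filter_volume` (avoids refiltering per
    cell).  The rolling mean uses a centered window of ``window`` samples,
    shrunk at the trace ends so output length equals input length.
    """
    vals = series.intensities
    if volume is not None:
        if volume.ndim != 4:
            raise ValueError("volume must be channel-first (F, Z, Y, X)")
        med = volume if prefiltered else median_filter_volume(volume)
        out = sample_volume(med, series.coords, series.node_ids)
    else:
        out = np.stack(
            [ndimage.median_filter(vals[:, c], size=3, mode="nearest")
             for c in range(vals.shape[1])],
            axis=1,
        )
    rolled = (
        pd.DataFrame(out)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(series, intensities=rolled)


def normalize_channels(
    v: np.ndarray, floor: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sum-normalize channel vectors; flag pixels below the background floor.

    Returns ``(normalized, background)`` where ``normalized`` has unit-sum
    rows (zeros where background) and ``background`` marks pixels whose
    channel sum fell below ``floor`` (or is exactly zero).
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensities must be nonnegative")
    sums = arr.sum(axis=-1, keepdims=True)
    background = (sums <= max(floor, 0.0)) | (sums == 0.0)
    safe = np.where(background, 1.0, sums)
    normed = np.where(background, 0.0, arr / safe)
    return normed, background[..., 0]


def background_floor(volume: np.ndarray, fraction: float = 0.01) -> float:
    """Default background floor: ``fraction`` of the 99th-percentile summed
    intensity of a channel-first volume."""
    summed = volume.sum(axis=0)
    return float(fraction * np.percentile(summed, 99))


@dataclass(frozen=True)
class CellColor:
    """Aggregated, normalized color of one cell and its called code."""

    aggregate: np.ndarray
    code: BitbowCode
    margins: np.ndarray
    thresholds: np.ndarray = field(repr=False)
    cell_id: str | int | None = None


def call_bits(
    pixels: np.ndarray,
    thresholds: float | np.ndarray = DEFAULT_THRESHOLD,
    cell_id: str | int | None = None,
    aggregator: str = "median",
) -> CellColor:
    """Call a binary code from a cell's normalized pixel vectors.

    Pixels aggregate per channel by the median (robust to soma/neurite
    brightness gradients; ``aggregator='mean'`` available); a bit is ON iff
    its aggregate meets or exceeds the channel threshold (ties count as
    ON).  Margins report ``|aggregate - threshold|`` per channel.
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 1:
        px = px[None, :]
    if px.shape[0] == 0 or not np.any(px.sum(axis=1) > 0):
        raise UnlabeledCellError("no non-background pixels for this cell")
    if aggregator == "median":
        agg = np.median(px, axis=0)
    elif aggregator == "mean":
        agg = px.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float), agg.shape)
    bits = tuple(int(a >= t) for a, t in zip(agg, thr))
    return CellColor(
        aggregate=agg,
        code=BitbowCode(bits),
        margins=np.abs(agg - thr),
        thresholds=np.array(thr),
        cell_id=cell_id,
    )


def auto_thresholds(
    aggregates: np.ndarray,
    fallback: float = DEFAULT_THRESHOLD,
    min_separation: float = 0.1,
) -> np.ndarray:
    """Per-channel two-class (Otsu) thresholds across a population of cells.

    Expects the (n_cells, n_channels) matrix of per-cell aggregated
    normalized intensities.  Otsu's criterion picks the two-class split;
    the returned cutoff is the midpoint of the two class means, which is
    robust to tail outliers near the raw Otsu value.  A channel whose
    values do not split into two classes separated by at least
    ``min_separation`` (e.g. every cell has the bit OFF) falls back to the
    fixed threshold.
    """
    A = np.asarray(aggregates, dtype=float)
    if A.ndim != 2:
        raise ValueError("aggregates must be (n_cells, n_channels)")
    out = np.full(A.shape[1], float(fallback))
    for c in range(A.shape[1]):
        vals = A[:, c]
        if np.ptp(vals) < min_separation:
            continue
        try:
            t = float(threshold_otsu(vals))
        except ValueError:
            continue
        lo, hi = vals[vals < t], vals[vals >= t]
        if lo.size == 0 or hi.size == 0 or hi.mean() - lo.mean() < min_separation:
            continue
        out[c] = 0.5 * (lo.mean() + hi.mean())
    return out


def call_cells(
    cell_pixels: list[np.ndarray],
    thresholds: float | np.ndarray | str = "auto",
    cell_ids: list | None = None,
) -> list[CellColor]:
    """Call codes for a population of cells, with optional auto-thresholding.

    ``thresholds='auto'`` first aggregates every cell, fits per-channel
    Otsu thresholds across the population, then calls each cell against
    them; otherwise the given fixed threshold(s) apply directly.
    """
    if cell_ids is None:
        cell_ids = list(range(len(cell_pixels)))
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError(f"unknown threshold mode {thresholds!r}")
        aggs = np.stack(
            [np.median(np.atleast_2d(px), axis=0) for px in cell_pixels]
        )
        thr = auto_thresholds(aggs)
    else:
        thr = thresholds
    return [
        call_bits(px, thresholds=thr, cell_id=cid)
        for px, cid in zip(cell_pixels, cell_ids)
    ]


def consistency_stats(
    soma: TraceIntensitySeries, neurite: TraceIntensitySeries
) -> dict:
    """Soma-vs-neurite color agreement for one neuron.

    Returns per-channel ``|median(soma) - median(neurite)|`` and the scalar
    consistency distance (their maximum).  Small distances mean the cell's
    color — hence its called code — is stable along its processes.
    """
    if len(soma) == 0 or len(neurite) == 0:
        raise ValueError("both series must be non-empty")
    ds = np.abs(
        np.median(soma.intensities, axis=0) - np.median(neurite.intensities, axis=0)
    )
    return {"per_channel": ds, "distance": float(ds.max())}


def assignment_accuracy(
    somas: list[TraceIntensitySeries], neurites: list[TraceIntensitySeries]
) -> float:
    """Nearest-centroid neurite-to-soma assignment accuracy.

    Each neurite's median color vector is assigned to the closest soma
    median (Euclidean); the fraction assigned to its own soma is returned.
    Lists must be index-aligned by cell.
    """
    if len(somas) != len(neurites) or not somas:
        raise ValueError("need equal, non-empty soma and neurite lists")
    centroids = np.stack([np.median(s.intensities, axis=0) for s in somas])
    hits = 0
    for i, n in enumerate(neurites):
        v = np.median(n.intensities, axis=0)
        j = int(np.argmin(np.linalg.norm(centroids - v, axis=1)))
        hits += j == i
    return hits / len(neurites)
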