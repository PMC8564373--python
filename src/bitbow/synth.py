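"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: biased
per-module recombination frequencies, per-brain cluster tables drawn from
the induced code distribution, bleed-through mixing matrices, and noisy
multichannel image volumes with matching SWC traces and true codes.  Every
generator is a pure function of its seed and configuration.

The default configuration mirrors a heat-shock lineage-labeling experiment
in the larval fly brain: 6 brains, 200 neuronal lineages per brain, a
~48% lineage activation rate, and per-module ON frequencies biased the way
the FRT sites are (the mNeonGreen module's FRT-545 recombines most
readily; the mTFP1/mKO2 modules' FRT-F14/FRT-F13 are the laziest).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import MixingMatrix
from .frequency import (
    CodeDistribution,
    ModuleFrequencyTable,
    build_code_distribution,
)
from .io import SWC_SOMA_TYPE, write_cluster_table, write_swc, write_volume

__all__ = [
    "SynthConfig",
    "LabeledVolume",
    "gen_module_frequencies",
    "gen_cluster_table",
    "gen_mixing_matrix",
    "gen_labeled_volume",
]

#: Baseline per-module ON frequencies for the "bitbow-like" preset, in bit
#: order A, T, G, O, K.  The ordering G > A > K > T ~ O follows the relative
#: recombination efficiencies of the FRT sites paired with each fluorophore
#: (545 > F3 > 5T2 > F14 ~ F13).
BITBOW_LIKE_BASE = np.array([0.40, 0.22, 0.55, 0.21, 0.32])


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for all synthetic generators.

    ``freqs`` is either an explicit per-slot probability vector or the
    preset name ``"bitbow-like"``.  ``noise_sd`` is the Gaussian imaging
    noise SD expressed in the same units as the (unit-mean) ON-bit
    amplitude; ``bleed`` is the off-target fraction of each fluorophore's
    emission.  A seed is mandatory: generators are deterministic in it.
    """

    seed: int
    n_bits: int = 5
    freqs: str | tuple[float, ...] = "bitbow-like"
    brains: int = 6
    lineages_per_brain: int = 200
    activation_rate: float = 0.4808
    n_channels: int = 5
    bleed: float = 0.2
    noise_sd: float = 0.05
    n_cells: int = 200
    # ON-bit amplitudes are log-normal with this sigma; kept small enough
    # that an ON bit's sum-normalized share cannot drop below the calling
    # threshold - expression-level variation must never flip a called bit
    amp_sigma: float = 0.12
    cell_box: int = 14
    freq_jitter: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation_rate <= 1.0:
            raise ValueError("activation_rate must lie in [0, 1]")
        if not 0.0 <= self.bleed < 1.0:
            raise ValueError("bleed must lie in [0, 1)")
        if self.n_channels < 5:
            raise ValueError("need at least 5 detection channels")


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator, derived from the seed."""
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode()) % 2**31])


def gen_module_frequencies(cfg: SynthConfig) -> ModuleFrequencyTable:
    """Per-module ON frequencies, explicit or from the biased preset.

    The preset jitters the baseline by up to ``freq_jitter`` per slot
    (independently per compartment group), preserving the characteristic
    ordering G > A > K > T ~ O.
    """
    if not isinstance(cfg.freqs, str):
        p = np.asarray(cfg.freqs, dtype=float)
        if p.size != cfg.n_bits:
            raise ValueError(f"expected {cfg.n_bits} frequencies, got {p.size}")
        return ModuleFrequencyTable(p)
    if cfg.freqs != "bitbow-like":
        raise ValueError(f"unknown frequency preset {cfg.freqs!r}")
    if cfg.n_bits % 5 != 0:
        raise ValueError("the bitbow-like preset needs a multiple of 5 bits")
    rng = _rng(cfg, "freqs")
    groups = []
    for _ in range(cfg.n_bits // 5):
        jitter = rng.uniform(-cfg.freq_jitter, cfg.freq_jitter, size=5)
        groups.append(np.clip(BITBOW_LIKE_BASE + jitter, 0.01, 0.99))
    return ModuleFrequencyTable(np.concatenate(groups))


def gen_cluster_table(
    cfg: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-brain cluster tables drawn from the induced code distribution.

    Per brain, each lineage activates independently with
    ``activation_rate``; activated lineages draw one code from the code
    distribution induced by the module frequencies (all progeny of a
    recombined neuroblast share that code, so one lineage = one cluster).

    Returns ``(clusters, truth)``: the observable table (brain_id,
    cluster_id, code) and the hidden lineage->cluster map for recovery
    tests.
    """
    freqs = gen_module_frequencies(cfg)
    dist = build_code_distribution(freqs)
    rng = _rng(cfg, "clusters")
    rows, truth_rows = [], []
    for b in range(cfg.brains):
        brain = f"brain{b + 1:02d}"
        active = rng.random(cfg.lineages_per_brain) < cfg.activation_rate
        draws = rng.choice(dist.pool_size, size=int(active.sum()), p=dist.probs)
        it = iter(draws)
        cluster_n = 0
        for lineage in range(cfg.lineages_per_brain):
            if active[lineage]:
                cluster_n += 1
                code = dist.code_string(int(next(it)))
                cid = f"c{cluster_n:04d}"
                rows.append({"brain_id": brain, "cluster_id": cid, "code": code})
                truth_rows.append(
                    {"brain_id": brain, "lineage_id": lineage, "cluster_id": cid,
                     "code": code}
                )
            else:
                truth_rows.append(
                    {"brain_id": brain, "lineage_id": lineage, "cluster_id": None,
                     "code": None}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_mixing_matrix(
    n_channels: int = 5,
    bleed: float = 0.2,
    n_fluorophores: int = 5,
    seed: int | None = None,
) -> MixingMatrix:
    """Diagonal-dominant bleed-through reference matrix.

    Each fluorophore puts ``1 - bleed`` of its emission into its target
    detection channel and spreads the remaining ``bleed`` over the other
    channels with exponential spectral falloff.  Columns are unit-sum and
    the matrix has full column rank (jittered and re-checked if a
    pathological configuration makes columns collinear).
    """
    if n_channels < n_fluorophores:
        raise ValueError("need at least as many channels as fluorophores")
    if not 0.0 <= bleed < 1.0:
        raise ValueError("bleed must lie in [0, 1)")
    if n_fluorophores > 1:
        targets = np.round(
            np.linspace(0, n_channels - 1, n_fluorophores)
        ).astype(int)
    else:
        targets = np.array([0])
    m = np.zeros((n_channels, n_fluorophores))
    rows = np.arange(n_channels)
    for j, t in enumerate(targets):
        m[t, j] = 1.0 - bleed
        if bleed > 0:
            off = rows != t
            w = np.exp(-np.abs(rows[off] - t).astype(float))
            m[off, j] = bleed * w / w.sum()
    rng = np.random.default_rng(seed if seed is not None else 0)
    for attempt in range(5):
        try:
            return MixingMatrix(m)
        except ValueError:
            warnings.warn(
                "mixing matrix columns were collinear; regenerating with jitter"
            )
            m = m + rng.uniform(0, 0.02, m.shape)
    raise RuntimeError("could not build a full-rank mixing matrix")


@dataclass(frozen=True)
class LabeledVolume:
    """A rendered multichannel volume with its full ground truth."""

    volume: np.ndarray  # (C, Z, Y, X) float32
    traces: list[pd.DataFrame]  # SWC per cell
    codes: list[str]  # true 5-bit code strings, aligned with traces
    amplitudes: np.ndarray  # (n_cells, 5) true fluorophore abundances
    mixing: MixingMatrix
    config: SynthConfig = field(repr=False)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.volume, out / "volume.tif")
        self.mixing.to_csv(out / "mixing_matrix.csv")
        for i, trace in enumerate(self.traces):
            write_swc(trace, out / f"cell{i:04d}.swc")
        pd.DataFrame(
            {"cell_id": range(len(self.codes)), "code": self.codes}
        ).to_csv(out / "truth_codes.tsv", sep="\t", index=False)


def _paint_sphere(mask: np.ndarray, center: tuple[int, int, int], r: float) -> None:
    cz, cy, cx = center
    rr = int(math.ceil(r))
    z, y, x = np.ogrid[-rr : rr + 1, -rr : rr + 1, -rr : rr + 1]
    ball = z * z + y * y + x * x <= r * r
    mask[cz - rr : cz + rr + 1, cy - rr : cy + rr + 1, cx - rr : cx + rr + 1] |= ball


def gen_labeled_volume(cfg: SynthConfig) -> LabeledVolume:
    """Render labeled cells into a multichannel volume with SWC traces.

    Cells sit on a cubic grid, one per ``cell_box``-voxel box: a spherical
    soma plus a short tube-like neurite along +x, both filled with the
    channel intensities of the mixing-matrix forward model of the cell's
    5-bit code (ON bits at log-normal random amplitudes, OFF bits at 0).
    Gaussian noise of SD ``noise_sd`` is added everywhere and clipped at 0.
    Geometry is deliberately minimal - just enough structure to exercise
    volumetric median filtering and along-trace smoothing.
    """
    box = cfg.cell_box
    if box < 12:
        raise ValueError("cell_box must be >= 12 to fit a soma and neurite")
    freqs = gen_module_frequencies(cfg)
    dist = build_code_distribution(
        ModuleFrequencyTable(freqs.probs[:5])
    )  # imaging codes are 5-bit (one compartment)
    mix = gen_mixing_matrix(cfg.n_channels, cfg.bleed, seed=cfg.seed)
    rng = _rng(cfg, "volume")

    g = int(math.ceil(cfg.n_cells ** (1 / 3)))
    shape = (g * box, g * box, g * box)  # (Z, Y, X)
    volume = np.zeros((cfg.n_channels,) + shape, dtype=np.float32)

    code_idx = rng.choice(dist.pool_size, size=cfg.n_cells, p=dist.probs)
    codes = [dist.code_string(int(i)) for i in code_idx]
    bits = np.array([[int(c) for c in s] for s in codes], dtype=float)
    amps = np.where(bits > 0, rng.lognormal(0.0, cfg.amp_sigma, bits.shape), 0.0)

    traces: list[pd.DataFrame] = []
    half = box // 2
    for i in range(cfg.n_cells):
        gz, gy, gx = np.unravel_index(i, (g, g, g))
        cz, cy, cx = gz * box + half, gy * box + half, gx * box + half
        y = mix.matrix @ amps[i]

        mask = np.zeros(shape, dtype=bool)
        _paint_sphere(mask, (cz, cy, cx), 2.5)
        # neurite: 3x3 cross-section tube along +x so 3x3x3 neighborhoods
        # of axis nodes stay inside the signal
        x0, x1 = cx + 3, min(cx + 6, gx * box + box - 2)
        mask[cz - 1 : cz + 2, cy - 1 : cy + 2, x0 : x1 + 1] = True
        volume[:, mask] = y[:, None].astype(np.float32)

        rows = []
        nid = 1
        for dx in (-1, 0, 1):  # soma nodes (type 1)
            rows.append((nid, SWC_SOMA_TYPE, cx + dx, cy, cz, 2.5,
                         -1 if nid == 1 else nid - 1))
            nid += 1
        for x in range(x0, x1 + 1):  # neurite nodes (type 3)
            rows.append((nid, 3, x, cy, cz, 1.0, nid - 1))
            nid += 1
        traces.append(
            pd.DataFrame(
                rows,
                columns=["node_id", "type", "x", "y", "z", "radius", "parent"],
            )
        )

    if cfg.noise_sd > 0:
        volume += rng.normal(0.0, cfg.noise_sd, volume.shape).astype(np.float32)
        np.clip(volume, 0.0, None, out=volume)

    return LabeledVolume(
        volume=volume, traces=traces, codes=codes, amplitudes=amps,
        mixing=mix, config=cfg,
    )


def save_clusters(cfg: SynthConfig, out_dir) -> None:
    """Convenience: generate and write a cluster table plus its truth."""
    clusters, truth = gen_cluster_table(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cluster_table(clusters, out / "clusters.tsv")
    truth.to_csv(out / "truth_lineages.tsv", sep="\t", index=False)
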