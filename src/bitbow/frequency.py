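"""Barcode-frequency model: from per-module recombination rates to the
distribution over all nonzero codes, plus estimation and whitelisting.

Modules recombine independently (the incompatible-FRT design prevents
inter-module recombination), so a code's probability is the product of its
per-bit ON/OFF probabilities, conditioned on at least one bit being ON
(all-OFF cells are invisible and never observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import (
    DEFAULT_COMPARTMENTS,
    DEFAULT_FLUOROPHORES,
    code_capacity,
)

__all__ = [
    "ModuleFrequencyTable",
    "CodeDistribution",
    "Whitelist",
    "ModuleFrequencyEstimate",
    "build_code_distribution",
    "estimate_module_frequencies",
    "decondition_marginals",
    "whitelist_exclude_top",
]


class DegenerateDistributionError(ValueError):
    """All probability mass vanished (e.g. every module frequency is 0)."""


class NonConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _slot_labels(n_bits: int, fp_labels: tuple[str, ...]) -> list[tuple[str, str]]:
    g = len(fp_labels)
    k = n_bits // g
    compartments = DEFAULT_COMPARTMENTS[:k] if k <= 3 else tuple(
        f"compartment{i + 1}" for i in range(k)
    )
    return [(comp, fp) for comp in compartments for fp in fp_labels]


@dataclass(frozen=True)
class ModuleFrequencyTable:
    """Per-slot probability that an FRT module recombines to ON.

    Slot order matches the Bitbow bit order: fluorophores A,T,G,O,K within
    each compartment, compartments membrane -> nucleus -> golgi.
    """

    probs: np.ndarray
    fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probs must be a nonempty 1-D vector")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("module frequencies must lie in [0, 1]")
        if p.size % len(self.fp_labels) != 0:
            raise ValueError(
                f"{p.size} slots is not a multiple of the fluorophore count"
            )
        object.__setattr__(self, "probs", p)

    @property
    def n_bits(self) -> int:
        return self.probs.size

    @property
    def slots(self) -> list[tuple[str, str]]:
        return _slot_labels(self.n_bits, self.fp_labels)

    def to_frame(self) -> pd.DataFrame:
        slots = self.slots
        return pd.DataFrame(
            {
                "compartment": [s[0] for s in slots],
                "fluorophore": [s[1] for s in slots],
                "frequency": self.probs,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES):
        df = pd.read_csv(path)
        required = {"compartment", "fluorophore", "frequency"}
        if not required.issubset(df.columns):
            raise ValueError(f"frequency CSV must have columns {sorted(required)}")
        table = cls(df["frequency"].to_numpy(float), fp_labels=fp_labels)
        expected = table.slots
        got = list(zip(df["compartment"], df["fluorophore"]))
        if got != expected:
            raise ValueError(
                "slot order in CSV does not match the configured alphabet: "
                f"expected {expected}, got {got}"
            )
        return table


@dataclass(frozen=True)
class CodeDistribution:
    """Probability mass over all nonzero codes of a fixed bit length.

    Codes are indexed by their integer value read MSB-first, so index ``i``
    of ``probs`` corresponds to integer code ``i + 1`` and ascending index
    equals lexicographic order on code strings.
    """

    n_bits: int
    probs: np.ndarray
    fp_labels: tuple[str, ...] = field(default=DEFAULT_FLUOROPHORES, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        b = code_capacity(self.n_bits)
        if p.size != b:
            raise ValueError(f"expected {b} probabilities, got {p.size}")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "probs", p)

    @property
    def pool_size(self) -> int:
        return self.probs.size

    def code_string(self, index: int) -> str:
        """Grouped 0/1 string for pool index ``index`` (0-based)."""
        g = len(self.fp_labels)
        raw = format(index + 1, f"0{self.n_bits}b")
        return "-".join(raw[i : i + g] for i in range(0, self.n_bits, g))

    def codes(self) -> list[str]:
        return [self.code_string(i) for i in range(self.pool_size)]

    def index_of(self, code: str) -> int:
        raw = code.replace("-", "")
        if len(raw) != self.n_bits or set(raw) - {"0", "1"}:
            raise ValueError(f"malformed code {code!r} for {self.n_bits} bits")
        value = int(raw, 2)
        if value == 0:
            raise ValueError("the all-zero code is not in the pool")
        return value - 1

    def marginals(self) -> np.ndarray:
        """Per-slot ON fraction among labeled cells (conditional marginals)."""
        idx = np.arange(1, self.pool_size + 1)
        m = np.empty(self.n_bits)
        for i in range(self.n_bits):
            on = (idx >> (self.n_bits - 1 - i)) & 1
            m[i] = self.probs[on.astype(bool)].sum()
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"code": self.codes(), "probability": self.probs})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES):
        df = pd.read_csv(path, sep="\t", dtype={"code": str})
        if not {"code", "probability"}.issubset(df.columns):
            raise ValueError("distribution TSV must have columns code, probability")
        n_bits = len(str(df["code"].iloc[0]).replace("-", ""))
        probs = np.zeros(code_capacity(n_bits))
        for code, p in zip(df["code"], df["probability"]):
            raw = str(code).replace("-", "")
            probs[int(raw, 2) - 1] = p
        return cls(n_bits, probs, fp_labels=fp_labels)


def build_code_distribution(
    freqs: ModuleFrequencyTable | np.ndarray,
    fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES,
) -> CodeDistribution:
    """Enumerate P(code) for every nonzero code from per-module ON rates.

    Under module independence P(code) is proportional to
    ``prod_i p_i**bit_i * (1-p_i)**(1-bit_i)``; the all-zero outcome is
    dropped and the remainder renormalized, because unlabeled cells cannot
    be observed.
    """
    if isinstance(freqs, ModuleFrequencyTable):
        p = freqs.probs
        fp_labels = freqs.fp_labels
    else:
        p = np.asarray(freqs, dtype=float)
    n = p.size
    if np.all(p == 0):
        raise DegenerateDistributionError(
            "all module frequencies are 0: no cell can be labeled"
        )
    idx = np.arange(1, 2**n)
    prob = np.ones(idx.size)
    for i in range(n):
        on = ((idx >> (n - 1 - i)) & 1).astype(bool)
        prob *= np.where(on, p[i], 1.0 - p[i])
    total = prob.sum()
    if total <= 0:
        raise DegenerateDistributionError("nonzero codes carry no probability mass")
    return CodeDistribution(n, prob / total, fp_labels=fp_labels)


@dataclass(frozen=True)
class ModuleFrequencyEstimate:
    """Per-brain and pooled module-frequency estimates from a cluster table."""

    per_brain: pd.DataFrame  # rows = brains, columns = slot labels
    mean: np.ndarray  # across brains
    sd: np.ndarray  # across brains (0 when a single brain)
    pooled: np.ndarray  # all clusters pooled
    n_brains: int
    fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES

    @property
    def table(self) -> ModuleFrequencyTable:
        """Mean-across-brains frequencies as a ModuleFrequencyTable."""
        return ModuleFrequencyTable(self.mean, fp_labels=self.fp_labels)


def _codes_to_bits(codes: pd.Series, n_bits: int) -> np.ndarray:
    raw = codes.astype(str).str.replace("-", "", regex=False)
    if not (raw.str.len() == n_bits).all():
        raise ValueError("cluster codes have inconsistent bit lengths")
    return np.array([[int(c) for c in s] for s in raw], dtype=float)


def estimate_module_frequencies(
    clusters: pd.DataFrame,
    fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES,
) -> ModuleFrequencyEstimate:
    """Per-slot ON fraction among observed clusters, per brain and pooled.

    For each slot the estimate is the fraction of clusters in which that
    bit is ON, computed within each brain; the summary is the mean and SD
    of the per-brain fractions.  These are *conditional* marginals (every
    observed cluster has at least one bit ON); see
    :func:`decondition_marginals` to recover unconditional module rates.
    """
    if clusters is None or len(clusters) == 0:
        raise ValueError("empty cluster table")
    n_bits = len(str(clusters["code"].iloc[0]).replace("-", ""))
    bits = _codes_to_bits(clusters["code"], n_bits)
    brains = clusters["brain_id"].to_numpy()
    slots = _slot_labels(n_bits, fp_labels)
    labels = [f"{c}:{f}" for c, f in slots]
    per_brain = (
        pd.DataFrame(bits, columns=labels, index=brains)
        .groupby(level=0, sort=True)
        .mean()
    )
    mean = per_brain.mean(axis=0).to_numpy()
    n_brains = per_brain.shape[0]
    sd = (
        per_brain.std(axis=0, ddof=1).to_numpy()
        if n_brains > 1
        else np.zeros(n_bits)
    )
    pooled = bits.mean(axis=0)
    return ModuleFrequencyEstimate(
        per_brain=per_brain,
        mean=mean,
        sd=sd,
        pooled=pooled,
        n_brains=n_brains,
        fp_labels=fp_labels,
    )


def decondition_marginals(
    marginals: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES,
) -> ModuleFrequencyTable:
    """Invert labeled-cell marginals back to unconditional module rates.

    Observed per-slot ON fractions ``m`` condition on the cell being
    labeled, so ``m_i = p_i / (1 - prod_j (1 - p_j))``.  This solves for
    ``p`` by fixed-point iteration ``p_i <- m_i * (1 - prod_j (1 - p_j))``
    starting from ``p = m``.

    A labeled cell carries at least one ON bit, so feasible marginals have
    ``sum(m) >= 1``; smaller sums admit only the degenerate p = 0 solution
    and are rejected.
    """
    m = np.asarray(marginals, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("marginals must lie in [0, 1]")
    if not np.any(m > 0):
        raise ValueError("at least one marginal must be positive")
    if m.sum() < 1.0 - tol:
        raise ValueError(
            f"marginals sum to {m.sum():.6f} < 1: infeasible for labeled cells "
            "(each labeled cell carries at least one ON bit)"
        )
    p = m.copy()
    for _ in range(max_iter):
        label_mass = 1.0 - np.prod(1.0 - p)
        p_new = m * label_mass
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    else:
        residual = float(np.max(np.abs(m * (1.0 - np.prod(1.0 - p)) - p)))
        raise NonConvergenceError(
            f"fixed point not reached in {max_iter} iterations", residual
        )
    return ModuleFrequencyTable(np.clip(p, 0.0, 1.0), fp_labels=fp_labels)


@dataclass(frozen=True)
class Whitelist:
    """Ordered (lexicographic) set of retained codes with their mask."""

    dist: CodeDistribution
    mask: np.ndarray  # boolean over the pool, True = retained
    excluded_top: int

    @property
    def codes(self) -> list[str]:
        return [self.dist.code_string(i) for i in np.flatnonzero(self.mask)]

    @property
    def mass(self) -> float:
        """Probability mass the whitelist retains under the distribution."""
        return float(self.dist.probs[self.mask].sum())

    def __len__(self) -> int:
        return int(self.mask.sum())

    def __contains__(self, code: str) -> bool:
        return bool(self.mask[self.dist.index_of(code)])


def whitelist_exclude_top(dist: CodeDistribution, m: int) -> Whitelist:
    """Retain all codes except the ``m`` highest-probability ones.

    High-frequency codes dominate collision events; excluding them trades
    labeling coverage for assignment confidence.  Probability ties are
    broken by lexicographic code order so the whitelist is reproducible.
    """
    if m < 0 or m >= dist.pool_size:
        raise ValueError(
            f"m must satisfy 0 <= m < pool size ({dist.pool_size}), got {m}"
        )
    # descending probability, ties by ascending code index
    order = np.lexsort((np.arange(dist.pool_size), -dist.probs))
    mask = np.ones(dist.pool_size, dtype=bool)
    mask[order[:m]] = False
    return Whitelist(dist=dist, mask=mask, excluded_top=int(m))
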