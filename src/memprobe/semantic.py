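"""Pseudo-semantic fluidity analysis.

Per-frame SCD profiles are turned into letter strings (one letter per
carbon, uniform bins over the |S_CD| range), compared through the
Szymkiewicz-Simpson overlap coefficient of their k-mer sets (k = 2..8
pooled by default), assembled into a distance matrix (1 - similarity),
embedded in 2-D with t-SNE on the precomputed distances, and scored with
a silhouette against a chosen grouping.  The overlap distance is not a
metric (the triangle inequality can fail); t-SNE and the silhouette only
need dissimilarities, so this is documented rather than enforced.
"""

from __future__ import annotations

import string as _string
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .errors import (
    ConfigurationError,
    EmptyInputError,
    EmptySetError,
    ShortStringError,
)
from .order import OrderProfile


@dataclass
class EncodingConfig:
    """Uniform-width letter binning of |S_CD| values."""

    scd_low: float = 0.0
    scd_high: float = 0.52
    alphabet: str = _string.ascii_uppercase  # 26 bins of width 0.02

    def __post_init__(self):
        if not self.scd_low < self.scd_high:
            raise ConfigurationError("scd_low must be below scd_high")
        if len(self.alphabet) < 2:
            raise ConfigurationError("alphabet needs at least 2 letters")

    @property
    def bin_width(self) -> float:
        return (self.scd_high - self.scd_low) / len(self.alphabet)

    def letter(self, scd: float) -> str:
        clamped = min(max(scd, self.scd_low), self.scd_high)
        if clamped != scd:
            warnings.warn(
                f"SCD value {scd:g} outside [{self.scd_low:g}, {self.scd_high:g}]; clamped",
                stacklevel=2,
            )
        b = int((clamped - self.scd_low) / self.bin_width)
        return self.alphabet[min(b, len(self.alphabet) - 1)]


@dataclass
class KmerConfig:
    """Substring lengths and how per-k similarities are combined."""

    k_min: int = 2
    k_max: int = 8
    pooling: str = "pooled-set"  # or "per-k-mean"

    def __post_init__(self):
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigurationError("need 2 <= k_min <= k_max")
        if self.pooling not in ("pooled-set", "per-k-mean"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ConfigurationError("matrix shape must match label count")


@dataclass
class Embedding:
    labels: list[str]
    coordinates: np.ndarray  # (n, 2)
    seed: int
    perplexity: float
    kl_divergence: float | None = None


def encode_profile(
    profiles: OrderProfile | list[OrderProfile], config: EncodingConfig | None = None
) -> str:
    """One letter per carbon, chains concatenated in the order given.

    For a phospholipid this is sn-1 then sn-2, carbons ascending — one
    string per frame once the per-carbon SCD has been averaged over the
    selected lipids.
    """
    config = config or EncodingConfig()
    if isinstance(profiles, OrderProfile):
        profiles = [profiles]
    if not profiles or all(not p.scd_values for p in profiles):
        raise EmptyInputError("no SCD values to encode")
    return "".join(
        config.letter(v) for p in profiles for v in p.scd_values
    )


def kmer_set(s: str, config: KmerConfig | None = None) -> set[str]:
    """Unique contiguous substrings of every length k in [k_min, k_max]."""
    config = config or KmerConfig()
    if len(s) < config.k_min:
        raise ShortStringError(
            f"string of length {len(s)} shorter than k_min={config.k_min}"
        )
    out: set[str] = set()
    for k in range(config.k_min, min(config.k_max, len(s)) + 1):
        for i in range(len(s) - k + 1):
            out.add(s[i : i + k])
    return out


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """Szymkiewicz-Simpson coefficient |A n B| / min(|A|, |B|)."""
    if not a or not b:
        raise EmptySetError("overlap coefficient of an empty set is undefined")
    return len(a & b) / min(len(a), len(b))


def string_similarity(s1: str, s2: str, config: KmerConfig | None = None) -> float:
    """k-mer overlap similarity of two strings under the configured pooling."""
    config = config or KmerConfig()
    if config.pooling == "pooled-set":
        return overlap_coefficient(kmer_set(s1, config), kmer_set(s2, config))
    sims = []
    for k in range(config.k_min, config.k_max + 1):
        if min(len(s1), len(s2)) < k:
            break
        sub = KmerConfig(k, k, "pooled-set")
        sims.append(overlap_coefficient(kmer_set(s1, sub), kmer_set(s2, sub)))
    if not sims:
        raise ShortStringError("strings shorter than k_min")
    return float(np.mean(sims))


def deduplicate(labeled_strings: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop exact duplicate strings, keeping first occurrence (optional pre-step)."""
    seen: set[str] = set()
    out = []
    for label, s in labeled_strings:
        if s not in seen:
            seen.add(s)
            out.append((label, s))
    return out


def distance_matrix(
    labeled_strings: list[tuple[str, str]],
    config: KmerConfig | None = None,
    *,
    drop_duplicates: bool = False,
) -> DistanceMatrix:
    """Pairwise 1 - overlap similarity; symmetric with an exactly zero diagonal."""
    config = config or KmerConfig()
    if drop_duplicates:
        labeled_strings = deduplicate(labeled_strings)
    if len(labeled_strings) < 2:
        raise EmptyInputError("need at least two strings")
    labels = [lab for lab, _ in labeled_strings]
    strings = [s for _, s in labeled_strings]
    if config.pooling == "pooled-set":
        sets = [kmer_set(s, config) for s in strings]
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if config.pooling == "pooled-set":
                sim = overlap_coefficient(sets[i], sets[j])
            else:
                sim = string_similarity(strings[i], strings[j], config)
            d[i, j] = d[j, i] = 1.0 - sim
    return DistanceMatrix(labels, d)


def embed_2d(
    matrix: DistanceMatrix, seed: int = 42, perplexity: float = 10.0
) -> Embedding:
    """t-SNE on the precomputed distances; deterministic for a fixed seed."""
    n = len(matrix.labels)
    if perplexity >= n:
        raise ConfigurationError(
            f"perplexity {perplexity:g} must be below the number of items ({n})"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
        n_jobs=1,
    )
    coords = tsne.fit_transform(matrix.values.astype(np.float64))
    return Embedding(
        labels=list(matrix.labels),
        coordinates=np.asarray(coords, dtype=float),
        seed=seed,
        perplexity=perplexity,
        kl_divergence=float(getattr(tsne, "kl_divergence_", np.nan)),
    )


def cluster_quality(matrix: DistanceMatrix, groups: list[str]) -> float:
    """Mean silhouette over items on the pseudo-semantic distances, in [-1, 1]."""
    if len(groups) != len(matrix.labels):
        raise ConfigurationError("one group label per matrix row required")
    if len(set(groups)) < 2:
        raise ConfigurationError("silhouette needs at least two groups")
    return float(silhouette_score(matrix.values, np.asarray(groups), metric="precomputed"))
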