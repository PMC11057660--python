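"""Rarefaction and the per-sample diversity/clonality statistic suite.

All statistics operate on clone frequencies p_i = count_i / total of a
(usually rarefied) repertoire and use natural logarithms:

* Shannon entropy H = −Σ p_i ln p_i, and its normalized (Pielou evenness)
  form H / ln S, which is 1 for a perfectly even repertoire;
* the Rényi profile H_α = ln(Σ p_i^α)/(1−α), with the limits H_0 = ln S,
  H_1 = H, H_∞ = −ln max p_i; H_α is non-increasing in α, so the profile
  uniquely characterizes how clonal a repertoire is across emphasis on rare
  (small α) versus dominant (large α) clones;
* the Gini inequality coefficient of the clone-count vector, together with
  its evenness-oriented complement 1 − G (both are reported because figure
  conventions in the field differ on orientation);
* rank-abundance band masses and the count of "large" clones occupying more
  than a fixed fraction (default 0.5%) of the repertoire.

Rarefaction is a single multivariate-hypergeometric subsample (without
replacement) to a common depth — the smallest total count across the samples
being compared — which makes diversity comparable across samples of very
different sequencing depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .repertoire_model import EmptyRepertoireError, RepertoireSample, key_of

__all__ = [
    "DEFAULT_ALPHAS",
    "DEFAULT_RANK_BANDS",
    "LARGE_CLONE_THRESHOLD",
    "DiversityProfile",
    "common_depth",
    "rarefy",
    "shannon",
    "renyi_profile",
    "gini",
    "gini_evenness",
    "rank_abundance",
    "large_clones",
    "diversity_profile",
    "profile_table",
]

#: Conventional Rényi order grid (0 = log-richness ... inf = dominance).
DEFAULT_ALPHAS: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, math.inf)

#: Rank bands for rank-abundance mass summaries (1-based, inclusive; None = open end).
DEFAULT_RANK_BANDS: tuple[tuple[int, int | None], ...] = (
    (1, 10),
    (11, 100),
    (101, 1000),
    (1001, None),
)

#: A clone is "large" when it occupies strictly more than this repertoire fraction.
LARGE_CLONE_THRESHOLD = 0.005


def _require_nonempty(sample: RepertoireSample) -> None:
    if sample.richness == 0:
        raise EmptyRepertoireError(f"{sample.meta.sample_id}: empty repertoire")


def common_depth(samples: Sequence[RepertoireSample]) -> int:
    """Rarefaction depth for a comparison set: the smallest total count."""
    if not samples:
        raise ValueError("common_depth requires at least one sample")
    return min(int(s.total_count) for s in samples)


def rarefy(
    sample: RepertoireSample,
    depth: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RepertoireSample:
    """Down-sample to ``depth`` transcripts without replacement.

    Draws a multivariate hypergeometric subsample from the multiset of the
    input's transcripts; clones drawn to zero are dropped.  Deterministic
    given ``seed`` (or an explicit ``rng``).  Raises if ``depth`` exceeds the
    sample's total count — repertoires are never up-sampled.
    """
    _require_nonempty(sample)
    depth = int(depth)
    total = sample.total_count
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if depth > total:
        raise ValueError(
            f"{sample.meta.sample_id}: depth {depth} exceeds total count {total}; "
            "rarefaction never up-samples"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(sample.counts(), depth)
    kept = [c.with_count(n) for c, n in zip(sample.clonotypes, sub) if n > 0]
    return sample.with_clonotypes(kept)


def shannon(sample: RepertoireSample) -> tuple[float, float]:
    """Shannon entropy (nats) and its normalized (evenness) form.

    Returns ``(H, H/ln S)``; for a single-clone repertoire both are defined
    as 0 (no diversity, and no evenness measurable).
    """
    _require_nonempty(sample)
    p = sample.frequencies()
    h = float(-(p * np.log(p)).sum())
    s = sample.richness
    norm = 0.0 if s < 2 else h / math.log(s)
    return h, norm


def renyi_profile(
    sample: RepertoireSample, alphas: Sequence[float] = DEFAULT_ALPHAS
) -> list[tuple[float, float]]:
    """Rényi entropy H_α (nats) over an ordered grid of α values.

    H_α = ln(Σ p_i^α)/(1−α) for α outside {1, ∞}; H_1 is the Shannon limit
    and H_∞ = −ln(max p_i).  For any repertoire the profile is non-increasing
    in α.
    """
    _require_nonempty(sample)
    p = sample.frequencies()
    out = []
    for alpha in alphas:
        if alpha < 0:
            raise ValueError(f"Renyi order must be >= 0, got {alpha}")
        if math.isinf(alpha):
            h = float(-np.log(p.max()))
        elif alpha == 1.0:
            h = float(-(p * np.log(p)).sum())
        elif alpha == 0.0:
            h = math.log(len(p))
        else:
            h = float(np.log((p**alpha).sum()) / (1.0 - alpha))
        out.append((float(alpha), h))
    return out


def gini(sample: RepertoireSample) -> float:
    """Gini inequality coefficient of the clone-count vector.

    G = Σ_i Σ_j |x_i − x_j| / (2 S² x̄), computed via the sorted form.  G = 0
    for a perfectly even repertoire and approaches 1 under extreme clonal
    dominance.  A single-clone repertoire returns 0 by convention (no
    inequality is measurable with S = 1).
    """
    _require_nonempty(sample)
    x = np.sort(sample.counts()).astype(float)
    s = x.size
    if s < 2:
        return 0.0
    i = np.arange(1, s + 1, dtype=float)
    return float(((2.0 * i - s - 1.0) * x).sum() / (s * x.sum()))


def gini_evenness(sample: RepertoireSample) -> float:
    """Evenness-oriented Gini, 1 − G, so that 1 = even/diverse."""
    return 1.0 - gini(sample)


def _ranked_clonotypes(sample: RepertoireSample):
    """Clones in rank order: descending count, ties by lexicographic key."""
    return sorted(
        sample.clonotypes, key=lambda c: (-c.count, key_of(c, sample.key_scheme))
    )


def rank_abundance(
    sample: RepertoireSample,
    bands: Sequence[tuple[int, int | None]] = DEFAULT_RANK_BANDS,
) -> dict[str, float]:
    """Summed clone frequency per rank band; band masses sum to 1."""
    _require_nonempty(sample)
    ranked = _ranked_clonotypes(sample)
    total = float(sample.total_count)
    out: dict[str, float] = {}
    for lo, hi in bands:
        label = f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
        upper = hi if hi is not None else len(ranked)
        mass = sum(c.count for c in ranked[lo - 1 : upper]) / total
        out[label] = float(mass)
    return out


def large_clones(
    sample: RepertoireSample, threshold: float = LARGE_CLONE_THRESHOLD
) -> tuple[int, list[str]]:
    """Clones occupying strictly more than ``threshold`` of the repertoire.

    Returns the count and the identity keys (in rank order).  The comparison
    is strict, so a clone sitting exactly at the threshold is excluded.
    """
    _require_nonempty(sample)
    total = float(sample.total_count)
    keys = [
        key_of(c, sample.key_scheme)
        for c in _ranked_clonotypes(sample)
        if c.count / total > threshold
    ]
    return len(keys), keys


@dataclass
class DiversityProfile:
    """Per-sample diversity statistic bundle (computed at a stated depth)."""

    sample_id: str
    depth: int
    richness_S: int
    shannon_H: float
    shannon_norm: float
    gini: float
    gini_evenness: float
    renyi: list[tuple[float, float]]
    top_k_mass: dict[str, float]
    large_clone_count: int
    degenerate: bool = False  # single-clone repertoire: evenness conventions applied

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "sample_id": self.sample_id,
            "depth": self.depth,
            "richness_S": self.richness_S,
            "shannon_H": self.shannon_H,
            "shannon_norm": self.shannon_norm,
            "gini": self.gini,
            "gini_evenness": self.gini_evenness,
            "large_clone_count": self.large_clone_count,
            "degenerate": self.degenerate,
        }
        for alpha, h in self.renyi:
            label = "inf" if math.isinf(alpha) else f"{alpha:g}"
            row[f"renyi_{label}"] = h
        for band, mass in self.top_k_mass.items():
            row[f"mass_rank_{band}"] = mass
        return row


def diversity_profile(
    sample: RepertoireSample,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    bands: Sequence[tuple[int, int | None]] = DEFAULT_RANK_BANDS,
    threshold: float = LARGE_CLONE_THRESHOLD,
) -> DiversityProfile:
    """Compute the full statistic bundle for one (already rarefied) sample."""
    h, norm = shannon(sample)
    n_large, _ = large_clones(sample, threshold)
    return DiversityProfile(
        sample_id=sample.meta.sample_id,
        depth=sample.total_count,
        richness_S=sample.richness,
        shannon_H=h,
        shannon_norm=norm,
        gini=gini(sample),
        gini_evenness=gini_evenness(sample),
        renyi=renyi_profile(sample, alphas),
        top_k_mass=rank_abundance(sample, bands),
        large_clone_count=n_large,
        degenerate=sample.richness < 2,
    )


def profile_table(
    samples: Sequence[RepertoireSample],
    depth: int | str = "auto",
    seed: int = 0,
    reps: int = 1,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    bands: Sequence[tuple[int, int | None]] = DEFAULT_RANK_BANDS,
    threshold: float = LARGE_CLONE_THRESHOLD,
) -> pd.DataFrame:
    """Rarefy a comparison set to a common depth and profile every sample.

    ``depth='auto'`` uses the smallest total count across the set.  With
    ``reps > 1`` the numeric statistics are averaged over that many
    independent rarefaction draws (richness/large-clone counts are averaged
    too and may be non-integer); the default is a single seeded draw.
    """
    if not samples:
        raise ValueError("profile_table requires at least one sample")
    d = common_depth(samples) if depth == "auto" else int(depth)
    ss = np.random.SeedSequence(seed)
    rows = []
    for sample, child in zip(samples, ss.spawn(len(samples))):
        rng = np.random.default_rng(child)
        rep_rows = []
        for _ in range(max(1, reps)):
            prof = diversity_profile(rarefy(sample, d, rng=rng), alphas, bands, threshold)
            rep_rows.append(prof.to_row())
        frame = pd.DataFrame(rep_rows)
        num = frame.select_dtypes("number").mean()
        row = dict(num)
        row["sample_id"] = sample.meta.sample_id
        row["degenerate"] = bool(frame["degenerate"].any())
        m = sample.meta
        row.update(
            subject_id=m.subject_id,
            compartment=m.compartment,
            flank=m.flank,
            timepoint=m.timepoint,
            group=m.group,
            tumor_model=m.tumor_model,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["sample_id", "subject_id", "compartment", "flank", "timepoint", "group", "tumor_model"]
    return df[lead + [c for c in df.columns if c not in lead]]
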