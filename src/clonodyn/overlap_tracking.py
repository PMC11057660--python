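"""Pairwise repertoire similarity and longitudinal clone-trajectory analysis.

The Morisita-Horn (MH) index is the abundance-weighted overlap between two
repertoires:

    MH = 2 Σ_i x_i y_i / ((Σ x_i²/X² + Σ y_i²/Y²) · X · Y)

summed over the union of clone keys, where x_i, y_i are clone counts and
X, Y the sample totals.  MH is 1 exactly when the two repertoires have
identical clone frequency distributions and 0 when they share no clones.
It is symmetric and invariant to uniform scaling of either count vector.
The implementation evaluates the algebraically equivalent integer form
2·Σxy·X·Y / (Σx²·Y² + Σy²·X²) in exact integer arithmetic so that the
boundary identities hold exactly in floating point.

Clone trajectories track individual clones across serial samples from one
subject.  A clone is *persistent and abundant* when it ranks in the top
``top_n`` (default 100) by count at more than one timepoint; rank ties at
the cutoff are resolved inclusively (every clone tied with the 100th-ranked
count is in the top set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .repertoire_model import EmptyRepertoireError, RepertoireSample, key_of

__all__ = [
    "OverlapResult",
    "CloneTrajectory",
    "morisita_horn",
    "shared_clone_count",
    "overlap_matrix",
    "overlap_summary",
    "track_clones",
    "persistent_count",
]


def _count_map(sample: RepertoireSample) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in sample.clonotypes:
        k = key_of(c, sample.key_scheme)
        out[k] = out.get(k, 0) + int(c.count)
    return out


def morisita_horn(a: RepertoireSample, b: RepertoireSample) -> float:
    """Morisita-Horn overlap of two non-empty repertoires, in [0, 1]."""
    if a.richness == 0 or b.richness == 0:
        raise EmptyRepertoireError("Morisita-Horn is undefined for empty repertoires")
    xa, xb = _count_map(a), _count_map(b)
    keys = set(xa) | set(xb)
    # exact integer arithmetic: MH = 2*Sxy*X*Y / (Sxx*Y^2 + Syy*X^2)
    sxy = sxx = syy = 0
    x_total = sum(xa.values())
    y_total = sum(xb.values())
    for k in keys:
        x = xa.get(k, 0)
        y = xb.get(k, 0)
        sxy += x * y
        sxx += x * x
        syy += y * y
    num = 2 * sxy * x_total * y_total
    den = sxx * y_total * y_total + syy * x_total * x_total
    return num / den


def shared_clone_count(a: RepertoireSample, b: RepertoireSample) -> int:
    """Number of clone keys present in both samples."""
    return len(set(_count_map(a)) & set(_count_map(b)))


@dataclass(frozen=True)
class OverlapResult:
    sample_a: str
    sample_b: str
    mh: float
    shared_clones: int
    stratum: str  # within_subject | between_subject


def overlap_matrix(
    samples: Sequence[RepertoireSample], strata_by: str = "subject_id"
) -> pd.DataFrame:
    """Morisita-Horn for every unordered sample pair, labeled by stratum.

    A pair is ``within_subject`` when the two samples share the metadata
    field named by ``strata_by`` (subject id, for bilateral-tumor designs),
    otherwise ``between_subject``.
    """
    if len(samples) < 2:
        raise ValueError("overlap_matrix requires at least two samples")
    rows = []
    for a, b in combinations(samples, 2):
        same = getattr(a.meta, strata_by) == getattr(b.meta, strata_by)
        rows.append(
            OverlapResult(
                sample_a=a.meta.sample_id,
                sample_b=b.meta.sample_id,
                mh=morisita_horn(a, b),
                shared_clones=shared_clone_count(a, b),
                stratum="within_subject" if same else "between_subject",
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def overlap_summary(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of MH per stratum (the group-level summary of pairwise plots)."""
    g = overlaps.groupby("stratum")["mh"]
    return pd.DataFrame(
        {"n_pairs": g.size(), "mh_mean": g.mean(), "mh_sd": g.std(ddof=1)}
    ).reset_index()


@dataclass
class CloneTrajectory:
    """One clone's frequency/rank across the timepoints of a subject series.

    ``rank`` entries exist only at timepoints where the clone was observed
    (frequency > 0); absence and low rank are thereby distinguishable.
    """

    clone_key: str
    frequency: dict[int, float] = field(default_factory=dict)
    rank: dict[int, int] = field(default_factory=dict)
    in_top: dict[int, bool] = field(default_factory=dict)
    persistent_abundant: bool = False


def _top_set(sample: RepertoireSample, top_n: int) -> tuple[set[str], dict[str, int]]:
    """Tie-inclusive top-``top_n`` keys, plus rank (1-based, deterministic order)."""
    ranked = sorted(
        sample.clonotypes, key=lambda c: (-c.count, key_of(c, sample.key_scheme))
    )
    ranks = {key_of(c, sample.key_scheme): i + 1 for i, c in enumerate(ranked)}
    if len(ranked) <= top_n:
        return set(ranks), ranks
    cutoff = ranked[top_n - 1].count
    top = {key_of(c, sample.key_scheme) for c in ranked if c.count >= cutoff}
    return top, ranks


def track_clones(
    series: Sequence[RepertoireSample], top_n: int = 100
) -> tuple[list[CloneTrajectory], pd.DataFrame]:
    """Track abundant clones across the serial samples of one subject.

    ``series`` must hold >= 2 samples from the same subject and compartment
    (they are sorted by timepoint internally; rarefy to a common depth
    beforehand for comparability).  Returns trajectories for every clone in
    the tie-inclusive top-``top_n`` set of at least one timepoint, with
    ``persistent_abundant`` set when the clone is in the top set at >= 2
    timepoints, plus a long-format flow table (clone, timepoint pair,
    frequencies) of top clones between consecutive timepoints, suitable as
    input for circos-style clone-flow plots.
    """
    if len(series) < 2:
        raise ValueError("track_clones requires samples from >= 2 timepoints")
    subjects = {s.meta.subject_id for s in series}
    compartments = {s.meta.compartment for s in series}
    if len(subjects) != 1 or len(compartments) != 1:
        raise ValueError(
            "track_clones requires a single subject and compartment; "
            f"got subjects={sorted(subjects)}, compartments={sorted(compartments)}"
        )
    ordered = sorted(series, key=lambda s: s.meta.timepoint)
    tps = [s.meta.timepoint for s in ordered]
    if len(set(tps)) != len(tps):
        raise ValueError(f"duplicate timepoints in series: {tps}")

    freq_maps = [s.frequency_map() for s in ordered]
    tops, rank_maps = zip(*(_top_set(s, top_n) for s in ordered))

    tracked = sorted(set().union(*tops))
    trajectories = []
    for k in tracked:
        traj = CloneTrajectory(clone_key=k)
        n_top = 0
        for tp, freqs, ranks, top in zip(tps, freq_maps, rank_maps, tops):
            f = freqs.get(k, 0.0)
            traj.frequency[tp] = f
            if f > 0:
                traj.rank[tp] = ranks[k]
            traj.in_top[tp] = k in top
            n_top += k in top
        traj.persistent_abundant = n_top >= 2
        trajectories.append(traj)

    flow_rows = []
    for i in range(len(ordered) - 1):
        pair_keys = sorted(tops[i] | tops[i + 1])
        for k in pair_keys:
            flow_rows.append(
                {
                    "clone_key": k,
                    "timepoint_from": tps[i],
                    "timepoint_to": tps[i + 1],
                    "freq_from": freq_maps[i].get(k, 0.0),
                    "freq_to": freq_maps[i + 1].get(k, 0.0),
                }
            )
    flow = pd.DataFrame(
        flow_rows,
        columns=["clone_key", "timepoint_from", "timepoint_to", "freq_from", "freq_to"],
    )
    return trajectories, flow


def persistent_count(series: Sequence[RepertoireSample], top_n: int = 100) -> int:
    """Number of persistent-and-abundant clones in a subject series."""
    trajectories, _ = track_clones(series, top_n=top_n)
    return sum(t.persistent_abundant for t in trajectories)
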