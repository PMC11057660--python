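"""Tracking of antigen-associated clonotype panels across samples.

A clonotype panel is a small curated list of (V gene, J gene, CDR3) entries
describing TCRβ sequences with known or presumed antigen specificity — for
example public clonotypes of tumor-associated antigens, or the CDR3 of a
transgenic TCR clone.  Matching against a repertoire is exact string
equality on the chosen clonal key (``vjcdr3aa``: exact V, J and CDR3 match
after gene-label normalization; ``cdr3aa``: CDR3 alone), never fuzzy.

The package ships a synthetic stand-in panel with the same shape as a
public tumor-antigen panel (60 V/J/CDR3 entries) for tests and examples;
real analyses should supply their own panel CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .repertoire_model import (
    AA_ALPHABET,
    MAX_CDR3_LEN,
    MIN_CDR3_LEN,
    RepertoireSample,
    normalize_gene,
)

__all__ = [
    "ClonotypePanel",
    "PanelHitSummary",
    "match_panel",
    "panel_trajectory",
    "load_builtin_panel",
]

MATCH_MODES = ("vjcdr3aa", "cdr3aa")


@dataclass
class ClonotypePanel:
    """A named panel of antigen-associated (v_gene, j_gene, cdr3_aa) entries.

    Gene labels are normalized on construction (allele suffixes stripped,
    TCRBV/TRBV prefixes unified); entries must be unique under the V|J|CDR3
    key and every CDR3 must pass the standard length/alphabet filter.
    """

    panel_id: str
    entries: list[tuple[str, str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"panel {self.panel_id!r}: no entries")
        normed = []
        seen = set()
        for v, j, cdr3 in self.entries:
            v, j, cdr3 = normalize_gene(v), normalize_gene(j), str(cdr3).strip()
            if not (MIN_CDR3_LEN <= len(cdr3) <= MAX_CDR3_LEN):
                raise ValueError(
                    f"panel {self.panel_id!r}: CDR3 {cdr3!r} fails length filter "
                    f"[{MIN_CDR3_LEN}, {MAX_CDR3_LEN}]"
                )
            if not set(cdr3) <= AA_ALPHABET:
                raise ValueError(
                    f"panel {self.panel_id!r}: CDR3 {cdr3!r} contains non-standard residues"
                )
            key = f"{v}|{j}|{cdr3}"
            if key in seen:
                raise ValueError(f"panel {self.panel_id!r}: duplicate entry {key}")
            seen.add(key)
            normed.append((v, j, cdr3))
        self.entries = normed

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self, mode: str = "vjcdr3aa") -> list[str]:
        """Entry identity keys under the chosen matching mode (may repeat in cdr3aa mode)."""
        _check_mode(mode)
        if mode == "cdr3aa":
            return [cdr3 for _, _, cdr3 in self.entries]
        return [f"{v}|{j}|{cdr3}" for v, j, cdr3 in self.entries]

    @classmethod
    def from_csv(cls, path: str | Path, panel_id: str | None = None) -> "ClonotypePanel":
        """Read a panel CSV with columns v_gene, j_gene, cdr3_aa[, source]."""
        path = Path(path)
        df = pd.read_csv(path, dtype=str)
        for col in ("v_gene", "j_gene", "cdr3_aa"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required panel column {col!r}")
        provenance = ""
        if "source" in df.columns and len(df):
            provenance = "; ".join(sorted(df["source"].fillna("").unique()))
        return cls(
            panel_id=panel_id or path.stem,
            entries=[(r.v_gene, r.j_gene, r.cdr3_aa) for r in df.itertuples()],
            provenance=provenance,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "v_gene": [v for v, _, _ in self.entries],
                "j_gene": [j for _, j, _ in self.entries],
                "cdr3_aa": [c for _, _, c in self.entries],
                "source": self.provenance,
            }
        ).to_csv(path, index=False)


def load_builtin_panel() -> ClonotypePanel:
    """The packaged synthetic stand-in panel (60 entries, simulator-generated)."""
    ref = importlib.resources.files("clonodyn.data") / "synthetic_gp70_panel.csv"
    with importlib.resources.as_file(ref) as path:
        return ClonotypePanel.from_csv(path, panel_id="synthetic-gp70-standin")


@dataclass
class PanelHitSummary:
    """Exact-match result of one panel against one sample."""

    sample_id: str
    panel_id: str
    mode: str
    n_matched_clones: int
    matched_mass: float
    per_entry: dict[str, float] = field(default_factory=dict)  # V|J|CDR3 key -> frequency


def _check_mode(mode: str) -> None:
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode: {mode!r}; expected one of {MATCH_MODES}")


def match_panel(
    sample: RepertoireSample, panel: ClonotypePanel, mode: str = "vjcdr3aa"
) -> PanelHitSummary:
    """Match a panel against a (filtered) sample by exact key equality.

    ``matched_mass`` is the summed frequency of the distinct sample clones
    hit by at least one panel entry; ``per_entry`` reports the sample
    frequency each entry accounts for (0 for absent entries).  In ``cdr3aa``
    mode several panel entries sharing a CDR3 report the same frequency.
    """
    _check_mode(mode)
    freqs = sample.frequency_map(scheme=mode)
    per_entry: dict[str, float] = {}
    matched_sample_keys = set()
    for (v, j, cdr3), match_key, entry_key in zip(
        panel.entries, panel.keys(mode), panel.keys("vjcdr3aa")
    ):
        f = freqs.get(match_key, 0.0)
        per_entry[entry_key] = f
        if f > 0.0:
            matched_sample_keys.add(match_key)
    mass = float(sum(freqs[k] for k in matched_sample_keys))
    return PanelHitSummary(
        sample_id=sample.meta.sample_id,
        panel_id=panel.panel_id,
        mode=mode,
        n_matched_clones=len(matched_sample_keys),
        matched_mass=mass,
        per_entry=per_entry,
    )


def panel_trajectory(
    samples: Sequence[RepertoireSample],
    panel: ClonotypePanel,
    mode: str = "vjcdr3aa",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel hits per subject across group × timepoint, plus occupancy matrix.

    Returns a long table (group, timepoint, subject, sample, n_matched,
    matched_mass) and the panel-entry × sample occupancy matrix of entry
    frequencies used for heatmap-style views of which entries appear in
    which animals.
    """
    if not samples:
        raise ValueError("panel_trajectory requires at least one sample")
    rows = []
    occupancy: dict[str, dict[str, float]] = {}
    for s in samples:
        hits = match_panel(s, panel, mode=mode)
        m = s.meta
        rows.append(
            {
                "group": m.group,
                "timepoint": m.timepoint,
                "subject_id": m.subject_id,
                "sample_id": m.sample_id,
                "n_matched": hits.n_matched_clones,
                "matched_mass": hits.matched_mass,
            }
        )
        occupancy[m.sample_id] = hits.per_entry
    long = pd.DataFrame(rows).sort_values(
        ["group", "timepoint", "subject_id", "sample_id"], ignore_index=True
    )
    occ = pd.DataFrame(occupancy).fillna(0.0)
    occ.index.name = "panel_entry"
    return long, occ
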