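"""Synthetic longitudinal bilateral-tumor repertoire studies with ground truth.

The generator emulates a serial-sampling checkpoint-therapy study design:
two response groups of subjects, each bearing bilateral tumors drawn from a
single per-subject latent clone distribution (so contralateral flanks are
biological replicates differing only by multinomial sampling), plus serial
blood samples with a near-uniform clone distribution.  A designated
tumor-antigen-specific clone panel — CDR3s carrying a planted sequence
motif, with fixed V/J assignments, partly shared ("public") across subjects
— expands geometrically over timepoints, faster in responders than in
non-responders; after each expansion step the latent frequencies are
renormalized, so expansion changes clonal structure without changing
sequencing depth.

Key default study conditions:

* 8 subjects per response group, timepoints day 0/2/4/6;
* tumor sample totals log-uniform in [10^3, 10^5] with latent richness
  log-uniform in [10^2, 10^4]; blood near-uniform over 3000 clones;
* a 50-clone panel starting at 5% of tumor repertoire mass, fold 2.0 per
  timepoint step in responders vs 1.2 in non-responders (≈30% vs ≈8% of the
  repertoire by day 6); within-panel clone sizes follow a steep power law
  (exponent 1.5) so that expansion is oligoclonal — a few dominant
  antigen-specific clones carry most of the expanded mass;
* background clone sizes follow a power law (rank exponent 0.65), giving a
  pre-treatment top-10 clone mass around one fifth of the repertoire;
* blood carries the panel at a constant, tiny mass (0.2%) in both groups.

Everything is reproducible: the config plus seed fully determine the output.
A ground-truth channel records panel membership and the latent per-timepoint
expected frequencies so downstream analyses can be tested against the
generative truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .antigen_matching import ClonotypePanel
from .repertoire_model import (
    AA_ALPHABET,
    Clonotype,
    RepertoireSample,
    SampleMeta,
    write_repertoire,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SubjectTruth",
    "StudyResult",
    "simulate_study",
    "truth_check",
    "random_cdr3s",
]

TRBV_GENES = tuple(f"TRBV{i}" for i in (1, 2, 3, 4, 5, 12, 13, 14, 15, 16, 17, 19, 20, 23, 26, 29, 31))
TRBJ_GENES = tuple(f"TRBJ{a}-{b}" for a in (1, 2) for b in (1, 2, 3, 4, 5, 6))

_AA = sorted(AA_ALPHABET)
# CDR3 length law: discrete gaussian peaked at 14 within [8, 20]
_LENGTHS = np.arange(8, 21)
_LENGTH_W = np.exp(-0.5 * ((_LENGTHS - 14) / 2.0) ** 2)
_LENGTH_W = _LENGTH_W / _LENGTH_W.sum()


def random_cdr3s(
    rng: np.random.Generator,
    n: int,
    motif: str | None = None,
    exclude: set[str] | None = None,
) -> list[str]:
    """Random CDR3-like sequences: 'C' + random middle + 'F', lengths peaked 13-15.

    If ``motif`` is given it is spliced into the middle of each sequence at a
    random position (length preserved).  Sequences are unique among
    themselves and against ``exclude``.
    """
    taken = set() if exclude is None else set(exclude)
    out: list[str] = []
    while len(out) < n:
        m = n - len(out)
        lengths = rng.choice(_LENGTHS, size=m, p=_LENGTH_W)
        for length in lengths:
            mid = "".join(rng.choice(_AA, size=length - 2))
            seq = "C" + mid + "F"
            if motif:
                pos = int(rng.integers(1, length - 1 - len(motif)))
                seq = seq[:pos] + motif + seq[pos + len(motif) :]
            if seq in taken:
                continue
            taken.add(seq)
            out.append(seq)
    return out


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic longitudinal repertoire study."""

    n_subjects: int = 8
    groups: tuple[str, ...] = ("responder", "non_responder")
    timepoints: tuple[int, ...] = (0, 2, 4, 6)
    compartments: tuple[str, ...] = ("tumor", "blood")
    bilateral: bool = True
    tumor_model: str = "AB1"

    tumor_depth_log10: tuple[float, float] = (3.0, 5.0)
    tumor_richness_log10: tuple[float, float] = (2.0, 4.0)
    blood_depth_log10: tuple[float, float] = (4.0, 4.5)
    blood_richness: int = 3000
    blood_sigma: float = 0.3

    clone_law: str = "power_law"  # or "lognormal"
    power_exponent: float = 0.65
    lognormal_sigma: float = 1.0

    panel_size: int = 50
    panel_motif: str = "WGQ"
    panel_initial_mass: float = 0.05
    panel_within_exponent: float = 1.5
    blood_panel_mass: float = 0.002
    fold_responder: float = 2.0
    fold_nonresponder: float = 1.2
    public_sharing: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects: must be >= 1")
        if len(self.groups) < 1 or not set(self.groups) <= {"responder", "non_responder", "control"}:
            raise ValueError(f"groups: invalid group set {self.groups}")
        if len(self.timepoints) < 1 or list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints: must be a strictly increasing non-empty sequence")
        if not set(self.compartments) <= {"tumor", "blood"}:
            raise ValueError(f"compartments: invalid {self.compartments}")
        for name in ("tumor_depth_log10", "tumor_richness_log10", "blood_depth_log10"):
            lo, hi = getattr(self, name)
            if not (lo <= hi) or lo <= 0:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")
        if self.blood_richness < 2:
            raise ValueError("blood_richness: must be >= 2")
        if self.clone_law not in ("power_law", "lognormal"):
            raise ValueError(f"clone_law: unknown law {self.clone_law!r}")
        if self.panel_size < 1:
            raise ValueError("panel_size: must be >= 1")
        if not set(self.panel_motif) <= AA_ALPHABET or not (1 <= len(self.panel_motif) <= 5):
            raise ValueError("panel_motif: must be 1-5 standard amino-acid letters")
        if not (0.0 < self.panel_initial_mass < 1.0):
            raise ValueError("panel_initial_mass: must be in (0, 1)")
        if not (0.0 <= self.blood_panel_mass < 1.0):
            raise ValueError("blood_panel_mass: must be in [0, 1)")
        if self.fold_responder <= 0 or self.fold_nonresponder <= 0:
            raise ValueError("fold_responder/fold_nonresponder: must be > 0")
        if not (0.0 <= self.public_sharing <= 1.0):
            raise ValueError("public_sharing: must be in [0, 1]")

    def fold_for(self, group: str) -> float:
        if group == "responder":
            return self.fold_responder
        if group == "non_responder":
            return self.fold_nonresponder
        return 1.0  # control: no treatment-driven expansion

    def panel_mass_at(self, group: str, step: int) -> float:
        """Expected tumor panel mass after ``step`` expansion steps (renormalized)."""
        m0 = self.panel_initial_mass
        g = self.fold_for(group) ** step
        return m0 * g / (1.0 - m0 + m0 * g)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SubjectTruth:
    """Latent generative state for one subject."""

    subject_id: str
    group: str
    tumor_keys: list[str]        # background then panel, in latent order
    tumor_base: np.ndarray       # latent frequencies at step 0
    panel_flags: np.ndarray      # boolean mask over tumor_keys
    panel_entries: list[tuple[str, str, str]]
    blood_keys: list[str]
    blood_base: np.ndarray
    blood_panel_flags: np.ndarray

    def tumor_frequencies(self, config: SimulationConfig, step: int) -> np.ndarray:
        """Expected tumor clone frequencies after ``step`` expansion steps."""
        g = config.fold_for(self.group) ** step
        f = np.where(self.panel_flags, self.tumor_base * g, self.tumor_base)
        return f / f.sum()

    def expected_panel_mass(self, config: SimulationConfig, step: int) -> float:
        return float(self.tumor_frequencies(config, step)[self.panel_flags].sum())


@dataclass
class GroundTruth:
    """Truth channel for a simulated study."""

    config: SimulationConfig
    subjects: dict[str, SubjectTruth]
    shared_panel: list[tuple[str, str, str]]

    def union_panel(self, panel_id: str = "planted-panel") -> ClonotypePanel:
        """All planted panel entries across subjects as one matchable panel."""
        seen: dict[str, tuple[str, str, str]] = {}
        for st in self.subjects.values():
            for v, j, c in st.panel_entries:
                seen.setdefault(f"{v}|{j}|{c}", (v, j, c))
        return ClonotypePanel(panel_id, sorted(seen.values()), provenance="synthetic (planted)")

    def expected_frequencies(
        self, subject_id: str, timepoint: int, compartment: str
    ) -> tuple[list[str], np.ndarray]:
        st = self.subjects[subject_id]
        step = list(self.config.timepoints).index(timepoint)
        if compartment == "tumor":
            return st.tumor_keys, st.tumor_frequencies(self.config, step)
        return st.blood_keys, st.blood_base.copy()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(self.config).items()},
            "shared_panel": [list(e) for e in self.shared_panel],
            "subjects": {
                sid: {
                    "group": st.group,
                    "panel_entries": [list(e) for e in st.panel_entries],
                    "expected_panel_mass": {
                        str(tp): st.expected_panel_mass(self.config, k)
                        for k, tp in enumerate(self.config.timepoints)
                    },
                }
                for sid, st in self.subjects.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class StudyResult:
    samples: list[RepertoireSample]
    meta: pd.DataFrame
    truth: GroundTruth

    def by_id(self, sample_id: str) -> RepertoireSample:
        for s in self.samples:
            if s.meta.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, **criteria) -> list[RepertoireSample]:
        """Samples whose metadata matches every keyword (e.g. compartment='tumor')."""
        out = []
        for s in self.samples:
            if all(getattr(s.meta, k) == v for k, v in criteria.items()):
                out.append(s)
        return out


def _base_frequencies(config: SimulationConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    if config.clone_law == "power_law":
        w = np.arange(1, size + 1, dtype=float) ** -config.power_exponent
    else:
        w = np.exp(rng.normal(0.0, config.lognormal_sigma, size=size))
        w = np.sort(w)[::-1]
    return w / w.sum()


def _draw_sample(
    rng: np.random.Generator,
    meta: SampleMeta,
    keys: Sequence[str],
    freqs: np.ndarray,
    genes: Sequence[tuple[str, str]],
    depth: int,
) -> RepertoireSample:
    counts = rng.multinomial(depth, freqs)
    clonotypes = [
        Clonotype(cdr3_aa=k, count=int(n), v_gene=v, j_gene=j)
        for k, n, (v, j) in zip(keys, counts, genes)
        if n > 0
    ]
    return RepertoireSample(meta, clonotypes, key_scheme="cdr3aa")


def simulate_study(config: SimulationConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Generate a full longitudinal study; optionally write it to disk.

    Per subject: a latent background clone distribution is drawn from the
    clone-size law and merged with the planted panel at the configured
    initial mass; at timepoint step k the panel frequencies are rescaled by
    the group's fold change to the k-th power and renormalized; every
    tumor flank and blood sample is then an independent multinomial draw at
    its own sequencing depth.  When ``out_dir`` is given, writes one AIRR
    TSV per sample under ``samples/``, plus ``meta.csv``, ``panel.csv`` (the
    union of planted panel entries), ``truth.json`` and ``config.yaml``.
    """
    rng = np.random.default_rng(config.seed)

    n_shared = int(round(config.panel_size * config.public_sharing))
    shared_cdr3 = random_cdr3s(rng, n_shared, motif=config.panel_motif)
    shared_panel = [
        (str(rng.choice(TRBV_GENES)), str(rng.choice(TRBJ_GENES)), c) for c in shared_cdr3
    ]

    samples: list[RepertoireSample] = []
    meta_rows: list[dict] = []
    subjects: dict[str, SubjectTruth] = {}
    flanks = ("left", "right") if config.bilateral else ("right",)
    prefix = {"responder": "R", "non_responder": "N", "control": "C"}

    for group in config.groups:
        for i in range(config.n_subjects):
            subject_id = f"{prefix[group]}{i + 1}"
            used: set[str] = set(shared_cdr3)

            # planted panel: shared (public) entries plus private ones
            private_cdr3 = random_cdr3s(
                rng, config.panel_size - n_shared, motif=config.panel_motif, exclude=used
            )
            used.update(private_cdr3)
            panel_entries = shared_panel + [
                (str(rng.choice(TRBV_GENES)), str(rng.choice(TRBJ_GENES)), c)
                for c in private_cdr3
            ]
            panel_keys = [c for _, _, c in panel_entries]
            panel_genes = [(v, j) for v, j, _ in panel_entries]
            panel_w = np.arange(1, config.panel_size + 1, dtype=float) ** -config.panel_within_exponent
            panel_w = panel_w / panel_w.sum()

            # tumor background
            lo, hi = config.tumor_richness_log10
            bg_size = int(round(10 ** rng.uniform(lo, hi)))
            bg_keys = random_cdr3s(rng, bg_size, exclude=used)
            used.update(bg_keys)
            bg_genes = [
                (str(rng.choice(TRBV_GENES)), str(rng.choice(TRBJ_GENES))) for _ in bg_keys
            ]
            bg_f = _base_frequencies(config, bg_size, rng)

            m0 = config.panel_initial_mass
            tumor_keys = bg_keys + panel_keys
            tumor_genes = bg_genes + panel_genes
            tumor_base = np.concatenate([bg_f * (1.0 - m0), panel_w * m0])
            panel_flags = np.zeros(len(tumor_keys), dtype=bool)
            panel_flags[bg_size:] = True

            # blood: near-uniform background plus the panel at constant small mass
            blood_bg = random_cdr3s(rng, config.blood_richness, exclude=used)
            blood_bg_genes = [
                (str(rng.choice(TRBV_GENES)), str(rng.choice(TRBJ_GENES))) for _ in blood_bg
            ]
            wb = np.exp(rng.normal(0.0, config.blood_sigma, size=config.blood_richness))
            wb = wb / wb.sum()
            mb = config.blood_panel_mass
            blood_keys = blood_bg + panel_keys
            blood_genes = blood_bg_genes + panel_genes
            blood_base = np.concatenate([wb * (1.0 - mb), panel_w * mb])
            blood_panel_flags = np.zeros(len(blood_keys), dtype=bool)
            blood_panel_flags[config.blood_richness:] = True

            st = SubjectTruth(
                subject_id=subject_id,
                group=group,
                tumor_keys=tumor_keys,
                tumor_base=tumor_base,
                panel_flags=panel_flags,
                panel_entries=panel_entries,
                blood_keys=blood_keys,
                blood_base=blood_base,
                blood_panel_flags=blood_panel_flags,
            )
            subjects[subject_id] = st

            for step, tp in enumerate(config.timepoints):
                if "tumor" in config.compartments:
                    f_tumor = st.tumor_frequencies(config, step)
                    for flank in flanks:
                        lo_d, hi_d = config.tumor_depth_log10
                        depth = int(round(10 ** rng.uniform(lo_d, hi_d)))
                        meta = SampleMeta(
                            sample_id=f"{subject_id}_tumor_{flank}_d{tp}",
                            subject_id=subject_id,
                            compartment="tumor",
                            flank=flank,
                            timepoint=tp,
                            group=group,
                            tumor_model=config.tumor_model,
                        )
                        samples.append(
                            _draw_sample(rng, meta, tumor_keys, f_tumor, tumor_genes, depth)
                        )
                if "blood" in config.compartments:
                    lo_d, hi_d = config.blood_depth_log10
                    depth = int(round(10 ** rng.uniform(lo_d, hi_d)))
                    meta = SampleMeta(
                        sample_id=f"{subject_id}_blood_none_d{tp}",
                        subject_id=subject_id,
                        compartment="blood",
                        flank="none",
                        timepoint=tp,
                        group=group,
                        tumor_model=config.tumor_model,
                    )
                    samples.append(
                        _draw_sample(rng, meta, blood_keys, blood_base, blood_genes, depth)
                    )

    for s in samples:
        m = s.meta
        meta_rows.append(
            {
                "sample_id": m.sample_id,
                "subject_id": m.subject_id,
                "compartment": m.compartment,
                "flank": m.flank,
                "timepoint": m.timepoint,
                "group": m.group,
                "tumor_model": m.tumor_model,
                "path": f"samples/{m.sample_id}.tsv",
            }
        )
    meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(config=config, subjects=subjects, shared_panel=shared_panel)
    result = StudyResult(samples=samples, meta=meta, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "samples").mkdir(parents=True, exist_ok=True)
        for s in samples:
            write_repertoire(s, out / "samples" / f"{s.meta.sample_id}.tsv", dialect="airr")
        meta.to_csv(out / "meta.csv", index=False)
        truth.union_panel().to_csv(out / "panel.csv")
        truth.to_json(out / "truth.json")
        config.to_yaml(out / "config.yaml")
    return result


def truth_check(result: StudyResult, pass_fraction: float = 0.98) -> dict:
    """Verify simulator output against its own generative truth.

    Checks, each aggregated across samples (a check passes when at least
    ``pass_fraction`` of its per-sample comparisons are within tolerance —
    with hundreds of samples a handful of 3σ excursions are expected by
    chance):

    * ``depth_bounds``: every sample total within its compartment's depth range;
    * ``panel_mass_calibration``: empirical tumor panel mass within 3σ
      (binomial) of the scheduled latent mass;
    * ``frequency_calibration``: spot-checked clone counts within 3σ
      (binomial) of depth × latent frequency.
    """
    cfg = result.truth.config
    checks: list[dict] = []

    def add(name: str, results: list[bool], detail: str) -> None:
        frac = float(np.mean(results)) if results else 1.0
        checks.append(
            {"name": name, "passed": bool(frac >= pass_fraction), "fraction_ok": frac, "detail": detail}
        )

    depth_ok = []
    for s in result.samples:
        lo, hi = (
            cfg.tumor_depth_log10 if s.meta.compartment == "tumor" else cfg.blood_depth_log10
        )
        depth_ok.append(10**lo * 0.999 <= s.total_count <= 10**hi * 1.001)
    add("depth_bounds", depth_ok, "sample totals within configured depth ranges")

    mass_ok = []
    panel = result.truth.union_panel()
    panel_cdr3 = {c for _, _, c in panel.entries}
    for s in result.subset(compartment="tumor"):
        st = result.truth.subjects[s.meta.subject_id]
        step = list(cfg.timepoints).index(s.meta.timepoint)
        expected = st.expected_panel_mass(cfg, step)
        observed = sum(c.count for c in s.clonotypes if c.cdr3_aa in panel_cdr3) / s.total_count
        sigma = math.sqrt(max(expected * (1 - expected), 1e-12) / s.total_count)
        mass_ok.append(abs(observed - expected) <= 3 * sigma)
    add("panel_mass_calibration", mass_ok, "tumor panel mass vs expansion schedule (3 sigma)")

    freq_ok = []
    rng = np.random.default_rng(cfg.seed + 1)
    tumor_samples = result.subset(compartment="tumor")
    spot = tumor_samples[:: max(1, len(tumor_samples) // 20)]
    for s in spot:
        keys, f = result.truth.expected_frequencies(
            s.meta.subject_id, s.meta.timepoint, "tumor"
        )
        count_map = {c.cdr3_aa: c.count for c in s.clonotypes}
        ix = rng.choice(len(keys), size=min(50, len(keys)), replace=False)
        n = s.total_count
        for i in ix:
            mu = n * f[i]
            sigma = math.sqrt(max(n * f[i] * (1 - f[i]), 1e-12))
            freq_ok.append(abs(count_map.get(keys[i], 0) - mu) <= 3 * max(sigma, 1.0))
    add("frequency_calibration", freq_ok, "clone counts vs latent frequencies (3 sigma)")

    return {"passed": all(c["passed"] for c in checks), "checks": checks}
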