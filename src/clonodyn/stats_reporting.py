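"""Group-comparison statistics and the end-to-end study report.

This module owns the *design mapping* — which test is applied where, and
which multiple-comparison family is adjusted — while the tests themselves
are standard implementations (scipy.stats; statsmodels for the adjustment
procedures):

* Mann-Whitney U (two-sided; exact when both groups have n <= 10 and no
  ties, normal approximation with tie correction otherwise) for
  responder-vs-non-responder comparisons of a metric at each timepoint,
  with Holm-Bonferroni adjustment across the timepoints of a metric;
* Kruskal-Wallis (the nonparametric one-way ANOVA) when more than two
  groups are compared at a timepoint;
* Friedman for within-subject comparisons across timepoints (complete
  blocks required);
* Benjamini-Hochberg at a stated FDR as the alternative adjustment family.

:func:`build_report` joins every analysis stage over a simulated or loaded
study into one machine-readable bundle.
"""

from __future__ import annotations

import json
import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import diversity as dv
from . import overlap_tracking as ot
from .antigen_matching import ClonotypePanel, panel_trajectory
from .repertoire_model import RepertoireSample, load_study
from .signature_classifier import ClassifierConfig, fit_signature, signature_timecourse
from .synthetic_data import SimulationConfig

__all__ = ["compare_groups", "build_report", "TESTS", "ADJUSTMENTS"]

TESTS = ("mann_whitney", "kruskal_wallis", "friedman")
ADJUSTMENTS = ("holm_bonferroni", "benjamini_hochberg", "none")


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _degenerate(values: Sequence[np.ndarray]) -> str | None:
    if any(len(v) < 2 for v in values):
        return "degenerate: fewer than 2 observations in a group"
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        return "degenerate: all observations tied"
    return None


def compare_groups(
    values: pd.DataFrame,
    metric: str = "value",
    group_col: str = "group",
    time_col: str = "timepoint",
    subject_col: str = "subject_id",
    test: str = "mann_whitney",
    adjust: str = "holm_bonferroni",
    q: float = 0.1,
) -> pd.DataFrame:
    """Run the design-specified test per timepoint (or per subject series).

    ``values`` is a long table with one row per observation.  For
    ``mann_whitney``/``kruskal_wallis`` one test is run per timepoint across
    groups, and the adjustment is applied family-wise across the timepoints.
    For ``friedman`` one test is run per group across timepoints on
    complete subject blocks.  Degenerate designs (a group with n < 2, or all
    values tied) yield a flagged row with no p-value.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjust!r}; expected one of {ADJUSTMENTS}")

    rows: list[dict] = []
    if test in ("mann_whitney", "kruskal_wallis"):
        for tp, sub in values.groupby(time_col, sort=True):
            groups = [g for _, g in sub.groupby(group_col, sort=True)]
            arrays = [np.asarray(g[metric], dtype=float) for g in groups]
            row = {"metric": metric, "scope": tp, "test": test}
            flag = _degenerate(arrays) if len(arrays) >= 2 else "degenerate: single group"
            if flag is None and test == "mann_whitney" and len(arrays) != 2:
                flag = f"degenerate: mann_whitney needs 2 groups, got {len(arrays)}"
            if flag:
                row.update(statistic=math.nan, p_raw=math.nan, flag=flag)
            elif test == "mann_whitney":
                stat, p = _mann_whitney(arrays[0], arrays[1])
                row.update(statistic=stat, p_raw=p, flag="")
            else:
                res = stats.kruskal(*arrays)
                row.update(statistic=float(res.statistic), p_raw=float(res.pvalue), flag="")
            rows.append(row)
    else:  # friedman: within-subject across timepoints, per group
        for grp, sub in values.groupby(group_col, sort=True):
            block = sub.pivot_table(index=subject_col, columns=time_col, values=metric)
            block = block.dropna(axis=0)  # complete blocks only
            row = {"metric": metric, "scope": grp, "test": test}
            if block.shape[0] < 2 or block.shape[1] < 3:
                row.update(
                    statistic=math.nan,
                    p_raw=math.nan,
                    flag="degenerate: friedman needs >= 2 complete blocks and >= 3 timepoints",
                )
            else:
                res = stats.friedmanchisquare(*[block[c].to_numpy() for c in block.columns])
                row.update(statistic=float(res.statistic), p_raw=float(res.pvalue), flag="")
            rows.append(row)

    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    testable = out["p_raw"].notna()
    if testable.any() and adjust != "none":
        method = "holm" if adjust == "holm_bonferroni" else "fdr_bh"
        alpha = 0.05 if adjust == "holm_bonferroni" else q
        _, p_adj, _, _ = multipletests(out.loc[testable, "p_raw"], alpha=alpha, method=method)
        out.loc[testable, "p_adjusted"] = p_adj
    elif adjust == "none":
        out["p_adjusted"] = out["p_raw"]
    out["adjustment"] = adjust
    out["q"] = q if adjust == "benjamini_hochberg" else np.nan
    return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def build_report(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    seed: int = 0,
    run_classifier: bool = True,
    classifier_config: ClassifierConfig | None = None,
) -> dict:
    """Join every analysis stage over one study directory into a report bundle.

    Expects the layout written by the simulator (``meta.csv`` + ``samples/``,
    optionally ``panel.csv``).  Produces figure-level tables: per-sample
    diversity with responder/non-responder tests, bilateral overlap strata,
    persistent-clone counts from blood series, panel trajectories, and
    (optionally) the day-0-trained signature timecourse.  Sections whose
    inputs are absent from the study are marked absent rather than failing.
    Deterministic given the study and seed.
    """
    study_dir = Path(study_dir)
    samples = load_study(study_dir / "meta.csv", dialect="airr")
    report: dict = {"study_dir": str(study_dir), "seed": seed, "sections": {}}
    tables: dict[str, pd.DataFrame] = {}

    tumor = [s for s in samples if s.meta.compartment == "tumor"]
    blood = [s for s in samples if s.meta.compartment == "blood"]
    groups = sorted({s.meta.group for s in samples})
    two_groups = len(groups) == 2

    # --- diversity (tumor, right flank to keep one observation per subject) ---
    tumor_right = [s for s in tumor if s.meta.flank == "right"] or tumor
    if tumor_right:
        div = dv.profile_table(tumor_right, depth="auto", seed=seed)
        tables["diversity_tumor"] = div
        section = {"n_samples": len(div), "depth": int(div["depth"].iloc[0])}
        if two_groups:
            tests = compare_groups(
                div.rename(columns={"shannon_norm": "value"}),
                metric="value",
                test="mann_whitney",
                adjust="holm_bonferroni",
            )
            tests["metric"] = "shannon_norm"
            tables["diversity_tests"] = tests
            section["tests"] = tests.to_dict(orient="records")
        report["sections"]["diversity"] = section
    else:
        report["sections"]["diversity"] = {"absent": True}

    # --- bilateral overlap strata per timepoint ---
    flanks_present = {s.meta.flank for s in tumor}
    if {"left", "right"} <= flanks_present:
        frames = []
        for tp in sorted({s.meta.timepoint for s in tumor}):
            at_tp = [s for s in tumor if s.meta.timepoint == tp]
            depth = dv.common_depth(at_tp)
            ss = np.random.SeedSequence([seed, tp])
            rarefied = [
                dv.rarefy(s, depth, rng=np.random.default_rng(child))
                for s, child in zip(at_tp, ss.spawn(len(at_tp)))
            ]
            ov = ot.overlap_matrix(rarefied)
            ov["timepoint"] = tp
            frames.append(ov)
        overlaps = pd.concat(frames, ignore_index=True)
        tables["overlap_tumor"] = overlaps
        summary = ot.overlap_summary(overlaps)
        tables["overlap_summary"] = summary
        report["sections"]["overlap"] = {"strata": summary.to_dict(orient="records")}
    else:
        report["sections"]["overlap"] = {"absent": True}

    # --- persistent abundant clones in blood series ---
    if blood:
        rows = []
        for subject in sorted({s.meta.subject_id for s in blood}):
            series = [s for s in blood if s.meta.subject_id == subject]
            if len(series) < 2:
                continue
            depth = dv.common_depth(series)
            ss = np.random.SeedSequence([seed, zlib.crc32(subject.encode()) % (2**31)])
            rarefied = [
                dv.rarefy(s, depth, rng=np.random.default_rng(child))
                for s, child in zip(series, ss.spawn(len(series)))
            ]
            rows.append(
                {
                    "subject_id": subject,
                    "group": series[0].meta.group,
                    "persistent_abundant": ot.persistent_count(rarefied, top_n=100),
                }
            )
        if rows:
            persist = pd.DataFrame(rows)
            tables["persistent_clones"] = persist
            report["sections"]["tracking"] = {
                "per_group_mean": persist.groupby("group")["persistent_abundant"]
                .mean()
                .to_dict()
            }
        else:
            report["sections"]["tracking"] = {"absent": True}
    else:
        report["sections"]["tracking"] = {"absent": True}

    # --- antigen panel trajectory ---
    panel_path = study_dir / "panel.csv"
    if panel_path.exists() and tumor_right:
        panel = ClonotypePanel.from_csv(panel_path)
        long, occ = panel_trajectory(tumor_right, panel, mode="vjcdr3aa")
        tables["panel_trajectory"] = long
        tables["panel_occupancy"] = occ.reset_index()
        section = {
            "per_group_timepoint_mass": long.groupby(["group", "timepoint"])["matched_mass"]
            .mean()
            .reset_index()
            .to_dict(orient="records")
        }
        if two_groups:
            tests = compare_groups(
                long.rename(columns={"matched_mass": "value"}),
                metric="value",
                test="mann_whitney",
                adjust="benjamini_hochberg",
                q=0.1,
            )
            tests["metric"] = "matched_mass"
            tables["panel_tests"] = tests
            section["tests"] = tests.to_dict(orient="records")
        report["sections"]["panel"] = section
    else:
        report["sections"]["panel"] = {"absent": True}

    # --- signature timecourse (day-0-trained tumor-response signature) ---
    if run_classifier and two_groups and tumor_right:
        cfg = classifier_config or ClassifierConfig(
            label_field="group", train_timepoints=(min(s.meta.timepoint for s in tumor_right),),
            n_splits=5, seed=seed,
        )
        try:
            model = fit_signature(tumor_right, cfg)
            tc = signature_timecourse(model, tumor_right)
            tables["signature_timecourse"] = tc
            report["sections"]["signature"] = {
                "train_timepoints": list(cfg.train_timepoints or []),
                "positive_label": model.positive_label,
                "per_group_timepoint_mean": tc.groupby(["group", "timepoint"])[
                    f"w_{model.positive_label}"
                ]
                .mean()
                .reset_index()
                .to_dict(orient="records"),
            }
        except ValueError as err:
            report["sections"]["signature"] = {"absent": True, "reason": str(err)}
    else:
        report["sections"]["signature"] = {"absent": True}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default, sort_keys=True)
    return report
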