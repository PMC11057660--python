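# clonodyn

Longitudinal TCRβ repertoire dynamics for immune checkpoint therapy (ICT)
studies: clonotype filtering and I/O, rarefaction, diversity/clonality
statistics, repertoire overlap, clone-trajectory tracking, public
antigen-specific clonotype matching, and a transparent repertoire signature
classifier with permutation validation — plus a ground-truth synthetic study
generator so the entire pipeline is testable without any sequencing data.

## Who this is for

Analysts of bulk AIRR-seq (TCRβ CDR3) data from serial-sampling designs:
subjects (e.g. tumor-bearing mice) sampled in blood and tumor before and
during therapy, with a response label per subject. The package answers the
standard questions of such designs: does clonal expansion precede response,
do bilateral tumors share a repertoire, do known antigen-specific clonotypes
expand, and is there a sequence-level signature predictive of outcome.

## The statistics at its core

All statistics operate on clone frequencies `p_i = count_i / N` of a
repertoire rarefied (hypergeometric subsampling without replacement) to the
smallest total count of the comparison set. Clonal T cells are defined by
distinct CDR3 amino-acid sequences; CDR3s shorter than 8 or longer than 20
residues are excluded.

- **Shannon diversity** `H = −Σ p_i ln p_i` and its normalized (Pielou)
  form `H / ln S` (1 = perfectly even repertoire).
- **Rényi profile** `H_α = ln(Σ p_i^α)/(1−α)`, with `H_0 = ln S`,
  `H_1 = H`, `H_∞ = −ln max p_i`; non-increasing in α.
- **Gini index** of the clone-count vector — both the inequality
  coefficient `G` and its evenness complement `1 − G` are reported, since
  orientation conventions differ across figures in the field.
- **Morisita-Horn overlap**
  `MH = 2 Σ x_i y_i / ((Σ x_i²/X² + Σ y_i²/Y²)·X·Y)` over the union of
  clone keys: exactly 1 for identical repertoires, exactly 0 for disjoint
  ones (computed in exact integer arithmetic so the identities hold to the
  bit).
- **Persistent-and-abundant clones**: clones ranked in the top 100 by
  abundance at more than one timepoint of a subject series.
- **Panel matching**: exact V/J/CDR3 (or CDR3-only) string equality against
  a curated antigen-associated clonotype panel, reporting matched clone
  counts and repertoire mass.
- **Signature classifier**: every TCRβ inherits its sample's label and its
  within-sample frequency as a loss weight; a regularized linear model over
  CDR3 3-mer counts, V/J one-hots and CDR3 length scores each sequence, and
  the sample score is the frequency-weighted mean probability ("weighted
  proportion of signature"). Validation is strictly sample-level
  (Monte-Carlo CV) with a label-permutation null.

## Worked example

```python
import numpy as np
from clonodyn import (SimulationConfig, simulate_study, common_depth, rarefy,
                      shannon, morisita_horn, match_panel)

cfg = SimulationConfig(seed=17)          # 8 subjects/group, days 0/2/4/6, bilateral tumors
study = simulate_study(cfg)

tumors = study.subset(compartment="tumor", flank="right")
depth = common_depth(tumors)
print(f"{len(study.samples)} samples; rarefying {len(tumors)} right-flank tumors to depth {depth}")

for group in ("responder", "non_responder"):
    for tp in (0, 6):
        vals = [shannon(rarefy(s, depth, seed=1))[1] for s in tumors
                if s.meta.group == group and s.meta.timepoint == tp]
        print(f"  {group:13s} day {tp}: normalized Shannon {np.mean(vals):.3f} +/- {np.std(vals):.3f}")
```

prints

```
192 samples; rarefying 64 right-flank tumors to depth 1013
  responder     day 0: normalized Shannon 0.937 +/- 0.022
  responder     day 6: normalized Shannon 0.862 +/- 0.006
  non_responder day 0: normalized Shannon 0.932 +/- 0.020
  non_responder day 6: normalized Shannon 0.927 +/- 0.017
```

— responders' tumors lose diversity as their planted tumor-antigen-specific
clones expand (fold 2.0 per timepoint step vs 1.2 in non-responders), while
the groups start indistinguishable at day 0. The same study shows the
bilateral-tumor property and the antigen-panel expansion:

```python
left, right = study.by_id("R1_tumor_left_d0"), study.by_id("R1_tumor_right_d0")
other = study.by_id("R2_tumor_right_d0")
d = common_depth([left, right, other])
l, r, o = (rarefy(s, d, seed=2) for s in (left, right, other))
print(f"within-subject MH: {morisita_horn(l, r):.3f}; between-subject: {morisita_horn(r, o):.3f}")

panel = study.truth.union_panel()
for tp in (0, 6):
    mass = [match_panel(s, panel).matched_mass for s in tumors
            if s.meta.group == "responder" and s.meta.timepoint == tp]
    print(f"responder panel mass day {tp}: {np.mean(mass):.3f}")
```

```
within-subject MH: 0.734; between-subject: 0.052
responder panel mass day 0: 0.051
responder panel mass day 6: 0.304
```

Contralateral tumors drawn from one subject's latent clone distribution
overlap strongly; repertoires of different subjects share almost nothing —
and the antigen panel grows from ~5% to ~30% of responders' repertoires.

The same analyses are available from the shell:

```bash
clonodyn simulate --config sim.yaml --out study/
clonodyn diversity --meta study/meta.csv --depth auto --seed 17 --out diversity.csv
clonodyn overlap   --meta study/meta.csv --out overlap.csv
clonodyn track     --meta study/meta.csv --subject R1 --compartment blood --out tracks.csv
clonodyn match     --meta study/meta.csv --panel study/panel.csv --out hits.csv
clonodyn classify  --meta study/meta.csv --label group --train-timepoints 0 --out signature/
clonodyn report    --study study/ --out report/
```

Real data enters through AIRR-C rearrangement TSVs (columns `junction_aa`,
`v_call`, `j_call`, `duplicate_count`, …) or a minimal CSV dialect, plus a
sample-metadata sheet (`sample_id, subject_id, compartment, flank,
timepoint, group, tumor_model, path`). Antigen panels are CSVs with
`v_gene, j_gene, cdr3_aa` columns; the packaged 60-entry panel is a
synthetic stand-in for shape only.

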