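"""Transparent multiple-instance repertoire classification with permutation nulls.

The protocol: every TCRβ sequence in a labeled sample is an *instance*
inheriting its sample's label, weighted by its within-sample frequency p_i.
A regularized linear (logistic) model over interpretable sequence features
— position-free CDR3 amino-acid 3-mer counts, one-hot V and J genes, and
CDR3 length — yields a per-sequence signature probability for each label.
Sample-level scores aggregate per-sequence probabilities as the
frequency-weighted mean (the "weighted proportion of signature"), and the
predicted label is the argmax.

Validation is always at the sample level, never the clone level: Monte-Carlo
cross-validation splits whole samples, the feature vocabulary is rebuilt
from each training split, and the permutation null refits the model after
shuffling sample labels (preserving each sample's sequences).  AUC is the
Mann-Whitney rank statistic with mid-ranked ties.

The model can be trained on a timepoint-restricted subset (e.g. only
pre-treatment samples) and applied to the remaining timepoints, which is
the standard design for asking whether an early signature is predictive of
later labels.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata, spearmanr
from sklearn.linear_model import LogisticRegression

from .repertoire_model import Clonotype, RepertoireSample, key_of, normalize_gene

__all__ = [
    "Vocabulary",
    "ClassifierConfig",
    "SignatureModel",
    "SampleScore",
    "ValidationRecord",
    "kmer_counts",
    "build_vocabulary",
    "featurize",
    "fit_signature",
    "score_sequences",
    "score_sample",
    "score_samples",
    "signature_timecourse",
    "crossvalidate",
    "correlate_signatures",
    "auc_rank",
    "roc_points",
]


@lru_cache(maxsize=1 << 20)
def _kmer_items(seq: str, k: int) -> tuple[tuple[str, int], ...]:
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    return tuple(sorted(counts.items()))


def kmer_counts(seq: str, k: int = 3) -> Counter:
    """Position-free k-mer counts of an amino-acid sequence."""
    return Counter(dict(_kmer_items(seq, k)))


@dataclass(frozen=True)
class Vocabulary:
    """Fixed feature vocabulary built from a training set.

    Feature layout: [k-mer counts | one-hot V gene | one-hot J gene | CDR3
    length].  Sorted construction makes the layout deterministic; k-mers or
    genes unseen in training are dropped at scoring time.
    """

    kmers: tuple[str, ...]
    v_genes: tuple[str, ...]
    j_genes: tuple[str, ...]
    k: int = 3

    @property
    def dim(self) -> int:
        return len(self.kmers) + len(self.v_genes) + len(self.j_genes) + 1

    def indices(self) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
        kmer_ix = {m: i for i, m in enumerate(self.kmers)}
        off_v = len(self.kmers)
        v_ix = {g: off_v + i for i, g in enumerate(self.v_genes)}
        off_j = off_v + len(self.v_genes)
        j_ix = {g: off_j + i for i, g in enumerate(self.j_genes)}
        return kmer_ix, v_ix, j_ix


def build_vocabulary(clones: Sequence[Clonotype], k: int = 3) -> Vocabulary:
    """Deterministic vocabulary: sorted k-mers and genes observed in training clones."""
    kmers: set[str] = set()
    v_genes: set[str] = set()
    j_genes: set[str] = set()
    for c in clones:
        kmers.update(m for m, _ in _kmer_items(c.cdr3_aa, k))
        v = normalize_gene(c.v_gene)
        j = normalize_gene(c.j_gene)
        if v:
            v_genes.add(v)
        if j:
            j_genes.add(j)
    return Vocabulary(tuple(sorted(kmers)), tuple(sorted(v_genes)), tuple(sorted(j_genes)), k)


def featurize(clones: Sequence[Clonotype], vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse feature matrix (n_clones × vocab.dim) under a fixed vocabulary."""
    kmer_ix, v_ix, j_ix = vocab.indices()
    len_col = vocab.dim - 1
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for c in clones:
        for m, n in _kmer_items(c.cdr3_aa, vocab.k):
            if m in kmer_ix:
                indices.append(kmer_ix[m])
                data.append(float(n))
        v = normalize_gene(c.v_gene)
        if v in v_ix:
            indices.append(v_ix[v])
            data.append(1.0)
        j = normalize_gene(c.j_gene)
        if j in j_ix:
            indices.append(j_ix[j])
            data.append(1.0)
        indices.append(len_col)
        data.append(float(len(c.cdr3_aa)))
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices), np.asarray(indptr)),
        shape=(len(clones), vocab.dim),
    )


@dataclass
class ClassifierConfig:
    """Hyperparameters and protocol settings, with seeds threaded through.

    ``C=None`` selects the L2 strength by inner Monte-Carlo CV on the
    training samples only; permutation refits reuse the already-selected
    value so the null stays affordable.  ``weight_mode`` chooses whether an
    instance's loss weight is its within-sample frequency (default) or its
    raw count.
    """

    label_field: str = "group"
    k: int = 3
    C: float | None = 1.0
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    inner_splits: int = 2
    test_fraction: float = 0.25
    n_splits: int = 10
    n_permutations: int = 0
    weight_mode: str = "frequency"  # or "count"
    train_timepoints: tuple[int, ...] | None = None
    seed: int = 0


@dataclass
class SignatureModel:
    """A fitted per-sequence scorer plus its training-protocol descriptor."""

    labels: tuple[str, ...]
    vocab: Vocabulary
    estimator: LogisticRegression
    base_rate: np.ndarray  # training label frequencies, for feature-less clones
    config: ClassifierConfig
    train_sample_ids: tuple[str, ...]
    train_timepoints: tuple[int, ...] | None

    @property
    def positive_label(self) -> str:
        """The label treated as 'positive' in binary summaries (last in sorted order)."""
        return self.labels[-1]


@dataclass
class SampleScore:
    sample_id: str
    weighted_signature: dict[str, float]  # label -> frequency-weighted mean probability
    predicted_label: str


@dataclass
class ValidationRecord:
    """Cross-validation and permutation summary for one classification design."""

    positive_label: str
    fold_aucs: list[float]
    observed_auc: float
    roc: pd.DataFrame
    sample_scores: pd.DataFrame
    permutation_aucs: list[float] = field(default_factory=list)
    permutation_mean: float = math.nan
    permutation_p: float = math.nan
    n_permutations: int = 0
    seed: int = 0
    selected_C: float = math.nan


def _label_of(sample: RepertoireSample, label_field: str) -> str:
    return str(getattr(sample.meta, label_field))


def _select_training(samples, config: ClassifierConfig):
    if config.train_timepoints is None:
        return list(samples)
    keep = set(config.train_timepoints)
    return [s for s in samples if s.meta.timepoint in keep]


def _instances(samples: Sequence[RepertoireSample], config: ClassifierConfig, labels):
    clones: list[Clonotype] = []
    y: list[str] = []
    w: list[float] = []
    for s, lab in zip(samples, labels):
        total = float(s.total_count)
        for c in s.clonotypes:
            clones.append(c)
            y.append(lab)
            w.append(c.count / total if config.weight_mode == "frequency" else float(c.count))
    weights = np.asarray(w, dtype=float)
    if weights.sum() > 0:
        weights = weights * (len(weights) / weights.sum())  # mean weight 1 vs fixed penalty
    return clones, np.asarray(y), weights


def _fit_on(samples, labels, config: ClassifierConfig, C: float) -> SignatureModel:
    label_set = tuple(sorted(set(labels)))
    if len(label_set) < 2:
        raise ValueError(f"training set has a single label: {label_set}")
    clones, y, w = _instances(samples, config, labels)
    vocab = build_vocabulary(clones, config.k)
    X = featurize(clones, vocab)
    # liblinear: fast deterministic coordinate descent, well-suited to the
    # binary, sparse, high-dimensional instance problems this protocol produces
    est = LogisticRegression(C=C, solver="liblinear", max_iter=500, random_state=config.seed)
    est.fit(X, y, sample_weight=w)
    counts = Counter(labels)
    base = np.array([counts[l] / len(labels) for l in label_set], dtype=float)
    return SignatureModel(
        labels=label_set,
        vocab=vocab,
        estimator=est,
        base_rate=base,
        config=config,
        train_sample_ids=tuple(s.meta.sample_id for s in samples),
        train_timepoints=config.train_timepoints,
    )


def _stratified_splits(labels: np.ndarray, config: ClassifierConfig, rng: np.random.Generator):
    """Monte-Carlo sample-level splits; every label appears in train and test."""
    label_set = sorted(set(labels.tolist()))
    idx_by_label = {l: np.flatnonzero(labels == l) for l in label_set}
    for l, idx in idx_by_label.items():
        if len(idx) < 2:
            raise ValueError(f"need >= 2 samples per label; label {l!r} has {len(idx)}")
    splits = []
    for _ in range(config.n_splits):
        test: list[int] = []
        for l, idx in idx_by_label.items():
            n_test = max(1, int(round(config.test_fraction * len(idx))))
            n_test = min(n_test, len(idx) - 1)  # keep >= 1 training sample per label
            test.extend(rng.permutation(idx)[:n_test].tolist())
        test_set = set(test)
        train = [i for i in range(len(labels)) if i not in test_set]
        splits.append((train, sorted(test)))
    return splits


def _choose_C(samples, labels, config: ClassifierConfig, rng: np.random.Generator) -> float:
    """Inner CV over the C grid using training samples only."""
    inner_cfg = replace(config, n_splits=config.inner_splits)
    labels_arr = np.asarray(labels)
    try:
        splits = _stratified_splits(labels_arr, inner_cfg, rng)
    except ValueError:
        return inner_cfg.c_grid[len(inner_cfg.c_grid) // 2]
    best_c, best_auc = config.c_grid[0], -1.0
    for c in config.c_grid:
        aucs = []
        for train_ix, test_ix in splits:
            model = _fit_on(
                [samples[i] for i in train_ix], [labels[i] for i in train_ix], config, c
            )
            scores, truth = _test_scores(model, [samples[i] for i in test_ix],
                                         [labels[i] for i in test_ix])
            if len(set(truth)) == 2:
                aucs.append(auc_rank(truth, scores))
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        if mean_auc > best_auc:
            best_c, best_auc = c, mean_auc
    return best_c


def fit_signature(
    samples: Sequence[RepertoireSample],
    config: ClassifierConfig | None = None,
    labels: Mapping[str, str] | None = None,
) -> SignatureModel:
    """Fit the frequency-weighted per-sequence signature model.

    Labels come from each sample's metadata field ``config.label_field``
    unless an explicit ``sample_id -> label`` mapping is given.  When
    ``config.train_timepoints`` is set only those timepoints are used.
    """
    config = config or ClassifierConfig()
    train = _select_training(samples, config)
    if not train:
        raise ValueError("no training samples after timepoint selection")
    labs = [
        labels[s.meta.sample_id] if labels is not None else _label_of(s, config.label_field)
        for s in train
    ]
    rng = np.random.default_rng(config.seed)
    C = config.C if config.C is not None else _choose_C(train, labs, config, rng)
    return _fit_on(train, labs, config, C)


def score_sequences(model: SignatureModel, sample: RepertoireSample) -> pd.DataFrame:
    """Per-clone signature probabilities (one row per clone, one column per label).

    Clones whose feature vector is empty under the training vocabulary fall
    back to the training-set base rate.  Identical clones receive identical
    scores by construction.
    """
    clones = sample.clonotypes
    X = featurize(clones, model.vocab)
    # the length column is always set; "empty" means no k-mer/V/J features at all
    informative = np.diff(X.indptr) > 1
    proba = np.tile(model.base_rate, (len(clones), 1))
    if informative.any():
        est_proba = model.estimator.predict_proba(X[informative])
        order = [list(model.estimator.classes_).index(l) for l in model.labels]
        proba[informative] = est_proba[:, order]
    df = pd.DataFrame(proba, columns=list(model.labels))
    df.insert(0, "clone_key", [key_of(c, sample.key_scheme) for c in clones])
    df.insert(1, "frequency", sample.frequencies())
    return df


def score_sample(model: SignatureModel, sample: RepertoireSample) -> SampleScore:
    """Frequency-weighted mean of per-clone probabilities; argmax prediction."""
    df = score_sequences(model, sample)
    f = df["frequency"].to_numpy()
    weighted = {l: float((f * df[l].to_numpy()).sum() / f.sum()) for l in model.labels}
    predicted = max(model.labels, key=lambda l: weighted[l])
    return SampleScore(sample.meta.sample_id, weighted, predicted)


def score_samples(model: SignatureModel, samples: Sequence[RepertoireSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        sc = score_sample(model, s)
        row = {"sample_id": sc.sample_id, "predicted_label": sc.predicted_label}
        row.update({f"w_{l}": v for l, v in sc.weighted_signature.items()})
        m = s.meta
        row.update(
            subject_id=m.subject_id,
            compartment=m.compartment,
            timepoint=m.timepoint,
            group=m.group,
            tumor_model=m.tumor_model,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def signature_timecourse(
    model: SignatureModel, samples: Sequence[RepertoireSample]
) -> pd.DataFrame:
    """Per-sample weighted signature with group/timepoint metadata, long format."""
    df = score_samples(model, samples)
    return df.sort_values(["group", "timepoint", "subject_id", "sample_id"], ignore_index=True)


def auc_rank(truth: Sequence[bool], scores: Sequence[float]) -> float:
    """AUC via the Mann-Whitney rank statistic (ties mid-ranked)."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(truth: Sequence[bool], scores: Sequence[float]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) over the observed score set."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    rows = []
    n_pos = truth.sum()
    n_neg = (~truth).sum()
    for t in thresholds:
        called = scores >= t
        rows.append(
            {
                "threshold": t,
                "tpr": float((called & truth).sum() / n_pos),
                "fpr": float((called & ~truth).sum() / n_neg),
            }
        )
    return pd.DataFrame(rows)


def _test_scores(model: SignatureModel, samples, labels):
    pos = model.positive_label
    scores = [score_sample(model, s).weighted_signature[pos] for s in samples]
    truth = [l == pos for l in labels]
    return np.asarray(scores), np.asarray(truth)


def _run_cv(samples, labels, config: ClassifierConfig, C: float, rng: np.random.Generator):
    """One full Monte-Carlo CV pass; returns fold AUCs and pooled test scores."""
    labels_arr = np.asarray(labels)
    splits = _stratified_splits(labels_arr, config, rng)
    fold_aucs = []
    pooled: list[dict] = []
    for train_ix, test_ix in splits:
        model = _fit_on([samples[i] for i in train_ix], [labels[i] for i in train_ix], config, C)
        scores, truth = _test_scores(
            model, [samples[i] for i in test_ix], [labels[i] for i in test_ix]
        )
        fold_aucs.append(auc_rank(truth, scores))
        for i, sc, tr in zip(test_ix, scores, truth):
            pooled.append(
                {"sample_id": samples[i].meta.sample_id, "score": float(sc), "is_positive": bool(tr)}
            )
    return fold_aucs, pd.DataFrame(pooled)


def crossvalidate(
    samples: Sequence[RepertoireSample],
    config: ClassifierConfig | None = None,
    labels: Mapping[str, str] | None = None,
) -> ValidationRecord:
    """Sample-level Monte-Carlo cross-validation with a label-permutation null.

    Whole samples are held out (clones never leak between train and test),
    the vocabulary is rebuilt per training split, and each of
    ``config.n_permutations`` null replicates shuffles the sample labels
    before re-running the identical CV.  The permutation p-value is the
    add-one estimate of P(permuted AUC >= observed AUC).
    """
    config = config or ClassifierConfig()
    samples = _select_training(samples, config)
    labs = [
        labels[s.meta.sample_id] if labels is not None else _label_of(s, config.label_field)
        for s in samples
    ]
    label_set = sorted(set(labs))
    if len(label_set) != 2:
        raise ValueError(f"crossvalidate requires exactly 2 labels, got {label_set}")
    if len(samples) < 4:
        raise ValueError("crossvalidate requires at least 4 samples (2 per label)")
    rng = np.random.default_rng(config.seed)
    C = config.C if config.C is not None else _choose_C(samples, labs, config, rng)
    fold_aucs, pooled = _run_cv(samples, labs, config, C, rng)
    observed = float(np.mean(fold_aucs))
    roc = roc_points(pooled["is_positive"], pooled["score"])

    perm_aucs: list[float] = []
    for _ in range(config.n_permutations):
        perm = [labs[i] for i in rng.permutation(len(labs))]
        p_aucs, _ = _run_cv(samples, perm, config, C, rng)
        perm_aucs.append(float(np.mean(p_aucs)))
    n_perm = len(perm_aucs)
    return ValidationRecord(
        positive_label=label_set[-1],
        fold_aucs=[float(a) for a in fold_aucs],
        observed_auc=observed,
        roc=roc,
        sample_scores=pooled,
        permutation_aucs=perm_aucs,
        permutation_mean=float(np.mean(perm_aucs)) if perm_aucs else math.nan,
        permutation_p=(1 + sum(a >= observed for a in perm_aucs)) / (n_perm + 1)
        if n_perm
        else math.nan,
        n_permutations=n_perm,
        seed=config.seed,
        selected_C=float(C),
    )


@dataclass
class CorrelationResult:
    pairs: pd.DataFrame
    rho: float
    p_value: float
    degenerate: bool


def correlate_signatures(
    model_a: SignatureModel,
    model_b: SignatureModel,
    samples: Sequence[RepertoireSample],
) -> CorrelationResult:
    """Rank correlation between two models' per-clone positive-label scores.

    Scores the union of distinct clones across ``samples`` with both models
    and reports Spearman's rho.  When either scorer is constant over the
    clone set the correlation is undefined and flagged as degenerate
    (rho = NaN) rather than guessed.
    """
    seen: dict[str, Clonotype] = {}
    for s in samples:
        for c in s.clonotypes:
            seen.setdefault(key_of(c, "vjcdr3aa"), c)
    keys = sorted(seen)
    clones = [seen[k] for k in keys]
    pseudo_meta = samples[0].meta
    pseudo = RepertoireSample(pseudo_meta, [c.with_count(1) for c in clones], "vjcdr3aa")
    sa = score_sequences(model_a, pseudo).set_index("clone_key")[model_a.positive_label]
    sb = score_sequences(model_b, pseudo).set_index("clone_key")[model_b.positive_label]
    pairs = pd.DataFrame({"score_a": sa, "score_b": sb}).reset_index()
    if pairs["score_a"].nunique() < 2 or pairs["score_b"].nunique() < 2:
        return CorrelationResult(pairs, math.nan, math.nan, True)
    rho, p = spearmanr(pairs["score_a"], pairs["score_b"])
    return CorrelationResult(pairs, float(rho), float(p), False)
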