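"""Clonotype data model, clonal-definition keys, CDR3 filtering, and repertoire I/O.

A *clonotype* is one distinct TCRβ rearrangement, identified by its CDR3
amino-acid sequence (optionally together with V/J gene calls) and carrying a
UMI-corrected transcript count.  A *repertoire sample* is the set of
clonotypes observed in one specimen (a blood draw or a tumor), together with
its study metadata (subject, compartment, flank, timepoint, response group).

Two clonal definitions are supported, selected by a key scheme:

``cdr3aa``
    clonal T cells are defined by distinct CDR3 amino-acid sequences alone
    (the default used throughout diversity and overlap analysis);
``vjcdr3aa``
    identity additionally requires exact TRBV and TRBJ gene matches with
    allele suffixes stripped (used for public antigen-specific clonotype
    matching).

Productive-chain analysis is assumed: CDR3s shorter than 8 or longer than 20
residues, and CDR3s containing stop (``*``), frameshift (``_``) or ambiguous
(``X``) characters, are removed by :func:`filter_cdr3`.  Counts are consumed
as UMI/PID-corrected numbers; no read-level processing happens here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "MIN_CDR3_LEN",
    "MAX_CDR3_LEN",
    "KEY_SCHEMES",
    "Clonotype",
    "SampleMeta",
    "RepertoireSample",
    "RepertoireFormatError",
    "EmptyRepertoireError",
    "normalize_gene",
    "key_of",
    "filter_cdr3",
    "read_repertoire",
    "write_repertoire",
    "read_metadata",
    "load_study",
]

#: The 20 standard amino-acid one-letter codes.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Inclusive CDR3 amino-acid length bounds; sequences with fewer than 8 or
#: more than 20 residues are excluded from analysis.
MIN_CDR3_LEN = 8
MAX_CDR3_LEN = 20

KEY_SCHEMES = ("cdr3aa", "vjcdr3aa")

COMPARTMENTS = ("blood", "tumor")
FLANKS = ("left", "right", "none")
GROUPS = ("responder", "non_responder", "control")

# AIRR-C rearrangement dialect (TSV)
AIRR_COLUMNS = ("junction_aa", "junction", "v_call", "d_call", "j_call", "duplicate_count")
AIRR_REQUIRED = ("junction_aa", "v_call", "j_call", "duplicate_count")
# minimal CSV dialect
SIMPLE_COLUMNS = ("cdr3_aa", "v_gene", "j_gene", "count")
SIMPLE_REQUIRED = SIMPLE_COLUMNS

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "compartment",
    "flank",
    "timepoint",
    "group",
    "tumor_model",
    "path",
)


class RepertoireFormatError(ValueError):
    """A clonotype table is malformed (e.g. a required column is missing)."""


class EmptyRepertoireError(ValueError):
    """A repertoire with at least one clonotype was required but none found."""


def normalize_gene(label: object) -> str:
    """Normalize a V/J gene-segment label for comparison.

    Strips allele suffixes (``TRBV13-2*01`` → ``TRBV13-2``), surrounding
    whitespace, and unifies the legacy ``TCRBV``/``TCRBJ`` prefixes with the
    IMGT ``TRBV``/``TRBJ`` spelling.  ``None``/NaN/empty map to ``""``.
    """
    if label is None:
        return ""
    if isinstance(label, float) and np.isnan(label):
        return ""
    g = str(label).strip()
    if not g or g.lower() == "nan":
        return ""
    g = g.split("*", 1)[0].strip()
    if g.upper().startswith("TCRB"):
        g = "TRB" + g[4:]
    return g


@dataclass(frozen=True)
class Clonotype:
    """One distinct TCRβ rearrangement with sequence identity and abundance.

    ``count`` is the UMI-corrected transcript count for this clonotype in one
    sample; it must be >= 1 for any retained clonotype.
    """

    cdr3_aa: str
    count: int
    v_gene: str = ""
    j_gene: str = ""
    d_gene: str = ""
    cdr3_nt: str = ""

    def with_count(self, count: int) -> "Clonotype":
        return dataclasses.replace(self, count=int(count))


def key_of(c: Clonotype, scheme: str = "cdr3aa") -> str:
    """Clonotype identity key under the chosen clonal definition.

    ``cdr3aa`` keys on the CDR3 amino-acid sequence alone; ``vjcdr3aa`` keys
    on ``V|J|CDR3`` with allele suffixes stripped from the gene labels.
    """
    if scheme == "cdr3aa":
        return c.cdr3_aa
    if scheme == "vjcdr3aa":
        return f"{normalize_gene(c.v_gene)}|{normalize_gene(c.j_gene)}|{c.cdr3_aa}"
    raise ValueError(f"unknown clonotype key scheme: {scheme!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Study metadata for one repertoire sample.

    ``timepoint`` is in days relative to the first treatment dose.  The
    combination (subject_id, compartment, flank, timepoint) identifies a
    specimen uniquely within a study.
    """

    sample_id: str
    subject_id: str = ""
    compartment: str = "blood"
    flank: str = "none"
    timepoint: int = 0
    group: str = "control"
    tumor_model: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}")
        if self.flank not in FLANKS:
            raise ValueError(f"flank must be one of {FLANKS}, got {self.flank!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


def _merge_duplicates(clonotypes: Iterable[Clonotype], scheme: str) -> list[Clonotype]:
    """Aggregate clonotypes sharing an identity key by summing counts.

    The representative sequence fields (V/J/nt) of a merged clonotype are
    those of its most abundant contributor; ties broken lexicographically so
    aggregation is order-independent.
    """
    groups: dict[str, list[Clonotype]] = {}
    for c in clonotypes:
        groups.setdefault(key_of(c, scheme), []).append(c)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            c = members[0]
        else:
            rep = min(members, key=lambda m: (-m.count, m.v_gene, m.j_gene, m.cdr3_nt))
            c = rep.with_count(sum(m.count for m in members))
        merged.append(c)
    return merged


@dataclass
class RepertoireSample:
    """A clonotype table plus sample metadata.

    On construction, clonotypes with an identical identity key (under
    ``key_scheme``) are aggregated by summing counts, zero/negative counts are
    dropped, and rows are stored in the canonical deterministic order:
    descending count, then lexicographic key.
    """

    meta: SampleMeta
    clonotypes: list[Clonotype]
    key_scheme: str = "cdr3aa"

    def __post_init__(self) -> None:
        if self.key_scheme not in KEY_SCHEMES:
            raise ValueError(f"unknown clonotype key scheme: {self.key_scheme!r}")
        kept = [c for c in self.clonotypes if c.count >= 1]
        merged = _merge_duplicates(kept, self.key_scheme)
        merged.sort(key=lambda c: (-c.count, key_of(c, self.key_scheme)))
        self.clonotypes = merged

    # -- derived quantities -------------------------------------------------
    @property
    def total_count(self) -> int:
        return int(sum(c.count for c in self.clonotypes))

    @property
    def richness(self) -> int:
        return len(self.clonotypes)

    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=np.int64)

    def keys(self) -> list[str]:
        return [key_of(c, self.key_scheme) for c in self.clonotypes]

    def frequencies(self) -> np.ndarray:
        """Clone frequencies p_i = count_i / total; sums to 1 for non-empty samples."""
        n = self.counts()
        total = n.sum()
        if total == 0:
            return np.zeros(0, dtype=float)
        return n / float(total)

    def frequency_map(self, scheme: str | None = None) -> dict[str, float]:
        """Map identity key -> frequency, re-aggregated under ``scheme`` if given."""
        scheme = scheme or self.key_scheme
        total = float(self.total_count)
        out: dict[str, float] = {}
        for c in self.clonotypes:
            k = key_of(c, scheme)
            out[k] = out.get(k, 0.0) + c.count / total
        return out

    def with_clonotypes(self, clonotypes: Iterable[Clonotype]) -> "RepertoireSample":
        return RepertoireSample(self.meta, list(clonotypes), self.key_scheme)

    def regroup(self, scheme: str) -> "RepertoireSample":
        """Re-aggregate under a different clonal definition."""
        return RepertoireSample(self.meta, list(self.clonotypes), scheme)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": self.keys(),
                "cdr3_aa": [c.cdr3_aa for c in self.clonotypes],
                "v_gene": [c.v_gene for c in self.clonotypes],
                "j_gene": [c.j_gene for c in self.clonotypes],
                "count": self.counts(),
            }
        )


def filter_cdr3(
    sample: RepertoireSample,
    min_len: int = MIN_CDR3_LEN,
    max_len: int = MAX_CDR3_LEN,
    standard_aa_only: bool = True,
) -> RepertoireSample:
    """Apply the CDR3 quality filter.

    Retains exactly the clonotypes whose CDR3 amino-acid length lies in
    [min_len, max_len] and (when ``standard_aa_only``) whose sequence is drawn
    from the 20 standard amino-acid letters — clonotypes containing stop
    (``*``), frameshift (``_``) or other non-standard characters are removed
    rather than raising.  Totals and richness are recomputed; the result may
    be empty.  Idempotent.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must be <= max_len ({max_len})")
    kept = []
    for c in sample.clonotypes:
        aa = c.cdr3_aa
        if not (min_len <= len(aa) <= max_len):
            continue
        if standard_aa_only and not set(aa) <= AA_ALPHABET:
            continue
        kept.append(c)
    return sample.with_clonotypes(kept)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    for col in required:
        if col not in df.columns:
            raise RepertoireFormatError(f"{path}: missing required column {col!r}")


def _clean_str(value: object) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    s = str(value).strip()
    return "" if s.lower() == "nan" else s


def read_repertoire(
    path: str | Path,
    dialect: str = "airr",
    meta: SampleMeta | None = None,
    key_scheme: str = "cdr3aa",
) -> RepertoireSample:
    """Read one clonotype table.

    ``dialect='airr'`` expects an AIRR-C rearrangement TSV with columns
    junction_aa, v_call, j_call, duplicate_count (junction and d_call
    optional); ``dialect='simple_csv'`` expects a CSV with columns cdr3_aa,
    v_gene, j_gene, count.  Rows sharing an identity key are aggregated by
    summing counts.  Metadata defaults to a bare sample id derived from the
    file name when not supplied.
    """
    path = Path(path)
    if dialect == "airr":
        df = pd.read_csv(path, sep="\t", dtype=str)
        _require_columns(df, AIRR_REQUIRED, path)
        getters = {
            "cdr3_aa": "junction_aa",
            "cdr3_nt": "junction",
            "v_gene": "v_call",
            "d_gene": "d_call",
            "j_gene": "j_call",
            "count": "duplicate_count",
        }
    elif dialect == "simple_csv":
        df = pd.read_csv(path, dtype=str)
        _require_columns(df, SIMPLE_REQUIRED, path)
        getters = {
            "cdr3_aa": "cdr3_aa",
            "cdr3_nt": "cdr3_nt",
            "v_gene": "v_gene",
            "d_gene": "d_gene",
            "j_gene": "j_gene",
            "count": "count",
        }
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if len(df) == 0:
        raise EmptyRepertoireError(f"{path}: no clonotype rows")

    clonotypes = []
    for _, row in df.iterrows():
        count = int(float(row[getters["count"]]))
        clonotypes.append(
            Clonotype(
                cdr3_aa=_clean_str(row[getters["cdr3_aa"]]),
                count=count,
                v_gene=_clean_str(row.get(getters["v_gene"], "")),
                j_gene=_clean_str(row.get(getters["j_gene"], "")),
                d_gene=_clean_str(row.get(getters["d_gene"], "")),
                cdr3_nt=_clean_str(row.get(getters["cdr3_nt"], "")),
            )
        )
    if meta is None:
        meta = SampleMeta(sample_id=path.stem)
    return RepertoireSample(meta, clonotypes, key_scheme)


def write_repertoire(sample: RepertoireSample, path: str | Path, dialect: str = "airr") -> None:
    """Write a clonotype table; inverse of :func:`read_repertoire`.

    Rows are emitted in the canonical order (descending count, then
    lexicographic key); an empty repertoire yields a header-only file.
    """
    path = Path(path)
    if dialect == "airr":
        df = pd.DataFrame(
            {
                "junction_aa": [c.cdr3_aa for c in sample.clonotypes],
                "junction": [c.cdr3_nt for c in sample.clonotypes],
                "v_call": [c.v_gene for c in sample.clonotypes],
                "d_call": [c.d_gene for c in sample.clonotypes],
                "j_call": [c.j_gene for c in sample.clonotypes],
                "duplicate_count": [c.count for c in sample.clonotypes],
            },
            columns=list(AIRR_COLUMNS),
        )
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "simple_csv":
        df = pd.DataFrame(
            {
                "cdr3_aa": [c.cdr3_aa for c in sample.clonotypes],
                "v_gene": [c.v_gene for c in sample.clonotypes],
                "j_gene": [c.j_gene for c in sample.clonotypes],
                "count": [c.count for c in sample.clonotypes],
            },
            columns=list(SIMPLE_COLUMNS),
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata sheet (CSV, one row per sample)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    _require_columns(df, [c for c in METADATA_COLUMNS if c != "path"], path)
    return df


def meta_from_row(row: Mapping[str, object]) -> SampleMeta:
    return SampleMeta(
        sample_id=str(row["sample_id"]),
        subject_id=str(row["subject_id"]),
        compartment=str(row["compartment"]),
        flank=str(row["flank"]),
        timepoint=int(row["timepoint"]),
        group=str(row["group"]),
        tumor_model=_clean_str(row.get("tumor_model", "")),
    )


def load_study(
    meta_path: str | Path,
    dialect: str = "airr",
    key_scheme: str = "cdr3aa",
    apply_filter: bool = True,
) -> list[RepertoireSample]:
    """Load every sample listed in a metadata sheet.

    The sheet's ``path`` column is resolved relative to the sheet's own
    directory.  By default the CDR3 length/alphabet filter is applied on load.
    """
    meta_path = Path(meta_path)
    df = read_metadata(meta_path)
    if "path" not in df.columns:
        raise RepertoireFormatError(f"{meta_path}: missing required column 'path'")
    samples = []
    for _, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = meta_path.parent / p
        s = read_repertoire(p, dialect=dialect, meta=meta_from_row(row), key_scheme=key_scheme)
        if apply_filter:
            s = filter_cdr3(s)
        samples.append(s)
    return samples
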