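"""VJ-gene-usage feature matrices from immune-repertoire rearrangement tables.

T- and B-cell receptors arise from somatic V(D)J recombination; while exact
clonotypes are essentially private to an individual, the V and J gene segments
are shared, so per-sample gene-pair usage is directly comparable across
subjects.  This module reads AIRR-style rearrangement TSVs, collapses them to
unique clonotypes at the gene level, and produces samples x VJ-combination
usage matrices: the fraction of a sample's unique clonotypes assigned to each
V/J pair, or — for paired timepoints — signed log2 usage ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClonotypeTable",
    "UsageMatrix",
    "RearrangementFormatError",
    "read_airr_rearrangements",
    "compute_vj_usage",
    "log2_usage_ratio",
    "summarize_repertoire",
]

#: default AIRR Rearrangement column names
DEFAULT_DIALECT = {"v_call": "v_call", "j_call": "j_call", "count": "duplicate_count"}


class RearrangementFormatError(ValueError):
    """Malformed or empty rearrangement file."""


@dataclass
class ClonotypeTable:
    """Unique gene-level clonotypes of one sample, with clonal counts.

    ``records`` holds (v_gene, j_gene, count) with count >= 1, one record per
    unique clonotype; either gene may be ``None`` when the original call was
    missing or unresolvable.  Distinct alleles of the same gene are distinct
    clonotypes that map onto the same gene-level VJ pair.  The record count is
    the sample's number of unique clonotypes and the count sum its clonal
    count (read depth).
    """

    sample_id: str
    records: list[tuple[str | None, str | None, int]]

    def __post_init__(self) -> None:
        for v, j, c in self.records:
            if c < 1:
                raise ValueError(f"clonal count must be >= 1, got {c} in {self.sample_id}")

    @property
    def n_unique_clonotypes(self) -> int:
        return len(self.records)

    @property
    def clonal_count(self) -> int:
        return sum(c for _, _, c in self.records)

    def vj_pairs(self) -> dict[str, int]:
        """Unique-clonotype tally per resolvable "V/J" pair label."""
        tally: dict[str, int] = {}
        for v, j, _ in self.records:
            if v is None or j is None:
                continue
            key = f"{v}/{j}"
            tally[key] = tally.get(key, 0) + 1
        return tally


@dataclass
class UsageMatrix:
    """Samples x VJ-combination matrix of usage fractions or log2 ratios."""

    samples: list[str]
    features: list[str]
    values: np.ndarray  # (n_samples, n_features)
    mode: str = "usage"  # {"usage", "log2_ratio"}
    n_unique: np.ndarray | None = None  # per-sample unique-clonotype denominators

    def __post_init__(self) -> None:
        if self.mode not in ("usage", "log2_ratio"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("values shape disagrees with sample/feature labels")
        if self.mode == "usage" and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValueError("usage entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "usage") -> "UsageMatrix":
        return cls(
            samples=list(df.index.astype(str)),
            features=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            mode=mode,
        )


def _normalize_gene_call(call) -> str | None:
    """Collapse an AIRR gene call to the gene level.

    Allele suffixes (``*01``) are stripped and ambiguous comma-separated calls
    resolved to the first listed gene.
    """
    if call is None or (isinstance(call, float) and math.isnan(call)):
        return None
    s = str(call).strip()
    if not s:
        return None
    s = s.split(",")[0].strip()
    s = s.split("*")[0].strip()
    return s or None


def read_airr_rearrangements(
    path, sample_id: str | None = None, dialect: dict | None = None
) -> ClonotypeTable:
    """Read one sample's AIRR-style rearrangement TSV into a ClonotypeTable.

    The file must be tab-delimited with a header carrying V- and J-call
    columns; rows lacking a count column count as one read each.  Rows mapping
    to the same gene-level V/J pair are collapsed into one clonotype with
    summed counts.
    """
    path = Path(path)
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise RearrangementFormatError(f"{path}: empty rearrangement file") from None
    if df.empty:
        raise RearrangementFormatError(f"{path}: no rearrangement rows")
    for key in ("v_call", "j_call"):
        if d[key] not in df.columns:
            raise RearrangementFormatError(
                f"{path}: missing mandatory column {d[key]!r}"
            )
    if d["count"] in df.columns:
        counts = pd.to_numeric(df[d["count"]], errors="coerce").fillna(1).astype(int)
        counts = counts.clip(lower=1)
    else:
        counts = pd.Series(1, index=df.index)

    # clonotype identity is the raw allele-level call pair: duplicate rows of
    # the same clonotype collapse (counts summed), but two alleles of one gene
    # stay distinct clonotypes even though they share a gene-level VJ pair
    tally: dict[tuple[str, str], int] = {}
    for v_raw, j_raw, c in zip(df[d["v_call"]], df[d["j_call"]], counts):
        key = (str(v_raw).strip() if pd.notna(v_raw) else "",
               str(j_raw).strip() if pd.notna(j_raw) else "")
        tally[key] = tally.get(key, 0) + int(c)
    records = [
        (_normalize_gene_call(v), _normalize_gene_call(j), c)
        for (v, j), c in sorted(tally.items())
    ]
    return ClonotypeTable(sample_id=sample_id or path.stem, records=records)


def compute_vj_usage(tables: list[ClonotypeTable]) -> UsageMatrix:
    """Usage fraction per sample and VJ pair.

    Entry (s, vj) = number of unique clonotypes of sample s using pair vj,
    divided by the sample's number of unique clonotypes.  The feature set is
    the union of pairs observed in any sample; unobserved pairs score 0.
    """
    if not tables:
        raise ValueError("need at least one ClonotypeTable")
    tallies = []
    for t in tables:
        if t.n_unique_clonotypes == 0:
            raise ValueError(f"sample {t.sample_id}: empty clonotype table")
        pairs = t.vj_pairs()
        if not pairs:
            raise ValueError(f"sample {t.sample_id}: no resolvable VJ pairs")
        tallies.append(pairs)
    features = sorted(set().union(*tallies))
    values = np.zeros((len(tables), len(features)))
    col = {f: i for i, f in enumerate(features)}
    for r, (t, pairs) in enumerate(zip(tables, tallies)):
        denom = t.n_unique_clonotypes
        for f, c in pairs.items():
            values[r, col[f]] = c / denom
    return UsageMatrix(
        samples=[t.sample_id for t in tables], features=features,
        values=values, mode="usage",
        n_unique=np.array([t.n_unique_clonotypes for t in tables]),
    )


def log2_usage_ratio(
    post: UsageMatrix, baseline: UsageMatrix, pseudocount: float | np.ndarray | None = None
) -> UsageMatrix:
    """log2((post + c) / (baseline + c)) per sample and VJ pair.

    Feature sets are unioned (missing pairs read as usage 0) so a pair unused
    at both timepoints yields exactly 0.  The default pseudocount is
    per-sample 1 / (number of unique clonotypes) — the finest resolvable
    usage — taken as the smaller of the two timepoints' denominators when the
    matrices carry them, else 1 / (number of features).  Pass a scalar or a
    per-sample vector to override.
    """
    if post.samples != baseline.samples:
        raise ValueError("post/baseline sample labels disagree (order included)")
    if post.mode != "usage" or baseline.mode != "usage":
        raise ValueError("log2 ratios are defined on usage-mode matrices")
    features = sorted(set(post.features) | set(baseline.features))
    a = post.to_frame().reindex(columns=features, fill_value=0.0).to_numpy()
    b = baseline.to_frame().reindex(columns=features, fill_value=0.0).to_numpy()
    if pseudocount is None:
        if post.n_unique is not None and baseline.n_unique is not None:
            pseudocount = 1.0 / np.minimum(post.n_unique, baseline.n_unique)
        else:
            pseudocount = 1.0 / len(features)
    c = np.asarray(pseudocount, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if (c <= 0).any():
        raise ValueError("pseudocount must be positive")
    values = np.log2((a + c) / (b + c))
    return UsageMatrix(
        samples=list(post.samples), features=features, values=values, mode="log2_ratio"
    )


def _fmt_number(v, digits: int = 4) -> str:
    v = float(v)
    return str(int(v)) if v.is_integer() else f"{v:.{digits}g}"


def _fmt_median_range(x: np.ndarray, digits: int = 4) -> str:
    parts = (_fmt_number(np.median(x), digits), _fmt_number(x.min(), digits),
             _fmt_number(x.max(), digits))
    return f"{parts[0]} [{parts[1]}, {parts[2]}]"


def summarize_repertoire(
    tables: list[ClonotypeTable], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Median [range] summaries of clonotype counts, read depth and usage.

    ``groups`` optionally maps sample_id -> group label; omitted samples fall
    into group "all".  Returns one row per group with formatted
    "median [min, max]" strings alongside the raw numbers.
    """
    if not tables:
        raise ValueError("need at least one ClonotypeTable")
    usage = compute_vj_usage(tables)
    labels = [
        (groups or {}).get(t.sample_id, "all") for t in tables
    ]
    rows = []
    for g in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        uniq = np.array([tables[i].n_unique_clonotypes for i in idx])
        depth = np.array([tables[i].clonal_count for i in idx])
        uvals = usage.values[idx].ravel()
        rows.append(
            {
                "group": g,
                "n_samples": len(idx),
                "unique_clonotypes": _fmt_median_range(uniq),
                "clonal_counts": _fmt_median_range(depth),
                "vj_usage": _fmt_median_range(uvals),
                "median_unique_clonotypes": float(np.median(uniq)),
                "min_unique_clonotypes": int(uniq.min()),
                "max_unique_clonotypes": int(uniq.max()),
                "median_clonal_counts": float(np.median(depth)),
                "min_clonal_counts": int(depth.min()),
                "max_clonal_counts": int(depth.max()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
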