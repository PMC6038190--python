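"""Read-to-reference quantification and abundance-derived statistics.

Adapter-trimmed small-RNA reads are assigned to reference piRNAs by exact
length match and Hamming distance at most one (substitutions only — for
reads under ~32 nt indel-free matching is the standard contract). Counts are
collected into a feature x sample matrix; RPKM, marker-content covariates
and positional base-composition profiles are derived from it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference import ReferenceSet, normalize_rna, _open_text

MATCH_MODES = ("all", "unique", "fractional")


@dataclass
class ReadSet:
    """Adapter-trimmed reads for one sample (RNA or DNA alphabet)."""

    sample_id: str
    reads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass
class CountMatrix:
    """Non-negative integral feature x sample count table."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("CountMatrix: duplicate feature or sample ids")
        vals = df.to_numpy()
        if vals.size and ((vals < 0).any() or not np.allclose(vals, np.round(vals))):
            raise ValueError("CountMatrix: entries must be non-negative integers")
        self.counts = df.astype(np.int64)
        self.counts.index.name = "feature_id"
        self.counts.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV (first column ``sample_id``) into a DataFrame."""
    sheet = pd.read_csv(path, sep="\t", index_col=0)
    if sheet.index.has_duplicates:
        raise ValueError("sample sheet has duplicate sample ids")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.rename_axis("sample_id").to_csv(path, sep="\t", lineterminator="\n")


def read_fastq(path: str | Path, sample_id: str | None = None) -> ReadSet:
    """Load a (plain or gzipped) FASTQ file of adapter-trimmed reads."""
    sid = sample_id or Path(path).name.split(".")[0]
    with _open_text(path) as fh:
        reads = [str(r.seq) for r in SeqIO.parse(fh, "fastq")]
    return ReadSet(sample_id=sid, reads=reads)


def trim_adapter_3p(read: str, adapter: str, min_overlap: int = 10) -> str:
    """Exact-prefix 3' adapter trimming (convenience helper, non-core).

    Scans for the leftmost position where the read suffix equals a prefix of
    the adapter of length >= min_overlap, and trims from there.
    """
    read_u, ad_u = read.upper(), adapter.upper()
    n = len(read_u)
    for i in range(0, n - min_overlap + 1):
        tail = read_u[i:]
        if len(tail) <= len(ad_u):
            if ad_u.startswith(tail):
                return read[:i]
        elif tail.startswith(ad_u):
            return read[:i]
    return read


def _hamming_within(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def _length_index(ref: ReferenceSet) -> dict[int, list[tuple[str, str]]]:
    idx: dict[int, list[tuple[str, str]]] = {}
    for rec in ref:
        idx.setdefault(rec.length, []).append((rec.id, rec.sequence))
    return idx


def match_read(
    read: str,
    ref: ReferenceSet,
    max_mismatch: int = 1,
    _index: dict[int, list[tuple[str, str]]] | None = None,
) -> list[str]:
    """Feature ids matching ``read``: equal length, Hamming distance <= max_mismatch.

    Reads containing N (or any non-ACGU symbol after T->U normalization)
    never match. Result order follows reference order.
    """
    r = normalize_rna(read)
    if not r or set(r) - set("ACGU"):
        return []
    idx = _index if _index is not None else _length_index(ref)
    bucket = idx.get(len(r), [])
    return [rid for rid, seq in bucket if _hamming_within(r, seq, max_mismatch)]


def quantify_sample(
    reads: ReadSet,
    ref: ReferenceSet,
    mode: str = "all",
    max_mismatch: int = 1,
) -> np.ndarray:
    """Count reads per reference feature under a multi-match policy.

    mode="all": a read matching m features adds 1 to each. mode="unique":
    multi-matching reads are discarded. mode="fractional": each match gets
    1/m, with the per-feature totals rounded half-to-even at the end so the
    count matrix stays integral.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"invalid mode {mode!r}; expected one of {MATCH_MODES}")
    idx = _length_index(ref)
    pos = {rid: i for i, rid in enumerate(ref.ids)}
    acc = np.zeros(len(ref), dtype=float)
    for read in reads.reads:
        hits = match_read(read, ref, max_mismatch, _index=idx)
        if not hits:
            continue
        if mode == "all":
            for h in hits:
                acc[pos[h]] += 1
        elif mode == "unique":
            if len(hits) == 1:
                acc[pos[hits[0]]] += 1
        else:  # fractional
            w = 1.0 / len(hits)
            for h in hits:
                acc[pos[h]] += w
    if mode == "fractional":
        acc = np.round(acc)  # numpy rounds half to even
    return acc.astype(np.int64)


def build_count_matrix(
    per_sample_counts: Mapping[str, np.ndarray],
    ref: ReferenceSet,
    sample_order: Sequence[str] | None = None,
) -> CountMatrix:
    """Assemble per-sample count vectors (in reference order) into a matrix."""
    order = list(sample_order) if sample_order is not None else list(per_sample_counts)
    missing = [s for s in order if s not in per_sample_counts]
    if missing:
        raise KeyError(f"missing count vectors for samples: {missing}")
    nfeat = len(ref)
    cols = {}
    for s in order:
        v = np.asarray(per_sample_counts[s])
        if v.shape != (nfeat,):
            raise ValueError(
                f"sample {s!r}: count vector length {v.shape} != reference size {nfeat}"
            )
        cols[s] = v
    df = pd.DataFrame(cols, index=ref.ids)
    return CountMatrix(df)


def rpkm(counts: CountMatrix | pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of (mature-sequence) model per million mapped reads.

    value = count / ((length/1000) * (column_total/1e6)). For small RNAs the
    "exon model" is the mature sequence length.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lens = lengths.reindex(df.index)
    if lens.isna().any():
        raise KeyError("lengths missing for some features")
    if (lens <= 0).any():
        raise ValueError("feature lengths must be positive")
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total mapped counts for samples: {bad}")
    return df.div(lens / 1e3, axis=0).div(totals / 1e6, axis=1)


def marker_content_score(rpkm_matrix: pd.DataFrame, marker_ids: Sequence[str]) -> pd.Series:
    """Per-sample mean RPKM over a marker gene set.

    Used to derive the neuronal-content covariate for tissue contrasts, where
    cell-type composition differences would otherwise confound the disease
    contrast.
    """
    markers = list(marker_ids)
    if not markers:
        raise ValueError("empty marker list")
    missing = [m for m in markers if m not in rpkm_matrix.index]
    if missing:
        raise KeyError(f"marker ids absent from matrix: {missing}")
    return rpkm_matrix.loc[markers].mean(axis=0)


def positional_base_content(
    sequences: Iterable[str], base: str, max_pos: int = 29
) -> pd.DataFrame:
    """Per-position fraction of sequences carrying ``base`` (1-based, 5'->3').

    The denominator at position k counts only sequences of length >= k, so
    denominators are non-increasing in k; positions with denominator 0 get a
    NaN fraction. Returns a DataFrame indexed by position with columns
    ``fraction`` and ``denominator``.
    """
    b = normalize_rna(base)
    if b not in set("ACGU"):
        raise ValueError(f"invalid base {base!r}")
    seqs = [normalize_rna(s) for s in sequences]
    if not seqs:
        raise ValueError("positional_base_content: empty input")
    denom = np.zeros(max_pos, dtype=int)
    hits = np.zeros(max_pos, dtype=int)
    for s in seqs:
        upto = min(len(s), max_pos)
        denom[:upto] += 1
        for k in range(upto):
            if s[k] == b:
                hits[k] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, hits / np.maximum(denom, 1), np.nan)
    return pd.DataFrame(
        {"fraction": frac, "denominator": denom},
        index=pd.RangeIndex(1, max_pos + 1, name="position"),
    )
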