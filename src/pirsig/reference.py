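"""piRNA reference handling.

Loads a piRNA/piRNA-like reference (FASTA + element-of-origin annotation),
normalizes sequences to the RNA alphabet, and provides the sequence-level QC
statistics used throughout the pipeline: the genome-wide element-of-origin
proportions (the null for enrichment tests), the 5'-uridine bias, the
canonical-length fraction, and a snoRNA contamination screen.

piRNAs are 24-32 nt PIWI-interacting small RNAs; database catalogs also
contain shorter "piRNA-like" species. Each reference record carries the class
of genomic element it derives from (SINE, LINE, LTR retrotransposons, genic
regions, or other), which drives the downstream transposon-enrichment
statistics.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

ORIGIN_CLASSES: tuple[str, ...] = ("SINE", "LINE", "LTR", "GENIC", "OTHER", "UNKNOWN")

#: canonical piRNA length window, nt
CANONICAL_MIN = 24
CANONICAL_MAX = 32

#: sanity range for reference sequences; records outside are rejected
LENGTH_MIN = 15
LENGTH_MAX = 45

_RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def normalize_origin(label: object) -> str:
    """Map an annotation string onto the fixed origin-class set.

    Known classes pass through; ``GENE``/``GENIC`` both map to ``GENIC``;
    anything else maps to ``OTHER``; missing values map to ``UNKNOWN``.
    """
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return "UNKNOWN"
    s = str(label).strip().upper()
    if not s:
        return "UNKNOWN"
    if s == "GENE":
        return "GENIC"
    return s if s in ORIGIN_CLASSES else "OTHER"


@dataclass(frozen=True)
class PiRNARecord:
    """One reference small RNA: id, U-normalized sequence, origin class."""

    id: str
    sequence: str
    origin_class: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(expected A/C/G/U after T->U normalization)"
            )
        n = len(self.sequence)
        if not (LENGTH_MIN <= n <= LENGTH_MAX):
            raise ValueError(
                f"record {self.id!r}: length {n} outside sanity range "
                f"[{LENGTH_MIN}, {LENGTH_MAX}]"
            )
        if self.origin_class not in ORIGIN_CLASSES:
            raise ValueError(
                f"record {self.id!r}: unknown origin class {self.origin_class!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_canonical(self) -> bool:
        return CANONICAL_MIN <= self.length <= CANONICAL_MAX


class ReferenceSet:
    """Ordered, id-unique collection of :class:`PiRNARecord`."""

    def __init__(self, records: Sequence[PiRNARecord]):
        records = list(records)
        if not records:
            raise ValueError("reference must contain at least one record")
        by_id: dict[str, PiRNARecord] = {}
        for rec in records:
            if rec.id in by_id:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            by_id[rec.id] = rec
        self.records: list[PiRNARecord] = records
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PiRNARecord]:
        return iter(self.records)

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    def __getitem__(self, rid: str) -> PiRNARecord:
        return self._by_id[rid]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self, ids: Iterable[str] | None = None) -> list[str]:
        if ids is None:
            return [r.sequence for r in self.records]
        return [self._by_id[i].sequence for i in ids]

    @property
    def lengths(self) -> pd.Series:
        return pd.Series({r.id: r.length for r in self.records}, name="length")

    @property
    def origins(self) -> pd.Series:
        return pd.Series({r.id: r.origin_class for r in self.records}, name="origin_class")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_reference(fasta_path: str | Path, annotation_path: str | Path | None = None) -> ReferenceSet:
    """Load a piRNA reference FASTA plus an element-of-origin annotation TSV.

    The annotation file is tab-separated with columns ``id`` and
    ``origin_class``; ids absent from it get ``UNKNOWN``. On duplicate
    annotation rows the last one wins. FASTA sequences are T->U normalized;
    duplicate FASTA ids, non-ACGTU characters and lengths outside
    [15, 45] nt are rejected.
    """
    origin_map: Mapping[str, str] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        missing = {"id", "origin_class"} - set(ann.columns)
        if missing:
            raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
        origin_map = {
            row.id: normalize_origin(row.origin_class) for row in ann.itertuples()
        }

    records: list[PiRNARecord] = []
    seen: set[str] = set()
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            seq = normalize_rna(str(rec.seq))
            records.append(
                PiRNARecord(
                    id=rec.id,
                    sequence=seq,
                    origin_class=origin_map.get(rec.id, "UNKNOWN"),
                )
            )
    return ReferenceSet(records)


def write_fasta(ref: ReferenceSet, path: str | Path, ids: Iterable[str] | None = None) -> None:
    """Write reference sequences (U alphabet) as plain FASTA."""
    use = ref.ids if ids is None else list(ids)
    with open(path, "wt") as fh:
        for rid in use:
            fh.write(f">{rid}\n{ref[rid].sequence}\n")


def origin_proportions(
    ref: ReferenceSet,
    universe: Iterable[str] | None = None,
    include_unknown: bool = True,
) -> pd.Series:
    """Fraction of each origin class among ``universe`` (default: all ids).

    This is the genome-wide null proportion p0 used by the enrichment test.
    ``include_unknown=False`` drops UNKNOWN records from the denominator.
    Returns a Series over all six classes summing to 1.
    """
    ids = ref.ids if universe is None else list(universe)
    unknown = [i for i in ids if i not in ref]
    if unknown:
        raise KeyError(f"universe ids not in reference: {unknown[:5]}")
    if not include_unknown:
        ids = [i for i in ids if ref[i].origin_class != "UNKNOWN"]
    if not ids:
        raise ValueError("empty universe for origin proportions")
    counts = pd.Series(0, index=list(ORIGIN_CLASSES), dtype=float)
    for i in ids:
        counts[ref[i].origin_class] += 1
    return counts / len(ids)


def u1_fraction(sequences: Iterable[str]) -> float:
    """Fraction of sequences whose 5' base is uridine (the 1U bias)."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("u1_fraction: empty input")
    return sum(1 for s in seqs if s[:1] == "U") / len(seqs)


def canonical_fraction(ref: ReferenceSet) -> float:
    """Fraction of reference records in the canonical 24-32 nt window."""
    return sum(1 for r in ref if r.is_canonical) / len(ref)


@dataclass(frozen=True)
class SnoOverlapReport:
    """Result of the snoRNA contamination screen."""

    n_overlapping: int
    n_reference: int
    overlapping_ids: tuple[str, ...]

    @property
    def fraction_overlapping(self) -> float:
        return self.n_overlapping / self.n_reference


def snorna_overlap(ref: ReferenceSet, sno_fasta: str | Path) -> SnoOverlapReport:
    """Screen the reference against a snoRNA FASTA.

    A reference piRNA counts as overlapping iff its full sequence occurs as an
    exact substring of at least one snoRNA (given strand only). snoRNA
    degradation fragments are a known contaminant of piRNA catalogs; a
    negligible overlap supports the bona fide piRNA interpretation.
    """
    with _open_text(sno_fasta) as fh:
        snos = [normalize_rna(str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    hits = tuple(
        rec.id for rec in ref if any(rec.sequence in s for s in snos)
    )
    return SnoOverlapReport(
        n_overlapping=len(hits), n_reference=len(ref), overlapping_ids=hits
    )
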