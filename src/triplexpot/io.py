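"""Sequence input/output: validated nucleotide records, FASTA and gene-map reading.

Sequences are normalized to the DNA alphabet {A, C, G, T}: input is
uppercased and U is mapped to T, so RNA transcripts and DNA regions are
consumed uniformly. Records containing N can either be dropped (and
logged) or rejected; any other IUPAC ambiguity code is always an error so
that dirty inputs surface immediately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGT")

POSITIVE = "positive"
NEGATIVE = "negative"

#: Positive-subtype tags. ``weak`` marks the minority positive subtype that
#: receives extra weight during bagging (experimentally reported triplex
#: lncRNAs); ``strong`` marks the majority subtype (triplex-peak-derived).
SUBTYPE_STRONG = "strong"
SUBTYPE_WEAK = "weak"


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One validated nucleotide sequence.

    Parameters
    ----------
    id : str
        Record identifier, unique within a :class:`Dataset`.
    seq : str
        Sequence over {A, C, G, T} after normalization.
    gene : str, optional
        Gene-level grouping key used by leave-gene-out splits.
    subtype : {"strong", "weak"}, optional
        Positive-subtype tag; ``weak`` is the minority subtype.
    label : {"positive", "negative"}, optional
        Class label.
    """

    id: str
    seq: str
    gene: Optional[str] = None
    subtype: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(sequences must be normalized to A/C/G/T)"
            )
        if self.subtype not in (None, SUBTYPE_STRONG, SUBTYPE_WEAK):
            raise ValueError(f"record {self.id!r}: unknown subtype {self.subtype!r}")
        if self.label not in (None, POSITIVE, NEGATIVE):
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Dataset:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset {self.name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def with_label(self, label: str) -> "Dataset":
        """Return a copy with ``label`` set on every record."""
        return Dataset([replace(r, label=label) for r in self.records], name=self.name)

    def subset(self, ids: Iterable[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset([r for r in self.records if r.id in wanted], name=self.name)

    def require_labels(self) -> None:
        missing = [r.id for r in self.records if r.label is None]
        if missing:
            raise ValueError(
                f"dataset {self.name!r}: {len(missing)} records lack labels "
                f"(first: {missing[:3]})"
            )


def normalize_sequence(raw: str, record_id: str, drop_n: bool = False) -> Optional[str]:
    """Uppercase, map U→T, and validate one raw sequence string.

    Returns None when the sequence contains N and ``drop_n`` is set;
    raises :class:`FastaError` for N without ``drop_n`` or for any other
    ambiguity code.
    """
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FastaError(f"record {record_id!r}: empty sequence")
    residues = set(seq)
    if "N" in residues:
        if drop_n:
            return None
        raise FastaError(
            f"record {record_id!r} contains N; pass drop_n=True to exclude such records"
        )
    bad = residues - VALID_ALPHABET
    if bad:
        raise FastaError(
            f"record {record_id!r}: ambiguity codes {sorted(bad)} are not supported "
            "(only N is recognized, via drop_n)"
        )
    return seq


def read_fasta(
    path: str | Path,
    label: Optional[str] = None,
    drop_n: bool = False,
    name: Optional[str] = None,
    dropped_log: Optional[str | Path] = None,
) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Sequences are uppercased with U mapped to T. With ``drop_n`` set,
    records containing N are excluded, counted in the log, and (optionally)
    written one id per line to ``dropped_log``; without it an N raises.
    File order is preserved. Line wrapping, mixed case and CRLF endings are
    tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    dropped: list[str] = []
    seen: set[str] = set()
    n_parsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        rid = rec.id
        if not rid:
            raise FastaError(f"{path}: record #{n_parsed} has an empty identifier")
        if rid in seen:
            raise FastaError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = normalize_sequence(str(rec.seq), rid, drop_n=drop_n)
        if seq is None:
            dropped.append(rid)
            continue
        records.append(SequenceRecord(id=rid, seq=seq, label=label))
    if n_parsed == 0:
        raise FastaError(f"{path}: no FASTA records found")
    if dropped:
        logger.info("%s: dropped %d record(s) containing N", path, len(dropped))
        if dropped_log is not None:
            Path(dropped_log).write_text("".join(f"{i}\n" for i in dropped))
    return Dataset(records, name=name or path.stem)


def write_fasta(data: Dataset, path: str | Path, width: int = 70) -> None:
    """Write a dataset as FASTA (plumbing writer; round-trips sequence content)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in data:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping transcript id → gene id.

    A header line is tolerated (detected as the exact pair of column names
    or skipped when the first line repeats no ids). Each transcript must
    map to exactly one gene.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    lines = path.read_text().splitlines()
    if not lines:
        warnings.warn(f"{path}: empty gene map", stacklevel=2)
        return mapping
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
        tx, gene = (p.strip() for p in parts)
        if lineno == 1 and tx.lower() in {"transcript", "transcript_id", "tx", "id"}:
            continue
        if tx in mapping and mapping[tx] != gene:
            raise ValueError(
                f"{path}: transcript {tx!r} mapped to both {mapping[tx]!r} and {gene!r}"
            )
        mapping[tx] = gene
    return mapping


def attach_genes(data: Dataset, gene_map: dict[str, str]) -> Dataset:
    """Return a copy of ``data`` with gene labels joined from ``gene_map``.

    Unknown ids produce a warning and keep gene=None.
    """
    missing = [r.id for r in data if r.id not in gene_map]
    if missing:
        warnings.warn(
            f"{len(missing)} record(s) absent from gene map (first: {missing[:3]})",
            stacklevel=2,
        )
    return Dataset(
        [replace(r, gene=gene_map.get(r.id)) for r in data],
        name=data.name,
    )
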