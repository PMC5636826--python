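"""Peptide data model, I/O, length stratification and hexapeptide extraction.

Experimentally annotated amyloid data sets consist of short peptides
(typically 6-25 residues) with a binary label: amyloid (the peptide forms
cross-beta fibrillar aggregates) or non-amyloid.  The atomic unit of
classification downstream is the *hexapeptide*: every overlapping
6-residue window of a peptide, inheriting the parent's label.  A peptide
of length L therefore contributes exactly L - 5 hexapeptides.

Only the 20 canonical one-letter amino-acid codes are accepted.
Non-canonical codes (B, J, O, U, X, Z) and gap characters are rejected by
default because silently coercing them would corrupt the n-gram features;
a permissive mode drops the offending record with a warning instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Window length of the classification unit.
WINDOW = 6

#: Default length filter applied to curated peptide sets.
MIN_LENGTH = 6
MAX_LENGTH = 25

#: Cumulative training strata and disjoint test strata (inclusive bounds).
TRAIN_STRATA: dict[str, tuple[int, int]] = {
    "6": (6, 6),
    "6-10": (6, 10),
    "6-15": (6, 15),
}
TEST_STRATA: dict[str, tuple[int, int]] = {
    "6": (6, 6),
    "7-10": (7, 10),
    "11-15": (11, 15),
    "16-25": (16, 25),
}


def _validate_sequence(seq: str, rec_id: str) -> None:
    bad = sorted(set(seq) - _AA_SET)
    if bad:
        raise ValueError(
            f"record {rec_id!r}: invalid residue(s) {', '.join(map(repr, bad))}; "
            f"only the 20 canonical one-letter codes are accepted"
        )


@dataclass(frozen=True)
class PeptideRecord:
    """One labelled peptide: identifier, sequence, binary amyloid label."""

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        _validate_sequence(self.sequence, self.id)
        if self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hexapeptide:
    """A 6-residue window of a peptide with provenance back to its parent."""

    residues: str
    parent_id: str
    offset: int  # 0-based start within the parent
    label: int

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW:
            raise ValueError(
                f"hexapeptide from {self.parent_id!r}: length {len(self.residues)} != {WINDOW}"
            )
        _validate_sequence(self.residues, self.parent_id)
        if self.offset < 0:
            raise ValueError(f"hexapeptide from {self.parent_id!r}: negative offset")


class PeptideSet:
    """Ordered collection of :class:`PeptideRecord` with unique identifiers."""

    def __init__(self, records: Iterable[PeptideRecord], name: str = "") -> None:
        self.records: tuple[PeptideRecord, ...] = tuple(records)
        self.name = name
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate peptide id {rec.id!r} in set {name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(rec.label for rec in self.records)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(rec) for rec in self.records)

    def subset(self, ids: Iterable[str], name: str = "") -> "PeptideSet":
        wanted = set(ids)
        return PeptideSet((r for r in self.records if r.id in wanted), name or self.name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sequence": [r.sequence for r in self.records],
                "length": self.lengths,
                "label": self.labels,
            }
        )

    # -- writers -----------------------------------------------------------

    def write_fasta(self, fasta_path: str | Path, labels_path: str | Path) -> None:
        """Write a FASTA file and a tab-separated id -> label table."""
        with open(fasta_path, "w") as fa:
            for rec in self.records:
                fa.write(f">{rec.id}\n{rec.sequence}\n")
        with open(labels_path, "w") as lab:
            for rec in self.records:
                lab.write(f"{rec.id}\t{rec.label}\n")

    def write_table(self, path: str | Path) -> None:
        """Write a two-column whitespace-separated sequence/label file."""
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f"{rec.sequence} {rec.label}\n")


def _check_label_conflicts(records: Iterable[PeptideRecord]) -> None:
    by_seq: dict[str, int] = {}
    for rec in records:
        prev = by_seq.get(rec.sequence)
        if prev is not None and prev != rec.label:
            raise ValueError(
                f"record {rec.id!r}: sequence {rec.sequence!r} appears with "
                f"conflicting labels {prev} and {rec.label}"
            )
        by_seq[rec.sequence] = rec.label


def _read_label_table(path: str | Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"label table {path}: malformed line {line!r}")
            labels[parts[0]] = int(parts[1])
    return labels


def load_peptides(
    path: str | Path,
    format: str = "auto",
    labels: str | Path | Mapping[str, int] | None = None,
    on_invalid: str = "error",
) -> PeptideSet:
    """Load a labelled peptide set.

    Two dialects are supported: a FASTA file plus a tab-separated
    ``id<TAB>label`` table (``format="fasta"``), or a two-column
    whitespace-separated ``sequence label`` file (``format="table"``).
    ``format="auto"`` picks FASTA when ``labels`` is given or the file
    suffix is .fa/.fasta/.faa.

    Parameters
    ----------
    on_invalid:
        ``"error"`` (default) raises on records with non-canonical
        residues; ``"drop"`` discards them with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = (
            "fasta"
            if labels is not None or path.suffix.lower() in {".fa", ".fasta", ".faa"}
            else "table"
        )
    if on_invalid not in ("error", "drop"):
        raise ValueError(f"on_invalid must be 'error' or 'drop', got {on_invalid!r}")

    raw: list[tuple[str, str, int]] = []
    if format == "fasta":
        if labels is None:
            raise ValueError("FASTA input requires a label table")
        label_map = labels if isinstance(labels, Mapping) else _read_label_table(labels)
        for seq_rec in SeqIO.parse(str(path), "fasta"):
            if seq_rec.id not in label_map:
                raise ValueError(f"record {seq_rec.id!r}: no label in label table")
            raw.append((seq_rec.id, str(seq_rec.seq).upper(), int(label_map[seq_rec.id])))
    elif format == "table":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}: line {i + 1}: expected 'sequence label'")
                raw.append((f"p{len(raw) + 1}", parts[0].upper(), int(parts[1])))
    else:
        raise ValueError(f"unknown format {format!r}")

    records: list[PeptideRecord] = []
    for rec_id, seq, label in raw:
        try:
            records.append(PeptideRecord(rec_id, seq, label))
        except ValueError:
            if on_invalid == "drop":
                logger.warning("dropping invalid record %r", rec_id)
            else:
                raise
    _check_label_conflicts(records)
    return PeptideSet(records, name=path.stem)


def filter_by_length(
    ps: PeptideSet, min_len: int = MIN_LENGTH, max_len: int = MAX_LENGTH
) -> PeptideSet:
    """Keep records with ``min_len <= length <= max_len`` (inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in ps.records if min_len <= len(r) <= max_len]
    n_short = sum(1 for r in ps.records if len(r) < min_len)
    n_long = sum(1 for r in ps.records if len(r) > max_len)
    if n_short or n_long:
        logger.info(
            "filter_by_length: removed %d too-short and %d too-long records", n_short, n_long
        )
    return PeptideSet(kept, name=ps.name)


def stratify_sets(ps: PeptideSet) -> dict[str, PeptideSet]:
    """Split a 6-25-residue set into training and test length strata.

    Training strata are cumulative (``train_6 ⊂ train_6-10 ⊂ train_6-15``);
    test strata are pairwise disjoint and together cover the input.
    Keys: ``train_6``, ``train_6-10``, ``train_6-15``, ``test_6``,
    ``test_7-10``, ``test_11-15``, ``test_16-25``.
    """
    for rec in ps:
        if not (MIN_LENGTH <= len(rec) <= MAX_LENGTH):
            raise ValueError(
                f"record {rec.id!r}: length {len(rec)} outside {MIN_LENGTH}-{MAX_LENGTH}; "
                f"apply filter_by_length first"
            )
    out: dict[str, PeptideSet] = {}
    for stratum, (lo, hi) in TRAIN_STRATA.items():
        out[f"train_{stratum}"] = PeptideSet(
            (r for r in ps if lo <= len(r) <= hi), name=f"{ps.name}_train_{stratum}"
        )
    for stratum, (lo, hi) in TEST_STRATA.items():
        out[f"test_{stratum}"] = PeptideSet(
            (r for r in ps if lo <= len(r) <= hi), name=f"{ps.name}_test_{stratum}"
        )
    return out


def extract_hexapeptides(ps: PeptideSet | Iterable[PeptideRecord]) -> list[Hexapeptide]:
    """All overlapping 6-residue windows, each inheriting its parent's label."""
    hexes: list[Hexapeptide] = []
    for rec in ps:
        if len(rec) < WINDOW:
            raise ValueError(f"record {rec.id!r}: length {len(rec)} < {WINDOW}")
        for off in range(len(rec) - WINDOW + 1):
            hexes.append(
                Hexapeptide(rec.sequence[off : off + WINDOW], rec.id, off, rec.label)
            )
    return hexes


def write_hexapeptides(hexes: Iterable[Hexapeptide], path: str | Path) -> None:
    """Tab-separated hexapeptide table: parent_id, offset, sequence, label."""
    with open(path, "w") as fh:
        fh.write("parent_id\toffset\tsequence\tlabel\n")
        for h in hexes:
            fh.write(f"{h.parent_id}\t{h.offset}\t{h.residues}\t{h.label}\n")
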