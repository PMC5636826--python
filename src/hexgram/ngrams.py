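"""Gapped n-gram feature space over encoded hexapeptides.

Features are position-free patterns of encoded symbols matched anywhere
inside a 6-residue window.  The template families are:

* 1-grams (one symbol);
* 2-grams with a gap of 0-3 wildcard positions between the two symbols;
* 3-grams that are contiguous or carry a single 1-position gap, either
  between the first and second or between the second and third symbol.

For an alphabet of m groups this yields m + 4 m^2 + 3 m^3 distinct
features (120, 260, 480, 798 for m = 3, 4, 5, 6).  Occurrence is
binarized: a feature is 1 for a hexapeptide if its symbol tuple matches
at any admissible alignment, regardless of how many times.

Feature identifiers are stable strings: symbols joined by ``.``, then an
underscore and the gap lengths joined by ``.`` (omitted for 1-grams),
e.g. ``"3.3_1"`` is symbol 3, one wildcard, symbol 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import itertools

import numpy as np
import pandas as pd

from .alphabets import Encoding
from .peptides import WINDOW, Hexapeptide


@dataclass(frozen=True)
class NGramTemplate:
    """A length-and-gap pattern: n matched positions, fixed gaps between them."""

    n: int
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.gaps) != self.n - 1:
            raise ValueError(f"need {self.n - 1} gap entries for an {self.n}-gram")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be >= 0")
        if self.span > WINDOW:
            raise ValueError(f"template span {self.span} exceeds window {WINDOW}")

    @property
    def span(self) -> int:
        return self.n + sum(self.gaps)

    @property
    def positions(self) -> tuple[int, ...]:
        """Matched-position offsets relative to the alignment start."""
        pos = [0]
        for g in self.gaps:
            pos.append(pos[-1] + 1 + g)
        return tuple(pos)


#: The complete template family, in canonical generation order.
TEMPLATES: tuple[NGramTemplate, ...] = (
    NGramTemplate(1, ()),
    NGramTemplate(2, (0,)),
    NGramTemplate(2, (1,)),
    NGramTemplate(2, (2,)),
    NGramTemplate(2, (3,)),
    NGramTemplate(3, (0, 0)),
    NGramTemplate(3, (1, 0)),
    NGramTemplate(3, (0, 1)),
)


@dataclass(frozen=True)
class NGramFeature:
    """A template instantiated with concrete encoded-group symbols."""

    template: NGramTemplate
    symbols: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != self.template.n:
            raise ValueError("symbol count must equal template length")

    @property
    def id(self) -> str:
        head = ".".join(str(s) for s in self.symbols)
        if self.template.n == 1:
            return head
        return head + "_" + ".".join(str(g) for g in self.template.gaps)

    @classmethod
    def from_id(cls, fid: str) -> "NGramFeature":
        if "_" in fid:
            head, tail = fid.split("_", 1)
            gaps = tuple(int(g) for g in tail.split("."))
        else:
            head, gaps = fid, ()
        symbols = tuple(int(s) for s in head.split("."))
        return cls(NGramTemplate(len(symbols), gaps), symbols)

    def __str__(self) -> str:
        return self.id


def _group_ids(alphabet: int | Encoding) -> tuple[int, ...]:
    if isinstance(alphabet, Encoding):
        return alphabet.group_ids
    if alphabet < 2:
        raise ValueError("alphabet must have at least 2 groups")
    return tuple(range(1, alphabet + 1))


def generate_feature_space(alphabet: int | Encoding) -> list[NGramFeature]:
    """All n-gram features over an encoding (or plain group count).

    Deterministic order: templates in :data:`TEMPLATES` order, symbol
    tuples in lexicographic order within a template.
    """
    ids = _group_ids(alphabet)
    features: list[NGramFeature] = []
    for tpl in TEMPLATES:
        for symbols in itertools.product(ids, repeat=tpl.n):
            features.append(NGramFeature(tpl, symbols))
    return features


def encode_sequence(seq: str, enc: Encoding) -> tuple[int, ...]:
    """Positionwise substitution of residues by group ids."""
    return tuple(enc.group_of(aa) for aa in seq)


def present_features(encoded: Sequence[int]) -> set[tuple[NGramTemplate, tuple[int, ...]]]:
    """(template, symbols) pairs occurring anywhere in an encoded window."""
    if len(encoded) != WINDOW:
        raise ValueError(f"expected a {WINDOW}-symbol window, got {len(encoded)}")
    present: set[tuple[NGramTemplate, tuple[int, ...]]] = set()
    for tpl in TEMPLATES:
        offsets = tpl.positions
        for start in range(WINDOW - tpl.span + 1):
            present.add((tpl, tuple(encoded[start + o] for o in offsets)))
    return present


class FeatureMatrix:
    """Binary hexapeptide x n-gram occurrence matrix with row provenance."""

    def __init__(
        self,
        X: np.ndarray,
        feature_ids: Sequence[str],
        provenance: pd.DataFrame,
        encoding: Encoding | None = None,
    ) -> None:
        X = np.asarray(X, dtype=np.uint8)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("feature matrix cells must be binary")
        if X.shape[1] != len(feature_ids):
            raise ValueError("feature_ids length must match column count")
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("feature ids must be unique")
        required = {"parent_id", "offset", "label"}
        if not required.issubset(provenance.columns):
            raise ValueError(f"provenance must have columns {sorted(required)}")
        if len(provenance) != X.shape[0]:
            raise ValueError("provenance row count must match matrix")
        self.X = X
        self.feature_ids: tuple[str, ...] = tuple(feature_ids)
        self.provenance = provenance.reset_index(drop=True)
        self.encoding = encoding
        self._col = {fid: j for j, fid in enumerate(self.feature_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def labels(self) -> np.ndarray:
        return self.provenance["label"].to_numpy(dtype=int)

    def column(self, feature_id: str) -> np.ndarray:
        try:
            return self.X[:, self._col[feature_id]]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def subset(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        cols = [self._col[f] for f in feature_ids]  # KeyError on unknown id
        return FeatureMatrix(
            self.X[:, cols], list(feature_ids), self.provenance, encoding=self.encoding
        )

    def to_tsv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        """Dense TSV with a feature-id header; provenance as sidecar TSV."""
        pd.DataFrame(self.X, columns=list(self.feature_ids)).to_csv(
            path, sep="\t", index=False
        )
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, sep="\t", index=False)

    def to_triplets(self, path: str | Path) -> None:
        """Sparse triplet text: row, column, value (1), 0-based, one per line."""
        rows, cols = np.nonzero(self.X)
        with open(path, "w") as fh:
            fh.write(f"%rows={self.X.shape[0]} cols={self.X.shape[1]}\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r}\t{c}\t1\n")


def extract_features(
    hexes: Iterable[Hexapeptide],
    enc: Encoding,
    feature_space: Sequence[NGramFeature] | None = None,
) -> FeatureMatrix:
    """Binarized occurrence matrix of every feature over every hexapeptide."""
    hexes = list(hexes)
    features = list(feature_space) if feature_space is not None else generate_feature_space(enc)
    col_of = {(f.template, f.symbols): j for j, f in enumerate(features)}
    X = np.zeros((len(hexes), len(features)), dtype=np.uint8)
    for i, h in enumerate(hexes):
        if len(h.residues) != WINDOW:
            raise ValueError(f"row {i}: not a hexapeptide ({h.residues!r})")
        encoded = encode_sequence(h.residues, enc)
        for key in present_features(encoded):
            j = col_of.get(key)
            if j is not None:
                X[i, j] = 1
    provenance = pd.DataFrame(
        {
            "parent_id": [h.parent_id for h in hexes],
            "offset": [h.offset for h in hexes],
            "sequence": [h.residues for h in hexes],
            "label": [h.label for h in hexes],
        }
    )
    return FeatureMatrix(X, [f.id for f in features], provenance, encoding=enc)
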