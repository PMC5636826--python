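"""Reduced amino-acid alphabets from physicochemical properties.

A reduced alphabet (here: *encoding*) is a partition of the 20 canonical
amino acids into a small number of groups that share physicochemical
character.  Encodings are generated by Ward hierarchical clustering of
the amino acids in the space spanned by a chosen subset of normalized
property scales (AAIndex-style: hydrophobicity, beta-sheet propensity,
flexibility, ...), cut to exactly k groups for k in {3, 4, 5, 6}.

Crossing every non-empty subset of P retained properties with every
group count yields (2^P - 1) * |k| candidate configurations; many of the
resulting partitions coincide, so catalogues are deduplicated up to
relabelling of the groups.

Two encodings are compared by pair counting: the fraction of the
C(20, 2) = 190 unordered residue pairs that both encodings classify
concordantly (together in both, or apart in both).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .peptides import AMINO_ACIDS

logger = logging.getLogger(__name__)

_AA_SET = frozenset(AMINO_ACIDS)


class PropertyTable:
    """A 20 x P table of numeric amino-acid property scales.

    Rows are indexed by one-letter amino-acid code (all 20 required, no
    missing values); columns are named property scales.
    """

    def __init__(self, values: pd.DataFrame) -> None:
        df = values.copy()
        df.index = [str(i).upper() for i in df.index]
        missing = _AA_SET - set(df.index)
        if missing:
            raise ValueError(f"property table missing amino acids: {sorted(missing)}")
        extra = set(df.index) - _AA_SET
        if extra:
            raise ValueError(f"property table has unknown rows: {sorted(extra)}")
        if df.index.has_duplicates:
            raise ValueError("property table has duplicate amino-acid rows")
        if df.columns.has_duplicates:
            raise ValueError("property table has duplicate property names")
        df = df.loc[list(AMINO_ACIDS)].astype(float)
        if df.isna().any().any():
            raise ValueError("property table contains missing values")
        if df.shape[1] < 1:
            raise ValueError("property table needs at least one property")
        self.df = df

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self.df.columns)

    @property
    def n_properties(self) -> int:
        return self.df.shape[1]

    def subset(self, names: Sequence[str]) -> "PropertyTable":
        return PropertyTable(self.df[list(names)])

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "PropertyTable":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep)


class Encoding:
    """A partition of the 20 amino acids into labelled groups.

    ``groups[i]`` is the sorted residue string of group id ``i + 1``.
    Equality and hashing compare the *partition* only, i.e. two encodings
    that differ just by group numbering are equal; :meth:`canonicalize`
    returns the representative whose groups are ordered by their
    alphabetically smallest member.
    """

    def __init__(
        self,
        groups: Iterable[str | Iterable[str]],
        provenance: tuple | None = None,
    ) -> None:
        norm: list[str] = []
        for g in groups:
            chars = g if isinstance(g, str) else "".join(g)
            s = "".join(sorted(set(chars.upper())))
            if not s:
                raise ValueError("encoding contains an empty group")
            norm.append(s)
        self.groups: tuple[str, ...] = tuple(norm)
        covered = "".join(self.groups)
        if len(set(covered)) != len(covered):
            raise ValueError("encoding groups are not disjoint")
        if set(covered) != _AA_SET:
            missing = sorted(_AA_SET - set(covered))
            extra = sorted(set(covered) - _AA_SET)
            raise ValueError(
                f"encoding must cover exactly the 20 amino acids "
                f"(missing {missing}, unknown {extra})"
            )
        self.provenance = provenance
        self._map = {aa: i + 1 for i, g in enumerate(self.groups) for aa in g}
        self._key = frozenset(frozenset(g) for g in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.groups) + 1))

    def group_of(self, residue: str) -> int:
        try:
            return self._map[residue.upper()]
        except KeyError:
            raise KeyError(f"residue {residue!r} not covered by encoding") from None

    @property
    def mapping(self) -> dict[str, int]:
        return dict(self._map)

    def canonical_key(self) -> frozenset:
        return self._key

    def canonicalize(self) -> "Encoding":
        """Representative with groups ordered by smallest member, ids 1..k."""
        return Encoding(sorted(self.groups, key=lambda g: g[0]), provenance=self.provenance)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Encoding) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"Encoding({', '.join(self.groups)})"

    # -- plain-text format: one group per line ----------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "Encoding":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(lines)

    def to_file(self, path: str | Path) -> None:
        canon = self.canonicalize()
        with open(path, "w") as fh:
            for g in canon.groups:
                fh.write(g + "\n")


@dataclass(frozen=True)
class EncodingCatalog:
    """Deduplicated collection of encodings."""

    encodings: tuple[Encoding, ...]
    configuration_count: int
    unique_count: int


def filter_correlated_properties(pt: PropertyTable, r_max: float = 0.95) -> PropertyTable:
    """Greedily drop properties correlated with an earlier-kept one.

    Properties are scanned in column order; a property is dropped when its
    absolute Pearson correlation with any already-kept property is
    ``>= r_max``.  A constant-valued property (undefined correlation)
    raises.
    """
    if pt.n_properties < 2:
        raise ValueError("need at least two properties to prune correlations")
    df = pt.df
    for name in df.columns:
        if df[name].nunique() == 1:
            raise ValueError(f"property {name!r} is constant; correlation undefined")
    corr = df.corr().abs()
    kept: list[str] = []
    dropped: list[str] = []
    for name in df.columns:
        if any(corr.loc[name, k] >= r_max for k in kept):
            dropped.append(name)
        else:
            kept.append(name)
    if dropped:
        logger.info("filter_correlated_properties: dropped %s", dropped)
    return PropertyTable(df[kept])


def count_configurations(n_properties: int, k_values: Iterable[int] = (3, 4, 5, 6)) -> int:
    """Closed form (2^P - 1) * |k_values|."""
    ks = set(k_values)
    if not ks:
        raise ValueError("k_values must be non-empty")
    return (2**n_properties - 1) * len(ks)


def enumerate_configurations(
    pt: PropertyTable | Sequence[str],
    k_values: Iterable[int] = (3, 4, 5, 6),
) -> Iterator[tuple[tuple[str, ...], int]]:
    """Lazily yield every (non-empty property subset, group count) pair.

    Subsets are emitted in order of increasing size, lexicographic within
    a size; group counts ascend within a subset.
    """
    names = tuple(pt.property_names if isinstance(pt, PropertyTable) else pt)
    if not names:
        raise ValueError("property table has no properties")
    ks = sorted(set(k_values))
    if not ks:
        raise ValueError("k_values must be non-empty")
    for size in range(1, len(names) + 1):
        for subset in itertools.combinations(names, size):
            for k in ks:
                yield subset, k


def _normalize(df: pd.DataFrame, scale: str) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    if scale == "minmax":
        lo = x.min(axis=0)
        rng = x.max(axis=0) - lo
        rng[rng == 0] = 1.0
        return (x - lo) / rng
    if scale == "zscore":
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=0)) / sd
    raise ValueError(f"unknown scale {scale!r}")


def build_encoding(
    pt: PropertyTable,
    subset: Sequence[str],
    k: int,
    scale: str = "minmax",
) -> Encoding:
    """Ward-cluster the 20 amino acids on a property subset into k groups.

    Property columns are normalized (min-max to [0, 1] by default,
    z-score optionally) before clustering; the squared-Euclidean Ward
    criterion (scipy ``linkage(method="ward")``, the Ward.D2 dialect) is
    cut to exactly ``k`` clusters.  ``k = 20`` short-circuits to the
    identity (full, unreduced) alphabet.  The result is canonical: groups
    ordered by their alphabetically smallest member.
    """
    if k == 20:
        return Encoding(list(AMINO_ACIDS), provenance=(tuple(subset), 20, scale))
    if not subset:
        raise ValueError("property subset must be non-empty")
    if not 3 <= k <= 6:
        raise ValueError(f"group count k must be in 3..6 (or 20 for the full alphabet), got {k}")
    x = _normalize(pt.df[list(subset)], scale)
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct property vectors in the subset"
        )
    labels = fcluster(linkage(x, method="ward"), t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for aa, lab in zip(AMINO_ACIDS, labels):
        groups.setdefault(int(lab), []).append(aa)
    enc = Encoding(
        ["".join(g) for g in groups.values()], provenance=(tuple(subset), k, scale)
    )
    return enc.canonicalize()


def canonicalize_and_deduplicate(encodings: Iterable[Encoding]) -> EncodingCatalog:
    """One canonical representative per distinct partition, first occurrence kept."""
    seen: dict[frozenset, Encoding] = {}
    total = 0
    for enc in encodings:
        total += 1
        key = enc.canonical_key()
        if key not in seen:
            seen[key] = enc.canonicalize()
    return EncodingCatalog(
        encodings=tuple(seen.values()),
        configuration_count=total,
        unique_count=len(seen),
    )


def pair_counting_similarity(a: Encoding, b: Encoding) -> float:
    """Fraction of the 190 unordered residue pairs classified concordantly."""
    concordant = 0
    total = 0
    for x, y in itertools.combinations(AMINO_ACIDS, 2):
        total += 1
        if (a.group_of(x) == a.group_of(y)) == (b.group_of(x) == b.group_of(y)):
            concordant += 1
    return concordant / total


def encoding_similarity(
    a: Encoding,
    b: Encoding,
    measure: str | Callable[[Encoding, Encoding], float] = "pair_counting",
) -> float:
    """Similarity in [0, 1] between two partitions; 1 iff identical.

    The default pair-counting measure is pluggable: pass any callable
    taking two encodings.
    """
    if callable(measure):
        return measure(a, b)
    if measure == "pair_counting":
        return pair_counting_similarity(a, b)
    raise ValueError(f"unknown similarity measure {measure!r}")


# ---------------------------------------------------------------------------
# Built-in encodings

#: Best-performing 6-group encoding selected by the cross-validation study:
#: I = {G}, II = {K,P,R}, III = {I,L,V}, IV = {F,W,Y}, V = {A,C,H,M},
#: VI = {D,E,N,Q,S,T}.  Group ids follow the published subgroup numbering.
BEST_ENCODING = Encoding(["G", "KPR", "ILV", "FWY", "ACHM", "DENQST"])

#: Classic general-purpose 5-group reductions used as comparison baselines.
STANDARD_ENCODING_A = Encoding(["ADEGHKNPQRST", "C", "FY", "ILMV", "W"])
STANDARD_ENCODING_B = Encoding(["AG", "C", "DEKNPQRST", "FILMVWY", "H"])

#: Full, unreduced 20-letter alphabet (each residue its own group).
FULL_ALPHABET = Encoding(list(AMINO_ACIDS))

NAMED_ENCODINGS: dict[str, Encoding] = {
    "best6": BEST_ENCODING,
    "standard5a": STANDARD_ENCODING_A,
    "standard5b": STANDARD_ENCODING_B,
    "full": FULL_ALPHABET,
}


# Example property scales (classic published values, for demonstration and
# tests; a production run would load a user-supplied AAIndex-style CSV).
_EXAMPLE_SCALES: dict[str, dict[str, float]] = {
    # Kyte-Doolittle hydropathy
    "hydropathy": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    # Chou-Fasman beta-sheet conformational preference
    "beta_sheet": {
        "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
        "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
        "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
        "Y": 1.47, "V": 1.70,
    },
    # Bhaskaran-Ponnuswamy average flexibility
    "flexibility": {
        "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493,
        "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466,
        "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305,
        "Y": 0.420, "V": 0.386,
    },
    # Zimmerman polarity
    "polarity": {
        "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48, "Q": 3.53,
        "E": 49.90, "G": 0.00, "H": 51.60, "I": 0.13, "L": 0.13, "K": 49.50,
        "M": 1.43, "F": 0.35, "P": 1.58, "S": 1.67, "T": 1.66, "W": 2.10,
        "Y": 1.61, "V": 0.13,
    },
    # Zamyatnin residue volume
    "volume": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
        "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
        "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
        "Y": 193.6, "V": 140.0,
    },
}


def example_property_table() -> PropertyTable:
    """Small built-in table of five classic property scales."""
    return PropertyTable(pd.DataFrame(_EXAMPLE_SCALES))
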