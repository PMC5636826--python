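"""Synthetic labelled peptide sets with planted encoding-level motifs.

The generator emulates the statistical structure the pipeline assumes:
amyloid-positive peptides carry a short n-gram motif (defined at the
level of encoding groups, realized by sampling concrete residues from
those groups) at a random admissible position, while negatives mostly do
not.  Residues outside motif positions are drawn from a background
distribution over encoding groups, uniform within a group.

Defaults emulate the curated amyloid study conditions: 200 positive and
200 negative peptides; motif present in 90% of positives and 10% of
negatives; the peptide length mix mirrors the empirical 6-15-residue
training data (about 81.5% hexapeptides, 14.1% of lengths 7-10, 4.3% of
lengths 11-15); the motif is a contiguous repeat of the hydrophobic
subgroup-III symbol of the built-in best 6-group encoding, the signature
reported for amyloid hot spots.

Occurrence is controlled exactly: a peptide designated a motif carrier
is guaranteed to contain the motif (it is planted), and a designated
non-carrier is rejection-sampled until no accidental occurrence of the
motif remains, so the per-class occurrence rate is exactly
Bernoulli(p_pos) / Bernoulli(p_neg).

A ground-truth table (peptide_id, motif_id, offset) is emitted as a
separate sidecar, never inside FASTA headers, so the pipeline cannot
leak it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabets import BEST_ENCODING, Encoding, PropertyTable
from .ngrams import NGramFeature, NGramTemplate, encode_sequence, present_features
from .peptides import AMINO_ACIDS, WINDOW, PeptideRecord, PeptideSet

#: Empirical length mix of 6-15-residue training peptides (see module docs).
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    6: 0.8155,
    **{length: 0.1409 / 4 for length in range(7, 11)},
    **{length: 0.0436 / 5 for length in range(11, 16)},
}


def default_motif() -> NGramFeature:
    """Contiguous 3-gram of the hydrophobic subgroup-III symbol (I/L/V runs)."""
    return NGramFeature(NGramTemplate(3, (0, 0)), (3, 3, 3))


@dataclass(frozen=True)
class MotifSpec:
    """A planted feature with its occurrence probabilities per class."""

    feature: NGramFeature
    p_pos: float = 0.9
    p_neg: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_neg <= self.p_pos <= 1.0:
            raise ValueError("require 0 <= p_neg <= p_pos <= 1")


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_pos: int = 200
    n_neg: int = 200
    encoding: Encoding = field(default_factory=lambda: BEST_ENCODING)
    motifs: tuple[MotifSpec, ...] = field(
        default_factory=lambda: (MotifSpec(default_motif()),)
    )
    #: Frequencies over encoding group ids; None = proportional to group
    #: size (i.e. residues uniform over the 20 amino acids).
    background: dict[int, float] | None = None
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one peptide per class")
        if not self.length_distribution:
            raise ValueError("length distribution is empty")
        if any(not 6 <= length <= 25 for length in self.length_distribution):
            raise ValueError("peptide lengths must lie in 6..25")
        if abs(sum(self.length_distribution.values()) - 1.0) > 1e-6:
            raise ValueError("length distribution must sum to 1")
        if self.background is not None:
            if set(self.background) != set(self.encoding.group_ids):
                raise ValueError("background must cover exactly the encoding's groups")
            if abs(sum(self.background.values()) - 1.0) > 1e-6:
                raise ValueError("background frequencies must sum to 1")
        for m in self.motifs:
            for s in m.feature.symbols:
                if s not in self.encoding.group_ids:
                    raise ValueError(f"motif symbol {s} not a group of the encoding")


def hydrophobic_background(enc: Encoding = BEST_ENCODING, boost: float = 2.0) -> dict[int, float]:
    """Background preset skewed toward groups containing I/L/V and F/W/Y."""
    weights = {}
    for gid, group in zip(enc.group_ids, enc.groups):
        w = len(group)
        if set(group) & set("ILVFWY"):
            w *= boost
        weights[gid] = w
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def _residue_sampler(cfg: SynthConfig):
    enc = cfg.encoding
    if cfg.background is None:
        residues = np.array(list(AMINO_ACIDS))
        probs = np.full(len(residues), 1 / len(residues))
    else:
        residues_list: list[str] = []
        probs_list: list[float] = []
        for gid, group in zip(enc.group_ids, enc.groups):
            for aa in group:
                residues_list.append(aa)
                probs_list.append(cfg.background[gid] / len(group))
        residues = np.array(residues_list)
        probs = np.array(probs_list)
        probs = probs / probs.sum()
    return residues, probs


def sample_property_table(
    k_clusters: int,
    separation: float,
    seed: int,
    n_properties: int = 4,
) -> tuple[PropertyTable, Encoding]:
    """Synthetic 20 x P property table with a planted residue partition.

    The 20 amino acids are split at random into ``k_clusters`` non-empty
    clusters; cluster centers are scaled so their minimum pairwise
    distance equals ``separation`` while within-cluster noise has unit
    variance per property.  Returns the table and the planted partition
    (as an :class:`Encoding`) for recovery tests.
    """
    if not 2 <= k_clusters <= 20:
        raise ValueError("k_clusters must be in 2..20")
    rng = np.random.default_rng(seed)
    # non-empty random partition: seed one residue per cluster, rest random
    order = rng.permutation(20)
    assignment = np.empty(20, dtype=int)
    assignment[order[:k_clusters]] = np.arange(k_clusters)
    assignment[order[k_clusters:]] = rng.integers(0, k_clusters, 20 - k_clusters)
    centers = rng.normal(size=(k_clusters, n_properties))
    if k_clusters > 1 and separation > 0:
        dists = [
            np.linalg.norm(centers[i] - centers[j])
            for i in range(k_clusters)
            for j in range(i + 1, k_clusters)
        ]
        centers *= separation / max(min(dists), 1e-12)
    values = centers[assignment] + rng.normal(size=(20, n_properties))
    df = pd.DataFrame(
        values,
        index=list(AMINO_ACIDS),
        columns=[f"prop_{i + 1}" for i in range(n_properties)],
    )
    groups: dict[int, list[str]] = {}
    for aa, c in zip(AMINO_ACIDS, assignment):
        groups.setdefault(int(c), []).append(aa)
    planted = Encoding(["".join(g) for g in groups.values()]).canonicalize()
    return PropertyTable(df), planted


def contains_feature(seq: str, enc: Encoding, feature: NGramFeature) -> bool:
    """Whether the feature occurs in any 6-residue window of the sequence."""
    encoded = encode_sequence(seq, enc)
    key = (feature.template, feature.symbols)
    for off in range(len(encoded) - WINDOW + 1):
        if key in present_features(encoded[off : off + WINDOW]):
            return True
    return False


def generate_peptide_set(cfg: SynthConfig) -> tuple[PeptideSet, pd.DataFrame]:
    """Sample a labelled peptide set plus its ground-truth motif table.

    Carrier status is drawn per motif and per peptide; carriers get the
    motif planted at a random admissible offset, non-carriers are
    resampled until they contain no accidental occurrence, so occurrence
    rates equal p_pos / p_neg exactly in distribution.
    """
    rng = np.random.default_rng(cfg.seed)
    enc = cfg.encoding
    residues, probs = _residue_sampler(cfg)
    lengths = np.array(sorted(cfg.length_distribution))
    length_p = np.array([cfg.length_distribution[length] for length in lengths])
    length_p = length_p / length_p.sum()

    records: list[PeptideRecord] = []
    truth_rows: list[dict] = []
    for label, count, prefix in ((1, cfg.n_pos, "pos"), (0, cfg.n_neg, "neg")):
        for i in range(count):
            pid = f"{prefix}_{i + 1:04d}"
            L = int(rng.choice(lengths, p=length_p))
            carrier = [
                rng.random() < (m.p_pos if label == 1 else m.p_neg)
                for m in cfg.motifs
            ]
            for m in cfg.motifs:
                if m.feature.template.span > L:
                    raise ValueError(
                        f"motif span {m.feature.template.span} exceeds "
                        f"sampled peptide length {L}"
                    )
            for _ in range(10_000):
                seq = list(rng.choice(residues, size=L, p=probs))
                offsets: list[int | None] = []
                for motif, is_carrier in zip(cfg.motifs, carrier):
                    if not is_carrier:
                        offsets.append(None)
                        continue
                    span = motif.feature.template.span
                    offset = int(rng.integers(0, L - span + 1))
                    for rel, sym in zip(
                        motif.feature.template.positions, motif.feature.symbols
                    ):
                        group = enc.groups[sym - 1]
                        seq[offset + rel] = group[int(rng.integers(0, len(group)))]
                    offsets.append(offset)
                s = "".join(seq)
                if all(
                    is_carrier or not contains_feature(s, enc, motif.feature)
                    for motif, is_carrier in zip(cfg.motifs, carrier)
                ):
                    break
            else:  # pragma: no cover - pathological motif/background combination
                raise RuntimeError(
                    f"could not sample a peptide respecting carrier status for {pid}"
                )
            for motif, offset in zip(cfg.motifs, offsets):
                if offset is not None:
                    truth_rows.append(
                        {
                            "peptide_id": pid,
                            "motif_id": motif.feature.id,
                            "offset": offset,
                        }
                    )
            records.append(PeptideRecord(pid, s, label))
    truth = pd.DataFrame(truth_rows, columns=["peptide_id", "motif_id", "offset"])
    return PeptideSet(records, name=f"synth_seed{cfg.seed}"), truth


def write_synthetic_set(
    cfg: SynthConfig,
    fasta_path: str | Path,
    labels_path: str | Path,
    truth_path: str | Path,
) -> PeptideSet:
    """Generate and write FASTA + label table + ground-truth sidecar TSV."""
    ps, truth = generate_peptide_set(cfg)
    ps.write_fasta(fasta_path, labels_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return ps
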