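"""Benchmark-style dataset construction for protein-pair classification.

Covers the standard steps used to build PPI benchmarks from an annotated
proteome: quality filtering of sequences, sampling of presumed
non-interacting pairs across different subcellular compartments,
hold-out splitting, removal of hold-out pairs redundant with the
training proteins by global-alignment sequence identity, and stratified
k-fold assignment for cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_codec import ProteinRecord

DEFAULT_MIN_LENGTH = 50
DEFAULT_IDENTITY_THRESHOLD = 0.25


@dataclass(frozen=True)
class PairSample:
    """A labelled protein pair: label 1 = interaction, 0 = non-interaction."""

    idA: str
    idB: str
    label: int
    split: str = "pretrain"

    def key(self) -> frozenset:
        """Unordered-pair identity."""
        return frozenset((self.idA, self.idB))


@dataclass
class SplitSpec:
    holdout_size: int = 0
    n_folds: int = 10
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold < 1:
            raise ValueError("identity_threshold must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


# ------------------------------------------------------------------ filtering


def filter_proteins(
    records: list[ProteinRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    require_unique_location: bool = True,
    locations: dict[str, list[str]] | None = None,
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Apply benchmark quality filters; returns kept records and a rejection log.

    Removes sequences shorter than ``min_length`` and, when
    ``require_unique_location``, records without exactly one compartment
    annotation.  ``locations`` may map an id to its full annotation list
    (a record annotated to several compartments is ambiguous and dropped).
    Non-standard residues are already rejected by :class:`ProteinRecord`.
    """
    kept: list[ProteinRecord] = []
    log: dict[str, list[str]] = {"min_length": [], "no_location": [], "multi_location": []}
    for rec in records:
        if len(rec) < min_length:
            log["min_length"].append(rec.id)
            continue
        if require_unique_location:
            anns = locations.get(rec.id) if locations is not None else (
                [rec.compartment] if rec.compartment is not None else []
            )
            anns = anns or []
            if len(anns) == 0:
                log["no_location"].append(rec.id)
                continue
            if len(set(anns)) > 1:
                log["multi_location"].append(rec.id)
                continue
            if rec.compartment is None:
                rec = ProteinRecord(rec.id, rec.seq, anns[0])
        kept.append(rec)
    if not kept:
        raise ValueError(
            "all records rejected by the benchmark filters; review min_length "
            "and location requirements"
        )
    return kept, log


# ----------------------------------------------------------- negative sampling


def _cross_compartment_pairs(records: list[ProteinRecord]):
    for a, b in itertools.combinations(records, 2):
        if a.compartment != b.compartment:
            yield (a.id, b.id)


def sample_negatives(
    records: list[ProteinRecord],
    n: int,
    seed: int = 0,
    exclude: set[frozenset] | None = None,
) -> list[PairSample]:
    """Draw ``n`` unique unordered cross-compartment pairs, uniformly at random.

    Self-pairs are never produced, pairs in ``exclude`` (e.g. the positive
    set) are skipped, and both members must carry different compartment
    labels.  Deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    comp = [r.compartment for r in records]
    if len(set(c for c in comp if c is not None)) < 2:
        raise ValueError("negative sampling needs >= 2 distinct compartments")
    exclude = exclude or set()
    rng = np.random.default_rng(seed)
    chosen: set[frozenset] = set()
    out: list[PairSample] = []
    n_rec = len(records)
    attempts = 0
    budget = 50 * n + 1000
    while len(out) < n and attempts < budget:
        attempts += 1
        i, j = rng.choice(n_rec, size=2, replace=False)
        a, b = records[i], records[j]
        if a.compartment == b.compartment:
            continue
        key = frozenset((a.id, b.id))
        if key in chosen or key in exclude:
            continue
        chosen.add(key)
        out.append(PairSample(a.id, b.id, 0))
    if len(out) < n:
        # sampling stalled: enumerate the remaining candidates exactly
        remaining = [
            (ia, ib)
            for ia, ib in _cross_compartment_pairs(records)
            if frozenset((ia, ib)) not in chosen and frozenset((ia, ib)) not in exclude
        ]
        needed = n - len(out)
        if needed > len(remaining):
            achievable = len(out) + len(remaining)
            raise ValueError(
                f"requested {n} negatives but only {achievable} distinct "
                f"cross-compartment pairs are available"
            )
        picks = rng.choice(len(remaining), size=needed, replace=False)
        out.extend(PairSample(*remaining[k], 0) for k in sorted(picks))
    return out


# ---------------------------------------------------------- sequence identity


def _make_aligner(gap_open: float = 10.0, gap_extend: float = 0.5, matrix: str = "BLOSUM62"):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_identity(
    seqA: str,
    seqB: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> float:
    """Percent identity between two sequences from one optimal global alignment.

    Identity is counted as identical aligned residues divided by the full
    alignment length including gap columns (Needleman-Wunsch, BLOSUM62,
    affine gap cost ``open + (L-1) * extend`` by default).  Symmetric in
    its arguments up to co-optimal alignment choice.
    """
    if not seqA or not seqB:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    alignment = next(iter(aligner.align(seqA, seqB)))
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length


def alignment_score(
    seqA: str,
    seqB: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> float:
    """Optimal global alignment score under the same scoring as pairwise_identity."""
    return float(_make_aligner(gap_open, gap_extend, matrix).score(seqA, seqB))


# -------------------------------------------------------- redundancy removal


@dataclass
class RemovalReport:
    """One hold-out pair removed by the identity filter and why."""

    idA: str
    idB: str
    test_protein: str
    train_protein: str
    identity: float


def remove_redundant(
    test_pairs: list[PairSample],
    train_records: list[ProteinRecord],
    sequences: dict[str, str],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[list[PairSample], list[RemovalReport]]:
    """Drop hold-out pairs redundant with the training proteins.

    A pair is removed when *either* member has global-alignment identity
    >= ``threshold`` to *any* training protein — a conservative rule that
    prevents homology leakage through a single member.  Identity against
    the training set is cached per test protein; the report records the
    first triggering training protein.
    """
    cache: dict[str, tuple[bool, str, float]] = {}

    def hit(pid: str) -> tuple[bool, str, float]:
        if pid not in cache:
            seq = sequences[pid]
            best = ("", 0.0)
            found = False
            for tr in train_records:
                ident = pairwise_identity(seq, tr.seq)
                if ident > best[1]:
                    best = (tr.id, ident)
                if ident >= threshold:
                    cache[pid] = (True, tr.id, ident)
                    found = True
                    break
            if not found:
                cache[pid] = (False, best[0], best[1])
        return cache[pid]

    kept: list[PairSample] = []
    removed: list[RemovalReport] = []
    for pair in test_pairs:
        for pid in (pair.idA, pair.idB):
            is_hit, train_id, ident = hit(pid)
            if is_hit:
                removed.append(RemovalReport(pair.idA, pair.idB, pid, train_id, ident))
                break
        else:
            kept.append(pair)
    return kept, removed


# ------------------------------------------------------------------ splitting


def holdout_split(
    samples: list[PairSample], n_holdout: int, seed: int = 0
) -> tuple[list[PairSample], list[PairSample]]:
    """Uniform random split into (pretrain, holdout) of exact sizes."""
    if n_holdout <= 0:
        raise ValueError("n_holdout must be positive")
    if n_holdout >= len(samples):
        raise ValueError(f"n_holdout={n_holdout} must be < number of samples {len(samples)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    hold_idx = set(order[:n_holdout].tolist())
    pretrain = [s for i, s in enumerate(samples) if i not in hold_idx]
    holdout = [s for i, s in enumerate(samples) if i in hold_idx]
    return pretrain, holdout


def make_folds(samples: list[PairSample] | np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment: an integer array in [0, k) per sample.

    Within each label class the samples are shuffled and dealt round-robin
    with a fold counter carried across classes, so fold sizes differ by at
    most one overall and by at most one within each class.
    """
    if isinstance(samples, np.ndarray):
        labels = samples.astype(int)
    else:
        labels = np.array([s.label for s in samples], dtype=int)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    counter = rng.integers(k)  # random starting fold, carried across classes
    for label in np.unique(labels):
        idx = np.nonzero(labels == label)[0]
        rng.shuffle(idx)
        for i in idx:
            folds[i] = counter % k
            counter += 1
    return folds
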