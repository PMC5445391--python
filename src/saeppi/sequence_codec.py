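"""Sequence encodings for protein-pair classification.

Two fixed-length per-protein encodings are provided:

* **Autocovariance (AC).** Each residue is mapped to seven normalized
  physicochemical descriptor values; for every descriptor *j* and lag
  ``lag = 1..lag_max`` the sequence autocovariance

  .. math::

     AC_{lag,j} = \\frac{1}{n-lag} \\sum_{i=1}^{n-lag}
        (X_{i,j} - \\bar X_j)(X_{i+lag,j} - \\bar X_j)

  is computed, where :math:`\\bar X_j` is the mean descriptor value over
  the whole sequence of length *n*.  With 7 descriptors and the default
  ``lag_max = 30`` a protein becomes a 210-vector, independent of length.

* **Conjoint triad (CT).** The 20 amino acids are collapsed into 7 groups
  by dipole moment and side-chain volume; a width-3 window slides along
  the grouped sequence and the count of each of the :math:`7^3 = 343`
  possible triads forms the feature vector.

A protein pair is represented by min-max scaling each member's vector
(scaler fitted on training data only) and concatenating the two halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_DESCRIPTORS = 7
N_CT_GROUPS = 7
CT_DIM = N_CT_GROUPS**3  # 343
DEFAULT_LAG_MAX = 30


@dataclass
class ProteinRecord:
    """A protein sequence with an identifier and optional compartment label.

    The sequence must be non-empty and restricted to the 20 standard
    amino acids; records containing ambiguity codes (B, Z, X) or
    non-standard residues (U, O) are rejected at construction.
    """

    id: str
    seq: str
    compartment: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = sorted(set(self.seq) - set(AMINO_ACIDS))
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residue(s) {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DescriptorTable:
    """Seven physicochemical descriptors for the 20 standard residues.

    ``raw`` holds the literature values; ``normalized`` holds the same
    rows standardized to zero mean and unit variance across the 20
    residues (population standard deviation), which is the form entering
    the autocovariance sum.  Column order follows :data:`AMINO_ACIDS`.
    """

    names: list[str]
    raw: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (N_DESCRIPTORS, len(AMINO_ACIDS)):
            raise ValueError(
                f"descriptor matrix must be {N_DESCRIPTORS}x{len(AMINO_ACIDS)}, "
                f"got {self.raw.shape}"
            )
        if len(self.names) != N_DESCRIPTORS:
            raise ValueError("expected exactly 7 descriptor names")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("descriptor values must be finite")
        sd = self.raw.std(axis=1)
        if np.any(sd == 0):
            flat = [self.names[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"constant descriptor row(s): {flat}; normalization undefined")
        self.normalized = (self.raw - self.raw.mean(axis=1, keepdims=True)) / sd[:, None]

    def profile(self, seq: str) -> np.ndarray:
        """Normalized descriptor profile of a sequence, shape (7, n)."""
        idx = np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
        return self.normalized[:, idx]


def normalize_descriptors(raw: np.ndarray, names: list[str] | None = None) -> DescriptorTable:
    """Standardize a raw 7x20 descriptor matrix into a :class:`DescriptorTable`."""
    raw = np.asarray(raw, dtype=float)
    if names is None:
        names = [f"descriptor_{j+1}" for j in range(raw.shape[0])] if raw.ndim == 2 else []
    return DescriptorTable(names=list(names), raw=raw)


def default_descriptor_table() -> DescriptorTable:
    """The packaged descriptor table: hydrophobicity, hydrophilicity, net
    charge index of side chains, polarity, polarizability, solvent-accessible
    surface area and side-chain volume."""
    path = resources.files("saeppi.data") / "descriptors.tsv"
    names: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        order = header[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            names.append(parts[0])
            by_aa = dict(zip(order, map(float, parts[1:])))
            rows.append([by_aa[aa] for aa in AMINO_ACIDS])
    return DescriptorTable(names=names, raw=np.array(rows))


@dataclass
class CTClusterMap:
    """Partition of the 20 residues into the 7 conjoint-triad groups."""

    groups: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.groups))
        if missing:
            raise ValueError(f"cluster map missing residues {''.join(missing)!r}")
        used = set(self.groups[aa] for aa in AMINO_ACIDS)
        if used != set(range(1, N_CT_GROUPS + 1)):
            raise ValueError(
                f"cluster map must use exactly groups 1..{N_CT_GROUPS}, got {sorted(used)}"
            )

    def __getitem__(self, residue: str) -> int:
        try:
            return self.groups[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in cluster map") from None


def default_cluster_map() -> CTClusterMap:
    """The packaged dipole / side-chain-volume 7-group classification."""
    path = resources.files("saeppi.data") / "ct_groups.tsv"
    groups: dict[str, int] = {}
    with path.open() as fh:
        fh.readline()
        for line in fh:
            parts = line.split()
            if len(parts) == 2:
                groups[parts[0]] = int(parts[1])
    return CTClusterMap(groups)


@dataclass
class FeatureVector:
    """Fixed-length encoding of one protein under a named scheme."""

    values: np.ndarray
    scheme: str  # "AC" or "CT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme not in ("AC", "CT"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return self.values.size


def encode_ac(
    p: ProteinRecord,
    table: DescriptorTable | None = None,
    lag_max: int = DEFAULT_LAG_MAX,
) -> FeatureVector:
    """Autocovariance encoding: a 7*lag_max vector ordered descriptor-major.

    Entry (j, lag) is the lag-autocovariance of descriptor j along the
    sequence, centred on the per-sequence descriptor mean.  Requires the
    sequence to be strictly longer than ``lag_max``.
    """
    if table is None:
        table = default_descriptor_table()
    if lag_max < 1:
        raise ValueError("lag_max must be >= 1")
    n = len(p.seq)
    if n <= lag_max:
        raise ValueError(
            f"protein {p.id!r}: length {n} must exceed lag_max={lag_max}"
        )
    prof = table.profile(p.seq)  # (7, n)
    centred = prof - prof.mean(axis=1, keepdims=True)
    out = np.empty((N_DESCRIPTORS, lag_max))
    for lag in range(1, lag_max + 1):
        out[:, lag - 1] = (centred[:, : n - lag] * centred[:, lag:]).sum(axis=1) / (n - lag)
    return FeatureVector(out.ravel(), "AC")


def cluster_sequence(p: ProteinRecord, m: CTClusterMap | None = None) -> str:
    """Replace each residue by its conjoint-triad group number (a digit string)."""
    if m is None:
        m = default_cluster_map()
    return "".join(str(m[c]) for c in p.seq)


def triad_index(a: int, b: int, c: int) -> int:
    """1-based flat feature index of the group triad (a, b, c).

    The first window position varies fastest: (1,1,1) -> 1, (2,1,1) -> 2,
    ..., (7,1,1) -> 7, (1,2,1) -> 8, ..., (7,7,7) -> 343.
    """
    for g in (a, b, c):
        if not 1 <= g <= N_CT_GROUPS:
            raise ValueError(f"group {g} outside 1..{N_CT_GROUPS}")
    return a + N_CT_GROUPS * (b - 1) + N_CT_GROUPS**2 * (c - 1)


def encode_ct(p: ProteinRecord, m: CTClusterMap | None = None) -> FeatureVector:
    """Conjoint-triad encoding: raw counts of the 343 group triads.

    A width-3 window slides one position at a time, so the counts sum to
    ``len(seq) - 2``.
    """
    if len(p.seq) < 3:
        raise ValueError(f"protein {p.id!r}: CT encoding needs length >= 3, got {len(p.seq)}")
    digits = cluster_sequence(p, m)
    g = np.fromiter((int(d) for d in digits), dtype=np.intp, count=len(digits))
    flat = (g[:-2] - 1) + N_CT_GROUPS * (g[1:-1] - 1) + N_CT_GROUPS**2 * (g[2:] - 1)
    counts = np.bincount(flat, minlength=CT_DIM).astype(float)
    return FeatureVector(counts, "CT")


class PairScaler:
    """Per-feature min-max scaler for protein feature vectors.

    Fitted on training-set per-protein vectors only; transformed values are
    clipped to [0, 1] so unseen test values stay in the bounded range the
    sigmoid units expect.  Features constant in training map to 0.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.range_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.min_ is not None

    def fit(self, X: np.ndarray) -> "PairScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        rng[rng == 0] = 1.0
        self.range_ = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        X = np.asarray(X, dtype=float)
        return np.clip((X - self.min_) / self.range_, 0.0, 1.0)

    def to_dict(self) -> dict:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        return {"min": self.min_.tolist(), "range": self.range_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PairScaler":
        s = cls()
        s.min_ = np.asarray(d["min"], dtype=float)
        s.range_ = np.asarray(d["range"], dtype=float)
        return s


def encode_pair(vA: FeatureVector, vB: FeatureVector, scaler: PairScaler) -> np.ndarray:
    """Scale each member's vector and concatenate: length 420 (AC) or 686 (CT)."""
    if vA.scheme != vB.scheme:
        raise ValueError(f"scheme mismatch: {vA.scheme} vs {vB.scheme}")
    if len(vA) != len(vB):
        raise ValueError(f"length mismatch: {len(vA)} vs {len(vB)}")
    if not scaler.fitted:
        raise ValueError("scaler has not been fitted")
    a = scaler.transform(vA.values[None, :])[0]
    b = scaler.transform(vB.values[None, :])[0]
    return np.concatenate([a, b])


def feature_matrix(
    records: list[ProteinRecord],
    scheme: str,
    table: DescriptorTable | None = None,
    cluster_map: CTClusterMap | None = None,
    lag_max: int = DEFAULT_LAG_MAX,
) -> np.ndarray:
    """Encode a list of proteins into an (n_records, dim) matrix."""
    if scheme == "AC":
        if table is None:
            table = default_descriptor_table()
        rows = [encode_ac(r, table, lag_max).values for r in records]
    elif scheme == "CT":
        if cluster_map is None:
            cluster_map = default_cluster_map()
        rows = [encode_ct(r, cluster_map).values for r in records]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return np.vstack(rows) if rows else np.empty((0, 0))


def pair_feature_arrays(
    records: list[ProteinRecord],
    pairs,
    scheme: str,
    lag_max: int = DEFAULT_LAG_MAX,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unscaled per-protein feature rows (Va, Vb) and labels for a pair list."""
    by_id = {r.id: r for r in records}
    used_ids = sorted({pid for p in pairs for pid in (p.idA, p.idB)})
    missing = [pid for pid in used_ids if pid not in by_id]
    if missing:
        raise KeyError(f"pair ids missing from records: {missing[:5]}")
    V = feature_matrix([by_id[i] for i in used_ids], scheme, lag_max=lag_max)
    row = {pid: i for i, pid in enumerate(used_ids)}
    Va = V[[row[p.idA] for p in pairs]]
    Vb = V[[row[p.idB] for p in pairs]]
    y = np.array([p.label for p in pairs], dtype=int)
    return Va, Vb, y
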