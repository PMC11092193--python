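"""Readers, writers and the core in-memory containers of the pipeline.

Every matrix in the package is indexed by the canonical protein order: index
``i`` always refers to the ``i``-th record of the FASTA file (or of the
generated :class:`ProteinSet`).  Pair files are plain 3-column TSV
(``id_a<TAB>id_b<TAB>label``), embeddings are TSV with an ``id`` column and
one column per dimension.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: 20 standard amino acids plus tolerated ambiguity / non-standard codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(STANDARD_AA) | frozenset("BJOUXZ")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class ProteinSet:
    """Ordered protein identifiers with their amino-acid sequences.

    The identifier order is the canonical index 0..n-1 used by every matrix
    downstream.
    """

    ids: tuple[str, ...]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("protein identifiers must be unique")
        for pid in self.ids:
            if not pid:
                raise ValueError("empty protein identifier")
            seq = self.sequences.get(pid)
            if not seq:
                raise ValueError(f"protein {pid!r}: empty or missing sequence")
            bad = set(seq) - ALLOWED_RESIDUES
            if bad:
                raise ValueError(
                    f"protein {pid!r}: illegal residue character(s) {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, pid: str) -> int:
        try:
            return self.ids.index(pid)
        except ValueError:
            raise KeyError(f"unknown protein identifier {pid!r}") from None

    def sequence_list(self) -> list[str]:
        """Sequences in canonical index order."""
        return [self.sequences[pid] for pid in self.ids]


@dataclass(frozen=True)
class InteractionNetwork:
    """Symmetric binary interaction graph over the canonical protein order."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if (np.diag(a) != 0).any():
            raise ValueError("adjacency diagonal must be zero")
        if (a != a.T).any():
            raise ValueError("adjacency must be symmetric")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class PairDataset:
    """Labelled unordered protein pairs, canonicalised as (min_index, max_index)."""

    pairs: np.ndarray  # (m, 2) int
    labels: np.ndarray  # (m,) int in {0, 1}

    def __post_init__(self) -> None:
        pairs = np.atleast_2d(np.asarray(self.pairs, dtype=np.int64))
        if pairs.size == 0:
            pairs = pairs.reshape(0, 2)
        labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if pairs.shape[0] != labels.shape[0]:
            raise ValueError("pairs and labels must align")
        if pairs.shape[0] and pairs.shape[1] != 2:
            raise ValueError("pairs must have two columns")
        if (pairs[:, 0] == pairs[:, 1]).any():
            raise ValueError("self-pairs are not allowed")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        canon = np.sort(pairs, axis=1)
        seen: dict[tuple[int, int], int] = {}
        for (a, b), lab in zip(map(tuple, canon), labels):
            if seen.setdefault((a, b), int(lab)) != lab:
                raise ValueError(f"conflicting labels for pair ({a}, {b})")
        object.__setattr__(self, "pairs", canon)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def positives(self) -> np.ndarray:
        return self.pairs[self.labels == 1]


def read_fasta(path: str | Path) -> ProteinSet:
    """Parse a FASTA file into a :class:`ProteinSet`, preserving record order.

    Sequences are uppercased.  Duplicate identifiers, empty files and illegal
    residue characters are rejected with the offending record named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate identifier {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"record {record.id!r}: empty sequence")
        bad = set(seq) - ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"record {record.id!r}: illegal residue character(s) {sorted(bad)}"
            )
        ids.append(record.id)
        sequences[record.id] = seq
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    return ProteinSet(ids=tuple(ids), sequences=sequences)


def write_fasta(path: str | Path, proteins: ProteinSet) -> None:
    with open(path, "w") as fh:
        for pid in proteins.ids:
            fh.write(f">{pid}\n{proteins.sequences[pid]}\n")


def read_pairs_tsv(
    path: str | Path,
    proteins: "ProteinSet | list[str] | tuple[str, ...]",
    positives_only: bool = False,
) -> PairDataset:
    """Read a 3-column pair TSV (``id_a  id_b  label``) against a protein set.

    ``proteins`` may be a :class:`ProteinSet` or a plain ordered id list (as
    read back from an embeddings file).  With ``positives_only`` the label
    column is omitted and every row is a positive.  A header line
    ``id_a\tid_b[\tlabel]`` is tolerated.  Errors report the 1-based line
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids = proteins.ids if isinstance(proteins, ProteinSet) else tuple(proteins)
    lookup = {pid: i for i, pid in enumerate(ids)}
    pairs: list[tuple[int, int]] = []
    labels: list[int] = []
    n_cols = 2 if positives_only else 3
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["id_a", "id_b"]:
                continue
            if len(fields) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated columns"
                )
            id_a, id_b = fields[0], fields[1]
            try:
                a, b = lookup[id_a], lookup[id_b]
            except KeyError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unknown protein identifier {exc.args[0]!r}"
                ) from None
            if a == b:
                raise FormatError(f"{path}:{lineno}: self-pair {id_a!r}")
            if positives_only:
                lab = 1
            else:
                if fields[2] not in ("0", "1"):
                    raise FormatError(
                        f"{path}:{lineno}: label must be 0 or 1, got {fields[2]!r}"
                    )
                lab = int(fields[2])
            pairs.append((a, b))
            labels.append(lab)
    try:
        return PairDataset(pairs=np.array(pairs), labels=np.array(labels))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_pairs_tsv(path: str | Path, proteins: ProteinSet, dataset: PairDataset) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for (a, b), lab in zip(dataset.pairs, dataset.labels):
            fh.write(f"{proteins.ids[a]}\t{proteins.ids[b]}\t{lab}\n")


def build_network(pairs: PairDataset, n: int) -> InteractionNetwork:
    """Assemble the symmetric binary adjacency from the positive pairs.

    The Gaussian interaction-profile bandwidth is undefined on an edgeless
    graph, so an all-negative dataset is rejected here.
    """
    if n < 2:
        raise ValueError("need at least two proteins")
    pos = pairs.positives
    if pos.shape[0] == 0:
        raise ValueError(
            "no positive pairs: interaction network would be edgeless and the "
            "GIP bandwidth undefined"
        )
    if pos.max() >= n:
        raise ValueError("pair index out of range")
    adjacency = np.zeros((n, n), dtype=np.int8)
    adjacency[pos[:, 0], pos[:, 1]] = 1
    adjacency[pos[:, 1], pos[:, 0]] = 1
    return InteractionNetwork(adjacency=adjacency)


def sample_negative_pairs(
    network: InteractionNetwork, count: int, seed: int
) -> PairDataset:
    """Sample ``count`` distinct non-adjacent unordered pairs, all labelled 0.

    Sampling is uniform without replacement and reproducible per seed.
    """
    n = network.n
    mask = np.triu(np.ones((n, n), dtype=bool), k=1) & (network.adjacency == 0)
    candidates = np.argwhere(mask)
    if count > len(candidates):
        raise ValueError(
            f"requested {count} negatives but only {len(candidates)} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    chosen = candidates[rng.choice(len(candidates), size=count, replace=False)]
    return PairDataset(pairs=chosen, labels=np.zeros(count, dtype=np.int64))


def concat_datasets(*datasets: PairDataset) -> PairDataset:
    pairs = np.concatenate([d.pairs.reshape(-1, 2) for d in datasets])
    labels = np.concatenate([d.labels for d in datasets])
    return PairDataset(pairs=pairs, labels=labels)


def write_embeddings(path: str | Path, ids: list[str] | tuple[str, ...], matrix: np.ndarray) -> None:
    """Write an embedding matrix as TSV with header ``id  e0 ... e{d-1}``."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.size == 0:
        matrix = matrix.reshape(0, matrix.shape[-1] if matrix.ndim else 0)
    if matrix.shape[0] != len(ids):
        raise ValueError("row count must equal id count")
    d = matrix.shape[1]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"e{j}" for j in range(d)) + "\n")
        for pid, row in zip(ids, matrix):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id" or any(
            h != f"e{j}" for j, h in enumerate(header[1:])
        ):
            raise FormatError(f"{path}: malformed embeddings header")
        d = len(header) - 1
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != d + 1:
                raise FormatError(f"{path}:{lineno}: expected {d + 1} columns")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, d))
    return ids, matrix


def write_matrix_tsv(path: str | Path, ids: tuple[str, ...], values: np.ndarray) -> None:
    """Square matrix as TSV with an id header row and id first column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for pid, row in zip(ids, values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["id"]:
            raise FormatError(f"{path}: malformed matrix header")
        ids = tuple(header[1:])
        rows = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(ids) + 1:
                raise FormatError(f"{path}:{lineno}: ragged row")
            rows.append([float(v) for v in fields[1:]])
    if len(rows) != len(ids):
        raise FormatError(f"{path}: row count does not match header")
    return ids, np.array(rows, dtype=float)
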