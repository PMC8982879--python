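"""Descriptor databases and ranking by length-scaling cosine distance.

Retrieval compares unit descriptors instead of atomic coordinates.  The
distance is the cosine distance divided by ``1 + max((l_b - l_a)/l_max, 0)``
where ``l_a`` is the query length, ``l_b`` the key length and ``l_max``
the longest chain in the database: when the key is no longer than the
query it reduces to plain cosine distance, and longer keys are pulled
closer, mimicking the query-length normalisation (and hence asymmetry)
of TM-score.  The scaling is a test-time device only; training always
uses plain cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoder import Descriptor, GraphEncoder
from .featurization import featurize
from .structure_io import ProteinStructure

__all__ = [
    "DescriptorDB",
    "RankingResult",
    "length_scaling_distance",
    "rank_database",
    "build_descriptor_db",
]


@dataclass
class DescriptorDB:
    """Stacked unit descriptors with residue counts and the frozen l_max."""

    ids: list[str]
    vectors: np.ndarray  # (n, L), rows unit-norm
    lengths: np.ndarray  # (n,) residue counts
    l_max: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.ids) != len(self.vectors) or len(self.ids) != len(self.lengths):
            raise ValueError("ids, vectors and lengths must align")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-4):
            raise ValueError("descriptor vectors must be unit-norm")
        if len(self.lengths) and self.l_max < int(self.lengths.max()):
            raise ValueError("l_max below a stored length")

    def __len__(self) -> int:
        return len(self.ids)

    def descriptor(self, structure_id: str) -> Descriptor:
        i = self.ids.index(structure_id)
        return Descriptor(structure_id, self.vectors[i], int(self.lengths[i]))

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            ids=np.array(self.ids),
            vectors=self.vectors,
            lengths=self.lengths,
            l_max=np.array(self.l_max),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorDB":
        with np.load(path, allow_pickle=False) as npz:
            return cls(
                ids=[str(x) for x in npz["ids"]],
                vectors=npz["vectors"],
                lengths=npz["lengths"],
                l_max=int(npz["l_max"]),
            )


@dataclass
class RankingResult:
    """Database ids in ascending order of distance to one query."""

    query_id: str
    ordered_ids: list[str]
    distances: np.ndarray


def length_scaling_distance(y_a: Descriptor, y_b: Descriptor,
                            l_max: int) -> float:
    """Length-scaling cosine distance d(a, b) in [0, 2].

    d = (1 - y_a . y_b) / (1 + max((l_b - l_a) / l_max, 0)).  Asymmetric:
    a key longer than the query shrinks the distance, so
    d(a, b) <= d(b, a) whenever l_a < l_b — the direction TM-score's
    query-length normalisation induces (a short query matching part of a
    long key scores well; the reverse does not).
    """
    for y in (y_a, y_b):
        norm = np.linalg.norm(y.vector)
        if norm == 0.0:
            raise ValueError(f"zero-norm descriptor {y.structure_id!r}")
        if abs(norm - 1.0) > 1e-4:
            raise ValueError(f"descriptor {y.structure_id!r} is not unit-norm")
    cosine = float(np.dot(y_a.vector, y_b.vector))
    scale = 1.0 + max((y_b.n_residues - y_a.n_residues) / l_max, 0.0)
    return max(1.0 - cosine, 0.0) / scale


def rank_database(query: Descriptor, db: DescriptorDB) -> RankingResult:
    """Rank all database entries by ascending length-scaling distance.

    The query itself (matched by id) is excluded; ties break by
    ascending id, so rankings are stable across runs.
    """
    if len(db) == 0:
        raise ValueError("empty descriptor database")
    cosines = db.vectors @ query.vector
    scales = 1.0 + np.maximum(
        (db.lengths - query.n_residues) / db.l_max, 0.0
    )
    distances = np.maximum(1.0 - cosines, 0.0) / scales
    entries = [
        (float(distances[i]), sid)
        for i, sid in enumerate(db.ids)
        if sid != query.structure_id
    ]
    entries.sort()
    return RankingResult(
        query_id=query.structure_id,
        ordered_ids=[sid for _, sid in entries],
        distances=np.array([d for d, _ in entries]),
    )


def build_descriptor_db(
    model: GraphEncoder,
    structures: list[ProteinStructure],
    M: int = 5,
) -> DescriptorDB:
    """Encode structures into a database; failures are reported per id.

    Structures that cannot be featurized (e.g. shorter than the minimum
    chain length) are skipped with a warning naming the id.
    """
    import warnings

    ids: list[str] = []
    vectors: list[np.ndarray] = []
    lengths: list[int] = []
    for s in structures:
        try:
            _, desc = model.encode(featurize(s, M=M))
        except ValueError as exc:
            warnings.warn(f"skipping {s.id}: {exc}")
            continue
        ids.append(s.id)
        vectors.append(desc.vector)
        lengths.append(desc.n_residues)
    if not ids:
        raise ValueError("no structure could be encoded")
    return DescriptorDB(
        ids=ids,
        vectors=np.stack(vectors),
        lengths=np.array(lengths),
        l_max=int(max(lengths)),
    )
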