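"""Ground-truth pairwise similarity tables (TM-score supervision).

A :class:`SimilarityTable` holds per-query similarity scores over a
database, typically TM-scores from an external aligner or from the
built-in same-length oracle.  On disk it is a TSV with header columns
``query_id``, ``key_id``, ``score``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimilarityTable"]


class SimilarityTable:
    """Dense query x key similarity matrix keyed by structure ids."""

    def __init__(self, ids: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (len(ids), len(ids)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match {len(ids)} ids"
            )
        self.ids = list(ids)
        self.matrix = matrix
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def score(self, query_id: str, key_id: str) -> float:
        return float(self.matrix[self._index[query_id], self._index[key_id]])

    def has(self, structure_id: str) -> bool:
        return structure_id in self._index

    def row(self, query_id: str, exclude_self: bool = True) -> dict[str, float]:
        """Scores of one query against the database, as id -> score."""
        i = self._index[query_id]
        return {
            sid: float(self.matrix[i, j])
            for j, sid in enumerate(self.ids)
            if not (exclude_self and j == i)
        }

    # -- persistence -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        records = [
            (q, k, self.matrix[i, j])
            for i, q in enumerate(self.ids)
            for j, k in enumerate(self.ids)
        ]
        pd.DataFrame(records, columns=["query_id", "key_id", "score"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityTable":
        df = pd.read_csv(path, sep="\t")
        required = {"query_id", "key_id", "score"}
        if not required.issubset(df.columns):
            raise ValueError(f"similarity TSV needs columns {sorted(required)}")
        pivot = df.pivot(index="query_id", columns="key_id", values="score")
        ids = sorted(set(df["query_id"]) | set(df["key_id"]))
        pivot = pivot.reindex(index=ids, columns=ids)
        if pivot.isna().any().any():
            raise ValueError("similarity table is not complete over all pairs")
        return cls(ids, pivot.to_numpy())
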