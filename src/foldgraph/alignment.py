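"""Residue-level superposition from learned embeddings.

Two structures are superposed without any sequence information: the
cosine-similarity matrix between their residue embeddings serves as the
scoring matrix for global Needleman-Wunsch alignment (gap open 0, gap
extension 0.1 per gap column), and the resulting residue correspondence
feeds the Kabsch algorithm, which finds the least-squares optimal proper
rotation and translation and reports the C-alpha RMSD over the paired
residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoder import GraphEncoder, ResidueEmbeddings
from .featurization import featurize
from .structure_io import ProteinStructure, write_structure

__all__ = [
    "SuperpositionResult",
    "cosine_similarity_matrix",
    "nw_align",
    "kabsch",
    "superpose",
]


@dataclass
class SuperpositionResult:
    """Residue correspondence plus the optimal rigid transform.

    ``rotation`` and ``translation`` map structure B onto structure A:
    x_b -> rotation @ x_b + translation.  ``pairs`` is strictly
    increasing in both coordinates (a global, non-crossing alignment).
    """

    pairs: list[tuple[int, int]]
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float


def cosine_similarity_matrix(e_a: ResidueEmbeddings,
                             e_b: ResidueEmbeddings) -> np.ndarray:
    """C[i, j] = cosine of residue i of A with residue j of B, in [-1, 1]."""
    a, b = e_a.matrix, e_b.matrix
    if a.size == 0 or b.size == 0:
        raise ValueError("empty residue embeddings")
    return a @ b.T


def nw_align(C: np.ndarray, gap_open: float = 0.0,
             gap_extend: float = 0.1) -> list[tuple[int, int]]:
    """Global alignment maximising matched similarity minus gap penalties.

    Affine gaps: a gap of g columns costs gap_open + gap_extend * g (with
    the default open of 0 this is a linear 0.1 per gap column).  Traceback
    ties break diagonal > up (gap in B) > left (gap in A); the returned
    matched pairs are strictly increasing in both indices.
    """
    C = np.asarray(C, dtype=np.float64)
    if not np.all(np.isfinite(C)):
        raise ValueError("similarity matrix must be finite")
    n, m = C.shape
    neg = -np.inf
    # Gotoh three-state DP: M ends in a match, IX in a gap consuming A
    # rows (B gapped), IY in a gap consuming B columns (A gapped).
    M = np.full((n + 1, m + 1), neg)
    IX = np.full((n + 1, m + 1), neg)
    IY = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        IX[i, 0] = -gap_open - gap_extend * i
    for j in range(1, m + 1):
        IY[0, j] = -gap_open - gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = C[i - 1, j - 1] + max(
                M[i - 1, j - 1], IX[i - 1, j - 1], IY[i - 1, j - 1]
            )
            # cross IX<->IY transitions are allowed: with negative
            # similarities, skipping a residue of each structure can beat
            # matching them
            IX[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                IX[i - 1, j] - gap_extend,
                IY[i - 1, j] - gap_open - gap_extend,
            )
            IY[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                IY[i, j - 1] - gap_extend,
                IX[i, j - 1] - gap_open - gap_extend,
            )

    # traceback from the best terminal state; ties: diagonal > up > left
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("IX", IX[n, m]), ("IY", IY[n, m])),
        key=lambda kv: (kv[1], kv[0] == "M", kv[0] == "IX"),
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev = C[i - 1, j - 1]
            options = (
                ("M", M[i - 1, j - 1]),
                ("IX", IX[i - 1, j - 1]),
                ("IY", IY[i - 1, j - 1]),
            )
            target = M[i, j] - prev
            state = _pick(options, target)
            i, j = i - 1, j - 1
        elif state == "IX":
            options = (
                ("M", M[i - 1, j] - gap_open - gap_extend),
                ("IX", IX[i - 1, j] - gap_extend),
                ("IY", IY[i - 1, j] - gap_open - gap_extend),
            )
            state = _pick(options, IX[i, j])
            i -= 1
        else:  # IY
            options = (
                ("M", M[i, j - 1] - gap_open - gap_extend),
                ("IX", IX[i, j - 1] - gap_open - gap_extend),
                ("IY", IY[i, j - 1] - gap_extend),
            )
            state = _pick(options, IY[i, j])
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "IY"
        elif j == 0:
            state = "IX"
    pairs.reverse()
    return pairs


def _pick(options: tuple, target: float, tol: float = 1e-9) -> str:
    for name, value in options:  # options listed in tie-break priority
        if abs(value - target) <= tol:
            return name
    # numerical fallback: closest value
    return min(options, key=lambda kv: abs(kv[1] - target))[0]


def nw_score(C: np.ndarray, pairs: list[tuple[int, int]],
             gap_open: float = 0.0, gap_extend: float = 0.1) -> float:
    """Score of a monotone alignment under the nw_align gap model."""
    n, m = np.asarray(C).shape
    score = sum(C[i, j] for i, j in pairs)
    # charge gaps between consecutive matches and at both ends
    prev_i, prev_j = -1, -1
    segments = []
    for i, j in pairs + [(n, m)]:
        gap_a = i - prev_i - 1  # unmatched rows of A
        gap_b = j - prev_j - 1  # unmatched columns of B
        segments.extend(g for g in (gap_a, gap_b) if g > 0)
        prev_i, prev_j = i, j
    for g in segments:
        score -= gap_open + gap_extend * g
    return float(score)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray,
           pairs: list[tuple[int, int]],
           weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired C-alpha atoms.

    SVD of the weighted covariance with a determinant correction so the
    rotation is proper (no reflection).  The transform maps B onto A;
    RMSD is the unweighted root-mean-square deviation over the pairs.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 residue pairs")
    coords_a = np.asarray(coords_a, dtype=np.float64)
    coords_b = np.asarray(coords_b, dtype=np.float64)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    A = coords_a[ia]
    B = coords_b[ib]
    if weights is None:
        w = np.ones(len(pairs))
    else:
        w = np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    cen_a = w @ A
    cen_b = w @ B
    H = (B - cen_b).T @ ((A - cen_a) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(pairs=list(pairs), rotation=R, translation=t,
                               rmsd=rmsd)


def superpose(
    structure_a: ProteinStructure,
    structure_b: ProteinStructure,
    model: GraphEncoder,
    out_path: str | Path | None = None,
    gap_open: float = 0.0,
    gap_extend: float = 0.1,
) -> SuperpositionResult:
    """Full pipeline: embeddings -> cosine matrix -> NW -> Kabsch.

    With ``out_path`` set, a two-model PDB of the superposed pair is
    written (MODEL 1 = structure A, MODEL 2 = transformed structure B).
    """
    emb_a, _ = model.encode(featurize(structure_a))
    emb_b, _ = model.encode(featurize(structure_b))
    C = cosine_similarity_matrix(emb_a, emb_b)
    pairs = nw_align(C, gap_open=gap_open, gap_extend=gap_extend)
    result = kabsch(structure_a.ca_coords, structure_b.ca_coords, pairs)
    if out_path is not None:
        moved = structure_b.ca_coords @ result.rotation.T + result.translation
        _write_two_model_pdb(
            out_path,
            structure_a,
            ProteinStructure(id=structure_b.id, ca_coords=moved),
        )
    return result


def _write_two_model_pdb(path: str | Path, a: ProteinStructure,
                         b: ProteinStructure) -> None:
    import io
    import tempfile

    chunks = []
    with tempfile.TemporaryDirectory() as tmp:
        for idx, s in enumerate((a, b), start=1):
            p = Path(tmp) / f"model{idx}.pdb"
            write_structure(s, p)
            body = "\n".join(
                line for line in p.read_text().splitlines()
                if line.startswith(("ATOM", "TER"))
            )
            chunks.append(f"MODEL     {idx:>4}\n{body}\nENDMDL")
    Path(path).write_text("\n".join(chunks) + "\nEND\n")
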