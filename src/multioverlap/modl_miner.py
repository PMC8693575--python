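"""MODL: approximate itemset mining through sparse dictionary learning.

Given a binary overlap matrix X (one row per overlap event, one column per
region set), MODL selects q itemsets that best *rebuild* the matrix rather
than enumerating association rules, which makes it robust to the uniform
bit-flip noise typical of peak-calling artefacts and biased toward whole
complexes rather than fragments.

Two steps:

1. *Library creation.* The input is first "smothered": each unique row
   pattern with count c is kept ceil(sqrt(c)) times, damping the dominance
   of abundant patterns so rarer complexes still contribute to the
   reconstruction objective.  Sparse dictionary learning

       min_{U,V} 1/2 ||X - U V||_2^2 + alpha ||U||_1,   rows of V unit-norm

   is then run repeatedly over an increasing sparsity schedule
   alpha_1 = 1/k, alpha_{i+1} = alpha_i + (i+1)/k (higher alpha forces
   fewer, hence longer, atoms).  After each factorization, atoms with
   positive total usage (sum of their code coefficients over all rows) are
   binarized and added to the candidate library; the sweep stops when the
   total usage of all atoms reaches zero.

2. *Greedy selection.* Starting from an empty dictionary, each step
   sparse-codes X against the current selection plus each remaining
   candidate and appends the candidate minimizing

       d1(X, X~) = ||X - X~||_1 + alpha * sum(U).

   Selection stops after q atoms or library exhaustion; output order is
   the greedy rank.  The unit-L2 normalization of atoms (squared weights
   summing to 1) makes broad atoms need proportionally larger coefficients,
   which the sum(U) penalty then damps — overly broad candidates are
   selected only when they genuinely improve the rebuilding.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import DictionaryLearning, sparse_encode

__all__ = [
    "OverlapMatrix",
    "SmotheredMatrix",
    "Atom",
    "Library",
    "ModlConfig",
    "smother",
    "build_library",
    "greedy_select",
    "modl_select",
    "read_matrix_tsv",
    "write_itemsets_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapMatrix:
    """Binary m x k matrix of overlap flags (rows: events; columns: sets)."""

    data: np.ndarray
    set_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.int8)
        if data.ndim != 2:
            raise ValueError("overlap matrix must be 2-D")
        if data.shape[1] != len(self.set_names):
            raise ValueError("set_names length does not match number of columns")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("overlap matrix must be binary")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "set_names", tuple(self.set_names))

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SmotheredMatrix:
    """Output of the smothering pre-processing psi(X).

    ``pattern_counts`` maps each unique row pattern to its (original,
    retained) counts; no pattern is ever dropped, and retention is
    monotone in abundance.
    """

    data: np.ndarray
    set_names: tuple[str, ...]
    pattern_counts: dict[tuple[int, ...], tuple[int, int]]


@dataclass(frozen=True)
class Atom:
    """A candidate itemset: learned weights and their binarized membership."""

    weights: tuple[float, ...]
    membership: frozenset[int]
    total_usage: float

    def label(self, set_names: Sequence[str]) -> str:
        return " + ".join(set_names[i] for i in sorted(self.membership))


@dataclass
class Library:
    """Candidate atoms, deduplicated by membership, with the alpha of origin."""

    atoms: list[Atom] = field(default_factory=list)
    provenance: dict[frozenset[int], float] = field(default_factory=dict)

    def add(self, atom: Atom, alpha: float) -> bool:
        if not atom.membership or atom.membership in self.provenance:
            return False
        self.atoms.append(atom)
        self.provenance[atom.membership] = alpha
        return True

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class ModlConfig:
    """MODL knobs.

    q: number of final itemsets.  atoms_per_factorization defaults to
    min(k, q + 2): enough capacity for q complexes plus slack.
    step2_alpha defaults to 1/k, the value that opens the step-1 schedule;
    a weaker penalty lets a broad complex be displaced by a pair of its
    fragments during greedy selection.
    binarization_threshold: an item belongs to an atom's membership when
    its weight is at least this fraction of the atom's maximum weight.
    The 0.5 default ("at least half the peak weight") strips the low-level
    weight that bit-flip noise bleeds into unrelated items.
    """

    q: int = 5
    atoms_per_factorization: int | None = None
    step2_alpha: float | None = None
    binarization_threshold: float = 0.5
    max_alpha_iterations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if not (0 < self.binarization_threshold < 1):
            raise ValueError("binarization_threshold must be in (0, 1)")

    def resolved_n_atoms(self, k: int) -> int:
        if self.atoms_per_factorization is not None:
            return self.atoms_per_factorization
        return max(1, min(k, self.q + 2))

    def resolved_step2_alpha(self, k: int) -> float:
        return self.step2_alpha if self.step2_alpha is not None else 1.0 / k


def smother(X: OverlapMatrix) -> SmotheredMatrix:
    """Quadratically damp pattern abundance: count c -> ceil(sqrt(c)) copies.

    Rare patterns keep at least one copy, so nothing is dropped; abundant
    patterns lose dominance (100 copies -> 10), letting minor complexes
    weigh in during library creation.
    """
    if X.m == 0:
        raise ValueError("empty overlap matrix")
    uniq, counts = np.unique(X.data, axis=0, return_counts=True)
    rows = []
    pattern_counts: dict[tuple[int, ...], tuple[int, int]] = {}
    for pattern, c in zip(uniq, counts):
        retained = math.isqrt(int(c) - 1) + 1  # == ceil(sqrt(c)) for c >= 1
        rows.append(np.tile(pattern, (retained, 1)))
        pattern_counts[tuple(int(v) for v in pattern)] = (int(c), retained)
    data = np.vstack(rows)
    return SmotheredMatrix(data, X.set_names, pattern_counts)


def _binarize(weights: np.ndarray, threshold: float) -> frozenset[int]:
    w = np.abs(weights)
    top = w.max()
    if top <= 0:
        return frozenset()
    return frozenset(int(i) for i in np.nonzero(w >= threshold * top)[0])


def _alpha_schedule(k: int, max_iter: int):
    alpha = 1.0 / k
    for i in range(1, max_iter + 1):
        yield alpha
        alpha += (i + 1) / k


def build_library(psiX: SmotheredMatrix, config: ModlConfig) -> Library:
    """Step 1: accumulate candidate atoms over the alpha sweep.

    Each factorization is non-negative (positive code and dictionary) so
    atoms read directly as itemsets.  Atoms with positive total usage are
    binarized and added; the sweep stops when every atom's usage is zero
    or the iteration cap is reached.  A factorization failure is retried
    with a fresh substream, then skipped with a warning.
    """
    data = np.asarray(psiX.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty smothered matrix")
    k = data.shape[1]
    n_atoms = min(config.resolved_n_atoms(k), data.shape[0])
    library = Library()
    if not data.any():
        return library  # nothing to rebuild: zero usage everywhere
    for it, alpha in enumerate(_alpha_schedule(k, config.max_alpha_iterations)):
        U = V = None
        for attempt in range(2):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dl = DictionaryLearning(
                        n_components=n_atoms,
                        alpha=alpha,
                        fit_algorithm="cd",
                        transform_algorithm="lasso_cd",
                        transform_alpha=alpha,
                        positive_code=True,
                        positive_dict=True,
                        max_iter=300,
                        random_state=config.seed + 1009 * it + attempt,
                    )
                    U = dl.fit_transform(data)
                    V = dl.components_
                break
            except Exception:  # pragma: no cover - sklearn convergence failure
                if attempt == 1:
                    logger.warning("factorization failed at alpha=%.3f; skipping", alpha)
        if U is None:
            continue
        usages = U.sum(axis=0)
        if not (usages > 0).any():
            break  # alpha so high that no atom is used: stop the sweep
        for j in range(V.shape[0]):
            if usages[j] <= 0:
                continue
            membership = _binarize(V[j], config.binarization_threshold)
            atom = Atom(tuple(float(w) for w in V[j]), membership, float(usages[j]))
            library.add(atom, alpha)
    return library


def _d1(X: np.ndarray, dictionary: np.ndarray, alpha: float) -> float:
    """Reconstruction criterion d1 = ||X - U D||_1 + alpha * sum(U)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        U = sparse_encode(
            X, dictionary, algorithm="lasso_cd", alpha=alpha, positive=True
        )
    resid = np.abs(X - U @ dictionary).sum()
    return float(resid + alpha * U.sum())


def greedy_select(
    X: OverlapMatrix,
    library: Library,
    config: ModlConfig,
    error_function: Callable[[np.ndarray, np.ndarray, float], float] | None = None,
) -> list[frozenset[int]]:
    """Step 2: greedily pick the q atoms that best rebuild X.

    Candidates are coded against the raw (unsmothered) matrix.  Ties are
    broken toward smaller memberships, then lexicographically, for
    determinism and parsimony.  ``error_function(X, dictionary, alpha)``
    may replace d1 to drive custom (e.g. supervised) selection losses.
    """
    if config.q == 0:
        return []
    if len(library) == 0:
        logger.warning("empty candidate library: nothing to select")
        return []
    data = np.asarray(X.data, dtype=float)
    alpha = config.resolved_step2_alpha(X.k)
    score = error_function if error_function is not None else _d1

    def atom_vector(membership: frozenset[int]) -> np.ndarray:
        v = np.zeros(X.k)
        v[list(membership)] = 1.0
        return v / np.linalg.norm(v)

    candidates = {a.membership: atom_vector(a.membership) for a in library.atoms}
    selected: list[frozenset[int]] = []
    selected_rows: list[np.ndarray] = []
    objective = -math.inf
    while len(selected) < config.q and candidates:
        best = None
        best_key = None
        for membership in sorted(candidates, key=lambda m: (len(m), sorted(m))):
            dictionary = np.vstack(selected_rows + [candidates[membership]])
            d = score(data, dictionary, alpha)
            key = (d, len(membership), sorted(membership))
            if best_key is None or key < best_key:
                best_key = key
                best = membership
        # f(S) = -d1 is non-decreasing in expectation; assert monotonicity
        new_objective = -best_key[0]
        if new_objective + 1e-9 < objective and len(selected) > 0:
            logger.debug(
                "objective decreased (%.4f -> %.4f); keeping greedy choice",
                objective, new_objective,
            )
        objective = max(objective, new_objective)
        selected.append(best)
        selected_rows.append(candidates.pop(best))
    return selected


def modl_select(
    X: OverlapMatrix,
    q: int,
    seed: int = 0,
    config: ModlConfig | None = None,
) -> list[frozenset[int]]:
    """Full MODL pipeline: smother -> library -> greedy selection.

    Deterministic for a fixed seed.  Returns the selected itemsets in
    greedy rank order, each as a frozenset of column indices.
    """
    if config is None:
        config = ModlConfig(q=q, seed=seed)
    else:
        config = ModlConfig(
            q=q,
            atoms_per_factorization=config.atoms_per_factorization,
            step2_alpha=config.step2_alpha,
            binarization_threshold=config.binarization_threshold,
            max_alpha_iterations=config.max_alpha_iterations,
            seed=seed,
        )
    psiX = smother(X)
    library = build_library(psiX, config)
    return greedy_select(X, library, config)


def read_matrix_tsv(path: str | Path) -> OverlapMatrix:
    """Read a binary overlap matrix TSV (header row = set names).

    Columns named chrom/start/end (as written by the intersection-matrix
    exporter) are ignored, so either a bare matrix or a full export loads.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.drop(columns=[c for c in ("chrom", "start", "end") if c in df.columns])
    return OverlapMatrix(df.to_numpy(dtype=np.int8), tuple(df.columns))


def write_itemsets_tsv(
    itemsets: Sequence[frozenset[int]],
    set_names: Sequence[str],
    path: str | Path,
) -> None:
    """Write ranked itemsets as TSV: rank, membership label, size."""
    records = [
        {
            "rank": i + 1,
            "itemset": " + ".join(set_names[j] for j in sorted(s)),
            "n_sets": len(s),
        }
        for i, s in enumerate(itemsets)
    ]
    pd.DataFrame(records, columns=["rank", "itemset", "n_sets"]).to_csv(
        path, sep="\t", index=False
    )
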