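"""Diagonal design (DD) of multicomponent calibration experiments.

Samples are placed along the main diagonals of a factor hypercube on an
integer grid of *conditional coordinates* so that (a) pairwise factor
correlations stay small, (b) every level of every factor is occupied by
exactly one sample (Latin hypercube condition), and (c) a built-in test
subset can be carved out of the spiral of positions without unbalancing
the training set.

Coordinates live in [-L, L] where L is the number of centrally symmetric
spiral positions; they are unitless grid indices that are mapped affinely
onto real concentration ranges by :func:`to_concentrations`.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "DesignScheme",
    "FactorMapping",
    "DesignDiagnostics",
    "DesignWarning",
    "direction_vectors",
    "parse_designation",
    "format_designation",
    "build_scheme",
    "select_test_set",
    "scheme_from_spec",
    "to_concentrations",
    "validate_scheme",
    "optimize_diagonal_sequence",
    "read_design",
    "write_design",
]

_DESIGNATION_RE = re.compile(r"^d(\d)(\d)v(\d)(\d+)$")


class DesignWarning(UserWarning):
    """Raised as a warning when a built scheme violates a soft design rule."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a diagonal design.

    ``first_train_id`` / ``first_test_id`` are the DS / VS fields of the
    designation string ``d{k}{DS}v{VS}{N}``: the IDs of the first sample in
    the training and validation subsets.  The center sample always has
    ID 0, so ``min(DS, VS) == 0`` iff the center is part of the design.
    """

    k: int
    n_positions: int
    include_center: bool = True
    first_train_id: int = 0
    first_test_id: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"factor count k must be >= 1, got {self.k}")
        if self.n_positions < 0:
            raise ValueError(f"n_positions must be >= 0, got {self.n_positions}")
        has_zero_id = min(self.first_train_id, self.first_test_id) == 0
        if self.include_center != has_zero_id:
            raise ValueError(
                "include_center inconsistent with DS/VS: sample 0 exists iff "
                "min(DS, VS) == 0"
            )

    @property
    def n_samples(self) -> int:
        return 2 * self.n_positions + (1 if self.include_center else 0)

    @property
    def designation(self) -> str:
        return format_designation(self)


def parse_designation(text: str) -> DesignSpec:
    """Parse a ``d{k}{DS}v{VS}{N}`` designation string.

    Grammar: literal ``d``, one digit k, one digit DS, literal ``v``,
    one digit VS, remaining digits N.  Examples: ``d20v125`` is a
    two-factor design of 25 samples whose training set starts at sample 0
    and test set at sample 1.
    """
    m = _DESIGNATION_RE.match(text.strip())
    if m is None:
        raise ValueError(
            f"malformed designation {text!r}: expected d<k><DS>v<VS><N> with "
            "single-digit k, DS, VS"
        )
    k, ds, vs, n = (int(g) for g in m.groups())
    if k == 0:
        raise ValueError("designation with k = 0 factors is invalid")
    include_center = n % 2 == 1
    n_positions = n // 2
    spec = DesignSpec(
        k=k,
        n_positions=n_positions,
        include_center=include_center,
        first_train_id=ds,
        first_test_id=vs,
    )
    if spec.n_samples != n:
        raise ValueError(
            f"designation {text!r} inconsistent: N={n} cannot be formed from "
            f"{n_positions} symmetric pairs"
        )
    return spec


def format_designation(spec: DesignSpec) -> str:
    return (
        f"d{spec.k}{spec.first_train_id}v{spec.first_test_id}{spec.n_samples}"
    )


def direction_vectors(k: int) -> np.ndarray:
    """The 2^(k-1) semi-diagonal unit direction vectors of the k-cube.

    Vector ``j`` has first component +1 and component ``i`` (i >= 1) equal
    to -1 iff bit ``i-1`` of ``j`` is set.  For k=3 the order is
    (1,1,1), (1,-1,1), (1,1,-1), (1,-1,-1); each vector together with its
    negation spans one main diagonal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_diag = 2 ** (k - 1)
    v = np.ones((n_diag, k), dtype=int)
    for j in range(n_diag):
        for i in range(1, k):
            if (j >> (i - 1)) & 1:
                v[j, i] = -1
    return v


@dataclass
class DesignScheme:
    """A built diagonal design: integer coordinates plus bookkeeping.

    ``position`` is the spiral position (0 for the center), ``diagonal``
    the direction-vector index (-1 for the center), ``roles`` is
    'train'/'test' per sample.
    """

    spec: DesignSpec
    coords: np.ndarray  # (N, k) int
    ids: np.ndarray  # (N,) int
    roles: np.ndarray  # (N,) object: 'train' | 'test'
    position: np.ndarray  # (N,) int
    diagonal: np.ndarray  # (N,) int

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def to_frame(self, concentrations: np.ndarray | None = None) -> pd.DataFrame:
        data = {
            "id": self.ids,
            "position": self.position,
            "role": self.roles,
        }
        for i in range(self.k):
            data[f"coord_{i + 1}"] = self.coords[:, i]
        if concentrations is not None:
            for i in range(concentrations.shape[1]):
                data[f"conc_{i + 1}"] = concentrations[:, i]
        return pd.DataFrame(data)


def build_scheme(
    spec: DesignSpec, diagonal_sequence: list[int] | None = None
) -> DesignScheme:
    """Build the diagonal scheme by the spiral cross-filling rule.

    Position p (1..L) contributes the centrally symmetric pair
    {+p*v, -p*v} on the direction vector v assigned to p; the default
    sequence cycles through the 2^(k-1) diagonals starting with the
    all-positive one.  The Latin hypercube condition holds by
    construction because position p occupies levels +-p of every factor.
    """
    k, n_pos = spec.k, spec.n_positions
    vecs = direction_vectors(k)
    n_diag = vecs.shape[0]
    if diagonal_sequence is None:
        diagonal_sequence = [(p - 1) % n_diag for p in range(1, n_pos + 1)]
    else:
        diagonal_sequence = list(diagonal_sequence)
        if len(diagonal_sequence) != n_pos:
            raise ValueError(
                f"diagonal_sequence length {len(diagonal_sequence)} != "
                f"n_positions {n_pos}"
            )
        for j in diagonal_sequence:
            if not 0 <= j < n_diag:
                raise ValueError(
                    f"diagonal index {j} out of range [0, {n_diag})"
                )

    rows, ids, positions, diags = [], [], [], []
    if spec.include_center:
        rows.append(np.zeros(k, dtype=int))
        ids.append(0)
        positions.append(0)
        diags.append(-1)
    for p in range(1, n_pos + 1):
        j = diagonal_sequence[p - 1]
        v = vecs[j]
        rows.append(p * v)
        ids.append(2 * p - 1)
        positions.append(p)
        diags.append(j)
        rows.append(-p * v)
        ids.append(2 * p)
        positions.append(p)
        diags.append(j)

    coords = (
        np.array(rows, dtype=int) if rows else np.empty((0, k), dtype=int)
    )
    scheme = DesignScheme(
        spec=spec,
        coords=coords,
        ids=np.array(ids, dtype=int),
        roles=np.array(["train"] * len(ids), dtype=object),
        position=np.array(positions, dtype=int),
        diagonal=np.array(diags, dtype=int),
    )
    return scheme


def select_test_set(
    scheme: DesignScheme,
    start_position: int = 1,
    step: int = 3,
    center_is_test: bool = False,
) -> DesignScheme:
    """Assign train/test roles along the spiral.

    Positions start, start+step, ... are marked test, except the maximal
    position (edge samples on the diagonals are never used for testing).
    Everything else, center included, stays in the training set unless
    ``center_is_test`` marks sample 0 as test (VS = 0 designations).
    The adjacency rule — no two test samples on adjacent levels of any
    factor — is re-verified and a :class:`DesignWarning` is emitted if it
    is violated.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if start_position < 1:
        raise ValueError("start_position must be >= 1")
    n_pos = int(scheme.position.max(initial=0))
    if n_pos == 0 and not center_is_test:
        raise ValueError("scheme has no spiral positions to select from")

    test_positions = {
        p for p in range(start_position, n_pos + 1, step) if p != n_pos
    }
    roles = np.array(
        [
            "test" if p in test_positions else "train"
            for p in scheme.position
        ],
        dtype=object,
    )
    if center_is_test:
        roles[scheme.position == 0] = "test"

    out = replace(scheme, roles=roles)
    _check_adjacency_rule(out)
    return out


def _check_adjacency_rule(scheme: DesignScheme) -> None:
    test = scheme.coords[scheme.roles == "test"]
    for a, b in itertools.combinations(range(test.shape[0]), 2):
        if np.any(np.abs(test[a] - test[b]) == 1):
            warnings.warn(
                "test samples occupy adjacent levels of a factor "
                f"(samples at {test[a]} and {test[b]})",
                DesignWarning,
                stacklevel=3,
            )
            return


def scheme_from_spec(
    spec: DesignSpec, diagonal_sequence: list[int] | None = None
) -> DesignScheme:
    """Build a scheme and assign roles implied by the designation.

    VS = 0 marks the center as a test sample and starts the spiral test
    positions at ``step`` instead of 1 (a test pair at position 1 would sit
    on levels adjacent to the center).
    """
    scheme = build_scheme(spec, diagonal_sequence)
    if spec.n_positions == 0:
        return scheme
    if spec.first_test_id == 0:
        return select_test_set(
            scheme, start_position=3, step=3, center_is_test=True
        )
    start = (spec.first_test_id + 1) // 2
    return select_test_set(scheme, start_position=start, step=3)


@dataclass(frozen=True)
class FactorMapping:
    """Per-factor (low, high) concentration bounds and directions."""

    bounds: tuple[tuple[float, float], ...]
    directions: tuple[str, ...] | None = None  # 'increasing' | 'decreasing'

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"factor bounds must satisfy low < high, got ({lo}, {hi})")
        if self.directions is not None:
            if len(self.directions) != len(self.bounds):
                raise ValueError("directions length must match bounds length")
            for d in self.directions:
                if d not in ("increasing", "decreasing"):
                    raise ValueError(f"unknown direction {d!r}")

    @property
    def k(self) -> int:
        return len(self.bounds)


def to_concentrations(scheme: DesignScheme, mapping: FactorMapping) -> np.ndarray:
    """Affine map of conditional coordinates onto concentration ranges.

    Level -L maps to low and +L to high (reversed for a decreasing
    factor); the center maps to the midpoint.  A center-only design
    (L = 0) maps to midpoints.
    """
    if mapping.k != scheme.k:
        raise ValueError(
            f"mapping has {mapping.k} factors but scheme has {scheme.k}"
        )
    L = scheme.spec.n_positions
    out = np.empty(scheme.coords.shape, dtype=float)
    for i, (lo, hi) in enumerate(mapping.bounds):
        mid = 0.5 * (lo + hi)
        if L == 0:
            out[:, i] = mid
            continue
        frac = scheme.coords[:, i] / (2.0 * L)  # in [-0.5, 0.5]
        vals = mid + frac * (hi - lo)
        if mapping.directions is not None and mapping.directions[i] == "decreasing":
            vals = mid - frac * (hi - lo)
        out[:, i] = vals
    return out


@dataclass
class DesignDiagnostics:
    """Design quality report: never a gatekeeper, always descriptive."""

    latin_hypercube: bool
    pairwise_correlations: np.ndarray  # (k, k)
    coverage: float
    balance: dict[int, int] = field(default_factory=dict)


def _population_correlations(coords: np.ndarray) -> np.ndarray:
    """Pearson correlations of the coordinate columns (divide-by-N).

    Column means are exactly zero for centrally symmetric schemes, so
    r_ij = sum(x_i x_j) / sqrt(sum(x_i^2) sum(x_j^2)).
    """
    k = coords.shape[1]
    x = coords - coords.mean(axis=0)
    gram = x.T @ x
    norms = np.sqrt(np.diag(gram))
    corr = np.eye(k)
    for i in range(k):
        for j in range(k):
            denom = norms[i] * norms[j]
            corr[i, j] = gram[i, j] / denom if denom > 0 else (1.0 if i == j else 0.0)
    return corr


def _coverage(coords: np.ndarray, L: int) -> float:
    if L == 0 or coords.shape[0] == 0:
        return 0.0
    k = coords.shape[1]
    total = float((2 * L) ** k)
    if k == 1:
        return float(coords.max() - coords.min()) / total
    if coords.shape[0] < k + 1:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(coords.astype(float))
    except QhullError:
        return 0.0
    return float(hull.volume) / total


def validate_scheme(scheme: DesignScheme) -> DesignDiagnostics:
    """Compute Latin-hypercube flag, factor correlations, coverage, balance."""
    if scheme.n_samples < 1:
        raise ValueError("cannot validate an empty scheme")
    L = scheme.spec.n_positions
    lh = True
    for i in range(scheme.k):
        col = scheme.coords[:, i]
        expected = set(range(-L, L + 1))
        if not scheme.spec.include_center:
            expected.discard(0)
        values, counts = np.unique(col, return_counts=True)
        if set(values.tolist()) != expected or np.any(counts != 1):
            lh = False
            break
    corr = _population_correlations(scheme.coords)
    cov = _coverage(scheme.coords, L)
    non_center = scheme.diagonal >= 0
    diags, counts = np.unique(scheme.diagonal[non_center], return_counts=True)
    balance = dict(zip(diags.tolist(), counts.tolist()))
    return DesignDiagnostics(
        latin_hypercube=lh,
        pairwise_correlations=corr,
        coverage=cov,
        balance=balance,
    )


def optimize_diagonal_sequence(
    spec: DesignSpec, max_positions: int = 10
) -> list[int]:
    """Exhaustive search for the diagonal sequence minimizing the maximum
    absolute pairwise factor correlation.

    For k <= 3 the filling is invariant to the diagonal order, so the
    default cyclic sequence is returned unchanged.  For k >= 4 all
    permutations of the 2^(k-1) diagonals are tried as cyclic assignment
    orders; ``max_positions`` bounds the instance size for which the
    exhaustive search is attempted.
    """
    n_diag = 2 ** (spec.k - 1)
    default = [(p - 1) % n_diag for p in range(1, spec.n_positions + 1)]
    if spec.k <= 3:
        return default
    if spec.n_positions > max_positions:
        raise ValueError(
            f"search space too large: n_positions={spec.n_positions} exceeds "
            f"bound {max_positions}; use the default cyclic sequence instead"
        )
    if spec.k > 4:
        raise ValueError(
            f"search space too large: {n_diag}! permutations for k={spec.k}; "
            "use the default cyclic sequence instead"
        )
    L = spec.n_positions
    if L == 0:
        return []
    vecs = direction_vectors(spec.k)
    p = np.arange(1, L + 1, dtype=float)
    w = p**2 / np.sum(p**2)
    # pairwise sign products per diagonal, upper triangle of k x k
    iu = np.triu_indices(spec.k, k=1)
    prods = vecs[:, iu[0]] * vecs[:, iu[1]]  # (n_diag, n_pairs)

    best_obj = np.inf
    best_seq = default
    for perm in itertools.permutations(range(n_diag)):
        seq = [perm[(pos - 1) % n_diag] for pos in range(1, L + 1)]
        corr = w @ prods[seq]  # (n_pairs,) weighted correlation of columns
        obj = float(np.max(np.abs(corr)))
        if obj < best_obj - 1e-12 or (
            abs(obj - best_obj) <= 1e-12 and seq < best_seq
        ):
            best_obj = obj
            best_seq = seq
    return best_seq


def write_design(
    scheme: DesignScheme,
    path,
    concentrations: np.ndarray | None = None,
) -> None:
    scheme.to_frame(concentrations).to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "position", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    return df
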