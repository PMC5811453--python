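"""Singular spectrum analysis with a forward-backward trajectory matrix.

The standardized series x_1 ... x_N is lag-embedded at order p (default
p = floor(N/2), the conventional half-length window) into a 2(N-p) x p
matrix that stacks a forward block of reversed lag windows

    row i   (1 <= i <= N-p):  (x_{p+i-1}, x_{p+i-2}, ..., x_i)

on top of a backward block of direct windows

    row N-p+j (1 <= j <= N-p):  (x_{j+1}, x_{j+2}, ..., x_{j+p}).

Stacking both blocks doubles the number of rows relative to a plain Hankel
embedding — the same construction used to stabilize autoregressive
coefficient estimates on short records.  Eigendecomposition of the implied
lag-covariance splits the series into eigentriple components; the cumulative
eigenvalue fraction separates oscillatory signal from the white-noise floor,
consecutive eigentriples are paired (a stationary sinusoid occupies a
near-degenerate eigenvalue pair), and anti-diagonal (Hankel) averaging maps
each grouped matrix back to a length-N additive component of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError
from .preprocess import StandardizedSeries

__all__ = [
    "TrajectoryMatrix",
    "SingularSpectrum",
    "EigentripleGroup",
    "ComponentSeries",
    "build_fb_trajectory",
    "eigendecompose",
    "select_leading",
    "group_eigentriples",
    "diagonal_average",
    "ssa_filter",
]

#: Eigenvalues below this multiple of the largest are treated as exactly zero.
RANK_TOL = 1e-12


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Forward-backward lag embedding of a length-N series at order p."""

    entries: np.ndarray  # shape (2(N-p), p)
    p: int
    N: int

    @property
    def forward_rows(self) -> np.ndarray:
        """Reversed-window block, rows 1 .. N-p."""
        return self.entries[: self.N - self.p]

    @property
    def backward_rows(self) -> np.ndarray:
        """Direct-window block, rows N-p+1 .. 2(N-p)."""
        return self.entries[self.N - self.p :]


@dataclass(frozen=True)
class SingularSpectrum:
    """Eigentriples (lambda_i, U_i, V_i) of a trajectory matrix.

    Eigenvalues are the squared singular values of T, sorted descending;
    only the d eigenvalues above the rank tolerance are kept, so
    T == sum_i U_i sqrt(lambda_i) V_i^T within numerical precision.
    """

    eigenvalues: np.ndarray  # (d,), descending
    left_vectors: np.ndarray  # (2(N-p), d) columns U_i
    right_vectors: np.ndarray  # (p, d) columns V_i
    p: int
    N: int

    @property
    def d(self) -> int:
        return len(self.eigenvalues)

    @cached_property
    def fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @cached_property
    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.fractions)

    def eigentriple_matrix(self, indices: np.ndarray) -> np.ndarray:
        """Sum of rank-1 terms U_i sqrt(lambda_i) V_i^T over 1-based indices."""
        idx = np.asarray(indices, int) - 1
        U = self.left_vectors[:, idx]
        V = self.right_vectors[:, idx]
        s = np.sqrt(self.eigenvalues[idx])
        return (U * s) @ V.T

    def to_table(self) -> np.ndarray:
        """(index, eigenvalue, fraction, cumulative fraction) rows."""
        return np.column_stack(
            [
                np.arange(1, self.d + 1),
                self.eigenvalues,
                self.fractions,
                self.cumulative_fractions,
            ]
        )


@dataclass(frozen=True)
class EigentripleGroup:
    """A pairwise group of eigentriples and its rank-limited matrix Y_I."""

    group_index: int  # 1-based I
    member_indices: tuple[int, ...]  # 1-based eigentriple indices
    spectrum: SingularSpectrum

    @property
    def matrix(self) -> np.ndarray:
        """Y_I = sum over members of U_i sqrt(lambda_i) V_i^T (computed on demand)."""
        return self.spectrum.eigentriple_matrix(np.asarray(self.member_indices))


@dataclass(frozen=True)
class ComponentSeries:
    """One additive, length-N component of the standardized series."""

    values: np.ndarray
    group_index: int
    member_indices: tuple[int, ...] = ()

    @property
    def N(self) -> int:
        return len(self.values)


def build_fb_trajectory(
    s: StandardizedSeries | np.ndarray, p: int | str = "auto"
) -> TrajectoryMatrix:
    """Build the 2(N-p) x p forward-backward trajectory matrix.

    ``p="auto"`` uses the half-length convention p = floor(N/2).
    """
    x = np.asarray(s.values if hasattr(s, "values") else s, dtype=float)
    N = len(x)
    if N < 4:
        raise ParameterError("need N >= 4 to embed")
    if p == "auto":
        p = N // 2
    p = int(p)
    if p < 2 or p > N - 1:
        raise ParameterError(f"embedding order p={p} outside [2, N-1]")
    M = N - p
    fwd = sliding_window_view(x, p)[:M, ::-1]  # row i: x[p+i-1] ... x[i]
    bwd = sliding_window_view(x[1:], p)[:M]  # row j: x[j+1] ... x[j+p]
    return TrajectoryMatrix(entries=np.vstack([fwd, bwd]), p=p, N=N)


def eigendecompose(T: TrajectoryMatrix) -> SingularSpectrum:
    """Eigentriples of T via thin SVD (lambda_i are the squared singular values).

    Equivalent to the eigenvalue decomposition of the covariance C = T T';
    the SVD route yields the same eigentriples from the smaller p-dimensional
    problem in one numerically stable step.
    """
    U, sv, Vt = np.linalg.svd(T.entries, full_matrices=False)
    lam = sv**2
    keep = lam > RANK_TOL * lam[0] if lam[0] > 0 else np.zeros(len(lam), bool)
    return SingularSpectrum(
        eigenvalues=lam[keep],
        left_vectors=U[:, keep],
        right_vectors=Vt[keep].T,
        p=T.p,
        N=T.N,
    )


def select_leading(spec: SingularSpectrum, threshold: float) -> list[int]:
    """Leading eigentriple indices up to the cumulative-fraction threshold.

    Returns the smallest prefix {1..k} whose cumulative eigenvalue fraction
    reaches the threshold (inclusive: the crossing eigenvalue is kept).
    Always returns at least {1}.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    # tiny slack so a cumulative fraction equal to the threshold is inclusive
    k = int(np.searchsorted(spec.cumulative_fractions, threshold - 1e-12)) + 1
    k = min(k, spec.d)
    return list(range(1, k + 1))


def group_eigentriples(
    spec: SingularSpectrum, leading: list[int]
) -> list[EigentripleGroup]:
    """Pair consecutive leading eigentriples into groups (1,2), (3,4), ...

    A stationary sinusoid spans two near-equal eigenvalues, so consecutive
    pairing reassembles whole oscillatory components.  A trailing unpaired
    index forms a singleton group.
    """
    if not leading:
        raise ParameterError("leading index set is empty")
    leading = sorted(int(i) for i in leading)
    if leading[0] < 1 or leading[-1] > spec.d:
        raise ParameterError("leading indices outside 1..d")
    groups = []
    for gi, start in enumerate(range(0, len(leading), 2), start=1):
        members = tuple(leading[start : start + 2])
        groups.append(
            EigentripleGroup(group_index=gi, member_indices=members, spectrum=spec)
        )
    return groups


def _hankel_average(H: np.ndarray) -> np.ndarray:
    """Average an m x q matrix over its anti-diagonals -> length m+q-1 series."""
    m, q = H.shape
    idx = (np.arange(m)[:, None] + np.arange(q)[None, :]).ravel()
    sums = np.bincount(idx, weights=H.ravel(), minlength=m + q - 1)
    counts = np.bincount(idx, minlength=m + q - 1)
    return sums / counts


def _diagonal_average_matrix(Y: np.ndarray, N: int, p: int) -> np.ndarray:
    """Diagonal averaging of a forward-backward component matrix.

    The left-right flip of the forward block is a Hankel embedding of
    positions 0..N-2; the backward block is a Hankel embedding of positions
    1..N-1.  Each block is anti-diagonal averaged and the two estimates are
    averaged elementwise where both exist (the first and last samples are
    covered by a single block).
    """
    M = N - p
    est_fwd = _hankel_average(Y[:M, ::-1])
    est_bwd = _hankel_average(Y[M:])
    out = np.zeros(N)
    wt = np.zeros(N)
    out[: N - 1] += est_fwd
    wt[: N - 1] += 1
    out[1:] += est_bwd
    wt[1:] += 1
    return out / wt


def diagonal_average(g: EigentripleGroup) -> ComponentSeries:
    """Transform a grouped matrix Y_I into a length-N component series."""
    spec = g.spectrum
    values = _diagonal_average_matrix(g.matrix, spec.N, spec.p)
    return ComponentSeries(
        values=values, group_index=g.group_index, member_indices=g.member_indices
    )


def ssa_filter(
    s: StandardizedSeries,
    threshold: float,
    p: int | str = "auto",
    min_pairs: int | None = None,
) -> tuple[ComponentSeries, list[ComponentSeries], SingularSpectrum]:
    """Noise-filter a standardized series by leading-eigentriple reconstruction.

    Composes embedding, eigendecomposition, threshold selection, pairwise
    grouping and diagonal averaging.  Returns the filtered series (sum of
    leading groups), the per-group component series, and the singular
    spectrum.

    ``min_pairs``, if given, enforces that at least that many eigentriple
    pairs survive the threshold — used by the pipeline so that a request for
    m oscillatory components is well-posed even when the signal holds a large
    share of total variance and the threshold alone would keep fewer.
    """
    T = build_fb_trajectory(s, p=p)
    spec = eigendecompose(T)
    leading = select_leading(spec, threshold)
    if min_pairs is not None:
        k = max(len(leading), min(2 * int(min_pairs), spec.d))
        leading = list(range(1, k + 1))
    groups = group_eigentriples(spec, leading)
    components = [diagonal_average(g) for g in groups]
    filtered_values = np.sum([c.values for c in components], axis=0)
    filtered = ComponentSeries(
        values=filtered_values, group_index=0, member_indices=tuple(leading)
    )
    return filtered, components, spec
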