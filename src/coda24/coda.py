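"""Aitchison-simplex machinery for 4-part daily time-use compositions.

A day is treated as a composition: minutes in sleep, sedentary time (SED),
light physical activity (LPA) and moderate-to-vigorous physical activity
(MVPA) carry only relative information, and every analysis operates on
log-ratios. This module provides closure, perturbation, compositional
geometric means, the variation matrix, pivot-coordinate isometric log-ratio
(ILR) transforms and their inverses, and the basis "rotation" that puts each
behaviour first so its part-vs-rest coordinate is directly interpretable.

Conventions
-----------
* Canonical part order is ``("sleep", "sed", "lpa", "mvpa")``.
* The closure constant defaults to 1440 minutes (a full day).
* Pivot coordinate ``k`` (1-based) of a D-part composition taken in pivot
  order :math:`(x_{(1)},\\dots,x_{(D)})` is

  .. math::

     z_k = \\sqrt{\\frac{D-k}{D-k+1}}\\,
           \\ln\\frac{x_{(k)}}{\\left(\\prod_{j>k} x_{(j)}\\right)^{1/(D-k)}}

  so a positive first coordinate means the pivot part is large relative to
  the geometric mean of the remaining parts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_PARTS",
    "Composition",
    "IlrBasis",
    "IlrCoordinates",
    "VariationMatrix",
    "close",
    "perturb",
    "geometric_mean_composition",
    "variation_matrix",
    "ilr_pivot",
    "ilr_inverse",
    "rotate_basis",
    "aitchison_distance",
]

#: Canonical behaviour order used throughout the package.
CANONICAL_PARTS: tuple[str, ...] = ("sleep", "sed", "lpa", "mvpa")

#: Minutes in a 24-hour day; the default closure constant.
FULL_DAY_MINUTES: float = 1440.0

_CLOSE_RTOL = 1e-9


class ZeroPartError(ValueError):
    """A compositional part is zero or negative where strict positivity is required."""


@dataclass(frozen=True)
class Composition:
    """A strictly positive composition closed to ``closure_constant``.

    Parameters
    ----------
    parts:
        Ordered part labels; the order is fixed and only changed through
        :func:`rotate_basis` (which permutes the ILR pivot order, never the
        stored data).
    values:
        Minutes per part. The constructor closes them so they sum to
        ``closure_constant``; ratios are preserved.
    closure_constant:
        Total the values are rescaled to (minutes; default 1440).
    """

    parts: tuple[str, ...]
    values: np.ndarray
    closure_constant: float = FULL_DAY_MINUTES

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != len(self.parts):
            raise ValueError(
                f"expected {len(self.parts)} values, got shape {vals.shape}"
            )
        if len(set(self.parts)) != len(self.parts):
            raise ValueError(f"duplicate part labels: {self.parts}")
        if self.closure_constant <= 0:
            raise ValueError("closure constant must be > 0")
        bad = np.flatnonzero(vals <= 0)
        if bad.size:
            names = ", ".join(self.parts[i] for i in bad)
            raise ZeroPartError(
                f"non-positive value for part(s): {names}; compositional "
                "analysis requires strictly positive parts (apply a "
                "zero-replacement pre-step upstream if appropriate)"
            )
        closed = vals * (self.closure_constant / vals.sum())
        object.__setattr__(self, "parts", tuple(self.parts))
        object.__setattr__(self, "values", closed)
        self.values.setflags(write=False)

    @property
    def proportions(self) -> np.ndarray:
        """Values rescaled to sum to 1."""
        return self.values / self.closure_constant

    @property
    def percentages(self) -> np.ndarray:
        """Percentage share of each part (sums to 100)."""
        return 100.0 * self.proportions

    def __getitem__(self, part: str) -> float:
        try:
            return float(self.values[self.parts.index(part)])
        except ValueError:
            raise KeyError(f"unknown part {part!r}; parts are {self.parts}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.parts, map(float, self.values)))

    def reclose(self, constant: float) -> "Composition":
        """Same composition expressed with a different closure constant."""
        return Composition(self.parts, self.values, constant)


def close(
    values: Sequence[float] | np.ndarray,
    constant: float = FULL_DAY_MINUTES,
    parts: Sequence[str] = CANONICAL_PARTS,
) -> Composition:
    """Close raw part values to ``constant``, preserving their ratios."""
    return Composition(tuple(parts), np.asarray(values, dtype=float), constant)


def _check_same_parts(a: Composition, b: Composition) -> None:
    if a.parts != b.parts:
        raise ValueError(f"part labels differ: {a.parts} vs {b.parts}")


def perturb(x: Composition, p: Composition) -> Composition:
    """Aitchison perturbation ``x ⊕ p``: part-wise product, re-closed."""
    _check_same_parts(x, p)
    return Composition(x.parts, x.values * p.values, x.closure_constant)


def geometric_mean_composition(sample: Iterable[Composition]) -> Composition:
    """Part-wise geometric mean across a sample, closed to the common constant.

    This is the compositional centre: the closed vector of per-part geometric
    means, the natural "average day" of a set of daily compositions.
    """
    sample = list(sample)
    if not sample:
        raise ValueError("cannot take the geometric mean of an empty sample")
    parts = sample[0].parts
    constant = sample[0].closure_constant
    for c in sample[1:]:
        _check_same_parts(sample[0], c)
    logs = np.log([c.values for c in sample])
    return Composition(parts, np.exp(logs.mean(axis=0)), constant)


@dataclass(frozen=True)
class VariationMatrix:
    """Pairwise log-ratio variances between parts.

    Entry (i, j) is the sample variance (n−1 denominator) of
    ``ln(x_i / x_j)`` across the sample. Small entries mean the two parts
    vary together (high co-dependence); the diagonal is exactly zero.
    """

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", e)
        e.setflags(write=False)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.entries[i, j])

    def ordered_pairs(self) -> list[tuple[str, str, float]]:
        """Unordered part pairs sorted by increasing log-ratio variance."""
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                out.append((self.labels[i], self.labels[j], float(self.entries[i, j])))
        return sorted(out, key=lambda t: t[2])


def variation_matrix(sample: Iterable[Composition]) -> VariationMatrix:
    """Compute the variation matrix of a sample of compositions."""
    sample = list(sample)
    if len(sample) < 2:
        raise ValueError("variation matrix needs at least 2 compositions")
    parts = sample[0].parts
    for c in sample[1:]:
        _check_same_parts(sample[0], c)
    logs = np.log([c.values for c in sample])  # (n, D)
    d = logs[:, :, None] - logs[:, None, :]  # ln(x_i/x_j) per sample
    entries = d.var(axis=0, ddof=1)
    entries = 0.5 * (entries + entries.T)
    np.fill_diagonal(entries, 0.0)
    return VariationMatrix(parts, entries)


@dataclass(frozen=True)
class IlrBasis:
    """A pivot ordering of the parts and the orthonormal ILR basis it induces."""

    pivot_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pivot_order", tuple(self.pivot_order))
        if len(set(self.pivot_order)) != len(self.pivot_order):
            raise ValueError(f"pivot order has duplicates: {self.pivot_order}")

    @property
    def D(self) -> int:
        return len(self.pivot_order)

    @property
    def pivot(self) -> str:
        """The part isolated by the first coordinate."""
        return self.pivot_order[0]

    def contrast_matrix(self, parts: Sequence[str]) -> np.ndarray:
        """Orthonormal (D, D−1) contrast matrix V for data stored in ``parts`` order.

        ``z = V.T @ ln(x)`` gives the pivot coordinates and ``V @ z`` the
        centred log-ratio vector, so ``V.T @ V = I`` and rows of V sum to 0
        column-wise.
        """
        parts = tuple(parts)
        if set(parts) != set(self.pivot_order):
            raise ValueError(
                f"basis parts {self.pivot_order} do not match data parts {parts}"
            )
        D = self.D
        V = np.zeros((D, D - 1))
        for k in range(1, D):  # coordinate index, 1-based
            r = D - k  # number of remaining parts
            coef = np.sqrt(r / (r + 1.0))
            V[parts.index(self.pivot_order[k - 1]), k - 1] = coef
            for j in range(k, D):
                V[parts.index(self.pivot_order[j]), k - 1] = -coef / r
        return V


@dataclass(frozen=True)
class IlrCoordinates:
    """D−1 real pivot coordinates together with the basis that produced them."""

    basis: IlrBasis
    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if z.shape[-1] != self.basis.D - 1:
            raise ValueError(
                f"expected {self.basis.D - 1} coordinates, got {z.shape[-1]}"
            )
        object.__setattr__(self, "z", z)
        z.setflags(write=False)


def rotate_basis(parts: Sequence[str], pivot: str) -> IlrBasis:
    """Basis with ``pivot`` first; the other parts keep their canonical order.

    Only the first coordinate (pivot vs geometric mean of the rest) is
    interpreted, so the tail order is a fixed convention chosen for
    reproducibility.
    """
    parts = tuple(parts)
    if pivot not in parts:
        raise ValueError(f"unknown pivot {pivot!r}; parts are {parts}")
    return IlrBasis((pivot,) + tuple(p for p in parts if p != pivot))


def ilr_pivot(x: Composition, basis: IlrBasis | None = None) -> IlrCoordinates:
    """Pivot-coordinate ILR transform of a composition.

    Closure-invariant: raw minutes and the closed composition give identical
    coordinates.
    """
    if basis is None:
        basis = IlrBasis(x.parts)
    V = basis.contrast_matrix(x.parts)
    return IlrCoordinates(basis, V.T @ np.log(x.values))


def ilr_transform(values: np.ndarray, parts: Sequence[str], basis: IlrBasis) -> np.ndarray:
    """Vectorised pivot ILR of an (n, D) array of strictly positive rows."""
    vals = np.asarray(values, dtype=float)
    if np.any(vals <= 0):
        raise ZeroPartError("all parts must be strictly positive")
    V = basis.contrast_matrix(parts)
    return np.log(vals) @ V


def ilr_inverse(
    z: IlrCoordinates | np.ndarray,
    constant: float = FULL_DAY_MINUTES,
    basis: IlrBasis | None = None,
    parts: Sequence[str] | None = None,
) -> Composition:
    """Map pivot coordinates back to a composition closed to ``constant``."""
    if isinstance(z, IlrCoordinates):
        basis = z.basis
        zvec = z.z
    else:
        if basis is None:
            raise ValueError("basis required when z is a bare array")
        zvec = np.asarray(z, dtype=float)
    out_parts = tuple(parts) if parts is not None else basis.pivot_order
    V = basis.contrast_matrix(out_parts)
    with np.errstate(over="raise"):
        vals = np.exp(V @ zvec)
    return Composition(out_parts, vals, constant)


def aitchison_distance(x: Composition, y: Composition) -> float:
    """Aitchison distance: Euclidean distance between ILR images.

    Identical in every orthonormal basis, hence invariant under pivot
    rotation, and translation-invariant under perturbation.
    """
    _check_same_parts(x, y)
    basis = IlrBasis(x.parts)
    zx = ilr_pivot(x, basis).z
    zy = ilr_pivot(y, basis).z
    return float(np.linalg.norm(zx - zy))
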