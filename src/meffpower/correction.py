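"""Eigenvalue-based effective number of tests (MEff) for correlated outcomes.

When an intervention study reports several correlated outcome measures, a
Bonferroni correction (alpha / k) over-penalises: the outcomes do not carry
k independent chances of a false positive.  The MEff statistic summarises
the correlation matrix of the outcomes by the spread of its eigenvalues,

    MEff = 1 + (k - 1) * (1 - Var(eigenvalues) / k),

where Var uses the sample (k - 1) denominator.  MEff runs from k (all
outcomes independent, eigenvalues all 1, variance 0) down to 1 (all
outcomes perfectly correlated, a single eigenvalue k).  Dividing the
nominal familywise alpha by MEff instead of k gives a per-outcome
threshold that adapts to the actual redundancy among the measures.

For an equicorrelated matrix (unit diagonal, common off-diagonal r) the
spectrum is known in closed form — 1 + (k-1)r once and 1 - r with
multiplicity k - 1 — which gives Var = k r^2 and MEff = 1 + (k-1)(1 - r^2).
These closed forms are used as oracles in the test-suite, never as the
computation path: MEff here is always computed from a numeric
eigendecomposition so that arbitrary user-supplied matrices work the same
way as the textbook cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "CorrelationMatrixError",
    "BlockSpec",
    "MeffResult",
    "eigen_variance",
    "meff",
    "alpha_meff",
    "equicorrelated_matrix",
    "block_matrix",
    "mean_offdiag",
    "lookup_table",
    "bonferroni_alpha",
    "sidak_alpha",
    "fwer_independent",
    "round_half_up",
]

#: eigenvalues down to -PSD_TOL are accepted and clipped to zero; anything
#: lower means the input is not a correlation matrix and is rejected.
PSD_TOL = 1e-8
#: maximum |R - R.T| accepted from user-supplied (e.g. CSV) matrices.
SYM_TOL = 1e-6


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Used only for table *presentation*; all computation is full precision.
    Decimal quantisation of the shortest repr avoids binary-float artefacts
    (e.g. 0.0125 -> 0.013, where banker's rounding would give 0.012).  The
    value is first quantised at 10 decimals so that eigensolver noise just
    below an exact tie (0.012499999999999997 for .05/4) does not flip the
    rounding direction.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-10), rounding=ROUND_HALF_UP)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


class CorrelationMatrixError(ValueError):
    """Raised when an input is not a valid correlation matrix."""


class CorrelationMatrix:
    """A validated k x k correlation matrix of outcome measures.

    Validation enforces squareness, symmetry (within ``SYM_TOL``), a unit
    diagonal, off-diagonals in [-1, 1] and positive semi-definiteness
    (eigenvalues >= -``PSD_TOL``, then clipped to zero).  Matrices from real
    data are validated, never repaired: there is no nearest-PSD projection.

    Parameters
    ----------
    values : array-like, shape (k, k)
        The correlation matrix, k >= 2.
    names : sequence of str, optional
        Outcome labels; defaults to ``V1 .. Vk``.
    """

    __slots__ = ("_values", "_names", "_eigenvalues")

    def __init__(self, values, names: Sequence[str] | None = None):
        a = np.asarray(values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise CorrelationMatrixError(
                f"correlation matrix must be square, got shape {a.shape}"
            )
        k = a.shape[0]
        if k < 2:
            raise CorrelationMatrixError(
                "need at least 2 outcome measures (k >= 2); with a single "
                "outcome no multiplicity correction applies"
            )
        if not np.isfinite(a).all():
            raise CorrelationMatrixError("matrix contains non-finite entries")
        asym = np.abs(a - a.T)
        if asym.max() > SYM_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise CorrelationMatrixError(
                f"matrix is not symmetric: entry ({i + 1},{j + 1})={a[i, j]:.6g} "
                f"vs ({j + 1},{i + 1})={a[j, i]:.6g}"
            )
        a = (a + a.T) / 2.0
        d = np.diag(a)
        if np.abs(d - 1.0).max() > 1e-8:
            i = int(np.argmax(np.abs(d - 1.0)))
            raise CorrelationMatrixError(
                f"diagonal entry ({i + 1},{i + 1})={d[i]:.6g} is not 1"
            )
        np.fill_diagonal(a, 1.0)
        off = a[~np.eye(k, dtype=bool)]
        if off.size and np.abs(off).max() > 1.0 + 1e-12:
            raise CorrelationMatrixError("off-diagonal correlations outside [-1, 1]")
        w = np.linalg.eigvalsh(a)
        if w[0] < -PSD_TOL:
            raise CorrelationMatrixError(
                f"matrix is not positive semi-definite (minimum eigenvalue {w[0]:.3g})"
            )
        self._values = a
        self._values.setflags(write=False)
        if names is not None:
            names = [str(n) for n in names]
            if len(names) != k:
                raise CorrelationMatrixError(
                    f"{len(names)} outcome names for a {k}x{k} matrix"
                )
        self._names = names if names is not None else [f"V{i + 1}" for i in range(k)]
        self._eigenvalues = np.sort(np.clip(w, 0.0, None))[::-1]
        self._eigenvalues.setflags(write=False)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def equicorrelated(cls, k: int, r: float) -> "CorrelationMatrix":
        """Unit diagonal, every off-diagonal equal to ``r``.

        PSD requires -1/(k-1) <= r <= 1.
        """
        k = int(k)
        if k < 2:
            raise CorrelationMatrixError("k must be >= 2")
        lo = -1.0 / (k - 1)
        if not (lo - 1e-12 <= r <= 1.0 + 1e-12):
            raise CorrelationMatrixError(
                f"equicorrelated matrix with k={k} requires {lo:.4g} <= r <= 1, got {r}"
            )
        a = np.full((k, k), float(r))
        np.fill_diagonal(a, 1.0)
        return cls(a)

    @classmethod
    def from_blocks(
        cls,
        block_sizes: Iterable[int],
        within_r: float,
        between_r: float = 0.0,
    ) -> "CorrelationMatrix":
        """Block-equicorrelated matrix: ``within_r`` inside each block,
        ``between_r`` (default 0) across blocks."""
        sizes = [int(b) for b in block_sizes]
        if not sizes or any(b < 1 for b in sizes):
            raise CorrelationMatrixError(f"invalid block sizes {sizes}")
        k = sum(sizes)
        if k < 2:
            raise CorrelationMatrixError("blocks must total at least 2 outcomes")
        a = np.full((k, k), float(between_r))
        start = 0
        for b in sizes:
            a[start : start + b, start : start + b] = within_r
            start += b
        np.fill_diagonal(a, 1.0)
        return cls(a)

    @classmethod
    def from_csv(cls, path) -> "CorrelationMatrix":
        """Read a square correlation matrix from CSV.

        Accepts a bare numeric grid or a grid with a header row and/or a
        leading column of outcome names.  Verifies squareness and symmetry
        (within ``SYM_TOL``).
        """
        raw = pd.read_csv(path, header=None, dtype=str)
        names = None
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        if numeric.iloc[0].isna().any():  # header row present
            raw = raw.iloc[1:].reset_index(drop=True)
            numeric = raw.apply(pd.to_numeric, errors="coerce")
        if numeric.shape[1] and numeric.iloc[:, 0].isna().any():  # name column
            names = raw.iloc[:, 0].tolist()
            numeric = numeric.iloc[:, 1:]
        if numeric.isna().any().any():
            col = numeric.columns[numeric.isna().any()][0]
            row = int(numeric[numeric[col].isna()].index[0])
            raise CorrelationMatrixError(
                f"{path}: non-numeric value at data row {row + 1}, column {col + 1}"
            )
        return cls(numeric.to_numpy(dtype=float), names=names)

    def to_csv(self, path, header: bool = True) -> None:
        df = pd.DataFrame(self._values, index=self._names, columns=self._names)
        df.to_csv(path, index=header, header=header)

    # -- views ----------------------------------------------------------------

    @property
    def k(self) -> int:
        """Number of outcome measures."""
        return self._values.shape[0]

    @property
    def values(self) -> np.ndarray:
        """The validated matrix (read-only view)."""
        return self._values

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending; negatives within tolerance clipped to 0."""
        return self._eigenvalues

    @property
    def mean_offdiag(self) -> float:
        """Arithmetic mean of the k(k-1)/2 upper-triangle correlations."""
        iu = np.triu_indices(self.k, 1)
        return float(self._values[iu].mean())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CorrelationMatrix(k={self.k}, mean_offdiag={self.mean_offdiag:.3f})"


@dataclass(frozen=True)
class BlockSpec:
    """Specification of a block-equicorrelated correlation structure:
    ``within_r`` inside each block, ``between_r`` across blocks (0 for two
    independent latent factors)."""

    block_sizes: tuple[int, ...]
    within_r: float
    between_r: float = 0.0

    def build(self) -> CorrelationMatrix:
        return CorrelationMatrix.from_blocks(
            self.block_sizes, self.within_r, self.between_r
        )


def _as_matrix(m) -> CorrelationMatrix:
    return m if isinstance(m, CorrelationMatrix) else CorrelationMatrix(m)


def equicorrelated_matrix(k: int, r: float) -> CorrelationMatrix:
    """See :meth:`CorrelationMatrix.equicorrelated`."""
    return CorrelationMatrix.equicorrelated(k, r)


def block_matrix(spec_or_sizes, within_r: float | None = None, between_r: float = 0.0):
    """Build a block-equicorrelated matrix from a :class:`BlockSpec` or from
    ``(block_sizes, within_r[, between_r])`` directly."""
    if isinstance(spec_or_sizes, BlockSpec):
        return spec_or_sizes.build()
    if within_r is None:
        raise TypeError("within_r is required when block sizes are given directly")
    return CorrelationMatrix.from_blocks(spec_or_sizes, within_r, between_r)


def eigen_variance(m) -> float:
    """Sample variance (denominator k - 1) of the eigenvalues of ``m``.

    The sample denominator is deliberate and load-bearing: the worked
    six-outcome examples (e.g. r = .4 -> Var = 0.96 = 4.8/5) only reproduce
    with ddof=1, and the MEff formula inherits the convention.
    """
    m = _as_matrix(m)
    return float(np.var(m.eigenvalues, ddof=1))


def meff(m) -> float:
    """Effective number of independent tests implied by ``m``.

    ``1 + (k-1) * (1 - Var(eigenvalues)/k)``, always in [1, k].
    """
    m = _as_matrix(m)
    k = m.k
    value = 1.0 + (k - 1) * (1.0 - eigen_variance(m) / k)
    return float(min(max(value, 1.0), float(k)))


def meff_from_eigenvalues(eigenvalues: np.ndarray) -> float:
    """MEff from a precomputed eigenvalue vector (fast path for simulation
    loops; no matrix validation)."""
    ev = np.asarray(eigenvalues, dtype=float)
    k = ev.size
    value = 1.0 + (k - 1) * (1.0 - np.var(ev, ddof=1) / k)
    return float(min(max(value, 1.0), float(k)))


def alpha_meff(m, nominal_alpha: float = 0.05) -> float:
    """Per-outcome alpha after MEff correction: ``nominal_alpha / MEff``."""
    if not 0.0 < nominal_alpha < 1.0:
        raise ValueError(f"nominal_alpha must be in (0, 1), got {nominal_alpha}")
    return nominal_alpha / meff(m)


def mean_offdiag(m) -> float:
    """Mean of the upper-triangle correlations of ``m``."""
    return _as_matrix(m).mean_offdiag


def bonferroni_alpha(k: int, nominal_alpha: float = 0.05) -> float:
    """Bonferroni per-test alpha: ``nominal_alpha / k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return nominal_alpha / k


def sidak_alpha(k: int, nominal_alpha: float = 0.05) -> float:
    """Sidak per-test alpha: ``1 - (1 - nominal_alpha)**(1/k)`` — exact
    familywise control for independent tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - nominal_alpha) ** (1.0 / k)


def fwer_independent(k: int, per_test_alpha: float) -> float:
    """Familywise error rate of k independent tests each run at
    ``per_test_alpha``: ``1 - (1 - alpha)**k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < per_test_alpha < 1.0:
        raise ValueError("per_test_alpha must be in (0, 1)")
    return 1.0 - (1.0 - per_test_alpha) ** k


def lookup_table(
    k_values: Iterable[int] = range(2, 13),
    r_values: Iterable[float] | None = None,
    nominal_alpha: float = 0.05,
    rounded: bool = True,
) -> pd.DataFrame:
    """MEff-adjusted alpha grid for equicorrelated outcome suites.

    Rows are mean inter-outcome correlations (default 0 to 1 in steps of
    .1), columns ``N<k>`` for each suite size (default 2..12).  Values are
    computed analytically from the equicorrelated matrix; with
    ``rounded=True`` they are presented half-up at 3 decimals.
    """
    if r_values is None:
        r_values = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1)
    k_values = [int(k) for k in k_values]
    rows = []
    for r in r_values:
        row: dict[str, float] = {"corr": float(r)}
        for k in k_values:
            a = alpha_meff(equicorrelated_matrix(k, r), nominal_alpha)
            row[f"N{k}"] = round_half_up(a, 3) if rounded else a
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MeffResult:
    """Eigen-summary of a correlation matrix and the adjusted alpha it implies.

    Attributes
    ----------
    eigenvalues : ndarray
        Sorted descending; they sum to k.
    eigen_variance : float
        Sample variance of the eigenvalues.
    meff : float
        Effective number of tests, in [1, k].
    nominal_alpha, alpha_meff : float
        Familywise alpha and the per-outcome threshold nominal_alpha / MEff.
    """

    eigenvalues: np.ndarray
    eigen_variance: float
    meff: float
    nominal_alpha: float
    alpha_meff: float

    @classmethod
    def from_matrix(cls, m, nominal_alpha: float = 0.05) -> "MeffResult":
        m = _as_matrix(m)
        var = eigen_variance(m)
        me = meff(m)
        return cls(
            eigenvalues=m.eigenvalues,
            eigen_variance=var,
            meff=me,
            nominal_alpha=nominal_alpha,
            alpha_meff=nominal_alpha / me,
        )

    @property
    def k(self) -> int:
        return int(self.eigenvalues.size)

    def summary(self) -> str:
        """Single-row report in the style of the worked eigenvalue tables:
        eigenvalues at 1 dp, Var at 2 dp, MEff at 1 dp, AlphaMEff at 3 dp."""
        head = [f"Eigen{i + 1}" for i in range(self.k)] + ["Var", "MEff", "AlphaMEff"]
        vals = (
            [f"{round_half_up(e, 1):.1f}" for e in self.eigenvalues]
            + [f"{round_half_up(self.eigen_variance, 2):.2f}"]
            + [f"{round_half_up(self.meff, 1):.1f}"]
            + [f"{round_half_up(self.alpha_meff, 3):.3f}"]
        )
        widths = [max(len(h), len(v)) for h, v in zip(head, vals)]
        line1 = "  ".join(h.rjust(w) for h, w in zip(head, widths))
        line2 = "  ".join(v.rjust(w) for v, w in zip(vals, widths))
        return line1 + "\n" + line2


def closed_form_equicorrelated_spectrum(k: int, r: float) -> np.ndarray:
    """Analytic spectrum of the equicorrelated matrix: 1+(k-1)r once and
    (1-r) with multiplicity k-1, sorted descending.  Exposed for use as an
    independent oracle."""
    top = 1.0 + (k - 1) * r
    rest = np.full(k - 1, 1.0 - r)
    return np.sort(np.append(rest, top))[::-1]
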