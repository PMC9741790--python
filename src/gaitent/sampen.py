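"""Sample Entropy (Richman–Moorman), with match-count transparency.

SampEn(m, r, N) = -ln[A^{m+1}(r) / B^m(r)], the negative log of the
conditional probability that two length-m subsequences ("templates") that
match within tolerance r (Chebyshev distance, match condition <= r) still
match when extended by one sample. Self-matches are excluded, and both the
m-length and (m+1)-length counts run over the same template index range
i, j in {0 .. N-m-1}, which guarantees A <= B and hence SampEn >= 0. A
perfectly repetitive series gives 0; increasingly irregular series diverge
toward infinity.

Two interchangeable strategies are provided: a vectorized matcher built on
an incremental Chebyshev match chain (used everywhere), and an explicit
pair-loop brute force (:func:`sample_entropy_brute`) kept as the readable
reference; both must produce identical A, B counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from gaitent.errors import LengthError, ParameterError, SignalQualityError, UndefinedEntropyError
from gaitent.preprocess import ProcessedSignal


@dataclass(frozen=True)
class SampEnParams:
    """Template length m, tolerance (absolute r or r_factor x SD), series length N."""

    m: int
    r: float | None = None
    r_factor: float | None = None
    N: int | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ParameterError("m", "template length must be >= 1")
        if (self.r is None) == (self.r_factor is None):
            raise ParameterError("r", "supply exactly one of r / r_factor")
        if self.r is not None and not self.r > 0:
            raise ParameterError("r", "tolerance must be > 0")
        if self.r_factor is not None and not self.r_factor > 0:
            raise ParameterError("r_factor", "tolerance factor must be > 0")


@dataclass
class SampEnResult:
    """SampEn value (nats) with its parameters and raw match counts.

    A is the number of unordered template pairs matching over m+1 samples,
    B over m samples; value = -ln(A/B).
    """

    value: float
    A: int
    B: int
    params: SampEnParams
    effective_r: float


def compute_r(series, r_factor: float = 0.2, cycle_length: int | None = None) -> float:
    """Tolerance r as a multiple of the series' standard deviation.

    Uses the population SD (denominator N) of the full analyzed series.
    ``cycle_length`` switches to the mean of per-cycle population SDs — an
    alternative reading of "average standard deviation" for segmented
    signals — but the per-series SD is the default convention.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise LengthError(2, len(x))
    if not r_factor > 0:
        raise ParameterError("r_factor", "must be > 0")
    if cycle_length is not None:
        if cycle_length < 2 or len(x) % cycle_length:
            raise ParameterError("cycle_length", f"does not divide series length {len(x)}")
        sd = float(x.reshape(-1, cycle_length).std(axis=1).mean())
    else:
        sd = float(x.std())
    if sd == 0.0:
        raise SignalQualityError("constant series: SD = 0 gives a zero tolerance")
    return r_factor * sd


def _resolve(series, params: SampEnParams) -> tuple[np.ndarray, float]:
    x = np.asarray(series, dtype=float).ravel()
    if len(x) <= params.m + 1:
        raise LengthError(params.m + 2, len(x))
    r = params.r if params.r is not None else compute_r(x, params.r_factor)
    return x, r


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered pair counts (A, B) via an incremental Chebyshev match chain.

    M_k[i, j] indicates a k-length template match starting at (i, j); the
    chain M_{k+1} = M_k[:-1, :-1] & D[k:, k:] extends matches one sample at
    a time, so the full O(N^2) distance matrix is scanned once per k.
    """
    counts = _grid_counts(x, r, [m])
    return counts[m]


def _grid_counts(x: np.ndarray, r: float, m_values) -> dict[int, tuple[int, int]]:
    """(A_m, B_m) for every requested m from one match-chain pass."""
    N = len(x)
    m_values = sorted(set(int(m) for m in m_values))
    if not m_values:
        return {}
    if m_values[0] < 1:
        raise ParameterError("m", "template length must be >= 1")
    if N <= m_values[-1] + 1:
        raise LengthError(m_values[-1] + 2, N)
    D = np.abs(x[:, None] - x[None, :]) <= r
    out: dict[int, tuple[int, int]] = {}
    wanted = set(m_values)
    M = D
    # after the k-th iteration M[i, j] == (k+1)-length match starting at (i, j)
    for k in range(1, m_values[-1] + 2):
        if k > 1:
            M = M[:-1, :-1] & D[k - 1 :, k - 1 :]
        if k - 1 in wanted:
            # A_{k-1}: (k)-length matches over templates 0..N-(k-1)-1 = full M
            n_templates = N - (k - 1)
            a = int(M.sum() - n_templates) // 2
            out[k - 1] = (a, out[k - 1][1]) if k - 1 in out else (a, 0)
        if k in wanted:
            # B_k: k-length matches restricted to templates 0..N-k-1
            nb = N - k
            b = int(M[:nb, :nb].sum() - nb) // 2
            out[k] = (out[k][0], b) if k in out else (0, b)
    return out


def sample_entropy(series, params: SampEnParams | None = None, **kwargs) -> SampEnResult:
    """Sample entropy of a 1-D series.

    Accepts a :class:`SampEnParams` or keyword shorthand
    (``m``, and one of ``r`` / ``r_factor``). Raises
    :class:`~gaitent.errors.UndefinedEntropyError` when no template pair
    matches at length m (B = 0) or none extends to m+1 (A = 0): the
    conditional probability has no finite value and no ceiling is
    substituted.
    """
    if params is None:
        params = SampEnParams(**kwargs)
    x, r = _resolve(series, params)
    A, B = _match_counts(x, params.m, r)
    if B == 0:
        raise UndefinedEntropyError("no_m_matches", params.m)
    if A == 0:
        raise UndefinedEntropyError("no_m_plus_1_matches", params.m)
    return SampEnResult(
        value=abs(-math.log(A / B)),
        A=A,
        B=B,
        params=SampEnParams(m=params.m, r=params.r, r_factor=params.r_factor, N=len(x)),
        effective_r=r,
    )


def sample_entropy_brute(series, m: int, r: float) -> SampEnResult:
    """Reference SampEn by explicit enumeration of all template pairs.

    O(N^2 m); intended for small inputs and as the ground truth the
    vectorized matcher is checked against.
    """
    x = np.asarray(series, dtype=float).ravel()
    if not r > 0:
        raise ParameterError("r", "tolerance must be > 0")
    N = len(x)
    if N <= m + 1:
        raise LengthError(m + 2, N)
    A = B = 0
    for i in range(N - m):
        for j in range(i + 1, N - m):
            if float(np.max(np.abs(x[i : i + m] - x[j : j + m]))) <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    if B == 0:
        raise UndefinedEntropyError("no_m_matches", m)
    if A == 0:
        raise UndefinedEntropyError("no_m_plus_1_matches", m)
    return SampEnResult(
        value=abs(-math.log(A / B)),
        A=A,
        B=B,
        params=SampEnParams(m=m, r=r, N=N),
        effective_r=r,
    )


@dataclass
class GridCell:
    """One (m, r_factor) cell of a SampEn grid; ``result`` is None when
    entropy is undefined there, with the failure mode in ``reason``."""

    m: int
    r_factor: float
    result: SampEnResult | None
    reason: str | None = None


def sampen_grid(signal, m_list, r_factor_list=(0.2,)) -> list[GridCell]:
    """SampEn over a grid of template lengths and tolerance factors.

    ``signal`` may be a :class:`~gaitent.preprocess.ProcessedSignal` or a
    bare array. The effective tolerance is recomputed per (signal, r_factor)
    from the full series' SD — not per cycle. Undefined cells (A = 0 or
    B = 0) are reported as missing with a reason code rather than failing
    the whole grid.
    """
    x = signal.values if isinstance(signal, ProcessedSignal) else np.asarray(signal, dtype=float)
    m_list = [int(m) for m in m_list]
    cells: list[GridCell] = []
    if not m_list:
        return cells
    for rf in r_factor_list:
        try:
            r = compute_r(x, rf)
        except SignalQualityError:
            for m in m_list:
                cells.append(GridCell(m=m, r_factor=rf, result=None, reason="zero_tolerance"))
            continue
        counts = _grid_counts(x, r, m_list)
        for m in m_list:
            A, B = counts[m]
            if B == 0:
                cells.append(GridCell(m=m, r_factor=rf, result=None, reason="no_m_matches"))
            elif A == 0:
                cells.append(GridCell(m=m, r_factor=rf, result=None, reason="no_m_plus_1_matches"))
            else:
                res = SampEnResult(
                    value=abs(-math.log(A / B)),
                    A=A,
                    B=B,
                    params=SampEnParams(m=m, r_factor=rf, N=len(x)),
                    effective_r=r,
                )
                cells.append(GridCell(m=m, r_factor=rf, result=res))
    return cells
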