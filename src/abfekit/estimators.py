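"""Free-energy estimators operating on per-window sample tables.

The multistate Bennett acceptance ratio (MBAR) solves for the dimensionless
per-window free energies f_k satisfying

    f_k = -ln Σ_n exp(-u_kn) / Σ_j N_j exp(f_j - u_jn),

where u_kn is the reduced potential (energy/RT) of sample n evaluated in
window k. BAR is the two-window special case. Thermodynamic integration with
Gaussian quadrature (TI-GQ) combines per-node means of ∂U/∂λ with the
n-point Gauss-Legendre weights mapped to [0, 1]:

    ΔG = Σ_i w_i <∂U/∂λ>_i.

Where an engine cannot expose ∂U/∂λ directly, a finite-difference estimate
divides the BAR free-energy difference between two windows at λ ± δλ/2 by δλ
(default δλ = 0.001). Uncertainties come from block data analysis: the
estimator is recomputed on contiguous equal blocks and the spread of block
estimates is scaled by 1/√n_blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import T_DEFAULT, rt
from .structio import logger


class ConvergenceError(RuntimeError):
    """MBAR self-consistent iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaSchedule:
    """Window schedule: explicit λ list or Gauss-Legendre nodes/weights."""

    mode: str                      # "explicit" | "gauss_quadrature"
    lambdas: tuple[float, ...]
    weights: tuple[float, ...] | None = None
    n: int = 0

    def __post_init__(self):
        if self.mode not in ("explicit", "gauss_quadrature"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        lams = np.asarray(self.lambdas, dtype=float)
        if lams.size == 0 or np.any(lams < 0) or np.any(lams > 1):
            raise ValueError("lambdas must be a non-empty subset of [0, 1]")
        object.__setattr__(self, "lambdas", tuple(float(x) for x in lams))
        if self.n == 0:
            object.__setattr__(self, "n", lams.size)
        if self.n != lams.size:
            raise ValueError("n must equal the number of lambda values")
        if self.mode == "gauss_quadrature":
            if self.weights is None:
                raise ValueError("quadrature mode requires weights")
            w = np.asarray(self.weights, dtype=float)
            if w.size != lams.size:
                raise ValueError("one weight per lambda node required")
            if abs(w.sum() - 1.0) > 1e-10:
                raise ValueError(f"quadrature weights must sum to 1, got {w.sum()}")
            if np.any(np.diff(lams) <= 0):
                raise ValueError("quadrature nodes must be strictly increasing")
            object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def to_dict(self) -> dict:
        return {"mode": self.mode, "lambdas": list(self.lambdas),
                "weights": list(self.weights) if self.weights else None, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "LambdaSchedule":
        w = d.get("weights")
        return cls(mode=d["mode"], lambdas=tuple(d["lambdas"]),
                   weights=tuple(w) if w else None, n=d.get("n", 0))


def gq_schedule(n: int) -> LambdaSchedule:
    """n-point Gauss-Legendre schedule mapped from [-1, 1] to [0, 1].

    The node/weight set is unique for each n; weights sum to 1 and the rule
    integrates polynomials of degree <= 2n-1 exactly.
    """
    if not 1 <= n <= 64:
        raise ValueError(f"window count n must be in [1, 64], got {n}")
    nodes, weights = np.polynomial.legendre.leggauss(n)
    return LambdaSchedule(mode="gauss_quadrature",
                          lambdas=tuple((nodes + 1.0) / 2.0),
                          weights=tuple(weights / 2.0), n=n)


# ---------------------------------------------------------------------------
# Window energy tables
# ---------------------------------------------------------------------------

@dataclass
class WindowEnergyTable:
    """Per-window samples of reduced potentials (and optionally ∂U/∂λ).

    ``u_kn`` has shape (K, N_total): every sample evaluated in every window,
    samples concatenated in origin-window order with counts ``N_k``.
    ``dudl_k`` holds per-window ∂U/∂λ samples in kcal/mol when available.
    """

    u_kn: np.ndarray
    N_k: np.ndarray
    schedule: LambdaSchedule | None = None
    dudl_k: list[np.ndarray] | None = None
    temperature: float = T_DEFAULT

    def __post_init__(self):
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.N_k = np.asarray(self.N_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be 2-D (K windows x N_total samples)")
        if self.N_k.ndim != 1 or self.N_k.size != self.u_kn.shape[0]:
            raise ValueError("N_k must have one entry per window")
        if np.any(self.N_k < 1):
            raise ValueError("every window needs at least one sample")
        if self.N_k.sum() != self.u_kn.shape[1]:
            raise ValueError("sum(N_k) must equal the number of sample columns")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn contains non-finite entries")
        if self.dudl_k is not None:
            if len(self.dudl_k) != self.K:
                raise ValueError("dudl_k must have one sample array per window")
            self.dudl_k = [np.asarray(a, dtype=float) for a in self.dudl_k]

    @property
    def K(self) -> int:
        return self.u_kn.shape[0]

    @property
    def n_total(self) -> int:
        return self.u_kn.shape[1]

    def origin_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.N_k)])
        return [slice(int(edges[k]), int(edges[k + 1])) for k in range(self.K)]

    def window_pair(self, i: int, j: int) -> "WindowEnergyTable":
        """Sub-table restricted to windows i and j (their own samples only)."""
        sl = self.origin_slices()
        cols = np.r_[np.arange(sl[i].start, sl[i].stop), np.arange(sl[j].start, sl[j].stop)]
        return WindowEnergyTable(
            u_kn=self.u_kn[np.ix_([i, j], cols)],
            N_k=np.array([self.N_k[i], self.N_k[j]]),
            temperature=self.temperature,
        )

    def dudl_means(self) -> np.ndarray:
        if self.dudl_k is None:
            raise ValueError("table carries no ∂U/∂λ samples")
        return np.array([a.mean() for a in self.dudl_k])


def write_table(table: WindowEnergyTable, path: str | Path) -> None:
    """Tidy delimited text: one row per (sample, evaluation window) pair.

    Columns: origin window index, evaluated-in-window index, reduced
    potential. Metadata (N_k, temperature, schedule, ∂U/∂λ samples) is kept
    in '#' header lines so the table round-trips.
    """
    path = Path(path)
    origin = np.repeat(np.arange(table.K), table.N_k)
    rows = []
    for k in range(table.K):
        for n in range(table.n_total):
            rows.append((int(origin[n]), k, table.u_kn[k, n]))
    header = [
        "# abfekit window energy table",
        f"# temperature= {table.temperature!r}",
        f"# N_k= {json.dumps(table.N_k.tolist())}",
        f"# schedule= {json.dumps(table.schedule.to_dict()) if table.schedule else 'null'}",
        f"# dudl_k= {json.dumps([a.tolist() for a in table.dudl_k]) if table.dudl_k is not None else 'null'}",
        "origin\teval\tu_reduced",
    ]
    body = "\n".join(f"{o}\t{k}\t{u:.12g}" for o, k, u in rows)
    path.write_text("\n".join(header) + "\n" + body + "\n")


def read_table(path: str | Path) -> WindowEnergyTable:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    N_k = np.asarray(json.loads(meta["N_k"]), dtype=int)
    temperature = float(meta.get("temperature", T_DEFAULT))
    schedule_d = json.loads(meta.get("schedule", "null"))
    dudl_d = json.loads(meta.get("dudl_k", "null"))
    df = pd.read_csv(path, sep="\t", comment="#")
    K, n_total = N_k.size, int(N_k.sum())
    u_kn = np.empty((K, n_total))
    sample_pos = df.groupby("eval", sort=True).cumcount()
    for k, group in df.groupby("eval", sort=True):
        u_kn[k, sample_pos[group.index]] = group["u_reduced"].to_numpy()
    return WindowEnergyTable(
        u_kn=u_kn, N_k=N_k,
        schedule=LambdaSchedule.from_dict(schedule_d) if schedule_d else None,
        dudl_k=[np.asarray(a) for a in dudl_d] if dudl_d else None,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# Free-energy estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with its block-analysis uncertainty."""

    value: float                  # kcal/mol
    uncertainty: float            # kcal/mol
    method: str                   # "MBAR" | "BAR" | "TI-GQ" | "analytical"
    blocks: int = 0

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be nonnegative")
        if self.method not in ("MBAR", "BAR", "TI-GQ", "analytical"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class MBARResult:
    """Converged MBAR free energies (f_1 fixed at 0)."""

    f: np.ndarray                  # dimensionless, f[0] = 0
    temperature: float
    n_iterations: int
    residual: float
    N_k: np.ndarray = field(repr=False, default=None)

    @property
    def free_energies(self) -> np.ndarray:
        """Per-window free energies in kcal/mol (first window = 0)."""
        return self.f * rt(self.temperature)

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        """Dimensionless f_j - f_i."""
        return float(self.f[j] - self.f[i])

    def delta_g(self, i: int = 0, j: int = -1) -> float:
        """Free-energy difference i -> j in kcal/mol."""
        return self.delta_f(i, j) * rt(self.temperature)

    def pairwise_dg(self) -> np.ndarray:
        g = self.free_energies
        return g[None, :] - g[:, None]


def _mbar_log_denom(u_kn: np.ndarray, f: np.ndarray, log_N: np.ndarray) -> np.ndarray:
    return logsumexp(log_N[:, None] + f[:, None] - u_kn, axis=0)


def _mbar_gradient_hessian(u_kn, N_k, f, log_N):
    log_denom = _mbar_log_denom(u_kn, f, log_N)
    # c[k, n] = N_k exp(f_k - u_kn) / D_n
    log_c = log_N[:, None] + f[:, None] - u_kn - log_denom[None, :]
    c = np.exp(log_c)
    grad = c.sum(axis=1) - N_k
    hess = np.diag(c.sum(axis=1)) - c @ c.T
    return grad, hess, log_denom


def mbar(table: WindowEnergyTable, tol: float = 1e-8, max_iter: int = 10000) -> MBARResult:
    """Solve the MBAR self-consistent equations.

    Starts from f = 0 with self-consistent iteration and switches to Newton
    steps once the iterate is close; falls back to self-consistent updates if
    a Newton step does not reduce the residual. Convergence is max |Δf| < tol
    in dimensionless units. Distribution overlap is checked and warned about,
    never fatal.
    """
    u_kn, N_k = table.u_kn, table.N_k
    K = table.K
    log_N = np.log(N_k)
    f = np.zeros(K)
    residual = np.inf
    newton_phase = False
    for iteration in range(1, max_iter + 1):
        if newton_phase:
            grad, hess, _ = _mbar_gradient_hessian(u_kn, N_k, f, log_N)
            try:
                step = np.zeros(K)
                step[1:] = np.linalg.solve(hess[1:, 1:], -grad[1:])
                f_new = f + step
            except np.linalg.LinAlgError:
                newton_phase = False
                continue
            f_new -= f_new[0]
            residual_new = float(np.max(np.abs(f_new - f)))
            if not np.all(np.isfinite(f_new)) or residual_new > residual * 10:
                newton_phase = False
                continue
        else:
            log_denom = _mbar_log_denom(u_kn, f, log_N)
            f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
            f_new -= f_new[0]
            residual_new = float(np.max(np.abs(f_new - f)))
        f, residual = f_new, residual_new
        if residual < tol:
            break
        if not newton_phase and residual < 1.0 and iteration >= 5:
            newton_phase = True
    else:
        raise ConvergenceError(
            f"MBAR did not converge in {max_iter} iterations (residual {residual:.3e})",
            residual,
        )

    # Overlap diagnostic: O[i, j] = sum_n N_i W_ni W_nj with W_nk = exp(f_k - u_kn)/D_n.
    log_denom = _mbar_log_denom(u_kn, f, log_N)
    W = np.exp(f[:, None] - u_kn - log_denom[None, :])
    overlap = (N_k[:, None] * W) @ W.T
    adjacent = np.diagonal(overlap, offset=1)
    if adjacent.size and adjacent.min() < 0.01:
        logger.warning("poor overlap between adjacent windows (min %.2e); "
                       "MBAR estimates may be unreliable", float(adjacent.min()))
    return MBARResult(f=f, temperature=table.temperature,
                      n_iterations=iteration, residual=residual, N_k=N_k.copy())


def bar(table: WindowEnergyTable, tol: float = 1e-8, max_iter: int = 10000) -> float:
    """Two-window Bennett acceptance ratio, ΔG(0→1) in kcal/mol.

    Implemented as the two-state case of MBAR, to which BAR is equivalent.
    """
    if table.K != 2:
        raise ValueError(f"BAR requires exactly two windows, got {table.K}")
    return mbar(table, tol=tol, max_iter=max_iter).delta_g(0, 1)


def ti_gq(dudl_means: Sequence[float], schedule: LambdaSchedule) -> float:
    """TI with Gaussian quadrature: ΔG = Σ_i w_i <∂U/∂λ>_i (kcal/mol)."""
    if schedule.mode != "gauss_quadrature":
        raise ValueError("ti_gq requires a gauss_quadrature schedule")
    means = np.asarray(dudl_means, dtype=float)
    if means.size != schedule.n:
        raise ValueError(f"expected {schedule.n} node means, got {means.size}")
    return float(np.dot(schedule.weights, means))


def fd_dudl(
    sampler: Callable[[float, float], WindowEnergyTable],
    lambda_i: float,
    delta_lambda: float = 0.001,
) -> float:
    """Finite-difference <∂U/∂λ> at λ_i via BAR over a δλ bracket.

    ``sampler(lo, hi)`` must return a two-window table sampled at
    λ_i - δλ/2 and λ_i + δλ/2; the estimate is δG_BAR / δλ in kcal/mol.
    """
    if delta_lambda <= 0:
        raise ValueError("delta_lambda must be positive")
    table = sampler(lambda_i - delta_lambda / 2.0, lambda_i + delta_lambda / 2.0)
    return bar(table) / delta_lambda


# ---------------------------------------------------------------------------
# Uncertainties and replica statistics
# ---------------------------------------------------------------------------

def block_uncertainty(
    series: Sequence[float],
    n_blocks: int,
    estimator: Callable[[np.ndarray], float] | None = None,
) -> float:
    """Block-data-analysis uncertainty of an estimator over a sample series.

    The series is split into ``n_blocks`` contiguous equal blocks (remainder
    dropped from the front), the estimator is recomputed per block, and the
    uncertainty is std(block estimates) / sqrt(n_blocks).
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if series.size < n_blocks:
        raise ValueError(f"series of length {series.size} cannot form {n_blocks} blocks")
    est = estimator if estimator is not None else np.mean
    block_len = series.size // n_blocks
    trimmed = series[series.size - n_blocks * block_len:]
    estimates = np.array([est(trimmed[b * block_len:(b + 1) * block_len])
                          for b in range(n_blocks)])
    return float(np.std(estimates, ddof=1) / np.sqrt(n_blocks))


def mbar_block_uncertainty(
    table: WindowEnergyTable,
    n_blocks: int,
    i: int = 0,
    j: int = -1,
) -> float:
    """Block uncertainty of the MBAR ΔG(i→j): MBAR recomputed per block.

    Each window's sample series is cut into ``n_blocks`` contiguous blocks
    (remainder dropped from the front of each window).
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if np.any(table.N_k < n_blocks):
        raise ValueError("every window needs at least n_blocks samples")
    slices = table.origin_slices()
    estimates = []
    for b in range(n_blocks):
        cols = []
        counts = []
        for k, sl in enumerate(slices):
            block_len = table.N_k[k] // n_blocks
            start = sl.stop - (n_blocks - b) * block_len
            cols.append(np.arange(start, start + block_len))
            counts.append(block_len)
        cols = np.concatenate(cols)
        sub = WindowEnergyTable(u_kn=table.u_kn[:, cols], N_k=np.asarray(counts),
                                temperature=table.temperature)
        estimates.append(mbar(sub).delta_g(i, j))
    return float(np.std(estimates, ddof=1) / np.sqrt(n_blocks))


@dataclass(frozen=True)
class ReplicaStats:
    """Mean and across-replica spread of repeated free-energy calculations."""

    mean: float
    spread: float  # population standard deviation (divisor n)
    n: int


def replica_stats(values: Sequence[float]) -> ReplicaStats:
    """Arithmetic mean and population SD across independent replicas.

    The population convention (divisor n) is the one used when quoting the
    across-replica spread of repeated binding free-energy calculations.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("replica statistics need at least 2 replicas")
    return ReplicaStats(mean=float(values.mean()),
                        spread=float(np.std(values, ddof=0)),
                        n=int(values.size))
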