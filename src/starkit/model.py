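r"""Kinetic model of a single cleavable regulatory-RNA-array transcription unit.

The unit transcribes a polycistronic array transcript ``A`` at rate ``u``.
Endonucleolytic cleavage (rate ``k_c``) releases ``eps * n`` free activator
RNAs per processed transcript into the pool ``S`` (``n`` activator copies
encoded on the array, ``eps`` the per-copy release efficiency).  The free
activator pool gates transcription of the target-controlled output RNA ``G``
through a saturating occupancy term ``theta(S) = S / (K + S)``, with an
off-state leak fraction ``lam``:

.. math::

    A' &= u - (k_c + d_A) A \\
    S' &= eps \cdot n \cdot k_c \cdot A - d_S S \\
    G' &= a_T (lam + (1 - lam)\,\theta(S)) - d_G G

All concentrations and rates are in arbitrary units.  The fixed point is
available in closed form and is used throughout as the reference the ODE
route is checked against:

.. math::

    A^* = u / (k_c + d_A),\quad
    S^* = eps\,n\,k_c A^* / d_S,\quad
    G^* = (a_T / d_G)(lam + (1 - lam)\,\theta(S^*))
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ParameterError

__all__ = [
    "ModelParams",
    "SteadyState",
    "Trajectory",
    "GainTable",
    "DEFAULT_PARAMS",
    "steady_state",
    "simulate_timecourse",
    "input_output_curve",
    "gain_vs_copies",
]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of one array transcription unit.

    Parameters
    ----------
    u : float
        Transcription input rate into the array (a.u./time).
    k_c : float
        Cleavage/processing rate of the array transcript (1/time).
    d_A, d_S, d_G : float
        First-order degradation rates of the array transcript, the free
        activator pool and the output RNA (1/time).  Must be positive.
    eps : float
        Per-copy release efficiency of cleavage, in [0, 1].
    n : float
        Activator copy number encoded on the array.  Integer in interfaces;
        the mathematics accepts real values.
    a_T : float
        Maximal transcription rate of the target-controlled output (a.u./time).
    K : float
        Half-activation level of the free activator pool (a.u.).
    lam : float
        Off-state leak fraction, in [0, 1].
    """

    u: float = 0.5
    k_c: float = 1.0
    d_A: float = 0.1
    d_S: float = 1.0
    d_G: float = 1.0
    eps: float = 0.9
    n: float = 1
    a_T: float = 1.0
    K: float = 10.0
    lam: float = 0.02

    def __post_init__(self):
        for name in ("u", "k_c", "a_T"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(name, f"must be a finite non-negative rate, got {v!r}")
        for name in ("d_A", "d_S", "d_G"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(name, f"degradation rate must be > 0, got {v!r}")
        if not (0.0 <= self.eps <= 1.0):
            raise ParameterError("eps", f"release efficiency must be in [0, 1], got {self.eps!r}")
        if not (0.0 <= self.lam <= 1.0):
            raise ParameterError("lam", f"leak fraction must be in [0, 1], got {self.lam!r}")
        if not (np.isfinite(self.K) and self.K > 0):
            raise ParameterError("K", f"half-activation level must be > 0, got {self.K!r}")
        if not np.isfinite(self.n) or self.n < 0:
            raise ParameterError("n", f"copy number must be >= 0, got {self.n!r}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ParameterError(sorted(extra)[0], "unknown parameter field")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a JSON or YAML file keyed by field name."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError("file", f"{path} does not contain a parameter mapping")
        return cls.from_dict(data)


#: Default parameter estimates (arbitrary units, not fitted values).
DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class SteadyState:
    """Closed-form fixed point of the unit."""

    A_star: float
    S_star: float
    G_star: float
    theta: float


@dataclass(frozen=True)
class Trajectory:
    """Time course of the three species on an increasing time grid."""

    times: np.ndarray
    A: np.ndarray
    S: np.ndarray
    G: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "A": self.A, "S": self.S, "G": self.G})

    @property
    def final(self) -> tuple[float, float, float]:
        return float(self.A[-1]), float(self.S[-1]), float(self.G[-1])


def activation_fraction(S, K) -> float:
    """Occupancy term ``theta(S) = S / (K + S)``."""
    return S / (K + S)


def steady_state(params: ModelParams) -> SteadyState:
    """Closed-form steady state of the unit.

    ``G_star`` is strictly increasing in ``u``, ``n`` and ``eps`` whenever
    ``lam < 1``, and bounded above by ``a_T / d_G``.
    """
    A = params.u / (params.k_c + params.d_A)
    S = params.eps * params.n * params.k_c * A / params.d_S
    theta = activation_fraction(S, params.K)
    G = (params.a_T / params.d_G) * (params.lam + (1.0 - params.lam) * theta)
    return SteadyState(A_star=A, S_star=S, G_star=G, theta=theta)


def _rhs(t, y, p: ModelParams):
    A, S, G = y
    theta = activation_fraction(max(S, 0.0), p.K)
    return (
        p.u - (p.k_c + p.d_A) * A,
        p.eps * p.n * p.k_c * A - p.d_S * S,
        p.a_T * (p.lam + (1.0 - p.lam) * theta) - p.d_G * G,
    )


def simulate_timecourse(
    params: ModelParams,
    t_end: float,
    initial: Sequence[float] | None = None,
    n_points: int = 201,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the unit ODEs from ``initial`` (default all-zero) to ``t_end``.

    Uses a stiff-safe adaptive integrator; small negative excursions from the
    absolute tolerance are clipped to zero in the returned trajectory.
    """
    if not (np.isfinite(t_end) and t_end > 0):
        raise ParameterError("t_end", f"must be a positive finite time, got {t_end!r}")
    y0 = np.zeros(3) if initial is None else np.asarray(initial, dtype=float)
    if y0.shape != (3,) or not np.all(np.isfinite(y0)) or np.any(y0 < 0):
        raise ParameterError("initial", f"must be 3 finite non-negative concentrations, got {initial!r}")
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        _rhs, (0.0, t_end), y0, t_eval=times, args=(params,), method=method, rtol=rtol, atol=atol
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"integration failed: {sol.message} (params={params.to_dict()}, t_end={t_end})"
        )
    y = np.clip(sol.y, 0.0, None)
    return Trajectory(times=sol.t, A=y[0], S=y[1], G=y[2])


def input_output_curve(
    params: ModelParams, u_grid: Iterable[float], n_list: Iterable[float]
) -> pd.DataFrame:
    """Steady-state output over a grid of inputs and copy numbers.

    Returns a long-format frame with columns ``u``, ``n``, ``G_star``.  Each
    constant-``n`` curve is monotone non-decreasing in ``u``, ordered
    pointwise by ``n``, and bounded above by ``a_T / d_G``.
    """
    u_grid = list(u_grid)
    if len(u_grid) == 0:
        raise ParameterError("u_grid", "must be non-empty")
    rows = []
    for n in n_list:
        for u in u_grid:
            p = params.replace(u=u, n=n)  # re-validates; negative u raises here
            rows.append({"u": u, "n": n, "G_star": steady_state(p).G_star})
    return pd.DataFrame(rows, columns=["u", "n", "G_star"])


@dataclass(frozen=True)
class GainTable:
    """Copy-number response at fixed input, with its straight-line summary."""

    copies: np.ndarray
    G_star: np.ndarray
    slope: float
    intercept: float
    r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.copies, "G_star": self.G_star})


def gain_vs_copies(params: ModelParams, copies: Sequence[float], u: float | None = None) -> GainTable:
    """Tabulate ``G_star`` against copy number and fit a straight line.

    In the sub-saturating regime (``S*(n_max) <= 0.1 K``) the relation is
    near-exactly linear: Pearson r > 0.999.  Lowering ``eps`` lowers the
    slope without degrading linearity.
    """
    copies = np.asarray(list(copies), dtype=float)
    if copies.size < 3:
        raise ParameterError("copies", "need at least 3 copy levels for a correlation")
    if np.unique(copies).size != copies.size:
        raise ParameterError("copies", "copy levels must be distinct")
    if np.any(copies < 1):
        raise ParameterError("copies", "copy levels must be >= 1")
    if u is None:
        u = params.u
    g = np.array([steady_state(params.replace(n=n, u=u)).G_star for n in copies])
    fit = stats.linregress(copies, g)
    return GainTable(copies=copies, G_star=g, slope=float(fit.slope),
                     intercept=float(fit.intercept), r=float(fit.rvalue))
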