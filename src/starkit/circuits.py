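"""Composition of array transcription units into circuits.

Three topologies are provided: an inducible array amplifier (one array unit
with its own reporter), an activation-activation cascade in which an array
amplifies the signal between two transcription nodes, and a 1-to-2 multiplex
motif in which one array carries copies of two orthogonal activator variants
weighting two reporters independently.

Coupling rule: a unit driven by another unit receives, as its transcription
input, the driver's activated transcription rate
``a_T * (lam + (1 - lam) * theta(S_driver))`` scaled by the receiving unit's
plasmid copy-number multiplier.  A unit's multiplier also scales its own
``a_T``.  There is no resource competition between branches: multiplex
outputs are weighted only by copy numbers on the shared transcript.

Steady states are evaluated in topological order through the per-unit closed
forms; :func:`simulate_circuit` can also integrate the joint ODE of every
species in the circuit, which is used as an independent cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import CircuitError, IntegrationError, ParameterError
from .model import DEFAULT_PARAMS, ModelParams, activation_fraction

__all__ = [
    "INSULATOR_EPS",
    "STAR_VARIANTS",
    "ArraySpec",
    "ConstantDriver",
    "InducibleDriver",
    "UnitDriver",
    "ArrayUnit",
    "ReporterUnit",
    "Circuit",
    "CircuitOutput",
    "build_amplifier",
    "build_cascade",
    "build_multiplex",
    "simulate_circuit",
    "fold_activation_sim",
    "random_circuit",
]

#: Release efficiency attributed to each insulator.  shcsy4hp folds robustly;
#: PlmJ performs poorly in tandem context.  Editable estimates, not fits.
INSULATOR_EPS: dict[str, float] = {"PlmJ": 0.15, "csy4hp": 0.75, "shcsy4hp": 0.9}

#: Known activator variants and the reporter each one targets by default.
STAR_VARIANTS: dict[str, str] = {"STAR10": "GFP", "STAR50": "RFP"}

MAX_TESTED_COPIES = 8


@dataclass(frozen=True)
class ArraySpec:
    """Composition of one array transcript.

    ``blocks`` is an ordered list of ``(variant id, copy count)`` pairs;
    ``insulator`` selects the cleavage element between copies and sets the
    default release efficiency ``eps``.
    """

    blocks: tuple[tuple[str, int], ...]
    insulator: str = "shcsy4hp"
    eps: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple((str(v), int(c)) for v, c in self.blocks))
        if not self.blocks:
            raise ParameterError("blocks", "array must contain at least one block")
        for variant, count in self.blocks:
            if variant not in STAR_VARIANTS:
                raise CircuitError(f"unknown STAR variant id {variant!r}; known: {sorted(STAR_VARIANTS)}")
            if count < 1:
                raise ParameterError("blocks", f"copy count must be >= 1, got {count} for {variant}")
        if self.insulator not in INSULATOR_EPS:
            raise ParameterError(
                "insulator", f"unrecognized insulator {self.insulator!r}; known: {sorted(INSULATOR_EPS)}"
            )
        if self.eps is None:
            object.__setattr__(self, "eps", INSULATOR_EPS[self.insulator])
        if not (0.0 <= self.eps <= 1.0):
            raise ParameterError("eps", f"release efficiency must be in [0, 1], got {self.eps!r}")
        if self.total_copies > MAX_TESTED_COPIES:
            warnings.warn(
                f"array has {self.total_copies} copies; behaviour above "
                f"{MAX_TESTED_COPIES} is outside the tested range",
                stacklevel=2,
            )

    @property
    def total_copies(self) -> int:
        return sum(c for _, c in self.blocks)

    @property
    def copies_by_variant(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for variant, count in self.blocks:
            out[variant] = out.get(variant, 0) + count
        return out


@dataclass(frozen=True)
class ConstantDriver:
    """Constitutive input: the same transcription rate in every condition."""

    level: float = 0.5

    def level_for(self, condition: str) -> float:
        return self.level


@dataclass(frozen=True)
class InducibleDriver:
    """Inducible input with distinct on/off transcription rates."""

    on: float = 0.5
    off: float = 0.0

    def level_for(self, condition: str) -> float:
        if condition == "on":
            return self.on
        if condition == "off":
            return self.off
        raise CircuitError(f"unknown condition {condition!r}; expected 'on' or 'off'")


@dataclass(frozen=True)
class UnitDriver:
    """Input taken from another unit's activated transcription rate.

    ``variant`` names which activator pool of the driver unit gates the
    transfer; defaults to the driver's sole variant.
    """

    unit: str
    variant: str | None = None


Driver = ConstantDriver | InducibleDriver | UnitDriver


@dataclass(frozen=True)
class ArrayUnit:
    """A transcription unit producing a cleavable array, with an optional
    target-controlled reporter transcribed from the same unit."""

    name: str
    array: ArraySpec
    driver: Driver = field(default_factory=ConstantDriver)
    params: ModelParams = DEFAULT_PARAMS
    multiplier: float = 1.0
    reporter: str | None = None
    reporter_variant: str | None = None

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ParameterError("multiplier", f"must be > 0, got {self.multiplier!r}")
        if self.reporter is not None:
            variants = [v for v, _ in self.array.blocks]
            rv = self.reporter_variant or variants[0]
            if rv not in dict(self.array.blocks):
                raise CircuitError(
                    f"reporter variant {rv!r} not present in array of unit {self.name!r}"
                )
            object.__setattr__(self, "reporter_variant", rv)


@dataclass(frozen=True)
class ReporterUnit:
    """A target-RNA-controlled reporter transcribed in response to a driver
    unit's activator pool."""

    name: str
    reporter: str
    driver: UnitDriver
    multiplier: float = 1.0
    d_G: float = 1.0

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ParameterError("multiplier", f"must be > 0, got {self.multiplier!r}")
        if self.d_G <= 0:
            raise ParameterError("d_G", f"must be > 0, got {self.d_G!r}")


Unit = ArrayUnit | ReporterUnit


@dataclass(frozen=True)
class Circuit:
    """Directed acyclic composition of transcription units."""

    units: tuple[Unit, ...]

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            raise CircuitError(f"duplicate unit names: {names}")
        self.topological_order()  # validates references and acyclicity

    def unit(self, name: str) -> Unit:
        for u in self.units:
            if u.name == name:
                return u
        raise CircuitError(f"unresolvable driver reference: no unit named {name!r}")

    def _driver_edges(self) -> list[tuple[str, str]]:
        edges = []
        for u in self.units:
            if isinstance(u.driver, UnitDriver):
                self.unit(u.driver.unit)  # existence check
                edges.append((u.driver.unit, u.name))
        return edges

    def topological_order(self) -> list[Unit]:
        """Kahn's algorithm over driver edges; raises on cycles."""
        edges = self._driver_edges()
        indeg = {u.name: 0 for u in self.units}
        for _, dst in edges:
            indeg[dst] += 1
        queue = [u.name for u in self.units if indeg[u.name] == 0]
        order: list[str] = []
        while queue:
            name = queue.pop(0)
            order.append(name)
            for src, dst in edges:
                if src == name:
                    indeg[dst] -= 1
                    if indeg[dst] == 0:
                        queue.append(dst)
        if len(order) != len(self.units):
            raise CircuitError("driver graph contains a cycle")
        return [self.unit(n) for n in order]

    @property
    def reporters(self) -> list[str]:
        tags = []
        for u in self.units:
            if u.reporter is not None:
                tags.append(u.reporter)
        return tags


@dataclass(frozen=True)
class CircuitOutput:
    """Steady-state snapshot of a circuit under one condition."""

    condition: str
    reporters: dict[str, float]
    unit_states: dict[str, dict[str, float]]


def _resolve_driver_variant(circuit: Circuit, drv: UnitDriver) -> str:
    src = circuit.unit(drv.unit)
    if not isinstance(src, ArrayUnit):
        raise CircuitError(f"unit {drv.unit!r} has no activator pool to drive from")
    variants = list(src.array.copies_by_variant)
    variant = drv.variant or (variants[0] if len(variants) == 1 else None)
    if variant is None:
        raise CircuitError(
            f"driver on multi-variant unit {drv.unit!r} must name a variant (has {variants})"
        )
    if variant not in src.array.copies_by_variant:
        raise CircuitError(f"unit {drv.unit!r} carries no copies of variant {variant!r}")
    return variant


def _activated_rate(unit: ArrayUnit, S_pool: float) -> float:
    """Driver output: the activated transcription rate of the unit's target
    promoter, gated by its activator pool."""
    p = unit.params
    theta = activation_fraction(S_pool, p.K)
    return p.a_T * (p.lam + (1.0 - p.lam) * theta)


def simulate_circuit(
    circuit: Circuit,
    condition: str = "on",
    method: str = "closed_form",
    t_end: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CircuitOutput:
    """Evaluate the circuit's steady state under a named condition.

    ``method="closed_form"`` propagates the per-unit closed forms in
    topological order.  ``method="ode"`` integrates the joint ODE of all
    species and reads off the final state; the two agree within integration
    tolerance on any acyclic circuit.
    """
    if method == "closed_form":
        return _simulate_topological(circuit, condition)
    if method == "ode":
        return _simulate_joint_ode(circuit, condition, t_end=t_end, rtol=rtol, atol=atol)
    raise ParameterError("method", f"unknown method {method!r}")


def _input_rate(circuit: Circuit, unit: Unit, condition: str,
                pools: Mapping[tuple[str, str], float]) -> float:
    drv = unit.driver
    if isinstance(drv, UnitDriver):
        variant = _resolve_driver_variant(circuit, drv)
        src = circuit.unit(drv.unit)
        base = _activated_rate(src, pools[(drv.unit, variant)])
    else:
        base = drv.level_for(condition)
    return unit.multiplier * base


def _simulate_topological(circuit: Circuit, condition: str) -> CircuitOutput:
    pools: dict[tuple[str, str], float] = {}
    unit_states: dict[str, dict[str, float]] = {}
    reporters: dict[str, float] = {}
    for unit in circuit.topological_order():
        if isinstance(unit, ArrayUnit):
            p = unit.params
            u_eff = _input_rate(circuit, unit, condition, pools)
            A = u_eff / (p.k_c + p.d_A)
            state = {"u": u_eff, "A": A}
            for variant, copies in unit.array.copies_by_variant.items():
                S = unit.array.eps * copies * p.k_c * A / p.d_S
                pools[(unit.name, variant)] = S
                state[f"S_{variant}"] = S
            if unit.reporter is not None:
                S = pools[(unit.name, unit.reporter_variant)]
                theta = activation_fraction(S, p.K)
                G = unit.multiplier * (p.a_T / p.d_G) * (p.lam + (1.0 - p.lam) * theta)
                state["G"] = G
                reporters[unit.reporter] = G
        else:
            rate = _input_rate(circuit, unit, condition, pools)
            G = rate / unit.d_G
            state = {"u": rate, "G": G}
            reporters[unit.reporter] = G
        unit_states[unit.name] = state
    return CircuitOutput(condition=condition, reporters=reporters, unit_states=unit_states)


def _species_layout(circuit: Circuit) -> list[tuple[str, str]]:
    """(unit, species) index layout for the joint state vector."""
    layout: list[tuple[str, str]] = []
    for unit in circuit.units:
        if isinstance(unit, ArrayUnit):
            layout.append((unit.name, "A"))
            for variant in unit.array.copies_by_variant:
                layout.append((unit.name, f"S_{variant}"))
            if unit.reporter is not None:
                layout.append((unit.name, "G"))
        else:
            layout.append((unit.name, "G"))
    return layout


def _simulate_joint_ode(circuit: Circuit, condition: str, t_end: float | None,
                        rtol: float, atol: float) -> CircuitOutput:
    layout = _species_layout(circuit)
    index = {key: i for i, key in enumerate(layout)}
    rates = []
    for u in circuit.units:
        if isinstance(u, ArrayUnit):
            rates.extend([u.params.d_A, u.params.d_S, u.params.d_G])
        else:
            rates.append(u.d_G)
    if t_end is None:
        t_end = 50.0 / min(rates)

    def rhs(t, y):
        dy = np.zeros_like(y)
        pools = {
            (name, sp[2:]): max(y[i], 0.0)
            for (name, sp), i in index.items()
            if sp.startswith("S_")
        }
        for unit in circuit.units:
            u_eff = _input_rate(circuit, unit, condition, pools)
            if isinstance(unit, ArrayUnit):
                p = unit.params
                A = y[index[(unit.name, "A")]]
                dy[index[(unit.name, "A")]] = u_eff - (p.k_c + p.d_A) * A
                for variant, copies in unit.array.copies_by_variant.items():
                    i = index[(unit.name, f"S_{variant}")]
                    dy[i] = unit.array.eps * copies * p.k_c * A - p.d_S * y[i]
                if unit.reporter is not None:
                    S = max(y[index[(unit.name, f"S_{unit.reporter_variant}")]], 0.0)
                    theta = activation_fraction(S, p.K)
                    i = index[(unit.name, "G")]
                    dy[i] = unit.multiplier * p.a_T * (p.lam + (1.0 - p.lam) * theta) - p.d_G * y[i]
            else:
                i = index[(unit.name, "G")]
                dy[i] = u_eff - unit.d_G * y[i]
        return dy

    y0 = np.zeros(len(layout))
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"joint circuit integration failed: {sol.message}")
    yf = np.clip(sol.y[:, -1], 0.0, None)

    unit_states: dict[str, dict[str, float]] = {u.name: {} for u in circuit.units}
    reporters: dict[str, float] = {}
    for (name, sp), i in index.items():
        unit_states[name][sp] = float(yf[i])
    for unit in circuit.units:
        if unit.reporter is not None:
            reporters[unit.reporter] = unit_states[unit.name]["G"]
    return CircuitOutput(condition=condition, reporters=reporters, unit_states=unit_states)


# ---------------------------------------------------------------------------
# Builders for the three studied topologies
# ---------------------------------------------------------------------------

def build_amplifier(
    array: ArraySpec,
    inducible_input: Driver | float = 0.5,
    params: ModelParams = DEFAULT_PARAMS,
    reporter: str | None = None,
) -> Circuit:
    """Single-stage inducible array amplifier with its target reporter.

    The steady state equals the core model's closed form with
    ``n = total copies`` and ``eps`` taken from the insulator.
    """
    if isinstance(inducible_input, (int, float)):
        inducible_input = InducibleDriver(on=float(inducible_input), off=0.0)
    variant = array.blocks[0][0]
    reporter = reporter or STAR_VARIANTS[variant]
    unit = ArrayUnit(
        name="amplifier", array=array, driver=inducible_input, params=params,
        reporter=reporter, reporter_variant=variant,
    )
    return Circuit(units=(unit,))


def build_cascade(
    stage1_variant: str = "STAR50",
    array: ArraySpec | None = None,
    reporter: str = "GFP",
    inducible_input: Driver | float = 0.5,
    params: ModelParams = DEFAULT_PARAMS,
    multipliers: Sequence[float] = (10.0, 5.0, 1.0),
) -> Circuit:
    """Three-unit activation-activation cascade with an array amplifier
    between the two transcription nodes.

    Stage 1 expresses ``stage1_variant`` from an inducible input; its target
    promoter transcribes the array (default 1x STAR10); the array's activator
    pool gates the terminal reporter.  ``multipliers`` are the plasmid
    copy-number scalings of the three units (high/medium/low by default).
    """
    if array is None:
        array = ArraySpec(blocks=(("STAR10", 1),))
    if stage1_variant not in STAR_VARIANTS:
        raise CircuitError(f"unknown STAR variant id {stage1_variant!r}")
    if stage1_variant in array.copies_by_variant:
        raise CircuitError(
            f"array must be orthogonal to stage-1 variant {stage1_variant!r}"
        )
    if isinstance(inducible_input, (int, float)):
        inducible_input = InducibleDriver(on=float(inducible_input), off=0.0)
    m1, m2, m3 = multipliers
    stage1 = ArrayUnit(
        name="stage1",
        array=ArraySpec(blocks=((stage1_variant, 1),), insulator="shcsy4hp", eps=1.0),
        driver=inducible_input, params=params, multiplier=m1,
    )
    amp = ArrayUnit(
        name="array", array=array, driver=UnitDriver(unit="stage1"),
        params=params, multiplier=m2,
    )
    out = ReporterUnit(
        name="output", reporter=reporter, driver=UnitDriver(unit="array"),
        multiplier=m3, d_G=params.d_G,
    )
    return Circuit(units=(stage1, amp, out))


def build_multiplex(
    n: int,
    m: int,
    driver: Driver | float = 0.5,
    params: ModelParams = DEFAULT_PARAMS,
    insulator: str = "shcsy4hp",
) -> Circuit:
    """1-to-2 multiplex motif: one array carrying ``n`` copies of STAR10 and
    ``m`` copies of STAR50 weights two independent reporters (GFP and RFP).

    GFP depends only on ``n`` and RFP only on ``m``: the model has no
    resource coupling because both outputs share one transcript.
    """
    if n < 1:
        raise ParameterError("n", f"must be >= 1, got {n!r}")
    if m < 1:
        raise ParameterError("m", f"must be >= 1, got {m!r}")
    if isinstance(driver, (int, float)):
        driver = ConstantDriver(level=float(driver))
    array = ArrayUnit(
        name="array",
        array=ArraySpec(blocks=(("STAR10", n), ("STAR50", m)), insulator=insulator),
        driver=driver, params=params,
    )
    gfp = ReporterUnit(name="gfp", reporter="GFP",
                       driver=UnitDriver(unit="array", variant="STAR10"), d_G=params.d_G)
    rfp = ReporterUnit(name="rfp", reporter="RFP",
                       driver=UnitDriver(unit="array", variant="STAR50"), d_G=params.d_G)
    return Circuit(units=(array, gfp, rfp))


def fold_activation_sim(circuit: Circuit, reporter: str | None = None) -> float:
    """On/off steady-state ratio of the terminal reporter.

    Returns ``math.inf`` (with a warning) when the off state is exactly zero,
    which happens only for fully tight circuits (``lam = 0`` everywhere).
    """
    tags = circuit.reporters
    if not tags:
        raise CircuitError("circuit has no reporter to compute fold activation for")
    reporter = reporter or tags[-1]
    if reporter not in tags:
        raise CircuitError(f"no reporter {reporter!r} in circuit (has {tags})")
    on = simulate_circuit(circuit, "on").reporters[reporter]
    off = simulate_circuit(circuit, "off").reporters[reporter]
    if off == 0.0:
        warnings.warn("off-state output is exactly zero; fold activation is infinite",
                      stacklevel=2)
        return math.inf
    return on / off


def random_circuit(rng: np.random.Generator, max_units: int = 5) -> Circuit:
    """Random acyclic circuit for cross-validation tests.

    Unit 0 is always an inducible array unit; each later unit is driven
    either externally or by a random earlier array unit.
    """
    n_units = int(rng.integers(2, max_units + 1))
    units: list[Unit] = []
    array_names: list[str] = []
    for i in range(n_units):
        params = ModelParams(
            u=float(rng.uniform(0.05, 1.0)),
            k_c=float(rng.uniform(0.2, 2.0)),
            d_A=float(rng.uniform(0.05, 0.5)),
            d_S=float(rng.uniform(0.2, 2.0)),
            d_G=float(rng.uniform(0.2, 2.0)),
            eps=float(rng.uniform(0.2, 1.0)),
            a_T=float(rng.uniform(0.5, 2.0)),
            K=float(rng.uniform(2.0, 20.0)),
            lam=float(rng.uniform(0.0, 0.2)),
        )
        if i > 0 and array_names and rng.random() < 0.7:
            driver: Driver = UnitDriver(unit=rng.choice(array_names))
        else:
            driver = InducibleDriver(on=float(rng.uniform(0.1, 1.0)), off=0.0)
        mult = float(rng.uniform(0.5, 5.0))
        if i > 0 and array_names and rng.random() < 0.3:
            units.append(ReporterUnit(
                name=f"u{i}", reporter=f"R{i}",
                driver=UnitDriver(unit=rng.choice(array_names)),
                multiplier=mult, d_G=params.d_G,
            ))
        else:
            variant = "STAR10" if rng.random() < 0.5 else "STAR50"
            copies = int(rng.integers(1, 5))
            units.append(ArrayUnit(
                name=f"u{i}",
                array=ArraySpec(blocks=((variant, copies),)),
                driver=driver, params=params, multiplier=mult,
                reporter=f"R{i}", reporter_variant=variant,
            ))
            array_names.append(f"u{i}")
    return Circuit(units=tuple(units))
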