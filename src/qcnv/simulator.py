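"""Ideal dense statevector simulator with exact marginals and shot sampling.

The register holds at most 16 qubits (the built-in problems use at most
14).  Measurement statistics of the swapper/class-index pair encode the
classification readout: with M classes,

    rho_1k = P(s = 1, m = k) = (1 / 2M) (1 - |A_k|^2),

where ``A_k = <t|d^k>``.  The measurement probability ratio
``MPR = rho_11 / rho_10`` is the classifier's readout; shot mode draws a
single multinomial over the four (s, m) outcomes from the exact joint
marginal, which is statistically identical to per-shot collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circuits import GateOp, QuantumCircuit, QubitRoleMap

MAX_QUBITS = 16

_H = np.array([[1.0, 1.0], [1.0, -1.0]]) / math.sqrt(2.0)
_X = np.array([[0.0, 1.0], [1.0, 0.0]])


def _ry(angle: float) -> np.ndarray:
    c, s = math.cos(angle / 2.0), math.sin(angle / 2.0)
    return np.array([[c, -s], [s, c]])


def _permutation(size: int, mapping: dict[int, int]) -> np.ndarray:
    u = np.zeros((size, size))
    for col in range(size):
        u[mapping.get(col, col), col] = 1.0
    return u


# Basis ordering within a gate matrix: the first listed qubit is the most
# significant bit of the local index (controls therefore lead).
_CNOT = _permutation(4, {0b10: 0b11, 0b11: 0b10})
_SWAP = _permutation(4, {0b01: 0b10, 0b10: 0b01})
_TOFFOLI = _permutation(8, {0b110: 0b111, 0b111: 0b110})
_FREDKIN = _permutation(8, {0b101: 0b110, 0b110: 0b101})


def gate_unitary(g: GateOp) -> np.ndarray:
    """The 2^k x 2^k unitary of a gate, first listed qubit as local MSB."""
    if g.kind == "H":
        return _H
    if g.kind == "X":
        return _X
    if g.kind == "RY":
        return _ry(g.angle)
    if g.kind == "CNOT":
        return _CNOT
    if g.kind == "SWAP":
        return _SWAP
    if g.kind == "TOFFOLI":
        return _TOFFOLI
    if g.kind == "FREDKIN":
        return _FREDKIN
    raise ValueError(f"unknown gate kind {g.kind!r}")


@dataclass(frozen=True)
class StateVector:
    """2^q complex amplitudes, unit norm; bit q of the index is qubit q."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=complex)
        object.__setattr__(self, "amplitudes", amps)
        q = int(math.log2(amps.size))
        if 1 << q != amps.size:
            raise ValueError("amplitude vector length must be a power of two")
        if q > MAX_QUBITS:
            raise ValueError(f"{q} qubits exceed the {MAX_QUBITS}-qubit dense-simulation cap")
        if abs(np.linalg.norm(amps) - 1.0) > 1e-10:
            raise ValueError("state vector is not unit norm")

    @property
    def num_qubits(self) -> int:
        return int(math.log2(self.amplitudes.size))

    @classmethod
    def ground(cls, num_qubits: int) -> "StateVector":
        amps = np.zeros(1 << num_qubits, dtype=complex)
        amps[0] = 1.0
        return cls(amps)


def apply_gate(state: StateVector, g: GateOp) -> StateVector:
    """Apply one gate; the state norm is preserved to machine precision."""
    nq = state.num_qubits
    if max(g.qubits) >= nq:
        raise ValueError(f"gate {g} addresses qubit outside the {nq}-qubit register")
    u = gate_unitary(g)
    k = len(g.qubits)
    tensor = state.amplitudes.reshape((2,) * nq)
    # axis of qubit q in the reshaped tensor
    axes = [nq - 1 - q for q in g.qubits]
    tensor = np.moveaxis(tensor, axes, range(k))
    shape = tensor.shape
    tensor = u @ tensor.reshape(1 << k, -1)
    tensor = np.moveaxis(tensor.reshape(shape), range(k), axes)
    return StateVector(tensor.reshape(-1))


def run(circuit: QuantumCircuit, initial_state: np.ndarray | StateVector | None = None) -> StateVector:
    """Apply all gates in order to |0...0> (or a supplied initial state)."""
    if circuit.num_qubits > MAX_QUBITS:
        raise ValueError(f"{circuit.num_qubits} qubits exceed the dense-simulation cap")
    if initial_state is None:
        state = StateVector.ground(circuit.num_qubits)
    elif isinstance(initial_state, StateVector):
        state = initial_state
    else:
        state = StateVector(np.asarray(initial_state, dtype=complex))
    if state.num_qubits != circuit.num_qubits:
        raise ValueError("initial state size does not match the circuit register")
    for g in circuit.gates:
        state = apply_gate(state, g)
    return state


def joint_probabilities(state: StateVector, roles: QubitRoleMap) -> dict[tuple[int, int], float]:
    """Exact joint (s, m) marginal, summed over all other qubits."""
    probs = np.abs(state.amplitudes) ** 2
    idx = np.arange(probs.size)
    s_bit = (idx >> roles.s) & 1
    m_bit = (idx >> roles.m) & 1
    return {
        (sb, mb): float(probs[(s_bit == sb) & (m_bit == mb)].sum())
        for sb in (0, 1)
        for mb in (0, 1)
    }


def rho(state: StateVector, roles: QubitRoleMap, M: int = 2) -> tuple[float, float]:
    """(rho_10, rho_11): probability of swapper 1 with class index 0 / 1.

    Each lies in [0, 1/(2M)]; rho_1k = 0 exactly when the test state
    coincides with class k's vector (|A_k| = 1).
    """
    joint = joint_probabilities(state, roles)
    return joint[(1, 0)], joint[(1, 1)]


@dataclass(frozen=True)
class MeasurementResult:
    """Exact and/or sampled (s, m) measurement statistics.

    ``rho_10``/``rho_11`` come from counts when ``shots`` is set and from
    the exact marginal otherwise.  ``mpr`` is rho_11 / rho_10, ``inf``
    when only rho_10 vanishes and ``nan`` (ambiguous) when both do.
    """

    probabilities: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int] | None = None
    shots: int | None = None
    seed: int | None = None
    rho_10: float = field(init=False)
    rho_11: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-10:
            raise ValueError("probabilities must sum to 1")
        if (self.counts is None) != (self.shots is None):
            raise ValueError("counts and shots must be supplied together")
        if self.counts is not None and sum(self.counts.values()) != self.shots:
            raise ValueError("counts must sum to shots")
        if self.counts is not None:
            r10 = self.counts[(1, 0)] / self.shots
            r11 = self.counts[(1, 1)] / self.shots
        else:
            r10 = self.probabilities[(1, 0)]
            r11 = self.probabilities[(1, 1)]
        object.__setattr__(self, "rho_10", float(r10))
        object.__setattr__(self, "rho_11", float(r11))

    @property
    def mpr(self) -> float:
        return mpr(self)


def sample(state: StateVector, roles: QubitRoleMap, shots: int, seed: int | None = None) -> MeasurementResult:
    """Draw ``shots`` (s, m) outcomes from the exact joint marginal."""
    if shots < 1:
        raise ValueError("shots must be a positive integer")
    joint = joint_probabilities(state, roles)
    outcomes = list(joint)
    p = np.array([joint[o] for o in outcomes])
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, p)
    counts = {o: int(c) for o, c in zip(outcomes, draws)}
    return MeasurementResult(probabilities=joint, counts=counts, shots=shots, seed=seed)


def exact_result(state: StateVector, roles: QubitRoleMap) -> MeasurementResult:
    return MeasurementResult(probabilities=joint_probabilities(state, roles))


def mpr(result: MeasurementResult | tuple[float, float]) -> float:
    """Measurement probability ratio rho_11 / rho_10.

    ``inf`` flags rho_10 = 0 with rho_11 > 0; ``nan`` flags both zero
    (ambiguous readout).
    """
    if isinstance(result, MeasurementResult):
        r10, r11 = result.rho_10, result.rho_11
    else:
        r10, r11 = result
    if r10 == 0.0:
        return math.inf if r11 > 0.0 else math.nan
    return r11 / r10


def inner_product_from_rho(rho_1k: float, M: int = 2, tol: float = 1e-9) -> float:
    """|A_k| recovered by inverting rho_1k = (1/2M)(1 - |A_k|^2).

    Sampled rho estimates may fall slightly outside [0, 1/(2M)]; values
    within ``tol`` are clamped, anything further is rejected.
    """
    upper = 1.0 / (2 * M)
    if rho_1k < -tol or rho_1k > upper + tol:
        raise ValueError(f"rho_1k = {rho_1k} outside [0, {upper}]")
    return math.sqrt(min(max(1.0 - 2 * M * rho_1k, 0.0), 1.0))
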