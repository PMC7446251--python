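"""Gate-level circuit representation and builders for the swap-test classifier.

A circuit runs on ``2n + 2`` qubits with four roles: the class-index
qubit ``m`` (entangled with the class vectors), the class-vector
register ``d_1..d_n``, the test register ``t_1..t_n`` and the swapper
``s``.  Classification circuits have two stages: data encoding (class
vectors entangled with ``m``, test state prepared in parallel) and the
n-qubit swap test — ``H`` on the swapper, one Fredkin (controlled-SWAP)
per paired ``(d_j, t_j)`` with the swapper as control, ``H`` again —
followed by measurement of ``(s, m)``.

Qubit index convention is little-endian within each register
(``d_1``/``t_1`` carry the least significant feature bit) with global
order ``(t_n..t_1, d_n..d_1, m, s)`` mapped to simulator qubits
``0..2n+1``; hardware-specific orderings are not reproduced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GATE_ARITY = {
    "H": 1,
    "X": 1,
    "RY": 1,
    "CNOT": 2,
    "SWAP": 2,
    "TOFFOLI": 3,
    "FREDKIN": 3,
}

_QASM_NAMES = {
    "H": "h",
    "X": "x",
    "RY": "ry",
    "CNOT": "cx",
    "SWAP": "swap",
    "TOFFOLI": "ccx",
    "FREDKIN": "cswap",
}


@dataclass(frozen=True)
class GateOp:
    """One gate: ``kind`` plus ordered qubit indices (controls first).

    ``CNOT(control, target)``, ``TOFFOLI(c1, c2, target)``,
    ``FREDKIN(control, a, b)``; ``RY`` carries a rotation ``angle`` with
    the convention ``RY(phi)|0> = cos(phi/2)|0> + sin(phi/2)|1>``.
    """

    kind: str
    qubits: tuple[int, ...]
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in GATE_ARITY:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        qubits = tuple(int(q) for q in self.qubits)
        object.__setattr__(self, "qubits", qubits)
        if len(qubits) != GATE_ARITY[self.kind]:
            raise ValueError(f"{self.kind} takes {GATE_ARITY[self.kind]} qubits, got {qubits}")
        if len(set(qubits)) != len(qubits):
            raise ValueError(f"{self.kind} qubits must be distinct, got {qubits}")
        if any(q < 0 for q in qubits):
            raise ValueError("qubit indices must be non-negative")
        if self.kind == "RY":
            if self.angle is None or not math.isfinite(self.angle):
                raise ValueError("RY requires a finite angle")
        elif self.angle is not None:
            raise ValueError(f"{self.kind} does not take an angle")


@dataclass(frozen=True)
class QubitRoleMap:
    """Assignment of simulator qubit indices to the circuit roles."""

    m: int
    d: tuple[int, ...]
    t: tuple[int, ...]
    s: int

    def __post_init__(self) -> None:
        d, t = tuple(self.d), tuple(self.t)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "t", t)
        if len(d) != len(t):
            raise ValueError("d and t registers must pair up")
        all_q = (self.m, *d, *t, self.s)
        if len(set(all_q)) != len(all_q):
            raise ValueError("role qubits must be distinct")

    @property
    def n(self) -> int:
        return len(self.d)

    @property
    def num_qubits(self) -> int:
        return 2 * self.n + 2

    @classmethod
    def default(cls, n: int) -> "QubitRoleMap":
        """t_j -> j-1, d_j -> n+j-1, m -> 2n, s -> 2n+1."""
        return cls(
            m=2 * n,
            d=tuple(range(n, 2 * n)),
            t=tuple(range(n)),
            s=2 * n + 1,
        )


@dataclass
class QuantumCircuit:
    """Ordered gate list over a fixed register, with a (s, m) measurement spec."""

    num_qubits: int
    gates: list[GateOp] = field(default_factory=list)
    measured_qubits: tuple[int, int] | None = None  # (s, m)

    def __post_init__(self) -> None:
        if not (1 <= self.num_qubits <= 16):
            raise ValueError("num_qubits must be between 1 and 16")
        for g in self.gates:
            self._check(g)
        if self.measured_qubits is not None:
            s, m = self.measured_qubits
            if not (0 <= s < self.num_qubits and 0 <= m < self.num_qubits and s != m):
                raise ValueError("invalid measurement spec")

    def _check(self, g: GateOp) -> None:
        if max(g.qubits) >= self.num_qubits:
            raise ValueError(f"gate {g} addresses a qubit outside the {self.num_qubits}-qubit register")

    def append(self, g: GateOp) -> None:
        self._check(g)
        self.gates.append(g)

    def extend(self, gates: Iterable[GateOp]) -> None:
        for g in gates:
            self.append(g)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "num_qubits": self.num_qubits,
                "gates": [
                    {"kind": g.kind, "qubits": list(g.qubits)}
                    | ({"angle": g.angle} if g.angle is not None else {})
                    for g in self.gates
                ],
                "measured_qubits": list(self.measured_qubits) if self.measured_qubits else None,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantumCircuit":
        obj = json.loads(text)
        gates = [
            GateOp(g["kind"], tuple(g["qubits"]), g.get("angle")) for g in obj["gates"]
        ]
        measured = tuple(obj["measured_qubits"]) if obj["measured_qubits"] else None
        return cls(num_qubits=obj["num_qubits"], gates=gates, measured_qubits=measured)

    def to_qasm(self) -> str:
        """OpenQASM 2.0 text (h, x, ry, cx, swap, ccx, cswap)."""
        lines = [
            "OPENQASM 2.0;",
            'include "qelib1.inc";',
            f"qreg q[{self.num_qubits}];",
        ]
        if self.measured_qubits is not None:
            lines.append("creg c[2];")
        for g in self.gates:
            args = ",".join(f"q[{q}]" for q in g.qubits)
            if g.kind == "RY":
                lines.append(f"ry({g.angle!r}) {args};")
            else:
                lines.append(f"{_QASM_NAMES[g.kind]} {args};")
        if self.measured_qubits is not None:
            s, m = self.measured_qubits
            lines.append(f"measure q[{s}] -> c[0];")
            lines.append(f"measure q[{m}] -> c[1];")
        return "\n".join(lines) + "\n"


# -- fragment builders ----------------------------------------------------

def _cry(angle: float, control: int, target: int) -> list[GateOp]:
    """Controlled-RY from the native set: RY(a/2), CNOT, RY(-a/2), CNOT."""
    return [
        GateOp("RY", (target,), angle / 2),
        GateOp("CNOT", (control, target)),
        GateOp("RY", (target,), -angle / 2),
        GateOp("CNOT", (control, target)),
    ]


def entanglement_routine_5q(theta: float, roles: QubitRoleMap) -> list[GateOp]:
    """Entangle the class-index qubit with the single class-vector qubit.

    Acting on |00>_md this produces
    ``(1/sqrt(2)) (|01>_md + sin(theta)|10>_md + cos(theta)|11>_md)``:
    class 0 with a CNV only in the second of two regions, class 1 with
    CNVs split across both regions in the ratio tan(theta).
    """
    if not (0.0 <= theta <= math.pi / 2):
        raise ValueError("theta must lie in [0, pi/2]")
    if roles.n != 1:
        raise ValueError("the 5-qubit routine needs a single d qubit")
    m, d = roles.m, roles.d[0]
    return [
        GateOp("H", (m,)),
        GateOp("X", (m,)),
        GateOp("CNOT", (m, d)),
        GateOp("X", (m,)),
        *_cry(math.pi - 2 * theta, m, d),
    ]


def class_prep_14q(variant: str, roles: QubitRoleMap) -> list[GateOp]:
    """Class-vector preparation on (m, d_6..d_1) for the 64-region problems.

    ``ex1``: H(m) then CNOT(m -> d_6) splits the classes by genome half
    (class 0 uniform over regions 1-32, class 1 over 33-64); Hadamards on
    d_5..d_1 spread each class over its half.  ``ex2`` additionally
    rotates d_6 by RY(pi/2), turning the halved supports into the
    {+1, -1} patterns of the symmetric encoding.
    """
    if variant not in ("ex1", "ex2"):
        raise ValueError(f"unknown variant {variant!r}")
    if roles.n != 6:
        raise ValueError("the 14-qubit routine needs six d qubits")
    m = roles.m
    d6 = roles.d[5]
    gates = [GateOp("H", (m,)), GateOp("CNOT", (m, d6))]
    if variant == "ex2":
        gates.append(GateOp("RY", (d6,), math.pi / 2))
    gates.extend(GateOp("H", (roles.d[j],)) for j in reversed(range(5)))
    return gates


def test_prep(variant: str, roles: QubitRoleMap) -> list[GateOp]:
    """Test-register preparation for the built-in problems.

    ``5q_ex1`` leaves |0>_t (a single CNV in region 1); ``14q_ex1``
    spreads the test uniformly over regions 1-16 (H on t_4..t_1);
    ``14q_ex2`` applies RY(-pi/2) on t_6 and H on t_5..t_1, encoding +1
    on regions 1-32 and -1 on 33-64.
    """
    if variant == "5q_ex1":
        return []
    if variant == "14q_ex1":
        return [GateOp("H", (roles.t[j],)) for j in reversed(range(4))]
    if variant == "14q_ex2":
        gates = [GateOp("RY", (roles.t[5],), -math.pi / 2)]
        gates.extend(GateOp("H", (roles.t[j],)) for j in reversed(range(5)))
        return gates
    raise ValueError(f"unknown variant {variant!r}")


def differing_pairs(
    class_prep: Sequence[GateOp],
    test_prep_gates: Sequence[GateOp],
    roles: QubitRoleMap,
    tol: float = 1e-9,
) -> list[tuple[int, int]]:
    """The (d_j, t_j) pairs whose preparations actually differ.

    A controlled swap of two identically prepared qubits contributes a
    factor of one to the overlap, so those Fredkin gates can be elided.
    The check is behavioral: a pair is elided exactly when swapping the
    two qubits leaves the encoded state invariant, which is conservative
    for entangled preparations.
    """
    from .simulator import StateVector, apply_gate  # local import: avoid a cycle

    state = StateVector.ground(roles.num_qubits)
    for g in (*class_prep, *test_prep_gates):
        state = apply_gate(state, g)
    return differing_pairs_from_state(state, roles, tol=tol)


def differing_pairs_from_state(state, roles: QubitRoleMap, tol: float = 1e-9) -> list[tuple[int, int]]:
    """Swap-invariance check on an already-encoded state (see :func:`differing_pairs`)."""
    from .simulator import StateVector, apply_gate

    if not isinstance(state, StateVector):
        state = StateVector(np.asarray(state, dtype=complex))
    pairs = []
    for dq, tq in zip(roles.d, roles.t):
        swapped = apply_gate(state, GateOp("SWAP", (dq, tq)))
        if not np.allclose(swapped.amplitudes, state.amplitudes, atol=tol, rtol=0.0):
            pairs.append((dq, tq))
    return pairs


def swap_test(pairs: Sequence[tuple[int, int]], s: int) -> list[GateOp]:
    """H(s), one Fredkin per (d_j, t_j) pair with s as control, H(s)."""
    seen: set[int] = set()
    for dq, tq in pairs:
        if s in (dq, tq):
            raise ValueError("swapper qubit cannot be a swap target")
        if dq in seen or tq in seen:
            raise ValueError("swap pairs must be disjoint")
        seen.update((dq, tq))
    gates = [GateOp("H", (s,))]
    gates.extend(GateOp("FREDKIN", (s, dq, tq)) for dq, tq in pairs)
    gates.append(GateOp("H", (s,)))
    return gates


def decompose_fredkin(g: GateOp) -> list[GateOp]:
    """Fredkin as CNOT(b -> a), Toffoli(s, a -> b), CNOT(b -> a)."""
    if g.kind != "FREDKIN":
        raise ValueError("expected a FREDKIN gate")
    s, a, b = g.qubits
    return [
        GateOp("CNOT", (b, a)),
        GateOp("TOFFOLI", (s, a, b)),
        GateOp("CNOT", (b, a)),
    ]


# -- full-problem assembly -------------------------------------------------

def assemble_example(name: str, theta: float = math.pi / 4) -> tuple[QuantumCircuit, QubitRoleMap]:
    """Assemble one of the built-in worked problems.

    ``5q1``: AIP on a 2-region genome (class-separation angle ``theta``);
    ``14q1``: AIP on 64 regions; ``14q2``: SIP on 64 regions.  Fredkin
    gates are emitted only for the register pairs whose preparations
    differ.
    """
    if name == "5q1":
        roles = QubitRoleMap.default(1)
        cp = entanglement_routine_5q(theta, roles)
        tp = test_prep("5q_ex1", roles)
    elif name == "14q1":
        roles = QubitRoleMap.default(6)
        cp = class_prep_14q("ex1", roles)
        tp = test_prep("14q_ex1", roles)
    elif name == "14q2":
        roles = QubitRoleMap.default(6)
        cp = class_prep_14q("ex2", roles)
        tp = test_prep("14q_ex2", roles)
    else:
        raise ValueError(f"unknown example {name!r}; expected 5q1, 14q1 or 14q2")
    circ = QuantumCircuit(num_qubits=roles.num_qubits, measured_qubits=(roles.s, roles.m))
    circ.extend(cp)
    circ.extend(tp)
    circ.extend(swap_test(differing_pairs(cp, tp, roles), roles.s))
    return circ, roles


class UnsynthesizableStateError(ValueError):
    """A target state has no product-form preparation within tolerance."""


def assemble_custom(
    class_amplitudes: Sequence[np.ndarray],
    test_amplitudes: np.ndarray,
    fit_tol: float = 1e-8,
    restarts: int = 16,
    seed: int = 0,
) -> tuple[QuantumCircuit, QubitRoleMap]:
    """Gate-level circuit for arbitrary product-form class/test states.

    Each class vector and the test state is fitted to a product of
    single-qubit states; per-qubit RY rotations (controlled on the class
    index for the class vectors) then prepare them.  Entangled targets
    have no such preparation and are refused.
    """
    from .synthesis import angles_from_pairs, fit_product_state

    if len(class_amplitudes) != 2:
        raise ValueError("exactly two class vectors are required")
    dim = len(test_amplitudes)
    n = int(math.log2(dim))
    if 1 << n != dim:
        raise ValueError("amplitude vectors must have power-of-two length")
    fits = []
    for label, target in (("class 0", class_amplitudes[0]),
                          ("class 1", class_amplitudes[1]),
                          ("test", test_amplitudes)):
        report = fit_product_state(np.asarray(target, float), tol=fit_tol,
                                   restarts=restarts, seed=seed)
        if not report.converged:
            raise UnsynthesizableStateError(
                f"{label} state is entangled beyond tolerance "
                f"(best product-fit residual {report.residual:.3g} > {fit_tol:g}); "
                "supply an explicit preparation fragment instead"
            )
        fits.append(report)
    roles = QubitRoleMap.default(n)
    circ = QuantumCircuit(num_qubits=roles.num_qubits, measured_qubits=(roles.s, roles.m))
    cp: list[GateOp] = [GateOp("H", (roles.m,)), GateOp("X", (roles.m,))]
    for j, ang in enumerate(angles_from_pairs(fits[0].pairs)):
        if ang != 0.0:
            cp.extend(_cry(ang, roles.m, roles.d[j]))
    cp.append(GateOp("X", (roles.m,)))
    for j, ang in enumerate(angles_from_pairs(fits[1].pairs)):
        if ang != 0.0:
            cp.extend(_cry(ang, roles.m, roles.d[j]))
    tp = [
        GateOp("RY", (roles.t[j],), ang)
        for j, ang in enumerate(angles_from_pairs(fits[2].pairs))
        if ang != 0.0
    ]
    circ.extend(cp)
    circ.extend(tp)
    circ.extend(swap_test(differing_pairs(cp, tp, roles), roles.s))
    return circ, roles


def joint_initial_state(
    class_amplitudes: Sequence[np.ndarray],
    test_amplitudes: np.ndarray,
    roles: QubitRoleMap,
) -> np.ndarray:
    """Statevector after data encoding, for direct amplitude initialization.

    ``(1/sqrt(M)) sum_k |k>_m |d^k>_d |t>_t |0>_s`` laid out on the role
    map's qubit indices.  Used when class vectors are entangled across
    feature qubits and therefore have no product-form gate preparation.
    """
    n = roles.n
    dim = 1 << n
    amps = [np.asarray(a, dtype=float) for a in class_amplitudes]
    test = np.asarray(test_amplitudes, dtype=float)
    if any(a.size != dim for a in amps) or test.size != dim:
        raise ValueError("amplitude vectors must all have length 2^n")
    if roles.t != tuple(range(n)) or roles.d != tuple(range(n, 2 * n)) or roles.m != 2 * n:
        raise ValueError("joint_initial_state requires the default qubit layout")
    M = len(amps)
    state = np.zeros(1 << roles.num_qubits, dtype=complex)
    for k, dvec in enumerate(amps):
        block = np.outer(dvec, test).reshape(-1)  # index = (d << n) | t
        lo = k << (2 * n)
        state[lo : lo + dim * dim] += block / math.sqrt(M)
    return state
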