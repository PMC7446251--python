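"""The three built-in worked problems and the classifiability sweep.

* ``5q1`` — AIP on a 2-region genome, named for the 5-qubit processor
  class it was sized for (the circuit itself needs 4 qubits: class
  index, one class-vector qubit, one test qubit and the swapper).
  Class 0 (disease) has its CNV in
  region 2, class 1 (normal) splits CNVs across both regions with
  mixing angle theta; the test carries one CNV in region 1.  Exact
  readout: rho_10 = 1/4, rho_11 = cos^2(theta)/4, so the theoretical
  MPR is cos^2(theta) = 1/2 at theta = pi/4.
* ``14q1`` — AIP on 64 regions: class 0 uniform over regions 1-32,
  class 1 over 33-64, test uniform over 1-16.  Exact rho_10 = 1/8,
  rho_11 = 1/4, MPR = 2; class 0 wins.
* ``14q2`` — SIP on 64 regions in the mismatches-dominant regime:
  class 0 has a CNV in every region, class 1 in regions 33-64 only,
  test in 1-32.  The test matches class 0 on 32 regions and mismatches
  on 32 (sigma = 0, A_0 = 0) while it mismatches class 1 everywhere
  (|sigma| = 64, |A_1| = 1), so rho_11 = 0, MPR = 0 and the test is
  assigned to class 0.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .circuits import assemble_example
from .features import AIP, SIP, MetricConfig, classifiability, classify
from .simulator import (
    exact_result,
    inner_product_from_rho,
    mpr,
    run,
    sample as sample_counts,
)

EXAMPLE_NAMES = ("5q1", "14q1", "14q2")

_EXAMPLE_CONFIG = {
    "5q1": MetricConfig(metric=AIP),
    "14q1": MetricConfig(metric=AIP),
    "14q2": MetricConfig(metric=SIP, sign_mode="mismatches_dominant"),
}


def run_example(
    name: str,
    theta: float = math.pi / 4,
    shots: int | None = None,
    seed: int | None = None,
) -> dict:
    """Solve one worked problem end to end on the simulator.

    Returns a report with the measured ``rho_10``/``rho_11`` (exact
    marginals, or shot frequencies when ``shots`` is given), the MPR,
    the recovered inner-product magnitudes, the classifiability F and
    the predicted class.
    """
    if name not in EXAMPLE_NAMES:
        raise ValueError(f"unknown example {name!r}; expected one of {EXAMPLE_NAMES}")
    if name != "5q1" and abs(theta - math.pi / 4) > 1e-12:
        raise ValueError("theta applies to the 5-qubit example only")
    circ, roles = assemble_example(name, theta=theta)
    state = run(circ)
    if shots is None:
        result = exact_result(state, roles)
    else:
        result = sample_counts(state, roles, shots=shots, seed=seed)
    # sampled rho can fluctuate above 1/(2M); a generous clamp tolerance applies
    a0 = inner_product_from_rho(result.rho_10, M=2, tol=1.0)
    a1 = inner_product_from_rho(result.rho_11, M=2, tol=1.0)
    config = _EXAMPLE_CONFIG[name]
    verdict = classify(a0, a1, config)
    return {
        "example": name,
        "metric": config.metric,
        "sign_mode": config.sign_mode,
        "mode": "exact" if shots is None else "shots",
        "shots": shots,
        "seed": seed,
        "theta": theta if name == "5q1" else None,
        "rho_10": result.rho_10,
        "rho_11": result.rho_11,
        "mpr": mpr(result),
        "A0": a0,
        "A1": a1,
        "F": classifiability(a0, a1),
        "predicted_class": verdict,
        "num_qubits": circ.num_qubits,
        "num_fredkins": sum(g.kind == "FREDKIN" for g in circ.gates),
    }


def sweep_5q(
    thetas: Iterable[float],
    shots: int | None = None,
    seed: int | None = None,
) -> list[dict]:
    """MPR versus classifiability on the 5-qubit generic family.

    For the test fixed at region 1, A_0 = 0 and A_1 = sin(theta), so
    F = sin(theta) and the exact MPR is cos^2(theta) = 1 - F^2.  Rows
    report theta, F, the exact MPR and (optionally) a sampled MPR.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for theta in thetas:
        if not (0.0 < theta <= math.pi / 2):
            raise ValueError("theta grid must lie in (0, pi/2]")
        circ, roles = assemble_example("5q1", theta=theta)
        state = run(circ)
        exact = exact_result(state, roles)
        row = {
            "theta": float(theta),
            "F": math.sin(theta),
            "exact_mpr": mpr(exact),
            "exact_rho_10": exact.rho_10,
            "exact_rho_11": exact.rho_11,
        }
        if shots is not None:
            sampled = sample_counts(
                state, roles, shots=shots, seed=int(rng.integers(0, 2**31 - 1))
            )
            row["sampled_mpr"] = mpr(sampled)
        rows.append(row)
    return rows
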