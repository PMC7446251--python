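# qcnv

Swap-test inner-product classification of genomic copy-number-variation
(CNV) profiles, with an exact statevector simulator.

## The problem

Single-cell sequencing can call CNVs — deviations from the diploid
expectation of two copies — in non-overlapping windows tiled across the
genome. A cohort of such profiles (e.g. neurons from diseased versus
healthy donors) becomes a set of binary vectors: bit *f* is 1 when
window *f* carries a CNV. Classifying a new genome then reduces to
scoring its bit vector against the training vectors of each class.

`qcnv` implements a compact quantum circuit formulation of this
classifier and everything needed to study it classically: the window
and cohort data layer, the exact feature-space metrics, gate-level
circuit builders, a dense statevector simulator with shot sampling,
product-state encoding synthesis, and a synthetic cohort generator.

## The method

Windows are indexed by computational basis states: `|f_n … f_1⟩` is
region `1 + Σ f_i 2^(i-1)`, so *n* qubits address `2^n` windows. Two
encodings turn a profile into a quantum state:

- **AIP** (active inner product): coefficients {0, 1}. The inner
  product of two encoded profiles counts aligned 1–1 matches — a dot
  product kernel.
- **SIP** (symmetric inner product): coefficients {+1, −1}. The inner
  product counts matches (1–1 and 0–0) minus mismatches, which ranks
  classes identically to negative total Hamming distance at fixed
  training-set size.

Both metrics are linear, so the `W` training vectors of a class are
pre-summed into a single *class vector* `|d^k⟩` whose raw Euclidean
norm η_k is kept alongside. A class-index qubit `m` is entangled with
the two class vectors, the test state `|t⟩` is prepared in parallel,
and an *n*-qubit swap test (Hadamard on a swapper qubit `s`, one
Fredkin per paired feature qubit, Hadamard) interferes the registers.
The joint measurement of `(s, m)` obeys

    ρ_1k = P(s=1, m=k) = (1/2M) (1 − |⟨t|d^k⟩|²),   M = 2 classes,

so the class with the *lower* ρ_1k has the higher inner product with
the test. The readout statistic is the measurement probability ratio
MPR = ρ_11/ρ_10: MPR < 1 favors class 1, MPR > 1 favors class 0.

## Worked example

The smallest built-in problem uses a two-window genome: the disease
class has its CNV in window 2 (`|d^0⟩ = |1⟩`), the normal class has
CNVs split evenly across both windows (`|d^1⟩ = (|0⟩+|1⟩)/√2`), and the
test genome has one CNV in window 1 (`|t⟩ = |0⟩`).

```sh
$ qcnv example 5q1
{
  "example": "5q1",
  ...
  "rho_10": 0.2499999999999999,
  "rho_11": 0.12499999999999992,
  "mpr": 0.4999999999999999,
  "A0": 2.1073424255447017e-08,
  "A1": 0.7071067811865478,
  "F": 0.7071067601131236,
  "predicted_class": 1,
  "num_qubits": 4,
  "num_fredkins": 1
}
```

ρ_10 = 1/4 says the test is orthogonal to the disease class
(|A_0| = 0); ρ_11 = 1/8 recovers |A_1| = 1/√2; MPR = 1/2 < 1, so the
genome is classified as normal (class 1) — the correct call, since its
CNV overlaps the normal class's support only. `14q1` (64 windows, AIP,
MPR = 2) and `14q2` (64 windows, SIP, MPR = 0) run the same way, and
`qcnv sweep` traces the exact curve MPR = 1 − F² over the
classifiability F = |A_1 − A_0|.

The library surface is a pair of scikit-learn estimators:

```python
import numpy as np
from qcnv import CohortSpec, SwapTestClassifier, generate_cohort

cohort = generate_cohort(CohortSpec(seed=0))
X = np.array([s.bits for s in cohort.train])
y = np.array([s.label for s in cohort.train])
clf = SwapTestClassifier(metric="sip").fit(X, y)
clf.predict(np.array([s.bits for s in cohort.test]))
```

`SwapTestClassifier` runs the full simulated circuit per test sample
(exact marginals, or seeded multinomial shots via `shots=`);
`InnerProductClassifier` is the classical twin computing the same inner
products directly. In exact mode the two agree on every input.

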