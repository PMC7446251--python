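# Methods

## Model

A genome is represented as a binary vector over N ordered,
non-overlapping genomic windows (BED, 0-based half-open): bit *f* is 1
iff the copy number of window *f* deviates from the diploid baseline of
2 — gains and losses are not distinguished. Window order defines
feature order, and the n-qubit basis state |f_n … f_1⟩ indexes region
1 + Σ f_i 2^(i−1), with n = ceil(log2(max(N, 2))).

Two encodings map a profile to state-vector coefficients:

- **AIP**: coefficient 1 for a CNV, 0 otherwise. ⟨t|d⟩ counts aligned
  1–1 matches. An all-zero profile has no AIP encoding (zero vector)
  and is rejected as degenerate.
- **SIP**: coefficient +1 for a CNV, −1 otherwise. ⟨t|d⟩ counts
  matches minus mismatches.

Per class k, the W training coefficient vectors are summed into a raw
class vector with Euclidean norm η_k ("raw normalization constant");
amplitudes are raw/η_k. For a test with raw norm η_t the exact
identities

    ⟨t|d^k⟩ · η_k · η_t = σ11(k)   (AIP, total 1–1 matches)
    ⟨t|d^k⟩ · η_k · η_t = σ(k)    (SIP, matches − mismatches)

hold, with σ and σ11 integer counts; the test suite verifies them to
1e−10 on randomized instances. With W fixed across classes,
σ = 2 Σ_D (S11 + S00) − W·F, so ranking classes by SIP equals ranking
by negative total Hamming distance; AIP is equivalent as well whenever
0–0 matches are fixed or monotone in 1–1 matches (true for sparse
CNVs). The Hamming distance itself is not linear over summed training
vectors — the package keeps the 1-d counterexample as a test — which
is exactly why the class vectors encode pre-summed data.

### Circuit

The register is (t_1..t_n, d_1..d_n, m, s), little-endian within each
register; hardware qubit orderings of the original devices are not
reproduced. Data encoding entangles m with the class vectors,
producing (1/√M) Σ_k |k⟩_m |d^k⟩_d |t⟩_t |0⟩_s. The n-qubit swap test
— H(s), one Fredkin (s; d_j, t_j) per pair, H(s) — yields

    ρ_1k = P(s=1, m=k) = (1/2M)(1 − |⟨t|d^k⟩|²),

and the measurement probability ratio MPR = ρ_11/ρ_10 is the readout.
Measuring the swapper in state 1 (rather than 0) is the convention used
throughout. Fredkin gates whose (d_j, t_j) preparations are identical
contribute a factor of one and are elided; the elision test is
behavioral (swap-invariance of the encoded state to 1e−9), which is
conservative for entangled preparations. A Fredkin decomposes as
CNOT(b→a) · Toffoli(s,a→b) · CNOT(b→a); correctness everywhere is
defined by statevector equality, never by native gate counts.

### Decision rule

Only |⟨t|d^k⟩| is measurable (probabilities square the amplitudes), so
the SIP sign is ambiguous. The caller declares the regime:
`matches_dominant` (the default — sparse CNV data guarantees σ ≥ 0, so
pick the larger |A_k|) or `mismatches_dominant` (pick the smaller).
AIP coefficients are non-negative, so AIP always picks the larger.
Scores tied within 1e−12 are reported as `ambiguous`; the sklearn
`predict` breaks such ties to the first class label, while `measure`
preserves the flag. Shot-mode classification uses the sampled MPR with
no significance test; the CLI warns below 1024 shots.

### Validity conditions

Classification compares normalized inner products, so it reflects the
raw scores only when η_0 ≈ η_1. `scaling_factor_check` reports
η_1/η_0 and flags deviations beyond `norm_ratio_warn` (default 0.1,
surfaced as a fit-time warning). Equal W across classes is enforced
(refusal, not warning), since the Hamming equivalence fixes W. When N
is not a power of two, AIP pads with zeros (no contribution) and SIP
pads every sample with −1 pseudo-regions, adding the same constant W·P
to each class's σ at equal W, so the ranking is unchanged.

Zero-coefficient exclusion (AIP only) drops the dimensions where the
test bit is 0 and re-indexes the remainder, shrinking n to
ceil(log2(#kept)). It is refused unless each class holds a single
training vector or the post-remap η's agree within tolerance
(default 1e−9); under the norm-agreement condition the verdict equals
the raw-score ranking before and after the remap.

## Simulation

Dense statevector propagation, capped at 16 qubits (the largest
built-in problem uses 14; the cap keeps the engine honestly in the
regime it was written for). Gates are applied by tensor contraction;
norm drift is below 1e−12 per gate. Shot sampling draws one multinomial
over the four (s, m) outcomes from the exact joint marginal —
statistically identical to per-shot collapse and far cheaper; the seed
is recorded in the result. Defaults follow the worked problems: 8192
shots per run, 4096 per sweep point. ρ values recovered from sampled
frequencies may exceed 1/(2M); inversion to |A_k| clamps into [0, 1]
(tolerance 1e−9 in exact mode, permissive in shot mode).

## Encoding synthesis

Product-form targets (a_n|0⟩+b_n|1⟩)…(a_1|0⟩+b_1|1⟩) are prepared by
one RY per qubit, with RY(φ)|0⟩ = cos(φ/2)|0⟩ + sin(φ/2)|1⟩ and
φ_i = 2·atan2(b_i, a_i). Arbitrary real targets are fitted by
least-squares over per-qubit angles — parameterizing by angles enforces
per-qubit normalization by construction — with 16 seeded uniform
restarts (L-BFGS-B, early exit on an exact fit). Entangled targets
keep a floor residual, which is reported, not hidden; no residual
threshold is imposed beyond the caller's `tol`. Only real amplitudes
are handled: the classifier's data never needs more than a global
sign. Patterned encodings (suppress or scale half of the regions at a
bit level) set the corresponding a_i/b_i directly, which is how the
64-region problems encode their block structure with a handful of
gates. Whole-problem gate synthesis (`assemble_custom`) prepares the
class-conditional rotations with controlled-RY built from
{RY, CNOT}; class vectors entangled across feature qubits have no
product preparation and are refused, and the estimator pipeline
instead initializes the encoded joint state directly by amplitude and
applies the swap-test gates — the measured statistics are identical.

## Synthetic cohorts

The generator emulates sparse single-cell CNV cohorts: equal-width
windows on a pseudo-chromosome (real coordinates are irrelevant), a
per-sample CNV count drawn from a zero-truncated Poisson with rate 1.0
(every genome carries at least one CNV, most exactly one), and CNV
positions drawn with probability `enrichment` (default 0.8) on a
class-specific salient region and uniformly otherwise. Both classes
share the count distribution, so raw normalization constants match in
expectation — the validity condition above. Defaults: 64 regions, 10
training and 5 held-out samples per class. What this does *not*
emulate: CNV-calling noise, correlated multi-window events, biased
genome coverage, or class-dependent CNV burden; a pass on these
cohorts shows the pipeline recovers planted regional structure under
the method's own assumptions, not robustness to real calling
artifacts.

## Problem sizes and numerical choices

The test suite runs the three built-in problems exactly (≤ 14 qubits,
milliseconds each), 100-seed shot-band checks at 8192 shots, ≥ 1000
randomized oracle-equivalence instances at n ≤ 4 and W ≤ 4, an
exhaustive length-8 pair sweep for the Hamming identity, and 50-seed
cohort recovery at 64 regions — sizes chosen to cover the regimes the
worked problems occupy while keeping the whole suite in seconds.
Ties break as documented above; degenerate inputs (all-zero AIP
profiles, cancelled SIP class sums) raise typed errors rather than
silently renormalizing.

## Known limitations

- No noise, readout-error or hardware-connectivity modelling: measured
  values from physical devices are out of scope by design, and the
  hardware-side numbers of the original experiments are not
  reproducible here.
- Two classes only; multi-class decision geometry is not implemented.
- The SIP sign regime must be declared, not inferred.
- Deletion/duplication typing and CNV calling from reads are upstream
  of this package.
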