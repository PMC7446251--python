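"""Classical feature-space layer: samples, class vectors and the inner-product metrics.

Two metrics score a binary CNV test profile against a class of training
profiles:

* AIP (active inner product): the total count of aligned 1-1 matches
  between the test and every training sample of the class.  Samples are
  amplitude-encoded with {0, 1} coefficients over computational basis
  states.
* SIP (symmetric inner product): total aligned matches (1-1 and 0-0)
  minus mismatches.  Samples are encoded with {+1, -1} coefficients.
  SIP ranks classes identically to (negative) total Hamming distance
  when the number of training samples per class is fixed.

The normalized inner product between the encoded test state |t> and the
class state |d^k> satisfies

    <t|d^k> = sigma / (eta_w * eta_t)        (SIP)
    <t|d^k> = sigma_11 / (eta_w * eta_t)     (AIP)

where sigma / sigma_11 are the integer match scores computed here
directly from bit counting, and eta_w, eta_t are the raw (Euclidean)
normalization constants.  These exact identities make this module the
oracle against which the quantum circuit pipeline is verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .genome import GenomicWindows

AIP = "aip"
SIP = "sip"
#: Returned by :func:`classify` when the two scores tie to within 1e-12.
AMBIGUOUS = "ambiguous"

_TIE_TOL = 1e-12


class DimensionError(ValueError):
    """Feature vectors of incompatible length."""


class DegenerateInputError(ValueError):
    """An input whose encoded state would be the (unnormalizable) zero vector."""


class ValidityError(ValueError):
    """A precondition of the classification metric does not hold."""


@dataclass(frozen=True)
class MetricConfig:
    """Configuration of a classification run.

    Parameters
    ----------
    metric
        ``"aip"`` or ``"sip"``.
    sign_mode
        Resolution of the SIP sign ambiguity: only |sigma| is measurable,
        so the caller declares whether matches are expected to dominate
        (pick the larger |inner product|) or mismatches (pick the
        smaller).  Ignored for AIP, which always picks the larger inner
        product.
    shots
        Shot count for sampled measurement; ``None`` means exact mode.
    norm_ratio_warn
        Warn when the class raw-normalization ratio deviates from 1 by
        more than this (metric validity caveat).
    """

    metric: Literal["aip", "sip"] = SIP
    sign_mode: Literal["matches_dominant", "mismatches_dominant"] = "matches_dominant"
    shots: int | None = 8192
    seed: int = 0
    norm_ratio_warn: float = 0.1

    def __post_init__(self) -> None:
        if self.metric not in (AIP, SIP):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.sign_mode not in ("matches_dominant", "mismatches_dominant"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")
        if self.shots is not None and self.shots < 1:
            raise ValueError("shots must be positive")

    @property
    def pad_value(self) -> int:
        """Coefficient assigned to padded pseudo-regions (0 for AIP, -1 for SIP)."""
        return 0 if self.metric == AIP else -1


@dataclass(frozen=True)
class BinarySample:
    """One individual's CNV presence/absence bit vector over N windows."""

    sample_id: str
    bits: np.ndarray = field(compare=False)
    label: int | None = None

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int64)
        if bits.ndim != 1 or bits.size == 0:
            raise DimensionError("bits must be a non-empty 1-d vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError(f"sample {self.sample_id!r}: bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")

    def __len__(self) -> int:
        return self.bits.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinarySample):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.label == other.label
            and np.array_equal(self.bits, other.bits)
        )


@dataclass(frozen=True)
class EncodedTest:
    """Unit-norm amplitude encoding of a test sample plus its raw norm."""

    amplitudes: np.ndarray
    eta_t: float

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if abs(np.linalg.norm(amps) - 1.0) > 1e-12:
            raise ValueError("encoded test state is not unit norm")


@dataclass(frozen=True)
class ClassVector:
    """Pre-summed training vectors of one class, raw and normalized.

    ``raw`` holds per-region summed coefficients over the W training
    samples (AIP: CNV counts >= 0; SIP: matches-minus-mismatch tallies in
    [-W, W]), padded to length 2^n.  ``eta`` is the raw normalization
    constant (Euclidean norm of ``raw``) and ``amplitudes = raw / eta``.
    """

    class_index: int
    raw: np.ndarray
    W: int
    eta: float = field(init=False)
    amplitudes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        object.__setattr__(self, "raw", raw)
        eta = float(np.linalg.norm(raw))
        if eta <= 0.0:
            raise DegenerateInputError(
                f"class {self.class_index}: raw class vector is zero and cannot be normalized"
            )
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "amplitudes", raw / eta)

    @property
    def n_qubits(self) -> int:
        return int(np.log2(self.raw.size))


class MatchCounts(NamedTuple):
    """Aligned match/mismatch counts between two bit vectors."""

    s11: int
    s00: int
    s01: int  # training bit 0, test bit 1
    s10: int  # training bit 1, test bit 0


def _bits(sample: BinarySample | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(sample, BinarySample):
        return sample.bits
    bits = np.asarray(sample, dtype=np.int64)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be 0 or 1")
    return bits


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size:
        raise DimensionError(f"length mismatch: {a.size} vs {b.size}")


def padded_size(n_features: int) -> int:
    """Smallest power of two >= max(n_features, 2)."""
    n = max(1, int(np.ceil(np.log2(max(n_features, 2)))))
    return 1 << n


def binarize_profile(
    copy_numbers: Sequence[int] | np.ndarray,
    baseline: int = 2,
    windows: GenomicWindows | None = None,
    sample_id: str = "sample",
    label: int | None = None,
) -> BinarySample:
    """Binarize integer copy numbers: 1 iff the copy number deviates from baseline.

    The diploid expectation is 2 copies per region; any deviation (gain
    or loss, no distinction) counts as a CNV.
    """
    cn = np.asarray(copy_numbers, dtype=np.int64)
    if cn.ndim != 1:
        raise DimensionError("copy_numbers must be a 1-d vector")
    if (cn < 0).any():
        raise ValueError("copy numbers must be non-negative")
    if windows is not None and cn.size != windows.N:
        raise DimensionError(
            f"profile has {cn.size} values but windows define {windows.N} regions"
        )
    return BinarySample(sample_id, (cn != baseline).astype(np.int64), label=label)


def _padded_coefficients(bits: np.ndarray, metric: str, size: int) -> np.ndarray:
    """Raw per-region coefficients of one sample, padded to ``size``.

    AIP keeps the bits and pads with 0 (no contribution); SIP maps
    0 -> -1 and pads with -1, so padding adds the same constant to every
    class score and preserves ranking at equal W.
    """
    coeff = np.full(size, 0 if metric == AIP else -1, dtype=np.int64)
    coeff[: bits.size] = bits if metric == AIP else 2 * bits - 1
    return coeff


def sample_to_amplitudes(sample: BinarySample, metric: str = AIP) -> EncodedTest:
    """Amplitude-encode a sample over the 2^n computational basis states."""
    bits = _bits(sample)
    size = padded_size(bits.size)
    coeff = _padded_coefficients(bits, metric, size).astype(float)
    eta = float(np.linalg.norm(coeff))
    if eta == 0.0:
        raise DegenerateInputError(
            f"sample {sample.sample_id!r} has no CNV: the AIP encoding is the zero vector"
        )
    return EncodedTest(coeff / eta, eta)


def build_class_vector(
    samples: Sequence[BinarySample], k: int, metric: str = AIP
) -> ClassVector:
    """Sum the training samples of class ``k`` into a class vector."""
    if not samples:
        raise ValueError("a class needs at least one training sample")
    lengths = {len(s) for s in samples}
    if len(lengths) != 1:
        raise DimensionError(f"training samples have differing lengths {sorted(lengths)}")
    size = padded_size(lengths.pop())
    raw = np.zeros(size, dtype=np.int64)
    for s in samples:
        raw += _padded_coefficients(s.bits, metric, size)
    try:
        return ClassVector(class_index=k, raw=raw, W=len(samples))
    except DegenerateInputError:
        raise DegenerateInputError(
            f"class {k}: summed {metric.upper()} coefficients are all zero "
            "(per-region +1/-1 contributions cancel)" if metric == SIP
            else f"class {k}: no training sample has any CNV"
        ) from None


def hamming_distance(a, b) -> int:
    """Number of positions at which two bit vectors differ."""
    ab, bb = _bits(a), _bits(b)
    _check_same_length(ab, bb)
    return int(np.count_nonzero(ab != bb))


def match_mismatch_counts(a, b) -> MatchCounts:
    """Aligned (1-1, 0-0, 0-1, 1-0) counts; ``a`` is training, ``b`` test."""
    ab, bb = _bits(a), _bits(b)
    _check_same_length(ab, bb)
    s11 = int(np.count_nonzero(ab & bb))
    s00 = int(np.count_nonzero((1 - ab) & (1 - bb)))
    s01 = int(np.count_nonzero((1 - ab) & bb))
    s10 = int(np.count_nonzero(ab & (1 - bb)))
    return MatchCounts(s11, s00, s01, s10)


def sip_score(test, class_samples: Sequence) -> int:
    """sigma: total matches minus mismatches of ``test`` against every class sample."""
    if len(class_samples) == 0:
        raise ValueError("class_samples must not be empty")
    total = 0
    for d in class_samples:
        c = match_mismatch_counts(d, test)
        total += c.s11 + c.s00 - c.s01 - c.s10
    return total


def aip_score(test, class_samples: Sequence) -> int:
    """sigma_11: total aligned 1-1 matches of ``test`` against every class sample."""
    if len(class_samples) == 0:
        raise ValueError("class_samples must not be empty")
    return sum(match_mismatch_counts(d, test).s11 for d in class_samples)


def feature_inner_product(test: EncodedTest, cv: ClassVector) -> float:
    """A_k = <t|d^k>, the inner product of the normalized encoded states.

    Equals sigma / (eta_w * eta_t) for SIP and sigma_11 / (eta_w * eta_t)
    for AIP, exactly.
    """
    if test.amplitudes.size != cv.amplitudes.size:
        raise DimensionError(
            f"dimension mismatch: test {test.amplitudes.size} vs class {cv.amplitudes.size}"
        )
    return float(np.dot(test.amplitudes, cv.amplitudes))


def classify(a0: float, a1: float, config: MetricConfig):
    """Pick the class from the two inner products A_0, A_1.

    AIP (and SIP in the matches-dominant regime) selects the larger
    |A_k|; SIP in the mismatches-dominant regime selects the smaller.
    Returns :data:`AMBIGUOUS` on an exact tie (within 1e-12); shot-based
    readouts never receive a significance test.
    """
    m0, m1 = abs(a0), abs(a1)
    if abs(m0 - m1) < _TIE_TOL:
        return AMBIGUOUS
    larger = 0 if m0 > m1 else 1
    if config.metric == AIP or config.sign_mode == "matches_dominant":
        return larger
    return 1 - larger


def classifiability(a0: float, a1: float) -> float:
    """F = |A_1 - A_0|: 0 for an equidistant test, 1 for a fully decided one."""
    return abs(a1 - a0)


class ScalingReport(NamedTuple):
    ratio: float
    flagged: bool


def scaling_factor_check(cv0: ClassVector, cv1: ClassVector, tol: float = 0.1) -> ScalingReport:
    """Ratio eta_1 / eta_0 of the raw normalization constants.

    The metrics are valid when the two classes have similar raw norms;
    the report is flagged when |ratio - 1| > tol.
    """
    ratio = cv1.eta / cv0.eta
    return ScalingReport(ratio=float(ratio), flagged=bool(abs(ratio - 1.0) > tol))


def zero_coefficient_exclusion(
    windows: GenomicWindows,
    test: BinarySample,
    class_vectors: Sequence[ClassVector],
    tol: float = 1e-9,
):
    """Drop feature dimensions where the test bit is 0 (AIP only).

    Regions without a test CNV cannot contribute to an active inner
    product, so they can be removed and the surviving regions re-indexed,
    shrinking the qubit count to ceil(log2(#kept)).  The AIP ranking is
    preserved whenever the post-remap raw normalization constants of the
    two classes agree (within ``tol``) or each class holds a single
    training vector; otherwise the remap is refused.

    Returns ``(new_windows, new_test, new_class_vectors)``.
    """
    bits = _bits(test)
    if bits.size != windows.N:
        raise DimensionError(f"test has {bits.size} bits but windows define {windows.N}")
    kept = np.flatnonzero(bits)
    if kept.size == 0:
        raise DegenerateInputError("test sample has no CNV; nothing would remain")
    new_windows = GenomicWindows([windows.windows[i] for i in kept])
    new_size = padded_size(kept.size)
    remapped = []
    for cv in class_vectors:
        if (cv.raw < 0).any():
            raise ValidityError("zero-coefficient exclusion applies to the AIP metric only")
        new_raw = np.zeros(new_size, dtype=cv.raw.dtype)
        new_raw[: kept.size] = cv.raw[kept]
        try:
            remapped.append(ClassVector(class_index=cv.class_index, raw=new_raw, W=cv.W))
        except DegenerateInputError:
            raise ValidityError(
                f"class {cv.class_index} has no CNV in any kept region after remapping"
            ) from None
    single_training = all(cv.W == 1 for cv in class_vectors)
    if not single_training and len(remapped) == 2:
        ratio = remapped[1].eta / remapped[0].eta
        if abs(ratio - 1.0) > tol:
            raise ValidityError(
                "zero-coefficient exclusion refused: post-remap raw normalization "
                f"constants differ (ratio {ratio:.6g}); the AIP ranking is no longer "
                "guaranteed unless each class holds a single training vector"
            )
    new_test = BinarySample(test.sample_id, np.ones(kept.size, dtype=np.int64), label=test.label)
    return new_windows, new_test, remapped
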