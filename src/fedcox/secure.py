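"""Fixed-point codec and the 2-party secure scalar product with a commodity server.

The protocol (Du–Zhan style) computes A.B between Alice and Bob without either
revealing its vector. A commodity server (trusted third party) pre-generates
correlated masks R_a, R_b with scalars r_a + r_b = R_a.R_b and sends (R_a, r_a)
to Alice, (R_b, r_b) to Bob; it never sees data or transcript messages. Then

    1. Alice sends  A_hat = A + R_a   to Bob,
       Bob   sends  B_hat = B + R_b   to Alice;
    2. Bob draws a random V_2 and sends  A_hat.B + (r_b - V_2)  to Alice;
    3. Alice computes  V_1 = (that message) - R_a.B_hat + r_a.

V_1 + V_2 = A.B holds as an exact integer identity (additive secret shares).
All arithmetic is on unbounded Python integers, so the identity is exact with
no modular ring and no overflow. Real-valued inputs are made protocol-ready by
fixed-point encoding: x is scaled by 10^precision and rounded half-away-from-zero;
the revealed result is divided back by the scale exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FixedPointCodec",
    "CommodityShares",
    "ProtocolTranscript",
    "encode_fixed_point",
    "decode_fixed_point",
    "commodity_generate",
    "run_two_party_dot",
    "secure_masked_sum",
    "secure_masked_sum_with_transcript",
    "DEFAULT_MASK_RANGE",
]

DEFAULT_MASK_RANGE = 2 ** 40


def _int_dot(a: Sequence[int], b: Sequence[int]) -> int:
    return sum(int(x) * int(y) for x, y in zip(a, b))


@dataclass(frozen=True)
class FixedPointCodec:
    """Decimal fixed-point encoding: reals <-> integers scaled by 10^precision."""

    precision: int = 5

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise ValueError("precision must be >= 0")

    @property
    def scale(self) -> int:
        return 10 ** self.precision

    def encode(self, x) -> list[int]:
        return encode_fixed_point(x, self)

    def decode(self, v: int) -> float:
        return decode_fixed_point(v, self)


def encode_fixed_point(x, codec: FixedPointCodec) -> list[int]:
    """Scale by 10^precision and round half-away-from-zero to exact integers."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(~np.isfinite(arr)):
        raise ValueError("cannot encode non-finite values")
    s = codec.scale
    out = []
    for v in arr:
        mag = int(math.floor(abs(v) * s + 0.5))
        out.append(mag if v >= 0 else -mag)
    return out


def decode_fixed_point(v: int, codec: FixedPointCodec) -> float:
    """Scale an integer protocol result back to the real domain."""
    return int(v) / codec.scale


@dataclass(frozen=True)
class CommodityShares:
    """Correlated masks from the commodity server: r_a + r_b = R_a . R_b exactly."""

    R_a: tuple[int, ...]
    R_b: tuple[int, ...]
    r_a: int
    r_b: int
    mask_range: int = DEFAULT_MASK_RANGE

    def __post_init__(self) -> None:
        if self.r_a + self.r_b != _int_dot(self.R_a, self.R_b):
            raise ValueError("invalid shares: r_a + r_b != R_a . R_b")


def commodity_generate(n: int, mask_range: int = DEFAULT_MASK_RANGE,
                       seed: int = 0) -> CommodityShares:
    """Generate commodity-server masks for a length-``n`` protocol run.

    Components of R_a, R_b and r_a are uniform integers on
    [-mask_range, mask_range]; r_b = R_a.R_b - r_a closes the identity exactly.
    The commodity role is a pure function of (n, mask_range, seed): it never
    sees the parties' vectors or any transcript message.
    """
    if n < 1:
        raise ValueError("protocol vectors must have length >= 1")
    if mask_range < 1:
        raise ValueError("mask_range must be >= 1")
    rng = np.random.default_rng(seed)
    draw = rng.integers(-mask_range, mask_range + 1, size=2 * n + 1)
    R_a = tuple(int(v) for v in draw[:n])
    R_b = tuple(int(v) for v in draw[n:2 * n])
    r_a = int(draw[2 * n])
    r_b = _int_dot(R_a, R_b) - r_a
    return CommodityShares(R_a=R_a, R_b=R_b, r_a=r_a, r_b=r_b,
                           mask_range=mask_range)


@dataclass(frozen=True)
class ProtocolTranscript:
    """Every message of one scalar-product run, for inspection and accounting.

    ``vector_elements_sent`` counts vector elements only (R_a, R_b, A_hat,
    B_hat: 4n); the three standalone scalars (r_a, r_b, Bob's combined message)
    are part of the transcript but excluded from the headline count.
    """

    A_masked: tuple[int, ...]
    B_masked: tuple[int, ...]
    bob_message: int
    V_1: int
    V_2: int
    vector_elements_sent: int


def run_two_party_dot(A: Sequence[int], B: Sequence[int], shares: CommodityShares,
                      seed: int = 0, v2: int | None = None) -> ProtocolTranscript:
    """Execute one secure scalar-product run; V_1 + V_2 = A.B exactly.

    ``v2`` injects Bob's random share deterministically (used to reproduce
    worked traces); otherwise V_2 is drawn uniformly from the mask range.
    """
    A = [int(a) for a in A]
    B = [int(b) for b in B]
    n = len(A)
    if len(B) != n:
        raise ValueError(f"length mismatch: |A|={n}, |B|={len(B)}")
    if len(shares.R_a) != n:
        raise ValueError(f"shares were generated for length {len(shares.R_a)}, not {n}")
    if v2 is None:
        rng = np.random.default_rng(seed)
        v2 = int(rng.integers(-shares.mask_range, shares.mask_range + 1))
    A_hat = [a + ra for a, ra in zip(A, shares.R_a)]         # Alice -> Bob
    B_hat = [b + rb for b, rb in zip(B, shares.R_b)]         # Bob -> Alice
    bob_message = _int_dot(A_hat, B) + (shares.r_b - v2)     # Bob -> Alice
    V_1 = bob_message - _int_dot(shares.R_a, B_hat) + shares.r_a
    return ProtocolTranscript(A_masked=tuple(A_hat), B_masked=tuple(B_hat),
                              bob_message=bob_message, V_1=V_1, V_2=v2,
                              vector_elements_sent=4 * n)


def secure_masked_sum(x, mask, codec: FixedPointCodec,
                      commodity_seed: int = 0,
                      mask_range: int = DEFAULT_MASK_RANGE) -> float:
    """Sum of ``x`` over the positions flagged by a Boolean ``mask``, securely.

    The party holds the real vector ``x`` (fixed-point encoded); the aggregator
    holds the raw 0/1 ``mask`` (left unscaled, so the result is decoded by a
    single division). The aggregator reveals its share V_2 to the party, which
    reconstructs (V_1 + V_2) / scale. The result matches the plaintext masked
    sum to within 0.5 * (number of ones) * 10^-precision.
    """
    value, _ = secure_masked_sum_with_transcript(
        x, mask, codec, commodity_seed=commodity_seed, mask_range=mask_range)
    return value


def secure_masked_sum_with_transcript(
        x, mask, codec: FixedPointCodec, commodity_seed: int = 0,
        mask_range: int = DEFAULT_MASK_RANGE) -> tuple[float, ProtocolTranscript]:
    """As :func:`secure_masked_sum`, also returning the run's transcript."""
    mask_arr = np.atleast_1d(np.asarray(mask))
    if not np.isin(mask_arr, (0, 1)).all():
        raise ValueError("mask must contain only 0/1 entries")
    A = encode_fixed_point(x, codec)
    B = [int(v) for v in mask_arr]
    shares = commodity_generate(len(A), mask_range=mask_range, seed=commodity_seed)
    transcript = run_two_party_dot(A, B, shares, seed=commodity_seed + 1)
    return decode_fixed_point(transcript.V_1 + transcript.V_2, codec), transcript
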