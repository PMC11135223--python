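"""Prime-field arithmetic underlying the secret-sharing schemes.

All secure computation here happens in Z_p for a public prime p. The prime
must exceed the panel length m, so that set cardinalities (sums of at most m
bits) are represented exactly and never wrap. The default modulus is the
Mersenne prime 2^61 - 1, which comfortably exceeds any realistic SNP panel
while keeping share values in machine-friendly 8-byte words.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy

#: Default field modulus: the Mersenne prime 2^61 - 1.
DEFAULT_PRIME = (1 << 61) - 1


class FieldError(ValueError):
    """Raised for invalid field parameters or out-of-domain elements."""


@dataclass(frozen=True)
class FieldParams:
    """Parameters of the prime field Z_p.

    Parameters
    ----------
    prime
        The field modulus. Checked for primality at construction
        (probabilistic Miller-Rabin via :func:`sympy.isprime`, exact for
        all moduli of practical size here).
    """

    prime: int

    def __post_init__(self) -> None:
        if not isinstance(self.prime, int) or self.prime < 2:
            raise FieldError(f"field modulus must be an integer >= 2, got {self.prime!r}")
        if not sympy.isprime(self.prime):
            raise FieldError(f"field modulus {self.prime} is not prime")

    @property
    def element_bytes(self) -> int:
        """Serialized width of one field element, in bytes."""
        return (self.prime.bit_length() + 7) // 8

    def element(self, value: int) -> "FieldElement":
        return FieldElement(value % self.prime, self)

    def contains(self, value: int) -> bool:
        return isinstance(value, int) and 0 <= value < self.prime


@dataclass(frozen=True)
class FieldElement:
    """An element of Z_p; closed under +, -, *, and inversion of nonzero values."""

    value: int
    params: FieldParams

    def __post_init__(self) -> None:
        if not self.params.contains(self.value):
            raise FieldError(
                f"value {self.value!r} not in field Z_{self.params.prime}"
            )

    def _check(self, other: "FieldElement") -> None:
        if self.params.prime != other.params.prime:
            raise FieldError("field mismatch between operands")

    def __add__(self, other: "FieldElement") -> "FieldElement":
        self._check(other)
        return FieldElement((self.value + other.value) % self.params.prime, self.params)

    def __sub__(self, other: "FieldElement") -> "FieldElement":
        self._check(other)
        return FieldElement((self.value - other.value) % self.params.prime, self.params)

    def __mul__(self, other: "FieldElement") -> "FieldElement":
        self._check(other)
        return FieldElement((self.value * other.value) % self.params.prime, self.params)

    def __neg__(self) -> "FieldElement":
        return FieldElement((-self.value) % self.params.prime, self.params)

    def inverse(self) -> "FieldElement":
        if self.value == 0:
            raise FieldError("0 has no multiplicative inverse")
        return FieldElement(pow(self.value, -1, self.params.prime), self.params)

    def __int__(self) -> int:
        return self.value
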