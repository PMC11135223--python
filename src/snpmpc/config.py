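"""Protocol configuration shared by the sharing layer and the MPC runtime."""

from __future__ import annotations

import json
import random
import secrets
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .field import DEFAULT_PRIME, FieldParams

SCHEMES = ("shamir", "additive")
TRANSPORTS = ("inprocess", "tcp")


class InvalidConfigError(ValueError):
    """Raised when (scheme, n, t, prime) are mutually inconsistent."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Public parameters of a protocol run.

    Defaults follow the honest-majority deployment the protocols target:
    three computing parties with threshold 1 under Shamir sharing. Additive
    sharing admits as few as two parties (the two input providers computing
    on their own shares).

    ``seed`` exists for reproducible tests and simulation only; when it is
    None (the default) all sharing randomness comes from the operating
    system's CSPRNG. Outputs that depend on randomness record whether a seed
    was used.
    """

    scheme: str = "shamir"
    n_parties: int = 3
    threshold: int = 1
    prime: int = DEFAULT_PRIME
    transport: str = "inprocess"
    seed: Optional[int] = None
    triple_budget: int = 0
    field_params: FieldParams = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise InvalidConfigError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.transport not in TRANSPORTS:
            raise InvalidConfigError(
                f"unknown transport {self.transport!r}; choose from {TRANSPORTS}"
            )
        if self.scheme == "shamir":
            if self.n_parties < 3:
                raise InvalidConfigError("shamir sharing requires at least 3 parties")
            if not 1 <= self.threshold < self.n_parties:
                raise InvalidConfigError(
                    f"shamir threshold must satisfy 1 <= t < n, got t={self.threshold}, "
                    f"n={self.n_parties}"
                )
        else:
            if self.n_parties < 2:
                raise InvalidConfigError("additive sharing requires at least 2 parties")
        object.__setattr__(self, "field_params", FieldParams(self.prime))

    def rng(self) -> random.Random:
        """Randomness source: seeded PRNG in test mode, CSPRNG otherwise."""
        if self.seed is not None:
            return random.Random(self.seed)
        return secrets.SystemRandom()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n": self.n_parties,
            "t": self.threshold,
            "prime": self.prime,
            "transport": self.transport,
            "seed": self.seed,
            "triple_budget": self.triple_budget,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        known = {
            "scheme": d.get("scheme", "shamir"),
            "n_parties": d.get("n", d.get("n_parties", 3)),
            "threshold": d.get("t", d.get("threshold", 1)),
            "prime": d.get("prime", DEFAULT_PRIME),
            "transport": d.get("transport", "inprocess"),
            "seed": d.get("seed"),
            "triple_budget": d.get("triple_budget", 0),
        }
        return cls(**known)

    @classmethod
    def from_file(cls, path: str | Path) -> "ProtocolConfig":
        """Load a config from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise InvalidConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
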