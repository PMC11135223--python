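"""Secret sharing: share generation (GENSHARE) and reconstruction (RECONSTRUCT).

Two schemes are provided, matching the two families of MPC protocols the
tool targets:

* **Shamir threshold sharing** — a secret s in Z_p is the constant term of a
  random polynomial f of degree t; party i holds the point (i, f(i)). Any
  t+1 shares reconstruct s by Lagrange interpolation at x=0; any t shares
  are jointly uniform and reveal nothing.
* **Additive sharing** — the secret is the sum of all n shares mod p; any
  proper subset of shares is uniform. Reconstruction needs every share.

Both schemes are linear: sums of shares are shares of sums, and scaling by a
public constant scales the secret, so affine operations on shared values
need no interaction between parties.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .config import ProtocolConfig
from .field import FieldElement, FieldParams


class SharingError(ValueError):
    """Base class for sharing/reconstruction failures."""


class InsufficientSharesError(SharingError):
    """Too few shares to reconstruct under the scheme's access structure."""


class InconsistentSharesError(SharingError):
    """Shares disagree on scheme, field, threshold, or party indices."""


@dataclass(frozen=True)
class Share:
    """One party's share of a single field element.

    Every share record carries the full sharing parameters so that
    reconstruction can fail loudly on any mismatch instead of silently
    combining incompatible shares.
    """

    party_index: int
    value: int
    scheme: str
    prime: int
    n_parties: int
    threshold: Optional[int] = None  # shamir only

    def __post_init__(self) -> None:
        if not 1 <= self.party_index <= self.n_parties:
            raise SharingError(
                f"party_index {self.party_index} outside [1, {self.n_parties}]"
            )
        if not 0 <= self.value < self.prime:
            raise SharingError(f"share value {self.value} outside field Z_{self.prime}")
        if self.scheme == "shamir" and self.threshold is None:
            raise SharingError("shamir share requires a threshold")


@dataclass(frozen=True)
class ShareVector:
    """One party's shares of an m-dimensional vector of field elements.

    The optional ``panel_digest`` binds the sharing to the SNP panel the
    underlying presence vector was encoded against; protocols refuse to
    combine vectors bound to different panels.
    """

    party_index: int
    values: tuple
    scheme: str
    prime: int
    n_parties: int
    threshold: Optional[int] = None
    panel_digest: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def share_at(self, i: int) -> Share:
        return Share(
            party_index=self.party_index,
            value=self.values[i],
            scheme=self.scheme,
            prime=self.prime,
            n_parties=self.n_parties,
            threshold=self.threshold,
        )


def _as_int(secret: int | FieldElement, params: FieldParams) -> int:
    if isinstance(secret, FieldElement):
        if secret.params.prime != params.prime:
            raise SharingError("secret belongs to a different field")
        return secret.value
    if not params.contains(secret):
        raise SharingError(f"secret {secret!r} not in field Z_{params.prime}")
    return secret


def genshare(
    secret: int | FieldElement,
    config: ProtocolConfig,
    rng: random.Random,
) -> list[Share]:
    """Split ``secret`` into one share per party under ``config``.

    Shamir: evaluates f(x) = secret + r_1 x + ... + r_t x^t at x = 1..n,
    with r_1..r_t drawn uniformly from Z_p. Additive: n-1 uniform shares,
    the last chosen so all n sum to the secret mod p.
    """
    p = config.prime
    s = _as_int(secret, config.field_params)
    vals = _genshare_values(s, config, rng)
    t = config.threshold if config.scheme == "shamir" else None
    return [
        Share(
            party_index=i + 1,
            value=v,
            scheme=config.scheme,
            prime=p,
            n_parties=config.n_parties,
            threshold=t,
        )
        for i, v in enumerate(vals)
    ]


def _genshare_values(s: int, config: ProtocolConfig, rng: random.Random) -> list[int]:
    p = config.prime
    n = config.n_parties
    if config.scheme == "shamir":
        coeffs = [rng.randrange(p) for _ in range(config.threshold)]
        out = []
        for x in range(1, n + 1):
            acc = 0
            for c in reversed(coeffs):  # Horner on the nonconstant part
                acc = (acc + c) * x % p
            out.append((acc + s) % p)
        return out
    head = [rng.randrange(p) for _ in range(n - 1)]
    return head + [(s - sum(head)) % p]


def lagrange_weights_at_zero(xs: Sequence[int], prime: int) -> list[int]:
    """Lagrange basis coefficients L_i(0) for interpolation points ``xs``."""
    ws = []
    for i, xi in enumerate(xs):
        num, den = 1, 1
        for j, xj in enumerate(xs):
            if i == j:
                continue
            num = num * (-xj) % prime
            den = den * (xi - xj) % prime
        ws.append(num * pow(den, -1, prime) % prime)
    return ws


def _check_consistent(shares: Sequence[Share]) -> Share:
    first = shares[0]
    for sh in shares[1:]:
        if (
            sh.scheme != first.scheme
            or sh.prime != first.prime
            or sh.threshold != first.threshold
            or sh.n_parties != first.n_parties
        ):
            raise InconsistentSharesError(
                "shares disagree on scheme/prime/threshold/party-count"
            )
    idx = [sh.party_index for sh in shares]
    if len(set(idx)) != len(idx):
        raise InconsistentSharesError(f"duplicate party indices in {idx}")
    return first


def reconstruct(shares: Iterable[Share]) -> FieldElement:
    """Recover the secret from a qualifying set of shares.

    Shamir needs any t+1 shares with distinct party indices; additive needs
    all n. The result is exact — reconstruction after genshare is the
    identity on the field.
    """
    shares = list(shares)
    if not shares:
        raise InsufficientSharesError("no shares given")
    first = _check_consistent(shares)
    params = FieldParams(first.prime)
    p = first.prime
    if first.scheme == "shamir":
        if len(shares) < first.threshold + 1:
            raise InsufficientSharesError(
                f"shamir with t={first.threshold} needs {first.threshold + 1} shares, "
                f"got {len(shares)}"
            )
        use = shares[: first.threshold + 1]
        ws = lagrange_weights_at_zero([sh.party_index for sh in use], p)
        val = sum(w * sh.value for w, sh in zip(ws, use)) % p
        return params.element(val)
    if len(shares) != first.n_parties:
        raise InsufficientSharesError(
            f"additive sharing needs all {first.n_parties} shares, got {len(shares)}"
        )
    return params.element(sum(sh.value for sh in shares) % p)


# -- vector sharing -------------------------------------------------------


def genshare_vector(
    values: Sequence[int],
    config: ProtocolConfig,
    rng: random.Random,
    panel_digest: Optional[str] = None,
) -> list[ShareVector]:
    """Elementwise genshare of a vector; returns one ShareVector per party."""
    per_party: list[list[int]] = [[] for _ in range(config.n_parties)]
    params = config.field_params
    for v in values:
        v = _as_int(v, params)
        for i, sv in enumerate(_genshare_values(v, config, rng)):
            per_party[i].append(sv)
    t = config.threshold if config.scheme == "shamir" else None
    return [
        ShareVector(
            party_index=i + 1,
            values=tuple(vals),
            scheme=config.scheme,
            prime=config.prime,
            n_parties=config.n_parties,
            threshold=t,
            panel_digest=panel_digest,
        )
        for i, vals in enumerate(per_party)
    ]


def reconstruct_vector(share_vectors: Sequence[ShareVector]) -> list[int]:
    """Elementwise reconstruction from a qualifying set of ShareVectors."""
    if not share_vectors:
        raise InsufficientSharesError("no share vectors given")
    m = len(share_vectors[0])
    if any(len(sv) != m for sv in share_vectors):
        raise InconsistentSharesError("share vectors have differing lengths")
    first = share_vectors[0]
    p = first.prime
    for sv in share_vectors[1:]:
        if (
            sv.scheme != first.scheme
            or sv.prime != p
            or sv.threshold != first.threshold
            or sv.n_parties != first.n_parties
        ):
            raise InconsistentSharesError("share vectors disagree on parameters")
        if sv.panel_digest != first.panel_digest:
            raise InconsistentSharesError("share vectors bound to different panels")
    idx = [sv.party_index for sv in share_vectors]
    if len(set(idx)) != len(idx):
        raise InconsistentSharesError(f"duplicate party indices in {idx}")
    if first.scheme == "shamir":
        if len(share_vectors) < first.threshold + 1:
            raise InsufficientSharesError(
                f"need {first.threshold + 1} share vectors, got {len(share_vectors)}"
            )
        use = share_vectors[: first.threshold + 1]
        ws = lagrange_weights_at_zero([sv.party_index for sv in use], p)
        return [
            sum(w * sv.values[j] for w, sv in zip(ws, use)) % p for j in range(m)
        ]
    if len(share_vectors) != first.n_parties:
        raise InsufficientSharesError(
            f"additive sharing needs all {first.n_parties} share vectors"
        )
    return [sum(sv.values[j] for sv in share_vectors) % p for j in range(m)]


# -- share files ----------------------------------------------------------
#
# Newline-delimited format: a JSON header line carrying the full sharing
# parameters, then one integer share value per line. Round-trips bit-exactly.


def write_share_vector(sv: ShareVector, path: str | Path) -> None:
    header = {
        "prime": sv.prime,
        "scheme": sv.scheme,
        "n": sv.n_parties,
        "t": sv.threshold,
        "party_index": sv.party_index,
        "vector_length": len(sv),
        "panel_digest": sv.panel_digest,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for v in sv.values:
            fh.write(f"{v}\n")


def read_share_vector(path: str | Path) -> ShareVector:
    with open(path) as fh:
        header = json.loads(fh.readline())
        values = [int(line) for line in fh if line.strip()]
    if len(values) != header["vector_length"]:
        raise SharingError(
            f"{path}: header declares {header['vector_length']} values, "
            f"found {len(values)}"
        )
    return ShareVector(
        party_index=header["party_index"],
        values=tuple(values),
        scheme=header["scheme"],
        prime=header["prime"],
        n_parties=header["n"],
        threshold=header["t"],
        panel_digest=header.get("panel_digest"),
    )
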