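"""Simulated multi-party execution environment.

The runtime executes secret-shared arithmetic among n computing parties in
lockstep within one process, while keeping each party's view honest: a party
only ever sees its own shares, publicly opened (masked) values, and
randomness issued by the trusted dealer. Messages travel through a pluggable
transport — an in-process queue by default, or real localhost TCP sockets —
and every byte sent is charged to a cost ledger, so communication and round
counts can be measured for any protocol built on top.

Multiplication of shared values (the interactive primitive, written π_mult
in protocol descriptions) uses Beaver triples issued by a trusted dealer
during preprocessing. The dealer is an explicit trust assumption of this
semihonest runtime: it learns nothing about inputs, but the triples it
issues must be correct and uniform. Affine operations — adding shares,
adding a public constant, scaling by a public constant — are local and cost
zero communication.

Recipient index 0 denotes the querying user: values opened "to the user"
are sent there and reconstructed outside the compute parties.
"""

from __future__ import annotations

import itertools
import json
import queue
import random
import socket
import threading
from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import InvalidConfigError, ProtocolConfig
from .sharing import (
    InconsistentSharesError,
    ShareVector,
    genshare_vector,
    lagrange_weights_at_zero,
    reconstruct_vector,
)

USER_INDEX = 0


class TripleExhaustedError(RuntimeError):
    """The preprocessed Beaver-triple pool is empty; no silent fallback."""


class TransportError(RuntimeError):
    pass


# -- serialization of field-element payloads ------------------------------


def serialize_elements(values: Sequence[int], width: int) -> bytes:
    return b"".join(v.to_bytes(width, "big") for v in values)


def deserialize_elements(payload: bytes, width: int) -> list[int]:
    return [
        int.from_bytes(payload[i : i + width], "big")
        for i in range(0, len(payload), width)
    ]


# -- transports -----------------------------------------------------------


class InProcessTransport:
    """Ordered, reliable, per-pair FIFO delivery via in-memory queues."""

    def __init__(self) -> None:
        self._queues: dict[tuple[int, int], deque] = defaultdict(deque)

    def send(self, src: int, dst: int, payload: bytes) -> None:
        self._queues[(src, dst)].append(payload)

    def recv(self, dst: int, src: int) -> bytes:
        q = self._queues[(src, dst)]
        if not q:
            raise TransportError(f"no pending message from {src} to {dst}")
        return q.popleft()

    def close(self) -> None:
        self._queues.clear()


class TcpTransport:
    """Full mesh of localhost TCP connections, one per endpoint pair.

    Each endpoint drains its sockets on background threads into per-sender
    queues, so lockstep send-all-then-receive-all scheduling cannot deadlock
    on kernel socket buffers. Frames are length-prefixed (4 bytes, big
    endian). Endpoints include the user (index 0).
    """

    def __init__(self, indices: Sequence[int], timeout: float = 30.0) -> None:
        self._timeout = timeout
        self._socks: dict[tuple[int, int], socket.socket] = {}
        self._queues: dict[tuple[int, int], queue.Queue] = {}
        self._threads: list[threading.Thread] = []
        for i, j in itertools.combinations(sorted(indices), 2):
            listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
            listener.bind(("127.0.0.1", 0))
            listener.listen(1)
            port = listener.getsockname()[1]
            client = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
            client.connect(("127.0.0.1", port))
            server, _ = listener.accept()
            listener.close()
            self._socks[(i, j)] = server  # endpoint held by i, peer j
            self._socks[(j, i)] = client
            for src, dst in ((i, j), (j, i)):
                self._queues[(src, dst)] = queue.Queue()
                th = threading.Thread(
                    target=self._reader,
                    args=(self._socks[(dst, src)], self._queues[(src, dst)]),
                    daemon=True,
                )
                th.start()
                self._threads.append(th)

    @staticmethod
    def _read_exact(sock: socket.socket, count: int) -> Optional[bytes]:
        buf = b""
        while len(buf) < count:
            chunk = sock.recv(count - len(buf))
            if not chunk:
                return None
            buf += chunk
        return buf

    def _reader(self, sock: socket.socket, q: queue.Queue) -> None:
        while True:
            try:
                head = self._read_exact(sock, 4)
            except OSError:
                return
            if head is None:
                return
            payload = self._read_exact(sock, int.from_bytes(head, "big"))
            if payload is None:
                return
            q.put(payload)

    def send(self, src: int, dst: int, payload: bytes) -> None:
        sock = self._socks[(src, dst)]
        sock.sendall(len(payload).to_bytes(4, "big") + payload)

    def recv(self, dst: int, src: int) -> bytes:
        try:
            return self._queues[(src, dst)].get(timeout=self._timeout)
        except queue.Empty:
            raise TransportError(f"timed out waiting for message {src} -> {dst}")

    def close(self) -> None:
        for sock in self._socks.values():
            try:
                sock.close()
            except OSError:
                pass


def make_transport(config: ProtocolConfig):
    if config.transport == "tcp":
        return TcpTransport([USER_INDEX] + list(range(1, config.n_parties + 1)))
    return InProcessTransport()


# -- cost accounting ------------------------------------------------------


@dataclass
class CostLedger:
    """Bytes per directed party pair, protocol rounds, and multiplications.

    Affine operations never touch the ledger; every interactive step (a
    batched masked-value opening, an output opening) adds exactly one round.
    """

    bytes_sent: dict = field(default_factory=lambda: defaultdict(int))
    rounds: int = 0
    multiplications: int = 0

    def record_send(self, src: int, dst: int, nbytes: int) -> None:
        self.bytes_sent[(src, dst)] += nbytes

    @property
    def total_bytes(self) -> int:
        return sum(self.bytes_sent.values())

    def to_dict(self) -> dict:
        return {
            "bytes_per_pair": {f"{s}->{d}": b for (s, d), b in sorted(self.bytes_sent.items())},
            "total_bytes": self.total_bytes,
            "rounds": self.rounds,
            "mults": self.multiplications,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# -- parties and preprocessing --------------------------------------------


@dataclass
class Party:
    """One computing party: its index, role, and private register file."""

    index: int
    role: str = "compute_only"  # or "input_provider"
    store: dict = field(default_factory=dict)
    triples: deque = field(default_factory=deque)  # (a_i, b_i, c_i) share tuples

    def take_triples(self, count: int) -> list[tuple[int, int, int]]:
        if len(self.triples) < count:
            raise TripleExhaustedError(
                f"party {self.index}: {count} triples requested, "
                f"{len(self.triples)} available — deal more preprocessing"
            )
        return [self.triples.popleft() for _ in range(count)]


def deal_triples(
    count: int, config: ProtocolConfig, rng: random.Random
) -> list[list[tuple[int, int, int]]]:
    """Trusted-dealer preprocessing: ``count`` Beaver triples per party.

    Each triple is a sharing of (a, b, c) with a, b uniform in Z_p and
    c = a*b mod p; reconstructing any dealt triple satisfies the
    multiplicative relation exactly.
    """
    if count < 0:
        raise InvalidConfigError("triple count must be nonnegative")
    p = config.prime
    pools: list[list[tuple[int, int, int]]] = [[] for _ in range(config.n_parties)]
    for _ in range(count):
        a = rng.randrange(p)
        b = rng.randrange(p)
        c = a * b % p
        sv = genshare_vector([a, b, c], config, rng)
        for i, party_shares in enumerate(sv):
            pools[i].append(tuple(party_shares.values))
    return pools


# -- session --------------------------------------------------------------


@dataclass(frozen=True)
class Handle:
    """Opaque reference to a secret-shared vector living inside the parties."""

    name: str
    length: int
    panel_digest: Optional[str] = None


class MpcSession:
    """Lockstep orchestration of n parties over a transport.

    The session schedules the parties but never centralizes secrets: secret
    values exist only as per-party shares inside each :class:`Party`'s
    store, and cross-party data flows exclusively through the transport,
    where it is metered by the :class:`CostLedger`.
    """

    def __init__(
        self,
        config: ProtocolConfig,
        transport=None,
        rng: Optional[random.Random] = None,
    ) -> None:
        self.config = config
        self.transport = transport if transport is not None else make_transport(config)
        self.ledger = CostLedger()
        self.rng = rng if rng is not None else config.rng()
        self.parties = [
            Party(index=i, role="input_provider" if i <= 2 else "compute_only")
            for i in range(1, config.n_parties + 1)
        ]
        self._counter = itertools.count()
        self._width = config.field_params.element_bytes
        if config.triple_budget:
            self.preprocess(config.triple_budget)

    # -- preprocessing ----------------------------------------------------

    def preprocess(self, count: int) -> None:
        """Have the trusted dealer issue ``count`` triples to every party."""
        pools = deal_triples(count, self.config, self.rng)
        for party, pool in zip(self.parties, pools):
            party.triples.extend(pool)

    @property
    def triples_available(self) -> int:
        return min(len(p.triples) for p in self.parties)

    # -- input / registers ------------------------------------------------

    def _new_handle(self, length: int, panel_digest=None) -> Handle:
        return Handle(f"r{next(self._counter)}", length, panel_digest)

    def load_shares(self, share_vectors: Sequence[ShareVector]) -> Handle:
        """Install pre-generated per-party share vectors as a secret input."""
        if len(share_vectors) != self.config.n_parties:
            raise InconsistentSharesError(
                f"need one ShareVector per party ({self.config.n_parties}), "
                f"got {len(share_vectors)}"
            )
        by_index = {sv.party_index: sv for sv in share_vectors}
        if sorted(by_index) != list(range(1, self.config.n_parties + 1)):
            raise InconsistentSharesError("share vectors must cover parties 1..n")
        first = share_vectors[0]
        if first.scheme != self.config.scheme or first.prime != self.config.prime:
            raise InconsistentSharesError("share vectors do not match session config")
        h = self._new_handle(len(first), first.panel_digest)
        for party in self.parties:
            party.store[h.name] = list(by_index[party.index].values)
        return h

    def share_input(self, values: Sequence[int], rng: Optional[random.Random] = None) -> Handle:
        """Secret-share plaintext input (input phase; happens owner-side)."""
        svs = genshare_vector(values, self.config, rng if rng is not None else self.rng)
        return self.load_shares(svs)

    # -- affine operations (local, zero communication) ---------------------

    def _vals(self, h: Handle) -> list[list[int]]:
        return [party.store[h.name] for party in self.parties]

    def _store(self, vecs: list[list[int]], panel_digest=None) -> Handle:
        h = self._new_handle(len(vecs[0]), panel_digest)
        for party, v in zip(self.parties, vecs):
            party.store[h.name] = v
        return h

    def add(self, x: Handle, y: Handle) -> Handle:
        self._check_lengths(x, y)
        p = self.config.prime
        return self._store(
            [
                [(a + b) % p for a, b in zip(xv, yv)]
                for xv, yv in zip(self._vals(x), self._vals(y))
            ]
        )

    def sub(self, x: Handle, y: Handle) -> Handle:
        self._check_lengths(x, y)
        p = self.config.prime
        return self._store(
            [
                [(a - b) % p for a, b in zip(xv, yv)]
                for xv, yv in zip(self._vals(x), self._vals(y))
            ]
        )

    def scale(self, x: Handle, constant: int) -> Handle:
        p = self.config.prime
        c = constant % p
        return self._store([[a * c % p for a in xv] for xv in self._vals(x)])

    def add_public(self, x: Handle, constant: int) -> Handle:
        """Add a public constant to every component of a shared vector.

        Under Shamir every party adds the constant (a constant polynomial);
        under additive sharing only party 1 does, keeping the sum correct.
        """
        p = self.config.prime
        c = constant % p
        out = []
        for party, xv in zip(self.parties, self._vals(x)):
            if self.config.scheme == "shamir" or party.index == 1:
                out.append([(a + c) % p for a in xv])
            else:
                out.append(list(xv))
        return self._store(out)

    def sum_components(self, x: Handle) -> Handle:
        """Local share-sum over components: a sharing of sum_i x_i (length 1)."""
        p = self.config.prime
        return self._store([[sum(xv) % p] for xv in self._vals(x)])

    def _check_lengths(self, x: Handle, y: Handle) -> None:
        if x.length != y.length:
            raise InconsistentSharesError(
                f"operand lengths differ: {x.length} vs {y.length}"
            )

    # -- interactive operations -------------------------------------------

    def _broadcast_open(self, per_party_vals: list[list[int]]) -> list[int]:
        """Every party announces its shares to every other; all reconstruct.

        Used only for masked (uniformly distributed) values inside Beaver
        multiplication. One batched broadcast = one round.
        """
        n = self.config.n_parties
        payloads = [serialize_elements(v, self._width) for v in per_party_vals]
        for src in range(1, n + 1):
            for dst in range(1, n + 1):
                if src != dst:
                    self.transport.send(src, dst, payloads[src - 1])
                    self.ledger.record_send(src, dst, len(payloads[src - 1]))
        received = {}
        for dst in range(1, n + 1):
            for src in range(1, n + 1):
                if src != dst:
                    received[(dst, src)] = self.transport.recv(dst, src)
        self.ledger.rounds += 1
        # All parties hold identical announced share sets; reconstruct once.
        p = self.config.prime
        m = len(per_party_vals[0])
        announced = [
            deserialize_elements(payloads[i], self._width) for i in range(n)
        ]
        if self.config.scheme == "shamir":
            use = list(range(self.config.threshold + 1))
            ws = lagrange_weights_at_zero([i + 1 for i in use], p)
            return [
                sum(w * announced[i][j] for w, i in zip(ws, use)) % p
                for j in range(m)
            ]
        return [sum(announced[i][j] for i in range(n)) % p for j in range(m)]

    def mul(self, x: Handle, y: Handle) -> Handle:
        """Elementwise secure multiplication (π_mult) via Beaver triples.

        Consumes one triple per component and costs one communication round
        for the batched opening of the masked differences d = x - a and
        e = y - b. Raises :class:`TripleExhaustedError` rather than ever
        degrading to insecure plaintext multiplication.
        """
        self._check_lengths(x, y)
        m = x.length
        p = self.config.prime
        triples = [party.take_triples(m) for party in self.parties]
        xs, ys = self._vals(x), self._vals(y)
        d_shares = [
            [(xv[j] - tr[j][0]) % p for j in range(m)]
            for xv, tr in zip(xs, triples)
        ]
        e_shares = [
            [(yv[j] - tr[j][1]) % p for j in range(m)]
            for yv, tr in zip(ys, triples)
        ]
        opened = self._broadcast_open([d + e for d, e in zip(d_shares, e_shares)])
        d, e = opened[:m], opened[m:]
        out = []
        for party, tr in zip(self.parties, triples):
            z = [
                (tr[j][2] + d[j] * tr[j][1] + e[j] * tr[j][0]) % p
                for j in range(m)
            ]
            if self.config.scheme == "shamir" or party.index == 1:
                z = [(z[j] + d[j] * e[j]) % p for j in range(m)]
            out.append(z)
        self.ledger.multiplications += m
        digest = x.panel_digest if x.panel_digest == y.panel_digest else None
        return self._store(out, digest)

    def open_to_user(self, x: Handle) -> list[int]:
        """Output phase: each party sends its shares to the user (index 0),
        who alone reconstructs the plaintext. One round per batched open."""
        per_party = self._vals(x)
        svs = []
        t = self.config.threshold if self.config.scheme == "shamir" else None
        for party, vals in zip(self.parties, per_party):
            payload = serialize_elements(vals, self._width)
            self.transport.send(party.index, USER_INDEX, payload)
            self.ledger.record_send(party.index, USER_INDEX, len(payload))
        for party, vals in zip(self.parties, per_party):
            payload = self.transport.recv(USER_INDEX, party.index)
            svs.append(
                ShareVector(
                    party_index=party.index,
                    values=tuple(deserialize_elements(payload, self._width)),
                    scheme=self.config.scheme,
                    prime=self.config.prime,
                    n_parties=self.config.n_parties,
                    threshold=t,
                    panel_digest=x.panel_digest,
                )
            )
        self.ledger.rounds += 1
        return reconstruct_vector(svs)

    def party_output_shares(self, x: Handle) -> list[ShareVector]:
        """Each party's final output shares, for offline delivery to the user."""
        t = self.config.threshold if self.config.scheme == "shamir" else None
        return [
            ShareVector(
                party_index=party.index,
                values=tuple(party.store[x.name]),
                scheme=self.config.scheme,
                prime=self.config.prime,
                n_parties=self.config.n_parties,
                threshold=t,
                panel_digest=x.panel_digest,
            )
            for party in self.parties
        ]

    def close(self) -> None:
        self.transport.close()

    def __enter__(self) -> "MpcSession":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
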