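"""The MPC runtime: triples, secure multiplication, opens, cost accounting."""

import random

import pytest
from scipy import stats

from snpmpc.config import ProtocolConfig
from snpmpc.runtime import (
    InProcessTransport,
    MpcSession,
    TcpTransport,
    TripleExhaustedError,
    deal_triples,
    deserialize_elements,
    serialize_elements,
)
from snpmpc.sharing import Share, reconstruct


def _reconstruct_triple(pools, cfg, idx=0):
    t = cfg.threshold if cfg.scheme == "shamir" else None
    out = []
    for pos in range(3):  # a, b, c
        shares = [
            Share(i + 1, pools[i][idx][pos], cfg.scheme, cfg.prime, cfg.n_parties, t)
            for i in range(cfg.n_parties)
        ]
        out.append(reconstruct(shares).value)
    return out


class TestDealTriples:
    def test_worked_example(self):
        """Dealer fixes a=2, b=5 in F_13: c must reconstruct to 10."""
        cfg = ProtocolConfig(scheme="additive", n_parties=2, prime=13)

        class Rig(random.Random):
            def __init__(self):
                super().__init__()
                self._seq = [2, 5]  # a, b; then sharing randomness
                self._tail = random.Random(0)

            def randrange(self, *args):
                if self._seq:
                    return self._seq.pop(0)
                return self._tail.randrange(*args)

        pools = deal_triples(1, cfg, Rig())
        a, b, c = _reconstruct_triple(pools, cfg)
        assert (a, b, c) == (2, 5, 10)

    def test_zero_count_then_exhaustion(self, additive_config):
        session = MpcSession(additive_config)
        session.preprocess(0)
        x = session.share_input([1])
        y = session.share_input([1])
        with pytest.raises(TripleExhaustedError):
            session.mul(x, y)

    @pytest.mark.parametrize("scheme,n,t", [("shamir", 3, 1), ("additive", 2, 1)])
    def test_multiplicative_relation_holds(self, scheme, n, t):
        cfg = ProtocolConfig(scheme=scheme, n_parties=n, threshold=t, prime=101)
        pools = deal_triples(200, cfg, random.Random(5))
        for idx in range(200):
            a, b, c = _reconstruct_triple(pools, cfg, idx)
            assert a * b % 101 == c


class TestSecureMult:
    def test_beaver_worked_example(self):
        """x=4, y=6 in F_13 with triple (2,5,10): opened d=2, e=1, result 11."""
        cfg = ProtocolConfig(scheme="additive", n_parties=2, prime=13)
        session = MpcSession(cfg, rng=random.Random(3))
        # install the triple by hand: shares of a=2, b=5, c=10
        session.parties[0].triples.append((1, 2, 4))
        session.parties[1].triples.append((1, 3, 6))
        x = session.share_input([4])
        y = session.share_input([6])
        z = session.mul(x, y)
        assert session.open_to_user(z) == [11]  # 4*6 mod 13

    def test_multiply_by_zero(self, shamir_config):
        session = MpcSession(shamir_config)
        session.preprocess(4)
        x = session.share_input([0, 0, 0, 0])
        y = session.share_input([5, 1, 0, 3])
        assert session.open_to_user(session.mul(x, y)) == [0, 0, 0, 0]

    @pytest.mark.parametrize("scheme,n,t", [("shamir", 3, 1), ("additive", 2, 1)])
    def test_random_products_exact(self, scheme, n, t):
        cfg = ProtocolConfig(scheme=scheme, n_parties=n, threshold=t, seed=17)
        p = cfg.prime
        rng = random.Random(99)
        xs = [rng.randrange(p) for _ in range(50)]
        ys = [rng.randrange(p) for _ in range(50)]
        session = MpcSession(cfg)
        session.preprocess(50)
        hz = session.mul(session.share_input(xs), session.share_input(ys))
        assert session.open_to_user(hz) == [x * y % p for x, y in zip(xs, ys)]

    def test_triple_consumed_once(self, additive_config):
        session = MpcSession(additive_config)
        session.preprocess(1)
        x = session.share_input([2])
        y = session.share_input([3])
        session.mul(x, y)
        with pytest.raises(TripleExhaustedError):
            session.mul(x, y)


class TestAffine:
    """Affine operations are local: exact results, zero communication."""

    def test_add_sub_scale_public(self, shamir_config):
        session = MpcSession(shamir_config)
        x = session.share_input([3])
        y = session.share_input([4])
        before = session.ledger.total_bytes
        s = session.add(x, y)
        d = session.sub(x, y)
        sc = session.scale(x, 2)
        pc = session.add_public(x, 1)
        assert session.ledger.total_bytes == before  # no communication yet
        p = shamir_config.prime
        assert session.open_to_user(s) == [7]
        assert session.open_to_user(d) == [(3 - 4) % p]
        assert session.open_to_user(sc) == [6]
        assert session.open_to_user(pc) == [4]

    def test_scale_wraps_in_field(self):
        cfg = ProtocolConfig(scheme="shamir", n_parties=3, threshold=1, prime=13, seed=1)
        session = MpcSession(cfg)
        h = session.scale(session.share_input([9]), 2)
        assert session.open_to_user(h) == [18 % 13]

    def test_add_public_constant_random_secrets(self, additive_config):
        session = MpcSession(additive_config)
        rng = random.Random(4)
        p = additive_config.prime
        secrets = [rng.randrange(p) for _ in range(100)]
        h = session.add_public(session.share_input(secrets), 1)
        assert session.open_to_user(h) == [(s + 1) % p for s in secrets]


class TestOpenAndLedger:
    def test_open_batching_one_round(self, shamir_config):
        session = MpcSession(shamir_config)
        h = session.share_input(list(range(100)))
        r0 = session.ledger.rounds
        opened = session.open_to_user(h)
        assert opened == list(range(100))
        assert session.ledger.rounds == r0 + 1

    def test_mult_costs_one_round_plus_open(self, additive_config):
        session = MpcSession(additive_config)
        session.preprocess(10)
        x = session.share_input([1] * 10)
        y = session.share_input([1] * 10)
        z = session.mul(x, y)
        assert session.ledger.rounds == 1
        session.open_to_user(z)
        assert session.ledger.rounds == 2
        assert session.ledger.multiplications == 10

    def test_bytes_grow_with_vector_length(self, additive_config):
        totals = []
        for m in (8, 64, 256):
            session = MpcSession(additive_config)
            session.preprocess(m)
            x = session.share_input([1] * m)
            y = session.share_input([0] * m)
            session.mul(x, y)
            totals.append(session.ledger.total_bytes)
        assert totals[0] < totals[1] < totals[2]

    def test_ledger_export(self, tmp_path, additive_config):
        session = MpcSession(additive_config)
        session.preprocess(2)
        z = session.mul(session.share_input([1, 1]), session.share_input([1, 0]))
        session.open_to_user(z)
        out = tmp_path / "ledger.json"
        session.ledger.to_json(out)
        import json

        d = json.loads(out.read_text())
        assert d["mults"] == 2
        assert d["rounds"] == 2
        assert d["total_bytes"] == sum(d["bytes_per_pair"].values())


class TestSchemeEquivalence:
    def test_identical_outputs_across_schemes(self):
        """The same plaintext pipeline gives identical results under both schemes."""
        rng = random.Random(21)
        xs = [rng.randrange(2) for _ in range(20)]
        ys = [rng.randrange(2) for _ in range(20)]
        results = []
        for scheme, n in (("shamir", 3), ("additive", 2)):
            cfg = ProtocolConfig(scheme=scheme, n_parties=n, threshold=1, seed=5)
            session = MpcSession(cfg)
            session.preprocess(20)
            z = session.mul(session.share_input(xs), session.share_input(ys))
            results.append(session.open_to_user(z))
        assert results[0] == results[1]


class TestTransports:
    def test_serialization_roundtrip(self):
        vals = [0, 1, 2**61 - 2]
        assert deserialize_elements(serialize_elements(vals, 8), 8) == vals

    def test_inprocess_fifo_order(self):
        tr = InProcessTransport()
        tr.send(1, 2, b"first")
        tr.send(1, 2, b"second")
        assert tr.recv(2, 1) == b"first"
        assert tr.recv(2, 1) == b"second"

    def test_tcp_transport_delivers(self):
        tr = TcpTransport([0, 1, 2])
        try:
            tr.send(1, 2, b"hello")
            tr.send(2, 0, b"out")
            assert tr.recv(2, 1) == b"hello"
            assert tr.recv(0, 2) == b"out"
        finally:
            tr.close()

    def test_protocol_over_tcp_matches_inprocess(self):
        results = []
        for transport in ("inprocess", "tcp"):
            cfg = ProtocolConfig(
                scheme="shamir", n_parties=3, threshold=1, seed=31, transport=transport
            )
            with MpcSession(cfg) as session:
                session.preprocess(8)
                x = session.share_input([1, 0, 1, 1, 0, 1, 0, 0])
                y = session.share_input([1, 1, 0, 1, 0, 0, 1, 0])
                results.append(session.open_to_user(session.mul(x, y)))
        assert results[0] == results[1] == [1, 0, 0, 1, 0, 0, 0, 0]


class TestTranscriptPrivacy:
    def test_received_messages_invariant_to_other_input(self):
        """A party's received messages are distributed identically whatever
        the other provider's secret input is (semihonest masking check)."""
        cfg_base = dict(scheme="shamir", n_parties=3, threshold=1, prime=101)
        a = [1, 0]
        counts = {}
        for label, b in (("b1", [1, 1]), ("b2", [0, 0])):
            hist = [0] * 101
            for seed in range(800):
                cfg = ProtocolConfig(**cfg_base, seed=seed + (0 if label == "b1" else 10**6))
                session = MpcSession(cfg)
                session.preprocess(2)
                tr = session.transport

                recorded = []
                orig_send = tr.send

                def send(src, dst, payload, _rec=recorded):
                    if dst == 3:
                        _rec.append(payload)
                    orig_send(src, dst, payload)

                tr.send = send
                session.mul(session.share_input(a), session.share_input(b))
                for payload in recorded:
                    for v in deserialize_elements(payload, session._width):
                        hist[v] += 1
            counts[label] = hist
        chi2, p, *_ = stats.chi2_contingency([counts["b1"], counts["b2"]])
        assert p > 0.001
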