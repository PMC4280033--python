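"""Tracker: announce/scrape flows, pruning, dashboards, confinement."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from seedportal import metainfo as mi
from seedportal.authz import PortalStore, Role
from seedportal.feedgen import publish_torrent
from seedportal.tracker import (AnnounceRequest, AnnounceResponse, Tracker,
                                TrackerFailure, decode_compact_peers,
                                encode_compact_peers)

PIECE = mi.MIN_PIECE_LENGTH


def _register(world, payload_file, feed_name="genomes", size=4 * PIECE,
              seed=3):
    """Publish a torrent into a feed; returns (info_hash, total_length)."""
    path = payload_file(size, seed=seed, name=f"p{seed}.bin")
    torrent = mi.create_torrent(path, PIECE, "https://portal.example/t")
    record = publish_torrent(world.store, world.feeds[feed_name].id,
                             torrent.to_bytes(), world.token("root@portal"))
    return record.info_hash, record.total_length


def _announce(world, token, info_hash, peer_no, left, event="",
              **overrides):
    req = AnnounceRequest(
        token=token,
        info_hash=info_hash,
        peer_id=bytes([peer_no]) * 20,
        port=6881 + peer_no,
        left=left,
        event=event,
        address=overrides.pop("address", f"10.0.0.{peer_no}"),
        **overrides,
    )
    return world.tracker.handle_announce(req)


@pytest.fixture
def registered(world, payload_file):
    return _register(world, payload_file)


def test_announce_registers_and_lists_other_peers(world, registered):
    ih, total = registered
    sub = world.token("sub@lab")
    first = _announce(world, sub, ih, 1, left=total, event="started")
    assert isinstance(first, AnnounceResponse)
    assert first.interval > 0
    assert first.peers == []  # requester excluded from its own list
    second = _announce(world, world.token("pub@lab"), ih, 2, left=0)
    assert [p.peer_id for p in second.peers] == [bytes([1]) * 20]
    assert (second.complete, second.incomplete) == (1, 1)


def test_announce_failure_modes(world, registered, payload_file):
    ih, total = registered
    sub = world.token("sub@lab")
    # unknown/rotated token -> unauthorized with HTTP auth status
    fail = _announce(world, "no-such-token", ih, 1, left=0)
    assert isinstance(fail, TrackerFailure)
    assert fail.reason == "unauthorized" and fail.http_status == 401
    old = sub
    world.tokens["sub@lab"] = world.store.rotate_token("sub@lab")
    assert _announce(world, old, ih, 1, left=0).reason == "unauthorized"
    # valid token, role none on the owning feed -> forbidden
    out = _announce(world, world.token("out@lab"), ih, 3, left=0)
    assert out.reason.startswith("forbidden")
    # foreign info-hash -> private-network refusal
    foreign = _announce(world, world.token("pub@lab"), b"\x01" * 20, 4, left=0)
    assert foreign.reason == "unregistered torrent"
    # malformed parameters
    bad = world.tracker.handle_announce(AnnounceRequest(
        token=world.token("pub@lab"), info_hash=b"short", peer_id=b"p" * 20,
        port=6881))
    assert bad.reason.startswith("bad request")
    assert bad.http_status == 200


def test_seeder_accounting_and_completion_percent(world, registered):
    ih, total = registered
    sub = world.token("sub@lab")
    resp = _announce(world, sub, ih, 1, left=0)
    assert (resp.complete, resp.incomplete) == (1, 0)
    peer = world.tracker._swarms[ih][bytes([1]) * 20]
    assert peer.completed and peer.completion_percent(total) == 100.0
    half = _announce(world, sub, ih, 2, left=total // 2)
    peer2 = world.tracker._swarms[ih][bytes([2]) * 20]
    assert peer2.completion_percent(total) == pytest.approx(50.0)
    assert (half.complete, half.incomplete) == (1, 1)


def test_keep_alive_idempotent_and_stopped_removes(world, registered):
    ih, total = registered
    sub = world.token("sub@lab")
    for _ in range(5):
        _announce(world, sub, ih, 1, left=total)
    assert world.tracker.swarm_size(ih) == 1
    resp = _announce(world, sub, ih, 1, left=total, event="stopped")
    assert world.tracker.swarm_size(ih) == 0
    assert resp.complete + resp.incomplete == 0


def test_peer_count_conservation(world, registered):
    ih, total = registered
    sub, pub = world.token("sub@lab"), world.token("pub@lab")
    for i, left in enumerate([0, total, total // 2, 0], start=1):
        resp = _announce(world, sub if i % 2 else pub, ih, i, left=left)
    assert resp.complete + resp.incomplete == world.tracker.swarm_size(ih) == 4


def test_prune_stale_and_seamless_reappearance(world, registered):
    ih, total = registered
    sub = world.token("sub@lab")
    now = [1000.0]
    world.tracker.clock = lambda: now[0]
    _announce(world, sub, ih, 1, left=total)
    now[0] += world.tracker.peer_timeout + 1
    assert world.tracker.prune_stale() == 1
    assert world.tracker.swarm_size(ih) == 0
    # infinite timeout removes nothing
    _announce(world, sub, ih, 2, left=total)
    now[0] += 10 ** 9
    assert world.tracker.prune_stale(timeout=float("inf")) == 0
    # the pruned peer simply re-announces with fresh counters
    resp = _announce(world, sub, ih, 1, left=0)
    assert world.tracker.swarm_size(ih) == 2
    assert isinstance(resp, AnnounceResponse)


def test_scrape_counts_and_confinement(world, registered, payload_file):
    ih, total = registered
    other_ih, _ = _register(world, payload_file, feed_name="assays", seed=9)
    sub = world.token("sub@lab")
    _announce(world, sub, ih, 1, left=0)
    _announce(world, sub, ih, 2, left=total)
    _announce(world, sub, ih, 3, left=total // 4)
    stats = world.tracker.handle_scrape(sub, [ih, other_ih, b"\x02" * 20])
    assert stats[ih] == {"complete": 1, "incomplete": 2, "downloaded": 1}
    # sub@lab holds no role on the assays feed: counts must not leak
    assert "error" in stats[other_ih]
    assert "complete" not in stats[other_ih]
    assert "error" in stats[b"\x02" * 20]
    # empty but registered swarm scrapes to zeros for an authorized token
    empty = world.tracker.handle_scrape(world.token("root@portal"),
                                        [other_ih])
    assert empty[other_ih] == {"complete": 0, "incomplete": 0, "downloaded": 0}


def test_no_peer_lists_across_roles_small_world(world, payload_file):
    """3 users x 2 feeds x all role assignments: an announce only ever
    succeeds (and hence only ever returns peers) when the token's role on
    the owning feed allows joining."""
    store = world.store
    ih_by_feed = {
        "genomes": _register(world, payload_file, "genomes", seed=21)[0],
        "assays": _register(world, payload_file, "assays", seed=22)[0],
    }
    users = ["pub@lab", "sub@lab", "out@lab"]
    roles = [Role.NONE, Role.SUBSCRIBER, Role.PUBLISHER]
    peer_no = itertools.count(10)
    for assignment in itertools.product(roles, repeat=len(users)):
        for feed_name, ih in ih_by_feed.items():
            feed = world.feeds[feed_name]
            for email, role in zip(users, assignment):
                store.grant_role(world.admin, email, feed.id, role)
            for email, role in zip(users, assignment):
                resp = _announce(world, world.token(email), ih,
                                 next(peer_no) % 200 + 1, left=0)
                if role is Role.NONE:
                    assert isinstance(resp, TrackerFailure)
                else:
                    assert isinstance(resp, AnnounceResponse)


def test_swarm_status_rows_and_denial(world, registered):
    ih, total = registered
    feed = world.feeds["genomes"]
    sub = world.token("sub@lab")
    _announce(world, sub, ih, 1, left=0)
    _announce(world, sub, ih, 2, left=total // 2)
    rows = world.tracker.swarm_status(feed.id, sub)
    assert [r.completion_percent for r in rows] == [100.0, 50.0]
    assert [r.is_seeder for r in rows] == [True, False]
    assert all(r.location == "unknown" for r in rows)  # stub geolocation
    # empty feed -> no rows
    assert world.tracker.swarm_status(world.feeds["assays"].id,
                                      world.token("root@portal")) == []
    denied = world.tracker.swarm_status(feed.id, world.token("out@lab"))
    assert not isinstance(denied, list) and not denied.allowed


def test_pluggable_geolocation(world, registered):
    ih, total = registered
    world.tracker.geolocate = lambda addr: f"geo:{addr}"
    sub = world.token("sub@lab")
    _announce(world, sub, ih, 1, left=0)
    rows = world.tracker.swarm_status(world.feeds["genomes"].id, sub)
    assert rows[0].location == "geo:10.0.0.1"


@settings(max_examples=100, deadline=None)
@given(st.lists(st.tuples(
    st.integers(0, 2 ** 32 - 1).map(
        lambda n: ".".join(str(n >> s & 0xFF) for s in (24, 16, 8, 0))),
    st.integers(1, 65535)), max_size=30))
def test_compact_peer_encoding_round_trip(peers):
    blob = encode_compact_peers(peers)
    assert len(blob) == 6 * len(peers)
    assert decode_compact_peers(blob) == peers
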