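"""Authenticated private-only BitTorrent tracker core.

Peers announce over HTTP to register themselves in a swarm (the set of
peers for one info-hash) and to learn about other members.  Unlike a
public tracker, every announce carries a per-user token in the URL path
and is checked against the portal's role matrix, and only info-hashes
registered in some portal feed are tracked at all — an unregistered
(foreign) hash is refused outright, which is what partitions the
network's data logically.

Failures follow tracker convention: a bencoded dictionary with a
``failure reason`` key, served with HTTP 200 — except authentication
failures, which additionally carry an HTTP 401 status so that
misconfigured clients fail loudly.

The registry is in-memory (a tracker restart merely forces re-announce,
as with stock trackers); peers that stop announcing are pruned after a
timeout and simply reappear when they announce again, which is how nodes
on intermittent connections recover membership.
"""

from __future__ import annotations

import ipaddress
import struct
import time
from dataclasses import dataclass, field
from typing import Callable, Optional

from . import bencode
from .authz import Action, Decision, PortalStore

__all__ = [
    "DEFAULT_ANNOUNCE_INTERVAL",
    "DEFAULT_MAX_PEERS",
    "AnnounceRequest",
    "PeerRecord",
    "AnnounceResponse",
    "TrackerFailure",
    "Tracker",
    "encode_compact_peers",
    "decode_compact_peers",
]

DEFAULT_ANNOUNCE_INTERVAL = 1800  # seconds between keep-alives
DEFAULT_MAX_PEERS = 50

EVENTS = ("started", "stopped", "completed", "")


@dataclass
class AnnounceRequest:
    """One announce: registration / keep-alive / status update."""

    token: str
    info_hash: bytes
    peer_id: bytes
    port: int
    uploaded: int = 0
    downloaded: int = 0
    left: int = 0
    event: str = ""
    compact: int = 1
    address: str = "127.0.0.1"
    secure_channel: bool = True

    def validate(self) -> Optional[str]:
        if len(self.info_hash) != 20:
            return "info_hash must be 20 bytes"
        if len(self.peer_id) != 20:
            return "peer_id must be 20 bytes"
        if not (0 < self.port < 65536):
            return "invalid port"
        if self.event not in EVENTS:
            return f"unknown event {self.event!r}"
        if min(self.uploaded, self.downloaded, self.left) < 0:
            return "negative byte counter"
        return None


@dataclass
class PeerRecord:
    peer_id: bytes
    address: str
    port: int
    uploaded: int = 0
    downloaded: int = 0
    left: int = 0
    last_announce: float = 0.0
    completed: bool = False

    @property
    def is_seeder(self) -> bool:
        return self.left == 0

    def completion_percent(self, total_bytes: int) -> float:
        """100 x (1 - left/total), clamped to [0, 100]."""
        if total_bytes <= 0:
            return 100.0 if self.left == 0 else 0.0
        return max(0.0, min(100.0, 100.0 * (1.0 - self.left / total_bytes)))


@dataclass
class AnnounceResponse:
    interval: int
    complete: int
    incomplete: int
    peers: list[PeerRecord]
    compact: bool = True

    def to_bencoded(self) -> bytes:
        doc: dict = {
            b"interval": self.interval,
            b"complete": self.complete,
            b"incomplete": self.incomplete,
        }
        if self.compact:
            ipv4 = [p for p in self.peers if _is_ipv4(p.address)]
            doc[b"peers"] = encode_compact_peers(
                [(p.address, p.port) for p in ipv4]
            )
            ipv6 = [p for p in self.peers if not _is_ipv4(p.address)]
            if ipv6:
                doc[b"peers_dict"] = [_peer_dict(p) for p in ipv6]
        else:
            doc[b"peers"] = [_peer_dict(p) for p in self.peers]
        return bencode.encode(doc)


@dataclass
class TrackerFailure:
    """A refused announce/scrape; ``http_status`` 401 for token failures,
    200 otherwise (standard tracker failure convention)."""

    reason: str
    http_status: int = 200

    def to_bencoded(self) -> bytes:
        return bencode.encode({b"failure reason": self.reason.encode("utf-8")})


def _is_ipv4(address: str) -> bool:
    try:
        return isinstance(ipaddress.ip_address(address), ipaddress.IPv4Address)
    except ValueError:
        return False


def _peer_dict(p: PeerRecord) -> dict:
    return {b"peer id": p.peer_id, b"ip": p.address.encode("ascii"),
            b"port": p.port}


def encode_compact_peers(peers: list[tuple[str, int]]) -> bytes:
    """BEP-0023 compact form: 6 bytes per peer — 4 address bytes and a
    big-endian 2-byte port."""
    out = bytearray()
    for address, port in peers:
        out += ipaddress.IPv4Address(address).packed
        out += struct.pack(">H", port)
    return bytes(out)


def decode_compact_peers(data: bytes) -> list[tuple[str, int]]:
    if len(data) % 6:
        raise ValueError("compact peer blob length not a multiple of 6")
    return [
        (str(ipaddress.IPv4Address(data[i:i + 4])),
         struct.unpack(">H", data[i + 4:i + 6])[0])
        for i in range(0, len(data), 6)
    ]


@dataclass
class DashboardRow:
    """One per-peer line of the operator dashboard."""

    torrent_name: str
    info_hash_hex: str
    peer_id_hex: str
    address: str
    location: str
    completion_percent: float
    last_announce: float
    is_seeder: bool


class Tracker:
    """Announce/scrape engine over the portal store's feeds and roles.

    ``geolocate`` is a pluggable ``address -> label`` resolver for the
    dashboard; the default stub reports ``"unknown"`` (real deployments
    plug in a GeoIP lookup).  ``clock`` is injectable for tests.
    """

    def __init__(
        self,
        store: PortalStore,
        *,
        interval: int = DEFAULT_ANNOUNCE_INTERVAL,
        peer_timeout: Optional[float] = None,
        max_peers: int = DEFAULT_MAX_PEERS,
        geolocate: Optional[Callable[[str], str]] = None,
        clock: Callable[[], float] = time.time,
    ):
        self.store = store
        self.interval = interval
        # keep-alive grace: a peer may miss one announce and a half
        self.peer_timeout = (
            2.5 * interval if peer_timeout is None else peer_timeout
        )
        self.max_peers = max_peers
        self.geolocate = geolocate or (lambda address: "unknown")
        self.clock = clock
        self._swarms: dict[bytes, dict[bytes, PeerRecord]] = {}

    # -- announce ----------------------------------------------------------

    def handle_announce(self, req: AnnounceRequest) -> AnnounceResponse | TrackerFailure:
        problem = req.validate()
        if problem:
            return TrackerFailure(f"bad request: {problem}")

        user = self.store.user_for_token(req.token)
        if user is None or not user.approved:
            return TrackerFailure("unauthorized", http_status=401)

        record = self.store.find_torrent(req.info_hash)
        if record is None:
            return TrackerFailure("unregistered torrent")

        decision = self.store.authorize(
            req.token, record.feed_id, Action.ANNOUNCE,
            secure_channel=req.secure_channel,
        )
        if not decision:
            return TrackerFailure(f"forbidden: {decision.reason}")

        swarm = self._swarms.setdefault(req.info_hash, {})
        now = self.clock()

        if req.event == "stopped":
            swarm.pop(req.peer_id, None)
            others: list[PeerRecord] = []
        else:
            peer = swarm.get(req.peer_id)
            if peer is None:
                peer = PeerRecord(peer_id=req.peer_id, address=req.address,
                                  port=req.port)
                swarm[req.peer_id] = peer
            peer.address = req.address
            peer.port = req.port
            peer.uploaded = req.uploaded
            peer.downloaded = req.downloaded
            peer.left = req.left
            peer.last_announce = now
            if req.event == "completed" or req.left == 0:
                peer.completed = True
            others = [p for pid, p in sorted(swarm.items())
                      if pid != req.peer_id][: self.max_peers]

        complete = sum(1 for p in swarm.values() if p.is_seeder)
        incomplete = len(swarm) - complete
        return AnnounceResponse(
            interval=self.interval,
            complete=complete,
            incomplete=incomplete,
            peers=others,
            compact=bool(req.compact),
        )

    # -- scrape ------------------------------------------------------------

    def handle_scrape(self, token: str, info_hashes: list[bytes],
                      *, secure_channel: bool = True) -> dict[bytes, dict]:
        """Swarm statistics per info-hash.

        Hashes the token may not access (unregistered, or registered in
        a feed where the caller holds no role) come back as an ``error``
        marker instead of counts — no statistics leak across feeds.
        """
        result: dict[bytes, dict] = {}
        for ih in info_hashes:
            record = self.store.find_torrent(ih)
            if record is None:
                result[ih] = {"error": "unregistered torrent"}
                continue
            decision = self.store.authorize(
                token, record.feed_id, Action.ANNOUNCE,
                secure_channel=secure_channel,
            )
            if not decision:
                result[ih] = {"error": f"forbidden: {decision.reason}"}
                continue
            swarm = self._swarms.get(ih, {})
            complete = sum(1 for p in swarm.values() if p.is_seeder)
            downloaded = sum(1 for p in swarm.values() if p.completed)
            result[ih] = {
                "complete": complete,
                "incomplete": len(swarm) - complete,
                "downloaded": downloaded,
            }
        return result

    # -- maintenance -------------------------------------------------------

    def prune_stale(self, now: Optional[float] = None,
                    timeout: Optional[float] = None) -> int:
        """Drop peers whose last announce is older than *timeout*.

        A pruned peer's next announce simply re-adds it with fresh
        counters; nothing else needs to happen for a node resuming on an
        intermittent connection.
        """
        now = self.clock() if now is None else now
        timeout = self.peer_timeout if timeout is None else timeout
        removed = 0
        for swarm in self._swarms.values():
            stale = [pid for pid, p in swarm.items()
                     if now - p.last_announce > timeout]
            for pid in stale:
                del swarm[pid]
                removed += 1
        return removed

    # -- dashboard ---------------------------------------------------------

    def swarm_status(self, feed_id: int, token: str,
                     *, secure_channel: bool = True) -> list[DashboardRow] | Decision:
        """Per-torrent, per-peer dashboard rows for a feed.

        Pure read; returns the deny :class:`~seedportal.authz.Decision`
        itself when the caller lacks ``view_feed``.
        """
        decision = self.store.authorize(
            token, feed_id, Action.VIEW_FEED, secure_channel=secure_channel
        )
        if not decision:
            return decision
        rows: list[DashboardRow] = []
        for record in self.store.list_torrents(feed_id):
            swarm = self._swarms.get(record.info_hash, {})
            for pid in sorted(swarm):
                peer = swarm[pid]
                rows.append(DashboardRow(
                    torrent_name=record.name,
                    info_hash_hex=record.info_hash.hex(),
                    peer_id_hex=peer.peer_id.hex(),
                    address=peer.address,
                    location=self.geolocate(peer.address),
                    completion_percent=peer.completion_percent(
                        record.total_length),
                    last_announce=peer.last_announce,
                    is_seeder=peer.is_seeder,
                ))
        return rows

    def swarm_size(self, info_hash: bytes) -> int:
        return len(self._swarms.get(info_hash, {}))
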