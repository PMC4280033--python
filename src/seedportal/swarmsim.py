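"""Deterministic piece-level swarm simulator, churn experiments and the
volunteer-storage calculator.

The simulator stands in for a live multi-client replication experiment:
it models a swarm at the level of *piece ownership*, not bytes on the
wire.  Time is discrete ticks; each node has a bitfield (one bit per
piece), an online flag driven by a churn schedule, and per-tick download
and upload capacities in pieces.  Every tick, each online node missing
pieces requests the *rarest* missing piece held by an online peer —
the standard swarm heuristic — with deterministic tie-breaking (lowest
piece index, then lowest provider id) so that a configuration replays
to an identical trace.

The central availability fact the model exercises: as long as the union
of online nodes' bitfields covers every piece at all times, every
downloader eventually completes, even when any single node (including
the original publisher) drops out.  Conversely a piece absent from all
nodes can never be recovered.

Pieces fetched during a tick become visible to other peers at the next
tick; a transfer consumes one unit of the downloader's and one of the
provider's capacity.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from . import metainfo as mi

__all__ = [
    "PB", "PIB", "GIB", "MIB",
    "Bitfield",
    "NodeSpec",
    "ChurnEvent",
    "SimConfig",
    "Transfer",
    "SimTrace",
    "AvailabilityResult",
    "aggregate_availability",
    "simulate",
    "storage_per_device",
    "make_fixture",
    "Fixture",
]

PB = 10 ** 15          # decimal petabyte (storage-vendor convention)
PIB = 2 ** 50          # binary pebibyte
GIB = 2 ** 30
MIB = 2 ** 20


# ---------------------------------------------------------------------------
# Bitfields and availability
# ---------------------------------------------------------------------------

class Bitfield:
    """Fixed-length per-piece ownership vector.

    Backed by an int bitmask; bit *i* set means piece *i* is held.
    """

    __slots__ = ("length", "_mask")

    def __init__(self, length: int, bits: Iterable[int] | int = 0):
        if length < 0:
            raise ValueError("negative bitfield length")
        self.length = length
        if isinstance(bits, int):
            self._mask = bits & ((1 << length) - 1)
        else:
            mask = 0
            for i in bits:
                if not 0 <= i < length:
                    raise IndexError(f"piece index {i} out of range")
                mask |= 1 << i
            self._mask = mask

    @classmethod
    def full(cls, length: int) -> "Bitfield":
        return cls(length, (1 << length) - 1)

    @classmethod
    def empty(cls, length: int) -> "Bitfield":
        return cls(length)

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, i: int) -> bool:
        if not 0 <= i < self.length:
            raise IndexError(i)
        return bool(self._mask >> i & 1)

    def set(self, i: int) -> None:
        if not 0 <= i < self.length:
            raise IndexError(i)
        self._mask |= 1 << i

    def count(self) -> int:
        return self._mask.bit_count()

    @property
    def complete(self) -> bool:
        return self._mask == (1 << self.length) - 1

    def missing(self) -> list[int]:
        return [i for i in range(self.length) if not self._mask >> i & 1]

    def as_mask(self) -> int:
        return self._mask

    def copy(self) -> "Bitfield":
        return Bitfield(self.length, self._mask)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Bitfield)
                and other.length == self.length
                and other._mask == self._mask)

    def __repr__(self) -> str:
        bits = "".join("1" if self[i] else "0" for i in range(self.length))
        return f"Bitfield({bits})"


@dataclass(frozen=True)
class AvailabilityResult:
    complete: bool
    missing: list[int]


def aggregate_availability(bitfields: list[Bitfield],
                           online_mask: list[bool]) -> AvailabilityResult:
    """Whether the union of online nodes' pieces covers the torrent.

    ``complete`` iff the bitwise OR over online bitfields is all-ones;
    ``missing`` lists the piece indices no online node holds.  All
    bitfields must share one length.
    """
    if len(bitfields) != len(online_mask):
        raise ValueError("bitfields and online_mask lengths differ")
    if not bitfields:
        raise ValueError("no bitfields given")
    length = bitfields[0].length
    if any(bf.length != length for bf in bitfields):
        raise ValueError("bitfield lengths differ")
    union = 0
    for bf, online in zip(bitfields, online_mask):
        if online:
            union |= bf.as_mask()
    missing = [i for i in range(length) if not union >> i & 1]
    return AvailabilityResult(complete=not missing, missing=missing)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class NodeSpec:
    """One simulated client.

    ``role`` is a semantic label: ``publisher`` (starts with the full
    payload), ``subscriber`` (starts empty, wants everything) or
    ``dedicated`` (a high-availability replica that also downloads
    everything).  ``seeded`` overrides the role's default starting
    bitfield when given.
    """

    id: str
    role: str = "subscriber"
    download_capacity: int = 1
    upload_capacity: int = 1
    online: bool = True
    seeded: Optional[bool] = None

    def starts_full(self) -> bool:
        return self.role == "publisher" if self.seeded is None else self.seeded

    def __post_init__(self):
        if self.download_capacity < 0 or self.upload_capacity < 0:
            raise ValueError("capacities must be >= 0")
        if self.role not in ("publisher", "subscriber", "dedicated"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class ChurnEvent:
    tick: int
    node_id: str
    online: bool


@dataclass
class SimConfig:
    piece_count: int
    nodes: list[NodeSpec]
    churn: list[ChurnEvent] = field(default_factory=list)
    tick_limit: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.piece_count <= 0:
            raise ValueError("piece_count must be positive")
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")

    def initially_recoverable(self) -> bool:
        """True iff at tick 0 the online nodes jointly hold every piece."""
        bfs = [Bitfield.full(self.piece_count) if n.starts_full()
               else Bitfield.empty(self.piece_count) for n in self.nodes]
        return aggregate_availability(
            bfs, [n.online for n in self.nodes]).complete

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        nodes = [NodeSpec(**spec) for spec in doc.get("nodes", [])]
        churn = [ChurnEvent(**ev) for ev in doc.get("churn", [])]
        return cls(
            piece_count=doc["piece_count"],
            nodes=nodes,
            churn=churn,
            tick_limit=doc.get("tick_limit", 1000),
            seed=doc.get("seed", 0),
        )


@dataclass(frozen=True)
class Transfer:
    tick: int
    piece: int
    src: str
    dst: str


@dataclass
class SimTrace:
    """Full record of one simulation run."""

    transfers: list[Transfer]
    completion_tick: dict[str, Optional[int]]
    final_bitfields: dict[str, Bitfield]
    availability: list[bool]          # aggregate completeness per tick
    ticks_run: int
    converged: bool                   # all downloaders completed
    seed: int

    def to_rows(self) -> list[dict]:
        return [
            {"tick": t.tick, "piece": t.piece, "src": t.src, "dst": t.dst}
            for t in self.transfers
        ]


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimTrace:
    """Run the piece-exchange model to completion or the tick limit.

    Per tick: churn events fire first; then every online node with
    missing pieces issues up to ``download_capacity`` requests.  A
    request picks, among pieces some online peer already held at the
    start of the tick and can still serve this tick, the piece with the
    fewest online holders (rarest-first); ties break to the lowest piece
    index, then the provider with the lowest node id.  Both parties'
    per-tick capacities bound the transfer count.

    Non-convergence is reported in the trace (``converged``), never
    raised: a schedule that starves a piece simply runs to the limit.
    """
    n_pieces = config.piece_count
    nodes = sorted(config.nodes, key=lambda n: n.id)
    bits = {n.id: (Bitfield.full(n_pieces) if n.starts_full()
                   else Bitfield.empty(n_pieces)) for n in nodes}
    online = {n.id: n.online for n in nodes}
    spec = {n.id: n for n in nodes}
    churn_by_tick: dict[int, list[ChurnEvent]] = {}
    for ev in config.churn:
        churn_by_tick.setdefault(ev.tick, []).append(ev)

    downloaders = [n.id for n in nodes if n.role != "publisher"]
    transfers: list[Transfer] = []
    completion: dict[str, Optional[int]] = {
        n.id: (0 if bits[n.id].complete else None) for n in nodes
    }
    availability: list[bool] = []

    ticks_run = 0
    for tick in range(1, config.tick_limit + 1):
        ticks_run = tick
        for ev in churn_by_tick.get(tick, []):
            if ev.node_id in online:
                online[ev.node_id] = ev.online

        availability.append(aggregate_availability(
            [bits[n.id] for n in nodes],
            [online[n.id] for n in nodes]).complete)

        # ownership snapshot: pieces fetched this tick serve only next tick
        snapshot = {nid: bits[nid].as_mask() for nid in bits if online[nid]}
        upload_left = {nid: spec[nid].upload_capacity
                       for nid in snapshot}

        gains: list[tuple[str, int]] = []
        for node in nodes:
            nid = node.id
            if not online[nid] or bits[nid].complete:
                continue
            got_this_tick: set[int] = set()
            for _ in range(node.download_capacity):
                choice = _pick_rarest(
                    nid, bits[nid], got_this_tick, snapshot, upload_left,
                    n_pieces,
                )
                if choice is None:
                    break
                piece, provider = choice
                upload_left[provider] -= 1
                got_this_tick.add(piece)
                gains.append((nid, piece))
                transfers.append(Transfer(tick, piece, provider, nid))

        for nid, piece in gains:
            bits[nid].set(piece)
            if bits[nid].complete and completion[nid] is None:
                completion[nid] = tick

        if all(completion[d] is not None for d in downloaders):
            break

    converged = all(completion[d] is not None for d in downloaders)
    return SimTrace(
        transfers=transfers,
        completion_tick=completion,
        final_bitfields={nid: bf.copy() for nid, bf in bits.items()},
        availability=availability,
        ticks_run=ticks_run,
        converged=converged,
        seed=config.seed,
    )


def _pick_rarest(nid: str, have: Bitfield, got: set[int],
                 snapshot: dict[str, int], upload_left: dict[str, int],
                 n_pieces: int) -> Optional[tuple[int, str]]:
    """Rarest servable missing piece and its provider, or None."""
    best: Optional[tuple[int, int, str]] = None  # (rarity, piece, provider)
    for piece in range(n_pieces):
        if have[piece] or piece in got:
            continue
        bit = 1 << piece
        holders = [pid for pid, mask in snapshot.items()
                   if pid != nid and mask & bit]
        if not holders:
            continue
        servers = sorted(p for p in holders if upload_left[p] > 0)
        if not servers:
            continue
        key = (len(holders), piece, servers[0])
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Volunteer-storage calculator
# ---------------------------------------------------------------------------

def storage_per_device(total_bytes: float, device_count: int,
                       participation_fraction: float) -> float:
    """Donated storage each participating device must contribute, in bytes.

    ``total_bytes / (device_count x participation_fraction)`` for a
    single replica of the archive spread over the participating subset
    of a volunteer network.  Convert with :data:`PB` / :data:`PIB` on
    the way in and :data:`GIB` on the way out; the module default
    convention is decimal petabytes in, binary gibibytes out.
    """
    if device_count <= 0:
        raise ValueError("device_count must be positive")
    if not 0 < participation_fraction <= 1:
        raise ValueError("participation_fraction must be in (0, 1]")
    return total_bytes / (device_count * participation_fraction)


# ---------------------------------------------------------------------------
# Reproducible fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    payload_path: Path
    torrent: mi.Metainfo
    piece_digests: list[bytes]

    @property
    def info_hash(self) -> mi.InfoHash:
        return self.torrent.info_hash()


def random_payload(size: int, seed: int) -> bytes:
    """Seeded random binary payload; same seed, same bytes, any platform."""
    return random.Random(seed).randbytes(size)


def make_fixture(dest_dir: str | Path, payload_size: int,
                 piece_length: int = mi.DEFAULT_PIECE_LENGTH,
                 seed: int = 0,
                 announce: str = "https://localhost/t") -> Fixture:
    """Write a seeded random payload file and build its torrent.

    Reproducible end to end: the same seed yields byte-identical payload
    and therefore an identical info-hash.  Used for desk-scale analogues
    of replication experiments on random binary content.
    """
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    path = dest / f"payload-{seed}-{payload_size}.bin"
    rng = random.Random(seed)
    with open(path, "wb") as fh:
        remaining = payload_size
        while remaining > 0:
            chunk = rng.randbytes(min(1 << 20, remaining))
            fh.write(chunk)
            remaining -= len(chunk)
    torrent = mi.create_torrent(path, piece_length, announce)
    return Fixture(payload_path=path, torrent=torrent,
                   piece_digests=torrent.piece_digests)
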