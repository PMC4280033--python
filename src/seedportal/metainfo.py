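"""Create, parse, privatize, tokenize and verify .torrent metainfo.

A metainfo document describes a payload without containing it: the
``info`` dictionary holds the payload name, the piece length, one 20-byte
SHA-1 digest per piece, and either a single ``length`` or a ``files``
list for directory payloads.  The SHA-1 over the canonically bencoded
``info`` entry — the *info-hash* — is the global identity of the torrent
and of its swarm; any change to an info field (including the BEP-0027
``private`` flag) produces a different swarm.

Only BitTorrent v1 metainfo (SHA-1, 20-byte digests) is supported; the
private-flag access model predates and is incompatible with v2/hybrid
torrents as deployed here.  Piece indexing is 0-based throughout.
"""

from __future__ import annotations

import hashlib
import os
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import bencode

__all__ = [
    "DEFAULT_PIECE_LENGTH",
    "MIN_PIECE_LENGTH",
    "MetainfoError",
    "InfoHash",
    "Metainfo",
    "VerificationReport",
    "create_torrent",
    "compute_info_hash",
    "privatize",
    "tokenize_announce",
    "verify_payload",
    "read_torrent",
    "write_torrent",
]

#: 4 MiB — the piece size used throughout this portal's reference
#: deployment; configurable per torrent.
DEFAULT_PIECE_LENGTH = 4 * 1024 * 1024

#: Smallest accepted piece size (16 KiB, the BitTorrent block size).
MIN_PIECE_LENGTH = 16 * 1024

SHA1_LEN = 20


class MetainfoError(ValueError):
    """Malformed metainfo or invalid torrent-creation input."""


@dataclass(frozen=True)
class InfoHash:
    """SHA-1 digest of the bencoded ``info`` entry, in its three renderings."""

    digest: bytes

    def __post_init__(self):
        if len(self.digest) != SHA1_LEN:
            raise MetainfoError("info-hash must be 20 bytes")

    @property
    def hex(self) -> str:
        return self.digest.hex()

    @property
    def urlencoded(self) -> str:
        """Percent-escaped form as sent in tracker query strings."""
        return urllib.parse.quote_from_bytes(self.digest)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hex


@dataclass
class Metainfo:
    """A parsed .torrent: announce URL plus the raw ``info`` dictionary.

    ``info`` is kept as the decoded bencode dictionary (bytes keys) so
    that re-encoding is exact; convenience accessors expose the common
    fields.  ``extras`` carries top-level keys other than ``announce``
    and ``info`` (e.g. ``creation date``, ``comment``).
    """

    announce: str
    info: dict
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        parsed = urllib.parse.urlsplit(self.announce)
        if parsed.scheme not in ("http", "https") or not parsed.netloc:
            raise MetainfoError(
                f"announce must be an absolute HTTP(S) URL, got {self.announce!r}"
            )
        _validate_info(self.info)

    # -- info accessors ----------------------------------------------------
    @property
    def name(self) -> str:
        return self.info[b"name"].decode("utf-8")

    @property
    def piece_length(self) -> int:
        return self.info[b"piece length"]

    @property
    def piece_count(self) -> int:
        return len(self.info[b"pieces"]) // SHA1_LEN

    @property
    def piece_digests(self) -> list[bytes]:
        raw = self.info[b"pieces"]
        return [raw[i:i + SHA1_LEN] for i in range(0, len(raw), SHA1_LEN)]

    @property
    def is_private(self) -> bool:
        return self.info.get(b"private", 0) == 1

    @property
    def is_multi_file(self) -> bool:
        return b"files" in self.info

    @property
    def total_length(self) -> int:
        if self.is_multi_file:
            return sum(f[b"length"] for f in self.info[b"files"])
        return self.info[b"length"]

    @property
    def file_entries(self) -> list[tuple[tuple[str, ...], int]]:
        """(relative path components, length) per payload file."""
        if not self.is_multi_file:
            return [((self.name,), self.total_length)]
        return [
            (tuple(c.decode("utf-8") for c in f[b"path"]), f[b"length"])
            for f in self.info[b"files"]
        ]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        doc = {b"announce": self.announce.encode("utf-8"), b"info": self.info}
        doc.update(self.extras)
        return doc

    def to_bytes(self) -> bytes:
        return bencode.encode(self.to_dict())

    @classmethod
    def from_bytes(cls, data: bytes, *, lenient: bool = True) -> "Metainfo":
        try:
            doc = bencode.decode(data, lenient=lenient)
        except bencode.BencodeError as exc:
            raise MetainfoError(f"malformed torrent: {exc}") from exc
        if not isinstance(doc, dict):
            raise MetainfoError("torrent document is not a dictionary")
        if b"announce" not in doc or b"info" not in doc:
            raise MetainfoError("torrent missing announce or info entry")
        extras = {
            k: v for k, v in doc.items() if k not in (b"announce", b"info")
        }
        return cls(
            announce=doc[b"announce"].decode("utf-8"),
            info=doc[b"info"],
            extras=extras,
        )

    def info_hash(self) -> InfoHash:
        """Info-hash of the canonical encoding of this metainfo."""
        return InfoHash(hashlib.sha1(bencode.encode(self.info)).digest())


def _validate_info(info: dict) -> None:
    if not isinstance(info, dict):
        raise MetainfoError("info entry is not a dictionary")
    for key in (b"name", b"piece length", b"pieces"):
        if key not in info:
            raise MetainfoError(f"info missing {key.decode()!r}")
    if info[b"piece length"] <= 0:
        raise MetainfoError("piece length must be positive")
    pieces = info[b"pieces"]
    if len(pieces) % SHA1_LEN != 0:
        raise MetainfoError("pieces length is not a multiple of 20")
    if (b"length" in info) == (b"files" in info):
        raise MetainfoError("info must have exactly one of length/files")
    if b"length" in info and info[b"length"] < 0:
        raise MetainfoError("negative file length")
    if b"files" in info:
        for f in info[b"files"]:
            if f[b"length"] < 0:
                raise MetainfoError("negative file length")
    private = info.get(b"private")
    if private is not None and private not in (0, 1):
        raise MetainfoError("private flag must be 0 or 1")
    total = (
        sum(f[b"length"] for f in info[b"files"])
        if b"files" in info
        else info[b"length"]
    )
    expected = -(-total // info[b"piece length"])  # ceil
    if len(pieces) // SHA1_LEN != expected:
        raise MetainfoError(
            f"piece digest count {len(pieces) // SHA1_LEN} != ceil(total/piece_length) = {expected}"
        )


# ---------------------------------------------------------------------------
# Torrent creation
# ---------------------------------------------------------------------------

def _collect_files(root: Path) -> list[tuple[tuple[str, ...], Path]]:
    """Payload files under *root*, ordered lexicographically (bytewise) by
    path components so that info-hashes are reproducible across platforms."""
    entries = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        for fn in filenames:
            p = Path(dirpath) / fn
            rel = p.relative_to(root).parts
            entries.append((rel, p))
    entries.sort(key=lambda e: tuple(c.encode("utf-8") for c in e[0]))
    return entries


def _iter_payload(files: Sequence[Path], lengths: Sequence[int]) -> Iterator[bytes]:
    """Concatenated payload stream; missing or short files are padded with
    zero bytes to their declared length so piece framing is preserved."""
    for path, length in zip(files, lengths):
        remaining = length
        if path.is_file():
            with open(path, "rb") as fh:
                while remaining > 0:
                    chunk = fh.read(min(1 << 20, remaining))
                    if not chunk:
                        break
                    remaining -= len(chunk)
                    yield chunk
        while remaining > 0:
            pad = min(1 << 20, remaining)
            yield b"\x00" * pad
            remaining -= pad


def _piece_digests(stream: Iterable[bytes], piece_length: int) -> list[bytes]:
    digests = []
    hasher = hashlib.sha1()
    filled = 0
    for chunk in stream:
        view = memoryview(chunk)
        while view:
            take = min(piece_length - filled, len(view))
            hasher.update(view[:take])
            filled += take
            view = view[take:]
            if filled == piece_length:
                digests.append(hasher.digest())
                hasher = hashlib.sha1()
                filled = 0
    if filled:
        digests.append(hasher.digest())
    return digests


def create_torrent(
    payload_path: str | os.PathLike,
    piece_length: int = DEFAULT_PIECE_LENGTH,
    announce: str = "https://localhost/t",
    *,
    private: bool = False,
) -> Metainfo:
    """Build metainfo for a file or directory payload.

    Pieces are SHA-1 digests over the concatenated payload stream; a
    directory payload produces a multi-file info dictionary with files in
    deterministic lexicographic order.  The final piece may be short.

    Raises :class:`MetainfoError` for unreadable paths, a zero-byte total
    payload, or a piece length below 16 KiB.
    """
    root = Path(payload_path)
    if piece_length < MIN_PIECE_LENGTH:
        raise MetainfoError(
            f"piece length {piece_length} below minimum {MIN_PIECE_LENGTH}"
        )
    if not root.exists():
        raise MetainfoError(f"payload path does not exist: {root}")

    if root.is_dir():
        entries = _collect_files(root)
        paths = [p for _, p in entries]
        lengths = [p.stat().st_size for p in paths]
        total = sum(lengths)
        if total == 0:
            raise MetainfoError("payload is empty")
        info = {
            b"name": root.name.encode("utf-8"),
            b"piece length": piece_length,
            b"pieces": b"".join(
                _piece_digests(_iter_payload(paths, lengths), piece_length)
            ),
            b"files": [
                {
                    b"path": [c.encode("utf-8") for c in rel],
                    b"length": length,
                }
                for (rel, _), length in zip(entries, lengths)
            ],
        }
    else:
        length = root.stat().st_size
        if length == 0:
            raise MetainfoError("payload is empty")
        info = {
            b"name": root.name.encode("utf-8"),
            b"piece length": piece_length,
            b"pieces": b"".join(
                _piece_digests(_iter_payload([root], [length]), piece_length)
            ),
            b"length": length,
        }
    if private:
        info[b"private"] = 1
    return Metainfo(announce=announce, info=info)


# ---------------------------------------------------------------------------
# Identity and portal transforms
# ---------------------------------------------------------------------------

def compute_info_hash(torrent_bytes: bytes) -> InfoHash:
    """SHA-1 over the exact bytes of the ``info`` entry of a serialized
    torrent (not a re-encoding — third-party torrents keep their identity)."""
    try:
        span = bencode.raw_slice(torrent_bytes, b"info")
    except KeyError:
        raise MetainfoError("torrent has no info entry") from None
    except bencode.BencodeError as exc:
        raise MetainfoError(f"malformed torrent: {exc}") from exc
    return InfoHash(hashlib.sha1(span).digest())


def privatize(torrent: Metainfo) -> Metainfo:
    """Return a copy with the BEP-0027 ``private`` flag forced to 1.

    Idempotent; no other info field changes.  Clients honouring the flag
    use only the embedded tracker (no DHT/PEX), which is what confines a
    swarm to token-holding portal users.
    """
    info = dict(torrent.info)
    info[b"private"] = 1
    if info == torrent.info:
        return torrent
    return Metainfo(announce=torrent.announce, info=info,
                    extras=dict(torrent.extras))


def tokenize_announce(torrent: Metainfo, tracker_base: str, token: str) -> Metainfo:
    """Rewrite the announce URL to ``<base>/<token>/announce``.

    The token travels as a path segment, not a query parameter, so it
    survives clients that rewrite query strings.  The info dictionary is
    untouched: every user's personalized torrent keeps the same
    info-hash and therefore joins the same swarm.
    """
    if not token:
        raise ValueError("empty authorization token")
    base = tracker_base.rstrip("/")
    announce = f"{base}/{token}/announce"
    return Metainfo(announce=announce, info=torrent.info,
                    extras=dict(torrent.extras))


# ---------------------------------------------------------------------------
# Payload verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Per-piece pass/fail outcome of checking a payload against metainfo."""

    piece_results: list[bool]
    missing_pieces: list[int]

    @property
    def completion_fraction(self) -> float:
        if not self.piece_results:
            return 0.0
        return sum(self.piece_results) / len(self.piece_results)

    @property
    def completion_percent(self) -> float:
        return 100.0 * self.completion_fraction

    @property
    def complete(self) -> bool:
        return not self.missing_pieces and bool(self.piece_results)


def verify_payload(torrent: Metainfo, payload_path: str | os.PathLike) -> VerificationReport:
    """Recompute per-piece SHA-1 digests of the payload and compare.

    *payload_path* is the file itself for single-file torrents, or the
    directory containing the payload tree for multi-file ones.  Missing
    files are read as zero bytes of their declared length, so the pieces
    they cover simply fail rather than shifting the framing.
    """
    root = Path(payload_path)
    if torrent.is_multi_file:
        paths = [root.joinpath(*rel) for rel, _ in torrent.file_entries]
    else:
        paths = [root]
    lengths = [length for _, length in torrent.file_entries]
    actual = _piece_digests(
        _iter_payload(paths, lengths), torrent.piece_length
    )
    expected = torrent.piece_digests
    # A wholly absent payload still yields digests over zero bytes; pad the
    # comparison to the declared piece count.
    results = [
        i < len(actual) and actual[i] == expected[i]
        for i in range(len(expected))
    ]
    missing = [i for i, ok in enumerate(results) if not ok]
    return VerificationReport(piece_results=results, missing_pieces=missing)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_torrent(path: str | os.PathLike, *, lenient: bool = True) -> Metainfo:
    with open(path, "rb") as fh:
        return Metainfo.from_bytes(fh.read(), lenient=lenient)


def write_torrent(torrent: Metainfo, path: str | os.PathLike) -> None:
    with open(path, "wb") as fh:
        fh.write(torrent.to_bytes())
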