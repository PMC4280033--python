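"""Canonical bencoding: the binary serialization used by .torrent files
and tracker responses.

Bencoding has four kinds of value: byte-strings (``4:spam``), signed
integers (``i-3e``), lists (``l...e``) and dictionaries (``d...e``) whose
byte-string keys appear in sorted (raw byte) order.  The encoding of a
value is unique once dictionary keys are sorted and integers carry no
leading zeros, which is what makes the SHA-1 of an encoded ``info``
dictionary a stable global identity for a torrent.

This module is strict by default: input that is not canonical (unsorted
or duplicate dictionary keys, leading zeros, negative zero, trailing
bytes) is rejected with the byte offset of the offence.  A ``lenient``
switch accepts unsorted keys and non-canonical integers as produced by
some real-world tools; re-encoding such a document always emits the
canonical form.

Byte-strings are the native string type.  ``encode`` accepts ``str`` for
convenience and converts with UTF-8; ``decode`` always returns ``bytes``.
Integers are unbounded (payload lengths well beyond 32 bits are normal).
"""

from __future__ import annotations

from typing import Union

BValue = Union[bytes, int, list, dict]

__all__ = [
    "BencodeError",
    "BencodeDecodeError",
    "BencodeEncodeError",
    "encode",
    "decode",
    "raw_slice",
]


class BencodeError(ValueError):
    """Base class for bencoding failures."""


class BencodeEncodeError(BencodeError):
    """A value cannot be represented in bencoding."""


class BencodeDecodeError(BencodeError):
    """Malformed or non-canonical bencoded input.

    ``offset`` is the byte position at which decoding failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _encode_into(value: BValue, out: bytearray) -> None:
    if isinstance(value, bool):
        # bool is an int subclass; allowing it would silently encode i1e/i0e
        raise BencodeEncodeError("booleans are not a bencode type")
    if isinstance(value, bytes):
        out += str(len(value)).encode("ascii")
        out += b":"
        out += value
    elif isinstance(value, str):
        _encode_into(value.encode("utf-8"), out)
    elif isinstance(value, int):
        out += b"i"
        out += str(value).encode("ascii")
        out += b"e"
    elif isinstance(value, (list, tuple)):
        out += b"l"
        for item in value:
            _encode_into(item, out)
        out += b"e"
    elif isinstance(value, dict):
        out += b"d"
        items = []
        for key, val in value.items():
            if isinstance(key, str):
                key = key.encode("utf-8")
            if not isinstance(key, bytes):
                raise BencodeEncodeError(
                    f"dictionary keys must be byte-strings, got {type(key).__name__}"
                )
            items.append((key, val))
        items.sort(key=lambda kv: kv[0])
        prev = None
        for key, val in items:
            if key == prev:
                raise BencodeEncodeError(f"duplicate dictionary key {key!r}")
            prev = key
            _encode_into(key, out)
            _encode_into(val, out)
        out += b"e"
    else:
        raise BencodeEncodeError(
            f"cannot bencode value of type {type(value).__name__}"
        )


def encode(value: BValue) -> bytes:
    """Serialize *value* to its unique canonical bencoding.

    Dictionary keys are emitted in sorted raw-byte order regardless of
    insertion order, so ``encode`` is a canonicalizing function:
    ``encode(decode(b, lenient=True))`` is canonical even when ``b`` was not.
    """
    out = bytearray()
    _encode_into(value, out)
    return bytes(out)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _decode_int_body(data: bytes, pos: int, strict: bool) -> tuple[int, int]:
    # pos points just past 'i'
    end = data.find(b"e", pos)
    if end == -1:
        raise BencodeDecodeError("unterminated integer", pos)
    body = data[pos:end]
    if not body or body == b"-":
        raise BencodeDecodeError("empty integer", pos)
    if strict:
        if body == b"-0":
            raise BencodeDecodeError("negative zero is invalid", pos)
        digits = body[1:] if body[:1] == b"-" else body
        if len(digits) > 1 and digits[:1] == b"0":
            raise BencodeDecodeError("integer has leading zero", pos)
    try:
        return int(body), end + 1
    except ValueError:
        raise BencodeDecodeError(f"malformed integer {body!r}", pos) from None


def _decode_string(data: bytes, pos: int, strict: bool) -> tuple[bytes, int]:
    colon = data.find(b":", pos)
    if colon == -1:
        raise BencodeDecodeError("malformed length prefix", pos)
    length_bytes = data[pos:colon]
    if not length_bytes.isdigit():
        raise BencodeDecodeError(f"malformed length prefix {length_bytes!r}", pos)
    if strict and len(length_bytes) > 1 and length_bytes[:1] == b"0":
        raise BencodeDecodeError("length prefix has leading zero", pos)
    length = int(length_bytes)
    start = colon + 1
    end = start + length
    if end > len(data):
        raise BencodeDecodeError("truncated byte-string", pos)
    return data[start:end], end


def _decode_at(data: bytes, pos: int, strict: bool) -> tuple[BValue, int]:
    if pos >= len(data):
        raise BencodeDecodeError("truncated input", pos)
    lead = data[pos:pos + 1]
    if lead == b"i":
        return _decode_int_body(data, pos + 1, strict)
    if lead.isdigit():
        return _decode_string(data, pos, strict)
    if lead == b"l":
        pos += 1
        items: list = []
        while True:
            if pos >= len(data):
                raise BencodeDecodeError("unterminated list", pos)
            if data[pos:pos + 1] == b"e":
                return items, pos + 1
            item, pos = _decode_at(data, pos, strict)
            items.append(item)
    if lead == b"d":
        pos += 1
        result: dict = {}
        prev_key = None
        while True:
            if pos >= len(data):
                raise BencodeDecodeError("unterminated dictionary", pos)
            if data[pos:pos + 1] == b"e":
                return result, pos + 1
            key_pos = pos
            key, pos = _decode_string(data, pos, strict)
            if key in result:
                raise BencodeDecodeError(f"duplicate key {key!r}", key_pos)
            if strict and prev_key is not None and key < prev_key:
                raise BencodeDecodeError(
                    f"dictionary keys not sorted ({key!r} after {prev_key!r})",
                    key_pos,
                )
            prev_key = key
            result[key], pos = _decode_at(data, pos, strict)
    raise BencodeDecodeError(f"unexpected byte {lead!r}", pos)


def decode(data: bytes, *, lenient: bool = False) -> BValue:
    """Parse one complete bencoded document.

    Trailing bytes after the top-level value are always rejected.  With
    ``lenient=True`` unsorted dictionary keys, leading zeros and negative
    zero are tolerated (duplicate keys never are); the parsed value
    re-encodes canonically via :func:`encode`.
    """
    if not isinstance(data, (bytes, bytearray, memoryview)):
        raise TypeError("decode expects bytes")
    data = bytes(data)
    value, pos = _decode_at(data, 0, strict=not lenient)
    if pos != len(data):
        raise BencodeDecodeError("trailing bytes after document", pos)
    return value


def raw_slice(data: bytes, top_level_key: bytes) -> bytes:
    """Return the exact byte span of one top-level dictionary entry's value.

    The info-hash of a torrent is the SHA-1 over the bytes of the ``info``
    entry *as they appear in the file*; for third-party torrents those
    bytes must be sliced out verbatim, not re-encoded.
    """
    if isinstance(top_level_key, str):
        top_level_key = top_level_key.encode("utf-8")
    data = bytes(data)
    if data[:1] != b"d":
        raise BencodeDecodeError("top-level value is not a dictionary", 0)
    pos = 1
    while pos < len(data) and data[pos:pos + 1] != b"e":
        key, pos = _decode_string(data, pos, strict=False)
        start = pos
        _, pos = _decode_at(data, pos, strict=False)
        if key == top_level_key:
            return data[start:pos]
    raise KeyError(top_level_key)
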