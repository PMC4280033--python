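"""Independent reference implementations used only as test oracles.

These are deliberately naive and share no code with the package: a
minimal recursive bencoder, and an info-dictionary builder that hashes a
payload file with its own piece loop.  They exist so that encoding and
info-hash tests compare two independently written routes.
"""

import hashlib
from pathlib import Path


def oracle_bencode(value) -> bytes:
    """Reference bencoder (recursive, sorted byte keys)."""
    if isinstance(value, int):
        return b"i%de" % value
    if isinstance(value, bytes):
        return b"%d:%s" % (len(value), value)
    if isinstance(value, str):
        return oracle_bencode(value.encode("utf-8"))
    if isinstance(value, list):
        return b"l" + b"".join(oracle_bencode(v) for v in value) + b"e"
    if isinstance(value, dict):
        keys = sorted(k if isinstance(k, bytes) else k.encode() for k in value)
        body = b"".join(
            oracle_bencode(k) + oracle_bencode(
                value[k] if k in value else value[k.decode()])
            for k in keys
        )
        return b"d" + body + b"e"
    raise TypeError(type(value))


def oracle_single_file_info(path, piece_length: int) -> dict:
    """Build a single-file info dictionary straight from the file bytes,
    with an explicit piece loop independent of the package's streaming."""
    data = Path(path).read_bytes()
    pieces = b"".join(
        hashlib.sha1(data[i:i + piece_length]).digest()
        for i in range(0, len(data), piece_length)
    )
    return {
        b"name": Path(path).name.encode(),
        b"piece length": piece_length,
        b"pieces": pieces,
        b"length": len(data),
    }


def oracle_info_hash(info: dict) -> bytes:
    return hashlib.sha1(oracle_bencode(info)).digest()
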