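"""Shared fixtures: a small portal world and payload factories."""

from dataclasses import dataclass, field

import pytest

from seedportal import metainfo as mi
from seedportal.authz import PortalStore, Role, User
from seedportal.tracker import Tracker


@dataclass
class World:
    """A populated portal: one admin, a publisher, a subscriber and an
    outsider, with two feeds and clear tokens for each account."""

    store: PortalStore
    tracker: Tracker
    admin: User
    tokens: dict = field(default_factory=dict)   # email -> clear token
    feeds: dict = field(default_factory=dict)    # name -> Feed

    def token(self, email: str) -> str:
        return self.tokens[email]


@pytest.fixture
def world() -> World:
    store = PortalStore()
    admin, admin_token = store.bootstrap_admin("root@portal", "s3cret")
    w = World(store=store, tracker=Tracker(store, interval=60), admin=admin,
              tokens={"root@portal": admin_token})
    for email in ("pub@lab", "sub@lab", "out@lab"):
        store.register_user(email, "pw-" + email)
        store.approve_user(admin, email)
        w.tokens[email] = store.issue_token(email)
    w.feeds["genomes"] = store.create_feed(admin, "genomes", "reference sets")
    w.feeds["assays"] = store.create_feed(admin, "assays", "raw assay data")
    store.grant_role(admin, "pub@lab", w.feeds["genomes"].id, Role.PUBLISHER)
    store.grant_role(admin, "sub@lab", w.feeds["genomes"].id, Role.SUBSCRIBER)
    # out@lab holds no role anywhere
    return w


@pytest.fixture
def payload_file(tmp_path):
    """Factory writing a deterministic pseudo-random payload file."""

    def make(size: int, seed: int = 7, name: str = "payload.bin"):
        import random

        path = tmp_path / name
        path.write_bytes(random.Random(seed).randbytes(size))
        return path

    return make


@pytest.fixture
def small_torrent(payload_file):
    """A 5-piece torrent over a 72 KiB payload (16 KiB pieces)."""
    path = payload_file(72 * 1024)
    torrent = mi.create_torrent(path, mi.MIN_PIECE_LENGTH,
                                "https://portal.example/t")
    return path, torrent
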