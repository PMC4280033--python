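"""Portal access control: users, feeds, per-feed roles and auth tokens.

The portal's model is deliberately small.  Accounts are email/password
pairs that an administrator must approve before any other check can
succeed.  Authorization is role-based *per user per feed*:

``none``
    The default when no grant exists: the user may neither view the feed
    nor join any of its torrents.
``subscriber``
    The default granted role: may view the feed, use download links,
    fetch the RSS document and announce (join torrents).
``publisher``
    Everything a subscriber may do, plus publishing torrents and
    managing the feed.

A global *administrator* bit grants publisher rights on every feed plus
user management.  Every request outside the login form authenticates
with an opaque per-user token (32 bytes from a CSPRNG, URL-safe, stored
hashed); rotating a token invalidates the old one everywhere at once.

One :class:`PortalStore` instance is one network: a single namespace of
users, feeds and swarms, persisted in an embedded SQLite database.
"""

from __future__ import annotations

import enum
import hashlib
import hmac
import secrets
import sqlite3
import time
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Role",
    "Action",
    "Decision",
    "AuthzError",
    "ConflictError",
    "NotAuthorizedError",
    "User",
    "Feed",
    "TorrentRecord",
    "PortalStore",
]

_PBKDF2_ITERATIONS = 60_000
_TOKEN_BYTES = 32  # 256 bits of entropy


class Role(enum.Enum):
    NONE = "none"
    SUBSCRIBER = "subscriber"
    PUBLISHER = "publisher"


class Action(enum.Enum):
    VIEW_FEED = "view_feed"
    DOWNLOAD_TORRENT = "download_torrent"
    ANNOUNCE = "announce"
    FETCH_RSS = "fetch_rss"
    PUBLISH_TORRENT = "publish_torrent"
    MANAGE_FEED = "manage_feed"
    MANAGE_USERS = "manage_users"


#: Allowed actions per role.  Anything not listed is denied; the admin
#: bit short-circuits to publisher-everywhere plus MANAGE_USERS.
ROLE_ACTIONS: dict[Role, frozenset[Action]] = {
    Role.NONE: frozenset(),
    Role.SUBSCRIBER: frozenset(
        {Action.VIEW_FEED, Action.DOWNLOAD_TORRENT, Action.ANNOUNCE,
         Action.FETCH_RSS}
    ),
    Role.PUBLISHER: frozenset(
        {Action.VIEW_FEED, Action.DOWNLOAD_TORRENT, Action.ANNOUNCE,
         Action.FETCH_RSS, Action.PUBLISH_TORRENT, Action.MANAGE_FEED}
    ),
}


@dataclass(frozen=True)
class Decision:
    """An allow/deny outcome with a human-readable reason.

    Deny is a value, not an exception: callers branch on truthiness.
    """

    allowed: bool
    reason: str

    def __bool__(self) -> bool:
        return self.allowed


class AuthzError(Exception):
    """Base class for portal store failures."""


class ConflictError(AuthzError):
    """Uniqueness violated (duplicate email, duplicate info-hash)."""


class NotAuthorizedError(AuthzError):
    """An operation was attempted by a caller lacking the right."""


@dataclass(frozen=True)
class User:
    id: int
    email: str
    approved: bool
    admin: bool


@dataclass(frozen=True)
class Feed:
    id: int
    name: str
    description: str


@dataclass(frozen=True)
class TorrentRecord:
    feed_id: int
    info_hash: bytes
    name: str
    torrent_bytes: bytes
    total_length: int
    published_at: float


def _hash_password(password: str, salt: bytes) -> bytes:
    return hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt,
                               _PBKDF2_ITERATIONS)


def _hash_token(token: str) -> str:
    return hashlib.sha256(token.encode("utf-8")).hexdigest()


_SCHEMA = """
CREATE TABLE IF NOT EXISTS users (
    id INTEGER PRIMARY KEY,
    email TEXT NOT NULL UNIQUE,
    pw_salt BLOB NOT NULL,
    pw_hash BLOB NOT NULL,
    approved INTEGER NOT NULL DEFAULT 0,
    admin INTEGER NOT NULL DEFAULT 0,
    token_hash TEXT UNIQUE
);
CREATE TABLE IF NOT EXISTS feeds (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS roles (
    user_id INTEGER NOT NULL REFERENCES users(id),
    feed_id INTEGER NOT NULL REFERENCES feeds(id),
    role TEXT NOT NULL,
    PRIMARY KEY (user_id, feed_id)
);
CREATE TABLE IF NOT EXISTS torrents (
    feed_id INTEGER NOT NULL REFERENCES feeds(id),
    info_hash BLOB NOT NULL,
    name TEXT NOT NULL,
    torrent_bytes BLOB NOT NULL,
    total_length INTEGER NOT NULL,
    published_at REAL NOT NULL,
    PRIMARY KEY (feed_id, info_hash)
);
"""


class PortalStore:
    """Embedded persistent store for one portal network.

    ``path`` may be ``":memory:"`` (default, for tests and simulations)
    or a filesystem path for a durable portal database.  The schema is
    four tables: ``users``, ``feeds``, ``roles`` (one row per effective
    (user, feed) assignment; absence means role *none*) and ``torrents``
    (the privatized canonical metainfo bytes per feed).
    """

    def __init__(self, path: str = ":memory:", *, require_https: bool = False):
        self._db = sqlite3.connect(path)
        self._db.executescript(_SCHEMA)
        self.require_https = require_https

    def close(self) -> None:
        self._db.close()

    # -- accounts ----------------------------------------------------------

    def register_user(self, email: str, password: str) -> User:
        """Create a pending (unapproved) account.  Every authorization
        check denies until an administrator approves it."""
        salt = secrets.token_bytes(16)
        try:
            cur = self._db.execute(
                "INSERT INTO users (email, pw_salt, pw_hash) VALUES (?, ?, ?)",
                (email, salt, _hash_password(password, salt)),
            )
        except sqlite3.IntegrityError:
            raise ConflictError(f"email already registered: {email}") from None
        self._db.commit()
        return User(id=cur.lastrowid, email=email, approved=False, admin=False)

    def bootstrap_admin(self, email: str, password: str) -> tuple[User, str]:
        """Create (or fetch) the first administrator, pre-approved.

        Someone has to approve everyone else.  Returns the user and a
        freshly issued token.
        """
        existing = self.get_user(email)
        if existing is None:
            self.register_user(email, password)
        self._db.execute(
            "UPDATE users SET approved = 1, admin = 1 WHERE email = ?", (email,)
        )
        self._db.commit()
        return self.get_user(email), self.issue_token(email)

    def approve_user(self, admin: User, target_email: str) -> User:
        admin = self._refresh(admin)
        if not admin.admin:
            raise NotAuthorizedError("only administrators approve accounts")
        target = self.get_user(target_email)
        if target is None:
            raise AuthzError(f"no such user: {target_email}")
        self._db.execute(
            "UPDATE users SET approved = 1 WHERE id = ?", (target.id,)
        )
        self._db.commit()
        return self.get_user(target_email)

    def set_admin(self, granter: User, target_email: str, value: bool = True) -> User:
        granter = self._refresh(granter)
        if not granter.admin:
            raise NotAuthorizedError("only administrators manage the admin bit")
        self._db.execute(
            "UPDATE users SET admin = ? WHERE email = ?",
            (1 if value else 0, target_email),
        )
        self._db.commit()
        return self.get_user(target_email)

    def verify_login(self, email: str, password: str) -> Optional[User]:
        """Stage-one (portal login) check; None on bad credentials or a
        still-pending account."""
        row = self._db.execute(
            "SELECT id, pw_salt, pw_hash, approved, admin FROM users WHERE email = ?",
            (email,),
        ).fetchone()
        if row is None:
            return None
        uid, salt, stored, approved, admin = row
        if not hmac.compare_digest(stored, _hash_password(password, salt)):
            return None
        if not approved:
            return None
        return User(id=uid, email=email, approved=True, admin=bool(admin))

    def get_user(self, email: str) -> Optional[User]:
        row = self._db.execute(
            "SELECT id, email, approved, admin FROM users WHERE email = ?",
            (email,),
        ).fetchone()
        if row is None:
            return None
        return User(id=row[0], email=row[1], approved=bool(row[2]),
                    admin=bool(row[3]))

    def any_admin(self) -> Optional[User]:
        """Some administrator account, if one exists (used by operator
        tooling acting directly on the database)."""
        row = self._db.execute(
            "SELECT email FROM users WHERE admin = 1 ORDER BY id LIMIT 1"
        ).fetchone()
        return None if row is None else self.get_user(row[0])

    def _refresh(self, user: User) -> User:
        current = self.get_user(user.email)
        if current is None:
            raise AuthzError(f"no such user: {user.email}")
        return current

    # -- tokens ------------------------------------------------------------

    def issue_token(self, email: str) -> str:
        """Issue a fresh token for the user, invalidating any prior one.

        The clear token is returned exactly once; only its SHA-256 is
        stored, so a database leak does not leak announce credentials.
        """
        user = self.get_user(email)
        if user is None:
            raise AuthzError(f"no such user: {email}")
        token = secrets.token_urlsafe(_TOKEN_BYTES)
        self._db.execute(
            "UPDATE users SET token_hash = ? WHERE id = ?",
            (_hash_token(token), user.id),
        )
        self._db.commit()
        return token

    rotate_token = issue_token

    def user_for_token(self, token: str) -> Optional[User]:
        if not token:
            return None
        row = self._db.execute(
            "SELECT id, email, approved, admin FROM users WHERE token_hash = ?",
            (_hash_token(token),),
        ).fetchone()
        if row is None:
            return None
        return User(id=row[0], email=row[1], approved=bool(row[2]),
                    admin=bool(row[3]))

    # -- feeds and roles ---------------------------------------------------

    def create_feed(self, actor: User, name: str, description: str = "") -> Feed:
        """Create a feed.  Allowed for administrators and for users who
        already hold publisher on some feed; the creator becomes the new
        feed's publisher."""
        actor = self._refresh(actor)
        if not actor.admin and not self._is_publisher_anywhere(actor):
            raise NotAuthorizedError("feed creation requires admin or publisher")
        cur = self._db.execute(
            "INSERT INTO feeds (name, description) VALUES (?, ?)",
            (name, description),
        )
        feed = Feed(id=cur.lastrowid, name=name, description=description)
        self._db.execute(
            "INSERT OR REPLACE INTO roles (user_id, feed_id, role) VALUES (?, ?, ?)",
            (actor.id, feed.id, Role.PUBLISHER.value),
        )
        self._db.commit()
        return feed

    def get_feed(self, feed_id: int) -> Optional[Feed]:
        row = self._db.execute(
            "SELECT id, name, description FROM feeds WHERE id = ?", (feed_id,)
        ).fetchone()
        return None if row is None else Feed(*row)

    def list_feeds(self) -> list[Feed]:
        return [Feed(*row) for row in self._db.execute(
            "SELECT id, name, description FROM feeds ORDER BY id")]

    def _is_publisher_anywhere(self, user: User) -> bool:
        row = self._db.execute(
            "SELECT 1 FROM roles WHERE user_id = ? AND role = ? LIMIT 1",
            (user.id, Role.PUBLISHER.value),
        ).fetchone()
        return row is not None

    def role_of(self, user: Optional[User], feed_id: int) -> Role:
        """Effective role; an absent assignment is role none."""
        if user is None:
            return Role.NONE
        row = self._db.execute(
            "SELECT role FROM roles WHERE user_id = ? AND feed_id = ?",
            (user.id, feed_id),
        ).fetchone()
        return Role.NONE if row is None else Role(row[0])

    def grant_role(self, granter: User, target_email: str, feed_id: int,
                   role: Role = Role.SUBSCRIBER) -> Role:
        """Set the effective role of *target* on a feed.

        Granters must be administrators or publishers on the feed.
        Demoting a publisher is reserved to administrators.
        """
        granter = self._refresh(granter)
        if self.get_feed(feed_id) is None:
            raise AuthzError(f"no such feed: {feed_id}")
        granter_role = self.role_of(granter, feed_id)
        if not granter.admin and granter_role is not Role.PUBLISHER:
            raise NotAuthorizedError(
                "granting requires admin or publisher on the feed"
            )
        target = self.get_user(target_email)
        if target is None:
            raise AuthzError(f"no such user: {target_email}")
        current = self.role_of(target, feed_id)
        if current is Role.PUBLISHER and role is not Role.PUBLISHER \
                and not granter.admin:
            raise NotAuthorizedError("only administrators demote publishers")
        if role is Role.NONE:
            self._db.execute(
                "DELETE FROM roles WHERE user_id = ? AND feed_id = ?",
                (target.id, feed_id),
            )
        else:
            self._db.execute(
                "INSERT OR REPLACE INTO roles (user_id, feed_id, role) "
                "VALUES (?, ?, ?)",
                (target.id, feed_id, role.value),
            )
        self._db.commit()
        return role

    # -- the decision procedure --------------------------------------------

    def authorize(self, token: Optional[str], feed_id: Optional[int],
                  action: Action, *, secure_channel: bool = True) -> Decision:
        """Deny-by-default decision for (token, feed, action).

        The matrix: unknown/rotated tokens and unapproved accounts deny
        everything; role none denies everything on the feed; subscribers
        get the view/download/announce/RSS set; publishers additionally
        publish and manage the feed; the admin bit acts as publisher on
        every feed and alone allows ``manage_users`` (feed may be None).
        """
        if self.require_https and not secure_channel:
            return Decision(False, "secure channel required")
        user = self.user_for_token(token) if token else None
        if user is None:
            return Decision(False, "unknown or rotated token")
        if not user.approved:
            return Decision(False, "account pending approval")
        if action is Action.MANAGE_USERS:
            if user.admin:
                return Decision(True, "administrator")
            return Decision(False, "user management requires the admin bit")
        if feed_id is None or self.get_feed(feed_id) is None:
            return Decision(False, "unknown feed")
        if user.admin:
            return Decision(True, "administrator (publisher on all feeds)")
        role = self.role_of(user, feed_id)
        if action in ROLE_ACTIONS[role]:
            return Decision(True, f"role {role.value}")
        return Decision(False, f"role {role.value} does not allow {action.value}")

    # -- torrent records ---------------------------------------------------

    def add_torrent_record(self, feed_id: int, info_hash: bytes, name: str,
                           torrent_bytes: bytes, total_length: int,
                           published_at: Optional[float] = None) -> TorrentRecord:
        if self.get_feed(feed_id) is None:
            raise AuthzError(f"no such feed: {feed_id}")
        ts = time.time() if published_at is None else published_at
        try:
            self._db.execute(
                "INSERT INTO torrents (feed_id, info_hash, name, torrent_bytes,"
                " total_length, published_at) VALUES (?, ?, ?, ?, ?, ?)",
                (feed_id, info_hash, name, torrent_bytes, total_length, ts),
            )
        except sqlite3.IntegrityError:
            raise ConflictError(
                f"info-hash {info_hash.hex()} already in feed {feed_id}"
            ) from None
        self._db.commit()
        return TorrentRecord(feed_id, info_hash, name, torrent_bytes,
                             total_length, ts)

    def list_torrents(self, feed_id: int) -> list[TorrentRecord]:
        rows = self._db.execute(
            "SELECT feed_id, info_hash, name, torrent_bytes, total_length,"
            " published_at FROM torrents WHERE feed_id = ?"
            " ORDER BY published_at DESC, info_hash",
            (feed_id,),
        ).fetchall()
        return [TorrentRecord(*row) for row in rows]

    def find_torrent(self, info_hash: bytes) -> Optional[TorrentRecord]:
        """Locate a registered torrent by info-hash, across all feeds.

        One portal is one network: an info-hash not registered in any
        feed is foreign and must not be tracked.
        """
        row = self._db.execute(
            "SELECT feed_id, info_hash, name, torrent_bytes, total_length,"
            " published_at FROM torrents WHERE info_hash = ?",
            (info_hash,),
        ).fetchone()
        return None if row is None else TorrentRecord(*row)
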