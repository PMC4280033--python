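"""Single-process portal service: tracker, feeds and admin API over HTTP.

One process serves everything a deployment needs behind TLS
termination: the authenticated announce/scrape endpoints, per-user RSS
documents, tokenized .torrent downloads, and a small JSON admin API.
The app is a plain WSGI callable with no framework dependency, so it
runs under ``wsgiref`` for development and under any WSGI server in
production.

URL scheme (token always a path segment, mirroring the announce URLs
embedded in served torrents)::

    GET  /health
    POST /register                          {"email":..., "password":...}
    GET  /<token>/announce?...              standard tracker announce
    GET  /<token>/scrape?info_hash=...      standard tracker scrape
    GET  /<token>/feeds/<id>.rss            per-user RSS document
    GET  /<token>/feeds/<id>/status         dashboard rows (JSON)
    GET  /<token>/torrents/<hex>.torrent    tokenized metainfo
    POST /<token>/feeds                     create feed (JSON)
    POST /<token>/feeds/<id>/torrents       publish raw .torrent body
    POST /<token>/admin/approve             {"email":...}
    POST /<token>/admin/grant               {"email","feed_id","role"}
    POST /<token>/admin/rotate              {"email":...}

Every authorization decision is logged as one JSON line tagged with its
stage — ``portal`` (login/admin), ``rss`` (feed update requests) or
``announce`` (client registration and keep-alive) — the three points at
which authentication and authorization are checked.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import urllib.parse
import wsgiref.simple_server
from dataclasses import dataclass, field
from typing import Callable, Optional

from . import feedgen, metainfo as mi
from .authz import (Action, AuthzError, ConflictError, NotAuthorizedError,
                    PortalStore, Role)
from .tracker import AnnounceRequest, Tracker, TrackerFailure

__all__ = ["PortalConfig", "Portal", "serve"]

log = logging.getLogger("seedportal.service")


@dataclass
class PortalConfig:
    """One config = one portal instance = one network of feeds and users."""

    host: str = "127.0.0.1"
    port: int = 8420
    data_dir: str = "."
    db_path: str = ":memory:"
    base_url: str = ""               # external URL; derived from host:port if empty
    announce_interval: int = 1800    # seconds
    peer_timeout: Optional[float] = None   # default: 2.5 x interval
    max_peers: int = 50
    piece_length: int = mi.DEFAULT_PIECE_LENGTH
    require_https: bool = False
    admin_email: str = "admin@localhost"
    admin_password: str = ""

    def external_base(self) -> str:
        if self.base_url:
            return self.base_url.rstrip("/")
        scheme = "https" if self.require_https else "http"
        return f"{scheme}://{self.host}:{self.port}"

    @classmethod
    def from_dict(cls, doc: dict) -> "PortalConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


class Portal:
    """The portal service object and its WSGI interface."""

    def __init__(self, config: Optional[PortalConfig] = None,
                 store: Optional[PortalStore] = None,
                 geolocate: Optional[Callable[[str], str]] = None):
        self.config = config or PortalConfig()
        self.store = store or PortalStore(
            self.config.db_path, require_https=self.config.require_https
        )
        self.store.require_https = self.config.require_https
        self.tracker = Tracker(
            self.store,
            interval=self.config.announce_interval,
            peer_timeout=self.config.peer_timeout,
            max_peers=self.config.max_peers,
            geolocate=geolocate,
        )
        if self.config.admin_password:
            # someone must be able to approve everyone else
            self.store.bootstrap_admin(
                self.config.admin_email, self.config.admin_password
            )

    # -- decision logging --------------------------------------------------

    def _log_decision(self, stage: str, token: str, action: str,
                      allowed: bool, reason: str) -> None:
        user = self.store.user_for_token(token)
        log.info(json.dumps({
            "stage": stage,
            "user": user.email if user else None,
            "action": action,
            "allowed": allowed,
            "reason": reason,
        }, sort_keys=True))

    # -- WSGI --------------------------------------------------------------

    def __call__(self, environ, start_response):
        try:
            status, headers, body = self._route(environ)
        except ConflictError as exc:
            status, headers, body = _json_response(409, {"error": str(exc)})
        except (NotAuthorizedError, feedgen.FeedAccessError) as exc:
            status, headers, body = _json_response(403, {"error": str(exc)})
        except (feedgen.NotFoundError,) as exc:
            status, headers, body = _json_response(404, {"error": str(exc)})
        except (AuthzError, mi.MetainfoError, ValueError, KeyError) as exc:
            status, headers, body = _json_response(400, {"error": str(exc)})
        start_response(status, headers)
        return [body]

    def _route(self, environ):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        secure = environ.get("wsgi.url_scheme", "http") == "https"
        query = environ.get("QUERY_STRING", "")

        if path == "/health" and method == "GET":
            return _json_response(200, {"status": "ok"})

        if path == "/register" and method == "POST":
            doc = _read_json(environ)
            user = self.store.register_user(doc["email"], doc["password"])
            self._log_decision("portal", "", "register", True,
                               "account pending approval")
            return _json_response(201, {"email": user.email,
                                        "approved": user.approved})

        m = re.match(r"^/([^/]+)(/.*)$", path)
        if not m:
            return _json_response(404, {"error": "not found"})
        token, rest = m.group(1), m.group(2)

        if rest == "/announce" and method == "GET":
            return self._announce(token, query, environ, secure)
        if rest == "/scrape" and method == "GET":
            return self._scrape(token, query, secure)

        m = re.match(r"^/feeds/(\d+)\.rss$", rest)
        if m and method == "GET":
            feed_id = int(m.group(1))
            try:
                doc = feedgen.generate_feed(
                    self.store, feed_id, token,
                    self.config.external_base(), secure_channel=secure,
                )
            except feedgen.FeedAccessError as exc:
                self._log_decision("rss", token, "fetch_rss", False, str(exc))
                raise
            self._log_decision("rss", token, "fetch_rss", True, "ok")
            return ("200 OK",
                    [("Content-Type", "application/rss+xml")], doc)

        m = re.match(r"^/feeds/(\d+)/status$", rest)
        if m and method == "GET":
            rows = self.tracker.swarm_status(int(m.group(1)), token,
                                             secure_channel=secure)
            if not isinstance(rows, list):
                self._log_decision("portal", token, "view_feed", False,
                                   rows.reason)
                return _json_response(403, {"error": rows.reason})
            self._log_decision("portal", token, "view_feed", True, "ok")
            return _json_response(200, {"peers": [
                dataclasses.asdict(r) for r in rows
            ]})

        m = re.match(r"^/torrents/([0-9a-f]{40})\.torrent$", rest)
        if m and method == "GET":
            info_hash = bytes.fromhex(m.group(1))
            record = self.store.find_torrent(info_hash)
            if record is None:
                raise feedgen.NotFoundError("unknown torrent")
            body = feedgen.download_torrent(
                self.store, record.feed_id, info_hash, token,
                self.config.external_base(), secure_channel=secure,
            )
            self._log_decision("portal", token, "download_torrent", True, "ok")
            return ("200 OK",
                    [("Content-Type", feedgen.MEDIA_TYPE)], body)

        if rest == "/feeds" and method == "POST":
            doc = _read_json(environ)
            user = self._require_user(token)
            feed = self.store.create_feed(user, doc["name"],
                                          doc.get("description", ""))
            self._log_decision("portal", token, "create_feed", True, "ok")
            return _json_response(201, {"id": feed.id, "name": feed.name})

        m = re.match(r"^/feeds/(\d+)/torrents$", rest)
        if m and method == "POST":
            body = _read_body(environ)
            record = feedgen.publish_torrent(
                self.store, int(m.group(1)), body, token,
                secure_channel=secure,
            )
            self._log_decision("portal", token, "publish_torrent", True, "ok")
            return _json_response(201, {
                "info_hash": record.info_hash.hex(),
                "name": record.name,
            })

        if rest.startswith("/admin/") and method == "POST":
            return self._admin(token, rest.removeprefix("/admin/"),
                               environ, secure)

        return _json_response(404, {"error": "not found"})

    # -- handlers ----------------------------------------------------------

    def _require_user(self, token: str):
        user = self.store.user_for_token(token)
        if user is None or not user.approved:
            raise NotAuthorizedError("unknown token or unapproved account")
        return user

    def _announce(self, token: str, query: str, environ, secure: bool):
        params = _parse_raw_query(query)
        try:
            req = AnnounceRequest(
                token=token,
                info_hash=params.get(b"info_hash", b""),
                peer_id=params.get(b"peer_id", b""),
                port=int(params.get(b"port", b"0")),
                uploaded=int(params.get(b"uploaded", b"0")),
                downloaded=int(params.get(b"downloaded", b"0")),
                left=int(params.get(b"left", b"0")),
                event=params.get(b"event", b"").decode("ascii", "replace"),
                compact=int(params.get(b"compact", b"1")),
                address=environ.get("REMOTE_ADDR", "127.0.0.1"),
                secure_channel=secure,
            )
        except ValueError:
            return ("200 OK", [("Content-Type", "text/plain")],
                    TrackerFailure("bad request: malformed parameter")
                    .to_bencoded())
        result = self.tracker.handle_announce(req)
        if isinstance(result, TrackerFailure):
            self._log_decision("announce", token, "announce", False,
                               result.reason)
            status = "401 Unauthorized" if result.http_status == 401 else "200 OK"
            return (status, [("Content-Type", "text/plain")],
                    result.to_bencoded())
        self._log_decision("announce", token, "announce", True, "ok")
        return ("200 OK", [("Content-Type", "text/plain")],
                result.to_bencoded())

    def _scrape(self, token: str, query: str, secure: bool):
        hashes = _parse_raw_query_multi(query).get(b"info_hash", [])
        stats = self.tracker.handle_scrape(token, hashes,
                                           secure_channel=secure)
        files = {}
        for ih, entry in stats.items():
            if "error" in entry:
                continue
            files[ih] = {
                b"complete": entry["complete"],
                b"incomplete": entry["incomplete"],
                b"downloaded": entry["downloaded"],
            }
        from . import bencode
        return ("200 OK", [("Content-Type", "text/plain")],
                bencode.encode({b"files": files}))

    def _admin(self, token: str, verb: str, environ, secure: bool):
        doc = _read_json(environ)
        decision = self.store.authorize(token, None, Action.MANAGE_USERS,
                                        secure_channel=secure)
        self._log_decision("portal", token, f"admin/{verb}", decision.allowed,
                           decision.reason)
        if not decision:
            return _json_response(403, {"error": decision.reason})
        admin = self.store.user_for_token(token)
        if verb == "approve":
            user = self.store.approve_user(admin, doc["email"])
            return _json_response(200, {"email": user.email,
                                        "approved": user.approved})
        if verb == "grant":
            role = Role(doc.get("role", "subscriber"))
            self.store.grant_role(admin, doc["email"],
                                  int(doc["feed_id"]), role)
            return _json_response(200, {"email": doc["email"],
                                        "role": role.value})
        if verb == "rotate":
            new_token = self.store.rotate_token(doc["email"])
            return _json_response(200, {"email": doc["email"],
                                        "token": new_token})
        return _json_response(404, {"error": f"unknown admin verb {verb}"})


# ---------------------------------------------------------------------------
# WSGI plumbing helpers
# ---------------------------------------------------------------------------

def _json_response(code: int, doc: dict):
    body = json.dumps(doc).encode("utf-8")
    reasons = {200: "OK", 201: "Created", 400: "Bad Request", 403: "Forbidden",
               404: "Not Found", 409: "Conflict"}
    status = f"{code} {reasons.get(code, 'Error')}"
    return (status, [("Content-Type", "application/json")], body)


def _read_body(environ) -> bytes:
    try:
        length = int(environ.get("CONTENT_LENGTH") or 0)
    except ValueError:
        length = 0
    return environ["wsgi.input"].read(length) if length else b""


def _read_json(environ) -> dict:
    body = _read_body(environ)
    if not body:
        return {}
    return json.loads(body.decode("utf-8"))


def _parse_raw_query(query: str) -> dict[bytes, bytes]:
    """Query parsing that preserves binary values (info_hash, peer_id are
    raw 20-byte strings, percent-escaped; stdlib parse_qsl would mangle
    them through text decoding)."""
    out: dict[bytes, bytes] = {}
    for key, values in _parse_raw_query_multi(query).items():
        out[key] = values[-1]
    return out


def _parse_raw_query_multi(query: str) -> dict[bytes, list[bytes]]:
    out: dict[bytes, list[bytes]] = {}
    for pair in query.split("&"):
        if not pair:
            continue
        key, _, value = pair.partition("=")
        k = urllib.parse.unquote_to_bytes(key)
        v = urllib.parse.unquote_to_bytes(value)
        out.setdefault(k, []).append(v)
    return out


class _QuietHandler(wsgiref.simple_server.WSGIRequestHandler):
    def log_message(self, *args):  # request lines go to the JSON log instead
        pass


def serve(config: PortalConfig):  # pragma: no cover - exercised via CLI test
    """Run the portal under wsgiref until interrupted."""
    portal = Portal(config)
    with wsgiref.simple_server.make_server(
            config.host, config.port, portal,
            handler_class=_QuietHandler) as httpd:
        log.info(json.dumps({"stage": "portal", "action": "serve",
                             "host": config.host, "port": config.port}))
        httpd.serve_forever()
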