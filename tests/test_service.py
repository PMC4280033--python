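"""End-to-end portal service (WSGI) and command-line interface."""

import json
import threading
import urllib.parse
import urllib.request
import wsgiref.simple_server
import xml.etree.ElementTree as ET

import pytest
import yaml
from click.testing import CliRunner

from seedportal import bencode, metainfo as mi
from seedportal.cli import main as cli_main
from seedportal.service import Portal, PortalConfig

PIECE = mi.MIN_PIECE_LENGTH


def call(app, method, path, body=b"", query="", scheme="http",
         remote="127.0.0.1"):
    """Drive the WSGI callable directly; returns (status_code, body)."""
    import io

    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "QUERY_STRING": query,
        "CONTENT_LENGTH": str(len(body)),
        "REMOTE_ADDR": remote,
        "wsgi.input": io.BytesIO(body),
        "wsgi.url_scheme": scheme,
    }
    captured = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    out = b"".join(app(environ, start_response))
    return captured["status"], out


def call_json(app, method, path, doc=None, **kw):
    body = json.dumps(doc).encode() if doc is not None else b""
    status, out = call(app, method, path, body, **kw)
    return status, json.loads(out) if out else {}


@pytest.fixture
def portal():
    return Portal(PortalConfig(admin_email="root@portal",
                               admin_password="bootpw",
                               base_url="http://portal.test"))


@pytest.fixture
def populated(portal, payload_file):
    """Portal with approved publisher+subscriber, one feed, one torrent."""
    app = portal
    admin = portal.store.issue_token("root@portal")
    for email in ("alice@lab", "bob@lab"):
        status, _ = call_json(app, "POST", "/register",
                              {"email": email, "password": "pw"})
        assert status == 201
        status, _ = call_json(app, "POST", f"/{admin}/admin/approve",
                              {"email": email})
        assert status == 200
    status, feed = call_json(app, "POST", f"/{admin}/feeds",
                             {"name": "genomes"})
    assert status == 201
    for email, role in (("alice@lab", "publisher"), ("bob@lab", "subscriber")):
        status, _ = call_json(app, "POST", f"/{admin}/admin/grant",
                              {"email": email, "feed_id": feed["id"],
                               "role": role})
        assert status == 200
    tokens = {}
    for email in ("alice@lab", "bob@lab"):
        _, doc = call_json(app, "POST", f"/{admin}/admin/rotate",
                           {"email": email})
        tokens[email] = doc["token"]
    path = payload_file(3 * PIECE, seed=77)
    torrent = mi.create_torrent(path, PIECE, "http://portal.test/t")
    status, published = call_json(
        app, "POST", f"/{tokens['alice@lab']}/feeds/{feed['id']}/torrents")
    # empty body is a bad request; now send the real bytes
    assert status == 400
    status, published = call(
        app, "POST", f"/{tokens['alice@lab']}/feeds/{feed['id']}/torrents",
        body=torrent.to_bytes())
    assert status == 201
    info_hash = json.loads(published)["info_hash"]
    return {"app": app, "admin": admin, "tokens": tokens,
            "feed_id": feed["id"], "info_hash": info_hash}


def test_health_endpoint(portal):
    status, doc = call_json(portal, "GET", "/health")
    assert status == 200 and doc == {"status": "ok"}


def test_register_conflict_and_pending_denial(portal):
    call_json(portal, "POST", "/register",
              {"email": "x@lab", "password": "pw"})
    status, doc = call_json(portal, "POST", "/register",
                            {"email": "x@lab", "password": "pw"})
    assert status == 409
    # pending user's token is useless at every endpoint
    token = portal.store.issue_token("x@lab")
    status, _ = call(portal, "GET", f"/{token}/feeds/1.rss")
    assert status == 403


def test_full_subscription_cycle(populated):
    """RSS fetch -> tokenized torrent download -> announce -> dashboard."""
    app = populated["app"]
    bob = populated["tokens"]["bob@lab"]
    feed_id = populated["feed_id"]

    status, rss = call(app, "GET", f"/{bob}/feeds/{feed_id}.rss")
    assert status == 200
    items = ET.fromstring(rss).find("channel").findall("item")
    assert len(items) == 1
    url = items[0].find("enclosure").get("url")
    assert bob in url

    # follow the enclosure URL path on the same app
    path = urllib.parse.urlsplit(url).path
    status, torrent_bytes = call(app, "GET", path)
    assert status == 200
    downloaded = mi.Metainfo.from_bytes(torrent_bytes)
    assert downloaded.is_private
    assert f"/{bob}/announce" in downloaded.announce
    ih = downloaded.info_hash()
    assert ih.hex == populated["info_hash"]

    # announce through the HTTP surface with percent-encoded binary params
    query = (f"info_hash={ih.urlencoded}"
             f"&peer_id={urllib.parse.quote_from_bytes(b'B' * 20)}"
             f"&port=6881&uploaded=0&downloaded=0&left=0&event=started")
    status, body = call(app, "GET", f"/{bob}/announce", query=query)
    assert status == 200
    resp = bencode.decode(body)
    assert resp[b"interval"] > 0
    assert resp[b"complete"] == 1 and resp[b"incomplete"] == 0

    status, body = call(app, "GET", f"/{bob}/scrape",
                        query=f"info_hash={ih.urlencoded}")
    files = bencode.decode(body)[b"files"]
    assert files[ih.digest][b"complete"] == 1

    status, doc = call_json(app, "GET", f"/{bob}/feeds/{feed_id}/status")
    assert status == 200
    assert [p["completion_percent"] for p in doc["peers"]] == [100.0]


def test_announce_rejections_over_http(populated):
    app = populated["app"]
    bob = populated["tokens"]["bob@lab"]
    ih_hex = populated["info_hash"]
    ih = bytes.fromhex(ih_hex)
    good_query = (f"info_hash={urllib.parse.quote_from_bytes(ih)}"
                  f"&peer_id={urllib.parse.quote_from_bytes(b'Z' * 20)}"
                  "&port=6881&left=0")
    # bad token: bencoded failure with HTTP auth status
    status, body = call(app, "GET", "/wrong-token/announce", query=good_query)
    assert status == 401
    assert bencode.decode(body)[b"failure reason"] == b"unauthorized"
    # unregistered hash: conventional 200 + failure reason
    foreign = urllib.parse.quote_from_bytes(b"\x09" * 20)
    status, body = call(app, "GET", f"/{bob}/announce",
                        query=good_query.replace(
                            urllib.parse.quote_from_bytes(ih), foreign))
    assert status == 200
    assert b"unregistered" in bencode.decode(body)[b"failure reason"]


def test_https_requirement_blocks_plain_http(payload_file):
    portal = Portal(PortalConfig(admin_email="root@portal",
                                 admin_password="pw", require_https=True))
    token = portal.store.issue_token("root@portal")
    feed = portal.store.create_feed(portal.store.get_user("root@portal"), "f")
    status, _ = call(portal, "GET", f"/{token}/feeds/{feed.id}.rss",
                     scheme="http")
    assert status == 403
    status, _ = call(portal, "GET", f"/{token}/feeds/{feed.id}.rss",
                     scheme="https")
    assert status == 200


def test_served_over_real_http(populated):
    """Smoke the same app through an actual socket server."""
    app = populated["app"]
    server = wsgiref.simple_server.make_server("127.0.0.1", 0, app)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        port = server.server_address[1]
        with urllib.request.urlopen(
                f"http://127.0.0.1:{port}/health", timeout=10) as resp:
            assert json.load(resp) == {"status": "ok"}
    finally:
        server.shutdown()
        thread.join(timeout=10)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_create_verify_round_trip(tmp_path, payload_file):
    runner = CliRunner()
    payload = payload_file(2 * PIECE + 100)
    out = tmp_path / "x.torrent"
    result = runner.invoke(cli_main, [
        "create-torrent", str(payload), "-o", str(out),
        "--piece-size", str(PIECE)])
    assert result.exit_code == 0, result.output
    meta = json.loads(result.output)
    assert meta["piece_count"] == 3
    result = runner.invoke(cli_main, ["verify", str(out), str(payload)])
    assert result.exit_code == 0
    assert json.loads(result.output)["completion_percent"] == 100.0


def test_cli_failure_paths_exit_nonzero(tmp_path):
    runner = CliRunner()
    result = runner.invoke(cli_main, [
        "create-torrent", str(tmp_path / "missing.bin"),
        "-o", str(tmp_path / "x.torrent")])
    assert result.exit_code != 0
    assert "error:" in result.output + (result.stderr or "")


def test_cli_default_piece_size_applied(tmp_path):
    runner = CliRunner()
    payload = tmp_path / "big.bin"
    payload.write_bytes(b"\x5a" * (5 * 1024 * 1024))
    out = tmp_path / "big.torrent"
    result = runner.invoke(cli_main,
                           ["create-torrent", str(payload), "-o", str(out)])
    assert result.exit_code == 0
    assert json.loads(result.output)["piece_length"] == mi.DEFAULT_PIECE_LENGTH


def test_cli_simulate_deterministic(tmp_path):
    scenario = {
        "piece_count": 12,
        "nodes": [
            {"id": "pub", "role": "publisher", "upload_capacity": 2},
            {"id": "s1"}, {"id": "s2"},
        ],
        "churn": [{"tick": 3, "node_id": "s1", "online": False},
                  {"tick": 6, "node_id": "s1", "online": True}],
        "tick_limit": 100,
        "seed": 9,
    }
    spath = tmp_path / "scenario.yaml"
    spath.write_text(yaml.safe_dump(scenario))
    runner = CliRunner()
    traces = []
    for name in ("t1.jsonl", "t2.jsonl"):
        result = runner.invoke(cli_main, ["simulate", str(spath),
                                          "--out", str(tmp_path / name)])
        assert result.exit_code == 0, result.output
        summary = json.loads(result.output)
        assert summary["converged"] and summary["initially_recoverable"]
        traces.append((tmp_path / name).read_bytes())
    assert traces[0] == traces[1]  # same seed, byte-identical trace


def test_cli_simulate_flags_unrecoverable(tmp_path):
    scenario = {
        "piece_count": 4,
        "nodes": [{"id": "a", "role": "subscriber"},
                  {"id": "b", "role": "subscriber"}],
        "tick_limit": 10,
    }
    spath = tmp_path / "bad.yaml"
    spath.write_text(yaml.safe_dump(scenario))
    result = CliRunner().invoke(cli_main, ["simulate", str(spath)])
    assert result.exit_code == 0
    summary = json.loads(result.output)
    assert not summary["initially_recoverable"]
    assert not summary["converged"]


def test_cli_admin_workflow(tmp_path):
    db = str(tmp_path / "portal.db")
    runner = CliRunner()
    boot = runner.invoke(cli_main, ["admin", "--db", db, "bootstrap",
                                    "root@portal", "pw"])
    assert boot.exit_code == 0
    from seedportal.authz import PortalStore, Role

    store = PortalStore(db)
    store.register_user("carol@lab", "pw")
    store.close()

    approve = runner.invoke(cli_main,
                            ["admin", "--db", db, "approve", "carol@lab"])
    assert approve.exit_code == 0
    assert json.loads(approve.output)["approved"] is True

    feed = runner.invoke(cli_main,
                         ["admin", "--db", db, "create-feed", "genomes"])
    feed_id = json.loads(feed.output)["id"]
    grant = runner.invoke(cli_main, ["admin", "--db", db, "grant",
                                     "carol@lab", str(feed_id), "subscriber"])
    assert grant.exit_code == 0

    rotate = runner.invoke(cli_main,
                           ["admin", "--db", db, "rotate", "carol@lab"])
    token = json.loads(rotate.output)["token"]
    store = PortalStore(db)
    assert store.user_for_token(token).email == "carol@lab"
    assert store.role_of(store.get_user("carol@lab"), feed_id) is Role.SUBSCRIBER
    # rotating again invalidates the old token
    rotate2 = runner.invoke(cli_main,
                            ["admin", "--db", db, "rotate", "carol@lab"])
    assert json.loads(rotate2.output)["token"] != token
    store2 = PortalStore(db)
    assert store2.user_for_token(token) is None
    store.close(); store2.close()

    missing = runner.invoke(cli_main,
                            ["admin", "--db", db, "approve", "ghost@lab"])
    assert missing.exit_code != 0
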